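"""End-to-end voxel-wise reflectivity analysis.

Builds a test scan whose sample tube is 20% brighter than the control
scan's (emulating contrast-agent uptake), misaligns it, and runs the full
chain: tube detection -> water normalization -> distance maps -> affine +
B-spline registration -> resampling -> voxel-wise reflectivity and color
map.
"""

from voxreflect import PipelineConfig, run_pipeline
from voxreflect.benchmarks import pipeline_pair

test_scan, control_scan = pipeline_pair(seed=101)  # truth: R = 20%
result, report = run_pipeline(test_scan, control_scan, PipelineConfig())

print(f"global reflectivity R = {result.global_percent:.2f}% "
      f"over {result.n_voxels} tube voxels (ground truth 20%)")
print(f"water means: test {report['test_water_mean']:.2f}, "
      f"control {report['control_water_mean']:.2f} (scans rescaled to a common unit)")
print(f"elastic stage max displacement {report['elastic_max_displacement_mm']:.2f} mm")
rgba = result.provenance["color_map"]
print(f"color map rendered: {rgba.shape[:3]} voxels, "
      f"diverging scale over {report['color_range_percent']}%")

ablation, _ = run_pipeline(test_scan, control_scan, PipelineConfig(registration=False, render=False))
print(f"without registration the same pair reads R = {ablation.global_percent:.2f}% "
      "- the misalignment destroys the measurement")
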