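"""Xylenol-orange gadolinium quantification.

Free Gd(III) shifts the xylenol orange absorption bands; the A573/A433
ratio is converted to concentration through a calibration line.  Two
inversion conventions are provided because the bundled published
coefficient pair is not the exact algebraic inverse of its own line.
"""

from voxreflect import GdCalibration, gd_from_ratio, invert_calibration

A, B = invert_calibration(0.3244, -1.0944)
print(f"inverting the line Y = 0.3244 X - 1.0944: A = 1/slope = {A:.4f}, "
      f"B = -intercept/slope = {B:.4f}")

printed = GdCalibration.published_default()                  # verbatim A, B
consistent = GdCalibration.from_line(0.3244, -1.0944)        # exact inverse

for ratio in (0.0, 0.5, 1.0):
    a = gd_from_ratio(ratio, printed)["concentration"]
    b = gd_from_ratio(ratio, consistent)["concentration"]
    print(f"ratio {ratio:.1f} -> as-printed {a:7.4f}, inverse-consistent {b:7.4f}")
print("the two conventions disagree everywhere because the published pair "
      "(A, B) is not the algebraic inverse of the line; constructing it "
      "emits a warning rather than silently picking one")
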