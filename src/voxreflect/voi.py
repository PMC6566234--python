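"""Background removal, 3D region growing and tube VOI extraction.

The analysis chain starts by separating signal-bearing voxels from air with
a global Otsu threshold (the value maximizing between-class variance over a
256-bin histogram), then isolating each sample tube as a 26-connected
component and cropping a padded Volume of Interest around it with the tube
centered in the crop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volio import Volume3D

__all__ = [
    "TubeVOI",
    "remove_background",
    "grow_region_3d",
    "detect_tubes",
    "extract_voi",
    "assign_roles",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TubeVOI:
    """A labeled voxel mask for one tube, with bounding box and centroid."""

    mask: np.ndarray
    role: str = "unknown"
    bbox: tuple[tuple[int, int], ...] = None
    centroid_mm: np.ndarray = None
    voxel_count: int = 0

    @classmethod
    def from_mask(cls, mask: np.ndarray, volume: Volume3D, role: str = "unknown") -> "TubeVOI":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != volume.shape:
            raise ValueError("mask shape must match its parent volume")
        idx = np.nonzero(mask)
        if idx[0].size == 0:
            raise ValueError("tube mask is empty")
        bbox = tuple((int(a.min()), int(a.max())) for a in idx)
        centroid_idx = np.array([a.mean() for a in idx])
        centroid_mm = volume.index_to_physical(centroid_idx)
        return cls(mask, role, bbox, centroid_mm, int(idx[0].size))


def remove_background(volume: Volume3D) -> np.ndarray:
    """Foreground mask via Otsu's between-class-variance threshold.

    Raises on (near-)constant volumes, where no threshold separates two
    classes.
    """
    vals = volume.values[volume.valid_mask()]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ValueError("volume has a single intensity value; no threshold exists")
    thr = threshold_otsu(vals, nbins=256)
    mask = volume.values > thr
    if volume.valid is not None:
        mask &= volume.valid
    return mask


def grow_region_3d(volume: Volume3D, seed, low: float, high: float) -> np.ndarray:
    """26-connected region growing from a seed voxel within [low, high]."""
    seed = tuple(int(s) for s in seed)
    if any(s < 0 or s >= n for s, n in zip(seed, volume.shape)):
        raise ValueError(f"seed {seed} outside the grid {volume.shape}")
    sv = float(volume.values[seed])
    if not (low <= sv <= high):
        raise ValueError(f"seed value {sv} outside the inclusion band [{low}, {high}]")
    band = (volume.values >= low) & (volume.values <= high)
    labels, _ = ndimage.label(band, structure=_STRUCT_26)
    return labels == labels[seed]


def assign_roles(vois: list[TubeVOI], volume: Volume3D, roles) -> list[TubeVOI]:
    """Assign tube roles, either from an ordering rule or from seed points.

    ``roles`` may be a list of role names applied to the VOIs in their sorted
    (left-to-right) order, or a mapping ``{role: voxel_index}`` naming a seed
    voxel inside each tube of interest.
    """
    if isinstance(roles, dict):
        for role, seed in roles.items():
            seed = tuple(int(s) for s in seed)
            hits = [v for v in vois if v.mask[seed]]
            if not hits:
                raise ValueError(f"seed {seed} for role {role!r} is not inside any detected tube")
            hits[0].role = role
    else:
        if len(roles) != len(vois):
            raise ValueError(f"got {len(roles)} roles for {len(vois)} tubes")
        for voi, role in zip(vois, roles):
            voi.role = role
    return vois


def detect_tubes(
    volume: Volume3D,
    min_voxels: int = 50,
    max_voxels: int | None = None,
    roles=None,
) -> list[TubeVOI]:
    """Detect sample tubes as 26-connected foreground components.

    Components with voxel count in [min_voxels, max_voxels] are returned as
    TubeVOIs sorted by centroid position (lexicographic in physical x, y, z).
    """
    fg = remove_background(volume)
    labels, n = ndimage.label(fg, structure=_STRUCT_26)
    vois = []
    for lab in range(1, n + 1):
        m = labels == lab
        count = int(m.sum())
        if count < min_voxels or (max_voxels is not None and count > max_voxels):
            continue
        vois.append(TubeVOI.from_mask(m, volume))
    if not vois:
        raise ValueError(
            "no tube-sized foreground components found; review the background "
            "threshold and the [min_voxels, max_voxels] size window"
        )
    vois.sort(key=lambda v: tuple(np.round(v.centroid_mm, 6)))
    if roles is not None:
        assign_roles(vois, volume, roles)
    return vois


def extract_voi(volume: Volume3D, tube: TubeVOI, pad_voxels: int = 4):
    """Crop a padded subvolume centered on the tube.

    The crop spans the tube bounding box extended by ``pad_voxels`` per side
    (clipped at the image border; clipping is recorded in the returned
    volume's metadata).  For a symmetric tube the rounded centroid lands on
    the crop's central voxel.  The origin is updated so every voxel keeps its
    physical coordinate.  Returns ``(subvolume, submask)``.
    """
    if tube.voxel_count == 0:
        raise ValueError("tube mask is empty")
    lo = np.array([b[0] for b in tube.bbox]) - pad_voxels
    hi = np.array([b[1] for b in tube.bbox]) + pad_voxels
    shape = np.array(volume.shape)
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, shape - 1)
    clipped = bool(np.any(lo_c != lo) or np.any(hi_c != hi))
    sl = tuple(slice(a, b + 1) for a, b in zip(lo_c, hi_c))
    sub = Volume3D(
        volume.values[sl].copy(),
        volume.spacing.copy(),
        volume.index_to_physical(lo_c),
        volume.direction.copy(),
        dict(volume.meta),
        None if volume.valid is None else volume.valid[sl].copy(),
    )
    sub.meta["voi_offset_voxels"] = lo_c.tolist()
    sub.meta["voi_clipped"] = clipped
    return sub, tube.mask[sl].copy()
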