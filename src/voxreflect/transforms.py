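"""Spatial transforms: 12-DOF affine, cubic B-spline free-form deformation,
and volume resampling.

All transforms act on physical (mm) coordinates.  An affine transform maps

    y = M @ (x - c) + c + t

with a fixed rotation center ``c`` (typically the reference-tube centroid).
A B-spline field adds a displacement parameterized by a uniform grid of
3-vector control coefficients; the displacement at a point is the
tensor-product cubic B-spline sum of the 4x4x4 surrounding controls, so zero
coefficients give the identity everywhere.  The composite deformation used
throughout the package is ``T(x) = A(x) + u(x)`` (elastic field composed
after the global affine).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates

from .volio import Volume3D

__all__ = [
    "AffineTransform12",
    "BSplineField",
    "sample_volume",
    "resample",
    "save_transform",
    "load_transform",
]


@dataclass
class AffineTransform12:
    """Affine transform with 12 free parameters (3x3 matrix + translation)."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix must be invertible")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform12":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, dtype=float))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "AffineTransform12":
        Minv = np.linalg.inv(self.matrix)
        return AffineTransform12(Minv, -Minv @ self.translation, self.center)

    def to_homogeneous(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.matrix
        H[:3, 3] = self.center + self.translation - self.matrix @ self.center
        return H

    @classmethod
    def from_homogeneous(cls, H, center=(0.0, 0.0, 0.0)) -> "AffineTransform12":
        H = np.asarray(H, dtype=float)
        c = np.asarray(center, dtype=float)
        M = H[:3, :3]
        t = H[:3, 3] - c + M @ c
        return cls(M, t, c)

    def compose(self, other: "AffineTransform12") -> "AffineTransform12":
        """Return self∘other (apply ``other`` first), centered at self.center."""
        return AffineTransform12.from_homogeneous(
            self.to_homogeneous() @ other.to_homogeneous(), self.center
        )


def _bspline_basis(u: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values b0..b3 for fractional offsets u."""
    u = np.asarray(u, dtype=float)
    u2, u3 = u * u, u * u * u
    return np.stack(
        [
            (1 - u) ** 3 / 6.0,
            (3 * u3 - 6 * u2 + 4) / 6.0,
            (-3 * u3 + 3 * u2 + 3 * u + 1) / 6.0,
            u3 / 6.0,
        ],
        axis=0,
    )


@dataclass
class BSplineField:
    """Cubic B-spline displacement field on a uniform control grid.

    ``coefficients`` has shape (n0, n1, n2, 3) and holds a 3-vector mm
    displacement per control point.  Points outside the grid's cubic support
    get zero displacement (identity beyond the modeled region).
    """

    origin: np.ndarray  # mm position of control point (0,0,0)
    spacing: np.ndarray  # mm between control points
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("control spacing must be positive")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[3] != 3:
            raise ValueError("coefficients must have shape (n0, n1, n2, 3)")
        if min(self.coefficients.shape[:3]) < 4:
            raise ValueError("need at least 4 control points per axis")

    @classmethod
    def for_domain(
        cls, dom_min, dom_max, control_spacing_mm
    ) -> "BSplineField":
        """Zero field whose cubic support covers [dom_min, dom_max]."""
        dom_min = np.asarray(dom_min, dtype=float)
        dom_max = np.asarray(dom_max, dtype=float)
        spacing = np.broadcast_to(np.asarray(control_spacing_mm, dtype=float), (3,)).copy()
        # interior span needs controls at floor(t)-1 .. floor(t)+2
        n = np.ceil((dom_max - dom_min) / spacing).astype(int) + 4
        origin = dom_min - spacing * 1.5
        return cls(origin, spacing, np.zeros((*n, 3)))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]

    def _support(self, pts: np.ndarray):
        t = (np.asarray(pts, dtype=float) - self.origin) / self.spacing
        i = np.floor(t).astype(int)
        u = t - i
        n = np.array(self.grid_shape)
        inside = np.all((i - 1 >= 0) & (i + 2 <= n - 1), axis=-1)
        return i, u, inside

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        """Displacement (mm) at physical points, shape (N, 3)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        i, u, inside = self._support(pts)
        out = np.zeros_like(pts)
        if not inside.any():
            return out
        ii, uu = i[inside], u[inside]
        w = [_bspline_basis(uu[:, a]) for a in range(3)]  # each (4, m)
        acc = np.zeros((inside.sum(), 3))
        for a in range(4):
            for b in range(4):
                wab = w[0][a] * w[1][b]
                for c in range(4):
                    wt = wab * w[2][c]
                    acc += wt[:, None] * self.coefficients[
                        ii[:, 0] + a - 1, ii[:, 1] + b - 1, ii[:, 2] + c - 1
                    ]
        out[inside] = acc
        return out

    def weights_matrix(self, pts: np.ndarray) -> sparse.csr_matrix:
        """Sparse (N x n_controls) matrix W with displacement = W @ C.

        C is the flattened (n_controls, 3) coefficient array; each point row
        holds the 64 tensor-product basis weights of its support.  Points
        outside the support get an all-zero row.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        i, u, inside = self._support(pts)
        n = self.grid_shape
        rows, cols, vals = [], [], []
        idx_pts = np.nonzero(inside)[0]
        if idx_pts.size:
            ii, uu = i[inside], u[inside]
            w = [_bspline_basis(uu[:, a]) for a in range(3)]
            for a in range(4):
                for b in range(4):
                    for c in range(4):
                        wt = w[0][a] * w[1][b] * w[2][c]
                        flat = (
                            (ii[:, 0] + a - 1) * n[1] + (ii[:, 1] + b - 1)
                        ) * n[2] + (ii[:, 2] + c - 1)
                        rows.append(idx_pts)
                        cols.append(flat)
                        vals.append(wt)
        ncontrols = n[0] * n[1] * n[2]
        if rows:
            W = sparse.csr_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(pts.shape[0], ncontrols),
            )
        else:
            W = sparse.csr_matrix((pts.shape[0], ncontrols))
        return W

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.coefficients, axis=-1).max()) if self.coefficients.size else 0.0

    def refine(self) -> "BSplineField":
        """Halve the control spacing by exact dyadic B-spline subdivision.

        Uses the uniform cubic subdivision masks (c'_{2i} = (c_{i-1} + 6 c_i
        + c_{i+1})/8, c'_{2i+1} = (c_i + c_{i+1})/2), applied per axis, so the
        refined grid reproduces the same displacement field away from the
        outermost control points (which are zero-padded).
        """

        def subdivide(arr: np.ndarray, axis: int) -> np.ndarray:
            arr = np.moveaxis(arr, axis, 0)
            n = arr.shape[0]
            padded = np.concatenate(
                [np.zeros_like(arr[:1]), arr, np.zeros_like(arr[:1])], axis=0
            )
            even = (padded[:-2] + 6 * padded[1:-1] + padded[2:]) / 8.0  # n entries
            odd = (padded[1:-1][:-1] + padded[1:-1][1:]) / 2.0  # n-1 entries
            out = np.empty((2 * n - 1, *arr.shape[1:]))
            out[0::2] = even
            out[1::2] = odd
            return np.moveaxis(out, 0, axis)

        coeff = self.coefficients
        for ax in range(3):
            coeff = subdivide(coeff, ax)
        return BSplineField(self.origin.copy(), self.spacing / 2.0, coeff)


# --------------------------------------------------------------------------
# Sampling and resampling
# --------------------------------------------------------------------------


def sample_volume(volume: Volume3D, pts: np.ndarray, order: int = 1):
    """Sample a volume at physical points with nearest/linear interpolation.

    Returns ``(values, valid)``: NaN and ``valid=False`` where a point falls
    outside the grid (or lands on voxels flagged invalid / non-finite).
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    idx = volume.physical_to_index(pts)
    n = np.array(volume.shape)
    if order == 0:
        valid = np.all((idx >= -0.5) & (idx <= n - 0.5), axis=-1)
    else:
        valid = np.all((idx >= 0.0) & (idx <= n - 1.0), axis=-1)
    vals = np.full(pts.shape[0], np.nan)
    if valid.any():
        coords = idx[valid].T
        v = map_coordinates(volume.values, coords, order=order, mode="nearest")
        if volume.valid is not None:
            ok = map_coordinates(
                (~volume.valid).astype(float), coords, order=min(order, 1), mode="constant", cval=1.0
            ) == 0.0
            v = np.where(ok, v, np.nan)
        vals[valid] = v
        valid = valid & np.isfinite(vals)
    return vals, valid


def _total_map(pts, affine: AffineTransform12 | None, warp: BSplineField | None):
    mapped = affine.apply(pts) if affine is not None else np.asarray(pts, dtype=float)
    if warp is not None:
        mapped = mapped + warp.displacement(pts)
    return mapped


def resample(
    volume: Volume3D,
    affine: AffineTransform12 | None = None,
    warp: BSplineField | None = None,
    reference: Volume3D | None = None,
    interpolation: str = "linear",
) -> Volume3D:
    """Resample ``volume`` through a transform onto the reference grid.

    Each output voxel takes the interpolated input value at its mapped
    physical location ``T(x) = A(x) + u(x)``; voxels that map outside the
    input domain are flagged invalid (never zero-filled).
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 0 if interpolation == "nearest" else 1
    ref = reference if reference is not None else volume
    pts = ref.grid_points().reshape(-1, 3)
    mapped = _total_map(pts, affine, warp)
    vals, valid = sample_volume(volume, mapped, order=order)
    out = Volume3D(
        vals.reshape(ref.shape),
        ref.spacing.copy(),
        ref.origin.copy(),
        ref.direction.copy(),
        dict(volume.meta),
        valid.reshape(ref.shape),
    )
    return out


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def save_transform(
    path: str | Path,
    affine: AffineTransform12 | None = None,
    warp: BSplineField | None = None,
) -> None:
    doc: dict = {}
    if affine is not None:
        doc["affine"] = {
            "matrix": affine.matrix.tolist(),
            "translation_mm": affine.translation.tolist(),
            "center_mm": affine.center.tolist(),
        }
    if warp is not None:
        doc["bspline"] = {
            "origin_mm": warp.origin.tolist(),
            "control_spacing_mm": warp.spacing.tolist(),
            "grid_shape": list(warp.grid_shape),
            "coefficients": warp.coefficients.reshape(-1, 3).tolist(),
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_transform(path: str | Path):
    doc = json.loads(Path(path).read_text())
    affine = warp = None
    if "affine" in doc:
        a = doc["affine"]
        affine = AffineTransform12(
            np.array(a["matrix"]), np.array(a["translation_mm"]), np.array(a["center_mm"])
        )
    if "bspline" in doc:
        b = doc["bspline"]
        coeff = np.array(b["coefficients"]).reshape(*b["grid_shape"], 3)
        warp = BSplineField(np.array(b["origin_mm"]), np.array(b["control_spacing_mm"]), coeff)
    return affine, warp
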