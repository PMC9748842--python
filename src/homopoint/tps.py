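"""Thin-plate-spline transform resolver.

A TPS maps the plane through an affine part plus radial-basis terms with the
kernel ``U(r) = r^2 log r`` (``U(0) = 0``), interpolating paired control
points while minimizing integral bending energy.  Fitting solves the bordered
linear system

    [K + lam*I  P] [w]   [t]
    [P^T        0] [a] = [0]

where ``K_ij = U(|s_i - s_j|)``, ``P = [1 | y | x]``, one right-hand side per
output axis.  ``lam = 0`` gives exact interpolation; ``lam > 0`` trades
interpolation error for smoothness (useful when the targets are noisy network
predictions).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .core import Image2D, PointSet

__all__ = ["ThinPlateSplineTransform", "fit_tps", "transform_points", "warp_image", "tps_backward_map"]


def _U(r: np.ndarray) -> np.ndarray:
    """TPS kernel r^2 log r with the removable singularity U(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


@dataclasses.dataclass
class ThinPlateSplineTransform:
    source_points: np.ndarray  # (k, 2), in the (possibly rescaled) fit frame
    affine: np.ndarray  # (3, 2): rows = const, y, x; columns = (y', x')
    weights: np.ndarray  # (k, 2) radial coefficients
    regularization: float = 0.0
    coord_scale: float = 1.0  # pixels per fit-frame unit (1 = fit in pixels)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64)) / self.coord_scale
        ones = np.ones((len(pts), 1))
        design = np.hstack([ones, pts])
        rad = _U(cdist(pts, self.source_points))
        return (design @ self.affine + rad @ self.weights) * self.coord_scale

    @property
    def source_points_px(self) -> np.ndarray:
        """Source control points in pixel coordinates."""
        return self.source_points * self.coord_scale

    def bending_energy(self) -> float:
        """Non-negative; zero iff the fitted map is purely affine."""
        K = _U(cdist(self.source_points, self.source_points))
        return float(np.trace(self.weights.T @ K @ self.weights))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source_points": self.source_points.tolist(),
            "affine": self.affine.tolist(),
            "weights": self.weights.tolist(),
            "regularization": self.regularization,
            "coord_scale": self.coord_scale,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThinPlateSplineTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["source_points"], dtype=np.float64),
            np.asarray(d["affine"], dtype=np.float64),
            np.asarray(d["weights"], dtype=np.float64),
            float(d["regularization"]),
            float(d.get("coord_scale", 1.0)),
        )


def _as_coords(points: PointSet | np.ndarray) -> np.ndarray:
    if isinstance(points, PointSet):
        return points.valid_coords()
    return np.atleast_2d(np.asarray(points, dtype=np.float64))


def fit_tps(
    source: PointSet | np.ndarray,
    target: PointSet | np.ndarray,
    regularization: float = 0.0,
    coord_scale: float = 1.0,
) -> ThinPlateSplineTransform:
    """Fit a TPS mapping source points onto target points.

    Only valid rows of ``PointSet`` inputs participate.  Requires at least
    three non-collinear source points; with ``regularization = 0`` duplicate
    or collinear sources make the system singular and raise.  Fitting is in
    pixel units by default; ``coord_scale`` (e.g. the image size) rescales
    coordinates to [0, 1]-order units before solving, which conditions the
    system differently.
    """
    src = _as_coords(source) / coord_scale
    dst = _as_coords(target) / coord_scale
    if src.shape != dst.shape:
        raise ValueError(f"source/target point counts differ: {src.shape} vs {dst.shape}")
    k = len(src)
    if k < 3:
        raise ValueError("TPS requires at least 3 point pairs")
    lam = float(regularization)
    if lam < 0:
        raise ValueError("regularization must be >= 0")
    if lam == 0.0:
        err = _check_general_position(src)
        if err is not None:
            raise err
    K = _U(cdist(src, src)) + lam * np.eye(k)
    P = np.hstack([np.ones((k, 1)), src])
    A = np.zeros((k + 3, k + 3))
    A[:k, :k] = K
    A[:k, k:] = P
    A[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = dst
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        raise _diagnose_singular(src, lam) from None
    if not np.all(np.isfinite(sol)):
        raise _diagnose_singular(src, lam)
    return ThinPlateSplineTransform(src.copy(), sol[k:], sol[:k], lam, float(coord_scale))


def _check_general_position(src: np.ndarray) -> ValueError | None:
    """Duplicate or collinear sources make the lam=0 system singular."""
    d = cdist(src, src)
    np.fill_diagonal(d, np.inf)
    dup = np.argwhere(d < 1e-9)
    if len(dup):
        i, j = dup[0]
        return ValueError(
            f"singular TPS system: duplicate source points {i} and {j} at {src[i]}"
        )
    centered = src - src.mean(axis=0)
    scale = max(np.abs(centered).max(), 1.0)
    if np.linalg.matrix_rank(centered / scale, tol=1e-9) < 2:
        return ValueError("singular TPS system: source points are collinear")
    return None


def _diagnose_singular(src: np.ndarray, lam: float) -> ValueError:
    d = cdist(src, src)
    np.fill_diagonal(d, np.inf)
    dup = np.argwhere(d < 1e-9)
    if len(dup):
        i, j = dup[0]
        return ValueError(
            f"singular TPS system with lam={lam}: duplicate source points {i} and {j} at {src[i]}"
        )
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        return ValueError(f"singular TPS system with lam={lam}: source points are collinear")
    return ValueError(f"singular TPS system with lam={lam}")


def transform_points(t: ThinPlateSplineTransform, pts: PointSet | np.ndarray) -> PointSet | np.ndarray:
    """Map points through a fitted transform; invalid rows pass through unchanged."""
    if isinstance(pts, PointSet):
        out = pts.copy()
        if out.n_valid:
            out.coords[out.valid] = t(out.coords[out.valid])
        return out
    return t(pts)


def warp_image(
    moving: Image2D,
    moving_pts: PointSet | np.ndarray,
    fixed_pts: PointSet | np.ndarray,
    out_size: int | tuple[int, int] | None = None,
    regularization: float = 0.0,
) -> Image2D:
    """Warp the moving image into fixed-image space.

    Backward warping: a TPS is fitted from fixed-space coordinates to
    moving-space coordinates (``fixed_pts -> moving_pts``); each output pixel
    samples the moving image at the mapped location with bilinear
    interpolation, 0-filled outside.
    """
    if out_size is None:
        shape = moving.shape
    elif np.isscalar(out_size):
        shape = (int(out_size), int(out_size))
    else:
        shape = (int(out_size[0]), int(out_size[1]))
    back = fit_tps(fixed_pts, moving_pts, regularization)
    # pixel i spans [i, i+1): indices convert to continuous centers via +0.5
    yy, xx = np.meshgrid(np.arange(shape[0], dtype=np.float64), np.arange(shape[1], dtype=np.float64), indexing="ij")
    src = back(np.stack([yy.ravel() + 0.5, xx.ravel() + 0.5], axis=1)) - 0.5
    out = ndimage.map_coordinates(
        moving.pixels,
        [src[:, 0].reshape(shape), src[:, 1].reshape(shape)],
        order=1,
        mode="constant",
        cval=0.0,
    )
    return Image2D(out, moving.modality)


def tps_backward_map(
    forward: ThinPlateSplineTransform,
    shape: tuple[int, int],
    n_iter: int = 8,
) -> np.ndarray:
    """Numerically invert a forward TPS on a pixel grid.

    Returns an array ``(H, W, 2)`` of moving-frame coordinates ``m`` such that
    ``forward(m) = q`` for each output pixel ``q``, found by fixed-point
    iteration ``m <- m - (forward(m) - q)``.  Converges quickly when the
    displacement field is smooth and sub-pixel accurate for the deformation
    magnitudes used here.
    """
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
    q = np.stack([yy.ravel() + 0.5, xx.ravel() + 0.5], axis=1)  # pixel centers
    m = q.copy()
    for _ in range(n_iter):
        m = m - (forward(m) - q)
    return m.reshape(h, w, 2)
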