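"""Synthetic phantom generator: modality-styled image pairs with known truth.

Each phantom emulates the structure of a whole-mount histology / T2 MR slice
pair: a smooth organ-scale blob (low-order Fourier perturbation of a circle)
with a handful of internal structures (a urethra-like lumen plus lobe-like
sub-regions), rendered twice with very different appearance models:

* moving (histology-styled): bright field, dark organ capsule and structure
  contours, fine-grained tissue texture;
* fixed (MR-styled): dark field, mid-gray tissue with coarse smooth noise and
  a mild blur, rendered from a nonlinearly deformed copy of the geometry.

The deformation between the frames is a random thin-plate spline whose
control displacements are rescaled so that the mean ground-truth point
displacement equals ``deformation_px`` exactly.  Ground-truth homologous
pairs are sampled half on the organ boundary and half on internal structure
contours, and are related by the forward TPS exactly (the central fixture
invariant the test suite leans on).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import Image2D, Modality, PointSet, write_image, write_points_csv
from .tps import ThinPlateSplineTransform, fit_tps

__all__ = ["PhantomParams", "Phantom", "generate_phantom", "generate_corpus", "degrade_phantom"]


@dataclasses.dataclass
class PhantomParams:
    size: int = 512
    organ_radius_frac: tuple[float, float] = (0.24, 0.32)  # fraction of image size
    n_internal: tuple[int, int] = (2, 5)
    deformation_px: float = 12.0
    n_gt_points: int = 24

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("phantom size must be >= 32")
        if self.deformation_px < 0:
            raise ValueError("deformation magnitude must be >= 0")
        if self.n_gt_points < 3:
            raise ValueError("need at least 3 ground-truth points")


@dataclasses.dataclass
class _FourierBlob:
    """Closed curve rho(theta) = r0 * (1 + sum_k a_k cos k theta + b_k sin k theta).

    ``band_freq``/``band_phase`` describe the angular morphology profile of
    the blob's contour band (capsule thickness / gland density variation) —
    a tissue property, so both modality renders derive their contour
    appearance from this one profile.
    """

    center: np.ndarray  # (y, x)
    r0: float
    coef: np.ndarray  # (n_harmonics, 2) for harmonics k = 2, 3, ...
    band_freq: int = 8
    band_phase: float = 0.0

    def band_profile(self, theta: np.ndarray) -> np.ndarray:
        """Contour morphology in [0, 1] as a function of angle."""
        return 0.5 * (1.0 + np.sin(self.band_freq * theta + self.band_phase))

    def radius(self, theta: np.ndarray) -> np.ndarray:
        r = np.ones_like(theta)
        for i, (a, b) in enumerate(self.coef):
            k = i + 2
            r = r + a * np.cos(k * theta) + b * np.sin(k * theta)
        return self.r0 * r

    def signed(self, pts: np.ndarray) -> np.ndarray:
        """Approximate signed distance: negative inside, ~px units near the curve."""
        d = pts - self.center
        rho = np.hypot(d[..., 0], d[..., 1])
        theta = np.arctan2(d[..., 1], d[..., 0])
        return rho - self.radius(theta)

    def contour_points(self, thetas: np.ndarray, inset: float = 0.0) -> np.ndarray:
        r = self.radius(thetas) - inset
        return self.center + np.stack([r * np.cos(thetas), r * np.sin(thetas)], axis=-1)


@dataclasses.dataclass
class Phantom:
    mask: Image2D  # moving-frame organ mask (binary)
    fixed_mask: Image2D  # fixed-frame organ mask (binary)
    moving: Image2D  # histology-styled render, moving frame
    fixed: Image2D  # MR-styled render, fixed frame
    gt_moving: PointSet
    gt_fixed: PointSet
    true_deformation: ThinPlateSplineTransform  # moving-frame -> fixed-frame points
    seed: int

    @property
    def gt_pairs(self) -> tuple[PointSet, PointSet]:
        return self.gt_moving, self.gt_fixed


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float, amp: float) -> np.ndarray:
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = n.std()
    return amp * n / s if s > 0 else n


def _make_geometry(rng: np.random.Generator, params: PhantomParams):
    size = params.size
    c = size / 2.0 + rng.uniform(-0.03, 0.03, 2) * size
    r0 = rng.uniform(*params.organ_radius_frac) * size

    def bands():
        return int(rng.integers(6, 12)), float(rng.uniform(0, 2 * np.pi))

    f, p = bands()
    organ = _FourierBlob(c, r0, rng.uniform(-0.05, 0.05, (3, 2)), f, p)
    n_int = int(rng.integers(params.n_internal[0], params.n_internal[1] + 1))
    structures: list[_FourierBlob] = []
    # first structure: urethra-like lumen near the center
    f, p = bands()
    structures.append(
        _FourierBlob(
            c + rng.uniform(-0.15, 0.15, 2) * r0,
            rng.uniform(0.08, 0.14) * r0,
            rng.uniform(-0.08, 0.08, (2, 2)),
            f, p,
        )
    )
    for _ in range(n_int - 1):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.15, 0.5) * r0
        ctr = c + rad * np.array([np.cos(ang), np.sin(ang)])
        f, p = bands()
        structures.append(
            _FourierBlob(ctr, rng.uniform(0.14, 0.3) * r0, rng.uniform(-0.06, 0.06, (2, 2)), f, p)
        )
    return organ, structures


def _theta(coords: np.ndarray, blob: _FourierBlob) -> np.ndarray:
    d = coords - blob.center
    return np.arctan2(d[..., 1], d[..., 0])


def _make_parenchyma(rng: np.random.Generator, size: int):
    """Shared mid-scale tissue texture, defined in the moving frame.

    Both modalities render (differently mapped) views of this one field, so
    internal appearance deforms consistently between the frames — the
    correspondence cue the clinical histology/MR pair also carries.
    """
    arr = _smooth_noise(rng, (size, size), size / 28.0, 1.0)

    def field(coords: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            arr, [coords[..., 0] - 0.5, coords[..., 1] - 0.5], order=1, mode="nearest"
        )

    return field


def _render_histology(
    coords, organ: _FourierBlob, structures, parenchyma, rng: np.random.Generator
) -> np.ndarray:
    shape = coords.shape[:-1]
    img = np.full(shape, 0.93)
    s_org = organ.signed(coords)
    inside = s_org < 0
    img[inside] = (0.62 + 0.13 * parenchyma(coords))[inside]
    img += np.where(inside, _smooth_noise(rng, shape, 0.8, 0.04), 0.0)
    for i, b in enumerate(structures):
        s = b.signed(coords)
        reg = (s < 0) & inside
        if i == 0:
            img[reg] = 0.95  # lumen
        else:
            img[reg] += 0.1 if i % 2 else -0.08
        # contour morphology shows as bead-like staining variation
        bead = b.band_profile(_theta(coords, b))
        band = (np.abs(s) < 1.3) & inside
        img[band] = 0.1 + 0.45 * bead[band]
    bead = organ.band_profile(_theta(coords, organ))
    band = np.abs(s_org) < 1.6
    img[band] = 0.04 + 0.5 * bead[band]  # organ capsule
    return np.clip(img, 0.0, 1.0)


def _render_mr(
    coords, organ: _FourierBlob, structures, parenchyma, rng: np.random.Generator
) -> np.ndarray:
    shape = coords.shape[:-1]
    img = np.full(shape, 0.08)
    s_org = organ.signed(coords)
    inside = s_org < 0
    # inverted intensity mapping of the shared texture (cross-modality gap)
    img[inside] = (0.55 - 0.11 * parenchyma(coords))[inside]
    for i, b in enumerate(structures):
        s = b.signed(coords)
        reg = (s < 0) & inside
        if i == 0:
            img[reg] = 0.13  # lumen dark on T2-style render
        else:
            img[reg] += -0.12 if i % 2 else 0.12
        # the same contour morphology, mapped to T2-style brightness; the
        # band stays distinct from tissue and background at every angle
        bead = b.band_profile(_theta(coords, b))
        band = (np.abs(s) < 1.5) & inside
        img[band] = 0.68 + 0.24 * bead[band]
    bead = organ.band_profile(_theta(coords, organ))
    band = np.abs(s_org) < 2.0
    img[band] = 0.18 + 0.2 * bead[band]  # capsule rim, thickness/intensity varying
    img = ndimage.gaussian_filter(img, 0.8)
    img += _smooth_noise(rng, shape, 2.0, 0.03) + _smooth_noise(rng, shape, 0.8, 0.015)
    return np.clip(img, 0.0, 1.0)


def _identity_tps(size: int) -> ThinPlateSplineTransform:
    g = np.linspace(0, size, 4)
    grid = np.array([(y, x) for y in g for x in g], dtype=np.float64)
    affine = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    return ThinPlateSplineTransform(grid, affine, np.zeros((len(grid), 2)), 0.0)


def _random_deformation(
    rng: np.random.Generator, size: int, magnitude: float, gt_pts: np.ndarray
) -> ThinPlateSplineTransform:
    """Random TPS rescaled so mean displacement over gt_pts equals magnitude."""
    if magnitude == 0:
        return _identity_tps(size)
    g = np.linspace(0, size, 4)
    grid = np.array([(y, x) for y in g for x in g], dtype=np.float64)
    disp = rng.uniform(-1.0, 1.0, grid.shape) * magnitude
    f = fit_tps(grid, grid + disp)
    mean_d = float(np.linalg.norm(f(gt_pts) - gt_pts, axis=1).mean())
    if mean_d > 0:
        disp *= magnitude / mean_d
    return fit_tps(grid, grid + disp)


def generate_phantom(seed: int, params: PhantomParams | None = None) -> Phantom:
    """Generate one phantom pair; bit-reproducible for a fixed seed."""
    params = params or PhantomParams()
    size = params.size
    rng = np.random.default_rng(seed)
    organ, structures = _make_geometry(rng, params)

    perimeter = 2 * np.pi * organ.r0
    n_boundary = params.n_gt_points // 2
    if n_boundary > perimeter / 2:
        raise ValueError(
            f"{params.n_gt_points} ground-truth points infeasible for organ perimeter {perimeter:.0f} px"
        )

    # ground-truth points: half on the organ boundary, half on structure contours
    thetas = np.sort(rng.uniform(0, 2 * np.pi, n_boundary))
    gt = [organ.contour_points(thetas, inset=1.5)]
    n_interior = params.n_gt_points - n_boundary
    per_struct = np.array_split(np.arange(n_interior), len(structures))
    for b, idx in zip(structures, per_struct):
        if len(idx) == 0:
            continue
        th = np.sort(rng.uniform(0, 2 * np.pi, len(idx)))
        gt.append(b.contour_points(th, inset=0.5))
    gt_moving = np.vstack(gt)

    deform = _random_deformation(rng, size, params.deformation_px, gt_moving)
    gt_fixed = deform(gt_moving)

    yy, xx = np.meshgrid(np.arange(size, dtype=np.float64), np.arange(size, dtype=np.float64), indexing="ij")
    grid = np.stack([yy, xx], axis=-1) + 0.5  # pixel centers
    parenchyma = _make_parenchyma(rng, size)
    moving_px = _render_histology(grid, organ, structures, parenchyma, rng)
    mask_px = (organ.signed(grid) < 0).astype(np.float64)

    # fixed frame: evaluate the geometry at backward-mapped coordinates
    if params.deformation_px == 0:
        back_coords = grid
    else:
        back = fit_tps(deform(deform.source_points), deform.source_points)
        back_coords = back(grid.reshape(-1, 2)).reshape(grid.shape)
    fixed_px = _render_mr(back_coords, organ, structures, parenchyma, rng)
    fixed_mask_px = (organ.signed(back_coords) < 0).astype(np.float64)

    return Phantom(
        mask=Image2D(mask_px, Modality.HISTOLOGY),
        fixed_mask=Image2D(fixed_mask_px, Modality.MR),
        moving=Image2D(moving_px, Modality.HISTOLOGY),
        fixed=Image2D(fixed_px, Modality.MR),
        gt_moving=PointSet(gt_moving),
        gt_fixed=PointSet(gt_fixed),
        true_deformation=deform,
        seed=int(seed),
    )


def generate_corpus(
    n: int,
    seed: int,
    params: PhantomParams | None = None,
    out_dir: str | Path = "corpus",
    split: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> dict:
    """Write ``n`` phantoms (PNGs + point CSVs) and a train/val/test manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or PhantomParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    entries = []
    for i in range(n):
        ph = generate_phantom(int(child_seeds[i]), params)
        pid = f"phantom_{i:03d}"
        d = out / pid
        d.mkdir(exist_ok=True)
        write_image(d / "moving.png", ph.moving)
        write_image(d / "fixed.png", ph.fixed)
        write_image(d / "moving_mask.png", ph.mask)
        write_image(d / "fixed_mask.png", ph.fixed_mask)
        write_points_csv(d / "moving_points.csv", ph.gt_moving)
        write_points_csv(d / "fixed_points.csv", ph.gt_fixed)
        if i < n_train:
            part = "train"
        elif i < n_train + n_val:
            part = "val"
        else:
            part = "test"
        entries.append(
            {
                "id": pid,
                "split": part,
                "seed": int(child_seeds[i]),
                "moving": str(d / "moving.png"),
                "fixed": str(d / "fixed.png"),
                "moving_mask": str(d / "moving_mask.png"),
                "fixed_mask": str(d / "fixed_mask.png"),
                "moving_points": str(d / "moving_points.csv"),
                "fixed_points": str(d / "fixed_points.csv"),
            }
        )
    manifest = {"seed": int(seed), "size": params.size, "slides": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def degrade_phantom(ph: Phantom, mode: str, severity: float) -> Phantom:
    """Stress-test degradations of the moving (histology) side.

    tear: a crack polygon from the boundary toward the center is removed;
    fold: a strip is mirrored and overlaid on its neighbor;
    partial: only a fraction ``1 - severity`` of the section is retained.
    Ground-truth moving points falling in destroyed regions are invalidated.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    if mode not in {"tear", "fold", "partial"}:
        raise ValueError(f"unknown degradation mode {mode!r}")
    if severity == 0.0:
        return ph
    size = ph.moving.height
    rng = np.random.default_rng(ph.seed + 9173)
    moving = ph.moving.pixels.copy()
    mask = ph.mask.pixels.copy().astype(bool)
    gt_m = ph.gt_moving.copy()
    gt_f = ph.gt_fixed.copy()
    ys, xs = np.nonzero(mask)
    c = np.array([ys.mean(), xs.mean()])
    yy, xx = np.meshgrid(np.arange(size, dtype=np.float64), np.arange(size, dtype=np.float64), indexing="ij")

    if mode == "partial":
        # horizontal guillotine retaining ~ (1 - severity) of the mask area
        rows = mask.sum(axis=1).astype(np.float64)
        csum = np.cumsum(rows) / rows.sum()
        cut = int(np.searchsorted(csum, 1.0 - severity))
        destroyed = yy >= cut
    elif mode == "tear":
        ang = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(ang), np.sin(ang)])
        nvec = np.array([-u[1], u[0]])
        rel = np.stack([yy - c[0], xx - c[1]], axis=-1)
        along = rel @ u
        across = rel @ nvec
        width = 2.0 + severity * 12.0
        destroyed = (along > 0) & (np.abs(across) < width * (0.3 + along / along.max()))
    else:  # fold
        band = max(3, int(severity * 0.2 * size))
        x0 = int(c[1] + 0.3 * size * (1 - severity))
        x0 = min(x0, size - 2 * band - 1)
        strip = moving[:, x0 : x0 + band]
        moving[:, x0 + band : x0 + 2 * band] = np.minimum(
            moving[:, x0 + band : x0 + 2 * band], strip[:, ::-1] * 0.7
        )
        destroyed = (xx >= x0) & (xx < x0 + 2 * band)

    if mode != "fold":
        moving[destroyed] = 0.93  # slide background
        mask[destroyed] = False
    pt_idx = np.clip(np.round(gt_m.coords).astype(int), 0, size - 1)
    hit = destroyed[pt_idx[:, 0], pt_idx[:, 1]]
    gt_m.valid &= ~hit
    gt_f.valid &= ~hit
    return dataclasses.replace(
        ph,
        moving=Image2D(moving, Modality.HISTOLOGY),
        mask=Image2D(mask.astype(np.float64), Modality.HISTOLOGY),
        gt_moving=gt_m,
        gt_fixed=gt_f,
    )
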