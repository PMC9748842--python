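"""Training harness: augmentation, modality-mixing sampler, masked MAE loss,
and the optimization loop.

The mixing schema follows the mono/multi-modal scheme: half of the examples
(in expectation, per-example Bernoulli) are two differently-augmented copies
of a *single* modality's slide, with the encoder branch switched so that
histology weights never see MR pixels and vice versa.  Augmentation is a
random thin-plate-spline warp (per-axis control displacements capped at
``tps_max_dev`` px, applied to both sides) plus a random rotation of the
fixed side only.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Image2D, Modality, PointSet, pad_points
from .model import HomologousPointNet, ModelConfig
from .nn.autodiff import Tensor, mul, tabs, tsum
from .nn.layers import Adam
from .tps import fit_tps, tps_backward_map

__all__ = [
    "Slide",
    "TrainingExample",
    "AugmentationParams",
    "random_tps_augment",
    "random_rotation_augment",
    "sample_training_example",
    "masked_mae_loss",
    "train",
    "TrainResult",
]


@dataclasses.dataclass
class Slide:
    """One training slide: paired histology/MR images with homologous points."""

    moving: Image2D  # histology
    fixed: Image2D  # MR
    moving_points: PointSet
    fixed_points: PointSet
    slide_id: str = ""

    def __post_init__(self) -> None:
        if self.moving_points.n_valid != self.fixed_points.n_valid:
            raise ValueError("moving/fixed annotations must have equal valid counts")


@dataclasses.dataclass
class TrainingExample:
    moving: Image2D
    fixed: Image2D
    X: PointSet  # moving frame
    Y_true: PointSet  # fixed frame
    moving_modality: Modality
    fixed_modality: Modality

    def __post_init__(self) -> None:
        if not np.array_equal(self.X.valid, self.Y_true.valid):
            raise ValueError("X and Y_true must share the same validity mask")


@dataclasses.dataclass
class AugmentationParams:
    tps_max_dev: float = 16.0  # per-axis control-point displacement cap, px
    rotation_deg: float = 20.0  # fixed-side rotation range +/- deg
    control_grid: int = 4

    def __post_init__(self) -> None:
        if self.tps_max_dev < 0:
            raise ValueError("tps_max_dev must be >= 0")
        if self.rotation_deg < 0:
            raise ValueError("rotation_deg must be >= 0")


def _warp_image_by_map(img: Image2D, coords: np.ndarray) -> Image2D:
    """Backward-warp by a map of continuous source coordinates (pixel i at i+0.5)."""
    out = ndimage.map_coordinates(
        img.pixels, [coords[..., 0] - 0.5, coords[..., 1] - 0.5], order=1, mode="constant", cval=0.0
    )
    return Image2D(out, img.modality)


def sample_tps_deformation(
    size: int, params: AugmentationParams, rng: np.random.Generator
):
    """Draw one random TPS deformation for augmentation.

    Returns the forward transform and the sampled control-point displacement
    array; each per-axis displacement is uniform in [-tps_max_dev, +tps_max_dev].
    """
    g = np.linspace(0, size, params.control_grid)
    grid = np.array([(y, x) for y in g for x in g], dtype=np.float64)
    disp = rng.uniform(-params.tps_max_dev, params.tps_max_dev, grid.shape)
    return fit_tps(grid, grid + disp), disp


def random_tps_augment(
    img: Image2D, pts: PointSet, params: AugmentationParams, rng: np.random.Generator
) -> tuple[Image2D, PointSet]:
    """Random smooth TPS warp of an image with consistently warped points.

    A ``control_grid`` x ``control_grid`` lattice is displaced by i.i.d.
    per-axis uniform offsets in [-tps_max_dev, +tps_max_dev].  Points map
    forward through the fitted spline; the image is backward-warped through
    the numerically inverted spline so that image content tracks the points.
    """
    if params.tps_max_dev == 0:
        return Image2D(img.pixels.copy(), img.modality), pts.copy()
    forward, _ = sample_tps_deformation(img.height, params, rng)
    out_pts = pts.copy()
    if out_pts.n_valid:
        out_pts.coords[out_pts.valid] = forward(out_pts.coords[out_pts.valid])
    back = tps_backward_map(forward, img.shape)
    return _warp_image_by_map(img, back), out_pts


def _rotation_matrix(theta_rad: float) -> np.ndarray:
    c, s = math.cos(theta_rad), math.sin(theta_rad)
    # (y, x) convention: y' = y cos + x sin ; x' = -y sin + x cos
    return np.array([[c, s], [-s, c]])


def random_rotation_augment(
    img: Image2D, pts: PointSet, params: AugmentationParams, rng: np.random.Generator, theta_deg: float | None = None
) -> tuple[Image2D, PointSet]:
    """Rotate about the image center by theta ~ U(-rotation_deg, +rotation_deg)."""
    if theta_deg is None:
        theta_deg = float(rng.uniform(-params.rotation_deg, params.rotation_deg))
    th = math.radians(theta_deg)
    c = np.array([img.height / 2.0, img.width / 2.0])
    R = _rotation_matrix(th)
    out_pts = pts.copy()
    if out_pts.n_valid:
        rel = out_pts.coords[out_pts.valid] - c
        out_pts.coords[out_pts.valid] = rel @ R.T + c
    # backward warp: sample source = inverse-rotated output pixel centers
    yy, xx = np.meshgrid(np.arange(img.height, dtype=np.float64), np.arange(img.width, dtype=np.float64), indexing="ij")
    rel = np.stack([yy + 0.5 - c[0], xx + 0.5 - c[1]], axis=-1)
    src = rel @ _rotation_matrix(-th).T + c
    return _warp_image_by_map(img, src), out_pts


def _invalidate_out_of_frame(x_pts: PointSet, y_pts: PointSet, size: int) -> None:
    """Jointly invalidate pairs whose augmented position left the image frame."""
    for pts in (x_pts, y_pts):
        inside = np.all((pts.coords >= 0) & (pts.coords < size), axis=1)
        x_pts.valid &= inside
    y_pts.valid &= x_pts.valid
    x_pts.valid &= y_pts.valid


def sample_training_example(
    dataset: list[Slide],
    rng: np.random.Generator,
    same_modality_fraction: float = 0.5,
    aug: AugmentationParams | None = None,
) -> TrainingExample:
    """Draw one (possibly mono-modal) augmented training example.

    With probability ``same_modality_fraction`` both branches receive
    independently augmented copies of one slide from a single modality
    (chosen uniformly); otherwise the moving side is the histology slide and
    the fixed side its paired MR slide.  The fixed side additionally gets
    the rotation augmentation.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    aug = aug or AugmentationParams()
    slide = dataset[int(rng.integers(len(dataset)))]
    mono = bool(rng.random() < same_modality_fraction)
    if mono:
        modality = Modality.HISTOLOGY if rng.random() < 0.5 else Modality.MR
        if modality is Modality.HISTOLOGY:
            img, pts = slide.moving, slide.moving_points
        else:
            img, pts = slide.fixed, slide.fixed_points
        m_img, m_pts = random_tps_augment(img, pts, aug, rng)
        f_img, f_pts = random_tps_augment(img, pts, aug, rng)
        f_img, f_pts = random_rotation_augment(f_img, f_pts, aug, rng)
        _invalidate_out_of_frame(m_pts, f_pts, m_img.height)
        return TrainingExample(m_img, f_img, m_pts, f_pts, modality, modality)
    m_img, m_pts = random_tps_augment(slide.moving, slide.moving_points, aug, rng)
    f_img, f_pts = random_tps_augment(slide.fixed, slide.fixed_points, aug, rng)
    f_img, f_pts = random_rotation_augment(f_img, f_pts, aug, rng)
    _invalidate_out_of_frame(m_pts, f_pts, m_img.height)
    return TrainingExample(m_img, f_img, m_pts, f_pts, Modality.HISTOLOGY, Modality.MR)


def masked_mae_loss(Y_pred: PointSet | np.ndarray, Y_true: PointSet) -> float:
    """Mean absolute error over the coordinates of valid points only."""
    if isinstance(Y_pred, PointSet):
        if not np.array_equal(Y_pred.valid, Y_true.valid):
            raise ValueError("validity masks of prediction and truth differ")
        pred = Y_pred.coords
    else:
        pred = np.asarray(Y_pred, dtype=np.float64)
        if pred.shape != Y_true.coords.shape:
            raise ValueError("prediction shape does not match truth")
    m = Y_true.valid
    if not m.any():
        warnings.warn("masked_mae_loss: no valid points; defining loss as 0")
        return 0.0
    return float(np.abs(pred[m] - Y_true.coords[m]).mean())


def _loss_node(Y: Tensor, Y_true: PointSet) -> Tensor:
    """Autodiff masked-MAE node used by the training loop."""
    mask = Y_true.valid.astype(np.float64)[:, None]
    n_valid = int(Y_true.valid.sum())
    diff = mul(Y - Tensor(Y_true.with_sentinels()), Tensor(mask))
    denom = max(2 * n_valid, 1)
    return tsum(tabs(diff)) / denom


@dataclasses.dataclass
class TrainResult:
    model: HomologousPointNet
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_state: dict[str, np.ndarray]  # weights at the best validation loss
    best_val_loss: float


def _branches_for(ex: TrainingExample) -> tuple[str, str]:
    return ex.moving_modality.value, ex.fixed_modality.value


def evaluate_loss(model: HomologousPointNet, slides: list[Slide]) -> float:
    """Cross-modality masked MAE on un-augmented slides (validation metric)."""
    losses = []
    for s in slides:
        X = pad_points(s.moving_points, model.config.L)
        Yt = pad_points(s.fixed_points, model.config.L)
        pred = model.predict_points(s.moving, s.fixed, X)
        losses.append(masked_mae_loss(pred, Yt))
    return float(np.mean(losses)) if losses else float("nan")


def train(
    dataset: list[Slide],
    config: ModelConfig,
    epochs: int = 128,
    aug: AugmentationParams | None = None,
    val_dataset: list[Slide] | None = None,
    same_modality_fraction: float = 0.5,
    lr: float = 1e-4,
    batch_size: int = 4,
    steps_per_epoch: int | None = None,
    seed: int = 0,
    model: HomologousPointNet | None = None,
    lr_schedule: str = "constant",
    verbose: bool = False,
) -> TrainResult:
    """Train the point network with the modality-mixing schema.

    Gradients are averaged over ``batch_size`` examples per Adam step; one
    epoch is ``steps_per_epoch`` steps (default: one pass worth of examples).
    ``lr_schedule`` is "constant" or "cosine" (smooth decay to ~0 over the
    run).  The best-validation-loss weights are retained alongside the final
    ones.  Reproducible for a fixed seed.
    """
    if lr_schedule not in ("constant", "cosine"):
        raise ValueError(f"unknown lr_schedule {lr_schedule!r}")
    if not dataset:
        raise ValueError("empty training dataset")
    aug = aug or AugmentationParams()
    rng = np.random.default_rng(seed)
    if model is None:
        model = HomologousPointNet(config, seed=int(rng.integers(2**31)))
    opt = Adam(model.params, lr=lr)
    if steps_per_epoch is None:
        steps_per_epoch = max(1, math.ceil(len(dataset) / batch_size))
    records = []
    best_val = float("inf")
    best_state = model.state_dict()
    for epoch in range(epochs):
        if lr_schedule == "cosine":
            opt.lr = lr * 0.5 * (1.0 + math.cos(math.pi * epoch / max(epochs, 1)))
        epoch_losses = []
        for _ in range(steps_per_epoch):
            opt.zero_grad()
            batch_loss = 0.0
            for _ in range(batch_size):
                ex = sample_training_example(dataset, rng, same_modality_fraction, aug)
                X = pad_points(ex.X, config.L)
                Yt = pad_points(ex.Y_true, config.L)
                mb, fb = _branches_for(ex)
                out = model.forward(ex.moving, ex.fixed, X, moving_branch=mb, fixed_branch=fb)
                loss = _loss_node(out["Y"], Yt) / batch_size
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                loss.backward()
                batch_loss += float(loss.data)
            opt.step()
            epoch_losses.append(batch_loss)
        val = evaluate_loss(model, val_dataset) if val_dataset else float("nan")
        if val_dataset and val < best_val:
            best_val = val
            best_state = model.state_dict()
        records.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)), "val_loss": val})
        if verbose:
            print(f"epoch {epoch}: train {records[-1]['train_loss']:.3f} val {val:.3f}")
    if not val_dataset:
        best_state = model.state_dict()
        best_val = float("nan")
    history = pd.DataFrame(records, columns=["epoch", "train_loss", "val_loss"])
    return TrainResult(model, history, best_state, best_val)
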