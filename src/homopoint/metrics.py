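"""Registration evaluation: control point deviation, Dice, and reports.

Control point deviation is always computed on *held-out ground-truth* pairs
(phantom truth or human annotations), never on the landmark/prediction pairs
the transform was fitted from; the API takes the fitted transform and the
ground-truth sets separately to keep those roles apart.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import Image2D, PointSet, pad_points
from .landmarks import select_landmarks
from .model import HomologousPointNet
from .tps import ThinPlateSplineTransform, fit_tps, warp_image

__all__ = ["control_point_deviation", "dice", "EvaluationReport", "evaluate_pipeline"]


def control_point_deviation(
    t: ThinPlateSplineTransform, moving_gt: PointSet | np.ndarray, fixed_gt: PointSet | np.ndarray
) -> float:
    """Mean Euclidean distance between transformed moving-GT and fixed-GT points."""
    if isinstance(moving_gt, PointSet) and isinstance(fixed_gt, PointSet):
        m = moving_gt.valid & fixed_gt.valid
        a, b = moving_gt.coords[m], fixed_gt.coords[m]
    else:
        a = np.atleast_2d(np.asarray(moving_gt, dtype=np.float64))
        b = np.atleast_2d(np.asarray(fixed_gt, dtype=np.float64))
    if len(a) != len(b):
        raise ValueError("ground-truth point counts differ")
    if len(a) == 0:
        raise ValueError("no valid ground-truth pairs")
    return float(np.linalg.norm(t(a) - b, axis=1).mean())


def dice(mask_a: Image2D | np.ndarray, mask_b: Image2D | np.ndarray, empty_value: float = 1.0) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary masks.

    Two empty masks score ``empty_value`` (default 1.0: vacuous agreement;
    pass ``float('nan')`` for the undefined convention).
    """
    a = (mask_a.pixels if isinstance(mask_a, Image2D) else np.asarray(mask_a)) > 0.5
    b = (mask_b.pixels if isinstance(mask_b, Image2D) else np.asarray(mask_b)) > 0.5
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return empty_value
    return 2.0 * int((a & b).sum()) / denom


@dataclasses.dataclass
class EvaluationReport:
    per_slide: pd.DataFrame  # columns: id, deviation_px, dice (NaN when no masks)

    @property
    def mean_deviation(self) -> float:
        return float(self.per_slide["deviation_px"].mean())

    @property
    def sd_deviation(self) -> float:
        return float(self.per_slide["deviation_px"].std(ddof=1))

    @property
    def mean_dice(self) -> float:
        return float(self.per_slide["dice"].mean())

    @property
    def sd_dice(self) -> float:
        return float(self.per_slide["dice"].std(ddof=1))

    def to_csv(self, path) -> None:
        agg = pd.DataFrame(
            [{
                "id": "aggregate(mean±sd)",
                "deviation_px": self.mean_deviation,
                "dice": self.mean_dice,
                "deviation_sd": self.sd_deviation,
                "dice_sd": self.sd_dice,
            }]
        )
        pd.concat([self.per_slide, agg], ignore_index=True).to_csv(path, index=False)


def evaluate_pipeline(
    test_set,
    model: HomologousPointNet | None = None,
    min_dist: float = 30.0,
    tps_regularization: float = 0.0,
    transform_fn=None,
    landmark_kwargs: dict | None = None,
) -> EvaluationReport:
    """Run the full registration pipeline over a test set and score it.

    Each entry needs ``moving``/``fixed`` images, ground-truth point pairs
    ``gt_moving``/``gt_fixed``, and (optionally, for Dice) ``mask`` /
    ``fixed_mask`` attributes — the ``Phantom`` container satisfies this,
    as do manifest-backed slide records.  Per slide the pipeline is
    select_landmarks -> predict_points -> fit_tps; deviation is then scored
    on the ground-truth pairs (never on the landmark correspondences) and
    Dice on the warped moving mask vs the fixed mask.

    ``transform_fn(entry) -> ThinPlateSplineTransform`` replaces the learned
    pipeline (e.g., with an oracle or the identity) when provided.
    """
    rows = []
    for i, entry in enumerate(test_set):
        gt_m, gt_f = entry.gt_moving, entry.gt_fixed
        if gt_m.n_valid == 0 or gt_f.n_valid == 0:
            continue  # slide has no usable ground truth
        if transform_fn is not None:
            t = transform_fn(entry)
        else:
            if model is None:
                raise ValueError("either a model or a transform_fn is required")
            L = model.config.L
            lm = select_landmarks(entry.moving, min_dist=min_dist, max_points=L, **(landmark_kwargs or {}))
            X = pad_points(lm, L)
            Y = model.predict_points(entry.moving, entry.fixed, X)
            t = fit_tps(X, Y, tps_regularization)
        dev = control_point_deviation(t, gt_m, gt_f)
        d = float("nan")
        mask = getattr(entry, "mask", None)
        fixed_mask = getattr(entry, "fixed_mask", None)
        if mask is not None and fixed_mask is not None:
            src_px = t.source_points_px
            warped = warp_image(mask, src_px, t(src_px), out_size=fixed_mask.shape)
            d = dice(warped.pixels > 0.5, fixed_mask.pixels > 0.5)
        rows.append({"id": getattr(entry, "seed", i), "deviation_px": dev, "dice": d})
    if not rows:
        raise ValueError("no slides with usable ground truth")
    return EvaluationReport(pd.DataFrame(rows))
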