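"""Shared domain types, coordinate conventions, and image/point preprocessing.

Coordinate convention, fixed repo-wide: points are ``(y, x)`` pairs (row,
column), 0-based, continuous, where pixel ``i`` spans ``[i, i + 1)``.  Images
are 2-D float arrays with intensities in ``[0, 1]``.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology

__all__ = [
    "Modality",
    "PointClass",
    "Image2D",
    "PointSet",
    "ZoomTransform",
    "EmptyForegroundError",
    "normalize_image",
    "foreground_bbox",
    "center_zoom",
    "apply_zoom_to_points",
    "pad_points",
    "read_image",
    "write_image",
    "read_points_csv",
    "write_points_csv",
]

#: Luma weights for RGB -> grayscale (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])

SENTINEL = (0.0, 0.0)


class Modality(str, enum.Enum):
    HISTOLOGY = "histology"
    MR = "mr"


class PointClass(str, enum.Enum):
    EDGE = "edge"
    INTERIOR = "interior"


class EmptyForegroundError(ValueError):
    """No foreground pixels found when computing a bounding box."""


@dataclasses.dataclass
class Image2D:
    """A 2-D single-channel image with intensities in [0, 1]."""

    pixels: np.ndarray
    modality: Modality = Modality.HISTOLOGY

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"Image2D requires a 2-D array, got shape {self.pixels.shape}")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class PointSet:
    """An ordered set of (y, x) points with per-point validity and class.

    Invalid points are placeholders (the model I/O boundary writes them as
    the ``(0, 0)`` sentinel); validity is tracked explicitly by the boolean
    mask so a legitimate point at exactly (0, 0) is representable.
    """

    coords: np.ndarray
    valid: np.ndarray | None = None
    classes: np.ndarray | None = None  # PointClass values, optional

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.float64))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 2)
        if self.coords.shape[1] != 2:
            raise ValueError("PointSet coords must be (n, 2)")
        n = len(self.coords)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (n,):
                raise ValueError("valid mask must match number of points")
        if self.classes is not None:
            self.classes = np.asarray(self.classes, dtype=object)
            if self.classes.shape != (n,):
                raise ValueError("classes must match number of points")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_coords(self) -> np.ndarray:
        return self.coords[self.valid]

    def copy(self) -> "PointSet":
        return PointSet(
            self.coords.copy(),
            self.valid.copy(),
            None if self.classes is None else self.classes.copy(),
        )

    def with_sentinels(self) -> np.ndarray:
        """Coordinates with invalid rows replaced by the (0, 0) sentinel."""
        out = self.coords.copy()
        out[~self.valid] = SENTINEL
        return out


@dataclasses.dataclass
class ZoomTransform:
    """Similarity map ``p' = scale * p + offset`` in (y, x) pixel coordinates."""

    scale: float
    offset: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("ZoomTransform scale must be > 0")
        self.offset = (float(self.offset[0]), float(self.offset[1]))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return self.scale * pts + np.asarray(self.offset)

    def inverse(self) -> "ZoomTransform":
        inv_scale = 1.0 / self.scale
        off = np.asarray(self.offset)
        return ZoomTransform(inv_scale, tuple(-off * inv_scale))


def normalize_image(raw: np.ndarray, modality: Modality | str = Modality.HISTOLOGY) -> Image2D:
    """Scale intensities to [0, 1]; RGB inputs are converted to grayscale first.

    Min-max scaling: a constant image maps to all zeros.  3-channel input is
    collapsed with standard luma weights; a 4th (alpha) channel is dropped.
    """
    modality = Modality(modality)
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim == 3:
        if raw.shape[2] == 4:
            raw = raw[:, :, :3]
        if raw.shape[2] == 3:
            raw = raw @ _LUMA
        elif raw.shape[2] == 1:
            raw = raw[:, :, 0]
        else:
            raise ValueError(f"unsupported channel count {raw.shape[2]}")
    elif raw.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D image array, got ndim={raw.ndim}")
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo < 1e-300:
        return Image2D(np.zeros_like(raw), modality)
    return Image2D((raw - lo) / (hi - lo), modality)


def foreground_bbox(img: Image2D) -> tuple[int, int, int, int]:
    """Locate the organ/tissue bounding box ``(y0, x0, y1, x1)`` (half-open).

    Otsu thresholding with modality-dependent polarity (dark tissue on a light
    field for histology; bright tissue on a dark field for MR), then removal
    of connected components smaller than 0.1% of the image area.
    """
    px = img.pixels
    if float(px.max()) - float(px.min()) < 1e-12:
        raise EmptyForegroundError("image is constant; no foreground found")
    t = filters.threshold_otsu(px)
    fg = px < t if img.modality is Modality.HISTOLOGY else px > t
    min_size = max(1, int(0.001 * px.size))
    fg = morphology.remove_small_objects(fg, max_size=min_size - 1)
    if not fg.any():
        raise EmptyForegroundError("no foreground component above size threshold")
    ys, xs = np.nonzero(fg)
    return int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1


def center_zoom(
    img: Image2D,
    bbox: tuple[int, int, int, int],
    pad: int = 50,
    out_size: int = 512,
) -> tuple[Image2D, ZoomTransform]:
    """Zoom so the bbox content is centered with ``pad`` px of margin.

    The content is scaled (aspect preserved, sized by its longer axis) so it
    spans ``out_size - 2 * pad`` pixels and its center lands at the image
    center.  Returns the resampled image and the point transform from the
    original frame to the zoomed frame.
    """
    y0, x0, y1, x1 = bbox
    if not (y1 > y0 and x1 > x0):
        raise ValueError("empty bbox")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if y1 - y0 > img.height or x1 - x0 > img.width:
        raise ValueError("bbox larger than image")
    span = max(y1 - y0, x1 - x0)
    target = out_size - 2 * pad
    if target <= 0:
        raise ValueError("pad too large for output size")
    scale = target / span
    c_in = np.array([(y0 + y1) / 2.0, (x0 + x1) / 2.0])
    c_out = np.array([out_size / 2.0, out_size / 2.0])
    zt = ZoomTransform(scale, tuple(c_out - scale * c_in))
    # Backward sampling: each output pixel center maps into the input frame.
    # Continuous convention: pixel i spans [i, i+1), its center is i + 0.5,
    # so array indices convert to continuous coordinates via +0.5.
    inv = zt.inverse()
    grid = np.stack(
        np.meshgrid(np.arange(out_size, dtype=np.float64), np.arange(out_size, dtype=np.float64), indexing="ij"),
        axis=-1,
    )
    src = inv.apply(grid.reshape(-1, 2) + 0.5).reshape(out_size, out_size, 2) - 0.5
    out = ndimage.map_coordinates(
        img.pixels, [src[..., 0], src[..., 1]], order=1, mode="constant", cval=0.0
    )
    return Image2D(out, img.modality), zt


def apply_zoom_to_points(points: PointSet, zt: ZoomTransform) -> PointSet:
    """Map valid points affinely through ``zt``; invalid placeholders pass through."""
    out = points.copy()
    out.coords[out.valid] = zt.apply(out.coords[out.valid])
    return out


def pad_points(points: PointSet, L: int = 75) -> PointSet:
    """Pad to exactly ``L`` entries with invalid (0, 0) sentinels."""
    n = len(points)
    if n > L:
        raise ValueError(
            f"point set has {n} points but L={L}; raise L or thin the point set"
        )
    coords = np.zeros((L, 2))
    valid = np.zeros(L, dtype=bool)
    coords[:n] = points.coords
    valid[:n] = points.valid
    classes = None
    if points.classes is not None:
        classes = np.empty(L, dtype=object)
        classes[:] = None
        classes[:n] = points.classes
    return PointSet(coords, valid, classes)


# ---------------------------------------------------------------------------
# I/O: PNG/TIFF rasters and the CSV point dialect "id,y,x[,class]"
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(str(path)))


def write_image(path: str | Path, img: Image2D | np.ndarray) -> None:
    import imageio.v3 as iio

    px = img.pixels if isinstance(img, Image2D) else np.asarray(img)
    if px.dtype != np.uint8:
        px = np.clip(np.asarray(px, dtype=np.float64), 0.0, 1.0)
        px = np.round(px * 255).astype(np.uint8)
    iio.imwrite(str(path), px)


def read_points_csv(path: str | Path) -> PointSet:
    df = pd.read_csv(path)
    required = {"id", "y", "x"}
    if not required.issubset(df.columns):
        raise ValueError(f"point CSV must have columns id,y,x[,class]; got {list(df.columns)}")
    coords = df[["y", "x"]].to_numpy(dtype=np.float64)
    classes = None
    if "class" in df.columns:
        classes = df["class"].to_numpy(dtype=object)
    return PointSet(coords, None, classes)


def write_points_csv(path: str | Path, points: PointSet, valid_only: bool = True) -> None:
    sel = points.valid if valid_only else np.ones(len(points), dtype=bool)
    rows = {
        "id": np.arange(int(sel.sum())),
        "y": points.coords[sel, 0],
        "x": points.coords[sel, 1],
    }
    if points.classes is not None:
        cls = points.classes[sel]
        rows["class"] = [c.value if isinstance(c, PointClass) else c for c in cls]
    pd.DataFrame(rows).to_csv(path, index=False)
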