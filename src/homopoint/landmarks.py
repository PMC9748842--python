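"""Histology landmark generation.

Candidate keypoints are 26-neighborhood extrema of a difference-of-Gaussians
(DoG) scale-space pyramid, as in the classic SIFT detector.  Candidates are
then (1) filtered on contrast (|DoG| on [0, 1]-scaled intensities, default
threshold 0.04), (2) scored for edge-ness with the trace^2/determinant
surrogate of the Hessian eigenvalue ratio, (3) split into edge vs interior
classes (the top 19% by edge score are edges), and (4) thinned by a greedy
minimum-distance pass in which edge points take priority over interior
points.  The output is a point set with roughly uniform density covering the
organ boundary and internal structure contours.

Pyramid defaults follow Lowe: 3 scales per octave, sigma0 = 1.6, octaves
until the smaller image dimension drops below 16 px.  The pyramid starts at
the native resolution (no initial upsampling octave).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .core import Image2D, PointClass, PointSet

__all__ = [
    "Candidate",
    "detect_candidates",
    "filter_contrast",
    "score_edges",
    "classify_edges",
    "enforce_min_distance",
    "select_landmarks",
]


@dataclasses.dataclass
class Candidate:
    y: float  # base-image pixel coordinates
    x: float
    octave: int
    interval: int
    contrast: float  # |DoG response|, [0,1]-intensity units
    edge_score: float | None = None  # Tr(H)^2 / Det(H); inf flags a saddle
    point_class: PointClass | None = None
    # cached spatial Hessian entries of the DoG at the candidate
    _hess: tuple[float, float, float] | None = None  # (dyy, dxx, dxy)

    @property
    def position(self) -> tuple[float, float]:
        return (self.y, self.x)


def _gaussian_pyramid(base: np.ndarray, n_octaves: int, s: int, sigma0: float, sigma_in: float):
    """Per octave: s + 3 Gaussian images, incremental blurs; returns list of stacks."""
    k = 2.0 ** (1.0 / s)
    sigmas = [sigma0 * k**i for i in range(s + 3)]
    # incremental blur increments: sigma_total(i)^2 = sigma_total(i-1)^2 + inc^2
    incs = [math.sqrt(max(sigmas[i] ** 2 - sigmas[i - 1] ** 2, 1e-12)) for i in range(1, s + 3)]
    octaves = []
    current = ndimage.gaussian_filter(base, math.sqrt(max(sigma0**2 - sigma_in**2, 1e-12)), mode="nearest")
    for _ in range(n_octaves):
        imgs = [current]
        for inc in incs:
            imgs.append(ndimage.gaussian_filter(imgs[-1], inc, mode="nearest"))
        octaves.append(np.stack(imgs))
        current = imgs[s][::2, ::2]  # next octave base: 2x-sigma image downsampled
    return octaves


def detect_candidates(
    img: Image2D,
    n_octaves: int | None = None,
    scales_per_octave: int = 3,
    sigma0: float = 1.6,
    refine: bool = True,
    prefilter: float = 0.5 * 0.04 / 3,
    upsample: bool = True,
) -> list[Candidate]:
    """Find DoG scale-space extrema with populated contrast and Hessian cache.

    ``refine`` enables one step of quadratic sub-pixel/sub-scale refinement;
    the contrast is then the interpolated ``|D(x̂)|`` rather than the raw
    lattice value.  ``prefilter`` discards clearly flat responses early
    (well below the 0.04 contrast gate applied later).  ``upsample`` starts
    the pyramid from a 2x bilinearly upsampled base (the classic "-1"
    octave), assuming an input blur of 0.5 px.
    """
    px = img.pixels
    if min(px.shape) < 16:
        raise ValueError(f"image {px.shape} smaller than one pyramid octave (min dim 16)")
    s = scales_per_octave
    if upsample:
        px = ndimage.zoom(px, 2.0, order=1, mode="nearest", grid_mode=True)
        sigma_in = 1.0  # 2 * assumed 0.5 px input blur
    else:
        sigma_in = 0.5
    if n_octaves is None:
        n_octaves = int(math.log2(min(px.shape) / 16)) + 1
    gauss = _gaussian_pyramid(px, n_octaves, s, sigma0, sigma_in)
    cands: list[Candidate] = []
    for o, G in enumerate(gauss):
        dog = G[1:] - G[:-1]  # (s+2, H, W)
        mx = ndimage.maximum_filter(dog, size=3, mode="nearest")
        mn = ndimage.minimum_filter(dog, size=3, mode="nearest")
        for i in range(1, s + 1):
            D = dog[i]
            is_ext = ((D == mx[i]) & (D > prefilter)) | ((D == mn[i]) & (D < -prefilter))
            is_ext[:1, :] = is_ext[-1:, :] = False
            is_ext[:, :1] = is_ext[:, -1:] = False
            ys, xs = np.nonzero(is_ext)
            for y, x in zip(ys, xs):
                val = float(D[y, x])
                dy = dx = di = 0.0
                if refine:
                    g = np.array(
                        [
                            (dog[i + 1][y, x] - dog[i - 1][y, x]) / 2,
                            (D[y + 1, x] - D[y - 1, x]) / 2,
                            (D[y, x + 1] - D[y, x - 1]) / 2,
                        ]
                    )
                    dss = dog[i + 1][y, x] - 2 * val + dog[i - 1][y, x]
                    dyy = D[y + 1, x] - 2 * val + D[y - 1, x]
                    dxx = D[y, x + 1] - 2 * val + D[y, x - 1]
                    dsy = (dog[i + 1][y + 1, x] - dog[i + 1][y - 1, x] - dog[i - 1][y + 1, x] + dog[i - 1][y - 1, x]) / 4
                    dsx = (dog[i + 1][y, x + 1] - dog[i + 1][y, x - 1] - dog[i - 1][y, x + 1] + dog[i - 1][y, x - 1]) / 4
                    dyx = (D[y + 1, x + 1] - D[y + 1, x - 1] - D[y - 1, x + 1] + D[y - 1, x - 1]) / 4
                    H = np.array([[dss, dsy, dsx], [dsy, dyy, dyx], [dsx, dyx, dxx]])
                    try:
                        off = np.linalg.solve(H, -g)
                    except np.linalg.LinAlgError:
                        off = np.zeros(3)
                    off = np.clip(off, -0.5, 0.5)
                    di, dy, dx = off
                    val = val + 0.5 * float(g @ off)
                dyy = float(D[y + 1, x] - 2 * D[y, x] + D[y - 1, x])
                dxx = float(D[y, x + 1] - 2 * D[y, x] + D[y, x - 1])
                dxy = float(D[y + 1, x + 1] - D[y + 1, x - 1] - D[y - 1, x + 1] + D[y - 1, x - 1]) / 4
                scale_mult = 2.0**o / (2.0 if upsample else 1.0)
                # +0.5: array index -> continuous pixel-center coordinate
                cands.append(
                    Candidate(
                        y=(y + dy + 0.5) * scale_mult,
                        x=(x + dx + 0.5) * scale_mult,
                        octave=o,
                        interval=i,
                        contrast=abs(val),
                        _hess=(dyy, dxx, dxy),
                    )
                )
    return cands


def filter_contrast(cands: list[Candidate], threshold: float = 0.04) -> list[Candidate]:
    """Drop candidates whose |DoG| contrast is below the threshold; order kept."""
    return [c for c in cands if c.contrast >= threshold]


def score_edges(img: Image2D, cands: list[Candidate]) -> list[Candidate]:
    """Set each candidate's edge score to Tr(H)^2 / Det(H) of the spatial Hessian.

    Monotone in the eigenvalue ratio r for Det > 0 (minimum 4 at r = 1);
    non-positive determinants (saddles) are flagged with +inf.  Uses the
    Hessian cached at detection time; the image argument re-derives it only
    for candidates produced elsewhere.
    """
    missing = [c for c in cands if c._hess is None]
    if missing:
        fresh = detect_candidates(img)
        lut = {(round(c.y, 3), round(c.x, 3), c.octave, c.interval): c._hess for c in fresh}
        for c in missing:
            c._hess = lut.get((round(c.y, 3), round(c.x, 3), c.octave, c.interval))
            if c._hess is None:
                raise ValueError(f"cannot recover Hessian for candidate at {(c.y, c.x)}")
    out = []
    for c in cands:
        dyy, dxx, dxy = c._hess
        tr = dyy + dxx
        det = dyy * dxx - dxy * dxy
        c = dataclasses.replace(c, edge_score=(tr * tr / det) if det > 0 else float("inf"))
        out.append(c)
    return out


def classify_edges(cands: list[Candidate], edge_fraction: float = 0.19) -> list[Candidate]:
    """Label the top ``ceil(edge_fraction * n)`` by edge score as edges.

    Ties break by higher contrast, then by scan order, so labeling is
    deterministic.
    """
    n = len(cands)
    if n == 0:
        return []
    n_edge = math.ceil(edge_fraction * n)
    order = sorted(range(n), key=lambda i: (-cands[i].edge_score, -cands[i].contrast, i))
    labels = [PointClass.INTERIOR] * n
    for i in order[:n_edge]:
        labels[i] = PointClass.EDGE
    return [dataclasses.replace(c, point_class=labels[i]) for i, c in enumerate(cands)]


def enforce_min_distance(cands: list[Candidate], min_dist: float) -> PointSet:
    """Greedy thinning: edges (by descending contrast) first, then interiors.

    A point is kept iff it lies at least ``min_dist`` from every point
    already kept — so in any edge/interior conflict the interior point is
    the one eliminated.
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be > 0")
    edges = [c for c in cands if c.point_class is PointClass.EDGE]
    interiors = [c for c in cands if c.point_class is not PointClass.EDGE]
    ordered = sorted(edges, key=lambda c: -c.contrast) + sorted(interiors, key=lambda c: -c.contrast)
    kept: list[Candidate] = []
    kept_xy = np.empty((0, 2))
    for c in ordered:
        p = np.array([c.y, c.x])
        if len(kept_xy) == 0 or np.all(np.linalg.norm(kept_xy - p, axis=1) >= min_dist):
            kept.append(c)
            kept_xy = np.vstack([kept_xy, p])
    if not kept:
        return PointSet(np.zeros((0, 2)), np.zeros(0, dtype=bool), np.zeros(0, dtype=object))
    coords = np.array([[c.y, c.x] for c in kept])
    classes = np.array([c.point_class for c in kept], dtype=object)
    return PointSet(coords, None, classes)


def select_landmarks(
    img: Image2D,
    min_dist: float = 30.0,
    max_points: int = 75,
    contrast_threshold: float = 0.04,
    edge_fraction: float = 0.19,
    **detect_kwargs,
) -> PointSet:
    """Full landmark selection: detect, gate on contrast, classify, thin.

    If more than ``max_points`` survive thinning, lowest-contrast interior
    points are dropped first (then lowest-contrast edges) so the result fits
    the network's fixed input length L.
    """
    cands = detect_candidates(img, **detect_kwargs)
    cands = filter_contrast(cands, contrast_threshold)
    if not cands:
        return PointSet(np.zeros((0, 2)), np.zeros(0, dtype=bool), np.zeros(0, dtype=object))
    cands = score_edges(img, cands)
    cands = classify_edges(cands, edge_fraction)
    pts = enforce_min_distance(cands, min_dist)
    if len(pts) > max_points:
        # thinning emits points in elimination-priority order (edges by
        # descending contrast, then interiors); truncating from the back
        # drops lowest-contrast interior points first, then edges
        pts = PointSet(pts.coords[:max_points], pts.valid[:max_points], pts.classes[:max_points])
    return pts
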