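"""Segmentation quality metrics and dermatology-inspired morphological descriptors.

Overlap metrics (Dice, IoU), detection rates (sensitivity, specificity,
precision), boundary metrics (tolerance-band boundary accuracy, Hausdorff
distance), structural metrics (windowed SSIM, proportion of correct patches)
and a set of lesion-shape/texture descriptors used by the augmentation
plausibility and interpolation-fidelity analyses.

Conventions
-----------
* Masks are ``{0,1}`` rasters (any integer/bool dtype accepted).
* Images are ``H x W`` or ``H x W x 3`` floats in ``[0, 1]``.
* A mask boundary is the set of foreground pixels with at least one
  8-connected neighbour in the background.
* Two empty masks compare as perfectly overlapping (Dice = IoU = 1);
  boundary metrics on empty boundaries return an undefined flag instead
  of a silent number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "ConfusionCounts",
    "MetricConfig",
    "FlaggedValue",
    "MorphDescriptorSet",
    "confusion",
    "dice",
    "iou",
    "sensitivity",
    "specificity",
    "precision",
    "boundary_pixels",
    "boundary_accuracy",
    "hausdorff",
    "hausdorff_masks",
    "ssim",
    "pcp",
    "morph_descriptors",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts between a predicted and a true mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricConfig:
    """Hyperparameters of the metric suite.

    ba_tolerance_px
        Pixel tolerance of the boundary-accuracy band (default 2).
    pcp_iou_threshold
        Patch-level IoU above which a patch counts as correct (0.5 or 0.75
        are the customary choices; default 0.5).
    pcp_patch_size
        Side length of the square patches tiling the raster.
    ssim_k1, ssim_k2
        Stabilizing constants of SSIM, ``C1=(k1*L)**2``, ``C2=(k2*L)**2``
        with dynamic range ``L = 1``.
    ssim_window
        Odd side length of the uniform local window.
    hd_epsilon
        Guard added to the Hausdorff distance when it is inverted for
        fitness aggregation.
    """

    ba_tolerance_px: int = 2
    pcp_iou_threshold: float = 0.5
    pcp_patch_size: int = 32
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    ssim_window: int = 7
    hd_epsilon: float = 1e-6


@dataclass(frozen=True)
class FlaggedValue:
    """A metric value paired with a definedness flag.

    ``value`` is ``nan`` whenever ``defined`` is False, so downstream
    arithmetic can never silently consume an undefined ratio.
    """

    value: float
    defined: bool = True

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class MorphDescriptorSet:
    """Dermatology-inspired shape and texture descriptors of a lesion."""

    asymmetry_index: float
    border_irregularity: float
    area_perimeter_ratio: float
    boundary_smoothness: float
    color_variance: float
    texture_contrast: float
    texture_entropy: float
    defined: bool = True

    _FIELDS = (
        "asymmetry_index",
        "border_irregularity",
        "area_perimeter_ratio",
        "boundary_smoothness",
        "color_variance",
        "texture_contrast",
        "texture_entropy",
    )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    return m.astype(bool)


# ---------------------------------------------------------------------------
# confusion-based metrics


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/FN/TN pixels between two same-shape binary masks."""
    p = _as_bool_mask(pred)
    t = _as_bool_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient, 2TP / (2TP + FP + FN)."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0  # two empty masks overlap perfectly
    return 2.0 * counts.tp / denom


def iou(counts: ConfusionCounts) -> float:
    """Jaccard index, TP / (TP + FP + FN)."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def sensitivity(counts: ConfusionCounts) -> FlaggedValue:
    """Recall, TP / (TP + FN); undefined when the truth has no positives."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return FlaggedValue(float("nan"), defined=False)
    return FlaggedValue(counts.tp / denom)


def specificity(counts: ConfusionCounts) -> FlaggedValue:
    """TN / (TN + FP); undefined when the truth has no negatives."""
    denom = counts.tn + counts.fp
    if denom == 0:
        return FlaggedValue(float("nan"), defined=False)
    return FlaggedValue(counts.tn / denom)


def precision(counts: ConfusionCounts) -> FlaggedValue:
    """Positive predictive value, TP / (TP + FP); undefined without predictions."""
    denom = counts.tp + counts.fp
    if denom == 0:
        return FlaggedValue(float("nan"), defined=False)
    return FlaggedValue(counts.tp / denom)


# ---------------------------------------------------------------------------
# boundary metrics


_FULL_3X3 = np.ones((3, 3), dtype=bool)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean raster of 8-connected boundary pixels of ``mask``."""
    m = _as_bool_mask(mask)
    if not m.any():
        return np.zeros_like(m)
    interior = ndimage.binary_erosion(m, structure=_FULL_3X3, border_value=0)
    return m & ~interior


def boundary_accuracy(
    pred: np.ndarray, truth: np.ndarray, tolerance_px: int = 2
) -> FlaggedValue:
    """Symmetric tolerance-band boundary recall.

    Mean of (fraction of predicted boundary pixels within ``tolerance_px``
    of the true boundary) and the converse, with Euclidean distances taken
    from distance transforms.
    """
    bp = boundary_pixels(pred)
    bt = boundary_pixels(truth)
    if not bp.any() or not bt.any():
        return FlaggedValue(float("nan"), defined=False)
    # distance from every pixel to the nearest boundary pixel of the other set
    d_to_truth = ndimage.distance_transform_edt(~bt)
    d_to_pred = ndimage.distance_transform_edt(~bp)
    frac_pred = float(np.mean(d_to_truth[bp] <= tolerance_px))
    frac_truth = float(np.mean(d_to_pred[bt] <= tolerance_px))
    return FlaggedValue(0.5 * (frac_pred + frac_truth))


def hausdorff(pred_points: np.ndarray, truth_points: np.ndarray) -> float:
    """Hausdorff distance between two boundary point sets.

    ``max(sup_p inf_g d(p, g), sup_g inf_p d(g, p))`` with Euclidean ``d``.
    Point sets are ``(n, 2)`` arrays of (row, col) coordinates.
    """
    p = np.atleast_2d(np.asarray(pred_points, dtype=float))
    g = np.atleast_2d(np.asarray(truth_points, dtype=float))
    if p.size == 0 or g.size == 0:
        raise ValueError("hausdorff distance of an empty point set is undefined")
    d2 = ((p[:, None, :] - g[None, :, :]) ** 2).sum(axis=2)
    forward = np.sqrt(d2.min(axis=1)).max()
    backward = np.sqrt(d2.min(axis=0)).max()
    return float(max(forward, backward))


def hausdorff_masks(pred: np.ndarray, truth: np.ndarray) -> FlaggedValue:
    """Hausdorff distance between the boundaries of two masks.

    Uses distance transforms (exact on the pixel grid), which is fast for
    large rasters; equivalent to :func:`hausdorff` on the extracted
    boundary point sets.
    """
    bp = boundary_pixels(pred)
    bt = boundary_pixels(truth)
    if not bp.any() or not bt.any():
        return FlaggedValue(float("nan"), defined=False)
    d_to_truth = ndimage.distance_transform_edt(~bt)
    d_to_pred = ndimage.distance_transform_edt(~bp)
    return FlaggedValue(float(max(d_to_truth[bp].max(), d_to_pred[bt].max())))


# ---------------------------------------------------------------------------
# structural metrics


def ssim(x: np.ndarray, y: np.ndarray, config: MetricConfig | None = None) -> float:
    """Mean local SSIM between two grayscale rasters in [0, 1].

    Local means/variances/covariance over a uniform square window
    (side ``config.ssim_window``), combined as

        (2 mx my + C1)(2 sxy + C2) / ((mx^2 + my^2 + C1)(sx^2 + sy^2 + C2))

    and averaged over all window positions.  Symmetric, and exactly 1 when
    the inputs are identical.
    """
    cfg = config or MetricConfig()
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("ssim inputs must share a shape")
    if xa.ndim != 2:
        raise ValueError("ssim expects grayscale rasters")
    L = 1.0
    c1 = (cfg.ssim_k1 * L) ** 2
    c2 = (cfg.ssim_k2 * L) ** 2
    w = cfg.ssim_window

    def local_mean(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=w, mode="reflect")

    mx = local_mean(xa)
    my = local_mean(ya)
    sxx = local_mean(xa * xa) - mx * mx
    syy = local_mean(ya * ya) - my * my
    sxy = local_mean(xa * ya) - mx * my
    num = (2 * mx * my + c1) * (2 * sxy + c2)
    den = (mx * mx + my * my + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def pcp(
    pred: np.ndarray, truth: np.ndarray, config: MetricConfig | None = None
) -> float:
    """Proportion of correct patches, as a percentage.

    The raster is tiled by square patches of side ``pcp_patch_size`` (the
    partial patches at the right/bottom edge are kept as smaller tiles).
    A patch is correct when its patch-level IoU reaches
    ``pcp_iou_threshold``; a patch empty in both masks is trivially
    correct.  Returns ``100 * correct / total``.
    """
    cfg = config or MetricConfig()
    p = _as_bool_mask(pred)
    t = _as_bool_mask(truth)
    if p.shape != t.shape:
        raise ValueError("pcp inputs must share a shape")
    s = cfg.pcp_patch_size
    h, w = p.shape
    n_correct = 0
    n_total = 0
    for r0 in range(0, h, s):
        for c0 in range(0, w, s):
            pp = p[r0 : r0 + s, c0 : c0 + s]
            tt = t[r0 : r0 + s, c0 : c0 + s]
            inter = np.count_nonzero(pp & tt)
            union = np.count_nonzero(pp | tt)
            n_total += 1
            if union == 0:
                n_correct += 1
            elif inter / union >= cfg.pcp_iou_threshold:
                n_correct += 1
    if n_total == 0:
        raise ValueError("pcp has no patches to evaluate")
    return 100.0 * n_correct / n_total


# ---------------------------------------------------------------------------
# morphological descriptors


def _rec601_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


def _principal_axis_angle(coords: np.ndarray) -> float:
    """Orientation (radians) of the major principal axis of a point cloud."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / max(len(c) - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    major = vecs[:, int(np.argmax(vals))]
    return math.atan2(major[1], major[0])


def _reflection_overlap(coords: np.ndarray, axis_angle: float) -> float:
    """Fraction of mask pixels that land on mask pixels after reflection
    about the axis through the centroid at ``axis_angle``."""
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    ca, sa = math.cos(-axis_angle), math.sin(-axis_angle)
    rot = rel @ np.array([[ca, -sa], [sa, ca]]).T
    reflected = rot * np.array([1.0, -1.0])  # flip across the axis
    ca, sa = math.cos(axis_angle), math.sin(axis_angle)
    back = reflected @ np.array([[ca, -sa], [sa, ca]]).T + centroid
    original = {(int(r), int(c)) for r, c in np.round(coords).astype(int)}
    hits = sum(
        (int(r), int(c)) in original for r, c in np.round(back).astype(int)
    )
    return hits / len(coords)


def _boundary_curvature_variance(mask: np.ndarray, n_points: int = 64) -> float:
    padded = np.pad(_as_bool_mask(mask).astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    contour = max(contours, key=len)
    # arc-length resample to n_points
    seg = np.diff(contour, axis=0)
    seglen = np.sqrt((seg**2).sum(axis=1))
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        return 0.0
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    rows = np.interp(targets, arclen, contour[:, 0])
    cols = np.interp(targets, arclen, contour[:, 1])
    x = np.stack([rows, cols], axis=1)
    # circular central differences
    d1 = (np.roll(x, -1, axis=0) - np.roll(x, 1, axis=0)) / 2.0
    d2 = np.roll(x, -1, axis=0) - 2 * x + np.roll(x, 1, axis=0)
    speed2 = (d1**2).sum(axis=1)
    cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    kappa = cross / np.maximum(speed2, 1e-12) ** 1.5
    return float(np.var(kappa))


def _masked_cooccurrence_stats(
    gray: np.ndarray, mask: np.ndarray, levels: int = 16
) -> tuple[float, float]:
    """(contrast, entropy) of the quantized grayscale inside ``mask``.

    Contrast is the gray-level co-occurrence contrast, offset 1, averaged
    over the 4 directions, counting only pixel pairs that both lie inside
    the mask.  Entropy is the Shannon entropy (bits) of the ``levels``-bin
    intensity histogram inside the mask.
    """
    m = _as_bool_mask(mask)
    vals = gray[m]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        return 0.0, 0.0
    q = np.zeros(gray.shape, dtype=np.int64)
    q[m] = np.minimum(
        ((gray[m] - lo) / (hi - lo) * levels).astype(np.int64), levels - 1
    )
    offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
    contrasts = []
    for dr, dc in offsets:
        a_sl = (slice(max(0, -dr), gray.shape[0] - max(0, dr)),
                slice(max(0, -dc), gray.shape[1] - max(0, dc)))
        b_sl = (slice(max(0, dr), gray.shape[0] + min(0, dr) or None),
                slice(max(0, dc), gray.shape[1] + min(0, dc) or None))
        ma = m[a_sl]
        mb = m[b_sl]
        both = ma & mb
        if not both.any():
            contrasts.append(0.0)
            continue
        qa = q[a_sl][both]
        qb = q[b_sl][both]
        diffs = (qa - qb).astype(float)
        contrasts.append(float(np.mean(diffs**2)))
    hist = np.bincount(q[m], minlength=levels).astype(float)
    p = hist / hist.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return float(np.mean(contrasts)), entropy


def morph_descriptors(
    image: np.ndarray, mask: np.ndarray, levels: int = 16
) -> MorphDescriptorSet:
    """Compute the lesion descriptor set for one image/mask pair.

    asymmetry_index
        ``1 - max`` over the two principal axes of the fraction of mask
        pixels that coincide with the mask reflected about that axis.
    border_irregularity
        Compactness ``P**2 / (4 pi A)`` (1 for an ideal disc).
    area_perimeter_ratio
        ``A / P`` in pixels.
    boundary_smoothness
        ``1 / (1 + var(curvature))`` on a 64-point arc-length-resampled
        contour.
    color_variance
        Mean per-channel intensity variance inside the mask.
    texture_contrast, texture_entropy
        Co-occurrence contrast and histogram entropy of the 16-level
        quantized grayscale inside the mask.
    """
    m = _as_bool_mask(mask)
    area = int(np.count_nonzero(m))
    if area < 5:
        nan = float("nan")
        return MorphDescriptorSet(nan, nan, nan, nan, nan, nan, nan, defined=False)
    img = np.asarray(image, dtype=float)
    coords = np.argwhere(m).astype(float)

    angle = _principal_axis_angle(coords)
    overlap_major = _reflection_overlap(coords, angle)
    overlap_minor = _reflection_overlap(coords, angle + math.pi / 2)
    asymmetry = float(np.clip(1.0 - max(overlap_major, overlap_minor), 0.0, 1.0))

    perim = float(measure.perimeter_crofton(m, directions=4))
    compactness = perim**2 / (4.0 * math.pi * area)
    ap_ratio = area / max(perim, 1e-12)
    smoothness = 1.0 / (1.0 + _boundary_curvature_variance(m))

    if img.ndim == 3:
        color_var = float(np.mean([img[..., c][m].var() for c in range(img.shape[2])]))
    else:
        color_var = float(img[m].var())
    gray = _rec601_gray(img)
    contrast, entropy = _masked_cooccurrence_stats(gray, m, levels=levels)
    return MorphDescriptorSet(
        asymmetry_index=asymmetry,
        border_irregularity=float(compactness),
        area_perimeter_ratio=float(ap_ratio),
        boundary_smoothness=float(smoothness),
        color_variance=color_var,
        texture_contrast=contrast,
        texture_entropy=entropy,
    )
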