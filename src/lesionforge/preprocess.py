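"""Six-stage dermoscopic image enhancement chain.

Stages: per-channel statistical normalization, CLAHE contrast enhancement
with Otsu lesion localization, lesion-centric crop/resize, morphological
enhancement (Laplacian + morphological gradient), Shades-of-Gray colour
constancy, and black-hat hair detection with diffusion inpainting.

The default stage order runs the illuminant/artifact corrections
(Shades of Gray, hair removal) before the statistics-based normalization,
so the channel statistics are estimated on artifact-free pixels; the
literal normalize-first order is also available via ``PreprocessConfig``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology, transform

__all__ = [
    "PreprocessConfig",
    "BoundingBox",
    "rec601_gray",
    "normalize_channels",
    "otsu_threshold",
    "illumination_localize",
    "crop_resize",
    "morphology_enhance",
    "shades_of_gray",
    "hair_remove",
    "run_pipeline",
    "PipelineResult",
]

_DEFAULT_ORDER = (
    "shades_of_gray",
    "hair_remove",
    "normalize_channels",
    "illumination_localize",
    "crop_resize",
    "morphology_enhance",
)


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``minkowski_p`` is the Shades-of-Gray norm order (6 by default; 4 is
    the common alternative).  ``target_size`` is the output raster size
    after the lesion-centric crop.  ``stage_order`` lists the enabled
    stages in execution order; removing a name disables that stage.
    """

    clahe_clip: float = 0.01
    clahe_tile: int = 8
    minkowski_p: float = 6.0
    target_size: tuple[int, int] = (224, 224)
    crop_margin_frac: float = 0.1
    hair_blackhat_len: int = 9
    hair_threshold: float = 0.06
    epsilon: float = 1e-8
    stage_order: tuple[str, ...] = _DEFAULT_ORDER

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0 <= self.crop_margin_frac <= 0.5):
            raise ValueError("crop_margin_frac must lie in [0, 0.5]")
        if not (0 < self.hair_threshold < 1):
            raise ValueError("hair_threshold must lie in (0, 1)")
        unknown = set(self.stage_order) - set(_DEFAULT_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self):
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("bounding box must have positive extent")

    def clamped(self, shape: tuple[int, int]) -> "BoundingBox":
        h, w = shape
        return BoundingBox(
            max(0, self.row0), max(0, self.col0), min(h, self.row1), min(w, self.col1)
        )


def rec601_gray(image: np.ndarray) -> np.ndarray:
    """Rec.601 luma: 0.299 R + 0.587 G + 0.114 B (identity on grayscale)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


# ---------------------------------------------------------------------------
# stage 1: channel normalization


def normalize_channels(
    image: np.ndarray, epsilon: float = 1e-8, rescale: bool = False
) -> np.ndarray:
    """Standardize each channel to zero mean, unit population SD.

    A constant channel maps to all zeros through the epsilon guard.  With
    ``rescale=True`` the standardized raster is min-max rescaled to [0, 1]
    globally (across channels), which is how the pipeline consumes it.
    """
    img = np.asarray(image, dtype=float)
    chans = img if img.ndim == 3 else img[..., None]
    mu = chans.mean(axis=(0, 1), keepdims=True)
    sigma = chans.std(axis=(0, 1), keepdims=True)
    # a (numerically) constant channel maps to exact zeros
    out = np.where(sigma > epsilon, (chans - mu) / (sigma + epsilon), 0.0)
    if rescale:
        lo, hi = out.min(), out.max()
        out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    if img.ndim == 2:
        out = out[..., 0]
    return out


# ---------------------------------------------------------------------------
# stage 2: CLAHE + Otsu localization


def otsu_threshold(gray: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing the between-class criterion w1*m1^2 + w2*m2^2.

    Equivalent to the classical between-class-variance maximization (the
    two differ by the constant global mean squared).  Candidate thresholds
    are the histogram bin edges; ties break toward the lower threshold.
    Returns a value on the intensity scale of ``gray``.
    """
    g = np.asarray(gray, dtype=float).ravel()
    lo, hi = float(g.min()), float(g.max())
    if hi - lo < 1e-12:
        raise ValueError("constant image: Otsu threshold undefined")
    hist, edges = np.histogram(g, bins=nbins, range=(lo, hi))
    p = hist.astype(float) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w1 = np.cumsum(p)
    w2 = 1.0 - w1
    cum_mean = np.cumsum(p * centers)
    total_mean = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = np.where(w1 > 0, cum_mean / w1, 0.0)
        mu2 = np.where(w2 > 0, (total_mean - cum_mean) / w2, 0.0)
    crit = w1 * mu1**2 + w2 * mu2**2
    crit = crit[:-1]  # splitting above the top bin leaves one empty class
    # ties (within float noise) break toward the lower threshold
    peak = crit.max()
    best = int(np.argmax(crit >= peak - 1e-10 * max(abs(peak), 1.0)))
    return float(edges[best + 1])


@dataclass
class LocalizationResult:
    enhanced: np.ndarray
    mask: np.ndarray
    threshold: float
    degenerate: bool = False
    polarity_flipped: bool = False


def illumination_localize(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> LocalizationResult:
    """CLAHE-enhance the image and localize the lesion by Otsu thresholding.

    The rough lesion mask selects the darker Otsu class (dermoscopic
    lesions are typically darker than skin); if that covers more than half
    of the frame the polarity is flipped.  A constant image yields the
    mid-range threshold, an empty mask and ``degenerate=True``.
    """
    cfg = config or PreprocessConfig()
    img = np.asarray(image, dtype=float)
    if img.max() - img.min() < 1e-12:
        return LocalizationResult(
            enhanced=img.copy(),
            mask=np.zeros(img.shape[:2], dtype=np.uint8),
            threshold=0.5 * (float(img.min()) + float(img.max())) if img.size else 0.5,
            degenerate=True,
        )
    enhanced = exposure.equalize_adapthist(
        np.clip(img, 0.0, 1.0),
        kernel_size=cfg.clahe_tile,
        clip_limit=cfg.clahe_clip,
    )
    gray = rec601_gray(enhanced)
    threshold = otsu_threshold(gray)
    mask = (gray < threshold).astype(np.uint8)
    flipped = False
    if mask.mean() > 0.5:
        mask = 1 - mask
        flipped = True
    return LocalizationResult(enhanced, mask, threshold, polarity_flipped=flipped)


# ---------------------------------------------------------------------------
# stage 3: lesion-centric crop and resize


def mask_bbox(mask: np.ndarray) -> BoundingBox:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r = np.where(rows)[0]
    c = np.where(cols)[0]
    return BoundingBox(int(r[0]), int(c[0]), int(r[-1]) + 1, int(c[-1]) + 1)


def crop_resize(
    image: np.ndarray, mask: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Crop around the mask bounding box (with margin) and resize.

    The box is expanded by ``crop_margin_frac`` of its size on each side
    and clamped to the canvas.  The image is resized bilinearly, the mask
    by nearest neighbour so it stays binary.  An empty mask falls back to
    the full frame.
    """
    cfg = config or PreprocessConfig()
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask)
    h, w = m.shape
    if m.any():
        box = mask_bbox(m)
        mr = int(round(cfg.crop_margin_frac * (box.row1 - box.row0)))
        mc = int(round(cfg.crop_margin_frac * (box.col1 - box.col0)))
        box = BoundingBox(box.row0 - mr, box.col0 - mc, box.row1 + mr, box.col1 + mc)
        box = box.clamped((h, w))
    else:
        box = BoundingBox(0, 0, h, w)
    img_c = img[box.row0 : box.row1, box.col0 : box.col1]
    m_c = m[box.row0 : box.row1, box.col0 : box.col1]
    th, tw = cfg.target_size
    img_r = transform.resize(
        img_c, (th, tw), order=1, anti_aliasing=False, preserve_range=True
    )
    m_r = transform.resize(
        m_c.astype(float), (th, tw), order=0, anti_aliasing=False, preserve_range=True
    )
    return img_r, (m_r > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# stage 4: morphological enhancement

_LAPLACIAN_STENCIL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


def morphology_enhance(
    image: np.ndarray, selem_radius: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """4-neighbour Laplacian and disc morphological gradient of the luma.

    Returns the raw (signed) Laplacian and the non-negative gradient
    ``dilate - erode``; no clipping is applied here, the composite used by
    the pipeline clips when it attaches these as enhancement channels.
    """
    gray = rec601_gray(image)
    laplacian = ndimage.convolve(gray, _LAPLACIAN_STENCIL, mode="reflect")
    selem = morphology.disk(selem_radius)
    gradient = ndimage.grey_dilation(gray, footprint=selem) - ndimage.grey_erosion(
        gray, footprint=selem
    )
    return laplacian, gradient


# ---------------------------------------------------------------------------
# stage 5: Shades-of-Gray colour constancy


def shades_of_gray(
    image: np.ndarray, p: float = 6.0, epsilon: float = 1e-8
) -> np.ndarray:
    """Minkowski-norm colour constancy.

    Per channel, the illuminant estimate is ``E_c = (mean |I_c|^p)^(1/p)``;
    the image is divided channel-wise by ``E_c`` and then globally rescaled
    so its maximum is 1.  ``p -> inf`` recovers the white-patch (max-RGB)
    estimate; ``p = 1`` is the gray-world assumption.  Idempotent up to the
    global scale.
    """
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3:
        raise ValueError("shades_of_gray expects an RGB image")
    e = np.power(np.mean(np.abs(img) ** p, axis=(0, 1)), 1.0 / p)
    e = np.maximum(e, epsilon)
    out = img / e
    peak = out.max()
    if peak > 0:
        out = out / peak
    return out


# ---------------------------------------------------------------------------
# stage 6: hair removal (black-hat detection + diffusion inpainting)


def _line_selems(length: int) -> list[np.ndarray]:
    """Linear structuring elements at 0, 45, 90, 135 degrees."""
    horiz = np.ones((1, length), dtype=bool)
    vert = np.ones((length, 1), dtype=bool)
    diag = np.eye(length, dtype=bool)
    anti = np.fliplr(diag)
    return [horiz, vert, diag, anti]


def detect_hair(gray: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Union of thresholded black-hat responses over 4 line orientations.

    Dark lesion rims also trigger the black-hat (their chords are locally
    shorter than the structuring line), so detected components are kept
    only when their spatial extent exceeds 1.5x the line length — a rim
    artifact's extent is bounded by the line length itself, while real
    hairs run much longer.  The surviving mask is dilated by one pixel.
    """
    cfg = config or PreprocessConfig()
    mask = np.zeros(gray.shape, dtype=bool)
    for selem in _line_selems(cfg.hair_blackhat_len):
        closed = ndimage.grey_closing(gray, footprint=selem, mode="reflect")
        blackhat = closed - gray
        mask |= blackhat > cfg.hair_threshold
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    min_extent = 1.5 * cfg.hair_blackhat_len
    keep = np.zeros(n + 1, dtype=bool)
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        extent = max(sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
        keep[idx] = extent >= min_extent
    mask = keep[labels]
    if mask.any():
        mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))
    return mask


def diffusion_inpaint(
    image: np.ndarray, hole: np.ndarray, tol: float = 1e-4, max_iter: int = 500
) -> np.ndarray:
    """Fill ``hole`` pixels by iterative 4-neighbour mean diffusion.

    Pixels outside the hole are never modified.  Iterates until the
    largest per-pixel change drops below ``tol`` or ``max_iter`` sweeps.
    """
    img = np.asarray(image, dtype=float).copy()
    h = np.asarray(hole, dtype=bool)
    if not h.any():
        return img
    chans = img if img.ndim == 3 else img[..., None]
    kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float) / 4.0
    for c in range(chans.shape[2]):
        plane = chans[..., c]
        plane[h] = plane[~h].mean() if (~h).any() else 0.5
        for _ in range(max_iter):
            smoothed = ndimage.convolve(plane, kernel, mode="reflect")
            delta = np.abs(smoothed[h] - plane[h]).max()
            plane[h] = smoothed[h]
            if delta < tol:
                break
        chans[..., c] = plane
    return chans[..., 0] if image.ndim == 2 else chans


def hair_remove(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detect dark linear hair artifacts and inpaint them.

    Returns the restored image and the (dilated) hair mask.  With an
    empty hair mask the output equals the input exactly; pixels outside
    the mask are never altered.
    """
    cfg = config or PreprocessConfig()
    img = np.asarray(image, dtype=float)
    gray = rec601_gray(img)
    hair = detect_hair(gray, cfg)
    if not hair.any():
        return img.copy(), hair.astype(np.uint8)
    restored = diffusion_inpaint(img, hair)
    return restored, hair.astype(np.uint8)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineResult:
    image: np.ndarray
    mask: np.ndarray
    log: list[dict] = field(default_factory=list)
    laplacian: np.ndarray | None = None
    gradient: np.ndarray | None = None
    hair_mask: np.ndarray | None = None
    threshold: float | None = None


def run_pipeline(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> PipelineResult:
    """Run the enabled stages of the enhancement chain in order.

    With every stage disabled (empty ``stage_order``) the pipeline is the
    identity.  The provenance log records each executed stage with its
    parameters.  The morphology-enhancement rasters are attached to the
    result, not substituted for the image.
    """
    cfg = config or PreprocessConfig()
    img = np.asarray(image, dtype=float)
    result = PipelineResult(image=img.copy(), mask=np.zeros(img.shape[:2], dtype=np.uint8))

    for stage in cfg.stage_order:
        if stage == "shades_of_gray":
            result.image = shades_of_gray(result.image, cfg.minkowski_p, cfg.epsilon)
            result.log.append({"stage": stage, "p": cfg.minkowski_p})
        elif stage == "hair_remove":
            result.image, result.hair_mask = hair_remove(result.image, cfg)
            result.log.append(
                {
                    "stage": stage,
                    "length": cfg.hair_blackhat_len,
                    "threshold": cfg.hair_threshold,
                    "hair_px": int(result.hair_mask.sum()),
                }
            )
        elif stage == "normalize_channels":
            result.image = normalize_channels(result.image, cfg.epsilon, rescale=True)
            result.log.append({"stage": stage, "epsilon": cfg.epsilon})
        elif stage == "illumination_localize":
            loc = illumination_localize(result.image, cfg)
            result.image, result.mask = loc.enhanced, loc.mask
            result.threshold = loc.threshold
            result.log.append(
                {
                    "stage": stage,
                    "clip": cfg.clahe_clip,
                    "tile": cfg.clahe_tile,
                    "threshold": loc.threshold,
                    "degenerate": loc.degenerate,
                }
            )
        elif stage == "crop_resize":
            result.image, result.mask = crop_resize(result.image, result.mask, cfg)
            result.log.append(
                {
                    "stage": stage,
                    "target": list(cfg.target_size),
                    "margin": cfg.crop_margin_frac,
                }
            )
        elif stage == "morphology_enhance":
            result.laplacian, result.gradient = morphology_enhance(result.image)
            result.log.append({"stage": stage})
    result.image = np.clip(result.image, 0.0, 1.0)
    return result
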