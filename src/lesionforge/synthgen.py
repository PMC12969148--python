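"""Seeded generator of synthetic dermoscopic scenes.

Produces lesion masks with controllable asymmetry and border irregularity,
pigmented lesion renderings on a skin-toned background, hair overlays,
illumination gradients and colour casts, and imbalanced class manifests —
so the whole pipeline is testable without downloading any dataset.

Every output is a pure function of its (spec, seed) arguments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "LesionSpec",
    "SceneSpec",
    "DatasetManifest",
    "CanvasTooSmallError",
    "generate_lesion",
    "render_scene",
    "generate_dataset",
]

_MARGIN_PX = 2
_SKIN_RGB = np.array([0.82, 0.62, 0.54])


class CanvasTooSmallError(ValueError):
    """The requested lesion cannot fit in the canvas with a 2 px margin."""


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one synthetic lesion.

    ``asymmetry`` and ``border_irregularity`` are in [0, 1] and control,
    independently and monotonically, the reflection-asymmetry and the
    radial-noise amplitude of the boundary.  ``pigment_palette`` is a list
    of RGB triples blended across the lesion interior.
    """

    class_label: str = "benign"
    radius_px: float = 20.0
    asymmetry: float = 0.0
    border_irregularity: float = 0.0
    n_boundary_harmonics: int = 6
    pigment_palette: tuple[tuple[float, float, float], ...] = (
        (0.45, 0.28, 0.20),
        (0.30, 0.18, 0.14),
    )
    texture_noise_sd: float = 0.02

    def __post_init__(self):
        if self.radius_px < 4:
            raise ValueError("radius_px must be >= 4")
        if not (0 <= self.asymmetry <= 1 and 0 <= self.border_irregularity <= 1):
            raise ValueError("asymmetry and border_irregularity must lie in [0, 1]")
        if self.n_boundary_harmonics < 1:
            raise ValueError("n_boundary_harmonics must be positive")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    """Corruption operators applied on top of a clean lesion rendering."""

    canvas_size: tuple[int, int] = (96, 96)
    hair_count: int = 0
    hair_darkness: float = 0.7
    illumination_gradient: float = 0.0
    color_cast: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if any(g <= 0 for g in self.color_cast):
            raise ValueError("color cast gains must be positive")
        if self.hair_count < 0:
            raise ValueError("hair_count must be non-negative")


@dataclass
class DatasetManifest:
    """Rows of (image path, mask path, class label) plus derived counts."""

    records: list[dict] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec["label"]] = counts.get(rec["label"], 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        paths = [r["image"] for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest image paths must be unique")

    _BASE_COLUMNS = ("image", "mask", "label")

    def to_csv(self, path: str | Path) -> None:
        self.validate()
        extra = sorted(
            {k for r in self.records for k in r} - set(self._BASE_COLUMNS)
        )
        cols = list(self._BASE_COLUMNS) + extra
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for rec in self.records:
                writer.writerow({c: rec.get(c, "") for c in cols})

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        with open(path, newline="") as fh:
            records = [dict(row) for row in csv.DictReader(fh)]
        return cls(records=records)


# ---------------------------------------------------------------------------
# lesion geometry


def _boundary_radii(spec: LesionSpec, thetas: np.ndarray, rng) -> np.ndarray:
    """Radial boundary function r(theta) with seeded harmonic noise."""
    r = np.ones_like(thetas)
    if spec.border_irregularity > 0:
        total = np.zeros_like(thetas)
        weight = 0.0
        for h in range(2, 2 + spec.n_boundary_harmonics):
            amp = 1.0 / h
            phase = rng.uniform(0, 2 * np.pi)
            total += amp * np.cos(h * thetas + phase)
            weight += amp
        # bounded so r stays positive: peak deformation <= 0.45 * irregularity
        total *= 0.45 * spec.border_irregularity / weight
        r = r + total
    return spec.radius_px * np.clip(r, 0.2, None)


def _lesion_polygon(spec: LesionSpec, rng) -> np.ndarray:
    thetas = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    radii = _boundary_radii(spec, thetas, rng)
    x = radii * np.cos(thetas)
    y = radii * np.sin(thetas)
    # asymmetry: anisotropic axis scaling then shear, about the centroid
    a = spec.asymmetry
    x = x * (1.0 + 0.45 * a)
    y = y * (1.0 - 0.25 * a)
    x = x + 0.5 * a * y
    return np.stack([y, x], axis=1)  # (row, col) offsets


def generate_lesion(
    spec: LesionSpec, seed: int, canvas_size: tuple[int, int] = (96, 96)
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one lesion: returns (RGB image in [0,1], {0,1} mask).

    The mask is a single 4-connected component fitting inside the canvas
    with at least a 2 px margin; with asymmetry and irregularity both 0
    it is a rasterized disc of ``radius_px``.
    """
    from skimage.draw import polygon as draw_polygon

    h, w = canvas_size
    rng = np.random.default_rng(seed)
    poly = _lesion_polygon(spec, rng)
    # recenter the polygon bounding box on the origin so the margin check
    # holds on both sides of the canvas
    poly = poly - (poly.max(axis=0) + poly.min(axis=0)) / 2.0
    extent_h = poly[:, 0].max() - poly[:, 0].min()
    extent_w = poly[:, 1].max() - poly[:, 1].min()
    if extent_h + 2 * _MARGIN_PX + 2 > h or extent_w + 2 * _MARGIN_PX + 2 > w:
        raise CanvasTooSmallError(
            f"canvas {canvas_size} too small for lesion extent "
            f"({extent_h:.0f} x {extent_w:.0f}) plus {_MARGIN_PX} px margin"
        )
    center = np.array([h / 2.0, w / 2.0])
    rows, cols = draw_polygon(poly[:, 0] + center[0], poly[:, 1] + center[1], shape=(h, w))
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[rows, cols] = 1
    # enforce a single 4-connected, hole-free component
    mask = ndimage.binary_fill_holes(mask).astype(np.uint8)
    labels, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        mask = (labels == 1 + int(np.argmax(sizes))).astype(np.uint8)
    if not mask.any():
        raise CanvasTooSmallError("lesion rasterized to an empty mask")

    image = _render_pigment(spec, mask, rng)
    return image, mask


def _render_pigment(spec: LesionSpec, mask: np.ndarray, rng) -> np.ndarray:
    """Paint the lesion interior with a blended pigment palette on skin."""
    h, w = mask.shape
    image = np.empty((h, w, 3))
    image[:] = _SKIN_RGB * (1.0 + rng.normal(0.0, 0.015, size=3))

    palette = np.asarray(spec.pigment_palette, dtype=float)
    # smooth seeded field selects the palette mixture per pixel
    field_ = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=6.0)
    fmin, fmax = field_.min(), field_.max()
    t = (field_ - fmin) / (fmax - fmin) if fmax > fmin else np.full((h, w), 0.5)
    # radial darkening toward the lesion core
    dist = ndimage.distance_transform_edt(mask)
    depth = dist / max(dist.max(), 1.0)

    idx = np.clip(t * (len(palette) - 1), 0, len(palette) - 1)
    lo = np.floor(idx).astype(int)
    hi = np.minimum(lo + 1, len(palette) - 1)
    frac = (idx - lo)[..., None]
    pigment = palette[lo] * (1 - frac) + palette[hi] * frac
    pigment = pigment * (1.0 - 0.25 * depth[..., None])

    inside = mask.astype(bool)
    image[inside] = pigment[inside]
    if spec.texture_noise_sd > 0:
        noise = rng.normal(0.0, spec.texture_noise_sd, size=(h, w, 3))
        image[inside] += noise[inside]
    return np.clip(image, 0.0, 1.0)


# ---------------------------------------------------------------------------
# scene corruption


def _bezier_points(p0, p1, p2, n: int = 200) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _draw_hairs(shape: tuple[int, int], count: int, rng) -> np.ndarray:
    """Raster of quadratic-Bezier hair strokes, width 1-3 px."""
    from skimage.draw import disk as draw_disk

    h, w = shape
    hair = np.zeros(shape, dtype=bool)
    for _ in range(count):
        p0 = rng.uniform([0, 0], [h, w])
        p2 = rng.uniform([0, 0], [h, w])
        mid = (p0 + p2) / 2 + rng.normal(0, 0.2 * max(h, w), size=2)
        thick = rng.uniform() < 0.25
        for r, c in _bezier_points(p0, mid, p2):
            if thick:
                rr, cc = draw_disk((r, c), radius=1.0, shape=shape)
                hair[rr, cc] = True
            else:
                ri, ci = int(round(r)), int(round(c))
                if 0 <= ri < h and 0 <= ci < w:
                    hair[ri, ci] = True
    return hair


class SceneRender(NamedTuple):
    """Output of :func:`render_scene`.

    ``image`` is the corrupted scene; ``clean`` is the hair-free ground
    truth (cast and illumination applied, no hair), kept for
    hair-removal restoration oracles.
    """

    image: np.ndarray
    mask: np.ndarray
    hair_mask: np.ndarray
    clean: np.ndarray


def render_scene(
    image: np.ndarray, mask: np.ndarray, scene: SceneSpec, seed: int
) -> SceneRender:
    """Apply colour cast, illumination gradient and hair to a clean scene.

    Returns ``(corrupted image, unchanged mask, hair mask, hair-free
    ground truth)``.  The lesion mask raster is never modified; with no
    hair, unit cast and zero gradient the output equals the input
    exactly.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask)
    if img.shape[:2] != m.shape:
        raise ValueError(f"image {img.shape[:2]} and mask {m.shape} shapes disagree")
    rng = np.random.default_rng(seed)
    out = img.copy()

    cast = np.asarray(scene.color_cast, dtype=float)
    if not np.allclose(cast, 1.0):
        out = np.clip(out * cast, 0.0, 1.0)

    g = scene.illumination_gradient
    if g > 0:
        h, w = m.shape
        angle = rng.uniform(0, 2 * np.pi)
        rr, cc = np.mgrid[0:h, 0:w]
        proj = (rr - h / 2) * np.sin(angle) + (cc - w / 2) * np.cos(angle)
        pmax = np.abs(proj).max()
        ramp = 1.0 + 0.5 * g * proj / max(pmax, 1.0)
        out = np.clip(out * ramp[..., None], 0.0, 1.0)

    clean = out.copy()
    hair = _draw_hairs(m.shape, scene.hair_count, rng)
    if hair.any():
        shade = 1.0 - 0.85 * scene.hair_darkness
        out[hair] = out[hair] * shade
    return SceneRender(image=out, mask=m, hair_mask=hair.astype(np.uint8), clean=clean)


# ---------------------------------------------------------------------------
# dataset generation


def _jitter_spec(spec: LesionSpec, rng) -> LesionSpec:
    """Per-sample variation around a class prior (radius, irregularity)."""
    return replace(
        spec,
        radius_px=float(spec.radius_px * rng.uniform(0.85, 1.15)),
        border_irregularity=float(
            np.clip(spec.border_irregularity + rng.uniform(-0.08, 0.08), 0, 1)
        ),
        asymmetry=float(np.clip(spec.asymmetry + rng.uniform(-0.05, 0.05), 0, 1)),
    )


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0,1] image (or {0,1} mask) as an 8-bit PNG."""
    arr = np.asarray(image)
    # {0,1} masks and [0,1] floats are both stored on the 8-bit scale
    arr = np.clip(arr.astype(float) * 255, 0, 255).round().astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG as float in [0,1] (masks come back as {0,1} floats)."""
    arr = iio.imread(Path(path)).astype(float) / 255.0
    return arr


def generate_dataset(
    class_counts: dict[str, int],
    lesion_priors: dict[str, LesionSpec],
    scene: SceneSpec,
    seed: int,
    out_dir: str | Path,
) -> DatasetManifest:
    """Write a seeded synthetic dataset and its manifest CSV.

    One PNG image and one PNG mask per record, exact per-class counts,
    reproducible under ``seed``.  The manifest (``manifest.csv`` with
    header ``image,mask,label``) is written into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = DatasetManifest()
    for label in sorted(class_counts):
        count = class_counts[label]
        if count < 0:
            raise ValueError("class counts must be non-negative")
        prior = lesion_priors[label]
        for i in range(count):
            sample_seed = int(rng.integers(0, 2**31 - 1))
            spec = _jitter_spec(prior, np.random.default_rng(sample_seed))
            image, mask = generate_lesion(spec, sample_seed, scene.canvas_size)
            corrupted, mask, _hair, _clean = render_scene(image, mask, scene, sample_seed)
            img_path = out / f"{label}_{i:04d}.png"
            mask_path = out / f"{label}_{i:04d}_mask.png"
            write_image(img_path, corrupted)
            write_image(mask_path, mask)
            manifest.records.append(
                {"image": str(img_path), "mask": str(mask_path), "label": label}
            )
    manifest.to_csv(out / "manifest.csv")
    return manifest
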