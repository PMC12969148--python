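"""Morphology-guided latent interpolation and synthesis for lesion augmentation.

The engine that rebalances an imbalanced lesion dataset by synthesizing
minority-class samples in a learned latent space:

1. lesion-masked encoding of images into latent vectors,
2. per-cluster latent statistics (mean, empirical covariance, whitener),
3. covariance-preserving interpolation between same-cluster latents
   (whitened spherical direction interpolation with geometric norm
   interpolation), alongside the plain linear interpolant it improves on,
4. decoding of interpolated latents back to images, with a composite
   adversarial/reconstruction/perceptual/shape loss available for the
   conditional-GAN synthesis path,
5. shape- and texture-constrained filtering (convexity defect score and
   boundary edge sharpness),
6. class-balance planning with an inflation cap, and
7. statistical plausibility and interpolation-fidelity reporting.

Why spherical interpolation preserves covariance: after whitening a
cluster, its members are isotropic with identity second moment.  A linear
blend ``a*u + (1-a)*v`` of independent isotropic vectors shrinks the
second moment by ``a**2 + (1-a)**2``; interpolating the *direction* on the
unit sphere and the *norm* geometrically keeps both marginals of the
whitened distribution intact, so un-whitening reproduces the cluster's
full covariance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import transform
from skimage.morphology import convex_hull_image

from . import metrics as _metrics
from .nn import MLPAutoencoder, RandomFeatureNet, TinyDiscriminator
from .preprocess import otsu_threshold, rec601_gray
from .synthgen import DatasetManifest, read_image, write_image

__all__ = [
    "AutoencoderSpec",
    "LatentCluster",
    "SynthesisCandidate",
    "FilterThresholds",
    "AugmentationPlan",
    "GanLossWeights",
    "CompositeLoss",
    "masked_feature_extract",
    "train_autoencoder",
    "save_autoencoder",
    "load_autoencoder",
    "linear_interpolate",
    "estimate_clusters",
    "riemannian_interpolate",
    "decode_to_image",
    "cgan_composite_loss",
    "convexity_defect_score",
    "edge_sharpness",
    "filter_candidates",
    "plan_balance",
    "augment_dataset",
    "plausibility_report",
    "interpolation_fidelity_compare",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class AutoencoderSpec:
    """Architecture and training parameters of the latent autoencoder.

    One convolution-free dense autoencoder over masked lesion images
    serves both as the lesion-aware feature extractor and as the
    latent-to-image decoder; ``input_size`` is the working resolution the
    masked images are resized to before flattening.
    """

    latent_dim: int = 8
    hidden_widths: tuple[int, ...] = (96,)
    input_size: tuple[int, int] = (32, 32)
    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 2e-3
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.epochs < 0 or self.batch_size <= 0 or self.learning_rate < 0:
            raise ValueError("training parameters must be positive")

    @property
    def input_dim(self) -> int:
        return self.input_size[0] * self.input_size[1] * 3


@dataclass
class LatentCluster:
    """A morphology cluster in latent space with cached whitening maps."""

    member_ids: list
    mean: np.ndarray
    covariance: np.ndarray
    whitener: np.ndarray  # Sigma^{-1/2}
    colorer: np.ndarray  # Sigma^{1/2}

    def __post_init__(self):
        ident = self.whitener @ self.covariance @ self.whitener.T
        if not np.allclose(ident, np.eye(len(self.mean)), atol=1e-6):
            raise ValueError("whitener does not whiten the covariance")


@dataclass
class SynthesisCandidate:
    """One synthesized sample with provenance and filter scores."""

    image: np.ndarray
    mask: np.ndarray
    latent: np.ndarray
    parents: tuple
    alpha: float
    cds: float | None = None
    edge_sharpness: float | None = None
    accepted: bool | None = None
    rejection_reason: str | None = None


@dataclass
class FilterThresholds:
    """Acceptance thresholds of the shape/texture filter.

    ``delta_c`` caps the convexity defect score (plausible lesions are
    near-convex; 0.1-0.3 is the customary range).  ``delta_s`` is the
    minimum boundary edge sharpness; by default it is set data-relative
    to the 25th percentile of the real lesions' sharpness.
    ``min_texture_entropy`` is an optional third criterion (minimum
    Shannon entropy of the masked intensity histogram, rejecting
    texture-less decodes); disabled by default.
    """

    delta_c: float = 0.2
    delta_s: float = 0.0
    min_texture_entropy: float | None = None

    def __post_init__(self):
        if self.delta_c < 0:
            raise ValueError("delta_c must be non-negative")
        if self.delta_s < 0:
            raise ValueError("delta_s must be non-negative")


@dataclass
class AugmentationPlan:
    """Per-class synthesis deficits toward a capped target count."""

    class_counts: dict[str, int]
    cap: int
    target: int = field(init=False)
    deficits: dict[str, int] = field(init=False)

    def __post_init__(self):
        if not self.class_counts:
            raise ValueError("at least one class is required")
        self.target = min(max(self.class_counts.values()), self.cap)
        self.deficits = {
            label: max(0, self.target - n) for label, n in self.class_counts.items()
        }


@dataclass
class GanLossWeights:
    """Weights of the composite synthesis loss terms."""

    lambda1: float = 1.0  # reconstruction (L1)
    lambda2: float = 0.1  # perceptual
    lambda3: float = 0.5  # segmentation-shape preservation


@dataclass
class CompositeLoss:
    total: float
    adv: float
    recon: float
    percep: float
    seg: float


# ---------------------------------------------------------------------------
# encoding


def _masked_input(
    image: np.ndarray, mask: np.ndarray, input_size: tuple[int, int]
) -> np.ndarray:
    masked = np.asarray(image, dtype=float) * np.asarray(mask, dtype=float)[..., None]
    resized = transform.resize(
        masked, input_size, order=1, anti_aliasing=False, preserve_range=True
    )
    return resized.ravel()


def masked_feature_extract(
    image: np.ndarray, mask: np.ndarray, encoder: MLPAutoencoder,
    input_size: tuple[int, int] = (32, 32),
) -> np.ndarray:
    """Encode the lesion-masked image (background pixels contribute zero).

    Two images differing only outside the mask encode identically.  An
    empty mask is accepted (all-zero input) but flagged with a warning.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask)
    if img.shape[:2] != m.shape:
        raise ValueError("image and mask shapes disagree")
    if not m.any():
        warnings.warn("masked_feature_extract called with an empty mask", stacklevel=2)
    return encoder.encode(_masked_input(img, m, input_size))


def save_autoencoder(
    path: str | Path,
    ae: MLPAutoencoder,
    spec: AutoencoderSpec,
    loss_curve: list[float],
) -> None:
    """Write a single-file checkpoint: JSON header + weight arrays."""
    header = {
        "latent_dim": spec.latent_dim,
        "hidden_widths": list(spec.hidden_widths),
        "input_size": list(spec.input_size),
        "epochs": spec.epochs,
        "batch_size": spec.batch_size,
        "learning_rate": spec.learning_rate,
        "seed": spec.seed,
        "loss_curve": [float(v) for v in loss_curve],
    }
    arrays = {f"w{i}": w for i, w in enumerate(ae.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(ae.biases)})
    np.savez(path, header=json.dumps(header), **arrays)


def load_autoencoder(
    path: str | Path,
) -> tuple[MLPAutoencoder, AutoencoderSpec, list[float]]:
    """Restore an autoencoder checkpoint written by :func:`save_autoencoder`."""
    data = np.load(path, allow_pickle=False)
    header = json.loads(str(data["header"]))
    spec = AutoencoderSpec(
        latent_dim=header["latent_dim"],
        hidden_widths=tuple(header["hidden_widths"]),
        input_size=tuple(header["input_size"]),
        epochs=header["epochs"],
        batch_size=header["batch_size"],
        learning_rate=header["learning_rate"],
        seed=header["seed"],
    )
    ae = MLPAutoencoder(
        input_dim=spec.input_dim,
        latent_dim=spec.latent_dim,
        hidden=spec.hidden_widths,
        seed=spec.seed,
    )
    ae.weights = [data[f"w{i}"] for i in range(len(ae.weights))]
    ae.biases = [data[f"b{i}"] for i in range(len(ae.biases))]
    return ae, spec, header["loss_curve"]


def train_autoencoder(
    samples: list[tuple[np.ndarray, np.ndarray]], spec: AutoencoderSpec
) -> tuple[MLPAutoencoder, MLPAutoencoder, list[float]]:
    """Train the dense autoencoder on lesion-masked images.

    Returns ``(encoder, decoder, per-epoch loss curve)``; encoder and
    decoder are the two halves of the same network.  Deterministic under
    ``spec.seed``.
    """
    if len(samples) < 8:
        raise ValueError("need at least 8 samples to train the autoencoder")
    x = np.stack([_masked_input(img, m, spec.input_size) for img, m in samples])
    ae = MLPAutoencoder(
        input_dim=spec.input_dim,
        latent_dim=spec.latent_dim,
        hidden=spec.hidden_widths,
        seed=spec.seed,
    )
    curve = ae.fit(
        x,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        lr=spec.learning_rate,
        seed=spec.seed,
    )
    return ae, ae, curve


# ---------------------------------------------------------------------------
# latent interpolation


def linear_interpolate(za: np.ndarray, zb: np.ndarray, alpha: float) -> np.ndarray:
    """Plain latent blend ``alpha * za + (1 - alpha) * zb``.

    Note the convention: ``alpha`` weights the *first* argument, so
    ``alpha = 1`` returns ``za``.
    """
    za = np.asarray(za, dtype=float)
    zb = np.asarray(zb, dtype=float)
    if za.shape != zb.shape:
        raise ValueError("latent dimensions disagree")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * za + (1.0 - alpha) * zb


def estimate_clusters(
    latents: np.ndarray,
    labels: np.ndarray | None = None,
    k_clusters: int | None = None,
    ridge: float = 1e-6,
    seed: int = 0,
) -> list[LatentCluster]:
    """Group latents and estimate per-cluster mean/covariance/whitener.

    Grouping is by the provided ``labels``, or by k-means with
    ``k_clusters`` groups, or (``k_clusters=None`` and no labels) by
    k-means with k chosen by silhouette score over k in {2, 3, 4}.  The
    covariance uses the unbiased (n-1) denominator and is ridge-
    regularized (``+ ridge * I``) whenever its smallest eigenvalue falls
    below ``ridge``.  Clusters of size < 2 are an error.
    """
    z = np.asarray(latents, dtype=float)
    if labels is None:
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        if k_clusters is None:
            best_k, best_score = 2, -np.inf
            for k in (2, 3, 4):
                if k >= len(z):
                    break
                km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(z)
                score = silhouette_score(z, km.labels_)
                if score > best_score:
                    best_k, best_score = k, score
            k_clusters = best_k
        labels = KMeans(n_clusters=k_clusters, n_init=4, random_state=seed).fit(z).labels_
    labels = np.asarray(labels)
    clusters = []
    for lab in sorted(set(labels.tolist())):
        idx = np.where(labels == lab)[0]
        if len(idx) < 2:
            raise ValueError(f"cluster {lab!r} has fewer than 2 members")
        member = z[idx]
        mu = member.mean(axis=0)
        cov = np.cov(member, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        cov = (cov + cov.T) / 2.0
        vals = np.linalg.eigvalsh(cov)
        if vals.min() < ridge:
            cov = cov + ridge * np.eye(cov.shape[0])
        evals, evecs = np.linalg.eigh(cov)
        whitener = evecs @ np.diag(evals**-0.5) @ evecs.T
        colorer = evecs @ np.diag(evals**0.5) @ evecs.T
        clusters.append(
            LatentCluster(
                member_ids=idx.tolist(),
                mean=mu,
                covariance=cov,
                whitener=whitener,
                colorer=colorer,
            )
        )
    return clusters


def riemannian_interpolate(
    cluster: LatentCluster, za: np.ndarray, zb: np.ndarray, alpha: float
) -> np.ndarray:
    """Covariance-preserving interpolation in a cluster's local geometry.

    Whiten both endpoints (``u = Sigma^{-1/2} (z - mu)``), spherically
    interpolate the unit directions at parameter ``1 - alpha`` (so
    ``alpha = 1`` returns ``za``, matching the linear convention),
    interpolate the norms geometrically (``|ua|**alpha * |ub|**(1-alpha)``)
    and un-whiten.  Endpoints are reproduced exactly; antipodal or
    zero-norm endpoints fall back to whitened linear interpolation.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    za = np.asarray(za, dtype=float)
    zb = np.asarray(zb, dtype=float)
    ua = cluster.whitener @ (za - cluster.mean)
    ub = cluster.whitener @ (zb - cluster.mean)
    na, nb = np.linalg.norm(ua), np.linalg.norm(ub)
    if na < 1e-12 or nb < 1e-12:
        u = alpha * ua + (1.0 - alpha) * ub  # degenerate endpoint fallback
        return cluster.mean + cluster.colorer @ u
    da, db = ua / na, ub / nb
    cosang = float(np.clip(da @ db, -1.0, 1.0))
    omega = np.arccos(cosang)
    if omega > np.pi - 1e-6:
        u = alpha * ua + (1.0 - alpha) * ub  # antipodal fallback
        return cluster.mean + cluster.colorer @ u
    t = 1.0 - alpha
    if omega < 1e-9:
        direction = da
    else:
        s = np.sin(omega)
        direction = (np.sin((1.0 - t) * omega) * da + np.sin(t * omega) * db) / s
    r = na**alpha * nb ** (1.0 - alpha)
    return cluster.mean + cluster.colorer @ (r * direction)


# ---------------------------------------------------------------------------
# synthesis


def decode_to_image(
    latent: np.ndarray, decoder: MLPAutoencoder, output_size: tuple[int, int] = (32, 32)
) -> np.ndarray:
    """Decode one latent vector to an RGB image in (0, 1)."""
    flat = decoder.decode(latent)
    return flat.reshape(output_size[0], output_size[1], 3)


def derive_mask(decoded: np.ndarray, border_frac: float = 0.1) -> np.ndarray:
    """Segment a decoded lesion image into a binary mask.

    Otsu threshold estimated on the central region (the outer
    ``border_frac`` ring is excluded from the statistics), darker side
    taken as lesion, largest connected component kept, holes filled.
    Returns an all-zero mask when the image is constant.
    """
    gray = rec601_gray(decoded)
    h, w = gray.shape
    b = max(1, int(round(border_frac * min(h, w))))
    central = gray[b : h - b, b : w - b]
    if central.max() - central.min() < 1e-6:
        return np.zeros((h, w), dtype=np.uint8)
    thr = otsu_threshold(central)
    mask = (gray < thr).astype(np.uint8)
    if mask.mean() > 0.5:
        mask = 1 - mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        mask = (labels == 1 + int(np.argmax(sizes))).astype(np.uint8)
    return ndimage.binary_fill_holes(mask).astype(np.uint8)


def cgan_composite_loss(
    real: np.ndarray,
    fake: np.ndarray,
    cond: int,
    weights: GanLossWeights,
    mask: np.ndarray,
    discriminator: TinyDiscriminator | None = None,
    feature_net: RandomFeatureNet | None = None,
) -> CompositeLoss:
    """Composite synthesis loss: adversarial + weighted auxiliary terms.

    ``recon`` is the mean absolute (L1) pixel difference; ``percep`` is
    the squared distance between fixed-random-convnet features; ``seg`` is
    ``1 - Dice`` between the Otsu-derived mask of the fake image and the
    provided lesion mask; ``adv`` is the conditional discriminator score
    term ``log D(real) + log(1 - D(fake))``.  The total is
    ``adv + l1*recon + l2*percep + l3*seg``.
    """
    real = np.asarray(real, dtype=float)
    fake = np.asarray(fake, dtype=float)
    if real.shape != fake.shape:
        raise ValueError("real and fake images must share a shape")
    disc = discriminator or TinyDiscriminator()
    feats = feature_net or disc.features
    recon = float(np.mean(np.abs(real - fake)))
    fr = feats(real)
    ff = feats(fake)
    percep = float(np.mean((fr - ff) ** 2))
    fake_mask = derive_mask(fake)
    seg = 1.0 - _metrics.dice(_metrics.confusion(fake_mask, mask))
    d_real = np.clip(disc.score(real, cond), 1e-12, 1 - 1e-12)
    d_fake = np.clip(disc.score(fake, cond), 1e-12, 1 - 1e-12)
    adv = float(np.log(d_real) + np.log(1.0 - d_fake))
    total = adv + weights.lambda1 * recon + weights.lambda2 * percep + weights.lambda3 * seg
    return CompositeLoss(total=total, adv=adv, recon=recon, percep=percep, seg=seg)


# ---------------------------------------------------------------------------
# shape/texture filters


def convexity_defect_score(mask: np.ndarray) -> float:
    """(hull area - mask area) / mask area, areas in pixel counts.

    Zero for convex shapes; grows with boundary spikes and concavities.
    The hull is computed on pixel centers and rasterized.
    """
    m = np.asarray(mask).astype(bool)
    area = int(np.count_nonzero(m))
    if area == 0:
        raise ValueError("convexity defect score of an empty mask is undefined")
    hull = convex_hull_image(m)
    hull_area = int(np.count_nonzero(hull))
    return (hull_area - area) / area


def edge_sharpness(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean gradient magnitude of the luma over the mask boundary.

    Gradients are central differences with reflective borders; the
    boundary is the 8-connected boundary pixel set of the mask.  Linear in
    the image intensity scale.
    """
    m = np.asarray(mask).astype(bool)
    boundary = _metrics.boundary_pixels(m)
    if not boundary.any():
        raise ValueError("edge sharpness of an empty boundary is undefined")
    gray = rec601_gray(image)
    padded = np.pad(gray, 1, mode="reflect")
    gr = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gc = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    magnitude = np.sqrt(gr**2 + gc**2)
    return float(magnitude[boundary].mean())


def filter_candidates(
    candidates: list[SynthesisCandidate], thresholds: FilterThresholds
) -> tuple[list[SynthesisCandidate], list[SynthesisCandidate]]:
    """Accept candidates with CDS <= delta_c and edge sharpness >= delta_s.

    Scores missing on a candidate are computed in place.  Rejected
    candidates carry the failed criterion; relaxing the thresholds never
    shrinks the accepted set.
    """
    accepted, rejected = [], []
    for cand in candidates:
        if cand.cds is None:
            cand.cds = convexity_defect_score(cand.mask)
        if cand.edge_sharpness is None:
            cand.edge_sharpness = edge_sharpness(cand.image, cand.mask)
        reasons = []
        if cand.cds > thresholds.delta_c:
            reasons.append("shape")
        if cand.edge_sharpness < thresholds.delta_s:
            reasons.append("sharpness")
        if thresholds.min_texture_entropy is not None:
            d = _metrics.morph_descriptors(cand.image, cand.mask)
            if not d.defined or d.texture_entropy < thresholds.min_texture_entropy:
                reasons.append("texture")
        cand.accepted = not reasons
        cand.rejection_reason = "+".join(reasons) if reasons else None
        (accepted if cand.accepted else rejected).append(cand)
    return accepted, rejected


def sharpness_percentile_threshold(
    samples: list[tuple[np.ndarray, np.ndarray]], percentile: float = 25.0
) -> float:
    """Data-relative delta_s: a percentile of real lesions' edge sharpness."""
    scores = [edge_sharpness(img, m) for img, m in samples]
    return float(np.percentile(scores, percentile))


# ---------------------------------------------------------------------------
# class balancing


def plan_balance(manifest: DatasetManifest, cap: int) -> AugmentationPlan:
    """Compute per-class deficits toward ``min(max class count, cap)``.

    Classes at or above the target get deficit 0; nothing is ever
    downsampled.
    """
    return AugmentationPlan(class_counts=manifest.class_counts, cap=cap)


def augment_dataset(
    manifest: DatasetManifest,
    encoder: MLPAutoencoder,
    decoder: MLPAutoencoder,
    plan: AugmentationPlan,
    thresholds: FilterThresholds,
    seed: int,
    out_dir: str | Path,
    max_attempts_per_sample: int = 20,
    alpha_range: tuple[float, float] = (0.25, 0.75),
    input_size: tuple[int, int] = (32, 32),
    ridge: float = 1e-4,
) -> tuple[DatasetManifest, list[SynthesisCandidate]]:
    """Fill per-class deficits with filtered synthetic samples.

    For each deficient class: encode its (training) lesions, estimate one
    latent cluster, repeatedly sample parent pairs and an interpolation
    ratio ``alpha ~ U(0.25, 0.75)``, interpolate on the cluster manifold,
    decode, derive a mask, composite the decoded lesion onto the class's
    mean background colour, and keep candidates passing the shape/
    sharpness filter until the deficit is filled or the attempt budget is
    exhausted (a partial fill emits a warning, never a silent shortfall).

    Original records are never modified; synthetic records carry
    ``synthetic=1`` plus parents, alpha and the filter scores.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    new_manifest = DatasetManifest(records=[dict(r) for r in manifest.records])
    all_candidates: list[SynthesisCandidate] = []

    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(manifest.records):
        by_class.setdefault(rec["label"], []).append(i)

    for label in sorted(plan.deficits):
        deficit = plan.deficits[label]
        if deficit == 0:
            continue
        idx = by_class.get(label, [])
        if len(idx) < 2:
            warnings.warn(f"class {label!r}: fewer than 2 parents, cannot augment")
            continue
        images, masks, latents = [], [], []
        for i in idx:
            rec = manifest.records[i]
            img = read_image(rec["image"])[..., :3]
            m = (read_image(rec["mask"]) > 0.5).astype(np.uint8)
            if m.ndim == 3:
                m = m[..., 0]
            images.append(img)
            masks.append(m)
            latents.append(masked_feature_extract(img, m, encoder, input_size))
        latents = np.asarray(latents)
        cluster = estimate_clusters(
            latents, labels=np.zeros(len(latents), dtype=int), ridge=ridge
        )[0]
        # mean background colour of the parents, for compositing
        bg_pixels = np.concatenate(
            [img[~m.astype(bool)].reshape(-1, 3) for img, m in zip(images, masks)]
        )
        bg_color = bg_pixels.mean(axis=0) if len(bg_pixels) else np.full(3, 0.8)

        produced = 0
        attempts = 0
        budget = deficit * max_attempts_per_sample
        while produced < deficit and attempts < budget:
            attempts += 1
            a_i, b_i = rng.choice(len(idx), size=2, replace=False)
            alpha = float(rng.uniform(*alpha_range))
            z = riemannian_interpolate(cluster, latents[a_i], latents[b_i], alpha)
            decoded = decode_to_image(z, decoder, input_size)
            m_syn = derive_mask(decoded)
            if m_syn.sum() < 5 or not _metrics.boundary_pixels(m_syn).any():
                continue
            composite = np.where(
                m_syn.astype(bool)[..., None], decoded, bg_color[None, None, :]
            )
            cand = SynthesisCandidate(
                image=composite,
                mask=m_syn,
                latent=z,
                parents=(idx[a_i], idx[b_i]),
                alpha=alpha,
            )
            acc, _rej = filter_candidates([cand], thresholds)
            all_candidates.append(cand)
            if not acc:
                continue
            img_path = out / f"syn_{label}_{produced:04d}.png"
            mask_path = out / f"syn_{label}_{produced:04d}_mask.png"
            write_image(img_path, cand.image)
            write_image(mask_path, cand.mask)
            new_manifest.records.append(
                {
                    "image": str(img_path),
                    "mask": str(mask_path),
                    "label": label,
                    "synthetic": "1",
                    "parent_a": str(cand.parents[0]),
                    "parent_b": str(cand.parents[1]),
                    "alpha": f"{cand.alpha:.4f}",
                    "cds": f"{cand.cds:.4f}",
                    "edge_sharpness": f"{cand.edge_sharpness:.4f}",
                }
            )
            produced += 1
        if produced < deficit:
            warnings.warn(
                f"class {label!r}: filled {produced}/{deficit} synthetic samples "
                f"within {budget} attempts"
            )
    return new_manifest, all_candidates


# ---------------------------------------------------------------------------
# reporting


_PLAUSIBILITY_DESCRIPTORS = (
    "asymmetry_index",
    "border_irregularity",
    "color_variance",
    "texture_contrast",
)

_FIDELITY_DESCRIPTORS = (
    "asymmetry_index",
    "border_irregularity",
    "area_perimeter_ratio",
    "boundary_smoothness",
)


def _descriptor_table(
    samples: list[tuple[np.ndarray, np.ndarray]], names: tuple[str, ...]
) -> pd.DataFrame:
    rows = []
    for img, m in samples:
        d = _metrics.morph_descriptors(img, m)
        if d.defined:
            rows.append({k: getattr(d, k) for k in names})
    return pd.DataFrame(rows)


def plausibility_report(
    real_samples: list[tuple[np.ndarray, np.ndarray]],
    synthetic_samples: list[tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Compare descriptor distributions of real and synthetic lesions.

    Per descriptor (asymmetry, border irregularity, colour variance,
    texture contrast): a two-sided Mann-Whitney rank test and the relative
    deviation of the synthetic mean from the real mean.  Large p-values
    indicate the synthesis does not measurably distort that descriptor.
    """
    if len(real_samples) < 5 or len(synthetic_samples) < 5:
        raise ValueError("need at least 5 samples per group")
    real = _descriptor_table(real_samples, _PLAUSIBILITY_DESCRIPTORS)
    syn = _descriptor_table(synthetic_samples, _PLAUSIBILITY_DESCRIPTORS)
    rows = []
    for name in _PLAUSIBILITY_DESCRIPTORS:
        a = real[name].to_numpy()
        b = syn[name].to_numpy()
        if np.ptp(np.concatenate([a, b])) < 1e-15:
            stat_val, p = 0.5 * len(a) * len(b), 1.0  # all tied
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat_val, p = float(res.statistic), float(res.pvalue)
        mean_r, mean_s = float(a.mean()), float(b.mean())
        rel_dev = abs(mean_s - mean_r) / (abs(mean_r) + 1e-12)
        rows.append(
            {
                "descriptor": name,
                "statistic": stat_val,
                "p_value": p,
                "mean_real": mean_r,
                "mean_synthetic": mean_s,
                "relative_deviation": rel_dev,
            }
        )
    return pd.DataFrame(rows)


def interpolation_fidelity_compare(
    cluster: LatentCluster,
    latents: np.ndarray,
    pairs: list[tuple[int, int]],
    decoder: MLPAutoencoder,
    real_samples: list[tuple[np.ndarray, np.ndarray]],
    alphas: tuple[float, ...] = (0.25, 0.5, 0.75),
    input_size: tuple[int, int] = (32, 32),
) -> pd.DataFrame:
    """Morphological deviation of both interpolation strategies.

    For every pair and ratio, synthesize via linear and via covariance-
    preserving interpolation, derive a mask, and measure each descriptor's
    absolute z-score against the real lesions' descriptor distribution.
    One output row per (pair, alpha, strategy); ``deviation`` is the mean
    |z| over the shape descriptors (asymmetry, border irregularity,
    area/perimeter ratio, boundary smoothness).
    """
    real = _descriptor_table(real_samples, _FIDELITY_DESCRIPTORS)
    mu = real.mean()
    sd = real.std(ddof=1).replace(0.0, np.nan)
    rows = []
    strategies = {
        "linear": lambda za, zb, a: linear_interpolate(za, zb, a),
        "riemannian": lambda za, zb, a: riemannian_interpolate(cluster, za, zb, a),
    }
    for pa, pb in pairs:
        for alpha in alphas:
            for name, fn in strategies.items():
                z = fn(latents[pa], latents[pb], alpha)
                decoded = decode_to_image(z, decoder, input_size)
                m = derive_mask(decoded)
                if m.sum() < 5:
                    deviation = np.nan
                else:
                    d = _metrics.morph_descriptors(decoded, m)
                    zs = [
                        abs((getattr(d, k) - mu[k]) / sd[k])
                        for k in _FIDELITY_DESCRIPTORS
                        if np.isfinite(sd[k])
                    ]
                    deviation = float(np.mean(zs)) if zs else np.nan
                rows.append(
                    {
                        "pair_a": pa,
                        "pair_b": pb,
                        "alpha": alpha,
                        "strategy": name,
                        "deviation": deviation,
                    }
                )
    return pd.DataFrame(rows)
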