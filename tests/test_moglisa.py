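"""MoG-LISA: latent machinery, interpolation, filtering, balancing, reports."""

import warnings

import numpy as np
import pytest

from lesionforge import metrics as M, moglisa, synthgen
from lesionforge.nn import MLPAutoencoder


# ---------------------------------------------------------------------------
# masked encoding and autoencoder


def test_masked_extract_contracts(trained_ae, small_samples):
    encoder = trained_ae[0]
    img, mask = small_samples[0]
    full = moglisa.masked_feature_extract(img, np.ones_like(mask), encoder)
    raw = encoder.encode(
        moglisa._masked_input(img, np.ones_like(mask), (32, 32))
    )
    assert np.allclose(full, raw)
    # pixels outside the mask are irrelevant
    noisy = img.copy()
    noisy[~mask.astype(bool)] = 0.123
    z1 = moglisa.masked_feature_extract(img, mask, encoder)
    z2 = moglisa.masked_feature_extract(noisy, mask, encoder)
    assert np.allclose(z1, z2)


def test_masked_extract_empty_mask_flagged(trained_ae, small_samples):
    encoder = trained_ae[0]
    img, mask = small_samples[0]
    with pytest.warns(UserWarning):
        z = moglisa.masked_feature_extract(img, np.zeros_like(mask), encoder)
    zero = encoder.encode(np.zeros(32 * 32 * 3))
    assert np.allclose(z, zero)


def test_autoencoder_lr_zero_constant_curve(small_samples):
    spec = moglisa.AutoencoderSpec(epochs=5, learning_rate=0.0, seed=1)
    _, _, curve = moglisa.train_autoencoder(small_samples, spec)
    assert len(set(np.round(curve, 12))) == 1


def test_autoencoder_learns_and_is_deterministic(trained_ae, small_samples):
    _, _, curve, spec = trained_ae
    assert curve[-1] < curve[0]
    _, _, curve2 = moglisa.train_autoencoder(small_samples, spec)
    assert np.allclose(curve, curve2)


def test_autoencoder_needs_eight_samples(small_samples):
    with pytest.raises(ValueError):
        moglisa.train_autoencoder(small_samples[:4], moglisa.AutoencoderSpec())


def test_reconstruction_beats_transfer(trained_ae, small_samples):
    """decode(encode(x)) is closer to x than to an unrelated sample."""
    encoder, decoder = trained_ae[0], trained_ae[1]
    img, mask = small_samples[0]
    other_img, other_mask = small_samples[-1]
    x = moglisa._masked_input(img, mask, (32, 32))
    x_other = moglisa._masked_input(other_img, other_mask, (32, 32))
    recon = decoder.decode(encoder.encode(x))
    assert np.mean(np.abs(recon - x)) < np.mean(np.abs(recon - x_other))


def test_decode_contracts(trained_ae):
    decoder = trained_ae[1]
    z = np.zeros(trained_ae[3].latent_dim)
    img = moglisa.decode_to_image(z, decoder)
    assert img.shape == (32, 32, 3)
    assert img.min() >= 0.0 and img.max() <= 1.0
    img2 = moglisa.decode_to_image(z, decoder)
    assert np.array_equal(img, img2)
    with pytest.raises(ValueError):
        decoder.decode(np.zeros(trained_ae[3].latent_dim + 1))


def test_checkpoint_roundtrip(trained_ae, tmp_path, small_samples):
    encoder, _, curve, spec = trained_ae
    path = tmp_path / "ae.npz"
    moglisa.save_autoencoder(path, encoder, spec, curve)
    restored, spec2, curve2 = moglisa.load_autoencoder(path)
    assert spec2 == spec
    assert np.allclose(curve2, curve)
    x = moglisa._masked_input(*small_samples[0], spec.input_size)
    assert np.allclose(restored.encode(x), encoder.encode(x))


# ---------------------------------------------------------------------------
# interpolation


def test_linear_interpolate_cases():
    za, zb = np.array([0.0, 2.0]), np.array([2.0, 0.0])
    assert np.allclose(moglisa.linear_interpolate(za, zb, 1.0), za)
    assert np.allclose(moglisa.linear_interpolate(za, zb, 0.0), zb)
    assert np.allclose(moglisa.linear_interpolate(za, zb, 0.5), [1.0, 1.0])
    with pytest.raises(ValueError):
        moglisa.linear_interpolate(za, zb, 1.2)


def test_estimate_cluster_hand_arithmetic():
    pts = np.array([[0.0, 0.0], [2.0, 2.0]])
    cl = moglisa.estimate_clusters(pts, labels=np.zeros(2, int), ridge=1e-6)[0]
    assert np.allclose(cl.mean, [1.0, 1.0])
    assert np.allclose(cl.covariance, [[2.0, 2.0], [2.0, 2.0]], atol=1e-5)


def test_estimate_cluster_degenerate_and_symmetry():
    same = np.tile([1.0, 2.0, 3.0], (6, 1))
    cl = moglisa.estimate_clusters(same, labels=np.zeros(6, int), ridge=1e-3)[0]
    assert np.allclose(cl.covariance, 1e-3 * np.eye(3), atol=1e-9)
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(10, 3))
    c1 = moglisa.estimate_clusters(pts, labels=np.zeros(10, int))[0]
    c2 = moglisa.estimate_clusters(pts[::-1], labels=np.zeros(10, int))[0]
    assert np.allclose(c1.mean, c2.mean)
    assert np.allclose(c1.covariance, c2.covariance)


def test_estimate_cluster_too_small_raises():
    with pytest.raises(ValueError):
        moglisa.estimate_clusters(np.zeros((3, 2)), labels=np.array([0, 1, 1]))


def test_cluster_whitener_invariant():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(40, 5)) @ rng.normal(size=(5, 5))
    cl = moglisa.estimate_clusters(pts, labels=np.zeros(40, int))[0]
    ident = cl.whitener @ cl.covariance @ cl.whitener.T
    assert np.allclose(ident, np.eye(5), atol=1e-6)


def test_riemannian_endpoints_and_degenerate():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(50, 4))
    cl = moglisa.estimate_clusters(pts, labels=np.zeros(50, int))[0]
    za, zb = pts[0], pts[1]
    assert np.allclose(moglisa.riemannian_interpolate(cl, za, zb, 1.0), za, atol=1e-8)
    assert np.allclose(moglisa.riemannian_interpolate(cl, za, zb, 0.0), zb, atol=1e-8)
    for alpha in (0.0, 0.3, 0.7, 1.0):
        assert np.allclose(
            moglisa.riemannian_interpolate(cl, za, za, alpha), za, atol=1e-8
        )


def test_riemannian_antipodal_fallback():
    pts = np.random.default_rng(3).normal(size=(30, 3))
    cl = moglisa.estimate_clusters(pts, labels=np.zeros(30, int))[0]
    u = np.array([1.0, 0.0, 0.0])
    za = cl.mean + cl.colorer @ u
    zb = cl.mean - cl.colorer @ u  # exactly antipodal in whitened space
    mid = moglisa.riemannian_interpolate(cl, za, zb, 0.5)
    assert np.allclose(mid, cl.mean, atol=1e-8)  # whitened-linear fallback


def test_covariance_preservation_montecarlo():
    """Spherical/geometric interpolation keeps the cluster's second moment;
    linear interpolation shrinks it by alpha^2 + (1-alpha)^2."""
    k = 8
    rng = np.random.default_rng(0)
    z = rng.standard_normal((3000, k))
    cl = moglisa.estimate_clusters(z, labels=np.zeros(len(z), int))[0]
    pairs = rng.integers(0, len(z), size=(3000, 2))
    riem = np.array(
        [moglisa.riemannian_interpolate(cl, z[a], z[b], 0.5) for a, b in pairs]
    )
    lin = np.array([moglisa.linear_interpolate(z[a], z[b], 0.5) for a, b in pairs])
    tr_riem = np.trace(np.cov(riem, rowvar=False))
    tr_lin = np.trace(np.cov(lin, rowvar=False))
    assert abs(tr_riem - k) / k < 0.10
    assert abs(tr_lin - 0.5 * k) / (0.5 * k) < 0.10


# ---------------------------------------------------------------------------
# composite synthesis loss


def test_cgan_loss_self_comparison(small_samples):
    img = small_samples[0][0][:32, :32]
    mask = moglisa.derive_mask(img)
    loss = moglisa.cgan_composite_loss(
        img, img, 0, moglisa.GanLossWeights(), mask
    )
    assert loss.recon == 0.0
    assert loss.percep == 0.0
    assert loss.seg == pytest.approx(0.0)


def test_cgan_loss_weight_degeneracy(small_samples):
    img = small_samples[0][0][:32, :32]
    other = small_samples[1][0][:32, :32]
    mask = moglisa.derive_mask(img)
    w0 = moglisa.GanLossWeights(0.0, 0.0, 0.0)
    loss = moglisa.cgan_composite_loss(img, other, 0, w0, mask)
    assert loss.total == pytest.approx(loss.adv)


def test_cgan_recon_l1_arithmetic():
    a = np.full((16, 16, 3), 0.2)
    b = np.full((16, 16, 3), 0.5)
    mask = np.ones((16, 16), np.uint8)
    mask[0] = 0  # give the mask a boundary
    loss = moglisa.cgan_composite_loss(a, b, 0, moglisa.GanLossWeights(), mask)
    assert loss.recon == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# shape/texture filters


def test_cds_convex_and_u_shape():
    rect = np.zeros((10, 10), np.uint8)
    rect[2:8, 3:9] = 1
    assert moglisa.convexity_defect_score(rect) == 0.0
    u = np.ones((3, 3), np.uint8)
    u[1, 1] = 0
    u[0, 1] = 0
    assert moglisa.convexity_defect_score(u) == pytest.approx(2 / 7)
    with pytest.raises(ValueError):
        moglisa.convexity_defect_score(np.zeros((5, 5), np.uint8))


def test_cds_translation_invariant():
    u = np.zeros((12, 12), np.uint8)
    u[2:5, 2:5] = 1
    u[3, 3] = 0
    u[2, 3] = 0
    shifted = np.roll(u, (4, 5), axis=(0, 1))
    assert moglisa.convexity_defect_score(u) == pytest.approx(
        moglisa.convexity_defect_score(shifted)
    )


def test_edge_sharpness_cases():
    flat = np.zeros((9, 9, 3))
    mask = np.zeros((9, 9), np.uint8)
    mask[3:6, 3:6] = 1
    assert moglisa.edge_sharpness(flat, mask) == 0.0
    # vertical unit step with the mask boundary exactly on the step column
    img = np.zeros((9, 9))
    img[:, 4:] = 1.0
    col = np.zeros((9, 9), np.uint8)
    col[:, 4] = 1
    assert moglisa.edge_sharpness(np.dstack([img] * 3), col) == pytest.approx(0.5)
    # linear in intensity scale
    assert moglisa.edge_sharpness(np.dstack([img * 0.4] * 3), col) == pytest.approx(0.2)


def test_filter_candidates_thresholds_and_monotonicity():
    def make(cds, sharp):
        return moglisa.SynthesisCandidate(
            image=np.zeros((4, 4, 3)),
            mask=np.ones((4, 4), np.uint8),
            latent=np.zeros(2),
            parents=(0, 1),
            alpha=0.5,
            cds=cds,
            edge_sharpness=sharp,
        )

    cands = [make(0.05, 1.0), make(2 / 7, 1.0), make(0.15, 0.01)]
    acc, rej = moglisa.filter_candidates(
        cands, moglisa.FilterThresholds(delta_c=0.2, delta_s=0.1)
    )
    assert len(acc) == 1
    reasons = {c.rejection_reason for c in rej}
    assert reasons == {"shape", "sharpness"}
    # vacuous thresholds accept everything
    acc_all, _ = moglisa.filter_candidates(
        cands, moglisa.FilterThresholds(delta_c=np.inf, delta_s=0.0)
    )
    assert len(acc_all) == 3
    # relaxing thresholds never shrinks the accepted set
    tight, _ = moglisa.filter_candidates(
        cands, moglisa.FilterThresholds(delta_c=0.1, delta_s=0.5)
    )
    assert {id(c) for c in tight} <= {id(c) for c in acc_all}


def test_texture_entropy_filter_optional():
    flat = moglisa.SynthesisCandidate(
        image=np.full((8, 8, 3), 0.5),  # zero-entropy texture
        mask=np.ones((8, 8), np.uint8),
        latent=np.zeros(2),
        parents=(0, 1),
        alpha=0.5,
        cds=0.0,
        edge_sharpness=1.0,
    )
    # disabled by default: accepted
    acc, _ = moglisa.filter_candidates([flat], moglisa.FilterThresholds())
    assert len(acc) == 1
    flat.accepted = None
    _, rej = moglisa.filter_candidates(
        [flat], moglisa.FilterThresholds(min_texture_entropy=0.5)
    )
    assert rej and rej[0].rejection_reason == "texture"


# ---------------------------------------------------------------------------
# balancing and augmentation


def test_plan_balance_arithmetic():
    m = synthgen.DatasetManifest(
        records=(
            [{"image": f"a{i}", "mask": "", "label": "A"} for i in range(100)]
            + [{"image": f"b{i}", "mask": "", "label": "B"} for i in range(20)]
            + [{"image": f"c{i}", "mask": "", "label": "C"} for i in range(30)]
        )
    )
    plan = moglisa.plan_balance(m, cap=80)
    assert plan.target == 80
    assert plan.deficits == {"A": 0, "B": 60, "C": 50}


def test_plan_balance_degenerate_cases():
    balanced = synthgen.DatasetManifest(
        records=(
            [{"image": f"a{i}", "mask": "", "label": "A"} for i in range(50)]
            + [{"image": f"b{i}", "mask": "", "label": "B"} for i in range(50)]
        )
    )
    plan = moglisa.plan_balance(balanced, cap=100)
    assert plan.deficits == {"A": 0, "B": 0}
    low_cap = moglisa.plan_balance(balanced, cap=10)
    assert all(v == 0 for v in low_cap.deficits.values())


def test_augment_zero_deficit_noop(small_dataset, trained_ae, tmp_path):
    encoder, decoder = trained_ae[0], trained_ae[1]
    plan = moglisa.plan_balance(small_dataset, cap=1)  # everyone at target
    out, cands = moglisa.augment_dataset(
        small_dataset, encoder, decoder, plan,
        moglisa.FilterThresholds(delta_c=np.inf), 0, tmp_path,
    )
    assert len(out) == len(small_dataset)
    assert cands == []


def test_augment_fills_deficit_and_preserves_originals(
    small_dataset, trained_ae, tmp_path
):
    encoder, decoder = trained_ae[0], trained_ae[1]
    plan = moglisa.plan_balance(small_dataset, cap=1000)
    thresholds = moglisa.FilterThresholds(delta_c=0.5, delta_s=0.0)
    out, _ = moglisa.augment_dataset(
        small_dataset, encoder, decoder, plan, thresholds, 3, tmp_path / "a"
    )
    assert out.class_counts["melanoma"] == plan.target
    # originals unchanged and first in the manifest
    for orig, new in zip(small_dataset.records, out.records):
        assert orig == new
    synth = [r for r in out.records if r.get("synthetic") == "1"]
    assert len(synth) == plan.deficits["melanoma"]
    for rec in synth:
        assert rec["label"] == "melanoma"
        assert 0.25 <= float(rec["alpha"]) <= 0.75
        assert int(rec["parent_a"]) != int(rec["parent_b"])

    # determinism under the seed
    out2, _ = moglisa.augment_dataset(
        small_dataset, encoder, decoder, plan, thresholds, 3, tmp_path / "b"
    )
    alphas1 = [r["alpha"] for r in out.records if r.get("synthetic") == "1"]
    alphas2 = [r["alpha"] for r in out2.records if r.get("synthetic") == "1"]
    assert alphas1 == alphas2 and len(alphas1) > 0


def test_augment_partial_fill_warns(small_dataset, trained_ae, tmp_path):
    encoder, decoder = trained_ae[0], trained_ae[1]
    plan = moglisa.plan_balance(small_dataset, cap=1000)
    impossible = moglisa.FilterThresholds(delta_c=0.0, delta_s=1e9)
    with pytest.warns(UserWarning, match="filled"):
        out, _ = moglisa.augment_dataset(
            small_dataset, encoder, decoder, plan, impossible, 0, tmp_path,
            max_attempts_per_sample=2,
        )
    assert out.class_counts == small_dataset.class_counts


# ---------------------------------------------------------------------------
# plausibility and fidelity reports


def test_plausibility_self_comparison(small_samples):
    rep = moglisa.plausibility_report(small_samples, small_samples)
    assert (rep["relative_deviation"] == 0).all()
    assert (rep["p_value"] >= 0.05).all()


def test_plausibility_detects_shifted_descriptor(small_samples):
    """A 5-pooled-SD shift in one descriptor must be detected (p < 0.05)."""
    rng = np.random.default_rng(0)
    real, shifted = [], []
    base = small_samples[0]
    for i in range(30):
        img = np.clip(base[0] + rng.normal(0, 0.01, base[0].shape), 0, 1)
        real.append((img, base[1]))
        img_s = img.copy()
        # push colour variance far up inside the mask
        inside = base[1].astype(bool)
        img_s[inside] = np.clip(
            img_s[inside] + rng.normal(0, 0.25, img_s[inside].shape), 0, 1
        )
        shifted.append((img_s, base[1]))
    rep = moglisa.plausibility_report(real, shifted)
    row = rep[rep.descriptor == "color_variance"].iloc[0]
    assert row.p_value < 0.05


def test_plausibility_permutation_invariant(small_samples):
    rng = np.random.default_rng(1)
    perm = list(rng.permutation(len(small_samples)))
    rep1 = moglisa.plausibility_report(small_samples, small_samples)
    rep2 = moglisa.plausibility_report(
        [small_samples[i] for i in perm], small_samples
    )
    assert np.allclose(rep1.p_value, rep2.p_value)


def test_plausibility_needs_five(small_samples):
    with pytest.raises(ValueError):
        moglisa.plausibility_report(small_samples[:3], small_samples)


class RadialDecoder:
    """Synthetic decoder: latent norm sets the lesion radius.

    Renders a disc whose radius is proportional to the whitened latent
    norm, on a fixed background — a stand-in decoder with a strong,
    nonlinear latent-to-morphology coupling, labelled synthetic.
    """

    def __init__(self, mean, whitener, size=48):
        self.mean = mean
        self.whitener = whitener
        self.size = size
        self.latent_dim = len(mean)

    def decode(self, z):
        u = self.whitener @ (np.asarray(z) - self.mean)
        radius = 2.0 + 3.0 * np.linalg.norm(u)
        rr, cc = np.mgrid[0 : self.size, 0 : self.size]
        disc = ((rr - self.size / 2) ** 2 + (cc - self.size / 2) ** 2) <= radius**2
        img = np.full((self.size, self.size), 0.8)
        img[disc] = 0.3
        return np.dstack([img] * 3).ravel()


def test_fidelity_table_shape_and_endpoint_equality(trained_ae, small_samples):
    encoder, decoder = trained_ae[0], trained_ae[1]
    latents = np.array(
        [moglisa.masked_feature_extract(i, m, encoder) for i, m in small_samples]
    )
    cl = moglisa.estimate_clusters(
        latents, labels=np.zeros(len(latents), int), ridge=1e-4
    )[0]
    pairs = [(0, 1), (2, 3)]
    table = moglisa.interpolation_fidelity_compare(
        cl, latents, pairs, decoder, small_samples, alphas=(0.0, 0.5, 1.0)
    )
    assert len(table) == len(pairs) * 3 * 2
    # both strategies decode identical endpoints
    for alpha in (0.0, 1.0):
        sub = table[table.alpha == alpha]
        lin = sub[sub.strategy == "linear"].deviation.to_numpy()
        rie = sub[sub.strategy == "riemannian"].deviation.to_numpy()
        assert np.allclose(lin, rie, equal_nan=True)


def test_fidelity_riemannian_beats_linear_on_structured_cluster():
    """With strong latent-norm structure, covariance-preserving
    interpolation deviates less from the real morphology distribution."""
    k = 6
    rng = np.random.default_rng(7)
    z = rng.standard_normal((120, k)) * np.array([3.0, 2.0, 1.0, 1.0, 0.5, 0.5])
    cl = moglisa.estimate_clusters(z, labels=np.zeros(len(z), int))[0]
    dec = RadialDecoder(cl.mean, cl.whitener)
    real = []
    for zi in z[:60]:
        img = dec.decode(zi).reshape(48, 48, 3)
        real.append((img, moglisa.derive_mask(img)))
    pairs = [tuple(p) for p in rng.integers(0, len(z), size=(60, 2)) if p[0] != p[1]]
    table = moglisa.interpolation_fidelity_compare(
        cl, z, pairs[:50], dec, real, alphas=(0.5,), input_size=(48, 48)
    )
    means = table.groupby("strategy").deviation.mean()
    assert means["riemannian"] <= means["linear"]
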