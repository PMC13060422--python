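"""Batch correction, standardization, SVD and silhouette contracts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rmdskit.harmonize import (
    Standardizer,
    apply_correction,
    fit_correction,
    silhouette_separation,
    standardize,
    svd_reduce,
    sum_contrast,
)


def _simulate_matrix(rng, n_per_institute=40, n_bins=60, institute_offsets=(0.0, 0.0),
                     response_effect=0.0, effect_bins=10, noise_sd=1.0):
    """Samples x bins with additive institute offsets and a response shift."""
    institutes = ["instA", "instB"]
    rows, meta = [], []
    i = 0
    for inst, off in zip(institutes, institute_offsets):
        for s in range(n_per_institute):
            resp = "Responder" if s % 2 == 0 else "Non-Responder"
            base = rng.normal(0, noise_sd, n_bins) + off
            if resp == "Responder":
                base[:effect_bins] += response_effect
            rows.append(base)
            meta.append({"sample_id": f"s{i}", "patient_id": f"p{i}",
                         "institute": inst, "response": resp})
            i += 1
    mat = pd.DataFrame(rows, index=[m["sample_id"] for m in meta],
                       columns=[f"bin{j}" for j in range(n_bins)])
    return mat, pd.DataFrame(meta)


def test_sum_contrast_encoding():
    s = pd.Series(["a", "b", "c", "a"])
    enc = sum_contrast(s, ["a", "b", "c"])
    assert enc.tolist() == [[1, 0], [0, 1], [-1, -1], [1, 0]]
    with pytest.warns(UserWarning, match="unseen"):
        enc2 = sum_contrast(pd.Series(["d"]), ["a", "b", "c"])
    assert enc2.tolist() == [[0, 0]]


def test_zero_batch_effect_gives_null_coefficients(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=100, institute_offsets=(0, 0),
                                 response_effect=1.0)
    model = fit_correction(mat, meta, batch_factors=["institute"])
    # SE of the contrast coefficient ~ sd/sqrt(n); 4 SE bound
    assert np.abs(model.batch_coef).max() < 4 / np.sqrt(200)


def test_planted_institute_offsets_recovered(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=100, noise_sd=0.1,
                                 institute_offsets=(0.5, -0.5))
    model = fit_correction(mat, meta, batch_factors=["institute"])
    # sum contrast: coefficient of instA column should be ~ +0.5 per bin
    assert np.abs(model.batch_coef[0] - 0.5).max() < 0.05
    corrected = apply_correction(mat, meta, model)
    ma = corrected[meta["institute"].to_numpy() == "instA"].mean().to_numpy()
    mb = corrected[meta["institute"].to_numpy() == "instB"].mean().to_numpy()
    assert np.abs(ma - mb).max() < 0.1


def test_confounded_design_raises(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=20)
    meta = meta.copy()
    meta["institute"] = np.where(meta["response"] == "Responder", "siteR", "siteN")
    with pytest.raises(ValueError, match="rank deficient"):
        fit_correction(mat, meta, batch_factors=["institute"])


def test_single_level_factor_raises(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=10)
    meta = meta.copy()
    meta["institute"] = "only"
    with pytest.raises(ValueError, match="fewer than 2 levels"):
        fit_correction(mat, meta, batch_factors=["institute"])


def test_apply_equals_classical_fit_and_subtract(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=15, institute_offsets=(0.3, -0.3),
                                 response_effect=0.8)
    model = fit_correction(mat, meta, batch_factors=["institute"])
    corrected = apply_correction(mat, meta, model)
    # classical: OLS on [1, batch, response], subtract batch term only
    enc = np.where(meta["institute"].to_numpy() == "instA", 1.0, -1.0)[:, None]
    resp = np.where(meta["response"].to_numpy() == "Responder", 1.0, -1.0)[:, None]
    X = np.hstack([np.ones_like(enc), enc, resp])
    beta, *_ = np.linalg.lstsq(X, mat.to_numpy(), rcond=None)
    expected = mat.to_numpy() - enc @ beta[1:2]
    assert np.allclose(corrected.to_numpy(), expected, atol=1e-10)


def test_heldout_seen_institute_corrected(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=100, noise_sd=0.1,
                                 institute_offsets=(0.5, -0.5))
    fit_idx = mat.index[:150]
    hold_idx = mat.index[150:]
    model = fit_correction(mat.loc[fit_idx], meta[meta["sample_id"].isin(fit_idx)],
                           batch_factors=["institute"])
    corr = apply_correction(mat.loc[hold_idx], meta, model)
    hold_meta = meta.set_index("sample_id").loc[hold_idx]
    # held-out samples are all instB (offset -0.5); offset removed
    assert (hold_meta["institute"] == "instB").all()
    assert abs(corr.mean().mean() - 0.0) < 0.1


def test_unseen_institute_gets_grand_mean_only(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=20)
    model = fit_correction(mat, meta, batch_factors=["institute"])
    new = mat.iloc[:2].copy()
    new_meta = meta.iloc[:2].copy()
    new_meta["institute"] = "neverSeen"
    with pytest.warns(UserWarning, match="unseen"):
        out = apply_correction(new, new_meta, model)
    assert np.allclose(out.to_numpy(), new.to_numpy())  # zero encoding: no change


def test_no_leakage_heldout_values_cannot_move_model(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=20)
    fit_idx = mat.index[:30]
    model1 = fit_correction(mat.loc[fit_idx], meta, batch_factors=["institute"])
    perturbed = mat.copy()
    perturbed.loc[mat.index[30:]] += 100.0
    model2 = fit_correction(perturbed.loc[fit_idx], meta, batch_factors=["institute"])
    assert np.array_equal(model1.batch_coef, model2.batch_coef)
    out1 = apply_correction(mat.loc[fit_idx], meta, model1)
    out2 = apply_correction(mat.loc[fit_idx], meta, model2)
    assert out1.equals(out2)


def test_bin_mismatch_raises(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=10)
    model = fit_correction(mat, meta, batch_factors=["institute"])
    with pytest.raises(ValueError, match="mismatch"):
        apply_correction(mat.iloc[:, :10], meta, model)


def test_model_json_roundtrip(tmp_path, rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=10)
    model = fit_correction(mat, meta, batch_factors=["institute"])
    model.to_json(tmp_path / "m.json")
    from rmdskit.harmonize import CorrectionModel

    back = CorrectionModel.from_json(tmp_path / "m.json")
    assert np.allclose(back.batch_coef, model.batch_coef)
    assert back.levels == model.levels
    out1 = apply_correction(mat, meta, model)
    out2 = apply_correction(mat, meta, back)
    assert np.allclose(out1.to_numpy(), out2.to_numpy())


# ---------------------------------------------------------------------------
# standardize


def test_standardize_moments_and_idempotence(rng):
    mat = pd.DataFrame(rng.normal(2, 3, (30, 20)),
                       columns=[f"b{i}" for i in range(20)])
    out = standardize(mat)
    assert np.allclose(out.mean(axis=0), 0, atol=1e-10)
    assert np.allclose(out.std(axis=0, ddof=0), 1, atol=1e-10)
    again = standardize(out)
    assert np.allclose(again.to_numpy(), out.to_numpy(), atol=1e-8)


def test_standardize_drops_constant_bins(rng):
    mat = pd.DataFrame(rng.normal(0, 1, (10, 3)), columns=["a", "b", "c"])
    mat["b"] = 5.0
    with pytest.warns(UserWarning, match="zero-variance"):
        out = standardize(mat)
    assert list(out.columns) == ["a", "c"]


def test_standardizer_frozen_on_new_data(rng):
    mat = pd.DataFrame(rng.normal(0, 1, (20, 5)), columns=list("abcde"))
    sc = Standardizer().fit(mat)
    new = pd.DataFrame(rng.normal(3, 2, (4, 5)), columns=list("abcde"))
    out = sc.transform(new)
    # uses training moments, not the new data's
    assert abs(out.mean().mean()) > 0.5


# ---------------------------------------------------------------------------
# SVD


def test_svd_rank2_exact_reconstruction(rng):
    u = rng.normal(size=(20, 2))
    v = rng.normal(size=(2, 50))
    mat = pd.DataFrame(u @ v, columns=[f"b{i}" for i in range(50)])
    emb = svd_reduce(mat, n_components=2)
    recon = emb.scores.to_numpy() @ emb.components
    assert np.allclose(recon, mat.to_numpy(), atol=1e-8)
    assert emb.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)


def test_svd_full_rank_explains_everything(rng):
    mat = pd.DataFrame(rng.normal(size=(10, 30)))
    emb = svd_reduce(mat, n_components=10)
    assert emb.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)
    assert (np.diff(emb.explained_variance_ratio) <= 1e-12).all()


def test_svd_matches_gram_eigendecomposition(rng):
    mat = pd.DataFrame(rng.normal(size=(50, 500)))
    emb = svd_reduce(mat, n_components=6)
    gram = mat.to_numpy() @ mat.to_numpy().T
    eig = np.sort(np.linalg.eigvalsh(gram))[::-1]
    assert np.allclose(emb.singular_values**2, eig[:6], rtol=1e-8)


def test_svd_orthogonal_components_and_sign_determinism(rng):
    mat = pd.DataFrame(rng.normal(size=(25, 40)))
    e1 = svd_reduce(mat, n_components=5)
    e2 = svd_reduce(mat.copy(), n_components=5)
    assert np.allclose(e1.scores.to_numpy(), e2.scores.to_numpy())
    g = e1.components @ e1.components.T
    assert np.allclose(g, np.eye(5), atol=1e-8)
    # canonical sign: largest-magnitude loading positive
    for row in e1.components:
        assert row[np.abs(row).argmax()] > 0


def test_svd_transform_consistency(rng):
    mat = pd.DataFrame(rng.normal(size=(15, 30)), columns=[f"b{i}" for i in range(30)])
    emb = svd_reduce(mat, n_components=4)
    assert np.allclose(emb.transform(mat).to_numpy(), emb.scores.to_numpy(), atol=1e-8)


def test_svd_too_many_components(rng):
    mat = pd.DataFrame(rng.normal(size=(5, 8)))
    with pytest.raises(ValueError):
        svd_reduce(mat, n_components=6)


# ---------------------------------------------------------------------------
# silhouette


def test_silhouette_tight_far_clusters(rng):
    a = rng.normal(0, 0.1, (20, 3))
    b = rng.normal(10, 0.1, (20, 3))
    _, mean = silhouette_separation(np.vstack([a, b]), ["x"] * 20 + ["y"] * 20)
    assert mean > 0.9


def test_silhouette_random_labels_near_zero(rng):
    X = rng.normal(size=(40, 3))
    means = []
    for _ in range(20):
        labels = rng.permutation(["x"] * 20 + ["y"] * 20)
        _, m = silhouette_separation(X, labels)
        means.append(m)
    assert abs(np.mean(means)) < 0.1


def test_silhouette_identical_points_zero():
    X = np.ones((6, 2))
    _, mean = silhouette_separation(X, ["a", "a", "a", "b", "b", "b"])
    assert mean == 0.0


def test_silhouette_singleton_cluster_zero_with_warning(rng):
    X = rng.normal(size=(5, 2))
    with pytest.warns(UserWarning, match="singleton"):
        scores, _ = silhouette_separation(X, ["a", "a", "a", "a", "b"])
    assert scores.iloc[4] == 0.0


def test_silhouette_single_label_raises(rng):
    with pytest.raises(ValueError):
        silhouette_separation(rng.normal(size=(4, 2)), ["a"] * 4)


# ---------------------------------------------------------------------------
# preservation property (single-seed unit check; the multi-seed version is
# part of the acceptance suite)


def test_correction_preserves_response_separation(rng):
    mat, meta = _simulate_matrix(rng, n_per_institute=40, n_bins=80,
                                 institute_offsets=(1.0, -1.0),
                                 response_effect=1.2, effect_bins=30, noise_sd=0.5)
    resp = meta.set_index("sample_id").loc[mat.index, "response"]
    inst = meta.set_index("sample_id").loc[mat.index, "institute"]
    _, sil_resp_before = silhouette_separation(mat, resp)
    _, sil_inst_before = silhouette_separation(mat, inst)
    model = fit_correction(mat, meta, batch_factors=["institute"])
    corr = apply_correction(mat, meta, model)
    _, sil_resp_after = silhouette_separation(corr, resp)
    _, sil_inst_after = silhouette_separation(corr, inst)
    assert sil_inst_after < sil_inst_before
    assert abs(sil_inst_after) < 0.05
    assert sil_resp_after >= sil_resp_before * 0.9
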