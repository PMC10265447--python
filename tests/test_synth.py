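"""Synthetic-data generator: determinism, calibration, polarization, proxies."""

import numpy as np
import pytest
from scipy import stats

from erfusion.folds import polarization_report
from erfusion.metrics import concordance_index, mse
from erfusion.synth import (SyntheticSpec, derive_annotations, derive_similarity,
                            generate_affinity, generate_dti)


def test_regeneration_is_bit_identical():
    spec = SyntheticSpec(n_drugs=50, n_proteins=40, n_cells=300)
    a = generate_dti(spec, seed=11)
    b = generate_dti(spec, seed=11)
    np.testing.assert_array_equal(a.cells, b.cells)
    np.testing.assert_array_equal(a.values, b.values)
    np.testing.assert_array_equal(a.U, b.U)
    c = generate_dti(spec, seed=12)
    assert not np.array_equal(a.values, c.values)


def test_null_model_is_coin_flips_at_pos_fraction():
    spec = SyntheticSpec(n_drugs=100, n_proteins=80, n_cells=4000,
                         bias_scale=0.0, interaction_scale=0.0, pos_fraction=0.3)
    ds = generate_dti(spec, seed=0)
    # Bernoulli(0.3) mean, 3 sigma band
    assert abs(ds.values.mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 4000)


@pytest.mark.parametrize("pos_fraction", [0.35, 0.5])
def test_positive_fraction_calibration(pos_fraction):
    spec = SyntheticSpec(n_cells=5000, pos_fraction=pos_fraction)
    devs = [abs(generate_dti(spec, seed=s).values.mean() - pos_fraction)
            for s in range(10)]
    assert max(devs) <= 0.02


def test_polarization_monotone_in_bias_scale():
    pols = []
    for bias in (0.0, 1.0, 3.0, 6.0, 12.0):
        vals = []
        for seed in (0, 1, 2):
            ds = generate_dti(SyntheticSpec(bias_scale=bias), seed=seed)
            vals.append(polarization_report(ds.cells, ds.values).combined)
        pols.append(np.mean(vals))
    assert all(b >= a - 0.01 for a, b in zip(pols, pols[1:]))


def test_default_regime_sits_at_the_ninety_four_percent_polarization():
    pols = [polarization_report(d.cells, d.values).combined
            for d in (generate_dti(SyntheticSpec(), seed=s) for s in range(6))]
    assert abs(np.mean(pols) - 0.94) <= 0.03


def test_affinity_oracle_predictor_limits():
    spec = SyntheticSpec(n_drugs=120, n_proteins=100, n_cells=4000, noise_sd=0.0,
                         bias_scale=2.0, assortativity=0.0)
    ds = generate_affinity(spec, seed=4)
    # noiseless: the generative mean ranks perfectly
    assert concordance_index(ds.values, ds.true_logits()) == 1.0
    noisy = generate_affinity(
        SyntheticSpec(n_drugs=120, n_proteins=100, n_cells=4000, noise_sd=500.0,
                      bias_scale=2.0, assortativity=0.0), seed=4)
    ci = concordance_index(noisy.values, noisy.true_logits())
    assert abs(ci - 0.5) < 0.05


def test_affinity_oracle_mse_matches_noise_variance():
    spec = SyntheticSpec(n_drugs=150, n_proteins=120, n_cells=10000, noise_sd=0.7,
                         bias_scale=2.0, assortativity=0.0)
    ds = generate_affinity(spec, seed=9)
    assert mse(ds.true_logits(), ds.values) == pytest.approx(0.49, rel=0.06)


def test_derived_similarity_properties(rng):
    X = rng.normal(size=(40, 5))
    S0 = derive_similarity(X, noise_sd=0.0)
    assert np.allclose(np.diag(S0), 1.0)
    assert S0.min() >= 0.0 and S0.max() <= 1.0
    S = derive_similarity(X, noise_sd=0.05, seed=2)
    assert np.abs(S - S.T).max() < 1e-12
    assert S.min() >= 0.0 and S.max() <= 1.0
    # similarity falls with latent distance
    iu = np.triu_indices(40, 1)
    dists = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)[iu]
    rho = stats.spearmanr(S[iu], dists).statistic
    assert rho < -0.3


def test_derived_annotations_structure(rng):
    X = rng.normal(size=(30, 4))
    M = derive_annotations(X, n_terms=5, seed=0)
    assert M.shape == (30, 5)
    assert (M.sum(axis=1) >= 1).all()          # cluster term always present
    assert derive_annotations(X, n_terms=1, seed=0).shape == (30, 1)
    np.testing.assert_array_equal(derive_annotations(X, 1, 0), 1)
    # entities sharing a cluster share that term
    from sklearn.cluster import KMeans
    labels = KMeans(n_clusters=5, n_init=4, random_state=0).fit_predict(X)
    for a in range(30):
        for b in range(a + 1, 30):
            if labels[a] == labels[b]:
                assert (M[a] & M[b]).any()


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(n_drugs=5, n_proteins=5, n_cells=26)
    with pytest.raises(ValueError):
        SyntheticSpec(pos_fraction=1.0)
    with pytest.raises(ValueError):
        SyntheticSpec(assortativity=1.5)
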