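import numpy as np
import pytest

from conftest import random_design
from oracles import rrblup_dgv
from treehap.bayes import (
    ChainSettings,
    MixturePrior,
    derive_scale,
    fit_bayes,
    predict_dgv,
)
from treehap.design import ColumnMeta, CovariateMatrix


def test_derive_scale_formula_and_linearity():
    x = random_design(0, 50, 10)
    f = x.values.mean(axis=0) / 2.0
    ssq = float(np.sum(2 * f * (1 - f)))
    # hand-evaluated: S2 = V (nu-2) / (nu (1-pi) ssq)
    expected = 3.0 * 2.2 / (4.2 * 0.1 * ssq)
    assert derive_scale(3.0, x, 0.9, 4.2) == pytest.approx(expected)
    assert derive_scale(6.0, x, 0.9, 4.2) == pytest.approx(2 * expected)


def test_derive_scale_rejects_degenerate_inputs():
    x = random_design(0, 20, 5)
    with pytest.raises(ValueError):
        derive_scale(1.0, x, 0.5, nu_a=2.0)
    with pytest.raises(ValueError):
        derive_scale(1.0, x, 1.0)


def test_pi_one_gives_zero_dgv_and_weighted_mean():
    rng = np.random.default_rng(1)
    x = random_design(1, 40, 30)
    y = rng.standard_normal(40) * 2 + 7
    w = rng.uniform(0.5, 4.0, 40)
    fit = fit_bayes(y, w, x, method="bayesC", prior=MixturePrior(pi=1.0),
                    chain=ChainSettings(1500, 300, seed=2))
    assert np.all(fit.dgv == 0.0)
    assert np.all(fit.inclusion == 0.0)
    wmean = float(np.average(y, weights=w))
    mc_se = np.sqrt(fit.var_e / w.sum() / fit.n_samples)
    assert abs(fit.mu - wmean) < 6 * mc_se + 1e-3


def test_pi_zero_includes_every_covariate():
    rng = np.random.default_rng(2)
    x = random_design(2, 30, 10)
    y = rng.standard_normal(30)
    fit = fit_bayes(y, np.ones(30), x, method="bayesC", prior=MixturePrior(pi=0.0),
                    chain=ChainSettings(800, 200, seed=3))
    assert np.all(fit.inclusion == 1.0)


def test_single_covariate_conjugate_posterior():
    """pi=0, fixed variances, centered covariate: draws are iid from the
    exact normal posterior with mean (z'y)/(z'z + var_e/var_a)."""
    rng = np.random.default_rng(3)
    n = 60
    z_raw = rng.binomial(2, 0.4, n).astype(np.int16)
    x = CovariateMatrix(z_raw.reshape(-1, 1), [f"i{i}" for i in range(n)],
                        [ColumnMeta("marker", "m0")])
    zc = z_raw - z_raw.mean()
    y = 1.5 * zc + rng.standard_normal(n)
    var_a, var_e = 2.0, 1.0
    fit = fit_bayes(y, np.ones(n), x, method="bayesC",
                    prior=MixturePrior(pi=0.0, s2_a=var_a),
                    chain=ChainSettings(6000, 1000, seed=4),
                    fixed_var_a=var_a, fixed_var_e=var_e,
                    store_effect_trace=True)
    ztz = float(zc @ zc)
    post_mean = float(zc @ y) / (ztz + var_e / var_a)
    post_var = var_e / (ztz + var_e / var_a)
    mc_se = np.sqrt(post_var / fit.n_samples)
    assert abs(fit.effects[0] - post_mean) < 3 * mc_se
    # the sample variance should match the exact posterior variance
    assert np.var(fit.effect_trace[:, 0]) == pytest.approx(post_var, rel=0.15)


def test_fixed_variance_pi_zero_matches_weighted_ridge():
    """With pi=0 and both variances fixed, the posterior mean equals the
    weighted ridge (RR-BLUP) solution; checked within Monte-Carlo error."""
    rng = np.random.default_rng(5)
    n, k = 100, 50
    x = random_design(5, n, k)
    f = x.values.mean(0) / 2
    mc = x.values - 2 * f
    a_true = rng.standard_normal(k) * 0.3
    y = mc @ a_true + rng.standard_normal(n) * 2
    w = rng.uniform(0.5, 3.0, n)
    s = float(np.sum(2 * f * (1 - f)))
    var_g, var_e = 1.5, 4.0
    fit = fit_bayes(y, w, x, method="bayesC",
                    prior=MixturePrior(pi=0.0, s2_a=var_g / s),
                    chain=ChainSettings(50_000, 5_000, seed=6),
                    fixed_var_a=var_g / s, fixed_var_e=var_e)
    oracle = rrblup_dgv(x.values, np.arange(n), y, w, var_g, var_e)
    resid = fit.dgv - fit.dgv.mean() - (oracle - oracle.mean())
    # 3 MC standard errors on the DGV scale, conservatively via the spread
    assert np.corrcoef(fit.dgv, oracle)[0, 1] > 0.999
    assert np.max(np.abs(resid)) < 0.05 * np.std(oracle)


def test_seeded_chains_are_bit_identical():
    rng = np.random.default_rng(7)
    x = random_design(7, 50, 40)
    y = rng.standard_normal(50)
    chain = ChainSettings(400, 100, seed=11)
    f1 = fit_bayes(y, np.ones(50), x, method="bayesCpi", chain=chain)
    f2 = fit_bayes(y, np.ones(50), x, method="bayesCpi", chain=chain)
    assert np.array_equal(f1.effects, f2.effects)
    assert np.array_equal(f1.dgv, f2.dgv)
    assert np.array_equal(f1.pi_samples, f2.pi_samples)


def test_bayesb_runs_with_per_covariate_variances():
    rng = np.random.default_rng(8)
    x = random_design(8, 60, 40)
    mc = x.values - x.values.mean(0)
    y = mc[:, 0] * 2.0 + rng.standard_normal(60) * 0.5
    fit = fit_bayes(y, np.ones(60), x, method="bayesB",
                    prior=MixturePrior(pi=0.9), chain=ChainSettings(1500, 300, seed=9))
    # the causal covariate should be included nearly always
    assert fit.inclusion[0] > 0.9
    assert np.argmax(np.abs(fit.effects)) == 0


def test_predict_dgv_linearity_and_errors():
    rng = np.random.default_rng(10)
    x = random_design(10, 40, 20)
    y = rng.standard_normal(40)
    fit = fit_bayes(y, np.ones(40), x, method="bayesC",
                    prior=MixturePrior(pi=0.5), chain=ChainSettings(800, 200, seed=12))
    # all-zero covariate row -> DGV exactly 0
    zero_row = CovariateMatrix(np.zeros((1, 20), dtype=np.int16), ["new"], x.columns)
    assert predict_dgv(fit, zero_row)[0] == 0.0
    # prediction on the training design matches the per-iteration accumulator
    assert np.allclose(predict_dgv(fit, x), fit.dgv, atol=1e-8)
    # two-column hand dot product
    two = CovariateMatrix(np.array([[1, 2] + [0] * 18], dtype=np.int16), ["n2"], x.columns)
    assert predict_dgv(fit, two)[0] == pytest.approx(fit.effects[0] + 2 * fit.effects[1])
    # column provenance mismatch is a hard error
    bad = CovariateMatrix(x.values[:, :19], x.individual_ids, x.columns[:19])
    with pytest.raises(ValueError, match="columns do not match"):
        predict_dgv(fit, bad)


@pytest.mark.parametrize("n", [250, 500, 1000])
def test_effect_recovery_improves_with_sample_size(n, results={}):
    rng = np.random.default_rng(100)
    k = 300
    f = rng.uniform(0.1, 0.5, k)
    x_vals = np.random.default_rng(200 + n).binomial(2, f, size=(n, k)).astype(np.int16)
    x = CovariateMatrix(x_vals, [f"i{i}" for i in range(n)],
                        [ColumnMeta("marker", f"m{j}") for j in range(k)])
    a_true = np.zeros(k)
    idx = rng.choice(k, 15, replace=False)
    a_true[idx] = rng.standard_normal(15)
    g = (x_vals - x_vals.mean(0)) @ a_true
    y = g + np.random.default_rng(300 + n).standard_normal(n) * np.std(g)
    fit = fit_bayes(y, np.ones(n), x, method="bayesC",
                    prior=MixturePrior(pi=0.9, h2=0.5),
                    chain=ChainSettings(2000, 400, seed=13))
    results[n] = np.corrcoef(fit.effects, a_true)[0, 1]
    if len(results) == 3:
        assert results[250] < results[1000]
        assert results[250] > 0.3
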