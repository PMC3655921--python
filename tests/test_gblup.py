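import numpy as np
import pytest

from conftest import random_design
from oracles import rrblup_dgv
from treehap import genealogy as gn
from treehap.design import ColumnMeta, CovariateMatrix, haplotype_design
from treehap.gblup import build_grm, compare_grms, fit_gblup


def _design(values):
    values = np.asarray(values, dtype=np.int16)
    return CovariateMatrix(values, [f"i{r}" for r in range(values.shape[0])],
                           [ColumnMeta("marker", f"m{c}") for c in range(values.shape[1])])


def test_grm_matches_hand_arithmetic():
    x = _design([[0, 2], [1, 1], [2, 0]])
    g = build_grm(x, ridge=0.0)
    # by hand: f = (0.5, 0.5), centered columns +-(1,0,-1), s = 2*0.25*2 = 1
    mc = np.array([[-1.0, 1.0], [0.0, 0.0], [1.0, -1.0]])
    assert np.allclose(g.matrix, mc @ mc.T / 1.0)
    assert g.scale == pytest.approx(1.0)


def test_zero_variance_column_contributes_nothing():
    x1 = _design([[0, 2], [1, 1], [2, 0]])
    with_const = _design([[0, 2, 1], [1, 1, 1], [2, 0, 1]])
    assert np.allclose(build_grm(x1, ridge=0.0).matrix,
                       build_grm(with_const, ridge=0.0).matrix)


def test_identical_rows_give_identical_grm_rows():
    x = _design([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
    g = build_grm(x, ridge=0.0).matrix
    assert np.allclose(g[0], g[1])


def test_all_constant_design_is_error():
    with pytest.raises(ValueError, match="zero variance"):
        build_grm(_design([[1, 1], [1, 1]]))


def test_compare_grms_trivial_and_scale_invariant():
    g1 = build_grm(random_design(0, 8, 12), ridge=0.0)
    g2 = build_grm(random_design(0, 8, 12), ridge=0.0)
    assert compare_grms(g1, g2) == (pytest.approx(1.0), pytest.approx(1.0))
    import copy

    g3 = copy.deepcopy(g2)
    g3.matrix = 2.0 * g3.matrix
    d, o = compare_grms(g1, g3)
    assert d == pytest.approx(1.0) and o == pytest.approx(1.0)


def test_compare_grms_matches_flatten_oracle():
    rng = np.random.default_rng(1)
    g1 = build_grm(random_design(2, 5, 9), ridge=0.0)
    g2 = build_grm(random_design(3, 5, 9), ridge=0.0)
    d, o = compare_grms(g1, g2)
    assert d == pytest.approx(np.corrcoef(np.diag(g1.matrix), np.diag(g2.matrix))[0, 1])
    il = np.tril_indices(5, k=-1)
    assert o == pytest.approx(np.corrcoef(g1.matrix[il], g2.matrix[il])[0, 1])


def test_vanishing_genetic_variance_shrinks_to_weighted_mean():
    rng = np.random.default_rng(4)
    x = random_design(4, 12, 20)
    g = build_grm(x, ridge=1e-6)
    y = rng.standard_normal(12) + 3.0
    w = rng.uniform(0.5, 3.0, 12)
    fit = fit_gblup(y, w, g, var_g=1e-10, var_e=1.0)
    assert np.allclose(fit.g, 0.0, atol=1e-6)
    assert fit.mu == pytest.approx(float(np.average(y, weights=w)), abs=1e-6)


def test_equal_weights_match_unweighted_normal_equations():
    # the reference block must be a proper subset: with frequencies computed
    # from the full sample, the vector of ones is in the null space of G
    rng = np.random.default_rng(5)
    x = random_design(5, 15, 25)
    g = build_grm(x, ridge=0.0)
    n = 12
    ref = np.arange(n)
    y = rng.standard_normal(n)
    fit = fit_gblup(y, np.ones(n), g, ref=ref, var_g=0.7, var_e=1.3)
    # unweighted oracle: [n 1'; 1 I + lam*Ginv] [mu; g] = [1'y; y]
    ginv = np.linalg.inv(g.matrix[:n, :n])
    lam = 1.3 / 0.7
    c = np.zeros((n + 1, n + 1))
    c[0, 0] = n
    c[0, 1:] = 1.0
    c[1:, 0] = 1.0
    c[1:, 1:] = np.eye(n) + lam * ginv
    sol = np.linalg.solve(c, np.concatenate([[y.sum()], y]))
    assert fit.mu == pytest.approx(sol[0])
    assert np.allclose(fit.g, sol[1:], atol=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_gblup_equals_rrblup_marker_design(seed):
    rng = np.random.default_rng(seed)
    x = random_design(seed, 20, 30)
    g = build_grm(x, ridge=0.0)
    ref = np.arange(14)
    y = rng.standard_normal(14) * 2 + 10
    w = rng.uniform(0.5, 5.0, 14)
    fit = fit_gblup(y, w, g, ref=ref, var_g=1.1, var_e=0.9)
    oracle = rrblup_dgv(x.values, ref, y, w, 1.1, 0.9)
    scale = np.max(np.abs(oracle))
    assert np.max(np.abs(fit.dgv - oracle)) / scale < 1e-9


@pytest.mark.parametrize("seed", range(3))
def test_gblup_equals_rrblup_haplotype_design(seed):
    # LD panels give multi-cluster trees, so the cluster design has enough
    # effective rank for a ridge-free G on the reference block
    from treehap.simulate import SimConfig, simulate_panel

    panel, _ = simulate_panel(SimConfig(n_individuals=20, n_markers=40, seed=seed))
    x = haplotype_design(panel, gn.cluster_panel(panel))
    g = build_grm(x, ridge=0.0)
    rng = np.random.default_rng(seed)
    ref = np.arange(14)
    y = rng.standard_normal(14)
    w = rng.uniform(0.5, 5.0, 14)
    fit = fit_gblup(y, w, g, ref=ref, var_g=1.0, var_e=1.0)
    oracle = rrblup_dgv(x.values, ref, y, w, 1.0, 1.0)
    scale = np.max(np.abs(oracle))
    assert np.max(np.abs(fit.dgv - oracle)) / scale < 1e-9


def test_scaling_y_scales_solution_and_reml_variances():
    rng = np.random.default_rng(9)
    x = random_design(9, 40, 60)
    g = build_grm(x, ridge=1e-6)
    a = rng.standard_normal(60) * 0.3
    y = (x.values - x.values.mean(0)) @ a + rng.standard_normal(40)
    w = rng.uniform(0.5, 2.0, 40)
    fit1 = fit_gblup(y, w, g, reml=True)
    fit3 = fit_gblup(3.0 * y, w, g, reml=True)
    assert fit3.mu == pytest.approx(3.0 * fit1.mu, rel=1e-4)
    assert np.allclose(fit3.dgv, 3.0 * fit1.dgv, rtol=1e-4, atol=1e-8)
    assert fit3.var_g == pytest.approx(9.0 * fit1.var_g, rel=1e-3)
    assert fit3.var_e == pytest.approx(9.0 * fit1.var_e, rel=1e-3)


def test_reml_recovers_plausible_components_with_signal():
    rng = np.random.default_rng(12)
    x = random_design(12, 80, 120)
    g = build_grm(x, ridge=1e-6)
    f = x.values.mean(0) / 2
    mc = x.values - 2 * f
    a = rng.standard_normal(120) * 0.2
    gv = mc @ a
    y = 5 + gv + rng.standard_normal(80) * np.sqrt(np.var(gv))
    fit = fit_gblup(y, np.ones(80), g, reml=True)
    total = fit.var_g + fit.var_e
    assert 0.15 < fit.var_g / total < 0.85
    assert fit.reml_iterations < 500
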