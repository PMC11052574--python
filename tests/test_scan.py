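"""Trio regression, AIC selection, classification and Bonferroni control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import tadscan as ts
from tadscan.scan import aic, enumerate_trios


def normal_equations_oracle(y, g, a):
    """Brute-force OLS via two explicit normal-equation solves + F formulas."""
    X = np.column_stack([np.ones_like(g), g, a, g * a])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss_full = float(np.sum((y - X @ beta) ** 2))
    X3 = X[:, :3]
    beta3 = np.linalg.solve(X3.T @ X3, X3.T @ y)
    rss_null = float(np.sum((y - X3 @ beta3) ** 2))
    n = len(y)
    f = (rss_null - rss_full) / (rss_full / (n - 4))
    p = float(stats.f.sf(f, 1, n - 4))
    return beta, rss_full, rss_null, f, p


def random_trio(rng, n=176):
    g = rng.binomial(2, rng.uniform(0.2, 0.8), n).astype(float)
    while np.ptp(g) == 0:
        g = rng.binomial(2, 0.5, n).astype(float)
    a = rng.lognormal(1.0, 0.5, n)
    y = rng.normal(4.0, 1.0, n) + 0.3 * g + 0.1 * a + rng.normal(0, 0.5, n)
    return y, g, a


def test_noiseless_recovery():
    rng = np.random.default_rng(1)
    g = rng.integers(0, 3, 12).astype(float)
    a = rng.lognormal(1, 0.5, 12)
    y = 2 + 1 * g + 0.5 * a + 0.25 * g * a
    fit = ts.fit_trio(y, g, a)
    np.testing.assert_allclose(fit.betas, (2, 1, 0.5, 0.25), atol=1e-9)
    assert fit.rss_full < 1e-18


def test_constant_y():
    rng = np.random.default_rng(2)
    g = rng.integers(0, 3, 20).astype(float)
    a = rng.lognormal(1, 0.5, 20)
    fit = ts.fit_trio(np.full(20, 3.0), g, a)
    np.testing.assert_allclose(fit.betas[1:], 0.0, atol=1e-9)
    assert fit.f_stat == 0.0
    assert fit.p_raw == 1.0


def test_degenerate_inputs_raise():
    y = np.arange(10.0)
    with pytest.raises(ts.DegenerateInputError):
        ts.fit_trio(y, np.ones(10), y)
    with pytest.raises(ts.DegenerateInputError):
        ts.fit_trio(y, y, np.full(10, 2.0))


def test_collinear_design_flagged():
    # binary g makes g*a collinear with a when a = g (interaction = g*g = g... )
    g = np.array([0, 1] * 10, dtype=float)
    a = g.copy() + 0.0
    a[0] = 0.0  # a == g exactly: g*a == g^2 == g, collinear with g
    y = np.random.default_rng(3).normal(size=20)
    fit = ts.fit_trio(y, g, g)
    assert fit.flagged_collinear
    assert np.isnan(fit.f_stat)


def test_fit_matches_normal_equations_oracle(rng):
    """Betas, F and p match an explicit normal-equations solve to 1e-8 rel."""
    for _ in range(200):
        y, g, a = random_trio(rng)
        fit = ts.fit_trio(y, g, a)
        beta_o, rf_o, rn_o, f_o, p_o = normal_equations_oracle(y, g, a)
        np.testing.assert_allclose(fit.betas, beta_o, rtol=1e-8)
        # atol guards the F comparison when the interaction is truly absent
        # and F ~ 0 sits at the cancellation floor of rss_null - rss_full
        np.testing.assert_allclose(fit.f_stat, f_o, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(fit.p_raw, p_o, rtol=1e-8)


def test_stepwise_trivial_cases():
    rng = np.random.default_rng(4)
    g = rng.binomial(2, 0.5, 60).astype(float)
    a = rng.lognormal(1, 0.5, 60)
    assert ts.stepwise_select(2 + 3 * g, g, a) == {"x1"}
    y = 1 + 2 * g + 1.5 * a + 3 * g * a
    assert ts.stepwise_select(y, g, a) == {"x1", "x2", "x1x2"}


def exhaustive_selection_oracle(y, g, a):
    """Greedy backward path over exhaustively enumerated submodel AICs,
    with RSS from an independent QR solve."""
    X = np.column_stack([np.ones_like(g), g, a, g * a])
    subsets = {
        frozenset(): (0,), frozenset({"x1"}): (0, 1), frozenset({"x2"}): (0, 2),
        frozenset({"x1", "x2"}): (0, 1, 2),
        frozenset({"x1", "x2", "x1x2"}): (0, 1, 2, 3),
    }
    n = len(y)
    aics = {}
    for terms, cols in subsets.items():
        Q, R = np.linalg.qr(X[:, cols])
        resid = y - Q @ (Q.T @ y)
        aics[terms] = aic(float(resid @ resid), n, len(cols), float(y @ y))
    cur = frozenset({"x1", "x2", "x1x2"})
    while True:
        drops = ["x1x2"] if "x1x2" in cur else [t for t in ("x1", "x2") if t in cur]
        if not drops:
            break
        options = sorted(
            ((aics[cur - {d}], d) for d in drops),
            key=lambda t: (t[0], t[1] != "x1x2", t[1] != "x2"),
        )
        best_aic, drop = options[0]
        if best_aic < aics[cur]:
            cur = cur - {drop}
        else:
            break
    return cur


def test_stepwise_matches_exhaustive_oracle(rng):
    for _ in range(100):
        y, g, a = random_trio(rng, n=60)
        assert ts.stepwise_select(y, g, a) == exhaustive_selection_oracle(y, g, a)


@pytest.mark.parametrize(
    "retained,expected",
    [
        ({"x1", "x2", "x1x2"}, "interacting"),
        ({"x1", "x2"}, "additive"),
        ({"x1"}, "genotype_only"),
        ({"x2"}, "atac_only"),
        (set(), "null"),
    ],
)
def test_classify_model(retained, expected):
    assert ts.classify_model(retained) == expected


def test_classify_rejects_non_hierarchical():
    with pytest.raises(ValueError):
        ts.classify_model({"x1", "x1x2"})


def test_bonferroni_arithmetic():
    np.testing.assert_allclose(ts.bonferroni_adjust([0.01], 5), [0.05])
    np.testing.assert_allclose(ts.bonferroni_adjust([0.5], 10), [1.0])
    # a genome-scale family pushes a strong raw p above the 1e-7 cutoff
    adj = ts.bonferroni_adjust([2e-9], 39_000_000)
    np.testing.assert_allclose(adj, [0.078])
    assert adj[0] >= 1e-7


def test_bonferroni_validation():
    with pytest.raises(ValueError):
        ts.bonferroni_adjust([1.5], 10)
    with pytest.raises(ValueError):
        ts.bonferroni_adjust([0.1, 0.2], 1)


@given(st.floats(0, 1), st.integers(1, 10**9))
def test_bonferroni_bounds_property(p, m):
    adj = ts.bonferroni_adjust([p], m)[0]
    assert p <= adj <= 1.0


def test_toy_enumeration_covers_all_trios():
    """Random mode with n_models = all combos enumerates each exactly once."""
    cfg = ts.SimulationConfig(
        chromosome_lengths=(2_000_000,), n_genes=2, n_markers=3, n_peaks=3,
        tad_mean_bp=500_000.0, tad_sd_bp=100_000.0, tad_min_bp=100_000,
    )
    ds = ts.generate_genome(cfg, seed=1)
    plan = ts.ScanPlan(n_models=18, seed=0)
    trios = enumerate_trios(ds, plan)
    assert len(trios) == 18
    assert len({tuple(t) for t in map(tuple, trios)}) == 18


def test_tad_mode_enumeration_is_deterministic(mixed_world):
    ds, _ = mixed_world
    a = enumerate_trios(ds, ts.ScanPlan(mode="tad_constrained", seed=None, n_models=None))
    b = enumerate_trios(ds, ts.ScanPlan(mode="tad_constrained", seed=None, n_models=None))
    assert np.array_equal(a, b)


def test_scan_table_invariants(mixed_scan):
    t = mixed_scan.table
    assert (t["p_adj"] >= t["p_raw"] - 1e-15).all()
    assert (t["p_adj"] <= 1.0).all()
    assert (t["rss_full"] <= t["rss_null"] + 1e-9).all()
    # marginality: interacting iff x1x2 retained
    has_int = t["retained"].str.contains("x1x2")
    assert ((t["model_class"] == "interacting") == has_int).all()
    for r in t["retained"].unique():
        terms = set(r.split(",")) if r else set()
        if "x1x2" in terms:
            assert {"x1", "x2"} <= terms


def test_scan_batch_matches_single_trio_path(mixed_world, mixed_scan):
    """The vectorised scan agrees with the one-trio API row by row."""
    ds, _ = mixed_world
    t = mixed_scan.table.sample(50, random_state=0)
    for _, row in t.iterrows():
        y = ds.expression[ds.gene_index(row["gene_id"])]
        g = ds.dosage[ds.marker_index(row["variant_id"])]
        a = ds.atac[ds.peak_index(row["peak_id"])]
        fit = ts.fit_and_classify(y, g, a)
        np.testing.assert_allclose(
            [row["beta0"], row["beta1"], row["beta2"], row["beta3"]],
            fit.betas, rtol=1e-6, atol=1e-9,
        )
        np.testing.assert_allclose(row["f_stat"], fit.f_stat, rtol=1e-6)
        assert row["model_class"] == fit.model_class


def test_permutation_invariance_of_f(rng):
    """F is invariant to a joint sample permutation of (y, g, a)."""
    y, g, a = random_trio(rng, n=80)
    fit = ts.fit_trio(y, g, a)
    perm = rng.permutation(80)
    fit_p = ts.fit_trio(y[perm], g[perm], a[perm])
    np.testing.assert_allclose(fit.f_stat, fit_p.f_stat, rtol=1e-9)


def test_fit_matches_statsmodels():
    """Independent library cross-check of the OLS route."""
    import statsmodels.api as sm

    rng = np.random.default_rng(55)
    y, g, a = random_trio(rng, n=100)
    X = sm.add_constant(np.column_stack([g, a, g * a]))
    ref = sm.OLS(y, X).fit()
    fit = ts.fit_trio(y, g, a)
    np.testing.assert_allclose(fit.betas, ref.params, rtol=1e-8)
    np.testing.assert_allclose(fit.bse, ref.bse, rtol=1e-8)


def test_trio_model_summary_runs():
    rng = np.random.default_rng(6)
    y, g, a = random_trio(rng, n=60)
    res = ts.TrioInteractionModel(y, g, a).fit()
    text = res.summary()
    assert "genotype:atac" in text and "model class" in text
    ci = res.conf_int()
    assert (ci["upper"] >= ci["lower"]).all()
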