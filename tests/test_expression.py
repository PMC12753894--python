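import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhopath.expression import (
    aaic_filter,
    between_lane_normalize,
    de_count_enrichment,
    low_expression_filter,
    nb_differential_expression,
    pan_cancer_classify,
    substrate_specificity_tally,
    within_lane_gc_normalize,
)
from rhopath.synthetic import SimulationConfig, simulate_expression, synthetic_catalog
from rhopath.tables import ExpressionMatrix


def _matrix(counts, condition=None, gc=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    if condition is None:
        half = counts.shape[1] // 2
        condition = ["tumor"] * half + ["normal"] * (counts.shape[1] - half)
    cond = pd.Series(condition, index=counts.columns)
    gc_series = None
    if gc is not None:
        gc_series = pd.Series(gc, index=counts.index)
    return ExpressionMatrix(counts=counts, condition=cond, gc=gc_series)


# --- AAIC -----------------------------------------------------------------

def test_aaic_identical_samples_kept():
    col = np.arange(1, 11)
    m = _matrix(np.column_stack([col, col, col]), condition=["tumor"] * 3)
    filtered, report = aaic_filter(m)
    assert np.allclose(report["mean_pairwise_r"], 1.0)
    assert not report["removed"].any()
    assert filtered.counts.shape[1] == 3


def test_aaic_removes_uncorrelated_outlier():
    rng = np.random.default_rng(0)
    base = rng.lognormal(4, 1, size=200)
    cols = [np.random.default_rng(i).poisson(base) for i in range(20)]
    noise = rng.permutation(rng.lognormal(4, 1, size=200)).astype(int)
    m = _matrix(np.column_stack(cols + [noise]), condition=["tumor"] * 21)
    filtered, report = aaic_filter(m)
    assert report["removed"].iloc[-1]
    assert report["removed"].sum() == 1


def test_aaic_constant_sample_treated_as_zero_and_removed():
    col = np.arange(1, 11)
    const = np.full(10, 7)
    m = _matrix(np.column_stack([col, col, col, const]), condition=["tumor"] * 4)
    filtered, report = aaic_filter(m)
    assert report.loc[3, "mean_pairwise_r"] <= 0.6
    assert report.loc[3, "removed"]


def test_aaic_needs_three_samples():
    m = _matrix(np.ones((5, 2)), condition=["tumor", "tumor"])
    with pytest.raises(ValueError):
        aaic_filter(m)


# --- lowest-quartile filter ----------------------------------------------

def test_low_expression_percentile_forced():
    """Gene means 1..8: P25 = 2.75 removes the two lowest genes."""
    counts = np.tile(np.arange(1, 9)[:, None], (1, 4))
    m = _matrix(counts, condition=["tumor"] * 2 + ["normal"] * 2)
    filtered, removed = low_expression_filter(m)
    assert set(removed) == {"g0", "g1"}
    assert filtered.counts.shape[0] == 6


def test_low_expression_all_equal_none_removed():
    m = _matrix(np.full((6, 4), 5), condition=["tumor"] * 2 + ["normal"] * 2)
    filtered, removed = low_expression_filter(m)
    assert removed == []


def test_low_expression_matches_sort_oracle():
    rng = np.random.default_rng(3)
    counts = rng.poisson(50, size=(40, 6))
    m = _matrix(counts, condition=["tumor"] * 3 + ["normal"] * 3)
    filtered, removed = low_expression_filter(m)
    means = counts.mean(axis=1)
    p25 = np.percentile(means, 25)
    expected_removed = {f"g{i}" for i in range(40) if means[i] < p25}
    assert set(removed) == expected_removed


def test_low_expression_tiny_matrix_warns_noop():
    m = _matrix(np.arange(12).reshape(3, 4) + 1, condition=["tumor"] * 2 + ["normal"] * 2)
    with pytest.warns(UserWarning):
        filtered, removed = low_expression_filter(m)
    assert removed == [] and filtered.counts.shape[0] == 3


# --- within-lane GC normalization ----------------------------------------

def test_gc_normalize_flat_bias_near_identity():
    cat = synthetic_catalog(200, seed=1)
    cfg = SimulationConfig(seed=1, n_samples=10, gc_bias_strength=0.0)
    m = simulate_expression(cfg, cat)
    normalized = within_lane_gc_normalize(m)
    logs_in = np.log2(m.counts.to_numpy(dtype=float) + 1)
    logs_out = np.log2(normalized.counts.to_numpy() + 1)
    assert np.abs(logs_in - logs_out).mean() < 0.2


def test_gc_normalize_removes_planted_trend():
    cat = synthetic_catalog(300, seed=5)
    cfg = SimulationConfig(seed=5, n_samples=15, gc_bias_strength=2.0)
    m = simulate_expression(cfg, cat)
    normalized = within_lane_gc_normalize(m)
    gc = m.gc.loc[m.counts.index].to_numpy()
    for s in normalized.counts.columns:
        rho = stats.spearmanr(np.log2(normalized.counts[s] + 1), gc)[0]
        assert abs(rho) < 0.1


def test_gc_normalize_gene_order_equivariance():
    cat = synthetic_catalog(100, seed=2)
    cfg = SimulationConfig(seed=2, n_samples=6, gc_bias_strength=1.0)
    m = simulate_expression(cfg, cat)
    normalized = within_lane_gc_normalize(m)
    rng = np.random.default_rng(0)
    perm = rng.permutation(m.counts.index.to_numpy())
    m_perm = ExpressionMatrix(
        counts=m.counts.loc[perm], condition=m.condition, gc=m.gc, cohort=m.cohort
    )
    normalized_perm = within_lane_gc_normalize(m_perm)
    pd.testing.assert_frame_equal(
        normalized_perm.counts, normalized.counts.loc[perm], atol=1e-9
    )


def test_gc_normalize_constant_gc_warns_noop():
    m = _matrix(np.arange(24).reshape(6, 4) + 1, gc=[0.5] * 6)
    with pytest.warns(UserWarning):
        out = within_lane_gc_normalize(m)
    pd.testing.assert_frame_equal(out.counts, m.counts.astype(out.counts.dtypes.iloc[0]))


# --- between-lane full-quantile normalization -----------------------------

def test_quantile_normalize_scalar_multiples_become_identical():
    col = np.array([1.0, 5.0, 2.0, 9.0])
    m = _matrix(np.column_stack([col, 3 * col]), condition=["tumor", "normal"])
    out = between_lane_normalize(m)
    assert np.allclose(out.counts.iloc[:, 0], out.counts.iloc[:, 1])


def test_quantile_normalize_sorted_columns_identical():
    # continuous draws: tie-free, where the sorted-multiset identity is exact
    rng = np.random.default_rng(1)
    m = _matrix(rng.lognormal(3, 1, size=(50, 5)), condition=["tumor"] * 3 + ["normal"] * 2)
    out = between_lane_normalize(m).counts.to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(out.shape[1]):
        assert np.allclose(np.sort(out[:, j]), ref)


def test_quantile_normalize_preserves_rank_order_and_tie_means():
    col_a = np.array([4.0, 4.0, 1.0, 10.0])
    col_b = np.array([1.0, 2.0, 3.0, 4.0])
    m = _matrix(np.column_stack([col_a, col_b]), condition=["tumor", "normal"])
    out = between_lane_normalize(m).counts.to_numpy()
    mean_q = (np.sort(col_a) + np.sort(col_b)) / 2
    # the tied 4.0s span sorted positions 1 and 2 -> both get their mean
    assert out[0, 0] == pytest.approx(mean_q[1:3].mean())
    assert out[1, 0] == pytest.approx(mean_q[1:3].mean())
    assert out[2, 0] == pytest.approx(mean_q[0])
    assert out[3, 0] == pytest.approx(mean_q[3])
    # column b is strictly increasing -> gets mean_q directly
    assert np.allclose(out[:, 1], mean_q)


def test_quantile_normalize_matches_sort_average_restore_oracle():
    rng = np.random.default_rng(7)
    X = rng.poisson(20, size=(30, 4)).astype(float)
    m = _matrix(X, condition=["tumor"] * 2 + ["normal"] * 2)
    out = between_lane_normalize(m).counts.to_numpy()
    mean_q = np.sort(X, axis=0).mean(axis=1)
    for j in range(4):
        order = np.argsort(X[:, j], kind="stable")
        expected = np.empty(30)
        expected[order] = mean_q  # no ties in this draw at float resolution
        vals = X[order, j]
        if len(np.unique(vals)) == 30:
            assert np.allclose(out[:, j], expected)


# --- NB differential expression -------------------------------------------

def test_de_mirrored_groups_give_exact_zero_log2fc():
    rng = np.random.default_rng(4)
    block = rng.poisson(40, size=(30, 5))
    m = _matrix(np.hstack([block, block]), condition=["tumor"] * 5 + ["normal"] * 5)
    de = nb_differential_expression(m)
    assert (de["log2fc"] == 0.0).all()
    assert (de["status"] == "ns").all()


def test_de_label_swap_negates_log2fc():
    cat = synthetic_catalog(60, seed=3)
    cfg = SimulationConfig(
        seed=3, n_samples=10, planted_log2fc={cat.symbols[0]: 1.5}, gc_bias_strength=0.0
    )
    m = simulate_expression(cfg, cat)
    de = nb_differential_expression(m)
    swapped = ExpressionMatrix(
        counts=m.counts,
        condition=m.condition.map({"tumor": "normal", "normal": "tumor"}),
        gc=m.gc,
    )
    de_swapped = nb_differential_expression(swapped)
    assert np.allclose(de["log2fc"], -de_swapped["log2fc"])


def test_de_recovery_coverage_matches_normal_theory():
    """Planted log2FC 2 at 20v20, dispersion 0.1: the fraction of estimates
    within +-0.3 matches the per-gene normal-theory prediction."""
    hits, predicted = [], []
    for rep in range(10):
        cat = synthetic_catalog(150, seed=rep)
        planted = {g: 2.0 for g in cat.symbols[:15]}
        cfg = SimulationConfig(
            seed=100 + rep,
            n_samples=20,
            nb_dispersion=0.1,
            gc_bias_strength=0.0,
            planted_log2fc=planted,
        )
        m = simulate_expression(cfg, cat)
        de = nb_differential_expression(m)
        for g in planted:
            hits.append(abs(de.loc[g, "log2fc"] - 2.0) <= 0.3)
            mu0 = de.loc[g, "mean_ref"]
            se = np.sqrt(
                (1 / de.loc[g, "mean_test"] + 0.1) / 20
                + (1 / mu0 + 0.1) / 20
            ) / np.log(2)
            predicted.append(2 * stats.norm.cdf(0.3 / se) - 1)
    observed_rate = np.mean(hits)
    predicted_rate = np.mean(predicted)
    se_mc = np.sqrt(predicted_rate * (1 - predicted_rate) / len(hits))
    assert abs(observed_rate - predicted_rate) < 4 * se_mc + 0.02


def test_de_null_calibration_within_binomial_ci():
    pvals = []
    for rep in range(20):
        cat = synthetic_catalog(50, seed=rep)
        cfg = SimulationConfig(
            seed=1000 + rep, n_samples=20, nb_dispersion=0.1, gc_bias_strength=0.0
        )
        m = simulate_expression(cfg, cat)
        de = nb_differential_expression(m)
        pvals.extend(de["pvalue"].tolist())
    rate = np.mean(np.array(pvals) < 0.05)
    half_width = 1.96 * np.sqrt(0.05 * 0.95 / len(pvals))
    assert abs(rate - 0.05) < half_width + 0.01


def test_de_fdr_monotone_in_p():
    cat = synthetic_catalog(80, seed=6)
    cfg = SimulationConfig(seed=6, n_samples=8, gc_bias_strength=0.0)
    m = simulate_expression(cfg, cat)
    de = nb_differential_expression(m).sort_values("pvalue")
    assert (np.diff(de["fdr"].to_numpy()) >= -1e-12).all()


def test_de_requires_two_samples_per_group():
    m = _matrix(np.ones((5, 3)) * 10, condition=["tumor", "tumor", "normal"])
    with pytest.raises(ValueError):
        nb_differential_expression(m)


# --- DE-count enrichment ---------------------------------------------------

def test_de_count_enrichment_no_de_genes(catalog60, background60):
    de = pd.DataFrame(
        {"status": ["ns"] * len(catalog60)}, index=catalog60.symbols
    )
    result = de_count_enrichment(de, catalog60, background60, n_lists=50, seed=0)
    assert result.observed == 0
    assert result.p == 1.0


def test_de_count_enrichment_planted_in_catalog_only(catalog60, background60):
    genes = catalog60.symbols + background60["symbol"].tolist()
    status = ["up" if g in set(catalog60.symbols[:30]) else "ns" for g in genes]
    de = pd.DataFrame({"status": status}, index=genes)
    result = de_count_enrichment(de, catalog60, background60, n_lists=200, seed=1)
    assert result.observed == 30
    assert result.p < 0.001


# --- pan-cancer classing ---------------------------------------------------

def _oracle_pan_class(statuses):
    """Independent restatement of the classing rule for cross-checking."""
    n_up = statuses.count("up")
    n_down = statuses.count("down")
    breadth = (n_up + n_down) / len(statuses)
    if n_up == 0 and n_down == 0:
        return "none"
    if n_up == n_down:
        return "mixed"
    if breadth > 0.25:
        return "pan_up" if n_up > n_down else "pan_down"
    if n_up > 0 and n_down > 0:
        return "mixed"
    return "restricted"


def test_pan_classify_broadly_upregulated_gene():
    """Up in 11 of 20 cohorts, down in none: pan-up in the top breadth tier
    (the cytokinesis GEF ECT2 pattern)."""
    statuses = ["up"] * 11 + ["ns"] * 9
    out = pan_cancer_classify(statuses, gene="ECT2like")
    assert out["class"] == "pan_up"
    assert out["tier"] == "gt50pct"
    assert out["breadth_fraction"] == pytest.approx(0.55)


def test_pan_classify_no_de_is_none():
    assert pan_cancer_classify(["ns"] * 6)["class"] == "none"


def test_pan_classify_exhaustive_rule_oracle():
    from itertools import product

    for n in range(1, 7):
        for combo in product(["up", "down", "ns"], repeat=n):
            expected = _oracle_pan_class(list(combo))
            assert pan_cancer_classify(list(combo))["class"] == expected


# --- substrate tallies ------------------------------------------------------

def _catalog_with_substrates(spec):
    """spec: list of (symbol, category, substrate)."""
    from rhopath.catalog import GeneCatalogEntry, PathwayCatalog

    return PathwayCatalog(
        [
            GeneCatalogEntry(sym, frozenset({cat}), 1000, 0.5, sub)
            for sym, cat, sub in spec
        ]
    )


def test_substrate_tally_published_percentages():
    """12 pan-down GAPs with 6 RHOA-specific tally at 50%; 11 pan-up GAPs
    with 4 RAC1-specific tally at 36.4%."""
    spec = []
    profiles = {}
    for i in range(12):
        sym = f"DGAP{i}"
        spec.append((sym, "GAP", "RHOA" if i < 6 else "UNKNOWN"))
        profiles[sym] = "pan_down"
    for i in range(11):
        sym = f"UGAP{i}"
        spec.append((sym, "GAP", "RAC1" if i < 4 else "UNKNOWN"))
        profiles[sym] = "pan_up"
    catalog = _catalog_with_substrates(spec)
    prof = pd.DataFrame(
        {"class": [profiles[s] for s in profiles]}, index=list(profiles)
    )
    tally = substrate_specificity_tally(prof, catalog)
    down_rhoa = tally.query(
        "category == 'GAP' and direction == 'pan_down' and substrate == 'RHOA'"
    ).iloc[0]
    assert down_rhoa["count"] == 6 and down_rhoa["pct"] == 50.0
    up_rac1 = tally.query(
        "category == 'GAP' and direction == 'pan_up' and substrate == 'RAC1'"
    ).iloc[0]
    assert up_rac1["count"] == 4 and up_rac1["pct"] == 36.4


def test_substrate_tally_empty_profiles():
    catalog = _catalog_with_substrates([("A", "GEF", "RHOA")])
    prof = pd.DataFrame({"class": []}, index=pd.Index([], name="gene"))
    tally = substrate_specificity_tally(prof, catalog)
    assert (tally["count"] == 0).all()
    assert (tally["pct"] == 0.0).all()
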