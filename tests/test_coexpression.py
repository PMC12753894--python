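import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhopath.coexpression import (
    cross_cohort_summary,
    enrichment_score,
    pairwise_spearman,
    preranked_gsea,
    top_processes,
)
from rhopath.tables import ExpressionMatrix


def _matrix(rows, genes, condition="tumor"):
    counts = pd.DataFrame(rows, index=genes)
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    return ExpressionMatrix(
        counts=counts,
        condition=pd.Series([condition] * counts.shape[1], index=counts.columns),
    )


def test_spearman_monotone_and_antimonotone():
    x = np.arange(1, 13)
    m = _matrix([x, x**2, x.max() - x + 1], ["a", "b", "c"])
    out = pairwise_spearman(m, ["a"], ["b", "c"]).set_index("gene_b")
    assert out.loc["b", "rho"] == pytest.approx(1.0)
    assert out.loc["c", "rho"] == pytest.approx(-1.0)


def test_spearman_small_n_exact_matches_enumeration_oracle():
    """n = 6: the reported p equals per-permutation scipy enumeration."""
    rng = np.random.default_rng(8)
    x = rng.random(6)
    y = rng.random(6)
    m = _matrix([x * 100, y * 100], ["a", "b"])
    out = pairwise_spearman(m, ["a"], ["b"])
    rho_obs = stats.spearmanr(x, y)[0]
    count = 0
    for perm in itertools.permutations(y):
        if abs(stats.spearmanr(x, perm)[0]) >= abs(rho_obs) - 1e-12:
            count += 1
    assert out["p"].iloc[0] == pytest.approx(count / 720)
    assert out["rho"].iloc[0] == pytest.approx(rho_obs)


def test_spearman_zero_variance_flagged():
    m = _matrix([np.arange(10), np.full(10, 3)], ["a", "b"])
    out = pairwise_spearman(m, ["a"], ["b"])
    assert out["degenerate"].iloc[0]
    assert np.isnan(out["rho"].iloc[0])


def test_spearman_needs_five_samples():
    m = _matrix([np.arange(4), np.arange(4)], ["a", "b"])
    with pytest.raises(ValueError):
        pairwise_spearman(m, ["a"], ["b"])


def test_cross_cohort_summary_forced_arithmetic():
    """Significant in 6 of 20 cohorts: 30%, tier gt25pct."""
    rows = []
    for c in range(20):
        rows.append(
            {
                "gene_a": "a",
                "gene_b": "b",
                "cohort": f"C{c}",
                "rho": 0.8,
                "p": 0.001,
                "fdr": 0.01 if c < 6 else 0.5,
                "significant": c < 6,
                "degenerate": False,
            }
        )
    out = cross_cohort_summary(pd.DataFrame(rows)).iloc[0]
    assert out["pct_significant"] == pytest.approx(30.0)
    assert out["tier"] == "gt25pct"
    assert out["dominant_sign"] == "positive"


def test_cross_cohort_summary_none_significant():
    rows = [
        {
            "gene_a": "a",
            "gene_b": "b",
            "cohort": f"C{c}",
            "rho": 0.1,
            "p": 0.9,
            "fdr": 0.9,
            "significant": False,
            "degenerate": False,
        }
        for c in range(5)
    ]
    out = cross_cohort_summary(pd.DataFrame(rows)).iloc[0]
    assert out["pct_significant"] == 0.0 and out["tier"] == "below"


def test_cross_cohort_summary_matches_brute_force():
    rng = np.random.default_rng(4)
    rows = []
    for pair in [("a", "b"), ("a", "c")]:
        for c in range(12):
            sig = bool(rng.random() < 0.5)
            rho = float(rng.normal())
            rows.append(
                {
                    "gene_a": pair[0],
                    "gene_b": pair[1],
                    "cohort": f"C{c}",
                    "rho": rho,
                    "p": 0.01,
                    "fdr": 0.01 if sig else 0.5,
                    "significant": sig,
                    "degenerate": False,
                }
            )
    df = pd.DataFrame(rows)
    out = cross_cohort_summary(df).set_index(["gene_a", "gene_b"])
    for pair, sub in df.groupby(["gene_a", "gene_b"]):
        sig = sub[sub["significant"]]
        assert out.loc[pair, "pct_significant"] == pytest.approx(
            100 * len(sig) / len(sub)
        )
        n_pos = (sig["rho"] > 0).sum()
        n_neg = (sig["rho"] < 0).sum()
        expected = (
            "positive" if n_pos > n_neg else "negative" if n_neg > n_pos else "mixed"
        )
        assert out.loc[pair, "dominant_sign"] == expected


def test_cross_cohort_summary_empty_errors():
    with pytest.raises(ValueError):
        cross_cohort_summary(pd.DataFrame())


# --- GSEA ------------------------------------------------------------------

def _ranked(n=20, seed=5):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(0, 1, n))[::-1]
    return pd.Series(scores, index=[f"g{i}" for i in range(n)])


def test_es_singleton_extremes():
    ranked = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("ABCD"))
    assert enrichment_score(ranked, ["A"]) == pytest.approx(1.0)
    assert enrichment_score(ranked, ["D"]) == pytest.approx(-1.0)


def test_es_invariant_to_positive_rescaling():
    ranked = _ranked()
    gene_set = ["g0", "g3", "g8"]
    es1 = enrichment_score(ranked, gene_set)
    es2 = enrichment_score(ranked * 7.5, gene_set)
    assert es1 == pytest.approx(es2)


def test_es_weight_zero_invariant_to_monotone_transform():
    ranked = _ranked()
    gene_set = ["g1", "g5", "g9"]
    es1 = enrichment_score(ranked, gene_set, weight=0.0)
    monotone = pd.Series(
        np.exp(ranked.to_numpy()), index=ranked.index
    )  # order-preserving
    es2 = enrichment_score(monotone, gene_set, weight=0.0)
    assert es1 == pytest.approx(es2)


def _es_oracle(positions, scores):
    """Independent O(N) running-sum construction."""
    n = len(scores)
    hit = np.zeros(n, dtype=bool)
    hit[list(positions)] = True
    w = np.abs(scores)
    hit_total = w[hit].sum()
    miss_total = n - hit.sum()
    running = 0.0
    best = 0.0
    for i in range(n):
        if hit[i]:
            running += w[i] / hit_total
        else:
            running -= 1.0 / miss_total
        if abs(running) > abs(best):
            best = running
    return best


def test_es_matches_independent_running_sum_oracle():
    rng = np.random.default_rng(10)
    ranked = _ranked(30, seed=10)
    scores = ranked.to_numpy()
    for _ in range(20):
        k = int(rng.integers(2, 10))
        positions = np.sort(rng.choice(30, size=k, replace=False))
        gene_set = [f"g{i}" for i in positions]
        assert enrichment_score(ranked, gene_set) == pytest.approx(
            _es_oracle(positions, scores)
        )


def test_gsea_permutation_p_matches_exhaustive_enumeration():
    """5-gene set on a 20-gene ranking: permutation p within Monte-Carlo
    error of the exact p over all 15,504 placements."""
    ranked = _ranked(20, seed=5)
    scores = ranked.to_numpy()
    positions = [0, 2, 3, 7, 11]
    gene_set = [f"g{i}" for i in positions]
    es_obs = _es_oracle(positions, scores)
    all_es = np.array(
        [
            _es_oracle(comb, scores)
            for comb in itertools.combinations(range(20), 5)
        ]
    )
    same = all_es >= 0 if es_obs >= 0 else all_es < 0
    p_exact = (np.abs(all_es[same]) >= abs(es_obs) - 1e-12).sum() / same.sum()
    out = preranked_gsea(ranked, {"S": gene_set}, n_perm=8000, seed=3)
    p_perm = out["p"].iloc[0]
    mc_se = np.sqrt(p_exact * (1 - p_exact) / 8000)
    assert abs(p_perm - p_exact) < 3 * mc_se + 2 / 8000
    assert out["es"].iloc[0] == pytest.approx(es_obs)
    assert np.sign(out["nes"].iloc[0]) == np.sign(out["es"].iloc[0])


def test_gsea_seed_reproducible_and_size_limits():
    ranked = _ranked(30, seed=2)
    sets = {
        "ok": [f"g{i}" for i in range(0, 12, 2)],
        "too_small": ["g1", "g2"],
        "big": [f"g{i}" for i in range(30)],
    }
    out1 = preranked_gsea(ranked, sets, n_perm=500, max_size=20, seed=9)
    out2 = preranked_gsea(ranked, sets, n_perm=500, max_size=20, seed=9)
    pd.testing.assert_frame_equal(out1, out2)
    assert out1["set_name"].tolist() == ["ok"]  # others dropped


def test_gsea_random_set_nes_near_symmetric():
    rng = np.random.default_rng(11)
    ranked = _ranked(60, seed=11)
    nes = []
    for rep in range(30):
        members = rng.choice(ranked.index.to_numpy(), size=8, replace=False)
        out = preranked_gsea(ranked, {"R": list(members)}, n_perm=300, seed=rep)
        nes.append(out["nes"].iloc[0])
    assert abs(np.mean(nes)) < 0.35


def test_top_processes_median_and_tiebreak():
    rows = []
    for cohort, nes_values in [("C1", {"A": 2.0, "B": 1.0}), ("C2", {"A": 1.0, "B": 2.0})]:
        for name, nes in nes_values.items():
            rows.append({"set_name": name, "cohort": cohort, "nes": nes})
    out = top_processes(pd.DataFrame(rows), k=10)
    # equal medians (1.5): tie broken by name
    assert out["set_name"].tolist() == ["A", "B"]
    assert out["median_nes"].tolist() == [1.5, 1.5]


def test_top_processes_matches_brute_force():
    rng = np.random.default_rng(3)
    rows = [
        {"set_name": f"S{i}", "cohort": f"C{c}", "nes": float(rng.normal())}
        for i in range(10)
        for c in range(4)
    ]
    df = pd.DataFrame(rows)
    out = top_processes(df, k=5)
    expected = (
        df.groupby("set_name")["nes"].median().sort_values(ascending=False)
    )
    assert out["median_nes"].tolist() == expected.head(5).tolist()
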