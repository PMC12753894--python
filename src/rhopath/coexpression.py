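"""Cross-cohort co-expression and pre-ranked GSEA.

Co-regulation between regulator pairs is measured by pairwise Spearman
correlation per cohort (BH FDR < 0.05 within cohort), then summarized as
the percentage of cohorts in which a pair is significantly co-regulated.
Gene lists ranked by correlation feed a pre-ranked GSEA: a weighted
Kolmogorov–Smirnov running-sum enrichment score with weight exponent 1, a
gene-label permutation null, NES = ES over the mean same-sign null |ES|,
and a permutation p with the +1 correction.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import ExpressionMatrix

COEXPRESSION_FDR_CUTOFF = 0.05
EXACT_PERMUTATION_MAX_N = 9
GSEA_MIN_SET_SIZE = 5


# ---------------------------------------------------------------------------
# pairwise Spearman
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact permutation p for Spearman rho at small n.

    Enumerates all n! orderings of the y ranks; ties use average ranks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = float(stats.pearsonr(rx, ry)[0])
    xc = rx - rx.mean()
    denom_x = np.sqrt((xc**2).sum())
    count = 0
    total = 0
    for perm in permutations(ry):
        py = np.asarray(perm)
        yc = py - py.mean()
        denom = denom_x * np.sqrt((yc**2).sum())
        rho = float((xc * yc).sum() / denom)
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return rho_obs, count / total


def pairwise_spearman(
    expression: ExpressionMatrix,
    list_a: list[str],
    list_b: list[str],
    condition: str = "tumor",
    fdr_cutoff: float = COEXPRESSION_FDR_CUTOFF,
) -> pd.DataFrame:
    """Spearman correlation for every (a, b) gene pair over one cohort.

    Ties receive average ranks. The p-value uses the t approximation, or
    exact permutation enumeration for n <= 9 samples. BH FDR within the
    cohort; significant ⇔ FDR < ``fdr_cutoff``. Zero-variance genes yield
    a flagged row with undefined rho.
    """
    samples = expression.samples_in(condition)
    n = len(samples)
    if n < 5:
        raise ValueError(f"need >= 5 samples, got {n}")
    sub = expression.counts[samples]
    rows = []
    for a in list_a:
        for b in list_b:
            if a == b:
                continue
            x = sub.loc[a].to_numpy(dtype=float)
            y = sub.loc[b].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append(
                    {
                        "gene_a": a,
                        "gene_b": b,
                        "cohort": expression.cohort,
                        "rho": np.nan,
                        "p": np.nan,
                        "degenerate": True,
                    }
                )
                continue
            if n <= EXACT_PERMUTATION_MAX_N:
                rho, p = _spearman_exact_p(x, y)
            else:
                rho, p = stats.spearmanr(x, y)
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "cohort": expression.cohort,
                    "rho": float(rho),
                    "p": float(p),
                    "degenerate": False,
                }
            )
    out = pd.DataFrame(rows)
    ok = ~out["degenerate"]
    fdr = np.full(len(out), np.nan)
    if ok.any():
        _, adj, _, _ = multipletests(out.loc[ok, "p"], method="fdr_bh")
        fdr[ok.to_numpy()] = adj
    out["fdr"] = fdr
    out["significant"] = out["fdr"] < fdr_cutoff
    return out


def cross_cohort_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Summarize per-cohort pair correlations across cohorts.

    ``results`` concatenates :func:`pairwise_spearman` outputs over
    cohorts. Per pair: percentage of tested cohorts significant, dominant
    sign among significant cohorts (``mixed`` on a tie), and the strict
    > 50% / > 25% tier.
    """
    if len(results) == 0:
        raise ValueError("zero tested cohorts")
    rows = []
    for (a, b), sub in results.groupby(["gene_a", "gene_b"]):
        tested = len(sub)
        if tested == 0:
            raise ValueError("zero tested cohorts")
        sig = sub[sub["significant"].fillna(False)]
        pct = 100.0 * len(sig) / tested
        n_pos = int((sig["rho"] > 0).sum())
        n_neg = int((sig["rho"] < 0).sum())
        if n_pos > n_neg:
            sign = "positive"
        elif n_neg > n_pos:
            sign = "negative"
        else:
            sign = "mixed"
        tier = "gt50pct" if pct > 50 else ("gt25pct" if pct > 25 else "below")
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "n_cohorts_tested": tested,
                "pct_significant": pct,
                "dominant_sign": sign,
                "tier": tier,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_genes: int
) -> float:
    """Signed KS running-sum extremum for sorted hit positions.

    ``weights`` are the |score| hit increments at those positions. The
    running sum is evaluated just after and just before each hit, where
    its extrema occur.
    """
    k = len(positions)
    wsum = weights.sum()
    hit_cum = np.cumsum(weights) / wsum if wsum > 0 else np.arange(1, k + 1) / k
    miss_step = 1.0 / (n_genes - k)
    ranks = np.arange(k)
    # deviation just after hit i and just before hit i
    after = hit_cum - (positions - ranks) * miss_step
    before = np.concatenate([[0.0], hit_cum[:-1]]) - (positions - ranks) * miss_step
    dev_max = float(np.max(after))
    dev_min = float(np.min(before))
    return dev_max if dev_max >= -dev_min else dev_min


def _es_batch(
    idx: np.ndarray, abs_scores: np.ndarray, n_genes: int
) -> np.ndarray:
    """Vectorized ES for many permutation position sets (rows of ``idx``)."""
    pos = np.sort(idx, axis=1)
    w = abs_scores[pos]
    wsum = w.sum(axis=1, keepdims=True)
    safe = np.where(wsum > 0, wsum, 1.0)
    hit_cum = np.cumsum(w, axis=1) / safe
    k = idx.shape[1]
    miss_step = 1.0 / (n_genes - k)
    ranks = np.arange(k)[None, :]
    after = hit_cum - (pos - ranks) * miss_step
    before = np.concatenate(
        [np.zeros((idx.shape[0], 1)), hit_cum[:, :-1]], axis=1
    ) - (pos - ranks) * miss_step
    dev_max = after.max(axis=1)
    dev_min = before.min(axis=1)
    return np.where(dev_max >= -dev_min, dev_max, dev_min)


def enrichment_score(
    ranked: pd.Series, gene_set: list[str], weight: float = 1.0
) -> float:
    """Weighted KS enrichment score of ``gene_set`` on a ranked list.

    ``ranked`` maps genes to ranking scores; genes are ordered by
    descending score. Hit increments are proportional to |score|^weight;
    miss increments are uniform.
    """
    order = ranked.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    abs_scores = np.abs(order.to_numpy(dtype=float)) ** weight
    members = set(gene_set)
    positions = np.flatnonzero(np.isin(genes, list(members)))
    if len(positions) == 0 or len(positions) == len(genes):
        raise ValueError("gene set empty or spans the whole universe")
    return _es_from_positions(positions, abs_scores[positions], len(genes))


def preranked_gsea(
    ranked: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 10000,
    max_size: int = 800,
    min_size: int = GSEA_MIN_SET_SIZE,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-label permutation null.

    Sets are intersected with the ranked universe; sets larger than
    ``max_size`` or smaller than ``min_size`` after intersection are
    dropped. For each set, ``n_perm`` random placements of the same size
    give the null ES distribution; NES = ES / mean(|ES*|) over same-sign
    permutations, and p = (1 + #{|ES*| >= |ES|, same sign}) /
    (1 + #same-sign). BH FDR across sets.
    """
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranking scores must be finite")
    order = ranked.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    abs_scores = np.abs(order.to_numpy(dtype=float)) ** weight
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(sets):
        members = sorted(set(sets[name]) & set(genes))
        k = len(members)
        if k < min_size or k > max_size or k == n_genes:
            continue
        positions = np.sort(np.array([gene_pos[g] for g in members]))
        es = _es_from_positions(positions, abs_scores[positions], n_genes)

        keys = rng.random((n_perm, n_genes))
        idx = np.argpartition(keys, k, axis=1)[:, :k]
        es_null = _es_batch(idx, abs_scores, n_genes)

        same_sign = es_null >= 0 if es >= 0 else es_null < 0
        n_same = int(same_sign.sum())
        if n_same:
            mean_abs = float(np.abs(es_null[same_sign]).mean())
            nes = es / mean_abs if mean_abs > 0 else 0.0
            exceed = int((np.abs(es_null[same_sign]) >= abs(es)).sum())
        else:
            nes = 0.0
            exceed = 0
        p = (1 + exceed) / (1 + n_same)
        rows.append(
            {"set_name": name, "size": k, "es": es, "nes": nes, "p": p}
        )
    out = pd.DataFrame(rows, columns=["set_name", "size", "es", "nes", "p"])
    if len(out):
        _, fdr, _, _ = multipletests(out["p"], method="fdr_bh")
        out["fdr"] = fdr
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def top_processes(results: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """Rank gene sets by median NES over the cohorts where tested.

    ``results`` concatenates per-cohort GSEA tables with a ``cohort``
    column. Descending median NES; ties broken by set name for
    determinism. Returns at most ``k`` rows.
    """
    med = (
        results.groupby("set_name")
        .agg(median_nes=("nes", "median"), n_cohorts=("nes", "size"))
        .reset_index()
    )
    med = med.sort_values(
        ["median_nes", "set_name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return med.head(k)


def correlation_ranked_list(
    expression: ExpressionMatrix, anchor_gene: str, condition: str = "tumor"
) -> pd.Series:
    """Rank every other gene by Spearman correlation with an anchor gene."""
    samples = expression.samples_in(condition)
    sub = expression.counts[samples]
    x = sub.loc[anchor_gene].to_numpy(dtype=float)
    ranks_x = stats.rankdata(x)
    mat = stats.rankdata(sub.to_numpy(dtype=float), axis=1)
    xc = ranks_x - ranks_x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((mc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (mc @ xc) / denom
    out = pd.Series(rho, index=sub.index).drop(anchor_gene)
    return out.replace([np.inf, -np.inf], np.nan).dropna().sort_values(ascending=False)
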