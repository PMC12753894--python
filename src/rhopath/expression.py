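"""Expression QC, normalization, NB differential expression, DE-count
enrichment, pan-cancer deregulation classing, and substrate tallies.

Pipeline order is fixed: sample QC by mean pairwise correlation (AAIC) →
lowest-quartile gene filter → within-lane GC normalization → between-lane
full-quantile normalization → negative-binomial differential expression.
A gene is called differentially expressed at |log2FC| > 1 and BH FDR < 0.01.

The differential-expression engine is a from-scratch NB Wald test: per-gene
dispersions are estimated by adjusted method-of-moments, shrunk halfway
toward a fitted mean–dispersion trend, and the Wald statistic is referred
to a Student-t distribution with n1 + n2 − 2 degrees of freedom (plug-in
variance makes a normal reference anticonservative at cohort sizes of a
few dozen samples).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .catalog import PathwayCatalog
from .mutations import BackgroundEnsemble, EnrichmentResult, sample_length_matched_lists
from .tables import ExpressionMatrix

AAIC_CUTOFF = 0.6
LOG2FC_CUTOFF = 1.0
DE_FDR_CUTOFF = 0.01


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def aaic_filter(
    matrix: ExpressionMatrix, cutoff: float = AAIC_CUTOFF
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove outlier samples by array–array intensity correlation.

    Per-sample score = mean Pearson r of log2(count + 1) against every
    other sample; samples scoring below ``cutoff`` are removed in one pass.
    An undefined correlation (constant sample) counts as 0. Returns the
    filtered matrix and a per-sample report.
    """
    n = matrix.counts.shape[1]
    if n < 3:
        raise ValueError("AAIC filter needs at least 3 samples")
    logs = np.log2(matrix.counts.to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(logs, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, np.nan)
    mean_r = np.nanmean(corr, axis=1)
    samples = list(matrix.counts.columns)
    report = pd.DataFrame(
        {
            "sample": samples,
            "mean_pairwise_r": mean_r,
            "removed": mean_r < cutoff,
        }
    )
    keep = [s for s, rm in zip(samples, report["removed"]) if not rm]
    return matrix.subset_samples(keep), report


def low_expression_filter(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose mean count falls strictly below the 25th percentile
    (linear interpolation) of gene means. Returns the filtered matrix and
    the removed gene symbols. Fewer than 4 genes → no-op with a warning."""
    means = matrix.counts.mean(axis=1)
    if len(means) < 4:
        warnings.warn("fewer than 4 genes; lowest-quartile filter skipped", stacklevel=2)
        return matrix, []
    p25 = float(np.percentile(means.to_numpy(), 25))
    removed = means.index[means < p25].tolist()
    kept = means.index[means >= p25]
    out = ExpressionMatrix(
        counts=matrix.counts.loc[kept],
        condition=matrix.condition,
        cohort=matrix.cohort,
        gc=matrix.gc,
        mu=None if matrix.mu is None else matrix.mu.loc[kept],
        ground_truth=matrix.ground_truth,
    )
    return out, removed


def _tie_averaged_lowess(y: np.ndarray, x: np.ndarray, frac: float) -> np.ndarray:
    fitted = lowess(y, x, frac=frac, it=2, return_sorted=False)
    # equal GC values must receive equal fitted values regardless of row order
    if len(np.unique(x)) < len(x):
        df = pd.DataFrame({"x": x, "f": fitted})
        fitted = df.groupby("x")["f"].transform("mean").to_numpy()
    return fitted


def within_lane_gc_normalize(
    matrix: ExpressionMatrix, frac: float = 0.5
) -> ExpressionMatrix:
    """Remove each sample's smooth GC trend from log2(count + 1).

    Per sample, a lowess regression of log2(count + 1) on GC fraction is
    fit; the fitted trend is subtracted and the sample's mean log level
    added back, then values are re-exponentiated and clipped at 0. With a
    constant GC vector the matrix is returned unchanged with a warning.
    """
    if matrix.gc is None:
        raise ValueError("expression matrix lacks per-gene GC fractions")
    gc = matrix.gc.loc[matrix.counts.index].to_numpy(dtype=float)
    if np.allclose(gc, gc[0]):
        warnings.warn("constant GC vector; within-lane normalization skipped", stacklevel=2)
        return matrix
    logs = np.log2(matrix.counts.to_numpy(dtype=float) + 1.0)
    out = np.empty_like(logs)
    for j in range(logs.shape[1]):
        fitted = _tie_averaged_lowess(logs[:, j], gc, frac)
        out[:, j] = logs[:, j] - fitted + fitted.mean()
    normalized = np.clip(2.0 ** out - 1.0, 0.0, None)
    return ExpressionMatrix(
        counts=pd.DataFrame(
            normalized, index=matrix.counts.index, columns=matrix.counts.columns
        ),
        condition=matrix.condition,
        cohort=matrix.cohort,
        gc=matrix.gc,
        ground_truth=matrix.ground_truth,
    )


def between_lane_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Full-quantile normalization across samples.

    Afterwards every sample has the identical sorted value multiset (the
    per-rank mean of the sorted input columns); within-sample rank order is
    preserved, and tied values receive the mean of the quantile values
    their tie group spans.
    """
    X = matrix.counts.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    sorted_cols = np.sort(X, axis=0)
    mean_q = sorted_cols.mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        order = np.argsort(X[:, j], kind="stable")
        vals = X[order, j]
        assigned = np.empty(n_genes)
        start = 0
        while start < n_genes:
            end = start + 1
            while end < n_genes and vals[end] == vals[start]:
                end += 1
            assigned[start:end] = mean_q[start:end].mean()
            start = end
        out[order, j] = assigned
    return ExpressionMatrix(
        counts=pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns),
        condition=matrix.condition,
        cohort=matrix.cohort,
        gc=matrix.gc,
        ground_truth=matrix.ground_truth,
    )


# ---------------------------------------------------------------------------
# NB differential expression
# ---------------------------------------------------------------------------

def _dispersion_trend(mean: np.ndarray, alpha_raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a + b / mu by non-negative least squares."""
    from scipy.optimize import nnls

    ok = (mean > 0) & (alpha_raw > 0)
    if ok.sum() < 10:
        fallback = (
            float(np.median(alpha_raw[alpha_raw > 0])) if (alpha_raw > 0).any() else 1e-6
        )
        return np.full_like(mean, max(fallback, 1e-6))
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, _ = nnls(A, alpha_raw[ok])
    trend = coef[0] + coef[1] / np.maximum(mean, 1e-8)
    return np.maximum(trend, 1e-8)


def nb_differential_expression(
    matrix: ExpressionMatrix,
    groups: pd.Series | None = None,
    shrinkage_weight: float = 0.5,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    fdr_cutoff: float = DE_FDR_CUTOFF,
) -> pd.DataFrame:
    """Per-gene NB Wald test of tumor versus normal (or explicit groups).

    log2FC is computed from group means with a 0.5 pseudo-count (tumor over
    normal). Gene-wise dispersions come from an adjusted method-of-moments
    estimate pooled across groups and are shrunk toward a fitted
    mean–dispersion trend with weight ``shrinkage_weight``. The Wald
    statistic uses the NB variance mu + alpha mu² of each group mean and a
    t reference with n1 + n2 − 2 df. Status: ``up`` when log2FC > cutoff
    and FDR < cutoff, ``down`` symmetric, else ``ns``.
    """
    if groups is None:
        groups = matrix.condition
    labels = groups.loc[list(matrix.counts.columns)]
    levels = sorted(labels.unique())
    if set(levels) == {"normal", "tumor"}:
        test_level, ref_level = "tumor", "normal"
    elif len(levels) == 2:
        ref_level, test_level = levels
    else:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    cols1 = [s for s in matrix.counts.columns if labels[s] == test_level]
    cols0 = [s for s in matrix.counts.columns if labels[s] == ref_level]
    n1, n0 = len(cols1), len(cols0)
    if min(n1, n0) < 2:
        raise ValueError("need >= 2 samples per group")

    X1 = matrix.counts[cols1].to_numpy(dtype=float)
    X0 = matrix.counts[cols0].to_numpy(dtype=float)
    m1, m0 = X1.mean(axis=1), X0.mean(axis=1)
    v1 = X1.var(axis=1, ddof=1)
    v0 = X0.var(axis=1, ddof=1)

    # adjusted method-of-moments dispersion pooled over groups
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (v1 - m1) / np.square(m1)
        a0 = (v0 - m0) / np.square(m0)
    a1 = np.nan_to_num(a1, nan=0.0, posinf=0.0, neginf=0.0)
    a0 = np.nan_to_num(a0, nan=0.0, posinf=0.0, neginf=0.0)
    w1, w0 = n1 - 1, n0 - 1
    alpha_raw = np.clip((w1 * a1 + w0 * a0) / (w1 + w0), 0.0, None)
    pooled_mean = (n1 * m1 + n0 * m0) / (n1 + n0)
    alpha_trend = _dispersion_trend(pooled_mean, alpha_raw)
    alpha = shrinkage_weight * alpha_trend + (1.0 - shrinkage_weight) * alpha_raw

    log2fc = np.log2((m1 + 0.5) / (m0 + 0.5))
    var_m1 = (m1 + alpha * np.square(m1)) / n1
    var_m0 = (m0 + alpha * np.square(m0)) / n0
    se = np.sqrt(
        var_m1 / np.square(m1 + 0.5) + var_m0 / np.square(m0 + 0.5)
    ) / np.log(2.0)
    se = np.maximum(se, 1e-12)
    tstat = log2fc / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n1 + n0 - 2)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    status = np.where(
        (log2fc > log2fc_cutoff) & (fdr < fdr_cutoff),
        "up",
        np.where((log2fc < -log2fc_cutoff) & (fdr < fdr_cutoff), "down", "ns"),
    )
    zero_group = (X1.sum(axis=1) == 0) | (X0.sum(axis=1) == 0)
    return pd.DataFrame(
        {
            "gene": matrix.counts.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "status": status,
            "dispersion": alpha,
            "mean_test": m1,
            "mean_ref": m0,
            "zero_group_flag": zero_group,
        }
    ).set_index("gene")


def run_expression_pipeline(
    matrix: ExpressionMatrix,
    aaic_cutoff: float = AAIC_CUTOFF,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    fdr_cutoff: float = DE_FDR_CUTOFF,
) -> tuple[pd.DataFrame, dict]:
    """AAIC → quartile filter → within-lane → between-lane → DE.

    Returns the DE table plus a manifest of stage in/out row counts.
    """
    filtered, qc = aaic_filter(matrix, cutoff=aaic_cutoff)
    filtered, removed_genes = low_expression_filter(filtered)
    if matrix.gc is not None:
        filtered = within_lane_gc_normalize(filtered)
    filtered = between_lane_normalize(filtered)
    de = nb_differential_expression(
        filtered, log2fc_cutoff=log2fc_cutoff, fdr_cutoff=fdr_cutoff
    )
    manifest = {
        "samples_in": int(matrix.counts.shape[1]),
        "samples_removed_aaic": int(qc["removed"].sum()),
        "genes_in": int(matrix.counts.shape[0]),
        "genes_removed_low_expression": len(removed_genes),
        "genes_tested": int(de.shape[0]),
        "n_de": int((de["status"] != "ns").sum()),
    }
    return de, manifest


# ---------------------------------------------------------------------------
# DE-count resampling enrichment
# ---------------------------------------------------------------------------

def de_count_enrichment(
    de: pd.DataFrame,
    catalog: PathwayCatalog,
    background: pd.DataFrame,
    n_lists: int = 1000,
    seed: int = 0,
    cohort: str = "COHORT",
) -> EnrichmentResult:
    """Is the number of DE pathway genes higher than length-matched chance?

    Observed = count of catalog genes with status != ns. The background is
    the DE count in ``n_lists`` length-matched random gene lists; p is the
    Poisson upper tail at the background mean.
    """
    ensemble: BackgroundEnsemble = sample_length_matched_lists(
        catalog, background, n_lists=n_lists, seed=seed
    )
    de_genes = set(de.index[de["status"] != "ns"])
    observed = float(len(de_genes & set(catalog.symbols)))
    per_list = np.array(
        [float(len(de_genes & set(genes))) for genes in ensemble.lists]
    )
    ensemble.per_list_statistic = per_list
    ensemble.statistic_kind = "de_count"
    mean = float(per_list.mean())
    sd = float(per_list.std(ddof=1))
    z = ensemble.z_of(observed)
    if mean > 0:
        p = float(stats.poisson.sf(np.ceil(observed) - 1, mean))
    else:
        p = 1.0 if observed <= 0 else 0.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(
        cohort=cohort,
        statistic_kind="de_count",
        observed=observed,
        background_mean=mean,
        background_sd=sd,
        z=z,
        p=p,
    ).with_tier()


# ---------------------------------------------------------------------------
# pan-cancer classing
# ---------------------------------------------------------------------------

BREADTH_BAR = 0.25


def pan_cancer_classify(statuses: list[str] | pd.Series, gene: str = "") -> dict:
    """Class one gene's per-cohort DE statuses into a pan-cancer profile.

    breadth = (n_up + n_down) / n_tested. Tier: > 50% → ``gt50pct``,
    (25%, 50%] → ``25to50pct``, else ``lt25pct``. Class: ``none`` with no
    DE cohort; ``pan_up`` / ``pan_down`` when one direction dominates and
    breadth exceeds 25%; ``mixed`` on a direction tie or both directions
    below the breadth bar; ``restricted`` otherwise (narrow,
    single-direction deregulation).
    """
    statuses = list(statuses)
    n_tested = len(statuses)
    if n_tested == 0:
        raise ValueError("no cohorts tested")
    n_up = sum(s == "up" for s in statuses)
    n_down = sum(s == "down" for s in statuses)
    breadth = (n_up + n_down) / n_tested
    if breadth > 0.5:
        tier = "gt50pct"
    elif breadth > 0.25:
        tier = "25to50pct"
    else:
        tier = "lt25pct"
    if n_up == 0 and n_down == 0:
        klass = "none"
    elif n_up == n_down:
        klass = "mixed"
    elif breadth > BREADTH_BAR:
        klass = "pan_up" if n_up > n_down else "pan_down"
    elif n_up > 0 and n_down > 0:
        klass = "mixed"
    else:
        klass = "restricted"
    return {
        "gene": gene,
        "n_cohorts_tested": n_tested,
        "n_up": n_up,
        "n_down": n_down,
        "class": klass,
        "breadth_fraction": breadth,
        "tier": tier,
    }


def pan_cancer_profiles(per_cohort_de: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Apply :func:`pan_cancer_classify` to every gene over cohorts.

    ``per_cohort_de`` maps cohort name → DE table indexed by gene. Genes are
    classed over the cohorts in which they were tested.
    """
    genes: set[str] = set()
    for de in per_cohort_de.values():
        genes |= set(de.index)
    rows = []
    for g in sorted(genes):
        statuses = [
            str(de.loc[g, "status"]) for de in per_cohort_de.values() if g in de.index
        ]
        rows.append(pan_cancer_classify(statuses, gene=g))
    return pd.DataFrame(rows).set_index("gene")


def substrate_specificity_tally(
    profiles: pd.DataFrame,
    catalog: PathwayCatalog,
    denominator: str = "all",
) -> pd.DataFrame:
    """Substrate composition of pan-up / pan-down GEF and GAP lists.

    For each regulator category (GEF, GAP) and direction (pan_up,
    pan_down), counts the list members specific for each GTPase substrate
    and reports the percentage over the list size at one decimal. With
    ``denominator="known"`` percentages are over substrate-annotated
    members only; the default counts all members of the tallied list.
    """
    if denominator not in ("all", "known"):
        raise ValueError("denominator must be 'all' or 'known'")
    rows = []
    for category in ("GEF", "GAP"):
        members = set(catalog.in_category(category))
        for direction in ("pan_up", "pan_down"):
            in_list = [
                g
                for g in profiles.index
                if g in members and profiles.loc[g, "class"] == direction
            ]
            substrates = [catalog.substrate_of(g) for g in in_list]
            denom = (
                len(in_list)
                if denominator == "all"
                else sum(s != "UNKNOWN" for s in substrates)
            )
            for substrate in ("RHOA", "RAC1", "CDC42", "UNKNOWN"):
                count = sum(s == substrate for s in substrates)
                pct = round(100.0 * count / denom, 1) if denom else 0.0
                rows.append(
                    {
                        "category": category,
                        "direction": direction,
                        "substrate": substrate,
                        "count": count,
                        "list_size": len(in_list),
                        "pct": pct,
                    }
                )
    return pd.DataFrame(rows)
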