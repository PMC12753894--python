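"""Mutation-burden analysis: hypermutator filtering, gene load/prevalence,
and the length-matched resampling enrichment test.

The enrichment question is whether a curated gene list carries more
protein-altering mutations than expected for its gene lengths. The null is
built by resampling many background gene lists that reproduce the pathway
list's length distribution (decile bins on log10 coding length), computing
the statistic on each, and referring the observed value to a Poisson upper
tail at the background mean; the Z-score against the background ensemble is
reported as an effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import PathwayCatalog
from .tables import MutationTable, NONSYNONYMOUS_CLASSES, TableError

#: Samples exceeding this multiple of the cohort-mean burden are dropped.
HYPERMUTATOR_FOLD = 4.5


@dataclass
class BackgroundEnsemble:
    """Resampled length-matched gene lists and their per-list statistics."""

    n_lists: int
    lists: list[list[str]]
    per_list_statistic: np.ndarray | None = None
    statistic_kind: str | None = None

    def z_of(self, observed: float) -> float:
        if self.per_list_statistic is None:
            raise ValueError("ensemble statistics not populated")
        mean = float(np.mean(self.per_list_statistic))
        sd = float(np.std(self.per_list_statistic, ddof=1))
        if sd == 0.0:
            if observed == mean:
                return 0.0
            return float(np.sign(observed - mean)) * float("inf")
        return (observed - mean) / sd

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, genes in enumerate(self.lists):
            stat = (
                float(self.per_list_statistic[i])
                if self.per_list_statistic is not None
                else np.nan
            )
            rows.append({"list_id": i, "genes": ";".join(genes), "statistic": stat})
        return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    cohort: str
    statistic_kind: str
    observed: float
    background_mean: float
    background_sd: float
    z: float
    p: float
    fdr: float | None = None
    tier: str | None = None

    def with_tier(self) -> "EnrichmentResult":
        if self.p < 0.001:
            tier = "p<0.001"
        elif self.p < 0.01:
            tier = "p<0.01"
        elif self.p < 0.05:
            tier = "p<0.05"
        else:
            tier = "ns"
        self.tier = tier
        return self


def filter_hypermutators(
    mutations: MutationTable, fold: float = HYPERMUTATOR_FOLD
) -> tuple[MutationTable, pd.DataFrame]:
    """Remove samples whose burden exceeds ``fold`` × the cohort mean.

    The cohort mean is computed once over all samples (non-iterative).
    Returns the retained table and a per-sample report with columns
    ``sample_id``, ``cohort_id``, ``per_sample_count``, ``cohort_mean``,
    ``hypermutator_flag``.
    """
    if len(mutations.records) == 0:
        raise TableError("no samples: empty mutation table")
    rec = mutations.records
    burden = (
        rec.groupby(["cohort_id", "sample_id"]).size().rename("per_sample_count").reset_index()
    )
    burden["cohort_mean"] = burden.groupby("cohort_id")["per_sample_count"].transform("mean")
    burden["hypermutator_flag"] = burden["per_sample_count"] > fold * burden["cohort_mean"]
    flagged = set(burden.loc[burden["hypermutator_flag"], "sample_id"])
    retained = MutationTable(
        records=rec[~rec["sample_id"].isin(flagged)].reset_index(drop=True),
        ground_truth=mutations.ground_truth,
    )
    return retained, burden


def gene_load(
    mutations: MutationTable,
    genes: list[str] | set[str],
    n_samples: int | None = None,
    include_synonymous: bool = False,
) -> pd.DataFrame:
    """Per-gene mutational load and prevalence over retained samples.

    ``load`` counts protein-altering records (missense, truncating, other);
    synonymous records are excluded unless ``include_synonymous``.
    ``prevalence`` is the fraction of samples carrying at least one counted
    mutation in the gene. Genes absent from the table get zeros.

    Hypermutator filtering is the caller's responsibility; apply
    :func:`filter_hypermutators` first.
    """
    rec = mutations.records
    if n_samples is None:
        n_samples = rec["sample_id"].nunique()
    if not include_synonymous:
        rec = rec[rec["variant_class"].isin(NONSYNONYMOUS_CLASSES)]
    genes = list(genes)
    grouped = rec[rec["gene"].isin(set(genes))].groupby("gene")
    load = grouped.size()
    carriers = grouped["sample_id"].nunique()
    out = pd.DataFrame(
        {
            "gene": genes,
            "load": [int(load.get(g, 0)) for g in genes],
            "n_carriers": [int(carriers.get(g, 0)) for g in genes],
        }
    )
    out["prevalence"] = out["n_carriers"] / n_samples if n_samples else 0.0
    return out


def _length_bins(path_lengths: np.ndarray) -> np.ndarray:
    """Decile bin edges of log10 length, computed on the pathway list."""
    logs = np.log10(path_lengths.astype(float))
    edges = np.quantile(logs, np.linspace(0, 1, 11))
    # guard against duplicate edges on small or tied lists
    edges[0], edges[-1] = -np.inf, np.inf
    return edges


def sample_length_matched_lists(
    catalog: PathwayCatalog,
    background: pd.DataFrame,
    n_lists: int = 1000,
    seed: int = 0,
) -> BackgroundEnsemble:
    """Draw ``n_lists`` background gene lists length-matched to the catalog.

    Pathway genes are binned into deciles of log10 coding length; every
    sampled list reproduces the pathway per-bin counts exactly, sampling
    without replacement within a list (independently across lists).
    Pathway genes are excluded from the background pool.

    Raises
    ------
    ValueError
        If some bin has fewer eligible background genes than the pathway
        list needs, naming the bin.
    """
    path_lengths = catalog.lengths()
    edges = _length_bins(path_lengths.to_numpy())
    path_bins = np.digitize(np.log10(path_lengths.to_numpy(dtype=float)), edges[1:-1])
    need = np.bincount(path_bins, minlength=10)

    pool = background[~background["symbol"].isin(set(catalog.symbols))]
    pool_symbols = pool["symbol"].to_numpy()
    pool_bins = np.digitize(
        np.log10(pool["coding_length_bp"].to_numpy(dtype=float)), edges[1:-1]
    )

    by_bin: list[np.ndarray] = []
    for b in range(10):
        members = pool_symbols[pool_bins == b]
        if need[b] > len(members):
            raise ValueError(
                f"length bin {b} has only {len(members)} background genes, "
                f"needs {need[b]}"
            )
        by_bin.append(members)

    rng = np.random.default_rng(seed)
    lists: list[list[str]] = []
    for _ in range(n_lists):
        drawn: list[str] = []
        for b in range(10):
            if need[b]:
                drawn.extend(rng.choice(by_bin[b], size=need[b], replace=False))
        lists.append(drawn)
    return BackgroundEnsemble(n_lists=n_lists, lists=lists)


def populate_ensemble_statistic(
    ensemble: BackgroundEnsemble,
    mutations: MutationTable,
    statistic_kind: str,
    n_samples: int | None = None,
) -> BackgroundEnsemble:
    """Compute the per-list load or prevalence statistic on ``mutations``.

    ``load`` sums per-gene protein-altering counts over the list;
    ``prevalence`` is the fraction of samples carrying >=1 such mutation in
    any list gene.
    """
    if statistic_kind not in ("load", "prevalence"):
        raise ValueError(f"unknown statistic_kind {statistic_kind!r}")
    rec = mutations.records
    rec = rec[rec["variant_class"].isin(NONSYNONYMOUS_CLASSES)]
    if n_samples is None:
        n_samples = mutations.records["sample_id"].nunique()

    stats_out = np.empty(ensemble.n_lists)
    if statistic_kind == "load":
        per_gene = rec.groupby("gene").size()
        for i, genes in enumerate(ensemble.lists):
            stats_out[i] = float(per_gene.reindex(genes).fillna(0).sum())
    else:
        pairs = rec[["gene", "sample_id"]].drop_duplicates()
        by_gene = {g: set(sub["sample_id"]) for g, sub in pairs.groupby("gene")}
        for i, genes in enumerate(ensemble.lists):
            carriers: set[str] = set()
            for g in genes:
                carriers |= by_gene.get(g, set())
            stats_out[i] = len(carriers) / n_samples if n_samples else 0.0
    ensemble.per_list_statistic = stats_out
    ensemble.statistic_kind = statistic_kind
    return ensemble


def observed_statistic(
    mutations: MutationTable,
    catalog: PathwayCatalog,
    statistic_kind: str,
    n_samples: int | None = None,
) -> float:
    """The pathway-list load or prevalence on the retained mutation table."""
    loads = gene_load(mutations, catalog.symbols, n_samples=n_samples)
    if statistic_kind == "load":
        return float(loads["load"].sum())
    rec = mutations.records
    rec = rec[
        rec["variant_class"].isin(NONSYNONYMOUS_CLASSES)
        & rec["gene"].isin(set(catalog.symbols))
    ]
    if n_samples is None:
        n_samples = mutations.records["sample_id"].nunique()
    return rec["sample_id"].nunique() / n_samples if n_samples else 0.0


def enrichment_test(
    observed: float,
    ensemble: BackgroundEnsemble,
    statistic_kind: str,
    cohort: str = "COHORT",
    n_samples: int | None = None,
) -> EnrichmentResult:
    """Poisson upper-tail test of the observed statistic against the
    background ensemble, with the ensemble Z-score as effect size.

    ``lambda`` is the mean per-list statistic. For prevalence both the
    observed value and ``lambda`` are scaled to expected carrier counts
    (fraction × ``n_samples``) before the Poisson tail. ``p`` is
    ``P(X >= observed | Poisson(lambda))``. BH adjustment across cohorts is
    the caller's job (see :func:`adjust_enrichment_results`).
    """
    if ensemble.per_list_statistic is None:
        raise ValueError("ensemble statistics not populated")
    if ensemble.statistic_kind != statistic_kind:
        raise ValueError(
            f"ensemble holds {ensemble.statistic_kind!r} statistics, "
            f"requested {statistic_kind!r}"
        )
    mean = float(np.mean(ensemble.per_list_statistic))
    sd = float(np.std(ensemble.per_list_statistic, ddof=1))
    z = ensemble.z_of(observed)

    if statistic_kind == "prevalence":
        if n_samples is None:
            raise ValueError("n_samples required to scale prevalence to counts")
        lam = mean * n_samples
        obs_count = observed * n_samples
    else:
        lam = mean
        obs_count = observed
    # P(X >= obs) with X ~ Poisson(lam); sf(k-1) gives P(X >= k)
    p = float(stats.poisson.sf(np.ceil(obs_count) - 1, lam)) if lam > 0 else (
        1.0 if obs_count <= 0 else 0.0
    )
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(
        cohort=cohort,
        statistic_kind=statistic_kind,
        observed=observed,
        background_mean=mean,
        background_sd=sd,
        z=z,
        p=p,
    ).with_tier()


def adjust_enrichment_results(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini–Hochberg FDR across cohorts; significance at FDR < 0.05."""
    from statsmodels.stats.multitest import multipletests

    if not results:
        return results
    pvals = [r.p for r in results]
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    return results


def background_normality_diagnostic(ensemble: BackgroundEnsemble) -> dict:
    """Shapiro–Wilk statistic on the background distribution.

    Diagnostic only — never gates the enrichment test.
    """
    if ensemble.per_list_statistic is None:
        raise ValueError("ensemble statistics not populated")
    values = np.asarray(ensemble.per_list_statistic, dtype=float)
    sub = values[:500] if len(values) > 500 else values
    if len(sub) < 3 or np.std(sub) == 0:
        return {"statistic": float("nan"), "pvalue": float("nan")}
    stat, p = stats.shapiro(sub)
    return {"statistic": float(stat), "pvalue": float(p)}
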