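"""Post-classification of positive-selection and mutation-cluster outputs.

dN/dS q-values (global, missense, truncating) and mutation-cluster tables
come from external tools; this module applies the classification tiers:
a gene is under significant positive selection when qglobal < 0.01, and
the missense/truncating sub-q-values decide which mutation class carries
the signal. Cluster ("hotspot") summaries report the fraction of each
mutation class falling inside clusters (flag at > 30%) and the fraction of
cohort samples carrying an in-cluster mutation (flag at > 3%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .tables import MutationTable, TableError

Q_CUTOFF = 0.01
FRACTION_FLAG_CUTOFF = 0.30
PREVALENCE_FLAG_CUTOFF = 0.03


@dataclass(frozen=True)
class ClusterTable:
    """Per-(gene, cohort) sets of clustered 1-based protein positions."""

    clusters: pd.DataFrame  # columns: gene, cohort, start, end

    def positions_for(self, gene: str, cohort: str) -> set[int]:
        sub = self.clusters[
            (self.clusters["gene"] == gene) & (self.clusters["cohort"] == cohort)
        ]
        out: set[int] = set()
        for row in sub.itertuples(index=False):
            out.update(range(int(row.start), int(row.end) + 1))
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClusterTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cohort": str})
        missing = [c for c in ("gene", "cohort", "start", "end") if c not in df.columns]
        if missing:
            raise TableError(f"cluster table missing column(s): {missing}")
        return cls(df)


def load_selection_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cohort": str})
    missing = [
        c
        for c in ("gene", "cohort", "qglobal_cv", "qmis_cv", "qtrunc_cv")
        if c not in df.columns
    ]
    if missing:
        raise TableError(f"selection table missing column(s): {missing}")
    return df


def classify_selection(table: pd.DataFrame, q_cutoff: float = Q_CUTOFF) -> pd.DataFrame:
    """Class each (gene, cohort) row by which mutation class is selected.

    ``none`` when qglobal >= cutoff; otherwise ``missense_selected``,
    ``truncation_selected``, or ``both`` according to the sub-q-values.
    A qglobal-significant row with neither sub-q significant is classed
    ``none`` and surfaced with a warning (the external tools' q-values
    rarely produce this).
    """
    for col in ("qglobal_cv", "qmis_cv", "qtrunc_cv"):
        vals = table[col]
        if ((vals < 0) | (vals > 1)).any():
            bad = table.loc[(vals < 0) | (vals > 1), "gene"].tolist()
            raise ValueError(f"{col} outside [0, 1] for gene(s): {bad}")

    classes = []
    for row in table.itertuples(index=False):
        if row.qglobal_cv >= q_cutoff:
            classes.append("none")
            continue
        mis = row.qmis_cv < q_cutoff
        trunc = row.qtrunc_cv < q_cutoff
        if mis and trunc:
            classes.append("both")
        elif mis:
            classes.append("missense_selected")
        elif trunc:
            classes.append("truncation_selected")
        else:
            warnings.warn(
                f"{row.gene}/{row.cohort}: qglobal < {q_cutoff} but neither "
                "sub-q significant; classed none",
                stacklevel=2,
            )
            classes.append("none")
    out = table[["gene", "cohort"]].copy()
    out["selection_class"] = classes
    return out


def hotspot_fractions(
    mutations: MutationTable,
    clusters: ClusterTable,
    cohort_size: int,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-(gene, cohort) in-cluster mutation fractions and hotspot prevalence.

    ``missense_fraction_in_clusters`` and ``truncating_fraction_in_clusters``
    are in-cluster counts over total counts of that class (0 when the class
    has no mutations). ``hotspot_prevalence`` is the fraction of cohort
    samples carrying >= 1 in-cluster mutation. Flags apply the strict
    > 30% (fraction) and > 3% (prevalence) tiers.

    With ``pooled=True`` cohorts are merged and prevalence uses
    ``cohort_size`` as the pooled sample count.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    rec = mutations.records
    if "position" not in rec.columns:
        raise TableError("mutation table lacks a position column")
    if rec["position"].isna().any():
        raise TableError("mutation positions missing for some records")

    rec = rec.copy()
    if pooled:
        rec["cohort_id"] = "POOLED"

    rows = []
    for (gene, cohort), sub in rec.groupby(["gene", "cohort_id"]):
        cluster_positions = (
            clusters.positions_for(gene, cohort)
            if not pooled
            else set().union(
                *(
                    clusters.positions_for(gene, c)
                    for c in clusters.clusters["cohort"].unique()
                )
            )
            if len(clusters.clusters)
            else set()
        )
        in_cluster = sub["position"].astype(int).isin(cluster_positions)
        fractions = {}
        for klass in ("missense", "truncating"):
            mask = sub["variant_class"] == klass
            total = int(mask.sum())
            fractions[klass] = (
                float((mask & in_cluster).sum()) / total if total else 0.0
            )
        carriers = sub.loc[in_cluster, "sample_id"].nunique()
        prevalence = carriers / cohort_size
        rows.append(
            {
                "gene": gene,
                "cohort": cohort,
                "missense_fraction_in_clusters": fractions["missense"],
                "truncating_fraction_in_clusters": fractions["truncating"],
                "hotspot_prevalence": prevalence,
                "fraction_flag": (
                    fractions["missense"] > FRACTION_FLAG_CUTOFF
                    or fractions["truncating"] > FRACTION_FLAG_CUTOFF
                ),
                "prevalence_flag": prevalence > PREVALENCE_FLAG_CUTOFF,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cohort",
            "missense_fraction_in_clusters",
            "truncating_fraction_in_clusters",
            "hotspot_prevalence",
            "fraction_flag",
            "prevalence_flag",
        ],
    )
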