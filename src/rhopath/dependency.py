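"""Pan-cancer essentiality and lineage-specific vulnerability statistics
on CRISPR dependency score matrices.

A gene is pan-cancer essential when its Chronos-like score falls below
−0.5 in strictly more than 10% of screened cell lines. Lineage
vulnerability compares each lineage's score distribution for a gene with
all remaining lines: Welch's unequal-variance test provides the p-value
(BH-adjusted over all gene × lineage tests), and a gene is flagged when
|median difference| > 0.5 with FDR < 0.01, direction ``sensitizing`` when
knockout depletes the lineage (negative difference) and ``protective``
otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import DependencyMatrix

CHRONOS_CUTOFF = -0.5
ESSENTIAL_FRACTION = 0.10
MEDIAN_DIFF_CUTOFF = 0.5
VULNERABILITY_FDR_CUTOFF = 0.01
MIN_LINEAGE_SIZE = 3


def pan_cancer_essential(
    dep: DependencyMatrix,
    threshold: float = CHRONOS_CUTOFF,
    fraction: float = ESSENTIAL_FRACTION,
) -> pd.DataFrame:
    """Percentage of dependent lines per gene and the pan-essential call.

    A line counts as dependent iff its score is strictly below
    ``threshold``; the call requires strictly more than ``fraction`` of
    lines dependent.
    """
    if dep.scores.size == 0:
        raise ValueError("empty dependency matrix")
    dependent = (dep.scores < threshold).sum(axis=1)
    pct = 100.0 * dependent / dep.scores.shape[1]
    return pd.DataFrame(
        {
            "gene": dep.scores.index,
            "n_lines_dependent": dependent.to_numpy(),
            "pct_lines_dependent": pct.to_numpy(),
            "pan_essential": (pct > 100.0 * fraction).to_numpy(),
        }
    ).set_index("gene")


def lineage_vulnerability(
    dep: DependencyMatrix,
    min_group: int = MIN_LINEAGE_SIZE,
    median_diff_cutoff: float = MEDIAN_DIFF_CUTOFF,
    fdr_cutoff: float = VULNERABILITY_FDR_CUTOFF,
    test: str = "welch",
) -> pd.DataFrame:
    """Per-(gene, lineage) vulnerability statistics.

    For every lineage with at least ``min_group`` lines (smaller lineages
    are skipped with a warning), each gene's scores in the lineage are
    compared with all remaining lines. ``median_diff`` = in-lineage median
    − out-of-lineage median; the p-value comes from Welch's test
    (``test="student"`` for the pooled-variance variant); BH FDR is taken
    over all gene × lineage tests. ``flagged`` ⇔ |median_diff| >
    ``median_diff_cutoff`` and FDR < ``fdr_cutoff``.
    """
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    lineages = dep.lineage.loc[list(dep.scores.columns)]
    scores = dep.scores.to_numpy(dtype=float)
    rows = []
    for lineage in sorted(lineages.unique()):
        mask = (lineages == lineage).to_numpy()
        n_in = int(mask.sum())
        if n_in < min_group:
            warnings.warn(
                f"lineage {lineage!r} has {n_in} < {min_group} lines; skipped",
                stacklevel=2,
            )
            continue
        inside = scores[:, mask]
        outside = scores[:, ~mask]
        med_in = np.median(inside, axis=1)
        med_out = np.median(outside, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(
                inside, outside, axis=1, equal_var=(test == "student")
            )
        # zero variance in both groups: equal medians -> p = 1
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        for gi, gene in enumerate(dep.scores.index):
            rows.append(
                {
                    "gene": gene,
                    "lineage": lineage,
                    "n_in": n_in,
                    "median_in": med_in[gi],
                    "median_out": med_out[gi],
                    "median_diff": med_in[gi] - med_out[gi],
                    "p": float(pvals[gi]),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["gene", "lineage", "n_in", "median_in", "median_out", "median_diff", "p"],
    )
    if len(out):
        _, fdr, _, _ = multipletests(out["p"], method="fdr_bh")
        out["fdr"] = fdr
    else:
        out["fdr"] = pd.Series(dtype=float)
    out["flagged"] = (np.abs(out["median_diff"]) > median_diff_cutoff) & (
        out["fdr"] < fdr_cutoff
    )
    out["direction"] = np.where(out["median_diff"] < 0, "sensitizing", "protective")
    return out
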