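"""Copy-number–expression integration: genotype classing, SCN-vs-diploid
expression contrasts, driver co-occurrence, and concordance classing.

Thresholded calls (−2 deep deletion … +2 deep amplification) stratify
tumor samples per gene; deep and shallow alterations are analyzed
separately. An alteration class with prevalence above 10% of tumor samples
is "high prevalence". The SCN-vs-diploid expression contrast reuses the NB
differential-expression engine; co-occurrence with driver genes uses the
one-sided Fisher exact test on binary alteration matrices; concordance
between the SCN contrast and the tumor-vs-normal contrast classes a gene
as reinforcing (dosage and disease point the same way), opposing, or inert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import DE_FDR_CUTOFF, LOG2FC_CUTOFF, nb_differential_expression
from .tables import CnvMatrix, ExpressionMatrix

PREVALENCE_CUTOFF = 0.10
COOC_FDR_CUTOFF = 0.05

GENOTYPE_MAP = {
    -2: "deep_del",
    -1: "shallow_del",
    0: "diploid",
    1: "shallow_amp",
    2: "deep_amp",
}

#: alteration class -> (call value, depth, direction sign)
ALTERATION_CLASSES = {
    "deep_amp": (2, "deep", +1),
    "deep_del": (-2, "deep", -1),
    "shallow_amp": (1, "shallow", +1),
    "shallow_del": (-1, "shallow", -1),
}


def genotype_classify(cnv: CnvMatrix, gene: str) -> pd.Series:
    """Map a gene's thresholded calls to genotype classes per sample."""
    calls = cnv.calls.loc[gene]
    bad = set(calls.unique()) - set(GENOTYPE_MAP)
    if bad:
        raise ValueError(f"{gene}: out-of-vocabulary call value(s) {sorted(bad)}")
    return calls.map(GENOTYPE_MAP)


def alteration_prevalence(
    cnv: CnvMatrix, gene: str, alteration_class: str
) -> float:
    """Fraction of samples carrying the given alteration class."""
    call, _, _ = ALTERATION_CLASSES[alteration_class]
    calls = cnv.calls.loc[gene]
    return float((calls == call).sum()) / len(calls)


@dataclass
class ScnContrast:
    gene: str
    alteration_class: str
    prevalence: float
    high_prevalence: bool
    log2fc: float
    fdr: float
    testable: bool
    n_altered: int
    n_diploid: int


def scn_vs_diploid_contrast(
    cnv: CnvMatrix,
    expression: ExpressionMatrix,
    gene: str,
    alteration_class: str,
    min_group: int = 2,
) -> ScnContrast:
    """Expression contrast of altered-at-depth versus diploid tumor samples.

    Delegates to the NB differential-expression engine with groups =
    {altered, diploid}; a group smaller than ``min_group`` flags the result
    not-testable instead of erroring.
    """
    call, _, _ = ALTERATION_CLASSES[alteration_class]
    tumor = [
        s
        for s in cnv.calls.columns
        if s in expression.counts.columns and expression.condition[s] == "tumor"
    ]
    calls = cnv.calls.loc[gene, tumor]
    altered = [s for s in tumor if calls[s] == call]
    diploid = [s for s in tumor if calls[s] == 0]
    prevalence = len(altered) / len(tumor) if tumor else 0.0
    base = dict(
        gene=gene,
        alteration_class=alteration_class,
        prevalence=prevalence,
        high_prevalence=prevalence > PREVALENCE_CUTOFF,
        n_altered=len(altered),
        n_diploid=len(diploid),
    )
    if len(altered) < min_group or len(diploid) < min_group:
        return ScnContrast(log2fc=np.nan, fdr=np.nan, testable=False, **base)
    sub = expression.subset_samples(altered + diploid)
    groups = pd.Series(
        ["altered"] * len(altered) + ["diploid"] * len(diploid),
        index=altered + diploid,
    )
    # 'altered' sorts before 'diploid'; engine takes the later level as test,
    # so relabel to keep altered as the test group
    groups = groups.map({"diploid": "a_ref", "altered": "b_test"})
    de = nb_differential_expression(sub, groups=groups)
    row = de.loc[gene]
    return ScnContrast(
        log2fc=float(row["log2fc"]),
        fdr=float(row["fdr"]),
        testable=True,
        **base,
    )


def cooccurrence_with_drivers(
    cnv: CnvMatrix,
    pathway_genes: list[str],
    driver_genes: list[str],
    depth: str,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher exact tests of co-alteration with driver genes.

    Calls are binarized at the given depth (``deep``: |call| = 2,
    ``shallow``: |call| = 1), same direction (amplification with
    amplification, deletion with deletion). BH adjustment across pairs
    within the matrix; linked ⇔ adjusted p < 0.05. Degenerate margins
    (a gene altered in no or all samples) give p = 1 and a flag.
    """
    if depth not in ("deep", "shallow"):
        raise ValueError("depth must be 'deep' or 'shallow'")
    magnitude = 2 if depth == "deep" else 1
    rows = []
    n = cnv.calls.shape[1]
    for direction, sign in (("amp", +1), ("del", -1)):
        target = sign * magnitude
        for pg in pathway_genes:
            a = (cnv.calls.loc[pg] == target).to_numpy()
            for dg in driver_genes:
                if dg == pg:
                    continue
                b = (cnv.calls.loc[dg] == target).to_numpy()
                both = int((a & b).sum())
                only_a = int((a & ~b).sum())
                only_b = int((~a & b).sum())
                neither = n - both - only_a - only_b
                degenerate = a.sum() in (0, n) or b.sum() in (0, n)
                if degenerate:
                    p = 1.0
                else:
                    _, p = stats.fisher_exact(
                        [[both, only_a], [only_b, neither]], alternative=alternative
                    )
                rows.append(
                    {
                        "pathway_gene": pg,
                        "driver_gene": dg,
                        "cohort": cnv.cohort,
                        "depth": depth,
                        "direction": direction,
                        "n_both": both,
                        "n_pathway_only": only_a,
                        "n_driver_only": only_b,
                        "n_neither": neither,
                        "p": float(p),
                        "degenerate": degenerate,
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        _, adj, _, _ = multipletests(out["p"], method="fdr_bh")
        out["adjusted_p"] = adj
        out["linked"] = out["adjusted_p"] < COOC_FDR_CUTOFF
    else:
        out["adjusted_p"] = pd.Series(dtype=float)
        out["linked"] = pd.Series(dtype=bool)
    return out


def concordance_classify(
    alteration_class: str,
    log2fc_scn: float,
    fdr_scn: float,
    log2fc_tn: float,
    fdr_tn: float,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    fdr_cutoff: float = DE_FDR_CUTOFF,
) -> str:
    """Concordance between the SCN-vs-diploid and tumor-vs-normal contrasts.

    ``reinforcing_up``: amplification with both contrasts significant and
    positive; ``reinforcing_down``: deletion with both significant and
    negative; ``opposing``: both significant with discordant signs;
    otherwise ``inert``.
    """
    _, _, sign = ALTERATION_CLASSES[alteration_class]
    sig_scn = (
        np.isfinite(log2fc_scn)
        and np.isfinite(fdr_scn)
        and abs(log2fc_scn) > log2fc_cutoff
        and fdr_scn < fdr_cutoff
    )
    sig_tn = (
        np.isfinite(log2fc_tn)
        and np.isfinite(fdr_tn)
        and abs(log2fc_tn) > log2fc_cutoff
        and fdr_tn < fdr_cutoff
    )
    if not (sig_scn and sig_tn):
        return "inert"
    if log2fc_scn > 0 and log2fc_tn > 0 and sign > 0:
        return "reinforcing_up"
    if log2fc_scn < 0 and log2fc_tn < 0 and sign < 0:
        return "reinforcing_down"
    if (log2fc_scn > 0) != (log2fc_tn > 0):
        return "opposing"
    return "inert"


def integrate_cnv_expression(
    cnv: CnvMatrix,
    expression: ExpressionMatrix,
    pathway_genes: list[str],
    tumor_vs_normal_de: pd.DataFrame,
    min_group: int = 2,
) -> pd.DataFrame:
    """Full association table over genes × alteration classes.

    ``tumor_vs_normal_de`` supplies the log2FC/FDR of diploid tumors versus
    normals (the disease axis of the concordance call).
    """
    rows = []
    for gene in pathway_genes:
        if gene not in cnv.calls.index or gene not in expression.counts.index:
            continue
        if gene in tumor_vs_normal_de.index:
            tn = tumor_vs_normal_de.loc[gene]
            lfc_tn, fdr_tn = float(tn["log2fc"]), float(tn["fdr"])
        else:
            lfc_tn, fdr_tn = np.nan, np.nan
        for alteration_class in ALTERATION_CLASSES:
            contrast = scn_vs_diploid_contrast(
                cnv, expression, gene, alteration_class, min_group=min_group
            )
            concordance = (
                concordance_classify(
                    alteration_class,
                    contrast.log2fc,
                    contrast.fdr,
                    lfc_tn,
                    fdr_tn,
                )
                if contrast.testable
                else "inert"
            )
            rows.append(
                {
                    "gene": gene,
                    "cohort": cnv.cohort,
                    "alteration_class": alteration_class,
                    "prevalence": contrast.prevalence,
                    "high_prevalence": contrast.high_prevalence,
                    "log2fc_scn_vs_diploid": contrast.log2fc,
                    "fdr_scn": contrast.fdr,
                    "log2fc_tumor_vs_normal": lfc_tn,
                    "fdr_tn": fdr_tn,
                    "testable": contrast.testable,
                    "concordance": concordance,
                }
            )
    return pd.DataFrame(rows)


def diploid_tumor_vs_normal_de(
    cnv: CnvMatrix, expression: ExpressionMatrix, gene: str | None = None
) -> pd.DataFrame:
    """Tumor-vs-normal DE restricted to diploid tumor samples.

    When ``gene`` is given, diploid status is taken for that gene;
    otherwise samples diploid for all pathway genes in the call matrix are
    used.
    """
    tumor = [
        s
        for s in expression.counts.columns
        if expression.condition[s] == "tumor" and s in cnv.calls.columns
    ]
    if gene is not None:
        diploid = [s for s in tumor if cnv.calls.loc[gene, s] == 0]
    else:
        diploid = [s for s in tumor if (cnv.calls[s] == 0).all()]
    normals = [
        s for s in expression.counts.columns if expression.condition[s] == "normal"
    ]
    sub = expression.subset_samples(diploid + normals)
    return nb_differential_expression(sub)
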