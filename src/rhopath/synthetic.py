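"""Seeded synthetic cohorts with the statistical structure each stage assumes.

The generator plants known effects (mutation-burden enrichment, expression
log2 fold changes, copy-number dosage, driver co-occurrence, lineage-specific
dependency shifts) and records every planted effect in a ground-truth sidecar
table attached to the returned container, so recovery tests never re-derive
truth from the data.

Default parameters emulate TCGA/DepMap-scale structure at desk scale:
~1 somatic mutation per Mb per sample, a small hypermutated subpopulation,
negative-binomial RNA-seq counts with dispersion 0.1 and a per-sample GC
trend, dosage-coupled copy-number calls, and Gaussian dependency scores with
sigma 0.2 around lineage-specific shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import PathwayCatalog
from .tables import (
    CnvMatrix,
    DependencyMatrix,
    ExpressionMatrix,
    MutationTable,
    VARIANT_CLASSES,
)


class ConfigError(ValueError):
    """Raised for out-of-range simulation parameters."""


DEFAULT_LINEAGES = (
    "bone",
    "breast",
    "cns",
    "colorectal",
    "leukemia",
    "lung",
    "lymphoma",
    "ovary",
    "pancreas",
    "kidney",
    "skin",
)


@dataclass
class SimulationConfig:
    """Parameters shared by the four simulators.

    ``seed`` fully determines every output. Rates and fractions are
    validated at construction.
    """

    seed: int = 0
    n_samples: int = 200
    n_genes: int = 2000
    n_cohorts: int = 1
    #: expected somatic mutations per coding bp per sample (~1/Mb).
    mutation_rate: float = 1e-6
    hypermutator_fraction: float = 0.02
    hypermutator_multiplier: float = 20.0
    #: burden multiplier applied to catalog genes (1 = null).
    pathway_enrichment_factor: float = 1.0
    #: NB dispersion alpha, variance = mu + alpha * mu^2.
    nb_dispersion: float = 0.1
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    #: scale of the per-sample multiplicative GC trend on log counts.
    gc_bias_strength: float = 1.0
    cnv_dosage_log2fc_per_copy: float = 1.0
    #: lineage-specific dependency shift added in one lineage.
    dependency_shift: float = -1.0
    lineage_labels: list[str] = field(default_factory=lambda: list(DEFAULT_LINEAGES))
    n_cell_lines: int = 220
    dependency_sigma: float = 0.2
    pan_essential_genes: list[str] = field(default_factory=list)
    #: gene -> lineage receiving ``dependency_shift``.
    lineage_specific: dict[str, str] = field(default_factory=dict)
    variant_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "synonymous": 0.25,
            "missense": 0.55,
            "truncating": 0.12,
            "other": 0.08,
        }
    )
    #: categorical over thresholded calls {-2,-1,0,1,2}.
    cnv_class_probs: dict[int, float] = field(
        default_factory=lambda: {-2: 0.02, -1: 0.08, 0: 0.80, 1: 0.08, 2: 0.02}
    )
    #: pathway gene -> driver gene co-altered at ``cooccurrence_odds_ratio``.
    driver_pairs: dict[str, str] = field(default_factory=dict)
    cooccurrence_odds_ratio: float = 1.0
    #: baseline alteration probability for planted driver genes.
    driver_alteration_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.mutation_rate < 0:
            raise ConfigError("mutation_rate must be >= 0")
        if not 0 <= self.hypermutator_fraction < 1:
            raise ConfigError("hypermutator_fraction must lie in [0, 1)")
        if self.hypermutator_multiplier <= 1:
            raise ConfigError("hypermutator_multiplier must be > 1")
        if self.pathway_enrichment_factor <= 0:
            raise ConfigError("pathway_enrichment_factor must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.gc_bias_strength < 0:
            raise ConfigError("gc_bias_strength must be >= 0")
        if min(self.n_samples, self.n_genes, self.n_cohorts) <= 0:
            raise ConfigError("n_samples, n_genes, n_cohorts must be positive")
        if not self.lineage_labels:
            raise ConfigError("lineage_labels must be non-empty")
        for name, probs in (
            ("variant_class_probs", self.variant_class_probs),
            ("cnv_class_probs", self.cnv_class_probs),
        ):
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {total}")
        if self.cooccurrence_odds_ratio <= 0:
            raise ConfigError("cooccurrence_odds_ratio must be > 0")
        if self.dependency_sigma <= 0:
            raise ConfigError("dependency_sigma must be > 0")


#: category proportions mirroring the curated pathway list's composition.
CATEGORY_WEIGHTS = {
    "GTPASE": 23,
    "GEF": 85,
    "GAP": 68,
    "GDI": 3,
    "KINASE_EFFECTOR": 64,
    "NONKINASE_ELEMENT": 243,
}


def synthetic_catalog(n_genes: int = 100, seed: int = 0) -> PathwayCatalog:
    """A synthetic pathway catalog stand-in with realistic composition.

    Categories are drawn in the proportions of the curated list, coding
    lengths are log-normal (median ~1.5 kb), GC fractions Normal(0.5,
    0.08), and GEF/GAP entries receive a GTPase substrate (RHOA-heavy for
    GEFs, balanced for GAPs). Synthetic: stands in for the curated gene
    list, which is not re-derived here.
    """
    from .catalog import GeneCatalogEntry

    rng = np.random.default_rng(seed + 7)
    cats = list(CATEGORY_WEIGHTS)
    weights = np.array([CATEGORY_WEIGHTS[c] for c in cats], dtype=float)
    weights /= weights.sum()
    entries = []
    for i in range(n_genes):
        category = cats[rng.choice(len(cats), p=weights)]
        length = int(np.clip(round(10 ** rng.normal(np.log10(1500.0), 0.35)), 90, None))
        gc = float(np.clip(rng.normal(0.5, 0.08), 0.25, 0.75))
        substrate = "UNKNOWN"
        if category == "GEF":
            substrate = ["RHOA", "RAC1", "CDC42", "UNKNOWN"][
                rng.choice(4, p=[0.5, 0.15, 0.15, 0.2])
            ]
        elif category == "GAP":
            substrate = ["RHOA", "RAC1", "CDC42", "UNKNOWN"][
                rng.choice(4, p=[0.35, 0.35, 0.1, 0.2])
            ]
        entries.append(
            GeneCatalogEntry(
                symbol=f"RP{i:04d}",
                categories=frozenset({category}),
                coding_length=length,
                gc_fraction=round(gc, 4),
                substrate=substrate,
            )
        )
    return PathwayCatalog(entries)


def background_gene_table(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    length_like: pd.Series | None = None,
) -> pd.DataFrame:
    """Random background genes with lengths and GC fractions.

    When ``length_like`` (a Series of pathway lengths) is given, background
    lengths are drawn from a log-normal fit to it so length-matched
    resampling always has donors in every decile bin; otherwise a generic
    coding-length log-normal (median ~1.5 kb) is used.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 101)
    n = config.n_genes
    if length_like is not None and len(length_like) >= 2:
        logs = np.log10(length_like.to_numpy(dtype=float))
        mu, sd = float(np.mean(logs)), float(np.std(logs))
        # widen slightly so the extreme pathway bins stay fillable
        lengths = np.round(10 ** rng.normal(mu, sd * 1.15 + 1e-6, size=n)).astype(int)
        lo, hi = int(length_like.min()), int(length_like.max())
        lengths = np.clip(lengths, max(30, lo // 2), hi * 2)
    else:
        lengths = np.round(10 ** rng.normal(np.log10(1500.0), 0.35, size=n)).astype(int)
        lengths = np.clip(lengths, 90, None)
    gc = np.clip(rng.normal(0.5, 0.08, size=n), 0.25, 0.75)
    return pd.DataFrame(
        {
            "symbol": [f"BG{i:05d}" for i in range(n)],
            "coding_length_bp": lengths,
            "gc_fraction": np.round(gc, 4),
        }
    )


# ---------------------------------------------------------------------------
# somatic mutations
# ---------------------------------------------------------------------------

def simulate_mutations(
    config: SimulationConfig,
    catalog: PathwayCatalog,
    background_genes: pd.DataFrame,
) -> MutationTable:
    """Poisson mutation counts proportional to gene length.

    Per gene ``g`` and non-hypermutated sample, the count is
    ``Poisson(mutation_rate * length_g * enrichment_g)`` where the
    enrichment factor applies to catalog genes only. Hypermutated samples
    multiply the rate by ``hypermutator_multiplier``. Variant classes are
    drawn from ``variant_class_probs``; 1-based protein positions are drawn
    uniformly over ``length // 3`` codons.
    """
    if (background_genes["coding_length_bp"] <= 0).any():
        raise ConfigError("background gene lengths must be positive")
    rng = np.random.default_rng(config.seed)

    path_lengths = catalog.lengths()
    genes = np.concatenate([path_lengths.index.to_numpy(), background_genes["symbol"].to_numpy()])
    lengths = np.concatenate(
        [path_lengths.to_numpy(dtype=float), background_genes["coding_length_bp"].to_numpy(dtype=float)]
    )
    enrich = np.concatenate(
        [
            np.full(len(path_lengths), config.pathway_enrichment_factor),
            np.ones(len(background_genes)),
        ]
    )

    class_names = list(VARIANT_CLASSES)
    class_p = np.array([config.variant_class_probs[c] for c in class_names])

    frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for cohort_idx in range(config.n_cohorts):
        cohort_id = f"COH{cohort_idx:02d}"
        sample_ids = np.array(
            [f"{cohort_id}_S{j:04d}" for j in range(config.n_samples)]
        )
        is_hyper = rng.random(config.n_samples) < config.hypermutator_fraction
        sample_mult = np.where(is_hyper, config.hypermutator_multiplier, 1.0)
        lam = (
            config.mutation_rate
            * lengths[:, None]
            * enrich[:, None]
            * sample_mult[None, :]
        )
        counts = rng.poisson(lam)
        gene_idx, sample_idx = np.nonzero(counts)
        reps = counts[gene_idx, sample_idx]
        gene_rep = np.repeat(gene_idx, reps)
        sample_rep = np.repeat(sample_idx, reps)
        n_rec = len(gene_rep)
        classes = rng.choice(len(class_names), size=n_rec, p=class_p)
        n_codons = np.maximum(lengths[gene_rep] // 3, 1).astype(int)
        positions = (rng.random(n_rec) * n_codons).astype(int) + 1
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids[sample_rep],
                    "cohort_id": cohort_id,
                    "gene": genes[gene_rep],
                    "variant_class": np.array(class_names, dtype=object)[classes],
                    "position": positions,
                }
            )
        )
        for sid in sample_ids[is_hyper]:
            truth_rows.append(
                {
                    "gene": sid,
                    "effect_type": "hypermutator_sample",
                    "magnitude": config.hypermutator_multiplier,
                    "cohort": cohort_id,
                }
            )

    if config.pathway_enrichment_factor != 1.0:
        for g in path_lengths.index:
            truth_rows.append(
                {
                    "gene": g,
                    "effect_type": "burden_enrichment",
                    "magnitude": config.pathway_enrichment_factor,
                    "cohort": "*",
                }
            )

    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["sample_id", "cohort_id", "gene", "variant_class", "position"])
    )
    if len(records) == 0:
        records = records.astype(
            {"sample_id": object, "cohort_id": object, "gene": object, "variant_class": object}
        )
    truth = pd.DataFrame(truth_rows, columns=["gene", "effect_type", "magnitude", "cohort"])
    return MutationTable(records=records, ground_truth=truth)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + alpha * mu^2."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, scale=mu * alpha)
    return rng.poisson(lam)


def simulate_expression(
    config: SimulationConfig,
    catalog: PathwayCatalog,
    background_genes: pd.DataFrame | None = None,
    n_tumor: int | None = None,
    n_normal: int | None = None,
    cohort_id: str = "COH00",
) -> ExpressionMatrix:
    """Negative-binomial counts for tumor and matched normal samples.

    Baseline gene means are log-normal (median ~100 counts). Tumor means of
    genes in ``planted_log2fc`` are multiplied by ``2**log2fc``. Each sample
    carries a lane factor that tilts log-mean linearly in centered GC with
    scale ``gc_bias_strength``, giving within-lane normalization a real
    signal to remove.
    """
    unknown = set(config.planted_log2fc) - set(catalog.symbols) - (
        set(background_genes["symbol"]) if background_genes is not None else set()
    )
    if unknown:
        raise ConfigError(f"planted_log2fc for unknown gene(s): {sorted(unknown)}")

    rng = np.random.default_rng(config.seed + 1)
    n_tumor = config.n_samples if n_tumor is None else n_tumor
    n_normal = config.n_samples if n_normal is None else n_normal

    gc_series = catalog.gc()
    if background_genes is not None:
        gc_series = pd.concat(
            [
                gc_series,
                pd.Series(
                    background_genes["gc_fraction"].to_numpy(),
                    index=background_genes["symbol"].to_numpy(),
                ),
            ]
        )
    genes = gc_series.index.to_numpy()
    gc = gc_series.to_numpy(dtype=float)

    base_mu = 10 ** rng.normal(2.0, 0.5, size=len(genes))
    lfc = np.array([config.planted_log2fc.get(g, 0.0) for g in genes])

    tumor_ids = [f"{cohort_id}_T{j:03d}" for j in range(n_tumor)]
    normal_ids = [f"{cohort_id}_N{j:03d}" for j in range(n_normal)]
    sample_ids = tumor_ids + normal_ids
    is_tumor = np.array([True] * n_tumor + [False] * n_normal)

    lane = rng.normal(0.0, 1.0, size=len(sample_ids))
    gc_centered = gc - gc.mean()

    log_mu = (
        np.log(base_mu)[:, None]
        + np.log(2.0) * np.where(is_tumor[None, :], lfc[:, None], 0.0)
        + config.gc_bias_strength * lane[None, :] * gc_centered[:, None]
    )
    mu = np.exp(log_mu)
    counts = _nb_draw(rng, mu, config.nb_dispersion)

    truth = pd.DataFrame(
        [
            {"gene": g, "effect_type": "log2fc", "magnitude": v, "cohort": cohort_id}
            for g, v in config.planted_log2fc.items()
        ],
        columns=["gene", "effect_type", "magnitude", "cohort"],
    )
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        condition=pd.Series(
            np.where(is_tumor, "tumor", "normal"), index=sample_ids
        ),
        cohort=cohort_id,
        gc=pd.Series(gc, index=genes),
        mu=pd.DataFrame(mu, index=genes, columns=sample_ids),
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def simulate_cnv(
    config: SimulationConfig,
    expression: ExpressionMatrix,
    cnv_genes: list[str] | None = None,
) -> tuple[CnvMatrix, ExpressionMatrix]:
    """Thresholded calls coupled to expression by a dosage effect.

    Calls are drawn per gene × tumor sample from ``cnv_class_probs``
    (normals stay diploid). For altered cells the expression count is
    re-drawn from the stored generating mean multiplied by
    ``2**(cnv_dosage_log2fc_per_copy * call)``. Planted driver genes are
    appended to the call matrix, deep-amplified with odds multiplied by
    ``cooccurrence_odds_ratio`` when the paired pathway gene is deep-
    amplified.
    """
    if expression.mu is None:
        raise ConfigError("expression matrix lacks generating means; simulate it first")
    rng = np.random.default_rng(config.seed + 2)

    genes = list(expression.genes) if cnv_genes is None else list(cnv_genes)
    samples = list(expression.counts.columns)
    tumor_mask = (expression.condition.loc[samples] == "tumor").to_numpy()

    call_values = np.array(sorted(config.cnv_class_probs), dtype=int)
    call_p = np.array([config.cnv_class_probs[int(v)] for v in call_values])

    calls = np.zeros((len(genes), len(samples)), dtype=int)
    calls[:, tumor_mask] = call_values[
        rng.choice(len(call_values), size=(len(genes), int(tumor_mask.sum())), p=call_p)
    ]

    counts = expression.counts.copy()
    mu = expression.mu
    dosage = config.cnv_dosage_log2fc_per_copy
    if dosage != 0.0:
        for i, g in enumerate(genes):
            if g not in counts.index:
                continue
            altered = np.nonzero(calls[i])[0]
            if len(altered) == 0:
                continue
            cols = [samples[j] for j in altered]
            factor = 2.0 ** (dosage * calls[i, altered])
            new_mu = mu.loc[g, cols].to_numpy(dtype=float) * factor
            counts.loc[g, cols] = _nb_draw(rng, new_mu, config.nb_dispersion)

    call_df = pd.DataFrame(calls, index=genes, columns=samples)
    truth_rows = [
        {"gene": g, "effect_type": "cnv_dosage_log2fc_per_copy", "magnitude": dosage, "cohort": expression.cohort}
        for g in genes
    ]

    # planted driver co-occurrence (deep amplification, same direction)
    p0 = config.driver_alteration_rate
    omega = config.cooccurrence_odds_ratio
    odds0 = p0 / (1.0 - p0)
    p1 = (omega * odds0) / (1.0 + omega * odds0)
    n_tumor = int(tumor_mask.sum())
    for pathway_gene, driver_gene in config.driver_pairs.items():
        if pathway_gene not in call_df.index:
            raise ConfigError(f"driver pair references unknown gene {pathway_gene!r}")
        partner_amp = call_df.loc[pathway_gene].to_numpy() == 2
        driver_calls = np.zeros(len(samples), dtype=int)
        prob = np.where(partner_amp, p1, p0)
        driver_calls[tumor_mask] = np.where(
            rng.random(n_tumor) < prob[tumor_mask], 2, 0
        )
        call_df.loc[driver_gene] = driver_calls
        truth_rows.append(
            {
                "gene": f"{pathway_gene}|{driver_gene}",
                "effect_type": "cooccurrence_odds_ratio",
                "magnitude": omega,
                "cohort": expression.cohort,
            }
        )

    truth = pd.DataFrame(truth_rows, columns=["gene", "effect_type", "magnitude", "cohort"])
    coupled = ExpressionMatrix(
        counts=counts,
        condition=expression.condition,
        cohort=expression.cohort,
        gc=expression.gc,
        mu=expression.mu,
        ground_truth=expression.ground_truth,
    )
    return CnvMatrix(calls=call_df, cohort=expression.cohort, ground_truth=truth), coupled


# ---------------------------------------------------------------------------
# dependency screens
# ---------------------------------------------------------------------------

def simulate_dependency(
    config: SimulationConfig,
    genes: list[str] | None = None,
) -> DependencyMatrix:
    """Gaussian dependency scores with planted essentiality structure.

    Baseline scores are Normal(0, sigma). Pan-essential genes are shifted
    by −1 in every line; each gene in ``lineage_specific`` is shifted by
    ``dependency_shift`` only in its designated lineage. Cell lines are
    split evenly across ``lineage_labels``.
    """
    if not config.lineage_labels:
        raise ConfigError("lineage_labels must be non-empty")
    rng = np.random.default_rng(config.seed + 3)
    if genes is None:
        genes = [f"G{i:04d}" for i in range(min(config.n_genes, 500))]
    bad = set(config.lineage_specific.values()) - set(config.lineage_labels)
    if bad:
        raise ConfigError(f"lineage_specific references unknown lineage(s): {sorted(bad)}")

    n_lines = config.n_cell_lines
    lines = [f"CL{j:04d}" for j in range(n_lines)]
    lineages = pd.Series(
        [config.lineage_labels[j % len(config.lineage_labels)] for j in range(n_lines)],
        index=lines,
    )

    scores = rng.normal(0.0, config.dependency_sigma, size=(len(genes), n_lines))
    truth_rows = []
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in config.pan_essential_genes:
        if g in gene_pos:
            scores[gene_pos[g], :] -= 1.0
            truth_rows.append(
                {"gene": g, "effect_type": "pan_essential", "magnitude": -1.0, "cohort": "*"}
            )
    for g, lin in config.lineage_specific.items():
        if g in gene_pos:
            mask = (lineages == lin).to_numpy()
            scores[gene_pos[g], mask] += config.dependency_shift
            truth_rows.append(
                {
                    "gene": g,
                    "effect_type": "lineage_shift",
                    "magnitude": config.dependency_shift,
                    "cohort": lin,
                }
            )

    truth = pd.DataFrame(truth_rows, columns=["gene", "effect_type", "magnitude", "cohort"])
    return DependencyMatrix(
        scores=pd.DataFrame(scores, index=genes, columns=lines),
        lineage=lineages,
        ground_truth=truth,
    )


def write_ground_truth(obj, path: str | Path) -> None:
    """Persist a simulation's ground-truth sidecar as TSV."""
    truth = getattr(obj, "ground_truth", None)
    if truth is None:
        truth = pd.DataFrame(columns=["gene", "effect_type", "magnitude", "cohort"])
    truth.to_csv(path, sep="\t", index=False)
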