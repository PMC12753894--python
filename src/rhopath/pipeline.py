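"""Config-driven end-to-end runner: input validation, stage execution,
per-stage TSV outputs, and a JSON manifest sufficient to re-run
bit-identically.

Stage order: mutation_enrichment → selection_hotspots → expression_de →
cnv_integration → coexpression_gsea → dependency_screens. Each stage runs
only when enabled and its inputs are configured; cnv_integration requires
expression_de. All thresholds default to the published analysis values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import PathwayCatalog, load_catalog
from .cnv import diploid_tumor_vs_normal_de, cooccurrence_with_drivers, integrate_cnv_expression
from .coexpression import cross_cohort_summary, pairwise_spearman, preranked_gsea, correlation_ranked_list, top_processes
from .dependency import lineage_vulnerability, pan_cancer_essential
from .expression import de_count_enrichment, run_expression_pipeline
from .mutations import (
    adjust_enrichment_results,
    enrichment_test,
    filter_hypermutators,
    gene_load,
    observed_statistic,
    populate_ensemble_statistic,
    sample_length_matched_lists,
)
from .selection import ClusterTable, classify_selection, hotspot_fractions, load_selection_table
from .tables import (
    CnvMatrix,
    DependencyMatrix,
    ExpressionMatrix,
    MutationTable,
    CNV_CALLS,
    read_gene_list,
    read_gmt,
)

log = logging.getLogger("rhopath")

STAGES = (
    "mutation_enrichment",
    "selection_hotspots",
    "expression_de",
    "cnv_integration",
    "coexpression_gsea",
    "dependency_screens",
)

#: downstream stage -> stage it needs
STAGE_DEPENDENCIES = {"cnv_integration": "expression_de"}

FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All input paths, stage toggles, and thresholds.

    Threshold defaults are the published analysis values: 4.5× hypermutator
    fold, AAIC 0.6, |log2FC| > 1 with FDR < 0.01, q < 0.01 for selection,
    > 30% in-cluster fraction, > 3% hotspot prevalence, > 10% SCNV
    prevalence, Chronos < −0.5 in > 10% of lines, median difference > 0.5
    with FDR < 0.01, 1,000 resampled lists, 10,000 GSEA permutations, and
    a maximum set size of 800.
    """

    # inputs
    catalog: str | None = None
    mutations: str | None = None
    background_genes: str | None = None
    selection_table: str | None = None
    cluster_table: str | None = None
    counts: str | None = None
    sample_sheet: str | None = None
    gene_gc: str | None = None
    cnv_calls: str | None = None
    driver_genes: str | None = None
    dependency_scores: str | None = None
    lineage_sheet: str | None = None
    gene_sets: str | None = None
    coexpression_genes: str | None = None
    # toggles
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # thresholds (published defaults)
    hypermutator_fold: float = 4.5
    aaic_cutoff: float = 0.6
    log2fc_cutoff: float = 1.0
    de_fdr_cutoff: float = 0.01
    q_cutoff: float = 0.01
    hotspot_fraction_cutoff: float = 0.30
    hotspot_prevalence_cutoff: float = 0.03
    scnv_prevalence_cutoff: float = 0.10
    chronos_cutoff: float = -0.5
    essential_fraction: float = 0.10
    median_diff_cutoff: float = 0.5
    vulnerability_fdr_cutoff: float = 0.01
    cohort_size: int | None = None
    n_lists: int = 1000
    n_perm: int = 10000
    max_set_size: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.hypermutator_fold <= 0 or self.n_lists <= 0 or self.n_perm <= 0:
            raise ValueError("thresholds out of legal range")
        if not 0 < self.de_fdr_cutoff < 1 or not 0 < self.q_cutoff < 1:
            raise ValueError("FDR/q cutoffs must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def validate_inputs(config: RunConfig) -> dict:
    """Schema and invariant checks for every configured input file.

    Report-only: returns ``{"errors": [...], "warnings": [...]}``.
    """
    errors: list[str] = []
    warnings_: list[str] = []

    def check_exists(name: str, path: str | None) -> bool:
        if path is None:
            return False
        if not Path(path).exists():
            errors.append(f"{name}: file not found: {path}")
            return False
        return True

    if check_exists("catalog", config.catalog):
        try:
            load_catalog(config.catalog)
        except Exception as exc:
            errors.append(f"catalog: {exc}")
    if check_exists("mutations", config.mutations):
        try:
            MutationTable.from_tsv(config.mutations)
        except Exception as exc:
            errors.append(f"mutations: {exc}")
    if check_exists("counts", config.counts) and check_exists("sample_sheet", config.sample_sheet):
        try:
            matrix = ExpressionMatrix.from_tsv(config.counts, config.sample_sheet, config.gene_gc)
            if (matrix.counts.to_numpy() < 0).any():
                errors.append("counts: negative count present")
        except Exception as exc:
            errors.append(f"counts: {exc}")
    if check_exists("cnv_calls", config.cnv_calls):
        try:
            raw = pd.read_csv(config.cnv_calls, sep="\t").set_index("gene")
            bad = ~raw.isin(CNV_CALLS)
            if bad.any().any():
                gene = raw.index[bad.any(axis=1)][0]
                sample = raw.columns[bad.any(axis=0)][0]
                errors.append(
                    f"cnv_calls: out-of-vocabulary value at gene {gene!r}, sample {sample!r}"
                )
        except Exception as exc:
            errors.append(f"cnv_calls: {exc}")
    if check_exists("dependency_scores", config.dependency_scores) and check_exists(
        "lineage_sheet", config.lineage_sheet
    ):
        try:
            DependencyMatrix.from_csv(config.dependency_scores, config.lineage_sheet)
        except Exception as exc:
            errors.append(f"dependency_scores: {exc}")
    if check_exists("selection_table", config.selection_table):
        try:
            load_selection_table(config.selection_table)
        except Exception as exc:
            errors.append(f"selection_table: {exc}")
    if check_exists("cluster_table", config.cluster_table):
        try:
            ClusterTable.from_tsv(config.cluster_table)
        except Exception as exc:
            errors.append(f"cluster_table: {exc}")
    if config.gene_sets and check_exists("gene_sets", config.gene_sets):
        try:
            read_gmt(config.gene_sets)
        except Exception as exc:
            errors.append(f"gene_sets: {exc}")
    return {"errors": errors, "warnings": warnings_}


def _stage_inputs_present(config: RunConfig, stage: str) -> bool:
    needed = {
        "mutation_enrichment": (config.catalog, config.mutations, config.background_genes),
        "selection_hotspots": (config.selection_table,),
        "expression_de": (config.catalog, config.counts, config.sample_sheet),
        "cnv_integration": (config.catalog, config.cnv_calls, config.counts, config.sample_sheet),
        "coexpression_gsea": (config.catalog, config.counts, config.sample_sheet),
        "dependency_screens": (config.dependency_scores, config.lineage_sheet),
    }[stage]
    return all(p is not None for p in needed)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages and write the report bundle.

    Returns the manifest dict (also written to ``manifest.json``): package
    version, seed, thresholds, input checksums, per-stage row counts, and
    the outputs written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config.stages and _stage_inputs_present(config, s)]
    for stage, needs in STAGE_DEPENDENCIES.items():
        if stage in enabled and needs not in enabled:
            raise PipelineError(stage, f"depends on stage {needs!r}, which is disabled or unconfigured")

    report = validate_inputs(config)
    if report["errors"]:
        raise PipelineError("validate", "; ".join(report["errors"]))

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": enabled,
        "thresholds": {
            k: v
            for k, v in asdict(config).items()
            if isinstance(v, (int, float)) and k != "seed"
        },
        "inputs": {},
        "stage_counts": {},
        "outputs": [],
    }
    for f_ in fields(config):
        value = getattr(config, f_.name)
        if isinstance(value, str) and Path(value).exists():
            manifest["inputs"][f_.name] = _sha256(value)

    catalog: PathwayCatalog | None = (
        load_catalog(config.catalog) if config.catalog else None
    )
    background = (
        pd.read_csv(config.background_genes, sep="\t")
        if config.background_genes
        else None
    )
    de_table = None

    for stage in enabled:
        try:
            counts = _run_stage(
                stage, config, catalog, background, outdir, manifest,
                de_holder := {"de": de_table},
            )
            de_table = de_holder["de"]
            manifest["stage_counts"][stage] = counts
            log.info("stage %s: %s", stage, counts)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _run_stage(
    stage: str,
    config: RunConfig,
    catalog: PathwayCatalog | None,
    background: pd.DataFrame | None,
    outdir: Path,
    manifest: dict,
    de_holder: dict,
) -> dict:
    counts: dict = {}
    if stage == "mutation_enrichment":
        mutations = MutationTable.from_tsv(config.mutations)
        retained, burden = filter_hypermutators(mutations, fold=config.hypermutator_fold)
        counts["samples_in"] = int(burden.shape[0])
        counts["samples_removed_hypermutator"] = int(burden["hypermutator_flag"].sum())
        _write(burden, outdir / "hypermutator_report.tsv")
        loads = gene_load(retained, catalog.symbols)
        _write(loads, outdir / "gene_load.tsv")
        ensemble = sample_length_matched_lists(
            catalog, background, n_lists=config.n_lists, seed=config.seed
        )
        results = []
        for kind in ("load", "prevalence"):
            n_samples = retained.records["sample_id"].nunique()
            populate_ensemble_statistic(ensemble, retained, kind, n_samples=n_samples)
            obs = observed_statistic(retained, catalog, kind, n_samples=n_samples)
            results.append(
                enrichment_test(obs, ensemble, kind, cohort="ALL", n_samples=n_samples)
            )
        adjust_enrichment_results(results)
        _write(pd.DataFrame([vars(r) for r in results]), outdir / "mutation_enrichment.tsv")
        counts["records_retained"] = len(retained.records)
        manifest["outputs"] += [
            "hypermutator_report.tsv", "gene_load.tsv", "mutation_enrichment.tsv",
        ]
    elif stage == "selection_hotspots":
        table = load_selection_table(config.selection_table)
        calls = classify_selection(table, q_cutoff=config.q_cutoff)
        _write(calls, outdir / "selection_calls.tsv")
        counts["rows"] = len(calls)
        counts["selected"] = int((calls["selection_class"] != "none").sum())
        manifest["outputs"].append("selection_calls.tsv")
        if config.cluster_table and config.mutations and config.cohort_size:
            clusters = ClusterTable.from_tsv(config.cluster_table)
            mutations = MutationTable.from_tsv(config.mutations)
            summary = hotspot_fractions(mutations, clusters, config.cohort_size)
            _write(summary, outdir / "hotspot_summary.tsv")
            counts["hotspot_rows"] = len(summary)
            manifest["outputs"].append("hotspot_summary.tsv")
    elif stage == "expression_de":
        matrix = ExpressionMatrix.from_tsv(config.counts, config.sample_sheet, config.gene_gc)
        de, de_manifest = run_expression_pipeline(
            matrix,
            aaic_cutoff=config.aaic_cutoff,
            log2fc_cutoff=config.log2fc_cutoff,
            fdr_cutoff=config.de_fdr_cutoff,
        )
        de_holder["de"] = de
        _write(de.reset_index(), outdir / "de_results.tsv")
        counts.update(de_manifest)
        manifest["outputs"].append("de_results.tsv")
        if background is not None and catalog is not None:
            enr = de_count_enrichment(
                de, catalog, background, n_lists=config.n_lists, seed=config.seed
            )
            _write(pd.DataFrame([vars(enr)]), outdir / "de_count_enrichment.tsv")
            manifest["outputs"].append("de_count_enrichment.tsv")
    elif stage == "cnv_integration":
        de = de_holder["de"]
        if de is None:
            raise PipelineError(stage, "expression_de produced no DE table")
        cnv = CnvMatrix.from_tsv(config.cnv_calls)
        matrix = ExpressionMatrix.from_tsv(config.counts, config.sample_sheet, config.gene_gc)
        pathway = [g for g in catalog.symbols if g in cnv.calls.index]
        assoc = integrate_cnv_expression(cnv, matrix, pathway, de)
        _write(assoc, outdir / "cnv_associations.tsv")
        counts["associations"] = len(assoc)
        manifest["outputs"].append("cnv_associations.tsv")
        if config.driver_genes:
            drivers = [g for g in read_gene_list(config.driver_genes) if g in cnv.calls.index]
            frames = [
                cooccurrence_with_drivers(cnv, pathway, drivers, depth)
                for depth in ("deep", "shallow")
            ]
            cooc = pd.concat(frames, ignore_index=True)
            _write(cooc, outdir / "driver_cooccurrence.tsv")
            counts["cooccurrence_pairs"] = len(cooc)
            manifest["outputs"].append("driver_cooccurrence.tsv")
    elif stage == "coexpression_gsea":
        matrix = ExpressionMatrix.from_tsv(config.counts, config.sample_sheet, config.gene_gc)
        if config.coexpression_genes:
            genes = [
                g for g in read_gene_list(config.coexpression_genes)
                if g in matrix.counts.index
            ]
        else:
            genes = [g for g in catalog.symbols if g in matrix.counts.index][:10]
        if len(genes) >= 2 and len(matrix.samples_in("tumor")) >= 5:
            coex = pairwise_spearman(matrix, genes, genes)
            _write(coex, outdir / "coexpression.tsv")
            summary = cross_cohort_summary(coex)
            _write(summary, outdir / "coexpression_summary.tsv")
            counts["pairs"] = len(coex)
            manifest["outputs"] += ["coexpression.tsv", "coexpression_summary.tsv"]
        if config.gene_sets and genes:
            sets = read_gmt(config.gene_sets)
            ranked = correlation_ranked_list(matrix, genes[0])
            gsea = preranked_gsea(
                ranked,
                sets,
                n_perm=config.n_perm,
                max_size=config.max_set_size,
                seed=config.seed,
            )
            gsea["cohort"] = matrix.cohort
            _write(gsea, outdir / "gsea_results.tsv")
            _write(top_processes(gsea, k=100), outdir / "gsea_top_processes.tsv")
            counts["gene_sets_tested"] = len(gsea)
            manifest["outputs"] += ["gsea_results.tsv", "gsea_top_processes.tsv"]
    elif stage == "dependency_screens":
        dep = DependencyMatrix.from_csv(config.dependency_scores, config.lineage_sheet)
        essential = pan_cancer_essential(
            dep, threshold=config.chronos_cutoff, fraction=config.essential_fraction
        )
        _write(essential.reset_index(), outdir / "pan_essential.tsv")
        vulnerability = lineage_vulnerability(
            dep,
            median_diff_cutoff=config.median_diff_cutoff,
            fdr_cutoff=config.vulnerability_fdr_cutoff,
        )
        _write(vulnerability, outdir / "lineage_vulnerability.tsv")
        counts["genes"] = int(dep.scores.shape[0])
        counts["pan_essential"] = int(essential["pan_essential"].sum())
        counts["flagged_vulnerabilities"] = int(vulnerability["flagged"].sum())
        manifest["outputs"] += ["pan_essential.tsv", "lineage_vulnerability.tsv"]
    return counts


def simulate_bundle(outdir: str | Path, seed: int = 0, n_samples: int = 60, n_genes: int = 800, n_catalog: int = 60) -> RunConfig:
    """Generate a full synthetic input bundle plus a matching RunConfig.

    Writes catalog, background table, mutation TSV, counts + sample sheet +
    GC sidecar, CNV calls, driver list, dependency CSVs, a selection table,
    a cluster table, a small GMT, and ground-truth sidecars.
    """
    from . import synthetic as syn
    from .catalog import write_catalog

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    catalog = syn.synthetic_catalog(n_catalog, seed=seed)
    write_catalog(catalog, outdir / "catalog.tsv")

    config = syn.SimulationConfig(
        seed=seed,
        n_samples=n_samples,
        n_genes=n_genes,
        pathway_enrichment_factor=2.0,
        planted_log2fc={catalog.symbols[0]: 2.0, catalog.symbols[1]: -2.0},
        driver_pairs={catalog.symbols[0]: "DRIVER1"},
        cooccurrence_odds_ratio=6.0,
        lineage_specific={"G0000": "breast"},
        pan_essential_genes=["G0001"],
    )
    background = syn.background_gene_table(config, length_like=catalog.lengths())
    background.to_csv(outdir / "background_genes.tsv", sep="\t", index=False)

    mutations = syn.simulate_mutations(config, catalog, background)
    mutations.to_tsv(outdir / "mutations.tsv")
    syn.write_ground_truth(mutations, outdir / "mutations.truth.tsv")

    small_bg = background.iloc[: max(n_genes // 4, 50)]
    expression = syn.simulate_expression(config, catalog, small_bg)
    cnv, expression = syn.simulate_cnv(config, expression, cnv_genes=catalog.symbols)
    expression.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    syn.write_ground_truth(expression, outdir / "expression.truth.tsv")
    cnv.to_tsv(outdir / "cnv_calls.tsv")
    syn.write_ground_truth(cnv, outdir / "cnv.truth.tsv")
    (outdir / "drivers.txt").write_text("DRIVER1\n")

    dep = syn.simulate_dependency(config)
    dep.to_csv(outdir / "dependency.csv", outdir / "lineages.csv")
    syn.write_ground_truth(dep, outdir / "dependency.truth.tsv")

    qs = 0.05 + 0.95 * rng.random((10, 3))
    selection = pd.DataFrame(
        {
            "gene": catalog.symbols[:10],
            "cohort": "COH00",
            "qglobal_cv": np.round(qs[:, 0], 6),
            "qmis_cv": np.round(qs[:, 1], 6),
            "qtrunc_cv": np.round(qs[:, 2], 6),
        }
    )
    selection.loc[0, ["qglobal_cv", "qmis_cv", "qtrunc_cv"]] = [0.001, 0.002, 0.4]
    selection.to_csv(outdir / "selection.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene": [catalog.symbols[0]], "cohort": ["COH00"], "start": [25], "end": [35]}
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    members = rng.choice(catalog.symbols, size=8, replace=False)
    gmt = "SET_A\tsynthetic\t" + "\t".join(members) + "\n"
    gmt += "SET_B\tsynthetic\t" + "\t".join(catalog.symbols[10:20]) + "\n"
    (outdir / "sets.gmt").write_text(gmt)

    run_config = RunConfig(
        catalog=str(outdir / "catalog.tsv"),
        mutations=str(outdir / "mutations.tsv"),
        background_genes=str(outdir / "background_genes.tsv"),
        selection_table=str(outdir / "selection.tsv"),
        cluster_table=str(outdir / "clusters.tsv"),
        counts=str(outdir / "counts.tsv"),
        sample_sheet=str(outdir / "samples.tsv"),
        gene_gc=str(outdir / "samples.gc.tsv"),
        cnv_calls=str(outdir / "cnv_calls.tsv"),
        driver_genes=str(outdir / "drivers.txt"),
        dependency_scores=str(outdir / "dependency.csv"),
        lineage_sheet=str(outdir / "lineages.csv"),
        gene_sets=str(outdir / "sets.gmt"),
        cohort_size=n_samples,
        n_lists=100,
        n_perm=500,
        seed=seed,
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: v for k, v in asdict(run_config).items() if v is not None}, fh
        )
    return run_config
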