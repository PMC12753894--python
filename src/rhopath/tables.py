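"""Shared tabular containers used across pipeline stages.

All containers wrap pandas objects and carry the minimal labels the stages
need (condition, cohort, lineage). Validation happens at construction so
downstream code can assume the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VARIANT_CLASSES = ("synonymous", "missense", "truncating", "other")
NONSYNONYMOUS_CLASSES = ("missense", "truncating", "other")
CNV_CALLS = (-2, -1, 0, 1, 2)

#: MAF ``Variant_Classification`` tokens mapped onto the 4-class vocabulary.
MAF_CLASS_MAP = {
    "Silent": "synonymous",
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "truncating",
    "Frame_Shift_Del": "truncating",
    "Frame_Shift_Ins": "truncating",
    "Nonstop_Mutation": "truncating",
    "Splice_Site": "truncating",
    "Translation_Start_Site": "truncating",
    "In_Frame_Del": "other",
    "In_Frame_Ins": "other",
    "5'UTR": "other",
    "3'UTR": "other",
    "Intron": "other",
    "RNA": "other",
}


class TableError(ValueError):
    """Raised when an input table violates its schema or invariants."""


@dataclass
class MutationTable:
    """Per-sample per-gene somatic variant records (MAF-like, long format).

    Columns: ``sample_id``, ``cohort_id``, ``gene``, ``variant_class`` and
    optionally ``position`` (1-based protein coordinate).
    """

    records: pd.DataFrame
    ground_truth: pd.DataFrame | None = None

    REQUIRED = ("sample_id", "cohort_id", "gene", "variant_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise TableError(f"mutation table missing column(s): {missing}")
        bad = set(self.records["variant_class"].unique()) - set(VARIANT_CLASSES)
        if bad:
            raise TableError(f"unknown variant class token(s): {sorted(bad)}")
        # each sample belongs to exactly one cohort
        per_sample = self.records.groupby("sample_id")["cohort_id"].nunique()
        if (per_sample > 1).any():
            offenders = per_sample[per_sample > 1].index.tolist()
            raise TableError(f"sample(s) mapped to >1 cohort: {offenders}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort_id": str, "gene": str}))

    @classmethod
    def from_maf(cls, path: str | Path, cohort_id: str | None = None) -> "MutationTable":
        """Read a MAF-like TSV, mapping ``Variant_Classification`` tokens
        onto the 4-class vocabulary (unknown tokens map to ``other``)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableError(f"MAF file missing column(s): {missing}")
        out = pd.DataFrame(
            {
                "sample_id": df["Tumor_Sample_Barcode"],
                "cohort_id": df.get("cohort_id", cohort_id or "COHORT"),
                "gene": df["Hugo_Symbol"],
                "variant_class": df["Variant_Classification"].map(
                    lambda v: MAF_CLASS_MAP.get(v, "other")
                ),
            }
        )
        if "Protein_position" in df.columns:
            out["position"] = pd.to_numeric(df["Protein_position"], errors="coerce")
        return cls(out)


@dataclass
class ExpressionMatrix:
    """Gene × sample integer count matrix with condition labels.

    ``counts`` rows are genes, columns are samples; ``condition`` maps each
    sample to ``tumor`` or ``normal``; ``gc`` is the per-gene GC fraction.
    ``mu`` (optional) holds the generating per-cell means for simulated
    matrices so coupled simulators can re-draw counts consistently.
    """

    counts: pd.DataFrame
    condition: pd.Series
    cohort: str = "COHORT"
    gc: pd.Series | None = None
    mu: pd.DataFrame | None = field(default=None, repr=False)
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.isna().any().any():
            raise TableError("expression matrix contains missing cells")
        if (self.counts.values < 0).any():
            raise TableError("expression matrix contains negative counts")
        if not set(self.counts.columns) <= set(self.condition.index):
            raise TableError("condition labels missing for some samples")
        bad = set(self.condition.unique()) - {"tumor", "normal"}
        if bad:
            raise TableError(f"unknown condition label(s): {sorted(bad)}")
        if self.gc is not None and not set(self.counts.index) <= set(self.gc.index):
            raise TableError("gc fractions missing for some genes")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def samples_in(self, condition: str) -> list[str]:
        mask = self.condition.loc[list(self.counts.columns)] == condition
        return [s for s, m in mask.items() if m]

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts[samples],
            condition=self.condition.loc[samples],
            cohort=self.cohort,
            gc=self.gc,
            mu=None if self.mu is None else self.mu[samples],
            ground_truth=self.ground_truth,
        )

    def to_tsv(self, counts_path: str | Path, sheet_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        sheet = pd.DataFrame(
            {
                "sample": list(self.counts.columns),
                "condition": self.condition.loc[list(self.counts.columns)].values,
                "cohort": self.cohort,
            }
        )
        if self.gc is not None:
            sheet_dir = Path(sheet_path).parent
            gc_out = self.gc.rename("gc_fraction").rename_axis("gene").reset_index()
            gc_out.to_csv(sheet_dir / (Path(sheet_path).stem + ".gc.tsv"), sep="\t", index=False)
        sheet.to_csv(sheet_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        sheet_path: str | Path,
        gc_path: str | Path | None = None,
    ) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t")
        counts = counts.set_index("gene")
        sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
        condition = pd.Series(sheet["condition"].values, index=sheet["sample"].values)
        cohort = sheet["cohort"].iloc[0] if "cohort" in sheet.columns else "COHORT"
        gc = None
        if gc_path is not None:
            gc_df = pd.read_csv(gc_path, sep="\t")
            gc = pd.Series(gc_df["gc_fraction"].values, index=gc_df["gene"].values)
        return cls(counts=counts, condition=condition, cohort=str(cohort), gc=gc)


@dataclass
class CnvMatrix:
    """GISTIC-style thresholded copy-number calls, gene × sample."""

    calls: pd.DataFrame
    cohort: str = "COHORT"
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        values = set(np.unique(self.calls.values))
        bad = values - set(CNV_CALLS)
        if bad:
            raise TableError(
                f"copy-number calls outside {{-2..2}}: {sorted(bad)}"
            )

    def to_tsv(self, path: str | Path) -> None:
        out = self.calls.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, cohort: str = "COHORT") -> "CnvMatrix":
        calls = pd.read_csv(path, sep="\t").set_index("gene")
        return cls(calls=calls.astype(int), cohort=cohort)


@dataclass
class DependencyMatrix:
    """CRISPR dependency scores (Chronos-like), gene × cell line.

    More negative scores mean a stronger fitness cost of knockout.
    ``lineage`` maps every cell line to its tumor lineage.
    """

    scores: pd.DataFrame
    lineage: pd.Series
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.scores.columns) - set(self.lineage.index)
        if missing:
            raise TableError(f"lineage label missing for cell line(s): {sorted(missing)}")
        labels = self.lineage.loc[list(self.scores.columns)]
        if labels.isna().any():
            raise TableError("missing lineage labels")

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    def to_csv(self, scores_path: str | Path, lineage_path: str | Path) -> None:
        # DepMap convention: rows = cell lines, columns = genes
        self.scores.T.rename_axis("cell_line").to_csv(scores_path)
        self.lineage.rename("lineage").rename_axis("cell_line").loc[
            list(self.scores.columns)
        ].to_csv(lineage_path)

    @classmethod
    def from_csv(cls, scores_path: str | Path, lineage_path: str | Path) -> "DependencyMatrix":
        wide = pd.read_csv(scores_path, index_col=0)
        lin = pd.read_csv(lineage_path, index_col=0)["lineage"]
        lin.index = lin.index.astype(str)
        scores = wide.T
        scores.columns = scores.columns.astype(str)
        return cls(scores=scores, lineage=lin)


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name, description, members."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise TableError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
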