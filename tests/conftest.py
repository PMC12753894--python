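import numpy as np
import pandas as pd
import pytest

from rhopath.catalog import GeneCatalogEntry, PathwayCatalog
from rhopath.synthetic import SimulationConfig, background_gene_table, synthetic_catalog


@pytest.fixture
def tiny_catalog() -> PathwayCatalog:
    """Three-gene catalog with one dual-category regulator."""
    return PathwayCatalog(
        [
            GeneCatalogEntry("RHOA", frozenset({"GTPASE"}), 582, 0.55),
            GeneCatalogEntry("ARHGEF1", frozenset({"GEF"}), 2757, 0.60, "RHOA"),
            GeneCatalogEntry("BCR", frozenset({"GEF", "GAP"}), 3813, 0.58, "RAC1"),
        ]
    )


@pytest.fixture(scope="session")
def catalog60() -> PathwayCatalog:
    return synthetic_catalog(60, seed=7)


@pytest.fixture(scope="session")
def background60(catalog60) -> pd.DataFrame:
    cfg = SimulationConfig(seed=7, n_genes=1200)
    return background_gene_table(cfg, length_like=catalog60.lengths())


def census_catalog() -> PathwayCatalog:
    """Catalog reproducing the curated list's printed category sizes:
    23 GTPases, 85 GEFs (2 of them also GAPs), 68 GAPs, 3 GDIs, 64 kinase
    effectors, 243 non-kinase elements."""
    entries = []
    idx = 0

    def add(n, cats, substrate="UNKNOWN"):
        nonlocal idx
        for _ in range(n):
            entries.append(
                GeneCatalogEntry(
                    f"GEN{idx:04d}", frozenset(cats), 1500, 0.5, substrate
                )
            )
            idx += 1

    add(23, {"GTPASE"})
    add(83, {"GEF"}, "RHOA")
    add(2, {"GEF", "GAP"}, "RHOA")  # dual DH + GAP domain proteins
    add(66, {"GAP"}, "RAC1")
    add(3, {"GDI"})
    add(64, {"KINASE_EFFECTOR"})
    add(243, {"NONKINASE_ELEMENT"})
    return PathwayCatalog(entries)
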