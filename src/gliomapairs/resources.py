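"""Bundled reference tables: GRCh37 arm boundaries, driver gene loci,
pathway groupings, and the transcribed clinical cohort table."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml


def _data_path(name: str):
    return resources.files("gliomapairs.data") / name


@lru_cache(maxsize=None)
def load_arm_table() -> pd.DataFrame:
    """Chromosome-arm intervals for GRCh37 autosomes.

    Columns: chrom, arm (p/q), start, end — 0-based half-open. Centromere
    midpoints are approximate; the synthetic generator and the callers share
    this table, so arm assignment is internally consistent.
    """
    with resources.as_file(_data_path("grch37_arms.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


@lru_cache(maxsize=None)
def load_gene_table() -> pd.DataFrame:
    """Approximate GRCh37 loci for the recurrently mutated pHGG genes."""
    with resources.as_file(_data_path("genes_grch37.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


@lru_cache(maxsize=None)
def load_pathway_map() -> dict[str, str]:
    """Gene symbol -> pathway group (RTK, PI3K, histone_modifiers, ...)."""
    with resources.as_file(_data_path("pathway_groups.yaml")) as p:
        grouped = yaml.safe_load(p.read_text())
    return {gene: group for group, genes in grouped.items() for gene in genes}


def clinical_table_path():
    """Path to the bundled 16-pair clinical cohort TSV."""
    return _data_path("table1_clinical.tsv")


def chromosome_lengths() -> dict[str, int]:
    arms = load_arm_table()
    return arms.groupby("chrom", sort=False)["end"].max().to_dict()
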