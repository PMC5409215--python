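"""Packaged worked-example tables for the rapeseed reference genome.

Three small fixture tables ship with the package: predicted SLAF tag counts
and spacing per chromosome, SNP counts and densities per chromosome and
subgenome, and haplotype-block counts/lengths per chromosome. They provide
printed inputs for the spacing / density / block-frequency arithmetic
without any external download.

Each loader returns ``(per_chrom, aggregate)``: the 19 chromosome rows and
the printed aggregate rows kept separately so the aggregates can be
recomputed and checked rather than reused.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_AGG1 = ("Total",)
_AGG2 = ("A genome", "C genome", "AC genome")


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("slafpop").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _split(tab: pd.DataFrame, agg_names: tuple[str, ...]) -> tuple[pd.DataFrame, pd.DataFrame]:
    is_agg = tab["chrom"].isin(agg_names)
    return (
        tab[~is_agg].reset_index(drop=True),
        tab[is_agg].reset_index(drop=True),
    )


def slaf_tag_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predicted SLAF tags per chromosome: length, count, average spacing."""
    return _split(_load("table1_slaf_tags.tsv"), _AGG1)


def snp_density_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP counts and per-100-kb densities per chromosome and subgenome."""
    return _split(_load("table2_snp_density.tsv"), _AGG2)


def block_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Haplotype block counts, total lengths and genome fractions."""
    return _split(_load("table3_blocks.tsv"), _AGG1)
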