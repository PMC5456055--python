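"""Published reference values for the eleven Schima chloroplast genomes.

Four tables are bundled as TSV package data: genome/partition dimensions,
per-region divergence of the variable coding and noncoding regions (with one
IR copy removed), and the cpSSR inventory.  They serve as the regression
surface for the divergence formulas, the hotspot screen, the SSR census and
the partition arithmetic.

Also exposed here are the printed whole-concatenation totals for the
11-taxon, IR-stripped data set (aligned length, variable sites, indel events
and summed indel length), from which the substitution count and percent
variability follow arithmetically.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# 11-taxon IR-stripped concatenation totals
CONCAT_TOTALS = {
    "aligned_length": 130_508,
    "variable_positions": 1_121,
    "parsimony_informative": 261,
    "indel_events": 131,
    "indel_length": 586,
}


def _load(name: str) -> pd.DataFrame:
    with resources.files("plastome_compare.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def partition_table() -> pd.DataFrame:
    """Genome, LSC, SSC and IR lengths plus GC content per taxon."""
    return _load("table1_partitions.tsv")


def coding_divergence_table() -> pd.DataFrame:
    """The 49 variable coding regions (>150 bp aligned)."""
    return _load("table2_coding.tsv")


def noncoding_divergence_table() -> pd.DataFrame:
    """The 79 variable noncoding regions (>150 bp aligned)."""
    return _load("table3_noncoding.tsv")


def ssr_table() -> pd.DataFrame:
    """The 58 cpSSR loci with motif, genic context, region and length range."""
    return _load("table4_ssr.tsv")
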