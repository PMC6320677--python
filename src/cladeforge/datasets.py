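"""Bundled reference tabulations for the New World diploid cottons.

Small published summary tables for subgenus *Houzingenia* (the 13 D-genome
cotton species) used as worked-example inputs: per-chromosome indel counts
against the *G. longicalyx* outgroup, per-accession SNP and indel totals,
shared-derived SNP counts between the introgressed (Colima) and
non-introgressed (Jalisco) *G. aridum* accessions, and assembly-versus-
genome-size statistics.  The repeat-profiling read pool for these
accessions combined 3,872,016 standardized 85-nt reads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: total 85-nt reads in the combined 1% genome-size-equivalent pool
REPEAT_POOL_TOTAL_READS = 3_872_016


def _load(name: str) -> pd.DataFrame:
    with resources.files("cladeforge.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def indels_by_chromosome() -> pd.DataFrame:
    """Distinguishing-indel counts and chromosome lengths (Mb)."""
    return _load("houzingenia_indels_by_chromosome.tsv")


def snp_indel_counts() -> pd.DataFrame:
    """Per-accession SNP and indel totals against the outgroup."""
    return _load("houzingenia_snp_indel_counts.tsv")


def shared_derived_snps() -> pd.DataFrame:
    """Shared-derived SNP counts, introgressed vs control accession."""
    return _load("houzingenia_shared_derived_snps.tsv")


def assembly_stats() -> pd.DataFrame:
    """Assembled length vs flow-cytometry genome size per accession."""
    return _load("houzingenia_assembly_stats.tsv")
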