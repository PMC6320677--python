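"""Outgroup-polarized small-indel evolution and genic-effect annotation.

Small indels (1-270 nt by default) called against a reference are
polarized with an outgroup allele: the allele matching the outgroup is
taken as ancestral, so the event is an insertion when the derived allele
is the longer one and a deletion when it is the shorter, assigned to the
lineage carrying the derived allele.  Summaries report per-chromosome
counts, densities (indels/Mb), size statistics, per-accession SNP:indel
ratios, the net length change (inserted minus deleted bp), and the
deletion bias as count and length fold-ratios.

Genic consequences are classified against gene models: an indel whose
length change within the CDS is not a multiple of three is a frameshift;
in-frame events are insertions/deletions of whole codons, the 3-nt cases
flagged as single amino-acid gain/loss; events touching the first or last
codon lose the start/stop; in-frame events that introduce a premature
stop are stop-gains; events within 2 nt of an intron boundary disrupt the
splice signal.  Compound outcomes carry multiple flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

INSERTION = "insertion"
DELETION = "deletion"
UNKNOWN = "unknown"

EFFECT_CLASSES = (
    "frameshift",
    "inframe_insertion",
    "inframe_deletion",
    "single_aa_gain",
    "single_aa_loss",
    "start_lost",
    "stop_lost",
    "stop_gained",
    "splice_disrupted",
    "intronic",
    "intergenic",
)


def trim_indel(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim an indel record to anchor-base form.

    Shared suffix bases are removed first, then shared prefix bases beyond
    a single anchor; returns (pos, ref, alt) with pos pointing at the
    anchor base (1-based).  Position conventions otherwise change counts,
    so all records are normalized through here before comparison.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def polarize_indel(ref_allele: str, alt_allele: str, outgroup_allele: str) -> tuple[str, int]:
    """(polarity, length) of a simple indel relative to the outgroup.

    Exactly one of ref/alt must be longer.  The outgroup-matching allele
    is ancestral; the event belongs to the lineage carrying the other
    allele and is an insertion when that derived allele is longer.
    Returns polarity ``unknown`` when the outgroup matches neither.
    """
    lr, la = len(ref_allele), len(alt_allele)
    if lr == la:
        raise ValueError("not an indel: equal-length alleles")
    length = abs(lr - la)
    if outgroup_allele == ref_allele:
        return (DELETION if la < lr else INSERTION), length
    if outgroup_allele == alt_allele:
        return (DELETION if lr < la else INSERTION), length
    return UNKNOWN, length


def decompose_multiallelic(ref: str, alts: list[str]) -> list[tuple[str, str]]:
    """Split a multi-allelic record into biallelic (ref, alt) events."""
    return [(ref, a) for a in alts]


@dataclass
class IndelSummary:
    """Per-chromosome and per-accession indel statistics."""

    per_chromosome: pd.DataFrame
    per_accession: pd.DataFrame

    @property
    def total_indels(self) -> int:
        return int(self.per_chromosome["n_indels"].sum())

    def to_tsv(self) -> str:
        return (
            self.per_chromosome.to_csv(sep="\t", index=False)
            + "\n"
            + self.per_accession.to_csv(sep="\t", index=False)
        )


def _round_half_even(x: float) -> float:
    return float(np.round(x))


def summarize_indels(
    indels: pd.DataFrame,
    snp_counts: dict[str, int],
    chromosome_lengths_mb: dict[str, float],
) -> IndelSummary:
    """Summarize polarized indels per chromosome and per accession.

    ``indels`` needs columns ``chrom``, ``length``, ``polarity`` and
    ``accession`` (one row per indel x accession carrying it).
    Densities and SNP:indel ratios are rounded half-to-even to integers.
    """
    for mb in chromosome_lengths_mb.values():
        if mb <= 0:
            raise ValueError("chromosome lengths must be > 0 Mb")

    # Chromosome block counts unique events (an indel shared by several
    # accessions is one location).
    ev_cols = ["chrom", "pos", "length", "polarity"] if "pos" in indels.columns else [
        "chrom", "length", "polarity"
    ]
    events = indels.drop_duplicates(subset=ev_cols)
    chrom_rows = []
    for chrom, mb in chromosome_lengths_mb.items():
        sub = events[events["chrom"] == chrom]
        n = len(sub)
        chrom_rows.append(
            {
                "chrom": chrom,
                "n_indels": n,
                "length_mb": mb,
                "indels_per_mb": _round_half_even(n / mb),
                "mean_size": float(sub["length"].mean()) if n else 0.0,
                "max_size": int(sub["length"].max()) if n else 0,
            }
        )

    acc_rows = []
    for acc, sub in indels.groupby("accession"):
        n_ind = len(sub)
        n_snp = int(snp_counts.get(acc, 0))
        ins = sub[sub["polarity"] == INSERTION]
        dele = sub[sub["polarity"] == DELETION]
        ins_bp = int(ins["length"].sum())
        del_bp = int(dele["length"].sum())
        acc_rows.append(
            {
                "accession": acc,
                "n_snps": n_snp,
                "n_indels": n_ind,
                "snp_indel_ratio": _round_half_even(n_snp / n_ind) if n_ind else np.nan,
                "net_length_change_bp": ins_bp - del_bp,
                "deletion_count_fold": (len(dele) / len(ins)) if len(ins) else np.inf,
                "deletion_length_fold": (del_bp / ins_bp) if ins_bp else np.inf,
            }
        )

    return IndelSummary(pd.DataFrame(chrom_rows), pd.DataFrame(acc_rows))


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model; 1-based inclusive intervals."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def cds_positions(self) -> list[int]:
        """Genomic CDS positions in transcription order."""
        pos = [p for s, e in sorted(self.cds) for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]

    def extract_cds(self, chrom_seq: str) -> str:
        parts = [chrom_seq[s - 1 : e] for s, e in sorted(self.cds)]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class IndelEffect:
    gene_id: str
    effect: str  # primary class
    flags: tuple[str, ...] = ()

    @property
    def all_classes(self) -> tuple[str, ...]:
        return (self.effect,) + tuple(f for f in self.flags if f != self.effect)


def _deleted_interval(pos: int, ref: str) -> tuple[int, int]:
    """Genomic positions removed by a deletion record (anchor excluded)."""
    return pos + 1, pos + len(ref) - 1


def annotate_indel_effect(
    pos: int,
    ref: str,
    alt: str,
    gene: GeneModel,
    chrom_seq: str | None = None,
) -> IndelEffect:
    """Classify one normalized indel against one gene model.

    ``pos`` is the 1-based anchor position (VCF convention).  When
    ``chrom_seq`` is given, in-frame events are additionally screened for
    introduced premature stops by translating the edited CDS.
    """
    pos, ref, alt = trim_indel(pos, ref, alt)
    is_del = len(ref) > len(alt)
    net = len(alt) - len(ref)

    if is_del:
        lo, hi = _deleted_interval(pos, ref)
        affected = set(range(lo, hi + 1))
    else:
        affected = set()  # insertion: a point between pos and pos+1
    ins_point = pos  # insertion goes after this base

    if is_del:
        overlaps_gene = not (hi < gene.start or lo > gene.end)
    else:
        overlaps_gene = gene.start <= ins_point < gene.end
    if not overlaps_gene:
        return IndelEffect(gene.gene_id, "intergenic")

    flags: list[str] = []

    # Splice signal: 2 nt at each end of each intron.
    exons = sorted(gene.exons)
    splice_sites: set[int] = set()
    for (s1, e1), (s2, _) in zip(exons, exons[1:]):
        splice_sites |= {e1 + 1, e1 + 2, s2 - 2, s2 - 1}
    touched = affected if is_del else {ins_point, ins_point + 1}
    in_intron_signal = bool(touched & splice_sites) or (
        not is_del and ins_point in splice_sites and ins_point + 1 in splice_sites
    )
    if in_intron_signal:
        flags.append("splice_disrupted")

    cds_pos = gene.cds_positions()
    cds_set = set(cds_pos)

    if is_del:
        cds_removed = len(affected & cds_set)
        cds_overlap = cds_removed > 0
        net_cds = -cds_removed
    else:
        # Insertion changes the CDS only if its point lies strictly inside
        # a CDS segment (between two adjacent CDS bases).
        inside = any(s <= ins_point < e for s, e in (seg for seg in sorted(gene.cds)))
        cds_overlap = inside
        net_cds = net if inside else 0

    exonic = False
    for s, e in exons:
        if is_del and affected & set(range(s, e + 1)):
            exonic = True
        if not is_del and s <= ins_point < e:
            exonic = True

    if not cds_overlap:
        if flags:
            return IndelEffect(gene.gene_id, "splice_disrupted", tuple(flags))
        if exonic:
            # UTR exon; nearest informative label is intronic vs intergenic —
            # report as intronic-equivalent noncoding hit.
            return IndelEffect(gene.gene_id, "intronic")
        return IndelEffect(gene.gene_id, "intronic")

    # start / stop codon overlap (transcription order)
    first_codon = set(cds_pos[:3])
    last_codon = set(cds_pos[-3:])
    if is_del:
        if affected & first_codon:
            flags.append("start_lost")
        if affected & last_codon:
            flags.append("stop_lost")
    else:
        # An insertion disrupts a codon only when it lands *between* two of
        # its bases (transcription order).
        order = {p: i for i, p in enumerate(cds_pos)}
        i1 = order.get(ins_point)
        i2 = order.get(ins_point + 1)
        if i1 is not None and i2 is not None and abs(i1 - i2) == 1:
            lo_i = min(i1, i2)
            L = len(cds_pos)
            if lo_i in (0, 1):
                flags.append("start_lost")
            if lo_i in (L - 3, L - 2):
                flags.append("stop_lost")

    if net_cds % 3 != 0:
        return IndelEffect(gene.gene_id, "frameshift", tuple(flags))

    # in-frame
    if chrom_seq is not None:
        orig_cds = gene.extract_cds(chrom_seq)
        edited = _apply_edit(chrom_seq, pos, ref, alt)
        edited_cds = _extract_cds_after_edit(gene, edited, pos, ref, alt)
        if edited_cds is not None and _introduces_stop(orig_cds, edited_cds):
            flags.append("stop_gained")

    if abs(net_cds) == 3 and not (set(flags) & {"start_lost", "stop_lost", "stop_gained"}):
        primary = "single_aa_loss" if net_cds < 0 else "single_aa_gain"
    elif "start_lost" in flags:
        primary = "start_lost"
    elif "stop_gained" in flags:
        primary = "stop_gained"
    elif "stop_lost" in flags:
        primary = "stop_lost"
    elif abs(net_cds) == 3:
        primary = "single_aa_loss" if net_cds < 0 else "single_aa_gain"
    else:
        primary = "inframe_deletion" if net_cds < 0 else "inframe_insertion"
    return IndelEffect(gene.gene_id, primary, tuple(f for f in flags if f != primary))


def indel_effect_report(
    variants: pd.DataFrame,
    gene_models: list[GeneModel],
    chrom_seqs: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per indel x overlapping gene (plus an intergenic row for
    indels hitting no gene).  ``variants`` needs chrom/pos/ref/alt columns;
    multi-allelic alts (comma-separated) are decomposed first."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for rec in variants.itertuples(index=False):
        for ref, alt in decompose_multiallelic(rec.ref, str(rec.alt).split(",")):
            if len(ref) == len(alt):
                continue
            seq = chrom_seqs.get(rec.chrom) if chrom_seqs else None
            hit = False
            for g in by_chrom.get(rec.chrom, []):
                eff = annotate_indel_effect(int(rec.pos), ref, alt, g, seq)
                if eff.effect != "intergenic":
                    hit = True
                    rows.append(
                        {
                            "chrom": rec.chrom,
                            "pos": rec.pos,
                            "ref": ref,
                            "alt": alt,
                            "gene_id": g.gene_id,
                            "effect": eff.effect,
                            "flags": ",".join(eff.flags),
                        }
                    )
            if not hit:
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": ref,
                        "alt": alt,
                        "gene_id": "",
                        "effect": "intergenic",
                        "flags": "",
                    }
                )
    return pd.DataFrame(rows)


def _apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def _extract_cds_after_edit(
    gene: GeneModel, edited_seq: str, pos: int, ref: str, alt: str
) -> str | None:
    """Re-extract the CDS after an edit by shifting downstream coordinates.

    Only valid when the event is contained in a single CDS segment (the
    common case for small indels); returns None otherwise.
    """
    net = len(alt) - len(ref)
    segs = sorted(gene.cds)
    new_segs = []
    lo = pos + 1 if len(ref) > len(alt) else pos
    hi = pos + len(ref) - 1 if len(ref) > len(alt) else pos
    for s, e in segs:
        if e < lo:
            new_segs.append((s, e))
        elif s > hi:
            new_segs.append((s + net, e + net))
        else:
            if not (s <= lo and hi <= e):
                return None
            new_segs.append((s, e + net))
    parts = [edited_seq[s - 1 : e] for s, e in new_segs]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _translate(cds: str) -> str:
    n = len(cds) - len(cds) % 3
    return str(Seq(cds[:n]).translate())


def _introduces_stop(orig_cds: str, edited_cds: str) -> bool:
    p0 = _translate(orig_cds)
    p1 = _translate(edited_cds)
    i0 = p0.find("*")
    i1 = p1.find("*")
    stop0 = i0 if i0 >= 0 else len(p0)
    stop1 = i1 if i1 >= 0 else len(p1)
    # Premature if the edited protein stops earlier than the length change
    # alone explains.
    return stop1 < stop0 + (len(p1) - len(p0))
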