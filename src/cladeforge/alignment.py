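"""Alignment quality control and supermatrix construction.

Per-gene multi-species alignments are screened in two passes: sequences
(rows) whose ambiguity fraction exceeds a threshold are dropped first, then
alignment columns whose among-sequence ambiguity fraction exceeds a second
threshold are removed.  Genes are kept only if the filtered alignment falls
inside a length window and every species retains a minimum number of
accessions.  Surviving genes can be concatenated into a partitioned
supermatrix for downstream phylogenetic analysis.

Ambiguity means IUPAC degeneracy codes (N, R, Y, S, W, K, M, B, D, H, V);
gap characters are alignment artifacts, not base-call uncertainty, and are
not counted as ambiguous by default.  Thresholds are strict inequalities:
a row or column at exactly the threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC codes that denote base-call uncertainty.  '-' is deliberately absent.
AMBIGUITY_CODES = frozenset("NRYSWKMBDHVnryswkmbdhv")

GAP = "-"


class AlignmentRejected(Exception):
    """A gene alignment failed a filter; ``reason`` is a short machine code."""

    def __init__(self, gene_id: str, reason: str, detail: str = ""):
        self.gene_id = gene_id
        self.reason = reason
        super().__init__(f"{gene_id}: {reason}" + (f" ({detail})" if detail else ""))


@dataclass(frozen=True)
class AlignmentRow:
    species: str
    accession: str
    seq: str

    @property
    def label(self) -> str:
        return f"{self.species}|{self.accession}"


@dataclass
class GeneAlignment:
    """One gene's codon-aware multi-species alignment."""

    gene_id: str
    rows: list[AlignmentRow]

    def __post_init__(self) -> None:
        if self.rows:
            lengths = {len(r.seq) for r in self.rows}
            if len(lengths) != 1:
                raise ValueError(f"{self.gene_id}: unequal row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0].seq) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.rows:
            counts[r.species] = counts.get(r.species, 0) + 1
        return counts

    def to_array(self) -> np.ndarray:
        return np.array([list(r.seq) for r in self.rows], dtype="U1")

    @classmethod
    def from_fasta(cls, path, gene_id: str | None = None) -> "GeneAlignment":
        """Read a FASTA alignment; record ids are ``species|accession`` (or
        the whole id is taken as both species and accession)."""
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if "|" in rec.id:
                species, accession = rec.id.split("|", 1)
            else:
                species = accession = rec.id
            rows.append(AlignmentRow(species, accession, str(rec.seq).upper()))
        gid = gene_id if gene_id is not None else str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
        return cls(gid, rows)

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(r.seq), id=r.label, description="") for r in self.rows]
        SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for the two-pass ambiguity filter and the gene-level gates.

    ``count_gaps_as_ambiguous`` is off by default (gaps are treated as
    coverage, not uncertainty) but switchable because published pipelines
    differ on this point.
    """

    max_seq_ambig_frac: float = 0.10
    max_col_ambig_frac: float = 0.10
    min_len: int = 500
    max_len: int = 4051
    min_accessions_per_species: int = 1
    count_gaps_as_ambiguous: bool = False

    def __post_init__(self) -> None:
        for name in ("max_seq_ambig_frac", "max_col_ambig_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_len > self.max_len:
            raise ValueError(f"min_len {self.min_len} > max_len {self.max_len}")


def _ambig_mask(arr: np.ndarray, policy: FilterPolicy) -> np.ndarray:
    mask = np.isin(arr, list(AMBIGUITY_CODES))
    if policy.count_gaps_as_ambiguous:
        mask |= arr == GAP
    return mask


def filter_alignment(aln: GeneAlignment, policy: FilterPolicy | None = None) -> GeneAlignment:
    """Apply the row filter, then the column filter, then the gene gates.

    Returns the filtered alignment or raises :class:`AlignmentRejected` with
    a reason code: ``empty``, ``all_rows_removed``, ``too_short``,
    ``too_long`` or ``species_dropout``.
    """
    policy = policy or FilterPolicy()
    if not aln.rows or aln.length == 0:
        raise AlignmentRejected(aln.gene_id, "empty")

    arr = aln.to_array()
    ambig = _ambig_mask(arr, policy)

    # Row pass: strict > threshold removes the sequence.
    row_frac = ambig.mean(axis=1)
    keep_rows = row_frac <= policy.max_seq_ambig_frac
    if not keep_rows.any():
        raise AlignmentRejected(aln.gene_id, "all_rows_removed")
    arr = arr[keep_rows]
    ambig = ambig[keep_rows]
    rows = [r for r, k in zip(aln.rows, keep_rows) if k]

    # Column pass, computed on the surviving rows.
    col_frac = ambig.mean(axis=0)
    keep_cols = col_frac <= policy.max_col_ambig_frac
    arr = arr[:, keep_cols]

    new_len = arr.shape[1]
    if new_len < policy.min_len:
        raise AlignmentRejected(aln.gene_id, "too_short", f"{new_len} < {policy.min_len}")
    if new_len > policy.max_len:
        raise AlignmentRejected(aln.gene_id, "too_long", f"{new_len} > {policy.max_len}")

    out_rows = [replace(r, seq="".join(row)) for r, row in zip(rows, arr)]
    out = GeneAlignment(aln.gene_id, out_rows)
    for sp, n in out.species_counts().items():
        if n < policy.min_accessions_per_species:
            raise AlignmentRejected(aln.gene_id, "species_dropout", sp)
    # A species present before filtering but absent now also fails the gate.
    before = set(aln.species_counts())
    if policy.min_accessions_per_species > 0 and before - set(out.species_counts()):
        missing = sorted(before - set(out.species_counts()))
        raise AlignmentRejected(aln.gene_id, "species_dropout", ",".join(missing))
    return out


@dataclass
class Supermatrix:
    """Concatenated gene alignments with a 1-based inclusive partition table."""

    alignment: GeneAlignment
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def partition_tsv(self) -> str:
        lines = ["gene_id\tstart\tend"]
        lines += [f"{g}\t{s}\t{e}" for g, (s, e) in self.partitions.items()]
        return "\n".join(lines) + "\n"

    def partition_raxml(self) -> str:
        return "".join(f"DNA, {g} = {s}-{e}\n" for g, (s, e) in self.partitions.items())


def concatenate(alns: list[GeneAlignment]) -> Supermatrix:
    """Concatenate genes into a supermatrix, gap-padding missing accessions.

    Accessions are the union across genes; a gene missing an accession
    contributes a run of gaps for it.  Partition intervals are contiguous,
    disjoint and cover the supermatrix.
    """
    if not alns:
        raise ValueError("empty input: no gene alignments to concatenate")
    seen: set[str] = set()
    for a in alns:
        if a.gene_id in seen:
            raise ValueError(f"duplicate gene_id {a.gene_id!r}")
        seen.add(a.gene_id)

    labels: dict[str, tuple[str, str]] = {}
    for a in alns:
        for r in a.rows:
            labels.setdefault(r.label, (r.species, r.accession))
    order = sorted(labels)

    chunks: dict[str, list[str]] = {lab: [] for lab in order}
    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for a in alns:
        by_label = {r.label: r.seq for r in a.rows}
        pad = GAP * a.length
        for lab in order:
            chunks[lab].append(by_label.get(lab, pad))
        partitions[a.gene_id] = (pos + 1, pos + a.length)
        pos += a.length

    rows = [
        AlignmentRow(labels[lab][0], labels[lab][1], "".join(chunks[lab])) for lab in order
    ]
    return Supermatrix(GeneAlignment("supermatrix", rows), partitions)
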