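"""Pairwise synonymous/nonsynonymous divergence (Nei–Gojobori 1986 counting).

For two aligned coding sequences the estimator counts, per codon, the
number of synonymous and nonsynonymous *sites* (each codon position
contributes fractionally according to how many of its three possible
changes are synonymous) and the number of synonymous and nonsynonymous
*differences* (multi-difference codons averaged over all mutational
pathways with equal weight, pathways through stop codons excluded when any
stop-free pathway exists).  Proportions are corrected for multiple hits
with the Jukes–Cantor transform d = -3/4 ln(1 - 4/3 p), undefined
("saturated") at p >= 3/4.

Site counts are averaged between the two sequences, so N_sites + S_sites
always equals 3x the number of codons compared.  Codons containing an
ambiguity code or a gap in either sequence are skipped entirely.

Per-gene estimates are aggregated into a species-by-species matrix of
medians with lower/upper quartiles (linear-interpolation, i.e. numpy
default / R type-7), and divergence can be standardized to
substitutions/site/Myr by dividing by a node age.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .alignment import AMBIGUITY_CODES, GAP, GeneAlignment

_CODON_TABLE = {**standard_dna_table.forward_table}
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"
_BASES = "ACGT"


def _syn_site_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Changes creating a stop codon count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TABLE[alt] == aa:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


_SITE_CACHE = {c: _syn_site_fraction(c) for c in _CODON_TABLE if _CODON_TABLE[c] != "*"}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over mutational pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                through_stop = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        pathways.append((through_stop, sd, nd))
    clean = [p for p in pathways if not p[0]]
    use = clean if clean else pathways
    sd = sum(p[1] for p in use) / len(use)
    nd = sum(p[2] for p in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class RatePair:
    """NG86 estimates between two coding sequences."""

    dN: float
    dS: float
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    codons: int
    saturated_N: bool = False
    saturated_S: bool = False

    @property
    def saturated(self) -> bool:
        return self.saturated_N or self.saturated_S

    @property
    def omega(self) -> float:
        """dN/dS; nan when dS is 0 or either estimate is saturated."""
        if self.saturated or self.dS == 0:
            return math.nan
        return self.dN / self.dS


def _codon_ok(codon: str) -> bool:
    return not any(ch in AMBIGUITY_CODES or ch == GAP for ch in codon)


def ng86_pairwise(seq1: str, seq2: str) -> RatePair:
    """Nei–Gojobori dN/dS between two equal-length coding sequences.

    Codons with ambiguity or gaps in either sequence are dropped pairwise;
    internal stop codons (after that masking) are an error.
    """
    if len(seq1) != len(seq2):
        raise ValueError(f"length mismatch: {len(seq1)} vs {len(seq2)}")
    if len(seq1) % 3:
        raise ValueError(f"length {len(seq1)} not divisible by 3")
    seq1, seq2 = seq1.upper(), seq2.upper()

    S = N = Sd = Nd = 0.0
    codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if not (_codon_ok(c1) and _codon_ok(c2)):
            continue
        if _CODON_TABLE[c1] == "*" or _CODON_TABLE[c2] == "*":
            raise ValueError(f"internal stop codon at position {i + 1}")
        s1, n1 = _SITE_CACHE[c1]
        s2, n2 = _SITE_CACHE[c2]
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
        codons += 1

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    sat_S = pS >= 0.75
    sat_N = pN >= 0.75
    dS = math.nan if sat_S else _jukes_cantor(pS)
    dN = math.nan if sat_N else _jukes_cantor(pN)
    return RatePair(dN, dS, N, S, Nd, Sd, codons, sat_N, sat_S)


@dataclass
class RateMatrixSummary:
    """Median dN/dS per species pair with quartiles, Table-style layout."""

    species: list[str]
    median_dN: pd.DataFrame
    median_dS: pd.DataFrame
    q1_dN: pd.DataFrame
    q3_dN: pd.DataFrame
    q1_dS: pd.DataFrame
    q3_dS: pd.DataFrame
    n_genes: pd.DataFrame

    def to_table_tsv(self) -> str:
        """dN in the upper triangle, dS in the lower, quartiles in parens."""
        sp = self.species
        out = ["\t" + "\t".join(sp)]
        for i, a in enumerate(sp):
            cells = []
            for j, b in enumerate(sp):
                if i == j:
                    cells.append("")
                elif i < j:  # upper triangle: dN
                    m, lo, hi = (
                        self.median_dN.loc[a, b],
                        self.q1_dN.loc[a, b],
                        self.q3_dN.loc[a, b],
                    )
                    cells.append("" if np.isnan(m) else f"{m:.4f} ({lo:.4f}-{hi:.4f})")
                else:  # lower: dS
                    m, lo, hi = (
                        self.median_dS.loc[a, b],
                        self.q1_dS.loc[a, b],
                        self.q3_dS.loc[a, b],
                    )
                    cells.append("" if np.isnan(m) else f"{m:.4f} ({lo:.4f}-{hi:.4f})")
            out.append(a + "\t" + "\t".join(cells))
        return "\n".join(out) + "\n"


def rate_matrix(
    genes: list[GeneAlignment],
    pairing: dict[str, str] | None = None,
) -> RateMatrixSummary:
    """Aggregate per-gene NG86 estimates into a species-pair summary.

    ``pairing`` maps species -> accession to use; by default the first
    accession of each species in each gene is taken.  Saturated per-gene
    estimates are excluded from that pair's aggregate; a pair with no valid
    gene yields NaN (missing cell), never zero.
    """
    species: list[str] = []
    for g in genes:
        for r in g.rows:
            if r.species not in species:
                species.append(r.species)

    per_pair: dict[tuple[str, str], list[RatePair]] = {}
    for g in genes:
        chosen: dict[str, str] = {}
        for r in g.rows:
            if pairing is not None:
                if pairing.get(r.species) == r.accession:
                    chosen[r.species] = r.seq
            else:
                chosen.setdefault(r.species, r.seq)
        for a, b in itertools.combinations([s for s in species if s in chosen], 2):
            try:
                rp = ng86_pairwise(chosen[a], chosen[b])
            except ValueError:
                continue
            per_pair.setdefault((a, b), []).append(rp)

    def frame():
        return pd.DataFrame(np.nan, index=species, columns=species)

    med_dN, med_dS = frame(), frame()
    q1N, q3N, q1S, q3S = frame(), frame(), frame(), frame()
    ngen = pd.DataFrame(0, index=species, columns=species)

    for (a, b), pairs in per_pair.items():
        dNs = [p.dN for p in pairs if not p.saturated_N]
        dSs = [p.dS for p in pairs if not p.saturated_S]
        for src, med, q1, q3 in ((dNs, med_dN, q1N, q3N), (dSs, med_dS, q1S, q3S)):
            if src:
                vals = np.array(src)
                for x, y in ((a, b), (b, a)):
                    med.loc[x, y] = np.median(vals)
                    q1.loc[x, y] = np.quantile(vals, 0.25)
                    q3.loc[x, y] = np.quantile(vals, 0.75)
        ngen.loc[a, b] = ngen.loc[b, a] = len(pairs)

    return RateMatrixSummary(species, med_dN, med_dS, q1N, q3N, q1S, q3S, ngen)


def per_myr(rate: float, T: float) -> float:
    """Standardize substitutions/site to substitutions/site/Myr (rate / T)."""
    if T <= 0:
        raise ValueError(f"node age T must be > 0, got {T}")
    return rate / T
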