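"""ABBA-BABA introgression test and shared-derived-SNP tabulation.

Sites are polarized with an outgroup: the outgroup allele is taken as
ancestral and the alternative as derived.  On a four-taxon tree
(((H1,H2),H3),O) the D-statistic

    D = (nABBA - nBABA) / (nABBA + nBABA)

contrasts the two discordant site patterns; under incomplete lineage
sorting alone they are equally frequent, while gene flow between H3 and
one of H1/H2 inflates one of them.  Significance comes from a delete-one
block jackknife over contiguous genomic blocks, robust to linkage.

The shared-derived tabulation asks, partition by partition (genome-wide,
per chromosome, genic), whether a putatively introgressed accession shares
derived alleles with the donor more often than a non-introgressed control
does, using an exact binomial test (default), the goodness-of-fit
chi-square (a-b)^2/(a+b), or a permutation test with a 1/B p-value floor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PolarizedSites:
    """Derived/ancestral calls per retained site plus exclusion counters."""

    table: pd.DataFrame  # columns: chrom, pos, ancestral, derived + one per taxon (0/1 derived-allele indicator)
    n_excluded_outgroup_missing: int = 0
    n_excluded_outgroup_het: int = 0
    n_excluded_multiallelic: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.table)


def polarize_sites(
    variants: pd.DataFrame,
    outgroup: str,
    samples: list[str] | None = None,
) -> PolarizedSites:
    """Polarize biallelic SNPs against an outgroup column.

    ``variants`` needs columns ``chrom``, ``pos``, ``ref``, ``alt`` and one
    allele column per sample (single bases; '.'/''/None = missing).  Sites
    where the outgroup is missing, heterozygous (not a single base), or
    matches neither allele, and sites with >2 alleles overall, are dropped
    and counted.  Output carries a 0/1 derived-allele indicator per sample
    (NaN where the sample is missing).
    """
    if samples is None:
        samples = [
            c for c in variants.columns
            if c not in ("chrom", "pos", "ref", "alt") and c != outgroup
        ]
    keep_rows = []
    n_miss = n_het = n_multi = 0
    valid = set("ACGT")
    for row in variants.itertuples(index=False):
        d = row._asdict()
        og = d[outgroup]
        ref, alt = d["ref"], d["alt"]
        if "," in str(alt):
            n_multi += 1
            continue
        if og is None or og in (".", "", "N") or (isinstance(og, float) and math.isnan(og)):
            n_miss += 1
            continue
        if og not in valid:
            n_het += 1
            continue
        if og == ref:
            derived = alt
        elif og == alt:
            derived = ref
        else:
            n_multi += 1  # outgroup carries a third allele
            continue
        rec = {
            "chrom": d["chrom"],
            "pos": d["pos"],
            "ancestral": og,
            "derived": derived,
        }
        for s in samples:
            a = d[s]
            if a in valid:
                rec[s] = 1.0 if a == derived else 0.0
            else:
                rec[s] = np.nan
        keep_rows.append(rec)
    cols = ["chrom", "pos", "ancestral", "derived"] + samples
    table = pd.DataFrame(keep_rows, columns=cols)
    return PolarizedSites(table, n_miss, n_het, n_multi)


@dataclass
class SitePatternCounts:
    nABBA: float
    nBABA: float
    block_abba: np.ndarray
    block_baba: np.ndarray
    block_size: int | None = None


@dataclass
class DResult:
    """ABBA-BABA D with block-jackknife standard error and Z."""

    D: float
    Z: float
    se: float
    counts: SitePatternCounts

    def summary(self) -> str:
        c = self.counts
        return (
            f"ABBA-BABA: nABBA={c.nABBA:.1f} nBABA={c.nBABA:.1f} "
            f"D={self.D:.4f} SE={self.se:.4f} Z={self.Z:.2f}"
        )


def _pattern_counts(sites: pd.DataFrame, h1: str, h2: str, h3: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ABBA/BABA indicators; sites with missing taxa excluded."""
    a = sites[h1].to_numpy(float)
    b = sites[h2].to_numpy(float)
    c = sites[h3].to_numpy(float)
    ok = ~(np.isnan(a) | np.isnan(b) | np.isnan(c))
    abba = ok & (a == 0) & (b == 1) & (c == 1)
    baba = ok & (a == 1) & (b == 0) & (c == 1)
    return abba.astype(float), baba.astype(float)


def d_statistic(
    sites: PolarizedSites | pd.DataFrame,
    h1: str,
    h2: str,
    h3: str,
    *,
    block_size: int = 1_000_000,
    n_blocks: int | None = None,
) -> DResult:
    """D-statistic with delete-one block-jackknife Z.

    Blocks are contiguous runs of ``block_size`` bp per chromosome; pass
    ``n_blocks`` instead to split the site list into that many equal-count
    blocks (useful for short synthetic genomes).  The outgroup is implicit:
    sites must already be polarized (derived-allele indicators per taxon).
    """
    table = sites.table if isinstance(sites, PolarizedSites) else sites
    abba, baba = _pattern_counts(table, h1, h2, h3)
    nA, nB = abba.sum(), baba.sum()
    if nA + nB == 0:
        raise ValueError("no ABBA or BABA sites: D undefined")
    D = (nA - nB) / (nA + nB)

    if n_blocks is not None:
        idx = np.array_split(np.arange(len(table)), n_blocks)
        blocks = [(abba[i].sum(), baba[i].sum()) for i in idx if len(i)]
        bsize = None
    else:
        key = (
            table["chrom"].astype(str)
            + ":"
            + (table["pos"].to_numpy(int) // block_size).astype(str)
        )
        blocks = []
        for _, g in pd.Series(np.arange(len(table))).groupby(key.to_numpy()):
            i = g.to_numpy()
            blocks.append((abba[i].sum(), baba[i].sum()))
        bsize = block_size

    block_a = np.array([b[0] for b in blocks])
    block_b = np.array([b[1] for b in blocks])
    informative = (block_a + block_b) > 0
    # Jackknife only over blocks with informative sites.
    ba, bb = block_a[informative], block_b[informative]
    m = len(ba)
    if m < 2:
        return DResult(float(D), float("nan"), float("nan"),
                       SitePatternCounts(nA, nB, block_a, block_b, bsize))
    d_loo = ((nA - ba) - (nB - bb)) / ((nA - ba) + (nB - bb))
    var = (m - 1) / m * np.sum((d_loo - d_loo.mean()) ** 2)
    se = math.sqrt(var)
    Z = D / se if se > 0 else float("inf") * np.sign(D)
    return DResult(float(D), float(Z), float(se),
                   SitePatternCounts(nA, nB, block_a, block_b, bsize))


@dataclass
class SharedDerivedTable:
    """Per-partition shared-derived-SNP counts and equality-test p-values."""

    table: pd.DataFrame  # partition, n_recipient, n_control, p_value
    test: str
    recipient: str
    control: str
    donor: str

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def _equality_pvalue(a: int, b: int, test: str, B: int, rng) -> float:
    n = a + b
    if n == 0:
        return float("nan")
    if test == "binomial":
        return stats.binomtest(a, n, 0.5).pvalue
    if test == "chi2":
        chi2 = (a - b) ** 2 / n
        return float(stats.chi2.sf(chi2, df=1))
    if test == "permutation":
        draws = rng.binomial(n, 0.5, size=B)
        obs = abs(a - n / 2)
        extreme = int(np.sum(np.abs(draws - n / 2) >= obs - 1e-9))
        return max(extreme / B, 1.0 / B)
    raise ValueError(f"unknown test {test!r}")


def shared_derived_chi2(a: int, b: int) -> float:
    """Goodness-of-fit chi-square for equal counts: (a-b)^2/(a+b)."""
    if a + b == 0:
        return float("nan")
    return (a - b) ** 2 / (a + b)


def shared_derived_test(
    sites: PolarizedSites | pd.DataFrame,
    recipient: str,
    control: str,
    donor: str,
    *,
    gene_intervals: pd.DataFrame | None = None,
    test: str = "binomial",
    B: int = 2000,
    seed: int | None = None,
) -> SharedDerivedTable:
    """Tabulate derived alleles shared with the donor, recipient vs control.

    A site counts for the recipient when recipient and donor carry the
    derived allele and the control does not (and symmetrically for the
    control).  Partitions: genome-wide, each chromosome, genic sites (if
    ``gene_intervals`` with columns chrom/start/end/gene_id is given,
    half-open [start, end) coordinates), plus the number of distinct genes
    hit per accession.  ``test`` is ``binomial`` (exact, default),
    ``chi2``, or ``permutation`` (B replicates, p floored at 1/B).
    """
    if recipient == control:
        raise ValueError("recipient and control must be distinct accessions")
    table = sites.table if isinstance(sites, PolarizedSites) else sites
    rng = np.random.default_rng(seed)

    r = table[recipient].to_numpy(float)
    c = table[control].to_numpy(float)
    d = table[donor].to_numpy(float)
    ok = ~(np.isnan(r) | np.isnan(c) | np.isnan(d))
    rec_shared = ok & (r == 1) & (d == 1) & (c == 0)
    ctl_shared = ok & (c == 1) & (d == 1) & (r == 0)

    rows = []

    def add(partition: str, mask: np.ndarray):
        a = int(rec_shared[mask].sum())
        b = int(ctl_shared[mask].sum())
        if a + b == 0:
            warnings.warn(f"partition {partition!r} has no shared-derived sites")
            p = float("nan")
        else:
            p = _equality_pvalue(a, b, test, B, rng)
        rows.append(
            {"partition": partition, "n_recipient": a, "n_control": b, "p_value": p}
        )

    every = np.ones(len(table), bool)
    add("genome", every)
    for chrom in pd.unique(table["chrom"]):
        add(str(chrom), (table["chrom"] == chrom).to_numpy())

    if gene_intervals is not None:
        genic = np.zeros(len(table), bool)
        gene_hit_rec: set[str] = set()
        gene_hit_ctl: set[str] = set()
        pos = table["pos"].to_numpy(int)
        chroms = table["chrom"].to_numpy()
        for g in gene_intervals.itertuples(index=False):
            m = (chroms == g.chrom) & (pos >= g.start) & (pos < g.end)
            genic |= m
            if rec_shared[m].any():
                gene_hit_rec.add(g.gene_id)
            if ctl_shared[m].any():
                gene_hit_ctl.add(g.gene_id)
        add("genic", genic)
        a, b = len(gene_hit_rec), len(gene_hit_ctl)
        rows.append(
            {
                "partition": "genes_hit",
                "n_recipient": a,
                "n_control": b,
                "p_value": _equality_pvalue(a, b, test, B, rng) if a + b else float("nan"),
            }
        )

    return SharedDerivedTable(pd.DataFrame(rows), test, recipient, control, donor)
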