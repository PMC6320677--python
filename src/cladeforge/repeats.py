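"""Repeat-cluster occupancy, differential abundance, and relative-age calls.

Low-coverage read sets standardized to a fixed read length (default 85 nt)
are subsampled to a genome-size-equivalent fraction (default 1%), so the
fraction of subsampled reads falling in a repeat cluster converts directly
to genome occupancy in Mb.  Clusters smaller than a fraction of the total
input (default 0.01%) are discarded as noise.

Relative cluster age comes from the cluster's pairwise read-identity
histogram (1% bins over 70-100% identity).  Recently amplified ("young")
repeats have most read pairs near 100% identity; degraded ("old") repeats
are shifted left.  Null (flat), linear and quadratic trends are fitted to
bin counts by least squares and compared by BIC; the selected model's
shape maps onto six trend classes:

  1  positive linear                                        -> young
  2  null (no trend)                                        -> old
  3  negative linear                                        -> old
  4  positive quadratic, mass right of vertex               -> young
  4b positive quadratic, mass left of vertex                -> old
  5  negative quadratic, mass right of vertex               -> old
  6  negative quadratic, mass left of vertex, vertex > 99%  -> old

A negative quadratic with mass left of a vertex at <= 99% identity rises
toward its (interior) peak and is treated as class 5's mirror and called
young; the >99% vertex of class 6 means the apparent "rise" never enters
the data range.

Differential cluster abundance across phylogenetic depths is a two-sided
rank test per cluster between the two clades of a focal node, BH-adjusted;
deeper comparisons use Brownian-motion ancestral occupancies from
:mod:`cladeforge.chronogram` as the node-level inputs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .chronogram import bm_ancestral_states


@dataclass(frozen=True)
class RepeatSamplingConfig:
    genome_size_mb: float
    gse_fraction: float = 0.01
    read_len: int = 85
    cluster_min_fraction: float = 0.0001

    def __post_init__(self) -> None:
        if not 0 < self.gse_fraction < 1:
            raise ValueError("gse_fraction must be in (0, 1)")
        if not 0 < self.cluster_min_fraction < 1:
            raise ValueError("cluster_min_fraction must be in (0, 1)")
        if self.read_len <= 0:
            raise ValueError("read_len must be > 0")

    @property
    def n_reads(self) -> int:
        """Reads in a genome-size-equivalent subsample."""
        return int(self.gse_fraction * self.genome_size_mb * 1e6 // self.read_len)


def gse_subsample(reads: list[str], config: RepeatSamplingConfig, seed: int) -> list[str]:
    """Deterministic random subsample to the GSE read count."""
    n_out = config.n_reads
    if n_out > len(reads):
        raise ValueError(
            f"need {n_out} reads for a {config.gse_fraction:.2%} GSE but only "
            f"{len(reads)} available (short by {n_out - len(reads)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n_out, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


def cluster_threshold(total_input_reads: int, cluster_min_fraction: float = 0.0001) -> int:
    """Minimum reads for a cluster to be retained: floor(fraction x total).

    A zero floor is interpreted as "retain clusters with >= 1 read" (with a
    warning) since an empty cluster is not a cluster.
    """
    if total_input_reads <= 0:
        raise ValueError("total_input_reads must be > 0")
    t = int(cluster_min_fraction * total_input_reads)
    if t == 0:
        warnings.warn(
            "retention threshold rounds to 0 reads; retaining all clusters with >=1 read"
        )
        return 0
    return t


def occupancy_mb(cluster_reads: int, sample_reads: int, genome_size_mb: float) -> float:
    """Genome occupancy of a cluster in Mb: read share x genome size."""
    if sample_reads <= 0:
        raise ValueError("sample_reads must be > 0")
    if cluster_reads > sample_reads:
        raise ValueError(f"cluster_reads {cluster_reads} > sample_reads {sample_reads}")
    return cluster_reads / sample_reads * genome_size_mb


IDENTITY_BINS = np.arange(70.0, 100.0 + 1.0, 1.0)  # 1% bins over [70, 100]


def pairwise_identity_histogram(
    reads: list[str],
    *,
    min_overlap: int = 55,
    max_pairs: int | None = 20000,
    seed: int = 0,
) -> np.ndarray:
    """All-vs-all percent-identity histogram for a cluster's reads.

    Identity = 1 - editdistance/alignment-length from global (NW)
    alignment; pairs whose shorter read is below ``min_overlap`` are
    skipped.  ``max_pairs`` caps the quadratic all-vs-all cost by random
    pair subsampling.  Returns counts per 1% bin over [70, 100].
    """
    pairs = list(itertools.combinations(range(len(reads)), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sel]
    idents = []
    for i, j in pairs:
        a, b = reads[i], reads[j]
        if min(len(a), len(b)) < min_overlap:
            continue
        res = edlib.align(a, b, mode="NW", task="distance")
        alen = max(len(a), len(b))
        idents.append(100.0 * (1.0 - res["editDistance"] / alen))
    hist, _ = np.histogram(idents, bins=IDENTITY_BINS)
    return hist


YOUNG = "young"
OLD = "old"


@dataclass
class TrendFit:
    """Selected identity-trend model and the derived relative-age call."""

    model: str  # 'null' | 'linear' | 'quadratic'
    coefficients: tuple[float, ...]
    bic: dict[str, float]
    trend_class: str  # '1'..'6' (+ '4b')
    age: str  # 'young' | 'old'
    vertex: float | None = None  # %identity; quadratic only

    def summary(self) -> str:
        return (
            f"model={self.model} class={self.trend_class} age={self.age}"
            + (f" vertex={self.vertex:.2f}%" if self.vertex is not None else "")
        )


def _gaussian_bic(y: np.ndarray, yhat: np.ndarray, k_params: int) -> float:
    n = len(y)
    rss = float(np.sum((y - yhat) ** 2))
    # Floor sigma^2 at numerical noise relative to the data scale so that an
    # exactly-fitting model cannot win on float residue; the k ln(n) penalty
    # then favors the simpler of two equally exact models.
    sigma2 = max(rss / n, 1e-9 * (float(np.var(y)) + 1.0))
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = k_params + 1  # + residual variance
    return k * np.log(n) - 2.0 * loglik


def fit_identity_trend(
    histogram: np.ndarray,
    bin_edges: np.ndarray = IDENTITY_BINS,
    *,
    min_bins: int = 5,
) -> TrendFit | None:
    """Fit null/linear/quadratic trends to an identity histogram, pick by BIC.

    Only non-empty bins enter the regression (empty bins are unobserved
    identity levels, not zero-abundance observations).  Returns None
    (unclassified) with fewer than ``min_bins`` non-empty bins.
    """
    histogram = np.asarray(histogram, float)
    mids = (bin_edges[:-1] + bin_edges[1:]) / 2.0
    mask = histogram > 0
    if mask.sum() < min_bins:
        return None
    x, y = mids[mask], histogram[mask]

    fits = {}
    yhat0 = np.full_like(y, y.mean())
    fits["null"] = ((y.mean(),), yhat0, _gaussian_bic(y, yhat0, 1))
    c1 = np.polyfit(x, y, 1)
    fits["linear"] = (tuple(c1), np.polyval(c1, x), _gaussian_bic(y, np.polyval(c1, x), 2))
    c2 = np.polyfit(x, y, 2)
    fits["quadratic"] = (tuple(c2), np.polyval(c2, x), _gaussian_bic(y, np.polyval(c2, x), 3))

    bics = {m: f[2] for m, f in fits.items()}
    model = min(bics, key=bics.get)
    coefs = fits[model][0]

    vertex = None
    if model == "null":
        trend_class, age = "2", OLD
    elif model == "linear":
        slope = coefs[0]
        if slope > 0:
            trend_class, age = "1", YOUNG
        else:
            trend_class, age = "3", OLD
    else:
        a, b, _c = coefs
        vertex = -b / (2.0 * a)
        total = y.sum()
        mass_left = y[x < vertex].sum()
        left = mass_left > 0.5 * total
        if a > 0:  # positive (opening-up) parabola
            trend_class, age = ("4b", OLD) if left else ("4", YOUNG)
        else:  # negative (opening-down) parabola
            if left:
                trend_class, age = ("6", OLD) if vertex > 99.0 else ("5m", YOUNG)
            else:
                trend_class, age = "5", OLD
    return TrendFit(model, coefs, bics, trend_class, age, vertex)


@dataclass
class DifferentialAbundanceResult:
    table: pd.DataFrame  # cluster, group_a_mean, group_b_mean, effect, p, p_adj, flagged
    node_key: frozenset
    ancestral: dict[str, float]  # cluster -> BM ancestral occupancy at the node

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "cluster"])


def differential_abundance(
    occupancy: pd.DataFrame,
    tree,
    node_tips: frozenset[str] | None = None,
    *,
    alpha: float = 0.05,
) -> DifferentialAbundanceResult:
    """Two-clade differential cluster abundance at one phylogenetic node.

    ``occupancy`` is cluster x accession (Mb); ``node_tips`` selects the
    focal internal node by its descendant tip set (default: the root, i.e.
    the deepest comparison).  Accessions are split into the node's two
    child clades; each cluster gets a two-sided Mann-Whitney test between
    the clades with Benjamini-Hochberg adjustment at ``alpha``.  Brownian
    ancestral occupancies at the focal node are returned per cluster for
    use as the next-deeper level's inputs.  Clusters where either side is
    a singleton are skipped.
    """
    node = (
        tree.seed_node
        if node_tips is None
        else tree.mrca(taxon_labels=sorted(node_tips))
    )
    kids = node.child_nodes()
    if len(kids) < 2:
        raise ValueError("focal node must have two child clades")
    group_a = [lf.taxon.label for lf in kids[0].leaf_iter()]
    group_b = [lf.taxon.label for lf in itertools.chain(*[k.leaf_iter() for k in kids[1:]])]
    group_a = [g for g in group_a if g in occupancy.columns]
    group_b = [g for g in group_b if g in occupancy.columns]

    rows = []
    for cluster, vals in occupancy.iterrows():
        a = vals[group_a].to_numpy(float)
        b = vals[group_b].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            continue
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append(
            {
                "cluster": cluster,
                "group_a_mean": a.mean(),
                "group_b_mean": b.mean(),
                "effect": a.mean() - b.mean(),
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = stats.false_discovery_control(table["p"], method="bh")
        table["flagged"] = table["p_adj"] < alpha
    else:
        table["p_adj"] = []
        table["flagged"] = []

    ancestral: dict[str, float] = {}
    tip_labels = group_a + group_b
    node_key = frozenset(lf.taxon.label for lf in node.leaf_iter())
    for cluster, vals in occupancy.iterrows():
        tips = {t: float(vals[t]) for t in occupancy.columns}
        try:
            asr = bm_ancestral_states(tree, tips)
            # focal node label: match by leaf set
            for nd in tree.preorder_node_iter():
                if not nd.is_leaf() and frozenset(
                    lf.taxon.label for lf in nd.leaf_iter()
                ) == node_key:
                    ancestral[cluster] = asr.estimates[nd.label]
                    break
        except Exception:
            ancestral[cluster] = float("nan")
    return DifferentialAbundanceResult(table, node_key, ancestral)
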