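"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates, at toy scale, the inputs of a phylogenomic study
of closely related diploid genomes: a clock-like species tree with an
outgroup; per-gene codon alignments evolved under purifying selection
(dN/dS = omega); a polarized SNP + indel variant table with an optional
introgression event of known proportion; toy gene models; repeat-cluster
read sets and abundance tables with labelled age-trend shapes; orthogroup
copy numbers evolved under per-branch birth-death; and genome sizes
evolved under Brownian motion.  Every stochastic choice flows from one
integer seed, so a given configuration is bit-reproducible, and the
ground-truth parameters of each component are returned (and written to
``truth.json``) for parameter-recovery testing.

Codon evolution is a per-site Monte Carlo rather than a full codon rate
matrix: each nucleotide site accumulates Poisson(branch length) proposed
changes; synonymous proposals are always accepted, nonsynonymous ones
with probability omega, and changes creating stop codons are rejected.
With that scheme the expected synonymous divergence per unit branch
length is 1 and the expected dN/dS equals omega, which is what makes the
downstream rate estimators testable.

Time calibration: branch lengths are synonymous substitutions/site per
lineage; a species pair separated at depth t has expected dS = 2t, so a
node at depth t is 2t / r Myr old for a pairwise synonymous rate r
(subs/site/Myr).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .alignment import AlignmentRow, GeneAlignment
from .rates import _CODON_TABLE

_SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")
_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


class ConfigError(ValueError):
    """Invalid simulation configuration; ``field`` names the offender."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class IntrogressionEvent:
    donor: str
    recipient: str
    proportion: float


#: trend-shape label -> (trend class, expected age call)
TREND_SHAPES = {
    "pos_linear": ("1", "young"),
    "flat": ("2", "old"),
    "neg_linear": ("3", "old"),
    "pos_quad_right": ("4", "young"),
    "pos_quad_left": ("4b", "old"),
    "neg_quad_right": ("5", "old"),
    "neg_quad_left_high_vertex": ("6", "old"),
}


@dataclass(frozen=True)
class RepeatClusterSpec:
    trend_shape: str = "flat"
    mean_identity: float = 85.0  # % identity center used for read divergence
    spread: float = 5.0
    n_reads: int = 120


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with clade-realistic defaults.

    Defaults mirror the study system: a shallow radiation (root depth
    0.015 synonymous subs/site per lineage, so maximal pairwise dS around
    0.03), strong purifying selection (omega 0.12), a pairwise synonymous
    rate of 0.01 subs/site/Myr, a 2:1 deletion bias with mean indel size
    6.2 nt capped at 270 nt, 85-nt repeat reads, and an 880 Mb root
    genome.  Counts (genes, sites, clusters, orthogroups) are toy-scale.
    """

    seed: int = 0
    n_species: int = 4
    tree_height: float = 0.015  # subs/site per lineage, root depth
    omega: float = 0.12
    syn_rate_per_myr: float = 0.01  # pairwise dS per Myr (the clock rate r)
    introgression: IntrogressionEvent | None = None
    indel_rate: float = 0.05  # indel events per substitution event
    deletion_bias: float = 2.0  # odds of deletion vs insertion (beta)
    indel_size_mean: float = 6.2
    indel_max_size: int = 270
    ils_fraction: float = 0.1  # sites with a discordant (deep-coalescent) genealogy
    outgroup_mutation_rate: float = 0.005  # per variant site, breaks polarity
    repeat_age_params: tuple[RepeatClusterSpec, ...] = (
        RepeatClusterSpec("pos_linear"),
        RepeatClusterSpec("flat"),
        RepeatClusterSpec("neg_quad_left_high_vertex"),
    )
    genome_size_root_mb: float = 880.0
    genome_size_sigma2: float = 70.0  # Mb^2 per Myr of Brownian motion
    orthogroup_gain_rate: float = 0.1  # expected gains per family per branch
    orthogroup_loss_rate: float = 0.2
    read_len: int = 85
    n_genes: int = 50
    codons_per_gene: int = 250
    n_snp_sites: int = 2000
    n_indel_events: int = 300
    n_orthogroups: int = 200
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    outgroup_label: str = "outgroup"

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigError("n_species", "need at least 2 species")
        if self.tree_height <= 0:
            raise ConfigError("tree_height", "must be > 0")
        if self.omega < 0:
            raise ConfigError("omega", "must be >= 0")
        if self.syn_rate_per_myr <= 0:
            raise ConfigError("syn_rate_per_myr", "must be > 0")
        if self.introgression is not None:
            f = self.introgression.proportion
            if not 0.0 <= f <= 1.0:
                raise ConfigError("introgression.proportion", f"{f} not in [0, 1]")
        if self.deletion_bias < 0:
            raise ConfigError("deletion_bias", "must be >= 0")
        if self.indel_size_mean < 1:
            raise ConfigError("indel_size_mean", "must be >= 1 nt")
        if self.read_len <= 0:
            raise ConfigError("read_len", "must be > 0")
        if not 0.0 <= self.ils_fraction <= 1.0:
            raise ConfigError("ils_fraction", "must be in [0, 1]")
        for spec in self.repeat_age_params:
            if spec.trend_shape not in TREND_SHAPES:
                raise ConfigError(
                    "repeat_age_params",
                    f"unknown trend shape {spec.trend_shape!r}",
                )

    @property
    def deletion_fraction(self) -> float:
        """P(deletion) implied by the deletion-bias odds beta: beta/(1+beta)."""
        return self.deletion_bias / (1.0 + self.deletion_bias)

    def species_labels(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


# ---------------------------------------------------------------------------
# species tree


def simulate_tree(config: SimulationConfig, rng: np.random.Generator) -> dendropy.Tree:
    """Random clock-like rooted tree plus outgroup; lengths in subs/site.

    Topology by random sequential joins; internal-node depths are sorted
    uniforms scaled to ``tree_height``.  The outgroup attaches above the
    ingroup root at 2x the root depth.  Species labels are assigned in
    join order, so ``sp01`` and ``sp02`` are always a cherry and ``sp03``
    the next taxon to join them — a canonical (((H1,H2),H3),O) quartet is
    always available.
    """
    labels = config.species_labels()
    taxa = dendropy.TaxonNamespace(labels + [config.outgroup_label])
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes = []
    for _ in labels:
        nd = dendropy.Node()
        nd.depth = 0.0
        nodes.append(nd)
    depths = np.sort(rng.uniform(0.15, 1.0, size=len(labels) - 1)) * config.tree_height
    for d in depths:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.depth = float(d)
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = parent.depth - a.depth
        b.edge.length = parent.depth - b.depth
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    ingroup_root = nodes[0]
    # Label tips in the order they are swept up by the join process: the
    # first join's tips become sp01/sp02, the next tip to attach to that
    # growing clade sp03, and so on; tips of later, separate clades follow.
    ordered: list[dendropy.Node] = []
    for lf in ingroup_root.leaf_iter():
        ordered.append(lf)
    # leaf_iter follows child order, and children were appended join-first,
    # but we want accretion order around the first cherry: sort tips by the
    # depth of their MRCA with the first-joined pair.
    first_cherry = min(
        (nd for nd in ingroup_root.preorder_internal_node_iter()),
        key=lambda nd: nd.depth,
    )
    anchor = next(first_cherry.leaf_iter())

    def mrca_depth(tip):
        seen = set()
        p = anchor
        while p is not None:
            seen.add(id(p))
            p = p.parent_node
        p = tip
        while id(p) not in seen:
            p = p.parent_node
        return p.depth

    tips = list(ingroup_root.leaf_iter())
    tips.sort(key=mrca_depth)
    for lab, tip in zip(labels, tips):
        tip.taxon = taxa.get_taxon(lab)
    og = dendropy.Node()
    og.taxon = taxa.get_taxon(config.outgroup_label)
    og.depth = 0.0
    root = dendropy.Node()
    root.depth = 2.0 * config.tree_height
    root.add_child(ingroup_root)
    root.add_child(og)
    ingroup_root.edge.length = root.depth - ingroup_root.depth
    og.edge.length = root.depth
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def node_age_myr(depth_subs: float, syn_rate_per_myr: float) -> float:
    """Myr age of a node at clock depth ``depth_subs`` (pairwise dS = 2 x depth)."""
    return 2.0 * depth_subs / syn_rate_per_myr


# ---------------------------------------------------------------------------
# codon alignments


def _evolve_codon_seq(
    seq: np.ndarray, t: float, omega: float, rng: np.random.Generator
) -> tuple[np.ndarray, int, int]:
    """Evolve a nucleotide array (length divisible by 3) for branch length t.

    Returns (new seq, n_synonymous, n_nonsynonymous accepted events).
    """
    seq = seq.copy()
    n_sites = len(seq)
    n_events = rng.poisson(t * n_sites)
    n_syn = n_non = 0
    if n_events == 0:
        return seq, 0, 0
    sites = rng.integers(0, n_sites, size=n_events)
    for site in sites:
        old = seq[site]
        new = rng.integers(0, 3)
        if new >= old:
            new += 1
        c0 = site - site % 3
        codon = seq[c0 : c0 + 3]
        before = _BASES[codon[0]] + _BASES[codon[1]] + _BASES[codon[2]]
        after_l = list(before)
        after_l[site - c0] = _BASES[new]
        after = "".join(after_l)
        if _CODON_TABLE[after] == "*":
            continue
        if _CODON_TABLE[after] == _CODON_TABLE[before]:
            seq[site] = new
            n_syn += 1
        elif rng.random() < omega:
            seq[site] = new
            n_non += 1
    return seq, n_syn, n_non


def simulate_gene_alignments(
    config: SimulationConfig,
    tree: dendropy.Tree,
    rng: np.random.Generator,
) -> list[GeneAlignment]:
    """Evolve ``n_genes`` codon alignments down the tree (includes outgroup)."""
    genes = []
    for g in range(config.n_genes):
        codon_idx = rng.integers(0, len(_SENSE_CODONS), size=config.codons_per_gene)
        root_seq = np.fromiter(
            (
                _BASE_IDX[b]
                for i in codon_idx
                for b in _SENSE_CODONS[i]
            ),
            dtype=np.int8,
        )
        seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            parent_seq = seqs[id(nd.parent_node)]
            child, _, _ = _evolve_codon_seq(
                parent_seq, nd.edge.length or 0.0, config.omega, rng
            )
            seqs[id(nd)] = child
        rows = []
        for lf in tree.leaf_node_iter():
            s = "".join(_BASES[i] for i in seqs[id(lf)])
            rows.append(AlignmentRow(lf.taxon.label, lf.taxon.label, s))
        genes.append(GeneAlignment(f"gene{g + 1:05d}", rows))
    return genes


# ---------------------------------------------------------------------------
# variants (SNPs + indels) and gene models


def _branch_list(tree: dendropy.Tree, include_outgroup: bool, outgroup: str):
    branches = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if not include_outgroup and nd.is_leaf() and nd.taxon.label == outgroup:
            continue
        branches.append(nd)
    return branches


def simulate_variants(
    config: SimulationConfig,
    tree: dendropy.Tree,
    rng: np.random.Generator,
) -> dict:
    """SNP and indel records with full ground truth.

    Each variant arises from a single mutation on one ingroup branch
    (probability proportional to branch length); carriers are the tips
    below it.  Introgression then copies the donor's allele into the
    recipient at a fraction f of SNP sites.  The outgroup is ancestral
    except at a small fraction of sites (``outgroup_mutation_rate``) where
    its state is perturbed, breaking polarity on purpose.
    """
    labels = config.species_labels()
    outgroup = config.outgroup_label
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    chrom_len = config.chromosome_length

    ref = {
        c: rng.integers(0, 4, size=chrom_len).astype(np.int8) for c in chrom_names
    }

    branches = _branch_list(tree, include_outgroup=False, outgroup=outgroup)
    blens = np.array([b.edge.length or 0.0 for b in branches])
    bprobs = blens / blens.sum()
    carriers = [
        frozenset(lf.taxon.label for lf in b.leaf_iter()) - {outgroup}
        for b in branches
    ]

    n_sites = config.n_snp_sites + config.n_indel_events
    # distinct, spaced positions so indel alleles never overlap
    spacing = 300
    avail = config.n_chromosomes * (chrom_len // spacing - 2)
    if n_sites > avail:
        raise ConfigError("n_snp_sites", f"too many sites for genome ({n_sites} > {avail})")
    slots = rng.choice(avail, size=n_sites, replace=False)
    slots.sort()
    positions = []
    per_chrom = chrom_len // spacing - 2
    for s in slots:
        ci = s // per_chrom
        positions.append((chrom_names[ci], int((s % per_chrom) + 1) * spacing))
    rng.shuffle(positions)

    snp_records = []
    snp_truth = []
    for k in range(config.n_snp_sites):
        chrom, pos = positions[k]
        if rng.random() < config.ils_fraction and len(labels) >= 3:
            # deep coalescence: the site genealogy is discordant; a random
            # pair of species shares the derived allele, symmetrically.
            pick = rng.choice(len(labels), size=2, replace=False)
            derived_set = frozenset(labels[i] for i in pick)
        else:
            br = rng.choice(len(branches), p=bprobs)
            derived_set = carriers[br]
        anc = int(ref[chrom][pos - 1])
        der = int(rng.integers(0, 3))
        if der >= anc:
            der += 1
        og_mutated = rng.random() < config.outgroup_mutation_rate
        og_base = der if og_mutated else anc
        alleles = {lab: (der if lab in derived_set else anc) for lab in labels}
        alleles[outgroup] = og_base
        snp_records.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": _BASES[anc],
                "alt": _BASES[der],
                **{lab: _BASES[alleles[lab]] for lab in labels + [outgroup]},
            }
        )
        snp_truth.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ancestral": _BASES[anc],
                "derived": _BASES[der],
                "carriers": sorted(derived_set),
                "outgroup_mutated": bool(og_mutated),
            }
        )

    # introgression: overwrite recipient with donor allele at fraction f
    n_introgressed = 0
    if config.introgression is not None:
        ev = config.introgression
        if ev.donor not in labels or ev.recipient not in labels:
            raise ConfigError("introgression", "donor/recipient not among species")
        mask = rng.random(config.n_snp_sites) < ev.proportion
        for k in np.nonzero(mask)[0]:
            rec = snp_records[k]
            if rec[ev.recipient] != rec[ev.donor]:
                n_introgressed += 1
            rec[ev.recipient] = rec[ev.donor]
            snp_truth[k]["introgressed"] = True

    # indels
    indel_records = []
    indel_truth = []
    p_del = config.deletion_fraction
    for k in range(config.n_indel_events):
        chrom, pos = positions[config.n_snp_sites + k]
        br = rng.choice(len(branches), p=bprobs)
        derived_set = carriers[br]
        length = min(int(rng.geometric(1.0 / config.indel_size_mean)), config.indel_max_size)
        is_del = rng.random() < p_del
        anchor = _BASES[int(ref[chrom][pos - 1])]
        segment = "".join(_BASES[i] for i in ref[chrom][pos : pos + length])
        if is_del:
            ref_allele, alt_allele = anchor + segment, anchor
        else:
            ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
            ref_allele, alt_allele = anchor, anchor + ins
        og_mutated = rng.random() < config.outgroup_mutation_rate
        og_allele = alt_allele if og_mutated else ref_allele
        rec = {
            "chrom": chrom,
            "pos": pos,
            "ref": ref_allele,
            "alt": alt_allele,
            **{
                lab: (alt_allele if lab in derived_set else ref_allele)
                for lab in labels
            },
            config.outgroup_label: og_allele,
        }
        indel_records.append(rec)
        indel_truth.append(
            {
                "chrom": chrom,
                "pos": pos,
                "length": length,
                "polarity": "deletion" if is_del else "insertion",
                "carriers": sorted(derived_set),
                "outgroup_mutated": bool(og_mutated),
            }
        )

    # toy gene models: one gene every 10 kb, 2 exons of 900 nt CDS total
    gene_models = []
    gid = 0
    for chrom in chrom_names:
        for start in range(2000, chrom_len - 3000, 10_000):
            gid += 1
            gene_models.append(
                {
                    "gene_id": f"g{gid:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + 1800,
                    "strand": "+",
                    "exons": [(start, start + 800), (start + 1000, start + 1800)],
                }
            )

    return {
        "snps": snp_records,
        "snp_truth": snp_truth,
        "indels": indel_records,
        "indel_truth": indel_truth,
        "gene_models": gene_models,
        "chromosome_lengths": {c: chrom_len for c in chrom_names},
        "n_introgressed": n_introgressed,
    }


# ---------------------------------------------------------------------------
# repeat clusters


def _trend_expected_counts(shape: str, bins_mid: np.ndarray, scale: float) -> np.ndarray:
    """Expected histogram counts per bin for each labelled trend shape."""
    x = bins_mid
    if shape == "pos_linear":
        y = 1.0 + (x - 70.0) / 30.0 * 20.0
    elif shape == "flat":
        y = np.full_like(x, 10.0)
    elif shape == "neg_linear":
        y = 1.0 + (100.0 - x) / 30.0 * 20.0
    elif shape == "pos_quad_right":
        y = 2.0 + 0.08 * (x - 78.0) ** 2
        y[x < 78.0] *= 0.25  # keep mass right of the vertex
    elif shape == "pos_quad_left":
        y = 2.0 + 0.08 * (x - 95.0) ** 2
        y[x > 95.0] *= 0.25
    elif shape == "neg_quad_right":
        y = np.maximum(25.0 - 0.05 * (x - 76.0) ** 2, 0.5)
    elif shape == "neg_quad_left_high_vertex":
        y = np.maximum(25.0 - 0.035 * (x - 99.5) ** 2, 0.5)
    else:
        raise ValueError(f"unknown trend shape {shape!r}")
    return y * scale


def simulate_identity_histogram(
    shape: str, rng: np.random.Generator, *, scale: float = 5.0
) -> np.ndarray:
    """Poisson-noised identity histogram with a labelled trend shape."""
    from .repeats import IDENTITY_BINS

    mids = (IDENTITY_BINS[:-1] + IDENTITY_BINS[1:]) / 2.0
    lam = _trend_expected_counts(shape, mids, scale)
    return rng.poisson(lam)


def simulate_repeat_cluster_reads(
    spec: RepeatClusterSpec, config: SimulationConfig, rng: np.random.Generator
) -> list[str]:
    """Reads sampled from a cluster consensus with per-read divergence.

    Per-read divergence is drawn so pairwise read identities center on
    ``mean_identity`` with the requested spread; the detailed histogram
    *shape* is controlled separately via ``simulate_identity_histogram``.
    """
    consensus = rng.integers(0, 4, size=max(config.read_len, 120))
    reads = []
    for _ in range(spec.n_reads):
        # pairwise identity of two reads ~ 100 - (d_i + d_j); divide by 2
        div_pct = max(rng.normal((100.0 - spec.mean_identity) / 2.0, spec.spread / 2.0), 0.0)
        read = consensus[: config.read_len].copy()
        n_mut = rng.binomial(config.read_len, min(div_pct / 100.0, 0.95))
        sites = rng.choice(config.read_len, size=n_mut, replace=False)
        for s in sites:
            new = rng.integers(0, 3)
            if new >= read[s]:
                new += 1
            read[s] = new
        reads.append("".join(_BASES[i] for i in read))
    return reads


def simulate_repeat_clusters(
    config: SimulationConfig, rng: np.random.Generator
) -> dict:
    """Cluster read sets, abundance table and trend-shape truth labels."""
    labels = config.species_labels()
    clusters = {}
    abundance = {}
    truth = {}
    for i, spec in enumerate(config.repeat_age_params):
        cid = f"CL{i + 1:03d}"
        clusters[cid] = simulate_repeat_cluster_reads(spec, config, rng)
        abundance[cid] = {
            lab: int(rng.poisson(spec.n_reads)) for lab in labels
        }
        cls, age = TREND_SHAPES[spec.trend_shape]
        truth[cid] = {"trend_shape": spec.trend_shape, "trend_class": cls, "age": age}
    return {"clusters": clusters, "abundance": abundance, "truth": truth}


# ---------------------------------------------------------------------------
# orthogroups and genome sizes


def simulate_orthogroups(
    config: SimulationConfig, tree: dendropy.Tree, rng: np.random.Generator
) -> dict:
    """Copy numbers under branch-length-scaled birth-death.

    ``orthogroup_gain_rate`` / ``orthogroup_loss_rate`` are expected events
    per family on an average-length branch; each branch's rates scale with
    its relative length, so longer branches accumulate more turnover.
    Truth logs the realized per-branch gain/loss totals.
    """
    from .genefam import _label_internal

    _label_internal(tree)
    labels = set(config.species_labels())
    blens = [
        nd.edge.length or 0.0
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
    ]
    mean_blen = float(np.mean([b for b in blens if b > 0]) or 1.0)
    counts = {}
    branch_changes: dict[str, dict[str, int]] = {}
    for og_i in range(config.n_orthogroups):
        root_n = 1 + int(rng.poisson(0.5))
        states = {id(tree.seed_node): root_n}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            cur = states[id(nd.parent_node)]
            rel = (nd.edge.length or mean_blen) / mean_blen
            gains = int(rng.poisson(config.orthogroup_gain_rate * rel))
            p_loss = 1.0 - np.exp(-config.orthogroup_loss_rate * rel)
            losses = int(rng.binomial(cur, p_loss)) if cur > 0 else 0
            nxt = max(cur + gains - losses, 0)
            states[id(nd)] = nxt
            blabel = nd.taxon.label if nd.taxon else nd.label
            ch = branch_changes.setdefault(blabel, {"gains": 0, "losses": 0})
            d = nxt - cur
            if d > 0:
                ch["gains"] += d
            elif d < 0:
                ch["losses"] += -d
        counts[f"OG{og_i + 1:06d}"] = {
            lf.taxon.label: states[id(lf)]
            for lf in tree.leaf_node_iter()
            if lf.taxon.label in labels
        }
    return {"counts": counts, "branch_changes": branch_changes}


def simulate_genome_sizes(
    config: SimulationConfig, tree: dendropy.Tree, rng: np.random.Generator
) -> dict:
    """Brownian genome sizes (Mb) on the time-calibrated tree."""
    r = config.syn_rate_per_myr
    sizes = {id(tree.seed_node): config.genome_size_root_mb}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        dur_myr = 2.0 * (nd.edge.length or 0.0) / r
        step = rng.normal(0.0, np.sqrt(config.genome_size_sigma2 * max(dur_myr, 0.0)))
        sizes[id(nd)] = sizes[id(nd.parent_node)] + step
    tips = {
        lf.taxon.label: float(max(sizes[id(lf)], 1.0)) for lf in tree.leaf_node_iter()
    }
    return {
        "tip_sizes_mb": tips,
        "root_size_mb": config.genome_size_root_mb,
        "sigma2": config.genome_size_sigma2,
    }


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: dendropy.Tree
    genes: list[GeneAlignment]
    variants: dict
    repeats: dict
    orthogroups: dict
    genome_sizes: dict

    @property
    def truth(self) -> dict:
        cfg = asdict(self.config)
        cfg["introgression"] = (
            asdict(self.config.introgression) if self.config.introgression else None
        )
        cfg["repeat_age_params"] = [asdict(s) for s in self.config.repeat_age_params]
        return {
            "config": cfg,
            "snp_truth": self.variants["snp_truth"],
            "indel_truth": self.variants["indel_truth"],
            "n_introgressed": self.variants["n_introgressed"],
            "repeat_truth": self.repeats["truth"],
            "orthogroup_branch_changes": self.orthogroups["branch_changes"],
            "genome_sizes": self.genome_sizes,
        }


def simulate_dataset(config: SimulationConfig, out_dir: str | Path | None = None) -> SimulatedDataset:
    """Generate the full synthetic study; optionally write it to ``out_dir``.

    Files written: ``tree.nwk``, ``genes/*.fasta``, ``variants.vcf``,
    ``models.gff3``, ``clusters/*.fasta``, ``abundance.tsv``,
    ``orthogroups.tsv``, ``genome_sizes.tsv``, ``truth.json``.
    """
    root_rng = np.random.default_rng(config.seed)
    rngs = root_rng.spawn(5)

    tree = simulate_tree(config, rngs[0])
    genes = simulate_gene_alignments(config, tree, rngs[1])
    variants = simulate_variants(config, tree, rngs[2])
    repeats = simulate_repeat_clusters(config, rngs[3])
    orthos = simulate_orthogroups(config, tree, rngs[4])
    gsizes = simulate_genome_sizes(config, tree, root_rng)

    ds = SimulatedDataset(config, tree, genes, variants, repeats, orthos, gsizes)
    if out_dir is not None:
        write_dataset(ds, Path(out_dir))
    return ds


def write_dataset(ds: SimulatedDataset, out: Path) -> None:
    from . import io as cfio

    out.mkdir(parents=True, exist_ok=True)
    with open(out / "tree.nwk", "w") as fh:
        fh.write(ds.tree.as_string(schema="newick"))
    gene_dir = out / "genes"
    gene_dir.mkdir(exist_ok=True)
    for g in ds.genes:
        g.to_fasta(gene_dir / f"{g.gene_id}.fasta")

    samples = ds.config.species_labels() + [ds.config.outgroup_label]
    records = sorted(
        ds.variants["snps"] + ds.variants["indels"], key=lambda r: (r["chrom"], r["pos"])
    )
    cfio.write_vcf(
        records, samples, ds.variants["chromosome_lengths"], out / "variants.vcf"
    )
    cfio.write_gff3(ds.variants["gene_models"], out / "models.gff3")

    cl_dir = out / "clusters"
    cl_dir.mkdir(exist_ok=True)
    for cid, reads in ds.repeats["clusters"].items():
        with open(cl_dir / f"{cid}.fasta", "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f">{cid}_{i}\n{r}\n")
    with open(out / "abundance.tsv", "w") as fh:
        labs = ds.config.species_labels()
        fh.write("cluster\t" + "\t".join(labs) + "\n")
        for cid, ab in ds.repeats["abundance"].items():
            fh.write(cid + "\t" + "\t".join(str(ab[l]) for l in labs) + "\n")

    with open(out / "orthogroups.tsv", "w") as fh:
        labs = ds.config.species_labels()
        fh.write("Orthogroup\t" + "\t".join(labs) + "\n")
        for og, row in ds.orthogroups["counts"].items():
            fh.write(og + "\t" + "\t".join(str(row[l]) for l in labs) + "\n")

    with open(out / "genome_sizes.tsv", "w") as fh:
        fh.write("species\tgenome_size_mb\n")
        for sp, mb in ds.genome_sizes["tip_sizes_mb"].items():
            fh.write(f"{sp}\t{mb:.3f}\n")

    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
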