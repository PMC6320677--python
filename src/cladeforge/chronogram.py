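"""Node dating from synonymous divergence and Brownian-motion ancestral states.

Dating uses the molecular-clock identity T = dS / r, where r is a
synonymous substitution rate in substitutions/site/Myr taken from prior
work on the clade (it has no default: supply it explicitly).  A node's
minimum and maximum observed dS map to minimum and maximum ages, which act
as box constraints in a least-squares rate-smoothing step that turns a
substitution-length tree into an ultrametric chronogram: node ages (and a
single global rate) are chosen to minimize the squared deviation between
each branch's substitution length and rate x duration, subject to tip ages
of zero, parent-older-than-child ordering, and the calibration bounds.

Ancestral states for a continuous trait (here genome size in Mb) are
maximum-likelihood estimates under Brownian motion.  For each internal
node v the estimate is the GLS mean of the tips under the tree re-rooted
at v; the re-rooted tip covariance is obtained directly from path lengths,
C_v[i,j] = (d(v,i) + d(v,j) - d(i,j)) / 2, so no tree surgery is needed.
The BM rate sigma^2 is the ML estimate at the original root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize


@dataclass(frozen=True)
class CalibrationConfig:
    """Synonymous rate r (subs/site/Myr) plus per-node dS bounds.

    Nodes are addressed by a frozenset of tip labels whose MRCA they are;
    the special key ``"root"`` addresses the root.
    """

    r: float
    node_ds_bounds: dict[frozenset[str] | str, tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"rate r must be > 0, got {self.r}")
        for node, (lo, hi) in self.node_ds_bounds.items():
            if lo > hi:
                raise ValueError(f"dS_min > dS_max for node {node}: {lo} > {hi}")


def node_age_bounds(cal: CalibrationConfig, node) -> tuple[float, float]:
    """(T_min, T_max) in Myr for a calibrated node: T = dS / r."""
    if node not in cal.node_ds_bounds:
        raise KeyError(f"node {node!r} not calibrated")
    lo, hi = cal.node_ds_bounds[node]
    return lo / cal.r, hi / cal.r


@dataclass
class Chronogram:
    """A rooted ultrametric tree with node ages in Myr."""

    tree: dendropy.Tree
    node_ages: dict[int, float]  # id(node) -> age
    root_age: float
    rate: float  # fitted global substitution rate (subs/site/Myr)

    def age_of(self, node) -> float:
        return self.node_ages[id(node)]

    def as_newick(self) -> str:
        """Newick with branch lengths in Myr (durations)."""
        clone = self.tree.clone(depth=1)
        ages = {}
        for orig, cp in zip(self.tree, clone):
            ages[id(cp)] = self.node_ages[id(orig)]
        for nd in clone:
            if nd.parent_node is not None:
                nd.edge.length = ages[id(nd.parent_node)] - ages[id(nd)]
        return clone.as_string(schema="newick").strip()

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for nd in self.tree.preorder_node_iter():
            label = nd.taxon.label if nd.taxon else (nd.label or "")
            rows.append({"node": label, "age_myr": self.node_ages[id(nd)]})
        return pd.DataFrame(rows)


def _leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _resolve_calibrations(
    tree: dendropy.Tree, calibrations: dict
) -> dict[int, tuple[float, float]]:
    out = {}
    for key, bounds in calibrations.items():
        if key == "root":
            node = tree.seed_node
        else:
            node = tree.mrca(taxon_labels=sorted(key))
            if node is None:
                raise ValueError(f"no MRCA found for {sorted(key)}")
        out[id(node)] = tuple(bounds)
    return out


def ultrametricize(
    tree: dendropy.Tree,
    calibrations: dict[frozenset[str] | str, tuple[float, float]],
    *,
    label_internal: bool = True,
) -> Chronogram:
    """Constrained least-squares dating of a substitution-length tree.

    ``calibrations`` maps node keys (tip-label frozensets or ``"root"``)
    to (min_age, max_age) in Myr.  Raises ``ValueError`` on infeasible
    bounds (a node whose minimum exceeds an ancestor's maximum).
    """
    if not calibrations:
        raise ValueError("at least one calibration is required")
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    bounds_by_id = _resolve_calibrations(tree, calibrations)

    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    index = {id(nd): i for i, nd in enumerate(internal)}

    # Feasibility: a descendant's min age may not exceed any ancestor's max.
    for nd in internal:
        lo = bounds_by_id.get(id(nd), (0.0, np.inf))[0]
        anc = nd.parent_node
        while anc is not None:
            hi = bounds_by_id.get(id(anc), (0.0, np.inf))[1]
            if lo > hi:
                raise ValueError(
                    "infeasible calibrations: node with min age "
                    f"{lo} under ancestor with max age {hi}"
                )
            anc = anc.parent_node

    edges = []  # (parent_idx or None==?, child_idx or None for tips, subst length)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        p = index[id(nd.parent_node)]
        c = index.get(id(nd))  # None for tips (age 0)
        edges.append((p, c, nd.edge.length or 0.0))

    n = len(internal)

    def ages_of(x):
        return x[:n]

    def objective(x):
        t, r = x[:n], x[n]
        sse = 0.0
        for p, c, blen in edges:
            dur = t[p] - (t[c] if c is not None else 0.0)
            sse += (blen - r * dur) ** 2
        return sse

    def grad(x):
        t, r = x[:n], x[n]
        g = np.zeros(n + 1)
        for p, c, blen in edges:
            dur = t[p] - (t[c] if c is not None else 0.0)
            resid = blen - r * dur
            g[p] += -2.0 * resid * r
            if c is not None:
                g[c] += 2.0 * resid * r
            g[n] += -2.0 * resid * dur
        return g

    # Initial guess: node depths scaled so the root hits mid-calibration.
    depth = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = max(
                depth[id(ch)] + (ch.edge.length or 0.0) for ch in nd.child_nodes()
            )
    root_sub = depth[id(tree.seed_node)] or 1.0
    root_lo, root_hi = bounds_by_id.get(id(tree.seed_node), (0.0, np.inf))
    target_root = (
        (root_lo + root_hi) / 2.0
        if np.isfinite(root_hi)
        else max(root_lo, 1.0)
    )
    if target_root <= 0:
        # all-zero calibration: fall back to substitution depths as ages
        target_root = root_sub
    scale = target_root / root_sub
    x0 = np.empty(n + 1)
    for nd in internal:
        x0[index[id(nd)]] = depth[id(nd)] * scale
    x0[n] = root_sub / target_root  # initial rate

    box = []
    for nd in internal:
        lo, hi = bounds_by_id.get(id(nd), (0.0, np.inf))
        box.append((lo, hi if np.isfinite(hi) else None))
    box.append((1e-12, None))

    cons = []
    for p, c, _ in edges:
        if c is not None:
            cons.append(
                {"type": "ineq", "fun": (lambda x, p=p, c=c: x[p] - x[c])}
            )

    res = minimize(
        objective, x0, jac=grad, method="SLSQP", bounds=box, constraints=cons,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    t = ages_of(res.x)
    rate = res.x[n]

    if label_internal:
        k = 0
        for nd in internal:
            if nd.label is None and nd.taxon is None:
                nd.label = f"n{k}"
            k += 1

    node_ages = {}
    for nd in tree.preorder_node_iter():
        node_ages[id(nd)] = float(t[index[id(nd)]]) if id(nd) in index else 0.0
    return Chronogram(tree, node_ages, float(t[index[id(tree.seed_node)]]), float(rate))


@dataclass
class ASRResult:
    """ML Brownian-motion ancestral states for a continuous trait."""

    estimates: dict[str, float]  # internal node label -> state
    variances: dict[str, float]
    sigma2: float
    root_label: str
    degenerate: bool = False  # sigma2 == 0 (constant trait or zero tree)

    @property
    def root_estimate(self) -> float:
        return self.estimates[self.root_label]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "node": lab,
                "estimate": est,
                "variance": self.variances[lab],
                "sd": np.sqrt(max(self.variances[lab], 0.0)),
            }
            for lab, est in self.estimates.items()
        ]
        return pd.DataFrame(rows)


def asr_annotated_newick(tree: dendropy.Tree, asr: "ASRResult") -> str:
    """Newick with ancestral estimates as node comments ([&state=..])."""
    clone = tree.clone(depth=1)
    for nd in clone.preorder_node_iter():
        if nd.is_leaf():
            continue
        lab = nd.label
        if lab in asr.estimates:
            nd.annotations.add_new("state", f"{asr.estimates[lab]:.4f}")
    return clone.as_string(schema="newick", suppress_annotations=False).strip()


def _solve(C: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(C, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(C, b, rcond=None)[0]


def bm_ancestral_states(
    tree: dendropy.Tree, tip_values: dict[str, float]
) -> ASRResult:
    """ML ancestral states under Brownian motion (fastAnc-style).

    ``tree`` must have positive branch lengths (time or substitutions —
    sigma^2 is then per that unit); ``tip_values`` maps every tip label to
    its trait value.  Each internal node's estimate is the GLS mean under
    the tree re-rooted at that node; variances use the ML sigma^2.
    """
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [t for t in taxa if t not in tip_values]
    if missing:
        raise ValueError(f"missing tip values for {missing}")
    x = np.array([tip_values[t] for t in taxa], float)
    ntips = len(taxa)

    # Distances from every node to every tip via two traversals.
    tip_index = {t: i for i, t in enumerate(taxa)}
    d_node_tip: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            v = np.full(ntips, np.inf)
            v[tip_index[nd.taxon.label]] = 0.0
            d_node_tip[id(nd)] = v
        else:
            v = np.full(ntips, np.inf)
            for ch in nd.child_nodes():
                w = d_node_tip[id(ch)] + (ch.edge.length or 0.0)
                v = np.minimum(v, w)
            d_node_tip[id(nd)] = v
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            up = d_node_tip[id(nd.parent_node)] + (nd.edge.length or 0.0)
            d_node_tip[id(nd)] = np.minimum(d_node_tip[id(nd)], up)

    # Tip-tip distances from the root vector trick:
    # d(i,j) = min over nodes is exact only along paths; use root distances +
    # MRCA depths instead.  Compute d(i,j) via the root's covariance.
    droot = d_node_tip[id(tree.seed_node)]
    C_root = np.empty((ntips, ntips))
    # shared path length from root for each tip pair = depth of MRCA
    depth_to_root: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth_to_root[id(nd)] = 0.0
        else:
            depth_to_root[id(nd)] = depth_to_root[id(nd.parent_node)] + (
                nd.edge.length or 0.0
            )
    pdm = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            pdm[id(nd)] = {tip_index[nd.taxon.label]}
        else:
            kids = [pdm[id(ch)] for ch in nd.child_nodes()]
            merged = set()
            for a_i in range(len(kids)):
                for b_i in range(a_i + 1, len(kids)):
                    for i in kids[a_i]:
                        for j in kids[b_i]:
                            C_root[i, j] = C_root[j, i] = depth_to_root[id(nd)]
                merged |= kids[a_i]
            merged |= kids[-1]
            pdm[id(nd)] = merged
    np.fill_diagonal(C_root, droot)
    d_tips = droot[:, None] + droot[None, :] - 2.0 * C_root

    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    k = 0
    labels = {}
    for nd in internal:
        lab = nd.label or (nd.taxon.label if nd.taxon else None)
        if lab is None:
            lab = f"n{k}"
            nd.label = lab
        labels[id(nd)] = lab
        k += 1
    root_label = labels[id(tree.seed_node)]

    ones = np.ones(ntips)
    # sigma^2 at the original root
    Ci_x = _solve(C_root, x)
    Ci_1 = _solve(C_root, ones)
    denom = ones @ Ci_1
    a_root = (ones @ Ci_x) / denom
    resid = x - a_root
    sigma2 = float(resid @ _solve(C_root, resid) / ntips)
    degenerate = not np.isfinite(sigma2) or sigma2 <= 1e-15
    if degenerate:
        sigma2 = 0.0

    estimates, variances = {}, {}
    for nd in internal:
        dv = d_node_tip[id(nd)]
        Cv = (dv[:, None] + dv[None, :] - d_tips) / 2.0
        Ci_1v = _solve(Cv, ones)
        Ci_xv = _solve(Cv, x)
        den = ones @ Ci_1v
        est = (ones @ Ci_xv) / den
        estimates[labels[id(nd)]] = float(est)
        variances[labels[id(nd)]] = float(sigma2 / den) if den > 0 else float("nan")
    return ASRResult(estimates, variances, sigma2, root_label, degenerate)
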