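"""Gene-family gain/loss inference on a species tree by Wagner parsimony.

Orthogroup copy numbers per species are treated as integer characters
evolving on the tree under a linear (Manhattan) change cost.  Ancestral
family sizes minimizing total absolute change are found with the Farris
interval algorithm: a postorder pass assigns each internal node the
intersection of its children's intervals (or the gap between them when
disjoint), and a preorder pass picks, within each node's interval, the
state closest to its parent's.  Ties at the root are broken toward the
smaller count by default (switchable), which biases root-adjacent
ambiguity toward gains rather than losses.

Per-branch gains and losses are family-size increments summed over
orthogroups, reported raw, per family, and standardized by branch
substitution length (and per Myr when node ages are supplied).
Uncertainty comes from resampling orthogroup rows with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


@dataclass
class BranchChangeRates:
    """Per-branch gain/loss totals and rates from Wagner parsimony."""

    table: pd.DataFrame  # branch, gains, losses, gain_rate, loss_rate, ...
    n_families: int
    total_change: int

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def _branch_label(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or "node"


def _label_internal(tree: dendropy.Tree) -> None:
    k = 0
    for nd in tree.preorder_node_iter():
        if nd.taxon is None and nd.label is None:
            nd.label = f"n{k}"
        k += 1


def wagner_reconstruct(
    tree: dendropy.Tree,
    counts: dict[str, int],
    *,
    prefer_smaller: bool = True,
) -> tuple[dict[int, int], int]:
    """Minimum-change integer ancestral states for one family.

    Returns ({id(node): state}, total_cost).  ``prefer_smaller`` breaks
    interval ties at the root toward the smaller ancestral count.
    """
    intervals: dict[int, tuple[int, int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            v = int(counts[nd.taxon.label])
            intervals[id(nd)] = (v, v)
        else:
            kid_iv = [intervals[id(ch)] for ch in nd.child_nodes()]
            # Farris/Sankoff for linear cost: the optimal states form the
            # interval between the k-th and (k+1)-th order statistics of
            # the 2k child-interval endpoints (k children).  For a binary
            # node this is the intersection when nonempty, else the gap.
            k = len(kid_iv)
            endpoints = sorted(v for iv in kid_iv for v in iv)
            intervals[id(nd)] = (endpoints[k - 1], endpoints[k])

    states: dict[int, int] = {}
    for nd in tree.preorder_node_iter():
        lo, hi = intervals[id(nd)]
        if nd.parent_node is None:
            states[id(nd)] = lo if prefer_smaller else hi
        else:
            p = states[id(nd.parent_node)]
            states[id(nd)] = min(max(p, lo), hi)  # closest point in interval
    cost = 0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            cost += abs(states[id(nd)] - states[id(nd.parent_node)])
    return states, cost


def infer_gain_loss(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    *,
    prefer_smaller: bool = True,
    node_ages: dict[int, float] | None = None,
) -> BranchChangeRates:
    """Per-branch gain/loss totals over all orthogroups.

    ``matrix`` is orthogroup x species (non-negative integer copy
    numbers); species must match the tree's tips.  When ``node_ages``
    (id(node) -> Myr) is given, per-Myr rates are added.
    """
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(set(matrix.columns) ^ tips)
    if missing:
        raise ValueError(f"species mismatch between matrix and tree: {missing}")
    _label_internal(tree)

    branches = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    gains = {id(b): 0 for b in branches}
    losses = {id(b): 0 for b in branches}
    total = 0
    n_fam = 0
    for _, row in matrix.iterrows():
        if (row == 0).all():
            continue
        n_fam += 1
        states, cost = wagner_reconstruct(
            tree, row.to_dict(), prefer_smaller=prefer_smaller
        )
        total += cost
        for b in branches:
            delta = states[id(b)] - states[id(b.parent_node)]
            if delta > 0:
                gains[id(b)] += delta
            elif delta < 0:
                losses[id(b)] += -delta

    rows = []
    for b in branches:
        blen = b.edge.length or np.nan
        g, l = gains[id(b)], losses[id(b)]
        rec = {
            "branch": _branch_label(b),
            "gains": g,
            "losses": l,
            "gain_rate": g / n_fam if n_fam else np.nan,
            "loss_rate": l / n_fam if n_fam else np.nan,
            "gain_rate_per_subst": g / n_fam / blen if n_fam and blen else np.nan,
            "loss_rate_per_subst": l / n_fam / blen if n_fam and blen else np.nan,
        }
        if node_ages is not None:
            dur = node_ages[id(b.parent_node)] - node_ages[id(b)]
            rec["gain_rate_per_myr"] = g / n_fam / dur if n_fam and dur > 0 else np.nan
            rec["loss_rate_per_myr"] = l / n_fam / dur if n_fam and dur > 0 else np.nan
        rows.append(rec)
    return BranchChangeRates(pd.DataFrame(rows), n_fam, total)


@dataclass
class ResampledRates:
    """Observed per-branch rates plus resampled quantile envelopes."""

    observed: BranchChangeRates
    quantiles: pd.DataFrame  # branch, statistic, q025, q25, q50, q75, q975
    replicates: pd.DataFrame  # long format: replicate, branch, gain_rate, loss_rate

    def observed_outside_iqr(self, statistic: str = "loss_rate") -> pd.Series:
        """Branches where the observed rate falls outside the resampled IQR."""
        q = self.quantiles[self.quantiles["statistic"] == statistic].set_index("branch")
        obs = self.observed.table.set_index("branch")[statistic]
        q = q.reindex(obs.index)
        return (obs < q["q25"]) | (obs > q["q75"])


def resample_rates(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    B: int = 1000,
    seed: int | None = None,
    *,
    prefer_smaller: bool = True,
) -> ResampledRates:
    """Bootstrap-style orthogroup resampling of per-branch gain/loss rates.

    Rows of ``matrix`` are resampled with replacement B times and the
    per-branch rates recomputed; summary quantiles per branch accompany
    the observed rates.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    observed = infer_gain_loss(matrix, tree, prefer_smaller=prefer_smaller)

    rep_rows = []
    n = len(matrix)
    for rep in range(B):
        idx = rng.integers(0, n, size=n)
        res = infer_gain_loss(matrix.iloc[idx], tree, prefer_smaller=prefer_smaller)
        for _, r in res.table.iterrows():
            rep_rows.append(
                {
                    "replicate": rep,
                    "branch": r["branch"],
                    "gain_rate": r["gain_rate"],
                    "loss_rate": r["loss_rate"],
                }
            )
    reps = pd.DataFrame(rep_rows)

    q_rows = []
    for branch, g in reps.groupby("branch"):
        for statistic in ("gain_rate", "loss_rate"):
            v = g[statistic].to_numpy()
            q_rows.append(
                {
                    "branch": branch,
                    "statistic": statistic,
                    "q025": np.quantile(v, 0.025),
                    "q25": np.quantile(v, 0.25),
                    "q50": np.quantile(v, 0.50),
                    "q75": np.quantile(v, 0.75),
                    "q975": np.quantile(v, 0.975),
                }
            )
    return ResampledRates(observed, pd.DataFrame(q_rows), reps)


def read_orthogroup_counts(path) -> pd.DataFrame:
    """Read an OrthoFinder GeneCount-style TSV (orthogroup x species).

    Drops a trailing 'Total' column if present and all-zero rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "Total" in df.columns:
        df = df.drop(columns="Total")
    df = df[(df != 0).any(axis=1)]
    return df.astype(int)
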