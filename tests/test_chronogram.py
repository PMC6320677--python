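"""Node dating (T = dS/r), rate-smoothed ultrametricization, and BM ASR."""

import subprocess
import textwrap

import dendropy
import numpy as np
import pytest
from scipy.optimize import minimize

from cladeforge.chronogram import (
    CalibrationConfig,
    bm_ancestral_states,
    node_age_bounds,
    ultrametricize,
)


class TestNodeAgeBounds:
    def test_division(self):
        cal = CalibrationConfig(r=0.01, node_ds_bounds={"root": (0.02, 0.04)})
        assert node_age_bounds(cal, "root") == pytest.approx((2.0, 4.0))

    def test_zero_ds_zero_age(self):
        cal = CalibrationConfig(r=0.01, node_ds_bounds={"root": (0.0, 0.0)})
        assert node_age_bounds(cal, "root") == (0.0, 0.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            CalibrationConfig(r=0.0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            CalibrationConfig(r=0.01, node_ds_bounds={"root": (0.3, 0.2)})


def root_to_tip_ages(ch):
    ages = []
    for lf in ch.tree.leaf_node_iter():
        ages.append(ch.age_of(lf))
    return ages


class TestUltrametricize:
    def test_clock_tree_root_pinned_scales_linearly(self):
        # already-ultrametric tree; pinning the root at 6.58 Ma scales ages
        tree = dendropy.Tree.get(
            data="((A:1,B:1):2,(C:2,D:2):1);", schema="newick"
        )
        ch = ultrametricize(tree, {"root": (6.58, 6.58)})
        assert ch.root_age == pytest.approx(6.58, abs=1e-6)
        ab = ch.tree.mrca(taxon_labels=["A", "B"])
        cd = ch.tree.mrca(taxon_labels=["C", "D"])
        assert ch.age_of(ab) == pytest.approx(6.58 / 3, rel=1e-4)
        assert ch.age_of(cd) == pytest.approx(2 * 6.58 / 3, rel=1e-4)

    def test_three_taxon_brute_force_oracle(self, three_taxon_tree):
        """Grid search over the one free node age agrees with the solver."""
        ch = ultrametricize(three_taxon_tree, {"root": (2.0, 2.0)})
        inner = ch.tree.mrca(taxon_labels=["A", "B"])
        fitted = ch.age_of(inner)

        # brute force: minimize sum (blen - r*(dur))^2 over (t_inner, r)
        def sse(t, r):
            return (
                (1.0 - r * t) ** 2 * 2  # A, B branches
                + (1.0 - r * (2.0 - t)) ** 2  # inner branch
                + (2.0 - r * 2.0) ** 2  # C branch
            )

        grid = [
            (t, r)
            for t in np.linspace(0.01, 1.99, 397)
            for r in np.linspace(0.2, 3.0, 561)
        ]
        best_t = min(grid, key=lambda p: sse(*p))[0]
        assert fitted == pytest.approx(best_t, abs=0.02)
        assert fitted == pytest.approx(1.0, abs=0.02)

    def test_ultrametricity_invariant(self, quartet_dataset):
        tree = quartet_dataset.tree.clone(depth=1)
        ch = ultrametricize(tree, {"root": (3.0, 3.0)})
        ages = root_to_tip_ages(ch)
        assert np.allclose(ages, 0.0, atol=1e-9 * ch.root_age + 1e-12)
        for nd in ch.tree.preorder_node_iter():
            if nd.parent_node is not None:
                assert ch.age_of(nd.parent_node) >= ch.age_of(nd) - 1e-9

    def test_calibration_bounds_respected(self):
        tree = dendropy.Tree.get(
            data="((A:1,B:1):2,(C:2,D:2):1);", schema="newick"
        )
        ch = ultrametricize(
            tree,
            {"root": (5.0, 7.0), frozenset({"A", "B"}): (0.5, 1.0)},
        )
        ab = ch.tree.mrca(taxon_labels=["A", "B"])
        assert 0.5 - 1e-9 <= ch.age_of(ab) <= 1.0 + 1e-9
        assert 5.0 - 1e-9 <= ch.root_age <= 7.0 + 1e-9

    def test_infeasible_bounds_error(self):
        tree = dendropy.Tree.get(
            data="((A:1,B:1):2,(C:2,D:2):1);", schema="newick"
        )
        with pytest.raises(ValueError, match="infeasible"):
            ultrametricize(
                tree,
                {"root": (1.0, 2.0), frozenset({"A", "B"}): (3.0, 4.0)},
            )

    def test_no_calibration_error(self, three_taxon_tree):
        with pytest.raises(ValueError, match="calibration"):
            ultrametricize(three_taxon_tree, {})

    def test_perturbed_clock_recovery(self):
        """Ages recovered within 15% (median over seeds) after rate jitter."""
        from cladeforge.simulate import SimulationConfig, simulate_tree

        errs = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            cfg = SimulationConfig(seed=seed, n_species=6, tree_height=0.02)
            tree = simulate_tree(cfg, rng)
            true_ages = {}  # keyed by descendant leaf set (clone-safe)
            for nd in tree.preorder_internal_node_iter():
                key = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                true_ages[key] = nd.depth  # clock depths, subs/site
            for nd in tree.preorder_node_iter():
                if nd.parent_node is not None:
                    nd.edge.length = (nd.edge.length or 0.0) * rng.uniform(0.85, 1.15)
            root_age_myr = 2 * tree.seed_node.depth / cfg.syn_rate_per_myr
            ch = ultrametricize(tree, {"root": (root_age_myr, root_age_myr)})
            for nd in ch.tree.preorder_internal_node_iter():
                if nd.parent_node is None:
                    continue
                key = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                truth = 2 * true_ages[key] / cfg.syn_rate_per_myr
                if truth > 0.3 * root_age_myr:  # skip tiny, noise-dominated ages
                    errs.append(abs(ch.age_of(nd) - truth) / truth)
        assert np.median(errs) < 0.15


class TestBMAncestralStates:
    def test_constant_trait_degenerate(self, three_taxon_tree):
        asr = bm_ancestral_states(
            three_taxon_tree, {"A": 880.0, "B": 880.0, "C": 880.0}
        )
        assert all(v == pytest.approx(880.0) for v in asr.estimates.values())
        assert asr.sigma2 == 0.0
        assert asr.degenerate

    def test_star_tree_root_is_mean(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick")
        asr = bm_ancestral_states(tree, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert asr.root_estimate == pytest.approx(2.0)

    def test_three_tip_numeric_likelihood_oracle(self, three_taxon_tree):
        """Joint-likelihood maximization over ancestral states agrees."""
        tips = {"A": 10.0, "B": 14.0, "C": 3.0}
        asr = bm_ancestral_states(three_taxon_tree, tips)
        sigma2 = asr.sigma2

        # tree ((A:1,B:1):1,C:2): unknowns = root z0, inner z1
        def neg_joint(z):
            z0, z1 = z
            out = 0.0
            for delta, t in (
                (z1 - z0, 1.0),
                (tips["A"] - z1, 1.0),
                (tips["B"] - z1, 1.0),
                (tips["C"] - z0, 2.0),
            ):
                out += 0.5 * delta**2 / (sigma2 * t) + 0.5 * np.log(sigma2 * t)
            return out

        res = minimize(neg_joint, [8.0, 8.0], method="Nelder-Mead", options={"xatol": 1e-10})
        z0, z1 = res.x
        inner_label = [
            nd.label
            for nd in three_taxon_tree.preorder_internal_node_iter()
            if {lf.taxon.label for lf in nd.leaf_iter()} == {"A", "B"}
        ][0]
        assert asr.root_estimate == pytest.approx(z0, abs=1e-4)
        assert asr.estimates[inner_label] == pytest.approx(z1, abs=1e-4)

    def test_linearity_in_tip_values(self, three_taxon_tree, rng):
        tips = {"A": 5.0, "B": 9.0, "C": 2.0}
        base = bm_ancestral_states(three_taxon_tree, tips)
        scaled = bm_ancestral_states(
            three_taxon_tree, {k: 3.0 * v + 7.0 for k, v in tips.items()}
        )
        for lab in base.estimates:
            assert scaled.estimates[lab] == pytest.approx(
                3.0 * base.estimates[lab] + 7.0
            )

    def test_root_within_tip_range(self, rng):
        from cladeforge.simulate import SimulationConfig, simulate_tree

        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_species=7)
            tree = simulate_tree(cfg, np.random.default_rng(seed))
            tips = {
                lf.taxon.label: float(rng.uniform(800, 950))
                for lf in tree.leaf_node_iter()
            }
            asr = bm_ancestral_states(tree, tips)
            assert min(tips.values()) - 1e-9 <= asr.root_estimate <= max(tips.values()) + 1e-9

    def test_missing_tip_value_errors(self, three_taxon_tree):
        with pytest.raises(ValueError, match="missing"):
            bm_ancestral_states(three_taxon_tree, {"A": 1.0, "B": 2.0})

    def test_sigma2_and_root_recovered_from_bm_simulation(self):
        from cladeforge.simulate import (
            SimulationConfig,
            simulate_genome_sizes,
            simulate_tree,
        )

        hits = 0
        sig_ratios = []
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, n_species=13, genome_size_sigma2=70.0)
            rng = np.random.default_rng(seed)
            tree = simulate_tree(cfg, rng)
            # drop the outgroup: genome sizes are an ingroup trait here
            tree2 = tree.extract_tree_without_taxa_labels([cfg.outgroup_label])
            gs = simulate_genome_sizes(cfg, tree2, rng)
            # express branch lengths in Myr so sigma2 is per Myr
            for nd in tree2.preorder_node_iter():
                if nd.parent_node is not None and nd.edge.length is not None:
                    nd.edge.length = 2 * nd.edge.length / cfg.syn_rate_per_myr
            asr = bm_ancestral_states(tree2, gs["tip_sizes_mb"])
            sig_ratios.append(asr.sigma2 / cfg.genome_size_sigma2)
            root_sd = np.sqrt(max(asr.variances[asr.root_label], 1e-9))
            if abs(asr.root_estimate - cfg.genome_size_root_mb) <= 2.5 * root_sd:
                hits += 1
        assert np.median(sig_ratios) == pytest.approx(1.0, abs=0.9)  # within ~2-fold
        assert hits >= 6


class TestAnnotatedNewick:
    def test_estimates_embedded_as_node_comments(self, three_taxon_tree):
        from cladeforge.chronogram import asr_annotated_newick

        asr = bm_ancestral_states(three_taxon_tree, {"A": 1.0, "B": 2.0, "C": 6.0})
        nwk = asr_annotated_newick(three_taxon_tree, asr)
        assert "state=" in nwk
        assert f"{asr.root_estimate:.4f}" in nwk


class TestAgainstPhytools:
    def test_fastanc_agreement_on_small_tree(self, tmp_path):
        """Cross-check ML ancestral states against phytools::fastAnc."""
        newick = "((A:1.2,B:0.8):0.6,(C:1.5,D:0.5):1.1);"
        tips = {"A": 10.0, "B": 14.0, "C": 3.0, "D": 6.0}
        tree = dendropy.Tree.get(data=newick, schema="newick")
        asr = bm_ancestral_states(tree, tips)

        script = tmp_path / "fastanc.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(phytools))
                tree <- read.tree(text="{newick}")
                x <- c(A=10, B=14, C=3, D=6)
                a <- fastAnc(tree, x)
                cat(sprintf("%.10f\\n", as.numeric(a)))
                """
            )
        )
        try:
            out = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, timeout=120
            )
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        if out.returncode != 0:
            pytest.skip(f"phytools unavailable: {out.stderr[:200]}")
        r_vals = sorted(float(v) for v in out.stdout.split())
        ours = sorted(asr.estimates.values())
        assert np.allclose(ours, r_vals, atol=1e-6)
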