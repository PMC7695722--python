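"""Time trees, clock models, the FBD prior, calibrations and constraints."""

import numpy as np
import pytest
from scipy.stats import lognorm

import phylolex as px
from phylolex.clock import lognormal_log_density
from phylolex.fbd import fbd_log_density
from phylolex.priors import (calibration_log_prior, constraint_satisfied,
                             exponential_log_density, joint_log_prior)
from phylolex.state import ModelState


class TestTimeTree:
    def test_newick_round_trip_with_extinct_tip(self):
        nwk = "((A:2.0,B:1.3):1.0,(C:2.5,D:2.2):0.5);"
        tree = px.TimeTree.from_newick(nwk)
        # deepest tip (C) is extant; B sits above the present
        assert tree.find_tip("C").age == pytest.approx(0.0)
        assert tree.find_tip("B").age == pytest.approx(0.7)
        back = px.TimeTree.from_newick(tree.to_newick())
        for a, b in zip(tree.postorder(), back.postorder()):
            assert a.age == pytest.approx(b.age, abs=1e-9)
            assert a.label == b.label

    def test_tip_ages_pin_the_time_scale(self):
        nwk = "(A:1.0,B:0.5);"
        tree = px.TimeTree.from_newick(nwk, tip_ages={"B": 0.5})
        assert tree.root_age == pytest.approx(1.0)
        assert tree.find_tip("B").age == pytest.approx(0.5)

    def test_validate_rejects_age_inversion(self):
        root = px.Node(age=1.0)
        root.add_child(px.Node("A", 0.0))
        root.add_child(px.Node("B", 2.0))  # older than its parent
        with pytest.raises(ValueError, match="not above"):
            px.TimeTree(root).validate()

    def test_mrca(self, balanced_tree):
        assert balanced_tree.mrca(["A", "B"]).age == pytest.approx(1.0)
        assert balanced_tree.mrca(["A", "C"]) is balanced_tree.root


class TestFBDDensity:
    def test_yule_limit_matches_closed_form(self):
        tree = px.TimeTree.from_newick("((A:1.0,B:1.0):1.0,C:2.0);")
        lam = 0.8
        got = fbd_log_density(tree, px.FBDParams(lam, 0.0, 0.0, 1.0))
        want = (3 - 2) * np.log(lam) - lam * tree.total_branch_length()
        assert got == pytest.approx(want, abs=1e-12)

    def test_invalid_birth_rate(self):
        with pytest.raises(ValueError):
            px.FBDParams(0.0, 0.0, 0.0, 1.0)

    def test_extinct_tip_with_zero_psi_is_impossible(self):
        tree = px.TimeTree.from_newick("((A:2.0,B:1.0):1.0,C:3.0);")
        assert tree.find_tip("B").age > 0
        with pytest.warns(UserWarning, match="psi"):
            ld = fbd_log_density(tree, px.FBDParams(1.0, 0.1, 0.0, 1.0))
        assert ld == -np.inf

    def test_finite_on_simulated_trees(self, rng):
        p = px.FBDParams(1.0, 0.4, 0.3, 0.7)
        for _ in range(25):
            tree = px.simulate_fbd_tree(p, float(rng.uniform(0.5, 4.0)), rng)
            assert np.isfinite(fbd_log_density(tree, p))


class TestClock:
    def test_strict_expected_substitutions(self):
        tree = px.TimeTree.from_newick("(A:2.0,B:2.0);")
        clock = px.ClockModel(kind="strict", clock_rate=0.1)
        lengths = px.clock_branch_lengths(tree, clock)
        assert all(v == pytest.approx(0.2) for v in lengths.values())

    def test_sigma_zero_relaxed_equals_strict(self, rng, balanced_tree):
        px.simulate_branch_rates(balanced_tree, 1.0, 0.0, rng)
        relaxed = px.ClockModel(kind="relaxed-lognormal", clock_rate=0.3,
                                sigma=0.0)
        strict = px.ClockModel(kind="strict", clock_rate=0.3)
        assert (px.clock_branch_lengths(balanced_tree, relaxed)
                == px.clock_branch_lengths(balanced_tree, strict))

    def test_mean_one_parameterization(self, rng):
        sigma = 0.1
        draws = np.exp(rng.normal(np.log(1.0) - sigma ** 2 / 2, sigma,
                                  size=100_000))
        assert abs(draws.mean() - 1.0) < 0.01

    def test_lognormal_density_matches_scipy(self):
        mu, sigma = 1.0, 0.1
        scale = np.exp(np.log(mu) - sigma ** 2 / 2)
        for x in (0.5, 0.9, 1.0, 1.4):
            assert lognormal_log_density(x, mu, sigma) == pytest.approx(
                lognorm.logpdf(x, s=sigma, scale=scale), abs=1e-12)
        assert lognormal_log_density(-0.1, mu, sigma) == -np.inf
        assert lognormal_log_density(0.0, mu, sigma) == -np.inf

    def test_branch_rate_prior_mode_and_sigma_doubling(self, balanced_tree):
        clock = px.ClockModel(kind="relaxed-lognormal", sigma=0.1)
        mode = np.exp(clock.log_mean - clock.sigma ** 2)
        for node in balanced_tree.postorder():
            node.rate = mode
        got = px.branch_rate_log_prior(balanced_tree, clock)
        n_branches = 6
        assert got == pytest.approx(
            n_branches * lognormal_log_density(mode, 1.0, 0.1), abs=1e-10)
        wide = px.ClockModel(kind="relaxed-lognormal", sigma=0.2)
        got2 = px.branch_rate_log_prior(balanced_tree, wide)
        assert got2 == pytest.approx(
            n_branches * lognormal_log_density(mode, 1.0, 0.2), abs=1e-10)

    def test_strict_contributes_zero(self, balanced_tree):
        assert px.branch_rate_log_prior(
            balanced_tree, px.ClockModel(kind="strict")) == 0.0


class TestCalibrations:
    def test_mrca_bound_satisfied_and_violated(self, balanced_tree):
        ok = px.Calibration("mrca_min_age", frozenset(["A", "B"]), 0.5)
        bad = px.Calibration("mrca_min_age", frozenset(["A", "B"]), 1.5)
        assert calibration_log_prior(balanced_tree, [ok]) == 0.0
        assert calibration_log_prior(balanced_tree, [bad]) == -np.inf

    def test_tip_moved_off_its_date(self):
        tree = px.TimeTree.from_newick("((A:2.0,B:1.0):1.0,C:3.0);")
        pinned = px.Calibration("tip_date", frozenset(["B"]), 1.0)
        assert calibration_log_prior(tree, [pinned]) == 0.0
        wrong = px.Calibration("tip_date", frozenset(["B"]), 1.4)
        assert calibration_log_prior(tree, [wrong]) == -np.inf

    def test_unknown_taxon_errors(self, balanced_tree):
        cal = px.Calibration("mrca_min_age", frozenset(["A", "Zz"]), 1.0)
        with pytest.raises(KeyError, match="Zz"):
            calibration_log_prior(balanced_tree, [cal])


class TestMonophylyConstraint:
    def test_outgroup_satisfied(self, balanced_tree):
        con = px.MonophylyConstraint(frozenset(["A", "B"]), as_outgroup=True)
        assert constraint_satisfied(balanced_tree, con)

    def test_non_clade(self):
        tree = px.TimeTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert not constraint_satisfied(
            tree, px.MonophylyConstraint(frozenset(["A", "B"])))

    def test_exhaustive_4tip_agreement(self, rooted_4tip_topologies):
        assert len(rooted_4tip_topologies) == 15
        queries = [frozenset(q) for q in
                   (["A", "B"], ["A", "C"], ["B", "C", "D"], ["A"],
                    ["A", "B", "C"])]
        for tree in rooted_4tip_topologies:
            # brute force: collect descendant tip sets by direct recursion
            def tipset(n):
                if n.is_leaf:
                    return frozenset([n.label])
                return frozenset().union(*(tipset(c) for c in n.children))
            all_clades = set()
            stack = [tree.root]
            while stack:
                n = stack.pop()
                all_clades.add(tipset(n))
                stack.extend(n.children)
            root_children = {tipset(c) for c in tree.root.children}
            for q in queries:
                con = px.MonophylyConstraint(q)
                assert constraint_satisfied(tree, con) == (q in all_clades)
                out = px.MonophylyConstraint(q, as_outgroup=True)
                assert constraint_satisfied(tree, out) == (q in root_children)


class TestJointPrior:
    def make_state(self, tree):
        return ModelState(tree, px.SubstModel(kind="m1p",
                                              m1p=px.M1pParams(10.0, 1.0)),
                          px.ClockModel(), px.FBDParams(1.0, 0.0, 0.0, 1.0))

    def test_exponential_prior_value(self):
        assert exponential_log_density(10.0, 10.0) == pytest.approx(
            np.log(0.1) - 1.0)

    def test_additivity(self, balanced_tree):
        state = self.make_state(balanced_tree)
        spec = px.PriorSpec(root_age_mean=None)
        total = joint_log_prior(state, spec)
        parts = (fbd_log_density(balanced_tree, state.fbd)
                 + spec.parameter_log_prior(state)
                 + px.branch_rate_log_prior(balanced_tree, state.clock)
                 + calibration_log_prior(balanced_tree, spec.calibrations))
        assert total == pytest.approx(parts, abs=1e-12)

    def test_violated_constraint_gives_minus_inf(self, balanced_tree):
        state = self.make_state(balanced_tree)
        spec = px.PriorSpec(
            constraints=[px.MonophylyConstraint(frozenset(["A", "C"]))])
        assert joint_log_prior(state, spec) == -np.inf

    def test_prior_only_chain_respects_hard_bounds(self, rng):
        langs = ["A", "B", "C", "D", "E"]
        cals = [px.Calibration("mrca_min_age", frozenset(["A", "B"]), 1.0)]
        cons = [px.MonophylyConstraint(frozenset(["A", "B", "C"]))]
        spec = px.PriorSpec(root_age_mean=3.0, calibrations=cals,
                            constraints=cons)
        tree = px.initial_tree(langs, constraints=cons, calibrations=cals,
                               rng=rng, root_age_guess=3.0)
        init = ModelState(tree, px.SubstModel(), px.ClockModel(),
                          px.FBDParams(1.0, 0.2, 0.1, 0.9))
        cfg = px.MCMCConfig(chain_length=20_000, burn_in=0,
                            sample_every=100, seed=4)
        out = px.run_chain(None, init, spec, cfg)
        for t in out.trees:
            t.validate()
            assert t.mrca(["A", "B"]).age >= 1.0 - 1e-6
            assert constraint_satisfied(t, cons[0])
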