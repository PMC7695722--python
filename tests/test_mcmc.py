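"""Sampler mechanics: proposals, determinism, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import expon, kstest

import phylolex as px
from phylolex.cognates import SitePatterns
from phylolex.diagnostics import effective_sample_size, rhat
from phylolex.mcmc import MCMCConfig, available_moves, propose
from phylolex.state import ModelState


def simple_state(tree=None):
    if tree is None:
        tree = px.TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
    return ModelState(tree, px.SubstModel(), px.ClockModel(),
                      px.FBDParams(1.0, 0.2, 0.1, 0.9))


class TestProposals:
    def test_unknown_move_kind(self, rng):
        with pytest.raises(ValueError, match="unknown move"):
            propose(simple_state(), "teleport", rng)

    def test_scale_move_hastings_ratio(self, rng):
        state = simple_state()
        new, log_hr = propose(state, "gain_scale", rng, kappa=2.0)
        f = new.subst.m1p.gain / state.subst.m1p.gain
        assert log_hr == pytest.approx(np.log(f))
        assert 0.5 <= f <= 2.0

    def test_narrow_exchange_keeps_parent_ages(self, rng):
        state = simple_state()
        ages_before = sorted(n.age for n in state.tree.postorder())
        for _ in range(50):
            new, log_hr = propose(state, "narrow_exchange", rng)
            if new is None:
                continue
            assert log_hr == 0.0
            new.tree.validate()
            assert sorted(n.age for n in new.tree.postorder()) == ages_before
            assert frozenset(new.tree.tip_labels) == frozenset("ABCD")

    def test_wilson_balding_produces_valid_trees(self, rng):
        state = simple_state(px.TimeTree.from_newick(
            "(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,(E:0.7,F:0.7):2.3);"))
        seen_valid = 0
        for _ in range(200):
            new, _ = propose(state, "wilson_balding", rng)
            if new is None:
                continue
            new.tree.validate()
            assert frozenset(new.tree.tip_labels) == frozenset("ABCDEF")
            seen_valid += 1
        assert seen_valid > 10

    def test_rho_walk_reflects_into_unit_interval(self, rng):
        state = simple_state()
        state.fbd = px.FBDParams(1.0, 0.2, 0.1, 0.02)
        for _ in range(100):
            new, log_hr = propose(state, "rho_walk", rng)
            assert 0.0 <= new.fbd.rho <= 1.0
            assert log_hr == 0.0

    def test_available_moves_shrink_with_model(self):
        state = simple_state()
        kinds, probs = available_moves(state)
        assert "switch_on_scale" not in kinds      # no covarion component
        assert "branch_rate_scale" not in kinds    # strict clock
        assert probs.sum() == pytest.approx(1.0)

    def test_multiplier_move_targets_its_exponential_prior(self, rng):
        # prior-only sampling with only the gain scaler: the draw must
        # match the exponential prior, validating the Hastings ratio
        state = simple_state()
        spec = px.PriorSpec(root_age_mean=None)
        cfg = MCMCConfig(chain_length=200_000, burn_in=20_000,
                         sample_every=90, seed=9,
                         proposal_weights={"gain_scale": 1.0})
        out = px.run_chain(None, state, spec, cfg)
        draws = out.trace["gain_rate"].to_numpy()
        res = kstest(draws[::4], expon(scale=10.0).cdf)
        assert res.pvalue > 0.01


class TestRunChain:
    def test_same_seed_is_bit_identical(self, rng):
        langs, mat = self._tiny_alignment(rng)
        pats = SitePatterns(langs, *np.unique(mat.T, axis=0,
                                              return_counts=True))
        state = simple_state()
        spec = px.PriorSpec()
        cfg = MCMCConfig(chain_length=2_000, burn_in=400, sample_every=40,
                         seed=123)
        a = px.run_chain(pats, state, spec, cfg)
        b = px.run_chain(pats, state, spec, cfg)
        pd.testing.assert_frame_equal(a.trace, b.trace)
        assert [t.to_newick() for t in a.trees] == \
            [t.to_newick() for t in b.trees]

    def _tiny_alignment(self, rng):
        tree = px.TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        return px.simulate_binary_alignment(tree, px.SubstModel(), 40, rng,
                                            clock_rate=0.5)

    def test_sample_count_arithmetic(self):
        cfg = MCMCConfig(chain_length=1000, burn_in=200, sample_every=8,
                         seed=1)
        assert cfg.n_samples == 100
        state = simple_state()
        out = px.run_chain(None, state, px.PriorSpec(), cfg)
        assert len(out.trees) == 100
        assert len(out.trace) == 100

    def test_init_violating_constraint_errors_before_sampling(self):
        state = simple_state()
        spec = px.PriorSpec(
            constraints=[px.MonophylyConstraint(frozenset(["A", "C"]))])
        with pytest.raises(ValueError, match="violates"):
            px.run_chain(None, state, spec,
                         MCMCConfig(chain_length=100, burn_in=0,
                                    sample_every=10, seed=1))

    def test_cache_debug_mode_passes(self, rng):
        langs, mat = self._tiny_alignment(rng)
        pats = SitePatterns(langs, *np.unique(mat.T, axis=0,
                                              return_counts=True))
        cfg = MCMCConfig(chain_length=1_000, burn_in=0, sample_every=100,
                         seed=5, debug_check_every=200)
        px.run_chain(pats, simple_state(), px.PriorSpec(), cfg)

    def test_posterior_mean_consistent_with_longer_reference(self, rng):
        # fixed 2-taxon topology: only scalars and the root age move
        tree = px.TimeTree.from_newick("(A:1.0,B:1.0);")
        langs, mat = px.simulate_binary_alignment(
            tree, px.SubstModel(), 120, rng, clock_rate=0.5)
        pats = SitePatterns(langs, *np.unique(mat.T, axis=0,
                                              return_counts=True))
        state = simple_state(tree)
        spec = px.PriorSpec()
        short_cfg = MCMCConfig(chain_length=40_000, burn_in=8_000,
                               sample_every=80, seed=3)
        long_cfg = MCMCConfig(chain_length=120_000, burn_in=20_000,
                              sample_every=100, seed=17)
        short = px.run_chain(pats, state, spec, short_cfg)
        long = px.run_chain(pats, state, spec, long_cfg)
        xs = short.trace["gain_rate"].to_numpy()
        xl = long.trace["gain_rate"].to_numpy()
        ess = effective_sample_size(xs)
        mcse = xs.std(ddof=1) / np.sqrt(ess)
        assert abs(xs.mean() - xl.mean()) < 3 * mcse + 0.05 * xl.std(ddof=1)


class TestESS:
    def test_iid_normal_near_n(self, rng):
        x = rng.normal(size=1000)
        assert 700 <= effective_sample_size(x) <= 1300

    def test_alternating_series_flagged(self):
        x = np.tile([1.0, -1.0], 500)
        with pytest.warns(UserWarning, match="anticorrelated"):
            ess = effective_sample_size(x)
        assert ess == 1000.0

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert effective_sample_size(np.ones(50)) == 50.0

    def test_ar1_matches_closed_form(self, rng):
        phi, n = 0.9, 5000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        want = n * (1 - phi) / (1 + phi)
        got = effective_sample_size(x)
        assert abs(got - want) / want < 0.30

    def test_agrees_with_arviz_on_ar_series(self, rng):
        import arviz as az
        phi, n = 0.6, 4000
        x = np.empty(n)
        x[0] = 0.0
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        ours = effective_sample_size(x)
        theirs = float(az.ess(x))
        assert abs(ours - theirs) / theirs < 0.35

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5))


class TestRhat:
    def test_identical_chains_exactly_one(self, rng):
        c = rng.normal(size=500)
        assert rhat([c, c.copy()]) == 1.0

    def test_offset_chains_flagged(self, rng):
        a = rng.normal(0.0, 1.0, size=500)
        b = rng.normal(5.0, 1.0, size=500)
        assert rhat([a, b]) > 1.5

    def test_report_lists_every_scalar(self, rng):
        state = simple_state()
        spec = px.PriorSpec()
        cfg = MCMCConfig(chain_length=3_000, burn_in=600, sample_every=40,
                         seed=2, n_chains=2)
        chains = px.run_chains(None, state, spec, cfg)
        report = px.multichain_diagnostics(chains)
        expected = {c for c in chains[0].trace.columns if c != "Sample"}
        assert set(report["parameter"]) == expected
        assert {"rhat", "ess", "flagged"} <= set(report.columns)

    def test_mismatched_parameters_error(self, rng):
        state_cov = ModelState(
            px.TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);"),
            px.SubstModel(kind="m1p+CV", covarion=px.CovarionParams()),
            px.ClockModel(), px.FBDParams(1.0, 0.2, 0.1, 0.9))
        spec = px.PriorSpec()
        cfg = MCMCConfig(chain_length=1000, burn_in=0, sample_every=100,
                         seed=1)
        a = px.run_chain(None, simple_state(), spec, cfg)
        b = px.run_chain(None, state_cov, spec, cfg)
        with pytest.raises(ValueError, match="different parameters"):
            px.multichain_diagnostics([a, b])
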