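"""Parsimony, Mk likelihood, retention index and Bayesian ASR."""

import numpy as np
import pytest

from collemsel.ancestral_states import (bayes_asr, count_state_shifts,
                                        effective_sample_size, fit_mk,
                                        fitch_parsimony, mk_log_likelihood,
                                        mk_lrt, retention_index)
from collemsel.phylo_io import TraitTable, parse_tree
from collemsel.synthetic_data import simulate_bd_tree, simulate_mk_trait

from conftest import (brute_force_mk_likelihood, brute_force_parsimony,
                      random_tree)


def table(states, **assignments):
    return TraitTable(tuple(states), dict(assignments))


class TestFitchParsimony:
    def test_constant_character_zero_steps(self):
        tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        traits = table(["x", "y"], A="x", B="x", C="x", D="x")
        rec = fitch_parsimony(tree, traits)
        assert rec.total_steps == 0
        assert all(s == "x" for s in rec.resolved.values())

    def test_single_derived_tip(self):
        tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        traits = table(["hemi", "eu"], A="hemi", B="eu", C="hemi", D="hemi")
        rec = fitch_parsimony(tree, traits)
        assert rec.total_steps == 1
        assert rec.resolved[tree.root] == "hemi"

    def test_derived_cherry(self):
        tree = parse_tree("(((A:1,B:1):1,C:2):1,D:3);")
        traits = table(["hemi", "epi"], A="epi", B="epi", C="hemi", D="hemi")
        rec = fitch_parsimony(tree, traits)
        assert rec.total_steps == 1
        events = count_state_shifts(rec, "hemi")
        assert len(events) == 1
        assert sorted(events[0].members) == ["A", "B"]
        assert events[0].origin is tree.mrca({"A", "B"})

    def test_untraited_terminal_rejected(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        traits = table(["x", "y"], A="x", B="y")
        with pytest.raises(ValueError, match="untraited"):
            fitch_parsimony(tree, traits)

    def test_matches_exhaustive_minimum(self):
        # oracle: enumerate every full internal labeling on small trees
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(3, 7))
            k = int(rng.integers(2, 4))
            tree = random_tree(rng, n)
            states = tuple("abc"[:k])
            traits = TraitTable(states, {
                f"t{i + 1}": states[rng.integers(k)] for i in range(n)})
            rec = fitch_parsimony(tree, traits)
            assert rec.total_steps == brute_force_parsimony(tree, traits)
            assert rec.realized_steps() == rec.total_steps

    def test_polytomy_hartigan(self):
        # a 4-way star with a 2+2 split needs two changes (whatever state
        # the root takes, two children disagree); matches the oracle
        tree = parse_tree("(A:1,B:1,C:1,D:1);")
        traits = table(["x", "y"], A="x", B="x", C="y", D="y")
        rec = fitch_parsimony(tree, traits)
        assert rec.total_steps == 2
        assert rec.total_steps == brute_force_parsimony(tree, traits)


class TestShiftEvents:
    def test_zero_step_reconstruction_empty(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        traits = table(["x", "y"], A="x", B="x", C="x")
        rec = fitch_parsimony(tree, traits)
        assert count_state_shifts(rec, "x") == []

    def test_autapomorphy_event(self):
        tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        traits = table(["hemi", "eu"], A="hemi", B="eu", C="hemi", D="hemi")
        rec = fitch_parsimony(tree, traits)
        events = count_state_shifts(rec, "hemi")
        assert len(events) == 1
        ev = events[0]
        assert ev.derived_state == "eu"
        assert ev.members == ["B"]
        assert [s.label for s in ev.sister_branches] == ["A"]

    def test_unknown_state_rejected(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        traits = table(["x", "y"], A="x", B="x", C="x")
        rec = fitch_parsimony(tree, traits)
        with pytest.raises(ValueError):
            count_state_shifts(rec, "z")

    def test_events_disjoint_members(self, ingroup):
        tree, traits = ingroup
        rec = fitch_parsimony(tree, traits, prefer_state="hemiedaphic")
        events = count_state_shifts(rec, "hemiedaphic")
        all_members = [m for ev in events for m in ev.members]
        assert len(all_members) == len(set(all_members))
        for ev in events:
            assert all(traits.assignments[m] == ev.derived_state
                       for m in ev.members)


class TestRetentionIndex:
    def test_two_origins_five_tips(self, ingroup):
        tree, traits = ingroup
        r = retention_index(tree, traits, "epiedaphic")
        assert (r.g, r.s, r.r) == (5, 2, 1)
        assert r.ri == pytest.approx(0.75)

    def test_autapomorphy_reported_zero_undefined(self, ingroup):
        tree, traits = ingroup
        for state in ("myrmecophilous", "aquatic"):
            r = retention_index(tree, traits, state)
            assert r.ri == 0.0
            assert not r.defined

    def test_maximal_homoplasy_is_zero(self):
        # state scattered as far as possible: s = g
        tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        traits = table(["x", "y"], A="x", B="y", C="x", D="y")
        r = retention_index(tree, traits, "x")
        assert (r.g, r.s, r.r) == (2, 2, 1)
        assert r.ri == 0.0

    def test_no_homoplasy_is_one(self):
        tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        traits = table(["x", "y"], A="x", B="x", C="y", D="y")
        assert retention_index(tree, traits, "x").ri == 1.0


class TestMkLikelihood:
    def test_rate_zero_limit(self):
        # with q -> 0 only root-state uncertainty remains
        tree = parse_tree("((A:1,B:1):1,C:2);")
        traits = table(["x", "y"], A="x", B="x", C="x")
        ll = mk_log_likelihood(tree, traits, 1e-12)
        assert ll == pytest.approx(np.log(0.5), abs=1e-6)

    def test_rate_infinity_limit(self):
        # with q -> inf tip states are independent uniform draws
        tree = parse_tree("((A:1,B:1):1,C:2);")
        traits = table(["x", "y"], A="x", B="y", C="x")
        ll = mk_log_likelihood(tree, traits, 50.0)
        assert ll == pytest.approx(3 * np.log(0.5), abs=1e-3)

    def test_two_tip_closed_form(self):
        # p_same(t) = 1/2 + exp(-2qt)/2 for the 2-state kernel
        q, t = 0.1, 1.0
        tree = parse_tree(f"(A:{t},B:{t});")
        traits = table(["x", "y"], A="x", B="x")
        p_same = 0.5 + 0.5 * np.exp(-2 * q * t)
        p_diff = 0.5 - 0.5 * np.exp(-2 * q * t)
        expected = 0.5 * (p_same ** 2 + p_diff ** 2)
        ll = mk_log_likelihood(tree, traits, q)
        assert ll == pytest.approx(np.log(expected), rel=1e-9)

    def test_negative_rate_rejected(self):
        tree = parse_tree("(A:1,B:1);")
        traits = table(["x", "y"], A="x", B="x")
        with pytest.raises(ValueError):
            mk_log_likelihood(tree, traits, -0.1)

    def test_matches_brute_force_state_sums(self):
        # oracle: explicit summation over internal-node states
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = int(rng.integers(2, 6))
            k = int(rng.integers(2, 4))
            tree = random_tree(rng, n)
            states = tuple("abc"[:k])
            traits = TraitTable(states, {
                f"t{i + 1}": states[rng.integers(k)] for i in range(n)})
            if rng.random() < 0.5:
                Q = np.full((k, k), rng.uniform(0.01, 1.0))
                np.fill_diagonal(Q, -(k - 1) * Q[0, 1])
                rates = Q[0, 1]
            else:
                Q = rng.uniform(0.01, 1.0, (k, k))
                np.fill_diagonal(Q, 0.0)
                np.fill_diagonal(Q, -Q.sum(axis=1))
                rates = Q
            prior = np.full(k, 1.0 / k)
            ll = mk_log_likelihood(tree, traits, rates, prior)
            brute = brute_force_mk_likelihood(tree, traits, Q, prior)
            assert ll == pytest.approx(np.log(brute), rel=1e-9)

    def test_marginals_sum_to_one(self, ingroup):
        tree, traits = ingroup
        fit = fit_mk(tree, traits, "mk1")
        for nd, marg in fit.marginals.items():
            assert marg.sum() == pytest.approx(1.0, abs=1e-9)


class TestFitMk:
    def test_constant_character_rate_at_lower_bound(self):
        tree = parse_tree("((A:10,B:10):10,C:20);")
        traits = table(["x", "y"], A="x", B="x", C="x")
        fit = fit_mk(tree, traits, "mk1")
        assert fit.at_bound
        assert fit.rates[0, 1] < 1e-6

    def test_rate_recovery_pooled(self):
        # 100 iid characters on a deep 64-tip tree recover q within 30%
        q_true = 0.005
        tree = simulate_bd_tree(64, 1.0, 0.0, root_age=400.0, seed=21)
        k = 2
        Q = np.array([[-q_true, q_true], [q_true, -q_true]])
        rng = np.random.default_rng(22)
        sims = [simulate_mk_trait(tree, Q, ("x", "y"), "x", rng)
                for _ in range(100)]

        from scipy.optimize import minimize_scalar

        def pooled_nll(logq):
            q = 10.0 ** logq
            return -sum(mk_log_likelihood(tree, s.table, q) for s in sims)

        res = minimize_scalar(pooled_nll, bounds=(-5, 0), method="bounded")
        q_hat = 10.0 ** res.x
        assert abs(q_hat - q_true) / q_true < 0.30

    def test_asymm_nests_mk1(self, ingroup):
        tree, traits = ingroup
        f1 = fit_mk(tree, traits, "mk1")
        fa = fit_mk(tree, traits, "asymm", n_starts=2)
        stat, df, p = mk_lrt(f1, fa)
        assert stat >= 0
        assert df == traits.k * (traits.k - 1) - 1
        assert 0 <= p <= 1

    def test_lrt_type_one_error_calibrated(self):
        # data generated under Mk1 should reject the Mk1 null at ~ alpha;
        # binomial 95% band for 200 replicates at alpha = 0.05
        tree = simulate_bd_tree(16, 1.0, 0.0, root_age=400.0, seed=31)
        q = 0.003
        Q = np.array([[-q, q], [q, -q]])
        rng = np.random.default_rng(32)
        rejections = 0
        for _ in range(200):
            sim = simulate_mk_trait(tree, Q, ("x", "y"), "x", rng)
            counts = sim.table.counts()
            if 0 in counts.values():
                continue  # constant characters carry no rate information
            f1 = fit_mk(tree, sim.table, "mk1")
            fa = fit_mk(tree, sim.table, "asymm", n_starts=2)
            _, _, p = mk_lrt(f1, fa)
            rejections += (p < 0.05)
        assert 0.02 * 200 <= rejections <= 0.09 * 200


class TestBayesAsr:
    def test_uniform_data_recovers_state(self):
        # a constant character is called decisively; the posterior stays a
        # little below 1 because the hierarchical rate prior keeps mass in
        # strongly asymmetric regions whose root marginal is uninformative
        tree = parse_tree("(((A:1,B:1):1,(C:1,D:1):1):1,"
                          "((E:1,F:1):1,(G:1,H:1):1):1);")
        traits = table(["x", "y"], **{t: "x" for t in "ABCDEFGH"})
        res = bayes_asr(tree, traits, list("ABCDEFGH"), n_chains=2,
                        n_iter=3000, burn_in=750, seed=3)
        assert res.as_dict()["x"] > 0.9
        assert res.support_call == "x"

    def test_support_threshold_rule(self):
        # a 0.6/0.4 posterior is below the 0.7 support threshold
        from collemsel.ancestral_states import BayesAsrResult
        res = BayesAsrResult(("x", "y"), np.array([0.6, 0.4]),
                             np.array([[0.6, 0.4]]), np.array([500.0]),
                             1, 100, "unsupported")
        assert res.support_call == "unsupported"
        assert res.as_dict()["x"] == pytest.approx(0.6)

    def test_zero_length_tree_forced_by_data(self):
        tree = parse_tree("((A:0,B:0):0,C:0);")
        traits = table(["x", "y"], A="y", B="y", C="y")
        res = bayes_asr(tree, traits, ["A", "B", "C"], n_chains=2,
                        n_iter=1000, burn_in=200, seed=4)
        assert res.as_dict()["y"] > 0.99

    def test_burn_in_validation(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        traits = table(["x", "y"], A="x", B="x", C="x")
        with pytest.raises(ValueError):
            bayes_asr(tree, traits, ["A"], n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            bayes_asr(tree, traits, [], n_iter=100)

    def test_agrees_with_ml_marginal_on_four_tips(self):
        # long-run posterior under a flat-ish prior tracks the ML marginal
        tree = parse_tree("((A:30,B:30):30,(C:30,D:30):30);")
        traits = table(["x", "y"], A="x", B="x", C="y", D="y")
        fit = fit_mk(tree, traits, "mk1")
        ml_root = fit.marginal_at(tree.root)
        # equivocal_margin=0 keeps every sample so the comparison is fair
        res = bayes_asr(tree, traits, ["A", "B", "C", "D"], n_chains=2,
                        n_iter=6000, burn_in=1500, seed=5,
                        equivocal_margin=0.0)
        post = res.as_dict()
        assert post["x"] == pytest.approx(ml_root["x"], abs=0.12)

    def test_multiple_trees_accepted(self):
        t1 = parse_tree("((A:50,B:50):50,C:100);")
        t2 = parse_tree("((A:40,C:40):60,B:100);")
        traits = table(["x", "y"], A="x", B="x", C="x")
        res = bayes_asr([t1, t2], traits, ["A", "B", "C"], n_chains=2,
                        n_iter=1200, burn_in=300, seed=6)
        assert res.as_dict()["x"] > 0.9


def test_effective_sample_size_behaviour():
    rng = np.random.default_rng(8)
    iid = rng.normal(size=2000)
    assert effective_sample_size(iid) > 1000
    # a strongly autocorrelated AR(1) series has far fewer effective draws
    ar = np.empty(2000)
    ar[0] = 0.0
    for i in range(1, 2000):
        ar[i] = 0.95 * ar[i - 1] + rng.normal()
    assert effective_sample_size(ar) < 500
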