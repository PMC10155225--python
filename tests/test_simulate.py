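"""Birth-death simulator: determinism, histories, pipeline experiments."""

import numpy as np
import pytest

import euryalida as eu


class TestSimParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            eu.SimParams(lambda0=-1, lambda1=1, n_max=10)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            eu.SimParams(lambda0=0, lambda1=0, mu0=0, mu1=0, q01=0, q10=0,
                         t_max=1)

    def test_needs_a_stopping_rule(self):
        with pytest.raises(ValueError):
            eu.SimParams(lambda0=1, lambda1=1)


class TestSimulate:
    def test_no_flip_rates_means_no_transitions(self):
        params = eu.SimParams(lambda0=1, lambda1=1, q01=0, q10=0,
                              root_state=0, n_max=16, seed=5)
        sim = eu.simulate(params)
        assert sim.true_gains == 0 and sim.total_gains == 0
        assert all(v == frozenset({0}) for v in sim.tip_states.values())

    def test_pure_birth_hits_cap_and_is_seed_deterministic(self):
        params = eu.SimParams(lambda0=1, lambda1=1, mu0=0, mu1=0,
                              n_max=32, seed=123)
        a, b = eu.simulate(params), eu.simulate(params)
        assert a.n_tips == 32
        assert eu.write_newick(a.tree) == eu.write_newick(b.tree)
        assert a.tip_states == b.tip_states
        assert (a.true_gains, a.true_losses) == (b.true_gains, b.true_losses)

    def test_pure_death_always_goes_extinct(self):
        for seed in range(200):
            sim = eu.simulate(eu.SimParams(lambda0=0, lambda1=0, mu0=2,
                                           mu1=0, q01=0, t_max=1000,
                                           seed=seed))
            assert sim.extinct and sim.tree is None

    def test_reconstructed_tree_is_valid_and_binary_states_cover_tips(self):
        params = eu.SimParams(lambda0=1, lambda1=1.5, mu0=0.4, mu1=0.4,
                              q01=0.3, q10=0.1, n_max=40, seed=0)
        sim = eu.simulate(params)
        assert not sim.extinct
        assert set(sim.tip_states) == set(sim.tree.tip_labels())
        assert sim.true_gains <= sim.total_gains
        assert sim.true_losses <= sim.total_losses

    def test_parsimony_lower_bound_on_every_replicate(self):
        """The minimum-change count can never exceed the realized number
        of transitions on the reconstructed tree's lineages."""
        params = eu.SimParams(lambda0=1, lambda1=1, mu0=0.3, mu1=0.3,
                              q01=0.25, q10=0.25, n_max=40)
        checked = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            sim = eu.simulate(params, rng=rng)
            if sim.extinct or sim.n_tips < 2:
                continue
            cost = eu.fitch_min_changes(sim.tree, sim.tip_states,
                                        root_state=params.root_state)
            assert cost <= sim.true_gains + sim.true_losses
            checked += 1
        assert checked >= 30

    def test_irreversible_gains_bound_derived_clade_count(self):
        """With losses impossible (q10 = 0), distinct maximal derived
        clades must come from distinct origin events, so the clade count
        never exceeds the realized gains on surviving lineages — while the
        parsimony minimum stays below both."""
        import warnings
        params = eu.SimParams(lambda0=1, lambda1=1, mu0=0.2, mu1=0.2,
                              q01=0.3, q10=0.0, n_max=30)
        checked = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            sim = eu.simulate(params, rng=rng)
            if sim.extinct or sim.n_tips < 2:
                continue
            values = {next(iter(v)) for v in sim.tip_states.values()}
            if values != {0, 1}:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clades = eu.find_derived_clades(sim.tree, sim.tip_states)
            s = eu.mpr_gain_range(sim.tree, sim.tip_states, root_state=0)
            assert len(clades) <= sim.true_gains
            assert s.min_changes <= sim.true_gains
            assert s.min_changes <= len(clades)
            checked += 1
        assert checked >= 10


class TestMakeRichnessTable:
    def test_constant_rule_gives_all_ones(self):
        sim = eu.simulate(eu.SimParams(lambda0=1, lambda1=1, n_max=16, seed=2))
        matrix = eu.make_richness_table(sim, species_per_tip=1)
        assert all(r.species_count == 1 for r in matrix)

    def test_extinct_input_rejected(self):
        sim = eu.simulate(eu.SimParams(lambda0=0, lambda1=0, mu0=1, mu1=1,
                                       q01=0.5, t_max=50, seed=0))
        assert sim.extinct
        with pytest.raises(ValueError):
            eu.make_richness_table(sim)

    def test_seeded_rerun_identical(self):
        sim = eu.simulate(eu.SimParams(lambda0=1, lambda1=1, n_max=24, seed=4))
        m1 = eu.make_richness_table(sim, seed=11)
        m2 = eu.make_richness_table(sim, seed=11)
        assert [r.species_count for r in m1] == [r.species_count for r in m2]

    def test_state_dependent_means_recovered(self):
        """Pooled over replicates, geometric species counts hit their
        state-dependent means (m0=2, m1=6) to within 5%."""
        params = eu.SimParams(lambda0=1, lambda1=1, q01=0.5, q10=0.5,
                              n_max=400)
        by_state = {0: [], 1: []}
        rng = np.random.default_rng(777)
        for _ in range(30):
            sim = eu.simulate(params, rng=rng)
            matrix = eu.make_richness_table(sim, mean0=2.0, mean1=6.0, rng=rng)
            for r in matrix:
                by_state[1 if r.branched else 0].append(r.species_count)
        assert len(by_state[0]) + len(by_state[1]) >= 10_000
        assert np.mean(by_state[0]) == pytest.approx(2.0, rel=0.05)
        assert np.mean(by_state[1]) == pytest.approx(6.0, rel=0.05)


class TestRejectionRateExperiment:
    def test_single_rep_rate_is_zero_or_one(self):
        params = eu.SimParams(lambda0=1, lambda1=1, q01=0.2, q10=0.2, n_max=16)
        result = eu.rejection_rate_experiment(params, reps=1, seed=0)
        assert result.rate in (0.0, 1.0)

    def test_seeded_experiment_reproducible(self):
        params = eu.SimParams(lambda0=1, lambda1=1, q01=0.2, q10=0.2, n_max=32)
        r1 = eu.rejection_rate_experiment(params, reps=40, seed=5)
        r2 = eu.rejection_rate_experiment(params, reps=40, seed=5)
        assert r1 == r2

    def test_effect_raises_rejection_rate_over_null(self):
        """A richness-and-speciation advantage of the derived state must be
        rejected more often than the matched null with the same seeds."""
        null = eu.SimParams(lambda0=1, lambda1=1, mu0=0.1, mu1=0.1,
                            q01=0.3, q10=0.0, n_max=100)
        effect = eu.SimParams(lambda0=1, lambda1=1.5, mu0=0.1, mu1=0.1,
                              q01=0.3, q10=0.0, n_max=100)
        r_null = eu.rejection_rate_experiment(null, reps=200, seed=21,
                                              mean0=2.0, mean1=2.0)
        r_eff = eu.rejection_rate_experiment(effect, reps=200, seed=21,
                                             mean0=2.0, mean1=12.0)
        assert r_eff.rate > r_null.rate
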