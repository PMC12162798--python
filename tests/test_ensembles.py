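"""Critical RBN generation, fixture families, experiments and surveys."""

import numpy as np
import pytest

import boolmaa as bm
from boolmaa.ensembles import (EnsembleConfig, _net_from_2var_tables,
                               fragility_experiment, generate_critical_rbn,
                               maa_frequency_experiment, prototype_survey_2var,
                               reduction_experiment, wilson_interval)


class TestCriticalBias:
    def test_small_k_forces_one_half(self):
        assert bm.critical_p(1) == 0.5
        assert bm.critical_p(2) == 0.5

    def test_k3_closed_form(self):
        assert bm.critical_p(3) == pytest.approx((1 - np.sqrt(1 / 3)) / 2, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 5, 10])
    def test_defining_identity(self, k):
        # K = 1 admits no solution (2p(1-p) <= 1/2) and falls back to the
        # maximizing bias 0.5; the identity holds exactly from K = 2 on
        for p in bm.critical_p_roots(k):
            assert 2 * k * p * (1 - p) == pytest.approx(1.0, abs=1e-12)


class TestGenerator:
    def test_fixed_seed_reproduces_the_network(self):
        cfg = EnsembleConfig(N=8, K=3, seed=123)
        assert generate_critical_rbn(cfg) == generate_critical_rbn(cfg)

    def test_truth_table_bias_matches_p(self):
        """Empirical ones-fraction over ~10^5 table bits within 3 SE."""
        cfg = EnsembleConfig(N=10, K=10, seed=5)
        rng = np.random.default_rng(cfg.seed)
        names = [f"x{i}" for i in range(10)]
        ones = total = 0
        for _ in range(10):
            for i in range(10):
                rng.choice(10, size=10, replace=False)
                bits = rng.random(1 << 10) < cfg.p
                ones += bits.sum()
                total += bits.size
        frac = ones / total
        se = np.sqrt(cfg.p * (1 - cfg.p) / total)
        assert abs(frac - cfg.p) < 3 * se

    def test_dense_limit_uses_every_node_as_regulator(self):
        cfg = EnsembleConfig(N=4, K=4, p=0.5, seed=9)
        rng = np.random.default_rng(0)
        # pre-normalization regulators are all nodes; after pruning they are
        # a subset, never anything else
        for _ in range(20):
            net = generate_critical_rbn(cfg, rng)
            for v in net.variables:
                assert set(net.inputs(v)) <= set(net.variables)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig(N=3, K=4)
        with pytest.raises(ValueError):
            EnsembleConfig(N=3, K=2, p=1.5)


class TestStarFamily:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_star_validations(self, n):
        net = bm.star_network(n)
        ig = bm.interaction_graph(net)
        assert ig.number_of_edges() == n * n
        atts = bm.attractors(net)
        assert [a.kind for a in atts] == ["complex", "point"]
        assert atts[1].states == ((1 << n) - 1,)
        assert set(atts[0].states) == {0} | {1 << i for i in range(n)}

    def test_star2_is_the_canonical_xnor_pair(self):
        net = bm.star_network(2)
        for v in net.variables:
            assert net.function(v)[1].tolist() == [1, 0, 0, 1]

    def test_too_small_star_rejected(self):
        with pytest.raises(ValueError):
            bm.star_network(1)


class TestTwoVariableClassification:
    def test_exactly_one_maa_class_up_to_symmetry(self, star2):
        count, reps, orbits = bm.enumerate_2var_classes()
        assert count == 1
        # the flagged class contains the canonical XNOR pair; the variable
        # swap stabilizes it, so the orbit has 4 labeled members (the
        # XOR/XNOR combinations), giving the exact frequency 4/256 = 1/64
        star_tables = tuple(int(sum(b << x for x, b in
                                    enumerate(star2.function(v)[1])))
                            for v in ("A", "B"))
        flagged_orbit = next(o for rep, o in orbits.items()
                             if bm.has_maa(_net_from_2var_tables(rep)))
        assert star_tables in flagged_orbit
        assert len(flagged_orbit) == 4
        # cross-check against plain brute force over all 256 networks
        assert sum(bm.has_maa(_net_from_2var_tables((t0, t1)))
                   for t0 in range(16) for t1 in range(16)) == 4
        # orbits partition all 256 networks
        assert sum(len(o) for o in orbits.values()) == 256

    def test_orbit_members_share_the_maa_flag(self):
        _, _, orbits = bm.enumerate_2var_classes()
        rng = np.random.default_rng(0)
        for rep in list(orbits)[:20]:
            flags = {bm.has_maa(_net_from_2var_tables(t))
                     for t in list(orbits[rep])[:4]}
            assert len(flags) == 1


class TestWilson:
    def test_published_bound_for_230_negative_samples(self):
        lo, hi = wilson_interval(230, 0, 0.0)
        assert lo == 0.0
        assert round(hi * 100, 1) == 1.7

    def test_formula_arithmetic(self):
        assert wilson_interval(996, 0, 0.0) == (0.0, 0.004)

    def test_interval_contains_its_center(self):
        for n, m in ((10, 3), (50, 0), (50, 50)):
            q = m / n
            lo, hi = wilson_interval(n, m, q * (1 - q))
            assert lo <= (m + 2) / (n + 4) <= hi

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0, 0.0)
        with pytest.raises(ValueError):
            wilson_interval(10, 11, 0.0)


class TestExperiments:
    def test_results_are_reproducible_bit_for_bit(self):
        cfg = EnsembleConfig(N=6, K=3, seed=77, samples=200)
        a = maa_frequency_experiment(cfg)
        b = maa_frequency_experiment(cfg)
        assert (a.samples, a.positives, a.skipped, a.frequency, a.wilson) == \
            (b.samples, b.positives, b.skipped, b.frequency, b.wilson)

    def test_two_variable_frequency_converges_to_the_enumerated_value(self):
        """All 256 two-variable unbiased networks are equiprobable at
        p = 0.5; the MAA class has 4 labeled members, so the frequency
        converges to 1/64 (checked within 3 binomial SE)."""
        cfg = EnsembleConfig(N=2, K=2, seed=3, samples=4000)
        res = maa_frequency_experiment(cfg)
        exact = 1 / 64
        se = np.sqrt(exact * (1 - exact) / cfg.samples)
        assert abs(res.frequency - exact) < 3 * se

    def test_dense_networks_have_far_more_maas_than_sparse(self):
        """The N=10 dense (K=10) frequency exceeds the sparse (K=2) one by
        at least an order of magnitude."""
        dense = maa_frequency_experiment(
            EnsembleConfig(N=10, K=10, seed=31, samples=1500))
        sparse = maa_frequency_experiment(
            EnsembleConfig(N=10, K=2, seed=32, samples=10000))
        assert dense.frequency > 0
        if sparse.positives:
            assert dense.frequency >= 10 * sparse.frequency
        else:
            assert dense.frequency >= 10 * sparse.wilson[1] / 2

    def test_reduction_experiment_records_sizes_and_flags(self):
        res = reduction_experiment(EnsembleConfig(N=8, K=2, seed=41, samples=300),
                                   keep_records=True)
        assert res.samples == 300 and res.skipped == 0
        assert len(res.records) == 300
        assert 1.0 <= res.aux["mean_reduced_size"] <= 8.0
        for rec in res.records:
            if rec["reduced_size"] <= 1:
                assert not rec["maa"]

    def test_degenerate_fragility_on_the_canonical_network(self, star2):
        """A one-network ensemble consisting of the 2-variable MAA has
        resistant fraction 0 (every single delay succeeds)."""
        report = bm.find_maas(star2, include_metrics=False)[0]
        _, n_success = bm.single_delay_survey(star2, report)
        assert n_success == 4

    def test_fragility_experiment_small_run(self):
        res = fragility_experiment(EnsembleConfig(N=6, K=6, seed=51),
                                   maa_target=12)
        assert res.positives == 12
        assert res.aux["n_maas"] >= 12
        assert sum(res.aux["success_histogram"].values()) == res.aux["n_maas"]
        assert 0.0 <= res.aux["resistant_fraction"] <= 1.0


class TestEmbeddedPattern:
    def test_canonical_network_embeds_itself(self, star2):
        report = bm.find_maas(star2, include_metrics=False)[0]
        assert bm.detect_embedded_2var(star2, report)

    def test_star3_embeds_the_pattern_in_a_plane(self, star3):
        report = bm.find_maas(star3, include_metrics=False)[0]
        assert bm.detect_embedded_2var(star3, report)

    def test_ordered_six_cycle_does_not_embed(self, six_cycle):
        report = bm.find_maas(six_cycle, include_metrics=False)[0]
        assert not bm.detect_embedded_2var(six_cycle, report)


class TestTemplates:
    def test_two_variable_survey_finds_the_unique_template(self):
        templates = prototype_survey_2var()
        assert len(templates) == 1
        t = templates[0]
        assert set(t.states) == {0b00, 0b01, 0b10}
        assert t.metrics == (2, 2, 1)
        assert len(t.eliminating_edges) == 4

    def test_star_pattern_is_among_three_variable_templates(self, survey3):
        assert any(set(t.states) == {0, 1, 2, 4} and t.metrics == (3, 3, 2)
                   for t in survey3)

    def test_six_state_cycle_template_exists(self, survey3):
        def is_pure_cycle(t):
            if len(t.states) != 6 or len(t.internal_edges) != 6:
                return False
            outs = {s for s, _ in t.internal_edges}
            return outs == set(t.states)
        assert any(is_pure_cycle(t) for t in survey3)

    def test_unit_disagreement_templates_die_by_one_self_loop_delay(self, survey3):
        """Templates with M = d and m = 1 are eliminated by a delay on a
        single self-regulation."""
        qualifying = [t for t in survey3
                      if t.metrics[0] == t.metrics[1] and t.metrics[2] == 1]
        assert qualifying
        for t in qualifying:
            assert any(u == v for u, v in t.eliminating_edges)

    def test_every_template_attractor_oscillates_in_two_variables(self, survey3):
        for t in survey3:
            assert t.metrics[1] >= 2
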