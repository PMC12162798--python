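"""Linear extensions, memory states, projected STGs, delay search and
delay-count bounds."""

import numpy as np
import pytest

import boolmaa as bm
from boolmaa.delays import (DelayLimitError, classify_memory_transitions,
                            delay_upper_bound, minimal_delay_set_size,
                            projected_stg, worst_case_bound)
from boolmaa.dynamics import _async_successors
from boolmaa.network import BooleanNetwork
from conftest import random_net


def all_edges(net):
    return [(u, v) for v in net.variables for u in net.inputs(v)]


class TestLinearExtend:
    def test_extension_adds_one_variable_per_edge(self, star2):
        ext = bm.linear_extend(star2, all_edges(star2))
        assert ext.n == star2.n + 4
        assert not bm.has_maa(ext)

    def test_extension_then_deletion_is_identity(self, star3):
        ext = bm.linear_extend(star3, [("A", "B")])
        assert bm.delete_node(ext, "d_A_B") == star3

    def test_extending_one_edge_makes_the_trap_state_reachable(self, star2):
        """In the 2-variable MAA the update-order requirement for reaching
        11 is circular; one delay node breaks the circularity."""
        import networkx as nx
        g = bm.build_stg(star2, "asynchronous")
        assert not nx.has_path(g, "00", "11")
        ext = bm.linear_extend(star2, [("A", "B")])
        ge = bm.build_stg(ext, "asynchronous")
        assert nx.has_path(ge, "000", "111")

    def test_fixed_points_map_to_canonical_images(self, star3):
        ext = bm.linear_extend(star3, [("A", "A"), ("B", "C")])
        # 111 -> 11111 (delays copy their parents)
        vals = ext.values_on_all_states()
        allon = (1 << ext.n) - 1
        assert all(vals[allon, i] == 1 for i in range(ext.n))
        assert len(bm.minimal_trap_spaces(ext)) == len(bm.minimal_trap_spaces(star3))

    def test_non_edges_are_rejected(self, example1):
        with pytest.raises(ValueError, match="not an essential edge"):
            bm.linear_extend(example1, [("A", "A")])


class TestSingleDelaySurvey:
    def test_canonical_maa_is_destroyed_by_any_of_its_four_edges(self, star2):
        report = bm.find_maas(star2, include_metrics=False)[0]
        verdicts, n_success = bm.single_delay_survey(star2, report)
        assert n_success == 4 and all(verdicts.values())

    def test_no_single_delay_destroys_the_three_variable_star(self, star3):
        report = bm.find_maas(star3, include_metrics=False)[0]
        _, n_success = bm.single_delay_survey(star3, report)
        assert n_success == 0

    def test_non_avoidant_reports_are_rejected(self, star2):
        import dataclasses
        report = dataclasses.replace(bm.find_maas(star2)[0],
                                     is_motif_avoidant=False)
        with pytest.raises(ValueError):
            bm.single_delay_survey(star2, report)


class TestMinimalDelaySearch:
    def test_star_two_needs_one_delay(self, star2):
        size, witness = minimal_delay_set_size(star2)
        assert size == 1 and len(witness) == 1

    def test_star_three_needs_two_delays(self, star3):
        size, _ = minimal_delay_set_size(star3)
        assert size == 2

    def test_limit_exhaustion_reports_a_lower_bound(self, star3):
        with pytest.raises(DelayLimitError) as err:
            minimal_delay_set_size(star3, limit=1)
        assert err.value.lower_bound == 2

    def test_search_never_exceeds_the_closed_form_bound(self, star2, star3):
        for net in (star2, star3):
            report = bm.find_maas(net)[0]
            M, d, m = report.best_metrics()
            size, _ = minimal_delay_set_size(net)
            assert size <= delay_upper_bound(M, d, m)


class TestBounds:
    def test_single_delay_case(self):
        assert delay_upper_bound(2, 2, 1) == 1

    def test_star_metrics_give_triangular_bound(self):
        for n in range(2, 8):
            assert delay_upper_bound(n, n, n - 1) == n * (n - 1) // 2

    def test_direct_evaluation(self):
        assert delay_upper_bound(4, 3, 1) == 4

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            delay_upper_bound(3, 1, 1)
        with pytest.raises(ValueError):
            delay_upper_bound(3, 3, 3)

    def test_worst_case_form_matches_the_bound_at_maximal_disagreement(self):
        for n in range(2, 11):
            for d in range(2, n + 1):
                wc = worst_case_bound(n * n, d)
                assert wc == pytest.approx(delay_upper_bound(n, d, d - 1))
                assert wc < n * n

    def test_worst_case_small_example(self):
        assert worst_case_bound(4, 2) == 1

    def test_non_square_edge_count_rejected(self):
        with pytest.raises(ValueError, match="square"):
            worst_case_bound(5, 2)


class TestMemoryTransitions:
    def test_non_functional_delay_changes_nothing(self, star2):
        """A sink node that copies a variable creates memory states but no
        gained or lost transitions."""
        funcs = {v: star2.function(v) for v in star2.variables}
        funcs["z"] = (("A",), np.array([0, 1], dtype=np.uint8))
        ext = BooleanNetwork(funcs, variables=["A", "B", "z"])
        report = classify_memory_transitions(star2, extended=ext)
        assert report.gained == [] and report.lost == []

    def test_self_edge_delay_gains_escape_transitions(self, star2):
        report = classify_memory_transitions(star2, [("A", "A")])
        assert report.gained  # memory states enable reaching the trap space

    def test_canonical_states_never_appear_as_sources(self, star2):
        ext = bm.linear_extend(star2, [("A", "A")])
        report = classify_memory_transitions(star2, [("A", "A")])
        zi = ext.index("d_A_A")
        ai = ext.index("A")
        for s, _, _, _ in report.gained + report.lost:
            assert (s >> zi) & 1 != (s >> ai) & 1


class TestProjectedSTG:
    def test_empty_delay_set_reproduces_the_original_stg(self, star2):
        proj = projected_stg(star2, [])
        rows, cols = _async_successors(star2)
        assert set(proj.graph.edges) == set(zip(rows.tolist(), cols.tolist()))
        assert proj.gained_edges() == []

    def test_one_delay_gains_a_path_into_the_trap_space(self, star2):
        proj = projected_stg(star2, [("A", "B")])
        gained = proj.gained_edges()
        assert gained
        import networkx as nx
        # some MAA state now reaches the avoided trap state 11
        assert any(nx.has_path(proj.graph, s, 0b11) for s in (0b00, 0b01, 0b10))
        for u, v, data in proj.graph.edges(data=True):
            assert u != v
            if data["kind"] == "gained":
                assert data["witness"] is not None

    def test_canonical_connectivity_is_monotone_in_the_delay_set(self, star2):
        small = projected_stg(star2, [("A", "B")])
        large = projected_stg(star2, [("A", "B"), ("B", "A")])
        assert set(small.graph.edges) <= set(large.graph.edges)


class TestSingleDelayTheorem:
    def test_m_equal_d_and_unit_disagreement_implies_single_delay(self):
        """Whenever the smallest trap space containing the MAA and the
        avoided minimal trap space has exactly the oscillating variables
        free (M = d) and the minimal restricted disagreement is 1, a single
        delay eliminates the MAA."""
        rng = np.random.default_rng(21)
        qualifying = 0
        trials = 0
        while qualifying < 10 and trials < 4000:
            trials += 1
            net = random_net(rng, n_max=6, k_max=4)
            for report in bm.find_maas(net):
                if any(M == d and m == 1 for M, d, m in report.metrics.values()):
                    _, n_success = bm.single_delay_survey(net, report)
                    assert n_success >= 1
                    qualifying += 1
        assert qualifying >= 5


class TestFullExtension:
    def test_full_extension_eliminates_maas_in_random_networks(self):
        """Extending every edge of a network with a motif-avoidant
        attractor yields an L-cuttable, MAA-free network (100 random MAA
        networks from small dense critical ensembles)."""
        from boolmaa.structure import is_l_cuttable
        rng = np.random.default_rng(17)
        found = 0
        trials = 0
        while found < 100 and trials < 30000:
            trials += 1
            net = bm.generate_critical_rbn(bm.EnsembleConfig(N=4, K=3), rng)
            if not bm.has_maa(net):
                continue
            found += 1
            ext = bm.linear_extend(net, all_edges(net))
            assert is_l_cuttable(bm.interaction_graph(ext))
            assert not bm.has_maa(ext)
        assert found == 100
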