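"""Dependency graph, SCC detection, loop fixes, GML round trip, statistics."""

import networkx as nx
import pytest

from siglogic.boolean_model import BooleanSystem, SignallingEvent, classify_signals
from siglogic.curation import (
    AmbiguousMotifError,
    apply_catalysis_fix,
    apply_dissociation_fix,
    build_dependency_graph,
    classification_delta,
    curate_all,
    export_gml,
    find_sccs,
    graph_statistics,
    import_curated_gml,
)
from siglogic.fixtures import (
    FixtureSpec, mek_erk_model, random_system, toy_loop_model,
)
from siglogic.ilp_encoding import enumerate_satisfying, to_cnf
from siglogic.problems import brute_force_minimal_input_sets, minimum_input


def naive_scc_oracle(graph):
    """u, v share an SCC iff mutually reachable (reference implementation)."""
    reach = {n: set(nx.descendants(graph, n)) | {n} for n in graph.nodes}
    comps = set()
    for u in graph.nodes:
        comp = frozenset(v for v in reach[u] if u in reach[v])
        comps.add(comp)
    return {c for c in comps
            if len(c) >= 2 or graph.has_edge(next(iter(c)), next(iter(c)))}


class TestDependencyGraph:
    def test_single_event_graph(self):
        sysm = BooleanSystem.from_events(
            [SignallingEvent("r", frozenset({"S1"}), frozenset({"S2"}))])
        g = build_dependency_graph(sysm)
        assert set(g.nodes) == {"S1", "r", "S2"}
        assert set(g.edges) == {("S1", "r"), ("r", "S2")}

    def test_toy_loop_has_ten_nodes_ten_edges(self):
        g = build_dependency_graph(toy_loop_model())
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 10

    def test_inhibitor_produces_an_edge(self):
        sysm = BooleanSystem.from_events(
            [SignallingEvent("r", frozenset({"S1"}), frozenset({"S2"}),
                             frozenset({"I"}))])
        assert ("I", "r") in build_dependency_graph(sysm).edges


class TestFindSCCs:
    def test_toy_loop_single_component(self):
        sysm = toy_loop_model()
        report = find_sccs(build_dependency_graph(sysm), sysm)
        assert len(report) == 1
        assert report.components[0] == frozenset(
            {"X", "r_complex", "X:J", "r_convert", "X:J'", "r_dissoc"})
        assert report.classification[0] == "complex-dissociation"

    def test_curated_loop_has_none(self):
        sysm = toy_loop_model(curated=True)
        assert len(find_sccs(build_dependency_graph(sysm), sysm)) == 0

    def test_acyclic_random_fixture_has_none(self):
        for seed in range(5):
            sysm = random_system(FixtureSpec(
                n_inputs=4, n_internal=8, n_events=8, p_reuse=0.3, seed=seed))
            assert len(find_sccs(build_dependency_graph(sysm), sysm)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_naive_reachability_oracle(self, seed):
        sysm = random_system(FixtureSpec(
            n_inputs=3, n_internal=6, n_events=6,
            planted_catalysis=seed % 3, planted_dissociation=seed % 2,
            seed=seed))
        g = build_dependency_graph(sysm)
        assert g.number_of_nodes() <= 50
        report = find_sccs(g, sysm)
        assert set(report.components) == naive_scc_oracle(g)

    def test_deterministic_ordering(self):
        sysm = random_system(FixtureSpec(
            n_inputs=3, n_internal=4, n_events=4,
            planted_catalysis=2, planted_dissociation=1, seed=1))
        g = build_dependency_graph(sysm)
        r1, r2 = find_sccs(g, sysm), find_sccs(g, sysm)
        assert r1.components == r2.components
        mins = [min(c) for c in r1.components]
        assert mins == sorted(mins)


@pytest.fixture
def catalysis_system():
    # C catalyses X -> Y; C also supplied upstream by A
    return BooleanSystem.from_events([
        SignallingEvent("rc", frozenset({"C", "X"}), frozenset({"C", "Y"})),
        SignallingEvent("ra", frozenset({"A"}), frozenset({"C"})),
    ])


class TestCatalysisFix:
    def test_removes_catalyst_from_outputs_only(self, catalysis_system):
        report = find_sccs(build_dependency_graph(catalysis_system),
                           catalysis_system)
        (comp,) = report.components
        assert report.classification == ("catalysis",)
        fixed, action = apply_catalysis_fix(catalysis_system, comp)
        assert action.kind == "remove-catalyst-output"
        ev = fixed.events["rc"]
        assert "C" in ev.inputs and "C" not in ev.outputs
        assert len(find_sccs(build_dependency_graph(fixed), fixed)) == 0

    def test_derivation_statement_dropped_when_sole_producer(self):
        sysm = BooleanSystem.from_events([
            SignallingEvent("rc", frozenset({"C", "X"}), frozenset({"C", "Y"}))])
        report = find_sccs(build_dependency_graph(sysm), sysm)
        fixed, _ = apply_catalysis_fix(sysm, report.components[0])
        assert fixed.derivation_statement("C") is None

    def test_fix_stops_catalyst_bootstrapping(self):
        """Brute-force comparison pre/post on the 4-variable system: the
        uncurated loop lets the catalyst justify itself (C <=> r <=> C & X),
        so Y appears reachable from X alone; after the fix C must genuinely
        be supplied."""
        sysm = BooleanSystem.from_events([
            SignallingEvent("rc", frozenset({"C", "X"}),
                            frozenset({"C", "Y"}))])
        before = brute_force_minimal_input_sets(sysm, {"Y": 1})
        assert before.sets == frozenset({frozenset({"X"})})
        fixed, _ = apply_catalysis_fix(
            sysm, find_sccs(build_dependency_graph(sysm), sysm).components[0])
        after = brute_force_minimal_input_sets(fixed, {"Y": 1})
        assert after.sets == frozenset({frozenset({"C", "X"})})
        assert minimum_input(fixed, {"Y": 1}).objective_value == 2

    def test_non_catalysis_scc_rejected(self):
        # order-2 SCC between two signals cannot arise, so fake one
        with pytest.raises(ValueError):
            apply_catalysis_fix(toy_loop_model(), frozenset({"X", "X:J"}))

    def test_wrong_order_rejected(self, catalysis_system):
        with pytest.raises(ValueError, match="order-2"):
            apply_catalysis_fix(catalysis_system, frozenset({"C"}))

    def test_catalyst_without_other_producer_becomes_source(self):
        sysm = BooleanSystem.from_events([
            SignallingEvent("rc", frozenset({"C", "X"}), frozenset({"C", "Y"}))])
        fixed, _ = apply_catalysis_fix(
            sysm, find_sccs(build_dependency_graph(sysm), sysm).components[0])
        delta = classification_delta(sysm, fixed)
        assert "C" in delta["new_sources"]


class TestDissociationFix:
    def test_toy_loop_unrecycles_x_and_min_input_becomes_two(self):
        sysm = toy_loop_model()
        (comp,) = find_sccs(build_dependency_graph(sysm), sysm).components
        fixed, action = apply_dissociation_fix(sysm, comp)
        assert (action.event_id, action.signal_id) == ("r_dissoc", "X")
        assert "X" not in fixed.events["r_dissoc"].outputs
        assert minimum_input(fixed, {"J'": 1}).objective_value == 2
        assert len(find_sccs(build_dependency_graph(fixed), fixed)) == 0

    def test_matches_pre_curated_fixture(self):
        sysm = toy_loop_model()
        (comp,) = find_sccs(build_dependency_graph(sysm), sysm).components
        fixed, _ = apply_dissociation_fix(sysm, comp)
        curated = toy_loop_model(curated=True)
        assert set(fixed.statements) == set(curated.statements)

    def test_mek_erk_motif(self):
        """The kinase-complex loop: MEK recycling removed, phosphorylated
        product still derivable."""
        sysm = mek_erk_model()
        report = find_sccs(build_dependency_graph(sysm), sysm)
        (comp,) = report.components
        assert report.classification == ("complex-dissociation",)
        fixed, action = apply_dissociation_fix(sysm, comp)
        assert (action.event_id, action.signal_id) == ("r_dissoc", "MEK")
        res = minimum_input(fixed, {"ERKp": 1})
        assert res.optimal and res.objective_value == 2  # both upstream inputs

    def test_deleting_formation_edge_instead_is_wrong(self):
        """Negative control: a depth-first automatic strategy may delete
        the complex-formation dependency, after which the complex forms
        without its reactant -- the undesirable outcome the manual fix
        avoids."""
        sysm = toy_loop_model()
        ev = sysm.events["r_complex"]
        ev.inputs = ev.inputs - {"X"}  # simulate deleting edge X -> r_complex
        sysm.recompile()
        # complex achievable with only J supplied: X is never demanded
        bad = brute_force_minimal_input_sets(sysm, {"X:J": 1})
        assert bad.sets == frozenset({frozenset({"J"})})
        # whereas after the proper fix both inputs are required
        good = brute_force_minimal_input_sets(
            toy_loop_model(curated=True), {"X:J": 1})
        assert good.sets == frozenset({frozenset({"I", "J"})})

    def test_ambiguous_motif_requires_choice(self):
        # two recycled reactants from the same dissociation event
        sysm = BooleanSystem.from_events([
            SignallingEvent("r_f", frozenset({"A", "B"}), frozenset({"AB"})),
            SignallingEvent("r_m", frozenset({"AB"}), frozenset({"ABm"})),
            SignallingEvent("r_d", frozenset({"ABm"}),
                            frozenset({"A", "B", "P"})),
        ])
        (comp,) = find_sccs(build_dependency_graph(sysm), sysm).components
        with pytest.raises(AmbiguousMotifError) as exc:
            apply_dissociation_fix(sysm, comp)
        assert ("r_d", "A") in exc.value.candidates
        fixed, action = apply_dissociation_fix(sysm, comp,
                                               recycled=("r_d", "A"))
        assert action.signal_id == "A"

    def test_non_matching_scc_rejected(self, catalysis_system):
        (comp,) = find_sccs(build_dependency_graph(catalysis_system),
                            catalysis_system).components
        with pytest.raises(ValueError, match="dissociation motif"):
            apply_dissociation_fix(catalysis_system, comp)


class TestCurateAll:
    @pytest.mark.parametrize("n_cat, n_dis", [(3, 2), (1, 0), (0, 2)])
    def test_planted_motifs_fully_resolved(self, n_cat, n_dis):
        sysm = random_system(FixtureSpec(
            n_inputs=4, n_internal=6, n_events=6,
            planted_catalysis=n_cat, planted_dissociation=n_dis, seed=11))
        report = find_sccs(build_dependency_graph(sysm), sysm)
        assert len(report) == n_cat + n_dis
        curated, actions = curate_all(sysm)
        assert len(actions) == n_cat + n_dis
        assert len(find_sccs(build_dependency_graph(curated), curated)) == 0

    def test_actions_strictly_decrease_edge_count(self):
        sysm = random_system(FixtureSpec(
            n_inputs=3, n_internal=4, n_events=4,
            planted_catalysis=2, planted_dissociation=1, seed=3))
        edges = build_dependency_graph(sysm).number_of_edges()
        sccs = len(find_sccs(build_dependency_graph(sysm), sysm))
        curated = sysm
        while True:
            report = find_sccs(build_dependency_graph(curated), curated)
            fixable = [
                (c, k) for c, k in zip(report.components, report.classification)
                if k in ("catalysis", "complex-dissociation")]
            if not fixable:
                break
            comp, kind = fixable[0]
            if kind == "catalysis":
                curated, _ = apply_catalysis_fix(curated, comp)
            else:
                curated, _ = apply_dissociation_fix(curated, comp)
            new_edges = build_dependency_graph(curated).number_of_edges()
            new_sccs = len(find_sccs(build_dependency_graph(curated), curated))
            assert new_edges < edges
            assert new_sccs <= sccs
            edges, sccs = new_edges, new_sccs


class TestGMLRoundTrip:
    def test_unedited_round_trip_is_identity(self, tmp_path):
        sysm = toy_loop_model()
        path = tmp_path / "model.gml"
        export_gml(sysm, path, provenance="test")
        back = import_curated_gml(sysm, path)
        assert set(back.statements) == set(sysm.statements)

    def test_deleting_recycling_edge_equals_dissociation_fix(self, tmp_path):
        sysm = toy_loop_model()
        path = tmp_path / "model.gml"
        export_gml(sysm, path)
        g = nx.read_gml(path)
        g.remove_edge("r_dissoc", "X")
        nx.write_gml(g, path)
        edited = import_curated_gml(sysm, path)
        curated = toy_loop_model(curated=True)
        assert set(edited.statements) == set(curated.statements)

    def test_node_deletion_removes_incident_statements(self, tmp_path):
        sysm = toy_loop_model()
        path = tmp_path / "model.gml"
        export_gml(sysm, path)
        g = nx.read_gml(path)
        g.remove_node("r_X")
        nx.write_gml(g, path)
        edited = import_curated_gml(sysm, path)
        assert "r_X" not in edited.events
        assert all(st.consequent != "r_X" for st in edited.statements)

    def test_unknown_nodes_rejected(self, tmp_path):
        sysm = toy_loop_model()
        path = tmp_path / "model.gml"
        g = nx.DiGraph()
        g.add_node("mystery", label="m", cls="signal")
        nx.write_gml(g, path)
        with pytest.raises(ValueError, match="unknown nodes"):
            import_curated_gml(sysm, path)

    def test_malformed_gml_rejected(self, tmp_path):
        path = tmp_path / "bad.gml"
        path.write_text("this is { not gml ]")
        with pytest.raises(ValueError, match="cannot parse"):
            import_curated_gml(toy_loop_model(), path)


class TestGraphStatistics:
    def test_single_event_statistics(self):
        sysm = BooleanSystem.from_events(
            [SignallingEvent("r", frozenset({"S1"}), frozenset({"S2"}))])
        stats = graph_statistics(build_dependency_graph(sysm), sysm)
        assert stats.order == 3 and stats.size == 2
        assert stats.diameter == 2 and stats.radius == 1
        assert stats.n_nontrivial_sccs == 0
        assert stats.n_sources == 1 and stats.n_sinks == 1
        assert stats.max_indegree == 1 and stats.max_outdegree == 1
        assert stats.characteristic_path_length == pytest.approx(4 / 3)
        # each node has exactly one undirected neighbour except r (two)
        assert stats.avg_neighbours == pytest.approx(4 / 3)

    def test_toy_loop_statistics(self):
        sysm = toy_loop_model()
        stats = graph_statistics(build_dependency_graph(sysm), sysm)
        assert stats.order == 10 and stats.size == 10
        assert stats.n_nontrivial_sccs == 1
        assert stats.n_sources == 2 and stats.n_sinks == 1

    def test_curation_reduces_size_and_sccs(self):
        before = graph_statistics(
            build_dependency_graph(toy_loop_model()), toy_loop_model())
        after_sys = toy_loop_model(curated=True)
        after = graph_statistics(build_dependency_graph(after_sys), after_sys)
        assert after.size < before.size
        assert after.n_nontrivial_sccs == 0
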