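import pytest

from metahub import fixtures
from metahub.disease_map import (DiseaseMap, core_equation, hub_of_hubs,
                                 participating_genes, read_map, superimpose,
                                 write_map)
from metahub.synthetic_data import SyntheticSpec, gen_disease_maps


@pytest.fixture
def core_map():
    return fixtures.load_three_disease_map()


class TestReadMap:
    def test_shipped_fixture_counts(self, core_map):
        assert len(core_map.edges) == 9
        assert len(core_map.nodes) == 9
        assert "IFNG" in core_map.isolated

    def test_empty_file_gives_empty_map(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("source\ttarget\teffect\tdisease\n")
        m = read_map(p)
        assert not m.edges and not m.nodes

    def test_unknown_effect_errors(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("A\tB\tphosphorylates\tT2DM\n")
        with pytest.raises(ValueError, match="phosphorylates"):
            read_map(p)

    def test_self_edge_errors_with_line(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("A\tA\tactivate\tT2DM\n")
        with pytest.raises(ValueError, match=":1"):
            read_map(p)

    def test_round_trip(self, tmp_path, core_map):
        out = tmp_path / "again.tsv"
        write_map(core_map, out)
        again = read_map(out)
        assert again.edges == core_map.edges
        assert again.nodes == core_map.nodes


class TestSuperimpose:
    def test_identical_maps_keep_everything_at_full_support(self, core_map):
        maps = fixtures.per_disease_core_maps()
        smap = superimpose(maps)
        assert smap.edges == core_map.edges
        assert set(smap.support.values()) == {3}

    def test_min_support_threshold(self):
        shared = {("A", "B"): "activate"}
        m1 = DiseaseMap("d1", {**shared, ("C", "D"): "inhibit"})
        m2 = DiseaseMap("d2", {**shared, ("C", "D"): "inhibit"})
        m3 = DiseaseMap("d3", dict(shared))
        assert ("C", "D") not in superimpose([m1, m2, m3], 3).edges
        kept = superimpose([m1, m2, m3], 2)
        assert kept.support[("C", "D")] == 2

    def test_conflicting_effects_collapse_to_regulate(self):
        m1 = DiseaseMap("d1", {("A", "B"): "activate"})
        m2 = DiseaseMap("d2", {("A", "B"): "inhibit"})
        assert superimpose([m1, m2]).edges[("A", "B")] == "regulate"

    def test_support_bounds_and_map_count_errors(self):
        m = DiseaseMap("d", {("A", "B"): "activate"})
        with pytest.raises(ValueError):
            superimpose([m])
        with pytest.raises(ValueError):
            superimpose([m, m], 3)

    def test_union_and_intersection_limits(self):
        for seed in range(10):
            maps_raw, truth = gen_disease_maps(SyntheticSpec(rng_seed=seed))
            maps = [DiseaseMap(d, dict(e)) for d, e in maps_raw.items()]
            inter = superimpose(maps, len(maps))
            assert sorted([u, v] for u, v in inter.edges) == truth.map_core_edges
            union = superimpose(maps, 1)
            all_pairs = {p for m in maps for p in m.edges}
            assert set(union.edges) == all_pairs


class TestHubOfHubs:
    def test_fixture_hub_is_akt1_reaching_six(self, core_map):
        smap = superimpose(fixtures.per_disease_core_maps())
        assert hub_of_hubs(smap) == ("AKT1", 6)

    def test_single_edge_lexicographic_tie(self):
        m = DiseaseMap("d", {("A", "B"): "activate"})
        smap = superimpose([m, m])
        assert hub_of_hubs(smap) == ("A", 1)

    def test_out_star_center_wins(self):
        m = DiseaseMap("d", {("C", f"L{i}"): "activate" for i in range(4)})
        smap = superimpose([m, m])
        assert hub_of_hubs(smap) == ("C", 4)

    def test_connectivity_bounded_by_node_count(self):
        for seed in range(5):
            maps_raw, _ = gen_disease_maps(SyntheticSpec(rng_seed=seed))
            maps = [DiseaseMap(d, dict(e)) for d, e in maps_raw.items()]
            smap = superimpose(maps, 1)
            _, conn = hub_of_hubs(smap)
            assert conn <= len(smap.nodes) - 1

    def test_edgeless_map_errors(self):
        m = DiseaseMap("d", {}, isolated={"A"})
        smap = superimpose([m, m], 1)
        with pytest.raises(ValueError):
            hub_of_hubs(smap)


class TestCoreEquation:
    def test_fixture_equation_has_six_nodes(self):
        smap = superimpose(fixtures.per_disease_core_maps())
        eq = core_equation(smap, "AKT1")
        assert eq.inputs == {"EGFR", "CD44"}
        assert eq.outputs == {"NFKB1", "STAT3", "MMP9"}
        assert eq.node_count == 6
        assert str(eq) == "CD44,EGFR=>AKT1=>MMP9+NFKB1+STAT3"

    def test_isolated_hub_gives_trivial_equation(self):
        m = DiseaseMap("d", {("A", "B"): "activate"}, isolated={"Z"})
        smap = superimpose([m, m])
        eq = core_equation(smap, "Z")
        assert eq.node_count == 1 and not eq.inputs and not eq.outputs

    def test_node_count_identity_everywhere(self):
        smap = superimpose(fixtures.per_disease_core_maps())
        for hub in smap.nodes:
            eq = core_equation(smap, hub)
            assert eq.node_count == len(eq.inputs) + len(eq.outputs) + 1

    def test_absent_hub_errors(self):
        m = DiseaseMap("d", {("A", "B"): "activate"})
        with pytest.raises(ValueError):
            core_equation(superimpose([m, m]), "Q")


class TestParticipatingGenes:
    def test_fixture_excludes_isolated_ifng(self):
        smap = superimpose(fixtures.per_disease_core_maps())
        part = participating_genes(smap, set(fixtures.PRIORITIZED_CANDIDATES))
        assert len(part) == 8
        assert "IFNG" not in part

    def test_disjoint_candidates_empty(self):
        smap = superimpose(fixtures.per_disease_core_maps())
        assert participating_genes(smap, {"ZZZ9"}) == set()

    def test_all_nodes_returns_non_isolated(self):
        smap = superimpose(fixtures.per_disease_core_maps())
        assert participating_genes(smap, smap.nodes) == smap.nodes - {"IFNG"}


class TestWiringRobustness:
    """The published downstream wiring is ambiguous between MMP1/MMP9 targets;
    the headline quantities must not depend on which reading is pinned."""

    # readings consistent with "their downstream gene targets MMP1 and MMP9":
    # each downstream gene is targeted by at least one of NFKB1/STAT3
    ALT_WIRINGS = [
        {("NFKB1", "MMP9"), ("STAT3", "MMP1")},  # shipped reading
        {("NFKB1", "MMP1"), ("STAT3", "MMP9")},  # swapped
        {("NFKB1", "MMP1"), ("NFKB1", "MMP9"),
         ("STAT3", "MMP1"), ("STAT3", "MMP9")},  # both target both
    ]

    @pytest.mark.parametrize("downstream", ALT_WIRINGS)
    def test_hub_equation_and_participants_invariant(self, downstream):
        base = {
            ("EGFR", "AKT1"): "activate", ("CD44", "AKT1"): "activate",
            ("AKT1", "NFKB1"): "activate", ("AKT1", "STAT3"): "activate",
            ("AKT1", "MMP9"): "activate",
            ("CTNNB1", "MMP1"): "activate", ("CTNNB1", "MMP9"): "activate",
        }
        for u, v in downstream:
            base[(u, v)] = "activate"
        maps = [DiseaseMap(d, dict(base), isolated={"IFNG"}) for d in "xyz"]
        smap = superimpose(maps)
        hub, _ = hub_of_hubs(smap)
        assert hub == "AKT1"
        assert core_equation(smap, hub).node_count == 6
        part = participating_genes(smap, set(fixtures.PRIORITIZED_CANDIDATES))
        assert len(part) == 8
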