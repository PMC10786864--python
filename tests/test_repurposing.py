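import itertools

import numpy as np
import pytest

from oracles import count_conformer_pairs
from ppirep.repurposing import (CandidatePair, build_network, coverage_stats,
                                enumerate_conformer_pairs, region_filter,
                                repurpose_from, repurpose_to,
                                write_candidate_table)
from ppirep.similarity import InterfaceCluster


def _network(edges, conformers=None, pathway=frozenset()):
    rows = ["acc_a\tacc_b\tscore"] + [f"{a}\t{b}\t{s}" for a, b, s in edges]
    return build_network("\n".join(rows) + "\n", set(pathway),
                         conformer_counts=conformers or {})


class TestBuildNetwork:
    @pytest.mark.parametrize("score,kept", [(0.899, 0), (0.900, 1), (0.95, 1)])
    def test_confidence_threshold(self, score, kept):
        net = _network([("P1", "P2", score)])
        assert len(net.edges) == kept

    def test_duplicate_rows_collapse(self):
        net = _network([("P1", "P2", 0.91), ("P2", "P1", 0.93)])
        assert net.edges == [("P1", "P2")]

    def test_string_combined_score_normalized(self):
        text = "acc_a\tacc_b\tcombined_score\nP1\tP2\t950\nP2\tP3\t899\n"
        net = build_network(text, set())
        assert net.edges == [("P1", "P2")]

    def test_pathway_flag_and_unknown_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            net = _network([("P1", "P2", 0.95)], pathway={"P1", "MISSING"})
        assert net.graph.nodes["P1"]["in_pathway"]
        assert not net.graph.nodes["P2"]["in_pathway"]
        assert any("MISSING" in r.message for r in caplog.records)


class TestConformerPairs:
    @pytest.mark.parametrize("n_u,n_v,expected", [(3, 2, 6), (1, 1, 1),
                                                  (4, 5, 20)])
    def test_hetero_edge_product(self, n_u, n_v, expected):
        net = _network([("U", "V", 0.95)], {"U": n_u, "V": n_v})
        total, per_edge = enumerate_conformer_pairs(net)
        assert total == expected == per_edge[("U", "V")]

    def test_self_edge_unordered_with_repeats(self):
        net = _network([("U", "U", 0.95)], {"U": 3})
        total, _ = enumerate_conformer_pairs(net)
        assert total == 6  # 3 homo-pairs + 3 hetero-pairs of conformers

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"P{i}" for i in range(6)]
        edges = []
        for a, b in itertools.combinations_with_replacement(names, 2):
            if rng.random() < 0.4:
                edges.append((a, b, 0.95))
        if not edges:
            edges = [("P0", "P1", 0.95)]
        conformers = {n: int(rng.integers(1, 5)) for n in names}
        net = _network(edges, conformers)
        total, _ = enumerate_conformer_pairs(net)
        assert total == count_conformer_pairs(net.graph.edges, conformers)


class TestCoverage:
    def _net72(self):
        edges = [(f"A{i}", f"B{i}", 0.95) for i in range(72)]
        return _network(edges)

    @pytest.mark.parametrize("n_real,percent", [(15, 21), (66, 92), (0, 0)])
    def test_percentages(self, n_real, percent):
        net = self._net72()
        realized = set(net.edges[:n_real])
        stats = coverage_stats(net, realized)
        assert stats == (n_real, 72, percent)

    def test_monotone_in_realized_set(self):
        net = self._net72()
        prev = -1
        for k in (0, 10, 40, 72):
            pct = coverage_stats(net, set(net.edges[:k])).percent
            assert pct >= prev
            prev = pct
        assert 0 <= prev <= 100

    def test_realized_must_be_subset(self):
        net = _network([("P1", "P2", 0.95)])
        with pytest.raises(ValueError):
            coverage_stats(net, {("P1", "P9")})


class _FakeBinding:
    def __init__(self, code, iface):
        self.ligand_code = code
        self.interface_id = iface


def _cluster(cid, members):
    return InterfaceCluster(cid, frozenset(members), 0.311)


class TestRepurposing:
    def test_to_basic_pair(self):
        clusters = [_cluster(0, {"I_drug", "I_path"})]
        pairs = repurpose_to(clusters, [_FakeBinding("TPV", "I_drug")],
                             {"I_path"})
        assert [(p.drug, p.target_interface, p.direction) for p in pairs] == \
            [("TPV", "I_path", "to")]
        assert pairs[0].sources == ("I_drug",)

    def test_to_source_equals_target_excluded(self):
        clusters = [_cluster(0, {"I_path"})]
        assert repurpose_to(clusters, [_FakeBinding("TPV", "I_path")],
                            {"I_path"}) == []

    def test_to_cross_product_matches_brute_force(self):
        members = {"D1", "D2", "T1", "T2", "T3"}
        clusters = [_cluster(0, members)]
        bindings = [_FakeBinding("TPV", "D1"), _FakeBinding("MK1", "D2")]
        pathway = {"T1", "T2", "T3"}
        pairs = repurpose_to(clusters, bindings, pathway)
        brute = {(b.ligand_code, t) for b in bindings for t in pathway
                 if t != b.interface_id}
        assert {(p.drug, p.target_interface) for p in pairs} == brute
        assert len(pairs) == 6

    def test_from_mirror(self):
        clusters = [_cluster(0, {"I_path", "I_out", "I_path2"})]
        pairs = repurpose_from(clusters, [_FakeBinding("GNT", "I_path")],
                               {"I_path", "I_path2"})
        assert [(p.drug, p.target_interface, p.direction) for p in pairs] == \
            [("GNT", "I_out", "from")]

    def test_from_pathway_target_excluded(self):
        clusters = [_cluster(0, {"I_path", "I_path2"})]
        assert repurpose_from(clusters, [_FakeBinding("GNT", "I_path")],
                              {"I_path", "I_path2"}) == []

    def test_from_cross_product_matches_brute_force(self):
        members = {"P1", "P2", "O1", "O2"}
        clusters = [_cluster(0, members)]
        pathway = {"P1", "P2"}
        bindings = [_FakeBinding("GNT", "P1"), _FakeBinding("CWB", "P2")]
        pairs = repurpose_from(clusters, bindings, pathway)
        brute = {(b.ligand_code, t) for b in bindings
                 for t in members - pathway}
        assert {(p.drug, p.target_interface) for p in pairs} == brute

    def test_no_cross_cluster_pairs_and_dedup(self):
        clusters = [_cluster(0, {"D1", "T1"}), _cluster(1, {"D2", "T2"})]
        bindings = [_FakeBinding("TPV", "D1"), _FakeBinding("TPV", "D1")]
        pairs = repurpose_to(clusters, bindings, {"T1", "T2"})
        assert {(p.drug, p.target_interface) for p in pairs} == {("TPV", "T1")}
        assert len(pairs) == 1

    def test_multiple_sources_collapse_with_provenance(self):
        clusters = [_cluster(0, {"D1", "D2", "T1"})]
        bindings = [_FakeBinding("TPV", "D1"), _FakeBinding("TPV", "D2")]
        pairs = repurpose_to(clusters, bindings, {"T1"})
        assert len(pairs) == 1
        assert set(pairs[0].sources) == {"D1", "D2"}

    def test_determinism_under_input_reordering(self):
        clusters = [_cluster(0, {"D1", "T1", "T2"})]
        bindings = [_FakeBinding("TPV", "D1"), _FakeBinding("MK1", "D1")]
        fwd = repurpose_to(clusters, bindings, {"T1", "T2"})
        rev = repurpose_to(clusters, list(reversed(bindings)), {"T2", "T1"})
        assert write_candidate_table(fwd) == write_candidate_table(rev)


class TestRegionFilter:
    def _pair(self, source, target):
        return CandidatePair("TPV", target, "to", 0, (source,))

    def test_opposite_sides_removed(self):
        pairs = [self._pair("S", "T")]
        regions = {"S": "extracellular", "T": "intracellular"}
        assert region_filter(pairs, regions) == []

    def test_same_side_retained(self):
        pairs = [self._pair("S", "T")]
        regions = {"S": "extracellular", "T": "extracellular"}
        assert region_filter(pairs, regions) == pairs

    def test_transmembrane_compatible(self):
        pairs = [self._pair("S", "T")]
        regions = {"S": "transmembrane", "T": "intracellular"}
        assert region_filter(pairs, regions) == pairs

    def test_unannotated_retained_with_warning(self, caplog):
        import logging
        pairs = [self._pair("S", "T")]
        with caplog.at_level(logging.WARNING):
            kept = region_filter(pairs, {"S": "extracellular"})
        assert kept == pairs
        assert any("unannotated" in r.message for r in caplog.records)
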