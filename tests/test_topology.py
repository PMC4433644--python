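"""Degrees, scaled connectivity, hub calls and connecting scores."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from modmir.exceptions import InputError
from modmir.network import Module
from modmir.topology import (
    call_hubs,
    connecting_scores,
    maoc_degrees,
    scaled_connectivity,
    top_connectors,
    topology_report,
)


def mod(mid, members):
    return Module(module_id=mid, members=tuple(members), score=0.0, p_value=0.0,
                  n_scored=len(members))


class TestDegrees:
    def test_isolated_4clique(self):
        net = nx.complete_graph(["A", "B", "C", "D"])
        degrees, k_max = maoc_degrees(net, [mod("M1", "ABCD")])
        assert set(degrees.values()) == {3}
        assert k_max == 3

    def test_two_disjoint_triangles(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"),
                        ("X", "Y"), ("Y", "Z"), ("X", "Z")])
        degrees, k_max = maoc_degrees(net, [mod("M1", "ABC"), mod("M2", "XYZ")])
        assert all(k == 2 for k in degrees.values())
        assert k_max == 2

    def test_degrees_match_neighbor_scan(self, rng):
        net = nx.gnp_random_graph(15, 0.4, seed=3)
        net = nx.relabel_nodes(net, {i: f"g{i:02d}" for i in range(15)})
        members = sorted(net.nodes)
        degrees, k_max = maoc_degrees(net, [mod("M1", members)], scope="induced")
        for g in members:
            assert degrees[g] == sum(1 for _ in net.neighbors(g))
        assert k_max == max(degrees.values())

    def test_full_scope_counts_outside_edges(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("A", "OUT")])
        maocs = [mod("M1", "ABC")]
        induced, _ = maoc_degrees(net, maocs, scope="induced")
        full, _ = maoc_degrees(net, maocs, scope="full")
        assert induced["A"] == 2 and full["A"] == 3

    def test_empty_union_is_an_error(self):
        with pytest.raises(InputError):
            maoc_degrees(nx.Graph([("A", "B")]), [mod("M1", ["ZZ"])])


class TestHubs:
    def test_printed_degree_profile_yields_four_hubs(self):
        degrees = {"H1": 17, "H2": 16, "H3": 16, "H4": 16, "L1": 10, "L2": 5}
        hubs = call_hubs(degrees, 17, threshold=0.9)
        assert hubs == ["H1", "H2", "H3", "H4"]  # 16/17 > 0.9; 10/17 is not

    def test_all_equal_degrees_all_hubs(self):
        degrees = {"A": 4, "B": 4, "C": 4}
        assert set(call_hubs(degrees, 4, 0.9)) == {"A", "B", "C"}

    def test_strict_inequality_at_threshold_one(self):
        degrees = {"A": 4, "B": 4}
        assert call_hubs(degrees, 4, threshold=1.0) == []

    def test_scaled_connectivity_bounds_and_argmax(self):
        degrees = {"A": 7, "B": 3, "C": 7}
        K = scaled_connectivity(degrees, 7)
        assert all(0 <= v <= 1 for v in K.values())
        assert {g for g, v in K.items() if v == 1.0} == {"A", "C"}


def star_of_modules():
    """Three disjoint triangles plus an outside gene touching each."""
    net = nx.Graph()
    for mid, trio in (("M1", "ABC"), ("M2", "DEF"), ("M3", "GHI")):
        a, b, c = trio
        net.add_edges_from([(a, b), (b, c), (a, c)])
    net.add_edges_from([("OUT", "A"), ("OUT", "D"), ("OUT", "G")])
    maocs = [mod("M1", "ABC"), mod("M2", "DEF"), mod("M3", "GHI")]
    return net, maocs


class TestConnectingScores:
    def test_gene_with_only_own_module_neighbors_is_not_a_connector(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        intra, inter = connecting_scores(net, [mod("M1", "ABC")])
        assert len(intra) == 0 and len(inter) == 0

    def test_outside_gene_touching_three_modules(self):
        net, maocs = star_of_modules()
        intra, inter = connecting_scores(net, maocs)
        assert list(inter["gene"]) == ["OUT"]
        assert int(inter["cs"].iloc[0]) == 3

    def test_intra_score_counts_other_modules_only(self):
        # A in M1 links to D in M2 -> CS 1; membership itself is not linkage
        net, maocs = star_of_modules()
        net.add_edge("A", "D")
        intra, _ = connecting_scores(net, maocs)
        row = intra[intra["gene"] == "A"]
        assert int(row["cs"].iloc[0]) == 1

    def test_gene_in_every_module_has_zero_intra_cs(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("A", "D")])
        maocs = [mod("M1", "ABC"), mod("M2", "AD")]
        intra, _ = connecting_scores(net, maocs)
        assert "A" not in set(intra["gene"])

    def test_matches_exhaustive_pair_scan(self, rng):
        net = nx.gnp_random_graph(30, 0.15, seed=9)
        net = nx.relabel_nodes(net, {i: f"g{i:02d}" for i in range(30)})
        nodes = sorted(net.nodes)
        maocs = [mod(f"M{i}", nodes[i * 5 : i * 5 + 5]) for i in range(4)]
        intra, inter = connecting_scores(net, maocs, min_modules=1)
        membership = {}
        for m in maocs:
            for g in m.members:
                membership.setdefault(g, set()).add(m.module_id)
        for g in nodes:
            nbrs = set(net.neighbors(g))
            linked = {
                m.module_id for m in maocs if nbrs & set(m.members)
            }
            own = membership.get(g, set())
            if own:
                expect = len(linked - own)
                got = intra.loc[intra["gene"] == g, "cs"]
                assert (int(got.iloc[0]) if len(got) else 0) == expect
            else:
                got = inter.loc[inter["gene"] == g, "cs"]
                assert (int(got.iloc[0]) if len(got) else 0) == len(linked)

    def test_edge_removal_never_increases_scores(self):
        net, maocs = star_of_modules()
        net.add_edge("A", "D")
        before_intra, before_inter = connecting_scores(net, maocs, min_modules=1)
        net2 = net.copy()
        net2.remove_edge("OUT", "D")
        after_intra, after_inter = connecting_scores(net2, maocs, min_modules=1)
        b = dict(zip(before_inter["gene"], before_inter["cs"]))
        a = dict(zip(after_inter["gene"], after_inter["cs"]))
        for g, cs in a.items():
            assert cs <= b.get(g, 0) or g not in b
        bi = dict(zip(before_intra["gene"], before_intra["cs"]))
        ai = dict(zip(after_intra["gene"], after_intra["cs"]))
        for g, cs in ai.items():
            assert cs <= bi.get(g, cs)


class TestTopConnectors:
    def test_first_n_under_sort_order(self):
        df = pd.DataFrame(
            {"gene": list("ABCDEF"), "cs": [8, 7, 6, 6, 4, 3], "degree": [1] * 6}
        )
        top = top_connectors(df, 5)
        assert list(top["gene"]) == list("ABCDE")

    def test_fewer_candidates_than_n(self):
        df = pd.DataFrame({"gene": ["A"], "cs": [2], "degree": [1]})
        assert len(top_connectors(df, 5)) == 1

    def test_matches_independent_sort(self, rng):
        df = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(20)],
                "cs": rng.integers(0, 6, size=20),
                "degree": rng.integers(1, 10, size=20),
            }
        ).sort_values(["cs", "degree", "gene"], ascending=[False, False, True]).reset_index(drop=True)
        top = top_connectors(df, 7)
        ref = sorted(
            df.to_dict("records"), key=lambda r: (-r["cs"], -r["degree"], r["gene"])
        )[:7]
        assert top.to_dict("records") == ref


class TestReport:
    def test_roles_and_columns(self):
        net, maocs = star_of_modules()
        net.add_edge("A", "D")
        report = topology_report(net, maocs, min_modules=2)
        assert set(report.columns) == {"gene", "degree", "K", "roles", "cs", "member_of"}
        out_row = report[report["gene"] == "OUT"]
        assert out_row["roles"].iloc[0] == "inter_maoc"
        a_row = report[report["gene"] == "A"]
        assert "intra_maoc" in a_row["roles"].iloc[0]
        assert a_row["member_of"].iloc[0] == "M1"
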