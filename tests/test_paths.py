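"""Path enumeration against a recursive brute-force oracle, and the
essentiality metric on the published worked examples."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from grnctx.network import GRN
from grnctx.paths import (
    PathExplosionError,
    PathSet,
    enumerate_simple_paths,
    essentiality,
    rank_regulators,
)
from tests.conftest import make_grn

# published worked examples: species -> (N_TP, {gene: N_jP}, rounded EM)
TABLE_ROWS = {
    "mouse": (92, [("IRF1", 14, 0.85), ("CEBPB", 15, 0.84), ("CEBPD", 18, 0.80),
                   ("PRDM1", 22, 0.76), ("STAT1", 26, 0.72), ("JUNB", 45, 0.51)]),
    "human": (100, [("IRF1", 27, 0.73), ("ETS2", 44, 0.56), ("FOS", 46, 0.54),
                    ("VDR", 57, 0.43), ("RUNX1", 65, 0.35), ("RARA", 70, 0.30),
                    ("STAT4", 73, 0.27)]),
}


def brute_force_paths(g: nx.DiGraph, source, target):
    """Independent recursive simple-path enumerator."""
    out = []

    def walk(node, visited, acc):
        if node == target:
            out.append(tuple(acc))
            return
        for succ in g.successors(node):
            if succ not in visited:
                walk(succ, visited | {succ}, acc + [succ])

    walk(source, {source}, [source])
    return sorted(out)


def membership_pathset(n_total, present_counts, source="LPS", target="IRG1"):
    """Build a PathSet in which gene g rides exactly present_counts[g] paths;
    a per-path private filler node keeps node sequences distinct."""
    paths = []
    for i in range(n_total):
        interior = [g for g, k in sorted(present_counts.items()) if i < k]
        paths.append(tuple([source] + interior + [f"via{i:03d}", target]))
    return PathSet(source=source, target=target, paths=tuple(paths))


class TestEnumeration:
    def test_single_edge(self):
        ps = enumerate_simple_paths(make_grn([("S", "T", "+")]), "S", "T")
        assert ps.paths == (("S", "T"),)
        assert ps.n_total == 1

    def test_diamond(self, diamond_grn):
        ps = enumerate_simple_paths(diamond_grn, "S", "T")
        assert ps.paths == (("S", "A", "T"), ("S", "B", "T"))

    def test_signs_ignored_for_reachability(self):
        ps = enumerate_simple_paths(make_grn([("S", "A", "-"), ("A", "T", "-")]), "S", "T")
        assert ps.n_total == 1

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for trial in range(50):
            n = int(rng.integers(3, 11))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.5)),
                                    seed=int(rng.integers(0, 2**31)), directed=True)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            src, tgt = "n0", f"n{n - 1}"
            ps = enumerate_simple_paths(g, src, tgt)
            assert list(ps.paths) == brute_force_paths(g, src, tgt)

    def test_max_len_caps_path_length(self):
        grn = make_grn([("S", "A", "+"), ("A", "B", "+"), ("B", "T", "+"), ("S", "T", "+")])
        ps = enumerate_simple_paths(grn, "S", "T", max_len=1)
        assert ps.paths == (("S", "T"),)

    def test_path_explosion_guard(self):
        # complete digraph on 10 nodes has >100k simple paths between any pair
        g = nx.complete_graph(10, nx.DiGraph())
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        with pytest.raises(PathExplosionError):
            enumerate_simple_paths(g, "n0", "n9", max_paths=1000)

    def test_source_equals_target_rejected(self, diamond_grn):
        with pytest.raises(ValueError, match="differ"):
            enumerate_simple_paths(diamond_grn, "S", "S")

    def test_absent_node_rejected(self, diamond_grn):
        with pytest.raises(ValueError, match="not in network"):
            enumerate_simple_paths(diamond_grn, "S", "Z")


class TestEssentiality:
    def test_mouse_irf1_row(self):
        ps = membership_pathset(92, {"IRF1": 78})
        n_absent, em, em_round = essentiality(ps, "IRF1")
        assert n_absent == 14
        assert em == Fraction(78, 92)
        assert em_round == 0.85

    def test_gene_on_every_path_scores_one(self, diamond_grn):
        ps = enumerate_simple_paths(diamond_grn, "S", "T")
        assert essentiality(ps, "T") == (0, Fraction(1), 1.0)

    def test_diamond_intermediate(self, diamond_grn):
        ps = enumerate_simple_paths(diamond_grn, "S", "T")
        n_absent, em, em_round = essentiality(ps, "A")
        assert (n_absent, em, em_round) == (1, Fraction(1, 2), 0.5)

    def test_absent_gene_warns_and_scores_zero(self, diamond_grn):
        ps = enumerate_simple_paths(diamond_grn, "S", "T")
        with pytest.warns(UserWarning, match="no"):
            n_absent, em, _ = essentiality(ps, "ZZZ")
        assert em == 0 and n_absent == ps.n_total

    @pytest.mark.parametrize("species", ["mouse", "human"])
    def test_all_published_rows_reproduce(self, species):
        n_total, rows = TABLE_ROWS[species]
        present = {gene: n_total - absent for gene, absent, _ in rows}
        ps = membership_pathset(n_total, present)
        for gene, absent, expected in rows:
            n_absent, _, em_round = essentiality(ps, gene)
            assert n_absent == absent
            assert em_round == expected


class TestRanking:
    @pytest.mark.parametrize("species", ["mouse", "human"])
    def test_published_tables_rank_irf1_first(self, species):
        n_total, rows = TABLE_ROWS[species]
        present = {gene: n_total - absent for gene, absent, _ in rows}
        ranking = rank_regulators(membership_pathset(n_total, present))
        table = ranking.set_index("regulator")
        for gene, absent, expected in rows:
            assert table.loc[gene, "paths_absent"] == absent
            assert table.loc[gene, "essentiality"] == expected
        assert ranking.iloc[0]["regulator"] == "IRF1"
        assert ranking.iloc[0]["rank"] == 1

    def test_single_path_all_intermediates_tie_at_one(self):
        grn = make_grn([("S", "B", "+"), ("B", "A", "+"), ("A", "T", "+")])
        ranking = rank_regulators(enumerate_simple_paths(grn, "S", "T"))
        assert ranking["essentiality"].tolist() == [1.0, 1.0]
        assert ranking["regulator"].tolist() == ["A", "B"]  # alphabetical tie-break
        assert ranking["rank"].tolist() == [1, 1]

    def test_endpoints_excluded_by_default(self, diamond_grn):
        ps = enumerate_simple_paths(diamond_grn, "S", "T")
        assert set(rank_regulators(ps)["regulator"]) == {"A", "B"}
        with_ends = rank_regulators(ps, include_endpoints=True)
        assert {"S", "T"} <= set(with_ends["regulator"])

    def test_em_bounds_and_conservation_identity(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(9, 0.35, seed=42, directed=True)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        ps = enumerate_simple_paths(g, "n0", "n8")
        if ps.n_total == 0:
            pytest.skip("disconnected draw")
        ranking = rank_regulators(ps)
        assert ((ranking["essentiality_exact"] > 0)
                & (ranking["essentiality_exact"] <= 1)).all()
        # sum of per-gene path memberships == total interior node slots
        lhs = sum(ps.n_total - a for a in ranking["paths_absent"])
        rhs = sum(len(p) - 2 for p in ps.paths)
        assert lhs == rhs

    def test_em_one_gene_disconnects_on_removal(self):
        grn = make_grn([("S", "A", "+"), ("A", "T", "+"), ("S", "B", "+"), ("B", "A", "+")])
        ps = enumerate_simple_paths(grn, "S", "T")
        ranking = rank_regulators(ps).set_index("regulator")
        assert ranking.loc["A", "essentiality"] == 1.0
        pruned = GRN(
            [ix for ix in grn.edges.values() if "A" not in (ix.source, ix.target)],
            nodes=grn.nodes - {"A"},
        )
        assert enumerate_simple_paths(pruned, "S", "T").n_total == 0
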