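"""Expected edges, placement distances, EDPL, clade accuracy, assignment."""

from collections import deque

import pytest

from phatpack.errors import ValidationError
from phatpack.evaluation import (
    assign_taxonomy,
    clade_accuracy,
    distance_report,
    edge_distances,
    edge_taxopaths,
    edpl,
    expected_edge,
    weighted_distance,
)
from phatpack.fixtures import make_mock_jplace, make_random_tree
from phatpack.io_formats import (
    EdgeNumberedTree,
    Placement,
    PlacementDocument,
    Pquery,
    Taxopath,
)
from phatpack.multilevel import INNER, CladeAssociation
from phatpack.phat import ConsensusRecord


def T(*ranks):
    return Taxopath(tuple(ranks))


def _rec(label, *ranks):
    return ConsensusRecord(taxopath=T(*ranks), label=label, sequence="A", n_sequences=1)


# -- expected edge -----------------------------------------------------------


def test_expected_edge_longest_prefix_wins():
    tree = EdgeNumberedTree.from_newick("(A.B:0.1{0},A.B.C:0.1{1});", auto_number=False)
    records = [_rec("A.B", "A", "B"), _rec("A.B.C", "A", "B", "C")]
    assert expected_edge(T("A", "B", "C", "D"), records, tree) == 1
    assert expected_edge(T("A", "B"), records, tree) == 0  # exact match
    assert expected_edge(T("X"), records, tree) is None  # unmapped


# -- edge distances ----------------------------------------------------------


def test_same_edge_distance_is_zero():
    tree = make_random_tree(5, seed=0)
    assert edge_distances(tree, 2, 2, distal=0.03) == (0, 0.0)


def test_sibling_terminal_edges_three_tip_tree():
    tree = EdgeNumberedTree.from_newick(
        "((A:0.1{0},B:0.1{1}):0.2{2},C:0.3{3});", auto_number=False
    )
    # attachment at the child end of edge 0 must traverse all of edge 0
    topo, bl = edge_distances(tree, 0, 1, distal=0.0)
    assert topo == 1
    assert bl == pytest.approx(0.1)
    # attachment already at the shared node end
    _, bl2 = edge_distances(tree, 0, 1, distal=0.1)
    assert bl2 == pytest.approx(0.0)


def test_cherry_to_far_tip_of_balanced_four_tip_tree():
    tree = EdgeNumberedTree.from_newick(
        "((A:0.1{0},B:0.1{1}):0.2{2},(C:0.1{3},D:0.1{4}):0.2{5});",
        auto_number=False,
    )
    topo, _ = edge_distances(tree, 0, 3)
    assert topo == 3


def _bfs_oracle_topo(tree, e1, e2):
    """Independent BFS on an adjacency structure derived from node walks."""
    adjacency = {e: set() for e in tree.edge_numbers}
    for node in tree._preorder_nodes():
        incident = [c.edge_num for c in node.children if c.edge_num is not None]
        if node.edge_num is not None:
            incident.append(node.edge_num)
        for a in incident:
            for b in incident:
                if a != b:
                    adjacency[a].add(b)
    seen = {e1: 0}
    queue = deque([e1])
    while queue:
        cur = queue.popleft()
        if cur == e2:
            return seen[cur]
        for nxt in adjacency[cur]:
            if nxt not in seen:
                seen[nxt] = seen[cur] + 1
                queue.append(nxt)
    raise AssertionError("edges not connected")


@pytest.mark.parametrize("n_tips", [4, 6, 8, 10, 12])
def test_topological_distance_matches_bfs_oracle(n_tips):
    for seed in range(4):
        tree = make_random_tree(n_tips, seed=seed)
        for e1 in tree.edge_numbers:
            for e2 in tree.edge_numbers:
                assert tree.topo_distance(e1, e2) == _bfs_oracle_topo(tree, e1, e2)


def test_unknown_edge_is_an_error():
    tree = make_random_tree(4, seed=0)
    with pytest.raises(ValidationError):
        edge_distances(tree, 0, 99)


# -- weighted distance -------------------------------------------------------


def _pq(placements, name="q", mult=1):
    return Pquery(names=[(name, mult)], placements=placements)


def test_weighted_distance_examples():
    tree = EdgeNumberedTree.from_newick(
        "((A:0.1{0},B:0.1{1}):0.2{2},C:0.3{3});", auto_number=False
    )
    single = _pq([Placement(edge_num=3, like_weight_ratio=1.0)])
    assert weighted_distance(single, 3, tree) == (0.0, 0.0)
    split = _pq(
        [
            Placement(edge_num=0, like_weight_ratio=0.7),
            Placement(edge_num=1, like_weight_ratio=0.3, distal_length=0.1),
        ]
    )
    topo, _ = weighted_distance(split, 0, tree)
    assert topo == pytest.approx(0.3)  # 0.7*0 + 0.3*1


def test_weighted_distance_is_convex_combination():
    tree = make_random_tree(8, seed=1)
    pq = _pq(
        [
            Placement(edge_num=0, like_weight_ratio=0.2),
            Placement(edge_num=5, like_weight_ratio=0.5),
            Placement(edge_num=9, like_weight_ratio=0.3),
        ]
    )
    expected = 3
    per_topo = [edge_distances(tree, p.edge_num, expected)[0] for p in pq.placements]
    topo, bl = weighted_distance(pq, expected, tree)
    assert min(per_topo) - 1e-9 <= topo <= max(per_topo) + 1e-9
    assert bl >= 0


def test_weighted_distance_rejects_zero_mass():
    tree = make_random_tree(4, seed=0)
    pq = _pq([Placement(edge_num=0, like_weight_ratio=0.0)])
    with pytest.raises(ValidationError):
        weighted_distance(pq, 0, tree)


# -- EDPL --------------------------------------------------------------------


def test_edpl_single_placement_is_zero():
    tree = make_random_tree(4, seed=0)
    assert edpl(_pq([Placement(edge_num=0, like_weight_ratio=1.0)]), tree) == 0.0


def test_edpl_two_placements_hand_computed():
    # attachments 0.4 apart: 0.2 up edge 0 plus 0.2 up edge 1
    tree = EdgeNumberedTree.from_newick(
        "((A:0.3{0},B:0.3{1}):0.2{2},C:0.5{3});", auto_number=False
    )
    pq = _pq(
        [
            Placement(edge_num=0, like_weight_ratio=0.5, distal_length=0.1),
            Placement(edge_num=1, like_weight_ratio=0.5, distal_length=0.1),
        ]
    )
    assert edpl(pq, tree) == pytest.approx(2 * 0.25 * 0.4)


def test_edpl_three_equiprobable_mutually_equidistant():
    # star tree: attachments at the tips, all pairs 0.3 apart
    tree = EdgeNumberedTree.from_newick(
        "(A:0.15{0},B:0.15{1},C:0.15{2});", auto_number=False
    )
    pq = _pq(
        [Placement(edge_num=e, like_weight_ratio=1 / 3) for e in (0, 1, 2)]
    )
    assert edpl(pq, tree) == pytest.approx(6 * (1 / 9) * 0.3)


def test_edpl_invariant_under_placement_relabeling():
    tree = make_random_tree(6, seed=2)
    placements = [
        Placement(edge_num=0, like_weight_ratio=0.5, distal_length=0.01),
        Placement(edge_num=3, like_weight_ratio=0.3, distal_length=0.02),
        Placement(edge_num=7, like_weight_ratio=0.2, distal_length=0.0),
    ]
    forward = edpl(_pq(placements), tree)
    assert edpl(_pq(placements[::-1]), tree) == pytest.approx(forward)
    assert forward > 0


def test_edpl_normalizes_partial_mass():
    tree = EdgeNumberedTree.from_newick(
        "((A:0.3{0},B:0.3{1}):0.2{2},C:0.5{3});", auto_number=False
    )
    half = _pq(
        [
            Placement(edge_num=0, like_weight_ratio=0.25, distal_length=0.1),
            Placement(edge_num=1, like_weight_ratio=0.25, distal_length=0.1),
        ]
    )
    assert edpl(half, tree) == pytest.approx(0.2)  # same as 0.5/0.5 after norm


# -- clade accuracy ----------------------------------------------------------


def test_clade_accuracy_counts_best_hits():
    tree = EdgeNumberedTree.from_newick(
        "((A:0.1{0},B:0.1{1}):0.2{2},(C:0.1{3},D:0.1{4}):0.2{5});",
        auto_number=False,
    )
    assoc = CladeAssociation(
        {0: "L", 1: "L", 2: "L", 3: "R", 4: "R", 5: INNER}
    )
    pqueries = [
        _pq([Placement(edge_num=0, like_weight_ratio=1.0)], name="a"),
        _pq([Placement(edge_num=1, like_weight_ratio=1.0)], name="b"),
        _pq([Placement(edge_num=3, like_weight_ratio=1.0)], name="c"),
        _pq([Placement(edge_num=5, like_weight_ratio=1.0)], name="d"),
    ]
    doc = PlacementDocument(tree=tree, pqueries=pqueries)
    truth = {"a": "L", "b": "L", "c": "L", "d": "R"}
    result = clade_accuracy(doc, assoc, truth)
    assert result.overall == pytest.approx(0.5)  # c and d are wrong
    assert result.per_label["L"] == pytest.approx(2 / 3)
    assert result.per_label["R"] == 0.0


def test_clade_accuracy_overlap_any_edge_with_label_counts():
    tree = EdgeNumberedTree.from_newick(
        "((A:0.1{0},B:0.1{1}):0.2{2},C:0.1{3});", auto_number=False
    )
    assoc = CladeAssociation({0: "L", 1: "L", 2: "L", 3: INNER})
    pq1 = _pq([Placement(edge_num=0, like_weight_ratio=1.0)], name="x")
    pq2 = _pq([Placement(edge_num=2, like_weight_ratio=1.0)], name="y")
    doc = PlacementDocument(tree=tree, pqueries=[pq1, pq2])
    result = clade_accuracy(doc, assoc, {"x": "L", "y": "L"})
    assert result.overall == 1.0


def test_clade_accuracy_requires_truth_for_all(tmp_path):
    tree = make_random_tree(4, seed=0)
    doc = PlacementDocument(
        tree=tree,
        pqueries=[_pq([Placement(edge_num=0, like_weight_ratio=1.0)], name="q")],
    )
    assoc = CladeAssociation({e: "L" for e in tree.edge_numbers})
    with pytest.raises(ValidationError):
        clade_accuracy(doc, assoc, {})


# -- taxonomic assignment ----------------------------------------------------


@pytest.fixture
def labeled_tree():
    tree = EdgeNumberedTree.from_newick(
        "((A.B.x:0.1{0},A.B.y:0.1{1}):0.2{2},A.C.z:0.3{3});", auto_number=False
    )
    tip_paths = {
        "A.B.x": T("A", "B", "x"),
        "A.B.y": T("A", "B", "y"),
        "A.C.z": T("A", "C", "z"),
    }
    return tree, edge_taxopaths(tree, tip_paths)


def test_edge_taxopaths_internal_edges_use_common_prefix(labeled_tree):
    _, paths = labeled_tree
    assert paths[0] == T("A", "B", "x")
    assert paths[2] == T("A", "B")


def test_assignment_full_mass_on_tip(labeled_tree):
    tree, paths = labeled_tree
    doc = PlacementDocument(
        tree=tree,
        pqueries=[_pq([Placement(edge_num=0, like_weight_ratio=1.0)], name="q")],
    )
    assignments, profile = assign_taxonomy(doc, paths)
    assert assignments["q"] == T("A", "B", "x")
    assert profile[T("A", "B", "x")] == 1


def test_assignment_accumulates_over_shared_prefix(labeled_tree):
    tree, paths = labeled_tree
    doc = PlacementDocument(
        tree=tree,
        pqueries=[
            _pq(
                [
                    Placement(edge_num=0, like_weight_ratio=0.5),
                    Placement(edge_num=1, like_weight_ratio=0.5),
                ],
                name="q",
            )
        ],
    )
    assignments, _ = assign_taxonomy(doc, paths, threshold=0.66)
    assert assignments["q"] == T("A", "B")


def test_assignment_falls_back_to_root(labeled_tree):
    tree, paths = labeled_tree
    doc = PlacementDocument(
        tree=tree,
        pqueries=[
            _pq(
                [
                    Placement(edge_num=0, like_weight_ratio=0.4),
                    Placement(edge_num=3, like_weight_ratio=0.4),
                ],
                name="q",
            )
        ],
    )
    assignments, _ = assign_taxonomy(doc, paths, threshold=0.9)
    assert assignments["q"] == Taxopath(())


def test_assignment_threshold_validation(labeled_tree):
    tree, paths = labeled_tree
    doc = PlacementDocument(tree=tree, pqueries=[])
    with pytest.raises(ValueError):
        assign_taxonomy(doc, paths, threshold=1.5)


# -- report ------------------------------------------------------------------


def test_distance_report_aggregates_and_cumulative_curve():
    tree = make_random_tree(8, seed=5)
    truth = {f"q{i}": e for i, e in enumerate(tree.edge_numbers[:6])}
    doc = make_mock_jplace(tree, truth, noise_radius=1, seed=5)
    report = distance_report(doc, truth)
    assert report.n_unmapped == 0
    assert (report.table["weighted_edge_distance"] <= 1 + 1e-9).all()
    curve = report.cumulative("topo")
    assert (curve["cum_freq"].diff().dropna() >= -1e-12).all()
    assert curve["cum_freq"].iloc[-1] == pytest.approx(1.0)
    assert 0 <= report.fraction_exact() <= 1


def test_distance_report_counts_unmapped():
    tree = make_random_tree(4, seed=0)
    doc = make_mock_jplace(tree, {"a": 0, "b": 1}, seed=0)
    report = distance_report(doc, {"a": 0})
    assert report.n_unmapped == 1
    assert len(report.table) == 1
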