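"""Taxonomy expansion, consensus reference sets, constraint trees."""

import itertools
import math

import pytest

from phatpack.fixtures import FixtureConfig, make_taxonomy_and_alignment
from phatpack.io_formats import EdgeNumberedTree, SequenceSet, Taxopath
from phatpack.phat import (
    build_constraint_tree,
    build_reference_set,
    expand_taxonomy,
    sanitize_label,
)
from phatpack.taxonomy import build_taxonomy


def T(*ranks):
    return Taxopath(tuple(ranks))


def _toy():
    """Root X: 3 children with mutually different sequences (high entropy);
    root Y: a leaf with one sequence (entropy 0)."""
    assignments = [
        ("S1", T("X", "a")),
        ("S2", T("X", "b")),
        ("S3", T("X", "c")),
        ("S4", T("Y")),
    ]
    alignment = SequenceSet(
        [("S1", "AAAA"), ("S2", "CCCC"), ("S3", "GGGG"), ("S4", "TTTT")]
    )
    return build_taxonomy(assignments), alignment


def test_target_equal_to_initial_returns_unchanged():
    taxonomy, alignment = _toy()
    cands = expand_taxonomy(taxonomy, alignment, target_count=2)
    assert {c.name for c in cands.candidates} == {"X", "Y"}
    assert cands.expansion_log == []
    assert cands.taxa_count == 2


def test_most_diverse_clade_expanded_first():
    taxonomy, alignment = _toy()
    cands = expand_taxonomy(taxonomy, alignment, target_count=4)
    assert cands.taxa_count == 4
    assert {str(c.path) for c in cands.candidates} == {"X;a", "X;b", "X;c", "Y"}
    assert cands.expansion_log == [T("X")]


def test_expansion_terminates_when_all_candidates_are_leaves():
    assignments = [("S1", T("A")), ("S2", T("B")), ("S3", T("C"))]
    alignment = SequenceSet([("S1", "AC"), ("S2", "AG"), ("S3", "AT")])
    taxonomy = build_taxonomy(assignments)
    cands = expand_taxonomy(taxonomy, alignment, target_count=10)
    assert cands.taxa_count == 3  # target unreachable, leaves retained
    assert cands.deviation_percent == pytest.approx(70.0)


def test_target_below_initial_is_an_error():
    taxonomy, alignment = _toy()
    with pytest.raises(ValueError):
        expand_taxonomy(taxonomy, alignment, target_count=1)


def test_bookkeeping_identity_per_expansion(small_dataset):
    taxonomy, alignment, _ = small_dataset
    count = len(taxonomy.roots)
    cands = expand_taxonomy(taxonomy, alignment, target_count=9)
    # replay the log: each expansion replaces one candidate with its children
    for path in cands.expansion_log:
        clade = taxonomy.find(path)
        count += -1 + len(clade.children)
    assert count == cands.taxa_count == len(cands.candidates)


def test_equal_entropies_expand_in_lexicographic_order():
    cfg = FixtureConfig(seed=3, depth=3, branching=2, seqs_per_clade=2,
                        alignment_length=40, divergence=0.0, gap_fraction=0.0)
    taxonomy, alignment, _ = make_taxonomy_and_alignment(cfg)
    cands = expand_taxonomy(taxonomy, alignment, target_count=5)
    # all entropies are 0, so expansion follows sorted taxopaths
    assert [str(p) for p in cands.expansion_log] == ["t0", "t0;c0", "t0;c1"]


# -- oracle equivalence ------------------------------------------------------


def _entropy_from_scratch(clade, alignment):
    """Independent entropy: manual recursion + Counter per column, math.log2."""
    ids = []
    stack = [clade]
    while stack:
        c = stack.pop()
        ids.extend(c.sequence_ids)
        stack.extend(c.children)
    if not ids:
        return 0.0
    seqs = [alignment[i] for i in sorted(ids)]
    total = 0.0
    for col in zip(*seqs):
        n = len(col)
        for char in set(col):
            f = col.count(char) / n
            total -= f * math.log2(f)
    return total


def _greedy_oracle(taxonomy, alignment, target):
    """From-scratch greedy loop, recomputing every entropy each round."""
    cands = sorted(taxonomy.roots, key=lambda c: c.path)
    log = []
    count = len(cands)
    while count < target:
        expandable = [c for c in cands if c.children]
        if not expandable:
            break
        best = max(expandable, key=lambda c: _entropy_from_scratch(c, alignment))
        cands.remove(best)
        cands.extend(best.children)
        cands.sort(key=lambda c: c.path)
        count += -1 + len(best.children)
        log.append(best.path)
    return cands, log


@pytest.mark.parametrize("seed", range(25))
def test_expansion_matches_bruteforce_oracle(seed):
    """Memoized expansion equals a from-scratch greedy on random taxonomies."""
    depth = 2 + seed % 2
    branching = 2 + seed % (3 if depth == 2 else 2)
    cfg = FixtureConfig(
        seed=seed,
        depth=depth,
        branching=branching,
        seqs_per_clade=1 + seed % 3,
        alignment_length=30,
        divergence=0.02 + 0.03 * (seed % 4),
        diverse_divergence=0.6,
        diverse_clades=("t0",) if seed % 2 else (),
        gap_fraction=0.05,
    )
    taxonomy, alignment, _ = make_taxonomy_and_alignment(cfg)
    assert len(taxonomy) <= 50
    target = branching + 1 + seed % 6
    got = expand_taxonomy(taxonomy, alignment, target)
    want_cands, want_log = _greedy_oracle(taxonomy, alignment, target)
    assert [c.path for c in got.candidates] == [c.path for c in want_cands]
    assert got.expansion_log == want_log


def test_planted_diverse_clade_expanded_before_homogeneous(small_dataset):
    taxonomy, alignment, _ = small_dataset  # t1 planted diverse
    cands = expand_taxonomy(taxonomy, alignment, target_count=5)
    assert str(cands.expansion_log[0]) == "t1"


# -- reference set -----------------------------------------------------------


def test_reference_set_single_sequence_candidate_is_identity():
    assignments = [("S1", T("A")), ("S2", T("B"))]
    alignment = SequenceSet([("S1", "ACGT"), ("S2", "TTTT")])
    taxonomy = build_taxonomy(assignments)
    cands = expand_taxonomy(taxonomy, alignment, target_count=2)
    records = build_reference_set(cands, alignment)
    by_label = {r.label: r for r in records}
    assert by_label["A"].sequence == "ACGT"
    assert by_label["B"].sequence == "TTTT"
    assert by_label["A"].n_sequences == 1
    assert len({r.label for r in records}) == 2


def test_reference_set_consensus_covers_subtree(small_dataset):
    taxonomy, alignment, _ = small_dataset
    cands = expand_taxonomy(taxonomy, alignment, target_count=5)
    records = build_reference_set(cands, alignment)
    assert len(records) == cands.taxa_count
    total = sum(r.n_sequences for r in records)
    assert total == taxonomy.total_sequences()  # candidates partition the data
    for rec in records:
        assert len(rec.sequence) == alignment.length


def test_label_sanitization_is_newick_safe():
    label = sanitize_label(T("Euka ryota", "Alve(olata)", "Co:ccidia"))
    assert not set(label) & set(" (){}[]:;,'\"")


# -- constraint tree ---------------------------------------------------------


def test_constraint_tree_mirrors_taxonomy_restriction():
    assignments = [("S1", T("A", "B")), ("S2", T("A", "C")), ("S3", T("D"))]
    alignment = SequenceSet([("S1", "AC"), ("S2", "AG"), ("S3", "AT")])
    taxonomy = build_taxonomy(assignments)
    cands = expand_taxonomy(taxonomy, alignment, target_count=3)
    tree = build_constraint_tree(cands)
    assert tree.to_newick(edge_tags=False) == "((A.B,A.C),D);"


def test_constraint_tree_single_root_is_multifurcation():
    assignments = [("S1", T("A", "x")), ("S2", T("A", "y")), ("S3", T("A", "z"))]
    alignment = SequenceSet([("S1", "AC"), ("S2", "AG"), ("S3", "AT")])
    taxonomy = build_taxonomy(assignments)
    cands = expand_taxonomy(taxonomy, alignment, target_count=3)
    tree = build_constraint_tree(cands)
    assert tree.to_newick(edge_tags=False) == "(A.x,A.y,A.z);"


def test_constraint_tree_labels_round_trip():
    assignments = [("S1", T("A", "B")), ("S2", T("A", "C")), ("S3", T("D"))]
    alignment = SequenceSet([("S1", "AC"), ("S2", "AG"), ("S3", "AT")])
    cands = expand_taxonomy(build_taxonomy(assignments), alignment, 3)
    tree = build_constraint_tree(cands)
    reparsed = EdgeNumberedTree.from_newick(tree.to_newick())
    assert sorted(reparsed.tip_labels) == sorted(tree.tip_labels)


def test_constraint_tree_needs_two_candidates():
    assignments = [("S1", T("A"))]
    alignment = SequenceSet([("S1", "AC")])
    cands = expand_taxonomy(build_taxonomy(assignments), alignment, 1)
    with pytest.raises(ValueError):
        build_constraint_tree(cands)
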