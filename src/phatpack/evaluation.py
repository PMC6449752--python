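"""Accuracy machinery for placement results.

Given a reference set built from taxonomic consensus sequences, each query
carrying a taxonomic label has an *expected* edge: the terminal branch of
the consensus tip whose taxopath is the longest prefix of the query's
taxopath.  Placement quality is then the distance between actual and
expected placements, measured two ways:

* topologically — the number of branches between the two edges (adjacent
  edges are 1 apart, the same edge is 0);
* in branch-length units — from the placement's attachment point (set by
  its distal length) to the nearest point of the expected edge, so any
  position on the expected edge scores 0.

Because a query has several candidate placements, both distances are
averaged with the likelihood weight ratios.  The expected distance between
placement locations (EDPL) measures the spread of one query's placements:
the LWR-weighted mean pairwise branch-length distance between its
attachment points.  Pendant lengths are off-tree and excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import EdgeNumberedTree, PlacementDocument, Pquery, Taxopath
from .multilevel import CladeAssociation
from .phat import ConsensusRecord


def expected_edge(
    query_taxopath: Taxopath,
    records: list[ConsensusRecord],
    tree: EdgeNumberedTree,
) -> int | None:
    """Terminal edge of the candidate whose taxopath is the longest prefix
    of the query's taxopath, or None when no candidate matches."""
    best: ConsensusRecord | None = None
    for rec in records:
        if rec.taxopath.is_prefix_of(query_taxopath):
            if best is None or len(rec.taxopath) > len(best.taxopath):
                best = rec
    if best is None:
        return None
    return tree.terminal_edge(best.label)


def edge_distances(
    tree: EdgeNumberedTree, e1: int, e2: int, distal: float = 0.0
) -> tuple[int, float]:
    """Topological and branch-length distance from a placement to an edge.

    The placement sits on ``e1`` at ``distal`` from the child-side node;
    the branch-length distance is to the nearest point of ``e2``.
    """
    return tree.topo_distance(e1, e2), tree.distance_to_edge(e1, distal, e2)


def weighted_distance(
    pq: Pquery, expected: int, tree: EdgeNumberedTree
) -> tuple[float, float]:
    """LWR-weighted mean topological and branch-length distance to the
    expected edge, over all of a pquery's placements."""
    total = sum(p.like_weight_ratio for p in pq.placements)
    if total <= 0:
        raise ValidationError(f"pquery {pq.name!r} has all-zero likelihood weights")
    topo = 0.0
    bl = 0.0
    for p in pq.placements:
        t, b = edge_distances(tree, p.edge_num, expected, distal=p.distal_length)
        topo += p.like_weight_ratio * t
        bl += p.like_weight_ratio * b
    return topo / total, bl / total


def edpl(pq: Pquery, tree: EdgeNumberedTree) -> float:
    """Expected distance between placement locations of one pquery.

    LWRs are normalized to their sum; the result is
    Σ_i Σ_j p_i p_j · d(attachment_i, attachment_j) over ordered pairs.
    Zero iff all probability mass sits at a single attachment point.
    """
    total = sum(p.like_weight_ratio for p in pq.placements)
    if total <= 0:
        raise ValidationError(f"pquery {pq.name!r} has all-zero likelihood weights")
    ps = [p.like_weight_ratio / total for p in pq.placements]
    out = 0.0
    for i, pi in enumerate(pq.placements):
        for j in range(i + 1, len(pq.placements)):
            pj = pq.placements[j]
            d = tree.attachment_distance(
                pi.edge_num, pi.distal_length, pj.edge_num, pj.distal_length
            )
            out += 2.0 * ps[i] * ps[j] * d
    return out


@dataclass
class DistanceReport:
    """Per-pquery distances plus aggregate accuracy statistics."""

    table: pd.DataFrame  # columns: name, multiplicity, weighted_edge_distance,
    #                       weighted_bl_distance, edpl
    n_unmapped: int = 0

    def _weights(self) -> np.ndarray:
        return self.table["multiplicity"].to_numpy(dtype=float)

    def mean_topo(self) -> float:
        return float(
            np.average(self.table["weighted_edge_distance"], weights=self._weights())
        )

    def mean_bl(self) -> float:
        return float(
            np.average(self.table["weighted_bl_distance"], weights=self._weights())
        )

    def fraction_within(self, radius: float, kind: str = "topo") -> float:
        """Multiplicity-weighted fraction of queries whose weighted distance
        is at most ``radius``."""
        col = (
            "weighted_edge_distance" if kind == "topo" else "weighted_bl_distance"
        )
        w = self._weights()
        hit = (self.table[col].to_numpy() <= radius + 1e-12).astype(float)
        return float(np.average(hit, weights=w))

    def fraction_exact(self) -> float:
        return self.fraction_within(0.0, "topo")

    def cumulative(self, kind: str = "topo") -> pd.DataFrame:
        """Cumulative frequency curve of weighted distances.

        Returns a frame with columns ``distance`` and ``cum_freq``; the
        curve is non-decreasing and ends at 1.
        """
        col = (
            "weighted_edge_distance" if kind == "topo" else "weighted_bl_distance"
        )
        frame = self.table[[col, "multiplicity"]].sort_values(col)
        weights = frame["multiplicity"].to_numpy(dtype=float)
        cum = np.cumsum(weights) / weights.sum()
        out = pd.DataFrame({"distance": frame[col].to_numpy(), "cum_freq": cum})
        return out.groupby("distance", as_index=False)["cum_freq"].max()


def distance_report(
    doc: PlacementDocument,
    expected: Mapping[str, int],
    tree: EdgeNumberedTree | None = None,
) -> DistanceReport:
    """Evaluate every pquery of a document against its expected edge.

    ``expected`` maps pquery names to edge numbers; pqueries without an
    entry (unmapped queries) are excluded from the statistics but counted.
    """
    tree = tree if tree is not None else doc.tree
    rows = []
    unmapped = 0
    for pq in doc.pqueries:
        exp = expected.get(pq.name)
        if exp is None:
            unmapped += 1
            continue
        topo, bl = weighted_distance(pq, exp, tree)
        rows.append(
            {
                "name": pq.name,
                "multiplicity": pq.multiplicity,
                "weighted_edge_distance": topo,
                "weighted_bl_distance": bl,
                "edpl": edpl(pq, tree),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "name",
            "multiplicity",
            "weighted_edge_distance",
            "weighted_bl_distance",
            "edpl",
        ],
    )
    return DistanceReport(table=table, n_unmapped=unmapped)


@dataclass
class CladeAccuracy:
    """Fraction of queries whose best placement lands in the true clade."""

    overall: float
    per_label: dict[str, float]
    n: int


def clade_accuracy(
    doc: PlacementDocument,
    assoc: CladeAssociation,
    truth: Mapping[str, str],
) -> CladeAccuracy:
    """Best-hit clade identification accuracy.

    ``truth`` maps pquery names to clade-tree labels.  A query counts as
    correct when the label of its best placement's edge equals the truth —
    with overlapping associations, any edge carrying the right label counts.
    Fractions are multiplicity-weighted; the per-label breakdown groups by
    the *true* label.
    """
    assoc.validate_coverage(doc.tree)
    correct: dict[str, float] = {}
    total: dict[str, float] = {}
    for pq in doc.pqueries:
        if pq.name not in truth:
            raise ValidationError(f"no truth label for pquery {pq.name!r}")
        true_label = truth[pq.name]
        got = assoc.mapping[pq.best().edge_num]
        weight = float(pq.multiplicity)
        total[true_label] = total.get(true_label, 0.0) + weight
        if got == true_label:
            correct[true_label] = correct.get(true_label, 0.0) + weight
    grand_total = sum(total.values())
    if grand_total == 0:
        raise ValueError("no pqueries to evaluate")
    return CladeAccuracy(
        overall=sum(correct.values()) / grand_total,
        per_label={
            label: correct.get(label, 0.0) / total[label] for label in sorted(total)
        },
        n=len(doc.pqueries),
    )


def edge_taxopaths(
    tree: EdgeNumberedTree, tip_paths: Mapping[str, Taxopath]
) -> dict[int, Taxopath]:
    """Taxopath of every edge: a terminal edge carries its tip's path, an
    internal edge the longest common prefix of its descendant tips."""

    def lcp(paths: list[Taxopath]) -> Taxopath:
        if not paths:
            return Taxopath()
        first = paths[0]
        depth = 0
        while depth < min(len(p) for p in paths) and all(
            p[depth] == first[depth] for p in paths
        ):
            depth += 1
        return first.prefix(depth)

    out: dict[int, Taxopath] = {}
    for e in tree.edge_numbers:
        node = tree._node(e)
        tips = [n.label for n in _subtree_tips(node)]
        try:
            paths = [tip_paths[t] for t in tips]
        except KeyError as exc:
            raise ValidationError(f"no taxopath for tip {exc.args[0]!r}") from None
        out[e] = lcp(paths)
    return out


def _subtree_tips(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf():
            yield n
        stack.extend(n.children)


def assign_taxonomy(
    doc: PlacementDocument,
    edge_paths: Mapping[int, Taxopath],
    threshold: float = 0.66,
) -> tuple[dict[str, Taxopath], dict[Taxopath, float]]:
    """Placement-based taxonomic assignment and profile.

    Each pquery accumulates likelihood weight onto every prefix of the
    taxopath of each placed edge; the assignment is the deepest prefix whose
    accumulated weight reaches ``threshold``.  When no depth > 0 qualifies
    the query is assigned at the root (empty taxopath).  The profile sums
    pquery multiplicities per assigned path.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    assignments: dict[str, Taxopath] = {}
    profile: dict[Taxopath, float] = {}
    for pq in doc.pqueries:
        mass: dict[Taxopath, float] = {}
        for p in pq.placements:
            try:
                path = edge_paths[p.edge_num]
            except KeyError:
                raise ValidationError(
                    f"no taxopath for edge {p.edge_num}"
                ) from None
            for depth in range(1, len(path) + 1):
                prefix = path.prefix(depth)
                mass[prefix] = mass.get(prefix, 0.0) + p.like_weight_ratio
        qualifying = [
            (len(path), m, path)
            for path, m in mass.items()
            if m >= threshold - 1e-12
        ]
        if qualifying:
            _, _, best = max(qualifying, key=lambda t: (t[0], t[1], t[2]))
        else:
            best = Taxopath()
        assignments[pq.name] = best
        profile[best] = profile.get(best, 0.0) + pq.multiplicity
    return assignments, profile
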