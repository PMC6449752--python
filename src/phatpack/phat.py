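"""Phylogenetic Automatic (Reference) Tree construction.

Greedy, entropy-guided expansion of a taxonomy into a target number of
candidate clades, followed by consensus-sequence emission and a
taxonomy-constraint tree for downstream maximum-likelihood inference.

The expansion loop keeps a candidate list, initialized with the top-rank
clades; while the candidate count is below the target it removes the
candidate with the highest sequence entropy and replaces it with its
immediate sub-clades, so diverse clades are recursively refined while
homogeneous clades stay collapsed behind one consensus sequence.  Leaf
clades (no sub-clades) cannot be expanded and are simply retained; the loop
ends when the target is reached or every remaining candidate is a leaf, and
the final count may overshoot the target when the last expanded clade has
many sub-clades.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .entropy_consensus import clade_entropy, consensus
from .errors import ValidationError
from .io_formats import EdgeNumberedTree, SequenceSet, Taxopath
from .taxonomy import Clade, TaxonomyTree

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Result of the greedy taxonomy expansion."""

    candidates: list[Clade]
    taxa_count: int
    target_count: int
    expansion_log: list[Taxopath] = field(default_factory=list)

    @property
    def deviation_percent(self) -> float:
        """Relative deviation of the final count from the target, in %."""
        return abs(self.taxa_count - self.target_count) / self.target_count * 100.0


@dataclass(frozen=True)
class ConsensusRecord:
    """One reference-set entry: a clade, its label and consensus sequence."""

    taxopath: Taxopath
    label: str
    sequence: str
    n_sequences: int


def expand_taxonomy(
    tree: TaxonomyTree,
    alignment: SequenceSet,
    target_count: int,
    initial: list[Clade] | None = None,
) -> CandidateSet:
    """Greedily expand the most entropy-diverse clades up to ``target_count``.

    Each round removes the candidate clade with maximal entropy H(t) (ties
    broken lexicographically by full taxopath) and adds its immediate
    sub-clades, updating the count by ``−1 + #sub-clades``.  Entropies are
    memoized — a clade's sequence set never changes during expansion.
    """
    if initial is None:
        initial = list(tree.roots)
    if not initial:
        raise ValueError("no initial candidate clades")
    if target_count < len(initial):
        raise ValueError(
            f"target_count {target_count} below initial candidate count {len(initial)}"
        )
    candidates = sorted(initial, key=lambda c: c.path)
    cache: dict[int, float] = {}
    log: list[Taxopath] = []
    taxa_count = len(candidates)
    while taxa_count < target_count:
        expandable = [c for c in candidates if not c.is_leaf()]
        if not expandable:
            break
        # candidates are kept sorted by taxopath, and max() returns the first
        # maximal element, so entropy ties resolve lexicographically
        most_diverse = max(
            expandable, key=lambda c: clade_entropy(tree, c, alignment, cache)
        )
        candidates.remove(most_diverse)
        children = most_diverse.children
        candidates.extend(children)
        candidates.sort(key=lambda c: c.path)
        taxa_count += -1 + len(children)
        log.append(most_diverse.path)
    result = CandidateSet(
        candidates=candidates,
        taxa_count=taxa_count,
        target_count=target_count,
        expansion_log=log,
    )
    assert result.taxa_count == len(result.candidates)
    return result


_UNSAFE_LABEL = re.compile(r"[\s(){}\[\]:;,'\"]")


def sanitize_label(taxopath: Taxopath) -> str:
    """Newick-safe tip label for a taxopath: ranks joined by '.', unsafe
    characters replaced by '_'."""
    return _UNSAFE_LABEL.sub("_", ".".join(taxopath))


def build_reference_set(
    cands: CandidateSet,
    alignment: SequenceSet,
    method: str = "majority",
    threshold: float = 0.5,
) -> list[ConsensusRecord]:
    """One consensus record per candidate clade.

    All sequences in a candidate's subtree feed its consensus; candidates
    with empty subtrees are dropped with a warning.  ``method`` is any
    consensus method, plus ``"first"``: represent the clade by its
    lexicographically first actual sequence instead of a consensus (a
    deliberately simple alternative for comparisons).
    """
    records: list[ConsensusRecord] = []
    used_labels: dict[str, int] = {}
    for clade in cands.candidates:
        ids = sorted(clade.subtree_sequence_ids())
        if not ids:
            logger.warning("dropping candidate %s: no sequences", clade.path)
            continue
        seqs = alignment.subset(ids)
        if method == "first":
            seq = seqs[ids[0]]
        else:
            seq = consensus(seqs, method=method, threshold=threshold)
        label = sanitize_label(clade.path)
        if label in used_labels:
            used_labels[label] += 1
            label = f"{label}_{used_labels[label]}"
        else:
            used_labels[label] = 1
        records.append(
            ConsensusRecord(
                taxopath=clade.path,
                label=label,
                sequence=seq,
                n_sequences=len(ids),
            )
        )
    if not records:
        raise ValueError("all candidate clades have empty sequence sets")
    return records


def build_constraint_tree(cands: CandidateSet) -> EdgeNumberedTree:
    """Multifurcating constraint tree mirroring the taxonomy of the candidates.

    Tips are the candidates' sanitized labels; internal nodes reproduce the
    shared taxopath prefixes (unary chains collapsed).  No branch lengths —
    the tree is meant as a monophyly constraint for ML inference.
    """
    if len(cands.candidates) < 2:
        raise ValueError("constraint tree needs at least 2 candidates")

    trie: dict = {}
    for clade in cands.candidates:
        node = trie
        for rank in clade.path:
            node = node.setdefault(rank, {})
        node["\0label"] = sanitize_label(clade.path)

    def render(node: dict) -> str:
        if "\0label" in node:
            return node["\0label"]
        parts = [render(child) for _, child in sorted(node.items())]
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    parts = [render(child) for _, child in sorted(trie.items())]
    newick = (parts[0] if len(parts) == 1 else "(" + ",".join(parts) + ")") + ";"
    if "(" not in newick:
        raise ValidationError("degenerate constraint tree (single tip)")
    return EdgeNumberedTree.from_newick(newick, auto_number=True)
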