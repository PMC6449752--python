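"""Taxonomy tree: clade hierarchy, sequence attachment, subtree queries.

A taxonomy is a rooted forest of named clades (one root per top rank, e.g.
the three domains of life).  Sequences are attached at the clade of their
full taxonomic path; the sequences *belonging to* a clade are those attached
at the clade itself plus all of its sub-clades.  Ranks are purely positional
— no named-rank (Phylum/Class/...) semantics are attached.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from .errors import ValidationError
from .io_formats import SequenceSet, Taxopath


class Clade:
    """One clade of the taxonomy, with optional directly-attached sequences."""

    __slots__ = ("name", "parent", "_children", "sequence_ids", "_path")

    def __init__(self, name: str, parent: "Clade" | None = None):
        self.name = name
        self.parent = parent
        self._children: dict[str, Clade] = {}
        self.sequence_ids: set[str] = set()
        self._path: Taxopath | None = None

    def __repr__(self) -> str:
        return f"Clade({str(self.path)!r})"

    @property
    def children(self) -> list["Clade"]:
        return list(self._children.values())

    def child(self, name: str) -> "Clade":
        return self._children[name]

    def get_or_add_child(self, name: str) -> "Clade":
        if name not in self._children:
            self._children[name] = Clade(name, parent=self)
        return self._children[name]

    def is_leaf(self) -> bool:
        return not self._children

    @property
    def path(self) -> Taxopath:
        if self._path is None:
            ranks = []
            node: Clade | None = self
            while node is not None:
                ranks.append(node.name)
                node = node.parent
            self._path = Taxopath(tuple(reversed(ranks)))
        return self._path

    def subtree(self) -> Iterator["Clade"]:
        """Pre-order iteration over this clade and all its descendants."""
        stack = [self]
        while stack:
            clade = stack.pop()
            yield clade
            stack.extend(reversed(clade.children))

    def subtree_sequence_ids(self) -> set[str]:
        out: set[str] = set()
        for clade in self.subtree():
            out |= clade.sequence_ids
        return out


class TaxonomyTree:
    """Forest of top-rank clades plus a path index."""

    def __init__(self, roots: list[Clade]):
        self.roots = roots
        self._index: dict[tuple[str, ...], Clade] = {}
        for root in roots:
            for clade in root.subtree():
                self._index[clade.path.ranks] = clade

    def find(self, taxopath: Taxopath) -> Clade:
        try:
            return self._index[tuple(taxopath)]
        except KeyError:
            raise ValidationError(f"no clade at taxopath {taxopath}") from None

    def __contains__(self, taxopath: Taxopath) -> bool:
        return tuple(taxopath) in self._index

    def clades(self) -> Iterator[Clade]:
        for root in self.roots:
            yield from root.subtree()

    def __len__(self) -> int:
        return len(self._index)

    def total_sequences(self) -> int:
        return sum(len(c.sequence_ids) for c in self.clades())


def build_taxonomy(assignments: Iterable[tuple[str, Taxopath]]) -> TaxonomyTree:
    """Build the clade tree from ``(sequence_id, taxopath)`` assignments.

    One clade is created per distinct path prefix; each sequence is attached
    at the clade of its full path.  A sequence ID may appear only once.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("empty assignment list")
    roots: dict[str, Clade] = {}
    seen: set[str] = set()
    for sid, taxopath in assignments:
        if not len(taxopath):
            raise ValueError(f"sequence {sid!r} has an empty taxopath")
        if sid in seen:
            raise ValueError(f"sequence {sid!r} assigned twice")
        seen.add(sid)
        top = taxopath[0]
        if top not in roots:
            roots[top] = Clade(top)
        clade = roots[top]
        for rank in list(taxopath)[1:]:
            clade = clade.get_or_add_child(rank)
        clade.sequence_ids.add(sid)
    return TaxonomyTree(list(roots.values()))


def clade_sequences(
    tree: TaxonomyTree, clade: Clade, alignment: SequenceSet
) -> SequenceSet:
    """All aligned sequences belonging to ``clade``, including sub-clades.

    Returns an empty set when the clade's subtree holds no sequences; the
    caller decides how to handle that.
    """
    ids = sorted(clade.subtree_sequence_ids())
    return alignment.subset(ids)
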