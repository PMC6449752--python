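"""Readers, writers and core containers for the external formats.

Formats handled here:

* aligned FASTA over the 5-state nucleotide alphabet ``{A, C, G, T, -}``
  (ambiguity codes are normalized to gaps, ``U`` to ``T``);
* Silva-dialect taxonomy tables: ``sequence_id <TAB> Rank1;Rank2;...;``
  with an optional trailing semicolon;
* edge-numbered newick as used by the jplace standard, with the edge number
  in curly braces after the branch length (``A:0.1{0}``); the legacy
  square-bracket dialect (``A:0.1[0]``) is accepted on read, braces are
  always emitted on write;
* jplace v3 JSON placement documents.

Coordinate conventions
----------------------
Edges are identified solely by their jplace edge number.  ``distal_length``
of a placement is measured from the child-side (away-from-root) node of its
edge, following the jplace specification.  Pendant lengths are off-tree and
play no role in any distance computed on the tree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, FormatError, ValidationError

NUCLEOTIDES = ("A", "C", "G", "T", "-")

#: value used where a branch length is missing (constraint trees)
_NO_LENGTH = None


# ---------------------------------------------------------------------------
# Sequence normalization
# ---------------------------------------------------------------------------

def _build_normalization_table() -> bytes:
    table = bytearray(256)
    for b in range(256):
        c = chr(b).upper()
        if c == "U":
            c = "T"
        if len(c) == 1 and c in "ACGT-":
            table[b] = ord(c)
        else:
            table[b] = ord("-")
    return bytes(table)


_NORM_TABLE = _build_normalization_table()


def normalize_sequence(seq: str) -> str:
    """Normalize one aligned sequence to the 5-state alphabet.

    Uppercases, maps ``U`` to ``T`` and every other character outside
    ``{A, C, G, T, -}`` (ambiguity codes, ``.``, ``N`` ...) to a gap.
    Idempotent.
    """
    try:
        raw = seq.encode("latin-1")
    except UnicodeEncodeError as exc:  # pragma: no cover - exotic input
        raise FormatError(f"non-ASCII character in sequence: {exc}") from exc
    return raw.translate(_NORM_TABLE).decode("ascii")


# ---------------------------------------------------------------------------
# Taxopath
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Taxopath:
    """An ordered taxonomic path, top rank first.

    Components are compared by exact string match.  The empty path denotes
    the (virtual) root of a taxonomy, used e.g. for root-level taxonomic
    assignments.
    """

    ranks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for rank in self.ranks:
            if not rank:
                raise ValueError("taxopath components must be non-empty")

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "Taxopath":
        text = text.strip()
        if text.endswith(sep):
            text = text[: -len(sep)]
        if not text:
            raise ValueError("empty taxopath string")
        parts = tuple(p.strip() for p in text.split(sep))
        if any(not p for p in parts):
            raise ValueError(f"empty component in taxopath {text!r}")
        return cls(parts)

    def __str__(self) -> str:
        return ";".join(self.ranks)

    def __len__(self) -> int:
        return len(self.ranks)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ranks)

    def __getitem__(self, item):
        got = self.ranks[item]
        return Taxopath(got) if isinstance(item, slice) else got

    def prefix(self, depth: int) -> "Taxopath":
        return Taxopath(self.ranks[:depth])

    def is_prefix_of(self, other: "Taxopath") -> bool:
        return self.ranks == other.ranks[: len(self.ranks)]


# ---------------------------------------------------------------------------
# SequenceSet
# ---------------------------------------------------------------------------

class SequenceSet:
    """An ordered set of equal-length aligned sequences, keyed by ID."""

    def __init__(self, records: Iterable[tuple[str, str]]):
        self._seqs: dict[str, str] = {}
        length: int | None = None
        for sid, seq in records:
            if sid in self._seqs:
                raise FormatError(f"duplicate sequence ID {sid!r}")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {length}"
                )
            self._seqs[sid] = seq
        self.length: int = length or 0

    @property
    def ids(self) -> list[str]:
        return list(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __bool__(self) -> bool:
        return bool(self._seqs)

    def __contains__(self, sid: str) -> bool:
        return sid in self._seqs

    def __getitem__(self, sid: str) -> str:
        return self._seqs[sid]

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        try:
            return SequenceSet((sid, self._seqs[sid]) for sid in ids)
        except KeyError as exc:
            raise ValidationError(f"sequence ID {exc.args[0]!r} not in set") from exc

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single-byte characters."""
        if not self._seqs:
            raise ValueError("empty sequence set")
        joined = "".join(self._seqs.values()).encode("ascii")
        return np.frombuffer(joined, dtype="S1").reshape(len(self), self.length)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self._seqs.items():
                fh.write(f">{sid}\n{seq}\n")


def read_alignment(path, normalize: bool = True) -> SequenceSet:
    """Read an aligned FASTA file.

    With ``normalize`` (the default), sequences are uppercased, ``U`` becomes
    ``T`` and everything outside ``{A, C, G, T, -}`` becomes a gap.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if normalize:
            seq = normalize_sequence(seq)
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return SequenceSet(records)


# ---------------------------------------------------------------------------
# Taxonomy table
# ---------------------------------------------------------------------------

def read_taxonomy(path) -> list[tuple[str, Taxopath]]:
    """Read a Silva-dialect taxonomy table.

    One line per sequence: ``sequence_id <TAB> Rank1;Rank2;...;``.  Blank
    lines and lines starting with ``#`` are skipped.  Duplicate sequence IDs
    and empty path components are rejected.
    """
    out: list[tuple[str, Taxopath]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" not in line:
                raise FormatError(f"{path}:{lineno}: expected TAB-separated line")
            sid, raw_path = line.split("\t", 1)
            sid = sid.strip()
            if not sid:
                raise FormatError(f"{path}:{lineno}: empty sequence ID")
            if sid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate sequence ID {sid!r}")
            try:
                taxopath = Taxopath.from_string(raw_path)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            seen.add(sid)
            out.append((sid, taxopath))
    if not out:
        raise FormatError(f"no taxonomy entries in {path}")
    return out


def write_taxonomy(assignments: Iterable[tuple[str, Taxopath]], path) -> None:
    with open(path, "w") as fh:
        for sid, taxopath in assignments:
            fh.write(f"{sid}\t{taxopath};\n")


# ---------------------------------------------------------------------------
# Edge-numbered trees
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "length", "edge_num", "children", "parent", "index")

    def __init__(self) -> None:
        self.label: str | None = None
        self.length: float | None = None
        self.edge_num: int | None = None
        self.children: list["_Node"] = []
        self.parent: "_Node" | None = None
        self.index: int = -1

    def is_leaf(self) -> bool:
        return not self.children


_LABEL_STOP = set(":,(){}[]; \t\n")
_NUMBER_CHARS = set("0123456789+-.eE")


def _parse_newick(text: str) -> _Node:
    text = "".join(text.split())  # labels are sanitized; whitespace is noise
    if not text.endswith(";"):
        raise FormatError("newick string must end with ';'")
    pos = 0

    def error(msg: str) -> FormatError:
        return FormatError(f"newick parse error at position {pos}: {msg}")

    def parse_clade() -> _Node:
        nonlocal pos
        node = _Node()
        if text[pos] == "(":
            pos += 1
            while True:
                child = parse_clade()
                child.parent = node
                node.children.append(child)
                if pos >= len(text):
                    raise error("unbalanced parentheses")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {text[pos]!r}")
        # optional label
        start = pos
        while pos < len(text) and text[pos] not in _LABEL_STOP:
            pos += 1
        if pos > start:
            node.label = text[start:pos]
        # optional branch length
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] in _NUMBER_CHARS:
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                raise error("malformed branch length") from None
        # optional edge number, {N} or legacy [N]
        if pos < len(text) and text[pos] in "{[":
            close = "}" if text[pos] == "{" else "]"
            end = text.find(close, pos)
            if end < 0:
                raise error(f"unterminated edge tag, missing {close!r}")
            try:
                node.edge_num = int(text[pos + 1 : end])
            except ValueError:
                raise error("malformed edge number") from None
            pos = end + 1
        return node

    root = parse_clade()
    if pos >= len(text) or text[pos] != ";":
        raise error("trailing content before ';'")
    return root


class EdgeNumberedTree:
    """A rooted tree whose edges carry unique jplace edge numbers 0..E-1.

    Each edge is identified with its child-side node; the root may carry an
    extra "root edge" number (as emitted by some placement tools), in which
    case that edge's child-side node is the root itself.
    """

    def __init__(self, root: _Node, auto_number: bool = False):
        self.root = root
        nodes = list(self._preorder_nodes())
        for i, node in enumerate(nodes):
            node.index = i
        tagged = [n for n in nodes if n.edge_num is not None]
        if not tagged and auto_number:
            num = 0
            for node in nodes:
                if node is self.root:
                    continue
                node.edge_num = num
                num += 1
            tagged = [n for n in nodes if n.edge_num is not None]
        untagged = [n for n in nodes if n.edge_num is None and n is not self.root]
        if untagged:
            raise FormatError(
                f"{len(untagged)} edge(s) without an edge number"
            )
        numbers = [n.edge_num for n in tagged]
        if len(set(numbers)) != len(numbers):
            raise FormatError("duplicate edge numbers")
        if numbers and (min(numbers) != 0 or max(numbers) != len(numbers) - 1):
            raise FormatError(
                f"edge numbers must cover 0..{len(numbers) - 1} exactly"
            )
        self._edges: dict[int, _Node] = {n.edge_num: n for n in tagged}
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate tip labels")
        self._terminal: dict[str, int] | None = None
        self._edge_graph: nx.Graph | None = None
        self._node_graph: nx.Graph | None = None
        self._topo_cache: dict[int, dict[int, int]] = {}
        self._dist_cache: dict[int, dict[int, float]] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, auto_number: bool = True) -> "EdgeNumberedTree":
        return cls(_parse_newick(text), auto_number=auto_number)

    def to_newick(self, edge_tags: bool = True) -> str:
        def fmt(node: _Node) -> str:
            out = ""
            if node.children:
                out = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                out += node.label
            if node.length is not None:
                out += f":{node.length:.10g}"
            if edge_tags and node.edge_num is not None:
                out += "{%d}" % node.edge_num
            return out

        return fmt(self.root) + ";"

    # -- basic queries -----------------------------------------------------

    def _preorder_nodes(self) -> Iterator[_Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def num_edges(self) -> int:
        return len(self._edges)

    @property
    def edge_numbers(self) -> list[int]:
        return sorted(self._edges)

    @property
    def tip_labels(self) -> list[str]:
        return [n.label or "" for n in self._preorder_nodes() if n.is_leaf()]

    def has_edge(self, edge_num: int) -> bool:
        return edge_num in self._edges

    def _node(self, edge_num: int) -> _Node:
        try:
            return self._edges[edge_num]
        except KeyError:
            raise ValidationError(f"unknown edge number {edge_num}") from None

    def branch_length(self, edge_num: int) -> float:
        length = self._node(edge_num).length
        return 0.0 if length is None else length

    def is_terminal(self, edge_num: int) -> bool:
        return self._node(edge_num).is_leaf()

    def terminal_edge(self, tip_label: str) -> int:
        if self._terminal is None:
            self._terminal = {
                n.label: n.edge_num
                for n in self._preorder_nodes()
                if n.is_leaf() and n.label and n.edge_num is not None
            }
        try:
            return self._terminal[tip_label]
        except KeyError:
            raise ValidationError(f"no terminal edge for tip {tip_label!r}") from None

    def parent_edge(self, edge_num: int) -> int | None:
        node = self._node(edge_num)
        if node.parent is None:
            return None
        return node.parent.edge_num

    def subtree_edges(self, edge_num: int) -> frozenset[int]:
        """Edge numbers of the subtree hanging from ``edge_num``, inclusive."""
        top = self._node(edge_num)
        out = set()
        stack = [top]
        while stack:
            node = stack.pop()
            if node.edge_num is not None:
                out.add(node.edge_num)
            stack.extend(node.children)
        # when called on the root pseudo-edge, all edges are below it
        out.add(edge_num)
        return frozenset(out)

    # -- distances ---------------------------------------------------------

    def _ensure_graphs(self) -> None:
        if self._edge_graph is not None:
            return
        eg = nx.Graph()
        eg.add_nodes_from(self._edges)
        ng = nx.Graph()
        for node in self._preorder_nodes():
            ng.add_node(node.index)
            incident = [c.edge_num for c in node.children if c.edge_num is not None]
            if node.edge_num is not None:
                incident.append(node.edge_num)
            for i, e1 in enumerate(incident):
                for e2 in incident[i + 1 :]:
                    eg.add_edge(e1, e2)
            if node.parent is not None:
                ng.add_edge(
                    node.index,
                    node.parent.index,
                    weight=node.length if node.length is not None else 0.0,
                )
        self._edge_graph = eg
        self._node_graph = ng

    def topo_distance(self, e1: int, e2: int) -> int:
        """Number of branches between two edges; adjacent edges are 1 apart."""
        self._node(e1), self._node(e2)
        if e1 == e2:
            return 0
        self._ensure_graphs()
        if e1 not in self._topo_cache:
            self._topo_cache[e1] = dict(
                nx.single_source_shortest_path_length(self._edge_graph, e1)
            )
        return self._topo_cache[e1][e2]

    def _node_distances(self, index: int) -> dict[int, float]:
        if index not in self._dist_cache:
            self._ensure_graphs()
            self._dist_cache[index] = dict(
                nx.single_source_dijkstra_path_length(
                    self._node_graph, index, weight="weight"
                )
            )
        return self._dist_cache[index]

    def _attachment_ends(self, edge_num: int, distal: float) -> list[tuple[int, float]]:
        node = self._node(edge_num)
        length = node.length if node.length is not None else 0.0
        if distal < -1e-9 or distal > length + 1e-6:
            raise ValidationError(
                f"distal length {distal} outside edge {edge_num} of length {length}"
            )
        distal = min(max(distal, 0.0), length)
        ends = [(node.index, distal)]
        if node.parent is not None:
            ends.append((node.parent.index, length - distal))
        return ends

    def attachment_distance(
        self, e1: int, distal1: float, e2: int, distal2: float
    ) -> float:
        """Branch-length distance between two placement attachment points."""
        if e1 == e2:
            return abs(distal1 - distal2)
        ends1 = self._attachment_ends(e1, distal1)
        ends2 = self._attachment_ends(e2, distal2)
        best = math.inf
        for idx1, off1 in ends1:
            dists = self._node_distances(idx1)
            for idx2, off2 in ends2:
                best = min(best, off1 + dists[idx2] + off2)
        return best

    def distance_to_edge(self, e1: int, distal1: float, e2: int) -> float:
        """Branch-length distance from an attachment point to the nearest
        point of edge ``e2`` (zero anywhere on ``e2`` itself)."""
        if e1 == e2:
            return 0.0
        ends1 = self._attachment_ends(e1, distal1)
        node2 = self._node(e2)
        targets = [node2.index]
        if node2.parent is not None:
            targets.append(node2.parent.index)
        best = math.inf
        for idx1, off1 in ends1:
            dists = self._node_distances(idx1)
            for idx2 in targets:
                best = min(best, off1 + dists[idx2])
        return best

    # -- comparisons -------------------------------------------------------

    def _compare(self, other: "EdgeNumberedTree", lengths: bool, tol: float) -> bool:
        def eq(a: _Node, b: _Node) -> bool:
            if (a.label or None) != (b.label or None):
                return False
            if a.edge_num != b.edge_num:
                return False
            if lengths:
                if (a.length is None) != (b.length is None):
                    return False
                if a.length is not None and not math.isclose(
                    a.length, b.length, rel_tol=tol, abs_tol=tol
                ):
                    return False
            if len(a.children) != len(b.children):
                return False
            return all(eq(ca, cb) for ca, cb in zip(a.children, b.children))

        return eq(self.root, other.root)

    def semantically_equal(
        self, other: "EdgeNumberedTree", tol: float = 1e-6
    ) -> bool:
        """Same topology, labels, edge numbers and (approximately) lengths."""
        return self._compare(other, lengths=True, tol=tol)

    def same_reference(self, other: "EdgeNumberedTree") -> bool:
        """Same topology, labels and edge numbering (lengths ignored)."""
        return self._compare(other, lengths=False, tol=0.0)


# ---------------------------------------------------------------------------
# jplace
# ---------------------------------------------------------------------------

STANDARD_FIELDS = (
    "edge_num",
    "likelihood",
    "like_weight_ratio",
    "distal_length",
    "pendant_length",
)

_LWR_TOL = 1e-6


@dataclass
class Placement:
    """One candidate placement of a query on a reference-tree edge."""

    edge_num: int
    like_weight_ratio: float
    likelihood: float = 0.0
    distal_length: float = 0.0
    pendant_length: float = 0.0
    extras: dict = field(default_factory=dict)


@dataclass
class Pquery:
    """All candidate placements of one query (or bundle of identical reads)."""

    names: list[tuple[str, int]]
    placements: list[Placement]

    @property
    def name(self) -> str:
        return self.names[0][0]

    @property
    def multiplicity(self) -> int:
        return sum(m for _, m in self.names)

    def best(self) -> Placement:
        """The most likely placement; ties broken by lowest edge number."""
        return max(
            self.placements, key=lambda p: (p.like_weight_ratio, -p.edge_num)
        )


@dataclass
class PlacementDocument:
    """In-memory jplace document: reference tree plus pqueries."""

    tree: EdgeNumberedTree
    pqueries: list[Pquery]
    fields: list[str] = field(default_factory=lambda: list(STANDARD_FIELDS))
    version: int = 3
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.version != 3:
            raise FormatError(f"unsupported jplace version {self.version}")
        for want in ("edge_num", "like_weight_ratio"):
            if want not in self.fields:
                raise FormatError(f"jplace fields must contain {want!r}")
        for pq in self.pqueries:
            if not pq.names:
                raise ValidationError("pquery without names")
            if not pq.placements:
                raise ValidationError(f"pquery {pq.name!r} has no placements")
            for _, mult in pq.names:
                if mult < 1:
                    raise ValidationError(
                        f"pquery {pq.name!r} has multiplicity {mult} < 1"
                    )
            total = 0.0
            for p in pq.placements:
                if not self.tree.has_edge(p.edge_num):
                    raise ValidationError(
                        f"pquery {pq.name!r} references unknown edge {p.edge_num}"
                    )
                if p.like_weight_ratio < -_LWR_TOL or p.like_weight_ratio > 1 + _LWR_TOL:
                    raise ValidationError(
                        f"pquery {pq.name!r}: like_weight_ratio outside [0, 1]"
                    )
                if p.distal_length < -_LWR_TOL:
                    raise ValidationError(
                        f"pquery {pq.name!r}: negative distal length"
                    )
                if p.distal_length > self.tree.branch_length(p.edge_num) + _LWR_TOL:
                    raise ValidationError(
                        f"pquery {pq.name!r}: distal length exceeds branch length"
                    )
                if p.pendant_length < 0:
                    raise ValidationError(
                        f"pquery {pq.name!r}: negative pendant length"
                    )
                total += p.like_weight_ratio
            if total > 1 + _LWR_TOL:
                raise ValidationError(
                    f"pquery {pq.name!r}: like_weight_ratios sum to {total} > 1"
                )

    def semantically_equal(self, other: "PlacementDocument", tol: float = 1e-6) -> bool:
        if not self.tree.semantically_equal(other.tree, tol=tol):
            return False
        if len(self.pqueries) != len(other.pqueries):
            return False
        for a, b in zip(self.pqueries, other.pqueries):
            if a.names != b.names or len(a.placements) != len(b.placements):
                return False
            for pa, pb in zip(a.placements, b.placements):
                if pa.edge_num != pb.edge_num:
                    return False
                for attr in (
                    "like_weight_ratio",
                    "likelihood",
                    "distal_length",
                    "pendant_length",
                ):
                    if not math.isclose(
                        getattr(pa, attr), getattr(pb, attr), rel_tol=tol, abs_tol=tol
                    ):
                        return False
        return True


def parse_jplace(obj: Mapping) -> PlacementDocument:
    """Build a :class:`PlacementDocument` from a decoded jplace mapping."""
    for key in ("tree", "placements", "fields", "version"):
        if key not in obj:
            raise FormatError(f"jplace document missing key {key!r}")
    try:
        version = int(obj["version"])
    except (TypeError, ValueError):
        raise FormatError("jplace version must be an integer") from None
    tree = EdgeNumberedTree.from_newick(obj["tree"], auto_number=False)
    fields = list(obj["fields"])
    pqueries = []
    for entry in obj["placements"]:
        if "nm" in entry:
            names = [(str(n), int(m)) for n, m in entry["nm"]]
        elif "n" in entry:
            names = [(str(n), 1) for n in entry["n"]]
        else:
            raise FormatError("pquery without 'n' or 'nm' key")
        placements = []
        for row in entry.get("p", []):
            if len(row) != len(fields):
                raise FormatError(
                    f"placement row has {len(row)} values for {len(fields)} fields"
                )
            values = dict(zip(fields, row))
            extras = {k: v for k, v in values.items() if k not in STANDARD_FIELDS}
            placements.append(
                Placement(
                    edge_num=int(values["edge_num"]),
                    like_weight_ratio=float(values["like_weight_ratio"]),
                    likelihood=float(values.get("likelihood", 0.0)),
                    distal_length=float(values.get("distal_length", 0.0)),
                    pendant_length=float(values.get("pendant_length", 0.0)),
                    extras=extras,
                )
            )
        pqueries.append(Pquery(names=names, placements=placements))
    metadata = dict(obj.get("metadata", {}))
    return PlacementDocument(
        tree=tree, pqueries=pqueries, fields=fields, version=version,
        metadata=metadata,
    )


def read_jplace(path, validate: bool = True) -> PlacementDocument:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    doc = parse_jplace(obj)
    if validate:
        doc.validate()
    return doc


def jplace_to_mapping(doc: PlacementDocument) -> dict:
    placements = []
    for pq in doc.pqueries:
        rows = []
        for p in pq.placements:
            row = []
            for name in doc.fields:
                if name in STANDARD_FIELDS:
                    row.append(getattr(p, name))
                else:
                    row.append(p.extras.get(name))
            rows.append(row)
        placements.append({"p": rows, "nm": [[n, m] for n, m in pq.names]})
    out = {
        "version": doc.version,
        "tree": doc.tree.to_newick(edge_tags=True),
        "fields": list(doc.fields),
        "placements": placements,
    }
    if doc.metadata:
        out["metadata"] = doc.metadata
    return out


def write_jplace(doc: PlacementDocument, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(jplace_to_mapping(doc), fh, indent=1)
        fh.write("\n")
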