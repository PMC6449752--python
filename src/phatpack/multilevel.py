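"""Multilevel ("Russian Doll") placement support.

A broad backbone tree (BT) pre-classifies queries at the first level; each
clade tree (CT) then refines the placements of the queries that landed on
the BT branches associated with it.  A CT may own several BT branches (the
trees "overlap"); BT branches owned by no CT are *inner* branches, and
queries whose placement falls there are filtered out — phylogenetically
informed removal of spurious sequences.  More than two levels are obtained
by composing the same machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import FormatError, ValidationError
from .io_formats import EdgeNumberedTree, PlacementDocument, Taxopath

#: label marking backbone edges owned by no clade tree
INNER = "INNER"


@dataclass
class CladeAssociation:
    """Map from backbone-tree edge numbers to clade-tree labels (or INNER)."""

    mapping: dict[int, str]

    @property
    def labels(self) -> set[str]:
        return {v for v in self.mapping.values() if v != INNER}

    def label_edges(self, label: str) -> set[int]:
        return {e for e, v in self.mapping.items() if v == label}

    @classmethod
    def from_tsv(cls, path) -> "CladeAssociation":
        """Read ``edge_num <TAB> label`` lines; '#' comments allowed."""
        mapping: dict[int, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                try:
                    edge_str, label = line.split("\t", 1)
                    edge = int(edge_str)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: expected 'edge_num<TAB>label'"
                    ) from None
                if edge in mapping:
                    raise FormatError(f"{path}:{lineno}: duplicate edge {edge}")
                mapping[edge] = label.strip() or INNER
        if not mapping:
            raise FormatError(f"no association entries in {path}")
        return cls(mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for edge in sorted(self.mapping):
                fh.write(f"{edge}\t{self.mapping[edge]}\n")

    @classmethod
    def from_clade_paths(
        cls,
        tree: EdgeNumberedTree,
        clades: Mapping[str, Taxopath],
        tip_taxopaths: Mapping[str, Taxopath],
    ) -> "CladeAssociation":
        """Resolve named taxopaths against tip labels.

        Every terminal edge whose tip taxopath has a clade's taxopath as
        prefix gets that clade's label; all other edges (including all
        internal edges) are INNER.
        """
        mapping = {e: INNER for e in tree.edge_numbers}
        for tip in tree.tip_labels:
            try:
                tip_path = tip_taxopaths[tip]
            except KeyError:
                raise ValidationError(f"no taxopath for tip {tip!r}") from None
            matches = [
                (len(path), label)
                for label, path in clades.items()
                if path.is_prefix_of(tip_path)
            ]
            if matches:
                _, label = max(matches)
                mapping[tree.terminal_edge(tip)] = label
        return cls(mapping)

    def validate_coverage(self, tree: EdgeNumberedTree) -> None:
        missing = [e for e in tree.edge_numbers if e not in self.mapping]
        if missing:
            raise ValidationError(
                f"association misses {len(missing)} edge(s), e.g. {missing[0]}"
            )


@dataclass
class RoutingResult:
    """Per-label routed pquery names and the filtered (inner) remainder."""

    routed: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    filtered: list[tuple[str, int]] = field(default_factory=list)

    def total_multiplicity(self) -> int:
        total = sum(m for names in self.routed.values() for _, m in names)
        return total + sum(m for _, m in self.filtered)


def route(
    doc: PlacementDocument,
    assoc: CladeAssociation,
    mode: str = "best_hit",
    mass_threshold: float = 0.5,
) -> RoutingResult:
    """Route each pquery of a backbone placement to its clade tree(s).

    ``best_hit`` routes by the single placement with maximal likelihood
    weight ratio; ``mass_threshold`` routes to *every* label whose
    accumulated LWR over its associated edges reaches ``mass_threshold``
    (a pquery may then go to several clade trees).  Pqueries whose routing
    resolves to inner edges only are filtered.
    """
    if mode not in ("best_hit", "mass_threshold"):
        raise ValueError(f"unknown routing mode {mode!r}")
    assoc.validate_coverage(doc.tree)
    result = RoutingResult(routed={label: [] for label in sorted(assoc.labels)})
    for pq in doc.pqueries:
        if mode == "best_hit":
            label = assoc.mapping[pq.best().edge_num]
            targets = [] if label == INNER else [label]
        else:
            mass: dict[str, float] = {}
            for p in pq.placements:
                label = assoc.mapping[p.edge_num]
                if label != INNER:
                    mass[label] = mass.get(label, 0.0) + p.like_weight_ratio
            targets = sorted(
                label for label, m in mass.items() if m >= mass_threshold
            )
        if not targets:
            result.filtered.extend(pq.names)
        for label in targets:
            result.routed.setdefault(label, []).extend(pq.names)
    return result


def routing_summary(result: RoutingResult) -> dict:
    return {
        "labels": {
            label: {
                "pqueries": len(names),
                "multiplicity": sum(m for _, m in names),
            }
            for label, names in sorted(result.routed.items())
        },
        "filtered": {
            "pqueries": len(result.filtered),
            "multiplicity": sum(m for _, m in result.filtered),
        },
    }


def check_monophyly(
    tree: EdgeNumberedTree, assoc: CladeAssociation, label: str
) -> tuple[bool, int | None]:
    """Is the label's backbone edge set separable by a single split?

    True iff the edges equal one full subtree ``{e} ∪ edges-below-e``; the
    witness is that subtree's top edge ``e``.  Returns ``(False, None)``
    otherwise.
    """
    edges = assoc.label_edges(label)
    if not edges:
        raise ValueError(f"label {label!r} owns no edges")
    for e in edges:  # the witness, if any, must itself carry the label
        if tree.subtree_edges(e) == edges:
            return True, e
    return False, None


def cost_model(n_full: int, n_bt: int, n_ct: int) -> tuple[float, float]:
    """Analytic speedup and peak-memory factor of a two-level split.

    Placement cost is linear in the number of reference taxa and each query
    is placed once on the backbone (``n_bt`` taxa) and once on one clade
    tree (``n_ct`` taxa), so compared with a single comprehensive tree of
    ``n_full`` taxa the speedup is ``n_full / (n_bt + n_ct)`` and the peak
    memory shrinks by ``n_full / max(n_bt, n_ct)``.
    """
    for name, value in (("n_full", n_full), ("n_bt", n_bt), ("n_ct", n_ct)):
        if value < 1:
            raise ValueError(f"{name} must be >= 1, got {value}")
    return n_full / (n_bt + n_ct), n_full / max(n_bt, n_ct)


def write_routing(result: RoutingResult, out_dir) -> list[Path]:
    """Write per-label name lists, the filtered list and a summary JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for label, names in sorted(result.routed.items()):
        path = out_dir / f"{label}.names.tsv"
        with open(path, "w") as fh:
            for name, mult in names:
                fh.write(f"{name}\t{mult}\n")
        written.append(path)
    path = out_dir / "filtered.tsv"
    with open(path, "w") as fh:
        for name, mult in result.filtered:
            fh.write(f"{name}\t{mult}\n")
    written.append(path)
    path = out_dir / "summary.json"
    with open(path, "w") as fh:
        json.dump(routing_summary(result), fh, indent=1)
        fh.write("\n")
    written.append(path)
    return written
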