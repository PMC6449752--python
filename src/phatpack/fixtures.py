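"""Synthetic data generation: every module is testable with no download.

The generators emulate the shape of a taxonomically annotated reference
database (a complete b-ary taxonomy over aligned sequences that diverge
along the clade hierarchy), multi-sample read sets with duplicates, and
mock jplace documents with planted placement truth.  They deliberately use
the simplest mutation model that drives the entropy ordering — per-site
uniform substitution among the other three nucleotides, globally shared gap
columns, no indels or rate heterogeneity — so passing tests demonstrate
algorithmic correctness, not realism of rRNA evolution.

``make_reference_tree`` and ``make_mock_jplace`` are *synthetic stand-ins*
for the external maximum-likelihood inference and placement engines, which
are out of scope: the former decorates the taxonomy-constraint topology
with random branch lengths, the latter plants placements on the true edges
with a configurable topological noise radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    EdgeNumberedTree,
    PlacementDocument,
    Placement,
    Pquery,
    SequenceSet,
    Taxopath,
    write_taxonomy,
)
from .phat import CandidateSet, ConsensusRecord, build_constraint_tree
from .taxonomy import TaxonomyTree, build_taxonomy

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic study; same seed, same config → same bytes."""

    seed: int = 0
    depth: int = 3  # taxonomy depth (levels below nothing; leaves at depth)
    branching: int = 3  # children per clade
    seqs_per_clade: int = 6  # sequences attached at each leaf clade
    alignment_length: int = 200
    divergence: float = 0.05  # per-site substitution rate along each edge
    diverse_divergence: float = 0.5  # rate inside planted "diverse" top clades
    diverse_clades: tuple[str, ...] = ()  # names of planted top-rank clades
    gap_fraction: float = 0.1  # fraction of all-gap alignment columns
    n_samples: int = 3
    reads_per_sample: int = 100
    read_length: int = 100
    duplicate_rate: float = 0.5  # expected fraction of redundant reads
    noise_radius: int = 0  # topological radius of mock placements
    lwr_concentration: float = 10.0  # mass on the true edge vs neighbours


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    # substitute with one of the other three bases, uniformly
    idx = np.where(hit)[0]
    for i in idx:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def make_taxonomy_and_alignment(
    cfg: FixtureConfig,
) -> tuple[TaxonomyTree, SequenceSet, dict[str, Taxopath]]:
    """Generate a complete b-ary taxonomy with attached aligned sequences.

    Each top-rank clade draws a random ancestral sequence; child clades
    mutate their parent's ancestor at the clade's divergence rate, and each
    attached sequence mutates its leaf-clade ancestor once more.  Top
    clades named in ``cfg.diverse_clades`` use ``diverse_divergence``
    throughout their subtree, planting a known correct greedy expansion
    order.  Returns the taxonomy, the alignment and the per-sequence truth
    taxopaths.
    """
    rng = np.random.default_rng(cfg.seed)
    length = cfg.alignment_length
    n_gaps = int(round(cfg.gap_fraction * length))
    gap_cols = rng.choice(length, size=n_gaps, replace=False) if n_gaps else []
    assignments: list[tuple[str, Taxopath]] = []
    records: list[tuple[str, str]] = []

    def descend(path: tuple[str, ...], ancestor: np.ndarray, rate: float) -> None:
        if len(path) == cfg.depth:
            for k in range(cfg.seqs_per_clade):
                seq = _mutate(ancestor, rate, rng)
                seq[gap_cols] = b"-"
                sid = "_".join(path) + f"_s{k}"
                records.append((sid, seq.tobytes().decode("ascii")))
                assignments.append((sid, Taxopath(path)))
            return
        for j in range(cfg.branching):
            child = path + (f"c{j}",)
            descend(child, _mutate(ancestor, rate, rng), rate)

    for i in range(cfg.branching):
        top = f"t{i}"
        rate = (
            cfg.diverse_divergence if top in cfg.diverse_clades else cfg.divergence
        )
        ancestor = rng.choice(_BASES, size=length)
        descend((top,), ancestor, rate)

    alignment = SequenceSet(records)
    taxonomy = build_taxonomy(assignments)
    return taxonomy, alignment, dict(assignments)


def make_read_samples(cfg: FixtureConfig) -> dict[str, list[str]]:
    """Multi-sample read sets with cross-sample duplicates.

    A shared pool of unique reads is drawn once; each sample then samples
    from the pool with replacement, so the expected total-to-unique ratio
    is controlled by ``duplicate_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    total = cfg.n_samples * cfg.reads_per_sample
    pool_size = max(1, int(round(total * (1.0 - cfg.duplicate_rate))))
    pool = [
        "".join(rng.choice(_BASES, size=cfg.read_length).astype(str))
        for _ in range(pool_size)
    ]
    samples: dict[str, list[str]] = {}
    for s in range(cfg.n_samples):
        picks = rng.integers(0, pool_size, size=cfg.reads_per_sample)
        samples[f"sample{s:02d}"] = [pool[i] for i in picks]
    return samples


def make_random_tree(
    n_tips: int,
    seed: int = 0,
    min_bl: float = 0.05,
    max_bl: float = 1.0,
    tip_prefix: str = "T",
) -> EdgeNumberedTree:
    """Random binary tree with uniform branch lengths and preorder edge
    numbers; used as a small stand-in reference topology in tests."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    subtrees = [f"{tip_prefix}{i}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        la, lb = rng.uniform(min_bl, max_bl, size=2)
        subtrees.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    root = subtrees[0]
    if not root.startswith("("):  # pragma: no cover - n_tips >= 2 guards this
        root = f"({root})"
    return EdgeNumberedTree.from_newick(root + ";", auto_number=True)


def make_reference_tree(
    cands: CandidateSet,
    seed: int = 0,
    min_bl: float = 0.05,
    max_bl: float = 0.2,
) -> EdgeNumberedTree:
    """Synthetic reference tree over the candidate clades.

    Takes the taxonomy-constraint topology and assigns random branch
    lengths — a stand-in for the external maximum-likelihood inference
    step, sufficient for driving routing and evaluation end to end.
    """
    tree = build_constraint_tree(cands)
    rng = np.random.default_rng(seed)
    for node in tree._preorder_nodes():
        if node.parent is not None:
            node.length = float(rng.uniform(min_bl, max_bl))
    return EdgeNumberedTree.from_newick(tree.to_newick(), auto_number=False)


def make_mock_jplace(
    tree: EdgeNumberedTree,
    truth: dict[str, int],
    noise_radius: int = 0,
    lwr_concentration: float = 10.0,
    seed: int = 0,
    multiplicities: dict[str, int] | None = None,
) -> PlacementDocument:
    """Mock placement document with planted truth (placement-engine stand-in).

    Each query receives placements on its true edge and on every edge
    within ``noise_radius`` branches of it.  Likelihood weight ratios are
    drawn from a Dirichlet whose first concentration parameter is
    ``lwr_concentration`` (the rest 1), then sorted so the true edge always
    carries the largest weight; as the concentration grows the mass
    collapses onto the true edge.  Distal lengths are uniform on the edge.
    """
    rng = np.random.default_rng(seed)
    pqueries = []
    for name in sorted(truth):
        true_edge = truth[name]
        edges = sorted(
            (e for e in tree.edge_numbers if tree.topo_distance(true_edge, e) <= noise_radius),
            key=lambda e: (tree.topo_distance(true_edge, e), e),
        )
        m = len(edges)
        alphas = np.full(m, 1.0)
        alphas[0] = lwr_concentration
        weights = np.sort(rng.dirichlet(alphas))[::-1]
        placements = []
        for edge, w in zip(edges, weights):
            bl = tree.branch_length(edge)
            placements.append(
                Placement(
                    edge_num=edge,
                    like_weight_ratio=float(w),
                    likelihood=float(math.log(max(w, 1e-300))),
                    distal_length=float(rng.uniform(0.0, bl)),
                    pendant_length=float(rng.uniform(0.0, 0.05)),
                )
            )
        mult = (multiplicities or {}).get(name, 1)
        pqueries.append(Pquery(names=[(name, mult)], placements=placements))
    doc = PlacementDocument(tree=tree, pqueries=pqueries)
    doc.validate()
    return doc


PRESETS = {
    "small": FixtureConfig(
        depth=2,
        branching=3,
        seqs_per_clade=4,
        alignment_length=120,
        n_samples=2,
        reads_per_sample=40,
        diverse_clades=("t0",),
    ),
    "medium": FixtureConfig(
        depth=3,
        branching=3,
        seqs_per_clade=6,
        alignment_length=200,
        n_samples=4,
        reads_per_sample=200,
        diverse_clades=("t0",),
    ),
}


def write_preset(preset: str, seed: int, out_dir) -> dict[str, str]:
    """Materialize a named preset on disk for the CLI pipeline.

    Writes the taxonomy table, alignment, truth taxopaths, per-sample read
    FASTAs, plus a ready-made placement scenario (reference tree, mock
    jplace, clade association and expected-edge table) built from a small
    taxonomy expansion, so every subcommand has an input to chew on.
    """
    from . import evaluation, phat  # local import to avoid cycles

    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg_base = PRESETS[preset]
    cfg = FixtureConfig(**{**cfg_base.__dict__, "seed": seed})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    taxonomy, alignment, truth_paths = make_taxonomy_and_alignment(cfg)
    write_taxonomy(truth_paths.items(), out_dir / "taxonomy.tsv")
    alignment.write_fasta(out_dir / "alignment.fasta")

    samples_dir = out_dir / "samples"
    samples_dir.mkdir(exist_ok=True)
    for sample, reads in make_read_samples(cfg).items():
        with open(samples_dir / f"{sample}.fasta", "w") as fh:
            for i, read in enumerate(reads):
                fh.write(f">{sample}_r{i}\n{read}\n")

    # a placement scenario over an expanded reference set
    target = max(len(taxonomy.roots) + 1, cfg.branching * 2)
    cands = phat.expand_taxonomy(taxonomy, alignment, target)
    records = phat.build_reference_set(cands, alignment)
    tree = make_reference_tree(cands, seed=cfg.seed)
    expected = {
        sid: evaluation.expected_edge(path, records, tree)
        for sid, path in truth_paths.items()
    }
    expected = {sid: e for sid, e in expected.items() if e is not None}
    doc = make_mock_jplace(
        tree,
        expected,
        noise_radius=cfg.noise_radius,
        lwr_concentration=cfg.lwr_concentration,
        seed=cfg.seed,
    )
    from .io_formats import write_jplace

    write_jplace(doc, out_dir / "mock.jplace")
    with open(out_dir / "expected.tsv", "w") as fh:
        for sid in sorted(expected):
            fh.write(f"{sid}\t{expected[sid]}\n")
    with open(out_dir / "reference.labels.tsv", "w") as fh:
        for rec in records:
            fh.write(f"{rec.label}\t{rec.taxopath};\n")
    # clade association: terminal edges labelled by top rank, rest inner
    from .multilevel import INNER, CladeAssociation

    tip_paths = {rec.label: rec.taxopath for rec in records}
    top_labels = {path[0]: Taxopath((path[0],)) for path in tip_paths.values()}
    assoc = CladeAssociation.from_clade_paths(tree, top_labels, tip_paths)
    assoc.to_tsv(out_dir / "clades.tsv")
    with open(out_dir / "reference.newick", "w") as fh:
        fh.write(tree.to_newick() + "\n")
    return {
        "taxonomy": "taxonomy.tsv",
        "alignment": "alignment.fasta",
        "samples": "samples/",
        "jplace": "mock.jplace",
        "clades": "clades.tsv",
        "expected": "expected.tsv",
        "reference": "reference.newick",
    }
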