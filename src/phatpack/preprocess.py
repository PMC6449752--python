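"""Preprocessing pipeline for large placement datasets.

Reads from many samples are exactly deduplicated (identical strings after
uppercasing collapse to one unique sequence), fused into equally sized
chunks for the aligner/placement engine, and tracked in a per-sample
abundance map.  After placement, the per-chunk result files are resolved
back into per-sample placement documents in which each pquery carries its
original abundance as multiplicity.  The induced speedup is the ratio of
total to unique sequences; equal chunks restore load balance when samples
of very different sizes are processed in parallel.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import ConsistencyError, FormatError
from .io_formats import PlacementDocument, Pquery

logger = logging.getLogger(__name__)

DEFAULT_CHUNK_SIZE = 50_000  # recommended lower bound for real pipelines


@dataclass
class AbundanceMap:
    """Per-sample counts of unique sequence IDs.

    ``counts[sample][seq_id]`` is the number of reads in ``sample`` that
    collapsed onto the unique sequence ``seq_id``.  Samples that contained
    no reads are retained in ``samples`` with no count entries.
    """

    counts: dict[str, dict[str, int]]
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = list(self.counts)

    @property
    def total_reads(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    @property
    def unique_ids(self) -> set[str]:
        out: set[str] = set()
        for c in self.counts.values():
            out |= c.keys()
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#sample\tseq_id\tcount\n")
            for sample in self.samples:
                for sid, count in self.counts.get(sample, {}).items():
                    fh.write(f"{sample}\t{sid}\t{count}\n")

    @classmethod
    def from_tsv(cls, path) -> "AbundanceMap":
        counts: dict[str, dict[str, int]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                try:
                    sample, sid, count_str = line.split("\t")
                    count = int(count_str)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: expected 'sample<TAB>seq_id<TAB>count'"
                    ) from None
                counts.setdefault(sample, {})[sid] = count
        if not counts:
            raise FormatError(f"no abundance entries in {path}")
        return cls(counts)


@dataclass
class ChunkSet:
    """Deduplicated unique sequences, split into equally sized chunks."""

    chunks: list[list[tuple[str, str]]]
    chunk_size: int

    @property
    def n_unique(self) -> int:
        return sum(len(c) for c in self.chunks)

    def all_records(self) -> Iterator[tuple[str, str]]:
        for chunk in self.chunks:
            yield from chunk

    def write(self, out_dir) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, chunk in enumerate(self.chunks):
            path = out_dir / f"chunk_{i:04d}.fasta"
            with open(path, "w") as fh:
                for sid, seq in chunk:
                    fh.write(f">{sid}\n{seq}\n")
            paths.append(path)
        return paths

    def manifest(self) -> dict:
        return {
            "chunk_size": self.chunk_size,
            "n_chunks": len(self.chunks),
            "n_unique": self.n_unique,
            "chunk_lengths": [len(c) for c in self.chunks],
            "format_version": 1,
        }


def _iter_reads(source) -> Iterator[str]:
    """Yield raw read strings from a FASTA/FASTQ path or an iterable."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        with open(path) as fh:
            first = fh.read(1)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            return
        else:
            raise FormatError(f"{path}: neither FASTA nor FASTQ")
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq)
    else:
        yield from source


def deduplicate(
    samples: Iterable[tuple[str, object]],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    id_prefix: str = "q",
    id_width: int = 8,
) -> tuple[ChunkSet, AbundanceMap]:
    """Exact cross-sample deduplication with chunking.

    ``samples`` are ``(sample_name, source)`` pairs where ``source`` is a
    FASTA/FASTQ path or an iterable of read strings (quality strings are
    discarded).  Reads are uppercased before hashing; identity is the exact
    string.  Unique IDs are a zero-padded running index in first-occurrence
    order, so the output is deterministic for a fixed input order.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    ids: dict[str, str] = {}  # sequence -> unique ID
    order: list[tuple[str, str]] = []  # (id, sequence) in first-occurrence order
    counts: dict[str, dict[str, int]] = {}
    sample_names: list[str] = []
    for sample_name, source in samples:
        if sample_name in counts:
            raise ValueError(f"duplicate sample name {sample_name!r}")
        sample_names.append(sample_name)
        sample_counts: dict[str, int] = {}
        n_reads = 0
        for read in _iter_reads(source):
            read = read.upper()
            n_reads += 1
            sid = ids.get(read)
            if sid is None:
                sid = f"{id_prefix}{len(ids):0{id_width}d}"
                ids[read] = sid
                order.append((sid, read))
            sample_counts[sid] = sample_counts.get(sid, 0) + 1
        if n_reads == 0:
            logger.warning("sample %r contains no reads", sample_name)
        counts[sample_name] = sample_counts
    chunks = [
        order[i : i + chunk_size] for i in range(0, len(order), chunk_size)
    ] or [[]]
    return (
        ChunkSet(chunks=chunks, chunk_size=chunk_size),
        AbundanceMap(counts=counts, samples=sample_names),
    )


def dedup_gain(abund: AbundanceMap) -> float:
    """Speedup factor of deduplication: total reads / unique sequences."""
    unique = len(abund.unique_ids)
    if unique == 0:
        raise ValueError("abundance map is empty")
    return abund.total_reads / unique


def resolve(
    chunk_results: list[PlacementDocument], abund: AbundanceMap
) -> tuple[dict[str, PlacementDocument], list[str]]:
    """Resolve per-chunk placement results into per-sample documents.

    All chunk results must share one reference tree (same topology and edge
    numbering) and each unique ID must be placed in exactly one chunk.  The
    output holds, per sample, one pquery per unique sequence present in that
    sample with multiplicity equal to its abundance count; placements are
    copied verbatim.  IDs in the map that no chunk placed (engines may drop
    sequences) are returned separately as unplaced.
    """
    if not chunk_results:
        raise ValueError("no chunk results")
    reference = chunk_results[0].tree
    placed: dict[str, Pquery] = {}
    for i, doc in enumerate(chunk_results):
        if not doc.tree.same_reference(reference):
            raise ConsistencyError(
                f"chunk result {i} uses a different reference tree"
            )
        for pq in doc.pqueries:
            for name, _ in pq.names:
                if name in placed:
                    raise ConsistencyError(
                        f"sequence {name!r} placed in more than one chunk"
                    )
                placed[name] = pq
    per_sample: dict[str, PlacementDocument] = {}
    for sample in abund.samples:
        pqueries = []
        for sid, count in abund.counts.get(sample, {}).items():
            pq = placed.get(sid)
            if pq is None:
                continue
            pqueries.append(
                Pquery(
                    names=[(sid, count)],
                    placements=copy.deepcopy(pq.placements),
                )
            )
        per_sample[sample] = PlacementDocument(
            tree=reference,
            pqueries=pqueries,
            fields=list(chunk_results[0].fields),
            version=chunk_results[0].version,
            metadata={"sample": sample},
        )
    unplaced = sorted(abund.unique_ids - placed.keys())
    if unplaced:
        logger.warning("%d unique sequence(s) were never placed", len(unplaced))
    return per_sample, unplaced


def write_chunk_outputs(chunkset: ChunkSet, abund: AbundanceMap, out_dir) -> dict:
    """Write chunk FASTAs, the abundance TSV and a JSON manifest sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chunk_paths = chunkset.write(out_dir)
    abund_path = out_dir / "abundances.tsv"
    abund.to_tsv(abund_path)
    manifest = chunkset.manifest()
    manifest["samples"] = abund.samples
    manifest["total_reads"] = abund.total_reads
    manifest["abundances"] = abund_path.name
    manifest["chunks"] = [p.name for p in chunk_paths]
    with open(out_dir / "chunks.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest
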