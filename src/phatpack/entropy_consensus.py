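"""Per-site entropy, sequence-set entropy and consensus sequences.

The entropy of alignment site *i* over the five states
``c ∈ {A, C, G, T, -}`` is

    H_i = − Σ_c f_c,i · log2 f_c,i        (bits)

where ``f_c,i`` is the frequency of character *c* at site *i*.  Gaps are a
regular fifth state: counting them weighs down sites dominated by gaps,
which contribute nothing to a phylogenetic likelihood.  Ambiguity codes are
normalized to gaps upstream (see :func:`phatpack.io_formats.read_alignment`);
fractional counting of ambiguities is deliberately not implemented.  The
total entropy of a sequence set is the sum over sites, H(s) = Σ_i H_i; it is
0 exactly when all sequences are identical and grows with per-site character
diversity, peaking when all five states are equally frequent (20% each).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, MutableMapping, Sequence

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .io_formats import NUCLEOTIDES, SequenceSet
from .taxonomy import Clade, TaxonomyTree, clade_sequences

logger = logging.getLogger(__name__)

MAX_SITE_ENTROPY = float(np.log2(len(NUCLEOTIDES)))  # log2 5 ≈ 2.3219

_FREQ_TOL = 1e-6


@dataclass(frozen=True)
class EntropyProfile:
    """Per-site and total entropy of a sequence set.

    ``normalized`` rescales the total by its upper bound L·log2(5) to [0, 1];
    it is a reporting convenience only and enters no algorithm.
    """

    per_site: np.ndarray
    total: float
    normalized: float

    @property
    def length(self) -> int:
        return len(self.per_site)


def site_entropy(freqs: Mapping[str, float] | Sequence[float] | np.ndarray) -> float:
    """Shannon entropy (bits) of one site's 5-state frequency vector.

    Accepts a mapping keyed by ``{A, C, G, T, -}`` (missing states count as
    frequency 0) or a length-5 vector in that state order.  Frequencies must
    be non-negative and sum to 1; the 0·log2(0) terms contribute 0.
    """
    if isinstance(freqs, Mapping):
        vec = np.array([float(freqs.get(c, 0.0)) for c in NUCLEOTIDES])
    else:
        vec = np.asarray(freqs, dtype=float)
        if vec.shape != (len(NUCLEOTIDES),):
            raise ValueError(f"expected {len(NUCLEOTIDES)} frequencies, got {vec.shape}")
    if (vec < 0).any():
        raise ValueError("negative frequency")
    if abs(vec.sum() - 1.0) > _FREQ_TOL:
        raise ValueError(f"frequencies sum to {vec.sum()}, expected 1")
    return float(_scipy_entropy(vec, base=2))


def site_frequencies(seqs: SequenceSet) -> np.ndarray:
    """Per-site state frequencies of an aligned set; shape (L, 5)."""
    if not seqs:
        raise ValueError("empty sequence set")
    arr = seqs.to_array()
    counts = np.stack(
        [(arr == c.encode()).sum(axis=0) for c in NUCLEOTIDES], axis=1
    )
    return counts / len(seqs)


def set_entropy(seqs: SequenceSet) -> EntropyProfile:
    """Entropy profile of a non-empty, equal-length sequence set."""
    freqs = site_frequencies(seqs)
    if seqs.length == 0:
        per_site = np.zeros(0)
    else:
        per_site = _scipy_entropy(freqs, base=2, axis=1)
    total = float(per_site.sum())
    denom = seqs.length * MAX_SITE_ENTROPY
    normalized = total / denom if denom > 0 else 0.0
    return EntropyProfile(per_site=per_site, total=total, normalized=normalized)


def clade_entropy(
    tree: TaxonomyTree,
    clade: Clade,
    alignment: SequenceSet,
    cache: MutableMapping[int, float] | None = None,
) -> float:
    """Total entropy H(t) of all sequences belonging to a taxonomic clade.

    A clade whose subtree holds no sequences gets entropy 0 (it can never be
    worth expanding); a warning is logged.  Pass a ``cache`` dict to memoize
    across repeated calls — a clade's entropy never changes during taxonomy
    expansion.
    """
    if cache is not None and id(clade) in cache:
        return cache[id(clade)]
    seqs = clade_sequences(tree, clade, alignment)
    if not seqs:
        logger.warning("clade %s has no sequences; entropy defined as 0", clade.path)
        value = 0.0
    else:
        value = set_entropy(seqs).total
    if cache is not None:
        cache[id(clade)] = value
    return value


CONSENSUS_METHODS = ("majority", "cavener", "threshold")


def consensus(seqs: SequenceSet, method: str = "majority", threshold: float = 0.5) -> str:
    """Per-site consensus sequence of a non-empty aligned set.

    methods
        ``majority``
            the most frequent of ``{A, C, G, T, -}`` at each site;
        ``cavener``
            the top character if its frequency exceeds 0.5, else a gap (on
            this 5-letter alphabet the classic two-base branch of the rule
            would require an ambiguity code, so it collapses to a gap);
        ``threshold``
            the top character if its frequency is at least ``threshold``,
            else a gap.

    Ties prefer a non-gap state over the gap, then alphabetical order
    A < C < G < T, so runs are deterministic and biased toward retaining
    sequence signal.
    """
    if method not in CONSENSUS_METHODS:
        raise ValueError(f"unknown consensus method {method!r}")
    if not seqs:
        raise ValueError("empty sequence set")
    freqs = site_frequencies(seqs)  # column order = A, C, G, T, -
    out = []
    for site in freqs:
        best = max(range(len(NUCLEOTIDES)), key=lambda k: (site[k], -k))
        top_char, top_freq = NUCLEOTIDES[best], site[best]
        if method == "majority":
            out.append(top_char)
        elif method == "cavener":
            out.append(top_char if top_freq > 0.5 else "-")
        else:
            out.append(top_char if top_freq >= threshold else "-")
    return "".join(out)
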