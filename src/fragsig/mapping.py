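"""Fragment mapping enumeration and histogram-distance scoring.

Two molecules are compared through injective mappings between their fragment
sets that respect connectivity: whenever two mapped query fragments are
bonded, their images must be bonded in the target.  Mappings are grown
greedily from all single-fragment links and only maximal extensions are kept
(equivalently: consistent mappings not contained in a larger consistent
mapping).  Each mapping is scored as the L1 distance between the linked
fragments' normalized histograms, weighted by the ray-trace segment counts
of the fragments involved; the raw distance lies in [0, 2] and the
transform T(s) = 1 - log2(s) spreads it into a similarity score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signatures import Histogram1D, Histogram2D, MoleculeSignature

__all__ = [
    "FragmentGraph",
    "FragmentMapping",
    "MappedScore",
    "enumerate_mappings",
    "linear_mapping_count",
    "l1_distance",
    "mapped_score",
    "transform_score",
    "compare_molecules",
]

SCORE_VARIANTS = ("1d", "full", "reduced", "reduced_inverted")


@dataclass(frozen=True)
class FragmentGraph:
    """Fragment count plus bonded fragment pairs (a < b)."""

    n: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a fragment graph needs at least one fragment")
        for a, b in self.edges:
            if not (0 <= a < b < self.n):
                raise ValueError(f"bad fragment edge ({a}, {b})")

    @classmethod
    def path(cls, n: int) -> "FragmentGraph":
        return cls(n, frozenset((i, i + 1) for i in range(n - 1)))

    @classmethod
    def star(cls, n: int) -> "FragmentGraph":
        return cls(n, frozenset((0, i) for i in range(1, n)))

    @classmethod
    def from_signature(cls, sig: MoleculeSignature) -> "FragmentGraph":
        return cls(sig.n_fragments, frozenset(sig.adjacency))

    def adjacent(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.edges


@dataclass(frozen=True)
class FragmentMapping:
    """Injective set of (query fragment, target fragment) links."""

    links: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        qs = [q for q, _ in self.links]
        ts = [t for _, t in self.links]
        if len(set(qs)) != len(qs) or len(set(ts)) != len(ts):
            raise ValueError("mapping is not injective")
        object.__setattr__(self, "links", tuple(sorted(self.links)))

    def __len__(self) -> int:
        return len(self.links)

    @property
    def query_fragments(self) -> frozenset[int]:
        return frozenset(q for q, _ in self.links)

    @property
    def target_fragments(self) -> frozenset[int]:
        return frozenset(t for _, t in self.links)

    def inverse(self) -> "FragmentMapping":
        return FragmentMapping(tuple((t, q) for q, t in self.links))


def _consistent(
    links: tuple[tuple[int, int], ...],
    new: tuple[int, int],
    qgraph: FragmentGraph,
    tgraph: FragmentGraph,
) -> bool:
    q2, t2 = new
    for q1, t1 in links:
        if q1 == q2 or t1 == t2:
            return False
        if qgraph.adjacent(q1, q2) and not tgraph.adjacent(t1, t2):
            return False
    return True


def enumerate_mappings(
    qgraph: FragmentGraph, tgraph: FragmentGraph
) -> list[FragmentMapping]:
    """All maximal connectivity-consistent injective fragment mappings.

    Expansion starts from every single-fragment link and recursively adds
    links in all consistent ways; a mapping is kept only when no further
    link can be added (greedy maximal extension, duplicates removed).
    """
    maximal: set[frozenset[tuple[int, int]]] = set()
    visited: set[frozenset[tuple[int, int]]] = set()

    def extend(links: tuple[tuple[int, int], ...]) -> None:
        key = frozenset(links)
        if key in visited:
            return
        visited.add(key)
        extensions = [
            (q, t)
            for q in range(qgraph.n)
            for t in range(tgraph.n)
            if _consistent(links, (q, t), qgraph, tgraph)
        ]
        if not extensions:
            maximal.add(key)
            return
        for link in extensions:
            extend(links + (link,))

    extend(())
    return sorted(
        (FragmentMapping(tuple(m)) for m in maximal),
        key=lambda m: (-len(m), m.links),
    )


def linear_mapping_count(m: int, n: int) -> int:
    """Closed-form mapping count for linear (path) fragment arrangements.

    Counts all single-link maps plus contiguous multi-link maps in both
    orientations: ``mn + 2 * sum_{k=2}^{min(m,n)} (m-k+1)(n-k+1)``.
    """
    if m < 1 or n < 1:
        raise ValueError("fragment counts must be >= 1")
    total = m * n
    for k in range(2, min(m, n) + 1):
        total += 2 * (m - k + 1) * (n - k + 1)
    return total


def _padded_heights(h: Histogram1D | Histogram2D, other) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(h, Histogram1D) != isinstance(other, Histogram1D):
        raise ValueError("cannot compare histograms of different dimensionality")
    if h.bin_width != other.bin_width:
        raise ValueError(
            f"histogram bin widths differ ({h.bin_width} vs {other.bin_width}); "
            "descriptors from different database parameters are not comparable"
        )
    if isinstance(h, Histogram2D):
        if h.mep_axis != other.mep_axis:
            raise ValueError("MEP axes differ; descriptors are not comparable")
        n = max(h.counts.shape[0], other.counts.shape[0])
        a = np.zeros((n, h.mep_axis.n_bins))
        b = np.zeros((n, h.mep_axis.n_bins))
        a[: h.counts.shape[0]] = h.heights
        b[: other.counts.shape[0]] = other.heights
    else:
        n = max(len(h.counts), len(other.counts))
        a = np.zeros(n)
        b = np.zeros(n)
        a[: len(h.counts)] = h.heights
        b[: len(other.counts)] = other.heights
    return a, b


def l1_distance(hq: Histogram1D | Histogram2D, ht: Histogram1D | Histogram2D) -> float:
    """Discretized L1 metric between two normalized histograms, in [0, 2].

    The shorter histogram is zero-padded; bin widths and MEP axes must match.
    """
    a, b = _padded_heights(hq, ht)
    return float(np.abs(a - b).sum())


def transform_score(s: float) -> float:
    """Similarity transform T(s) = 1 - log2(s); zero at the maximal distance 2."""
    if s <= 0:
        raise ValueError(
            "transform_score requires s > 0 (stochastic descriptors never "
            "produce an exactly zero distance)"
        )
    return 1.0 - math.log2(s)


@dataclass(frozen=True)
class MappedScore:
    """Score of one fragment mapping between a query and a target."""

    raw: float  # weighted L1 distance, [0, 2]
    transformed: float | None  # T(raw); None when raw == 0 exactly
    mapping: FragmentMapping
    unused_query_pct: float
    unused_target_pct: float
    variant: str


def _fragment_histogram(sig: MoleculeSignature, fragment: int, variant: str):
    fs = sig.fragments[fragment]
    if fs.fragment != fragment:  # fragments are stored sorted by id
        fs = next(f for f in sig.fragments if f.fragment == fragment)
    if variant == "1d":
        return fs.hist1d
    return fs.hist2d[variant]


def mapped_score(
    qsig: MoleculeSignature,
    tsig: MoleculeSignature,
    mapping: FragmentMapping,
    variant: str = "1d",
) -> MappedScore:
    """Count-weighted mean of per-link L1 distances for one mapping.

    The weight of a link is the sum of the intra-fragment segment counts of
    the two linked fragments; unused percentages report the share of each
    molecule's segments sitting in fragments the mapping does not cover.
    """
    if variant not in SCORE_VARIANTS:
        raise ValueError(f"unknown descriptor variant {variant!r}")
    if not mapping.links:
        raise ValueError("cannot score an empty mapping")
    if not qsig.params.compatible(tsig.params):
        raise ValueError("signatures were generated with incompatible binning")
    qc = qsig.fragment_counts()
    tc = tsig.fragment_counts()
    num = 0.0
    den = 0.0
    for q, t in mapping.links:
        hq = _fragment_histogram(qsig, q, variant)
        ht = _fragment_histogram(tsig, t, variant)
        w = float(qc[q] + tc[t])
        if w == 0.0:
            continue  # neither fragment collected any segments
        if hq.total == 0 or ht.total == 0:
            dist = 2.0  # one side empty: no common support
        else:
            dist = l1_distance(hq, ht)
        num += w * dist
        den += w
    if den == 0.0:
        raise ValueError("every mapped fragment has a zero segment count")
    raw = num / den
    unused_q = 100.0 * (
        qc[[f for f in range(qsig.n_fragments) if f not in mapping.query_fragments]].sum()
        / max(qsig.total_segments, 1)
    )
    unused_t = 100.0 * (
        tc[[f for f in range(tsig.n_fragments) if f not in mapping.target_fragments]].sum()
        / max(tsig.total_segments, 1)
    )
    return MappedScore(
        raw=raw,
        transformed=transform_score(raw) if raw > 0 else None,
        mapping=mapping,
        unused_query_pct=float(unused_q),
        unused_target_pct=float(unused_t),
        variant=variant,
    )


def compare_molecules(
    qsig: MoleculeSignature,
    tsig: MoleculeSignature,
    variant: str = "1d",
    unused_threshold: float | None = None,
) -> list[MappedScore]:
    """Score every maximal fragment mapping between two signatures.

    Results are sorted by ascending raw score (ties: more links first, then
    lexicographic link list).  With ``unused_threshold`` set (percent),
    mappings leaving more than that share of either molecule's segments
    unused are discarded; the list may then be empty.
    """
    if not qsig.params.compatible(tsig.params):
        raise ValueError("signatures were generated with incompatible binning")
    mappings = enumerate_mappings(
        FragmentGraph.from_signature(qsig), FragmentGraph.from_signature(tsig)
    )
    scored = [mapped_score(qsig, tsig, m, variant) for m in mappings]
    if unused_threshold is not None:
        scored = [
            s
            for s in scored
            if s.unused_query_pct <= unused_threshold
            and s.unused_target_pct <= unused_threshold
        ]
    return sorted(scored, key=lambda s: (s.raw, -len(s.mapping), s.mapping.links))
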