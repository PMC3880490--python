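"""Shape-signature histograms: accumulation, normalization, serialization.

The 1D descriptor is the distribution of ray-trace segment lengths; the 2D
descriptors couple the summed incident segment lengths at a reflection with
the surface potential there, either on a full binned MEP axis or reduced to
its sign (and a sign-inverted variant for complementarity matching).  All
histograms are kept separately per fragment (intra) and per fragment pair
(inter); summing raw counts over all of them recovers the global,
non-fragment histogram exactly.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .fragmenter import Fragmentation
from .raytrace import RayTrace

__all__ = [
    "Histogram1D",
    "Histogram2D",
    "MepAxis",
    "FragmentSignature",
    "MoleculeSignature",
    "SignatureParams",
    "accumulate_1d",
    "accumulate_2d",
    "normalize",
    "build_signature",
    "global_histogram",
    "serialize_signature",
    "deserialize_signature",
    "signature_to_xml",
    "VARIANTS_2D",
]

VARIANTS_2D = ("full", "reduced", "reduced_inverted")

_MAGIC = b"FSIG"
_VERSION = 1


@dataclass
class Histogram1D:
    """Histogram over segment length, origin 0, uniform bins; raw counts kept."""

    bin_width: float
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or (self.counts < 0).any():
            raise ValueError("counts must be a 1D non-negative array")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def heights(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an empty histogram")
        return self.counts / self.total


@dataclass(frozen=True)
class MepAxis:
    """MEP axis of a 2D descriptor: full binned, or collapsed to the sign.

    Full axes clamp symmetrically: values beyond ``half_range`` land in the
    first/last (overflow) bin.  Reduced axes have two bins, negative then
    non-negative (an exactly zero potential counts as positive); the inverted
    variant flips the sign first.
    """

    kind: str  # "full" | "reduced" | "reduced_inverted"
    bin_width: float = 0.025  # e/Angstrom, full axis only
    half_range: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("full", "reduced", "reduced_inverted"):
            raise ValueError(f"unknown MEP axis kind {self.kind!r}")
        if self.kind == "full" and self.bin_width <= 0:
            raise ValueError("MEP bin_width must be positive")

    @property
    def n_bins(self) -> int:
        if self.kind == "full":
            return 2 * int(np.ceil(self.half_range / self.bin_width))
        return 2

    def bin_of(self, mep: np.ndarray) -> np.ndarray:
        mep = np.asarray(mep, dtype=float)
        if self.kind == "full":
            half = self.n_bins // 2
            idx = np.floor(mep / self.bin_width).astype(np.int64) + half
            return np.clip(idx, 0, self.n_bins - 1)
        if self.kind == "reduced_inverted":
            mep = -mep
        return (mep >= 0).astype(np.int64)


@dataclass
class Histogram2D:
    """Joint histogram over (summed incident segment length, MEP)."""

    bin_width: float  # shape axis, Angstrom
    mep_axis: MepAxis
    counts: np.ndarray  # (shape bins, MEP bins)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or (self.counts < 0).any():
            raise ValueError("counts must be a 2D non-negative array")
        if self.counts.shape[1] != self.mep_axis.n_bins:
            raise ValueError("MEP bin count does not match the axis")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def heights(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an empty histogram")
        return self.counts / self.total


def normalize(h: Histogram1D | Histogram2D):
    """Validate and mark a histogram as normalized (raw counts are retained)."""
    if h.total == 0:
        raise ValueError("cannot normalize an empty histogram")
    h.normalized = True
    return h


def _trim(counts: np.ndarray) -> np.ndarray:
    """Drop trailing all-zero shape bins (comparison pads back with zeros)."""
    if counts.ndim == 1:
        nz = np.flatnonzero(counts)
    else:
        nz = np.flatnonzero(counts.any(axis=1))
    n = int(nz[-1]) + 1 if len(nz) else 0
    return counts[:n]


# ---------------------------------------------------------------------------
# Accumulation
# ---------------------------------------------------------------------------

def accumulate_1d(
    trace: RayTrace, frag: Fragmentation | None = None, bin_width: float = 0.5
) -> tuple[dict[int, Histogram1D], dict[tuple[int, int], Histogram1D]]:
    """Per-fragment (intra) and per-pair (inter) segment-length histograms.

    Each segment adds one count to exactly one histogram; ``frag`` is only
    consulted to enumerate fragments that received no segments at all.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if trace.n_segments == 0:
        raise ValueError("empty ray trace")
    bins = np.floor(trace.segment_lengths / bin_width).astype(np.int64)
    fa = np.minimum(trace.segment_fragments[:, 0], trace.segment_fragments[:, 1])
    fb = np.maximum(trace.segment_fragments[:, 0], trace.segment_fragments[:, 1])

    intra: dict[int, Histogram1D] = {}
    inter: dict[tuple[int, int], Histogram1D] = {}
    n_frag = int(max(fa.max(), fb.max())) + 1 if frag is None else frag.n_fragments
    for f in range(n_frag):
        mask = (fa == f) & (fb == f)
        counts = np.bincount(bins[mask]) if mask.any() else np.zeros(0, dtype=np.int64)
        intra[f] = Histogram1D(bin_width, _trim(counts))
    inter_mask = fa != fb
    for a, b in {(int(x), int(y)) for x, y in zip(fa[inter_mask], fb[inter_mask])}:
        mask = (fa == a) & (fb == b)
        inter[(a, b)] = Histogram1D(bin_width, _trim(np.bincount(bins[mask])))
    return intra, inter


def accumulate_2d(
    trace: RayTrace,
    frag: Fragmentation | None = None,
    bin_width: float = 0.5,
    mep_axis: MepAxis | str = "reduced",
) -> tuple[dict[int, Histogram2D], dict[tuple[int, int], Histogram2D]]:
    """Joint (summed incident lengths, MEP) histograms per fragment and pair.

    Each interior reflection contributes one count.  A reflection belongs to
    the fragment of its element's primary atom; when an incident segment
    crosses into another fragment the count goes to that pair's inter
    histogram instead (the incoming side wins if both sides differ).
    """
    if isinstance(mep_axis, str):
        mep_axis = MepAxis(mep_axis)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if trace.n_segments < 2:
        raise ValueError("a 2D descriptor needs at least two segments")
    idx = trace.interior_reflections()
    length_sum = np.linalg.norm(
        trace.positions[idx] - trace.positions[idx - 1], axis=1
    ) + np.linalg.norm(trace.positions[idx + 1] - trace.positions[idx], axis=1)
    shape_bins = np.floor(length_sum / bin_width).astype(np.int64)
    mep_bins = mep_axis.bin_of(trace.meps[idx])

    f_prev = trace.fragments[idx - 1]
    f_here = trace.fragments[idx]
    f_next = trace.fragments[idx + 1]
    other = np.where(f_prev != f_here, f_prev, f_next)
    is_intra = (f_prev == f_here) & (f_next == f_here)
    pa = np.minimum(f_here, other)
    pb = np.maximum(f_here, other)

    n_frag = int(trace.fragments.max()) + 1 if frag is None else frag.n_fragments
    n_mep = mep_axis.n_bins
    n_shape = int(shape_bins.max()) + 1 if len(shape_bins) else 0

    def make(mask: np.ndarray) -> Histogram2D:
        counts = np.zeros((n_shape, n_mep), dtype=np.int64)
        np.add.at(counts, (shape_bins[mask], mep_bins[mask]), 1)
        return Histogram2D(bin_width, mep_axis, _trim(counts))

    intra = {f: make(is_intra & (f_here == f)) for f in range(n_frag)}
    inter: dict[tuple[int, int], Histogram2D] = {}
    cross = ~is_intra
    for a, b in {(int(x), int(y)) for x, y in zip(pa[cross], pb[cross])}:
        inter[(a, b)] = make(cross & (pa == a) & (pb == b))
    return intra, inter


# ---------------------------------------------------------------------------
# Molecule signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureParams:
    """Generation parameters; descriptors are only comparable when the
    binning parameters match."""

    bin_width: float = 0.5  # shape axis, Angstrom (1D and 2D)
    mep_bin_width: float = 0.025  # e/Angstrom, full 2D axis
    mep_half_range: float = 1.0
    probe_radius: float = 1.4
    mesh_density: float = 0.4
    cone_angle: float = 3.0
    n_segments: int = 100_000
    seed: int = 0
    dielectric: float = 1.0

    def compatible(self, other: "SignatureParams") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.mep_bin_width == other.mep_bin_width
            and self.mep_half_range == other.mep_half_range
        )


@dataclass
class FragmentSignature:
    """Intra-fragment descriptors plus the segment count used as weight."""

    fragment: int
    hist1d: Histogram1D
    hist2d: dict[str, Histogram2D] = field(default_factory=dict)
    count: int = 0  # intra-fragment 1D segment count


@dataclass
class MoleculeSignature:
    """Complete fragment-partitioned descriptor set for one molecule."""

    molecule_id: str
    n_fragments: int
    heavy_counts: tuple[int, ...]
    adjacency: frozenset[tuple[int, int]]
    fragments: list[FragmentSignature]
    inter_1d: dict[tuple[int, int], Histogram1D]
    inter_2d: dict[tuple[int, int], dict[str, Histogram2D]]
    total_segments: int
    params: SignatureParams

    def fragment_counts(self) -> np.ndarray:
        return np.array([fs.count for fs in self.fragments], dtype=np.int64)

    @property
    def intra_segments(self) -> int:
        return int(self.fragment_counts().sum())


def build_signature(
    trace: RayTrace,
    frag: Fragmentation,
    molecule_id: str,
    params: SignatureParams,
) -> MoleculeSignature:
    """Accumulate all descriptor variants of one trace into a signature."""
    intra1, inter1 = accumulate_1d(trace, frag, params.bin_width)
    axes = {
        "full": MepAxis("full", params.mep_bin_width, params.mep_half_range),
        "reduced": MepAxis("reduced"),
        "reduced_inverted": MepAxis("reduced_inverted"),
    }
    intra2: dict[str, dict] = {}
    inter2: dict[str, dict] = {}
    for name, axis in axes.items():
        intra2[name], inter2[name] = accumulate_2d(trace, frag, params.bin_width, axis)

    fragments = [
        FragmentSignature(
            fragment=f,
            hist1d=intra1[f],
            hist2d={name: intra2[name][f] for name in VARIANTS_2D},
            count=intra1[f].total,
        )
        for f in sorted(intra1)
    ]
    pairs = sorted(set(inter1) | {p for name in VARIANTS_2D for p in inter2[name]})
    axis_empty = {
        name: Histogram2D(params.bin_width, axes[name], np.zeros((0, axes[name].n_bins), dtype=np.int64))
        for name in VARIANTS_2D
    }
    inter_2d = {
        p: {name: inter2[name].get(p, axis_empty[name]) for name in VARIANTS_2D}
        for p in pairs
    }
    inter_1d = {
        p: inter1.get(p, Histogram1D(params.bin_width, np.zeros(0, dtype=np.int64)))
        for p in pairs
    }
    return MoleculeSignature(
        molecule_id=molecule_id,
        n_fragments=frag.n_fragments,
        heavy_counts=tuple(frag.heavy_counts),
        adjacency=frozenset(frag.adjacency),
        fragments=fragments,
        inter_1d=inter_1d,
        inter_2d=inter_2d,
        total_segments=trace.n_segments,
        params=params,
    )


def global_histogram(sig: MoleculeSignature) -> Histogram1D:
    """Recover the non-fragment histogram by summing all 1D raw counts."""
    parts = [fs.hist1d for fs in sig.fragments] + list(sig.inter_1d.values())
    n = max((len(h.counts) for h in parts), default=0)
    counts = np.zeros(n, dtype=np.int64)
    for h in parts:
        counts[: len(h.counts)] += h.counts
    return normalize(Histogram1D(sig.params.bin_width, _trim(counts)))


# ---------------------------------------------------------------------------
# Serialization: versioned, checksummed, zlib-compressed JSON container,
# with an XML export for interoperability.
# ---------------------------------------------------------------------------

def _h1_to_obj(h: Histogram1D) -> dict:
    return {"bin_width": h.bin_width, "counts": h.counts.tolist()}


def _h1_from_obj(o: dict) -> Histogram1D:
    return Histogram1D(o["bin_width"], np.asarray(o["counts"], dtype=np.int64))


def _h2_to_obj(h: Histogram2D) -> dict:
    return {
        "bin_width": h.bin_width,
        "mep_kind": h.mep_axis.kind,
        "mep_bin_width": h.mep_axis.bin_width,
        "mep_half_range": h.mep_axis.half_range,
        "counts": h.counts.tolist(),
    }


def _h2_from_obj(o: dict) -> Histogram2D:
    axis = MepAxis(o["mep_kind"], o["mep_bin_width"], o["mep_half_range"])
    counts = np.asarray(o["counts"], dtype=np.int64).reshape(-1, axis.n_bins)
    return Histogram2D(o["bin_width"], axis, counts)


def serialize_signature(sig: MoleculeSignature) -> bytes:
    payload = {
        "molecule_id": sig.molecule_id,
        "n_fragments": sig.n_fragments,
        "heavy_counts": list(sig.heavy_counts),
        "adjacency": sorted(list(p) for p in sig.adjacency),
        "total_segments": sig.total_segments,
        "params": {k: getattr(sig.params, k) for k in sig.params.__dataclass_fields__},
        "fragments": [
            {
                "fragment": fs.fragment,
                "count": fs.count,
                "hist1d": _h1_to_obj(fs.hist1d),
                "hist2d": {k: _h2_to_obj(v) for k, v in fs.hist2d.items()},
            }
            for fs in sig.fragments
        ],
        "inter_1d": [[list(p), _h1_to_obj(h)] for p, h in sorted(sig.inter_1d.items())],
        "inter_2d": [
            [list(p), {k: _h2_to_obj(v) for k, v in d.items()}]
            for p, d in sorted(sig.inter_2d.items())
        ],
    }
    blob = zlib.compress(json.dumps(payload).encode())
    digest = hashlib.sha256(blob).digest()
    header = _MAGIC + _VERSION.to_bytes(2, "big") + len(blob).to_bytes(8, "big")
    return header + digest + blob


def deserialize_signature(data: bytes) -> MoleculeSignature:
    if len(data) < 46 or data[:4] != _MAGIC:
        raise ValueError("not a fragsig signature container")
    version = int.from_bytes(data[4:6], "big")
    if version != _VERSION:
        raise ValueError(f"unsupported signature container version {version}")
    size = int.from_bytes(data[6:14], "big")
    digest = data[14:46]
    blob = data[46 : 46 + size]
    if len(blob) != size or hashlib.sha256(blob).digest() != digest:
        raise ValueError("signature container checksum failure (truncated or corrupt)")
    payload = json.loads(zlib.decompress(blob).decode())

    fragments = [
        FragmentSignature(
            fragment=fo["fragment"],
            hist1d=_h1_from_obj(fo["hist1d"]),
            hist2d={k: _h2_from_obj(v) for k, v in fo["hist2d"].items()},
            count=fo["count"],
        )
        for fo in payload["fragments"]
    ]
    return MoleculeSignature(
        molecule_id=payload["molecule_id"],
        n_fragments=payload["n_fragments"],
        heavy_counts=tuple(payload["heavy_counts"]),
        adjacency=frozenset(tuple(p) for p in payload["adjacency"]),
        fragments=fragments,
        inter_1d={tuple(p): _h1_from_obj(h) for p, h in payload["inter_1d"]},
        inter_2d={
            tuple(p): {k: _h2_from_obj(v) for k, v in d.items()}
            for p, d in payload["inter_2d"]
        },
        total_segments=payload["total_segments"],
        params=SignatureParams(**payload["params"]),
    )


def signature_to_xml(sig: MoleculeSignature) -> str:
    """Human-readable XML export of a signature (debugging/interoperability)."""
    import xml.etree.ElementTree as ET

    root = ET.Element("shape_signature", molecule=sig.molecule_id)
    params = ET.SubElement(root, "params")
    for k in sig.params.__dataclass_fields__:
        params.set(k, str(getattr(sig.params, k)))
    frags = ET.SubElement(
        root, "fragments", count=str(sig.n_fragments), total_segments=str(sig.total_segments)
    )
    for fs in sig.fragments:
        fe = ET.SubElement(frags, "fragment", id=str(fs.fragment), segments=str(fs.count))
        h1 = ET.SubElement(fe, "hist1d", bin_width=str(fs.hist1d.bin_width))
        h1.text = " ".join(str(c) for c in fs.hist1d.counts)
    inter = ET.SubElement(root, "inter")
    for (a, b), h in sorted(sig.inter_1d.items()):
        ie = ET.SubElement(inter, "pair", a=str(a), b=str(b), segments=str(h.total))
        ie.text = " ".join(str(c) for c in h.counts)
    return ET.tostring(root, encoding="unicode")
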