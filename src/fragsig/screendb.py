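"""Signature databases, lower-bound prefiltering and library searches.

A signature database is a single keyed container file (zip layout) holding
one serialized molecule signature per unique id plus a generation-parameter
header; a compact "reduced" companion (per-fragment shape-only histograms
and segment counts, connectivity dropped) is built in the same pass and
loaded into memory for fast prefiltering.  A search prefilters the library
with a cheap connectivity-free bound on the mapped score, runs the full
mapping comparison on the shortlisted candidates, filters weak substructure
matches by their unused-segment percentages, and ranks hits by ascending raw
score.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import Molecule, assign_radii, ensure_charges, read_molecules
from .fragmenter import Fragmentation, assign_fragments
from .mapping import MappedScore, compare_molecules
from .raytrace import trace
from .signatures import (
    MoleculeSignature,
    SignatureParams,
    build_signature,
    deserialize_signature,
    serialize_signature,
)
from .surface import molecular_surface

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureDB",
    "ReducedDB",
    "HitRecord",
    "HitList",
    "compute_signature",
    "build_db",
    "prefilter_search",
    "full_search",
    "search_library",
    "merge_hitlists",
    "roc_points",
]

DEFAULT_PREFILTER_K = 20_000
DEFAULT_MAX_HITS = 5_000
DEFAULT_UNUSED_THRESHOLD = 25.0  # percent


def _molecule_seed(base_seed: int, molecule_id: str) -> int:
    """Deterministic per-molecule ray-trace seed below 2**31."""
    return int((base_seed + zlib.crc32(molecule_id.encode())) % (2**31))


def compute_signature(
    mol: Molecule,
    params: SignatureParams = SignatureParams(),
    fragmentation: Fragmentation | None = None,
    charge_method: str = "auto",
    seed: int | None = None,
) -> MoleculeSignature:
    """Full pipeline: radii, charges, fragmentation, surface, trace, histograms."""
    mol = assign_radii(mol)
    if charge_method == "auto":
        charge_method = "keep-imported" if mol.has_charges else "gasteiger"
    mol = ensure_charges(mol, charge_method)
    frag = fragmentation if fragmentation is not None else assign_fragments(mol)
    surf = molecular_surface(
        mol, params.probe_radius, params.mesh_density, params.dielectric
    )
    rt = trace(
        surf,
        frag,
        n_segments=params.n_segments,
        cone_angle=params.cone_angle,
        seed=seed if seed is not None else _molecule_seed(params.seed, mol.id),
    )
    return build_signature(rt, frag, mol.id, params)


# ---------------------------------------------------------------------------
# Database container
# ---------------------------------------------------------------------------

@dataclass
class ReducedDB:
    """In-memory prefilter records: shape-only fragment histograms + counts."""

    ids: list[str]
    frag_ptr: np.ndarray  # (n_molecules + 1,) offsets into the fragment rows
    counts: np.ndarray  # (n_fragments_total,) intra segment counts
    heights: np.ndarray  # (n_fragments_total, n_bins) normalized histograms
    bin_width: float

    def __len__(self) -> int:
        return len(self.ids)


class SignatureDB:
    """Single-file keyed store of serialized signatures."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        with zipfile.ZipFile(self.path) as zf:
            header = json.loads(zf.read("header.json"))
        self.params = SignatureParams(**header["params"])
        self.ids: list[str] = header["ids"]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, molecule_id: str) -> bool:
        return molecule_id in set(self.ids)

    def get(self, molecule_id: str) -> MoleculeSignature:
        with zipfile.ZipFile(self.path) as zf:
            return deserialize_signature(zf.read(f"sigs/{molecule_id}.fsig"))

    def reduced(self) -> ReducedDB:
        with zipfile.ZipFile(self.path) as zf:
            data = np.load(io.BytesIO(zf.read("reduced.npz")), allow_pickle=False)
        return ReducedDB(
            ids=list(self.ids),
            frag_ptr=data["frag_ptr"],
            counts=data["counts"],
            heights=data["heights"],
            bin_width=float(data["bin_width"][0]),
        )


def _reduced_arrays(sigs: list[MoleculeSignature]) -> dict[str, np.ndarray]:
    n_bins = max(
        (len(fs.hist1d.counts) for sig in sigs for fs in sig.fragments), default=1
    )
    n_bins = max(n_bins, 1)
    rows = []
    counts = []
    ptr = [0]
    for sig in sigs:
        for fs in sig.fragments:
            row = np.zeros(n_bins)
            if fs.count > 0:
                row[: len(fs.hist1d.counts)] = fs.hist1d.heights
            rows.append(row)
            counts.append(fs.count)
        ptr.append(len(rows))
    return {
        "frag_ptr": np.array(ptr, dtype=np.int64),
        "counts": np.array(counts, dtype=np.int64),
        "heights": np.array(rows),
        "bin_width": np.array([sigs[0].params.bin_width if sigs else 0.5]),
    }


def build_db(
    inputs: str | Path | list[str | Path],
    out: str | Path,
    params: SignatureParams = SignatureParams(),
    charge_method: str = "auto",
    molecules: list[Molecule] | None = None,
) -> SignatureDB:
    """Index a molecule library into a signature database file.

    ``inputs`` is a directory or a list of MOL2/SDF files (ignored when
    ``molecules`` is given directly).  Duplicate ids are skipped and counted;
    appending to an existing database with different generation parameters is
    refused.
    """
    out = Path(out)
    if molecules is None:
        paths: list[Path]
        if isinstance(inputs, (str, Path)):
            p = Path(inputs)
            paths = (
                sorted(list(p.glob("*.mol2")) + list(p.glob("*.sdf")))
                if p.is_dir()
                else [p]
            )
        else:
            paths = [Path(p) for p in inputs]
        molecules = [m for path in paths for m in read_molecules(path)]

    existing: dict[str, bytes] = {}
    if out.exists():
        old = SignatureDB(out)
        if old.params != params:
            raise ValueError(
                f"database {out} exists with different generation parameters; "
                "refusing to mix descriptor sets"
            )
        with zipfile.ZipFile(out) as zf:
            existing = {i: zf.read(f"sigs/{i}.fsig") for i in old.ids}

    blobs: dict[str, bytes] = dict(existing)
    sigs: dict[str, MoleculeSignature] = {}
    duplicates = 0
    for mol in molecules:
        if mol.id in blobs:
            duplicates += 1
            continue
        sig = compute_signature(mol, params, charge_method=charge_method)
        sigs[mol.id] = sig
        blobs[mol.id] = serialize_signature(sig)
    if duplicates:
        logger.info("skipped %d duplicate molecule ids", duplicates)

    all_sigs = [
        sigs[i] if i in sigs else deserialize_signature(blobs[i]) for i in blobs
    ]
    reduced = _reduced_arrays(all_sigs)
    buf = io.BytesIO()
    np.savez(buf, **reduced)

    header = {
        "format": "fragsig-db",
        "version": 1,
        "params": {k: getattr(params, k) for k in params.__dataclass_fields__},
        "ids": list(blobs),
        "duplicates_skipped": duplicates,
    }
    with zipfile.ZipFile(out, "w", compression=zipfile.ZIP_STORED) as zf:
        zf.writestr("header.json", json.dumps(header))
        for molecule_id, blob in blobs.items():
            zf.writestr(f"sigs/{molecule_id}.fsig", blob)
        zf.writestr("reduced.npz", buf.getvalue())
    return SignatureDB(out)


# ---------------------------------------------------------------------------
# Prefilter and search
# ---------------------------------------------------------------------------

def prefilter_search(
    qsig: MoleculeSignature, reduced: ReducedDB, K: int, method: str = "admissible"
) -> list[tuple[str, float]]:
    """Shortlist the K targets with the lowest connectivity-free bound.

    For every query fragment the best (lowest) shape-only L1 distance to any
    target fragment is found, ignoring connectivity and with no limit on
    target fragment reuse.  The default ``admissible`` bound is the smallest
    of these optima: every mapped score is a weighted mean of link distances,
    each at least its query fragment's optimum, so this bound never exceeds
    the best full mapped score and never prunes the true best hit.  The
    ``weighted`` method instead returns the count-weighted mean of the
    per-fragment optima (the same weighting as full mapped scoring); it
    discriminates more sharply but exceeds the score of strong substructure
    matches, which leave query fragments uncovered.  Returns (id, bound)
    pairs in ascending bound order.
    """
    if K <= 0:
        raise ValueError("candidate count K must be positive")
    if method not in ("admissible", "weighted"):
        raise ValueError(f"unknown prefilter method {method!r}")
    if qsig.params.bin_width != reduced.bin_width:
        raise ValueError("query bin width does not match the reduced database")
    n_bins = reduced.heights.shape[1]
    q_heights = []
    q_counts = qsig.fragment_counts()
    for fs in qsig.fragments:
        n = max(n_bins, len(fs.hist1d.counts))
        row = np.zeros(n)
        if fs.count > 0:
            row[: len(fs.hist1d.counts)] = fs.hist1d.heights
        q_heights.append(row)

    db_heights = reduced.heights
    if q_heights and len(q_heights[0]) > n_bins:
        pad = np.zeros((db_heights.shape[0], len(q_heights[0]) - n_bins))
        db_heights = np.hstack([db_heights, pad])

    # (n_query_fragments, n_db_fragments) all-pairs L1 distances
    dists = np.stack(
        [np.abs(db_heights - h[None, :]).sum(axis=1) for h in q_heights]
    )
    bounds: list[tuple[str, float]] = []
    for i, molecule_id in enumerate(reduced.ids):
        lo, hi = reduced.frag_ptr[i], reduced.frag_ptr[i + 1]
        block = dists[:, lo:hi]  # (m, fragments of target i)
        best = np.argmin(block, axis=1)
        smin = block[np.arange(block.shape[0]), best]
        if method == "admissible":
            bound = float(smin.min())
        else:
            weights = q_counts + reduced.counts[lo:hi][best]
            total = weights.sum()
            bound = float((weights * smin).sum() / total) if total > 0 else 2.0
        bounds.append((molecule_id, bound))
    bounds.sort(key=lambda x: (x[1], x[0]))
    return bounds[: min(K, len(bounds))]


@dataclass(frozen=True)
class HitRecord:
    rank: int
    target_id: str
    raw: float
    transformed: float | None
    mapping: tuple[tuple[int, int], ...]
    unused_query_pct: float
    unused_target_pct: float


@dataclass
class HitList:
    query_id: str
    records: list[HitRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [r.rank for r in self.records],
                "id": [r.target_id for r in self.records],
                "score": [r.raw for r in self.records],
                "T": [r.transformed for r in self.records],
                "unused_q_pct": [r.unused_query_pct for r in self.records],
                "unused_t_pct": [r.unused_target_pct for r in self.records],
                "mapping": [
                    ";".join(f"{q}-{t}" for q, t in r.mapping) for r in self.records
                ],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _best_to_record(target_id: str, best: MappedScore, rank: int = 0) -> HitRecord:
    return HitRecord(
        rank=rank,
        target_id=target_id,
        raw=best.raw,
        transformed=best.transformed,
        mapping=best.mapping.links,
        unused_query_pct=best.unused_query_pct,
        unused_target_pct=best.unused_target_pct,
    )


def full_search(
    qsig: MoleculeSignature,
    db: SignatureDB,
    candidates: list[str] | None = None,
    max_hits: int = DEFAULT_MAX_HITS,
    unused_threshold: float | None = DEFAULT_UNUSED_THRESHOLD,
    variant: str = "1d",
) -> HitList:
    """Run the full mapped comparison on the candidate list and rank hits.

    Targets whose every mapping leaves more than ``unused_threshold`` percent
    of either molecule unused are dropped.  Hits are sorted by ascending raw
    score (ties by id) and truncated to ``max_hits``.
    """
    ids = candidates if candidates is not None else list(db.ids)
    unknown = [i for i in ids if i not in db]
    if unknown:
        raise ValueError(f"candidates not present in the database: {unknown[:5]}")
    scored: list[tuple[str, MappedScore]] = []
    for target_id in ids:
        results = compare_molecules(
            qsig, db.get(target_id), variant=variant, unused_threshold=unused_threshold
        )
        if results:
            scored.append((target_id, results[0]))
    scored.sort(key=lambda x: (x[1].raw, x[0]))
    records = [
        _best_to_record(tid, best, rank)
        for rank, (tid, best) in enumerate(scored[:max_hits], start=1)
    ]
    return HitList(query_id=qsig.molecule_id, records=records)


def search_library(
    qsig: MoleculeSignature,
    db: SignatureDB,
    prefilter_k: int = DEFAULT_PREFILTER_K,
    max_hits: int = DEFAULT_MAX_HITS,
    unused_threshold: float | None = DEFAULT_UNUSED_THRESHOLD,
    variant: str = "1d",
) -> HitList:
    """Prefilter the database, then fully score and rank the shortlist."""
    shortlist = prefilter_search(qsig, db.reduced(), min(prefilter_k, len(db)))
    return full_search(
        qsig,
        db,
        candidates=[i for i, _ in shortlist],
        max_hits=max_hits,
        unused_threshold=unused_threshold,
        variant=variant,
    )


def merge_hitlists(lists: list[HitList]) -> HitList:
    """Non-redundant union; each id keeps its best (lowest) score."""
    best: dict[str, HitRecord] = {}
    for hl in lists:
        for rec in hl.records:
            if rec.target_id not in best or rec.raw < best[rec.target_id].raw:
                best[rec.target_id] = rec
    merged = sorted(best.values(), key=lambda r: (r.raw, r.target_id))
    records = [
        HitRecord(
            rank=i,
            target_id=r.target_id,
            raw=r.raw,
            transformed=r.transformed,
            mapping=r.mapping,
            unused_query_pct=r.unused_query_pct,
            unused_target_pct=r.unused_target_pct,
        )
        for i, r in enumerate(merged, start=1)
    ]
    query_ids = ",".join(dict.fromkeys(hl.query_id for hl in lists))
    return HitList(query_id=query_ids, records=records)


def roc_points(
    scores: dict[str, float] | HitList,
    labels: dict[str, bool],
    thresholds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve using the raw score as the variable threshold.

    Lower scores mean stronger predicted similarity, so an id is called
    positive when its score is at or below the threshold.
    """
    if isinstance(scores, HitList):
        scores = {r.target_id: r.raw for r in scores.records}
    missing = [i for i in scores if i not in labels]
    if missing:
        raise ValueError(f"unlabeled ids: {missing[:5]}")
    y = np.array([bool(labels[i]) for i in scores])
    s = np.array([scores[i] for i in scores], dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC needs at least one positive and one negative label")
    if thresholds is None:
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve(y, -s)
        return fpr, tpr
    fpr = np.array([( (s <= t) & ~y).sum() / (~y).sum() for t in thresholds])
    tpr = np.array([((s <= t) & y).sum() / y.sum() for t in thresholds])
    return fpr, tpr
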