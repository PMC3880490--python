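import dataclasses

import numpy as np
import pytest

from fragsig.fixtures import make_synthetic_signature, make_toy_library, make_toy_molecule
from fragsig.mapping import compare_molecules
from fragsig.screendb import (
    HitList,
    HitRecord,
    ReducedDB,
    _reduced_arrays,
    build_db,
    full_search,
    merge_hitlists,
    prefilter_search,
    roc_points,
)
from fragsig.signatures import SignatureParams

FAST = SignatureParams(n_segments=10_000, mesh_density=0.45)


@pytest.fixture(scope="module")
def small_db(tmp_path_factory):
    path = tmp_path_factory.mktemp("db") / "toys.fsig"
    molecules = make_toy_library(10)
    db = build_db(None, path, params=FAST, molecules=molecules)
    return db


def _reduced_of(sig):
    arrays = _reduced_arrays([sig])
    return ReducedDB(
        ids=[sig.molecule_id],
        frag_ptr=arrays["frag_ptr"],
        counts=arrays["counts"],
        heights=arrays["heights"],
        bin_width=float(arrays["bin_width"][0]),
    )


def test_build_db_indexes_each_unique_molecule(small_db):
    assert len(small_db) == 10
    assert "benzene" in small_db
    sig = small_db.get("benzene")
    assert sig.molecule_id == "benzene"
    red = small_db.reduced()
    assert len(red) == 10
    assert red.frag_ptr[-1] == red.heights.shape[0]


def test_build_db_skips_duplicates_and_guards_params(small_db, tmp_path):
    molecules = make_toy_library(10)
    db2 = build_db(None, small_db.path, params=FAST, molecules=molecules)
    assert len(db2) == 10  # same ids ingested twice: still 10

    other = dataclasses.replace(FAST, bin_width=1.0)
    with pytest.raises(ValueError, match="different generation parameters"):
        build_db(None, small_db.path, params=other, molecules=molecules[:1])


def test_build_db_from_files(tmp_path):
    from fragsig.chemio import write_mol2

    path = tmp_path / "two.mol2"
    write_mol2([make_toy_molecule("methane"), make_toy_molecule("benzene")], path)
    db = build_db([path], tmp_path / "two.fsig", params=FAST)
    assert sorted(db.ids) == ["benzene", "methane"]


def test_prefilter_returns_self_with_near_zero_bound(small_db):
    qsig = small_db.get("hexylbenzene")
    red = small_db.reduced()
    results = prefilter_search(qsig, red, K=len(small_db))
    as_dict = dict(results)
    assert as_dict["hexylbenzene"] == pytest.approx(0.0, abs=1e-12)
    assert [r for r, _ in results][0] == "hexylbenzene"
    # K larger than the library returns everything
    assert len(prefilter_search(qsig, red, K=10_000)) == len(small_db)
    with pytest.raises(ValueError, match="positive"):
        prefilter_search(qsig, red, K=0)


@pytest.mark.parametrize("method", ["admissible", "weighted"])
def test_prefilter_methods_sorted_ascending(small_db, method):
    qsig = small_db.get("biphenyl")
    results = prefilter_search(qsig, small_db.reduced(), K=10, method=method)
    bounds = [b for _, b in results]
    assert bounds == sorted(bounds)


def test_prefilter_bound_is_admissible_on_synthetic_pairs():
    rng = np.random.default_rng(17)
    for _ in range(40):
        q = make_synthetic_signature(int(rng.integers(1, 5)), "path", seed=int(rng.integers(1e6)))
        t = make_synthetic_signature(int(rng.integers(1, 5)), "path", seed=int(rng.integers(1e6)))
        bound = prefilter_search(q, _reduced_of(t), K=1)[0][1]
        best = compare_molecules(q, t)[0].raw
        assert bound <= best + 1e-12


def test_full_search_ranks_self_first(small_db):
    qsig = small_db.get("diphenylethane")
    hits = full_search(qsig, small_db)
    assert hits.records[0].target_id == "diphenylethane"
    assert hits.records[0].rank == 1
    scores = [r.raw for r in hits.records]
    assert scores == sorted(scores)
    ranks = [r.rank for r in hits.records]
    assert ranks == list(range(1, len(hits) + 1))


def test_full_search_is_deterministic(small_db):
    qsig = small_db.get("toluene")
    a = full_search(qsig, small_db)
    b = full_search(qsig, small_db)
    assert a.records == b.records


def test_full_search_rejects_unknown_candidates(small_db):
    with pytest.raises(ValueError, match="not present"):
        full_search(small_db.get("benzene"), small_db, candidates=["nonexistent"])


def test_hitlist_tsv_round_trip(small_db, tmp_path):
    import pandas as pd

    hits = full_search(small_db.get("benzene"), small_db, max_hits=5)
    out = tmp_path / "hits.tsv"
    hits.write_tsv(out)
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns[:3]) == ["rank", "id", "score"]
    assert len(df) == len(hits)


def test_merge_hitlists_keeps_best_score_per_id():
    def rec(i, tid, s):
        return HitRecord(i, tid, s, None, ((0, 0),), 0.0, 0.0)

    a = HitList("q", [rec(1, "x", 0.3), rec(2, "y", 0.5)])
    b = HitList("q", [rec(1, "x", 0.2), rec(2, "z", 0.4)])
    merged = merge_hitlists([a, b])
    by_id = {r.target_id: r for r in merged.records}
    assert by_id["x"].raw == 0.2
    assert len(merged) == 3
    assert [r.raw for r in merged.records] == sorted(r.raw for r in merged.records)

    disjoint = merge_hitlists(
        [
            HitList("q", [rec(i, f"a{i}", 0.1 * i) for i in range(1, 6)]),
            HitList("q", [rec(i, f"b{i}", 0.1 * i + 0.05) for i in range(1, 6)]),
        ]
    )
    assert len(disjoint) == 10
    single = HitList("q", [rec(1, "x", 0.3)])
    assert merge_hitlists([single]).records[0].target_id == "x"


def test_roc_points_reference_behaviors():
    scores = {f"m{i}": s for i, s in enumerate([0.1, 0.2, 0.3, 0.9, 1.0, 1.1])}
    labels = {f"m{i}": i < 3 for i in range(6)}
    fpr, tpr = roc_points(scores, labels)
    assert any(f == 0.0 and t == 1.0 for f, t in zip(fpr, tpr))

    rng = np.random.default_rng(0)
    big_scores = {f"r{i}": float(rng.random()) for i in range(2000)}
    random_labels = {k: bool(rng.random() < 0.5) for k in big_scores}
    fpr, tpr = roc_points(big_scores, random_labels)
    auc = np.trapezoid(tpr, fpr)
    assert abs(auc - 0.5) < 0.05

    with pytest.raises(ValueError, match="positive and one negative"):
        roc_points(scores, {k: True for k in scores})

    grid_fpr, grid_tpr = roc_points(scores, labels, thresholds=np.array([0.0, 0.5, 2.0]))
    np.testing.assert_allclose(grid_tpr, [0.0, 1.0, 1.0])
    np.testing.assert_allclose(grid_fpr, [0.0, 0.0, 1.0])
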