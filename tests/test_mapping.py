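import numpy as np
import pytest

from fragsig.fixtures import make_synthetic_signature
from fragsig.mapping import (
    FragmentGraph,
    FragmentMapping,
    compare_molecules,
    enumerate_mappings,
    l1_distance,
    linear_mapping_count,
    mapped_score,
    transform_score,
)
from fragsig.signatures import Histogram1D
from oracles import brute_force_contiguous_mappings, brute_force_maximal_mappings


def _hist(counts, bw=0.5):
    return Histogram1D(bw, np.asarray(counts))


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def test_single_vs_single_fragment():
    maps = enumerate_mappings(FragmentGraph.path(1), FragmentGraph.path(1))
    assert len(maps) == 1
    assert maps[0].links == ((0, 0),)


def test_path2_vs_path2_has_two_orientations():
    maps = enumerate_mappings(FragmentGraph.path(2), FragmentGraph.path(2))
    assert {m.links for m in maps} == {((0, 0), (1, 1)), ((0, 1), (1, 0))}


@pytest.mark.parametrize("m,n", [(m, n) for m in range(1, 5) for n in range(1, 5)])
def test_enumeration_matches_brute_force_on_paths(m, n):
    q, t = FragmentGraph.path(m), FragmentGraph.path(n)
    got = {frozenset(mp.links) for mp in enumerate_mappings(q, t)}
    assert got == brute_force_maximal_mappings(q, t)


@pytest.mark.parametrize(
    "qgraph,tgraph",
    [
        (FragmentGraph.star(4), FragmentGraph.path(3)),
        (FragmentGraph.star(3), FragmentGraph.star(4)),
        (FragmentGraph(3, frozenset({(0, 1), (1, 2), (0, 2)})), FragmentGraph.path(4)),
        (FragmentGraph(3, frozenset({(0, 1), (1, 2), (0, 2)})), FragmentGraph.star(4)),
    ],
)
def test_enumeration_matches_brute_force_on_stars_and_triangles(qgraph, tgraph):
    got = {frozenset(mp.links) for mp in enumerate_mappings(qgraph, tgraph)}
    assert got == brute_force_maximal_mappings(qgraph, tgraph)


def test_mappings_are_maximal_and_injective():
    q, t = FragmentGraph.path(3), FragmentGraph.path(4)
    for mp in enumerate_mappings(q, t):
        qs = [a for a, _ in mp.links]
        ts = [b for _, b in mp.links]
        assert len(set(qs)) == len(qs) and len(set(ts)) == len(ts)


# ---------------------------------------------------------------------------
# Closed-form linear count
# ---------------------------------------------------------------------------

def test_linear_mapping_count_five_by_five():
    assert linear_mapping_count(5, 5) == 85


@pytest.mark.parametrize("m,n", [(m, n) for m in range(1, 7) for n in range(1, 7)])
def test_linear_count_matches_exhaustive_interval_enumeration(m, n):
    assert linear_mapping_count(m, n) == len(brute_force_contiguous_mappings(m, n))


def test_linear_count_edge_cases():
    assert linear_mapping_count(1, 1) == 1
    assert linear_mapping_count(2, 3) == 10
    with pytest.raises(ValueError):
        linear_mapping_count(0, 3)


# ---------------------------------------------------------------------------
# L1 distance
# ---------------------------------------------------------------------------

def test_l1_identical_is_zero_and_disjoint_is_two():
    a = _hist([3, 3, 2])
    assert l1_distance(a, _hist([3, 3, 2])) == 0.0
    assert l1_distance(_hist([5, 0]), _hist([0, 7])) == 2.0


def test_l1_simple_value_and_padding():
    assert l1_distance(_hist([1, 1]), _hist([2])) == pytest.approx(1.0)


def test_l1_requires_matching_bin_width():
    with pytest.raises(ValueError, match="bin width"):
        l1_distance(_hist([1], bw=0.5), _hist([1], bw=1.0))


def test_l1_is_a_metric_on_random_triples():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b, c = (_hist(rng.integers(1, 50, size=8)) for _ in range(3))
        dab, dbc, dac = l1_distance(a, b), l1_distance(b, c), l1_distance(a, c)
        assert dab == pytest.approx(l1_distance(b, a))
        assert dac <= dab + dbc + 1e-12
        assert l1_distance(a, a) == 0.0


# ---------------------------------------------------------------------------
# Mapped scoring and the transform
# ---------------------------------------------------------------------------

def test_transform_score_reference_points():
    assert transform_score(2.0) == 0.0
    assert transform_score(1.0) == 1.0
    assert transform_score(0.25) == 3.0
    with pytest.raises(ValueError):
        transform_score(0.0)


def _two_fragment_signature(counts, hists, seed=0):
    sig = make_synthetic_signature(len(counts), "path", bins=4, seed=seed)
    for fs, c, h in zip(sig.fragments, counts, hists):
        fs.count = c
        fs.hist1d = _hist(h)
    return sig


def test_single_link_score_equals_plain_l1():
    q = _two_fragment_signature([100], [[1, 0]])
    t = _two_fragment_signature([200], [[0, 1]], seed=1)
    result = mapped_score(q, t, FragmentMapping(((0, 0),)))
    assert result.raw == pytest.approx(2.0)


def test_two_link_weighted_score_hand_computed():
    # link distances 0.2 and 1.0; counts (100, 300) / (200, 200)
    # ((100+200)*0.2 + (300+200)*1.0) / 800 = 0.7
    q = _two_fragment_signature([100, 300], [[90, 10], [100, 0]])
    t = _two_fragment_signature([200, 200], [[80, 20], [50, 50]], seed=1)
    result = mapped_score(q, t, FragmentMapping(((0, 0), (1, 1))))
    assert result.raw == pytest.approx(0.7)


def test_equal_weights_give_unweighted_mean():
    q = _two_fragment_signature([100, 100], [[1, 0], [1, 0]])
    t = _two_fragment_signature([100, 100], [[1, 0], [0, 1]], seed=1)
    result = mapped_score(q, t, FragmentMapping(((0, 0), (1, 1))))
    assert result.raw == pytest.approx((0.0 + 2.0) / 2)


def test_mapped_score_symmetric_under_swap():
    rng = np.random.default_rng(3)
    q = make_synthetic_signature(3, "path", seed=11)
    t = make_synthetic_signature(3, "path", seed=12)
    mapping = FragmentMapping(((0, 1), (1, 2)))
    fwd = mapped_score(q, t, mapping)
    rev = mapped_score(t, q, mapping.inverse())
    assert fwd.raw == pytest.approx(rev.raw)
    assert fwd.unused_query_pct == pytest.approx(rev.unused_target_pct)


def test_compare_molecule_with_itself():
    sig = make_synthetic_signature(3, "path", seed=5)
    results = compare_molecules(sig, sig)
    assert results[0].raw == pytest.approx(0.0)
    identity = ((0, 0), (1, 1), (2, 2))
    assert identity in [r.mapping.links for r in results if r.raw == 0.0]


def test_unused_fraction_filter_can_empty_the_result():
    q = make_synthetic_signature(1, "path", seed=6)
    t = make_synthetic_signature(3, "path", seed=7)
    results = compare_molecules(q, t, unused_threshold=0.0)
    # every mapping leaves two of the three target fragments unused
    assert results == []


def test_incompatible_bin_widths_are_refused():
    import dataclasses

    q = make_synthetic_signature(2, "path", seed=8)
    t = make_synthetic_signature(2, "path", seed=9)
    t.params = dataclasses.replace(t.params, bin_width=1.0)
    with pytest.raises(ValueError, match="incompatible"):
        compare_molecules(q, t)
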