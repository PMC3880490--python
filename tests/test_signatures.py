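import numpy as np
import pytest

from fragsig.chemio import assign_radii, ensure_charges
from fragsig.fixtures import make_sphere_mesh, make_toy_molecule
from fragsig.fragmenter import assign_fragments
from fragsig.raytrace import RayTrace, trace
from fragsig.signatures import (
    Histogram1D,
    MepAxis,
    SignatureParams,
    accumulate_1d,
    accumulate_2d,
    build_signature,
    deserialize_signature,
    global_histogram,
    normalize,
    serialize_signature,
)
from fragsig.surface import molecular_surface


def _toy_trace(positions, fragments, meps=None, elements=None):
    positions = np.asarray(positions, dtype=float)
    k = len(positions)
    return RayTrace(
        positions=positions,
        elements=np.asarray(elements if elements is not None else range(k)),
        meps=np.asarray(meps if meps is not None else np.zeros(k), dtype=float),
        run_ids=np.zeros(k, dtype=np.int64),
        directions=np.zeros((k, 3)),
        fragments=np.asarray(fragments, dtype=np.int64),
        seed=0,
        cone_angle=0.0,
        restart_count=0,
    )


@pytest.fixture(scope="module")
def diphenylethane_signature():
    mol = ensure_charges(assign_radii(make_toy_molecule("diphenylethane")), "keep-imported")
    frag = assign_fragments(mol)
    surf = molecular_surface(mol)
    rt = trace(surf, frag, n_segments=30_000, seed=3)
    params = SignatureParams(n_segments=30_000, seed=3)
    return build_signature(rt, frag, mol.id, params), rt, frag


def test_two_segment_histogram_example():
    # consecutive segments of 4 A and 5 A, single fragment, 1 A bins
    rt = _toy_trace([[0, 0, 0], [4, 0, 0], [4, 5, 0]], [0, 0, 0])
    intra, inter = accumulate_1d(rt, None, bin_width=1.0)
    h = normalize(intra[0])
    assert inter == {}
    assert h.counts[4] == 1 and h.counts[5] == 1
    np.testing.assert_allclose(h.heights[[4, 5]], [0.5, 0.5])
    assert h.heights.sum() == pytest.approx(1.0)


def test_identical_lengths_fill_one_bin():
    rt = _toy_trace([[0, 0, 0], [3, 0, 0], [3, 3, 0], [0, 3, 0]], [0, 0, 0, 0])
    intra, _ = accumulate_1d(rt, None, bin_width=0.5)
    h = normalize(intra[0])
    assert (h.heights == 1.0).sum() == 1
    assert h.counts.sum() == 3


def test_segment_counts_are_conserved(diphenylethane_signature):
    sig, rt, frag = diphenylethane_signature
    intra, inter = accumulate_1d(rt, frag, sig.params.bin_width)
    total = sum(h.total for h in intra.values()) + sum(h.total for h in inter.values())
    assert total == rt.n_segments
    assert sig.total_segments == rt.n_segments


def test_reflection_worked_example_2d():
    # a reflection bounded by 4 A and 5 A segments with MEP -0.5 at the bounce
    rt = _toy_trace([[0, 0, 0], [4, 0, 0], [4, 5, 0]], [0, 0, 0], meps=[0.1, -0.5, 0.2])
    shape_bin = int(9.0 / 0.5)

    intra, _ = accumulate_2d(rt, None, bin_width=0.5, mep_axis="reduced")
    h = intra[0]
    assert h.counts.sum() == 1
    assert h.counts[shape_bin, 0] == 1  # negative-potential bin

    intra_inv, _ = accumulate_2d(rt, None, bin_width=0.5, mep_axis="reduced_inverted")
    assert intra_inv[0].counts[shape_bin, 1] == 1  # sign reversed: positive bin

    axis = MepAxis("full", 0.025, 1.0)
    intra_full, _ = accumulate_2d(rt, None, bin_width=0.5, mep_axis=axis)
    assert intra_full[0].counts[shape_bin, axis.bin_of(np.array([-0.5]))[0]] == 1


def test_zero_potential_lands_in_positive_bin_by_convention():
    rt = _toy_trace([[0, 0, 0], [4, 0, 0], [4, 5, 0]], [0, 0, 0], meps=[0, 0, 0])
    intra, _ = accumulate_2d(rt, None, bin_width=0.5, mep_axis="reduced")
    assert intra[0].counts[:, 1].sum() == 1 and intra[0].counts[:, 0].sum() == 0


def test_2d_interior_reflection_attribution_across_fragments():
    rt = _toy_trace([[0, 0, 0], [4, 0, 0], [4, 5, 0]], [0, 1, 1])
    intra, inter = accumulate_2d(rt, None, bin_width=0.5, mep_axis="reduced")
    # the middle reflection's incoming segment crosses fragments 0 -> 1
    assert sum(h.total for h in intra.values()) == 0
    assert inter[(0, 1)].total == 1


def test_normalize_validates_and_is_idempotent():
    h = Histogram1D(0.5, np.array([2, 2]))
    np.testing.assert_allclose(normalize(h).heights, [0.5, 0.5])
    np.testing.assert_allclose(normalize(normalize(h)).heights, [0.5, 0.5])
    np.testing.assert_allclose(normalize(Histogram1D(0.5, np.array([1]))).heights, [1.0])
    with pytest.raises(ValueError, match="empty"):
        normalize(Histogram1D(0.5, np.zeros(0, dtype=int)))


def test_global_histogram_reconstruction_is_exact(diphenylethane_signature):
    sig, rt, _ = diphenylethane_signature
    recovered = global_histogram(sig)
    direct = np.bincount(
        np.floor(rt.segment_lengths / sig.params.bin_width).astype(int)
    )
    np.testing.assert_array_equal(recovered.counts, direct)


def test_global_histogram_of_single_fragment_equals_intra():
    rt = _toy_trace([[0, 0, 0], [4, 0, 0], [4, 5, 0]], [0, 0, 0])
    from fragsig.fragmenter import Fragmentation

    frag = Fragmentation(np.zeros(3, dtype=int), (3,), frozenset())
    sig = build_signature(rt, frag, "toy", SignatureParams())
    np.testing.assert_array_equal(global_histogram(sig).counts, sig.fragments[0].hist1d.counts)


def test_serialization_round_trip(diphenylethane_signature):
    sig, _, _ = diphenylethane_signature
    blob = serialize_signature(sig)
    again = deserialize_signature(blob)
    assert again.molecule_id == sig.molecule_id
    assert again.n_fragments == sig.n_fragments
    assert again.adjacency == sig.adjacency
    assert again.params == sig.params
    assert again.total_segments == sig.total_segments
    for a, b in zip(again.fragments, sig.fragments):
        assert a.count == b.count
        np.testing.assert_array_equal(a.hist1d.counts, b.hist1d.counts)
        for key in b.hist2d:
            np.testing.assert_array_equal(a.hist2d[key].counts, b.hist2d[key].counts)
    for pair in sig.inter_1d:
        np.testing.assert_array_equal(again.inter_1d[pair].counts, sig.inter_1d[pair].counts)


def test_serialization_rejects_corruption(diphenylethane_signature):
    sig, _, _ = diphenylethane_signature
    blob = serialize_signature(sig)
    with pytest.raises(ValueError, match="checksum"):
        deserialize_signature(blob[:-10])
    tampered = blob[:4] + (99).to_bytes(2, "big") + blob[6:]
    with pytest.raises(ValueError, match="version"):
        deserialize_signature(tampered)
    with pytest.raises(ValueError, match="container"):
        deserialize_signature(b"not a signature")


def test_scaling_coordinates_scales_the_length_support():
    small = trace(make_sphere_mesh(1.0, 3), n_segments=30_000, seed=1)
    big = trace(make_sphere_mesh(2.0, 3), n_segments=30_000, seed=1)
    ratio = big.segment_lengths.mean() / small.segment_lengths.mean()
    assert ratio == pytest.approx(2.0, rel=0.03)


def test_signature_stability_between_seeds():
    from fragsig.mapping import l1_distance

    mol = ensure_charges(assign_radii(make_toy_molecule("benzene")), "keep-imported")
    frag = assign_fragments(mol)
    surf = molecular_surface(mol)
    params = SignatureParams(n_segments=50_000)
    sigs = [
        build_signature(trace(surf, frag, n_segments=50_000, seed=s), frag, "b", params)
        for s in (11, 12)
    ]
    d = l1_distance(sigs[0].fragments[0].hist1d, sigs[1].fragments[0].hist1d)
    assert d < 0.05
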