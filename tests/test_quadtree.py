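import numpy as np
import pytest

from bandelet import (
    NO_FLOW,
    TransformParams,
    bandeletize_block,
    best_quadtree,
    block_cost,
    build_dictionary,
    forward_bandelet,
    inverse_bandelet,
    inverse_bandeletize_block,
    load_representation,
    pad_to_dyadic_square,
    save_representation,
    threshold_representation,
)
from bandelet.flow import FlowCandidate
from bandelet.quadtree import DIRECT
from conftest import make_step_edge

from _oracles import oracle_quadtree_l0


def _flow(slope, index=1):
    return FlowCandidate(slope, index)


class TestBandeletizeBlock:
    @pytest.mark.parametrize("shape", [(1, 1), (2, 2), (4, 4), (8, 8), (2, 8)])
    @pytest.mark.parametrize("slope", [-2.0, 0.0, 0.75, 1.0])
    def test_round_trip_identity(self, rng, shape, slope):
        block = rng.uniform(-50, 50, shape)
        coeffs = bandeletize_block(block, _flow(slope))
        assert coeffs.size == block.size  # length preserved
        rec = inverse_bandeletize_block(coeffs, _flow(slope), shape)
        assert np.abs(rec - block).max() < 1e-8

    def test_one_by_one_block_is_identity(self):
        out = bandeletize_block(np.array([[5.0]]), _flow(1.0))
        np.testing.assert_array_equal(out, [5.0])

    def test_alignment_sparsifies_constant_warped_lines(self):
        """Values depending only on the warped key x2 - s*x1 collapse into
        few significant coefficients once transformed along slope s."""
        s = 1.0
        x1, x2 = np.mgrid[0:8, 0:8]
        block = 40.0 * np.sign(np.sin(0.9 * (x2 - s * x1))) + 41.0
        coeffs = bandeletize_block(block, _flow(s))
        T = 30.0
        raw_count = int(np.count_nonzero(np.abs(block) > T))
        assert int(np.count_nonzero(np.abs(coeffs) > T)) < raw_count

    def test_zero_vector_inverts_to_zero_block(self):
        rec = inverse_bandeletize_block(np.zeros(16), _flow(0.5), (4, 4))
        np.testing.assert_array_equal(rec, np.zeros((4, 4)))

    def test_impulse_inverts_to_constant_warped_atom(self):
        """A unit impulse at the coarsest 1D position reconstructs the
        scaling atom: compare against pywt's own 1D synthesis."""
        import pywt

        coeffs = np.zeros(16)
        coeffs[0] = 1.0
        rec = inverse_bandeletize_block(coeffs, _flow(0.0), (4, 4))
        parts = [np.array([1.0])] + [np.zeros(2**k) for k in range(4)]
        seq = pywt.waverec(parts, "db2", mode="periodization")
        # slope 0 warp is the column-major ordering
        oracle = seq.reshape(4, 4).T
        np.testing.assert_allclose(rec, oracle, atol=1e-10)

    def test_no_flow_rejected(self):
        nf = FlowCandidate(NO_FLOW, 0)
        with pytest.raises(ValueError):
            bandeletize_block(np.zeros((4, 4)), nf)
        with pytest.raises(ValueError):
            inverse_bandeletize_block(np.zeros(16), nf, (4, 4))

    def test_mismatched_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            inverse_bandeletize_block(np.zeros(15), _flow(1.0), (4, 4))


class TestBlockCost:
    def test_zero_block_costs_one_geometry_unit(self):
        nf = FlowCandidate(NO_FLOW, 0)
        T = 17.0
        cost = block_cost(np.zeros((4, 4)), nf, T, 1.0, geometry_bits=5)
        assert cost == pytest.approx(T * T)  # R_G=1 for NO_FLOW, R_B=0

    def test_all_significant_block_cost(self):
        nf = FlowCandidate(NO_FLOW, 0)
        block = np.full((4, 4), 90.0)
        cost = block_cost(block, nf, 30.0, 2.0, geometry_bits=5)
        assert cost == pytest.approx(2.0 * 900.0 * (1 + 16))  # zero distortion

    def test_cost_non_decreasing_in_lambda(self, rng):
        block = rng.uniform(-80, 80, (8, 8))
        f = _flow(1.0)
        costs = [block_cost(block, f, 30.0, lam, 5) for lam in (0.5, 1.0, 2.0, 4.0)]
        assert all(b >= a for a, b in zip(costs, costs[1:]))

    def test_rejects_bad_parameters(self):
        nf = FlowCandidate(NO_FLOW, 0)
        with pytest.raises(ValueError):
            block_cost(np.zeros((4, 4)), nf, -1.0, 1.0, 5)
        with pytest.raises(ValueError):
            block_cost(np.zeros((4, 4)), nf, 1.0, 0.0, 5)


class TestBestQuadtree:
    def test_constant_subband_is_direct_no_flow_root(self, small_dictionary):
        tree = best_quadtree(np.full((8, 8), 2.0), 30.0, 1.0, small_dictionary, 2)
        assert tree.decision == DIRECT
        assert not tree.flow.is_flow

    def test_matches_exhaustive_enumeration(self, rng, small_dictionary):
        """Dynamic-programming L0 equals explicit enumeration of all
        admissible quadtrees on random and structured 8x8 subbands."""
        bits = small_dictionary.geometry_bits
        cases = [rng.uniform(-70, 70, (8, 8)) for _ in range(8)]
        cases += [
            make_step_edge(8, 1.0, hi=80, lo=0),
            make_step_edge(8, -2.0, hi=60, lo=-60),
            np.zeros((8, 8)),
            np.pad(np.full((4, 4), 90.0), ((0, 4), (0, 4))),
        ]
        for sub in cases:
            tree = best_quadtree(sub, 25.0, 1.0, small_dictionary, 2)
            l0_oracle = oracle_quadtree_l0(
                sub, 25.0, 1.0, small_dictionary.slopes, bits, 2, "db2")
            assert tree.L0 == pytest.approx(l0_oracle, rel=1e-10)

    def test_node_cost_identities(self, rng, small_dictionary):
        """L0 = min(L_direct, L_tilde) everywhere; subdivision is strict."""
        tree = best_quadtree(rng.uniform(-70, 70, (16, 16)), 25.0, 1.0,
                             small_dictionary, 4)

        def walk(node):
            assert node.L0 == pytest.approx(min(node.L_direct, node.L_tilde))
            if node.decision == "SUBDIVIDE":
                child_sum = sum(c.L0 for c in node.children) + 1.0 * 25.0**2
                assert node.L_tilde == pytest.approx(child_sum)
                assert node.L_tilde < node.L_direct  # ties keep DIRECT
                for c in node.children:
                    walk(c)
            else:
                assert node.flow is not None

        walk(tree)

    def test_leaves_tile_region_exactly(self, rng, small_dictionary):
        tree = best_quadtree(rng.uniform(-90, 90, (16, 16)), 20.0, 1.0,
                             small_dictionary, 4)
        covered = np.zeros((16, 16), dtype=int)
        for leaf in tree.leaves():
            x1, x2, h, w = leaf.region
            covered[x1:x1 + h, x2:x2 + w] += 1
        assert (covered == 1).all()

    def test_enlarging_dictionary_never_increases_l0(self, rng):
        """Min over a superset of flow candidates at equal geometry pricing:
        extra slopes can only lower (or preserve) the optimal cost."""
        from bandelet.flow import FlowCandidate, FlowDictionary

        def make(slopes):
            entries = [FlowCandidate(NO_FLOW, 0)]
            entries += [FlowCandidate(s, i + 1) for i, s in enumerate(slopes)]
            return FlowDictionary(tuple(entries))

        small = make([-2.0, -1.0, 0.0, 1.0, 2.0])       # 6 entries -> 3 bits
        large = make([-2.0, -1.5, -1.0, 0.0, 1.0, 1.5, 2.0])  # 8 -> 3 bits
        assert small.geometry_bits == large.geometry_bits
        for _ in range(5):
            sub = rng.uniform(-70, 70, (8, 8))
            l_small = best_quadtree(sub, 25.0, 1.0, small, 2).L0
            l_large = best_quadtree(sub, 25.0, 1.0, large, 2).L0
            assert l_large <= l_small + 1e-9

    def test_oblique_edge_in_one_quadrant_localises_flow(self, default_dictionary):
        """An edge confined to one quadrant should trigger one subdivision
        with flow assigned only in that quadrant."""
        sub = np.zeros((16, 16))
        sub[:8, :8] = make_step_edge(8, 1.0, hi=90, lo=-90)
        tree = best_quadtree(sub, 30.0, 1.0, default_dictionary, 4)
        assert tree.L_tilde < tree.L_direct
        assert tree.decision == "SUBDIVIDE"
        flowed_quadrants = set()
        for qi, child in enumerate(tree.children):
            for leaf in child.leaves():
                if leaf.flow.is_flow:
                    flowed_quadrants.add(qi)
        assert flowed_quadrants <= {0}

    def test_rejects_non_dyadic_input(self, small_dictionary):
        with pytest.raises(ValueError, match="pad"):
            best_quadtree(np.zeros((6, 6)), 30.0, 1.0, small_dictionary, 2)
        with pytest.raises(ValueError, match="pad"):
            best_quadtree(np.zeros((8, 4)), 30.0, 1.0, small_dictionary, 2)


class TestForwardInverse:
    def test_round_trip_on_random_images(self, rng, fast_params):
        for _ in range(3):
            x = rng.uniform(0, 255, (64, 64))
            rep = forward_bandelet(x, fast_params)
            rec = inverse_bandelet(rep)
            assert np.abs(rec - x).max() < 1e-8

    def test_round_trip_with_padding(self, rng):
        """Odd-sized images force non-dyadic subbands and exercise padding."""
        params = TransformParams(levels=2, n_directions=4)
        x = rng.uniform(0, 255, (48, 80))
        rep = forward_bandelet(x, params)
        rec = inverse_bandelet(rep)
        assert np.abs(rec - x).max() < 1e-8

    def test_constant_image_all_direct_no_flow(self, fast_params):
        rep = forward_bandelet(np.full((64, 64), 99.0), fast_params)
        assert rep.significant_count == 0
        for level in rep.trees:
            for tree in level:
                assert tree.decision == DIRECT
                assert not tree.flow.is_flow

    def test_coefficient_count_preserved(self, rng, fast_params):
        x = rng.uniform(0, 255, (64, 64))
        rep = forward_bandelet(x, fast_params)
        # padded detail grids: 3 orientations x 32x32 at level 1
        assert rep.coefficient_count() == 3 * 32 * 32

    def test_significant_count_non_increasing_in_threshold(self, rng):
        x = rng.uniform(0, 255, (32, 32))
        counts = []
        for T in (5.0, 15.0, 30.0, 60.0):
            rep = forward_bandelet(x, TransformParams(levels=1, T=T, n_directions=4))
            counts.append(threshold_representation(rep, T)[1])
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_thresholded_error_equals_discarded_energy(self, rng, fast_params):
        """Orthonormality: pixel-domain squared error after thresholding
        equals the summed squared discarded coefficients."""
        x = rng.uniform(0, 255, (64, 64))
        rep = forward_bandelet(x, fast_params)
        thr, _ = threshold_representation(rep, 30.0)
        rec = inverse_bandelet(thr)
        discarded = sum(
            float(np.sum(v[np.abs(v) <= 30.0] ** 2))
            for v in rep.leaf_coeffs.values()
        )
        assert np.sum((rec - x) ** 2) == pytest.approx(discarded, rel=1e-6)

    def test_zero_representation_inverts_to_zero(self, fast_params):
        rep = forward_bandelet(np.zeros((64, 64)), fast_params)
        assert np.abs(inverse_bandelet(rep)).max() < 1e-10


class TestAnisotropyGain:
    def test_curved_boundary_beats_plain_wavelet(self):
        """The premise of geometric adaptation: on a curved-boundary phantom
        the bandelet transform keeps fewer significant coefficients than the
        separable wavelet at the same threshold."""
        from bandelet import dwt2, hard_threshold
        from bandelet.phantom import PhantomSpec, generate_phantom

        img = generate_phantom(
            PhantomSpec(size=(64, 64), class_label=1, seed=42, speckle_scale=0.0))
        params = TransformParams(levels=2, T=30.0)
        rep = forward_bandelet(img, params)
        _, wavelet_count = hard_threshold(dwt2(img, "db2", 2), 30.0)
        assert rep.significant_count < wavelet_count


def test_pad_to_dyadic_square():
    grid = np.ones((5, 9))
    padded, orig = pad_to_dyadic_square(grid)
    assert padded.shape == (16, 16)
    assert orig == (5, 9)
    np.testing.assert_array_equal(padded[:5, :9], grid)
    assert padded[5:].sum() == 0 and padded[:, 9:].sum() == 0


def test_representation_archive_bit_exact(tmp_path, rng, fast_params):
    x = rng.uniform(0, 255, (64, 64))
    rep = forward_bandelet(x, fast_params)
    path = tmp_path / "rep.npz"
    save_representation(path, rep)
    loaded = load_representation(path)
    assert loaded.params == rep.params
    assert loaded.total_cost == rep.total_cost
    assert loaded.significant_count == rep.significant_count
    assert set(loaded.leaf_coeffs) == set(rep.leaf_coeffs)
    for key, vec in rep.leaf_coeffs.items():
        np.testing.assert_array_equal(loaded.leaf_coeffs[key], vec)
    rec = inverse_bandelet(loaded)
    assert np.abs(rec - x).max() < 1e-8
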