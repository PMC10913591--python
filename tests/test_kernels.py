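"""Kernel correctness: optimized operations against their naive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikemesh import (IndexMesh, SparseWeights, SpikeHistory, SpikeVector,
                       WeightMatrix, cast_precision, clip_full, clip_mesh,
                       default_multi_lag_amplitudes, gen_spike_vector,
                       gen_weight_matrix, mesh_from_spikes, nominal_bytes,
                       normalize_afferent, normalize_efferent,
                       sparse_synaptic_input, stdp_mesh, stdp_multi_lag,
                       stdp_outer, synaptic_input_indexed,
                       synaptic_input_product, transpose_layout)
from spikemesh.kernels import (DST_MAJOR, SRC_MAJOR,
                               count_outer_multiplications_instrumented,
                               outer_update_multiplications)


def sv(*bits):
    return SpikeVector(np.array(bits, dtype=bool))


def random_instance(rng, size_cap=200, p=0.01, layout=SRC_MAJOR, dtype=np.float64):
    S = int(rng.integers(1, size_cap + 1))
    D = int(rng.integers(1, size_cap + 1))
    shape = (S, D) if layout == SRC_MAJOR else (D, S)
    W = WeightMatrix(rng.random(shape).astype(dtype), layout)
    src = SpikeVector(rng.random(S) < p)
    dst = SpikeVector(rng.random(D) < p)
    return W, src, dst


class TestSpikeVector:
    def test_active_is_sorted_true_positions(self, rng):
        v = rng.random(500) < 0.05
        s = SpikeVector(v)
        assert np.array_equal(s.active, np.flatnonzero(v))
        assert (np.diff(s.active) > 0).all()

    def test_cache_invalidated_on_replace(self):
        s = sv(1, 0, 0)
        assert list(s.active) == [0]
        s.replace([False, True, True])
        assert list(s.active) == [1, 2]

    def test_values_frozen(self):
        s = sv(1, 0)
        with pytest.raises(ValueError):
            s.values[0] = False


class TestSynapticInput:
    def test_all_false_source_gives_zeros(self):
        W = WeightMatrix(np.ones((3, 2)), DST_MAJOR)
        src = sv(0, 0)
        assert np.array_equal(synaptic_input_product(W, src), np.zeros(3))
        assert np.array_equal(synaptic_input_indexed(W, src), np.zeros(3))

    def test_identity_matrix_routes_unit_spike(self):
        W = WeightMatrix(np.eye(4), DST_MAJOR)
        src = sv(0, 0, 1, 0)
        expect = np.array([0, 0, 1, 0.0])
        assert np.array_equal(synaptic_input_product(W, src), expect)
        assert np.array_equal(synaptic_input_indexed(W, src), expect)

    def test_hand_summed_3x2_example(self):
        W = WeightMatrix(np.array([[1., 2], [3, 4], [5, 6]]), DST_MAJOR)
        src = sv(1, 0)
        assert np.array_equal(synaptic_input_product(W, src), [1, 3, 5])
        assert np.array_equal(synaptic_input_indexed(W, src), [1, 3, 5])

    def test_size_mismatch_rejected(self):
        W = WeightMatrix(np.ones((3, 2)), DST_MAJOR)
        with pytest.raises(ValueError, match="length"):
            synaptic_input_indexed(W, sv(1, 0, 0))

    def test_indexed_equals_product_sweep_f64_exact(self, rng):
        """1,000 random src-major instances, N<=200, 1% spikes: bit-equal."""
        for _ in range(1000):
            W, src, _ = random_instance(rng)
            assert np.array_equal(synaptic_input_product(W, src),
                                  synaptic_input_indexed(W, src))

    def test_indexed_vs_product_f32_within_tolerance(self, rng):
        for _ in range(300):
            W, src, _ = random_instance(rng, dtype=np.float32)
            a = synaptic_input_product(W, src).astype(np.float64)
            b = synaptic_input_indexed(W, src).astype(np.float64)
            scale = np.maximum(np.abs(a), np.abs(b))
            with np.errstate(invalid="ignore"):
                rel = np.where(scale > 0, np.abs(a - b) / scale, 0.0)
            assert rel.max(initial=0.0) < 1e-5

    def test_layout_invariance(self, rng):
        """Indexed input agrees elementwise across both storage layouts (f64)."""
        for _ in range(200):
            W, src, _ = random_instance(rng)
            Wt = transpose_layout(W)
            a = synaptic_input_indexed(W, src)
            b = synaptic_input_indexed(Wt, src)
            np.testing.assert_array_almost_equal_nulp(a, b, nulp=4)

    def test_zero_fill_density_neutrality(self, rng):
        """Input depends on values only, not on how many entries are zero."""
        sp = SparseWeights.random(80, 60, 0.05, rng)
        dense = sp.to_dense()  # mostly zeros
        src = gen_spike_vector(80, 0.1, rng)
        assert np.array_equal(synaptic_input_indexed(dense, src),
                              sparse_synaptic_input(sp, src))


class TestTransposeLayout:
    def test_double_transpose_is_identity(self, rng):
        W, *_ = random_instance(rng)
        W2 = transpose_layout(transpose_layout(W))
        assert W2.layout == W.layout
        assert np.array_equal(W2.data, W.data)

    def test_semantics_preserved_and_shape_flipped(self):
        W = gen_weight_matrix((10000, 5000), "zeros", "f32", layout=DST_MAJOR)
        Wt = transpose_layout(W)
        assert W.data.shape == (10000, 5000)
        assert Wt.data.shape == (5000, 10000)
        assert (Wt.src_size, Wt.dst_size) == (W.src_size, W.dst_size) == (5000, 10000)


class TestSTDP:
    def test_no_post_spikes_leaves_weights(self):
        W = WeightMatrix(np.zeros((2, 2)), DST_MAJOR)
        stdp_outer(W, sv(1, 0), sv(0, 0), 1.0)
        assert not W.data.any()

    def test_hand_outer_2x2(self):
        W = WeightMatrix(np.zeros((2, 2)), DST_MAJOR)
        stdp_outer(W, sv(1, 0), sv(0, 1), 1.0)
        assert np.array_equal(W.data, [[0, 0], [1, 0]])

    def test_mesh_matches_hand_outer_2x2(self):
        W = WeightMatrix(np.zeros((2, 2)), DST_MAJOR)
        mesh = mesh_from_spikes(sv(1, 0), sv(0, 1), DST_MAJOR)
        stdp_mesh(W, mesh, 1.0)
        assert np.array_equal(W.data, [[0, 0], [1, 0]])

    def test_mesh_construction(self):
        mesh = mesh_from_spikes(sv(1, 0), sv(0, 1), DST_MAJOR)
        assert list(mesh.rows) == [1] and list(mesh.cols) == [0]
        empty = mesh_from_spikes(sv(0, 0), sv(0, 0), DST_MAJOR)
        assert empty.size == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_mesh_size_counting_property(self, seed):
        rng = np.random.default_rng(seed)
        pre = SpikeVector(rng.random(30) < 0.3)
        post = SpikeVector(rng.random(20) < 0.3)
        mesh = mesh_from_spikes(pre, post, DST_MAJOR)
        assert mesh.size == pre.count() * post.count()

    @pytest.mark.parametrize("dtype", [np.float64, np.float32, np.float16])
    def test_mesh_equals_outer_bitwise_sweep(self, rng, dtype):
        """1,000 random instances (f64) / 200 (others): final W bit-identical."""
        n = 1000 if dtype is np.float64 else 200
        for _ in range(n):
            W, src, dst = random_instance(rng, dtype=dtype)
            Wa, Wb = W.copy(), W.copy()
            stdp_outer(Wa, src, dst, 0.25)
            stdp_mesh(Wb, mesh_from_spikes(src, dst, W.layout), 0.25)
            assert np.array_equal(Wa.data, Wb.data)

    def test_out_of_range_mesh_rejected(self):
        W = WeightMatrix(np.zeros((2, 2)), DST_MAJOR)
        with pytest.raises(IndexError):
            stdp_mesh(W, IndexMesh(rows=[2], cols=[0]), 1.0)

    def test_naive_multiplication_count(self):
        pre = gen_spike_vector(7, 0.3, 0)
        post = gen_spike_vector(11, 0.3, 1)
        assert count_outer_multiplications_instrumented(pre, post) == 77
        assert outer_update_multiplications(11, 7) == 77


class TestMultiLagSTDP:
    def _histories(self, rng, S, D, depth=5, p=0.2):
        pre, post = SpikeHistory(depth), SpikeHistory(depth)
        for _ in range(depth):
            pre.push(SpikeVector(rng.random(S) < p))
            post.push(SpikeVector(rng.random(D) < p))
        return pre, post

    def test_zero_amplitudes_noop(self, rng):
        W, *_ = random_instance(rng, size_cap=30)
        pre, post = self._histories(rng, W.src_size, W.dst_size)
        before = W.data.copy()
        stdp_multi_lag(W, pre, post, {1: 0.0, -1: 0.0})
        assert np.array_equal(W.data, before)

    def test_single_lag_reduces_to_one_step_rule(self, rng):
        W, *_ = random_instance(rng, size_cap=30)
        pre, post = self._histories(rng, W.src_size, W.dst_size)
        Wa, Wb = W.copy(), W.copy()
        stdp_multi_lag(Wa, pre, post, {1: 0.3})
        stdp_mesh(Wb, mesh_from_spikes(pre[1], post[0], W.layout), 0.3)
        assert np.array_equal(Wa.data, Wb.data)

    def test_nine_lag_equals_sequential_outer_sweep(self, rng):
        """Random 9-lag windows match nine sequential outer updates bitwise."""
        amps = default_multi_lag_amplitudes(0.1)
        assert len(amps) == 9
        for _ in range(200):
            W, *_ = random_instance(rng, size_cap=60)
            pre, post = self._histories(rng, W.src_size, W.dst_size, p=0.1)
            Wa, Wb = W.copy(), W.copy()
            stdp_multi_lag(Wa, pre, post, amps)
            for lag in sorted(amps):
                if amps[lag] == 0.0:
                    continue
                p_, q_ = (pre[lag], post[0]) if lag >= 0 else (pre[0], post[-lag])
                stdp_outer(Wb, p_, q_, amps[lag])
            assert np.array_equal(Wa.data, Wb.data)

    def test_insufficient_history_rejected(self, rng):
        W, *_ = random_instance(rng, size_cap=10)
        pre, post = self._histories(rng, W.src_size, W.dst_size, depth=2)
        with pytest.raises(ValueError, match="history"):
            stdp_multi_lag(W, pre, post, {4: 0.1})

    def test_default_window_antisymmetric_decaying(self):
        amps = default_multi_lag_amplitudes(1.0, n_lags=4, tau_lag=3.0)
        assert amps[0] == 0.0
        for lag in (1, 2, 3, 4):
            assert amps[lag] > 0 > amps[-lag]
            assert amps[lag] == -amps[-lag]
        mags = [amps[l] for l in (1, 2, 3, 4)]
        assert mags == sorted(mags, reverse=True)


class TestClipAndNormalize:
    def test_mesh_entries_clamped_others_untouched(self):
        W = WeightMatrix(np.array([[1.5, 7.0], [-0.5, 0.4]]), DST_MAJOR)
        clip_mesh(W, IndexMesh(rows=[0, 1], cols=[0]), 0.0, 1.0)
        assert np.array_equal(W.data, [[1.0, 7.0], [0.0, 0.4]])

    def test_clip_after_update_hits_upper_bound(self):
        W = WeightMatrix(np.array([[0.8]]), DST_MAJOR)
        mesh = IndexMesh(rows=[0], cols=[0])
        stdp_mesh(W, mesh, 0.5)
        clip_mesh(W, mesh, 0.0, 1.0)
        assert W.data[0, 0] == 1.0

    def test_in_range_mesh_unchanged_and_bad_bounds_rejected(self):
        W = WeightMatrix(np.array([[0.5, 0.6]]), DST_MAJOR)
        clip_mesh(W, IndexMesh(rows=[0], cols=[0, 1]), 0.0, 1.0)
        assert np.array_equal(W.data, [[0.5, 0.6]])
        with pytest.raises(ValueError, match="w_min"):
            clip_mesh(W, IndexMesh(rows=[0], cols=[0]), 1.0, 0.0)

    def test_non_mesh_multiset_preserved(self, rng):
        W, src, dst = random_instance(rng, p=0.2)
        before = W.data.copy()
        mesh = mesh_from_spikes(src, dst, W.layout)
        stdp_mesh(W, mesh, 5.0)
        clip_mesh(W, mesh, 0.0, 1.0)
        inside = np.zeros(W.data.shape, dtype=bool)
        if mesh.size:
            inside[np.ix_(mesh.rows, mesh.cols)] = True
        assert np.array_equal(W.data[~inside], before[~inside])
        if mesh.size:
            sub = W.data[np.ix_(mesh.rows, mesh.cols)]
            assert ((0.0 <= sub) & (sub <= 1.0)).all()

    @pytest.mark.parametrize("layout", [DST_MAJOR, SRC_MAJOR])
    def test_afferent_normalization_unit_sums_idempotent(self, rng, layout):
        W, *_ = random_instance(rng, layout=layout)
        normalize_afferent(W)
        arr = W.as_dst_major_array()
        sums = arr.sum(axis=1)
        assert np.abs(sums[sums != 0] - 1.0).max() < 1e-9
        once = W.data.copy()
        normalize_afferent(W)
        assert np.abs(W.data - once).max() < 1e-12

    def test_afferent_direct_division_example(self):
        W = WeightMatrix(np.array([[1.0, 3.0]]), DST_MAJOR)
        normalize_afferent(W)
        assert np.array_equal(W.data, [[0.25, 0.75]])

    def test_zero_sum_row_guarded(self):
        W = WeightMatrix(np.array([[0.0, 0.0], [1.0, 1.0]]), DST_MAJOR)
        normalize_afferent(W)
        assert np.array_equal(W.data, [[0.0, 0.0], [0.5, 0.5]])

    def test_efferent_normalization_unit_outgoing_sums(self, rng):
        W, *_ = random_instance(rng)
        normalize_efferent(W)
        arr = W.as_dst_major_array()
        sums = arr.sum(axis=0)
        assert np.abs(sums[sums != 0] - 1.0).max() < 1e-9

    def test_row_already_normalized_unchanged(self):
        W = WeightMatrix(np.array([[0.25, 0.75]]), DST_MAJOR)
        normalize_afferent(W)
        assert np.array_equal(W.data, [[0.25, 0.75]])


class TestSparse:
    def test_empty_sparse_gives_zeros(self, rng):
        sp_ = SparseWeights.random(20, 10, 0.0, rng)
        src = gen_spike_vector(20, 0.5, rng)
        assert np.array_equal(sparse_synaptic_input(sp_, src), np.zeros(10))

    @pytest.mark.parametrize("density", [0.001, 0.01, 0.1])
    def test_densify_and_compare_sweep(self, rng, density):
        for _ in range(170):
            S = int(rng.integers(1, 201))
            D = int(rng.integers(1, 201))
            sp_ = SparseWeights.random(S, D, density, rng)
            src = gen_spike_vector(S, 0.01, rng)
            assert np.array_equal(sparse_synaptic_input(sp_, src),
                                  synaptic_input_indexed(sp_.to_dense(), src))

    def test_density_round_trips(self, rng):
        sp_ = SparseWeights.random(400, 500, 0.01, rng)
        assert abs(sp_.density - 0.01) < 0.005

    def test_dense_reconstruction_matches_source(self, rng):
        W, *_ = random_instance(rng, size_cap=50)
        sp_ = SparseWeights.from_weight_matrix(W)
        assert np.array_equal(sp_.to_dense().data, W.data)


class TestPrecision:
    def test_identity_casts(self, rng):
        W, *_ = random_instance(rng, size_cap=20)
        assert np.array_equal(cast_precision(W, "f64").data, W.data)
        roundtrip = cast_precision(cast_precision(W, "f32"), "f64")
        W32 = cast_precision(W, "f32")
        assert np.array_equal(roundtrip.data, W32.data.astype(np.float64))

    def test_f32_representable_roundtrip_identity(self):
        data = np.array([[0.5, 0.25], [1.0, 2.0]])
        W = WeightMatrix(data, DST_MAJOR)
        back = cast_precision(cast_precision(W, "f32"), "f64")
        assert np.array_equal(back.data, data)

    def test_unsupported_dtype_rejected(self, rng):
        W, *_ = random_instance(rng, size_cap=5)
        with pytest.raises(ValueError, match="unsupported"):
            cast_precision(W, "f128")

    def test_nominal_bytes(self):
        assert nominal_bytes(gen_weight_matrix((10, 10), "zeros", "f64")) == 800
        assert nominal_bytes(gen_weight_matrix((10, 10), "zeros", "f16")) == 200
        assert nominal_bytes(WeightMatrix(np.zeros((0, 5)), DST_MAJOR)) == 0


class TestSpikeHistory:
    def test_ring_semantics(self):
        h = SpikeHistory(3)
        vs = [sv(1, 0), sv(0, 1), sv(1, 1), sv(0, 0)]
        for v in vs:
            h.push(v)
        assert len(h) == 3
        assert h[0] is vs[3]
        assert h[2] is vs[1]
        with pytest.raises(IndexError):
            h[3]
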