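import numpy as np
import pytest

from handlat.fcd import (
    FcdParams,
    Scope,
    Sign,
    compute_fcd,
    compute_fcd_profile,
    fcd_scope_decomposition_check,
    log_transform_counts,
)
from handlat.preprocess import DenseTimeSeries
from handlat.space import LEFT, RIGHT, SurfaceSpace

from conftest import brute_force_counts


def four_vertex_fixture(rng):
    """v0 == v1 (left), v2 = -v0 (right), v3 independent noise (right)."""
    T = 200
    base = rng.standard_normal(T)
    data = np.vstack([base, base, -base, rng.standard_normal(T)])
    hemi = np.array([LEFT, LEFT, RIGHT, RIGHT], dtype=np.int8)
    space = SurfaceSpace(coords=rng.normal(size=(4, 3)), hemisphere=hemi)
    return DenseTimeSeries(data=data, tr=0.8), space


class TestFourVertexExample:
    def test_positive_global(self, rng):
        ts, space = four_vertex_fixture(rng)
        res = compute_fcd(ts, space, FcdParams(threshold=0.6))
        assert res.counts.values.tolist() == [1, 1, 0, 0]
        oracle = brute_force_counts(ts.data, 0.6, "positive")
        assert np.array_equal(res.counts.values, oracle)

    def test_negative_global(self, rng):
        ts, space = four_vertex_fixture(rng)
        res = compute_fcd(ts, space, FcdParams(threshold=0.6, sign=Sign.NEGATIVE))
        oracle = brute_force_counts(ts.data, 0.6, "negative")
        assert np.array_equal(res.counts.values, oracle)
        # v0 and v2 each carry at least the r = -1 edge between them
        assert res.counts.values[0] == 1
        assert res.counts.values[2] == 2  # v2 anticorrelates with both copies

    def test_scope_split(self, rng):
        ts, space = four_vertex_fixture(rng)
        ipsi = compute_fcd(ts, space, FcdParams(scope=Scope.IPSI)).counts.values
        contra = compute_fcd(ts, space, FcdParams(scope=Scope.CONTRA)).counts.values
        assert ipsi.tolist() == [1, 1, 0, 0]
        assert contra.tolist() == [0, 0, 0, 0]


def test_long_white_noise_has_no_edges(rng):
    T, N = 2000, 40
    data = rng.standard_normal((N, T))
    hemi = np.array([LEFT] * 20 + [RIGHT] * 20, np.int8)
    space = SurfaceSpace(coords=rng.normal(size=(N, 3)), hemisphere=hemi)
    ts = DenseTimeSeries(data=data, tr=0.8)
    res = compute_fcd(ts, space, FcdParams(threshold=0.6))
    assert res.counts.values.sum() == 0


class TestInvariants:
    @pytest.fixture
    def noisy_ts(self, rng, small_space):
        shared = rng.standard_normal(150)
        data = 0.6 * rng.standard_normal((60, 150)) + 0.8 * shared
        data[30:] += 0.5 * rng.standard_normal((30, 150))
        return DenseTimeSeries(data=data, tr=0.8)

    def test_threshold_monotonicity(self, noisy_ts, small_space):
        prev = None
        for thr in (0.3, 0.5, 0.7, 0.9):
            c = compute_fcd(noisy_ts, small_space, FcdParams(threshold=thr)).counts.values
            if prev is not None:
                assert np.all(c <= prev)
            prev = c

    def test_permutation_equivariance(self, noisy_ts, small_space, rng):
        perm = rng.permutation(60)
        base = compute_fcd(noisy_ts, small_space, FcdParams()).counts.values
        sp2 = SurfaceSpace(
            coords=small_space.coords[perm], hemisphere=small_space.hemisphere[perm]
        )
        ts2 = DenseTimeSeries(data=noisy_ts.data[perm], tr=0.8)
        permuted = compute_fcd(ts2, sp2, FcdParams()).counts.values
        assert np.array_equal(permuted, base[perm])

    def test_chunk_sizes_bit_identical(self, rng):
        N, T = 300, 300
        data = rng.standard_normal((N, T)) + 0.4 * rng.standard_normal(T)
        hemi = np.array([LEFT] * 150 + [RIGHT] * 150, np.int8)
        space = SurfaceSpace(coords=rng.normal(size=(N, 3)), hemisphere=hemi)
        ts = DenseTimeSeries(data=data, tr=0.8)
        ref = None
        for cs in (13, 128, 300):
            c = compute_fcd(ts, space, FcdParams(threshold=0.4, chunk_size=cs)).counts.values
            if ref is None:
                ref = c
            assert np.array_equal(c, ref)
        oracle = brute_force_counts(data, 0.4, "positive")
        assert np.array_equal(ref, oracle)

    def test_scope_oracles(self, noisy_ts, small_space):
        for scope, name in ((Scope.IPSI, "ipsi"), (Scope.CONTRA, "contra")):
            got = compute_fcd(noisy_ts, small_space, FcdParams(threshold=0.5, scope=scope))
            oracle = brute_force_counts(
                noisy_ts.data, 0.5, "positive", hemi=small_space.hemisphere, scope=name
            )
            assert np.array_equal(got.counts.values, oracle)

    def test_masked_frames_ignored(self, rng, small_space):
        data = rng.standard_normal((60, 100))
        mask = np.ones(100, bool)
        mask[::7] = False
        ts_a = DenseTimeSeries(data=data, tr=0.8, frame_mask=mask)
        # replace masked frames with garbage: counts must not change
        data_b = data.copy()
        data_b[:, ~mask] = 1e6 * rng.standard_normal((60, (~mask).sum()))
        ts_b = DenseTimeSeries(data=data_b, tr=0.8, frame_mask=mask)
        pa = compute_fcd(ts_a, small_space, FcdParams(threshold=0.3)).counts.values
        pb = compute_fcd(ts_b, small_space, FcdParams(threshold=0.3)).counts.values
        assert np.array_equal(pa, pb)

    def test_zero_variance_rows_have_no_edges(self, rng, small_space):
        data = rng.standard_normal((60, 80))
        data[5] = 4.2  # constant row
        ts = DenseTimeSeries(data=data, tr=0.8)
        res = compute_fcd(ts, small_space, FcdParams(threshold=0.3))
        assert res.counts.values[5] == 0


class TestLogRule:
    def test_zero_count_maps_to_zero(self):
        assert log_transform_counts(np.array([0.0]))[0] == 0.0

    def test_natural_log(self):
        out = log_transform_counts(np.array([0.0, 1.0, np.e**2]))
        assert np.allclose(out, [0.0, 0.0, 2.0])

    def test_log10(self):
        out = log_transform_counts(np.array([100.0]), "log10")
        assert out[0] == pytest.approx(2.0)

    def test_none_keeps_counts(self):
        out = log_transform_counts(np.array([0.0, 7.0]), "none")
        assert out.tolist() == [0.0, 7.0]


class TestErrors:
    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            FcdParams(threshold=1.0)
        with pytest.raises(ValueError):
            FcdParams(threshold=0.0)

    def test_too_few_frames(self, small_space, rng):
        mask = np.zeros(10, bool)
        mask[:2] = True
        ts = DenseTimeSeries(data=rng.standard_normal((60, 10)), tr=0.8, frame_mask=mask)
        with pytest.raises(ValueError, match="3 retained"):
            compute_fcd(ts, small_space, FcdParams())

    def test_unknown_scope(self, small_space, rng):
        ts = DenseTimeSeries(data=rng.standard_normal((60, 30)), tr=0.8)
        params = FcdParams()
        object.__setattr__(params, "scope", "sideways")
        with pytest.raises(ValueError, match="unknown"):
            compute_fcd(ts, small_space, params)


class TestDecomposition:
    def test_holds_on_synthetic_subject(self, rng, small_space):
        data = rng.standard_normal((60, 120)) + 0.5 * rng.standard_normal(120)
        ts = DenseTimeSeries(data=data, tr=0.8)
        report = fcd_scope_decomposition_check(ts, small_space, FcdParams(threshold=0.4))
        assert report["ok"]
        assert (
            report["total_edges_global"]
            == report["total_edges_ipsi"] + report["total_edges_contra"]
        )

    def test_four_vertex_decomposition(self, rng):
        ts, space = four_vertex_fixture(rng)
        report = fcd_scope_decomposition_check(ts, space, FcdParams(threshold=0.6))
        assert report["ok"]

    def test_lone_opposite_vertex_gives_zero_contra(self, rng):
        # nearly single-hemisphere space: the lone right vertex is constant,
        # so no contralateral edge can exist anywhere
        data = rng.standard_normal((10, 100))
        data[9] = 0.0
        hemi = np.array([LEFT] * 9 + [RIGHT], np.int8)
        space = SurfaceSpace(coords=rng.normal(size=(10, 3)), hemisphere=hemi)
        ts = DenseTimeSeries(data=data, tr=0.8)
        contra = compute_fcd(ts, space, FcdParams(threshold=0.3, scope=Scope.CONTRA))
        assert contra.counts.values.sum() == 0

    def test_profile_matches_individual_calls(self, rng, small_space):
        data = rng.standard_normal((60, 90)) + 0.6 * rng.standard_normal(90)
        ts = DenseTimeSeries(data=data, tr=0.8)
        profile = compute_fcd_profile(ts, small_space, threshold=0.4)
        for sign in Sign:
            for scope in Scope:
                single = compute_fcd(
                    ts, small_space, FcdParams(threshold=0.4, sign=sign, scope=scope)
                )
                assert np.array_equal(
                    profile[(sign, scope)].counts.values, single.counts.values
                )
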