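"""Gray-matter extraction, band-pass contract, nuisance regression."""

import numpy as np
import pytest

from voxconn import (
    bandpass,
    extract_gray_timeseries,
    make_affine,
    regress_nuisance,
)
from voxconn.preprocess import VoxelMatrix, bandpass_series
from voxconn.synth import BOLDSession, NuisanceSet, TissueMasks
from voxconn.grid import NodeMap


def _toy_session(data, voxel_size=(2.0, 2.0, 2.0), tr=2.0):
    affine = make_affine(data.shape[:3], voxel_size)
    return BOLDSession(data=data, affine=affine, voxel_size_mm=voxel_size,
                       tr_seconds=tr, subject_id="sub-01", condition="rest",
                       session_index=1)


def _masks_for(gray):
    white = np.zeros_like(gray)
    csf = np.zeros_like(gray)
    # carve one voxel each for white/CSF outside gray so the masks are valid
    free = np.argwhere(~gray)
    white[tuple(free[0])] = True
    csf[tuple(free[1])] = True
    return TissueMasks(gray=gray, white=white, csf=csf)


class TestExtraction:
    def test_one_column_per_gray_voxel(self, rng):
        data = rng.normal(size=(2, 2, 2, 10))
        gray = np.zeros((2, 2, 2), bool)
        gray[0, 0, 0] = gray[1, 0, 0] = gray[0, 1, 0] = True
        vm = extract_gray_timeseries(_toy_session(data), _masks_for(gray))
        assert vm.values.shape == (10, 3)

    def test_columns_equal_raw_time_courses(self, rng):
        data = rng.normal(size=(3, 2, 2, 8))
        gray = np.zeros((3, 2, 2), bool)
        gray[2, 1, 0] = gray[0, 0, 1] = True
        vm = extract_gray_timeseries(_toy_session(data), _masks_for(gray))
        for node in range(vm.n_nodes):
            i, j, k = vm.node_map.ijk[node]
            np.testing.assert_array_equal(vm.values[:, node], data[i, j, k])

    def test_column_order_is_x_fastest(self, rng):
        data = rng.normal(size=(3, 3, 1, 4))
        gray = np.ones((3, 3, 1), bool)
        gray[1, 0, 0] = False
        white = np.zeros_like(gray); csf = np.zeros_like(gray)
        white[1, 0, 0] = True
        vm = extract_gray_timeseries(
            _toy_session(data), TissueMasks(gray, white, csf))
        # x fastest: (0,0,0), (2,0,0), (0,1,0), (1,1,0), ...
        expected = [(0, 0, 0), (2, 0, 0), (0, 1, 0), (1, 1, 0)]
        assert [tuple(r) for r in vm.node_map.ijk[:4]] == expected

    def test_node_mm_round_trip_is_identity(self, small_study):
        rec = small_study.sessions[0]
        vm = extract_gray_timeseries(rec.session, rec.masks)
        nm = vm.node_map
        for node in [0, nm.n_nodes // 2, nm.n_nodes - 1]:
            i, j, k = nm.ijk[node]
            assert nm.node_of_ijk(i, j, k) == node
        # mm coordinates invert through the affine
        back = (nm.mm - nm.affine[:3, 3]) @ np.linalg.inv(nm.affine[:3, :3]).T
        np.testing.assert_allclose(back, nm.ijk, atol=1e-9)

    def test_shape_mismatch_and_empty_mask_errors(self, rng):
        data = rng.normal(size=(2, 2, 2, 5))
        bad = np.zeros((3, 2, 2), bool)
        bad[0, 0, 0] = True
        masks = _masks_for(bad)
        with pytest.raises(ValueError, match="mask shape"):
            extract_gray_timeseries(_toy_session(data), masks)
        empty = np.zeros((2, 2, 2), bool)
        with pytest.raises(Exception):
            extract_gray_timeseries(_toy_session(data), _masks_for(empty))


def _vm_from_columns(cols, tr=2.0):
    cols = np.asarray(cols)
    n = cols.shape[1]
    gray = np.zeros((n, 1, 1), bool)
    gray[:, 0, 0] = True
    nm = NodeMap.from_mask(gray, make_affine((n, 1, 1), (2, 2, 2)))
    return VoxelMatrix(values=cols, node_map=nm, tr_seconds=tr)


class TestBandpass:
    t = np.arange(240) * 2.0

    @pytest.mark.parametrize("kind", ["fft", "butter"])
    def test_passband_sinusoid_preserved(self, kind):
        x = np.sin(2 * np.pi * 0.03 * self.t)[:, None]
        y = bandpass(_vm_from_columns(x), kind=kind).values
        assert np.sqrt((y ** 2).mean()) >= 0.8 * np.sqrt((x ** 2).mean())

    @pytest.mark.parametrize("kind", ["fft", "butter"])
    def test_dc_removed(self, kind):
        x = np.full((240, 1), 5.0)
        y = bandpass(_vm_from_columns(x), kind=kind).values
        assert np.sqrt((y ** 2).mean()) <= 0.01 * 5.0

    @pytest.mark.parametrize("kind", ["fft", "butter"])
    def test_stopband_suppressed(self, kind):
        x = np.sin(2 * np.pi * 0.2 * self.t)[:, None]
        y = bandpass(_vm_from_columns(x), kind=kind).values
        assert np.sqrt((y ** 2).mean()) <= 0.2 * np.sqrt((x ** 2).mean())

    def test_invalid_band_rejected(self):
        x = np.zeros((100, 1))
        with pytest.raises(ValueError, match="band"):
            bandpass(_vm_from_columns(x), low_hz=0.1, high_hz=0.3)  # > Nyquist
        with pytest.raises(ValueError, match="band"):
            bandpass(_vm_from_columns(x), low_hz=0.08, high_hz=0.009)

    def test_filter_recorded_in_metadata(self):
        vm = bandpass(_vm_from_columns(np.zeros((100, 1))))
        assert vm.meta["filter"] == dict(kind="fft", low_hz=0.009,
                                         high_hz=0.08)


def _nuisance(rng, t):
    return NuisanceSet(motion=rng.normal(size=(t, 6)),
                       global_signal=rng.normal(size=t),
                       white_signal=rng.normal(size=t),
                       csf_signal=rng.normal(size=t))


class TestNuisanceRegression:
    def test_column_equal_to_regressor_goes_to_zero(self, rng):
        t = 120
        nz = _nuisance(rng, t)
        vm = _vm_from_columns(nz.global_signal[:, None].copy())
        out = regress_nuisance(vm, nz, filter_regressors=False)
        assert np.max(np.abs(out.values)) <= 1e-8 * np.max(
            np.abs(nz.global_signal))

    def test_orthogonal_column_passes_through(self, rng):
        t = 120
        nz = _nuisance(rng, t)
        _, cols = nz.design_columns()
        X = np.column_stack([np.ones(t), cols])
        y = rng.normal(size=t)
        # project out the design so the column is exactly orthogonal
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        out = regress_nuisance(_vm_from_columns(y[:, None]), nz,
                               filter_regressors=False)
        np.testing.assert_allclose(out.values[:, 0], y, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        t = 120
        nz = _nuisance(rng, t)
        Y = rng.normal(size=(t, 10))
        out = regress_nuisance(_vm_from_columns(Y), nz,
                               filter_regressors=False)
        _, cols = nz.design_columns()
        X = np.column_stack([np.ones(t), cols])
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(out.values, Y - X @ beta, atol=1e-6)

    def test_residuals_orthogonal_to_all_regressors(self, rng):
        t = 150
        nz = _nuisance(rng, t)
        Y = rng.normal(size=(t, 12))
        out = regress_nuisance(_vm_from_columns(Y), nz,
                               filter_regressors=False)
        _, cols = nz.design_columns()
        for col in cols.T:
            r = np.corrcoef(np.column_stack([col[:, None],
                                             out.values]).T)[0, 1:]
            assert np.max(np.abs(r)) <= 1e-8

    def test_idempotent(self, rng):
        t = 100
        nz = _nuisance(rng, t)
        Y = rng.normal(size=(t, 6))
        once = regress_nuisance(_vm_from_columns(Y), nz,
                                filter_regressors=False)
        twice = regress_nuisance(once, nz, filter_regressors=False)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)

    def test_zero_variance_column_passes_through(self, rng, caplog):
        t = 80
        nz = _nuisance(rng, t)
        Y = rng.normal(size=(t, 3))
        Y[:, 1] = 0.0
        import logging
        with caplog.at_level(logging.WARNING, logger="voxconn.preprocess"):
            out = regress_nuisance(_vm_from_columns(Y), nz,
                                   filter_regressors=False)
        np.testing.assert_array_equal(out.values[:, 1], 0.0)
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_rank_deficient_design_drops_column(self, rng, caplog):
        t = 90
        nz = _nuisance(rng, t)
        nz.white_signal = nz.global_signal.copy()   # duplicate regressor
        Y = rng.normal(size=(t, 4))
        import logging
        with caplog.at_level(logging.WARNING, logger="voxconn.preprocess"):
            out = regress_nuisance(_vm_from_columns(Y), nz,
                                   filter_regressors=False)
        assert any("rank-deficient" in r.message for r in caplog.records)
        assert out.values.shape == Y.shape

    def test_length_mismatch_rejected(self, rng):
        nz = _nuisance(rng, 50)
        with pytest.raises(ValueError, match="length"):
            regress_nuisance(_vm_from_columns(rng.normal(size=(60, 2))), nz)

    def test_regressors_filtered_by_default(self, rng):
        """Filtering regressors changes the projection; flag disables it."""
        t = 120
        nz = _nuisance(rng, t)
        vm = bandpass(_vm_from_columns(rng.normal(size=(t, 5))))
        a = regress_nuisance(vm, nz)
        b = regress_nuisance(vm, nz, filter_regressors=False)
        assert a.meta["regressors_filtered"] is True
        assert not np.allclose(a.values, b.values)
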