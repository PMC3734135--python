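"""Spherical ROI masks, ROI means, and the 2 x S within-subject ANOVA."""

import numpy as np
import pandas as pd
import pytest

from voxconn import (
    ROISpec,
    make_affine,
    roi_mean,
    rm_anova_2xS,
    sphere_mask,
)
from voxconn.grid import NodeMap
from voxconn.metrics import MetricVolume
from voxconn.roistats import rm_anova_array
from oracles import anova_2way_within


class TestSphereMask:
    shape = (14, 14, 10)
    affine = make_affine(shape, (4.0, 4.0, 5.0))

    def test_radius_zero_at_voxel_center_selects_that_voxel(self):
        center_mm = (np.array([3, 3, 3]) @ self.affine[:3, :3].T
                     + self.affine[:3, 3])
        mask = sphere_mask(ROISpec("pt", [center_mm], 0.0),
                           self.shape, self.affine)
        assert mask.sum() == 1
        assert mask[3, 3, 3]

    def test_center_between_voxels_small_radius_empty(self, caplog):
        center_mm = (np.array([3.5, 3, 3]) @ self.affine[:3, :3].T
                     + self.affine[:3, 3])
        import logging
        with caplog.at_level(logging.WARNING, logger="voxconn.roistats"):
            mask = sphere_mask(ROISpec("gap", [center_mm], 1.5),
                               self.shape, self.affine)
        assert mask.sum() == 0
        assert any("no voxel centers" in r.message for r in caplog.records)

    def test_ten_mm_sphere_matches_brute_force_enumeration(self):
        center = np.array([2.0, -14.0, 7.5])
        mask = sphere_mask(ROISpec("roi", [center], 10.0),
                           self.shape, self.affine)
        count = 0
        for i in range(self.shape[0]):
            for j in range(self.shape[1]):
                for k in range(self.shape[2]):
                    mm = (np.array([i, j, k]) @ self.affine[:3, :3].T
                          + self.affine[:3, 3])
                    inside = np.sqrt(((mm - center) ** 2).sum()) <= 10.0
                    count += inside
                    assert mask[i, j, k] == inside
        assert mask.sum() == count > 0

    def test_bilateral_union(self):
        left = np.array([-20.0, 0.0, 0.0])
        right = np.array([20.0, 0.0, 0.0])
        union = sphere_mask(ROISpec("both", [left, right], 10.0),
                            self.shape, self.affine)
        l_only = sphere_mask(ROISpec("l", [left], 10.0),
                             self.shape, self.affine)
        r_only = sphere_mask(ROISpec("r", [right], 10.0),
                             self.shape, self.affine)
        np.testing.assert_array_equal(union, l_only | r_only)


class TestRoiMean:
    def _metric(self, values, mask_shape=(4, 4, 2)):
        gray = np.zeros(mask_shape, bool)
        gray.ravel()[:len(values)] = True
        nm = NodeMap.from_mask(gray, make_affine(mask_shape, (1, 1, 1)))
        return MetricVolume("K", np.asarray(values, float), nm), gray

    def test_constant_metric_returns_constant(self):
        mv, gray = self._metric([3.5] * 6)
        value, n = roi_mean(mv, gray)
        assert value == pytest.approx(3.5) and n == 6

    def test_two_voxel_mean(self):
        gray = np.zeros((2, 1, 1), bool)
        gray[:, 0, 0] = True
        nm = NodeMap.from_mask(gray, make_affine((2, 1, 1), (1, 1, 1)))
        mv = MetricVolume("K", np.array([1.0, 3.0]), nm)
        value, n = roi_mean(mv, gray)
        assert value == pytest.approx(2.0) and n == 2

    def test_matches_loop_accumulation_oracle(self, rng):
        gray = rng.random((5, 5, 3)) < 0.6
        gray[0, 0, 0] = True
        nm = NodeMap.from_mask(gray, make_affine((5, 5, 3), (2, 2, 2)))
        values = rng.normal(size=nm.n_nodes)
        mv = MetricVolume("K", values, nm)
        roi = rng.random((5, 5, 3)) < 0.5
        if not (roi & gray).any():
            roi |= gray
        total, count = 0.0, 0
        for node in range(nm.n_nodes):
            if roi[tuple(nm.ijk[node])]:
                total += values[node]
                count += 1
        value, n = roi_mean(mv, roi)
        assert n == count
        assert value == pytest.approx(total / count)

    def test_empty_intersection_rejected(self):
        gray = np.zeros((2, 2, 1), bool)
        gray[0, 0, 0] = True
        nm = NodeMap.from_mask(gray, make_affine((2, 2, 1), (1, 1, 1)))
        mv = MetricVolume("K", np.array([1.0]), nm)
        with pytest.raises(ValueError, match="no gray"):
            roi_mean(mv, np.zeros((2, 2, 1), bool))


class TestAnova:
    def test_all_identical_values_degenerate(self):
        y = np.full((5, 2, 5), 3.0)
        with pytest.warns(UserWarning, match="F undefined"):
            res = rm_anova_array(y)
        assert np.isnan(res["condition"].F)
        assert res["condition"].degenerate

    def test_pure_condition_effect_partial_eta_one(self):
        y = np.empty((5, 2, 5))
        y[:, 0, :] = 1.0
        y[:, 1, :] = 2.0
        with pytest.warns(UserWarning, match="boundary"):
            res = rm_anova_array(y)
        assert res["condition"].partial_eta_squared == pytest.approx(1.0)
        assert res["condition"].p == 0.0

    def test_matches_brute_force_ss_oracle(self, rng):
        y = rng.normal(size=(5, 2, 5))
        res = rm_anova_array(y)
        oracle = anova_2way_within(y)
        for eff in ("condition", "session", "condition x session"):
            assert res[eff].F == pytest.approx(oracle[eff]["F"], abs=1e-8)
            assert res[eff].df_num == oracle[eff]["df_num"]
            assert res[eff].df_den == oracle[eff]["df_den"]
            assert res[eff].partial_eta_squared == pytest.approx(
                oracle[eff]["partial_eta_squared"], abs=1e-8)

    def test_ss_decomposition_conserves_total(self, rng):
        y = rng.normal(size=(6, 2, 4))
        res = rm_anova_array(y)
        parts = (res.ss_subject
                 + sum(res[e].ss_effect + res[e].ss_error
                       for e in ("condition", "session",
                                 "condition x session")))
        assert parts == pytest.approx(res.ss_total, rel=1e-8)

    def test_scale_invariance(self, rng):
        y = rng.normal(size=(5, 2, 5)) + 10
        a = rm_anova_array(y)
        b = rm_anova_array(y * 37.5)
        for eff in ("condition", "session", "condition x session"):
            assert a[eff].F == pytest.approx(b[eff].F, rel=1e-10)
            assert a[eff].p == pytest.approx(b[eff].p, rel=1e-10)
            assert a[eff].partial_eta_squared == pytest.approx(
                b[eff].partial_eta_squared, rel=1e-10)

    def test_matches_statsmodels_anova_rm(self, rng):
        """Independent cross-check of F and p against statsmodels."""
        from statsmodels.stats.anova import AnovaRM
        y = rng.normal(size=(6, 2, 3))
        rows = [dict(subject=s, condition=f"c{c}", session=f"s{b}",
                     value=y[s, c, b])
                for s in range(6) for c in range(2) for b in range(3)]
        frame = pd.DataFrame(rows)
        sm_res = AnovaRM(frame, "value", "subject",
                         within=["condition", "session"]).fit().anova_table
        res = rm_anova_array(y)
        assert res["condition"].F == pytest.approx(
            sm_res.loc["condition", "F Value"], rel=1e-8)
        assert res["session"].F == pytest.approx(
            sm_res.loc["session", "F Value"], rel=1e-8)
        assert res["condition x session"].F == pytest.approx(
            sm_res.loc["condition:session", "F Value"], rel=1e-8)
        assert res["condition"].p == pytest.approx(
            sm_res.loc["condition", "Pr > F"], abs=1e-10)

    def test_table_interface_and_missing_cell(self, rng):
        y = rng.normal(size=(4, 2, 3))
        rows = [dict(subject=f"sub-{s}", condition=c, session=b,
                     scope="wholebrain", metric="Eloc",
                     value=y[s, ci, b - 1])
                for s in range(4)
                for ci, c in enumerate(["rest", "task"])
                for b in (1, 2, 3)]
        table = pd.DataFrame(rows)
        res = rm_anova_2xS(table, "Eloc", "wholebrain")
        direct = rm_anova_array(y)
        assert res["condition"].F == pytest.approx(direct["condition"].F)
        broken = table[~((table.subject == "sub-0")
                         & (table.condition == "task")
                         & (table.session == 2))]
        with pytest.raises(ValueError, match="missing cell"):
            rm_anova_2xS(broken, "Eloc", "wholebrain")

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova_array(np.zeros((1, 2, 5)))
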