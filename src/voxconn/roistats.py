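"""Spherical ROI masks, ROI-mean metrics, and 2 x S within-subject ANOVA.

ROIs are spheres in millimetre space (default radius 10 mm; bilateral
regions are the union of both spheres).  ROI values are arithmetic
means of the nodal metric over gray voxels inside the mask.

The inference is a fully within-subjects two-way ANOVA on the complete
subject x condition (2) x session (S) crossing: each effect (condition,
session, condition x session) is tested against its own
effect-by-subject error term, and the effect size reported is partial
eta squared, SS_effect / (SS_effect + SS_error).  With two conditions
the condition effect has df = (1, n_subjects - 1), so no sphericity
correction is needed for the primary contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import voxel_centers_mm
from .metrics import MetricVolume

log = logging.getLogger(__name__)


@dataclass
class ROISpec:
    """A named ROI: union of spheres at mm centers."""

    name: str
    centers_mm: Sequence
    radius_mm: float = 10.0

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers_mm, dtype=float))
        if centers.shape[1] != 3 or centers.shape[0] < 1:
            raise ValueError(f"ROI {self.name}: centers must be (k, 3) mm")
        if self.radius_mm < 0:
            raise ValueError(f"ROI {self.name}: radius must be >= 0")
        self.centers_mm = centers


def sphere_mask(spec: ROISpec, grid_shape, affine) -> np.ndarray:
    """Boolean volume: voxel centers within radius of any listed center."""
    mm = voxel_centers_mm(grid_shape, affine)
    mask = np.zeros(grid_shape, dtype=bool)
    for center in spec.centers_mm:
        dist = np.sqrt(((mm - center) ** 2).sum(axis=-1))
        mask |= dist <= spec.radius_mm
    if not mask.any():
        log.warning("ROI %s: sphere(s) contain no voxel centers on this grid",
                    spec.name)
    return mask


def roi_mean(metric: MetricVolume, mask: np.ndarray):
    """(mean, n_voxels) of the nodal metric over in-mask gray nodes."""
    if metric.node_map is None:
        raise ValueError("metric has no node map")
    inside = metric.node_map.nodes_of_volume_mask(mask)
    n = int(inside.sum())
    if n == 0:
        raise ValueError("ROI mask contains no gray-matter nodes")
    return float(metric.values[inside].mean()), n


@dataclass
class AnovaEffect:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_squared: float
    ss_effect: float
    ss_error: float
    degenerate: bool = False


@dataclass
class AnovaResult:
    effects: Dict[str, AnovaEffect]
    ss_total: float
    ss_subject: float
    grand_mean: float

    def __getitem__(self, key) -> AnovaEffect:
        return self.effects[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"effect": e.effect, "F": e.F, "df_num": e.df_num,
                 "df_den": e.df_den, "p": e.p,
                 "partial_eta_squared": e.partial_eta_squared,
                 "ss_effect": e.ss_effect, "ss_error": e.ss_error}
                for e in self.effects.values()]
        return pd.DataFrame(rows)


def _effect(name, ss_eff, ss_err, df_num, df_den) -> AnovaEffect:
    if df_num < 1 or df_den < 1:
        warnings.warn(f"{name}: no degrees of freedom; F undefined")
        return AnovaEffect(name, np.nan, df_num, df_den, np.nan, np.nan,
                           ss_eff, ss_err, degenerate=True)
    if ss_err <= 0:
        if ss_eff <= 0:
            warnings.warn(f"{name}: zero effect and error SS; F undefined")
            return AnovaEffect(name, np.nan, df_num, df_den, np.nan, np.nan,
                               ss_eff, ss_err, degenerate=True)
        warnings.warn(f"{name}: zero error SS; p reported at the boundary")
        return AnovaEffect(name, np.inf, df_num, df_den, 0.0, 1.0,
                           ss_eff, ss_err, degenerate=True)
    F = (ss_eff / df_num) / (ss_err / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    peta = ss_eff / (ss_eff + ss_err)
    return AnovaEffect(name, float(F), df_num, df_den, p, float(peta),
                       ss_eff, ss_err)


def rm_anova_array(y: np.ndarray) -> AnovaResult:
    """Fully within-subjects two-way ANOVA on y[subject, condition, session].

    Requires the complete balanced crossing (no missing cells) and at
    least two subjects.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("y must be (subjects, conditions, sessions)")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(y).any():
        raise ValueError("missing cells in the subject x condition x session "
                         "crossing")
    m = y.mean()
    m_s = y.mean(axis=(1, 2))            # subject means
    m_c = y.mean(axis=(0, 2))            # condition means
    m_b = y.mean(axis=(0, 1))            # session means
    m_sc = y.mean(axis=2)                # subject x condition
    m_sb = y.mean(axis=1)                # subject x session
    m_cb = y.mean(axis=0)                # condition x session

    ss_total = ((y - m) ** 2).sum()
    ss_subject = a * b * ((m_s - m) ** 2).sum()
    ss_cond = n * b * ((m_c - m) ** 2).sum()
    ss_sess = n * a * ((m_b - m) ** 2).sum()
    ss_cb = n * ((m_cb - m_c[:, None] - m_b[None, :] + m) ** 2).sum()
    ss_cond_err = b * ((m_sc - m_s[:, None] - m_c[None, :] + m) ** 2).sum()
    ss_sess_err = a * ((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2).sum()
    ss_cb_err = (ss_total - ss_subject - ss_cond - ss_sess - ss_cb
                 - ss_cond_err - ss_sess_err)
    ss_cb_err = max(ss_cb_err, 0.0)

    # components that are zero up to floating-point cancellation are
    # treated as exactly zero so degenerate inputs are flagged cleanly
    cancel = (np.finfo(float).eps * (np.abs(y).max() + 1.0)) ** 2 * y.size
    tol = 1e-12 * ss_total + 100.0 * cancel
    ss_cond, ss_sess, ss_cb, ss_cond_err, ss_sess_err, ss_cb_err = (
        0.0 if s <= tol else s
        for s in (ss_cond, ss_sess, ss_cb, ss_cond_err, ss_sess_err,
                  ss_cb_err))

    effects = {
        "condition": _effect("condition", ss_cond, ss_cond_err,
                             a - 1, (a - 1) * (n - 1)),
        "session": _effect("session", ss_sess, ss_sess_err,
                           b - 1, (b - 1) * (n - 1)),
        "condition x session": _effect("condition x session", ss_cb, ss_cb_err,
                                       (a - 1) * (b - 1),
                                       (a - 1) * (b - 1) * (n - 1)),
    }
    return AnovaResult(effects=effects, ss_total=float(ss_total),
                       ss_subject=float(ss_subject), grand_mean=float(m))


def rm_anova_2xS(table: pd.DataFrame, metric: str, scope: str,
                 value_col: str = "value") -> AnovaResult:
    """Run the 2 x S ANOVA on one metric / scope slice of a long table.

    ``table`` columns: subject, condition, session, scope, metric and a
    value column; ``scope`` selects the ROI name or "wholebrain".
    """
    sel = table[(table["metric"] == metric) & (table["scope"] == scope)]
    if sel.empty:
        raise ValueError(f"no rows for metric={metric!r} scope={scope!r}")
    pivot = sel.pivot_table(index="subject", columns=["condition", "session"],
                            values=value_col, aggfunc="mean")
    subjects = pivot.index.to_list()
    conditions = sorted(sel["condition"].unique())
    sessions = sorted(sel["session"].unique())
    y = np.full((len(subjects), len(conditions), len(sessions)), np.nan)
    for ci, cond in enumerate(conditions):
        for bi, ses in enumerate(sessions):
            if (cond, ses) not in pivot.columns:
                raise ValueError(f"missing cell condition={cond} "
                                 f"session={ses}")
            y[:, ci, bi] = pivot[(cond, ses)].to_numpy()
    if np.isnan(y).any():
        s_idx, c_idx, b_idx = np.argwhere(np.isnan(y))[0]
        raise ValueError(
            f"missing cell subject={subjects[s_idx]} "
            f"condition={conditions[c_idx]} session={sessions[b_idx]}")
    return rm_anova_array(y)
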