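"""Synthetic multi-subject, multi-session BOLD data with planted hubs.

The generator emulates an alternating rest / working-memory (n-back)
scanning design: each subject contributes ``n_sessions_per_condition``
sessions per condition, 120 volumes at TR = 2 s by default, on a common
pre-aligned grid (no realignment or normalization is simulated).

Signal model, per brain voxel and session::

    s(t) = baseline(tissue)
         + sqrt(lam) * u(t)                            # hub latent
         + sqrt(lam_loc) * v_p(t)                      # local parcel latent
         + sqrt(1 - lam - lam_loc) * eps(t)            # AR(1) noise
         + drift(t)                                    # < 0.009 Hz
         + w_physio * c(t)                             # shared physiological
         + L . m(t)                                    # motion loadings

``u`` is a band-limited (0.01-0.07 Hz) latent shared by a hub's voxels;
its loading ``lam`` is the hub's intra-voxel correlation and switches
with the session condition, so the rest hub is strongly intra-correlated
at rest and nearly silent on task, and vice versa for the task hub.  The
task hub's latent also loads onto a distal coupled region while on task,
planting long-range task connectivity.

``v_p`` is a slow latent shared by the voxels of a small spatial parcel
(the grid tiled into blocks): baseline local functional coherence, as
in real BOLD where nearby tissue fluctuates together.  Its loading is
larger at rest than on task (task load suppresses low-frequency local
coherence), which is what makes whole-network local efficiency higher
at rest.  ``eps`` is unit-variance AR(1) noise, ``c`` a shared
broadband confound, ``m`` the six motion series (slow random walks),
and the drift is a sum of the two lowest nonzero DFT frequencies of the
scan (both below 0.009 Hz for a 240 s run).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import nibabel as nib
import numpy as np
import yaml

from .config import ConfigurationError, SimulationConfig, save_yaml
from .grid import make_affine, voxel_centers_mm

log = logging.getLogger(__name__)

# baseline signal level per tissue class (arbitrary scanner units)
_BASELINE = {"gray": 800.0, "white": 700.0, "csf": 500.0}
# brain ellipsoid semi-axes as a fraction of the grid half-extent; > 1 so
# the ellipsoid is clipped by the grid faces and the gray shell fills the
# field of view corners
_BRAIN_SCALE = 1.08
# normalized-radius boundaries of the concentric tissue shells
_CSF_R, _WHITE_R = 0.2, 0.45


@dataclass
class TissueMasks:
    """Gray / white / CSF segmentation on the session grid."""

    gray: np.ndarray
    white: np.ndarray
    csf: np.ndarray

    def __post_init__(self):
        g, w, c = (np.asarray(m, bool) for m in (self.gray, self.white, self.csf))
        self.gray, self.white, self.csf = g, w, c
        if g.shape != w.shape or g.shape != c.shape:
            raise ConfigurationError("tissue masks: shapes differ")
        if np.any(g & w) or np.any(g & c) or np.any(w & c):
            raise ConfigurationError("tissue masks: classes overlap")
        if not g.any():
            raise ConfigurationError("tissue masks: gray mask is empty")

    @property
    def brain(self) -> np.ndarray:
        return self.gray | self.white | self.csf


@dataclass
class BOLDSession:
    """One session's 4-D time series plus grid geometry and labels."""

    data: np.ndarray              # (x, y, z, t)
    affine: np.ndarray
    voxel_size_mm: tuple
    tr_seconds: float
    subject_id: str
    condition: str                # "rest" or "task"
    session_index: int            # 1-based within condition

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class NuisanceSet:
    """Nuisance regressors: 6 motion series + tissue mean signals."""

    motion: np.ndarray            # (t, 6)
    global_signal: np.ndarray     # (t,)
    white_signal: np.ndarray
    csf_signal: np.ndarray

    def __post_init__(self):
        t = self.motion.shape[0]
        for nm in ("global_signal", "white_signal", "csf_signal"):
            if getattr(self, nm).shape[0] != t:
                raise ConfigurationError(f"nuisance {nm}: length != motion length")

    @classmethod
    def from_data(cls, data: np.ndarray, masks: TissueMasks,
                  motion: np.ndarray) -> "NuisanceSet":
        """Compute tissue mean signals from the data itself.

        The global signal is the mean over the union of all tissue
        masks (whole brain), as is standard practice.
        """
        def mean_over(mask):
            return data[mask].mean(axis=0)
        return cls(motion=np.asarray(motion, float),
                   global_signal=mean_over(masks.brain),
                   white_signal=mean_over(masks.white),
                   csf_signal=mean_over(masks.csf))

    def design_columns(self):
        """Named nuisance columns (without intercept), shape (t, 9)."""
        cols = [self.motion[:, i] for i in range(self.motion.shape[1])]
        names = [f"motion_{i + 1}" for i in range(self.motion.shape[1])]
        cols += [self.global_signal, self.white_signal, self.csf_signal]
        names += ["global", "white", "csf"]
        return names, np.column_stack(cols)


@dataclass
class SessionRecord:
    session: BOLDSession
    masks: TissueMasks
    nuisance: NuisanceSet


@dataclass
class GroundTruth:
    """Planted structure, retrievable for validation."""

    rest_hub_mask: np.ndarray
    task_hub_mask: np.ndarray
    coupled_mask: Optional[np.ndarray]
    rest_hub_center_mm: np.ndarray
    task_hub_center_mm: np.ndarray
    coupled_center_mm: Optional[np.ndarray]


@dataclass
class StudyData:
    config: SimulationConfig
    sessions: List[SessionRecord]
    masks: TissueMasks
    truth: GroundTruth
    affine: np.ndarray

    def subject_ids(self):
        seen = []
        for rec in self.sessions:
            if rec.session.subject_id not in seen:
                seen.append(rec.session.subject_id)
        return seen


# ---------------------------------------------------------------------------
# geometry


def tissue_layout(config: SimulationConfig) -> TissueMasks:
    """Concentric ellipsoid shells: CSF core, white shell, gray rind.

    A deliberately simple stand-in for anatomy: the brain is an ellipsoid
    filling the grid; normalized radius < 0.2 is CSF, 0.2-0.45 white
    matter, 0.45-1 gray matter, outside is background (zeros).
    """
    shape = config.grid_shape
    affine = make_affine(shape, config.voxel_size_mm)
    mm = voxel_centers_mm(shape, affine)
    half = np.asarray(shape) * np.asarray(config.voxel_size_mm) / 2.0
    semi = half * _BRAIN_SCALE
    rho = np.sqrt(((mm / semi) ** 2).sum(axis=-1))
    csf = rho < _CSF_R
    white = (rho >= _CSF_R) & (rho < _WHITE_R)
    gray = (rho >= _WHITE_R) & (rho <= 1.0)
    return TissueMasks(gray=gray, white=white, csf=csf)


def _region_mask(center_ijk, radius_mm, gray, affine, shape):
    mm = voxel_centers_mm(shape, affine)
    center_mm = (np.asarray(center_ijk, float) @ affine[:3, :3].T
                 + affine[:3, 3])
    dist = np.sqrt(((mm - center_mm) ** 2).sum(axis=-1))
    return (dist <= radius_mm) & gray, center_mm


def hub_masks(config: SimulationConfig, masks: TissueMasks,
              affine: np.ndarray) -> GroundTruth:
    shape = config.grid_shape
    rest, rest_c = _region_mask(config.rest_hub_spec.center_ijk,
                                config.rest_hub_spec.radius_mm,
                                masks.gray, affine, shape)
    task, task_c = _region_mask(config.task_hub_spec.center_ijk,
                                config.task_hub_spec.radius_mm,
                                masks.gray, affine, shape)
    coupled, coupled_c = None, None
    if config.task_hub_spec.coupled_center_ijk is not None:
        coupled, coupled_c = _region_mask(
            config.task_hub_spec.coupled_center_ijk,
            config.task_hub_spec.coupled_radius_mm,
            masks.gray, affine, shape)
        # regions are defined disjointly: hub membership wins over coupling
        coupled &= ~(rest | task)
    task &= ~rest
    return GroundTruth(rest_hub_mask=rest, task_hub_mask=task,
                       coupled_mask=coupled, rest_hub_center_mm=rest_c,
                       task_hub_center_mm=task_c, coupled_center_mm=coupled_c)


# ---------------------------------------------------------------------------
# signal components


def ar1_noise(rng, n_series, n_volumes, phi):
    """Unit-marginal-variance AR(1) noise, shape (n_series, n_volumes)."""
    innov_sd = np.sqrt(1.0 - phi ** 2)
    x = np.empty((n_series, n_volumes))
    x[:, 0] = rng.standard_normal(n_series)
    innov = rng.standard_normal((n_series, n_volumes - 1)) * innov_sd
    for t in range(1, n_volumes):
        x[:, t] = phi * x[:, t - 1] + innov[:, t - 1]
    return x

def band_limited_latent(rng, n_volumes, tr, low_hz=0.01, high_hz=0.07,
                        size=None):
    """Unit-variance Gaussian series with power confined to [low, high] Hz.

    With ``size`` an array of ``size`` independent series is returned,
    shape ``(size, n_volumes)``.
    """
    shape = (n_volumes,) if size is None else (size, n_volumes)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():          # degenerate very-short series: keep bin 1
        keep = np.zeros_like(freqs, bool)
        keep[min(1, len(freqs) - 1)] = True
    spec[..., ~keep] = 0.0
    x = np.fft.irfft(spec, n=n_volumes, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)

def drift_series(rng, n_volumes, tr, amplitude):
    """Scanner drift: the two lowest nonzero DFT frequencies of the run.

    For a 120-volume, TR = 2 s run these are 1/240 and 2/240 Hz, both
    below the 0.009 Hz band edge, so the band-pass removes the drift
    exactly.
    """
    t = np.arange(n_volumes)
    ph = rng.uniform(0, 2 * np.pi, size=2)
    return amplitude * (np.cos(2 * np.pi * t / n_volumes + ph[0])
                        + 0.5 * np.cos(4 * np.pi * t / n_volumes + ph[1]))

def motion_series(rng, n_volumes, step_sd=0.02):
    """Six slow random-walk motion parameters (3 translations, 3 rotations)."""
    return np.cumsum(rng.standard_normal((n_volumes, 6)) * step_sd, axis=0)


# ---------------------------------------------------------------------------
# study generation


def session_conditions(config: SimulationConfig):
    """Alternating condition sequence, e.g. rest, task, rest, task, ..."""
    first = config.first_condition
    second = "task" if first == "rest" else "rest"
    out = []
    for i in range(config.n_sessions_per_condition):
        out.append((first, i + 1))
        out.append((second, i + 1))
    return out


def parcel_labels(config: SimulationConfig) -> np.ndarray:
    """Spatial parcel id per voxel: the grid tiled into small blocks."""
    shape = config.grid_shape
    block = config.parcel_shape
    idx = np.indices(shape)
    tiles = [idx[d] // block[d] for d in range(3)]
    n_tiles = [int(np.ceil(shape[d] / block[d])) for d in range(3)]
    return (tiles[0] * n_tiles[1] + tiles[1]) * n_tiles[2] + tiles[2]


def _simulate_session(config, masks, truth, affine, condition, rng):
    shape = config.grid_shape
    T = config.n_volumes
    brain = masks.brain
    n_brain = int(brain.sum())

    data = np.zeros(shape + (T,))
    noise = ar1_noise(rng, n_brain, T, config.ar1_coefficient)

    # hub latent loadings per brain voxel for this condition
    lam = np.zeros(n_brain)
    which = np.zeros(n_brain, dtype=np.int8)     # 0 none, 1 rest hub, 2 task
    rest_nodes = truth.rest_hub_mask[brain]
    task_nodes = truth.task_hub_mask[brain]
    rh, th = config.rest_hub_spec, config.task_hub_spec
    lam[rest_nodes] = rh.rho_active if condition == "rest" else rh.rho_inactive
    which[rest_nodes] = 1
    lam[task_nodes] = th.rho_active if condition == "task" else th.rho_inactive
    which[task_nodes] = 2
    if truth.coupled_mask is not None:
        cp = truth.coupled_mask[brain]
        lam[cp] = (th.coupling_active if condition == "task"
                   else th.coupling_inactive)
        which[cp] = 2            # coupled region shares the task-hub latent

    u_rest = band_limited_latent(rng, T, config.tr_seconds)
    u_task = band_limited_latent(rng, T, config.tr_seconds)
    latent = np.zeros((n_brain, T))
    latent[which == 1] = u_rest
    latent[which == 2] = u_task

    # baseline local coherence: per-parcel slow latents shared by the
    # voxels of each small spatial block, stronger at rest than on task
    labels = parcel_labels(config)[brain]
    uniq, labels = np.unique(labels, return_inverse=True)
    v = band_limited_latent(rng, T, config.tr_seconds, size=uniq.size)
    lam_loc = config.local_coupling[condition] * (1.0 - lam)

    sig = (np.sqrt(lam)[:, None] * latent
           + np.sqrt(lam_loc)[:, None] * v[labels]
           + np.sqrt(1.0 - lam - lam_loc)[:, None] * noise)

    # shared confounds
    physio = band_limited_latent(rng, T, config.tr_seconds,
                                 low_hz=0.0, high_hz=1.0 / (2 * config.tr_seconds))
    motion = motion_series(rng, T)
    w = config.confound_weights
    sig = sig + w.get("physio", 0.0) * physio[None, :]
    loads = rng.standard_normal((n_brain, 6)) * w.get("motion", 0.0)
    sig = sig + loads @ motion.T

    # per-voxel drift with random phases and 0.5-1.5x amplitude scatter
    drift_scale = rng.uniform(0.5, 1.5, size=n_brain)
    base_drift = drift_series(rng, T, config.tr_seconds, config.drift_amplitude)
    sig = sig + drift_scale[:, None] * base_drift[None, :]

    # tissue baselines
    baseline = np.zeros(n_brain)
    baseline[masks.gray[brain]] = _BASELINE["gray"]
    baseline[masks.white[brain]] = _BASELINE["white"]
    baseline[masks.csf[brain]] = _BASELINE["csf"]
    sig = sig + baseline[:, None]

    data[brain] = sig
    nuisance = NuisanceSet.from_data(data, masks, motion)
    return data, nuisance


def generate_study(config: SimulationConfig) -> StudyData:
    """Simulate all subjects x conditions x sessions of a study.

    Identical ``config`` (including its ``seed``) yields bit-identical
    arrays.  Ground-truth hub masks are available as ``study.truth``.
    """
    affine = make_affine(config.grid_shape, config.voxel_size_mm)
    masks = tissue_layout(config)
    truth = hub_masks(config, masks, affine)

    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    records = []
    for s in range(config.n_subjects):
        subject_id = f"sub-{s + 1:02d}"
        conds = session_conditions(config)
        session_seeds = subject_seeds[s].spawn(len(conds))
        for (condition, idx), seed in zip(conds, session_seeds):
            rng = np.random.default_rng(seed)
            data, nuisance = _simulate_session(
                config, masks, truth, affine, condition, rng)
            session = BOLDSession(
                data=data, affine=affine,
                voxel_size_mm=config.voxel_size_mm,
                tr_seconds=config.tr_seconds, subject_id=subject_id,
                condition=condition, session_index=idx)
            records.append(SessionRecord(session=session, masks=masks,
                                         nuisance=nuisance))
    return StudyData(config=config, sessions=records, masks=masks,
                     truth=truth, affine=affine)


# ---------------------------------------------------------------------------
# disk I/O


def _nifti(array, affine):
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine)
    return img


def write_session(session: BOLDSession, masks: TissueMasks,
                  nuisance: NuisanceSet, directory) -> dict:
    """Write one session: 4-D BOLD NIfTI, 3-D mask NIfTIs, motion text.

    Data are stored as float64 so a read-back reproduces the arrays
    exactly.  The motion file is whitespace-delimited, 6 columns, one
    row per volume (realignment-tool convention).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["bold"] = str(directory / "bold.nii")
    _nifti(session.data, session.affine).to_filename(paths["bold"])
    for nm in ("gray", "white", "csf"):
        paths[nm] = str(directory / f"{nm}.nii")
        _nifti(getattr(masks, nm).astype(np.float64),
               session.affine).to_filename(paths[nm])
    paths["motion"] = str(directory / "motion.par")
    np.savetxt(paths["motion"], nuisance.motion, fmt="%.17g")
    return paths


def write_study(study: StudyData, directory) -> str:
    """Write a whole study plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in study.sessions:
        ses = rec.session
        sub_dir = (directory / ses.subject_id
                   / f"{ses.condition}-{ses.session_index:02d}")
        paths = write_session(ses, rec.masks, rec.nuisance, sub_dir)
        entries.append({
            "subject_id": ses.subject_id,
            "condition": ses.condition,
            "session_index": ses.session_index,
            "tr_seconds": float(ses.tr_seconds),
            **{k: str(Path(v).relative_to(directory)) for k, v in paths.items()},
        })
    save_yaml(study.config, directory / "config.yaml")
    # ground-truth masks, for validation against the planted structure
    _nifti(study.truth.rest_hub_mask.astype(float),
           study.affine).to_filename(str(directory / "truth_rest_hub.nii"))
    _nifti(study.truth.task_hub_mask.astype(float),
           study.affine).to_filename(str(directory / "truth_task_hub.nii"))
    manifest = {"sessions": entries, "config": "config.yaml"}
    manifest_path = directory / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return str(manifest_path)


def load_session(entry: dict, base_dir) -> SessionRecord:
    """Load one manifest entry back into in-memory session objects."""
    base = Path(base_dir)
    bold = nib.load(str(base / entry["bold"]))
    data = np.asarray(bold.dataobj, dtype=np.float64)
    affine = bold.affine
    vox = tuple(float(v) for v in bold.header.get_zooms()[:3])
    masks = TissueMasks(
        gray=np.asarray(nib.load(str(base / entry["gray"])).dataobj) > 0.5,
        white=np.asarray(nib.load(str(base / entry["white"])).dataobj) > 0.5,
        csf=np.asarray(nib.load(str(base / entry["csf"])).dataobj) > 0.5)
    motion = np.loadtxt(str(base / entry["motion"]))
    if motion.ndim == 1:
        motion = motion[:, None]
    session = BOLDSession(
        data=data, affine=affine, voxel_size_mm=vox,
        tr_seconds=float(entry.get("tr_seconds", 2.0)),
        subject_id=str(entry["subject_id"]),
        condition=str(entry["condition"]),
        session_index=int(entry["session_index"]))
    nuisance = NuisanceSet.from_data(data, masks, motion)
    return SessionRecord(session=session, masks=masks, nuisance=nuisance)


def load_manifest(manifest_path):
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    return manifest, manifest_path.parent
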