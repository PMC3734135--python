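"""Study configuration objects and their YAML round-trip.

:class:`SimulationConfig` fixes everything the synthetic BOLD generator
does; identical config + seed yields bit-identical data.
:class:`RunConfig` drives the end-to-end pipeline (synthetic or
file-based input, band limits, density exponents, consistency
thresholds, ROI definitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """A configuration field failed validation; the message names it."""


def _require(ok: bool, fieldname: str, msg: str):
    if not ok:
        raise ConfigurationError(f"{fieldname}: {msg}")


@dataclass
class HubSpec:
    """A planted connectivity hub.

    Voxels of the hub (gray-matter voxels within ``radius_mm`` of the
    center) share a condition-dependent latent signal; the pairwise
    correlation among them is ``rho_active`` in the hub's active
    condition and ``rho_inactive`` otherwise.  An optional coupled
    distal region shares the same latent with loading
    ``coupling_active`` / ``coupling_inactive`` (its own intra-region
    correlation), giving hub-to-region correlation
    ``sqrt(rho * coupling)``.
    """

    name: str
    center_ijk: tuple
    radius_mm: float
    rho_active: float
    rho_inactive: float
    coupled_center_ijk: Optional[tuple] = None
    coupled_radius_mm: float = 8.0
    coupling_active: float = 0.0
    coupling_inactive: float = 0.0

    def validate(self, grid_shape):
        _require(len(self.center_ijk) == 3, f"{self.name}.center_ijk",
                 "needs 3 grid indices")
        _require(all(0 <= c < s for c, s in zip(self.center_ijk, grid_shape)),
                 f"{self.name}.center_ijk", f"outside grid {grid_shape}")
        _require(self.radius_mm >= 0, f"{self.name}.radius_mm", "must be >= 0")
        for nm, v in (("rho_active", self.rho_active),
                      ("rho_inactive", self.rho_inactive),
                      ("coupling_active", self.coupling_active),
                      ("coupling_inactive", self.coupling_inactive)):
            _require(0.0 <= v < 1.0, f"{self.name}.{nm}", "must be in [0, 1)")


def _default_rest_hub():
    # posterior midline hub, strongly intra-correlated at rest (DMN-like)
    return HubSpec(name="rest_hub", center_ijk=(7, 3, 6), radius_mm=10.0,
                   rho_active=0.8, rho_inactive=0.05)


def _default_task_hub():
    # right-frontal hub active during the working-memory condition,
    # coupled to a distal parietal-like region while on task
    return HubSpec(name="task_hub", center_ijk=(10, 10, 6), radius_mm=8.0,
                   rho_active=0.8, rho_inactive=0.05,
                   coupled_center_ijk=(2, 6, 6), coupled_radius_mm=8.0,
                   coupling_active=0.4, coupling_inactive=0.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-session BOLD study.

    Defaults emulate the study design this package analyzes: 5 subjects,
    5 resting + 5 task sessions each (alternating, rest first), 120
    volumes at TR = 2 s on a desk-scale 14 x 14 x 10 grid of
    4 x 4 x 5 mm voxels (~1000 gray voxels).
    """

    n_subjects: int = 5
    n_sessions_per_condition: int = 5
    n_volumes: int = 120
    tr_seconds: float = 2.0
    grid_shape: tuple = (14, 14, 10)
    voxel_size_mm: tuple = (4.0, 4.0, 5.0)
    rest_hub_spec: HubSpec = field(default_factory=_default_rest_hub)
    task_hub_spec: HubSpec = field(default_factory=_default_task_hub)
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 1.0
    confound_weights: dict = field(
        default_factory=lambda: {"motion": 0.1, "physio": 0.3})
    # baseline local coherence: gray voxels are tiled into small spatial
    # parcels sharing a slow latent; the loading (the within-parcel raw
    # correlation) is higher at rest than on task, emulating the
    # task-load suppression of low-frequency local coherence
    parcel_shape: tuple = (3, 3, 2)
    local_coupling: dict = field(
        default_factory=lambda: {"rest": 0.25, "task": 0.12})
    first_condition: str = "rest"
    seed: int = 0

    def __post_init__(self):
        _require(self.n_subjects >= 1, "n_subjects", "must be >= 1")
        _require(self.n_sessions_per_condition >= 1,
                 "n_sessions_per_condition", "must be >= 1")
        _require(self.n_volumes >= 2, "n_volumes", "must be >= 2")
        _require(self.tr_seconds > 0, "tr_seconds", "must be > 0")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        _require(len(self.grid_shape) == 3, "grid_shape", "needs 3 dims")
        _require(all(s >= 1 for s in self.grid_shape), "grid_shape",
                 "all dims must be >= 1")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        _require(len(self.voxel_size_mm) == 3, "voxel_size_mm", "needs 3 sizes")
        _require(all(v > 0 for v in self.voxel_size_mm), "voxel_size_mm",
                 "all sizes must be > 0")
        _require(0.0 <= self.ar1_coefficient < 1.0, "ar1_coefficient",
                 "must be in [0, 1)")
        self.parcel_shape = tuple(int(s) for s in self.parcel_shape)
        _require(len(self.parcel_shape) == 3 and
                 all(s >= 1 for s in self.parcel_shape), "parcel_shape",
                 "needs 3 positive block sizes")
        for cond in ("rest", "task"):
            _require(cond in self.local_coupling, "local_coupling",
                     f"missing '{cond}' entry")
            _require(0.0 <= self.local_coupling[cond] < 1.0,
                     "local_coupling", f"'{cond}' must be in [0, 1)")
        _require(self.drift_amplitude >= 0, "drift_amplitude", "must be >= 0")
        _require(self.first_condition in ("rest", "task"), "first_condition",
                 "must be 'rest' or 'task'")
        self.rest_hub_spec.validate(self.grid_shape)
        self.task_hub_spec.validate(self.grid_shape)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("rest_hub_spec", "task_hub_spec"):
            if key in d and isinstance(d[key], dict):
                h = dict(d[key])
                for tkey in ("center_ijk", "coupled_center_ijk"):
                    if h.get(tkey) is not None:
                        h[tkey] = tuple(h[tkey])
                d[key] = HubSpec(**h)
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    mode: str = "synthetic"                 # "synthetic" or "files"
    sim: Optional[SimulationConfig] = None  # synthetic mode
    manifest: Optional[str] = None          # files mode: manifest YAML path
    low_hz: float = 0.009
    high_hz: float = 0.08
    filter_kind: str = "fft"
    filter_regressors: bool = True
    s_exponents: Sequence[float] = (3.0,)
    top_fraction_map: float = 0.20     # whole-brain consistency maps
    top_fraction_roi: float = 0.15     # ROI top-node selection
    session_min_fraction: float = 0.6  # >= 3 of 5 sessions
    subject_threshold: float = 0.5     # majority of subjects
    rois: Sequence["object"] = ()      # ROISpec list; synthetic default: hubs
    out_dir: str = "voxconn_out"
    seed: int = 0
    write_volumes: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        _require(self.mode in ("synthetic", "files"), "mode",
                 "must be 'synthetic' or 'files'")
        _require(0 < self.top_fraction_map <= 1, "top_fraction_map",
                 "must be in (0, 1]")
        _require(0 < self.top_fraction_roi <= 1, "top_fraction_roi",
                 "must be in (0, 1]")
        _require(0 < self.session_min_fraction <= 1, "session_min_fraction",
                 "must be in (0, 1]")
        _require(0 < self.subject_threshold <= 1, "subject_threshold",
                 "must be in (0, 1]")
        _require(all(s > 1 for s in self.s_exponents), "s_exponents",
                 "all S values must be > 1")
        if self.mode == "synthetic" and self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)
        if self.mode == "files":
            _require(self.manifest is not None, "manifest",
                     "required in files mode")


def save_yaml(config, path):
    """Serialize a SimulationConfig or RunConfig to YAML."""
    d = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(d), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))
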