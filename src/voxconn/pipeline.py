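"""End-to-end orchestration: simulate/ingest -> preprocess -> network ->
metrics -> consistency -> ROI statistics, with provenance.

``run_study`` executes every stage for every session and writes:

* ``metrics_summary.tsv``  -- whole-brain mean/SD per session, metric, S
* ``roi_metrics.tsv``      -- ROI-mean metric values per session and S
* ``anova.tsv``            -- 2 x S ANOVA per scope, metric and S
* ``consistency/``         -- per-subject session overlap maps, group
  meta maps and group connectivity maps (NIfTI)
* ``volumes/``             -- per-session nodal metric volumes (NIfTI)
* ``provenance.json``      -- config, seed, package version, per-session
  correlation threshold r_th and realized mean degree K, output paths

One network is built per session (sessions are never concatenated).
Completed runs are cached: when the output directory already holds a
provenance record with the same config hash, the run is skipped and the
existing manifest returned (``resume=False`` forces recomputation).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import consistency as cons
from . import metrics as met
from .config import RunConfig, _plain
from .network import build_network, target_mean_degree
from .preprocess import bandpass, extract_gray_timeseries, regress_nuisance
from .roistats import ROISpec, rm_anova_2xS, roi_mean, sphere_mask
from .synth import generate_study, load_manifest, load_session

log = logging.getLogger(__name__)

_METRICS = ("K", "Eglob", "Eloc")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_plain(asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _default_rois(sim_truth) -> list:
    rois = [ROISpec("rest_hub", [sim_truth.rest_hub_center_mm])]
    rois.append(ROISpec("task_hub", [sim_truth.task_hub_center_mm]))
    return rois


def _load_records(config: RunConfig):
    if config.mode == "synthetic":
        study = generate_study(config.sim)
        rois = list(config.rois) or _default_rois(study.truth)
        return study.sessions, rois
    manifest, base = load_manifest(config.manifest)
    records = [load_session(e, base) for e in manifest["sessions"]]
    rois = list(config.rois)
    return records, rois


def _session_metrics(rec, config: RunConfig):
    """Preprocess one session and compute nodal metrics per S."""
    vm = extract_gray_timeseries(rec.session, rec.masks)
    vm = bandpass(vm, config.low_hz, config.high_hz, config.filter_kind)
    vm = regress_nuisance(vm, rec.nuisance,
                          filter_regressors=config.filter_regressors)
    per_s = {}
    for S in config.s_exponents:
        net = build_network(vm, S)
        nodal = {"K": met.degree(net),
                 "Eglob": met.global_efficiency(net),
                 "Eloc": met.local_efficiency(net)}
        per_s[S] = {"net_info": {"r_threshold": net.r_threshold,
                                 "mean_degree": net.mean_degree,
                                 "edge_count": net.edge_count,
                                 "n_nodes": net.n_nodes,
                                 "target_mean_degree":
                                     target_mean_degree(net.n_nodes, S)},
                    "nodal": nodal, "net": net}
    return vm.node_map, per_s


def run_study(config: RunConfig, resume: bool = True) -> dict:
    """Run the full pipeline; returns the output manifest (also on disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    prov_path = out / "provenance.json"
    if resume and prov_path.exists():
        with open(prov_path) as fh:
            prov = json.load(fh)
        if prov.get("config_hash") == chash:
            log.info("cached run found (hash %s); skipping recompute", chash)
            return prov

    t0 = time.time()
    records, rois = _load_records(config)
    if not records:
        raise RuntimeError("stage ingest: no sessions to analyze")
    affine = records[0].session.affine
    grid_shape = records[0].session.grid_shape
    roi_masks = {r.name: sphere_mask(r, grid_shape, affine) for r in rois}

    summary_rows, roi_rows, session_info = [], [], []
    # nodal[(subject, condition, session, S)][metric] -> MetricVolume
    nodal_store, nets_store = {}, {}
    node_map = None
    for rec in records:
        ses = rec.session
        key_base = (ses.subject_id, ses.condition, ses.session_index)
        try:
            nm, per_s = _session_metrics(rec, config)
        except Exception as err:
            raise RuntimeError(
                f"stage preprocess/network failed for subject="
                f"{ses.subject_id} condition={ses.condition} "
                f"session={ses.session_index}: {err}") from err
        if node_map is None:
            node_map = nm
        elif not node_map.same_grid(nm):
            raise RuntimeError(
                f"stage network: node map of subject={ses.subject_id} "
                f"condition={ses.condition} session={ses.session_index} "
                "differs from the first session")
        for S, bundle in per_s.items():
            info = dict(subject=ses.subject_id, condition=ses.condition,
                        session=ses.session_index, S=S, **bundle["net_info"])
            session_info.append(info)
            nodal_store[key_base + (S,)] = bundle["nodal"]
            nets_store[key_base + (S,)] = bundle["net"]
            for mname in _METRICS:
                mv = bundle["nodal"][mname]
                summary_rows.append(dict(
                    subject=ses.subject_id, condition=ses.condition,
                    session=ses.session_index, S=S, scope="wholebrain",
                    metric=mname, value=mv.network_mean, sd=mv.network_sd))
                for rname, rmask in roi_masks.items():
                    value, nvox = roi_mean(mv, rmask)
                    roi_rows.append(dict(
                        subject=ses.subject_id, condition=ses.condition,
                        session=ses.session_index, S=S, scope=rname,
                        metric=mname, value=value, n_voxels=nvox))

    summary = pd.DataFrame(summary_rows)
    roi_cols = ["subject", "condition", "session", "S", "scope", "metric",
                "value", "n_voxels"]
    roi_table = pd.DataFrame(roi_rows, columns=roi_cols)
    summary.to_csv(out / "metrics_summary.tsv", sep="\t", index=False)
    roi_table.to_csv(out / "roi_metrics.tsv", sep="\t", index=False)

    # ANOVAs: whole brain + each ROI, per metric and S
    anova_frames = []
    subjects = sorted(summary["subject"].unique())
    conditions = sorted(summary["condition"].unique())
    keep = ["subject", "condition", "session", "S", "scope", "metric",
            "value"]
    frames = [summary[keep]] + ([roi_table[keep]] if len(roi_table) else [])
    long = pd.concat(frames)
    if len(subjects) >= 2 and len(conditions) == 2:
        for S in config.s_exponents:
            sub = long[long["S"] == S]
            for scope in ["wholebrain"] + list(roi_masks):
                for mname in _METRICS:
                    try:
                        res = rm_anova_2xS(sub, mname, scope)
                    except ValueError as err:
                        raise RuntimeError(
                            f"stage roistats failed for scope={scope} "
                            f"metric={mname}: {err}") from err
                    frame = res.to_frame()
                    frame.insert(0, "S", S)
                    frame.insert(0, "metric", mname)
                    frame.insert(0, "scope", scope)
                    anova_frames.append(frame)
        anova = pd.concat(anova_frames, ignore_index=True)
    else:
        log.warning("ANOVA skipped: needs >= 2 subjects and both conditions")
        anova = pd.DataFrame()
    anova.to_csv(out / "anova.tsv", sep="\t", index=False)

    written = _write_maps(config, out, node_map, affine, subjects,
                          conditions, roi_masks, nodal_store, nets_store)
    if config.write_volumes:
        written += _write_volumes(config, out, affine, nodal_store)

    prov = {
        "config_hash": chash,
        "config": _plain(asdict(config)),
        "seed": config.seed,
        "version": _version(),
        "n_nodes": int(node_map.n_nodes),
        "sessions": _plain(session_info),
        "outputs": sorted(str(p.relative_to(out)) for p in map(Path, [
            out / "metrics_summary.tsv", out / "roi_metrics.tsv",
            out / "anova.tsv"] + written)),
        "runtime_seconds": round(time.time() - t0, 2),
    }
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
    return prov


def _version() -> str:
    from . import __version__
    return __version__


def _save_map(volume, affine, path):
    nib.Nifti1Image(np.asarray(volume, dtype=np.float64),
                    affine).to_filename(str(path))
    return path


def _write_maps(config, out, node_map, affine, subjects, conditions,
                roi_masks, nodal_store, nets_store):
    """Consistency and connectivity maps, per condition and S."""
    cdir = out / "consistency"
    cdir.mkdir(exist_ok=True)
    written = []
    for S in config.s_exponents:
        stag = f"S{S:g}"
        for mname in ("K", "Eloc"):
            for condition in conditions:
                subject_sets = []
                for subject in subjects:
                    keys = sorted(k for k in nodal_store
                                  if k[0] == subject and k[1] == condition
                                  and k[3] == S)
                    masks = [cons.top_fraction_mask(
                        nodal_store[k][mname], config.top_fraction_map)
                        for k in keys]
                    overlap = cons.session_overlap(
                        masks, node_map, source_metric=mname,
                        top_fraction=config.top_fraction_map)
                    written.append(_save_map(
                        node_map.to_volume(overlap.values, missing=0.0),
                        affine,
                        cdir / f"overlap_{mname}_{condition}_{subject}_{stag}.nii"))
                    subject_sets.append(cons.threshold_consistency(
                        overlap, config.session_min_fraction))
                meta = cons.subject_meta_map(
                    subject_sets, node_map, source_metric=mname,
                    top_fraction=config.top_fraction_map)
                written.append(_save_map(
                    node_map.to_volume(meta.values, missing=0.0), affine,
                    cdir / f"meta_{mname}_{condition}_{stag}.nii"))

                # nodes connected to each ROI's top metric nodes
                for rname, rmask in roi_masks.items():
                    roi_nodes = node_map.nodes_of_volume_mask(rmask)
                    if not roi_nodes.any():
                        continue
                    conn_sets = []
                    for subject in subjects:
                        keys = sorted(k for k in nodal_store
                                      if k[0] == subject and k[1] == condition
                                      and k[3] == S)
                        sess = []
                        for k in keys:
                            top = cons.top_fraction_mask(
                                nodal_store[k][mname],
                                config.top_fraction_roi, within=roi_nodes)
                            sess.append(cons.connected_to_top_nodes(
                                nets_store[k], top))
                        overlap = cons.session_overlap(sess, node_map,
                                                       source_metric=mname)
                        conn_sets.append(cons.threshold_consistency(
                            overlap, config.session_min_fraction))
                    group = cons.group_connectivity_map(
                        conn_sets, config.subject_threshold)
                    written.append(_save_map(
                        node_map.to_volume(group.astype(float), missing=0.0),
                        affine,
                        cdir / f"connected_{rname}_{mname}_{condition}_{stag}.nii"))
    return written


def _write_volumes(config, out, affine, nodal_store):
    vdir = out / "volumes"
    vdir.mkdir(exist_ok=True)
    written = []
    for (subject, condition, session, S), nodal in nodal_store.items():
        for mname, mv in nodal.items():
            path = (vdir / f"{mname}_{subject}_{condition}-{session:02d}"
                           f"_S{S:g}.nii")
            written.append(_save_map(met.metric_to_volume(mv, missing=np.nan),
                                     affine, path))
    return written


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(manifest_path) -> list:
    """Check a file-mode manifest; returns a list of violation strings."""
    manifest, base = load_manifest(manifest_path)
    violations = []
    entries = manifest.get("sessions", [])
    if not entries:
        return ["manifest lists no sessions"]

    expected_volumes = None
    config_rel = manifest.get("config")
    if config_rel:
        try:
            from .config import load_simulation_config
            cfg = load_simulation_config(Path(base) / config_rel)
            expected_volumes = cfg.n_volumes
        except Exception as err:   # config may be absent or foreign
            violations.append(f"config unreadable: {err}")

    ref_affine, ref_shape = None, None
    for entry in entries:
        tag = (f"{entry.get('subject_id')}/{entry.get('condition')}-"
               f"{entry.get('session_index')}")
        try:
            img = nib.load(str(Path(base) / entry["bold"]))
        except Exception as err:
            violations.append(f"{tag}: cannot read bold ({err})")
            continue
        shape, affine = img.shape, img.affine
        if len(shape) != 4:
            violations.append(f"{tag}: {entry['bold']} is not 4-D")
            continue
        if ref_affine is None:
            ref_affine, ref_shape = affine, shape[:3]
        else:
            if shape[:3] != ref_shape:
                violations.append(
                    f"{tag}: {entry['bold']} grid {shape[:3]} != {ref_shape}")
            if not np.allclose(affine, ref_affine):
                violations.append(
                    f"{tag}: {entry['bold']} affine mismatch")
        if expected_volumes is not None and shape[3] != expected_volumes:
            violations.append(
                f"{tag}: {entry['bold']} has {shape[3]} volumes, config "
                f"expects {expected_volumes}")

        tissues = {}
        for nm in ("gray", "white", "csf"):
            try:
                mimg = nib.load(str(Path(base) / entry[nm]))
            except Exception as err:
                violations.append(f"{tag}: cannot read {nm} mask ({err})")
                continue
            if mimg.shape != shape[:3]:
                violations.append(
                    f"{tag}: {entry[nm]} grid {mimg.shape} != {shape[:3]}")
            if not np.allclose(mimg.affine, affine):
                violations.append(f"{tag}: {entry[nm]} affine mismatch "
                                  f"with {entry['bold']}")
            tissues[nm] = np.asarray(mimg.dataobj) > 0.5
        if len(tissues) == 3:
            for a, b in (("gray", "white"), ("gray", "csf"),
                         ("white", "csf")):
                if tissues[a].shape == tissues[b].shape and np.any(
                        tissues[a] & tissues[b]):
                    violations.append(f"{tag}: {a} and {b} masks overlap")
            if not tissues["gray"].any():
                violations.append(f"{tag}: gray mask is empty")

        try:
            motion = np.loadtxt(str(Path(base) / entry["motion"]))
            if motion.ndim != 2 or motion.shape[1] != 6:
                violations.append(
                    f"{tag}: {entry['motion']} is not 6-column")
            elif motion.shape[0] != shape[3]:
                violations.append(
                    f"{tag}: {entry['motion']} has {motion.shape[0]} rows "
                    f"for {shape[3]} volumes")
        except Exception as err:
            violations.append(f"{tag}: cannot read motion file ({err})")
    return violations
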