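# voxconn

Voxel-based functional brain-network analysis for multi-session,
two-condition BOLD studies — with a synthetic multi-session BOLD
generator so the whole pipeline is testable without scanner data.

## What it does

Resting-state and task fMRI can be turned into graphs: every
gray-matter voxel is a node, and two voxels are linked when their
preprocessed time courses correlate strongly enough. `voxconn`
implements that analysis end to end for studies that repeatedly scan
the same subjects in two conditions (e.g. rest vs a working-memory
task):

* temporal preprocessing — gray-matter extraction, zero-phase
  band-pass to 0.009–0.08 Hz, regression of motion, global, white
  matter and CSF signals from the filtered series;
* network construction — all-pairs Pearson correlations, binarized at
  the **density** implied by `N = K^S`: the correlation cutoff r_th is
  chosen so the mean degree is K = N^(1/S) (S = 3.0 by default; 2.5
  and 3.5 supported), keeping density comparable across sessions and
  subjects;
* graph metrics — degree K, degree distribution, nodal and network
  global efficiency E_glob (mean inverse shortest-path length) and
  local efficiency E_loc (efficiency of each node's neighbor
  subgraph), mappable back into brain volumes;
* consistency mapping — per-subject overlap of each session's top 20%
  nodes, thresholded at ≥ 3 of 5 sessions, aggregated into
  cross-subject "meta" maps; maps of the nodes connected to an ROI's
  top 15% nodes with a 50% subject threshold;
* ROI statistics — 10 mm spherical ROIs at mm coordinates, ROI-mean
  metrics, and fully within-subject 2 (condition) × S (session)
  ANOVAs with F, p and partial η² = SS_effect/(SS_effect+SS_error).

The synthetic generator emulates the alternating 5-rest + 5-task,
120-volume, TR = 2 s design on a desk-scale grid with planted
structure: a posterior rest hub, a frontal task hub coupled to a
distal region during task, and baseline local parcel coherence that is
stronger at rest. Ground truth is retrievable, so recovery of every
qualitative effect is a testable property.

## Worked example

```python
from voxconn import (SimulationConfig, bandpass, build_network, degree,
                     extract_gray_timeseries, generate_study,
                     global_efficiency, local_efficiency, regress_nuisance)

study = generate_study(SimulationConfig(n_subjects=1,
                                        n_sessions_per_condition=1, seed=3))
for rec in study.sessions:
    vm = extract_gray_timeseries(rec.session, rec.masks)
    vm = regress_nuisance(bandpass(vm), rec.nuisance)
    net = build_network(vm, S=3.0)
    print(rec.session.condition, round(net.mean_degree, 2),
          round(global_efficiency(net).network_mean, 3),
          round(local_efficiency(net).network_mean, 3))
```

prints (`examples/03_network_metrics.py` shows the full version):

```
rest: K = 10.58 +/- 7.49, Eglob = 0.271, Eloc = 0.342, rest-hub mean K = 43.0
task: K = 10.58 +/- 9.69, Eglob = 0.282, Eloc = 0.211, rest-hub mean K = 9.7
```

Both sessions land on the same mean degree (10.58 = 1184^(1/3)) — the
density rule makes K a controlled quantity — while local efficiency
drops from rest to task and the planted rest hub loses almost all of
its connections on task. `examples/05_full_pipeline_anova.py` runs the
orchestrated pipeline on 3 subjects and prints the inference:

```
whole-brain Eloc condition effect: F(1, 2) = 14968.7, p = 0.0001,
partial eta squared = 1.00
```

The other examples cover simulation (`01`), thresholding (`02`) and
consistency mapping (`04`). A thin CLI exists for shell use:

```
voxconn simulate --seed 1 --out study/      # write a synthetic study
voxconn validate study/manifest.yaml        # check grids, masks, motion
voxconn run --manifest study/manifest.yaml --out results/
```

`voxconn run` writes per-session metric volumes (NIfTI), summary and
ROI tables (TSV), ANOVA tables, consistency/connectivity maps, and a
provenance record (config hash, seed, per-session r_th and K).

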