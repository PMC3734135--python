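# Methods

`voxconn` implements a voxel-based functional-connectivity network
analysis for multi-session, two-condition BOLD studies, together with a
synthetic data generator that makes every stage testable without
scanner data. This note records the models, the parameters that
matter, and the design choices made where the method leaves room.

## Pipeline model

Each session is analyzed independently (one network per session; runs
are never concatenated):

1. **Gray-matter extraction.** Time courses are taken for every voxel
   of the gray-matter mask, ordered by a linear grid scan with the x
   index varying fastest. The node ↔ voxel ↔ mm mapping is fixed by
   this scan and the NIfTI affine and shared by all downstream stages.
2. **Band-pass filtering** to 0.009–0.08 Hz, the conventional window
   for slow spontaneous BOLD fluctuations. Default implementation is a
   hard DFT mask (exact zero-phase response: gain 1 at retained DFT
   frequencies, 0 elsewhere); a second-order forward–backward
   Butterworth is available (`kind="butter"`). The matrix records
   which filter produced it.
3. **Nuisance regression.** Ordinary least squares of each filtered
   voxel series on [intercept, 6 motion parameters, global, white,
   CSF means], keeping residuals. The global signal is the mean over
   the union of the tissue masks (configurable). The nuisance series
   are passed through the same band-pass before projection (flag to
   disable) so the regression acts in-band; the intercept is not
   filtered. Linearly dependent design columns are dropped with a
   warning (QR with pivoting); zero-variance voxel columns pass
   through with a warning. Regression follows filtering, matching the
   convention that regressors are taken from the filtered series.
4. **Network construction.** Pearson correlations over all voxel
   pairs; zero-variance voxels correlate 0 with everything. The
   binarization threshold is not a fixed r but a fixed **density**:
   with N nodes and exponent S, r_th is chosen so the mean degree K
   satisfies N = K^S, i.e. K = N^(1/S). Concretely the target edge
   count is m = ⌊N·N^(1/S)/2⌋ (with a relative-epsilon guard so
   analytically integral targets are not floored away) and r_th is the
   m-th largest off-diagonal correlation. Thresholding is inclusive
   (r ≥ r_th) on the *signed* correlation — the threshold is a lower
   bound, so strong negative correlations are excluded; an
   absolute-value mode exists but is off by default. Ties at r_th are
   all included, so K can exceed the target by the tie block (logged in
   metadata); with continuous data ties have measure zero and the edge
   count is exactly m. S defaults to 3.0; 2.5 and 3.5 are supported
   for threshold-robustness sweeps. Correlations are computed
   blockwise; the dense N×N matrix is never materialized in
   `build_network`, only the condensed upper triangle (float64 up to
   N = 4096, float32 above).
5. **Metrics** on the binary graph: degree K(i); nodal global
   efficiency Eglob(i) = mean over j≠i of 1/d(i,j) with BFS distances,
   unreachable pairs contributing 0 (no largest-component
   restriction — components are never extracted); local efficiency
   Eloc(i) = network global efficiency of the subgraph induced on i's
   neighbors (0 for degree < 2). Network values are all-node means
   (a connected-nodes-only alternative was considered and rejected to
   keep the mean comparable across sessions; it can be had by masking).
   Clustering coefficient and path length are available on request but
   are not part of the default read-outs, since the efficiencies carry
   the same information. Shortest paths use scipy's csgraph BFS; the
   test suite checks exact agreement with naive BFS oracles and with
   networkx on random graphs.
6. **Consistency maps.** Per subject and condition, each session's top
   fraction of nodes by a metric (default 0.20 for whole-brain maps)
   is selected — ties broken by (value descending, node index
   ascending), cut at exactly ⌈fraction·N⌉ — then the per-voxel
   fraction of sessions is computed, thresholded at ≥ 0.6 (generalizes
   "3 of 5"), and aggregated across subjects into a meta map. For ROI
   connectivity maps the top fraction (default 0.15) is taken *within*
   the ROI's nodes, the neighbors of those top nodes are collected
   (a top node counts only via adjacency to another top node; flag to
   include the top set), session-thresholded at 0.6 and
   subject-thresholded at 0.5. Both fractions are parameters; the
   defaults follow the convention of using a broader cut (20%) for
   whole-brain hub maps and a stricter one (15%) when selecting top
   nodes inside a small ROI.
7. **ROI statistics.** ROIs are unions of spheres in mm space (default
   radius 10 mm; bilateral regions analyzed as the left+right union);
   a voxel belongs if its center is within the radius. ROI values are
   arithmetic means over in-mask gray nodes. Inference is a fully
   within-subjects 2 (condition) × S (session) ANOVA via cell-means
   sums of squares: each effect is tested against its own
   effect-by-subject interaction, partial η² = SS_eff/(SS_eff+SS_err),
   p from the F distribution. With every factor within-subject this
   matches the reported df (1, n−1) for the condition effect. No
   sphericity correction is applied by default (the primary contrast
   has 1 numerator df and needs none). Degenerate inputs (zero error
   SS, or zero df) yield NaN/boundary results with a warning rather
   than an exception. The decomposition is hand-written because the
   installed ANOVA routines do not expose per-effect SS; statsmodels'
   AnovaRM is used as an independent cross-check in the tests.

Everything is deterministic given (config, seed); summary tables are
byte-identical across reruns, and provenance (config hash, seed,
version, per-session r_th and K) is written beside the outputs.
Completed runs are cached by config hash.

## Synthetic study generator

The generator emulates the study design the pipeline targets: 5
subjects × (5 rest + 5 task) sessions, alternating (rest first by
default; configurable since the original design does not state the
first session), 120 volumes at TR = 2 s, voxels 4×4×5 mm. The default
grid is desk-scale, 14×14×10 (~1200 gray voxels), so a full multi-seed
study runs in minutes on one CPU; full-size grids are configuration
only. Anatomy is a deliberately simple stand-in: concentric ellipsoid
shells (CSF core < 0.2, white 0.2–0.45, gray 0.45–1 in normalized
radius), background zero.

Per brain voxel and session the signal is

    s(t) = baseline(tissue) + √λ·u(t) + √λ_loc·v_p(t)
         + √(1−λ−λ_loc)·ε(t) + drift(t) + w_physio·c(t) + L·m(t)

with unit-variance components, so λ terms are raw correlations:

* **Hub latents u.** Gray voxels within a hub sphere share a
  band-limited (0.01–0.07 Hz) latent. The rest hub (posterior
  midline, 10 mm) loads at 0.8 at rest and 0.05 on task; the task hub
  (right frontal, 8 mm) the reverse; the task-hub latent also loads at
  0.4 onto a distal coupled region (8 mm) during task only, planting
  long-range task connectivity (cross-correlation √(0.8·0.4) ≈ 0.57
  before filtering). These produce the hub-degree condition effects.
* **Local parcel latents v_p.** Gray voxels are tiled into 3×3×2-voxel
  parcels, each sharing a slow latent with loading 0.25 at rest and
  0.12 on task (scaled by 1−λ so total latent variance stays < 1).
  This is the baseline local functional coherence of real BOLD, with
  the rest-state advantage emulating task-load suppression of slow
  local coherence; it is what makes whole-network local efficiency
  higher at rest. Without such a baseline the fixed-density threshold
  pushes the spare edge budget into the sampling-noise tail of the
  correlation distribution, which at ~30 effective degrees of freedom
  is strongly transitive, and the local-efficiency contrast comes out
  with the wrong sign.
* **Noise ε** is AR(1) (φ = 0.3) with unit marginal variance.
* **Drift** is the sum of the two lowest nonzero DFT frequencies of
  the run (1/240 and 2/240 Hz at default length — both below the
  0.009 Hz band edge, so filtering removes it exactly), with per-voxel
  random phase and 0.5–1.5× amplitude scatter.
* **Confounds**: a shared broadband physiological series (weight 0.3
  into every brain voxel) and six slow random-walk motion series with
  per-voxel Gaussian loadings (SD 0.1). Tissue mean signals are
  computed from the generated data itself, so the nuisance regressors
  are exactly what a real pipeline would extract.

Seeding uses `numpy` `SeedSequence` spawning per subject and session:
identical config + seed is bit-identical; different sessions are
independent.

What the generator does **not** emulate: hemodynamic response
convolution, task-evoked mean activation, spatially smooth noise at
sub-parcel scale, scanner spike/ghosting artifacts, subject-level
anatomical variability, or head-motion image displacement (data are
generated pre-aligned; motion enters only as nuisance series). Passing
recovery tests therefore show that the pipeline recovers planted
covariance structure under realistic temporal statistics — not that it
would survive every artifact of real scans.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] after the blockwise matmul;
  the diagonal is excluded from all edge logic.
* Whole-brain mean degree is constant across sessions by construction
  (fixed N and density rule), so its ANOVA is degenerate on synthetic
  data; it is reported as NaN with a warning, mirroring how any
  zero-variance metric is handled.
* Filter band validation requires 0 ≤ low < high < Nyquist.
* `solve_threshold` refuses networks with a target edge count below 1
  and inputs with N < 2 or S ≤ 1.
* Sphere masks that contain no voxel center warn and return empty.
* All consistency thresholds are inclusive (≥), so "3 of 5" is the
  fraction 0.6 and generalizes to other session counts.

## Problem sizes used in the test and acceptance runs

The shipped test suite and acceptance script use the default desk-scale
grid (~1200 nodes), ten replicate studies for direction-recovery
checks, 100 random graphs (N ≤ 60) for metric oracle equivalence, and
2000 simulated tables for ANOVA null calibration. These sizes were
chosen so a complete run is comfortable on a single CPU; all of them
are parameters, and larger replications only tighten the same checks.
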