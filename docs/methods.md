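# Methods

## Problem and representation

Input is a time series of per-frame cell detections, each reduced to a point
with features: centroid (x, y) in pixels, area in px², and the major-axis
orientation in radians. Orientation is *axial*: a segmented rod has no head or
tail, so angles are equivalent mod π and every angle difference is the minimal
axial difference in [0, π/2]. Coordinates are 0-based pixel centers with x =
column, y = row, fixed so Cell Tracking Challenge (CTC) interop is
well-defined. Masks are deliberately out of the core model — all scoring uses
derived features only — which keeps the tool desk-scale and format-agnostic.

A lineage hypothesis is a forest over detections with edges only between
consecutive *processed* frames and at most two children per node (a 2-child
node is a division). "Frame" always means the index in the processed series;
the physical interval Δt in minutes is a model parameter, so the same code
handles native and sub-sampled recordings.

## Assignment models

Each frame pair admits four assignment types: appear (0→1), disappear (1→0),
migrate (1→1) and divide (1→2). Scores are joint log-likelihoods built as sums
of univariate log-densities — independence is the only structure imposed, and
it is what makes the models composable. Migration:

- half-normal on ‖observed − predicted position‖ with scale σ_move·√Δt,
- normal on area_obs/area_pred around 1 with sd σ_area,
- (O) normal on the axial rotation angle with sd σ_angle,
- (G) normal on area_tgt/area_src around exp(colony_rate·Δt) with sd
  σ_area_growth.

Division replaces the position term with the daughter midpoint and the area
term with the summed daughter area, and adds (O) a normal on the axial angle
between the daughter major axes (mean μ_div_angle — the "snapping" geometry of
rod-shaped bacteria, which divide with a stereotyped kink) and (DD) a
half-normal on the inter-daughter distance with scale σ_div_dist. The division
score is symmetric in the daughters by construction. Appear and disappear are
constant log-penalties λ_appear, λ_disappear.

The growth (G) model is a *normal* on the area ratio centred on the
colony-level expectation; a half-normal here would put its mode at ratio 0
rather than at the colony growth factor, so the normal form is the coherent
reading and is what we implement. The colony rate itself is estimated without
tracking: the OLS slope of log(total segmented area) against physical time.

Scores mix densities of quantities with different units; they are therefore
comparable only within one frame pair, which is all the selection step needs.
Probabilistic interpretation across frames lives in the particle filter.

### Prediction and self-learning

NN predicts zero motion and growth. FO extrapolates each cell's own past:
velocity (pos − parent pos)/Δt and growth factor area/parent area, read from
the particle's lineage history by batched array traversal (one vectorized
gather per ancestor level; no per-cell recursion). Two conventions matter:

- a division daughter's growth reference is parent_area/2, not parent_area,
  so the growth feature does not see a spurious 0.5× collapse at divisions;
- a root (no history) uses velocity (0, 0) and growth exp(colony_rate·Δt) —
  the colony prior is the only information available for a cell without past.

Growth factors are clipped to [0.5, 4] (configurable) to tolerate
segmentation artifacts.

### Parameters

All scales are per ModelParams, overridable per call. Defaults: σ_move = 5
px/√min, σ_area = 0.1, σ_area_growth = 0.1, σ_angle = 0.3 rad, μ_div_angle =
0 rad, σ_div_angle = 0.3 rad, σ_div_dist = 8 px, λ_appear = λ_disappear =
−20, candidate radius r_max = 40·√Δt px, division-distance limit defaulting
to r_max. Displacement scales diffusively (√Δt) and growth exponentially
(exp(rate·Δt)) with the imaging interval: the standard physical choices for
Brownian-like jitter and exponential growth, both overridable. The λ
penalties are set so that any migration within ~2σ of its prediction
outscores explaining the same pair as disappearance plus appearance.

Six configurations compose the models: NN; FO; FO+O; FO+G; FO+DD; FO+G+O+DD
(alias FO+O+G+DD). A kernel-density scorer (`KernelDensityModel`) is provided
for fitting arbitrary feature densities from a reference forest but is not
part of the named configurations.

## Candidate generation and ILP selection

Candidates are filtered for plausibility: migrations within r_max of the
source, divisions with both daughters within r_max and inter-daughter
distance below the limit. One appear per target and one disappear per source
are always present, so a valid solution always exists. Selection is an exact
cover — each source and each target in exactly one chosen assignment — encoded
as an ILP with one binary per candidate, one equality row per detection, and
the summed log-score as objective, solved by HiGHS branch-and-bound
(`scipy.optimize.milp`). Ties are broken deterministically by an
infinitesimal objective perturbation (≈1e−7 against each appear/disappear,
≈1e−10·index per candidate), preferring biologically contiguous solutions and
fixed ordering; the perturbations are orders of magnitude below meaningful
likelihood differences. An exhaustive enumerator (guarded to ≤8 sources and
targets, exact tie rules) serves as an independent oracle in the tests and is
available as `solver="brute"`. k-best covers are obtained by re-solving with
an exclusion cut per found cover; since two distinct exact covers can never
be subsets of one another, each cut removes exactly one solution.

## Particle filter

N particles each hold a full lineage forest and a cumulative log-weight equal
to the sum of all their selected assignment scores (an invariant we test).
Per step and per particle: build histories from that particle's own forest,
generate and score candidates, take the k best covers, and sample one with
probability ∝ exp(score − max score) (softmax, temperature 1 — the minimal
choice given that extensions should be drawn from the most likely covers; k
is exposed). The population is then systematically resampled with weights
proportional to the per-step cover scores: right after a resampling the
population is uniform, so the per-step increment is the correct importance
weight, and resampling resets the population to uniform again. Cumulative
log-weights are never reset; the MAP particle is recorded each step *before*
resampling so resampling cannot destroy the best hypothesis. With N = 1 and
k = 1 the filter degenerates exactly to greedy per-frame ILP chaining — a
tested equivalence. Execution is sequential and deterministic given the seed;
covers are computed once per distinct hypothesis, so resampled duplicates
cost nothing extra.

## Synthetic colony generator

The simulator emulates a growing 2D monolayer of rod-shaped bacteria observed
at a base interval of 1 min: per step each cell's area grows by
exp((colony_rate + ε)·Δt) with ε ~ N(0, growth_noise); positions undergo a
random walk of sd motion_sd·√Δt on top of a deterministic radial expansion
flow (positions scaled by exp(colony_rate·Δt/2) about the colony origin, the
kinematic consequence of exponential area growth); orientations diffuse with
sd rotation_sd·√Δt. A cell whose area exceeds its threshold (division_area
with per-cell lognormal jitter) splits into two daughters of half its area
(± a lognormal asymmetry tied to growth_noise), centers offset ±d/2 along
the mother axis, orientations mother ± δ/2 with δ ~ N(div_angle_mean,
div_angle_sd) — so the inter-daughter axial angle directly follows the
configured snapping distribution. Detections are dropped independently with
probability detection_dropout; ground truth then truncates the track and the
re-detection starts a new root, as segmentation gaps do in real data.

The expansion flow is the one deliberate addition beyond pure noise terms: a
first-order motion model is only meaningful if cells have persistent motion,
and in real colonies they do — growth pushes cells outward. We model that
flow kinematically rather than with contact mechanics; crowding beyond it is
approximated by the random walk. Consequences for interpretation: passing
tests show the models exploit persistent radial motion and snapping division
geometry, but say nothing about contact-driven reorientation, non-radial
jostling in dense packs, or segmentation biases coupled to density — none of
which the generator produces.

Defaults (the study conditions for all experiments): 6 initial cells, 65
frames at 1 min, colony_rate 0.02/min, growth_noise 0.02, motion_sd 1 px/√min,
rotation_sd 0.05 rad/√min, division_area 200 px² with 10 % jitter,
div_distance 8 px, div_angle_sd 0.25 rad, dropout 0, population cap 1000
(stops early with a warning flag). These were chosen once as a realistic
desk-scale colony — ~800 detections, ~16 divisions per run, tracking
near-trivial at 1-min intervals and sharply degraded by 16-min intervals —
so that whole-suite experiments over 5 seeds, 4 sub-sampling factors and all
6 configurations complete in about a minute.

### Sub-sampling

Longer imaging intervals are emulated by keeping every f-th frame and
renumbering. Ground truth is composed across the gap: each kept-frame cell
links to its surviving descendants at the next kept frame — one descendant is
a migration, two a division. When >2 descendants survive (two divisions in
one gap), the pair whose lineage paths diverge latest (the intermediate
division closest to the later kept frame) is recorded as the division and the
remaining descendants become unresolvable new roots, counted and returned.
This is a documented convention; no principled composition exists once a gap
hides two generations.

## Metrics

Evaluation assumes identical detections in prediction and reference (vertex
correspondence is the identity), so only edges are compared.

- **Division F1**: a predicted division (parent, frame) matches an unmatched
  reference division on the same lineage within ±frame_tolerance frames,
  greedily by |Δframe|. Tolerance defaults to 0, including for sub-sampled
  runs — both forests live on the same sub-sampled frame axis.
- **LNK**: 1 − min(cost, cost_empty)/cost_empty, where cost counts edges to
  add (weight 1.5), redundant edges (1) and shared edges whose semantics
  differ (migration vs division link, weight 1), and cost_empty = 1.5·|ref
  edges|. The weights follow the acyclic-oriented-graph-matching edge
  convention used in the CTC ecosystem and are configurable. An empty
  reference scores 1 against an empty prediction, else 0.

## Numerical and degeneracy choices

- Densities are evaluated in closed form in log space; all scorers return
  finite values for any valid input.
- Forest validation distinguishes error classes (duplicate parent, >2
  children, frame gap, cycle); cycles are checked before frame consistency so
  mutually-parented pairs report as cycles.
- CTC track labels are assigned in (begin frame, first detection id) order;
  CSV floats are serialized at 17 significant digits and parsed with
  pandas' round-trip parser, making file round trips bitwise lossless.
- The CTC text format cannot identify which detection belongs to which track
  (real CTC uses label masks); the writer therefore also emits a
  detection→label map, and dataset directories persist forests as JSON edge
  lists alongside `res_track.txt`.
- All randomness flows from a single `numpy` Generator per run; identical
  (config, seed) reproduce simulate/track/evaluate outputs byte for byte.

## Limitations

- Merges (2→1), frame-skipping assignments and >2-daughter divisions are out
  of scope; sub-sampled gaps hiding two generations are only partially
  resolvable (see above).
- Appearance/disappearance penalties are constants; no boundary-aware
  modulation near the field-of-view edge.
- Model parameters are hand-set scales, not learned; the KDE scorer offers a
  data-driven alternative but no EM-style fitting is provided.
- Features are always computed within one particle's forest; there is no
  cross-particle feature averaging and no backward smoothing pass.
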