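# uatrack

Uncertainty-aware tracking of rod-shaped bacteria in time-lapse microscopy.

Live-cell imaging of microbial colonies in 2D monolayer chambers produces, per
frame, a set of segmented cell detections. Reconstructing which cell became
which — the **cell lineage tree (CLT)**, a bifurcated forest whose edges link a
cell instance in frame *t* to its identity or its two daughters in frame
*t + 1* — is ambiguous whenever the imaging interval is long, cells are
crowded, or segmentation drops cells. `uatrack` treats this ambiguity head-on:
instead of a single answer it maintains a **distribution over lineage trees**,
reporting a maximum-a-posteriori (MAP) lineage together with per-edge
confidence.

## Method

Between consecutive frames, four assignment types link detections: appearance,
disappearance, migration (1→1) and division (1→2). Each candidate assignment
is scored by a joint log-likelihood composed of univariate densities of
single-cell observables:

- displacement of the observed position from a predicted one:
  half-normal, scale σ_move·√Δt;
- relative deviation of observed from predicted area: normal around 1;
- migration rotation angle (axial, mod π): normal around 0;
- the "snapping" angle between daughter major axes at division: normal;
- inter-daughter distance: half-normal;
- single-cell area growth ratio: normal around exp(colony_rate·Δt), where the
  colony growth rate is estimated from segmentation alone.

Predictions come either from a nearest-neighbour assumption (NN: zero motion
and growth) or a first-order model (FO: each cell extrapolates its own past
velocity and growth, read off its lineage history — a self-learning feature).
Six named configurations (NN, FO, FO+O, FO+G, FO+DD, FO+G+O+DD) compose these
models.

Selecting assignments is an exact-cover problem — every detection in both
frames participates in exactly one chosen assignment — solved as an **integer
linear program** (one binary per candidate, one equality constraint per
detection, objective = total log-score) with a branch-and-bound backend
(HiGHS via SciPy). A **particle filter** maintains N lineage-tree hypotheses:
each particle scores candidates with its own history, samples one of the k
best covers (softmax over cover scores), and the population is systematically
resampled each step. Agreement across particles gives per-edge marginal
probabilities.

A synthetic colony simulator (exponential area growth, expansion flow plus
random-walk motion, orientation diffusion, threshold-triggered divisions with
snapping geometry, optional detection dropout) provides ground truth for every
experiment, including temporal sub-sampling that emulates longer imaging
intervals.

## Worked example

```python
import uatrack as ut

params = ut.SimParams(seed=42)              # 6 cells, 65 one-minute frames
sim = ut.simulate(params)
print("frames:", len(sim.frames), "detections:", sum(len(f) for f in sim.frames),
      "true divisions:", len(ut.divisions_of(sim.forest)))

# emulate an 8-minute imaging interval
frames, gt, _ = ut.subsample(sim.frames, sim.forest, 8)
rate = ut.estimate_colony_growth_rate(frames, dt=8.0)   # segmentation only
print(f"estimated colony rate: {rate:.4f}/min")

cfg = ut.make_config("FO+G+O+DD", dt=8.0, colony_rate=rate)
state = ut.run(frames, cfg, n_particles=8, k=3, seed=1)
report = ut.evaluate(ut.map_forest(state), gt)
print(f"division F1: {report.division_f1:.3f}  LNK: {report.lnk:.3f}")
marg = ut.edge_marginals(state)
print("uncertain edges:", {e: round(v, 2) for e, v in marg.items() if v < 1.0})
```

Output:

```
frames: 65 detections: 819 true divisions: 16
estimated colony rate: 0.0194/min
division F1: 1.000  LNK: 0.969
uncertain edges: {(386, 506): 0.88, (496, 634): 0.88, (647, 814): 0.25, ...}
```

The colony's generating growth rate (0.02/min) is recovered from total area
alone; at an 8-minute interval the composite configuration reconstructs all 16
divisions and 96.9 % of the linking structure (LNK, an edge-based score where
1 is perfect and 0 is no better than an empty prediction). The edges the
particles disagree on — e.g. edge (386, 506) present in 88 % of particles —
are exactly the crowded daughter-pairings a curator should review.

The same pipeline is scriptable from a shell:

```sh
uatrack simulate --seed 42 --out ref/
uatrack track --detections ref/detections.csv --config FO+G+O+DD \
        --particles 8 --kbest 3 --seed 1 --out pred/
uatrack evaluate --pred pred/ --ref ref/ --out report.json
uatrack degrade --factors 1,2,4,8,16 --configs NN,FO+G+O+DD --out table.csv
```

`track` writes a Cell Tracking Challenge style `res_track.txt`, a JSON edge
list with marginals, and per-frame log-scores; all outputs are bitwise
reproducible from (config, seed).

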