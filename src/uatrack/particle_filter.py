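"""Sequential Bayesian multi-hypothesis tracking over cell lineage trees.

The filter maintains N particles, each a complete lineage-forest hypothesis
over the frames processed so far.  At every frame pair each particle
generates and scores assignment candidates using features learned from its
own history (self-learning), obtains the k best exact covers by repeated ILP
solves, samples one cover (softmax over cover scores), and extends.  The
particle population is then systematically resampled in proportion to the
per-step cover scores.  The final population approximates the posterior over
lineage trees; the best cumulative-weight particle is the MAP lineage and
per-edge particle fractions express lineage uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .assignment_models import CellHistory, TrackingConfig
from .candidate_ilp import generate_candidates, k_best_covers
from .datamodel import Detection, LineageForest, Particle, extend_particle
from .lineage_walks import (
    estimate_growth_factor,
    estimate_velocity,
    to_indexed,
)


@dataclass
class FilterState:
    particles: List[Particle]
    frame: int
    rng: np.random.Generator
    map_particle: Particle
    # per-step log-score of the sampled cover of the MAP-tracked particle
    score_log: List[float] = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return len(self.particles)


def init_filter(
    frame0: Sequence[Detection], n_particles: int, seed: int
) -> FilterState:
    """Start the filter at frame 0 with N identical singleton-root forests."""
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    base = Particle(LineageForest(list(frame0), {}), 0.0)
    particles = [base for _ in range(n_particles)]
    return FilterState(
        particles=particles,
        frame=0,
        rng=np.random.default_rng(seed),
        map_particle=base,
    )


def particle_histories(
    particle: Particle, frame: int, config: TrackingConfig
) -> Dict[int, CellHistory]:
    """Self-learned velocity and growth features for every cell in ``frame``
    of one particle's forest."""
    p = config.params
    fif = to_indexed(particle.forest)
    if frame >= fif.n_frames:
        return {}
    fa = fif.frames[frame]
    vel = estimate_velocity(fif, frame, p.dt)
    growth = estimate_growth_factor(
        fif, frame, p.dt, p.colony_rate, clip=p.growth_clip
    )
    return {
        int(fa.ids[i]): CellHistory(float(vel[i, 0]), float(vel[i, 1]), float(growth[i]))
        for i in range(len(fa.ids))
    }


def _systematic_resample(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(max=len(weights) - 1)


def step(
    state: FilterState,
    next_detections: Sequence[Detection],
    config: TrackingConfig,
    k: int = 1,
) -> FilterState:
    """Advance the filter by one frame pair.

    Covers are computed once per distinct particle hypothesis; each particle
    slot samples its own extension.  Resampling weights are the per-step
    cover scores (population weights are uniform right after the previous
    resampling); cumulative log-weights are kept for MAP extraction and are
    never reset.
    """
    t = state.frame
    next_dets = sorted(next_detections, key=lambda d: d.id)

    # covers per distinct hypothesis (resampling duplicates share objects)
    covers_by_particle: Dict[int, list] = {}
    for particle in state.particles:
        key = id(particle)
        if key in covers_by_particle:
            continue
        hist = particle_histories(particle, t, config)
        sources = particle.forest.frame_detections(t)
        problem = generate_candidates(sources, next_dets, config, hist)
        covers_by_particle[key] = k_best_covers(problem, k)

    offspring: List[Particle] = []
    increments: List[float] = []
    for particle in state.particles:
        covers = covers_by_particle[id(particle)]
        scores = np.array([c.total_log_score for c in covers])
        probs = np.exp(scores - scores.max())
        probs /= probs.sum()
        idx = int(state.rng.choice(len(covers), p=probs))
        cover = covers[idx]
        offspring.append(extend_particle(particle, cover.candidates, next_dets))
        increments.append(cover.total_log_score)

    # MAP tracked pre-resampling; ties -> lowest particle index
    best = int(np.argmax([p.log_weight for p in offspring]))
    map_particle = offspring[best]

    inc = np.asarray(increments)
    w = np.exp(inc - inc.max())
    w /= w.sum()
    chosen = _systematic_resample(w, len(offspring), state.rng)
    particles = [offspring[int(i)] for i in chosen]

    return FilterState(
        particles=particles,
        frame=t + 1,
        rng=state.rng,
        map_particle=map_particle,
        score_log=state.score_log + [increments[best]],
    )


def run(
    frames: Sequence[Sequence[Detection]],
    config: TrackingConfig,
    n_particles: int = 1,
    k: int = 1,
    seed: int = 0,
) -> FilterState:
    """Track a whole time-lapse: init on frame 0, then one step per pair.

    Deterministic given (frames, config, n_particles, k, seed).  With
    ``n_particles=1, k=1`` this reduces to greedy per-frame ILP chaining.
    """
    if not frames:
        raise ValueError("need at least one frame")
    state = init_filter(frames[0], n_particles, seed)
    for next_dets in frames[1:]:
        state = step(state, next_dets, config, k)
    return state


def map_forest(state: FilterState) -> LineageForest:
    """Forest of the maximum cumulative-log-weight particle (pre-resampling)."""
    return state.map_particle.forest


def edge_marginals(state: FilterState) -> Dict[Tuple[int, int], float]:
    """Fraction of particles containing each lineage edge — an uncertainty
    summary of the posterior approximation."""
    counts: Dict[Tuple[int, int], int] = {}
    for particle in state.particles:
        for edge in particle.forest.edges():
            counts[edge] = counts.get(edge, 0) + 1
    n = state.n_particles
    return {e: c / n for e, c in counts.items()}
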