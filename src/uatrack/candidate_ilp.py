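"""Assignment-candidate generation and optimal frame-to-frame cover selection.

Between two consecutive processed frames the tracker enumerates plausible
assignment hypotheses (migrations within a displacement radius, divisions
with both daughters in radius, plus one appear per target and one disappear
per source), scores each with the configured models, and selects the most
likely valid subset.  Validity is an exact cover: every source and every
target detection participates in exactly one selected assignment.  The
selection is a small integer linear program — one binary variable per
candidate, one equality constraint per detection — solved with a
branch-and-bound MILP backend (HiGHS); an exhaustive enumerator provides an
independent oracle and the k-best covers feed particle sampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import csr_matrix

from .assignment_models import (
    CellHistory,
    TrackingConfig,
    root_history,
    score_appear,
    score_disappear,
    score_division,
    score_migration,
)
from .datamodel import (
    AssignmentCandidate,
    Detection,
    InvalidCoverError,
    appear,
    check_cover,
    disappear,
    divide,
    migrate,
)

BRUTE_FORCE_GUARD = 8  # max sources/targets for exhaustive enumeration

# Tie-breaking perturbations: prefer fewer appear/disappear events among
# equal-score optima, then lower candidate indices.  Both are far below any
# meaningful log-likelihood difference.
_EPS_UNARY = 1e-7
_EPS_LEX = 1e-10


@dataclass
class FramePairProblem:
    """All scored assignment candidates between frame t and frame t+1."""

    sources: List[Detection]
    targets: List[Detection]
    candidates: List[AssignmentCandidate]


@dataclass
class Cover:
    """An exact cover of one frame pair: each source and target detection is
    covered by exactly one selected candidate."""

    candidates: Tuple[AssignmentCandidate, ...]
    total_log_score: float

    @property
    def n_unary(self) -> int:
        return sum(1 for c in self.candidates if c.is_unary)


def generate_candidates(
    sources: Sequence[Detection],
    targets: Sequence[Detection],
    config: TrackingConfig,
    histories: Optional[Mapping[int, CellHistory]] = None,
) -> FramePairProblem:
    """Enumerate and score filtered assignment candidates for one frame pair.

    Migration candidates are kept for source-target pairs within ``r_max``
    px; division candidates require both daughters within ``r_max`` of the
    mother and an inter-daughter distance below the division-distance limit.
    One appearance per target and one disappearance per source guarantee
    feasibility of the exact cover.
    """
    p = config.params
    sources = sorted(sources, key=lambda d: d.id)
    targets = sorted(targets, key=lambda d: d.id)
    if histories is None:
        histories = {}
    cands: List[AssignmentCandidate] = []
    for s in sources:
        h = histories.get(s.id, root_history(p))
        near = [t for t in targets if math.hypot(t.x - s.x, t.y - s.y) <= p.r_max]
        for t in near:
            cands.append(migrate(s.id, t.id, score_migration(config, s, h, t)))
        for t1, t2 in itertools.combinations(near, 2):
            if math.hypot(t1.x - t2.x, t1.y - t2.y) <= p.div_distance_limit:
                cands.append(
                    divide(s.id, t1.id, t2.id, score_division(config, s, h, t1, t2))
                )
        cands.append(disappear(s.id, score_disappear(config, s)))
    for t in targets:
        cands.append(appear(t.id, score_appear(config, t)))
    return FramePairProblem(sources, targets, cands)


def _constraint_matrix(problem: FramePairProblem) -> Tuple[csr_matrix, int]:
    """Exact-cover equality matrix: one row per source, then per target."""
    src_row = {d.id: i for i, d in enumerate(problem.sources)}
    tgt_row = {d.id: len(src_row) + i for i, d in enumerate(problem.targets)}
    n_rows = len(src_row) + len(tgt_row)
    rows, cols = [], []
    for j, cand in enumerate(problem.candidates):
        for s in cand.source:
            rows.append(src_row[s])
            cols.append(j)
        for t in cand.targets:
            rows.append(tgt_row[t])
            cols.append(j)
    mat = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_rows, len(problem.candidates))
    )
    return mat, n_rows


def _solve_milp(
    problem: FramePairProblem,
    exclusions: Sequence[Tuple[int, ...]] = (),
) -> Optional[Cover]:
    """Solve the exact-cover MILP; returns None if infeasible (only possible
    once exclusion cuts forbid every cover)."""
    n = len(problem.candidates)
    if n == 0:
        if problem.sources or problem.targets:
            raise InvalidCoverError("no candidates but detections to cover")
        return Cover((), 0.0)
    scores = np.array([c.log_score for c in problem.candidates])
    perturbed = scores.copy()
    for j, cand in enumerate(problem.candidates):
        if cand.is_unary:
            perturbed[j] -= _EPS_UNARY
        perturbed[j] -= _EPS_LEX * (j + 1)
    mat, n_rows = _constraint_matrix(problem)
    constraints = [LinearConstraint(mat, np.ones(n_rows), np.ones(n_rows))]
    for excl in exclusions:
        row = np.zeros(n)
        row[list(excl)] = 1.0
        constraints.append(LinearConstraint(row, -np.inf, len(excl) - 1))
    res = milp(
        c=-perturbed,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=(0, 1),
    )
    if not res.success:
        return None
    chosen = tuple(
        problem.candidates[j] for j in range(n) if res.x[j] > 0.5
    )
    total = float(sum(c.log_score for c in chosen))
    return Cover(chosen, total)


def solve_optimal(problem: FramePairProblem, solver: str = "milp") -> Cover:
    """Maximum-score exact cover of one frame pair.

    Ties are broken deterministically toward fewer appear/disappear events,
    then toward the lexicographically smallest candidate index set.
    ``solver`` is "milp" (default, branch-and-bound) or "brute" (exhaustive,
    guarded to small problems).
    """
    if solver == "brute":
        covers = enumerate_bruteforce(problem)
        if not covers:
            raise InvalidCoverError("no feasible cover")
        return covers[0]
    if solver != "milp":
        raise ValueError(f"unknown solver {solver!r}")
    cover = _solve_milp(problem)
    if cover is None:
        raise InvalidCoverError("no feasible cover")
    check_cover(
        cover.candidates,
        {d.id for d in problem.sources},
        {d.id for d in problem.targets},
    )
    return cover


def enumerate_bruteforce(problem: FramePairProblem) -> List[Cover]:
    """All exact covers, best score first (test oracle; small problems only).

    Equal-score covers are ordered by fewer appear/disappear events, then by
    candidate index set.
    """
    if len(problem.sources) > BRUTE_FORCE_GUARD or len(problem.targets) > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute-force enumeration guarded to ≤{BRUTE_FORCE_GUARD} sources/targets"
        )
    index_of = {id(c): j for j, c in enumerate(problem.candidates)}
    by_source: Dict[int, List[AssignmentCandidate]] = {
        d.id: [] for d in problem.sources
    }
    appear_of: Dict[int, AssignmentCandidate] = {}
    for cand in problem.candidates:
        if cand.kind == "appear":
            appear_of[cand.targets[0]] = cand
        else:
            by_source[cand.source[0]].append(cand)
    source_ids = [d.id for d in problem.sources]
    target_ids = [d.id for d in problem.targets]
    missing = [t for t in target_ids if t not in appear_of]
    if missing:
        raise InvalidCoverError(f"targets without appearance candidate: {missing}")
    covers: List[Cover] = []

    def recurse(i: int, used: set, chosen: List[AssignmentCandidate]) -> None:
        if i == len(source_ids):
            leftovers = [appear_of[t] for t in target_ids if t not in used]
            full = chosen + leftovers
            total = sum(c.log_score for c in full)
            covers.append(Cover(tuple(full), total))
            return
        sid = source_ids[i]
        for cand in by_source[sid]:
            if any(t in used for t in cand.targets):
                continue
            recurse(i + 1, used | set(cand.targets), chosen + [cand])

    recurse(0, set(), [])

    def sort_key(cover: Cover):
        idx = tuple(sorted(index_of[id(c)] for c in cover.candidates))
        return (-cover.total_log_score, cover.n_unary, idx)

    covers.sort(key=sort_key)
    return covers


def k_best_covers(
    problem: FramePairProblem, k: int, solver: str = "milp"
) -> List[Cover]:
    """Up to ``k`` distinct covers in non-increasing score order.

    Found by iteratively re-solving with an exclusion cut forbidding each
    previously returned cover (two distinct exact covers can never be
    subsets of one another, so each cut removes exactly one cover).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if solver == "brute":
        return enumerate_bruteforce(problem)[:k]
    index_of = {id(c): j for j, c in enumerate(problem.candidates)}
    covers: List[Cover] = []
    exclusions: List[Tuple[int, ...]] = []
    for _ in range(k):
        cover = _solve_milp(problem, exclusions)
        if cover is None:
            break
        covers.append(cover)
        excl = tuple(index_of[id(c)] for c in cover.candidates)
        if not excl:  # empty cover (no detections): nothing further to exclude
            break
        exclusions.append(excl)
    return covers
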