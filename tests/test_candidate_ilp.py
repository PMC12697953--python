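import dataclasses
import math

import numpy as np
import pytest

from uatrack.assignment_models import make_config
from uatrack.candidate_ilp import (
    FramePairProblem,
    enumerate_bruteforce,
    generate_candidates,
    k_best_covers,
    solve_optimal,
)
from uatrack.datamodel import check_cover

from conftest import det


def cover_counts(cover):
    kinds = [c.kind for c in cover.candidates]
    return {k: kinds.count(k) for k in ("migrate", "divide", "appear", "disappear")}


def assert_conserved(cover, n_sources, n_targets):
    c = cover_counts(cover)
    assert c["migrate"] + c["divide"] + c["disappear"] == n_sources
    assert c["migrate"] + 2 * c["divide"] + c["appear"] == n_targets


def random_problem(rng, max_sources=5, max_targets=6):
    """Random geometry, then random scores (structure stays feasible)."""
    ns = int(rng.integers(0, max_sources + 1))
    nt = int(rng.integers(0, max_targets + 1))
    sources = [
        det(i, 0, x=rng.uniform(0, 60), y=rng.uniform(0, 60), area=rng.uniform(50, 200))
        for i in range(ns)
    ]
    targets = [
        det(100 + i, 1, x=rng.uniform(0, 60), y=rng.uniform(0, 60),
            area=rng.uniform(50, 200))
        for i in range(nt)
    ]
    cfg = make_config("NN", r_max=float(rng.uniform(20, 200)))
    problem = generate_candidates(sources, targets, cfg)
    problem.candidates = [
        dataclasses.replace(c, log_score=float(rng.normal(0, 5)))
        for c in problem.candidates
    ]
    return problem


class TestGenerateCandidates:
    def test_radius_filter(self):
        cfg = make_config("NN", r_max=50.0)
        sources = [det(0, 0, x=0, y=0)]
        targets = [det(1, 1, x=5, y=0), det(2, 1, x=100, y=0)]
        problem = generate_candidates(sources, targets, cfg)
        kinds = sorted(c.kind for c in problem.candidates)
        assert kinds == ["appear", "appear", "disappear", "migrate"]
        (mig,) = [c for c in problem.candidates if c.kind == "migrate"]
        assert mig.targets == (1,)

    def test_no_sources_gives_appearances_only(self):
        cfg = make_config("NN")
        problem = generate_candidates([], [det(1, 1), det(2, 1)], cfg)
        assert sorted(c.kind for c in problem.candidates) == ["appear", "appear"]

    def test_unbounded_radius_combinatorial_count(self):
        n, m = 3, 4
        cfg = make_config("NN", r_max=1e9)
        sources = [det(i, 0, x=i) for i in range(n)]
        targets = [det(100 + j, 1, x=j) for j in range(m)]
        problem = generate_candidates(sources, targets, cfg)
        counts = {k: sum(c.kind == k for c in problem.candidates)
                  for k in ("migrate", "divide", "appear", "disappear")}
        assert counts == {
            "migrate": n * m,
            "divide": n * math.comb(m, 2),
            "appear": m,
            "disappear": n,
        }


class TestEnumerateBruteforce:
    def test_one_to_one_has_two_covers(self):
        cfg = make_config("NN", r_max=1e9)
        problem = generate_candidates([det(0, 0)], [det(1, 1)], cfg)
        covers = enumerate_bruteforce(problem)
        assert len(covers) == 2
        assert {frozenset(c.kind for c in cv.candidates) for cv in covers} == {
            frozenset({"migrate"}),
            frozenset({"appear", "disappear"}),
        }

    def test_one_to_two_has_four_covers(self):
        cfg = make_config("NN", r_max=1e9)
        problem = generate_candidates([det(0, 0)], [det(1, 1), det(2, 1)], cfg)
        assert len(enumerate_bruteforce(problem)) == 4

    def test_empty_problem_single_empty_cover(self):
        problem = FramePairProblem([], [], [])
        covers = enumerate_bruteforce(problem)
        assert len(covers) == 1
        assert covers[0].total_log_score == 0.0

    def test_guard_rejects_large_problems(self, rng):
        cfg = make_config("NN")
        sources = [det(i, 0) for i in range(9)]
        problem = generate_candidates(sources, [], cfg)
        with pytest.raises(ValueError):
            enumerate_bruteforce(problem)


class TestSolveOptimal:
    def test_plausible_migration_selected(self):
        cfg = make_config("NN")
        problem = generate_candidates([det(0, 0)], [det(1, 1, x=3)], cfg)
        cover = solve_optimal(problem)
        assert [c.kind for c in cover.candidates] == ["migrate"]

    def test_tie_broken_toward_fewer_unary_events(self):
        # migrate score equals appear + disappear exactly
        cfg = make_config("NN", lambda_appear=-1.0, lambda_disappear=-1.0)
        src, tgt = det(0, 0), det(1, 1, x=5.0)
        problem = generate_candidates([src], [tgt], cfg)
        from uatrack.assignment_models import root_history, score_migration

        mig = score_migration(cfg, src, root_history(cfg.params), tgt)
        problem.candidates = [
            dataclasses.replace(c, log_score=mig if c.kind == "migrate" else mig / 2)
            for c in problem.candidates
        ]
        cover = solve_optimal(problem)
        assert [c.kind for c in cover.candidates] == ["migrate"]

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(60):
            problem = random_problem(rng)
            best = enumerate_bruteforce(problem)[0]
            cover = solve_optimal(problem)
            assert cover.total_log_score == pytest.approx(
                best.total_log_score, abs=1e-6
            )
            assert_conserved(cover, len(problem.sources), len(problem.targets))

    def test_adding_a_candidate_never_decreases_optimum(self, rng):
        for _ in range(20):
            problem = random_problem(rng)
            base = solve_optimal(problem).total_log_score
            extra = random_problem(rng)  # borrow a structure-compatible candidate
            added = False
            for cand in extra.candidates:
                ok_src = all(s in {d.id for d in problem.sources} for s in cand.source)
                ok_tgt = all(t in {d.id for d in problem.targets} for t in cand.targets)
                if ok_src and ok_tgt:
                    problem.candidates.append(cand)
                    added = True
                    break
            if not added:
                continue
            assert solve_optimal(problem).total_log_score >= base - 1e-9


class TestKBest:
    def test_first_equals_solve_optimal(self, rng):
        for _ in range(10):
            problem = random_problem(rng)
            covers = k_best_covers(problem, 3)
            assert covers[0].total_log_score == pytest.approx(
                solve_optimal(problem).total_log_score, abs=1e-9
            )

    def test_exhausts_distinct_covers(self):
        cfg = make_config("NN", r_max=1e9)
        problem = generate_candidates([det(0, 0)], [det(1, 1)], cfg)
        covers = k_best_covers(problem, 5)
        assert len(covers) == 2  # only two covers exist

    def test_scores_non_increasing_and_match_enumeration(self, rng):
        for _ in range(15):
            problem = random_problem(rng, max_sources=3, max_targets=4)
            covers = k_best_covers(problem, 6)
            scores = [c.total_log_score for c in covers]
            assert all(a >= b - 1e-9 for a, b in zip(scores, scores[1:]))
            expected = [c.total_log_score for c in enumerate_bruteforce(problem)[:6]]
            np.testing.assert_allclose(scores, expected, atol=1e-6)
            for c in covers:
                check_cover(
                    c.candidates,
                    {d.id for d in problem.sources},
                    {d.id for d in problem.targets},
                )
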