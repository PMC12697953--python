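import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from uatrack.assignment_models import (
    CONFIG_NAMES,
    CellHistory,
    ModelParams,
    axial_difference,
    halfnormal_logpdf,
    make_config,
    normal_logpdf,
    predict,
    root_history,
    score_appear,
    score_disappear,
    score_division,
    score_migration,
)

from conftest import det


class TestDensities:
    def test_halfnormal_closed_form_at_zero(self):
        assert halfnormal_logpdf(0.0, 1.0) == pytest.approx(
            math.log(math.sqrt(2.0 / math.pi)), abs=1e-12
        )

    @pytest.mark.parametrize("sigma", [0.3, 1.0, 7.5])
    def test_halfnormal_exponent_identity(self, sigma):
        assert halfnormal_logpdf(sigma, sigma) == pytest.approx(
            halfnormal_logpdf(0.0, sigma) - 0.5, abs=1e-12
        )

    @pytest.mark.parametrize("x,sigma", [(0.0, 1.0), (2.5, 0.7), (10.0, 3.0)])
    def test_halfnormal_matches_scipy(self, x, sigma):
        assert halfnormal_logpdf(x, sigma) == pytest.approx(
            stats.halfnorm.logpdf(x, scale=sigma), abs=1e-12
        )

    @pytest.mark.parametrize("x,mu,sigma", [(0.0, 0.0, 1.0), (1.3, -0.5, 0.2)])
    def test_normal_matches_scipy(self, x, mu, sigma):
        assert normal_logpdf(x, mu, sigma) == pytest.approx(
            stats.norm.logpdf(x, mu, sigma), abs=1e-12
        )

    def test_normal_peak_and_symmetry(self):
        assert normal_logpdf(2.0, 2.0, 0.5) == pytest.approx(
            -math.log(0.5 * math.sqrt(2 * math.pi)), abs=1e-12
        )
        assert normal_logpdf(2.7, 2.0, 0.5) == pytest.approx(
            normal_logpdf(1.3, 2.0, 0.5), abs=1e-12
        )

    @pytest.mark.parametrize("sigma", [0.4, 1.0, 5.0])
    def test_quadrature_normalization(self, sigma):
        hn, _ = quad(lambda x: math.exp(halfnormal_logpdf(x, sigma)), 0, np.inf)
        assert hn == pytest.approx(1.0, abs=1e-6)
        n, _ = quad(lambda x: math.exp(normal_logpdf(x, 1.0, sigma)), -np.inf, np.inf)
        assert n == pytest.approx(1.0, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            halfnormal_logpdf(-0.1, 1.0)
        with pytest.raises(ValueError):
            halfnormal_logpdf(1.0, 0.0)
        with pytest.raises(ValueError):
            normal_logpdf(0.0, 0.0, -1.0)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.floats(0, math.pi - 1e-9), st.floats(0, math.pi - 1e-9))
def test_axial_difference_range_and_symmetry(a, b):
    d = axial_difference(a, b)
    assert 0.0 <= d <= math.pi / 2 + 1e-12
    assert d == pytest.approx(axial_difference(b, a), abs=1e-12)
    # a rod flipped by pi is the same rod
    assert axial_difference((a + math.pi) % (2 * math.pi), b) == pytest.approx(d, abs=1e-9)


class TestConfigs:
    def test_nn_has_all_flags_off(self):
        cfg = make_config("NN")
        assert not any(
            [cfg.use_first_order, cfg.use_orientation, cfg.use_growth, cfg.use_div_distance]
        )

    def test_composite_has_all_flags_on(self):
        for name in ("FO+G+O+DD", "FO+O+G+DD"):
            cfg = make_config(name)
            assert all(
                [cfg.use_first_order, cfg.use_orientation, cfg.use_growth,
                 cfg.use_div_distance]
            )

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_config("FO+XYZ")

    def test_dt_scaling_of_radius_and_growth(self):
        c1 = make_config("FO", dt=1.0, colony_rate=0.02)
        c4 = make_config("FO", dt=4.0, colony_rate=0.02)
        assert c4.params.r_max == pytest.approx(2 * c1.params.r_max)
        assert c4.params.default_growth == pytest.approx(c1.params.default_growth**4)

    def test_all_named_configs_construct(self):
        for name in CONFIG_NAMES:
            make_config(name, dt=2.0, colony_rate=0.01)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(sigma_move=0.0)
        with pytest.raises(ValueError):
            ModelParams(r_max=-1.0)


class TestPredict:
    def test_nn_prediction_is_identity(self):
        cfg = make_config("NN", colony_rate=0.05)
        d = det(0, 0, x=10, y=20, area=120)
        assert predict(cfg, d, CellHistory(3.0, 4.0, 1.5)) == (10, 20, 120)

    def test_fo_extrapolates_velocity_and_growth(self):
        cfg = make_config("FO", dt=1.0)
        d = det(0, 0, x=0, y=0, area=100)
        assert predict(cfg, d, CellHistory(3.0, 4.0, 1.2)) == pytest.approx((3, 4, 120))

    def test_fo_root_equals_nn_apart_from_colony_growth(self):
        cfg = make_config("FO", dt=2.0, colony_rate=0.02)
        d = det(0, 0, x=5, y=6, area=100)
        x, y, a = predict(cfg, d, root_history(cfg.params))
        assert (x, y) == (5, 6)
        assert a == pytest.approx(100 * math.exp(0.04))


class TestScorers:
    def test_zero_residual_migration_is_sum_of_peaks(self):
        cfg = make_config("NN", dt=1.0)
        src = det(0, 0, x=0, y=0, area=100)
        tgt = det(1, 1, x=0, y=0, area=100)
        expected = halfnormal_logpdf(0.0, cfg.params.sigma_move) + normal_logpdf(
            1.0, 1.0, cfg.params.sigma_area
        )
        assert score_migration(cfg, src, root_history(cfg.params), tgt) == pytest.approx(
            expected, abs=1e-12
        )

    def test_migration_score_decreases_with_distance(self):
        cfg = make_config("NN")
        src = det(0, 0)
        h = root_history(cfg.params)
        scores = [
            score_migration(cfg, src, h, det(1, 1, x=r)) for r in (0, 5, 15, 30)
        ]
        assert scores == sorted(scores, reverse=True)

    def test_migration_hand_computed_sum(self):
        cfg = make_config("NN", dt=1.0, sigma_move=10.0, sigma_area=0.1)
        src = det(0, 0, x=0, y=0, area=100)
        tgt = det(1, 1, x=5, y=0, area=110)
        expected = halfnormal_logpdf(5.0, 10.0) + normal_logpdf(1.1, 1.0, 0.1)
        assert score_migration(cfg, src, root_history(cfg.params), tgt) == pytest.approx(
            expected, abs=1e-12
        )

    def test_division_symmetric_in_daughters(self):
        cfg = make_config("FO+G+O+DD", dt=1.0, colony_rate=0.02)
        src = det(0, 0, area=200)
        h = root_history(cfg.params)
        t1 = det(1, 1, x=-4, y=0, area=100, orientation=0.1)
        t2 = det(2, 1, x=4, y=1, area=105, orientation=0.4)
        assert score_division(cfg, src, h, t1, t2) == pytest.approx(
            score_division(cfg, src, h, t2, t1), abs=1e-12
        )

    def test_division_zero_residual_value(self):
        cfg = make_config("FO+DD", dt=1.0)
        p = cfg.params
        src = det(0, 0, x=0, y=0, area=200)
        h = CellHistory(0.0, 0.0, 1.0)
        t1 = det(1, 1, x=-3, y=0, area=100)
        t2 = det(2, 1, x=3, y=0, area=100)
        expected = (
            halfnormal_logpdf(0.0, p.sigma_move)
            + normal_logpdf(1.0, 1.0, p.sigma_area)
            + halfnormal_logpdf(6.0, p.sigma_div_dist)
        )
        assert score_division(cfg, src, h, t1, t2) == pytest.approx(expected, abs=1e-12)

    def test_division_score_decreases_with_separation(self):
        cfg = make_config("FO+DD")
        src = det(0, 0, area=200)
        h = CellHistory(0.0, 0.0, 1.0)
        scores = []
        for sep in (4, 10, 20, 40):
            t1 = det(1, 1, x=-sep / 2, area=100)
            t2 = det(2, 1, x=sep / 2, area=100)
            scores.append(score_division(cfg, src, h, t1, t2))
        assert scores == sorted(scores, reverse=True)

    def test_unary_scores_are_constant_penalties(self):
        cfg = make_config("NN", lambda_appear=-12.0, lambda_disappear=-7.0)
        assert score_appear(cfg, det(0, 1)) == -12.0
        assert score_disappear(cfg, det(0, 0)) == -7.0

    def test_plausible_migration_beats_unary_pair(self):
        """With default penalties, a migration within 2 sigma outscores
        explaining the same pair as disappearance + appearance."""
        cfg = make_config("NN")
        src = det(0, 0, area=100)
        tgt = det(1, 1, x=2 * cfg.params.sigma_move, area=100)
        mig = score_migration(cfg, src, root_history(cfg.params), tgt)
        assert mig > score_appear(cfg, tgt) + score_disappear(cfg, src)

    def test_scores_finite_for_extreme_inputs(self):
        cfg = make_config("FO+G+O+DD", dt=16.0, colony_rate=0.02)
        src = det(0, 0, x=0, y=0, area=1e-3, orientation=0.0)
        h = CellHistory(50.0, -50.0, 4.0)
        tgt = det(1, 1, x=500, y=500, area=1e5, orientation=3.1)
        assert math.isfinite(score_migration(cfg, src, h, tgt))
        t2 = det(2, 1, x=-500, y=0, area=1e-3, orientation=1.0)
        assert math.isfinite(score_division(cfg, src, h, tgt, t2))

    def test_nn_and_fo_rank_identically_without_motion_or_growth(self):
        """In the degenerate limit of zero past motion and growth the FO
        prediction collapses onto NN, so candidate rankings coincide."""
        nn = make_config("NN", dt=1.0)
        fo = make_config("FO", dt=1.0)
        src = det(0, 0, x=0, y=0, area=100)
        still = CellHistory(0.0, 0.0, 1.0)
        targets = [det(i, 1, x=3 * i, y=-2 * i, area=100 + 5 * i) for i in range(1, 6)]
        nn_rank = sorted(
            range(5), key=lambda i: -score_migration(nn, src, still, targets[i])
        )
        fo_rank = sorted(
            range(5), key=lambda i: -score_migration(fo, src, still, targets[i])
        )
        assert nn_rank == fo_rank
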