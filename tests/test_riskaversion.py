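import numpy as np
import pandas as pd
import pytest

from selhaz.exceptions import DegenerateSampleError
from selhaz.riskaversion import (
    ThetaEvaluator,
    _argmin_lex,
    _objective_matrix,
    bootstrap_se,
    grid_search_gamma,
    moment_conditions,
    run_grid_sizes,
    sample_moments,
    subgroup_assign,
)


class TestSubgroups:
    @pytest.mark.parametrize(
        "gender,education,expected",
        [
            ("male", "high school", "male_high"),
            ("male", "college", "male_high"),
            ("female", "primary school", "female_low"),
            ("female", "high", "female_high"),
            ("male", "low", "male_low"),
        ],
    )
    def test_assignment(self, gender, education, expected):
        assert subgroup_assign(gender, education) == expected

    def test_labels_partition_sample(self, det_world):
        _, df = det_world
        labels = df.apply(
            lambda r: subgroup_assign(r["gender"], r["education_level"]), axis=1
        )
        assert set(labels.unique()) <= {"male_low", "male_high", "female_low", "female_high"}
        assert labels.notna().all()

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError):
            subgroup_assign(None, "high")
        with pytest.raises(ValueError):
            subgroup_assign("male", float("nan"))
        with pytest.raises(ValueError):
            subgroup_assign("male", "??")


class TestMoments:
    def test_matches_textbook_loops_on_small_sample(self):
        rng = np.random.default_rng(12)
        x = rng.random(20)
        mean, var, skew, kurt = sample_moments(x)
        n = len(x)
        mu = sum(x) / n
        m2 = sum((v - mu) ** 2 for v in x) / n
        m3 = sum((v - mu) ** 3 for v in x) / n
        m4 = sum((v - mu) ** 4 for v in x) / n
        assert mean == pytest.approx(mu)
        assert var == pytest.approx(m2)
        assert skew == pytest.approx(m3 / m2**1.5)
        assert kurt == pytest.approx(m4 / m2**2)
        # Pearson's inequality for any sample
        assert kurt >= 1 + skew**2 - 1e-12

    def test_identical_waves_give_zero_conditions(self):
        x = np.random.default_rng(0).random(50)
        assert moment_conditions(x, x) == (0.0, 0.0, 0.0, 0.0)

    def test_location_shift_moves_only_the_mean(self):
        x = np.random.default_rng(1).random(200)
        h = moment_conditions(x, x + 0.1)
        assert h[0] == pytest.approx(0.1)
        assert h[1] == pytest.approx(0.0, abs=1e-12)
        assert h[2] == pytest.approx(0.0, abs=1e-9)
        assert h[3] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DegenerateSampleError):
            sample_moments(np.zeros(10))
        with pytest.raises(DegenerateSampleError):
            moment_conditions(np.arange(3), np.arange(8))


def _two_wave_frame(records_one_wave: pd.DataFrame) -> pd.DataFrame:
    """Clone one wave into a fake second wave (a permutation of the first)."""
    clone = records_one_wave.sample(frac=1.0, random_state=0).copy()
    clone["year"] = 2022
    first = records_one_wave.copy()
    first["year"] = 2020
    return pd.concat([first, clone], ignore_index=True)


class TestGridSearch:
    def test_objective_exactly_zero_for_permuted_waves(self, det_world):
        cfg, df = det_world
        wave1 = df[df["year"] == 2020]
        both = _two_wave_frame(wave1)
        gv = np.linspace(1, 9, 7)
        ev = ThetaEvaluator(both, gv, gv, schedule=cfg.schedule, route="policy")
        rows = sorted(ev.wave_rows)
        obj = _objective_matrix(ev, ev.wave_rows[rows[0]], ev.wave_rows[rows[1]])
        assert np.nanmax(obj[np.isfinite(obj)]) == pytest.approx(0.0, abs=1e-18)

    def test_truth_beats_far_corners(self, big_det_world):
        """Objective at the generating pair is below the extreme corners."""
        cfg, df = big_det_world
        sub = df[(df["gender"] == "male") & (df["education_level"] == "low")]
        truth = cfg.gammas["male_low"]
        gv1 = np.array([1.0, truth[0], 9.0])
        gv2 = np.array([1.0, truth[1], 9.0])
        ev = ThetaEvaluator(sub, gv1, gv2, schedule=cfg.schedule, route="policy")
        rows = sorted(ev.wave_rows)
        obj = _objective_matrix(ev, ev.wave_rows[rows[0]], ev.wave_rows[rows[1]])
        assert obj[1, 1] < obj[0, 0]
        assert obj[1, 1] < obj[2, 2]

    def test_medical_aversion_exceeds_composite_aversion(self, big_det_world):
        """gamma2 > gamma1 ordering is recovered (all subgroups generate with it)."""
        cfg, df = big_det_world
        est = grid_search_gamma(df, schedule=cfg.schedule, grid_size=20, route="policy")
        assert est.gamma2 > est.gamma1

    def test_deterministic_given_inputs(self, det_world):
        cfg, df = det_world
        a = grid_search_gamma(df, schedule=cfg.schedule, grid_size=20, route="policy")
        b = grid_search_gamma(df, schedule=cfg.schedule, grid_size=20, route="policy")
        assert (a.gamma1, a.gamma2, a.objective) == (b.gamma1, b.gamma2, b.objective)

    def test_estimates_on_grid_nodes(self, det_world):
        cfg, df = det_world
        for size in (20, 50):
            est = grid_search_gamma(df, schedule=cfg.schedule, grid_size=size,
                                    route="policy")
            gv = np.linspace(1, 9, size)
            assert est.gamma1 in gv and est.gamma2 in gv
            assert est.objective >= 0

    def test_argmin_lexicographic(self):
        obj = np.array([[3.0, 1.0], [1.0, 2.0]])
        assert _argmin_lex(obj) == (0, 1)  # first minimum in row-major order


class TestBootstrap:
    def test_identical_replicates_give_zero_se(self, det_world):
        """A 2-node grid makes every resample land on the same node -> SE 0."""
        cfg, df = det_world
        bs = bootstrap_se(df, schedule=cfg.schedule, grid_size=2, B=10, seed=0,
                          route="policy")
        assert (bs.estimates == bs.estimates[0]).all()
        assert bs.se_gamma1 == 0.0 and bs.se_gamma2 == 0.0

    def test_degenerate_single_record_waves_fail_loudly(self, det_world):
        from selhaz.exceptions import EstimationError

        cfg, df = det_world
        one = df[(df["year"] == 2020) & (df["expenditure"] > 0)].head(1)
        two = one.copy()
        two["year"] = 2022
        both = pd.concat([one, two], ignore_index=True)
        with pytest.raises(EstimationError):
            bootstrap_se(both, schedule=cfg.schedule, grid_size=5, B=10, seed=0,
                         route="policy")

    def test_same_seed_reproduces(self, det_world):
        cfg, df = det_world
        a = bootstrap_se(df, schedule=cfg.schedule, grid_size=10, B=8, seed=3,
                         route="policy")
        b = bootstrap_se(df, schedule=cfg.schedule, grid_size=10, B=8, seed=3,
                         route="policy")
        assert np.array_equal(a.estimates, b.estimates)

    def test_se_bounded_by_grid_span(self, det_world):
        cfg, df = det_world
        bs = bootstrap_se(df, schedule=cfg.schedule, grid_size=10, B=12, seed=1,
                          route="policy")
        assert 0.0 <= bs.se_gamma1 < 8.0
        assert 0.0 <= bs.se_gamma2 < 8.0
        assert not bs.unreliable

    def test_doubling_b_is_stable(self, det_world):
        """SEs at B and 2B agree within Monte-Carlo slack."""
        cfg, df = det_world
        small = bootstrap_se(df, schedule=cfg.schedule, grid_size=10, B=40, seed=5,
                             route="policy")
        big = bootstrap_se(df, schedule=cfg.schedule, grid_size=10, B=80, seed=5,
                           route="policy")
        for a, b in [(small.se_gamma1, big.se_gamma1), (small.se_gamma2, big.se_gamma2)]:
            assert b == pytest.approx(a, rel=0.5, abs=0.3)


def test_run_grid_sizes_reports_average(det_world):
    cfg, df = det_world
    res = run_grid_sizes(df, schedule=cfg.schedule, sizes=(20, 40), route="policy")
    per = res["per_grid"]
    assert set(per) == {20, 40}
    avg = res["average"]
    assert avg[0] == pytest.approx(np.mean([per[20].gamma1, per[40].gamma1]))
    assert avg[1] == pytest.approx(np.mean([per[20].gamma2, per[40].gamma2]))
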