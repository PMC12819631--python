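import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from selhaz.exceptions import DomainError
from selhaz.hazard import (
    compensated_budget,
    heterogeneity_ecdf,
    incidence_and_totals,
    slutsky_decompose,
    solve_demand,
)
from selhaz.structural import theta_closed_form, utility


class TestCompensatedBudget:
    def test_no_reimbursement_means_no_compensation(self):
        assert compensated_budget(10_250.0, 250.0, 0.0, 1_000.0) == 10_000.0

    def test_worked_example(self):
        assert compensated_budget(10_250.0, 250.0, 0.6, 1_000.0) == 10_600.0

    def test_observed_bundle_exactly_affordable(self):
        y, p, a1, m1 = 30_000.0, 380.0, 0.55, 2_400.0
        c1 = y - p - m1 * (1 - a1)
        W2 = compensated_budget(y, p, a1, m1)
        assert c1 + m1 == pytest.approx(W2)

    def test_domain_checks(self):
        with pytest.raises(DomainError):
            compensated_budget(1_000.0, 0.0, 1.5, 100.0)
        with pytest.raises(DomainError):
            compensated_budget(1_000.0, 0.0, 0.5, -1.0)


class TestSolveDemand:
    def test_symmetric_split(self):
        c, m = solve_demand(0.5, 3.0, 3.0, 100.0)
        assert c == pytest.approx(50.0, rel=1e-10)
        assert m == pytest.approx(50.0, rel=1e-10)

    def test_closed_form_ratio(self):
        _, m = solve_demand(0.8, 2.0, 2.0, 100.0)
        assert m == pytest.approx(200.0 / 3.0, rel=1e-10)

    def test_boundary_thetas(self):
        c, m = solve_demand(0.0, 2.0, 4.0, 500.0)
        assert (c, m) == (500.0, 0.0)
        c, m = solve_demand(1.0, 2.0, 4.0, 500.0)
        assert m == pytest.approx(500.0, rel=1e-9)

    @given(
        theta=st.floats(0.02, 0.98),
        g1=st.floats(1.0, 9.0),
        g2=st.floats(1.0, 9.0),
        W=st.floats(10.0, 1e6),
    )
    def test_foc_residual_vanishes(self, theta, g1, g2, W):
        c, m = solve_demand(theta, g1, g2, W)
        lhs = np.log1p(-theta) - g1 * np.log(c)
        rhs = np.log(theta) - g2 * np.log(m)
        assert lhs == pytest.approx(rhs, abs=1e-6)
        assert c + m == pytest.approx(W, rel=1e-12)

    def test_brute_force_budget_line(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            theta = rng.uniform(0.05, 0.95)
            g1, g2 = rng.uniform(1, 9, 2)
            W = rng.uniform(100, 50_000)
            _, m = solve_demand(theta, g1, g2, W)
            grid = np.linspace(W * 1e-6, W * (1 - 1e-6), 100_001)
            u = utility(W - grid, grid, theta, g1, g2)
            assert abs(m - grid[np.argmax(u)]) <= 1e-4 * W


def _records(y, p, m1, a1):
    n = len(m1)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "year": 2020,
            "insured": True,
            "income": y,
            "premium": p,
            "expenditure": m1,
            "realized_rate": a1,
        }
    )


class TestSlutsky:
    def test_worked_example(self):
        # theta from the degenerate closed form at the realized rate
        theta = theta_closed_form(1_000.0, 10_000.0, 0.0, 0.6, 2.0, 2.0)
        assert theta == pytest.approx(0.004322, abs=2e-5)
        rec = _records([10_000.0], [0.0], [1_000.0], [0.6])
        res = slutsky_decompose(rec, np.array([theta]), 2.0, 2.0)
        assert res["m2"].iloc[0] == pytest.approx(655.1, abs=0.5)
        assert res["over_consumption"].iloc[0] == pytest.approx(344.9, abs=0.5)
        assert res["share"].iloc[0] == pytest.approx(0.345, abs=1e-3)

    def test_no_price_change_no_over_consumption(self):
        rec = _records([20_000.0], [250.0], [1_500.0], [0.0])
        # the latent weight that rationalizes the observed bundle at price 1
        theta = theta_closed_form(1_500.0, 20_000.0, 250.0, 0.0, 3.0, 4.0)
        res = slutsky_decompose(rec, np.array([theta]), 3.0, 4.0)
        assert res["m2"].iloc[0] == pytest.approx(res["m1"].iloc[0], rel=1e-9)
        assert res["over_consumption"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_no_premium_collapses_income_effects(self):
        rec = _records([20_000.0], [0.0], [1_500.0], [0.5])
        res = slutsky_decompose(rec, np.array([0.2]), 3.0, 4.0)
        assert res["m3"].iloc[0] == pytest.approx(res["m4"].iloc[0], rel=1e-12)

    def test_compensated_law_and_identity(self, det_world):
        from selhaz.structural import estimate_theta_table

        cfg, df = det_world
        ins = df[df["insured"]].reset_index(drop=True)
        tbl = estimate_theta_table(ins, None, cfg.gammas, route="realized")
        ok = (~tbl["infeasible"]).to_numpy()
        sub = ins["gender"].str.cat(ins["education_level"], sep="_")
        g1 = np.array([cfg.gammas[s][0] for s in sub])[ok]
        g2 = np.array([cfg.gammas[s][1] for s in sub])[ok]
        res = slutsky_decompose(ins[ok], tbl.loc[ok, "theta"].to_numpy(), g1, g2)
        slack = 1e-9 * np.maximum(res["m1"], 1.0)
        assert (res["m2"] <= res["m1"] + slack).all()
        strict = (res["a1"] * res["m1"] > 0) & res["theta"].between(1e-12, 1 - 1e-12)
        assert (res.loc[strict, "m2"] < res.loc[strict, "m1"]).all()
        lhs = res["m1"] - res["m4"]
        rhs = (res["m1"] - res["m2"]) + (res["m2"] - res["m4"])
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


class TestIncidence:
    def test_hand_built_records(self):
        res = pd.DataFrame(
            {
                "id": [0, 1, 2],
                "year": [2020] * 3,
                "m1": [100.0, 200.0, 0.0],
                "m2": [80.0, 200.0, 0.0],
                "m3": [75.0, 190.0, 0.0],
                "m4": [78.0, 195.0, 0.0],
                "over_consumption": [20.0, 0.0, 0.0],
                "share": [0.2, 0.0, 0.0],
                "a1": [0.5, 0.0, 0.0],
                "theta": [0.1, 0.2, 0.0],
            }
        )
        out = incidence_and_totals(res)[2020]
        assert out["incidence"] == pytest.approx(1 / 3)
        assert out["n_zero_expenditure"] == 1
        assert out["over_consumption"]["mean"] == pytest.approx(20.0)
        assert out["share"]["mean"] == pytest.approx(0.2)
        assert out["actual"]["mean"] == pytest.approx(100.0)

    def test_all_zero_rates_no_incidence(self):
        rec = _records([9_000.0] * 4, [0.0] * 4, [100.0, 0.0, 50.0, 10.0], [0.0] * 4)
        res = slutsky_decompose(rec, np.array([0.05, 0.0, 0.03, 0.01]), 3.0, 4.0)
        out = incidence_and_totals(res)[2020]
        assert out["incidence"] == 0.0


class TestHeterogeneity:
    def _results(self, share, **covs):
        n = len(share)
        base = {
            "share": share,
            "age": np.full(n, 40.0),
            "income": np.full(n, 1e4),
            "education_level": ["low"] * n,
            "theta": np.linspace(0, 1, n),
            "exercise": [False] * n,
            "smoke": [False] * n,
            "gender": ["male"] * n,
            "married": [False] * n,
        }
        base.update(covs)
        return pd.DataFrame(base)

    def test_identical_groups_zero_gap(self):
        share = np.tile(np.linspace(0, 0.3, 10), 2)
        df = self._results(share, gender=["male"] * 10 + ["female"] * 10)
        out = heterogeneity_ecdf(df, "gender")
        assert out["max_gap"] == pytest.approx(0.0, abs=1e-12)

    def test_share_increasing_in_health_burden_dominates(self):
        n = 200
        theta = np.linspace(0, 1, n)
        share = 0.3 * theta  # sicker -> larger over-consumption share
        df = self._results(share, theta=theta)
        out = heterogeneity_ecdf(df, "health")
        yes = out["groups"]["yes"]  # theta above the mean
        no = out["groups"]["no"]
        # first-order dominance: the sicker group's ECDF lies to the right
        assert yes["share_sorted"].min() >= no["share_sorted"].max() - 0.3
        assert out["max_gap"] > 0.9

    def test_ecdf_reaches_one(self):
        df = self._results(np.random.default_rng(0).random(50),
                           gender=["male"] * 25 + ["female"] * 25)
        out = heterogeneity_ecdf(df, "gender")
        for g in ("yes", "no"):
            assert out["groups"][g]["ecdf"][-1] == 1.0

    def test_small_group_flagged(self):
        df = self._results(np.random.default_rng(0).random(10),
                           gender=["male"] * 9 + ["female"])
        out = heterogeneity_ecdf(df, "gender")
        assert out["groups"]["no"]["flag_small"]

    def test_unknown_grouping_rejected(self):
        with pytest.raises(KeyError):
            heterogeneity_ecdf(self._results(np.zeros(5)), "shoe_size")
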