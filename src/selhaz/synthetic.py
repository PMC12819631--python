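"""Seeded synthetic two-wave populations with known ground truth.

The generator emulates the statistical structure of resident-level survey data
from a voluntary health-insurance scheme: a latent health weight theta with a
point mass at 0 (no care demanded) plus a right-skewed continuous part on
(0, 1]; enrollment increasing in theta (adverse selection) and mildly
decreasing in income; log-normal incomes growing between waves; premiums rising
between waves; tiered deductible/rate/cap reimbursement; and a province-level
payment-reform treatment correlated with province covariates.  Every agent's
expenditure is the utility-maximizing choice given their insurance status, so
downstream estimators can be validated against stored ground truth
(theta_true, gamma1_true, gamma2_true).

Reimbursement is a deterministic function of expense (the schedule); optional
jitter on the realized rate emulates the dispersion seen in reimbursement data
and exercises the conditional-density estimation stage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .hazard import solve_demand
from .policy import PolicyEntry, PolicySchedule
from .structural import utility

__all__ = [
    "SyntheticConfig",
    "simulate_behavior",
    "generate_population",
    "simulate_selection_split",
    "DEFAULT_GAMMAS",
]

# subgroup-specific risk-aversion pairs (composite goods, medical care);
# medical-care aversion exceeds composite-goods aversion in every subgroup
DEFAULT_GAMMAS: dict[str, tuple[float, float]] = {
    "male_low": (4.067, 5.960),
    "male_high": (5.282, 7.154),
    "female_low": (5.191, 6.823),
    "female_high": (5.716, 7.935),
}


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic world (defaults are the demo scenario)."""

    n_per_wave: int = 2000
    seed: int = 0
    waves: tuple[int, int] = (2020, 2022)
    # latent health mixture: P(theta = 0) + Beta continuous part on (0, 1]
    p_zero: float = 0.60
    theta_beta: tuple[float, float] = (1.2, 1.8)
    # enrollment: sigmoid(intercept + slope_theta * theta + slope_logy * (log y - 10))
    enroll_intercept: float = 1.6
    enroll_slope_theta: float = 2.0
    enroll_slope_logy: float = -0.3
    # incomes: log-normal per wave, growing between waves; hard floor
    income_meanlog: dict = field(default_factory=lambda: {2020: 9.855, 2022: 10.068})
    income_sdlog: float = 1.0
    income_floor: float = 3000.0
    income_province_loading: float = 0.3
    # premiums per wave
    premium: dict = field(default_factory=lambda: {2020: 250.0, 2022: 380.0})
    gammas: dict = field(default_factory=lambda: dict(DEFAULT_GAMMAS))
    p_high_education: float = 0.30
    # service mix: P(inpatient | theta) = sigmoid(intercept + slope * theta)
    inpatient_intercept: float = -2.8
    inpatient_slope: float = 2.2
    inpatient_tier_probs: tuple[float, float, float] = (0.35, 0.35, 0.30)
    # reimbursement-rate jitter (0 = deterministic policy world)
    a_jitter_sd: float = 0.0
    # province-level payment reform applied to treated provinces in the post wave
    reform_effect: float = -0.10
    n_provinces: int = 31
    n_treated: int = 21
    # expenditure solver
    spend_cap_frac: float = 0.95
    grid_points: int = 2000
    schedule: PolicySchedule = field(default_factory=PolicySchedule.default)

    def validate(self) -> None:
        if not 0.0 <= self.p_zero <= 1.0:
            raise ConfigError("p_zero must lie in [0, 1]")
        for g1, g2 in self.gammas.values():
            if not (1.0 <= g1 <= 9.0 and 1.0 <= g2 <= 9.0):
                raise ConfigError("risk-aversion coefficients must lie in [1, 9]")
        if max(self.premium.values()) >= self.income_floor:
            raise ConfigError("premium must be below the minimum income")
        if self.n_treated >= self.n_provinces:
            raise ConfigError("need at least one control province")
        if not 0 < self.spend_cap_frac < 1:
            raise ConfigError("spend_cap_frac must lie in (0, 1)")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["schedule"] = self.schedule.to_dict()
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticConfig":
        d = yaml.safe_load(text)
        d["schedule"] = PolicySchedule.from_dict(d["schedule"])
        for key in ("income_meanlog", "premium"):
            d[key] = {int(k): float(v) for k, v in d[key].items()}
        d["waves"] = tuple(d["waves"])
        d["theta_beta"] = tuple(d["theta_beta"])
        d["inpatient_tier_probs"] = tuple(d["inpatient_tier_probs"])
        d["gammas"] = {k: tuple(v) for k, v in d["gammas"].items()}
        return cls(**d)


_INVPHI = 0.6180339887498949


def _golden_max(f, lo: np.ndarray, hi: np.ndarray, iters: int = 60):
    """Vectorized golden-section maximization of a unimodal f on [lo, hi]."""
    a, b = lo.astype(float), hi.astype(float)
    for _ in range(iters):
        x1 = b - _INVPHI * (b - a)
        x2 = a + _INVPHI * (b - a)
        take_left = f(x1) >= f(x2)
        b = np.where(take_left, x2, b)
        a = np.where(take_left, a, x1)
    return 0.5 * (a + b)


def _optimal_insured(theta, gamma1: float, gamma2: float, W, entry: PolicyEntry,
                     grid_points: int = 2000, frac: float = 0.95) -> np.ndarray:
    """Utility-maximizing expense under a kinked reimbursement schedule.

    Dense log-spaced grid over (0, frac * W] followed by golden-section
    refinement around the best knot.  The kinked budget can make realized
    utility bimodal (deductible) so the dense grid locates the global region
    first.  theta = 0 agents spend exactly 0.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    W = np.atleast_1d(np.asarray(W, dtype=float))
    m_out = np.zeros(theta.shape)
    pos = theta > 0
    if not np.any(pos):
        return m_out
    th = theta[pos]
    Wp = W[pos]
    rel = np.geomspace(1e-6, frac, grid_points)

    def realized_u(m, thv, Wv):
        c = Wv - m + entry.reimburse(m)
        return utility(c, m, thv, gamma1, gamma2)

    best_idx = np.empty(th.size, dtype=int)
    chunk = max(1, int(4e6 // grid_points))
    for s in range(0, th.size, chunk):
        sl = slice(s, min(s + chunk, th.size))
        M = Wp[sl, None] * rel[None, :]
        U = realized_u(M, th[sl, None], Wp[sl, None])
        best_idx[sl] = np.argmax(U, axis=1)
    lo = Wp * rel[np.maximum(best_idx - 1, 0)]
    hi = Wp * rel[np.minimum(best_idx + 1, grid_points - 1)]
    m_ref = _golden_max(lambda m: realized_u(m, th, Wp), lo, hi)
    # keep whichever of (grid best, refined) has higher utility
    m_grid_best = Wp * rel[best_idx]
    better = realized_u(m_ref, th, Wp) >= realized_u(m_grid_best, th, Wp)
    m_best = np.where(better, m_ref, m_grid_best)
    u_best = realized_u(m_best, th, Wp)
    # schedule kinks are non-differentiable maximizer candidates: agents bunch
    # exactly at the cap-exhaustion point, which golden-section only nears
    kinks = [entry.deductible]
    if np.isfinite(entry.cap) and entry.rate > 0:
        kinks.append(entry.deductible + entry.cap / entry.rate)
    for mk in kinks:
        if mk <= 0:
            continue
        ok = mk <= frac * Wp
        if not np.any(ok):
            continue
        uk = np.full(th.size, -np.inf)
        uk[ok] = realized_u(np.full(int(ok.sum()), float(mk)), th[ok], Wp[ok])
        # snap-to-kink tolerance absorbs float noise in the comparison: an
        # interior optimum strictly better than the kink clears it easily
        take = uk >= u_best - 1e-10 * np.abs(u_best)
        m_best = np.where(take, mk, m_best)
        u_best = np.where(take, uk, u_best)
    m_out[pos] = m_best
    return m_out


def simulate_behavior(theta: float, gamma1: float, gamma2: float, y: float,
                      p: float, schedule: PolicySchedule | None = None,
                      service_type: str | None = None, tier: str | None = None,
                      grid_points: int = 2000, spend_cap_frac: float = 0.95) -> float:
    """Optimal medical expenditure of one agent.

    Uninsured agents (``schedule is None``) solve the smooth price-1 problem on
    the budget ``y - p`` in closed form via the FOC.  Insured agents maximize
    realized utility with c = y - p - m + reimbursed(m) by dense grid search
    plus golden-section refinement.  Returns 0 exactly when theta == 0.
    """
    if not 0.0 <= theta <= 1.0:
        raise ConfigError("theta must lie in [0, 1]")
    if gamma1 < 1 or gamma2 < 1:
        raise ConfigError("risk-aversion coefficients must be >= 1")
    if y - p <= 0:
        raise ConfigError("disposable income must be positive")
    if theta == 0.0:
        return 0.0
    if schedule is None:
        _, m = solve_demand(theta, gamma1, gamma2, y - p)
        return float(m)
    entry = schedule.entry(service_type, tier)
    if not entry.covered:
        _, m = solve_demand(theta, gamma1, gamma2, y - p)
        return float(m)
    m = _optimal_insured(
        np.array([theta]), gamma1, gamma2, np.array([y - p]), entry,
        grid_points=grid_points, frac=spend_cap_frac,
    )
    return float(m[0])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def draw_theta(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent health weights: atom at 0 plus Beta continuous part."""
    zero = rng.random(n) < cfg.p_zero
    a, b = cfg.theta_beta
    theta = rng.beta(a, b, size=n)
    theta[zero] = 0.0
    return theta


def enrollment_probability(theta, log_income, cfg: SyntheticConfig):
    return _sigmoid(
        cfg.enroll_intercept
        + cfg.enroll_slope_theta * np.asarray(theta)
        + cfg.enroll_slope_logy * (np.asarray(log_income) - 10.0)
    )


def simulate_selection_split(cfg: SyntheticConfig, n: int, rng: np.random.Generator):
    """Draw theta and split by simulated enrollment (no behaviour stage).

    Utility: the enrollment tilt acts on theta before any spending happens, so
    distribution-level properties of the insured/uninsured theta split can be
    simulated cheaply for power and size studies of the dominance test.
    """
    theta = draw_theta(n, cfg, rng)
    logy = rng.normal(cfg.income_meanlog[cfg.waves[0]], cfg.income_sdlog, size=n)
    ins = rng.random(n) < enrollment_probability(theta, logy, cfg)
    return theta[ins], theta[~ins]


def _province_frame(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Province covariates and confounded reform assignment (fixed across waves)."""
    k = cfg.n_provinces
    z = rng.normal(size=k)
    frame = pd.DataFrame(
        {
            "province_id": np.arange(k),
            "prov_z": z,
            "log_gdp_pc": 10.9 + 0.4 * z + 0.1 * rng.normal(size=k),
            "med_personnel": 7.0 + 1.5 * z + 0.5 * rng.normal(size=k),
            "gp_per_10k": 3.0 + 0.8 * z + 0.3 * rng.normal(size=k),
            "beds_per_1k": 6.0 + 1.0 * z + 0.5 * rng.normal(size=k),
            "uebmi_ratio": 1.1 + 0.10 * z + 0.05 * rng.normal(size=k),
            "urrbmi_ratio": 1.0 + 0.10 * z + 0.05 * rng.normal(size=k),
        }
    )
    score = z + 0.8 * rng.normal(size=k)  # richer provinces reform first
    treated = np.zeros(k, dtype=bool)
    treated[np.argsort(-score)[: cfg.n_treated]] = True
    frame["treat"] = treated
    return frame


def generate_population(cfg: SyntheticConfig) -> pd.DataFrame:
    """Generate the full two-wave resident table (one row per person-year)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    provinces = _province_frame(cfg, rng)
    frames = []
    next_id = 0
    for wave_idx, year in enumerate(cfg.waves):
        n = cfg.n_per_wave
        gender = np.where(rng.random(n) < 0.5, "male", "female")
        education = np.where(rng.random(n) < cfg.p_high_education, "high", "low")
        subgroup = np.char.add(np.char.add(gender.astype(str), "_"), education.astype(str))
        age = np.clip(np.round(rng.normal(46, 16, size=n)), 16, 95).astype(int)
        married = rng.random(n) < 0.78
        children = rng.random(n) < 0.68
        smoke = rng.random(n) < np.where(gender == "male", 0.50, 0.05)
        drink = rng.random(n) < 0.15
        exercise = rng.random(n) < 0.50
        nap = rng.random(n) < 0.50
        late_sleep = rng.random(n) < 0.30

        prov = rng.integers(0, cfg.n_provinces, size=n)
        prov_z = provinces["prov_z"].to_numpy()[prov]
        income = np.exp(
            rng.normal(
                cfg.income_meanlog[year] + cfg.income_province_loading * prov_z * cfg.income_sdlog,
                cfg.income_sdlog,
                size=n,
            )
        )
        income = np.maximum(income, cfg.income_floor)

        theta = draw_theta(n, cfg, rng)
        insured = rng.random(n) < enrollment_probability(theta, np.log(income), cfg)
        premium = np.where(insured, cfg.premium[year], 0.0)

        service = np.array(["none"] * n, dtype=object)
        tier = np.array(["none"] * n, dtype=object)
        pos = theta > 0
        inpat = pos & (rng.random(n) < _sigmoid(cfg.inpatient_intercept + cfg.inpatient_slope * theta))
        outpat = pos & ~inpat
        service[inpat] = "inpatient"
        service[outpat] = "general_outpatient"
        tier[outpat] = "primary"
        tiers = np.array(["primary", "secondary", "tertiary"])
        tier[inpat] = rng.choice(tiers, size=int(inpat.sum()), p=cfg.inpatient_tier_probs)

        g1 = np.array([cfg.gammas[s][0] for s in subgroup])
        g2 = np.array([cfg.gammas[s][1] for s in subgroup])

        m = np.zeros(n)
        # uninsured (and insured-but-uncovered) agents: smooth price-1 problem
        smooth = pos & ~insured
        covered = np.zeros(n, dtype=bool)
        for (svc, tr), entry in cfg.schedule.items():
            sel = pos & insured & (service == svc) & (tier == tr)
            if not entry.covered:
                smooth |= sel
            else:
                covered |= sel
        unmatched = pos & insured & ~smooth & ~covered
        if np.any(unmatched):
            raise ConfigError("schedule lacks an entry for a generated (service, tier)")
        if np.any(smooth):
            _, m_s = solve_demand(theta[smooth], g1[smooth], g2[smooth],
                                  income[smooth] - premium[smooth])
            # cap gross spending like the insured solver does
            m[smooth] = np.minimum(
                m_s, cfg.spend_cap_frac * (income[smooth] - premium[smooth])
            )
        for (svc, tr), entry in cfg.schedule.items():
            if not entry.covered:
                continue
            sel = covered & (service == svc) & (tier == tr)
            if not np.any(sel):
                continue
            for sub in np.unique(subgroup[sel]):
                ss = sel & (subgroup == sub)
                gg1, gg2 = cfg.gammas[sub]
                m[ss] = _optimal_insured(
                    theta[ss], gg1, gg2, income[ss] - premium[ss], entry,
                    grid_points=cfg.grid_points, frac=cfg.spend_cap_frac,
                )

        post = wave_idx > 0
        treat = provinces["treat"].to_numpy()[prov]
        if post and cfg.reform_effect != 0.0:
            hit = (m > 0) & insured & treat
            m[hit] = m[hit] * np.exp(cfg.reform_effect)

        reimbursed = np.zeros(n)
        rate = np.zeros(n)
        for (svc, tr), entry in cfg.schedule.items():
            sel = insured & (service == svc) & (tier == tr) & (m > 0)
            if np.any(sel):
                reimbursed[sel] = entry.reimburse(m[sel])
                rate[sel] = entry.realized_rate(m[sel])

        if cfg.a_jitter_sd > 0:
            jit = insured & (rate > 0)
            rate[jit] = np.clip(
                rate[jit] + rng.normal(0.0, cfg.a_jitter_sd, size=int(jit.sum())),
                0.005, 1.0,
            )
            reimbursed[jit] = rate[jit] * m[jit]

        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(next_id, next_id + n),
                    "year": year,
                    "insured": insured,
                    "income": income,
                    "premium": premium,
                    "gender": gender,
                    "education_level": education,
                    "age": age,
                    "married": married,
                    "children": children,
                    "smoke": smoke,
                    "drink": drink,
                    "exercise": exercise,
                    "nap": nap,
                    "late_sleep": late_sleep,
                    "service_type": service,
                    "tier": tier,
                    "expenditure": m,
                    "reimbursed": reimbursed,
                    "realized_rate": rate,
                    "province_id": prov,
                    "treat": treat,
                    "post": post,
                    "theta_true": theta,
                    "gamma1_true": g1,
                    "gamma2_true": g2,
                }
            )
        )
        next_id += n
    df = pd.concat(frames, ignore_index=True)
    df = df.merge(
        provinces.drop(columns=["treat"]), on="province_id", how="left", sort=False
    )
    resid = df["income"] - df["premium"] - df["expenditure"] * (1 - df["realized_rate"])
    if not bool((resid > 0).all()):
        raise ConfigError("generator produced non-positive residual consumption")
    return df


def records_to_csv(df: pd.DataFrame, path=None) -> str | None:
    """Write records with stable formatting (same seed -> byte-identical file)."""
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    text = buf.getvalue()
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None
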