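"""Subgroup risk-aversion pairs by moment matching across two waves.

The latent-health estimator depends on the unknown risk-aversion pair
(g1, g2).  Identification uses the assumption that each demographic subgroup's
latent-health distribution is stable across the two survey waves: at the true
pair, the estimated theta samples of the two waves share their first four
moments, so the estimator is the grid node on [1, 9]^2 minimizing the sum of
squared differences in mean, variance, skewness and kurtosis between the
waves.  Because wave-level observables (income scale, premium) shift between
the waves, a wrong pair distorts the two waves' theta distributions
differently, which is what pins the minimum down.

The expensive part of each grid node is the FOC integral, which depends on g1
only; :class:`ThetaEvaluator` caches it per record per g1 so the full grid and
bootstrap replicates reuse one pass over the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateSampleError, EstimationError
from .policy import PolicySchedule

__all__ = [
    "subgroup_assign",
    "sample_moments",
    "moment_conditions",
    "ThetaEvaluator",
    "grid_search_gamma",
    "bootstrap_se",
    "run_grid_sizes",
    "RiskAversionEstimate",
]

GAMMA_LO, GAMMA_HI = 1.0, 9.0

#: education descriptions counting as the high-education group
#: (high school or above)
_HIGH_EDUCATION = {
    "high", "high school", "high_school", "college", "university", "graduate",
}
_LOW_EDUCATION = {
    "low", "illiterate", "primary", "primary school", "primary_school",
    "middle school", "middle_school", "junior high", "junior_high",
}


def subgroup_assign(gender, education_level) -> str:
    """Map (gender, education description) to one of the four subgroup labels.

    High school education or above counts as high education.  Raises
    ``ValueError`` on missing/unknown values (callers exclude and count those).
    """
    if gender is None or (isinstance(gender, float) and np.isnan(gender)):
        raise ValueError("missing gender")
    g = str(gender).strip().lower()
    if g not in ("male", "female"):
        raise ValueError(f"unknown gender {gender!r}")
    if education_level is None or (
        isinstance(education_level, float) and np.isnan(education_level)
    ):
        raise ValueError("missing education level")
    e = str(education_level).strip().lower()
    if e in _HIGH_EDUCATION:
        lvl = "high"
    elif e in _LOW_EDUCATION:
        lvl = "low"
    else:
        raise ValueError(f"unknown education level {education_level!r}")
    return f"{g}_{lvl}"


def sample_moments(x) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, kurtosis) with population central moments.

    Skewness and kurtosis are the standardized central moments g1 = m3/m2^1.5
    and m4/m2^2 (normal kurtosis = 3).  Raises for constant samples.
    """
    x = np.asarray(x, dtype=float)
    mu = float(x.mean())
    xc = x - mu
    m2 = float((xc**2).mean())
    if m2 <= 0:
        raise DegenerateSampleError("constant sample: skewness/kurtosis undefined")
    m3 = float((xc**3).mean())
    m4 = float((xc**4).mean())
    return mu, m2, m3 / m2**1.5, m4 / m2**2


def moment_conditions(theta_wave1, theta_wave2) -> tuple[float, float, float, float]:
    """Wave-2 minus wave-1 differences of the four theta moments."""
    t1 = np.asarray(theta_wave1, dtype=float)
    t2 = np.asarray(theta_wave2, dtype=float)
    if t1.size < 8 or t2.size < 8:
        raise DegenerateSampleError("need at least 8 observations per wave")
    m1 = sample_moments(t1)
    m2 = sample_moments(t2)
    return tuple(b - a for a, b in zip(m1, m2))


# ---------------------------------------------------------------------------


def _moments_block(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Four moments of each column of X; flags columns with no spread."""
    mu = X.mean(axis=0)
    Xc = X - mu
    X2 = Xc * Xc
    m2 = X2.mean(axis=0)
    m3 = (X2 * Xc).mean(axis=0)
    m4 = (X2 * X2).mean(axis=0)
    bad = m2 <= 1e-30
    safe = np.where(bad, 1.0, m2)
    return np.vstack([mu, m2, m3 / (safe * np.sqrt(safe)), m4 / (safe * safe)]), bad


class ThetaEvaluator:
    """Caches the g1-dependent FOC integral per record over a gamma grid.

    Routes per positive-expense record follow the latent-health estimator:
    quadrature over a fitted density surface for insured records whose stratum
    is available ('kde'), the schedule-implied degenerate point mass when
    ``route='policy'``, the realized-rate point mass otherwise; uninsured
    records always use the no-reimbursement rule (rate 0, premium 0).
    Zero-expense records have theta identically 0 at every node and infeasible
    records (non-positive residual consumption) are excluded and counted.
    """

    def __init__(self, records: pd.DataFrame, gamma1_values, gamma2_values,
                 surfaces: dict | None = None, schedule: PolicySchedule | None = None,
                 route: str = "auto"):
        self.g1_values = np.asarray(gamma1_values, dtype=float)
        self.g2_values = np.asarray(gamma2_values, dtype=float)
        n = len(records)
        self.n = n
        self.years = records["year"].to_numpy()
        m = records["expenditure"].to_numpy(dtype=float)
        y = records["income"].to_numpy(dtype=float)
        p = records["premium"].to_numpy(dtype=float)
        a = records["realized_rate"].to_numpy(dtype=float)
        insured = records["insured"].to_numpy(dtype=bool)
        self.zero = m <= 0
        valid = np.ones(n, dtype=bool)

        J = np.zeros((n, self.g1_values.size))
        pos_idx = np.where(~self.zero)[0]

        # degenerate rows: residual consumption and marginal rate per record
        a0 = np.where(insured, a, 0.0)
        marg = a0.copy()
        prem = np.where(insured, p, 0.0)
        kde_rows = np.zeros(n, dtype=bool)
        if route in ("auto", "kde") and surfaces:
            svc = records["service_type"].to_numpy()
            tier = records["tier"].to_numpy()
            for key in surfaces:
                yr, sv, tr = key
                kde_rows |= (
                    ~self.zero & insured & (self.years == yr) & (svc == sv) & (tier == tr)
                )
        if route == "policy":
            if schedule is None:
                raise ValueError("route='policy' requires a schedule")
            svc = records["service_type"].to_numpy()
            tier = records["tier"].to_numpy()
            for i in pos_idx:
                if insured[i]:
                    marg[i] = float(schedule.entry(svc[i], tier[i]).marginal_rate(m[i]))

        deg_rows = ~self.zero & ~kde_rows
        resid = y - prem - m * (1.0 - a0)
        bad_deg = deg_rows & (resid <= 0)
        valid[bad_deg] = False
        ok_deg = deg_rows & ~bad_deg
        if np.any(ok_deg):
            lc = np.log(resid[ok_deg])
            one_minus = 1.0 - marg[ok_deg]
            for j, g1 in enumerate(self.g1_values):
                J[ok_deg, j] = -one_minus * np.exp(-g1 * lc)

        if np.any(kde_rows):
            svc = records["service_type"].to_numpy()
            tier = records["tier"].to_numpy()
            for key, surf in surfaces.items():
                yr, sv, tr = key
                sel = np.where(kde_rows & (self.years == yr) & (svc == sv) & (tier == tr))[0]
                if sel.size == 0:
                    continue
                f_rows, df_rows = surf.interp_many(m[sel])
                ag = surf.a_grid
                res = y[sel, None] - p[sel, None] - m[sel, None] * (1.0 - ag[None, :])
                fmax = np.maximum(np.abs(f_rows).max(axis=1, keepdims=True), 1e-300)
                mass = (np.abs(f_rows) > 1e-12 * fmax) | (np.abs(df_rows) > 0)
                bad = np.any((res <= 0) & mass, axis=1)
                valid[sel[bad]] = False
                keep = sel[~bad]
                if keep.size == 0:
                    continue
                res = res[~bad]
                f_k = f_rows[~bad]
                df_k = df_rows[~bad]
                lr = np.log(np.where(res > 0, res, 1.0))
                w = np.empty_like(ag)  # trapezoid weights
                da = np.diff(ag)
                w[0], w[-1] = da[0] / 2, da[-1] / 2
                w[1:-1] = (da[:-1] + da[1:]) / 2
                A1 = (1.0 - ag)[None, :] * f_k * w[None, :]
                A2 = df_k * w[None, :]
                pos_res = res > 0
                for j, g1 in enumerate(self.g1_values):
                    E = np.where(pos_res, np.exp(-g1 * lr), 0.0)
                    if g1 == 1.0:
                        u = np.where(pos_res, lr, 0.0)
                    else:
                        u = E * res / (1.0 - g1)
                    J[keep, j] = -(A1 * E).sum(axis=1) + (A2 * u).sum(axis=1)

        self.J = J
        self.valid = valid
        self.n_excluded = int((~valid).sum())
        lm = np.log(np.where(self.zero, 1.0, m))
        # m^(-g2) per record per g2 node, gamma1-independent
        self.Mpow = np.exp(-lm[:, None] * self.g2_values[None, :])
        self.wave_rows = {
            int(yr): np.where(valid & (self.years == yr))[0]
            for yr in np.unique(self.years)
        }

    def block_cache(self, rows: np.ndarray) -> tuple:
        """Pre-sliced (J, m^-g2, zero-mask) arrays for repeated node evaluation."""
        return self.J[rows], self.Mpow[rows], self.zero[rows]

    @staticmethod
    def theta_from_cache(cache: tuple, i_g1: int) -> np.ndarray:
        Jsub, mp, zero = cache
        Jcol = Jsub[:, i_g1][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            th = Jcol / (Jcol - mp)
        th = np.where(np.isfinite(th), th, 1.0)
        th = np.clip(th, 0.0, 1.0)
        th[zero] = 0.0
        return th

    def theta_block(self, i_g1: int, rows: np.ndarray) -> np.ndarray:
        """theta of ``rows`` at gamma1 = g1_values[i_g1], for every gamma2 node."""
        return self.theta_from_cache(self.block_cache(rows), i_g1)

    def theta_at(self, g1: float, g2: float, rows: np.ndarray) -> np.ndarray:
        """theta of ``rows`` at an arbitrary grid node (must be on the g1 grid)."""
        i = int(np.argmin(np.abs(self.g1_values - g1)))
        j = int(np.argmin(np.abs(self.g2_values - g2)))
        return self.theta_block(i, rows)[:, j]


@dataclass
class RiskAversionEstimate:
    """Grid-search result for one subgroup."""

    subgroup: str | None
    grid_size: int
    gamma1: float
    gamma2: float
    objective: float
    n_wave1: int
    n_wave2: int
    n_excluded: int = 0
    se_gamma1: float | None = None
    se_gamma2: float | None = None
    se_unreliable: bool = False


def _objective_matrix(ev: ThetaEvaluator, rows1: np.ndarray, rows2: np.ndarray) -> np.ndarray:
    g = ev.g1_values.size
    obj = np.full((g, ev.g2_values.size), np.inf)
    c1 = ev.block_cache(rows1)
    c2 = ev.block_cache(rows2)
    for i in range(g):
        M1, bad1 = _moments_block(ev.theta_from_cache(c1, i))
        M2, bad2 = _moments_block(ev.theta_from_cache(c2, i))
        h = M2 - M1
        col = (h * h).sum(axis=0)
        col[bad1 | bad2] = np.inf
        obj[i] = col
    return obj


def _argmin_lex(obj: np.ndarray) -> tuple[int, int]:
    # row-major argmin ties break toward the smallest (gamma1, gamma2)
    flat = int(np.argmin(obj))
    return flat // obj.shape[1], flat % obj.shape[1]


def grid_search_gamma(
    records: pd.DataFrame,
    surfaces: dict | None = None,
    schedule: PolicySchedule | None = None,
    grid_size: int = 50,
    route: str = "auto",
    subgroup: str | None = None,
    evaluator: ThetaEvaluator | None = None,
) -> RiskAversionEstimate:
    """Minimize the summed squared moment differences over the [1, 9]^2 grid."""
    gv = np.linspace(GAMMA_LO, GAMMA_HI, grid_size)
    ev = evaluator or ThetaEvaluator(
        records, gv, gv, surfaces=surfaces, schedule=schedule, route=route
    )
    waves = sorted(ev.wave_rows)
    if len(waves) != 2:
        raise EstimationError("grid search needs exactly two waves of records")
    rows1, rows2 = ev.wave_rows[waves[0]], ev.wave_rows[waves[1]]
    if rows1.size == 0 or rows2.size == 0:
        raise EstimationError("a wave has no feasible records")
    obj = _objective_matrix(ev, rows1, rows2)
    if not np.any(np.isfinite(obj)):
        raise EstimationError("all grid nodes infeasible")
    i, j = _argmin_lex(obj)
    return RiskAversionEstimate(
        subgroup=subgroup,
        grid_size=grid_size,
        gamma1=float(ev.g1_values[i]),
        gamma2=float(ev.g2_values[j]),
        objective=float(obj[i, j]),
        n_wave1=int(rows1.size),
        n_wave2=int(rows2.size),
        n_excluded=ev.n_excluded,
    )


@dataclass
class BootstrapResult:
    se_gamma1: float
    se_gamma2: float
    estimates: np.ndarray  # (B_ok, 2)
    n_failed: int
    unreliable: bool
    seed: int


def bootstrap_se(
    records: pd.DataFrame,
    surfaces: dict | None = None,
    schedule: PolicySchedule | None = None,
    grid_size: int = 50,
    B: int = 100,
    seed: int = 0,
    route: str = "auto",
    evaluator: ThetaEvaluator | None = None,
) -> BootstrapResult:
    """Bootstrap standard errors of the grid-search estimator.

    Residents are resampled with replacement within subgroup x wave (the
    two-wave structure is preserved); each replicate re-runs the full grid
    search on the cached evaluator.  Replicates where the objective is
    degenerate are dropped and counted; more than 20% failures flags the SEs
    unreliable.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    gv = np.linspace(GAMMA_LO, GAMMA_HI, grid_size)
    ev = evaluator or ThetaEvaluator(
        records, gv, gv, surfaces=surfaces, schedule=schedule, route=route
    )
    waves = sorted(ev.wave_rows)
    if len(waves) != 2:
        raise EstimationError("bootstrap needs exactly two waves")
    rows1, rows2 = ev.wave_rows[waves[0]], ev.wave_rows[waves[1]]
    rng = np.random.default_rng(seed)
    ests = []
    n_failed = 0
    for _ in range(B):
        r1 = rng.choice(rows1, size=rows1.size, replace=True)
        r2 = rng.choice(rows2, size=rows2.size, replace=True)
        try:
            obj = _objective_matrix(ev, r1, r2)
            if not np.any(np.isfinite(obj)):
                raise EstimationError
            i, j = _argmin_lex(obj)
            ests.append((ev.g1_values[i], ev.g2_values[j]))
        except (EstimationError, DegenerateSampleError):
            n_failed += 1
    if len(ests) < 2:
        raise EstimationError("bootstrap produced fewer than 2 successful replicates")
    ests = np.asarray(ests)
    se1 = float(ests[:, 0].std(ddof=1))
    se2 = float(ests[:, 1].std(ddof=1))
    return BootstrapResult(
        se_gamma1=se1,
        se_gamma2=se2,
        estimates=ests,
        n_failed=n_failed,
        unreliable=n_failed > 0.2 * B,
        seed=seed,
    )


def run_grid_sizes(
    records: pd.DataFrame,
    surfaces: dict | None = None,
    schedule: PolicySchedule | None = None,
    sizes=(20, 40, 50),
    route: str = "auto",
    subgroup: str | None = None,
    bootstrap_B: int = 0,
    seed: int = 0,
) -> dict:
    """Grid-search estimates per grid size plus their average (the headline pair)."""
    out = {"per_grid": {}, "subgroup": subgroup}
    for size in sizes:
        gv = np.linspace(GAMMA_LO, GAMMA_HI, size)
        ev = ThetaEvaluator(
            records, gv, gv, surfaces=surfaces, schedule=schedule, route=route
        )
        est = grid_search_gamma(
            records, grid_size=size, subgroup=subgroup, evaluator=ev,
        )
        if bootstrap_B:
            bs = bootstrap_se(
                records, grid_size=size, B=bootstrap_B, seed=seed, evaluator=ev,
            )
            est.se_gamma1, est.se_gamma2 = bs.se_gamma1, bs.se_gamma2
            est.se_unreliable = bs.unreliable
        out["per_grid"][size] = est
    g1s = [e.gamma1 for e in out["per_grid"].values()]
    g2s = [e.gamma2 for e in out["per_grid"].values()]
    out["average"] = (float(np.mean(g1s)), float(np.mean(g2s)))
    return out
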