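"""Structural utility model and the latent-health estimator.

A resident with latent health weight ``theta`` (0 = perfectly healthy, 1 = only
medical care matters) splits disposable income between composite consumption
``c`` and medical care ``m`` under CRRA preferences

    U(c, m) = (1 - theta) c^(1-g1)/(1-g1) + theta m^(1-g2)/(1-g2),

with the log limit at a risk-aversion coefficient of 1.  Because the realized
reimbursement rate ``a`` is uncertain when ``m`` is chosen, the resident
maximizes expected utility over the conditional density f(a | m), and the
first-order condition can be inverted to recover ``theta`` from observed
behaviour:

    theta = J / (J - m^(-g2)),     J = d/dm  E[ (y - p - m(1-a))^(1-g1) / (1-g1) ],

where J is evaluated by numerical quadrature over an estimated density surface
(:func:`foc_integral`) or in closed form when the density is a point mass
(:func:`theta_closed_form`).  ``J * (1 - g1)`` is the integral in the familiar
textbook presentation; the J form is preferred here because it stays finite in
the log-utility limit g1 -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, InfeasibleRecordError
from .policy import PolicySchedule

__all__ = [
    "crra",
    "utility",
    "DegenerateRateSurface",
    "foc_integral",
    "estimate_theta",
    "theta_closed_form",
    "ThetaEstimate",
    "estimate_theta_table",
]


def crra(x, gamma: float):
    """CRRA felicity x^(1-gamma)/(1-gamma), with the log limit at gamma == 1."""
    x = np.asarray(x, dtype=float)
    if gamma == 1.0:
        return np.log(x)
    return x ** (1.0 - gamma) / (1.0 - gamma)


def utility(c, m, theta, gamma1: float, gamma2: float):
    """Realized utility of the bundle (c, m).

    ``c`` must be strictly positive (the marginal utility of composite goods
    diverges at zero, so zero composite consumption is never optimal).  ``m = 0``
    is admitted: its medical term is 0 when ``theta == 0`` and the limiting value
    -inf otherwise, which keeps grid maximizers well defined.
    """
    c = np.asarray(c, dtype=float)
    m = np.asarray(m, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(c <= 0):
        raise DomainError("composite consumption must be strictly positive")
    if np.any(m < 0):
        raise DomainError("medical expenditure must be non-negative")
    if np.any((theta < 0) | (theta > 1)):
        raise DomainError("theta must lie in [0, 1]")
    if gamma1 < 1 or gamma2 < 1:
        raise DomainError("risk-aversion coefficients must be >= 1")
    out = (1.0 - theta) * crra(c, gamma1)
    pos = m > 0
    med = np.full(np.broadcast(c, m, theta).shape, 0.0)
    if np.any(pos):
        with np.errstate(divide="ignore"):
            med = np.where(pos, theta * crra(np.where(pos, m, 1.0), gamma2), 0.0)
    med = np.where((~pos) & (theta > 0), -np.inf, med)
    return out + med


@dataclass(frozen=True)
class DegenerateRateSurface:
    """A reimbursement-rate density that is a point mass at ``a0``.

    ``marginal_rate`` is the rate applying to the marginal unit of expense; it
    defaults to ``a0`` (a flat schedule) but differs from the realized average
    rate under deductibles and caps.  When built from a policy schedule, the
    point mass tracks the schedule's a(m) curve and the induced d a/d m is what
    the conditional-density derivative term of the FOC would capture; folding it
    into ``marginal_rate`` gives the exact degenerate-limit integral.
    """

    a0: float
    marginal_rate: float | None = None

    @property
    def marg(self) -> float:
        return self.a0 if self.marginal_rate is None else self.marginal_rate


def _j_degenerate(m, y, p, a0, marg, gamma1):
    resid = y - p - m * (1.0 - np.asarray(a0, dtype=float))
    if np.any(resid <= 0):
        raise InfeasibleRecordError("residual consumption non-positive")
    return -(1.0 - np.asarray(marg, dtype=float)) * resid ** (-gamma1)


def _j_surface(m: float, y: float, p: float, surface, gamma1: float) -> float:
    """Quadrature of the expected-utility derivative over the rate grid."""
    a = surface.a_grid
    f_row, df_row = surface.interp(m)
    resid = y - p - m * (1.0 - a)
    mass_here = (np.abs(f_row) > 1e-12 * max(np.max(np.abs(f_row)), 1e-300)) | (
        np.abs(df_row) > 0
    )
    if np.any((resid <= 0) & mass_here):
        raise InfeasibleRecordError(
            "residual consumption non-positive on the support of f(a|m)"
        )
    safe = np.where(resid > 0, resid, 1.0)
    term1 = -(1.0 - a) * safe ** (-gamma1) * f_row
    if gamma1 == 1.0:
        u = np.log(safe)
    else:
        u = safe ** (1.0 - gamma1) / (1.0 - gamma1)
    term2 = u * df_row
    integrand = np.where(resid > 0, term1 + term2, 0.0)
    return float(np.trapezoid(integrand, a))


def _j_value(m, y, p, surface, gamma1):
    if isinstance(surface, DegenerateRateSurface):
        return float(_j_degenerate(m, y, p, surface.a0, surface.marg, gamma1))
    return _j_surface(m, y, p, surface, gamma1)


def foc_integral(m, y, p, surface, gamma1: float) -> float:
    """The definite integral I of the first-order condition (textbook form).

    I = integral over a of [ -(1-g1)(1-a)(y-p-m(1-a))^(-g1) f(a|m)
                             + (y-p-m(1-a))^(1-g1) df(a|m)/dm ].

    Evaluated with trapezoidal weights on the surface's rate grid, with the
    density interpolated to the resident's ``m``.  For a degenerate surface this
    collapses to the single-atom expression.  Note the (1-g1) factor makes this
    form vanish identically at g1 == 1; estimators use I/(1-g1) internally,
    which has a proper log-utility limit.
    """
    if m <= 0:
        raise DomainError("foc_integral requires m > 0")
    return (1.0 - gamma1) * _j_value(m, y, p, surface, gamma1)


def theta_closed_form(m, y, p, a0, gamma1: float, gamma2: float, marginal_rate=None):
    """Latent health weight under a point-mass reimbursement density.

    Solving the FOC with f(a|m) degenerate at ``a0`` gives the odds
    r = (1 - a_marg) (y - p - m(1-a0))^(-g1) m^(g2) and theta = r / (1 + r).
    ``marginal_rate`` defaults to ``a0``.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise DomainError("theta_closed_form requires m > 0")
    marg = a0 if marginal_rate is None else marginal_rate
    resid = y - p - m * (1.0 - np.asarray(a0, dtype=float))
    if np.any(resid <= 0):
        raise DomainError("residual consumption must be positive")
    # odds in logs to dodge overflow for large m^g2
    log_r = (
        np.log1p(-np.asarray(marg, dtype=float))
        - gamma1 * np.log(resid)
        + gamma2 * np.log(m)
    )
    out = 1.0 / (1.0 + np.exp(-log_r))
    return float(out) if out.ndim == 0 else out


@dataclass
class ThetaEstimate:
    """One resident's latent-health estimate and provenance flags."""

    theta: float
    J: float
    zero_expenditure: bool = False
    clipped: bool = False
    uninsured_rule: bool = False
    infeasible: bool = False
    stratum: tuple | None = None


def _theta_from_j(J: float, m: float, gamma1: float, gamma2: float,
                  convention: str = "derived") -> tuple[float, bool]:
    if convention == "derived":
        denom = J - m ** (-gamma2)
        theta = J / denom if denom != 0 else np.nan
    elif convention == "printed":
        # the literal printed form of the estimator, kept for audit; it uses
        # m^(+g2) and the un-normalized integral, and degenerates at g1 == 1
        I = (1.0 - gamma1) * J
        denom = I - (1.0 - gamma1) * m ** gamma2
        theta = I / denom if denom != 0 else np.nan
    else:
        raise ValueError(f"unknown convention {convention!r}")
    clipped = not (0.0 <= theta <= 1.0)
    if not np.isfinite(theta):
        theta, clipped = 1.0, True
    return float(np.clip(theta, 0.0, 1.0)), clipped


def estimate_theta(m, y, p, surface, gamma1: float, gamma2: float,
                   convention: str = "derived") -> ThetaEstimate:
    """Invert the first-order condition for one resident.

    ``surface`` is either a fitted conditional-density surface (insured
    residents, their stratum) or a :class:`DegenerateRateSurface` (uninsured
    residents use the no-reimbursement point mass at 0 with p = 0).
    """
    if m == 0:
        return ThetaEstimate(theta=0.0, J=0.0, zero_expenditure=True)
    try:
        J = _j_value(m, y, p, surface, gamma1)
    except InfeasibleRecordError:
        return ThetaEstimate(theta=np.nan, J=np.nan, infeasible=True)
    theta, clipped = _theta_from_j(J, m, gamma1, gamma2, convention)
    return ThetaEstimate(theta=theta, J=J, clipped=clipped)


# ---------------------------------------------------------------------------
# vectorized table estimation


def _interp_rows(surface, m_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate f(.|m) and df/dm rows of a surface to many m values."""
    return surface.interp_many(m_values)


def estimate_theta_table(
    records: pd.DataFrame,
    surfaces: dict | None,
    gammas: dict[str, tuple[float, float]],
    schedule: PolicySchedule | None = None,
    route: str = "auto",
    convention: str = "derived",
) -> pd.DataFrame:
    """Latent-health estimates for a table of resident records.

    Routes per record:

    * ``m == 0``                     -> theta = 0.
    * uninsured                      -> degenerate rate 0, premium 0 (the
                                        uninsured budget), closed form.
    * ``route == 'kde'`` (default when ``surfaces`` has the record's
      (year, service_type, tier) stratum) -> quadrature over the fitted surface.
    * ``route == 'policy'``          -> degenerate point mass at the realized
                                        rate with the schedule's marginal rate
                                        (deterministic-reimbursement inversion).
    * anything else                  -> degenerate point mass at the realized
                                        rate (flagged fallback).

    Returns a frame aligned with ``records`` (id, subgroup, theta, J, route,
    flags).  Infeasible records (residual consumption non-positive on the
    support) get NaN theta and ``infeasible=True``.
    """
    from .riskaversion import subgroup_assign  # local import to avoid a cycle

    n = len(records)
    theta = np.zeros(n)
    jval = np.zeros(n)
    routes = np.array(["zero"] * n, dtype=object)
    clipped = np.zeros(n, dtype=bool)
    infeasible = np.zeros(n, dtype=bool)

    sub = records.apply(
        lambda r: subgroup_assign(r["gender"], r["education_level"]), axis=1
    ) if n else pd.Series([], dtype=object)
    g1 = np.array([gammas[s][0] for s in sub]) if n else np.array([])
    g2 = np.array([gammas[s][1] for s in sub]) if n else np.array([])

    m = records["expenditure"].to_numpy(dtype=float)
    y = records["income"].to_numpy(dtype=float)
    p = records["premium"].to_numpy(dtype=float)
    a = records["realized_rate"].to_numpy(dtype=float)
    insured = records["insured"].to_numpy(dtype=bool)
    pos = m > 0

    # -- degenerate closed-form routes, vectorized per gamma pair
    def closed(idx, a0, marg, prem):
        a0 = np.broadcast_to(np.asarray(a0, dtype=float), idx.shape)
        marg = np.broadcast_to(np.asarray(marg, dtype=float), idx.shape)
        prem = np.broadcast_to(np.asarray(prem, dtype=float), idx.shape)
        resid = y[idx] - prem - m[idx] * (1.0 - a0)
        bad = resid <= 0
        infeasible[idx[bad]] = True
        theta[idx[bad]] = np.nan
        ok = idx[~bad]
        if ok.size == 0:
            return
        r_ok = resid[~bad]
        mg = marg[~bad]
        with np.errstate(divide="ignore"):
            lr = np.log1p(-mg) - g1[ok] * np.log(r_ok) + g2[ok] * np.log(m[ok])
        theta[ok] = 1.0 / (1.0 + np.exp(-lr))
        jval[ok] = -(1.0 - mg) * r_ok ** (-g1[ok])

    unins_idx = np.where(pos & ~insured)[0]
    if unins_idx.size:
        closed(unins_idx, 0.0, 0.0, 0.0)
        routes[unins_idx] = "uninsured"

    ins_idx = np.where(pos & insured)[0]
    handled = np.zeros(n, dtype=bool)
    if ins_idx.size and route in ("auto", "kde") and surfaces:
        for key, surf in surfaces.items():
            yr, svc, tier = key
            sel = ins_idx[
                (records["year"].to_numpy()[ins_idx] == yr)
                & (records["service_type"].to_numpy()[ins_idx] == svc)
                & (records["tier"].to_numpy()[ins_idx] == tier)
            ]
            if sel.size == 0:
                continue
            f_rows, df_rows = _interp_rows(surf, m[sel])
            ag = surf.a_grid
            resid = y[sel, None] - p[sel, None] - m[sel, None] * (1.0 - ag[None, :])
            fmax = np.maximum(np.abs(f_rows).max(axis=1, keepdims=True), 1e-300)
            mass = (np.abs(f_rows) > 1e-12 * fmax) | (np.abs(df_rows) > 0)
            bad = np.any((resid <= 0) & mass, axis=1)
            safe = np.where(resid > 0, resid, 1.0)
            for k in np.where(~bad)[0]:
                i = sel[k]
                gg1 = g1[i]
                t1 = -(1.0 - ag) * safe[k] ** (-gg1) * f_rows[k]
                if gg1 == 1.0:
                    u = np.log(safe[k])
                else:
                    u = safe[k] ** (1.0 - gg1) / (1.0 - gg1)
                integ = np.where(resid[k] > 0, t1 + u * df_rows[k], 0.0)
                J = float(np.trapezoid(integ, ag))
                th, cl = _theta_from_j(J, m[i], gg1, g2[i], convention)
                theta[i], jval[i], clipped[i] = th, J, cl
            infeasible[sel[bad]] = True
            theta[sel[bad]] = np.nan
            routes[sel] = "kde"
            handled[sel] = True

    rest = ins_idx[~handled[ins_idx]]
    if rest.size:
        if route == "policy":
            if schedule is None:
                raise ValueError("route='policy' requires a schedule")
            marg = np.array(
                [
                    float(
                        schedule.entry(
                            records["service_type"].iat[i], records["tier"].iat[i]
                        ).marginal_rate(m[i])
                    )
                    for i in rest
                ]
            )
            closed(rest, a[rest], marg, p[rest])
            routes[rest] = "policy"
        else:
            closed(rest, a[rest], a[rest], p[rest])
            routes[rest] = "realized_rate"

    out = pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "year": records["year"].to_numpy(),
            "insured": insured,
            "subgroup": sub.to_numpy() if n else [],
            "theta": theta,
            "J": jval,
            "route": routes,
            "zero_expenditure": ~pos,
            "clipped": clipped,
            "infeasible": infeasible,
        },
        index=records.index,
    )
    return out
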