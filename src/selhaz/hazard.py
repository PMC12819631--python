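"""Slutsky counterfactuals: substitution-effect over-consumption of medical care.

Insurance lowers the effective price of care from 1 to 1 - a.  Moving a resident
from insured to uninsured status decomposes, by Slutsky's construction, into

* a compensated price change (budget y - p + a1 m1, price 1): the resulting
  demand m2 differs from the observed m1 purely through the substitution
  effect, so m1 - m2 >= 0 is price-driven over-consumption (ex-post moral
  hazard, mixing demand- and supplier-side responses);
* income effects: m3 (budget y - p, price 1) removes the compensation, m4
  (budget y, price 1) also returns the premium.

All four bundles solve the same CRRA utility maximization; only the budget
line changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "compensated_budget",
    "solve_demand",
    "slutsky_decompose",
    "incidence_and_totals",
    "heterogeneity_ecdf",
]

#: relative tolerance below which over-consumption is treated as zero
OVERCONSUMPTION_TOL = 1e-9


def compensated_budget(y, p, a1, m1):
    """Income making the observed bundle exactly affordable at price 1.

    The compensating variation for the price rise from 1 - a1 to 1 is a1 * m1,
    so the compensated budget is y - p + a1 * m1.
    """
    a1 = np.asarray(a1, dtype=float)
    if np.any((a1 < 0) | (a1 > 1)):
        raise DomainError("a1 must lie in [0, 1]")
    if np.any(np.asarray(m1, dtype=float) < 0):
        raise DomainError("m1 must be >= 0")
    out = np.asarray(y, dtype=float) - p + a1 * m1
    return float(out) if out.ndim == 0 else out


def solve_demand(theta, gamma1, gamma2, W, iters: int = 80):
    """Utility-maximizing (c*, m*) on the budget line c + m = W at price ratio 1.

    The first-order condition (1-theta) c^(-g1) = theta m^(-g2) with m = W - c
    is strictly monotone in c, so the unique root is found by bisection in log
    space.  theta = 0 gives m* = 0; theta = 1 gives c* at the numerical floor
    (marginal utility of c diverges, so exactly zero is never attained).
    Scalars or broadcastable arrays are accepted.
    """
    theta = np.asarray(theta, dtype=float)
    W = np.asarray(W, dtype=float)
    gamma1 = np.asarray(gamma1, dtype=float)
    gamma2 = np.asarray(gamma2, dtype=float)
    if np.any(W <= 0):
        raise DomainError("budget must be positive")
    if np.any((theta < 0) | (theta > 1)):
        raise DomainError("theta must lie in [0, 1]")
    scalar = np.broadcast(theta, gamma1, gamma2, W).shape == ()
    theta_b, g1_b, g2_b, W_b = (
        np.atleast_1d(x) for x in np.broadcast_arrays(theta, gamma1, gamma2, W)
    )
    c = np.where(theta_b <= 0.0, W_b, np.nan)
    c = np.where(theta_b >= 1.0, W_b * 1e-12, c)
    interior = (theta_b > 0.0) & (theta_b < 1.0)
    if np.any(interior):
        th = theta_b[interior]
        g1 = g1_b[interior]
        g2 = g2_b[interior]
        Wi = W_b[interior]
        const = np.log1p(-th) - np.log(th)

        def g(ci):
            return const - g1 * np.log(ci) + g2 * np.log(Wi - ci)

        lo = Wi * 1e-15
        hi = Wi * (1.0 - 1e-15)
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            pos = g(mid) > 0  # g decreasing: root to the right of mid
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
        c[interior] = 0.5 * (lo + hi)
    m = np.where(theta_b <= 0.0, 0.0, W_b - c)
    c = W_b - m
    if scalar:
        return float(c[0]), float(m[0])
    return c, m


@dataclass
class SlutskyResult:
    """Per-resident counterfactual expenditures and effects (arrays)."""

    table: pd.DataFrame


def slutsky_decompose(records: pd.DataFrame, theta, gamma1, gamma2) -> pd.DataFrame:
    """Counterfactual expenditures m2..m4 and Slutsky effects for insured records.

    Parameters
    ----------
    records : DataFrame
        Insured resident records with columns income, premium, expenditure,
        realized_rate (and id/year carried through).
    theta, gamma1, gamma2 : arrays aligned with ``records``
        Latent health weight entering the counterfactual utility problem and
        the resident's subgroup risk-aversion pair.

    Returns a frame with m1..m4, the substitution effect m2 - m1 (<= 0), both
    income-effect readings (m3 - m2 and m4 - m2), the over-consumption
    m1 - m2 >= 0 and its share of m1.  The decomposition identity
    m1 - m4 = (m1 - m2) + (m2 - m4) holds by construction.
    """
    if not bool(np.all(records["insured"])):
        raise ValueError("slutsky_decompose expects insured records")
    y = records["income"].to_numpy(dtype=float)
    p = records["premium"].to_numpy(dtype=float)
    m1 = records["expenditure"].to_numpy(dtype=float)
    a1 = records["realized_rate"].to_numpy(dtype=float)
    theta = np.asarray(theta, dtype=float)
    g1 = np.broadcast_to(np.asarray(gamma1, dtype=float), m1.shape)
    g2 = np.broadcast_to(np.asarray(gamma2, dtype=float), m1.shape)

    W2 = compensated_budget(y, p, a1, m1)
    _, m2 = solve_demand(theta, g1, g2, W2)
    _, m3 = solve_demand(theta, g1, g2, y - p)
    _, m4 = solve_demand(theta, g1, g2, y)
    # zero-expenditure residents cannot over-consume; keep their m2 tied to m1
    m2 = np.where(m1 == 0, 0.0, m2)
    over = np.maximum(m1 - m2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(m1 > 0, over / np.where(m1 > 0, m1, 1.0), 0.0)
    out = pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "year": records["year"].to_numpy(),
            "m1": m1,
            "m2": m2,
            "m3": m3,
            "m4": m4,
            "substitution_effect": m2 - m1,
            "income_effect_uncompensated": m3 - m2,
            "income_effect_total": m4 - m2,
            "over_consumption": over,
            "share": share,
            "a1": a1,
            "theta": theta,
        },
        index=records.index,
    )
    return out


def incidence_and_totals(results: pd.DataFrame) -> dict:
    """Moral-hazard incidence and over-consumption summaries per wave.

    Incidence is the fraction of all insured residents whose observed
    expenditure exceeds the compensated counterfactual (beyond a relative
    tolerance); the descriptive block (mean/min/max/sd of actual,
    counterfactual, over-consumption and its share) is computed over that
    over-consuming subset, mirroring the usual reporting layout.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    out = {}
    for year, grp in results.groupby("year", sort=True):
        flag = grp["over_consumption"] > OVERCONSUMPTION_TOL * np.maximum(grp["m1"], 1.0)
        sub = grp[flag]
        block = {
            "n_insured": int(len(grp)),
            "n_zero_expenditure": int((grp["m1"] == 0).sum()),
            "n_over": int(len(sub)),
            "incidence": float(flag.mean()),
        }
        for col, name in [
            ("m1", "actual"),
            ("m2", "counterfactual"),
            ("over_consumption", "over_consumption"),
            ("share", "share"),
        ]:
            if len(sub):
                block[name] = {
                    "min": float(sub[col].min()),
                    "max": float(sub[col].max()),
                    "mean": float(sub[col].mean()),
                    "sd": float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0,
                }
            else:
                block[name] = None
        out[int(year)] = block
    return out


_GROUPERS = {
    "age65": lambda df: df["age"] >= 65,
    "income": lambda df: df["income"] > df["income"].mean(),
    "education": lambda df: df["education_level"] == "high",
    "health": lambda df: df["theta"] > df["theta"].mean(),
    "exercise": lambda df: df["exercise"].astype(bool),
    "smoking": lambda df: df["smoke"].astype(bool),
    "gender": lambda df: df["gender"] == "male",
    "marital": lambda df: df["married"].astype(bool),
}


def heterogeneity_ecdf(results: pd.DataFrame, group_var: str) -> dict:
    """Paired ECDFs of the over-consumption share split by a binary grouping.

    Groupings follow the usual heterogeneity cuts: age >= 65, income above the
    sample mean, high education (high school or above), latent health above the
    mean, any exercise in the past year, smoking in the past month, gender,
    marital status.  Returns per-group sorted shares + ECDF values and the
    maximum vertical gap between the two curves.
    """
    if group_var not in _GROUPERS:
        raise KeyError(f"unknown grouping variable {group_var!r}")
    mask = _GROUPERS[group_var](results).to_numpy(dtype=bool)
    share = results["share"].to_numpy(dtype=float)
    out = {"group_var": group_var, "groups": {}}
    pooled = np.unique(share)
    curves = {}
    for label, sel in [("yes", mask), ("no", ~mask)]:
        x = np.sort(share[sel])
        ecdf = np.arange(1, x.size + 1) / x.size if x.size else np.array([])
        curves[label] = x
        out["groups"][label] = {
            "n": int(x.size),
            "share_sorted": x,
            "ecdf": ecdf,
            "flag_small": bool(x.size < 5),
        }
    if all(out["groups"][g]["n"] > 0 for g in ("yes", "no")):
        fy = np.searchsorted(curves["yes"], pooled, side="right") / curves["yes"].size
        fn = np.searchsorted(curves["no"], pooled, side="right") / curves["no"].size
        out["max_gap"] = float(np.max(np.abs(fy - fn)))
        out["yes_minus_no_max"] = float(np.max(fn - fy))
    else:
        out["max_gap"] = None
    return out
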