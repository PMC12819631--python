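"""Tiered reimbursement schedules: deductible / rate / cap per service type and hospital tier.

A schedule maps (service_type, tier) to a reimbursement rule.  Reimbursement of a
gross medical expense ``m`` is ``clip(rate * max(m - deductible, 0), 0, cap)``; the
realized reimbursement rate is the reimbursed amount divided by ``m``.  Entries may
be marked uncovered (e.g. general outpatient care outside primary hospitals in many
resident schemes), in which case reimbursement is always zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ScheduleError

SERVICE_TYPES = ("general_outpatient", "chronic_outpatient", "inpatient")
TIERS = ("primary", "secondary", "tertiary")


@dataclass(frozen=True)
class PolicyEntry:
    """Reimbursement rule for one (service_type, tier) cell.

    Parameters
    ----------
    deductible : float
        Expense level below which nothing is reimbursed (currency, >= 0).
    rate : float
        Fraction of the expense above the deductible that is reimbursed, in [0, 1].
    cap : float
        Annual reimbursement ceiling (currency, > deductible); ``inf`` means no cap.
    covered : bool
        Uncovered entries always reimburse zero regardless of the other fields.
    """

    deductible: float = 0.0
    rate: float = 0.0
    cap: float = math.inf
    covered: bool = True

    def __post_init__(self) -> None:
        if self.covered:
            if not 0.0 <= self.rate <= 1.0:
                raise ScheduleError(f"rate must lie in [0, 1], got {self.rate}")
            if self.deductible < 0:
                raise ScheduleError("deductible must be >= 0")
            if not self.cap > self.deductible:
                raise ScheduleError("cap must exceed the deductible for covered entries")

    def reimburse(self, m):
        """Reimbursed amount for gross expense ``m`` (scalar or array)."""
        m = np.asarray(m, dtype=float)
        if np.any(m < 0):
            raise ScheduleError("expenditure must be non-negative")
        if not self.covered:
            return np.zeros_like(m)
        return np.clip(self.rate * np.maximum(m - self.deductible, 0.0), 0.0, self.cap)

    def realized_rate(self, m):
        """Reimbursed / m, defined as 0 when m == 0."""
        m = np.asarray(m, dtype=float)
        r = self.reimburse(m)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, r / np.where(m > 0, m, 1.0), 0.0)
        return a

    def marginal_rate(self, m):
        """Reimbursement rate of the marginal unit of expense at ``m``.

        Zero below the deductible and once the cap binds; equal to ``rate`` in
        between.  This is the rate that enters a rational spender's first-order
        condition, as opposed to the average realized rate.
        """
        m = np.asarray(m, dtype=float)
        if not self.covered:
            return np.zeros_like(m)
        interior = (m > self.deductible) & (self.rate * (m - self.deductible) < self.cap)
        return np.where(interior, self.rate, 0.0)


class PolicySchedule:
    """Collection of :class:`PolicyEntry` keyed by (service_type, tier)."""

    def __init__(self, entries: dict[tuple[str, str], PolicyEntry]):
        for service, tier in entries:
            if service not in SERVICE_TYPES or tier not in TIERS:
                raise ScheduleError(f"unknown schedule key ({service}, {tier})")
        self._entries = dict(entries)

    def entry(self, service_type: str, tier: str) -> PolicyEntry:
        try:
            return self._entries[(service_type, tier)]
        except KeyError:
            raise ScheduleError(
                f"no schedule entry for ({service_type}, {tier})"
            ) from None

    def keys(self):
        return self._entries.keys()

    def items(self):
        return self._entries.items()

    def to_dict(self) -> dict:
        out = {}
        for (service, tier), e in self._entries.items():
            out[f"{service}/{tier}"] = (
                {"covered": False}
                if not e.covered
                else {
                    "covered": True,
                    "deductible": e.deductible,
                    "rate": e.rate,
                    "cap": None if math.isinf(e.cap) else e.cap,
                }
            )
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PolicySchedule":
        entries = {}
        for key, spec in d.items():
            service, tier = key.split("/")
            if not spec.get("covered", True):
                entries[(service, tier)] = PolicyEntry(covered=False)
            else:
                cap = spec.get("cap")
                entries[(service, tier)] = PolicyEntry(
                    deductible=float(spec.get("deductible", 0.0)),
                    rate=float(spec["rate"]),
                    cap=math.inf if cap is None else float(cap),
                )
        return cls(entries)

    @classmethod
    def default(cls) -> "PolicySchedule":
        """Tiered schedule of a typical urban-rural resident scheme.

        General outpatient care is covered only at primary hospitals (50% rate,
        500 cap, no deductible); chronic/special outpatient and inpatient care are
        covered at all tiers with rates falling (80/70/60%) and inpatient
        deductibles rising (400/400/1,000) in the hospital tier, under a common
        250,000 cap.
        """
        big_cap = 250_000.0
        return cls(
            {
                ("general_outpatient", "primary"): PolicyEntry(0.0, 0.50, 500.0),
                ("general_outpatient", "secondary"): PolicyEntry(covered=False),
                ("general_outpatient", "tertiary"): PolicyEntry(covered=False),
                ("chronic_outpatient", "primary"): PolicyEntry(0.0, 0.80, big_cap),
                ("chronic_outpatient", "secondary"): PolicyEntry(200.0, 0.70, big_cap),
                ("chronic_outpatient", "tertiary"): PolicyEntry(200.0, 0.60, big_cap),
                ("inpatient", "primary"): PolicyEntry(400.0, 0.80, big_cap),
                ("inpatient", "secondary"): PolicyEntry(400.0, 0.70, big_cap),
                ("inpatient", "tertiary"): PolicyEntry(1000.0, 0.60, big_cap),
            }
        )


def apply_policy(schedule: PolicySchedule, service_type: str, tier: str, m):
    """Reimbursed amount and realized rate for expense ``m`` under ``schedule``.

    Returns ``(reimbursed, a)`` with ``a = reimbursed / m`` (0 when ``m == 0``).
    Unknown (service_type, tier) pairs raise :class:`ScheduleError`.
    """
    e = schedule.entry(service_type, tier)
    r = e.reimburse(m)
    a = e.realized_rate(m)
    if np.ndim(m) == 0:
        return float(r), float(a)
    return r, a
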