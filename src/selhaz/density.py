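"""Conditional kernel density of the realized reimbursement rate given expense.

For each stratum (year, service type, hospital tier) the realized reimbursement
rate ``a`` in [0, 1] is modelled given gross medical expense ``m > 0``.  The
estimator is a product-Epanechnikov kernel smoother: the conditional density is
the joint density divided by the expense marginal, which for a common expense
bandwidth reduces to a kernel-weighted density of ``a`` around each expense
knot.  Two boundary features of reimbursement data need special care:

* a point mass at ``a = 0`` (expenses below the deductible, uncovered claims),
  modelled as a discrete atom whose expense-varying weight is estimated by
  kernel-weighted frequency and mixed with the continuous part;
* hard support boundaries at 0 and 1, handled by reflecting the continuous
  kernel about both edges.

Bandwidths come from a robust Silverman rule rescaled by the Epanechnikov
canonical factor, or from least-squares cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSampleError, StratumSkippedError

__all__ = [
    "epanechnikov",
    "silverman_bandwidth",
    "cv_bandwidth",
    "ConditionalDensitySurface",
    "fit_surface",
    "fit_all_strata",
]

#: canonical-bandwidth factor converting a Gaussian-kernel rule of thumb to the
#: Epanechnikov kernel (ratio of canonical bandwidths, ~(40 sqrt(pi))^(1/5)/ ...)
EPANECHNIKOV_CANONICAL = 1.7188

N_RATE_CATEGORIES = 100


def epanechnikov(u):
    """Epanechnikov kernel 0.75 (1 - u^2) on |u| <= 1, zero outside."""
    u = np.asarray(u, dtype=float)
    out = 0.75 * (1.0 - u * u)
    out = np.where(np.abs(u) <= 1.0, out, 0.0)
    return float(out) if out.ndim == 0 else out


def silverman_bandwidth(x, kernel_factor: float = EPANECHNIKOV_CANONICAL) -> float:
    """Robust Silverman rule 0.9 min(sd, IQR/1.34) n^(-1/5), kernel-rescaled.

    The 0.9 min(sd, IQR/1.34) variant is the usual guard against heavy tails
    (medical expenses are strongly right-skewed); the result is multiplied by
    the Epanechnikov canonical factor so a rule derived for Gaussian kernels
    transfers to the kernel actually used.  Raises
    :class:`DegenerateSampleError` for samples with no spread.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateSampleError("need at least 2 observations")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr_scaled = (q75 - q25) / 1.34
    # float residue of a constant sample is not spread
    tiny = 1e-12 * max(float(np.abs(x).max()), 1.0)
    candidates = [s for s in (sd, iqr_scaled) if s > tiny]
    if not candidates:
        raise DegenerateSampleError("sample has zero spread")
    scale = min(candidates)
    return kernel_factor * 0.9 * scale * n ** (-0.2)


def _kde_eval(x: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Plain Epanechnikov KDE of sample ``x`` on ``grid``."""
    u = (grid[:, None] - x[None, :]) / h
    return epanechnikov(u).sum(axis=1) / (x.size * h)


def lscv_risk(x: np.ndarray, h: float, n_grid: int = 512) -> float:
    """Least-squares cross-validation risk  int f^2 - 2/n sum f_{-i}(x_i).

    The leave-one-out estimate leaves out *every* exact copy of x_i, not just
    the i-th observation: with tied data (heaped survey amounts, bunching at
    schedule kinks) the classical LOO term rewards an ever-narrower spike on
    the tie and the risk diverges to -inf as h -> 0.  Excluding duplicates
    removes that degeneracy and reduces to the classical criterion on
    continuous samples.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    lo, hi = x.min() - h, x.max() + h
    grid = np.linspace(lo, hi, n_grid)
    f = _kde_eval(x, grid, h)
    int_f2 = float(np.trapezoid(f * f, grid))
    # multiplicity of each observation's exact value
    _, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    mult = counts[inv].astype(float)
    k0 = 0.75  # K(0)
    loo_sum = 0.0
    chunk = max(1, int(2e6 // max(n, 1)))
    for s in range(0, n, chunk):
        xi = x[s : s + chunk]
        u = (xi[:, None] - x[None, :]) / h
        ks = epanechnikov(u).sum(axis=1) - k0 * mult[s : s + chunk]
        denom = np.maximum(n - mult[s : s + chunk], 1.0)
        loo_sum += float((ks / denom).sum())
    return int_f2 - 2.0 * loo_sum / (n * h)


def cv_bandwidth(x, candidates) -> float:
    """Candidate bandwidth minimizing least-squares CV risk (ties -> smaller h)."""
    x = np.asarray(x, dtype=float)
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        raise ValueError("empty candidate grid")
    if x.size < 10:
        raise DegenerateSampleError("cross-validation needs at least 10 observations")
    order = np.argsort(candidates)
    best_h, best_risk = None, np.inf
    for h in candidates[order]:
        risk = lscv_risk(x, float(h))
        if risk < best_risk - 1e-15:
            best_h, best_risk = float(h), risk
    return best_h


def default_cv_candidates(h_silverman: float, n: int = 13) -> np.ndarray:
    """Geometric candidate grid bracketing the Silverman rule (factor 1/3 .. 3)."""
    return h_silverman * np.geomspace(1.0 / 3.0, 3.0, n)


@dataclass
class ConditionalDensitySurface:
    """f(a | m) and its expense derivative on an (m, a) grid for one stratum."""

    key: tuple
    m_grid: np.ndarray
    a_grid: np.ndarray
    f_cond: np.ndarray  # (n_m, n_a)
    df_dm: np.ndarray  # (n_m, n_a)
    f_marginal: np.ndarray  # (n_m,)
    h_m: float
    h_a: float
    bandwidth_method: str
    n_obs: int
    atom: str = "mixture"

    @property
    def f_joint(self) -> np.ndarray:
        return self.f_cond * self.f_marginal[:, None]

    def interp(self, m: float):
        f, df = self.interp_many(np.asarray([m], dtype=float))
        return f[0], df[0]

    def interp_many(self, m_values: np.ndarray):
        """Rows of f_cond and df_dm at arbitrary m, linear in log m.

        Values outside the fitted expense range are clamped to the end knots.
        """
        lm = np.log(np.clip(m_values, self.m_grid[0], self.m_grid[-1]))
        lg = np.log(self.m_grid)
        hi = np.clip(np.searchsorted(lg, lm), 1, len(lg) - 1)
        lo = hi - 1
        span = lg[hi] - lg[lo]
        w = np.where(span > 0, (lm - lg[lo]) / np.where(span > 0, span, 1.0), 0.0)
        w = w[:, None]
        f = (1 - w) * self.f_cond[lo] + w * self.f_cond[hi]
        df = (1 - w) * self.df_dm[lo] + w * self.df_dm[hi]
        return f, df

    def slice_masses(self) -> np.ndarray:
        """Trapezoidal integral of each conditional slice (should be 1)."""
        return np.trapezoid(self.f_cond, self.a_grid, axis=1)


def _reflected_rate_kernel(a_grid: np.ndarray, a_pts: np.ndarray, h: float) -> np.ndarray:
    """(n_pts, n_a) Epanechnikov kernel with reflection at both boundaries."""
    d = a_grid[None, :] - a_pts[:, None]
    k = epanechnikov(d / h)
    k = k + epanechnikov((a_grid[None, :] + a_pts[:, None]) / h)  # reflect at 0
    k = k + epanechnikov((a_grid[None, :] - (2.0 - a_pts[:, None])) / h)  # at 1
    return k / h


def _finite_difference(m_grid: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Derivative of each column across m knots (central, one-sided at ends)."""
    df = np.empty_like(f)
    dm = np.diff(m_grid)
    df[1:-1] = (f[2:] - f[:-2]) / (m_grid[2:] - m_grid[:-2])[:, None]
    df[0] = (f[1] - f[0]) / dm[0]
    df[-1] = (f[-1] - f[-2]) / dm[-1]
    return df


def fit_surface(
    m,
    a,
    key: tuple = ("?", "?", "?"),
    bandwidth_method: str = "silverman",
    n_m: int = 100,
    n_a: int = N_RATE_CATEGORIES,
    atom: str = "mixture",
    cv_candidates=None,
    min_records: int = 30,
    marginal_floor: float = 1e-12,
) -> ConditionalDensitySurface:
    """Fit f(a | m) and df/dm for one stratum.

    Parameters
    ----------
    m, a : arrays
        Positive expenses and realized rates in [0, 1] of the stratum's insured
        records.
    atom : {'mixture', 'kde'}
        'mixture' models the a == 0 point mass as a discrete atom (kernel-
        weighted frequency) mixed with a reflected KDE of the positive rates;
        'kde' runs a single reflected KDE over all rates.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.size < min_records:
        raise StratumSkippedError(f"{key}: only {m.size} records (< {min_records})")
    if np.any(m <= 0):
        raise ValueError("expenses must be positive")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("rates must lie in [0, 1]")

    h_m_silverman = silverman_bandwidth(m)
    if bandwidth_method == "silverman":
        h_m = h_m_silverman
    elif bandwidth_method == "cross_validation":
        cand = (
            np.asarray(cv_candidates, dtype=float)
            if cv_candidates is not None
            else default_cv_candidates(h_m_silverman)
        )
        h_m = cv_bandwidth(m, cand)
    else:
        raise ValueError(f"unknown bandwidth_method {bandwidth_method!r}")

    zero = a <= 0.0
    a_pos = a[~zero]

    def _rate_bandwidth(sample):
        try:
            h = silverman_bandwidth(sample)
        except DegenerateSampleError:
            return 0.02  # degenerate rate column: narrow spike
        if bandwidth_method == "cross_validation" and sample.size >= 10:
            cand = (
                np.asarray(cv_candidates, dtype=float)
                if cv_candidates is not None
                else default_cv_candidates(h)
            )
            try:
                return cv_bandwidth(sample, cand)
            except DegenerateSampleError:
                return h
        return h

    if atom == "mixture":
        h_a = _rate_bandwidth(a_pos) if a_pos.size >= 2 else 0.02
    else:
        h_a = _rate_bandwidth(a)

    m_grid = np.geomspace(m.min(), m.max(), n_m)
    a_grid = np.linspace(0.0, 1.0, n_a)
    da = a_grid[1] - a_grid[0]

    # expense-kernel weights of every record at every knot
    w_all = epanechnikov((m_grid[:, None] - m[None, :]) / h_m)  # (n_m, n)
    sw_all = w_all.sum(axis=1)
    f_marginal = sw_all / (m.size * h_m)

    uniform = np.full(n_a, 1.0)  # will be normalized
    f_cond = np.empty((n_m, n_a))

    if atom == "mixture":
        if a_pos.size:
            k_pos = _reflected_rate_kernel(a_grid, a_pos, h_a)  # (n_pos, n_a)
            w_pos = w_all[:, ~zero]
            sw_pos = w_pos.sum(axis=1)
            cont = w_pos @ k_pos  # (n_m, n_a), unnormalized
        else:
            sw_pos = np.zeros(n_m)
            cont = np.zeros((n_m, n_a))
        # atom weight pi0(m): kernel-weighted frequency of a == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            pi0 = np.where(sw_all > 0, w_all[:, zero].sum(axis=1) / np.where(sw_all > 0, sw_all, 1.0), zero.mean())
        floor = marginal_floor * max(f_marginal.max(), 1e-300)
        for i in range(n_m):
            if f_marginal[i] <= floor:
                f_cond[i] = uniform
                continue
            slice_ = np.zeros(n_a)
            if sw_pos[i] > 0:
                slice_ = (1.0 - pi0[i]) * cont[i] / sw_pos[i]
            # the atom sits on the first knot; the trapezoid weight there is da/2
            slice_[0] += pi0[i] * 2.0 / da
            f_cond[i] = slice_
    elif atom == "kde":
        k_all = _reflected_rate_kernel(a_grid, a, h_a)
        floor = marginal_floor * max(f_marginal.max(), 1e-300)
        raw = w_all @ k_all
        for i in range(n_m):
            f_cond[i] = uniform if f_marginal[i] <= floor else raw[i] / sw_all[i]
    else:
        raise ValueError(f"unknown atom treatment {atom!r}")

    mass = np.trapezoid(f_cond, a_grid, axis=1)
    bad = ~np.isfinite(mass) | (mass <= 0)
    f_cond[bad] = uniform
    mass[bad] = np.trapezoid(uniform, a_grid)
    f_cond = f_cond / mass[:, None]

    if not np.all(np.isfinite(f_cond)):
        raise FloatingPointError(f"{key}: non-finite conditional density")

    df_dm = _finite_difference(m_grid, f_cond)
    return ConditionalDensitySurface(
        key=key,
        m_grid=m_grid,
        a_grid=a_grid,
        f_cond=f_cond,
        df_dm=df_dm,
        f_marginal=f_marginal,
        h_m=float(h_m),
        h_a=float(h_a),
        bandwidth_method=bandwidth_method,
        n_obs=int(m.size),
        atom=atom,
    )


def fit_all_strata(records, bandwidth_method: str = "silverman", atom: str = "mixture",
                   min_records: int = 30):
    """Fit a surface per (year, service_type, tier) over insured positive-expense records.

    Returns ``(surfaces, skipped)`` where ``skipped`` lists strata with too few
    records (these fall back to the degenerate realized-rate rule downstream).
    """
    surfaces, skipped = {}, []
    df = records[(records["insured"]) & (records["expenditure"] > 0)]
    for key, grp in df.groupby(["year", "service_type", "tier"], sort=True):
        try:
            surfaces[key] = fit_surface(
                grp["expenditure"].to_numpy(),
                grp["realized_rate"].to_numpy(),
                key=key,
                bandwidth_method=bandwidth_method,
                atom=atom,
                min_records=min_records,
            )
        except StratumSkippedError:
            skipped.append(key)
    return surfaces, skipped


def save_surfaces(surfaces: dict, path) -> None:
    """Serialize a surfaces dict to a single .npz archive."""
    arrays = {}
    keys = []
    for i, (key, s) in enumerate(surfaces.items()):
        keys.append("|".join(str(k) for k in key))
        arrays[f"m_grid_{i}"] = s.m_grid
        arrays[f"a_grid_{i}"] = s.a_grid
        arrays[f"f_cond_{i}"] = s.f_cond
        arrays[f"df_dm_{i}"] = s.df_dm
        arrays[f"f_marginal_{i}"] = s.f_marginal
        arrays[f"meta_{i}"] = np.array(
            [s.h_m, s.h_a, float(s.n_obs)], dtype=float
        )
        arrays[f"method_{i}"] = np.array([s.bandwidth_method, s.atom])
    arrays["keys"] = np.array(keys)
    np.savez(path, **arrays)


def load_surfaces(path) -> dict:
    with np.load(path, allow_pickle=False) as z:
        keys = z["keys"]
        out = {}
        for i, key in enumerate(keys):
            parts = key.split("|")
            tkey = (int(parts[0]), parts[1], parts[2])
            meta = z[f"meta_{i}"]
            method = z[f"method_{i}"]
            out[tkey] = ConditionalDensitySurface(
                key=tkey,
                m_grid=z[f"m_grid_{i}"],
                a_grid=z[f"a_grid_{i}"],
                f_cond=z[f"f_cond_{i}"],
                df_dm=z[f"df_dm_{i}"],
                f_marginal=z[f"f_marginal_{i}"],
                h_m=float(meta[0]),
                h_a=float(meta[1]),
                bandwidth_method=str(method[0]),
                n_obs=int(meta[2]),
                atom=str(method[1]),
            )
    return out
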