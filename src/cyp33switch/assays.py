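"""Quantitative assay computations behind the measured binding constants.

Four assay families are implemented as forward model + fitter pairs:

* **NMR fast-exchange titration** — under fast exchange the observed chemical
  shift is the population-weighted average of the free and bound shifts, so
  δ_obs follows the 1:1 bound fraction; fitting recovers Kd and δ_bound.
* **Combined chemical-shift perturbation** — the usual weighted Euclidean
  combination of amide ¹H and ¹⁵N shift differences.
* **ITC 1:1 isotherm** — sequential-injection heats with displacement
  dilution bookkeeping; fitting recovers stoichiometry n, Kd and ΔH.
* **PPIase coupled assay** — chymotrypsin-coupled cis→trans isomerization
  progress curves are single exponentials; the observed rate is linear in
  enzyme concentration, and the slope against E/S₀ is the turnover number.

All fitters use multi-start (log-spaced Kd decades) Levenberg–Marquardt-style
local refinement and report standard errors from the linearized covariance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .network import bound_fraction_1to1

__all__ = [
    "TitrationSeries", "ITCThermogram", "ProgressCurve", "FitResult",
    "predict_shift", "fit_titration", "csp_combined",
    "itc_heats", "fit_itc", "ppiase_kobs", "fit_ppiase",
]

CSP_N_WEIGHT = 0.2      # ¹⁵N scaling in the combined amide CSP
KD_GRID = np.logspace(-1, 5, 13)  # multi-start grid, 0.1–1e5 μM
S_CIS0_DEFAULT = 50.0   # μM cis substrate in the coupled assay


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationSeries:
    """One-reporter fast-exchange titration: total ligand vs observed shift."""

    p_total: float                 # μM (constant protein total)
    l_totals: np.ndarray           # μM
    observed_shifts: np.ndarray    # ppm
    delta_free: float              # ppm, fixed reference shift
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        l = np.asarray(self.l_totals, dtype=float)
        s = np.asarray(self.observed_shifts, dtype=float)
        object.__setattr__(self, "l_totals", l)
        object.__setattr__(self, "observed_shifts", s)
        if l.size < 4:
            raise ValueError("titration needs at least 4 points")
        if np.any(l < 0) or not np.all(np.isfinite(s)):
            raise ValueError("invalid titration data")


@dataclass(frozen=True)
class ITCThermogram:
    """Incremental-injection calorimetry record (baseline pre-subtracted)."""

    cell_volume: float             # μL
    cell_conc: float               # μM (cell species)
    syringe_conc: float            # μM (injected species)
    injection_volumes: np.ndarray  # μL
    heats: np.ndarray              # μcal per injection
    discard_first: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.injection_volumes, dtype=float)
        h = np.asarray(self.heats, dtype=float)
        object.__setattr__(self, "injection_volumes", v)
        object.__setattr__(self, "heats", h)
        if self.cell_volume <= 0 or np.any(v <= 0):
            raise ValueError("volumes must be positive")
        if v.shape != h.shape:
            raise ValueError("injection_volumes and heats must align")


@dataclass(frozen=True)
class ProgressCurve:
    """Absorbance-proportional isomerization progress curve."""

    enzyme_conc: float             # μM
    substrate_cis0: float          # μM cis isomer at t=0
    times: np.ndarray              # s
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.enzyme_conc < 0:
            raise ValueError("enzyme_conc must be non-negative")


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    stderr: dict[str, float]
    converged: bool
    residual_rms: float
    flags: tuple[str, ...] = ()

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]


# ---------------------------------------------------------------------------
# NMR titration
# ---------------------------------------------------------------------------

def predict_shift(p_total: float, l_total: float, kd: float,
                  delta_free: float, delta_bound: float) -> float:
    """Fast-exchange observed shift: population-weighted average of states."""
    fb = bound_fraction_1to1(p_total, l_total, kd)
    return delta_free + (delta_bound - delta_free) * fb


def _noise_estimate(values: np.ndarray) -> float:
    """Robust scatter from successive differences (insensitive to the trend)."""
    d = np.diff(np.asarray(values, dtype=float))
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2))


def fit_titration(series: TitrationSeries) -> FitResult:
    """Nonlinear least squares of the fast-exchange model over (Kd, δ_bound).

    δ_free is fixed from the series.  Multi-start over Kd decades 0.1–1e5 μM.
    A series whose shift range is below 3× the noise estimate is flagged
    non-binding and no Kd is reported.
    """
    l, obs = series.l_totals, series.observed_shifts
    span = float(np.max(obs) - np.min(obs))
    sigma = _noise_estimate(obs)
    if span < 3 * sigma or span == 0.0:
        return FitResult(estimates={}, stderr={}, converged=False,
                         residual_rms=span, flags=("non-binding",))

    df = series.delta_free
    # initial δ_bound guess: extrapolate the endpoint direction
    db0 = obs[np.argmax(np.abs(obs - df))]

    def resid(theta):
        log_kd, db = theta
        kd = math.exp(min(max(log_kd, -30.0), 30.0))  # guard exp underflow
        pred = np.array([predict_shift(series.p_total, li, kd, df, db)
                         for li in l])
        return pred - obs

    best = None
    for kd0 in KD_GRID:
        sol = least_squares(resid, x0=[math.log(kd0), db0 + (db0 - df) * 0.2 or db0],
                            method="lm", xtol=1e-12, ftol=1e-12, max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    kd = math.exp(best.x[0])
    db = best.x[1]
    se = _stderr_from_jac(best, n_obs=l.size)
    flags = []
    # identifiability: warn when the design never leaves the linear regime
    fb = np.array([bound_fraction_1to1(series.p_total, li, kd) for li in l])
    if fb.max() < 0.1 or fb.min() > 0.9:
        flags.append("poorly-constrained-design")
    rms = float(np.sqrt(2 * best.cost / l.size))
    return FitResult(
        estimates={"kd": kd, "delta_bound": db},
        stderr={"kd": se[0] * kd, "delta_bound": se[1]},  # log-kd → kd scale
        converged=bool(best.success), residual_rms=rms, flags=tuple(flags),
    )


def csp_combined(delta_h: float, delta_n: float,
                 weight: float = CSP_N_WEIGHT) -> float:
    """Weighted combined [¹H,¹⁵N] amide chemical-shift difference (ppm)."""
    if not weight > 0:
        raise ValueError("weight must be positive")
    return math.sqrt(delta_h ** 2 + (weight * delta_n) ** 2)


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def itc_heats(n: float, kd: float, dh: float, cell_volume: float,
              cell_conc: float, syringe_conc: float,
              injection_volumes: Sequence[float]) -> np.ndarray:
    """Sequential-injection 1:1 heats (μcal), displacement-dilution model.

    Each injection of volume v displaces a fraction v/V₀ of the cell
    contents; totals are tracked per injection and the heat is
    V₀·ΔH·([PL]_i − [PL]_{i-1}·(1−v/V₀)).
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    v0 = cell_volume
    p = cell_conc        # μM, cell species (n sites each)
    l = 0.0              # μM, titrant in the cell
    pl_prev = 0.0
    out = []
    for v in injection_volumes:
        d = 1.0 - v / v0
        p *= d
        l = l * d + syringe_conc * (v / v0)
        sites = n * p
        pl = bound_fraction_1to1(sites, l, kd) * sites if sites > 0 else 0.0
        # μcal = kcal/mol · (μM · μL · 1e-12 mol) · 1e9 μcal/kcal
        q = dh * v0 * (pl - pl_prev * d) * 1e-3
        out.append(q)
        pl_prev = pl
    return np.array(out)


def fit_itc(thermogram: ITCThermogram) -> FitResult:
    """Least squares of the 1:1 sequential-injection model over (n, Kd, ΔH).

    Multi-start over Kd decades.  Flags: ``non-binding`` when all heats are
    indistinguishable from zero; ``low-confidence`` when the Wiseman
    c-value n·[cell]/Kd falls outside [0.1, 1e4].
    """
    h = thermogram.heats.copy()
    v = thermogram.injection_volumes.copy()
    if thermogram.discard_first:
        h, v = h[1:], v[1:]
        lead = thermogram.injection_volumes[:1]
    else:
        lead = np.empty(0)
    if h.size < 10:
        raise ValueError("need at least 10 usable injections")
    scale = float(np.max(np.abs(h)))
    if scale == 0.0 or scale < 3 * _noise_estimate(h):
        return FitResult(estimates={}, stderr={}, converged=False,
                         residual_rms=scale, flags=("non-binding",))

    all_v = np.concatenate([lead, v])

    def model(theta):
        n, log_kd, dh = theta
        kd = math.exp(min(max(log_kd, -30.0), 30.0))
        q = itc_heats(abs(n), kd, dh, thermogram.cell_volume,
                      thermogram.cell_conc, thermogram.syringe_conc, all_v)
        return q[lead.size:]

    def resid(theta):
        return model(theta) - h

    dh0 = float(np.sum(h) * 1e3 / (thermogram.cell_volume * thermogram.cell_conc))
    best = None
    for kd0 in KD_GRID:
        sol = least_squares(resid, x0=[1.0, math.log(kd0), dh0 or -1.0],
                            method="lm", xtol=1e-12, ftol=1e-12, max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol
    n, kd, dh = abs(best.x[0]), math.exp(best.x[1]), best.x[2]
    se = _stderr_from_jac(best, n_obs=h.size)
    flags = []
    c = n * thermogram.cell_conc / kd
    if not (0.1 <= c <= 1e4):
        flags.append("low-confidence")
    rms = float(np.sqrt(2 * best.cost / h.size))
    return FitResult(
        estimates={"n": n, "kd": kd, "dH": dh},
        stderr={"n": se[0], "kd": se[1] * kd, "dH": se[2]},
        converged=bool(best.success), residual_rms=rms, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# PPIase coupled assay
# ---------------------------------------------------------------------------

def ppiase_kobs(k0: float, turnover: float, enzyme: float,
                substrate_cis0: float) -> float:
    """Pseudo-first-order observed isomerization rate (s⁻¹).

    k_obs = k₀ + TN·E/S₀ with the turnover number TN defined as the initial
    enzymatic velocity per enzyme at the assay substrate concentration.
    """
    if substrate_cis0 <= 0:
        raise ValueError("substrate_cis0 must be positive")
    return k0 + turnover * enzyme / substrate_cis0


def _fit_exponential(curve: ProgressCurve) -> tuple[float, float]:
    """Fit signal = A∞ − ΔA·exp(−k·t); returns (k_obs, stderr of k)."""
    t, s = curve.times, curve.signal

    def resid(theta):
        a_inf, da, log_k = theta
        k = math.exp(min(max(log_k, -30.0), 30.0))
        return a_inf - da * np.exp(-k * t) - s

    span = float(s[-1] - s[0]) or 1e-6
    k_guess = 1.0 / max(t[-1] / 3.0, 1e-6)
    sol = least_squares(resid, x0=[s[-1], span, math.log(k_guess)],
                        method="lm", xtol=1e-12, ftol=1e-12, max_nfev=5000)
    k = math.exp(sol.x[2])
    se = _stderr_from_jac(sol, n_obs=t.size)
    return k, se[2] * k


def fit_ppiase(curves: Sequence[ProgressCurve]) -> FitResult:
    """Turnover number and background rate from a set of progress curves.

    Each curve is fit to a single exponential; k_obs is then regressed
    (weighted by its standard error) on E/S₀.  Slope = turnover number,
    intercept = the uncatalyzed background rate k₀.  Curves whose
    exponential fit fails are excluded with a flag; fewer than 3 usable
    curves is an error.
    """
    xs, ys, ws, flags = [], [], [], []
    for c in curves:
        try:
            k, k_se = _fit_exponential(c)
        except Exception:
            flags.append(f"curve-excluded:E={c.enzyme_conc}")
            continue
        xs.append(c.enzyme_conc / c.substrate_cis0)
        ys.append(k)
        ws.append(1.0 / max(k_se, 1e-12) ** 2)
    if len(xs) < 3:
        raise ValueError("need at least 3 usable progress curves")
    x, y, w = np.array(xs), np.array(ys), np.array(ws)
    # weighted linear regression y = k0 + TN·x
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    cov = np.linalg.inv(X.T @ W @ X)
    beta = cov @ X.T @ W @ y
    resid = y - X @ beta
    dof = max(x.size - 2, 1)
    s2 = float(resid @ W @ resid) / dof
    se = np.sqrt(np.diag(cov) * s2)
    k0, tn = float(beta[0]), float(beta[1])
    if tn < 3 * se[1]:
        flags.append("no-catalysis")
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return FitResult(
        estimates={"turnover": tn, "k0": k0},
        stderr={"turnover": float(se[1]), "k0": float(se[0])},
        converged=True, residual_rms=rms, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _stderr_from_jac(sol, n_obs: int) -> np.ndarray:
    """Standard errors from the linearized covariance at the optimum."""
    J = sol.jac
    dof = max(n_obs - J.shape[1], 1)
    s2 = 2 * sol.cost / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], np.nan)
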