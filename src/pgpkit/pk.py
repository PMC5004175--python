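"""One- and two-compartment oral-absorption pharmacokinetics.

The one-compartment oral model is the Bateman function

    C(t) = (dose * ka) / (v_f * (ka - ke)) * (exp(-ke t) - exp(-ka t)),

with ka and ke the first-order absorption and elimination rate constants
(1/h) and v_f the apparent volume of distribution over bioavailability
(V/F, (mg/kg)/(ug/mL)). Bioavailability F is never estimated separately —
every volume and clearance carries the "/F" suffix. When ka -> ke the model
degenerates continuously to C(t) = (dose * ka * t / v_f) * exp(-ka t).

Closed-form secondary parameters: t_peak = ln(ka/ke)/(ka - ke),
c_max = C(t_peak), half-lives ln2/k, AUC = dose/(v_f * ke), and
CL/F = dose/AUC = v_f * ke.

Fitting is unweighted nonlinear least squares on uncensored observations
(1/C^2 weighting optional), initialized by curve stripping: the terminal
log-linear slope gives ke, the method of residuals gives ka. Compartment
models are compared with the least-squares AIC, n*ln(RSS/n) + 2k.

The Bateman curve is invariant under exchanging ka and ke with a rescaled
v_f ("flip-flop"); fits are canonicalized to ka >= ke, the regime of a
rapidly absorbed, slowly eliminated oral drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

DEFAULT_LOQ = 0.05  # ug/mL
DEFAULT_SCHEDULE_H = (0.083, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0,
                    6.0, 8.0, 12.0, 24.0)

KA_BOUNDS = (1e-4, 50.0)
KE_BOUNDS = (1e-4, 50.0)
VF_BOUNDS = (1e-3, 100.0)


class PKError(ValueError):
    pass


@dataclass(frozen=True)
class DoseRegimen:
    dose: float  # mg/kg
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise PKError("dose must be positive")
        if self.route != "oral":
            raise PKError("only the oral route is modeled")


@dataclass(frozen=True)
class ConcTimeSeries:
    """Per-animal plasma profile; observations below the LOQ are censored
    (flagged, never zero-filled)."""

    animal_id: str
    times: tuple[float, ...]      # h, strictly increasing
    conc: tuple[float, ...]       # ug/mL
    censored: tuple[bool, ...]
    loq: float = DEFAULT_LOQ

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if len(t) != len(self.conc) or len(t) != len(self.censored):
            raise PKError("times/conc/censored length mismatch")
        if np.any(np.diff(t) <= 0):
            raise PKError("times must be strictly increasing")
        if not np.all(np.isfinite(self.conc)):
            raise PKError("non-finite concentrations")

    @classmethod
    def from_observations(cls, animal_id, times, conc,
                          loq: float = DEFAULT_LOQ) -> "ConcTimeSeries":
        """Flag sub-LOQ observations as censored."""
        censored = tuple(c < loq for c in conc)
        return cls(animal_id, tuple(times), tuple(conc), censored, loq)

    def uncensored(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~np.asarray(self.censored)
        return (np.asarray(self.times)[keep],
                np.asarray(self.conc)[keep])


@dataclass(frozen=True)
class PKParams:
    ka: float    # 1/h
    ke: float    # 1/h
    v_f: float   # (mg/kg)/(ug/mL)

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0 or self.v_f <= 0:
            raise PKError("rate constants and V/F must be positive")


@dataclass(frozen=True)
class DerivedPK:
    t_half_ka: float
    t_half_ke: float
    t_peak: float
    c_max: float
    auc: float
    cl_f: float
    v_f: float


@dataclass(frozen=True)
class FitResult:
    params: PKParams | None
    rss: float
    n_obs: int
    k_params: int
    aic: float
    converged: bool
    model: str = "one-compartment"
    extra: dict = field(default_factory=dict)
    animal_id: str = ""


# ---------------------------------------------------------------------------
# model functions

def bateman_concentration(p: PKParams, d: DoseRegimen, t) -> np.ndarray | float:
    """Bateman one-compartment oral concentration at time(s) t (hours)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise PKError("negative time")
    if abs(p.ka - p.ke) < 1e-8:
        c = (d.dose * p.ka * t_arr / p.v_f) * np.exp(-p.ka * t_arr)
    else:
        coef = d.dose * p.ka / (p.v_f * (p.ka - p.ke))
        c = coef * (np.exp(-p.ke * t_arr) - np.exp(-p.ka * t_arr))
    return float(c) if np.isscalar(t) else c


def two_compartment_oral_concentration(params, t) -> np.ndarray:
    """C(t) = A e^{-alpha t} + B e^{-beta t} - (A+B) e^{-ka t}.

    ``params`` is (A, B, alpha, beta, ka); C(0) = 0 by construction.
    """
    a, b_, alpha, beta, ka = params
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise PKError("negative time")
    return (a * np.exp(-alpha * t_arr) + b_ * np.exp(-beta * t_arr)
            - (a + b_) * np.exp(-ka * t_arr))


def derived_parameters(p: PKParams, d: DoseRegimen) -> DerivedPK:
    """Closed-form secondary parameters of the one-compartment oral model."""
    if abs(p.ka - p.ke) < 1e-8:
        t_peak = 1.0 / p.ka
    else:
        t_peak = math.log(p.ka / p.ke) / (p.ka - p.ke)
    c_max = float(bateman_concentration(p, d, t_peak))
    auc = d.dose / (p.v_f * p.ke)
    return DerivedPK(
        t_half_ka=math.log(2) / p.ka,
        t_half_ke=math.log(2) / p.ke,
        t_peak=t_peak,
        c_max=c_max,
        auc=auc,
        cl_f=d.dose / auc,   # = v_f * ke
        v_f=p.v_f,
    )


# ---------------------------------------------------------------------------
# AUC by quadrature

def auc_trapezoid(series: ConcTimeSeries, extrapolate: bool = False,
                  ke: float | None = None) -> float:
    """Linear trapezoidal AUC over uncensored points; optional terminal
    extrapolation C_last/ke to infinity."""
    t, c = series.uncensored()
    if len(t) < 2:
        raise PKError("need at least two uncensored points")
    auc = float(np.trapezoid(c, t))
    if extrapolate:
        if ke is None or ke <= 0:
            raise PKError("extrapolation requires ke > 0")
        auc += float(c[-1]) / ke
    return auc


# ---------------------------------------------------------------------------
# fitting

def _strip_initial(t: np.ndarray, c: np.ndarray, dose: float) -> PKParams:
    """Curve-stripping initial estimates: terminal log-linear slope -> ke,
    method of residuals -> ka, terminal intercept -> V/F."""
    i_max = int(np.argmax(c))
    tail_start = max(i_max + 1, len(t) - max(3, len(t) // 3))
    tt, cc = t[tail_start:], c[tail_start:]
    if len(tt) >= 2 and np.all(cc > 0):
        slope, intercept = np.polyfit(tt, np.log(cc), 1)
        ke = max(-slope, 1e-3)
        b0 = math.exp(intercept)
    else:
        ke, b0 = 0.3, max(float(c.max()), 1e-3)
    # residuals of the back-extrapolated terminal line over the absorption phase
    ka = None
    head = slice(0, i_max + 1)
    resid = b0 * np.exp(-ke * t[head]) - c[head]
    ok = resid > 0
    if ok.sum() >= 2:
        slope_r, _ = np.polyfit(t[head][ok], np.log(resid[ok]), 1)
        if -slope_r > ke:
            ka = -slope_r
    if ka is None:
        ka = 5.0 * ke
    v_f = dose * ka / (b0 * (ka - ke)) if ka > ke else dose / b0
    clip = lambda x, lo, hi: min(max(x, lo * 1.01), hi * 0.99)
    return PKParams(ka=clip(ka, *KA_BOUNDS), ke=clip(ke, *KE_BOUNDS),
                    v_f=clip(v_f, *VF_BOUNDS))


def _aic(n: int, rss: float, k: int) -> float:
    rss = max(rss, 1e-300)  # guard log(0) on noise-free data
    return n * math.log(rss / n) + 2 * k


def aic_corrected(n: int, rss: float, k: int) -> float:
    """Small-sample AICc = AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return math.inf
    return _aic(n, rss, k) + 2 * k * (k + 1) / (n - k - 1)


def fit_one_compartment(series: ConcTimeSeries, d: DoseRegimen,
                        init: PKParams | None = None,
                        weighting: str = "none") -> FitResult:
    """Nonlinear least-squares fit of the Bateman model to uncensored points.

    ``weighting='1/C^2'`` minimizes relative residuals instead of absolute
    ones. Parameters are canonicalized to ka >= ke (flip-flop convention).
    """
    t, c = series.uncensored()
    if len(t) < 4:
        raise PKError("need at least 4 uncensored observations")
    p0 = init or _strip_initial(t, c, d.dose)

    def residuals(x):
        pred = bateman_concentration(PKParams(*x), d, t)
        r = pred - c
        if weighting == "1/C^2":
            r = r / np.maximum(c, series.loq)
        return r

    lo = [KA_BOUNDS[0], KE_BOUNDS[0], VF_BOUNDS[0]]
    hi = [KA_BOUNDS[1], KE_BOUNDS[1], VF_BOUNDS[1]]
    sol = least_squares(residuals, [p0.ka, p0.ke, p0.v_f],
                        bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    ka, ke, v_f = sol.x
    if ka < ke:  # identical curve with ka and ke exchanged and V/F rescaled
        ka, ke, v_f = ke, ka, v_f * ke / ka
    params = PKParams(ka=ka, ke=ke, v_f=v_f)
    pred = bateman_concentration(params, d, t)
    rss = float(np.sum((pred - c) ** 2))
    at_bounds = bool(np.any(np.isclose(sol.x, lo, rtol=1e-3))
                     or np.any(np.isclose(sol.x, hi, rtol=1e-3)))
    converged = bool(sol.success) and not at_bounds
    return FitResult(params=params, rss=rss, n_obs=len(t), k_params=3,
                     aic=_aic(len(t), rss, 3), converged=converged,
                     model="one-compartment",
                     extra={"status": int(sol.status), "at_bounds": at_bounds},
                     animal_id=series.animal_id)


def fit_two_compartment_oral(series: ConcTimeSeries, d: DoseRegimen,
                             init=None, weighting: str = "none") -> FitResult:
    """Fit the biexponential-with-absorption model (5 parameters).

    Multi-start: a generic stripping start plus a start embedded from the
    one-compartment solution (the model nests it at B = 0), keeping the best
    RSS. Canonicalized to alpha >= beta.
    """
    t, c = series.uncensored()
    if len(t) < 6:
        raise PKError("need at least 6 uncensored observations")

    def residuals(x):
        r = two_compartment_oral_concentration(x, t) - c
        if weighting == "1/C^2":
            r = r / np.maximum(c, series.loq)
        return r

    starts = []
    if init is not None:
        starts.append(list(init))
    one = fit_one_compartment(series, d, weighting=weighting)
    if one.params is not None:
        p = one.params
        coef = d.dose * p.ka / (p.v_f * (p.ka - p.ke)) if p.ka != p.ke else c.max()
        starts.append([coef, 1e-6, p.ke, p.ke / 2, p.ka])
        starts.append([coef * 0.7, coef * 0.3, p.ke * 3, p.ke, p.ka])
    lo = [1e-6, 0.0, 1e-4, 1e-4, 1e-4]
    hi = [1e3, 1e3, 50.0, 50.0, 50.0]
    best = None
    for x0 in starts:
        x0 = [min(max(v, l), h) for v, l, h in zip(x0, lo, hi)]
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(params=None, rss=math.inf, n_obs=len(t), k_params=5,
                         aic=math.inf, converged=False,
                         model="two-compartment", animal_id=series.animal_id)
    a, b_, alpha, beta, ka = best.x
    if alpha < beta:
        a, b_, alpha, beta = b_, a, beta, alpha
    pred = two_compartment_oral_concentration((a, b_, alpha, beta, ka), t)
    rss = float(np.sum((pred - c) ** 2))
    return FitResult(params=None, rss=rss, n_obs=len(t), k_params=5,
                     aic=_aic(len(t), rss, 5), converged=bool(best.success),
                     model="two-compartment",
                     extra={"coefficients": {"A": a, "B": b_, "alpha": alpha,
                                             "beta": beta, "ka": ka}},
                     animal_id=series.animal_id)


def select_model_aic(fits: list[FitResult]) -> FitResult:
    """Smallest least-squares AIC among converged fits on the same data;
    ties go to the model with fewer parameters.

    A candidate that failed to converge is not a valid fit and drops out of
    the comparison; if exactly one candidate converged it is selected by
    default. With no converged candidate the comparison is impossible.
    """
    if len(fits) < 2:
        raise PKError("need at least two candidate fits")
    if len({f.n_obs for f in fits}) != 1:
        raise PKError("fits compare different datasets (n_obs differ)")
    converged = [f for f in fits if f.converged]
    if not converged:
        raise PKError("no converged fit to select")
    return min(converged, key=lambda f: (f.aic, f.k_params))


# ---------------------------------------------------------------------------
# group summaries

def summarize_group(fits: list[FitResult], d: DoseRegimen) -> pd.DataFrame:
    """Mean +/- SEM of per-animal parameters (derived per animal, then
    averaged; SEM = SD/sqrt(n), absent for a single animal)."""
    if not fits:
        raise PKError("no fits to summarize")
    rows = []
    for f in fits:
        if f.params is None:
            continue
        der = derived_parameters(f.params, d)
        rows.append({"animal_id": f.animal_id,
                     "ka": f.params.ka, "ke": f.params.ke,
                     "t_half_ka": der.t_half_ka, "t_half_ke": der.t_half_ke,
                     "t_peak": der.t_peak, "c_max": der.c_max,
                     "auc": der.auc, "cl_f": der.cl_f, "v_f": der.v_f})
    per_animal = pd.DataFrame(rows)
    n = len(per_animal)
    stats_rows = []
    for col in per_animal.columns.drop("animal_id"):
        vals = per_animal[col].to_numpy(dtype=float)
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        stats_rows.append({"parameter": col, "mean": float(vals.mean()),
                           "sem": sem, "n": n})
    return pd.DataFrame(stats_rows)


def read_plasma_csv(path, loq: float = DEFAULT_LOQ) -> list[ConcTimeSeries]:
    """CSV with columns animal_id, time_h, conc_ug_ml -> one series per animal."""
    df = pd.read_csv(path)
    out = []
    for animal, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(ConcTimeSeries.from_observations(
            str(animal), grp.time_h.tolist(), grp.conc_ug_ml.tolist(), loq))
    return out
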