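"""Parametric survival modelling from digitized Kaplan-Meier curves.

Progression risk in the cohort model is driven by progression-free survival
(PFS) curves published for each treatment strategy.  Published curves come as
digitized (time, survival) points rather than patient-level data, so fitting
proceeds in two steps:

1. reconstruct pseudo individual-patient data (pseudo-IPD) whose Kaplan-Meier
   estimate reproduces the digitized curve, and
2. fit exponential, Weibull and log-normal models to the pseudo-IPD by
   right-censored maximum likelihood, selecting among families by AIC.

The fitted survival function is then converted into a per-cycle transition
probability schedule for the Markov cohort engine: the probability of
progressing during cycle ``t`` is the conditional probability
``[S(t*c) - S((t+1)*c)] / S(t*c)`` with ``c`` the cycle length in months.

Conventions
-----------
Time is measured in months throughout.  Cycle ``t`` covers months
``[t*c, (t+1)*c)`` and survival is evaluated at cycle starts.  Reconstructed
event times are placed at the midpoint of the digitized interval in which the
survival drop occurred, which keeps the Kaplan-Meier estimate of the
pseudo-IPD equal to the digitized curve at every digitized time while
removing most of the discretisation bias in the fitted location parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .exceptions import (
    ConvergenceError,
    FitImpossibleError,
    InvalidInputError,
    InvariantError,
)

FAMILIES = ("exponential", "weibull", "lognormal")

__all__ = [
    "FAMILIES",
    "KMCurve",
    "PseudoIPD",
    "ParametricFit",
    "TransitionSchedule",
    "reconstruct_pseudo_ipd",
    "fit_family",
    "select_by_aic",
    "median_survival",
    "fit_from_median",
    "survival_to_schedule",
    "km_estimate",
]


@dataclass(frozen=True)
class KMCurve:
    """A digitized Kaplan-Meier curve for one endpoint of one strategy.

    Parameters
    ----------
    endpoint : str
        Endpoint label, typically ``"PFS"`` or ``"OS"``.
    strategy : str
        Treatment strategy the curve belongs to.
    times : array-like
        Strictly increasing times in months, all >= 0.
    survival : array-like
        Survival probabilities in [0, 1], non-increasing; if time 0 is
        present its survival must be 1.
    n_at_risk : array-like, optional
        Numbers at risk aligned with ``times``; NaN where not reported.
    max_followup : float, optional
        Maximum follow-up in months; defaults to the last time point.
    """

    endpoint: str
    strategy: str
    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray | None = None
    max_followup: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise InvalidInputError("times and survival must be 1-d and aligned")
        if t.size and t[0] < 0:
            raise InvariantError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise InvariantError("times must be strictly increasing")
        if np.any((s < 0) | (s > 1)):
            raise InvariantError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise InvariantError("survival must be non-increasing")
        if t.size and t[0] == 0 and not math.isclose(s[0], 1.0, abs_tol=1e-9):
            raise InvariantError("survival at time 0 must equal 1")
        if self.n_at_risk is not None:
            r = np.asarray(self.n_at_risk, dtype=float)
            if r.shape != t.shape:
                raise InvalidInputError("n_at_risk must align with times")
            if np.any(r[np.isfinite(r)] < 0):
                raise InvariantError("n_at_risk counts must be non-negative")
            object.__setattr__(self, "n_at_risk", r)
        if self.max_followup is None:
            object.__setattr__(self, "max_followup", float(t[-1]) if t.size else 0.0)

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed patient-level records: times (months) and event flags
    (1 = event, 0 = right-censored)."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise InvalidInputError("times and events must be 1-d and aligned")
        if np.any(t <= 0):
            raise InvariantError("pseudo-IPD times must be positive")
        if not np.all(np.isin(e, (0, 1))):
            raise InvariantError("event indicators must be 0 or 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass(frozen=True)
class ParametricFit:
    """A fitted parametric survival model.

    ``params`` is family-specific: ``{"rate": λ}`` (exponential),
    ``{"shape": k, "scale": b}`` (Weibull) or ``{"mu": μ, "sigma": σ}``
    (log-normal).  ``loglik`` is the maximised right-censored log-likelihood;
    ``aic = 2 * n_params - 2 * loglik``.
    """

    family: str
    params: dict[str, float]
    loglik: float
    n_params: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidInputError(f"unknown family {self.family!r}")
        expected = 1 if self.family == "exponential" else 2
        if self.n_params != expected:
            raise InvariantError(
                f"{self.family} fit must have {expected} parameters"
            )
        for key, val in self.params.items():
            if key != "mu" and val <= 0:
                raise InvariantError(f"parameter {key} must be positive")

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def survival(self, t):
        """Survival function S(t) evaluated at months ``t`` (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            s = np.exp(-self.params["rate"] * t)
        elif self.family == "weibull":
            k, b = self.params["shape"], self.params["scale"]
            s = np.exp(-np.power(np.maximum(t, 0.0) / b, k))
        else:
            mu, sigma = self.params["mu"], self.params["sigma"]
            with np.errstate(divide="ignore"):
                z = np.where(t > 0, (np.log(np.maximum(t, 1e-300)) - mu) / sigma, -np.inf)
            s = norm.sf(z)
        return np.where(t <= 0, 1.0, s)

    def median(self) -> float:
        """Closed-form median survival time in months."""
        if self.family == "exponential":
            return math.log(2.0) / self.params["rate"]
        if self.family == "weibull":
            k, b = self.params["shape"], self.params["scale"]
            return b * math.log(2.0) ** (1.0 / k)
        return math.exp(self.params["mu"])


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle transition probabilities ``p(t)``, ``t = 0 .. horizon-1``."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise InvalidInputError("schedule must be a non-empty 1-d array")
        if np.any((p < 0) | (p > 1)):
            raise InvariantError("schedule probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", p)

    def __len__(self) -> int:
        return int(self.probs.size)


# ---------------------------------------------------------------------------
# pseudo-IPD reconstruction
# ---------------------------------------------------------------------------

def _anchored(curve: KMCurve) -> tuple[np.ndarray, np.ndarray]:
    """Curve points with a (0, 1) anchor prepended when absent."""
    t, s = curve.times, curve.survival
    if t[0] > 0:
        t = np.concatenate(([0.0], t))
        s = np.concatenate(([1.0], s))
    return t, s


def _reconstruct_no_censoring(
    t: np.ndarray, s: np.ndarray, n: int, max_fu: float
) -> PseudoIPD:
    # Cumulative rounding keeps the empirical survivor function within
    # 1/(2n) of the digitized curve at every digitized time.
    cum = np.rint(n * (1.0 - s)).astype(int)
    cum = np.maximum.accumulate(np.clip(cum, 0, n))
    times, events = [], []
    for i in range(1, t.size):
        d = int(cum[i] - cum[i - 1])
        if d > 0:
            times.extend([0.5 * (t[i - 1] + t[i])] * d)
            events.extend([1] * d)
    n_cens = n - int(cum[-1])
    if n_cens > 0:
        times.extend([max_fu] * n_cens)
        events.extend([0] * n_cens)
    return PseudoIPD(np.asarray(times), np.asarray(events))


def _reconstruct_with_risk(
    t: np.ndarray,
    s: np.ndarray,
    risk: np.ndarray,
    n: int,
    max_fu: float,
) -> PseudoIPD:
    """Interval-wise reconstruction in the spirit of the Guyot algorithm.

    Numbers at risk at reported anchors determine how much censoring to
    spread (uniformly, deterministically) within each inter-anchor interval;
    events are allocated so the running KM product tracks the digitized
    survival.  Anchor counts are rescaled so the output has ``n`` records.
    """
    finite = np.where(np.isfinite(risk))[0]
    if finite.size == 0 or risk[finite[0]] <= 0:
        return _reconstruct_no_censoring(t, s, n, max_fu)
    scale = n / risk[finite[0]]
    anchors = [(int(i), risk[i] * scale) for i in finite]
    if anchors[0][0] != 0:
        anchors.insert(0, (0, float(n)))

    times: list[float] = []
    events: list[int] = []
    n_cur = n
    km_cur = 1.0
    for a in range(len(anchors)):
        i_start, _ = anchors[a]
        if a + 1 < len(anchors):
            i_end, r_end = anchors[a + 1]
            target = int(round(r_end))
        else:
            i_end, target = t.size - 1, None
        if i_end <= i_start:
            continue
        seg_idx = range(i_start + 1, i_end + 1)
        c_guess = 0
        best = None
        for _ in range(50):
            n_sim, km_sim = n_cur, km_cur
            seg_t: list[float] = []
            seg_e: list[int] = []
            # deterministic uniform censor times over the segment
            lo, hi = t[i_start], t[i_end]
            cens = [lo + (j + 0.5) / c_guess * (hi - lo) for j in range(c_guess)]
            ci = 0
            for i in seg_idx:
                if km_sim > 0 and n_sim > 0:
                    d = int(round(n_sim * (1.0 - s[i] / km_sim)))
                else:
                    d = 0
                d = max(0, min(d, n_sim))
                if d > 0:
                    km_sim *= 1.0 - d / n_sim
                    seg_t.extend([0.5 * (t[i - 1] + t[i])] * d)
                    seg_e.extend([1] * d)
                    n_sim -= d
                # censors are recorded at the right endpoint of their
                # digitized subinterval so they remain at risk for the
                # midpoint-placed events of the same subinterval — the
                # recomputed product-limit estimator then sees the same
                # risk sets this allocation assumed
                while ci < len(cens) and cens[ci] <= t[i]:
                    if n_sim > 0:
                        seg_t.append(t[i])
                        seg_e.append(0)
                        n_sim -= 1
                    ci += 1
            best = (seg_t, seg_e, n_sim, km_sim)
            if target is None or n_sim == target:
                break
            step = n_sim - target
            if step <= 0:
                break
            c_guess += step
        seg_t, seg_e, n_cur, km_cur = best
        times.extend(seg_t)
        events.extend(seg_e)
    if n_cur > 0:
        times.extend([max_fu] * n_cur)
        events.extend([0] * n_cur)
    return PseudoIPD(np.asarray(times), np.asarray(events))


def reconstruct_pseudo_ipd(curve: KMCurve, target_n: int = 1000) -> PseudoIPD:
    """Reconstruct pseudo individual-patient data from a digitized KM curve.

    Events are allocated proportionally to the survival drops of the
    digitized curve; when numbers at risk are reported, censoring is spread
    uniformly within inter-anchor intervals, otherwise censoring is assumed
    to occur only at maximum follow-up.  The Kaplan-Meier estimate recomputed
    from the output matches ``curve`` within ±1/target_n at every digitized
    time point.
    """
    if curve.n_points < 2:
        raise InvalidInputError("need at least 2 digitized points to reconstruct")
    if target_n < 10:
        raise InvalidInputError("target_n must be at least 10")
    t, s = _anchored(curve)
    max_fu = float(curve.max_followup)
    if curve.n_at_risk is not None and np.any(np.isfinite(curve.n_at_risk)):
        risk = curve.n_at_risk
        if curve.times[0] > 0:
            risk = np.concatenate(([np.nan], risk))
        return _reconstruct_with_risk(t, s, risk, target_n, max_fu)
    return _reconstruct_no_censoring(t, s, target_n, max_fu)


def km_estimate(data: PseudoIPD, at_times: Sequence[float]) -> np.ndarray:
    """Kaplan-Meier survival estimate of pseudo-IPD evaluated at given times.

    Small self-contained product-limit estimator used to verify round-trip
    fidelity of the reconstruction.
    """
    order = np.argsort(data.times, kind="stable")
    t, e = data.times[order], data.events[order]
    ev_times = np.unique(t[e == 1])
    surv = 1.0
    steps_t, steps_s = [0.0], [1.0]
    for et in ev_times:
        n_risk = np.sum(t >= et)
        d = np.sum((t == et) & (e == 1))
        if n_risk > 0:
            surv *= 1.0 - d / n_risk
        steps_t.append(et)
        steps_s.append(surv)
    steps_t = np.asarray(steps_t)
    steps_s = np.asarray(steps_s)
    idx = np.searchsorted(steps_t, np.asarray(at_times, dtype=float), side="right") - 1
    return steps_s[np.clip(idx, 0, steps_s.size - 1)]


# ---------------------------------------------------------------------------
# censored maximum likelihood
# ---------------------------------------------------------------------------

def _nll_weibull(x: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    log_k, log_b = x
    k = math.exp(log_k)
    log_t = np.log(t)
    z = np.exp(k * (log_t - log_b))  # (t/b)^k
    ll = np.sum(e * (log_k - log_b + (k - 1.0) * (log_t - log_b)) - z)
    return -float(ll)


def _nll_lognormal(x: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    mu, log_sigma = x
    sigma = math.exp(log_sigma)
    log_t = np.log(t)
    z = (log_t - mu) / sigma
    ll_ev = norm.logpdf(z) - log_sigma - log_t
    ll_cens = norm.logsf(z)
    ll = np.sum(np.where(e == 1, ll_ev, ll_cens))
    return -float(ll)


def fit_family(data: PseudoIPD, family: str) -> ParametricFit:
    """Right-censored maximum-likelihood fit of one parametric family.

    The exponential rate has the closed form λ = events / total follow-up;
    Weibull and log-normal are optimised over log-parametrised coordinates
    with Nelder-Mead (log-likelihood tolerance 1e-8), started from the
    moment-matched exponential / empirical values.
    """
    if family not in FAMILIES:
        raise InvalidInputError(f"unknown family {family!r}")
    d = data.n_events
    if d == 0:
        raise FitImpossibleError("cannot fit a survival model with zero events")
    t, e = data.times, data.events
    total_time = float(t.sum())

    if family == "exponential":
        lam = d / total_time
        loglik = d * math.log(lam) - lam * total_time
        return ParametricFit("exponential", {"rate": lam}, float(loglik), 1)

    if family == "weibull":
        nll = _nll_weibull
        x0 = np.array([0.0, math.log(total_time / d)])
    else:
        log_ev = np.log(t[e == 1])
        mu0 = float(np.mean(log_ev))
        sig0 = float(np.std(log_ev)) or 0.5
        nll = _nll_lognormal
        x0 = np.array([mu0, math.log(sig0)])

    res = optimize.minimize(
        nll,
        x0,
        args=(t, e),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-8, "maxiter": 4000, "maxfev": 8000},
    )
    if not res.success:
        raise ConvergenceError(
            f"{family} fit did not converge: {res.message} "
            f"(nit={res.nit}, nfev={res.nfev})"
        )
    if family == "weibull":
        params = {"shape": math.exp(res.x[0]), "scale": math.exp(res.x[1])}
    else:
        params = {"mu": float(res.x[0]), "sigma": math.exp(res.x[1])}
    return ParametricFit(family, params, -float(res.fun), 2)


def select_by_aic(fits: Sequence[ParametricFit]) -> ParametricFit:
    """Pick the fit with minimal AIC.

    Ties are broken by fewer parameters, then by the fixed family order
    exponential, weibull, lognormal.
    """
    if not fits:
        raise InvalidInputError("select_by_aic requires at least one fit")
    return min(fits, key=lambda f: (f.aic, f.n_params, FAMILIES.index(f.family)))


def median_survival(fit: ParametricFit) -> float:
    """Median survival time in months (closed form for each family)."""
    return fit.median()


def fit_from_median(median: float, reference: ParametricFit) -> ParametricFit:
    """Log-normal fit with a shifted location: μ = ln(median), σ from
    ``reference``.

    Used by the sensitivity analyses, which express curve uncertainty on the
    interpretable median-PFS scale while preserving the fitted shape.  The
    returned fit carries no likelihood (NaN).
    """
    if median <= 0:
        raise InvalidInputError("median must be positive")
    if reference.family != "lognormal":
        raise InvalidInputError("reference fit must be log-normal")
    return ParametricFit(
        "lognormal",
        {"mu": math.log(median), "sigma": reference.params["sigma"]},
        float("nan"),
        2,
    )


def survival_to_schedule(
    fit: ParametricFit, horizon_cycles: int, cycle_months: float = 1.0
) -> TransitionSchedule:
    """Convert a fitted survival curve into per-cycle transition probabilities.

    ``p(t) = [S(t*c) - S((t+1)*c)] / S(t*c)`` — the interval-conditional
    probability, exact for any survival function; ``p(t) = 1`` where
    ``S(t*c) = 0``.
    """
    if horizon_cycles < 1:
        raise InvalidInputError("horizon_cycles must be >= 1")
    grid = np.arange(horizon_cycles + 1, dtype=float) * cycle_months
    s = fit.survival(grid)
    s_now, s_next = s[:-1], s[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(s_now > 0.0, (s_now - s_next) / np.where(s_now > 0, s_now, 1.0), 1.0)
    return TransitionSchedule(np.clip(p, 0.0, 1.0))
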