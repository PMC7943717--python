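"""Deterministic and probabilistic sensitivity analyses.

Three analyses surround the base case:

* **One-way (tornado)** — each parameter is pushed to its low and high value
  with all others at base; the ICER of a chosen strategy pair is recorded and
  parameters ranked by swing.
* **Two-way price-threshold** — with efficacy fixed at a chosen value, the
  monthly drug cost at which the ICER equals the willingness-to-pay (WTP)
  threshold is found by root bracketing/bisection.
* **Probabilistic (PSA)** — parameters are drawn jointly from per-parameter
  distributions (beta for probabilities/utilities, gamma for costs,
  log-normal for median PFS) moment-matched so the mean equals the base
  value and [low, high] approximates a 95% interval; the model is re-run per
  draw and the cost-effectiveness acceptability curve (CEAC) reports, per
  WTP value, the fraction of draws in which each strategy has the highest
  net monetary benefit.

The pipeline is passed in as a closure ``evaluate(overrides) -> CEResult``
where ``overrides`` maps parameter target paths (e.g.
``"strategies.AA+ADT.drug_cost_pf_monthly"`` or ``"median_pfs.AA+ADT"``)
to values; :meth:`mhspc_cea.model.MarkovCEResults.evaluate` provides it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import CEResult
from .exceptions import InvalidInputError, ParamSpecError

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSAResult",
    "CEAC",
    "ThresholdResult",
    "icer_between",
    "one_way_tornado",
    "two_way_threshold",
    "sample_psa",
    "run_psa",
    "compute_ceac",
]

PSA_FAMILIES = ("beta", "gamma", "lognormal", "fixed")

Pipeline = Callable[[Mapping[str, float]], CEResult]


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base/low/high values, PSA distribution family
    and the target path it overrides in the pipeline."""

    name: str
    base: float
    low: float
    high: float
    psa_family: str
    target: str

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ParamSpecError(
                f"{self.name}: low <= base <= high violated "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.psa_family not in PSA_FAMILIES:
            raise ParamSpecError(f"{self.name}: unknown family {self.psa_family!r}")
        if self.psa_family == "beta" and not (0 <= self.low and self.high <= 1):
            raise ParamSpecError(f"{self.name}: beta requires values in [0, 1]")
        if self.psa_family in ("gamma", "lognormal") and self.low < 0:
            raise ParamSpecError(f"{self.name}: {self.psa_family} requires values >= 0")


@dataclass(frozen=True)
class TornadoEntry:
    param: str
    icer_low: float
    icer_high: float
    error: str = ""

    @property
    def swing(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration discounted (cost, QALY) totals per strategy."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_iter, n_strategies)
    qalys: np.ndarray
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise InvalidInputError("n_iter must be >= 1")
        if np.any(self.costs < 0):
            raise InvalidInputError("PSA costs must be >= 0")


@dataclass(frozen=True)
class CEAC:
    """Probability each strategy is cost-effective over a WTP grid."""

    wtp_grid: np.ndarray
    strategies: tuple[str, ...]
    prob_ce: np.ndarray  # (len(wtp_grid), n_strategies)

    def __post_init__(self) -> None:
        p = np.asarray(self.prob_ce, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise InvalidInputError("CEAC probabilities must lie in [0, 1]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise InvalidInputError("CEAC probabilities must sum to 1 at each WTP")
        object.__setattr__(self, "prob_ce", p)
        object.__setattr__(self, "wtp_grid", np.asarray(self.wtp_grid, dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.prob_ce, columns=list(self.strategies))
        df.insert(0, "wtp", self.wtp_grid)
        return df


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float | None
    found: bool
    icer_at_threshold: float | None = None
    note: str = ""


def icer_between(ce: CEResult, intervention: str, comparator: str) -> float:
    """Pairwise ICER (Δcost / ΔQALY) between two named strategies."""
    a = ce.outcome(intervention)
    b = ce.outcome(comparator)
    dq = a.total_qalys - b.total_qalys
    dc = a.total_cost - b.total_cost
    if dq == 0:
        return math.inf if dc > 0 else -math.inf
    return dc / dq


def one_way_tornado(
    params: Sequence[ParamSpec],
    evaluate: Pipeline,
    comparison: tuple[str, str],
) -> list[TornadoEntry]:
    """Univariable sensitivity analysis on the ICER of ``comparison``.

    Each parameter is evaluated at its low and high value with all others at
    base; entries come back sorted by swing, largest first.  A pipeline
    failure at one extreme flags that entry without disturbing the rest.
    """
    if not params:
        raise InvalidInputError("params must be non-empty")
    entries = []
    for p in params:
        vals = {}
        err = ""
        for tag, v in (("low", p.low), ("high", p.high)):
            try:
                vals[tag] = icer_between(evaluate({p.target: v}), *comparison)
            except Exception as exc:  # noqa: BLE001 - flagged, not fatal
                vals[tag] = math.nan
                err = f"{tag}: {exc}"
        entries.append(TornadoEntry(p.name, vals["low"], vals["high"], err))
    return sorted(
        entries, key=lambda e: (0 if math.isnan(e.swing) else -e.swing, e.param)
    )


def two_way_threshold(
    evaluate: Pipeline,
    drug_cost_target: str,
    wtp: float,
    comparison: tuple[str, str],
    bracket: tuple[float, float] = (0.0, 20000.0),
    efficacy_target: str | None = None,
    efficacy_value: float | None = None,
    cost_tol: float = 0.5,
) -> ThresholdResult:
    """Monthly drug-cost threshold at which the pairwise ICER equals WTP.

    With the efficacy parameter (median PFS) held at ``efficacy_value``,
    bisection narrows the cost bracket below 2 * ``cost_tol`` dollars.
    Monotonicity of the ICER in drug cost over the bracket is verified
    numerically first; if the ICER never crosses WTP in the bracket a
    no-threshold result is returned.
    """
    fixed: dict[str, float] = {}
    if efficacy_target is not None:
        if efficacy_value is None:
            raise InvalidInputError("efficacy_value required with efficacy_target")
        fixed[efficacy_target] = efficacy_value

    def f(c: float) -> float:
        return icer_between(evaluate({**fixed, drug_cost_target: c}), *comparison) - wtp

    lo, hi = bracket
    if not lo < hi:
        raise InvalidInputError("bracket must satisfy lo < hi")
    f_lo, f_mid, f_hi = f(lo), f(0.5 * (lo + hi)), f(hi)
    if not (f_lo <= f_mid <= f_hi or f_lo >= f_mid >= f_hi):
        raise InvalidInputError(
            "ICER is not monotone in drug cost over the bracket"
        )
    if f_lo * f_hi > 0:
        side = "below" if f_lo > 0 else "above"
        return ThresholdResult(
            None,
            False,
            note=f"ICER stays {side} WTP for all costs in "
            f"[{lo:.0f}, {hi:.0f}]; no threshold",
        )
    while hi - lo > 2 * cost_tol:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid == 0.0:
            lo = hi = mid
            break
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    c_star = 0.5 * (lo + hi)
    return ThresholdResult(c_star, True, icer_at_threshold=f(c_star) + wtp)


def _draw(p: ParamSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if p.psa_family == "fixed" or p.high == p.low:
        return np.full(n, p.base)
    sd = (p.high - p.low) / (2.0 * 1.959964)
    m = p.base
    if p.psa_family == "beta":
        if not 0 < m < 1:
            raise ParamSpecError(f"{p.name}: beta mean must lie strictly in (0, 1)")
        nu = m * (1.0 - m) / sd**2 - 1.0
        if nu <= 0:
            raise ParamSpecError(
                f"{p.name}: beta moment match infeasible (variance too large)"
            )
        return rng.beta(m * nu, (1.0 - m) * nu, size=n)
    if p.psa_family == "gamma":
        if m <= 0:
            raise ParamSpecError(f"{p.name}: gamma mean must be positive")
        shape = (m / sd) ** 2
        return rng.gamma(shape, sd**2 / m, size=n)
    # lognormal: sigma from the log-range, mu set so the arithmetic mean = base
    if p.low <= 0:
        raise ParamSpecError(f"{p.name}: lognormal requires low > 0")
    sigma = (math.log(p.high) - math.log(p.low)) / (2.0 * 1.959964)
    mu = math.log(m) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size=n)


def sample_psa(
    params: Sequence[ParamSpec], n_iter: int, seed: int
) -> pd.DataFrame:
    """Draw the PSA parameter matrix (one column per parameter).

    Independent draws per iteration; distributions are moment-matched so the
    mean equals the base value and [low, high] approximates a central 95%
    interval.  The same seed reproduces the matrix bit-identically.
    """
    if n_iter < 1:
        raise InvalidInputError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({p.name: _draw(p, rng, n_iter) for p in params})


def run_psa(
    evaluate: Pipeline,
    params: Sequence[ParamSpec],
    strategies: Sequence[str],
    n_iter: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo propagation: re-run the pipeline once per joint draw."""
    draws = sample_psa(params, n_iter, seed)
    costs = np.empty((n_iter, len(strategies)))
    qalys = np.empty((n_iter, len(strategies)))
    targets = [p.target for p in params]
    mat = draws.to_numpy()
    for i in range(n_iter):
        overrides = dict(zip(targets, mat[i]))
        ce = evaluate(overrides)
        for j, s in enumerate(strategies):
            o = ce.outcome(s)
            costs[i, j] = o.total_cost
            qalys[i, j] = o.total_qalys
    return PSAResult(tuple(strategies), costs, qalys, n_iter, seed)


def compute_ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> CEAC:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each WTP value a strategy scores the fraction of iterations in which
    it attains the strictly highest net monetary benefit; exact ties share
    the iteration equally.
    """
    wtp = np.asarray(wtp_grid, dtype=float)
    probs = np.empty((wtp.size, len(psa.strategies)))
    for k, w in enumerate(wtp):
        nmb = w * psa.qalys - psa.costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        share = winners / winners.sum(axis=1, keepdims=True)
        probs[k] = share.mean(axis=0)
    return CEAC(wtp, psa.strategies, probs)
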