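"""Costs, utilities and incremental cost-effectiveness analysis.

Per-cycle costs and quality-adjusted life-years (QALYs) are attached to the
cohort trace from the payer perspective and discounted at an annual rate.
Cost components per cycle:

* progression-free occupancy pays ADT, plus drug and administration cost
  while the first-line drug is still given (a fixed number of cycles for
  docetaxel, until progression for the androgen receptor pathway inhibitors);
* progression occupancy pays the monthly CRPC care cost (which folds in the
  subsequent-line therapy mix);
* new entrants to death pay a one-time terminal care cost;
* adverse-event (AE) costs and disutilities enter as expected one-time
  amounts at treatment start — spread evenly over the treated cycles for
  fixed-duration regimens, all at cycle 0 otherwise.

Utilities: the on-treatment utility applies while the drug is given, the
post-treatment metastatic-on-ADT utility afterwards (progression-free only),
and the progression utility in the CRPC state.

``incremental_analysis`` builds the cost-effectiveness frontier: strategies
sorted by cost, strongly dominated ones (more costly, no more effective)
removed, extended dominance (decreasing ICERs along the frontier) removed
iteratively, and incremental cost-effectiveness ratios (ICERs) computed
against the previous non-dominated strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvariantError
from .markov import CohortTrace, ModelConfig

__all__ = [
    "AdverseEvent",
    "AdverseEventProfile",
    "StrategyEconomics",
    "CEOutcome",
    "CERow",
    "CEResult",
    "discount_factor",
    "cycle_cost",
    "cycle_qaly",
    "accumulate",
    "incremental_analysis",
    "net_monetary_benefit",
]


@dataclass(frozen=True)
class AdverseEvent:
    """A grade ≥3 adverse event: per-patient probability, one-time cost and
    one-time QALY decrement."""

    name: str
    rate: float
    cost: float
    disutility: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise InvariantError(f"AE {self.name}: rate must lie in [0, 1]")
        if self.cost < 0 or self.disutility < 0:
            raise InvariantError(f"AE {self.name}: cost and disutility must be >= 0")


@dataclass(frozen=True)
class AdverseEventProfile:
    events: tuple[AdverseEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def expected_cost(self) -> float:
        return sum(e.rate * e.cost for e in self.events)

    @property
    def expected_disutility(self) -> float:
        return sum(e.rate * e.disutility for e in self.events)


@dataclass(frozen=True)
class StrategyEconomics:
    """All cost/utility parameters for one treatment strategy.

    ``drug_duration_cycles`` is ``None`` for treat-until-progression
    regimens.  ``crpc_cost_monthly`` already includes the subsequent-line
    therapy mix; ``subsequent_therapy_proportion`` is carried so sensitivity
    analyses can re-derive it.
    """

    name: str
    drug_cost_pf_monthly: float
    drug_duration_cycles: int | None
    adt_cost_monthly: float
    admin_cost_per_cycle: float
    ae_profile: AdverseEventProfile
    utility_on_treatment: float
    utility_pf_post_treatment: float
    utility_progression: float
    crpc_cost_monthly: float
    death_cost_terminal: float
    subsequent_therapy_proportion: float = 0.0

    def __post_init__(self) -> None:
        for f in (
            "drug_cost_pf_monthly",
            "adt_cost_monthly",
            "admin_cost_per_cycle",
            "crpc_cost_monthly",
            "death_cost_terminal",
        ):
            if getattr(self, f) < 0:
                raise InvariantError(f"{self.name}: {f} must be >= 0")
        for f in (
            "utility_on_treatment",
            "utility_pf_post_treatment",
            "utility_progression",
        ):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise InvariantError(f"{self.name}: {f} must lie in [0, 1]")
        if self.drug_duration_cycles is not None and self.drug_duration_cycles < 1:
            raise InvariantError(f"{self.name}: finite duration must be >= 1 cycle")
        if not 0.0 <= self.subsequent_therapy_proportion <= 1.0:
            raise InvariantError(
                f"{self.name}: subsequent_therapy_proportion must lie in [0, 1]"
            )

    def with_override(self, field_name: str, value) -> "StrategyEconomics":
        if not hasattr(self, field_name):
            raise InvalidInputError(f"unknown economics field {field_name!r}")
        return replace(self, **{field_name: value})


@dataclass(frozen=True)
class CEOutcome:
    """Discounted lifetime totals for one strategy."""

    strategy: str
    total_cost: float
    total_qalys: float
    total_lys: float


@dataclass(frozen=True)
class CERow:
    strategy: str
    total_cost: float
    total_qalys: float
    total_lys: float
    incremental_cost: float | None
    incremental_qalys: float | None
    icer: float | None
    status: str  # referent | on-frontier | strongly-dominated | extended-dominated
    note: str = ""


@dataclass(frozen=True)
class CEResult:
    """Cost-ordered outcomes plus the incremental/dominance table."""

    outcomes: tuple[CEOutcome, ...]
    rows: tuple[CERow, ...]

    def outcome(self, strategy: str) -> CEOutcome:
        for o in self.outcomes:
            if o.strategy == strategy:
                return o
        raise KeyError(strategy)

    @property
    def frontier(self) -> tuple[str, ...]:
        return tuple(
            r.strategy for r in self.rows if r.status in ("referent", "on-frontier")
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": r.strategy,
                    "total_cost": r.total_cost,
                    "total_qalys": r.total_qalys,
                    "total_lys": r.total_lys,
                    "incremental_cost": r.incremental_cost,
                    "incremental_qalys": r.incremental_qalys,
                    "icer": r.icer,
                    "status": r.status,
                }
                for r in self.rows
            ]
        )


def discount_factor(annual_rate: float, cycle: int, cycle_months: float = 1.0) -> float:
    """Discount factor ``(1 + r)^(-cycle * cycle_months / 12)``."""
    if cycle < 0:
        raise InvalidInputError("cycle must be >= 0")
    return (1.0 + annual_rate) ** (-cycle * cycle_months / 12.0)


def _on_drug(econ: StrategyEconomics, cycle: int) -> bool:
    return econ.drug_duration_cycles is None or cycle < econ.drug_duration_cycles


def _ae_cost_at(econ: StrategyEconomics, cycle: int) -> float:
    ae = econ.ae_profile.expected_cost
    if econ.drug_duration_cycles is not None:
        return ae / econ.drug_duration_cycles if cycle < econ.drug_duration_cycles else 0.0
    return ae if cycle == 0 else 0.0


def _ae_disutility_at(econ: StrategyEconomics, cycle: int) -> float:
    ae = econ.ae_profile.expected_disutility
    if econ.drug_duration_cycles is not None:
        return ae / econ.drug_duration_cycles if cycle < econ.drug_duration_cycles else 0.0
    return ae if cycle == 0 else 0.0


def cycle_cost(econ: StrategyEconomics, trace: CohortTrace, cycle: int) -> float:
    """Undiscounted cost accrued during cycle ``cycle``."""
    if not 0 <= cycle < trace.horizon:
        raise InvalidInputError(f"cycle {cycle} outside trace horizon {trace.horizon}")
    pf, prog, _ = trace.occupancy[cycle]
    per_pf = econ.adt_cost_monthly
    if _on_drug(econ, cycle):
        per_pf += econ.drug_cost_pf_monthly + econ.admin_cost_per_cycle
    cost = pf * per_pf
    cost += prog * econ.crpc_cost_monthly
    cost += trace.entrants_to_death[cycle] * econ.death_cost_terminal
    cost += _ae_cost_at(econ, cycle)
    return float(cost)


def cycle_qaly(
    econ: StrategyEconomics, trace: CohortTrace, cycle: int, cycle_months: float = 1.0
) -> float:
    """Undiscounted QALYs accrued during cycle ``cycle``."""
    if not 0 <= cycle < trace.horizon:
        raise InvalidInputError(f"cycle {cycle} outside trace horizon {trace.horizon}")
    pf, prog, _ = trace.occupancy[cycle]
    u_pf = (
        econ.utility_on_treatment
        if _on_drug(econ, cycle)
        else econ.utility_pf_post_treatment
    )
    q = (pf * u_pf + prog * econ.utility_progression) * cycle_months / 12.0
    q -= _ae_disutility_at(econ, cycle)
    return float(q)


def accumulate(
    econ: StrategyEconomics, trace: CohortTrace, config: ModelConfig
) -> CEOutcome:
    """Discounted lifetime totals (cost, QALYs, life-years) for one strategy.

    Vectorised equivalent of summing ``discount_factor(t) * cycle_cost(t)``
    (and the QALY analogue) over all cycles; life-years count the alive
    fraction.  With ``config.half_cycle_correction`` the state occupancies
    are averaged between cycle start and end before valuation.
    """
    H = trace.horizon
    if H != config.horizon_cycles:
        raise InvalidInputError("trace horizon does not match config")
    c = config.cycle_months
    cyc = np.arange(H)
    disc = (1.0 + config.discount_annual) ** (-cyc * c / 12.0)

    occ = trace.occupancy
    if config.half_cycle_correction:
        pf = 0.5 * (occ[:-1, 0] + occ[1:, 0])
        prog = 0.5 * (occ[:-1, 1] + occ[1:, 1])
    else:
        pf = occ[:-1, 0]
        prog = occ[:-1, 1]

    if econ.drug_duration_cycles is None:
        on_drug = np.ones(H, dtype=bool)
    else:
        on_drug = cyc < econ.drug_duration_cycles

    per_pf = econ.adt_cost_monthly + np.where(
        on_drug, econ.drug_cost_pf_monthly + econ.admin_cost_per_cycle, 0.0
    )
    costs = pf * per_pf + prog * econ.crpc_cost_monthly
    costs = costs + trace.entrants_to_death[:H] * econ.death_cost_terminal
    ae_cost = econ.ae_profile.expected_cost
    ae_dis = econ.ae_profile.expected_disutility
    if econ.drug_duration_cycles is not None:
        d = econ.drug_duration_cycles
        costs[: min(d, H)] += ae_cost / d
    else:
        costs[0] += ae_cost

    u_pf = np.where(
        on_drug, econ.utility_on_treatment, econ.utility_pf_post_treatment
    )
    qalys = (pf * u_pf + prog * econ.utility_progression) * c / 12.0
    if econ.drug_duration_cycles is not None:
        d = econ.drug_duration_cycles
        qalys[: min(d, H)] -= ae_dis / d
    else:
        qalys[0] -= ae_dis

    lys = (pf + prog) * c / 12.0
    return CEOutcome(
        econ.name,
        float(disc @ costs),
        float(disc @ qalys),
        float(disc @ lys),
    )


def _strongly_dominated(outcomes: list[CEOutcome]) -> set[str]:
    out = set()
    for a in outcomes:
        for b in outcomes:
            if a is b:
                continue
            if (
                b.total_cost <= a.total_cost
                and b.total_qalys >= a.total_qalys
                and (b.total_cost < a.total_cost or b.total_qalys > a.total_qalys)
            ):
                out.add(a.strategy)
                break
    return out


def incremental_analysis(outcomes: list[CEOutcome]) -> CEResult:
    """Dominance and ICER analysis across strategies.

    Strategies are sorted by total cost.  The cheapest is the referent.
    Strongly dominated strategies (>= cost and <= QALYs versus some other,
    at least one strict) are excluded; extended dominance is then removed
    iteratively so ICERs strictly increase along the frontier.  Each
    non-referent row reports incremental cost/QALYs versus the previous
    non-dominated strategy; only frontier rows carry an ICER.
    """
    if len(outcomes) < 2:
        raise InvalidInputError("need at least two strategies to compare")
    names = [o.strategy for o in outcomes]
    if len(set(names)) != len(names):
        raise InvalidInputError("strategy names must be distinct")

    order = sorted(outcomes, key=lambda o: (o.total_cost, o.total_qalys))
    strong = _strongly_dominated(order)

    # identical (cost, QALY) pairs: kept, flagged, mutual ICER undefined
    tied: set[str] = set()
    for a in order:
        for b in order:
            if (
                a is not b
                and math.isclose(a.total_cost, b.total_cost, abs_tol=1e-9)
                and math.isclose(a.total_qalys, b.total_qalys, abs_tol=1e-12)
            ):
                tied.add(a.strategy)

    frontier = [o for o in order if o.strategy not in strong]
    extended: set[str] = set()
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        icers = []
        for i in range(1, len(frontier)):
            dq = frontier[i].total_qalys - frontier[i - 1].total_qalys
            dc = frontier[i].total_cost - frontier[i - 1].total_cost
            icers.append(dc / dq if dq > 0 else math.inf)
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                extended.add(frontier[i + 1].strategy)
                frontier.pop(i + 1)
                changed = True
                break

    frontier_names = [o.strategy for o in frontier]
    rows: list[CERow] = []
    prev_frontier: CEOutcome | None = None
    for i, o in enumerate(order):
        if i == 0:
            status = "referent"
        elif o.strategy in strong:
            status = "strongly-dominated"
        elif o.strategy in extended:
            status = "extended-dominated"
        else:
            status = "on-frontier"
        note = "tied" if o.strategy in tied else ""
        if prev_frontier is None:
            rows.append(
                CERow(
                    o.strategy, o.total_cost, o.total_qalys, o.total_lys,
                    None, None, None, status, note,
                )
            )
        else:
            dc = o.total_cost - prev_frontier.total_cost
            dq = o.total_qalys - prev_frontier.total_qalys
            icer = None
            if status in ("referent", "on-frontier"):
                icer = dc / dq if abs(dq) > 0 else None
                if icer is None:
                    note = (note + " tied-icer-undefined").strip()
            rows.append(
                CERow(
                    o.strategy, o.total_cost, o.total_qalys, o.total_lys,
                    dc, dq, icer, status, note,
                )
            )
        if o.strategy in frontier_names:
            prev_frontier = o
    return CEResult(tuple(order), tuple(rows))


def net_monetary_benefit(outcome: CEOutcome, wtp: float) -> float:
    """Net monetary benefit ``wtp * QALYs - cost``."""
    if wtp < 0:
        raise InvalidInputError("willingness-to-pay must be >= 0")
    return wtp * outcome.total_qalys - outcome.total_cost
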