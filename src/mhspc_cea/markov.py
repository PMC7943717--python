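"""Three-state Markov cohort engine with background mortality and OS calibration.

The cohort model tracks a hypothetical cohort of newly diagnosed metastatic
hormone-sensitive prostate cancer (mHSPC) patients through three states:
progression-free (on first-line therapy), progression (castration-resistant
disease, CRPC) and death.  Cycles are monthly by default; everyone starts
progression-free.

Within a cycle, competing risks are ordered death-first: progression-free
patients die of background (all-cause) mortality with probability
``p_bg(age)``, and survivors progress with the schedule probability
``p_prog(t)``.  In the progression state, background mortality and the
disease-specific CRPC death probability combine multiplicatively as
independent risks: ``1 - (1 - p_bg) * (1 - p_crpc_death)``.

The CRPC→death probability is a single time-independent number shared by all
strategies.  It is not observed directly; it is calibrated so that the
model's overall survival (OS) matches a published OS curve in least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import CalibrationBoundaryWarning, InvalidInputError, InvariantError
from .survival import KMCurve, TransitionSchedule

__all__ = [
    "LifeTable",
    "ModelConfig",
    "CohortTrace",
    "DeathProb",
    "monthly_background_mortality",
    "run_cohort",
    "model_os_curve",
    "calibrate_crpc_death",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause mortality by single year of age.

    ``q_annual[i]`` is the probability of dying within the year for a person
    of age ``ages[i]``.  Ages must be contiguous and the final row must have
    ``q_annual = 1`` so the table closes out the oldest ages.
    """

    ages: np.ndarray
    q_annual: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        if a.ndim != 1 or a.shape != q.shape or a.size == 0:
            raise InvalidInputError("ages and q_annual must be aligned 1-d arrays")
        if np.any(np.diff(a) != 1):
            raise InvariantError("life-table ages must be contiguous")
        if np.any((q < 0) | (q > 1)):
            raise InvariantError("q_annual must lie in [0, 1]")
        if not math.isclose(q[-1], 1.0, abs_tol=1e-12):
            raise InvariantError("final life-table row must have q_annual = 1")
        object.__setattr__(self, "ages", a)
        object.__setattr__(self, "q_annual", q)

    def q_at(self, age: float) -> float:
        """Annual death probability at ``age`` (whole years, range-checked)."""
        idx = int(math.floor(age)) - int(self.ages[0])
        if idx < 0 or idx >= self.ages.size:
            raise InvalidInputError(
                f"age {age} outside life-table range "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        return float(self.q_annual[idx])


@dataclass(frozen=True)
class ModelConfig:
    """Cohort simulation settings.

    Defaults reproduce the base-case framing: 60-year-old men (70 kg, carried
    for documentation only), one-month cycles over a lifetime horizon of 480
    cycles (to age 100), outcomes discounted at 3% per year.
    """

    start_age: int = 60
    cycle_months: float = 1.0
    horizon_cycles: int = 480
    discount_annual: float = 0.03
    cohort_weight_kg: float = 70.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise InvalidInputError("horizon_cycles must be >= 1")
        if not 0.0 <= self.discount_annual < 1.0:
            raise InvalidInputError("discount_annual must lie in [0, 1)")
        if self.cycle_months <= 0:
            raise InvalidInputError("cycle_months must be positive")


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy and per-cycle entrants from a cohort run.

    ``occupancy`` has ``horizon + 1`` rows of (progression-free, progression,
    death) fractions recorded at cycle starts; ``entrants_to_progression`` and
    ``entrants_to_death`` record the fraction making each transition during
    cycle ``t``.
    """

    occupancy: np.ndarray
    entrants_to_progression: np.ndarray
    entrants_to_death: np.ndarray
    cycle_months: float = 1.0
    strategy: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise InvalidInputError("occupancy must be (cycles+1, 3)")
        if np.any((occ < -1e-12) | (occ > 1 + 1e-12)):
            raise InvariantError("occupancy fractions must lie in [0, 1]")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-12):
            raise InvariantError("occupancy rows must sum to 1 within 1e-12")
        if np.any(np.diff(occ[:, 2]) < -1e-12):
            raise InvariantError("death occupancy must be non-decreasing")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(
            self,
            "entrants_to_progression",
            np.asarray(self.entrants_to_progression, dtype=float),
        )
        object.__setattr__(
            self,
            "entrants_to_death",
            np.asarray(self.entrants_to_death, dtype=float),
        )

    @property
    def horizon(self) -> int:
        return int(self.occupancy.shape[0] - 1)


@dataclass(frozen=True)
class DeathProb:
    """The calibrated monthly CRPC→death probability."""

    p_crpc_death_monthly: float
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_crpc_death_monthly <= 1.0:
            raise InvariantError("p_crpc_death_monthly must lie in [0, 1]")


def monthly_background_mortality(table: LifeTable, age: float) -> float:
    """Monthly all-cause death probability: ``1 - (1 - q_annual)^(1/12)``."""
    q = table.q_at(age)
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)


def _background_path(table: LifeTable, config: ModelConfig) -> np.ndarray:
    """Monthly background mortality for each cycle; ages past the table's
    last row are absorbed by the closure row."""
    max_age = int(table.ages[-1])
    p = np.empty(config.horizon_cycles)
    for t in range(config.horizon_cycles):
        age = config.start_age + int(math.floor(t * config.cycle_months / 12.0))
        p[t] = monthly_background_mortality(table, min(age, max_age))
    return p


def run_cohort(
    schedule: TransitionSchedule,
    death: DeathProb,
    table: LifeTable,
    config: ModelConfig,
    strategy: str = "",
) -> CohortTrace:
    """Run the three-state cohort recursion over the model horizon.

    The whole cohort starts progression-free.  See the module docstring for
    the within-cycle transition ordering.
    """
    H = config.horizon_cycles
    if len(schedule) < H:
        raise InvalidInputError(
            f"schedule covers {len(schedule)} cycles but horizon is {H}"
        )
    p_bg = _background_path(table, config)
    p_prog = schedule.probs[:H]
    p_crpc = death.p_crpc_death_monthly

    occ = np.zeros((H + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    new_prog = np.zeros(H)
    new_death = np.zeros(H)
    pf, prog, dead = 1.0, 0.0, 0.0
    for t in range(H):
        p_death_prog = 1.0 - (1.0 - p_bg[t]) * (1.0 - p_crpc)
        d_pf = pf * p_bg[t]
        entering = pf * (1.0 - p_bg[t]) * p_prog[t]
        d_prog = prog * p_death_prog
        pf = pf * (1.0 - p_bg[t]) * (1.0 - p_prog[t])
        prog = prog - d_prog + entering
        dead = dead + d_pf + d_prog
        new_prog[t] = entering
        new_death[t] = d_pf + d_prog
        occ[t + 1] = (pf, prog, dead)
    return CohortTrace(occ, new_prog, new_death, config.cycle_months, strategy)


def model_os_curve(trace: CohortTrace) -> KMCurve:
    """Model-predicted overall survival: fraction alive at each cycle start."""
    surv = 1.0 - trace.occupancy[:, 2]
    times = np.arange(trace.horizon + 1, dtype=float) * trace.cycle_months
    return KMCurve("OS", trace.strategy, times, np.minimum.accumulate(surv))


def _os_grid(
    schedule: TransitionSchedule,
    table: LifeTable,
    config: ModelConfig,
    p_grid: np.ndarray,
    cycles: np.ndarray,
) -> np.ndarray:
    """Model OS at the requested cycles for every candidate p_crpc_death.

    The progression-free trajectory does not depend on the CRPC death
    probability, so it is computed once and the progression-state recursion
    is vectorised across the candidate grid.
    """
    H = config.horizon_cycles
    p_bg = _background_path(table, config)
    p_prog = schedule.probs[:H]

    pf = np.empty(H + 1)
    pf[0] = 1.0
    entering = np.empty(H)
    for t in range(H):
        entering[t] = pf[t] * (1.0 - p_bg[t]) * p_prog[t]
        pf[t + 1] = pf[t] * (1.0 - p_bg[t]) * (1.0 - p_prog[t])

    prog = np.zeros(p_grid.size)
    dead = np.zeros(p_grid.size)
    want = np.zeros((cycles.size, p_grid.size))
    lookup = {int(c): i for i, c in enumerate(cycles)}
    if 0 in lookup:
        want[lookup[0]] = 1.0
    for t in range(H):
        p_death_prog = 1.0 - (1.0 - p_bg[t]) * (1.0 - p_grid)
        d_prog = prog * p_death_prog
        dead = dead + pf[t] * p_bg[t] + d_prog
        prog = prog - d_prog + entering[t]
        if (t + 1) in lookup:
            want[lookup[t + 1]] = 1.0 - dead
    return want


def calibrate_crpc_death(
    schedule: TransitionSchedule,
    table: LifeTable,
    config: ModelConfig,
    target_os: KMCurve,
    grid_step: float = 1e-3,
    tol: float = 1e-6,
) -> DeathProb:
    """Calibrate the monthly CRPC→death probability to a published OS curve.

    Minimises the sum of squared differences between model OS and the target
    OS at the target's digitized time points.  A grid scan (default step
    1e-3) over [0, 1] locates the global basin; a bounded scalar minimisation
    then refines to ``tol``.  If the optimum sits on a boundary a
    :class:`CalibrationBoundaryWarning` is issued and the boundary value
    returned.
    """
    if target_os.times.max() < 12.0:
        raise InvalidInputError("target OS curve must cover at least 12 months")
    cyc = np.rint(target_os.times / config.cycle_months).astype(int)
    keep = (cyc >= 0) & (cyc <= config.horizon_cycles)
    cyc = cyc[keep]
    target = target_os.survival[keep]
    cyc_u, first = np.unique(cyc, return_index=True)
    target_u = target[first]

    p_grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    os_grid = _os_grid(schedule, table, config, p_grid, cyc_u)
    sse = np.sum((os_grid - target_u[:, None]) ** 2, axis=0)
    i_best = int(np.argmin(sse))
    p0 = float(p_grid[i_best])

    def sse_scalar(p: float) -> float:
        col = _os_grid(schedule, table, config, np.array([p]), cyc_u)[:, 0]
        return float(np.sum((col - target_u) ** 2))

    lo = max(0.0, p0 - grid_step)
    hi = min(1.0, p0 + grid_step)
    res = optimize.minimize_scalar(
        sse_scalar, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    p_hat = float(res.x) if res.fun <= sse[i_best] else p0

    if p_hat <= 0.5 * grid_step and i_best == 0:
        warnings.warn(
            "calibration optimum at lower boundary p = 0",
            CalibrationBoundaryWarning,
        )
        return DeathProb(0.0, at_boundary=True)
    if p_hat >= 1.0 - 0.5 * grid_step and i_best == p_grid.size - 1:
        warnings.warn(
            "calibration optimum at upper boundary p = 1 "
            "(target OS falls faster than the model can)",
            CalibrationBoundaryWarning,
        )
        return DeathProb(1.0, at_boundary=True)
    return DeathProb(p_hat)
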