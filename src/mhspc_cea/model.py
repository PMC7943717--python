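"""The end-to-end cost-effectiveness model and its fitted results.

:class:`MarkovCEModel` bundles the study inputs — digitized PFS curves per
strategy, an overall-survival calibration target, a life table, strategy
economics and the cohort configuration.  :meth:`MarkovCEModel.fit` runs

1. pseudo-IPD reconstruction and parametric survival fitting (AIC-selected
   family) per strategy,
2. calibration of the shared CRPC→death monthly probability to the OS
   target,
3. the lifetime cohort simulation and discounted cost/QALY accumulation per
   strategy, and
4. the incremental/dominance (ICER) analysis,

returning a :class:`MarkovCEResults` that carries the fits, the calibrated
probability, cohort traces, totals and the cost-effectiveness table, and
from which the sensitivity analyses (tornado, threshold, PSA/CEAC) are run.

Example
-------
>>> from mhspc_cea import MarkovCEModel, default_scenario
>>> res = MarkovCEModel.from_scenario(default_scenario(seed=1)).fit()
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import io as _io
from .economics import (
    CEOutcome,
    CEResult,
    StrategyEconomics,
    accumulate,
    incremental_analysis,
    net_monetary_benefit,
)
from .exceptions import InvalidInputError, ParamSpecError
from .markov import (
    CohortTrace,
    DeathProb,
    LifeTable,
    ModelConfig,
    calibrate_crpc_death,
    run_cohort,
)
from .sensitivity import (
    CEAC,
    ParamSpec,
    PSAResult,
    ThresholdResult,
    TornadoEntry,
    compute_ceac,
    one_way_tornado,
    run_psa,
    two_way_threshold,
)
from .survival import (
    FAMILIES,
    KMCurve,
    ParametricFit,
    TransitionSchedule,
    fit_family,
    fit_from_median,
    reconstruct_pseudo_ipd,
    select_by_aic,
    survival_to_schedule,
)

__all__ = ["MarkovCEModel", "MarkovCEResults", "default_sensitivity_params"]


class MarkovCEModel:
    """Three-state Markov cost-effectiveness model for first-line mHSPC.

    Parameters
    ----------
    pfs_curves : mapping strategy -> KMCurve
        Digitized progression-free survival curves, one per strategy.
    strategies : mapping strategy -> StrategyEconomics
        Cost/utility parameters; keys must match ``pfs_curves``.
    life_table : LifeTable
        Annual background all-cause mortality.
    os_target : KMCurve
        Published overall-survival curve used to calibrate the CRPC→death
        probability (by default the curve's own strategy, normally the ADT
        referent, provides the progression schedule during calibration).
    config : ModelConfig, optional
    wtp : float
        Willingness-to-pay threshold in US$ per QALY (default 100,000).
    """

    def __init__(
        self,
        pfs_curves: Mapping[str, KMCurve],
        strategies: Mapping[str, StrategyEconomics],
        life_table: LifeTable,
        os_target: KMCurve,
        config: ModelConfig | None = None,
        wtp: float = 100_000.0,
        calibration_strategy: str | None = None,
    ) -> None:
        if set(pfs_curves) != set(strategies):
            raise InvalidInputError(
                "pfs_curves and strategies must cover the same strategy names"
            )
        self.pfs_curves = dict(pfs_curves)
        self.strategies = dict(strategies)
        self.life_table = life_table
        self.os_target = os_target
        self.config = config or ModelConfig()
        self.wtp = float(wtp)
        if calibration_strategy is None:
            calibration_strategy = (
                os_target.strategy
                if os_target.strategy in self.strategies
                else next(iter(self.strategies))
            )
        if calibration_strategy not in self.strategies:
            raise InvalidInputError(
                f"calibration strategy {calibration_strategy!r} unknown"
            )
        self.calibration_strategy = calibration_strategy

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_scenario(cls, scenario, config: ModelConfig | None = None,
                      wtp: float = 100_000.0) -> "MarkovCEModel":
        """Build the model from a :class:`~mhspc_cea.synthetic.SyntheticScenario`."""
        from .synthetic import gen_km_curve, gen_life_table, gen_parameter_set

        curves = {s: gen_km_curve(scenario, s, "PFS") for s in scenario.names}
        return cls(
            curves,
            gen_parameter_set(scenario),
            gen_life_table(scenario),
            gen_km_curve(scenario, scenario.referent, "OS"),
            config=config,
            wtp=wtp,
            calibration_strategy=scenario.referent,
        )

    @classmethod
    def from_files(
        cls,
        km_paths: Mapping[str, str],
        params_path: str,
        life_table_path: str,
        os_target_path: str,
        os_target_strategy: str | None = None,
        config: ModelConfig | None = None,
        wtp: float = 100_000.0,
    ) -> "MarkovCEModel":
        """Build the model from CSV/YAML inputs on disk."""
        strategies = _io.read_params(params_path)
        curves = {
            name: _io.read_km_csv(p, endpoint="PFS", strategy=name)
            for name, p in km_paths.items()
        }
        if os_target_strategy is None:
            os_target_strategy = next(iter(strategies))
        os_target = _io.read_km_csv(
            os_target_path, endpoint="OS", strategy=os_target_strategy
        )
        return cls(
            curves,
            strategies,
            _io.read_life_table_csv(life_table_path),
            os_target,
            config=config,
            wtp=wtp,
        )

    # -- estimation -------------------------------------------------------

    def fit(
        self,
        target_n: int = 1000,
        families: Sequence[str] = FAMILIES,
        calibration_grid_step: float = 1e-3,
    ) -> "MarkovCEResults":
        """Run the full estimation pipeline and return the fitted results."""
        fits_by_family: dict[str, dict[str, ParametricFit]] = {}
        fits: dict[str, ParametricFit] = {}
        for name, curve in self.pfs_curves.items():
            ipd = reconstruct_pseudo_ipd(curve, target_n)
            byfam = {fam: fit_family(ipd, fam) for fam in families}
            fits_by_family[name] = byfam
            fits[name] = select_by_aic(list(byfam.values()))

        schedules = {
            name: survival_to_schedule(
                fit, self.config.horizon_cycles, self.config.cycle_months
            )
            for name, fit in fits.items()
        }
        death = calibrate_crpc_death(
            schedules[self.calibration_strategy],
            self.life_table,
            self.config,
            self.os_target,
            grid_step=calibration_grid_step,
        )
        traces = {
            name: run_cohort(sched, death, self.life_table, self.config, name)
            for name, sched in schedules.items()
        }
        outcomes = [
            accumulate(self.strategies[name], traces[name], self.config)
            for name in self.strategies
        ]
        ce = incremental_analysis(outcomes)
        return MarkovCEResults(
            model=self,
            fits=fits,
            fits_by_family=fits_by_family,
            schedules=schedules,
            death_prob=death,
            traces=traces,
            ce=ce,
        )


@dataclass
class MarkovCEResults:
    """Fitted pipeline state: estimates, calibration, traces and CE table."""

    model: MarkovCEModel
    fits: dict[str, ParametricFit]
    fits_by_family: dict[str, dict[str, ParametricFit]]
    schedules: dict[str, TransitionSchedule]
    death_prob: DeathProb
    traces: dict[str, CohortTrace]
    ce: CEResult

    @property
    def outcomes(self) -> tuple[CEOutcome, ...]:
        return self.ce.outcomes

    def median_pfs(self, strategy: str) -> float:
        return self.fits[strategy].median()

    def nmb(self, strategy: str, wtp: float | None = None) -> float:
        return net_monetary_benefit(
            self.ce.outcome(strategy), self.model.wtp if wtp is None else wtp
        )

    def optimal_strategy(self, wtp: float | None = None) -> str:
        """Strategy with the highest net monetary benefit at the WTP."""
        w = self.model.wtp if wtp is None else wtp
        return max(
            (o.strategy for o in self.ce.outcomes),
            key=lambda s: net_monetary_benefit(self.ce.outcome(s), w),
        )

    # -- re-evaluation under parameter overrides --------------------------

    def _shifted_fit(self, strategy: str, median: float) -> ParametricFit:
        """The strategy's selected fit rescaled in time to the given median.

        For a log-normal fit this is exactly ``fit_from_median`` (location
        shifted, σ preserved); Weibull and exponential fits are rescaled
        analogously (shape preserved), so an override equal to the current
        median reproduces the base schedule for any selected family.
        """
        fit = self.fits[strategy]
        if fit.family == "lognormal":
            return fit_from_median(median, fit)
        if median <= 0:
            raise ParamSpecError(f"median override for {strategy} must be > 0")
        if fit.family == "weibull":
            k = fit.params["shape"]
            scale = median / math.log(2.0) ** (1.0 / k)
            return ParametricFit("weibull", {"shape": k, "scale": scale},
                                 float("nan"), 2)
        return ParametricFit(
            "exponential", {"rate": math.log(2.0) / median}, float("nan"), 1
        )

    def evaluate(
        self,
        overrides: Mapping[str, float] | None = None,
        recalibrate: bool = True,
        calibration_grid_step: float = 1e-3,
    ) -> CEResult:
        """Re-run simulation + economics with parameter overrides.

        Override paths:

        * ``strategies.<name>.<field>`` — any StrategyEconomics field;
        * ``median_pfs.<name>`` — shifts that strategy's log-normal fit to
          the given median (σ preserved) and rebuilds its schedule;
        * ``p_crpc_death`` — fixes the CRPC→death monthly probability;
        * ``config.<field>`` — ModelConfig field (e.g. discount_annual).

        Calibration is redone when the calibration strategy's schedule or
        the configuration changed (unless ``p_crpc_death`` is overridden or
        ``recalibrate`` is off).
        """
        overrides = dict(overrides or {})
        model = self.model
        strategies = dict(model.strategies)
        schedules = dict(self.schedules)
        config = model.config
        death = self.death_prob
        p_fixed = False
        config_changed = False
        touched_calib = False

        for path, value in overrides.items():
            parts = path.split(".")
            if parts[0] == "strategies" and len(parts) == 3:
                name, fld = parts[1], parts[2]
                if name not in strategies:
                    raise ParamSpecError(f"unknown strategy in target {path!r}")
                if fld == "drug_duration_cycles" and value is not None:
                    value = int(round(value))
                strategies[name] = strategies[name].with_override(fld, value)
            elif parts[0] == "median_pfs" and len(parts) == 2:
                name = parts[1]
                if name not in schedules:
                    raise ParamSpecError(f"unknown strategy in target {path!r}")
                shifted = self._shifted_fit(name, value)
                schedules[name] = survival_to_schedule(
                    shifted, config.horizon_cycles, config.cycle_months
                )
                if name == model.calibration_strategy:
                    touched_calib = True
            elif path == "p_crpc_death":
                death = DeathProb(float(value))
                p_fixed = True
            elif parts[0] == "config" and len(parts) == 2:
                config = replace(config, **{parts[1]: value})
                config_changed = True
            else:
                raise ParamSpecError(f"unrecognised override target {path!r}")

        if config_changed:
            schedules = {
                name: survival_to_schedule(
                    self.fits[name], config.horizon_cycles, config.cycle_months
                )
                for name in schedules
            }
            # re-apply median overrides on the new grid
            for path, value in overrides.items():
                if path.startswith("median_pfs."):
                    name = path.split(".", 1)[1]
                    schedules[name] = survival_to_schedule(
                        self._shifted_fit(name, value),
                        config.horizon_cycles, config.cycle_months,
                    )

        if recalibrate and not p_fixed and (touched_calib or config_changed):
            death = calibrate_crpc_death(
                schedules[model.calibration_strategy],
                model.life_table,
                config,
                model.os_target,
                grid_step=calibration_grid_step,
            )

        outcomes = []
        for name, econ in strategies.items():
            trace = run_cohort(
                schedules[name], death, model.life_table, config, name
            )
            outcomes.append(accumulate(econ, trace, config))
        return incremental_analysis(outcomes)

    # -- sensitivity analyses ---------------------------------------------

    def tornado(
        self,
        params: Sequence[ParamSpec],
        comparison: tuple[str, str],
        calibration_grid_step: float = 1e-2,
    ) -> list[TornadoEntry]:
        return one_way_tornado(
            params,
            lambda ov: self.evaluate(
                ov, calibration_grid_step=calibration_grid_step
            ),
            comparison,
        )

    def threshold(
        self,
        drug_cost_target: str,
        comparison: tuple[str, str],
        wtp: float | None = None,
        bracket: tuple[float, float] = (0.0, 20000.0),
        efficacy_target: str | None = None,
        efficacy_value: float | None = None,
        calibration_grid_step: float = 1e-2,
    ) -> ThresholdResult:
        return two_way_threshold(
            lambda ov: self.evaluate(
                ov, calibration_grid_step=calibration_grid_step
            ),
            drug_cost_target,
            self.model.wtp if wtp is None else wtp,
            comparison,
            bracket=bracket,
            efficacy_target=efficacy_target,
            efficacy_value=efficacy_value,
        )

    def psa(
        self,
        params: Sequence[ParamSpec],
        n_iter: int = 1000,
        seed: int = 0,
        calibration_grid_step: float = 1e-2,
    ) -> PSAResult:
        return run_psa(
            lambda ov: self.evaluate(
                ov, calibration_grid_step=calibration_grid_step
            ),
            params,
            list(self.model.strategies),
            n_iter=n_iter,
            seed=seed,
        )

    def ceac(
        self,
        psa: PSAResult,
        wtp_grid: Sequence[float] | None = None,
    ) -> CEAC:
        if wtp_grid is None:
            wtp_grid = np.arange(0.0, 200_001.0, 10_000.0)
        return compute_ceac(psa, wtp_grid)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable report of fits, calibration and the CE table."""
        cfg = self.model.config
        lines = [
            "Markov cohort cost-effectiveness model (mHSPC first-line therapy)",
            "=" * 68,
            f"Cohort: start age {cfg.start_age}, {cfg.horizon_cycles} cycles of "
            f"{cfg.cycle_months:g} month(s), discount "
            f"{cfg.discount_annual:.1%}/year, WTP ${self.model.wtp:,.0f}/QALY",
            f"Calibrated p(CRPC->death) = "
            f"{self.death_prob.p_crpc_death_monthly:.5f} per cycle "
            f"(target: {self.model.calibration_strategy} OS"
            + (", boundary)" if self.death_prob.at_boundary else ")"),
            "",
            "Survival fits (AIC-selected):",
        ]
        for name, fit in self.fits.items():
            pstr = ", ".join(f"{k}={v:.4g}" for k, v in fit.params.items())
            lines.append(
                f"  {name:<10s} {fit.family:<11s} median PFS "
                f"{fit.median():6.1f} mo   ({pstr}; AIC {fit.aic:,.1f})"
            )
        lines += ["", "Cost-effectiveness table (cost-ordered):"]
        df = self.ce.to_dataframe()
        with np.printoptions():
            txt = df.to_string(
                index=False,
                float_format=lambda x: f"{x:,.2f}",
                na_rep="—",
            )
        lines.append(txt)
        best = self.optimal_strategy()
        lines += [
            "",
            f"Highest net monetary benefit at WTP "
            f"${self.model.wtp:,.0f}/QALY: {best}",
        ]
        return "\n".join(lines)


def default_sensitivity_params(
    results: MarkovCEResults,
    spread: float = 0.2,
    strategies: Sequence[str] | None = None,
) -> list[ParamSpec]:
    """A conventional one-way/PSA parameter set: ±``spread`` around base.

    Covers per-strategy monthly drug cost (gamma), median PFS (log-normal),
    on-treatment utility (beta), CRPC monthly cost (gamma) and the
    calibrated CRPC→death probability (beta).
    """
    out: list[ParamSpec] = []
    names = strategies or list(results.model.strategies)

    def rng(base: float) -> tuple[float, float]:
        return base * (1 - spread), base * (1 + spread)

    for name in names:
        econ = results.model.strategies[name]
        if econ.drug_cost_pf_monthly > 0:
            lo, hi = rng(econ.drug_cost_pf_monthly)
            out.append(
                ParamSpec(
                    f"drug_cost[{name}]", econ.drug_cost_pf_monthly, lo, hi,
                    "gamma", f"strategies.{name}.drug_cost_pf_monthly",
                )
            )
        med = results.median_pfs(name)
        lo, hi = rng(med)
        out.append(
            ParamSpec(
                f"median_pfs[{name}]", med, lo, hi, "lognormal",
                f"median_pfs.{name}",
            )
        )
        u = econ.utility_on_treatment
        lo, hi = max(0.0, u * (1 - spread)), min(1.0, u * (1 + spread))
        out.append(
            ParamSpec(
                f"utility[{name}]", u, lo, hi, "beta",
                f"strategies.{name}.utility_on_treatment",
            )
        )
        lo, hi = rng(econ.crpc_cost_monthly)
        out.append(
            ParamSpec(
                f"crpc_cost[{name}]", econ.crpc_cost_monthly, lo, hi,
                "gamma", f"strategies.{name}.crpc_cost_monthly",
            )
        )
    p = results.death_prob.p_crpc_death_monthly
    if 0 < p < 1:
        lo, hi = max(0.0, p * (1 - spread)), min(1.0, p * (1 + spread))
        out.append(ParamSpec("p_crpc_death", p, lo, hi, "beta", "p_crpc_death"))
    return out
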