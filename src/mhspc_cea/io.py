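"""Readers and writers for the pipeline's plain-text interchange formats.

* KM curve CSV: columns ``time_months, survival`` (optional ``n_at_risk``).
* Life table CSV: columns ``age, q_annual``.
* Strategy parameter file: YAML (or JSON) with one entry per strategy.
* Results CSV: the incremental cost-effectiveness table.
* CEAC CSV: WTP grid plus one probability column per strategy.

Every reader/writer pair round-trips losslessly; malformed files raise
:class:`ValidationError` naming the field and (1-based data) row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .economics import (
    AdverseEvent,
    AdverseEventProfile,
    CEResult,
    StrategyEconomics,
)
from .exceptions import ValidationError
from .markov import CohortTrace, LifeTable
from .sensitivity import CEAC
from .survival import KMCurve, ParametricFit

__all__ = [
    "read_km_csv",
    "write_km_csv",
    "read_life_table_csv",
    "write_life_table_csv",
    "read_params",
    "write_params",
    "write_results",
    "write_ceac",
    "write_trace",
    "write_fit_json",
    "read_fit_json",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_km_csv(path, endpoint: str = "PFS", strategy: str = "") -> KMCurve:
    df = pd.read_csv(path)
    _require_columns(df, ["time_months", "survival"], path)
    t = df["time_months"].to_numpy(dtype=float)
    s = df["survival"].to_numpy(dtype=float)
    # +3: diff index i flags data row i+1, plus header line and 1-based count
    bad = np.where(np.diff(s) > 1e-12)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: survival increases at row {bad[0] + 3}"
        )
    bad = np.where(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: time_months not strictly increasing at row {bad[0] + 3}"
        )
    if np.any((s < 0) | (s > 1)):
        row = int(np.argmax((s < 0) | (s > 1))) + 2
        raise ValidationError(f"{path}: survival outside [0, 1] at row {row}")
    risk = None
    if "n_at_risk" in df.columns:
        risk = df["n_at_risk"].to_numpy(dtype=float)
    return KMCurve(endpoint, strategy, t, s, risk)


def write_km_csv(curve: KMCurve, path) -> None:
    data = {"time_months": curve.times, "survival": curve.survival}
    if curve.n_at_risk is not None:
        data["n_at_risk"] = curve.n_at_risk
    pd.DataFrame(data).to_csv(path, index=False)


def read_life_table_csv(path) -> LifeTable:
    df = pd.read_csv(path)
    _require_columns(df, ["age", "q_annual"], path)
    q = df["q_annual"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1)):
        row = int(np.argmax((q < 0) | (q > 1))) + 2
        raise ValidationError(f"{path}: q_annual outside [0, 1] at row {row}")
    return LifeTable(df["age"].to_numpy(dtype=int), q)


def write_life_table_csv(table: LifeTable, path) -> None:
    pd.DataFrame({"age": table.ages, "q_annual": table.q_annual}).to_csv(
        path, index=False
    )


def _econ_to_dict(e: StrategyEconomics) -> dict:
    return {
        "name": e.name,
        "drug_cost_pf_monthly": e.drug_cost_pf_monthly,
        "drug_duration_cycles": e.drug_duration_cycles,
        "adt_cost_monthly": e.adt_cost_monthly,
        "admin_cost_per_cycle": e.admin_cost_per_cycle,
        "utility_on_treatment": e.utility_on_treatment,
        "utility_pf_post_treatment": e.utility_pf_post_treatment,
        "utility_progression": e.utility_progression,
        "crpc_cost_monthly": e.crpc_cost_monthly,
        "death_cost_terminal": e.death_cost_terminal,
        "subsequent_therapy_proportion": e.subsequent_therapy_proportion,
        "adverse_events": [
            {
                "name": a.name,
                "rate": a.rate,
                "cost": a.cost,
                "disutility": a.disutility,
            }
            for a in e.ae_profile.events
        ],
    }


def _econ_from_dict(d: dict, path) -> StrategyEconomics:
    try:
        aes = tuple(
            AdverseEvent(a["name"], a["rate"], a["cost"], a["disutility"])
            for a in d.get("adverse_events", [])
        )
        return StrategyEconomics(
            name=d["name"],
            drug_cost_pf_monthly=d["drug_cost_pf_monthly"],
            drug_duration_cycles=d["drug_duration_cycles"],
            adt_cost_monthly=d["adt_cost_monthly"],
            admin_cost_per_cycle=d["admin_cost_per_cycle"],
            ae_profile=AdverseEventProfile(aes),
            utility_on_treatment=d["utility_on_treatment"],
            utility_pf_post_treatment=d["utility_pf_post_treatment"],
            utility_progression=d["utility_progression"],
            crpc_cost_monthly=d["crpc_cost_monthly"],
            death_cost_terminal=d["death_cost_terminal"],
            subsequent_therapy_proportion=d.get(
                "subsequent_therapy_proportion", 0.0
            ),
        )
    except KeyError as exc:
        raise ValidationError(
            f"{path}: strategy {d.get('name', '?')!r} missing field {exc}"
        ) from exc


def read_params(path) -> dict[str, StrategyEconomics]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(doc, dict) or "strategies" not in doc:
        raise ValidationError(f"{path}: expected a top-level 'strategies' list")
    return {
        d["name"]: _econ_from_dict(d, path) for d in doc["strategies"]
    }


def write_params(strategies: Mapping[str, StrategyEconomics], path) -> None:
    path = Path(path)
    doc = {"strategies": [_econ_to_dict(e) for e in strategies.values()]}
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def write_results(result: CEResult, path) -> None:
    df = result.to_dataframe()
    df.to_csv(path, index=False, float_format="%.6f")


def write_ceac(ceac: CEAC, path) -> None:
    ceac.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def write_trace(trace: CohortTrace, path) -> None:
    H = trace.horizon
    pd.DataFrame(
        {
            "cycle": np.arange(H),
            "pf": trace.occupancy[:H, 0],
            "prog": trace.occupancy[:H, 1],
            "death": trace.occupancy[:H, 2],
            "new_prog": trace.entrants_to_progression,
            "new_death": trace.entrants_to_death,
        }
    ).to_csv(path, index=False)


def write_fit_json(fits: Mapping[str, ParametricFit], path) -> None:
    doc = {
        name: {
            "family": f.family,
            "params": f.params,
            "loglik": f.loglik,
            "aic": f.aic,
        }
        for name, f in fits.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)


def read_fit_json(path) -> dict[str, ParametricFit]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    out = {}
    for name, d in doc.items():
        n_params = 1 if d["family"] == "exponential" else 2
        out[name] = ParametricFit(d["family"], d["params"], d["loglik"], n_params)
    return out
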