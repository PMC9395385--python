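"""Rank-based overall performance index across operating conditions.

Each operating condition (pressure, temperature, water-in-ethanol) carries
three criteria: solubility of the solute in CO2 (higher is better), annual
operational cost (lower is better) and the chemical safety total score
(lower is better — CSTS measures hazard). Each criterion column is converted
to a rank index on 1..n with n awarded to the best condition and ties
sharing the mean of their rank positions; the overall index is the
unweighted sum

    I_performance = I_solubility + I_cost + I_safety

and the condition maximising it is selected. Rank indices are invariant to
any strictly monotone transform of a criterion column, so the selection
depends only on orderings, never on criterion units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import MissingDataError

__all__ = [
    "ConditionRecord",
    "PerformanceTable",
    "rank_index",
    "overall_performance",
    "compare_with_rsm",
]


@dataclass(frozen=True)
class ConditionRecord:
    """One operating condition with its three criterion values."""

    condition: tuple[float, float, float]  # (P MPa, T degC, water % v/v)
    solubility: float | None
    oc: float | None
    csts: float | None


def rank_index(
    values: Sequence[float], direction: str = "higher_better"
) -> np.ndarray:
    """Rank a criterion column onto 1..n with n = best.

    ``direction="higher_better"`` awards n to the largest value,
    ``"lower_better"`` to the smallest. Ties share the mean of their rank
    positions (so each column sums to n(n+1)/2 regardless of ties).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot rank an empty list")
    if not np.all(np.isfinite(vals)):
        raise ValueError("rank_index requires finite values")
    if direction == "higher_better":
        return rankdata(vals, method="average")
    if direction == "lower_better":
        return rankdata(-vals, method="average")
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class PerformanceTable:
    """Per-condition rank indices, the overall index and the selected best."""

    table: pd.DataFrame  # columns: pressure, temperature, water_pct, solubility,
    #          oc, csts, i_solubility, i_cost, i_safety, i_performance
    best_condition: tuple[float, float, float]

    def as_dict(self) -> dict:
        return {
            "best_condition": {
                "pressure_mpa": self.best_condition[0],
                "temperature_c": self.best_condition[1],
                "water_pct": self.best_condition[2],
            },
            "conditions": self.table.to_dict(orient="records"),
        }


def overall_performance(records: Sequence[ConditionRecord]) -> PerformanceTable:
    """Rank conditions on all three criteria and select the best.

    Ties on I_performance are broken by higher I_solubility, then lower
    operational cost.
    """
    if len(records) == 0:
        raise ValueError("need at least one condition record")
    for r in records:
        missing = [
            name
            for name, v in (("solubility", r.solubility), ("oc", r.oc), ("csts", r.csts))
            if v is None or not np.isfinite(v)
        ]
        if missing:
            raise MissingDataError(
                f"condition {r.condition}: missing {', '.join(missing)}"
            )
    sol = np.array([r.solubility for r in records], dtype=float)
    oc = np.array([r.oc for r in records], dtype=float)
    cs = np.array([r.csts for r in records], dtype=float)
    i_sol = rank_index(sol, "higher_better")
    i_cost = rank_index(oc, "lower_better")
    i_safety = rank_index(cs, "lower_better")
    i_perf = i_sol + i_cost + i_safety

    # argmax with deterministic tie-break: i_performance, then i_solubility,
    # then lower cost
    order = sorted(
        range(len(records)),
        key=lambda k: (-i_perf[k], -i_sol[k], oc[k]),
    )
    best = records[order[0]].condition

    table = pd.DataFrame(
        {
            "pressure_mpa": [r.condition[0] for r in records],
            "temperature_c": [r.condition[1] for r in records],
            "water_pct": [r.condition[2] for r in records],
            "solubility": sol,
            "oc": oc,
            "csts": cs,
            "i_solubility": i_sol,
            "i_cost": i_cost,
            "i_safety": i_safety,
            "i_performance": i_perf,
        }
    )
    return PerformanceTable(table=table, best_condition=best)


def compare_with_rsm(
    perf: PerformanceTable,
    rsm_optimum: Sequence[float],
    fitted,
    factors,
) -> dict:
    """Side-by-side comparison of the index-selected and RSM-optimal points.

    Both conditions are evaluated with the same fitted solubility model, so
    the comparison isolates the choice of operating point from model error.
    """
    from .rsm import predict_at

    idx_cond = tuple(map(float, perf.best_condition))
    rsm_cond = tuple(map(float, rsm_optimum))
    sol_idx = predict_at(fitted, idx_cond, factors, warn_outside=False)
    sol_rsm = predict_at(fitted, rsm_cond, factors, warn_outside=False)
    return {
        "index_method": {"condition": idx_cond, "predicted_solubility": sol_idx},
        "rsm": {"condition": rsm_cond, "predicted_solubility": sol_rsm},
        "solubility_ratio_index_over_rsm": (
            sol_idx / sol_rsm if sol_rsm != 0 else float("nan")
        ),
    }
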