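"""End-to-end assessment: from design + responses to the performance table.

Glue layer that evaluates the cost model and safety score at every
operating condition of a design, attaches the measured (or model-predicted)
solubility, and runs the rank-based overall performance index. Replicated
centre runs are collapsed to a single condition with their mean solubility
by default — the index ranks operating conditions, not individual runs.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .econ import CostConfig, operational_cost
from .perfindex import ConditionRecord, PerformanceTable, overall_performance
from .safety import ComponentProperties, MixtureSpec, csts

__all__ = ["condition_records", "assess_conditions"]


def condition_records(
    frame: pd.DataFrame,
    cost_cfg: CostConfig,
    chemicals: dict[str, ComponentProperties],
    collapse_replicates: bool = True,
    activity_model: str | object = "van_laar",
    solubility_column: str = "solubility_e3",
) -> list[ConditionRecord]:
    """Build one ConditionRecord per operating condition.

    ``frame`` needs pressure_mpa, temperature_c, water_pct and the solubility
    column. With ``collapse_replicates`` (default) duplicate conditions are
    merged with their mean solubility; cost and CSTS are deterministic per
    condition so replication cannot change them.
    """
    cols = ["pressure_mpa", "temperature_c", "water_pct"]
    data = frame[cols + [solubility_column]].copy()
    if collapse_replicates:
        data = data.groupby(cols, as_index=False, sort=False)[solubility_column].mean()

    ethanol, water = chemicals["ethanol"], chemicals["water"]
    csts_cache: dict[float, float] = {}
    records = []
    for _, row in data.iterrows():
        w = float(row["water_pct"])
        if w not in csts_cache:
            mix = MixtureSpec.from_water_pct(w, ethanol, water)
            csts_cache[w] = csts(mix, activity_model=activity_model).csts
        breakdown = operational_cost(cost_cfg.with_water_pct(w))
        records.append(
            ConditionRecord(
                condition=(
                    float(row["pressure_mpa"]),
                    float(row["temperature_c"]),
                    w,
                ),
                solubility=float(row[solubility_column]),
                oc=breakdown.oc,
                csts=csts_cache[w],
            )
        )
    return records


def assess_conditions(
    frame: pd.DataFrame,
    cost_cfg: CostConfig,
    chemicals: dict[str, ComponentProperties],
    collapse_replicates: bool = True,
    activity_model: str | object = "van_laar",
    solubility_column: str = "solubility_e3",
) -> PerformanceTable:
    """Full assessment: criteria per condition, rank indices, best condition."""
    records = condition_records(
        frame,
        cost_cfg,
        chemicals,
        collapse_replicates=collapse_replicates,
        activity_model=activity_model,
        solubility_column=solubility_column,
    )
    return overall_performance(records)
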