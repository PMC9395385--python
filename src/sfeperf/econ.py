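"""Operational cost model for a co-solvent SFE unit.

The operational cost (OC, in RM/year) aggregates three direct-cost
components following the simplified manufacturing-cost relation

    OC = 2.73 * COL + 1.23 * (CUT + CRM)

with CRM the annualised raw-material spend (plant sample, CO2, ethanol),
CUT the annual electricity cost of the listed equipment and COL the annual
labour cost. Fixed capital and waste-treatment costs are excluded.

Across operating conditions the cost varies only through the water fraction
of the co-solvent (water displaces purchased ethanol) and the run duration;
per-run electrical energy is treated as pressure/temperature independent.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = ["CostConfig", "CostBreakdown", "operational_cost", "utility_itemization"]

# OC = 2.73*COL + 1.23*(CUT + CRM)
LABOUR_MULTIPLIER = 2.73
MATERIAL_UTILITY_MULTIPLIER = 1.23


def _default_equipment() -> dict[str, float]:
    # chiller dominates; pumps, oven, BPR and ambient loads are each < 1 kW
    return {
        "chiller": 13.82,
        "co2_pump": 0.9,
        "cosolvent_pump": 0.4,
        "bpr": 0.5,
        "oven": 0.8,
        "ambient": 0.9,
    }


@dataclass
class CostConfig:
    """Prices, consumption rates and duty cycle for the cost model.

    Monetary unit is RM. The electricity tariff is stored in sen/kWh, as
    utilities quote it, and divided by 100 when costs are computed.
    """

    sample_price_rm_per_kg: float = 70.0
    ethanol_price_rm_per_bottle: float = 86.0
    bottle_volume_l: float = 2.5
    co2_price_rm_per_cylinder: float = 224.0
    cylinder_mass_kg: float = 30.0
    electricity_tariff_sen_per_kwh: float = 36.5
    labour_salary_rm_per_month: float = 1800.0
    n_operators: int = 1
    equipment_power_kw: dict[str, float] = field(default_factory=_default_equipment)
    annual_hours: float = 8760.0
    run_duration_h: float = 8.0
    sample_mass_kg: float = 0.003
    co2_mass_kg: float = 2.0
    cosolvent_volume_l: float = 0.06
    water_pct_vv: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "sample_price_rm_per_kg", "ethanol_price_rm_per_bottle",
            "co2_price_rm_per_cylinder", "electricity_tariff_sen_per_kwh",
            "labour_salary_rm_per_month", "annual_hours", "sample_mass_kg",
            "co2_mass_kg", "cosolvent_volume_l",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bottle_volume_l <= 0 or self.cylinder_mass_kg <= 0:
            raise ValueError("bottle_volume_l and cylinder_mass_kg must be > 0")
        if self.run_duration_h <= 0:
            raise ValueError("run_duration_h must be > 0")
        if not 0.0 <= self.water_pct_vv <= 100.0:
            raise ValueError("water_pct_vv must be in [0, 100]")
        if any(p < 0 for p in self.equipment_power_kw.values()):
            raise ValueError("equipment powers must be >= 0")

    @property
    def tariff_rm_per_kwh(self) -> float:
        return self.electricity_tariff_sen_per_kwh / 100.0

    @property
    def runs_per_year(self) -> float:
        return self.annual_hours / self.run_duration_h

    def with_water_pct(self, water_pct_vv: float) -> "CostConfig":
        return replace(self, water_pct_vv=water_pct_vv)

    @classmethod
    def from_toml(cls, path: str | Path) -> "CostConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(**raw)


@dataclass(frozen=True)
class CostBreakdown:
    """Annualised cost components and the aggregated OC, all in RM/year."""

    crm: float
    cut: float
    col: float
    oc: float
    fractions: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "crm_rm_per_year": self.crm,
            "cut_rm_per_year": self.cut,
            "col_rm_per_year": self.col,
            "oc_rm_per_year": self.oc,
            "fractions": dict(self.fractions),
        }


def operational_cost(cfg: CostConfig) -> CostBreakdown:
    """Compute the annual operational cost breakdown for one condition."""
    ethanol_volume_l = cfg.cosolvent_volume_l * (1.0 - cfg.water_pct_vv / 100.0)
    per_run_crm = (
        cfg.sample_mass_kg * cfg.sample_price_rm_per_kg
        + cfg.co2_mass_kg * cfg.co2_price_rm_per_cylinder / cfg.cylinder_mass_kg
        + ethanol_volume_l * cfg.ethanol_price_rm_per_bottle / cfg.bottle_volume_l
    )
    crm = per_run_crm * cfg.runs_per_year
    cut = sum(utility_itemization(cfg).values())
    col = 12.0 * cfg.labour_salary_rm_per_month * cfg.n_operators
    oc = LABOUR_MULTIPLIER * col + MATERIAL_UTILITY_MULTIPLIER * (cut + crm)
    total = crm + cut + col
    if total > 0:
        fractions = {"crm": crm / total, "cut": cut / total, "col": col / total}
    else:
        fractions = {"crm": 0.0, "cut": 0.0, "col": 0.0}
    return CostBreakdown(crm=crm, cut=cut, col=col, oc=oc, fractions=fractions)


def utility_itemization(cfg: CostConfig) -> dict[str, float]:
    """Annual electricity cost per device (RM/year)."""
    return {
        name: power * cfg.annual_hours * cfg.tariff_rm_per_kwh
        for name, power in cfg.equipment_power_kw.items()
    }


def dominant_utility(cfg: CostConfig) -> str:
    """Name of the device with the largest annual electricity cost."""
    items = utility_itemization(cfg)
    if not items:
        raise ValueError("no equipment configured")
    return max(items, key=items.get)
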