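"""Chemical safety scoring for CO2 + ethanol-water co-solvent systems.

Mixture properties
------------------
For a binary ethanol-water co-solvent specified as % v/v water in ethanol,
mole fractions follow from component densities and molar masses. The mixture
boiling point and Hansen solubility parameter are mole-fraction-weighted
linear combinations of the component values. The mixture flash point is the
temperature at which Le Chatelier's rule is satisfied:

    sum_i  x_i * gamma_i * P_sat_i(T) / P_sat_i(T_fp,i)  =  1

summed over flammable components; P_sat from the Antoine equation
(log10 P[mmHg] = A - B/(C + T[degC])) and gamma from a configurable
liquid-phase activity model (van Laar by default; ethanol-water is strongly
non-ideal, so ideal gamma understates the mixture flash point).

Hazard scores
-------------
Four logistic scores on [0, 100] map physical hazard parameters onto a
common scale:

    S_FL  = 100 * (1 - 1/(1 + 3.37    * exp(-0.024 x))),  x = flash point (degC)
    S_TX  = 100 * (1 - 1/(1 + 403.4288* exp(-0.012 x))),  x = TLV-STEL (ppm)
    S_R   = 100 *      1/(1 + 270.43  * exp(-2.8   x)),   x = NFPA reactivity
    S_EXP = 100 *      1/(1 + 1096.63 * exp(-0.14  x)),   x = UEL - LEL (vol %)

and sum to the Chemical Safety Total Score, CSTS = S_FL + S_TX + S_R + S_EXP
(higher = more hazardous, range [0, 400]).

Composition policy: only S_FL varies with the water fraction (through the
Le Chatelier flash point). Toxicity, reactivity and explosiveness are those
of the flammable component — water carries no TLV-STEL, NFPA instability or
explosive range, so these scores are composition independent. This matches
the observed pattern that flammability dominates the variation of CSTS
across water levels while the other three scores are essentially flat.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import ConfigError, NoFlashPointError

__all__ = [
    "ComponentProperties",
    "MixtureSpec",
    "SafetyScores",
    "VanLaar",
    "vv_to_mole_fraction",
    "mixture_boiling_point",
    "mixture_flash_point",
    "hansen_mix",
    "score_flammability",
    "score_toxicity",
    "score_reactivity",
    "score_explosiveness",
    "csts",
]


@dataclass(frozen=True)
class ComponentProperties:
    """Physical and hazard properties of one solvent component.

    Antoine constants use the log10/mmHg/degC convention. ``flash_point_c``
    is None for non-flammable components (water); they contribute nothing to
    the Le Chatelier sum.
    """

    name: str
    boiling_point_c: float
    flash_point_c: float | None
    antoine: tuple[float, float, float]
    hansen_delta: float
    density_g_ml: float
    molar_mass: float
    tlv_stel_ppm: float | None = None
    nfpa_reactivity: int = 0
    lel_vol_pct: float | None = None
    uel_vol_pct: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.nfpa_reactivity <= 4:
            raise ConfigError(f"{self.name}: NFPA reactivity must be 0..4")
        if self.lel_vol_pct is not None and self.uel_vol_pct is not None:
            if not 0 <= self.lel_vol_pct <= self.uel_vol_pct:
                raise ConfigError(f"{self.name}: require 0 <= LEL <= UEL")
        if self.density_g_ml <= 0 or self.molar_mass <= 0:
            raise ConfigError(f"{self.name}: density and molar mass must be > 0")

    @property
    def flammable(self) -> bool:
        return self.flash_point_c is not None

    def vapour_pressure_mmhg(self, t_c: float) -> float:
        a, b, c = self.antoine
        return 10.0 ** (a - b / (c + t_c))

    @property
    def explosive_range(self) -> float:
        """UEL - LEL in vol %; zero when the component has no explosive range."""
        if self.lel_vol_pct is None or self.uel_vol_pct is None:
            return 0.0
        return self.uel_vol_pct - self.lel_vol_pct


class VanLaar:
    """Two-parameter van Laar activity model for a binary liquid.

    ln gamma_1 = a12 * (a21 x2 / (a12 x1 + a21 x2))^2 and symmetrically for
    gamma_2. Composition-only (temperature-independent) form.
    """

    def __init__(self, a12: float, a21: float):
        self.a12 = a12
        self.a21 = a21

    def gammas(self, x1: float) -> tuple[float, float]:
        x2 = 1.0 - x1
        if x1 <= 0.0:
            return math.exp(self.a12), 1.0
        if x2 <= 0.0:
            return 1.0, math.exp(self.a21)
        d = self.a12 * x1 + self.a21 * x2
        g1 = math.exp(self.a12 * (self.a21 * x2 / d) ** 2)
        g2 = math.exp(self.a21 * (self.a12 * x1 / d) ** 2)
        return g1, g2


class Ideal:
    """Ideal-solution activity model: gamma = 1."""

    def gammas(self, x1: float) -> tuple[float, float]:
        return 1.0, 1.0


# registry keyed by the names accepted in configs and on the CLI
ACTIVITY_MODELS: dict[str, Callable[..., object]] = {
    "ideal": lambda **kw: Ideal(),
    "van_laar": lambda a12, a21, **kw: VanLaar(a12, a21),
}

# van Laar ethanol(1)-water(2) constants from standard VLE compilations
VAN_LAAR_ETHANOL_WATER = {"a12": 1.6798, "a21": 0.9227}


def vv_to_mole_fraction(
    water_pct_vv: float, water: ComponentProperties, ethanol: ComponentProperties
) -> tuple[float, float]:
    """Convert % v/v water-in-ethanol to (x_water, x_ethanol).

    moles_i = volume_i * density_i / molar_mass_i on a 100-volume basis.
    """
    if not 0.0 <= water_pct_vv <= 100.0:
        raise ValueError("water_pct_vv must be in [0, 100]")
    n_w = water_pct_vv * water.density_g_ml / water.molar_mass
    n_e = (100.0 - water_pct_vv) * ethanol.density_g_ml / ethanol.molar_mass
    total = n_w + n_e
    if total <= 0:
        raise ConfigError("degenerate mixture: zero total moles")
    return n_w / total, n_e / total


@dataclass(frozen=True)
class MixtureSpec:
    """A binary co-solvent: component properties plus mole fractions.

    Component 1 is the flammable solvent (ethanol), component 2 the
    diluent (water). x1 + x2 = 1.
    """

    component1: ComponentProperties
    component2: ComponentProperties
    x1: float
    x2: float
    water_pct_vv: float | None = None

    def __post_init__(self) -> None:
        if abs(self.x1 + self.x2 - 1.0) > 1e-9:
            raise ValueError("mole fractions must sum to 1")

    @classmethod
    def from_water_pct(
        cls,
        water_pct_vv: float,
        ethanol: ComponentProperties,
        water: ComponentProperties,
    ) -> "MixtureSpec":
        x_w, x_e = vv_to_mole_fraction(water_pct_vv, water, ethanol)
        return cls(
            component1=ethanol, component2=water, x1=x_e, x2=x_w,
            water_pct_vv=water_pct_vv,
        )

    @property
    def components(self) -> tuple[ComponentProperties, ComponentProperties]:
        return (self.component1, self.component2)

    @property
    def mole_fractions(self) -> tuple[float, float]:
        return (self.x1, self.x2)


def mixture_boiling_point(mix: MixtureSpec) -> float:
    """Mole-fraction weighted boiling point (degC)."""
    return mix.x1 * mix.component1.boiling_point_c + mix.x2 * mix.component2.boiling_point_c


def hansen_mix(mix: MixtureSpec) -> float:
    """Mole-fraction weighted Hansen solubility parameter (MPa^0.5)."""
    return mix.x1 * mix.component1.hansen_delta + mix.x2 * mix.component2.hansen_delta


def _resolve_activity(mix: MixtureSpec, activity_model) -> object:
    if activity_model is None or activity_model == "van_laar":
        return VanLaar(**VAN_LAAR_ETHANOL_WATER)
    if activity_model == "ideal":
        return Ideal()
    if isinstance(activity_model, str):
        raise ConfigError(
            f"unknown activity model {activity_model!r}; "
            f"known: {sorted(ACTIVITY_MODELS)}"
        )
    return activity_model  # object with .gammas


def mixture_flash_point(
    mix: MixtureSpec,
    activity_model: str | object = "van_laar",
    bracket: tuple[float, float] = (-50.0, 200.0),
    xtol: float = 1e-8,
) -> float:
    """Flash point (degC) of the mixture via Le Chatelier's rule.

    Finds the temperature where the flammable-component Le Chatelier sum
    crosses 1, by bracketed root finding. Non-flammable components
    contribute zero to the sum.
    """
    model = _resolve_activity(mix, activity_model)
    comps = mix.components
    fracs = mix.mole_fractions
    if not any(c.flammable for c in comps):
        raise NoFlashPointError("no flammable component in the mixture")
    gammas = model.gammas(mix.x1)

    def le_chatelier(t_c: float) -> float:
        total = 0.0
        for x, g, comp in zip(fracs, gammas, comps):
            if not comp.flammable:
                continue
            total += (
                x * g * comp.vapour_pressure_mmhg(t_c)
                / comp.vapour_pressure_mmhg(comp.flash_point_c)
            )
        return total - 1.0

    lo, hi = bracket
    f_lo, f_hi = le_chatelier(lo), le_chatelier(hi)
    if f_lo * f_hi > 0:
        raise NoFlashPointError(
            f"Le Chatelier sum does not cross 1 in [{lo}, {hi}] degC"
        )
    return float(brentq(le_chatelier, lo, hi, xtol=xtol))


# ------------------------------------------------------------ logistic scores


def _falling_logistic(x: float, k: float, r: float) -> float:
    # 100*(1 - 1/(1 + k e^{-rx})) == 100*expit(ln k - r x), overflow-safe
    return 100.0 * float(expit(math.log(k) - r * x))


def _rising_logistic(x: float, k: float, r: float) -> float:
    # 100/(1 + k e^{-rx}) == 100*expit(r x - ln k), overflow-safe
    return 100.0 * float(expit(r * x - math.log(k)))


def score_flammability(flash_point_c: float) -> float:
    """Flammability hazard score; decreasing in the flash point."""
    return _falling_logistic(flash_point_c, 3.37, 0.024)


def score_toxicity(tlv_stel_ppm: float) -> float:
    """Toxicity hazard score; decreasing in the permissible exposure limit."""
    return _falling_logistic(tlv_stel_ppm, 403.4288, 0.012)


def score_reactivity(nfpa_reactivity: float) -> float:
    """Reactivity hazard score; increasing in the NFPA instability rating."""
    return _rising_logistic(nfpa_reactivity, 270.43, 2.8)


def score_explosiveness(uel_minus_lel: float) -> float:
    """Explosiveness hazard score; increasing in the explosive range width."""
    return _rising_logistic(uel_minus_lel, 1096.63, 0.14)


@dataclass(frozen=True)
class SafetyScores:
    """The four logistic hazard scores, their sum, and the inputs used."""

    s_fl: float
    s_tx: float
    s_r: float
    s_exp: float
    csts: float
    flash_point_c: float
    inputs_used: dict

    def as_dict(self) -> dict:
        return {
            "s_fl": self.s_fl, "s_tx": self.s_tx, "s_r": self.s_r,
            "s_exp": self.s_exp, "csts": self.csts,
            "flash_point_c": self.flash_point_c,
            "inputs_used": dict(self.inputs_used),
        }


def csts(
    mix: MixtureSpec, activity_model: str | object = "van_laar"
) -> SafetyScores:
    """Chemical Safety Total Score for a co-solvent mixture.

    S_FL uses the Le Chatelier mixture flash point; S_TX, S_R and S_EXP use
    the flammable component's TLV-STEL, NFPA rating and explosive range
    (composition independent — see module docstring).
    """
    flammables = [c for c in mix.components if c.flammable]
    if not flammables:
        raise NoFlashPointError("no flammable component in the mixture")
    flam = flammables[0]
    fp = mixture_flash_point(mix, activity_model=activity_model)
    if flam.tlv_stel_ppm is None:
        raise ConfigError(f"{flam.name}: TLV-STEL required for toxicity score")
    s_fl = score_flammability(fp)
    s_tx = score_toxicity(flam.tlv_stel_ppm)
    s_r = score_reactivity(flam.nfpa_reactivity)
    s_exp = score_explosiveness(flam.explosive_range)
    return SafetyScores(
        s_fl=s_fl, s_tx=s_tx, s_r=s_r, s_exp=s_exp,
        csts=s_fl + s_tx + s_r + s_exp,
        flash_point_c=fp,
        inputs_used={
            "flash_point_c": fp,
            "tlv_stel_ppm": flam.tlv_stel_ppm,
            "nfpa_reactivity": flam.nfpa_reactivity,
            "uel_minus_lel": flam.explosive_range,
            "water_pct_vv": mix.water_pct_vv,
        },
    )


def components_from_toml(path: str | Path) -> dict[str, ComponentProperties]:
    """Load one ComponentProperties per [components.<name>] TOML table."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    comps = {}
    for name, tbl in raw.get("components", {}).items():
        comps[name] = ComponentProperties(
            name=name,
            boiling_point_c=tbl["boiling_point_c"],
            flash_point_c=tbl.get("flash_point_c"),
            antoine=tuple(tbl["antoine"]),
            hansen_delta=tbl["hansen_delta"],
            density_g_ml=tbl["density_g_ml"],
            molar_mass=tbl["molar_mass"],
            tlv_stel_ppm=tbl.get("tlv_stel_ppm"),
            nfpa_reactivity=tbl.get("nfpa_reactivity", 0),
            lel_vol_pct=tbl.get("lel_vol_pct"),
            uel_vol_pct=tbl.get("uel_vol_pct"),
        )
    if not comps:
        raise ConfigError(f"no [components.*] tables found in {path}")
    return comps
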