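"""Packaged fixtures and a synthetic CCD response generator.

The fixture tables ship with the package as plain CSV/TOML and are verified
against frozen SHA-256 digests on load, so silent edits fail loudly:

- the 20-run three-factor CCD with measured yield (g/g %) and solubility
  ((g solute / g CO2) x 10^3) responses,
- the cost configuration (prices, consumption rates, equipment powers),
- component property sheets for the ethanol-water co-solvent,
- liquid densities at extraction conditions,
- the qualitative equipment hazard register.

:func:`generate_response` produces synthetic responses on any design from a
known coded-scale polynomial plus homoscedastic Gaussian noise, which makes
parameter-recovery and power studies possible with a known ground truth.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CCDRole, DesignPoint, DesignTable, FactorSpec, code_levels
from .econ import CostConfig
from .rsm import _expand
from .safety import ComponentProperties, components_from_toml

__all__ = [
    "paper_factors",
    "load_design_response",
    "load_design_table",
    "load_cost_config",
    "load_chemicals",
    "load_activity_constants",
    "load_densities",
    "load_hazard_register",
    "default_noise_sd",
    "SyntheticSpec",
    "generate_response",
]

_CHECKSUMS = {
    "design_response.csv": "cf8f131e6e36028f1c9b706159a501447f5c6f3af436c6c8a6cdf4fc62173b87",
    "cost.toml": "5a00f187ad35d6f1543cada3cc58dcef2e45c49dfca8bd06c75ec1d9d1718ee5",
    "chemicals.toml": "f1a84a7cf5dda3c4ee9e75127e03e8a119c99e5da674f5c98e1a95dc0551386c",
    "densities.csv": "be07fdc3ab2761cad421df34b8ef9a2f0afd845ba7a21bd23ac25979e31fefdd",
    "hazards.toml": "49d1bc3d79abba9adcd94af787daae8cf54b083c27084b46634ca888b572cc8f",
}


def _data_path(name: str) -> Path:
    path = Path(resources.files("sfeperf").joinpath("data", name))
    if name in _CHECKSUMS:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != _CHECKSUMS[name]:
            raise RuntimeError(
                f"packaged fixture {name} fails its integrity check "
                f"(sha256 {digest}); the file has been edited"
            )
    return path


def paper_factors() -> list[FactorSpec]:
    """The three extraction factors with their CCD levels.

    Pressure 17-25 MPa about 21, temperature 58-72 degC about 65, water in
    ethanol 7-33 % v/v about 20. Axial levels are verbatim operating
    settings; the nominal axial distance 1.32 is metadata (the temperature
    axials imply 1.4, which triggers the FactorSpec warning by design).
    """
    return [
        FactorSpec("pressure_mpa", "MPa", 21.0, 3.0, 17.0, 25.0, alpha=1.32),
        FactorSpec("temperature_c", "degC", 65.0, 5.0, 58.0, 72.0, alpha=1.32),
        FactorSpec("water_pct", "% v/v", 20.0, 10.0, 7.0, 33.0, alpha=1.32),
    ]


def load_design_response() -> pd.DataFrame:
    """The 20-run design with measured yield and solubility responses."""
    return pd.read_csv(_data_path("design_response.csv"))


def load_design_table() -> DesignTable:
    """The 20-run design as a DesignTable, in the published run order."""
    import warnings

    frame = load_design_response()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # alpha-mismatch warning is expected
        factors = paper_factors()
    points = []
    for _, row in frame.iterrows():
        actual = (row["pressure_mpa"], row["temperature_c"], row["water_pct"])
        coded = tuple(code_levels(actual, factors))
        points.append(
            DesignPoint(int(row["run_id"]), actual, coded, CCDRole(row["ccd_role"]))
        )
    return DesignTable(factors=factors, points=points)


def load_cost_config() -> CostConfig:
    return CostConfig.from_toml(_data_path("cost.toml"))


def load_chemicals() -> dict[str, ComponentProperties]:
    return components_from_toml(_data_path("chemicals.toml"))


def load_activity_constants() -> dict[str, float]:
    with open(_data_path("chemicals.toml"), "rb") as fh:
        raw = tomllib.load(fh)
    return dict(raw["activity"]["van_laar"])


def load_densities() -> pd.DataFrame:
    """Liquid densities (x10^-3 g/ml) at extraction temperature/pressure."""
    return pd.read_csv(_data_path("densities.csv"))


def load_hazard_register() -> dict:
    """Qualitative per-equipment risks and BLEVE secondary scenarios."""
    with open(_data_path("hazards.toml"), "rb") as fh:
        return tomllib.load(fh)


def default_noise_sd(response: str = "yield_pct") -> float:
    """Pooled SD of the centre-point replicates for a fixture response.

    The centre replicates show substantial scatter, so recovery and power
    studies run at a realistic noise level by default.
    """
    frame = load_design_response()
    centers = frame[frame["ccd_role"] == "center"][response]
    return float(centers.std(ddof=1))


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for a synthetic CCD response.

    ``true_coefficients`` are on the coded scale, ordered intercept first
    then the term order of :func:`sfeperf.rsm.model_terms` for ``order``.
    """

    design: DesignTable
    order: str
    true_coefficients: tuple[float, ...]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_response(spec: SyntheticSpec) -> pd.DataFrame:
    """Evaluate the ground-truth polynomial on the design and add noise.

    Returns a frame with run_id and value columns; identical seeds give
    identical tables.
    """
    X = spec.design.coded_matrix()
    M = np.column_stack([np.ones(len(X)), _expand(X, spec.order)])
    beta = np.asarray(spec.true_coefficients, dtype=float)
    if beta.shape != (M.shape[1],):
        raise ValueError(
            f"expected {M.shape[1]} coefficients for order {spec.order!r}, "
            f"got {beta.shape[0]}"
        )
    rng = np.random.default_rng(spec.seed)
    values = M @ beta + rng.normal(0.0, spec.noise_sd, size=len(X))
    return pd.DataFrame(
        {"run_id": [p.run_id for p in spec.design.points], "value": values}
    )
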