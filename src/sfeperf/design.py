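"""Three-factor central composite designs (CCD) on coded and actual scales.

A CCD for three factors consists of 2**3 = 8 factorial points (all +-1
combinations in coded units), 2*3 = 6 axial points (one factor displaced to
its low/high axial level, the others at the centre) and a block of replicated
centre points. Coded levels are defined as ``(actual - center) / step`` with
``step`` the half-range of the factorial levels.

Axial levels are stored verbatim on each :class:`FactorSpec` rather than
recomputed from a single axial distance alpha: published designs frequently
round axial settings to operable values, so the printed actual levels are the
ground truth and the implied per-factor alpha may differ slightly from the
nominal one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateFactorError, UnsupportedDesignError

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "DesignTable",
    "CCDRole",
    "build_ccd",
    "code_levels",
    "decode_levels",
]


class CCDRole(str, Enum):
    FACTORIAL = "factorial"
    AXIAL = "axial"
    CENTER = "center"


@dataclass(frozen=True)
class FactorSpec:
    """One design factor: centre, factorial half-range and axial levels.

    Parameters
    ----------
    name : str
        Factor label, e.g. ``"pressure"``.
    units : str
        Physical units, e.g. ``"MPa"``.
    center : float
        Centre-point level on the actual scale.
    step : float
        Half-range of the factorial levels; the coded-unit denominator.
    axial_low, axial_high : float
        Actual levels of the two axial (star) points on this factor's axis.
    alpha : float, optional
        Nominal axial distance recorded as metadata only; axial levels are
        always taken from ``axial_low``/``axial_high``.
    """

    name: str
    units: str
    center: float
    step: float
    axial_low: float
    axial_high: float
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise DegenerateFactorError(
                f"factor {self.name!r}: step must be > 0, got {self.step}"
            )
        if not (self.axial_low < self.center < self.axial_high):
            raise ValueError(
                f"factor {self.name!r}: require axial_low < center < axial_high, "
                f"got {self.axial_low}, {self.center}, {self.axial_high}"
            )
        implied = (self.axial_high - self.center) / self.step
        if self.alpha is not None and abs(implied - self.alpha) > 0.05:
            warnings.warn(
                f"factor {self.name!r}: axial levels imply coded distance "
                f"{implied:.3f}, not the nominal alpha={self.alpha}; verbatim "
                "axial levels take precedence",
                stacklevel=2,
            )

    def code(self, actual: float) -> float:
        return (actual - self.center) / self.step

    def decode(self, coded: float) -> float:
        return self.center + coded * self.step


@dataclass(frozen=True)
class DesignPoint:
    run_id: int
    actual_levels: tuple[float, ...]
    coded_levels: tuple[float, ...]
    ccd_role: CCDRole


@dataclass
class DesignTable:
    """A design: factor specifications plus an ordered list of runs."""

    factors: list[FactorSpec]
    points: list[DesignPoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def actual_matrix(self) -> np.ndarray:
        return np.array([p.actual_levels for p in self.points], dtype=float)

    def coded_matrix(self) -> np.ndarray:
        return np.array([p.coded_levels for p in self.points], dtype=float)

    def roles(self) -> list[CCDRole]:
        return [p.ccd_role for p in self.points]

    def role_counts(self) -> dict[str, int]:
        out = {r.value: 0 for r in CCDRole}
        for p in self.points:
            out[p.ccd_role.value] += 1
        return out

    def to_frame(self, coded: bool = True) -> pd.DataFrame:
        cols = {"run_id": [p.run_id for p in self.points]}
        act = self.actual_matrix()
        for j, f in enumerate(self.factors):
            cols[f.name] = act[:, j]
        cols["ccd_role"] = [p.ccd_role.value for p in self.points]
        if coded:
            cod = self.coded_matrix()
            for j, f in enumerate(self.factors):
                cols[f"coded_{f.name}"] = cod[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path, coded: bool = True) -> None:
        self.to_frame(coded=coded).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, factors: Sequence[FactorSpec]) -> "DesignTable":
        """Rebuild a table from a frame with run_id, per-factor and ccd_role columns."""
        factors = list(factors)
        points = []
        for _, row in frame.iterrows():
            actual = tuple(float(row[f.name]) for f in factors)
            coded = tuple(code_levels(actual, factors))
            points.append(
                DesignPoint(
                    run_id=int(row["run_id"]),
                    actual_levels=actual,
                    coded_levels=coded,
                    ccd_role=CCDRole(row["ccd_role"]),
                )
            )
        return cls(factors=factors, points=points)


def code_levels(
    point_actual: Iterable[float], factors: Sequence[FactorSpec]
) -> np.ndarray:
    """Map actual factor levels to coded units, (actual - center) / step."""
    pt = np.asarray(list(point_actual), dtype=float)
    if pt.shape != (len(factors),):
        raise ValueError(f"expected {len(factors)} levels, got {pt.shape}")
    return np.array([f.code(x) for f, x in zip(factors, pt)])


def decode_levels(
    point_coded: Iterable[float], factors: Sequence[FactorSpec]
) -> np.ndarray:
    """Inverse of :func:`code_levels`: center + coded * step."""
    pt = np.asarray(list(point_coded), dtype=float)
    if pt.shape != (len(factors),):
        raise ValueError(f"expected {len(factors)} levels, got {pt.shape}")
    return np.array([f.decode(x) for f, x in zip(factors, pt)])


def build_ccd(factors: Sequence[FactorSpec], n_center: int) -> DesignTable:
    """Build a three-factor CCD: factorial, then axial, then centre runs.

    Run ordering is deterministic: the 8 factorial points in
    ``itertools.product((-1, +1))`` order, then axial low/high per factor in
    factor order, then ``n_center`` centre replicates. Axial actual levels are
    taken verbatim from each factor's ``axial_low``/``axial_high``.
    """
    factors = list(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"only three-factor CCDs are supported, got {len(factors)} factors"
        )
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    points: list[DesignPoint] = []
    run = 1
    for signs in itertools.product((-1.0, 1.0), repeat=3):
        actual = tuple(f.decode(s) for f, s in zip(factors, signs))
        points.append(DesignPoint(run, actual, signs, CCDRole.FACTORIAL))
        run += 1
    center = tuple(f.center for f in factors)
    for j, f in enumerate(factors):
        for axial in (f.axial_low, f.axial_high):
            actual = list(center)
            actual[j] = axial
            coded = tuple(code_levels(actual, factors))
            points.append(DesignPoint(run, tuple(actual), coded, CCDRole.AXIAL))
            run += 1
    for _ in range(n_center):
        points.append(DesignPoint(run, center, (0.0, 0.0, 0.0), CCDRole.CENTER))
        run += 1
    return DesignTable(factors=factors, points=points)
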