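"""Deterministic core of the daily microplastic exposure model.

Plastic ingested per day, P (pieces d^-1), is the sum of two routes:

    P = V r  sum_d f_d C_d   +   (V f rho_y / m_y) C_y

where V is engulfment volume per lunge (m^3), r the fraction of suspended
particles retained by the baleen filter, f_d the daily lunge count in depth
bin d, C_d the water concentration in that bin (pieces m^-3), f = sum_d f_d
the total daily lunge count, rho_y the prey biomass density (kg m^-3), m_y
the individual prey mass (kg), and C_y the expected pieces per prey
individual (frequency of occurrence x pieces per contaminated individual,
the latter 1 by default).  The first term is direct filtration from water;
the second is trophic transfer via contaminated prey.

Pieces are real-valued expectations throughout; rounding happens only in
display.  Downstream conversions (mass per day, season totals, trophic
fraction, mass-specific rates) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ExposureInputs",
    "ExposureEstimate",
    "plastic_from_water",
    "plastic_from_prey",
    "total_exposure",
    "trophic_fraction",
    "plastic_mass",
    "season_total",
    "mass_specific",
]


@dataclass(frozen=True)
class ExposureInputs:
    """Everything the exposure equation needs for one whale-day."""

    V: float  # m^3 engulfed per lunge
    r: float  # baleen retention fraction, 0-1
    f_d: Mapping[str, float]  # lunges d^-1 per depth bin
    C_d: Mapping[str, float]  # pieces m^-3 per depth bin
    rho_y: float  # prey biomass density, kg m^-3
    m_y: float  # individual prey mass, kg
    C_y: float  # expected pieces per prey individual
    body_mass: float | None = None  # kg, for mass-specific reporting

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"retention r must be in [0, 1], got {self.r}")
        for name in ("V", "rho_y", "C_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.f_d.values()) or any(v < 0 for v in self.C_d.values()):
            raise ValueError("f_d and C_d must be non-negative")

    @property
    def f(self) -> float:
        """Total daily lunge count, sum over depth bins."""
        return float(sum(self.f_d.values()))


@dataclass(frozen=True)
class ExposureEstimate:
    """Daily exposure split by route; total is exactly water + prey."""

    pieces_from_water: float
    pieces_from_prey: float

    @property
    def pieces_total(self) -> float:
        return self.pieces_from_water + self.pieces_from_prey


def plastic_from_water(
    V: float, r: float, f_d: Mapping[str, float], C_d: Mapping[str, float]
) -> float:
    """Filtration route: V * r * sum_d f_d[d] * C_d[d] (pieces d^-1)."""
    if set(f_d) != set(C_d):
        only_f = sorted(set(f_d) - set(C_d))
        only_c = sorted(set(C_d) - set(f_d))
        raise ValueError(
            f"depth-bin labels differ between f_d and C_d: only in f_d {only_f}, "
            f"only in C_d {only_c}"
        )
    return V * r * sum(f_d[d] * C_d[d] for d in f_d)


def plastic_from_prey(V: float, f: float, rho_y: float, m_y: float, C_y: float) -> float:
    """Trophic-transfer route: (V * f * rho_y / m_y) * C_y (pieces d^-1).

    ``C_y`` is the expected pieces per prey individual — the frequency of
    occurrence times pieces per contaminated individual (1 under the
    one-piece assumption).
    """
    if m_y <= 0:
        raise ValueError("individual prey mass m_y must be > 0")
    return (V * f * rho_y / m_y) * C_y


def total_exposure(inputs: ExposureInputs) -> ExposureEstimate:
    """Evaluate both routes of the exposure equation for one whale-day."""
    water = plastic_from_water(inputs.V, inputs.r, inputs.f_d, inputs.C_d)
    prey = plastic_from_prey(inputs.V, inputs.f, inputs.rho_y, inputs.m_y, inputs.C_y)
    return ExposureEstimate(pieces_from_water=water, pieces_from_prey=prey)


def trophic_fraction(estimate: ExposureEstimate) -> float:
    """Fraction of total ingestion arriving via prey; NaN when total is zero."""
    if estimate.pieces_total == 0:
        return float("nan")
    return estimate.pieces_from_prey / estimate.pieces_total


def plastic_mass(pieces: float, per_piece_mass_mg: float) -> float:
    """Convert a piece count to kilograms at a given per-piece mass (mg)."""
    if pieces < 0 or per_piece_mass_mg < 0:
        raise ValueError("pieces and per-piece mass must be non-negative")
    return pieces * per_piece_mass_mg * 1e-6


def season_total(daily_pieces: float, season_days: float) -> float:
    """Pieces ingested over a feeding season of ``season_days`` days."""
    if daily_pieces < 0 or season_days < 0:
        raise ValueError("inputs must be non-negative")
    return daily_pieces * season_days


def mass_specific(estimate: ExposureEstimate, body_mass: float) -> ExposureEstimate:
    """Divide each route by body mass (pieces d^-1 kg^-1)."""
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    return ExposureEstimate(
        pieces_from_water=estimate.pieces_from_water / body_mass,
        pieces_from_prey=estimate.pieces_from_prey / body_mass,
    )
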