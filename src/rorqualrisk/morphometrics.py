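"""Allometric scaling from total body length to engulfment capacity and mass.

Rorqual engulfment capacity (the volume of water taken in per lunge) and
body mass both scale as power laws of total body length,
``response = 10**(a + b * log10(length))``.  Coefficients are configuration,
not constants: the shipped defaults are fixture values of field-plausible
magnitude and must be replaced with published fits for faithful work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AllometryCoefficients",
    "Morphology",
    "allometric_eval",
    "morphology_from_length",
    "invert_allometry",
]

RESPONSES = ("engulfment_volume_m3", "body_mass_kg")


@dataclass(frozen=True)
class AllometryCoefficients:
    """One power-law fit: log10(response) = intercept_log10 + slope*log10(L)."""

    species: str
    response: str
    intercept_log10: float
    slope: float

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass(frozen=True)
class Morphology:
    """Per-individual morphometrics derived from length."""

    total_length: float  # m
    engulfment_volume: float  # m^3 per lunge (V)
    body_mass: float  # kg

    def __post_init__(self) -> None:
        if min(self.total_length, self.engulfment_volume, self.body_mass) <= 0:
            raise ValueError("all morphology fields must be strictly positive")


def allometric_eval(coeffs: AllometryCoefficients, length):
    """Evaluate the power law at ``length`` (m; scalar or array)."""
    L = np.asarray(length, dtype=float)
    if (L <= 0).any():
        raise ValueError("length must be > 0")
    out = 10.0 ** (coeffs.intercept_log10 + coeffs.slope * np.log10(L))
    return float(out[()]) if out.ndim == 0 else out


def invert_allometry(coeffs: AllometryCoefficients, response):
    """Recover length from a response value (the power law is invertible)."""
    y = np.asarray(response, dtype=float)
    if (y <= 0).any() or coeffs.slope == 0:
        raise ValueError("response must be > 0 and slope nonzero")
    out = 10.0 ** ((np.log10(y) - coeffs.intercept_log10) / coeffs.slope)
    return float(out[()]) if out.ndim == 0 else out


def morphology_from_length(
    length: float, coeff_table: dict[tuple[str, str], AllometryCoefficients], species: str
) -> Morphology:
    """Bundle engulfment volume V and body mass for one individual.

    ``coeff_table`` maps (species, response) to coefficients; a missing pair
    is a configuration error.  V is held constant across all of an
    individual's lunges.
    """
    morks = {}
    for response in RESPONSES:
        key = (species, response)
        if key not in coeff_table:
            raise KeyError(f"missing allometry coefficients for {key}")
        morks[response] = allometric_eval(coeff_table[key], length)
    return Morphology(
        total_length=float(length),
        engulfment_volume=morks["engulfment_volume_m3"],
        body_mass=morks["body_mass_kg"],
    )


def coeff_table_from_config(allometry_cfg: dict) -> dict[tuple[str, str], AllometryCoefficients]:
    """Build a coefficient table from the config block
    ``{species: {volume: {a, b}, mass: {a, b}}}``."""
    table: dict[tuple[str, str], AllometryCoefficients] = {}
    names = {"volume": "engulfment_volume_m3", "mass": "body_mass_kg"}
    for species, block in allometry_cfg.items():
        for short, response in names.items():
            if short in block:
                table[(species, response)] = AllometryCoefficients(
                    species=species,
                    response=response,
                    intercept_log10=float(block[short]["a"]),
                    slope=float(block[short]["b"]),
                )
    return table
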