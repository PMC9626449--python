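"""Monte Carlo scenario engine for depth-stratified exposure risk.

Each replicate simulates one whale-day: a body length drawn from the
empirical length pool fixes engulfment volume V and body mass; a deployment
bootstrapped from the diel-rate pool supplies day/twilight/night lunge
rates, which are combined with that deployment's diel-hour proportions
(rescaled to a 24 h day) into a daily lunge count f; f is split across
depth bins by a multinomial draw from the species' depth mixture; water
concentrations C_d are bootstrapped per bin from the profile pool; prey
density is a lognormal draw.  Retention r and prey frequency of occurrence
(FO) are set by the scenario level — low (r=0.25), medium (r=0.50), high
(r=0.75) with the paired FO constants — and each replicate is pushed
through the exposure equation.

Scenario levels share replicate substreams: replicate i uses identical
stochastic draws at every level, so levels differ only through r and FO and
risk is ordered replicate-by-replicate (stochastic dominance under matched
seeds).  Replicate i is also invariant to the total replicate count.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import ExposureInputs, total_exposure
from .morphometrics import AllometryCoefficients, morphology_from_length
from .synthetic import FO_TABLE, PlasticProfile
from .tagproc import DEPTH_BINS, DielLungeRates, daily_lunge_count

__all__ = [
    "RETENTION_BY_LEVEL",
    "LEVELS",
    "SpeciesPools",
    "PreyConfig",
    "ScenarioConfig",
    "ScenarioCell",
    "SimulationSummary",
    "draw_whale",
    "run_scenario",
    "scenario_table",
    "compare_scenarios",
]

logger = logging.getLogger(__name__)

LEVELS = ("low", "medium", "high")
# Baleen retention fractions tested for the unknown r, paired with the FO
# level of the same name.
RETENTION_BY_LEVEL = {"low": 0.25, "medium": 0.50, "high": 0.75}

STATISTICS = (
    "lunge_count",
    "pieces_from_water",
    "pieces_from_prey",
    "pieces_total",
    "water_per_kg",
    "prey_per_kg",
    "total_per_kg",
)


@dataclass
class SpeciesPools:
    """Empirical pools backing the per-replicate draws for one species."""

    rate_pool: list[DielLungeRates]
    depth_mixture: dict[str, float]
    lengths: np.ndarray
    profiles: list[PlasticProfile]

    def validate(self) -> None:
        if not self.rate_pool or not len(self.lengths) or not self.profiles:
            raise ValueError("species pools must be non-empty")
        probs = np.array([self.depth_mixture.get(b, 0.0) for b in DEPTH_BINS])
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("depth mixture must be a probability vector over the bins")


@dataclass(frozen=True)
class PreyConfig:
    """Prey-field parameters for one prey type."""

    density_median: float  # kg m^-3
    density_sigma: float  # log-sd of the lognormal density
    individual_mass: float  # kg

    def __post_init__(self) -> None:
        if self.density_median <= 0 or self.individual_mass <= 0:
            raise ValueError("density_median and individual_mass must be > 0")


@dataclass
class ScenarioConfig:
    """The Monte Carlo contract: levels, pools, and the random-number seed."""

    pools: dict[str, SpeciesPools]
    prey: dict[str, PreyConfig]
    coeff_table: dict[tuple[str, str], AllometryCoefficients]
    retention: dict[str, float] = field(default_factory=lambda: dict(RETENTION_BY_LEVEL))
    fo_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in FO_TABLE.items()}
    )
    n_replicates: int = 1000
    seed: int = 0
    expectation_split: bool = False  # split f across bins by expectation, not multinomial

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for level, r in self.retention.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention for {level!r} must be in [0, 1]")
        for prey, by_level in self.fo_table.items():
            for level, fo in by_level.items():
                if not 0.0 <= fo <= 1.0:
                    raise ValueError(f"FO for ({prey!r}, {level!r}) must be in [0, 1]")
        for pools in self.pools.values():
            pools.validate()


def _replicate_rng(seed: int, species: str, prey_type: str, i: int) -> np.random.Generator:
    """Deterministic substream for replicate i, independent of level and of
    the total replicate count."""
    key = zlib.crc32(f"{species}|{prey_type}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key, i)))


def draw_whale(
    config: ScenarioConfig,
    species: str,
    prey_type: str,
    rng: np.random.Generator,
    level: str = "medium",
) -> ExposureInputs:
    """Draw one simulated whale-day as a full set of exposure inputs."""
    pools = config.pools.get(f"{species}:{prey_type}", config.pools.get(species))
    if pools is None:
        raise KeyError(f"no pools configured for species {species!r}")
    prey_cfg = config.prey[prey_type]

    length = float(rng.choice(pools.lengths))
    morph = morphology_from_length(length, config.coeff_table, species)

    record = pools.rate_pool[rng.integers(len(pools.rate_pool))]
    hours = np.array([record.hours_day, record.hours_twilight, record.hours_night])
    if hours.sum() <= 0:
        raise ValueError(f"deployment {record.deployment_id!r} has zero diel hours")
    h24 = tuple(24.0 * hours / hours.sum())
    f = daily_lunge_count(record, h24)

    probs = np.array([pools.depth_mixture.get(b, 0.0) for b in DEPTH_BINS])
    if config.expectation_split:
        f_d = dict(zip(DEPTH_BINS, f * probs))
    else:
        n_lunges = int(round(f))
        f_d = dict(zip(DEPTH_BINS, rng.multinomial(n_lunges, probs).astype(float)))

    C_d = {}
    for b in DEPTH_BINS:
        prof = pools.profiles[rng.integers(len(pools.profiles))]
        C_d[b] = prof.concentrations[b]

    if prey_cfg.density_sigma > 0:
        rho = float(prey_cfg.density_median * np.exp(prey_cfg.density_sigma * rng.standard_normal()))
    else:
        rho = prey_cfg.density_median

    return ExposureInputs(
        V=morph.engulfment_volume,
        r=config.retention[level],
        f_d=f_d,
        C_d=C_d,
        rho_y=rho,
        m_y=prey_cfg.individual_mass,
        C_y=config.fo_table[prey_type][level],
        body_mass=morph.body_mass,
    )


@dataclass
class ScenarioCell:
    """Replicate-level results and summary for one (species, prey, level)."""

    species: str
    prey_type: str
    level: str
    replicates: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Median / Q1 / Q3 per statistic, linear-interpolation quantiles."""
        rows = []
        for stat in STATISTICS:
            q1, med, q3 = np.quantile(
                self.replicates[stat].values, [0.25, 0.5, 0.75], method="linear"
            )
            rows.append(
                {
                    "species": self.species,
                    "prey_type": self.prey_type,
                    "level": self.level,
                    "statistic": stat,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
        return pd.DataFrame(rows)


def run_scenario(
    config: ScenarioConfig, species: str, prey_type: str, level: str = "medium"
) -> ScenarioCell:
    """Run ``n_replicates`` independent whale-days for one scenario cell."""
    rows = []
    for i in range(config.n_replicates):
        rng = _replicate_rng(config.seed, species, prey_type, i)
        inputs = draw_whale(config, species, prey_type, rng, level=level)
        est = total_exposure(inputs)
        mass = inputs.body_mass
        rows.append(
            {
                "replicate": i,
                "lunge_count": inputs.f,
                "pieces_from_water": est.pieces_from_water,
                "pieces_from_prey": est.pieces_from_prey,
                "pieces_total": est.pieces_total,
                "body_mass": mass,
                "water_per_kg": est.pieces_from_water / mass,
                "prey_per_kg": est.pieces_from_prey / mass,
                "total_per_kg": est.pieces_total / mass,
            }
        )
    return ScenarioCell(species, prey_type, level, pd.DataFrame(rows))


@dataclass
class SimulationSummary:
    """Full scenario table plus retained replicate-level results."""

    table: pd.DataFrame
    cells: dict[tuple[str, str, str], ScenarioCell]


def scenario_table(
    config: ScenarioConfig,
    combinations: list[tuple[str, str]] | None = None,
    levels: tuple[str, ...] = LEVELS,
) -> SimulationSummary:
    """Summaries for every requested (species, prey type) x level cell.

    Combinations whose species has no configured pools are skipped with a
    logged warning, never silently.
    """
    if combinations is None:
        combinations = []
        for key in config.pools:
            if ":" in key:
                sp, py = key.split(":", 1)
                combinations.append((sp, py))
            else:
                combinations.extend((key, py) for py in config.prey)
    parts = []
    cells: dict[tuple[str, str, str], ScenarioCell] = {}
    for species, prey_type in combinations:
        if f"{species}:{prey_type}" not in config.pools and species not in config.pools:
            logger.warning("skipping %s/%s: no pools for species", species, prey_type)
            continue
        if prey_type not in config.prey:
            logger.warning("skipping %s/%s: no prey config", species, prey_type)
            continue
        for level in levels:
            cell = run_scenario(config, species, prey_type, level)
            cells[(species, prey_type, level)] = cell
            parts.append(cell.summary())
    table = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["species", "prey_type", "level", "statistic", "median", "q1", "q3"]
    )
    return SimulationSummary(table=table, cells=cells)


def compare_scenarios(summary: SimulationSummary) -> pd.DataFrame:
    """Ordered low/medium/high ranges of total daily pieces, with ratios.

    For each (species, prey type), reports the median and interquartile
    range of ``pieces_total`` per level, and the ratio of each level's
    median to the previous (lower) level's.
    """
    tab = summary.table
    totals = tab[tab["statistic"] == "pieces_total"]
    present_levels = [lv for lv in LEVELS if lv in set(totals["level"])]
    if len(present_levels) < 2:
        raise ValueError("compare_scenarios needs at least two levels")
    rows = []
    for (species, prey_type), grp in totals.groupby(["species", "prey_type"], sort=True):
        by_level = {lv: g.iloc[0] for lv, g in grp.groupby("level")}
        prev_median = None
        for lv in LEVELS:
            if lv not in by_level:
                logger.warning("level %r missing for %s/%s", lv, species, prey_type)
                continue
            rec = by_level[lv]
            ratio = rec["median"] / prev_median if prev_median else np.nan
            rows.append(
                {
                    "species": species,
                    "prey_type": prey_type,
                    "level": lv,
                    "median": rec["median"],
                    "q1": rec["q1"],
                    "q3": rec["q3"],
                    "ratio_to_previous_level": ratio,
                }
            )
            prev_median = rec["median"]
    return pd.DataFrame(rows)
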