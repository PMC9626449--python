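"""Glue between the synthetic generators, the config schema, and the engine.

Builds scenario-engine pools either directly (synthetic diel-rate records
with the configured rate structure — fast, used by the simulation CLI and
reproduction script) or through the full trace pipeline (generate traces,
detect lunges, estimate diel rates — used end-to-end in validation).
"""

from __future__ import annotations

import numpy as np

from .morphometrics import coeff_table_from_config
from .scenarios import ScenarioConfig, SpeciesPools, PreyConfig
from .synthetic import (
    PlasticProfile,
    ProfileSpec,
    gen_morphology_sample,
    gen_plastic_profile,
)
from .tagproc import DEPTH_BINS, DielLungeRates

__all__ = ["synthetic_rate_pool", "build_scenario_config"]


def synthetic_rate_pool(
    rates: dict[str, float],
    hours: dict[str, float],
    n_deployments: int,
    rate_sigma: float,
    seed: int,
) -> list[DielLungeRates]:
    """Synthetic deployment-level diel-rate records.

    Each deployment's three diel rates are the configured medians times a
    shared lognormal deployment effect (log-sd ``rate_sigma``), with mild
    independent jitter per period; diel hours get +/-15% jitter.
    """
    rng = np.random.default_rng(seed)
    pool = []
    for i in range(n_deployments):
        effect = np.exp(rate_sigma * rng.standard_normal())
        jit = np.exp(0.1 * rng.standard_normal(3))
        h = {p: v * rng.uniform(0.85, 1.15) for p, v in hours.items()}
        pool.append(
            DielLungeRates(
                deployment_id=f"synthetic-pool-{i}",
                rate_day=rates["day"] * effect * jit[0],
                rate_twilight=rates["twilight"] * effect * jit[1],
                rate_night=rates["night"] * effect * jit[2],
                hours_day=h["day"],
                hours_twilight=h["twilight"],
                hours_night=h["night"],
            )
        )
    return pool


def build_scenario_config(
    cfg: dict,
    seed: int,
    n_replicates: int | None = None,
    degenerate: bool = False,
    combinations: list[tuple[str, str]] | None = None,
) -> ScenarioConfig:
    """Assemble a ScenarioConfig from a loaded YAML config dict.

    Pools are keyed ``species:prey`` and populated from the synthetic
    generators at the configured study conditions.  With ``degenerate=True``
    every pool collapses to a single noiseless value and the depth split is
    done by expectation, so one replicate reproduces the deterministic
    exposure-equation evaluation exactly.
    """
    rng = np.random.default_rng(seed)
    rates_cfg = cfg["rates"]
    prof_cfg = cfg["profile"]
    pools: dict[str, SpeciesPools] = {}

    if combinations is None:
        combinations = [
            (sp, py)
            for sp in ("blue", "fin", "humpback")
            if sp in rates_cfg
            for py in rates_cfg[sp]
        ]

    for species, prey in combinations:
        sub = int(rng.integers(2**31))
        lcfg = cfg["lengths"][species]
        if degenerate:
            lengths = np.array([lcfg["mean"]])
            pool = synthetic_rate_pool(
                rates_cfg[species][prey], rates_cfg["hours"], 1, 0.0, sub
            )
            pool = [
                DielLungeRates(
                    deployment_id=pool[0].deployment_id,
                    rate_day=rates_cfg[species][prey]["day"],
                    rate_twilight=rates_cfg[species][prey]["twilight"],
                    rate_night=rates_cfg[species][prey]["night"],
                    hours_day=rates_cfg["hours"]["day"],
                    hours_twilight=rates_cfg["hours"]["twilight"],
                    hours_night=rates_cfg["hours"]["night"],
                )
            ]
            profiles = [
                gen_plastic_profile(
                    ProfileSpec(
                        surface_concentration=prof_cfg["surface_concentration"],
                        enrichment_factor=prof_cfg["enrichment_factor"],
                        noise_cv=0.0,
                        seed=sub,
                    )
                )
            ]
        else:
            lengths = gen_morphology_sample(
                species, 200, lcfg["mean"], lcfg["cv"], seed=sub
            )
            pool = synthetic_rate_pool(
                rates_cfg[species][prey],
                rates_cfg["hours"],
                int(rates_cfg.get("n_deployments", 12)),
                float(rates_cfg.get("rate_sigma", 0.4)),
                sub + 1,
            )
            profiles = [
                gen_plastic_profile(
                    ProfileSpec(
                        surface_concentration=prof_cfg["surface_concentration"],
                        enrichment_factor=prof_cfg["enrichment_factor"],
                        noise_cv=prof_cfg["noise_cv"],
                        seed=sub + 2 + k,
                    )
                )
                for k in range(int(prof_cfg.get("n_profiles", 8)))
            ]
        mixture = cfg["depth_mixture"][species][prey]
        pools[f"{species}:{prey}"] = SpeciesPools(
            rate_pool=pool,
            depth_mixture={b: float(mixture.get(b, 0.0)) for b in DEPTH_BINS},
            lengths=np.asarray(lengths, dtype=float),
            profiles=profiles,
        )

    prey_cfgs = {}
    for prey, p in cfg["prey"].items():
        prey_cfgs[prey] = PreyConfig(
            density_median=float(p["density_median"]),
            density_sigma=0.0 if degenerate else float(p["density_sigma"]),
            individual_mass=float(p["individual_mass"]),
        )

    sc = cfg["scenario"]
    return ScenarioConfig(
        pools=pools,
        prey=prey_cfgs,
        coeff_table=coeff_table_from_config(cfg["allometry"]),
        retention={k: float(v) for k, v in sc["retention"].items()},
        fo_table={p: {k: float(v) for k, v in d.items()} for p, d in sc["fo"].items()},
        n_replicates=n_replicates or int(sc.get("n_replicates", 1000)),
        seed=seed,
        expectation_split=degenerate,
    )
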