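# rorqualrisk

Depth-stratified microplastic-ingestion exposure modelling for
lunge-feeding rorqual whales (blue, fin, humpback).

Filter-feeding whales meet microplastic two ways: directly, by filtering
particle-laden seawater through their baleen, and indirectly, by trophic
transfer from krill swarms and forage-fish schools that have themselves
ingested plastic. Because rorquals feed mostly at depth — where measured
plastic concentrations in the California Current are up to tenfold the
surface value — surface-only concentration maps misstate the risk. This
package provides the full modelling chain used to quantify that risk, for
ecologists and ecotoxicologists working from biologging data:

1. **Tag-trace processing** — decimate 10 Hz depth/speed traces, detect
   lunge-feeding events by their kinematic signature (a distinct speed
   maximum followed by rapid deceleration with continued forward
   momentum), and label each event with a depth bin (0–0.5, 0.5–5, 5–50,
   50–150, >150 m) and a diel period from apparent solar elevation.
2. **Allometry** — map total body length to engulfment capacity per lunge
   and to body mass via configurable power laws.
3. **The exposure equation** — daily plastic ingestion

   ```
   P = V r Σ_d f_d C_d  +  (V f ρ_y / m_y) C_y        [pieces d⁻¹]
   ```

   where `V` is engulfment volume per lunge (m³), `r` baleen retention,
   `f_d` daily lunges in depth bin `d`, `C_d` the water concentration in
   that bin (pieces m⁻³), `f = Σ_d f_d`, `ρ_y` prey biomass density
   (kg m⁻³), `m_y` individual prey mass (kg), and `C_y` expected pieces
   per prey individual (frequency of occurrence × one piece per
   contaminated individual).
4. **Monte Carlo scenario engine** — low / medium / high risk scenarios
   (retention 25/50/75% paired with prey-contamination frequencies:
   krill 0.01/0.06/0.50, fish 0.02/0.30/0.77), 1000 replicates per cell,
   summarised as median and interquartile range per species × prey type.
5. **Bayesian rate comparison** — a hierarchical Poisson model with a
   log-hours offset and deployment random intercepts, fit by a
   Metropolis-within-Gibbs sampler (10,000 iterations, 1,000 burn-in), to
   compare krill- versus fish-feeding lunge rates.
6. **Synthetic data** — seeded generators for traces with embedded lunge
   signatures, depth-binned plastic profiles, body-length samples, and
   prey parameters, so the whole pipeline is testable without field data.

## Worked example

A single deterministic evaluation of the exposure equation for a large
blue whale (V = 80 m³, r = 0.5, 190 lunges split across depth bins against
a surface-to-depth enriched concentration profile, dense krill at
1.2 kg m⁻³, 0.1 g individuals, 6% contamination frequency):

```sh
$ cat inputs.yaml
V: 80.0
r: 0.5
f_d: {surface: 1, sub-surface: 4, shallow: 27, moderate: 86, deep: 72}
C_d: {surface: 1.0, sub-surface: 1.1, shallow: 2.2, moderate: 5.5, deep: 10.0}
rho_y: 1.2
m_y: 1.0e-4
C_y: 0.06

$ rorqualrisk expose --inputs inputs.yaml
pieces from water: 5.03 × 10^4 pp/d
pieces from prey:  1.09 × 10^7 pp/d
total pieces:      1.1 × 10^7 pp/d
trophic fraction:  99.54%
mass at 0.23 mg/piece: 2.53 kg/d
mass at 4.0 mg/piece: 44 kg/d
```

Reading: this whale filters ~50,000 pieces per day directly from water
but swallows ~10.9 million pieces inside its prey — more than 99% of its
plastic load arrives by trophic transfer — which converts to roughly
2.5–44 kg of plastic per day depending on per-piece mass.

The full stochastic pipeline runs as subcommands over CSV/YAML files:

```sh
rorqualrisk --seed 1 --out run/ synth            # synthetic deployment
rorqualrisk --out run/ lunges --trace run/trace.csv --meta run/trace_meta.json
rorqualrisk --out run/ rates  --trace run/trace.csv --meta run/trace_meta.json \
            --events run/events.csv
rorqualrisk --seed 1 --out run/ simulate          # 1000-replicate scenarios
rorqualrisk --out run/ report --summary run/summary.csv
```

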