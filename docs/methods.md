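# Methods

## The exposure model

Daily microplastic ingestion for one whale-day is

    P = V r Σ_d f_d C_d + (V f ρ_y / m_y) C_y     [pieces d⁻¹]

The first term is direct filtration: engulfment volume per lunge times
baleen retention times the depth-weighted product of lunge counts and
water concentrations. The second is trophic transfer: the number of prey
individuals consumed per day (total engulfed volume × prey biomass
density / individual mass) times the expected plastic pieces per
individual. `f` in the prey term is the total daily lunge count
`Σ_d f_d`; prey contamination is treated as depth-independent.

Assumptions inherited by everything downstream:

- **One piece per contaminated prey individual.** `C_y` equals the
  frequency of occurrence (FO), making the prey term a conservative
  expectation. At ~10⁷ prey individuals per day the binomial noise around
  this expectation is negligible, so the deterministic core uses the
  expectation rather than a draw.
- **No elimination kinetics.** P is gross daily ingestion, not body
  burden; egestion and nanoplastic fragmentation are out of scope.
- **V constant per individual.** Engulfment volume follows the
  individual's length, not lunge depth or prey type.
- Pieces are real-valued expectations throughout; rounding is display
  only.

## Tag processing

Traces are regularly sampled depth/speed series (10 Hz after decimation;
the decimator applies a zero-phase FIR anti-alias filter — odd-extension
padding, so constants survive exactly — then subsamples). A lunge is
confirmed where the speed reaches a local maximum of at least
`peak_speed_min` (default 2.5 m s⁻¹) and, within `decel_window` (20 s),
the steepest mean deceleration from the peak reaches `decel_min`
(0.15 m s⁻²) while speed stays positive — the kinematic signature of
engulfment with continued forward momentum. Candidates closer than
`refractory` (30 s) merge, keeping the larger peak. These thresholds are
detector parameters, recorded in run metadata, not field-calibrated
constants: the original event lists were manually confirmed, so the
defaults were chosen to be unambiguous against the synthetic background
(see below) and must be revisited for real tags.

Depth bins follow the water-column strata of the concentration profile:
surface 0–0.5 m, sub-surface 0.5–5 m, shallow 5–50 m, moderate 50–150 m,
deep >150 m, half-open `[lower, upper)` with boundary ties going to the
deeper-starting bin.

Diel periods come from apparent solar elevation at the deployment
position (NOAA low-precision ephemeris, refraction-corrected; verified
against an independent PSA implementation to <0.5°): day above 0°,
twilight 0° to −12° (nautical), night below. Deployment diel hours are
counted by classifying ~1-minute subintervals at their midpoints rather
than by a sunrise equation — uniform behaviour at high latitudes where
the sun may never cross a band boundary. A diel period with zero hours
yields an undefined (NaN) rate, never a division by zero.

## Allometry

Responses follow `log10(y) = a + b·log10(L)` with per-species
coefficients for engulfment volume (m³) and body mass (kg). The shipped
coefficients are **fixture values** chosen for field-plausible magnitudes
(a 22 m blue whale: V ≈ 80 m³, mass ≈ 1×10⁵ kg); published fits should
replace them via the `allometry:` config block for faithful work.

## Scenario engine

One replicate = one simulated whale-day:

1. length bootstrapped from the length pool → (V, mass);
2. one deployment bootstrapped from the diel-rate pool; its three diel
   rates are combined with its own diel-hour proportions rescaled to a
   24 h day, giving the daily lunge count f (deployments are shorter than
   a day; proportional rescaling preserves each deployment's diel
   structure);
3. f rounded and split across depth bins by a multinomial draw from the
   species × prey depth mixture (an expectation-split option exists and
   is used by the degenerate mode);
4. per-bin concentrations bootstrapped independently from the profile
   pool; prey density drawn lognormally around its median.

Retention and FO travel together as named levels — low (r = 0.25),
medium (r = 0.50), high (r = 0.75) with the FO table above; the three
published scenarios imply pairing rather than a 3×3 cross.

Random-number contract: replicate i's substream is derived from the root
seed and (species, prey) only — not from the scenario level or the total
replicate count. Levels therefore share draws, so risk is ordered
replicate-by-replicate across levels (exact stochastic dominance), the
linearity audits (scale all C_d by k ⇒ water term scales by k; scale FO
by k ⇒ prey term scales by k) hold exactly under matched seeds, and
replicate i is invariant to how many replicates are requested.
Summaries are median and interquartile range with linear-interpolation
quantiles; replicate-level tables are retained for audit.

## Rate model

Lunge counts per deployment are compared between prey types with

    c_i ~ Poisson(h_i · exp(α + β·1[krill] + u_i)),  u_i ~ N(0, σ²)

α, β ~ N(0, 10²), σ ~ half-N(0, 2). The sampler is random-walk
Metropolis-within-Gibbs: O(1) incremental updates for α and β (a uniform
shift of the linear predictor changes the Poisson log-likelihood through
two sufficient statistics), a vectorised elementwise update for u, a
log-scale update for σ, plus two "ridge" translation moves —
(α, u) → (α+d, u−d) and the krill analogue for β — that leave the
likelihood invariant and walk along the fixed-effect/random-intercept
ridge that otherwise throttles mixing. Proposal scales adapt toward ~40%
acceptance during burn-in only, preserving detailed balance afterwards.
Defaults: 10,000 iterations, 1,000 burn-in, yielding ~400 effective
draws of β on 100-deployment datasets; an effective sample size below
100 flags non-convergence in the output. `pMCMC` is
2·min(Pr(β>0), Pr(β<0)) floored at 1/n_draws.

## Synthetic data: what it emulates, and what it does not

The generators provide the statistical structure the analysis assumes,
at toy scale (tens of deployments rather than 191):

- **Traces**: Ornstein–Uhlenbeck background speed (mean 1.5 m s⁻¹, sd
  0.2 m s⁻¹, 10 s correlation time — 5 sd below the peak threshold, so
  false positives are rare by construction) with embedded signatures: a
  30 s linear ramp to a 3.5 m s⁻¹ peak, then exponential decay back to
  cruise with a 4 s time constant (back at cruise within ~15 s). Depths
  drawn from a configurable bin mixture (uniform within bin, deep bin
  truncated at 300 m); event clock times drawn from diel weights against
  the minute-classified deployment window, with a 90 s minimum spacing.
- **Profiles**: surface bin at the configured surface concentration
  (default 1 piece m⁻³), bins meeting the 200–600 m band at the
  enrichment multiple (default 10×), intermediate bins interpolated
  linearly in bin-midpoint depth; multiplicative noise floored at zero.
- **Lengths**: zero-truncated normal by default (lognormal optional);
  the distributional family of the drone-photogrammetry lengths is not
  published, so this is a stand-in.
- **Diel rates and prey**: deployment-level rate records whose implied
  daily lunge counts sit at the field-reported species medians (blue
  ~190, fin ~177, krill-feeding humpback ~276, fish-feeding humpback
  ~95 lunges d⁻¹), with lognormal deployment effects; prey density
  medians (krill 1.2 kg m⁻³, anchovy school 5.0 kg m⁻³, lognormal
  log-sd 0.5) chosen so per-lunge prey intake matches the magnitudes
  implied by published daily ingestion medians. Individual prey masses
  (krill 10⁻⁴ kg, anchovy 2×10⁻² kg) are fixture values.

Because the synthetic lunge signature is built to satisfy the default
detector, the near-perfect recall the tests demonstrate validates the
detector's *logic* (and its equivalence to a brute-force scan), not its
performance on real tags, where speed is itself estimated from tag
vibration and signatures vary. Likewise the scenario medians produced at
these defaults land at field-plausible magnitudes by construction of the
inputs; they are not independent confirmations of published totals.

## Numerical choices

- Quantiles: linear interpolation between order statistics.
- Exposure totals satisfy `total = water + prey` exactly (no separate
  accumulation).
- Validation errors are explicit: mismatched depth-bin label sets list
  the difference; NaN speeds name the first offending timestamp; a trace
  too short for the requested lunges raises a placement error; zero
  totals yield NaN trophic fractions rather than raising.
- CSV round trips preserve full float precision
  (`float_precision="round_trip"` on read).
- Every output CSV embeds the run-manifest hash (config + seed) in a
  comment header; manifest timestamps live only in the `manifest.json`
  sidecar so data files re-run byte-identically under a fixed seed.

## Problem sizes

Default test and reproduction sizes — 20 synthetic deployments for
detector validation, 200–1000 Monte Carlo replicates, 50 deployments per
prey type for rate-model recovery, 10,000 MCMC iterations — were chosen
as the smallest sizes at which the statistical checks are stable.

## Known limitations

- Orientation correction, speed-from-vibration calibration, and
  audio/video alignment are upstream of this artifact; traces must
  already carry depth and speed.
- No within-individual autocorrelation of lunge times; deployments are
  treated as independent.
- Prey contamination is depth-independent and capped at one piece per
  individual; both are conservative.
- No spatial modelling of whale movement or plastic advection.
- The flow-tank retention experiment enters only through the 25/50/75%
  retention levels in configuration.
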