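# Default configuration for the exposure pipeline.
#
# Allometry coefficients are FIXTURE values: field-plausible power-law fits
# (log10 response = a + b * log10 length) chosen to give realistic
# magnitudes (e.g. a 22 m blue whale engulfs ~80 m^3 per lunge and weighs
# ~1e5 kg).  Replace them with published coefficients for faithful work.

allometry:
  blue:
    volume: {a: -2.876, b: 3.56}
    mass: {a: 0.637, b: 3.25}
  fin:
    volume: {a: -2.933, b: 3.56}
    mass: {a: 0.471, b: 3.25}
  humpback:
    volume: {a: -2.665, b: 3.56}
    mass: {a: 0.856, b: 3.25}

lengths:  # mean total body length (m) and CV for synthetic length samples
  blue: {mean: 22.0, cv: 0.08}
  fin: {mean: 20.0, cv: 0.08}
  humpback: {mean: 13.0, cv: 0.10}

# Diel lunge rates (lunges h^-1) per species and prey type, with the
# diel-hour budget of a typical deployment window.  The implied daily lunge
# counts (rate . hours) sit at the field-reported medians: ~190 d^-1 for
# blue whales, ~177 for fin, ~276 for krill-feeding and ~95 for
# fish-feeding humpbacks.
rates:
  blue:
    krill: {day: 12.0, twilight: 8.0, night: 3.0}
  fin:
    krill: {day: 11.0, twilight: 7.5, night: 3.0}
  humpback:
    krill: {day: 18.0, twilight: 10.0, night: 4.0}
    fish: {day: 6.0, twilight: 4.0, night: 1.5}
  rate_sigma: 0.4     # lognormal spread of deployment-level rates
  hours: {day: 12.0, twilight: 2.0, night: 10.0}
  n_deployments: 12   # synthetic diel-rate pool size per species x prey

# Depth-bin mixtures of lunges per species and prey type; krill feeders
# concentrate below 50 m (blue ~84%, humpback ~69%), fish feeders shallower
# (~52% below 50 m).
depth_mixture:
  blue:
    krill: {surface: 0.002, sub-surface: 0.018, shallow: 0.14, moderate: 0.45, deep: 0.39}
  fin:
    krill: {surface: 0.005, sub-surface: 0.025, shallow: 0.22, moderate: 0.45, deep: 0.30}
  humpback:
    krill: {surface: 0.005, sub-surface: 0.025, shallow: 0.28, moderate: 0.42, deep: 0.27}
    fish: {surface: 0.01, sub-surface: 0.04, shallow: 0.43, moderate: 0.37, deep: 0.15}

detector:
  peak_speed_min: 2.5   # m s^-1
  decel_min: 0.15       # m s^-2
  decel_window: 20.0    # s
  refractory: 30.0      # s

diel:
  day_floor: 0.0        # solar elevation (deg) above which it is day
  twilight_floor: -12.0 # nautical twilight band down to this elevation

scenario:
  n_replicates: 1000
  retention: {low: 0.25, medium: 0.50, high: 0.75}
  fo:
    krill: {low: 0.01, medium: 0.06, high: 0.50}
    fish: {low: 0.02, medium: 0.30, high: 0.77}

# Prey-field parameters.  Densities are the biomass of the engulfed swarm
# volume; the medians are set so the implied per-lunge prey intake matches
# field-reported magnitudes for dense krill swarms and anchovy schools.
prey:
  krill:
    density_median: 1.2    # kg m^-3 within an engulfed krill swarm
    density_sigma: 0.5     # log-sd of the lognormal density
    individual_mass: 1.0e-4  # kg per individual (fixture)
  fish:
    density_median: 5.0    # kg m^-3 within an engulfed anchovy school
    density_sigma: 0.5
    individual_mass: 2.0e-2  # kg per anchovy-sized fish (fixture)

profile:
  surface_concentration: 1.0  # pieces m^-3 at the surface
  enrichment_factor: 10.0     # applied where bins meet 200-600 m
  noise_cv: 0.15
  n_profiles: 8               # vertical profile samples in the pool

mcmc:
  iterations: 10000
  burn_in: 1000

reporting:
  per_piece_mass_mg: [0.23, 4.0]  # light and heavy per-piece masses
  season_days: [90, 120]
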