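# Methods

## Scope and model overview

`luxuvi` implements a complete illuminance→UVI→vitamin-D pipeline: a
synthetic daylight generator standing in for a multi-year spectroradiometer
campaign at latitude 36.85°N, longitude 127.15°E (UTC+9); a feedforward
regression from (illuminance, solar zenith angle, calendar month) to UVI; a
portable inference artifact with an independent interpreter; and the
vitamin-D dose chain with its published factor tables. Everything a user
needs at run time is computable from a timestamp, a location and a lux
reading.

## Solar position

Zenith angles come from the NOAA solar-calculator equations (Meeus-style
low-accuracy sun): Julian-century polynomials for the sun's mean longitude,
mean anomaly, eccentricity and obliquity; the equation of centre; apparent
longitude including the leading nutation/aberration term; declination and
the equation of time; then the hour angle from true solar time. Against an
independent implementation that derives the hour angle via Greenwich
sidereal time and right ascension, agreement is better than 0.01° over a
full 365 × 24 grid. Atmospheric refraction is deliberately omitted: it
exceeds 0.1° only within ~2° of the horizon, where UVI is ~0 and no dose is
accrued. Timestamps must carry an explicit UTC offset; all arithmetic is
done in UTC, so local civil time conventions (the site uses UTC+9, no DST)
never enter the astronomy.

## Synthetic sky model

The generator is statistical, not radiative-transfer. Its purpose is to
reproduce the *summary statistics* of the original measurement campaign,
which was not published, so that the downstream pipeline can be exercised
and tested under realistic structure.

Clear-sky laws, with μ = cos(zenith):

    illuminance = e0 · μ^a        uvi = u_month · μ^b ,   b > a

Clouds draw a shared attenuation factor c per record (c = 1 with
probability `cloud_clear_prob`, else Beta(α, β)-distributed), applied with
different sensitivities — illuminance × c^p_lux, UVI × c^q_uvi with
q_uvi > p_lux, because water clouds remove proportionally more UV than
visible light. Independent log-normal noise exp(ε), ε ~ N(0, σ²), perturbs
UVI only. Records are generated on a fixed cadence, 05:00–20:00 local time
(a daytime measurement campaign), with below-horizon instants omitted; all
randomness flows from one seeded generator (default seed 42).

Parameters (defaults are the calibration output, see below):

| parameter | default | meaning |
|---|---|---|
| `e0` | 125 000 lux | clear-sky illuminance scale |
| `a` | 0.20 | illuminance zenith exponent |
| `u_month` | 5.0 … 11.4 … 3.4 | monthly clear-sky UVI amplitudes (peak June, trough Nov–Jan) |
| `b` | 1.25 | UVI zenith exponent |
| `cloud_clear_prob` | 0.80 | fraction of perfectly clear draws |
| `cloud_alpha`, `cloud_beta` | 3.0, 1.2 | Beta shape of the attenuation factor |
| `p_lux`, `q_uvi` | 0.55, 0.90 | cloud sensitivity exponents |
| `sigma_uvi` | 0.10 | log-scale UVI noise |

The small illuminance exponent `a` deserves a note: the campaign's
*monthly maximum* illuminance is 95–125 klux in every month of the year,
December included. A horizontal-irradiance cosine law (a ≈ 1) cannot do
that — cos(60°) alone would halve the winter maximum — so matching the
reported statistics forces a weak zenith dependence for illuminance while
UVI keeps a strong one (b = 1.25). The model describes the instrument's
reported behaviour, not textbook horizontal illuminance.

`true_uvi(zenith, month, illuminance)` inverts the illuminance cloud law
for c and applies it to the clear-sky UVI; with σ = 0 it reproduces
generated UVI exactly (machine precision), which makes it the ground-truth
oracle for function-recovery experiments.

### Calibration

`calibrate()` is a coordinate search over (cloud shape, sensitivity
exponents, noise scale, a common amplitude scale), each round multiplying
one knob by 1.2 or 1/1.2 and keeping the best proposal, until a seeded
one-year simulation at 10-minute cadence meets every target:

- Pearson r(illuminance, UVI) over daytime records = 0.766 ± 0.05,
- Pearson r(zenith, UVI) = −0.931 ± 0.03,
- annual (and monthly) maximum illuminance ∈ [95, 125] klux,
- maximum 13:00-hour June UVI ∈ [12, 15],
- mean UVI at 110 ± 2 klux at least 3× higher in May than in December.

The shipped defaults are that search's output and meet all targets with
margin for every probe seed tried (measured r(lux, uvi) ≈ 0.748–0.753,
r(zenith, uvi) ≈ −0.915 … −0.917, June maxima 12.8–14.6, ratio ≈ 3.5–3.6).

### What the generator does not emulate

Weather persistence (cloud draws are independent across records), aerosol
and ozone variability, horizon obstruction, sensor drift and calibration
error, and the published December anomaly in which the monthly *maximum*
13:00 UVI (≈ 4.4) sits well above the typical UVI at peak illuminance
(≈ 2): the generator honours the second, ratio-defining behaviour, so its
December 13:00 maxima are lower than the campaign's. Passing tests
therefore demonstrate that the pipeline recovers the structure this model
encodes, not that it would meet the same error targets on raw field data.

## Dataset construction

Daytime records (zenith < 90°) become rows of [illuminance, zenith?,
month one-hot?] — dimensions 1, 2 or 14 for the three input
configurations. Continuous features are min–max normalized to [0, 1] with
constants taken from the training split only (physical defaults 120 000 lux
and 90° apply before a split exists); targets stay in natural UVI units so
MAE is directly interpretable. The split is 70/15/15, stratified by
calendar month and fully determined by a seed — stratification matters
because the month effect is exactly what the third input configuration must
learn, so every month must appear in every split.

## Network and training

A fully connected ReLU MLP with a linear scalar output, default hidden
layout 2 × 64 (grid runs use widths {8, 16, 32, 64, 128}, depths 1–4).
Training is mini-batch Adam (lr 10⁻³, batch 256, 200 epochs) directly on
mean absolute error — the selection metric — with squared error available
as a flag; early stopping on validation MAE with patience 20 restores the
best snapshot. He-normal initialization; everything is reproducible from
one seed. Predictions are clamped at 0 (UVI is nonnegative). Grid-search
cells share one data partition and average 3 training seeds so MAE
differences reflect architecture, not split luck.

Two caveats from the MAE/Adam combination: the sign gradient keeps step
sizes near the learning rate even at the optimum, so very tight convergence
(≪ 0.05 UVI) needs a smaller learning rate than the default; and sparse
edge regions of feature space converge last. Neither matters at the noise
levels of the calibrated generator (held-out MAE ≈ 0.3 with noise, ≈ 0.01
noiseless).

## Portable format and interpreter

`export_lite` writes a versioned JSON container: layer shapes, activation
tags, row-major float32 weight/bias blocks in base64, a CRC-32 of the
weight bytes, the input layout and the normalization constants. The loader
validates the dimension chain, byte counts and checksum and rejects
tampered files. `luxuvi.lite` executes the container using only the
standard library — no numpy, no training code — building the feature vector
itself from raw inputs (lux, location, aware timestamp): it computes the
zenith angle, applies the embedded normalization and sets the month
one-hot. Because both routes consume the same float32 values, interpreter
and backend agree to < 10⁻⁵ absolutely; remaining differences are
float64-accumulation order. The interpreter returns exactly 0 when the sun
is at or below the horizon: UVI is physically zero at night and the network
never saw nighttime rows, so extrapolating it there would be meaningless.

## Dosimetry

For a constant-UVI exposure of duration t:

    E_UV  = UVI / 40            [W/m²]
    DUV   = E_UV · ASCF · GCF   [W/m²]
    VUD   = DUV · t             [J/m²]   (trapezoidal integral for sampled series)
    VitD  = 49 · VUD · STF · PBE · AF · SPF   [IU]

Factor tables (latitude-35°N seasonal values): ASCF 1.049/1.104/1.029/0.842
and GCF 0.600/0.600/0.655/0.655 for spring/summer/autumn/winter; STF
3.2/3 … 3.2/7.5 for Fitzpatrick types II–V; AF 1.0 (≤21 y), 0.83 (22–40),
0.66 (41–59), 0.49 (≥60); SPF is sunscreen *transmission* in (0, 1]. AF and
SPF enter multiplicatively — the alternative exponent reading AF^SPF is
rejected on physical grounds, since full blocking (SPF → 0) must drive the
dose to zero, not toward AF⁰ = 1.

Two findings from reproducing the published hour-by-hour worked example:

1. The printed doses in *both* seasons are generated by the winter factor
   pair ASCF·GCF = 0.842·0.655 and AF = 1.0 (per-UVI constant
   129.72 IU; fitted across all 40 cells), not by the summer factors or the
   over-21 age band the surrounding description suggests. The package keeps
   the documented seasonal table for real use and pins the fitted set in an
   explicit `TABLE_PRESET` used by the reproduction code.
2. Cells with small printed UVI are quantization-limited: a UVI printed to
   two decimals carries up to ~2% dose error near UVI 0.25 and ~17% at
   0.03. All cells with UVI ≥ 0.38, every named reference cell and all four
   column means reproduce within 0.5% (means within 0.05%); the winter
   cells at UVI 0.23 and 0.26 land at 1.24% and 0.61% and cannot be
   reconciled with the same constant that fits the other 38 cells.

## Numerical and design choices

- Daytime is zenith < 90° throughout; correlations over daytime records
  only (nighttime zeros would inflate them).
- CSV: comma-separated, ISO-8601 timestamps with offset, UTF-8, values at
  6 significant digits; invalid rows are dropped and counted, not fatal.
- Monthly statistics report maxima (illuminance over all records, UVI over
  the 13:00 local hour) and the within-month illuminance–UVI correlation.
- Problem sizes: the standard experiment is one calendar year at 10-minute
  cadence (~26 000 daytime records); ablation uses 2 × 16 networks over 5
  seeds, the width sweep 2-layer networks over 3 seeds — sizes chosen so the
  ordering and plateau conclusions are stable across seeds.
- Degenerate inputs fail loudly: zero-variance correlation, empty splits,
  dimension mismatches, non-finite losses and corrupted weight files all
  raise typed errors.

## Known limitations

The generator's independence assumptions make its correlation targets
easier to hit stably than field data would be; the network's accuracy on
real skies is bounded by how well the synthetic structure matches them. The
dose chain assumes constant UVI across an exposure (hourly-snapshot
design) and inherits the uncertainty of the published conversion factors,
which are seasonal averages at one latitude band. The solar module ignores
refraction and topographic shading by design.
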