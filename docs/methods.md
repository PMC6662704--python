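# Methods

## Vial mass balance

Each incubation vial (60 mL serum vial, ~10 mL wet sediment, 2.5–5 mL
degassed water) is sampled at the start and end of a ~2-week occasion.
Before each measurement 8 mL of N2 is added and the vial shaken, so the
measured headspace mixing ratio x is diluted; the dilution is undone with
the pressure ratio measured before/after the addition,
`x_corr = x · p_after / p_before`. After equilibration the total amount of
a gas is

    n = x_corr · p_before · [ V_hs / (R·T) + K_H · V_liq ]        (µmol)

with the headspace pool from the ideal gas law (R = 0.082057 L atm mol⁻¹ K⁻¹)
and the dissolved pool from Henry's law. The liquid phase is the added water
plus the sediment pore water (wet mass × water content, density
1 g mL⁻¹). `K_H` comes from the Wiesenburg & Guinasso (1979) Bunsen-coefficient
fit for CH4 (converted to mol L⁻¹ atm⁻¹ by dividing by 22.414 L mol⁻¹) and
from the Weiss (1974) K0 fit for CO2, both at salinity 0 ‰ (configurable)
and valid for 271–313 K. At 25 °C these give 1.41 × 10⁻³ (CH4) and
3.40 × 10⁻² (CO2) mol L⁻¹ atm⁻¹. Dissolved CO2 is treated with the Henry
constant only; carbonate speciation is out of scope.

Net formation rates are amount differences divided by the occasion length
and by dry mass (`rate_dw`) or carbon mass (`rate_c`); negative net rates
are retained, since the measured quantity is net formation (production minus
consumption). The 7 mL gas extraction removes gas at the headspace mixing
ratio, leaving the mixing ratio itself unchanged, so only the pressure-based
dilution enters the correction.

Early measurements of deep, low-activity slices can be biased by trace
oxygen left from sample preparation. The exclusion rule flags (never
deletes) the first k ∈ {0, 1, 2} occasions of slices deeper than the
sub-surface layer whose first-occasion rate falls below a threshold
(defaults: k = 1, 0.5 µmol gC⁻¹ d⁻¹). The criterion is not uniquely
determined by the data; both knobs are configuration keys and every flagged
row stays in the output for audit.

## Age-depth model

Assuming a constant multi-year sedimentation rate, a slice's age is

    age = (slice mid depth / total sediment depth) · reservoir age
          + incubation length / 365 d.

The slice midpoint represents the 4 cm interval; the reservoir age is
counted from July 1 of the closure year (closure months are rarely
reported; configurable) to the sampling date; a 365-day year is used
throughout. Interannual variability in sedimentation adds random, not
systematic, error to these ages and is not modelled.

TC and TN are measured only at incubation start and end and interpolated
linearly to each occasion. Against a first-order exponential N loss at
0.16 yr⁻¹ over the 739-day experiment, the maximum chord–curve gap (closed
form at the tangency point, cross-checked by grid search) is ≈0.0011% TN
for a deep-sediment TN of 0.1% and scales linearly with TN — below
elemental-analysis precision for deep layers, and ≈0.0034% at TN = 0.3%.

## Per-core decay model and transition age

Per core, slice-occasion replicate-mean rates (µmol gC⁻¹ d⁻¹) vs age are
fitted with

    rate(age) = a · exp(−b · age) + c,    a, c ≥ 0, b > 0,

one decaying pool plus a constant background pool. Fitting minimises
**ln-scale** residuals by default: scatter around the decay curve is
multiplicative (roughly constant ln-variance), and under such noise
natural-scale least squares inflates a and c by the lognormal mean factor
exp(s²/2) and yields badly under-covering Wald intervals. A natural-scale
option remains (`scale="natural"`), and is the automatic fallback when
non-positive net rates are present. Initialisation uses c₀ = min rate,
a₀ = range, b₀ from a log-linear fit of (rate − 0.9 c₀), with 10
multiplicatively jittered restarts (fixed restart seed) and best residual
sum wins. A fit is flagged non-converged when the optimiser fails, the
decaying pool vanishes (a < 10⁻⁸), or b pins at its bounds
(10⁻⁶–50 yr⁻¹) — typical for cores with short age gradients. Standard
errors are Gauss–Newton Wald errors on the fitting scale; in simulation at
ln-scale residual variance 0.28 with 28 points their 95% intervals cover
the truth for ~93/90/94% of runs (a/b/c). At that noise level the sampling
distribution of a is strongly right-skewed: its mean overshoots by ~25%
even though its median bias is <5%, which is why recovery is asserted on
medians.

The transition age to low background formation is where the curve's slope,
with rate in µmol gC⁻¹ d⁻¹ against age in years, flattens to 179°
(|d rate/d age| = tan 1° ≈ 0.01746). Since the derivative is −a·b·e^(−b·t),

    t* = ln(a·b / tan 1°) / b,   or 0 when a·b ≤ tan 1°.

Both the angle and the unit convention are scale-dependent choices, fixed
by configuration. The corresponding depth inverts the age-depth map
(incubation term 0) and is capped at the interface depth. Transition age vs
surface-sediment C:N uses a Pearson correlation plus an ordinary
least-squares slope.

## Lifetime integration

A reservoir of lifetime L = 100 y (configurable) receives one layer per
year; the layer deposited in year y ages to L − y. Per layer, formation
between ages t₀ and t₁ is analytic,

    I(t₀, t₁) = a/b · (e^(−b·t₀) − e^(−b·t₁)) + c · (t₁ − t₀),

in rate-years; ×365 d gives µmol gC⁻¹. The beyond-transition share counts
formation at ages > t* within *every* layer (not just layers currently
older than t*), i.e. the CH4 formed in sediment older than the transition
age; it is 1 at t* = 0, 0 for t* ≥ L, and monotone non-increasing in t*.
Reservoir summaries are unweighted means ± sd across cores. A background
rate r µmol gC⁻¹ d⁻¹ converts to an annual carbon loss of
r·10⁻⁶·12·365·100 % of layer C per year (0.438% at r = 1).

## Global model and back-transformation

All usable slice-occasion mean rates per dry weight (the dry-weight basis
avoids the built-in TC dependence of per-gC rates) are pooled and fitted by
OLS:

    ln(rate) = β₁ ln(Age) + β₂ TN + β₃ ln(Age)·TN + β₀,

with s² the residual mean square. Exponentiating an ln-scale prediction
estimates the median, not the mean, of a lognormal response, so predictions
are corrected by `rate_corr = exp(ln_mean + s²/2)` with variance
`rate_corr²·(exp(s²) − 1)`. Non-positive net rates cannot be
ln-transformed and are dropped with a logged count. The published
three-reservoir coefficients (−0.59, 6.46, −0.99, −3.12; s² = 0.28,
R² = 0.81, n = 764) are frozen in `PUBLISHED_MODEL` for prediction without
refitting. The ancillary TN–TC line is an ordinary regression of TN on TC.

## Synthetic generator

The generator emulates the study design: reservoirs CDU (oligotrophic,
closed 1994), CUN (mesotrophic, 1977) and FUN (eutrophic, 1969) with
chemistry and water-content bounds matching their reported ranges; 17 cores
with fixed per-core slice counts (CDU 6×2, FUN 4+4+3+3, CUN 3+3+2+2+2+2+2)
giving 42 four-cm slices, 17 of them at 2–6 cm; 3 replicate vials per
slice; 7 occasions at the reported average day windows over 739 days at
25 °C. Mean interface depths (CDU 30, FUN 160, CUN 35 cm, ±30% per core)
are chosen so the depth-age gradients resemble the reported per-reservoir
age spans. TC is uniform within the reservoir range and TN is drawn around
0.067·TC + 0.077 (sd 0.03%), rejection-sampled into range; TC/TN decline
exponentially over the incubation at 0.08/0.16 yr⁻¹. True per-core
parameters are a ~ log-uniform [1, 35] µmol gC⁻¹ d⁻¹, b ~ uniform
[0.05, 0.6] yr⁻¹, c ~ uniform [0.1, 1.2] µmol gC⁻¹ d⁻¹, spanning the
reported rate extremes; CO2 is generated at a per-core multiple (1.5–3×) of
the CH4 curve.

Noise has two layers: a slice-occasion ln-scale residual
(sd √0.28, shared across replicates, since the global model's s² is a
slice-level quantity) and a per-replicate multiplicative lognormal factor
with unit mean and CV 8.6%. The noisy rates are inverted through the exact
vial mass balance above (baseline post-flush headspace of 5 ppm CH4 /
20 ppm CO2, 1 atm before N2 addition, 8 mL N2 into a 47.5 mL headspace);
draws implying negative amounts would be resampled and counted, never
clipped (they cannot occur with lognormal noise, but the guard is kept for
configurability). Consequently the pipeline applied to zero-noise output
reproduces `a·exp(−b·age)+c` to machine precision — this round-trip is the
core correctness test. One integer seed drives all substreams.

The regression-design generator draws Age log-uniform on 1–48 y and TN
uniform on 0.1–0.8% (the observed covariate ranges; the true field
distributions are unknown) and adds Gaussian ln-scale noise of variance s²
to the model surface.

What the generator does **not** emulate: spatial structure among coring
sites, hydrological variability in sedimentation rate, correlated TC/TN
measurement error, drifting incubation temperature, and any coupling of the
per-core decay truth to the ln(Age)×TN surface — so the synthetic global
fit's R²/s² differ from the field values, and passing tests demonstrate
correctness of the computational chain, not field realism.

## Problem sizes and numerical choices

Stochastic recovery checks use 200 refits of n = 764 (global model) and
200–1000 decay fits of 28 points; property sweeps use 1000 random parameter
draws (closed forms vs `brentq` root-finding at 1e-9 and vs adaptive
quadrature at 1e-8). The lifetime double sum is validated against a
brute-force daily summation. CSV outputs are byte-reproducible for a fixed
seed and configuration.

## Known limitations

- Rates are at a standardised 25 °C; in-situ prediction requires an
  external temperature correction, deliberately out of scope.
- The exclusion criterion for oxygen-contaminated early measurements is
  heuristic and configurable, not estimated from data.
- The transition age is operational and unit-dependent (179° on the
  µmol gC⁻¹ d⁻¹ vs years plane), not a mechanistic threshold.
- Two-slice cores leave (a, b) weakly identified at realistic noise;
  such fits are flagged rather than repaired, and short-gradient cores
  should be interpreted through the flags.
- Per-core fits are independent ("core as a factor"); no shared or
  mixed-effects formulation is provided.
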