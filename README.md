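# sedch4

Methane formation in reservoir sediments, predicted from sediment age and
nitrogen content.

Freshwater reservoirs — tropical ones in particular — emit substantial CH4,
and that CH4 is produced microbially in their anoxic sediments. `sedch4`
implements the complete computational chain used to quantify how sediment
CH4 formation declines as organic matter ages, starting from raw anoxic
incubation vial measurements and ending at a global predictive model:

1. **Gas calculations** (`sedch4.gascalc`) — headspace mixing ratios,
   vial pressures before/after N2 addition, and vial geometry are converted
   into total (headspace + dissolved) CH4 and CO2 amounts via the ideal gas
   law and Henry's law (CH4 solubility after Wiesenburg & Guinasso; CO2
   after Weiss), then differenced over each ~2-week sampling occasion into
   net formation rates per g dry weight and per g C.
2. **Age model** (`sedch4.agemodel`) — each sediment slice is dated from the
   multi-year average sedimentation rate:
   `age = (layer depth / total sediment depth) · reservoir age + incubation length`,
   and TC/TN are interpolated linearly across the incubation.
3. **Decay fits** (`sedch4.decayfit`) — per core, rates vs age are fitted
   with the exponential decay model `rate = a·exp(−b·Age) + c` (a decaying
   pool plus a constant background pool). The **transition age** — where the
   modelled curve flattens to a 179° slope, i.e. |d rate/d Age| = tan 1° —
   has the closed form `t* = ln(a·b / tan 1°) / b`.
4. **Lifetime integration** (`sedch4.lifetime`) — with yearly layer
   deposition over a 100-year reservoir lifetime, each layer's CH4 formation
   is integrated analytically and the share formed beyond the transition age
   is reported per core and per reservoir.
5. **Global model** (`sedch4.globalmodel`) — pooling all rates,
   `ln(CH4) = β₁·ln(Age) + β₂·TN + β₃·ln(Age)·TN + β₀` is fitted by OLS;
   back-transformed predictions are bias-corrected with the residual
   variance s²: `rate_corr = exp(ln_mean + s²/2)`,
   `var_corr = rate_corr²·(exp(s²) − 1)`. The published coefficient set
   (−0.59, 6.46, −0.99, −3.12; s² = 0.28) ships as `PUBLISHED_MODEL`.
6. **Synthetic data** (`sedch4.synthdata`) — a seeded generator reproduces
   the study design (3 reservoirs, 17 cores, 42 slices, 3 replicates,
   7 occasions over 739 days) and *inverts* the vial mass balance, so the
   whole pipeline is testable end to end without the field dataset.

It is aimed at biogeochemists working with sediment incubation experiments
who want reproducible rate calculations and a reference implementation of
the age×TN prediction model.

## Worked example

Run the full pipeline on synthetic data and predict a rate:

```sh
$ sedch4 run-all --seed 2 --out out/
$ sedch4 predict --age 10 --tn 0.5 --published-coefficients
ln_mean    -2.3883
rate_naive 0.09179 umol/g(dw)/d
rate_corr  0.1056 umol/g(dw)/d
var_corr   0.003602
```

Ten-year-old sediment with 0.5% TN is predicted to form CH4 at
0.106 µmol g(dw)⁻¹ d⁻¹ (the bias-corrected mean; the naive back-transform
0.092 underestimates the lognormal mean). The pipeline run writes
`slices.csv`, `vials.csv`, `rates.csv`, `decay_fits.csv`, `transition.csv`,
`lifetime.csv`, `reservoir_summary.csv`, `global_model.json` and a
`report.json` that summarises, per reservoir, the transition age/depth and
the beyond-transition share of lifetime CH4 formation — e.g. for seed 2 the
synthetic CDU reservoir gives transition age 11.0 ± 4.2 y at 17.2 ± 8.5 cm
with 34.5 ± 13.5% of lifetime CH4 formed beyond it. With all noise switched
off the pipeline recovers the generating (a, b, c), transition ages and
beyond-transition fractions to better than 1e-6 relative.

The same commands accept user-supplied `slices.csv`/`vials.csv` in the
documented dialects (`sedch4 validate` checks them).

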