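"""Seeded synthetic reservoirs, cores, slices and raw incubation tables.

The generator emulates the incubation study design the analysis assumes:
three tropical reservoirs of contrasting trophic state, 17 gravity cores,
42 sediment slices (17 sub-surface at 2-6 cm plus 25 deeper, 4 cm wide),
3 replicate vials per slice, and 7 sampling occasions spread over 739 days
at 25 °C.  Each core carries true decay parameters (a, b, c); each
slice-occasion rate gets a shared ln-scale residual (variance ~0.28) and
each replicate a multiplicative lognormal error with CV ~8.6%.  Crucially,
the noisy rates are then *inverted* through the same vial mass balance used
by :mod:`sedch4.gascalc`, so the emitted raw observables (ppm mixing ratios,
pressures, volumes, dry mass) round-trip through the rate pipeline to the
generating rates exactly at zero noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import R_L_ATM, YEAR_DAYS
from . import agemodel, gascalc
from .globalmodel import GlobalModel, PUBLISHED_MODEL

# --------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class ReservoirSpec:
    """One reservoir's history, chemistry bounds and coring design."""

    name: str
    closure_year: int
    sampling_date: str            # ISO date
    trophic_label: str
    tc_range: tuple               # mass % (min, max)
    tn_range: tuple               # mass % (min, max)
    water_range: tuple            # fraction (min, max)
    n_cores: int
    mean_total_depth_cm: float
    slices_per_core: tuple        # length n_cores, entries 1..4

    def __post_init__(self):
        from datetime import date
        if self.closure_year >= date.fromisoformat(self.sampling_date).year:
            raise ValueError("closure year must precede sampling year")
        for rng in (self.tc_range, self.tn_range):
            if not (0 < rng[0] <= rng[1]):
                raise ValueError("chemistry ranges need 0 < min <= max")
        if self.n_cores < 1:
            raise ValueError("need at least one core")
        if len(self.slices_per_core) != self.n_cores:
            raise ValueError("slices_per_core must have n_cores entries")
        if any(not 1 <= k <= 4 for k in self.slices_per_core):
            raise ValueError("slices per core must be between 1 and 4")


@dataclass(frozen=True)
class NoiseSpec:
    replicate_cv: float = 0.086
    ln_residual_sd: float = float(np.sqrt(0.28))
    seed: int = 0

    def __post_init__(self):
        if self.replicate_cv < 0 or self.ln_residual_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")


@dataclass(frozen=True)
class TrueCoreParams:
    core_id: str
    a_true: float        # µmol gC^-1 d^-1
    b_true: float        # yr^-1
    c_true: float        # µmol gC^-1 d^-1
    total_depth_cm: float
    n_slices: int

    def __post_init__(self):
        if self.a_true < 0 or self.b_true <= 0 or self.c_true < 0:
            raise ValueError("require a >= 0, b > 0, c >= 0")
        if not 1 <= self.n_slices <= 4:
            raise ValueError("slices per core must be between 1 and 4")


# Study-like defaults: trophic state, dam closure, Table-1-style chemistry
# bounds, and per-core slice counts summing to 42 (17 sub-surface + 25 deep).
DEFAULT_RESERVOIRS = (
    ReservoirSpec("CDU", 1994, "2016-03-07", "oligotrophic",
                  (0.9, 10.2), (0.1, 0.8), (0.48, 0.81),
                  6, 30.0, (2, 2, 2, 2, 2, 2)),
    ReservoirSpec("FUN", 1969, "2016-03-14", "eutrophic",
                  (1.8, 4.0), (0.2, 0.4), (0.53, 0.81),
                  4, 160.0, (4, 4, 3, 3)),
    ReservoirSpec("CUN", 1977, "2016-02-20", "mesotrophic",
                  (2.3, 12.3), (0.1, 0.8), (0.42, 0.87),
                  7, 35.0, (3, 3, 2, 2, 2, 2, 2)),
)

#: Average day windows (start, end) of the seven sampling occasions.
DEFAULT_SCHEDULE = ((1, 9), (9, 28), (72, 91), (185, 200),
                    (275, 290), (423, 442), (719, 736))

SLICE_THICKNESS_CM = 4.0
SURFACE_SLICE = (2.0, 6.0)
INCUBATION_DAYS = 739.0
INCUBATION_TEMP_K = 298.15
VIAL_ML = 60.0
SEDIMENT_ML = 10.0
WATER_ADDED_ML = 2.5
N2_ADDED_ML = 8.0
WET_MASS_G = 11.0            # 10 mL wet sediment at ~1.1 g/mL bulk density
TN_TC_SLOPE = 0.067
TN_TC_INTERCEPT = 0.077
TN_DECAY_PER_Y = 0.16        # first-order TN loss over the incubation
TC_DECAY_PER_Y = 0.08
A_RANGE = (1.0, 35.0)        # log-uniform initial-pool reactivity
B_RANGE = (0.05, 0.6)        # uniform decay constant
C_RANGE = (0.1, 1.2)         # uniform background pool
BASELINE_CH4_PPM = 5.0       # post-flush residual headspace CH4
BASELINE_CO2_PPM = 20.0
CO2_FACTOR_RANGE = (1.5, 3.0)


def _min_depth_for(n_slices: int) -> float:
    """Smallest interface depth (cm) holding n non-overlapping 4 cm slices
    with one fixed at 2-6 cm and the rest evenly spread down to the bottom."""
    w = SLICE_THICKNESS_CM
    if n_slices == 1:
        return SURFACE_SLICE[1]
    if n_slices == 2:
        return SURFACE_SLICE[1] + w
    # intermediate tops are linspace(6, depth-4, n)[1:-1]; spacing >= w
    return SURFACE_SLICE[1] + w + (n_slices - 1) * w


def _slice_intervals(total_depth: float, n_slices: int) -> list[tuple[float, float]]:
    """Non-overlapping 4 cm slice intervals: one sub-surface, rest spread to
    just above the soil-sediment interface."""
    w = SLICE_THICKNESS_CM
    if total_depth < _min_depth_for(n_slices):
        raise ValueError(f"total depth {total_depth} cm cannot hold "
                         f"{n_slices} non-overlapping {w} cm slices")
    tops = [SURFACE_SLICE[0]]
    if n_slices >= 2:
        deepest_top = total_depth - w
        if n_slices == 2:
            mids = []
        else:
            mids = list(np.linspace(SURFACE_SLICE[1], deepest_top, n_slices)[1:-1])
        tops += mids + [deepest_top]
    return [(round(t, 1), round(t + w, 1)) for t in tops]


def generate_design(reservoir_specs=DEFAULT_RESERVOIRS,
                    noise: NoiseSpec | None = None,
                    seed: int | None = None):
    """Generate the slice table and the true per-core parameter table.

    Returns ``(slices, truth)`` DataFrames.  With the default specs this
    reproduces the study's shape: 3 reservoirs, 17 cores, 42 slices of which
    17 occupy the 2-6 cm sub-surface layer.  TN is drawn correlated with TC
    (TN ~ 0.067 TC + 0.077 plus noise) and rejection-sampled into the
    reservoir's configured range.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    slice_rows, truth_rows = [], []
    for spec in reservoir_specs:
        duration_y = INCUBATION_DAYS / YEAR_DAYS
        for i in range(spec.n_cores):
            core_id = f"{spec.name}_{i + 1:02d}"
            n_slices = spec.slices_per_core[i]
            min_depth = _min_depth_for(n_slices) + 2.0
            depth = max(float(spec.mean_total_depth_cm * rng.uniform(0.7, 1.3)),
                        min_depth)
            depth = round(depth, 1)  # match 0.1 cm slice-boundary resolution
            a = float(np.exp(rng.uniform(*np.log(A_RANGE))))
            b = float(rng.uniform(*B_RANGE))
            c = float(rng.uniform(*C_RANGE))
            co2_factor = float(rng.uniform(*CO2_FACTOR_RANGE))
            truth_rows.append(dict(reservoir=spec.name, core_id=core_id,
                                   a_true=a, b_true=b, c_true=c,
                                   co2_factor=co2_factor,
                                   total_depth_cm=depth, n_slices=n_slices))
            for j, (top, bottom) in enumerate(_slice_intervals(depth, n_slices)):
                tc = float(rng.uniform(*spec.tc_range))
                tn = _draw_tn(rng, tc, spec.tn_range)
                wc = float(rng.uniform(*spec.water_range))
                slice_rows.append(dict(
                    slice_id=f"{core_id}_s{j + 1}",
                    reservoir=spec.name, core_id=core_id,
                    slice_top_cm=top, slice_bottom_cm=bottom,
                    total_depth_cm=depth,
                    closure_year=spec.closure_year,
                    sampling_date=spec.sampling_date,
                    water_content_frac=wc,
                    tc_pct_start=tc,
                    tn_pct_start=tn,
                    tc_pct_end=tc * float(np.exp(-TC_DECAY_PER_Y * duration_y)),
                    tn_pct_end=tn * float(np.exp(-TN_DECAY_PER_Y * duration_y)),
                    dry_mass_g=WET_MASS_G * (1.0 - wc),
                ))
    return pd.DataFrame(slice_rows), pd.DataFrame(truth_rows)


def _draw_tn(rng, tc: float, tn_range: tuple, sd: float = 0.03,
             max_tries: int = 100) -> float:
    mean = TN_TC_SLOPE * tc + TN_TC_INTERCEPT
    for _ in range(max_tries):
        tn = mean + rng.normal(0.0, sd)
        if tn_range[0] <= tn <= tn_range[1]:
            return float(tn)
    return float(np.clip(mean, *tn_range))


def generate_incubation(slices: pd.DataFrame, truth: pd.DataFrame,
                        noise: NoiseSpec | None = None,
                        schedule=DEFAULT_SCHEDULE,
                        n_replicates: int = 3) -> pd.DataFrame:
    """Emit the raw per-vial measurement table (``vials.csv`` dialect).

    For every slice, replicate and occasion the true carbon-normalised rate
    ``a*exp(-b*age)+c`` is evaluated at the occasion midpoint age, perturbed
    by the shared ln-scale residual and the per-replicate lognormal error,
    and inverted through the vial mass balance into start/end ppm such that
    :func:`sedch4.gascalc.compute_rates` (+ age annotation) recovers the
    noisy rate exactly.  Draws that would imply a negative gas amount are
    resampled, never clipped; the resample count is recorded in
    ``df.attrs["n_resampled"]``.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    tru = truth.set_index("core_id")
    k_ch4 = gascalc.solubility("ch4", INCUBATION_TEMP_K).value
    k_co2 = gascalc.solubility("co2", INCUBATION_TEMP_K).value
    headspace_ml = VIAL_ML - SEDIMENT_ML - WATER_ADDED_ML
    p_before = 1.0
    p_after = p_before * (1.0 + N2_ADDED_ML / headspace_ml)
    dil = p_after / p_before

    ln_sigma2 = np.log1p(noise.replicate_cv ** 2)
    ln_sigma = np.sqrt(ln_sigma2)

    rows = []
    n_resampled = 0
    for sl in slices.itertuples(index=False):
        core = tru.loc[sl.core_id]
        res_age = agemodel.reservoir_age_years(sl.closure_year, sl.sampling_date)
        geom = agemodel.CoreGeometry(sl.total_depth_cm, res_age)
        mid_depth = (sl.slice_top_cm + sl.slice_bottom_cm) / 2.0
        liquid_ml = WATER_ADDED_ML + WET_MASS_G * sl.water_content_frac
        conv_ch4 = dil * p_before * (headspace_ml / 1000.0 / (R_L_ATM * INCUBATION_TEMP_K)
                                     + k_ch4 * liquid_ml / 1000.0) * 1e6
        conv_co2 = dil * p_before * (headspace_ml / 1000.0 / (R_L_ATM * INCUBATION_TEMP_K)
                                     + k_co2 * liquid_ml / 1000.0) * 1e6
        for occ, (d0, d1) in enumerate(schedule, start=1):
            day_mid = (d0 + d1) / 2.0
            age = agemodel.sample_age(mid_depth, geom, incubation_days=day_mid)
            true_ch4 = core.a_true * np.exp(-core.b_true * age) + core.c_true
            true_co2 = true_ch4 * core.co2_factor
            # slice-occasion residual, shared across replicates
            eps_ch4 = rng.normal(0.0, noise.ln_residual_sd)
            eps_co2 = rng.normal(0.0, noise.ln_residual_sd)
            frac = day_mid / INCUBATION_DAYS
            tc_mid = sl.tc_pct_start + (sl.tc_pct_end - sl.tc_pct_start) * frac
            carbon_g = sl.dry_mass_g * tc_mid / 100.0
            dt = float(d1 - d0)
            for rep in range(1, n_replicates + 1):
                for _ in range(1000):
                    rep_ch4 = np.exp(rng.normal(-ln_sigma2 / 2, ln_sigma))
                    rep_co2 = np.exp(rng.normal(-ln_sigma2 / 2, ln_sigma))
                    r_ch4 = true_ch4 * np.exp(eps_ch4) * rep_ch4
                    r_co2 = true_co2 * np.exp(eps_co2) * rep_co2
                    ch4_end = (BASELINE_CH4_PPM * 1e-6 * conv_ch4
                               + r_ch4 * carbon_g * dt)
                    co2_end = (BASELINE_CO2_PPM * 1e-6 * conv_co2
                               + r_co2 * carbon_g * dt)
                    if ch4_end >= 0 and co2_end >= 0:
                        break
                    n_resampled += 1
                else:
                    raise RuntimeError("could not draw a physical measurement")
                rows.append(dict(
                    core_id=sl.core_id, slice_id=sl.slice_id, replicate=rep,
                    occasion=occ, day_start=float(d0), day_end=float(d1),
                    temp_K=INCUBATION_TEMP_K,
                    pressure_before_atm=p_before, pressure_after_atm=p_after,
                    headspace_ml=headspace_ml, liquid_ml=liquid_ml,
                    ch4_ppm_start=BASELINE_CH4_PPM,
                    ch4_ppm_end=ch4_end / conv_ch4 * 1e6,
                    co2_ppm_start=BASELINE_CO2_PPM,
                    co2_ppm_end=co2_end / conv_co2 * 1e6,
                ))
    vials = pd.DataFrame(rows)
    vials.attrs["n_resampled"] = n_resampled
    return vials


def generate_regression_design(n: int, age_range=(1.0, 48.0),
                               tn_range=(0.1, 0.8),
                               coeffs: GlobalModel = PUBLISHED_MODEL,
                               seed: int = 0) -> pd.DataFrame:
    """Synthetic (age, TN, ln_rate) table from the global model surface.

    Age is log-uniform over ``age_range`` (years), TN uniform over
    ``tn_range`` (mass %), and ln_rate adds Gaussian noise of variance
    ``coeffs.s2`` to the model surface.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if age_range[0] <= 0:
        raise ValueError("ages must be positive")
    rng = np.random.default_rng(seed)
    age = np.exp(rng.uniform(np.log(age_range[0]), np.log(age_range[1]), n))
    tn = rng.uniform(tn_range[0], tn_range[1], n)
    ln_rate = coeffs.ln_mean(age, tn) + rng.normal(0.0, np.sqrt(coeffs.s2), n)
    return pd.DataFrame(dict(age_years=age, tn_pct=tn, ln_rate=ln_rate))


def write_outputs(slices: pd.DataFrame, vials: pd.DataFrame,
                  truth: pd.DataFrame, outdir, seed: int) -> None:
    """Write ``slices.csv``, ``vials.csv`` and the ``truth.json`` sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    slices.to_csv(outdir / "slices.csv", index=False)
    vials.to_csv(outdir / "vials.csv", index=False)
    payload = dict(seed=seed,
                   n_resampled=int(vials.attrs.get("n_resampled", 0)),
                   cores=truth.to_dict(orient="records"))
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2))
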