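"""Headspace vial gas calculations.

Converts raw incubation observables (headspace mixing ratios, vial pressures
before/after N2 addition, volumes, dry mass) into total dissolved + headspace
gas amounts and net CH4/CO2 formation rates.

The vial mass balance accounts for two pools after equilibration by shaking:

* headspace:  n_hs = x * P * V_hs / (R * T)          (ideal gas law)
* dissolved:  n_aq = x * P * K_H * V_liq             (Henry's law)

where ``x`` is the N2-dilution-corrected mixing ratio, ``P`` the vial pressure
before N2 addition (so that ``x*P`` is the CH4 partial pressure at
equilibrium), and ``K_H`` a Henry-type solubility in mol L^-1 atm^-1.

Solubilities follow the temperature/salinity parameterizations of
Wiesenburg & Guinasso (1979) for CH4 (Bunsen coefficient divided by the molar
volume at STP) and Weiss (1974) for CO2 (K0 form).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import MOLAR_VOLUME_STP, R_L_ATM

GASES = ("ch4", "co2")

# ln(beta) Bunsen coefficient fit, mL gas (STP) per mL water per atm.
_CH4_BUNSEN = dict(a1=-68.8862, a2=101.4956, a3=28.7314,
                   b1=-0.076146, b2=0.043970, b3=-0.0068672)
# ln(K0) fit, mol L^-1 atm^-1.
_CO2_K0 = dict(a1=-58.0931, a2=90.5069, a3=22.2940,
               b1=0.027766, b2=-0.025888, b3=0.0050578)

TEMP_MIN_K = 271.0
TEMP_MAX_K = 313.0


@dataclass(frozen=True)
class SolubilityCoefficient:
    """Henry-type solubility of one gas at one temperature/salinity."""

    gas: str
    value: float          # mol L^-1 atm^-1
    temp_k: float
    salinity: float       # per mil


def _ln_fit(coeff: dict, temp_k: float, salinity: float) -> float:
    t100 = temp_k / 100.0
    return (coeff["a1"] + coeff["a2"] / t100 + coeff["a3"] * np.log(t100)
            + salinity * (coeff["b1"] + coeff["b2"] * t100 + coeff["b3"] * t100 ** 2))


def solubility(gas: str, temp_k: float, salinity: float = 0.0) -> SolubilityCoefficient:
    """Henry-type solubility coefficient in mol L^-1 atm^-1.

    Parameters
    ----------
    gas : {"ch4", "co2"}
    temp_k : float
        Water temperature in kelvin; valid 271-313 K.
    salinity : float
        Salinity in per mil (0 for freshwater).
    """
    if not TEMP_MIN_K < temp_k < TEMP_MAX_K:
        raise ValueError(f"temperature {temp_k} K outside valid range "
                         f"({TEMP_MIN_K}, {TEMP_MAX_K}) K")
    if salinity < 0:
        raise ValueError("salinity must be >= 0")
    gas = gas.lower()
    if gas == "ch4":
        value = float(np.exp(_ln_fit(_CH4_BUNSEN, temp_k, salinity))) / MOLAR_VOLUME_STP
    elif gas == "co2":
        value = float(np.exp(_ln_fit(_CO2_K0, temp_k, salinity)))
    else:
        raise ValueError(f"unknown gas {gas!r}; expected one of {GASES}")
    return SolubilityCoefficient(gas=gas, value=value, temp_k=temp_k, salinity=salinity)


def dilution_factor(pressure_before_atm: float, pressure_after_atm: float) -> float:
    """Mixing-ratio correction factor for N2 addition, = p_after / p_before.

    Adding N2 raises the vial pressure and dilutes the measured mixing ratio;
    multiplying the measured ratio by this factor undoes the dilution.
    """
    if pressure_before_atm <= 0:
        raise ValueError("pressure_before must be > 0")
    if pressure_after_atm < pressure_before_atm:
        raise ValueError(
            f"pressure after N2 addition ({pressure_after_atm}) below pressure "
            f"before ({pressure_before_atm}): data-quality error")
    return pressure_after_atm / pressure_before_atm


def total_gas_amount(mixing_ratio, pressure_atm, temp_k, headspace_l, liquid_l,
                     gas: str = "ch4", salinity: float = 0.0):
    """Total (headspace + dissolved) gas amount in a vial, in µmol.

    ``mixing_ratio`` is a mol fraction (already dilution-corrected);
    ``mixing_ratio * pressure_atm`` is the partial pressure driving both the
    ideal-gas headspace pool and the Henry dissolved pool.
    """
    k_h = solubility(gas, float(temp_k), salinity).value
    p_partial = np.asarray(mixing_ratio) * np.asarray(pressure_atm)
    n_mol = p_partial * (np.asarray(headspace_l) / (R_L_ATM * np.asarray(temp_k))
                         + k_h * np.asarray(liquid_l))
    return n_mol * 1e6


def formation_rate(start_umol, end_umol, dt_days, dry_mass_g, carbon_mass_g=None):
    """Net formation rate from two total-amount measurements.

    Returns ``(rate_dw, rate_c)`` in µmol g(dw)^-1 d^-1 and µmol gC^-1 d^-1
    (``rate_c`` is None when ``carbon_mass_g`` is not given).  Negative net
    rates are preserved.
    """
    dt_days = np.asarray(dt_days, dtype=float)
    if np.any(dt_days <= 0):
        raise ValueError("dt must be > 0")
    if np.any(np.asarray(dry_mass_g, dtype=float) <= 0):
        raise ValueError("dry mass must be > 0")
    delta_per_day = (np.asarray(end_umol, dtype=float) - np.asarray(start_umol, dtype=float)) / dt_days
    rate_dw = delta_per_day / np.asarray(dry_mass_g, dtype=float)
    rate_c = None
    if carbon_mass_g is not None:
        if np.any(np.asarray(carbon_mass_g, dtype=float) <= 0):
            raise ValueError("carbon mass must be > 0")
        rate_c = delta_per_day / np.asarray(carbon_mass_g, dtype=float)
    return rate_dw, rate_c


def compute_rates(vials: pd.DataFrame, slices: pd.DataFrame,
                  salinity: float = 0.0) -> pd.DataFrame:
    """Per-replicate net formation rates (dry-weight basis) for CH4 and CO2.

    Expects the ``vials.csv`` / ``slices.csv`` dialects (ppm mixing ratios,
    mL volumes, atm pressures at the boundary).  Returns a long table with
    one row per vial-occasion-gas carrying ``rate_dw`` in
    µmol g(dw)^-1 d^-1; the carbon-normalised rate is added downstream once
    interpolated TC is known (see :mod:`sedch4.agemodel`).
    """
    df = vials.merge(
        slices[["slice_id", "reservoir", "slice_top_cm", "slice_bottom_cm",
                "dry_mass_g"]],
        on="slice_id", how="left", validate="many_to_one")
    if df["dry_mass_g"].isna().any():
        missing = vials.loc[df["dry_mass_g"].isna(), "slice_id"].unique()
        raise ValueError(f"vials reference unknown slice ids: {missing[:5]}")

    dil = df["pressure_after_atm"].to_numpy() / df["pressure_before_atm"].to_numpy()
    if np.any(dil < 1.0 - 1e-12):
        raise ValueError("pressure_after below pressure_before in vials table")
    temp = df["temp_K"].to_numpy()
    v_hs = df["headspace_ml"].to_numpy() / 1000.0
    v_liq = df["liquid_ml"].to_numpy() / 1000.0
    dt = (df["day_end"] - df["day_start"]).to_numpy(dtype=float)

    out = []
    for gas in GASES:
        # per-row solubility (temperature may vary by row)
        k_h = np.array([solubility(gas, t, salinity).value for t in temp])
        conv = dil * df["pressure_before_atm"].to_numpy() * (
            v_hs / (R_L_ATM * temp) + k_h * v_liq) * 1e6  # µmol per unit mol fraction
        start = df[f"{gas}_ppm_start"].to_numpy() * 1e-6 * conv
        end = df[f"{gas}_ppm_end"].to_numpy() * 1e-6 * conv
        rate_dw, _ = formation_rate(start, end, dt, df["dry_mass_g"].to_numpy())
        part = df[["reservoir", "core_id", "slice_id", "slice_top_cm",
                   "slice_bottom_cm", "replicate", "occasion"]].copy()
        part["gas"] = gas
        part["day_mid"] = (df["day_start"] + df["day_end"]) / 2.0
        part["dt_days"] = dt
        part["amount_start_umol"] = start
        part["amount_end_umol"] = end
        part["rate_dw"] = rate_dw
        out.append(part)
    rates = pd.concat(out, ignore_index=True)
    rates["excluded"] = False
    return rates


@dataclass
class ExclusionRule:
    """Flag early measurements of low-activity deep slices.

    The first 1-2 occasions of deep, slowly methanogenic slices can be biased
    by trace oxygen carried over from sample preparation; they are flagged
    (never deleted).  Sub-surface (2-6 cm) slices are never flagged.
    """

    k: int = 1                        # number of leading occasions to flag (0-2)
    rate_threshold: float = 0.5       # µmol gC^-1 d^-1 at occasion 1
    surface_top_cm: float = 2.0       # slices with top <= this are sub-surface

    def __post_init__(self):
        if self.k not in (0, 1, 2):
            raise ValueError("k must be in {0, 1, 2}")


def apply_exclusions(rates: pd.DataFrame, rule: ExclusionRule | None = None) -> pd.DataFrame:
    """Set the ``excluded`` flag according to ``rule``; returns a copy.

    Requires a carbon-normalised ``rate_c`` column (see
    :func:`sedch4.agemodel.annotate_rates`) because the activity threshold is
    defined on the per-gC rate.
    """
    rule = rule or ExclusionRule()
    rates = rates.copy()
    rates["excluded"] = False
    if rule.k == 0:
        return rates
    if "rate_c" not in rates.columns:
        raise ValueError("apply_exclusions needs a rate_c column; annotate first")
    first_occ = int(rates["occasion"].min())
    ch4 = rates[rates["gas"] == "ch4"]
    occ1 = ch4[ch4["occasion"] == first_occ]
    slice_mean = occ1.groupby("slice_id")["rate_c"].mean()
    deep_tops = rates.drop_duplicates("slice_id").set_index("slice_id")["slice_top_cm"]
    flagged_slices = slice_mean[
        (slice_mean < rule.rate_threshold)
        & (deep_tops.reindex(slice_mean.index) > rule.surface_top_cm)
    ].index
    mask = (rates["slice_id"].isin(flagged_slices)
            & (rates["occasion"] < first_occ + rule.k))
    rates.loc[mask, "excluded"] = True
    return rates


def pool_replicates(rates: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean and sd of replicate rates per slice-occasion-gas.

    Downstream model fits consume the means.  A single-replicate group gets
    sd 0 with a warning.  The ``excluded`` flag (shared across replicates of a
    slice-occasion) is carried through.
    """
    keys = ["reservoir", "core_id", "slice_id", "slice_top_cm", "occasion",
            "gas", "day_mid"]
    agg = {"rate_dw": ["mean", "std", "size"], "excluded": "any"}
    extra = [c for c in ("rate_c", "age_years", "tc_interp", "tn_interp")
             if c in rates.columns]
    for c in extra:
        agg[c] = ["mean"] + (["std"] if c == "rate_c" else [])
    grouped = rates.groupby(keys, as_index=False, sort=True).agg(agg)
    grouped.columns = ["_".join(c).rstrip("_") if c[1] else c[0]
                       for c in grouped.columns]
    grouped = grouped.rename(columns={
        "rate_dw_mean": "rate_dw", "rate_dw_std": "rate_dw_sd",
        "rate_dw_size": "n_replicates", "excluded_any": "excluded",
        "rate_c_mean": "rate_c", "rate_c_std": "rate_c_sd",
        "age_years_mean": "age_years", "tc_interp_mean": "tc_interp",
        "tn_interp_mean": "tn_interp"})
    singles = grouped["n_replicates"] == 1
    if singles.any():
        warnings.warn(f"{int(singles.sum())} slice-occasion groups have a single "
                      "replicate; sd set to 0", stacklevel=2)
    for col in ("rate_dw_sd", "rate_c_sd"):
        if col in grouped.columns:
            grouped[col] = grouped[col].fillna(0.0)
    return grouped
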