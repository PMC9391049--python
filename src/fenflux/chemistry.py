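"""Microcosm gas/liquid chemistry bookkeeping.

Converts raw incubation measurements — headspace mixing ratios (ppmV), liquid
concentrations (mM), pH — into total molar amounts, liquid-phase molar
concentrations, dry-weight-normalised amounts and dissolved-gas partial
pressures, with left-censoring at an instrument detection limit.

Conventions
-----------
* A sealed tube holds ``total_volume`` ml of which ``liquid_volume_initial`` ml
  is liquid; the headspace is the difference.  After the first sampling the
  liquid volume drops to ``liquid_volume_postsampling`` ml (default 9.5), and
  that volume is the denominator when total amounts are expressed as mM.
* The total amount of a gas is the ideal-gas headspace amount plus the
  Henry's-law dissolved amount; for CO2 the dissolved pool additionally
  includes bicarbonate from the first carbonic-acid dissociation at the
  sample pH (carbonate is neglected: all measured pH < 6).
* Headspace pressure is taken as 1 atm at every sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_CONSTANTS, PhysChemConstants

ANALYTES = ("H2", "CO2", "CH4", "acetate", "ethanol", "propionate", "butyrate")
GASES = ("H2", "CO2", "CH4")
PHASES = ("headspace_ppmv", "liquid_mM", "dissolved_nmol_per_l")

#: Columns of a tidy measurement table.
MEASUREMENT_COLUMNS = (
    "treatment", "replicate", "day", "analyte", "phase", "value", "censored",
)


class ChemistryInputError(ValueError):
    """Invalid measurement or vessel input."""


@dataclass(frozen=True)
class VesselSpec:
    """Physical description of one incubation tube.

    Defaults describe the study vessels: 27 ml tubes with 1 g fresh material
    plus 9 ml mineral solution (10 ml liquid), 9.5 ml liquid after the first
    sampling, incubated at 15 degC under ~1 atm N2.
    """

    total_volume_ml: float = 27.0
    liquid_volume_initial_ml: float = 10.0
    liquid_volume_postsampling_ml: float = 9.5
    fresh_mass_g: float = 1.0
    dw_fraction: float = 0.11
    temperature_k: float = 288.15
    headspace_pressure_pa: float = 101325.0

    def __post_init__(self) -> None:
        if not (self.total_volume_ml > self.liquid_volume_initial_ml
                >= self.liquid_volume_postsampling_ml > 0):
            raise ChemistryInputError(
                "require total_volume > liquid_volume_initial >= "
                "liquid_volume_postsampling > 0, got "
                f"{self.total_volume_ml}/{self.liquid_volume_initial_ml}/"
                f"{self.liquid_volume_postsampling_ml} ml"
            )
        if not (0 < self.dw_fraction <= 1):
            raise ChemistryInputError("dw_fraction must lie in (0, 1]")
        if self.temperature_k <= 0:
            raise ChemistryInputError("temperature must be positive (kelvin)")

    @property
    def headspace_volume_ml(self) -> float:
        return self.total_volume_ml - self.liquid_volume_initial_ml


@dataclass(frozen=True)
class GasAmount:
    """Breakdown of a total gas amount (µmol) into its physical pools."""

    total_umol: float
    headspace_umol: float
    dissolved_umol: float
    bicarbonate_umol: float = 0.0


def headspace_to_total_amount(
    mixing_ratio_ppmv: float,
    gas: str,
    vessel: VesselSpec,
    ph: float | None = None,
    constants: PhysChemConstants = DEFAULT_CONSTANTS,
) -> GasAmount:
    """Total amount (µmol) of *gas* in the vessel from its headspace mixing ratio.

    Ideal gas law on the headspace plus Henry's law on the liquid; CO2
    additionally carries pH-dependent bicarbonate, so ``ph`` is mandatory for
    CO2 and ignored otherwise.
    """
    if mixing_ratio_ppmv < 0:
        raise ChemistryInputError("mixing ratio must be nonnegative (ppmV)")
    if gas == "CO2" and ph is None:
        raise ChemistryInputError(
            "CO2 requires a pH to speciate dissolved CO2 and bicarbonate"
        )
    if ph is not None and not (0 < ph < 14):
        raise ChemistryInputError(f"pH {ph} outside (0, 14)")

    hc = constants.henry_for(gas)
    p_partial_pa = mixing_ratio_ppmv * 1e-6 * vessel.headspace_pressure_pa
    v_head_l = vessel.headspace_volume_ml / 1000.0
    v_liq_l = vessel.liquid_volume_initial_ml / 1000.0
    t = vessel.temperature_k

    n_head_mol = p_partial_pa * (v_head_l * 1e-3) / (constants.gas_constant * t)
    c_aq = hc.at(t) * (p_partial_pa / constants.atm_pa)   # mol l-1
    n_dis_mol = c_aq * v_liq_l

    n_bic_mol = 0.0
    if gas == "CO2":
        pk1 = constants.carbonate_pk1(t)
        n_bic_mol = c_aq * 10.0 ** (ph - pk1) * v_liq_l

    head, dis, bic = (x * 1e6 for x in (n_head_mol, n_dis_mol, n_bic_mol))
    return GasAmount(head + dis + bic, head, dis, bic)


def headspace_mixing_ratio(
    headspace_umol: float,
    vessel: VesselSpec,
    constants: PhysChemConstants = DEFAULT_CONSTANTS,
) -> float:
    """Inverse of the headspace leg of :func:`headspace_to_total_amount` (ppmV)."""
    v_head_m3 = vessel.headspace_volume_ml * 1e-6
    p = headspace_umol * 1e-6 * constants.gas_constant * vessel.temperature_k / v_head_m3
    return p / vessel.headspace_pressure_pa * 1e6


def amount_to_concentration(amount_umol: float, vessel: VesselSpec) -> float:
    """Total amount (µmol) -> liquid-referenced concentration (mM).

    Divides by the post-sampling liquid volume (9.5 ml in the study design);
    µmol / ml is mM directly.
    """
    if amount_umol < 0:
        raise ChemistryInputError("amount must be nonnegative")
    return amount_umol / vessel.liquid_volume_postsampling_ml


def dry_weight_factor(vessel: VesselSpec) -> float:
    """mM -> µmol per g dry weight multiplier: V_liq / (fresh mass x dw fraction)."""
    gdw = vessel.fresh_mass_g * vessel.dw_fraction
    if gdw <= 0:
        raise ChemistryInputError("fresh_mass x dw_fraction must be positive")
    return vessel.liquid_volume_postsampling_ml / gdw


def mm_to_umol_per_gdw(concentration_mm: float, vessel: VesselSpec) -> tuple[float, float]:
    """Convert mM to µmol per g dry weight; returns (value, conversion factor)."""
    factor = dry_weight_factor(vessel)
    return concentration_mm * factor, factor


def dissolved_to_partial_pressure(
    concentration_nmol_per_l: float,
    gas: str,
    temperature_k: float,
    constants: PhysChemConstants = DEFAULT_CONSTANTS,
) -> float:
    """Dissolved gas (nmol l-1) -> equilibrium partial pressure (Pa) via Henry's law."""
    if concentration_nmol_per_l < 0:
        raise ChemistryInputError("concentration must be nonnegative")
    hc = constants.henry_for(gas)
    p_atm = concentration_nmol_per_l * 1e-9 / hc.at(temperature_k)
    return p_atm * constants.atm_pa


def partial_pressure_to_dissolved(
    pressure_pa: float,
    gas: str,
    temperature_k: float,
    constants: PhysChemConstants = DEFAULT_CONSTANTS,
) -> float:
    """Partial pressure (Pa) -> dissolved concentration (nmol l-1); round-trip inverse."""
    hc = constants.henry_for(gas)
    return hc.at(temperature_k) * (pressure_pa / constants.atm_pa) * 1e9


def total_amount_to_dissolved(
    amount_umol: float,
    gas: str,
    vessel: VesselSpec,
    ph: float | None = None,
    constants: PhysChemConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Re-partition a total gas amount into its equilibrium dissolved pool.

    Inverts :func:`headspace_to_total_amount`: given the total amount (µmol)
    in the sealed vessel, solves for the equilibrium partial pressure and
    returns ``(dissolved concentration in mol l-1, partial pressure in Pa)``.
    For CO2 a pH is required so the bicarbonate share of the total is
    accounted for.
    """
    if amount_umol < 0:
        raise ChemistryInputError("amount must be nonnegative")
    if gas == "CO2" and ph is None:
        raise ChemistryInputError("CO2 requires a pH to partition bicarbonate")
    hc = constants.henry_for(gas)
    t = vessel.temperature_k
    v_head_m3 = vessel.headspace_volume_ml * 1e-6
    v_liq_l = vessel.liquid_volume_initial_ml / 1000.0
    # mol per Pa of partial pressure, headspace + dissolved (+ bicarbonate)
    per_pa = v_head_m3 / (constants.gas_constant * t)
    speciation = 1.0
    if gas == "CO2":
        speciation += 10.0 ** (ph - constants.carbonate_pk1(t))
    per_pa += hc.at(t) / constants.atm_pa * v_liq_l * speciation
    p = amount_umol * 1e-6 / per_pa
    c_aq = hc.at(t) * p / constants.atm_pa
    return c_aq, p


@dataclass(frozen=True)
class RateFit:
    """OLS fit of concentration vs time.  Consumption shows as a negative slope."""

    slope_mm_per_day: float
    r_squared: float
    n_days: int

    @property
    def consumption_rate(self) -> float:
        """Positive magnitude of a falling trend (mM d-1)."""
        return -self.slope_mm_per_day


def fit_linear_rate(
    series: pd.DataFrame,
    day_window: tuple[float, float] | None = None,
    value_col: str = "value",
) -> RateFit:
    """Ordinary least-squares rate of one analyte stream.

    *series* is a tidy slice with ``day``, ``value`` and optional ``censored``
    columns for a single treatment/analyte; censored rows are dropped,
    replicate values are averaged per day before fitting, and at least three
    distinct days are required.  A zero-variance response returns slope 0 with
    R^2 = 0 by convention.
    """
    df = series.copy()
    if "censored" in df.columns:
        df = df[~df["censored"].astype(bool)]
    if day_window is not None:
        lo, hi = day_window
        df = df[(df["day"] >= lo) & (df["day"] <= hi)]
    per_day = df.groupby("day")[value_col].mean()
    if len(per_day) < 3:
        raise ChemistryInputError(
            f"need >= 3 distinct uncensored days in window, got {len(per_day)}"
        )
    days = per_day.index.to_numpy(dtype=float)
    values = per_day.to_numpy(dtype=float)
    if np.ptp(days) == 0:
        raise ChemistryInputError("zero variance in day values")
    if np.ptp(values) == 0:
        return RateFit(0.0, 0.0, len(per_day))
    res = stats.linregress(days, values)
    return RateFit(float(res.slope), float(res.rvalue) ** 2, len(per_day))


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Schema/sanity check of a tidy measurement table; returns the table."""
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ChemistryInputError(f"measurement table lacks columns {sorted(missing)}")
    if (df["value"] < 0).any():
        bad = df.index[df["value"] < 0][0]
        raise ChemistryInputError(f"negative value at row {bad}")
    unknown = set(df["analyte"]) - set(ANALYTES)
    if unknown:
        raise ChemistryInputError(f"unknown analytes {sorted(unknown)}")
    unknown_phase = set(df["phase"]) - set(PHASES)
    if unknown_phase:
        raise ChemistryInputError(f"unknown phases {sorted(unknown_phase)}")
    key = ["treatment", "replicate", "analyte", "phase"]
    dup = df.duplicated(subset=key + ["day"])
    if dup.any():
        raise ChemistryInputError(
            f"duplicate day within a stream at rows {list(df.index[dup][:3])}"
        )
    return df


def censor_below_detection(
    df: pd.DataFrame,
    detection_limit_ppmv: float = 10.0,
    analyte: str = "H2",
) -> pd.DataFrame:
    """Left-censor headspace records of *analyte* below the detection limit.

    Censored rows carry the detection limit itself (never zero) and
    ``censored=True``, so downstream code can treat them as upper bounds.
    """
    out = df.copy()
    mask = (
        (out["analyte"] == analyte)
        & (out["phase"] == "headspace_ppmv")
        & (out["value"] < detection_limit_ppmv)
    )
    out.loc[mask, "value"] = detection_limit_ppmv
    out.loc[mask, "censored"] = True
    return out
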