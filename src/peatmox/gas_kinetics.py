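"""Closed-bottle CH4 mass balance and first-order oxidation kinetics.

Sealed serum bottles (peat microcosms or cell suspensions) receive a CH4
headspace; repeated headspace measurements give a mixing-ratio time series.
This module converts mixing ratios into amounts of CH4 (ideal gas for the
headspace, temperature-corrected Henry's law for the dissolved phase),
corrects the series for the CH4 carried away with each gas/liquid sample,
fits the first-order rate constant k from the log-linear decline, and
normalizes rates per gram dry soil or per cell.

Units follow field convention: volumes in mL, temperatures in deg C
(Kelvin internally), pressure in atm, mixing ratios in ppm (v/v), amounts
in umol, dissolved concentrations in uM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Gas constant, L atm mol-1 K-1
R_GAS = 0.082057
#: Molar mass of CH4, g mol-1
CH4_MOLAR_MASS = 16.04
ABS_ZERO_C = -273.15


class ValidationError(ValueError):
    """Raised when a physical precondition is violated."""


@dataclass(frozen=True)
class HenryParams:
    """Temperature-dependent CH4 solubility (Henry's law).

    kH(T) = kH_ref * exp(vant_hoff * (1/T - 1/T_ref)), T in Kelvin, so the
    solubility decreases with temperature for positive van 't Hoff
    coefficients. Defaults are mid-literature values for CH4 in water.
    """

    kh_ref: float = 1.4e-3  # mol L-1 atm-1 at t_ref
    t_ref: float = 298.15   # K
    vant_hoff: float = 1750.0  # K

    def __post_init__(self) -> None:
        if self.kh_ref <= 0:
            raise ValidationError("kh_ref must be positive")
        if self.vant_hoff < 0:
            raise ValidationError("vant_hoff must be non-negative")

    def kh(self, temperature_c: float) -> float:
        """Solubility (mol L-1 atm-1) at the given temperature (deg C)."""
        if temperature_c <= ABS_ZERO_C:
            raise ValidationError(f"nonphysical temperature {temperature_c} C")
        t_k = temperature_c + 273.15
        return self.kh_ref * math.exp(self.vant_hoff * (1.0 / t_k - 1.0 / self.t_ref))


DEFAULT_HENRY = HenryParams()


@dataclass(frozen=True)
class BottleSpec:
    """Geometry and incubation context of one closed serum bottle."""

    total_volume: float            # mL
    liquid_volume: float = 0.0     # mL; 0 for soil microcosms
    temperature: float = 8.0       # deg C
    pressure: float = 1.0          # atm

    def __post_init__(self) -> None:
        if not 0 <= self.liquid_volume < self.total_volume:
            raise ValidationError(
                "liquid_volume must satisfy 0 <= liquid < total "
                f"(got {self.liquid_volume} / {self.total_volume} mL)"
            )
        if self.temperature <= ABS_ZERO_C:
            raise ValidationError("temperature below absolute zero")
        if self.pressure <= 0:
            raise ValidationError("pressure must be positive")

    @property
    def headspace_volume(self) -> float:
        """Headspace volume in mL."""
        return self.total_volume - self.liquid_volume

    @property
    def temperature_k(self) -> float:
        return self.temperature + 273.15


@dataclass
class GasTimeSeries:
    """Headspace CH4 mixing ratios measured over time in one bottle.

    gas_sample_volume / liquid_sample_volume are the volumes withdrawn at
    each measurement (mL); both default to 0 (no sampling losses).
    """

    times: np.ndarray              # h, strictly increasing
    mixing_ratios: np.ndarray      # ppm (v/v)
    bottle: BottleSpec
    gas_sample_volume: float = 0.0
    liquid_sample_volume: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mixing_ratios = np.asarray(self.mixing_ratios, dtype=float)
        if self.times.shape != self.mixing_ratios.shape:
            raise ValidationError("times and mixing_ratios must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.mixing_ratios < 0):
            raise ValidationError("mixing ratios must be non-negative")
        if self.gas_sample_volume < 0 or self.liquid_sample_volume < 0:
            raise ValidationError("sampling volumes must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RateFit:
    """First-order rate constant from OLS of ln(mixing ratio) on time."""

    k: float                 # h-1; positive for net consumption
    intercept: float         # ln(ppm)
    r_squared: float
    n_points: int
    degenerate: bool = False  # True when the series carries no variance


@dataclass(frozen=True)
class SoilContext:
    """Gravimetric dry-weight context of a soil microcosm."""

    fresh_mass: float        # g
    water_fraction: float    # in [0, 1)

    def __post_init__(self) -> None:
        if not 0 <= self.water_fraction < 1:
            raise ValidationError("water_fraction must lie in [0, 1)")
        if self.fresh_mass <= 0:
            raise ValidationError("fresh_mass must be positive")

    @property
    def dry_mass(self) -> float:
        return self.fresh_mass * (1.0 - self.water_fraction)


@dataclass
class CellStandard:
    """Linear OD410 -> cell count standard for a pure culture."""

    od_values: np.ndarray
    cell_counts: np.ndarray
    slope: float = field(init=False)
    intercept: float = field(init=False)
    r_squared: float = field(init=False)

    def __post_init__(self) -> None:
        self.od_values = np.asarray(self.od_values, dtype=float)
        self.cell_counts = np.asarray(self.cell_counts, dtype=float)
        if self.od_values.shape != self.cell_counts.shape:
            raise ValidationError("od_values and cell_counts must match in length")
        if len(self.od_values) < 2:
            raise ValidationError("a standard needs at least two points")
        slope, intercept, r2, _ = _ols(self.od_values, self.cell_counts)
        if slope <= 0:
            raise ValidationError("OD-cell standard slope must be positive")
        self.slope, self.intercept, self.r_squared = slope, intercept, r2


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """OLS with intercept; returns (slope, intercept, R2, degenerate).

    R2 is the ordinary coefficient of determination; a response with zero
    variance is reported as R2 = 0 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValidationError("predictor has zero variance")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    ss_tot = float(np.sum((y - ym) ** 2))
    if ss_tot == 0:
        return slope, intercept, 0.0, True
    ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
    return slope, intercept, 1.0 - ss_res / ss_tot, False


def dissolved_ch4(
    mixing_ratio: float,
    temperature: float,
    henry: HenryParams = DEFAULT_HENRY,
    pressure: float = 1.0,
) -> float:
    """Equilibrium dissolved CH4 concentration (uM) under a given headspace.

    Parameters
    ----------
    mixing_ratio : headspace CH4 in ppm (v/v).
    temperature : deg C.
    henry : solubility parameters; defaults reproduce ~2 uM under 0.1%
        CH4 at 8 deg C.
    pressure : total headspace pressure in atm.
    """
    if mixing_ratio < 0:
        raise ValidationError("mixing ratio must be non-negative")
    if pressure <= 0:
        raise ValidationError("pressure must be positive")
    partial_atm = pressure * mixing_ratio * 1e-6
    return henry.kh(temperature) * partial_atm * 1e6  # mol/L -> uM


def headspace_after_injection(
    bottle: BottleSpec, injected_volume: float, ch4_purity: float = 0.95
) -> float:
    """Headspace mixing ratio (ppm) after injecting a CH4 gas aliquot.

    Assumes ideal mixing of the injected aliquot into the expanded gas
    phase (headspace + injected volume).
    """
    if injected_volume < 0:
        raise ValidationError("injected volume must be non-negative")
    if not 0 <= ch4_purity <= 1:
        raise ValidationError("purity must lie in [0, 1]")
    return 1e6 * injected_volume * ch4_purity / (bottle.headspace_volume + injected_volume)


def headspace_moles(bottle: BottleSpec, mixing_ratio: float) -> float:
    """CH4 amount in the headspace (umol) from the ideal gas law."""
    if mixing_ratio < 0:
        raise ValidationError("mixing ratio must be non-negative")
    v_l = bottle.headspace_volume / 1000.0
    n_mol = bottle.pressure * v_l * mixing_ratio * 1e-6 / (R_GAS * bottle.temperature_k)
    return n_mol * 1e6


def total_ch4_mass(
    bottle: BottleSpec, mixing_ratio: float, henry: HenryParams = DEFAULT_HENRY
) -> float:
    """Total CH4 in the bottle (umol): headspace plus equilibrium dissolved."""
    gas = headspace_moles(bottle, mixing_ratio)
    if bottle.liquid_volume == 0:
        return gas
    conc_um = dissolved_ch4(mixing_ratio, bottle.temperature, henry, bottle.pressure)
    return gas + conc_um * bottle.liquid_volume / 1000.0  # uM * L = umol


@dataclass
class SamplingCorrected:
    """Sampling-corrected cumulative CH4 mass balance for one bottle.

    measured_mass[i] is the total CH4 (umol) implied by the measurement at
    times[i]; removed_cum[i] the CH4 withdrawn with samples before i;
    corrected_mass[i] = measured + removed (what oxidation alone would have
    left); oxidized_cum[i] the cumulative oxidized CH4.
    """

    times: np.ndarray
    measured_mass: np.ndarray
    removed_cum: np.ndarray
    corrected_mass: np.ndarray
    oxidized_cum: np.ndarray

    @property
    def initial_mass(self) -> float:
        return float(self.measured_mass[0])


def apply_sampling_corrections(
    series: GasTimeSeries, henry: HenryParams = DEFAULT_HENRY
) -> SamplingCorrected:
    """Correct a measured CH4 series for gas/liquid withdrawn at sampling.

    Each measurement removes gas_sample_volume of headspace (carrying its
    share of headspace CH4 at uniform mixing) and liquid_sample_volume of
    medium (carrying its share of dissolved CH4). The decline between
    consecutive measurements net of these known removals is attributed to
    oxidation, so that

        oxidized_cum[i] + removed_cum[i] + measured_mass[i] == measured_mass[0]

    holds exactly. With zero sampling volumes the transform is the identity
    on the mass series.
    """
    bottle = series.bottle
    if series.gas_sample_volume >= bottle.headspace_volume:
        raise ValidationError("gas sample volume exceeds headspace volume")
    if series.liquid_sample_volume > 0 and series.liquid_sample_volume >= bottle.liquid_volume:
        raise ValidationError("liquid sample volume exceeds liquid volume")

    n = len(series)
    mass = np.array([total_ch4_mass(bottle, x, henry) for x in series.mixing_ratios])
    # phase shares per unit ppm are constant across the series
    gas_unit = headspace_moles(bottle, 1.0)
    if bottle.liquid_volume > 0:
        diss_unit = (
            dissolved_ch4(1.0, bottle.temperature, henry, bottle.pressure)
            * bottle.liquid_volume / 1000.0
        )
    else:
        diss_unit = 0.0
    total_unit = gas_unit + diss_unit
    f_gas = series.gas_sample_volume / bottle.headspace_volume
    f_liq = (
        series.liquid_sample_volume / bottle.liquid_volume
        if bottle.liquid_volume > 0
        else 0.0
    )
    removal_share = (gas_unit * f_gas + diss_unit * f_liq) / total_unit

    removed = np.zeros(n)
    removed[:-1] = mass[:-1] * removal_share  # withdrawal after each measurement
    removed_cum = np.concatenate([[0.0], np.cumsum(removed[:-1])])
    corrected = mass + removed_cum
    oxidized_cum = mass[0] - mass - removed_cum
    return SamplingCorrected(
        times=series.times.copy(),
        measured_mass=mass,
        removed_cum=removed_cum,
        corrected_mass=corrected,
        oxidized_cum=oxidized_cum,
    )


def fit_first_order(series: GasTimeSeries) -> RateFit:
    """Fit the first-order rate constant from ln(mixing ratio) vs time.

    k is minus the OLS slope; negative k (net production) is reported
    as-is with a warning rather than clamped.
    """
    if len(series) < 2:
        raise ValidationError("need at least two time points to fit")
    if np.any(series.mixing_ratios <= 0):
        raise ValidationError("log transform undefined for non-positive mixing ratios")
    slope, intercept, r2, degenerate = _ols(series.times, np.log(series.mixing_ratios))
    k = -slope
    if k < 0:
        logger.warning("negative rate constant k=%.3g h-1 (net CH4 production)", k)
    return RateFit(k=k, intercept=intercept, r_squared=r2,
                   n_points=len(series), degenerate=degenerate)


def rate_at_concentration(fit: RateFit | float, concentration: float) -> float:
    """First-order rate (concentration unit per hour) at a given concentration."""
    k = fit.k if isinstance(fit, RateFit) else float(fit)
    return k * concentration


def equivalent_mixing_ratio(
    reference_ppm: float,
    reference_temperature: float,
    target_temperature: float,
    henry: HenryParams = DEFAULT_HENRY,
) -> float:
    """Headspace ppm at the target temperature giving the same dissolved CH4.

    Used to compare rates across temperatures at equal dissolved substrate:
    a warmer bottle needs a proportionally higher headspace mixing ratio
    because CH4 is less soluble.
    """
    return reference_ppm * henry.kh(reference_temperature) / henry.kh(target_temperature)


def rate_per_dry_weight(mass_rate: float, soil: SoilContext) -> float:
    """Convert a umol h-1 oxidation rate to ug CH4 per g dry soil per day."""
    if soil.dry_mass <= 0:
        raise ValidationError("dry mass must be positive")
    return mass_rate * CH4_MOLAR_MASS * 24.0 / soil.dry_mass


def cells_from_od(od: float, standard: CellStandard) -> float:
    """Cell density (cells per mL) from an OD410 reading via the standard.

    Non-physical negative predictions (OD below the intercept root) are
    clamped to 0 with a warning.
    """
    cells = standard.slope * od + standard.intercept
    if cells < 0:
        logger.warning("OD %.4f maps below zero cells; clamping to 0", od)
        return 0.0
    return cells


def rate_per_cell(mass_rate: float, cell_density: float, liquid_volume: float) -> float:
    """Normalize a umol h-1 rate to umol per 1e8 cells per hour."""
    total_cells = cell_density * liquid_volume
    if total_cells <= 0:
        raise ValidationError("total cell count must be positive")
    return mass_rate / total_cells * 1e8


def rates_from_tables(
    measurements: pd.DataFrame,
    bottles: pd.DataFrame,
    henry: HenryParams = DEFAULT_HENRY,
) -> pd.DataFrame:
    """Per-bottle rate table from long-format measurement + metadata tables.

    measurements: columns bottle_id, time_h, ch4_ppm.
    bottles: columns bottle_id, total_mL, liquid_mL, temp_C and optionally
    gas_sample_mL, liquid_sample_uL, fresh_g, water_fraction plus free
    metadata (treatment, ch4_level, block) that is carried through.

    Returns one row per bottle with k_per_h, r2, n, and, when the dry-mass
    columns are present, rate_ug_per_gdw_d evaluated at the initial
    measured mixing ratio, plus rate_dissolved_adjusted (uM h-1 at the
    initial dissolved concentration).
    """
    required = {"bottle_id", "time_h", "ch4_ppm"}
    if not required.issubset(measurements.columns):
        raise ValidationError(f"measurements table needs columns {sorted(required)}")
    bottles = bottles.set_index("bottle_id")
    rows = []
    for bottle_id, grp in measurements.groupby("bottle_id"):
        meta = bottles.loc[bottle_id]
        spec = BottleSpec(
            total_volume=float(meta["total_mL"]),
            liquid_volume=float(meta.get("liquid_mL", 0.0) or 0.0),
            temperature=float(meta["temp_C"]),
        )
        grp = grp.sort_values("time_h")
        series = GasTimeSeries(
            times=grp["time_h"].to_numpy(),
            mixing_ratios=grp["ch4_ppm"].to_numpy(),
            bottle=spec,
            gas_sample_volume=float(meta.get("gas_sample_mL", 0.0) or 0.0),
            liquid_sample_volume=float(meta.get("liquid_sample_uL", 0.0) or 0.0) / 1000.0,
        )
        fit = fit_first_order(series)
        row = {
            "bottle_id": bottle_id,
            "k_per_h": fit.k,
            "r2": fit.r_squared,
            "n": fit.n_points,
            "degenerate": fit.degenerate,
        }
        c0 = float(series.mixing_ratios[0])
        row["rate_dissolved_adjusted"] = rate_at_concentration(
            fit, dissolved_ch4(c0, spec.temperature, henry)
        )
        fresh = meta.get("fresh_g")
        if fresh is not None and not pd.isna(fresh):
            soil = SoilContext(float(fresh), float(meta["water_fraction"]))
            mass_rate = fit.k * total_ch4_mass(spec, c0, henry)
            row["rate_ug_per_gdw_d"] = rate_per_dry_weight(mass_rate, soil)
        for col in ("treatment", "ch4_level", "block", "temp_C"):
            if col in meta.index:
                row[col] = meta[col]
        rows.append(row)
    return pd.DataFrame(rows)
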