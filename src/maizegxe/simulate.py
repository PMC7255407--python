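"""Daily thermal-time maize growth simulation.

A deliberately compact re-creation of the CERES-Maize process chain that the
genotype coefficients P1, P2, P5, G2, G3 and PHINT parameterise:

* phenology as a thermal-time stage machine
  (sowing -> emergence -> end of juvenile phase at P1 degree-days ->
  photoperiod-delayed tassel initiation -> anthesis after the remaining
  leaves appear at PHINT degree-days each -> maturity P5 degree-days after
  silking),
* daily biomass as radiation-use efficiency times Beer-law light
  interception times the more limiting of a temperature and a water factor,
* kernel set as G2 scaled by the mean stress around anthesis, and linear
  grain fill at G3 mg per kernel per day modulated by temperature and water,
* the layered soil-water bucket of :mod:`maizegxe.soil`.

Nutrient dynamics, pests and post-maturity losses are not represented; the
simulator targets well-fertilised savanna trials where water, temperature
and radiation drive the genotype-by-environment signal.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np

from .cultivar import CultivarCoefficients, EcotypeParams, Management, SpeciesParams
from .soil import SoilProfile, SoilWaterState, priestley_taylor_et0, water_balance_step
from .weather import WeatherSeries, day_length

__all__ = [
    "SeasonResult", "IncompleteSeasonError", "NoPlantingError",
    "thermal_time_daily", "photoperiod_delay", "simulate_season",
    "auto_plant", "seasonal_analysis", "SeasonalSummary",
]

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# phenology constants (documented simplifications)
EMERGENCE_TT = 45.0        # degC d from sowing to emergence
INDUCTION_BASE_DAYS = 4.0  # minimum duration of the photoperiod-sensitive phase
BASAL_LEAVES = 5.0         # embryonic + flag leaves beyond those initiated in P1
LEAF_INIT_TT = 24.0        # degC d per leaf initiated during the juvenile phase
PAR_FRACTION = 0.5         # PAR as a fraction of global solar radiation
LAI_MAX_REFERENCE = 4.2    # canopy LAI at the reference plant density
REFERENCE_DENSITY = 53333.0
SENESCED_LAI_FRACTION = 0.15   # LAI remaining at physiological maturity
MAX_HARVEST_INDEX = 0.55   # grain cannot exceed this share of total biomass
ANTHESIS_STRESS_HALF_WINDOW = 7  # days either side of anthesis for kernel set
TT_OPT = 34.0              # optional thermal-time cap: optimum temperature
TT_CEILING = 44.0          # optional thermal-time cap: ceiling temperature


class IncompleteSeasonError(RuntimeError):
    """Weather series ended before the crop reached physiological maturity."""


class NoPlantingError(RuntimeError):
    """No day in the sowing window satisfied the moisture rule."""


def thermal_time_daily(tmax: float, tmin: float, tbase: float = 8.0,
                       cap: bool = False) -> float:
    """Growing degree-days for one day: max(0, (Tmax+Tmin)/2 - Tbase).

    With ``cap=True`` the mean temperature response is capped at the optimum
    (34 degC) and declines linearly to zero at the ceiling (44 degC), a
    DSSAT-style refinement for supra-optimal days; the cap never increases
    the value.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    tmean = 0.5 * (tmax + tmin)
    gdd = max(0.0, tmean - tbase)
    if cap and tmean > TT_OPT:
        if tmean >= TT_CEILING:
            return 0.0
        frac = (TT_CEILING - tmean) / (TT_CEILING - TT_OPT)
        gdd = min(gdd, (TT_OPT - tbase) * frac)
    return gdd


def photoperiod_delay(daylength: float, p2: float, threshold: float = 12.5) -> float:
    """Development delay in days for one day: P2 * max(0, daylength - threshold)."""
    if p2 < 0:
        raise ValueError("P2 must be >= 0")
    return p2 * max(0.0, daylength - threshold)


def total_leaf_number(cv: CultivarCoefficients) -> float:
    """Leaves still to appear after the juvenile phase: basal count plus one
    leaf per LEAF_INIT_TT degree-days of P1."""
    return BASAL_LEAVES + cv.P1 / LEAF_INIT_TT


@dataclass(frozen=True)
class SeasonResult:
    """Outcome of one cultivar-season."""

    cultivar: str
    sowing_date: np.datetime64
    dta: int                  # days from sowing to anthesis
    dtm: int                  # days from sowing to physiological maturity
    biomass_anthesis: float   # Mg ha^-1
    biomass_maturity: float   # Mg ha^-1
    kernel_number: float      # kernels m^-2
    grain_yield: float        # Mg ha^-1
    stress_water: float       # season mean water factor in [0, 1]
    stress_temp: float        # season mean temperature factor in [0, 1]
    water_balance_error_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.dta < self.dtm:
            raise ValueError("phenology must satisfy 0 < dta < dtm")
        if self.grain_yield < 0 or self.biomass_maturity < 0:
            raise ValueError("yields must be non-negative")
        if self.grain_yield > self.biomass_maturity + 1e-9:
            raise ValueError("grain yield cannot exceed total biomass")


def simulate_season(cv: CultivarCoefficients, eco: EcotypeParams, sp: SpeciesParams,
                    wx: WeatherSeries, soil: SoilProfile, mgmt: Management,
                    initial_paw_fraction: float = 0.6,
                    tt_cap: bool = False) -> SeasonResult:
    """Run one cultivar through one season of daily weather.

    ``mgmt.sowing_date`` must be a concrete date inside ``wx`` (use
    :func:`auto_plant` to resolve ``"auto"``).  Raises
    :class:`IncompleteSeasonError` if the weather ends before maturity.
    """
    if mgmt.sowing_date == "auto":
        raise ValueError("resolve sowing_date with auto_plant() before simulate_season()")
    start = wx.index_of(mgmt.sowing_date)

    state = SoilWaterState.at_fraction(soil, initial_paw_fraction)
    plants_m2 = mgmt.plant_density / 10000.0
    lai_max = LAI_MAX_REFERENCE * mgmt.plant_density / REFERENCE_DENSITY
    leaves_after_juvenile = total_leaf_number(cv)
    tt_leaf_phase = leaves_after_juvenile * cv.PHINT

    # stage bookkeeping
    stage = "pre_emergence"
    tt_stage = 0.0             # thermal time accumulated in current stage
    induction = 0.0
    day_anthesis: int | None = None
    day_maturity: int | None = None

    biomass = 0.0              # g m^-2
    biomass_anthesis = 0.0
    fill_mg_per_kernel = 0.0
    min_factors: list[float] = []     # daily min(water, temp), for kernel window
    water_factors: list[float] = []
    temp_factors: list[float] = []
    irrigation_total = rain_total = runoff_total = drain_total = 0.0
    et_total = 0.0
    closure_err = 0.0

    doys = wx.doy
    n = len(wx)
    for i in range(start, n):
        tmax, tmin = float(wx.tmax[i]), float(wx.tmin[i])
        srad, rain = float(wx.srad[i]), float(wx.rain[i])
        tmean = 0.5 * (tmax + tmin)
        gdd = thermal_time_daily(tmax, tmin, sp.tbase, cap=tt_cap)

        # --- canopy state before today's growth
        if stage == "pre_emergence":
            lai = 0.0
        elif day_anthesis is None:
            veg_tt_done = _veg_progress(stage, tt_stage, cv, tt_leaf_phase)
            lai = lai_max * min(1.0, veg_tt_done)
        else:
            frac = min(1.0, tt_stage / cv.P5) if stage == "grain_fill" else 0.0
            lai = lai_max * (1.0 - (1.0 - SENESCED_LAI_FRACTION) * frac)
        cover = 1.0 - math.exp(-eco.KCAN * lai)

        # --- water balance
        irrig = 0.0
        if (mgmt.irrigation_threshold is not None
                and state.paw_fraction < mgmt.irrigation_threshold):
            irrig = state.refill_to_dul()
        et0 = priestley_taylor_et0(srad, tmax, tmin, soil.albedo)
        flux = water_balance_step(state, rain, et0, cover)
        rain_total += rain
        irrigation_total += irrig
        runoff_total += flux.runoff
        drain_total += flux.drainage
        et_total += flux.soil_evap + flux.transpiration
        closure_err += flux.closure_mm

        wfac = flux.stress_factor
        tfac = sp.photosynthesis_factor(tmean)
        water_factors.append(wfac)
        temp_factors.append(tfac)
        min_factors.append(min(wfac, tfac))

        # --- growth
        if stage != "pre_emergence":
            par = PAR_FRACTION * srad
            biomass += eco.RUE * par * cover * min(tfac, wfac)
        if stage == "grain_fill":
            ffac = sp.grain_fill_factor(tmean) * (0.3 + 0.7 * wfac)
            fill_mg_per_kernel += cv.G3 * ffac

        # --- phenology advance
        if stage == "pre_emergence":
            tt_stage += gdd
            if tt_stage >= EMERGENCE_TT:
                stage, tt_stage = "juvenile", tt_stage - EMERGENCE_TT
        elif stage == "juvenile":
            tt_stage += gdd
            if tt_stage >= cv.P1:
                stage, tt_stage = "induction", 0.0
        elif stage == "induction":
            dl = day_length(wx.latitude, int(doys[i]))
            rate_days = INDUCTION_BASE_DAYS + photoperiod_delay(dl, cv.P2,
                                                                sp.photoperiod_threshold)
            induction += 1.0 / rate_days
            if induction >= 1.0:
                stage, tt_stage = "leaf_growth", 0.0
        elif stage == "leaf_growth":
            tt_stage += gdd
            if tt_stage >= tt_leaf_phase:
                stage, tt_stage = "grain_fill", 0.0
                day_anthesis = i
                biomass_anthesis = biomass
        elif stage == "grain_fill":
            tt_stage += gdd
            if tt_stage >= cv.P5:
                day_maturity = i
                break

    if day_maturity is None:
        raise IncompleteSeasonError(
            f"{cv.name}: weather series ended in stage '{stage}' before maturity "
            f"(sown {wx.dates[start]})")

    # kernel set: mean stress in a window around anthesis
    a = day_anthesis - start
    lo = max(0, a - ANTHESIS_STRESS_HALF_WINDOW)
    hi = min(len(min_factors), a + ANTHESIS_STRESS_HALF_WINDOW + 1)
    window = min_factors[lo:hi]
    kernel_stress = float(np.mean(window)) if window else 1.0
    kernels_m2 = cv.G2 * plants_m2 * kernel_stress

    grain_g_m2 = min(kernels_m2 * fill_mg_per_kernel / 1000.0,
                     MAX_HARVEST_INDEX * biomass)

    return SeasonResult(
        cultivar=cv.name,
        sowing_date=wx.dates[start],
        dta=day_anthesis - start + 1,
        dtm=day_maturity - start + 1,
        biomass_anthesis=biomass_anthesis * 0.01,   # g m^-2 -> Mg ha^-1
        biomass_maturity=biomass * 0.01,
        kernel_number=kernels_m2,
        grain_yield=grain_g_m2 * 0.01,
        stress_water=float(np.mean(water_factors)),
        stress_temp=float(np.mean(temp_factors)),
        water_balance_error_mm=abs(closure_err),
    )


def _veg_progress(stage: str, tt_stage: float, cv: CultivarCoefficients,
                  tt_leaf_phase: float) -> float:
    """Fraction of vegetative thermal time completed (for LAI growth)."""
    total = cv.P1 + tt_leaf_phase
    if stage == "juvenile":
        done = tt_stage
    elif stage == "induction":
        done = cv.P1
    elif stage == "leaf_growth":
        done = cv.P1 + tt_stage
    else:
        done = 0.0
    return done / total


def auto_plant(wx: WeatherSeries, soil: SoilProfile, window_start: np.datetime64,
               window_days: int, threshold: float = 0.4,
               initial_paw_fraction: float = 0.25) -> np.datetime64:
    """Pick the sowing date: first window day whose end-of-day top-layer
    plant-available water fraction reaches ``threshold``.

    The topsoil is spun up from ``initial_paw_fraction`` using bare-soil
    water balance from the window start.  Raises :class:`NoPlantingError`
    if the rule is never satisfied within the window.
    """
    if window_days < 1:
        raise ValueError("empty sowing window")
    start = wx.index_of(window_start)
    state = SoilWaterState.at_fraction(soil, initial_paw_fraction)
    for i in range(start, min(start + window_days, len(wx))):
        et0 = priestley_taylor_et0(float(wx.srad[i]), float(wx.tmax[i]),
                                   float(wx.tmin[i]), soil.albedo)
        water_balance_step(state, float(wx.rain[i]), et0, cover=0.0)
        if state.top_layer_paw_fraction() >= threshold:
            return wx.dates[i]
    raise NoPlantingError(
        f"topsoil never reached {threshold:.0%} of available-water capacity in the "
        f"{window_days}-day window from {window_start}")


@dataclass(frozen=True)
class SeasonalSummary:
    """Across-year yield summary and empirical CDF for one cultivar."""

    cultivar: str
    n_years: int
    max_yield: float
    min_yield: float
    mean_yield: float
    sd_yield: float
    yields: tuple[float, ...]          # per simulated year, Mg ha^-1

    @property
    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted yields, cumulative probabilities) for plotting."""
        ys = np.sort(np.asarray(self.yields))
        p = np.arange(1, len(ys) + 1) / len(ys)
        return ys, p


def seasonal_analysis(cultivars: list[CultivarCoefficients], eco: EcotypeParams,
                      sp: SpeciesParams, wx: WeatherSeries, soil: SoilProfile,
                      season_start_doy: int, window_days: int = 60,
                      plant_density: float = REFERENCE_DENSITY,
                      planting_threshold: float = 0.4) -> dict[str, SeasonalSummary]:
    """Long-term rainfed analysis: auto-plant and simulate every cultivar in
    every available year, then summarise max/min/mean/sd and the empirical
    yield CDF per cultivar.

    Years in which the moisture rule never triggers, or in which the weather
    ends before maturity, are skipped with a logged warning.
    """
    years = sorted(set(wx.dates.astype("datetime64[Y]").astype(int) + 1970))
    if len(years) < 2:
        raise ValueError("seasonal analysis needs at least 2 years of weather")

    yields: dict[str, list[float]] = {cv.name: [] for cv in cultivars}
    for year in years:
        window_start = (np.datetime64(f"{year}-01-01", "D")
                        + np.timedelta64(season_start_doy - 1, "D"))
        try:
            wx.index_of(window_start)
        except KeyError:
            continue
        try:
            sow = auto_plant(wx, soil, window_start, window_days,
                             threshold=planting_threshold)
        except NoPlantingError as exc:
            log.warning("year %d skipped: %s", year, exc)
            continue
        for cv in cultivars:
            mgmt = Management(sowing_date=str(sow), plant_density=plant_density,
                              irrigation_threshold=None)
            try:
                res = simulate_season(cv, eco, sp, wx, soil, mgmt)
            except IncompleteSeasonError as exc:
                log.warning("year %d, %s skipped: %s", year, cv.name, exc)
                continue
            yields[cv.name].append(res.grain_yield)

    out: dict[str, SeasonalSummary] = {}
    for cv in cultivars:
        ys = yields[cv.name]
        if not ys:
            raise NoPlantingError(f"{cv.name}: no year produced a completed season")
        arr = np.asarray(ys)
        out[cv.name] = SeasonalSummary(
            cultivar=cv.name, n_years=len(ys),
            max_yield=float(arr.max()), min_yield=float(arr.min()),
            mean_yield=float(arr.mean()),
            sd_yield=float(arr.std(ddof=1)) if len(ys) > 1 else 0.0,
            yields=tuple(float(y) for y in ys),
        )
    return out
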