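"""Layered soil-water bucket: SCS runoff, Priestley-Taylor ET, free drainage.

The profile is a small stack of layers, each with volumetric lower limit
(LL), drained upper limit (DUL) and saturation (SAT).  Daily dynamics follow
the classic tipping-bucket scheme: curve-number runoff partitioning of rain,
top-down infiltration, drainage of water above DUL at a fixed daily
fraction, two-stage (energy- vs supply-limited) soil evaporation, and root
water uptake capped at a fixed extractable fraction of plant-available
water.  Every step returns a closed mass balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SoilLayer", "SoilProfile", "SoilWaterState", "WaterFlux",
           "priestley_taylor_et0", "water_balance_step"]

#: daily fraction of water above DUL that drains to the layer below
DRAIN_FRACTION = 0.4
#: daily extractable fraction of root-zone plant-available water
EXTRACTABLE_FRACTION = 0.10
#: stage-1/stage-2 soil evaporation: extractable fraction of evaporable topsoil water
EVAP_SUPPLY_FRACTION = 0.5


@dataclass(frozen=True)
class SoilLayer:
    thickness_mm: float          # layer depth increment, mm
    LL: float                    # volumetric lower limit (wilting point)
    DUL: float                   # volumetric drained upper limit (field capacity)
    SAT: float                   # volumetric saturation

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be > 0")
        if not 0 < self.LL < self.DUL < self.SAT < 1:
            raise ValueError(f"need 0 < LL < DUL < SAT < 1, got {self.LL}, {self.DUL}, {self.SAT}")

    @property
    def ll_mm(self) -> float:
        return self.LL * self.thickness_mm

    @property
    def dul_mm(self) -> float:
        return self.DUL * self.thickness_mm

    @property
    def sat_mm(self) -> float:
        return self.SAT * self.thickness_mm


@dataclass(frozen=True)
class SoilProfile:
    name: str
    layers: tuple[SoilLayer, ...]
    curve_number: float = 75.0   # SCS runoff curve number
    albedo: float = 0.13

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if not 0 < self.curve_number <= 100:
            raise ValueError("curve number must be in (0, 100]")

    @property
    def paw_capacity_mm(self) -> float:
        """Total plant-available water between LL and DUL, mm."""
        return sum(l.dul_mm - l.ll_mm for l in self.layers)


@dataclass
class SoilWaterState:
    """Mutable per-layer water storage in mm."""

    profile: SoilProfile
    water_mm: np.ndarray

    @classmethod
    def at_fraction(cls, profile: SoilProfile, paw_fraction: float = 1.0) -> "SoilWaterState":
        """Initialise every layer at LL + fraction * (DUL - LL)."""
        w = np.array([l.ll_mm + paw_fraction * (l.dul_mm - l.ll_mm) for l in profile.layers])
        return cls(profile, w)

    @property
    def total_mm(self) -> float:
        return float(self.water_mm.sum())

    @property
    def paw_mm(self) -> float:
        return float(sum(max(0.0, w - l.ll_mm)
                         for w, l in zip(self.water_mm, self.profile.layers)))

    @property
    def paw_fraction(self) -> float:
        cap = self.profile.paw_capacity_mm
        return self.paw_mm / cap if cap > 0 else 0.0

    def top_layer_paw_fraction(self) -> float:
        l = self.profile.layers[0]
        return max(0.0, float(self.water_mm[0]) - l.ll_mm) / (l.dul_mm - l.ll_mm)

    def refill_to_dul(self) -> float:
        """Irrigate: raise every layer to DUL; returns mm applied."""
        applied = 0.0
        for i, l in enumerate(self.profile.layers):
            if self.water_mm[i] < l.dul_mm:
                applied += l.dul_mm - self.water_mm[i]
                self.water_mm[i] = l.dul_mm
        return applied


@dataclass(frozen=True)
class WaterFlux:
    """Water-balance terms for one day, all mm."""

    rain: float
    irrigation: float
    runoff: float
    infiltration: float
    drainage: float
    soil_evap: float
    transpiration: float
    delta_storage: float
    stress_factor: float         # 1 = unstressed, 0 = no extractable water

    @property
    def closure_mm(self) -> float:
        """Inputs minus outputs minus storage change (should be ~0)."""
        return (self.rain + self.irrigation
                - self.runoff - self.drainage - self.soil_evap - self.transpiration
                - self.delta_storage)


def priestley_taylor_et0(srad: float, tmax: float, tmin: float,
                         albedo: float = 0.13) -> float:
    """Equilibrium-evaporation form of Priestley-Taylor reference ET, mm/day.

    The DSSAT formulation: EEQ = SRAD * (2.04e-4 - 1.83e-4 * albedo) * (Td + 29)
    with Td = 0.6*Tmax + 0.4*Tmin, scaled by 1.1 (up-scaled above 35 degC,
    suppressed below 5 degC).
    """
    td = 0.6 * tmax + 0.4 * tmin
    eeq = srad * (2.04e-4 - 1.83e-4 * albedo) * (td + 29.0)
    if tmax > 35.0:
        factor = (tmax - 35.0) * 0.05 + 1.1
    elif tmax < 5.0:
        factor = 0.01 * np.exp(0.18 * (tmax + 20.0))
    else:
        factor = 1.1
    return max(0.0, eeq * factor)


def water_balance_step(state: SoilWaterState, rain: float, et0: float,
                       cover: float) -> WaterFlux:
    """Advance the soil water bucket one day.

    Parameters
    ----------
    rain : mm of rainfall (irrigation is applied separately by the caller)
    et0 : reference evapotranspiration demand, mm
    cover : canopy fractional light interception in [0, 1]; partitions et0
        into potential transpiration (cover) and soil evaporation (1-cover).

    Returns the day's fluxes including the crop water-stress factor
    ``min(1, extractable supply / transpiration demand)``.
    """
    if rain < 0:
        raise ValueError("negative rain")
    if et0 < 0:
        raise ValueError("negative ET demand")
    cover = min(1.0, max(0.0, cover))
    prof = state.profile
    layers = prof.layers
    w = state.water_mm
    storage0 = float(w.sum())

    # SCS curve-number runoff
    if rain > 0:
        s = 254.0 * (100.0 / prof.curve_number - 1.0)
        runoff = (rain - 0.2 * s) ** 2 / (rain + 0.8 * s) if rain > 0.2 * s else 0.0
        runoff = min(runoff, rain)
    else:
        runoff = 0.0

    # top-down infiltration, saturation excess returned to runoff
    infil = rain - runoff
    remaining = infil
    for i, l in enumerate(layers):
        room = l.sat_mm - w[i]
        dw = min(remaining, max(0.0, room))
        w[i] += dw
        remaining -= dw
    runoff += remaining
    infil -= remaining

    # drainage of water above DUL, cascading downwards
    drainage = 0.0
    for i, l in enumerate(layers):
        excess = w[i] - l.dul_mm
        if excess > 0:
            flow = DRAIN_FRACTION * excess
            w[i] -= flow
            if i + 1 < len(layers):
                w[i + 1] += flow
            else:
                drainage += flow
    # a receiving layer may now exceed SAT; push the surplus straight down
    for i, l in enumerate(layers):
        over = w[i] - l.sat_mm
        if over > 0:
            w[i] -= over
            if i + 1 < len(layers):
                w[i + 1] += over
            else:
                drainage += over

    # two-stage soil evaporation from the top layer
    top = layers[0]
    es_pot = et0 * (1.0 - cover)
    evaporable = max(0.0, w[0] - 0.5 * top.ll_mm)
    es = min(es_pot, EVAP_SUPPLY_FRACTION * evaporable)
    w[0] -= es

    # root uptake limited by extractable plant-available water
    ep_pot = et0 * cover
    paw_layers = np.array([max(0.0, w[i] - l.ll_mm) for i, l in enumerate(layers)])
    supply = EXTRACTABLE_FRACTION * paw_layers.sum()
    ep = min(ep_pot, supply)
    if paw_layers.sum() > 0 and ep > 0:
        w -= ep * paw_layers / paw_layers.sum()
    stress = 1.0 if ep_pot <= 0 else min(1.0, supply / ep_pot)

    delta = float(w.sum()) - storage0
    return WaterFlux(rain=rain, irrigation=0.0, runoff=runoff, infiltration=infil,
                     drainage=drainage, soil_evap=es, transpiration=ep,
                     delta_storage=delta, stress_factor=stress)
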