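"""Synthetic weather, soils and yield trials with known structure.

Everything downstream (the crop simulator, the ANOVA and the stability
estimators) is exercised against data from this module, so each generator
has controllable, documented statistical structure:

* :func:`generate_weather` - a first-order two-state (wet/dry day) rainfall
  occurrence chain with a seasonally varying wet-day probability and
  exponential intensities, plus sinusoid-with-bounded-noise temperature and
  radiation.  Two savanna archetypes are built in: a short-season dry
  savanna (~825 mm, ~3.5-month season, rain concentrated in July-August)
  and a longer wet savanna (~1125 mm, ~5-month season).  The occurrence
  chain is calibrated once, deterministically, so the expected annual total
  matches the archetype.
* :func:`generate_trial` - yield tables Y = mu + G + E + GE + R + eps whose
  component sums of squares realise requested variance fractions, with
  multiplicative (rank-k), slope (Finlay-Wilkinson) or unstructured
  interaction.
* :func:`generate_soil` - parameter sets for the layered bucket profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .soil import SoilLayer, SoilProfile
from .trial import YieldTrial
from .weather import WeatherSeries

__all__ = [
    "SavannaArchetype", "DRY_SAVANNA", "WET_SAVANNA", "archetype_by_name",
    "generate_weather", "TrialSpec", "generate_trial", "generate_soil",
    "DEFAULT_SEED",
]

#: documented default seed for all generators (an arbitrary fixed constant)
DEFAULT_SEED = 20160316


@dataclass(frozen=True)
class SavannaArchetype:
    """Climate template for a savanna agroecology."""

    name: str
    annual_rain_mm: float
    season_start_doy: int
    season_length_days: int
    peak_months: tuple[int, ...]       # calendar months holding the rainfall peak
    tmax_mean: float
    tmax_amp: float
    tmin_mean: float
    tmin_amp: float
    srad_mean: float                   # MJ m^-2 d^-1
    latitude: float

    def __post_init__(self) -> None:
        if self.annual_rain_mm <= 0:
            raise ValueError("annual_rain_mm must be > 0")
        if not 60 <= self.season_length_days <= 240:
            raise ValueError("season_length_days must be in [60, 240]")
        if self.tmax_mean <= self.tmin_mean:
            raise ValueError("tmax_mean must exceed tmin_mean")

    @property
    def peak_doy(self) -> float:
        return self.season_start_doy + self.season_length_days / 2.0

    @property
    def season_sigma(self) -> float:
        """Spread of the Gaussian wet-day probability profile, days."""
        return self.season_length_days / 4.0


DRY_SAVANNA = SavannaArchetype(
    name="dry", annual_rain_mm=825.0, season_start_doy=152,
    season_length_days=105, peak_months=(7, 8),
    tmax_mean=34.0, tmax_amp=4.0, tmin_mean=21.0, tmin_amp=4.0,
    srad_mean=20.0, latitude=12.0)

WET_SAVANNA = SavannaArchetype(
    name="wet", annual_rain_mm=1125.0, season_start_doy=121,
    season_length_days=150, peak_months=(6, 7, 8, 9),
    tmax_mean=31.5, tmax_amp=3.5, tmin_mean=19.5, tmin_amp=3.5,
    srad_mean=18.5, latitude=11.1)


def archetype_by_name(name: str) -> SavannaArchetype:
    table = {"dry": DRY_SAVANNA, "wet": WET_SAVANNA}
    try:
        return table[name]
    except KeyError:
        raise ValueError(f"unknown savanna archetype {name!r}; "
                         f"known: {sorted(table)}") from None


# ---------------------------------------------------------------------------
# weather generator

_WET_PERSISTENCE = 0.35      # added wet-after-wet probability
_P_CAP = 0.95                # occurrence probabilities never exceed this
_WET_FRACTION_OF_SEASON = 0.45   # target wet days as a share of season length


def _occurrence_profile(arch: SavannaArchetype, amplitude: float,
                        doys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(p01, p11) wet-day probabilities for each day of year."""
    s = np.exp(-0.5 * ((doys - arch.peak_doy) / arch.season_sigma) ** 2)
    p01 = np.minimum(_P_CAP, amplitude * s)
    p11 = np.minimum(_P_CAP, amplitude * s + _WET_PERSISTENCE)
    return p01, p11


def _expected_annual_rain(arch: SavannaArchetype, amplitude: float,
                          intensity: float) -> float:
    """Exact expected annual total of the chain, by forward marginals."""
    doys = np.arange(1, 366, dtype=float)
    p01, p11 = _occurrence_profile(arch, amplitude, doys)
    pi = 0.0
    # run two years so the marginal forgets the dry initial state
    total = 0.0
    for year_pass in range(2):
        total = 0.0
        for d in range(365):
            pi = pi * p11[d] + (1.0 - pi) * p01[d]
            total += pi * intensity
    return total


def _calibrate_amplitude(arch: SavannaArchetype, intensity: float) -> float:
    """Bisect the occurrence amplitude so expected annual rain hits target."""
    lo, hi = 1e-4, 4.0
    if _expected_annual_rain(arch, hi, intensity) < arch.annual_rain_mm:
        raise ValueError(f"{arch.name}: rainfall target {arch.annual_rain_mm} mm "
                         "unreachable for this season geometry")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_annual_rain(arch, mid, intensity) < arch.annual_rain_mm:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_weather(arch: SavannaArchetype | str, n_years: int, seed: int,
                     start_year: int = 1992, rain_scale: float = 1.0) -> WeatherSeries:
    """Generate ``n_years`` of contiguous daily weather for an archetype.

    ``rain_scale`` scales rainfall occurrence/intensity; 0 gives a completely
    dry series (temperature and radiation unchanged).  Reproducible for a
    fixed ``(archetype, n_years, seed)``.
    """
    if isinstance(arch, str):
        arch = archetype_by_name(arch)
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if rain_scale < 0:
        raise ValueError("rain_scale must be >= 0")

    intensity = arch.annual_rain_mm / (_WET_FRACTION_OF_SEASON * arch.season_length_days)
    amplitude = _calibrate_amplitude(arch, intensity) if rain_scale > 0 else 0.0

    start = np.datetime64(f"{start_year}-01-01", "D")
    end = np.datetime64(f"{start_year + n_years}-01-01", "D")
    dates = np.arange(start, end)
    years = dates.astype("datetime64[Y]").astype("datetime64[D]")
    doys = (dates - years).astype(int) + 1.0
    n = len(dates)

    rng = np.random.default_rng(np.random.SeedSequence([seed, n_years, 7]))

    # rainfall occurrence chain + exponential intensities
    p01, p11 = _occurrence_profile(arch, amplitude * rain_scale, doys)
    u = rng.random(n)
    wet = np.zeros(n, dtype=bool)
    prev = False
    for i in range(n):
        thresh = p11[i] if prev else p01[i]
        prev = wet[i] = u[i] < thresh
    rain = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet and rain_scale > 0:
        rain[wet] = rng.exponential(intensity * rain_scale, size=n_wet)

    # temperature / radiation: annual sinusoid (warmest ~April) + bounded noise
    season = np.cos(2.0 * np.pi * (doys - 105.0) / 365.0)
    tnoise = rng.uniform(-1.5, 1.5, size=(2, n))
    tmax = arch.tmax_mean + arch.tmax_amp * season - 2.0 * wet + tnoise[0]
    tmin = arch.tmin_mean + arch.tmin_amp * season - 0.5 * wet + tnoise[1]
    # bound: mean gap >= 10.5, wet-day narrowing 1.5, noise spread 3 -> gap > 0
    srad = (arch.srad_mean + 2.5 * season - 4.0 * wet
            + rng.uniform(-1.5, 1.5, size=n))
    srad = np.maximum(srad, 3.0)

    return WeatherSeries(dates, tmax, tmin, srad, rain, latitude=arch.latitude)


# ---------------------------------------------------------------------------
# yield-trial generator

@dataclass(frozen=True)
class TrialSpec:
    """Recipe for a synthetic balanced yield trial.

    ``var_fractions`` gives target shares of the total sum of squares for
    genotype (G), environment (E), interaction (GEI), replicate block (rep)
    and residual error; they must be non-negative and sum to 1.  Defaults
    mirror a savanna maize multi-environment trial: 16 genotypes x 8
    environments x 2 reps, E-dominant variance (67/19/13 % for E/G/GEI).

    ``gei_structure`` is ``"unstructured"``, ``"multiplicative"`` (rank
    ``gei_rank`` interaction) or ``"slope"`` (GE_ij = (beta_i - 1) E_j with
    per-genotype sensitivities ``betas``; the GEI fraction is then implied
    by the betas rather than taken from ``var_fractions``).
    """

    n_genotypes: int = 16
    n_environments: int = 8
    n_reps: int = 2
    grand_mean: float = 3.7                      # Mg ha^-1
    var_fractions: dict[str, float] = field(default_factory=lambda: {
        "E": 0.67, "G": 0.19, "GEI": 0.13, "rep": 0.0, "error": 0.01})
    total_variance: float = 1.5                  # (Mg ha^-1)^2 across all cells
    gei_structure: str = "multiplicative"
    gei_rank: int = 2
    betas: tuple[float, ...] | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_environments, self.n_reps) < 2:
            raise ValueError("counts must all be >= 2")
        keys = {"G", "E", "GEI", "rep", "error"}
        if set(self.var_fractions) != keys:
            raise ValueError(f"var_fractions must have keys {sorted(keys)}")
        vals = self.var_fractions
        if any(v < 0 for v in vals.values()):
            raise ValueError("variance fractions must be >= 0")
        if abs(sum(vals.values()) - 1.0) > 1e-12:
            raise ValueError(f"variance fractions sum to {sum(vals.values())}, not 1")
        if self.gei_structure not in ("unstructured", "multiplicative", "slope"):
            raise ValueError(f"unknown gei_structure {self.gei_structure!r}")
        if self.gei_structure == "slope":
            if self.betas is None or len(self.betas) != self.n_genotypes:
                raise ValueError("slope structure needs one beta per genotype")


def _centered_scaled(rng: np.random.Generator, size: int, target_ss: float) -> np.ndarray:
    """A centered vector with sum of squares exactly ``target_ss``."""
    if target_ss <= 0:
        return np.zeros(size)
    v = rng.standard_normal(size)
    v -= v.mean()
    while np.allclose(v, 0):      # pathologically degenerate draw
        v = rng.standard_normal(size)
        v -= v.mean()
    return v * math.sqrt(target_ss / float(v @ v))


def generate_trial(spec: TrialSpec) -> YieldTrial:
    """Draw one balanced trial realising the spec's variance structure.

    Main effects and the interaction matrix are centered and scaled exactly
    to their target sums of squares, so the realised ANOVA shares differ
    from the targets only through the random error leaking into each
    stratum (vanishing as the error fraction goes to 0).
    """
    p, q, r = spec.n_genotypes, spec.n_environments, spec.n_reps
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, p, q, r]))
    n = p * q * r
    total_ss = spec.total_variance * (n - 1)
    f = spec.var_fractions

    g = _centered_scaled(rng, p, f["G"] * total_ss / (q * r))
    e = _centered_scaled(rng, q, f["E"] * total_ss / (p * r))
    rep = _centered_scaled(rng, r, f["rep"] * total_ss / (p * q))

    if spec.gei_structure == "slope":
        betas = np.asarray(spec.betas, dtype=float)
        ge = np.outer(betas - 1.0, e)
    else:
        rank = spec.gei_rank if spec.gei_structure == "multiplicative" else min(p, q) - 1
        ge = np.zeros((p, q))
        for k in range(max(1, rank)):
            u = _centered_scaled(rng, p, 1.0)
            v = _centered_scaled(rng, q, 1.0)
            ge += np.outer(u, v) / (k + 1.0)
        ss_now = float((ge ** 2).sum())
        target = f["GEI"] * total_ss / r
        ge = ge * math.sqrt(target / ss_now) if ss_now > 0 else ge

    sigma_err = math.sqrt(f["error"] * total_ss / n)
    eps = rng.standard_normal((p, q, r)) * sigma_err

    y = (spec.grand_mean
         + g[:, None, None] + e[None, :, None] + ge[:, :, None]
         + rep[None, None, :] + eps)

    genotypes = tuple(f"G{i + 1:02d}" for i in range(p))
    environments = tuple(f"E{j + 1}" for j in range(q))
    reps = tuple(f"R{k + 1}" for k in range(r))
    return YieldTrial(y, genotypes, environments, reps)


# ---------------------------------------------------------------------------
# soil profiles

_SOIL_KINDS: dict[str, dict] = {
    # volumetric LL/DUL/SAT per layer (top, middle, bottom), SCS curve number
    "sandy": dict(ll=(0.055, 0.060, 0.065), dul=(0.130, 0.140, 0.145),
                  sat=(0.270, 0.270, 0.270), cn=70.0),
    "loamy": dict(ll=(0.110, 0.120, 0.125), dul=(0.240, 0.250, 0.255),
                  sat=(0.360, 0.360, 0.360), cn=76.0),
    "clay_loam": dict(ll=(0.155, 0.160, 0.165), dul=(0.295, 0.300, 0.305),
                      sat=(0.400, 0.400, 0.400), cn=82.0),
}
_LAYER_THICKNESS = (150.0, 300.0, 450.0)     # mm


def generate_soil(kind: str = "loamy", variant: int = 1) -> SoilProfile:
    """A three-layer bucket profile for a named soil kind.

    ``variant`` (1 or 2) emulates the two profile pits dug per site: variant
    2 holds 8 % less plant-available water and runs off slightly more,
    providing a deterministic replication device for simulated trials.
    """
    if kind == "default":
        kind = "loamy"
    try:
        spec = _SOIL_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown soil kind {kind!r}; known: {sorted(_SOIL_KINDS)}") from None
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    shrink = 1.0 if variant == 1 else 0.92
    layers = tuple(
        SoilLayer(thickness_mm=t, LL=ll, DUL=ll + shrink * (dul - ll), SAT=sat)
        for t, ll, dul, sat in zip(_LAYER_THICKNESS, spec["ll"], spec["dul"], spec["sat"]))
    cn = spec["cn"] + (0.0 if variant == 1 else 2.0)
    return SoilProfile(name=f"{kind}_pit{variant}", layers=layers, curve_number=cn)
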