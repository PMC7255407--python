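"""Genotype, ecotype and species parameter sets for the maize simulator.

The cultivar coefficients are the six genotype-specific parameters of the
CERES-Maize family of models:

* ``P1``    thermal time from seedling emergence to the end of the juvenile
  phase (degree-days above the 8 degC base),
* ``P2``    development delay (days) per hour of photoperiod above 12.5 h,
* ``P5``    thermal time from silking to physiological maturity (degree-days),
* ``G2``    potential kernel number per plant,
* ``G3``    kernel growth rate during linear grain fill (mg kernel^-1 day^-1),
* ``PHINT`` phyllochron interval: thermal time between successive leaf-tip
  appearances (degree-days per leaf).

A coefficient table for 16 Nigerian savanna varieties, spanning extra-early
to late maturity groups, ships with the package as
``data/cultivars_table2.csv``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "CultivarCoefficients",
    "EcotypeParams",
    "SpeciesParams",
    "Management",
    "MATURITY_GROUPS",
    "MATURITY_ORDER",
    "load_cultivars",
    "load_species",
    "default_cultivars",
    "default_species",
]


@dataclass(frozen=True)
class CultivarCoefficients:
    """One variety's genotype-specific parameters."""

    name: str
    P1: float   # degC d, emergence -> end of juvenile phase
    P2: float   # days delay per hour daylength above 12.5 h
    P5: float   # degC d, silking -> physiological maturity
    G2: float   # kernels per plant (potential)
    G3: float   # mg kernel^-1 d^-1
    PHINT: float  # degC d per leaf tip

    def __post_init__(self) -> None:
        if self.P2 < 0:
            raise ValueError(f"{self.name}: P2 must be >= 0, got {self.P2}")
        for attr in ("P1", "P5", "G2", "G3", "PHINT"):
            v = getattr(self, attr)
            if v <= 0:
                raise ValueError(f"{self.name}: {attr} must be > 0, got {v}")
        if not 150 <= self.P1 <= 350:
            raise ValueError(f"{self.name}: P1={self.P1} outside plausible range [150, 350]")
        if not 30 <= self.PHINT <= 55:
            raise ValueError(f"{self.name}: PHINT={self.PHINT} outside plausible range [30, 55]")


@dataclass(frozen=True)
class EcotypeParams:
    """Radiation-capture parameters shared by an ecotype.

    RUE is radiation-use efficiency in g aboveground biomass per MJ of
    intercepted photosynthetically active radiation; KCAN is the Beer-law
    canopy extinction coefficient in ``1 - exp(-KCAN * LAI)``.
    """

    RUE: float = 4.2
    KCAN: float = 0.85

    def __post_init__(self) -> None:
        if self.RUE <= 0:
            raise ValueError("RUE must be > 0")
        if not 0 < self.KCAN <= 1.5:
            raise ValueError("KCAN must be in (0, 1.5]")


def _check_breakpoints(table: tuple[tuple[float, float], ...], name: str) -> None:
    xs = [t for t, _ in table]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise ValueError(f"{name}: breakpoint temperatures must be strictly increasing")
    if any(not 0.0 <= f <= 1.0 for _, f in table):
        raise ValueError(f"{name}: factors must lie in [0, 1]")


@dataclass(frozen=True)
class SpeciesParams:
    """Species-level temperature and photoperiod responses.

    ``prftc`` scales daily photosynthesis and ``rgfil`` scales daily grain
    fill, both as piecewise-linear functions of daily mean temperature with
    values in [0, 1].  Defaults ship in ``data/species_default.yaml`` so the
    supra-optimal temperature response can be edited as data.
    """

    tbase: float = 8.0
    photoperiod_threshold: float = 12.5
    prftc: tuple[tuple[float, float], ...] = (
        (6.2, 0.0), (16.5, 1.0), (33.0, 1.0), (44.0, 0.0))
    rgfil: tuple[tuple[float, float], ...] = (
        (5.5, 0.0), (16.0, 1.0), (27.0, 1.0), (35.0, 0.0))

    def __post_init__(self) -> None:
        _check_breakpoints(self.prftc, "prftc")
        _check_breakpoints(self.rgfil, "rgfil")

    @staticmethod
    def _interp(table: tuple[tuple[float, float], ...], t: float) -> float:
        if t <= table[0][0]:
            return table[0][1]
        if t >= table[-1][0]:
            return table[-1][1]
        for (x0, y0), (x1, y1) in zip(table, table[1:]):
            if x0 <= t <= x1:
                return y0 + (y1 - y0) * (t - x0) / (x1 - x0)
        raise AssertionError("unreachable")

    def photosynthesis_factor(self, tmean: float) -> float:
        return self._interp(self.prftc, tmean)

    def grain_fill_factor(self, tmean: float) -> float:
        return self._interp(self.rgfil, tmean)


@dataclass(frozen=True)
class Management:
    """Agronomic management for one season.

    ``sowing_date`` is an ISO date string or the literal ``"auto"`` (plant on
    the first window day with enough topsoil moisture).  Plant density
    defaults to the regional recommendation of 53,333 plants per hectare.
    ``irrigation`` refills the profile to the drained upper limit whenever
    root-zone plant-available water drops below the given fraction of
    capacity; ``None`` means rainfed.
    """

    sowing_date: str = "auto"
    plant_density: float = 53333.0  # plants ha^-1
    irrigation_threshold: float | None = None  # fraction of PAW capacity

    def __post_init__(self) -> None:
        if self.plant_density <= 0:
            raise ValueError("plant_density must be > 0")
        if self.irrigation_threshold is not None and not 0 < self.irrigation_threshold <= 1:
            raise ValueError("irrigation_threshold must be in (0, 1]")


#: Maturity-group membership of the 16 packaged varieties.
MATURITY_GROUPS: dict[str, str] = {
    "Sammaz 54": "extra_early",
    "Sammaz 28": "extra_early",
    "Ife Hybrid 5": "extra_early",
    "Ife Hybrid 6": "extra_early",
    "Early White": "early",
    "Sammaz 32": "early",
    "Sammaz 34": "early",
    "Sammaz 41": "early",
    "M1026-10": "intermediate",
    "M1227-12": "intermediate",
    "IWDC2": "intermediate",
    "M0926-8": "intermediate",
    "Oba Super 9": "late",
    "Sammaz 11": "late",
    "TZL-COMP4": "late",
    "TZBSR": "late",
}

MATURITY_ORDER = ("extra_early", "early", "intermediate", "late")


def load_cultivars(path: str | Path) -> list[CultivarCoefficients]:
    """Read a cultivar coefficient CSV with header ``name,P1,P2,P5,G2,G3,PHINT``."""
    out: list[CultivarCoefficients] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "P1", "P2", "P5", "G2", "G3", "PHINT"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"cultivar file must have columns {sorted(required)}")
        for row in reader:
            out.append(CultivarCoefficients(
                name=row["name"].strip(),
                P1=float(row["P1"]), P2=float(row["P2"]), P5=float(row["P5"]),
                G2=float(row["G2"]), G3=float(row["G3"]), PHINT=float(row["PHINT"]),
            ))
    if not out:
        raise ValueError("cultivar file contains no rows")
    return out


def default_cultivars() -> list[CultivarCoefficients]:
    """The packaged 16-variety savanna coefficient table."""
    ref = resources.files("maizegxe.data").joinpath("cultivars_table2.csv")
    with resources.as_file(ref) as path:
        return load_cultivars(path)


def load_species(path: str | Path) -> SpeciesParams:
    """Read species parameters from a YAML file (see ``data/species_default.yaml``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return SpeciesParams(
        tbase=float(raw.get("tbase", 8.0)),
        photoperiod_threshold=float(raw.get("photoperiod_threshold", 12.5)),
        prftc=tuple((float(a), float(b)) for a, b in raw["prftc"]),
        rgfil=tuple((float(a), float(b)) for a, b in raw["rgfil"]),
    )


def default_species() -> SpeciesParams:
    ref = resources.files("maizegxe.data").joinpath("species_default.yaml")
    with resources.as_file(ref) as path:
        return load_species(path)
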