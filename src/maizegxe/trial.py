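"""Genotype x environment x replicate yield tables.

The long CSV interchange format has columns
``genotype,environment,rep,yield_mg_ha``; internally a trial is a dense,
balanced 3-D array (p genotypes x q environments x r reps) because every
stability estimator in :mod:`maizegxe.stability` assumes balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["YieldTrial", "read_trial_csv", "write_trial_csv"]


@dataclass(frozen=True)
class YieldTrial:
    """Balanced multi-environment yield trial, Mg ha^-1."""

    yields: np.ndarray               # shape (p, q, r)
    genotypes: tuple[str, ...]
    environments: tuple[str, ...]
    reps: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.yields, dtype=float)
        object.__setattr__(self, "yields", arr)
        p, q, r = len(self.genotypes), len(self.environments), len(self.reps)
        if arr.shape != (p, q, r):
            raise ValueError(f"yields shape {arr.shape} != (p={p}, q={q}, r={r})")
        if np.isnan(arr).any():
            raise ValueError("trial has missing cells; the estimators require "
                             "complete balanced data")

    @property
    def p(self) -> int:
        return len(self.genotypes)

    @property
    def q(self) -> int:
        return len(self.environments)

    @property
    def r(self) -> int:
        return len(self.reps)

    def cell_means(self) -> np.ndarray:
        """Genotype x environment means over replicates, shape (p, q)."""
        return self.yields.mean(axis=2)

    def genotype_means(self) -> np.ndarray:
        return self.yields.mean(axis=(1, 2))

    def environment_means(self) -> np.ndarray:
        return self.yields.mean(axis=(0, 2))

    def grand_mean(self) -> float:
        return float(self.yields.mean())

    def to_long(self) -> pd.DataFrame:
        p, q, r = self.yields.shape
        gi, ej, rk = np.meshgrid(np.arange(p), np.arange(q), np.arange(r),
                                 indexing="ij")
        return pd.DataFrame({
            "genotype": np.asarray(self.genotypes)[gi.ravel()],
            "environment": np.asarray(self.environments)[ej.ravel()],
            "rep": np.asarray(self.reps)[rk.ravel()],
            "yield_mg_ha": self.yields.ravel(),
        })

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "YieldTrial":
        required = {"genotype", "environment", "rep", "yield_mg_ha"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        gs = tuple(pd.unique(df["genotype"].astype(str)))
        es = tuple(pd.unique(df["environment"].astype(str)))
        rs = tuple(pd.unique(df["rep"].astype(str)))
        pivot = df.set_index(
            [df["genotype"].astype(str), df["environment"].astype(str),
             df["rep"].astype(str)])["yield_mg_ha"]
        if pivot.index.duplicated().any():
            raise ValueError("duplicate genotype/environment/rep rows")
        arr = np.full((len(gs), len(es), len(rs)), np.nan)
        for (g, e, r), y in pivot.items():
            arr[gs.index(g), es.index(e), rs.index(r)] = y
        if np.isnan(arr).any():
            raise ValueError("trial is unbalanced: some genotype x environment "
                             "x rep cells are missing")
        return cls(arr, gs, es, rs)


def read_trial_csv(path: str | Path) -> YieldTrial:
    return YieldTrial.from_long(pd.read_csv(path))


def write_trial_csv(trial: YieldTrial, path: str | Path) -> None:
    trial.to_long().to_csv(path, index=False)
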