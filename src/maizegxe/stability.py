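"""Variance partitioning and multi-model yield-stability statistics.

Given a balanced multi-environment trial this module provides:

* the combined two-way ANOVA (genotype, environment, GEI, replicate block,
  error) with %-of-total-SS variance shares,
* Finlay-Wilkinson joint regression (slope ``bi`` and deviation mean
  square ``S2d``),
* Wricke's ecovalence ``Wi`` (a genotype's share of the interaction SS),
* Shukla's unbiased stability variance ``sigma2_i`` (an affine,
  order-preserving function of ``Wi``),
* the AMMI decomposition (SVD of the double-centered cell-mean table) and
  the Purchase AMMI stability value (ASV),
* the Kang rank-sum yield-stability index (YSi),
* AICc comparison of the additive, Finlay-Wilkinson and AMMI cell-mean
  models, and
* rank concordance between two stability reports (e.g. observed vs
  simulated yields).

All stability statistics operate on genotype x environment cell means
(replicates averaged first), the convention of the classical estimators;
the error mean square from the full ANOVA feeds the significance tests in
the Kang index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trial import YieldTrial

__all__ = [
    "AnovaTable", "two_way_anova", "anova_from_sums_of_squares",
    "environment_index", "finlay_wilkinson", "wricke_ecovalence",
    "shukla_sigma2", "AmmiResult", "ammi", "asv", "kang_ysi",
    "aicc_compare", "StabilityReport", "build_stability_report",
    "rank_concordance", "STABILITY_PENALTY", "YIELD_ADJUSTMENT",
]

log = logging.getLogger(__name__)

_SOURCES = ("G", "E", "GEI", "Rep", "Error", "Total")


class ZeroVarianceError(ValueError):
    """All observations identical: variance shares are undefined."""


@dataclass(frozen=True)
class AnovaTable:
    """Balanced two-way ANOVA with a crossed replicate block."""

    df: dict[str, int]
    ss: dict[str, float]

    def __post_init__(self) -> None:
        for src in _SOURCES:
            if src not in self.df or src not in self.ss:
                raise ValueError(f"missing source {src!r}")
        if any(v < -1e-9 for v in self.ss.values()):
            raise ValueError("sums of squares must be non-negative")
        parts = sum(self.ss[s] for s in _SOURCES[:-1])
        if abs(parts - self.ss["Total"]) > 1e-9 * max(1.0, self.ss["Total"]):
            raise ValueError("component SS do not add up to the total")

    @property
    def ms(self) -> dict[str, float]:
        return {s: self.ss[s] / self.df[s] for s in _SOURCES[:-1] if self.df[s] > 0}

    @property
    def pct_ss(self) -> dict[str, float]:
        """% variance estimate: each source's share of the total SS."""
        total = self.ss["Total"]
        if total <= 0:
            raise ZeroVarianceError("total SS is zero; % shares undefined")
        return {s: 100.0 * self.ss[s] / total for s in _SOURCES[:-1]}

    def f_tests(self) -> dict[str, tuple[float, float]]:
        """(F, p) for G, E, GEI and Rep against the error mean square."""
        ms = self.ms
        err = ms.get("Error", 0.0)
        out = {}
        for s in ("G", "E", "GEI", "Rep"):
            if s not in ms or err <= 0:
                continue
            f = ms[s] / err
            out[s] = (f, float(sps.f.sf(f, self.df[s], self.df["Error"])))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        pct = self.pct_ss
        ms = self.ms
        for s in _SOURCES:
            rows.append({"source": s, "df": self.df[s], "SS": self.ss[s],
                         "MS": ms.get(s, float("nan")),
                         "pct_SS": pct.get(s, 100.0 if s == "Total" else float("nan"))})
        return pd.DataFrame(rows)


def anova_from_sums_of_squares(ss: dict[str, float], p: int, q: int, r: int) -> AnovaTable:
    """Build the ANOVA table from externally supplied sums of squares
    (e.g. a published table), deriving the balanced degrees of freedom."""
    df = {"G": p - 1, "E": q - 1, "GEI": (p - 1) * (q - 1), "Rep": r - 1,
          "Total": p * q * r - 1}
    df["Error"] = df["Total"] - df["G"] - df["E"] - df["GEI"] - df["Rep"]
    ss = dict(ss)
    if "Total" not in ss:
        ss["Total"] = sum(ss[s] for s in _SOURCES[:-1])
    return AnovaTable(df=df, ss=ss)


def two_way_anova(trial: YieldTrial) -> AnovaTable:
    """Partition a balanced trial's total SS into G, E, GEI, Rep and Error.

    The replicate is treated as a crossed block (df = r - 1); the error df
    is the remainder ``pqr - 1 - (p-1) - (q-1) - (p-1)(q-1) - (r-1)``.
    """
    y = trial.yields
    p, q, r = y.shape
    grand = y.mean()
    if np.allclose(y, grand):
        raise ZeroVarianceError("all cells identical; ANOVA undefined")

    ss_total = float(((y - grand) ** 2).sum())
    gm = y.mean(axis=(1, 2))
    em = y.mean(axis=(0, 2))
    rm = y.mean(axis=(0, 1))
    cell = y.mean(axis=2)
    ss_g = q * r * float(((gm - grand) ** 2).sum())
    ss_e = p * r * float(((em - grand) ** 2).sum())
    ss_rep = p * q * float(((rm - grand) ** 2).sum())
    inter = cell - gm[:, None] - em[None, :] + grand
    ss_gei = r * float((inter ** 2).sum())
    ss_err = ss_total - ss_g - ss_e - ss_gei - ss_rep
    ss_err = max(0.0, ss_err)

    df = {"G": p - 1, "E": q - 1, "GEI": (p - 1) * (q - 1), "Rep": r - 1,
          "Total": p * q * r - 1}
    df["Error"] = df["Total"] - df["G"] - df["E"] - df["GEI"] - df["Rep"]
    ss = {"G": ss_g, "E": ss_e, "GEI": ss_gei, "Rep": ss_rep, "Error": ss_err,
          "Total": ss_total}
    return AnovaTable(df=df, ss=ss)


def environment_index(trial: YieldTrial) -> np.ndarray:
    """Environment index I_j = (environment mean) - (grand mean); sums to 0."""
    em = trial.environment_means()
    return em - em.mean()


def finlay_wilkinson(trial: YieldTrial) -> tuple[np.ndarray, np.ndarray]:
    """Joint-regression slopes ``bi`` and deviation mean squares ``S2d``.

    Each genotype's cell means are regressed on the environment index; on
    balanced data the slopes average exactly 1.  S2d is the residual SS
    divided by q - 2.
    """
    q = trial.q
    if q < 3:
        raise ValueError("Finlay-Wilkinson needs at least 3 environments")
    idx = environment_index(trial)
    denom = float(idx @ idx)
    if denom == 0.0:
        raise ZeroVarianceError("no environmental gradient: all I_j are zero")
    cell = trial.cell_means()
    gm = cell.mean(axis=1)
    bi = (cell - gm[:, None]) @ idx / denom
    resid = cell - gm[:, None] - np.outer(bi, idx)
    s2d = (resid ** 2).sum(axis=1) / (q - 2)
    return bi, s2d


def wricke_ecovalence(trial: YieldTrial) -> np.ndarray:
    """W_i = sum_j (cell_ij - row_i - col_j + grand)^2 on the cell means.

    The W_i sum to the interaction SS of the cell-mean table.
    """
    cell = trial.cell_means()
    inter = (cell - cell.mean(axis=1, keepdims=True)
             - cell.mean(axis=0, keepdims=True) + cell.mean())
    return (inter ** 2).sum(axis=1)


def shukla_sigma2(w: np.ndarray, p: int, q: int) -> np.ndarray:
    """Shukla's unbiased stability variance from ecovalences.

    sigma2_i = p W_i / ((p-2)(q-1)) - sum_r W_r / ((p-1)(p-2)(q-1)).

    Linear and strictly increasing in W_i, so it preserves the ecovalence
    ranking; individual values may legitimately be negative and are never
    clamped.
    """
    w = np.asarray(w, dtype=float)
    if p < 3:
        raise ValueError("Shukla's estimator needs at least 3 genotypes")
    if q < 2:
        raise ValueError("Shukla's estimator needs at least 2 environments")
    return p * w / ((p - 2) * (q - 1)) - w.sum() / ((p - 1) * (p - 2) * (q - 1))


@dataclass(frozen=True)
class AmmiResult:
    """AMMI decomposition of a cell-mean table."""

    additive_fit: np.ndarray        # p x q additive model values
    genotype_scores: np.ndarray     # p x k, scaled by sqrt(singular value)
    environment_scores: np.ndarray  # q x k
    singular_values: np.ndarray     # k
    axis_ss: np.ndarray             # k, = singular value squared

    @property
    def gei_ss(self) -> float:
        return float(self.axis_ss.sum())


def ammi(trial: YieldTrial) -> AmmiResult:
    """Additive main effects + SVD of the doubly centered interaction.

    The squared singular values sum to the interaction SS of the cell-mean
    table; IPCA scores use the symmetric sqrt(lambda) scaling.  Axes with
    numerically zero singular value are dropped (a purely additive table
    yields zero axes).
    """
    if trial.p < 3 or trial.q < 3:
        raise ValueError("AMMI needs at least a 3 x 3 genotype x environment table")
    cell = trial.cell_means()
    gm = cell.mean(axis=1, keepdims=True)
    em = cell.mean(axis=0, keepdims=True)
    grand = cell.mean()
    additive = gm + em - grand
    inter = cell - additive
    u, s, vt = np.linalg.svd(inter, full_matrices=False)
    scale = max(1.0, float(np.abs(inter).max()))
    keep = s > 1e-12 * scale
    u, s, vt = u[:, keep], s[keep], vt[keep]
    return AmmiResult(
        additive_fit=additive,
        genotype_scores=u * np.sqrt(s),
        environment_scores=vt.T * np.sqrt(s),
        singular_values=s,
        axis_ss=s ** 2,
    )


def asv(ipca1: np.ndarray, ipca2: np.ndarray, ss1: float, ss2: float) -> np.ndarray:
    """Purchase's AMMI stability value.

    ASV_i = sqrt((SS1/SS2 * IPCA1_i)^2 + IPCA2_i^2).  If the second axis is
    degenerate (SS2 = 0) the fall-back |IPCA1| is returned with a warning.
    """
    ipca1 = np.asarray(ipca1, dtype=float)
    if ss2 <= 0:
        log.warning("ASV fall-back: second IPCA axis has zero SS; using |IPCA1|")
        return np.abs(ipca1)
    ipca2 = np.asarray(ipca2, dtype=float)
    return np.sqrt((ss1 / ss2 * ipca1) ** 2 + ipca2 ** 2)


#: Kang (1993) stability-variance penalty: (significance level, penalty).
STABILITY_PENALTY: tuple[tuple[float, int], ...] = ((0.001, -8), (0.01, -4), (0.05, -2))
#: Yield-rank adjustment: contribution (sign follows the deviation from the
#: grand mean): (significance level, magnitude); non-significant -> 1.
YIELD_ADJUSTMENT: tuple[tuple[float, int], ...] = ((0.01, 3), (0.05, 2))


def kang_ysi(trial: YieldTrial, sigma2: np.ndarray, error_ms: float,
             error_df: int) -> tuple[np.ndarray, np.ndarray]:
    """Kang rank-sum yield-stability index.

    Yield ranks run 1 (lowest) to p (highest) and are adjusted by +/-1, 2
    or 3 according to a t-test of each genotype mean against the grand
    mean.  A stability penalty of 0 / -2 / -4 / -8 is subtracted when the
    Shukla variance is significant at 5 / 1 / 0.1 % by an F-test against
    the pooled error of cell means.  Genotypes with YSi above the mean YSi
    are flagged stable.

    Returns ``(ysi, stable)`` arrays.
    """
    if error_ms < 0:
        raise ValueError("error mean square must be >= 0")
    p, q, r = trial.p, trial.q, trial.r
    gm = trial.genotype_means()
    grand = gm.mean()
    ranks = sps.rankdata(gm, method="average")

    # significance of the yield difference from the grand mean
    se = math.sqrt(error_ms / (q * r)) if error_ms > 0 else 0.0
    adj = np.empty(p)
    for i in range(p):
        dev = gm[i] - grand
        if se > 0:
            pval = 2.0 * float(sps.t.sf(abs(dev) / se, error_df))
        else:
            pval = 0.0 if dev != 0 else 1.0
        mag = 1
        for level, m in YIELD_ADJUSTMENT:
            if pval < level:
                mag = m
                break
        adj[i] = math.copysign(mag, dev) if dev != 0 else 0.0

    # stability penalty from the Shukla variance F-test
    penalty = np.zeros(p, dtype=int)
    pooled = error_ms / r if error_ms > 0 else 0.0
    for i in range(p):
        if pooled > 0:
            f = max(0.0, float(sigma2[i])) / pooled
            pval = float(sps.f.sf(f, q - 1, error_df))
        else:
            pval = 0.0 if sigma2[i] > 0 else 1.0
        for level, pen in STABILITY_PENALTY:
            if pval < level:
                penalty[i] = pen
                break

    ysi = ranks + adj + penalty
    stable = ysi > ysi.mean()
    return ysi, stable


class PerfectFitError(ArithmeticError):
    """A stability model fits the cell means exactly; AICc is -infinity."""


def aicc_compare(trial: YieldTrial,
                 models: tuple[str, ...] = ("additive", "FW", "AMMI1", "AMMI2"),
                 ) -> dict[str, float]:
    """Corrected AIC for competing cell-mean models; smaller is better.

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1) over the n = p*q cell means.
    Parameter counts: additive k = p+q-1; Finlay-Wilkinson adds p-1 slopes;
    AMMI-m adds m(p+q-1-m) score parameters.  A model with RSS = 0 raises
    :class:`PerfectFitError` rather than returning -infinity silently.
    """
    cell = trial.cell_means()
    p, q = cell.shape
    n = p * q
    gm = cell.mean(axis=1, keepdims=True)
    em = cell.mean(axis=0, keepdims=True)
    grand = cell.mean()
    additive = gm + em - grand

    fits: dict[str, tuple[np.ndarray, int]] = {}
    k_add = p + q - 1
    for name in models:
        if name == "additive":
            fits[name] = (additive, k_add)
        elif name == "FW":
            bi, _ = finlay_wilkinson(trial)
            idx = environment_index(trial)
            fits[name] = (cell.mean(axis=1)[:, None] + np.outer(bi, idx),
                          k_add + (p - 1))
        elif name.startswith("AMMI"):
            m = int(name[4:] or 1)
            dec = ammi(trial)
            kmax = dec.genotype_scores.shape[1]
            mm = min(m, kmax)
            fit = additive + dec.genotype_scores[:, :mm] @ dec.environment_scores[:, :mm].T
            fits[name] = (fit, k_add + m * (p + q - 1 - m))
        else:
            raise ValueError(f"unknown stability model {name!r}")

    out: dict[str, float] = {}
    for name, (fit, k) in fits.items():
        if n - k - 1 <= 0:
            raise ValueError(f"{name}: n - k - 1 = {n - k - 1} <= 0; "
                             "too few cells for this model")
        rss = float(((cell - fit) ** 2).sum())
        if rss <= 0.0:
            raise PerfectFitError(f"{name}: zero residual sum of squares")
        out[name] = n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return out


@dataclass(frozen=True)
class StabilityReport:
    """Per-genotype stability statistics for one yield source."""

    source: str                       # e.g. "observed" or "simulated"
    table: pd.DataFrame               # indexed by genotype
    aicc: dict[str, float]
    n_stable: int

    #: statistics for which per-genotype ranks are reported
    STATISTICS = ("mean_yield", "bi", "S2d", "ecovalence", "sigma2", "asv", "ysi")

    def ranks(self) -> pd.DataFrame:
        """Rank 1 = most stable (smallest statistic); for mean_yield and
        YSi rank 1 = best (largest).  Ties get average ranks."""
        out = {}
        for stat in self.STATISTICS:
            v = self.table[stat].to_numpy(dtype=float)
            if stat in ("mean_yield", "ysi"):
                v = -v
            elif stat == "bi":
                v = np.abs(v - 1.0)
            out[stat] = sps.rankdata(v, method="average")
        return pd.DataFrame(out, index=self.table.index)


def build_stability_report(trial: YieldTrial, source: str = "trial") -> StabilityReport:
    """Run the full stability battery on one trial."""
    anova = two_way_anova(trial)
    bi, s2d = finlay_wilkinson(trial)
    w = wricke_ecovalence(trial)
    sigma2 = shukla_sigma2(w, trial.p, trial.q)
    dec = ammi(trial)
    if dec.genotype_scores.shape[1] >= 2:
        asv_vals = asv(dec.genotype_scores[:, 0], dec.genotype_scores[:, 1],
                       float(dec.axis_ss[0]), float(dec.axis_ss[1]))
    else:
        score1 = (dec.genotype_scores[:, 0] if dec.genotype_scores.shape[1]
                  else np.zeros(trial.p))
        asv_vals = asv(score1, np.zeros(trial.p), 1.0, 0.0)
    ysi, stable = kang_ysi(trial, sigma2, anova.ms.get("Error", 0.0),
                           anova.df["Error"])
    table = pd.DataFrame({
        "mean_yield": trial.genotype_means(),
        "bi": bi, "S2d": s2d, "ecovalence": w, "sigma2": sigma2,
        "asv": asv_vals, "ysi": ysi, "stable": stable,
    }, index=pd.Index(trial.genotypes, name="genotype"))
    return StabilityReport(source=source, table=table,
                           aicc=aicc_compare(trial), n_stable=int(stable.sum()))


def rank_concordance(report_a: StabilityReport, report_b: StabilityReport,
                     top_k: int = 3) -> pd.DataFrame:
    """Spearman rank correlation and top-k agreement per statistic.

    Both reports must cover the same genotypes.  Returns a frame with one
    row per statistic: ``spearman_rho``, ``p_value`` and ``top{k}_overlap``
    (fraction of the k most stable genotypes shared).
    """
    if list(report_a.table.index) != list(report_b.table.index):
        raise ValueError("reports cover different genotype sets")
    ra, rb = report_a.ranks(), report_b.ranks()
    rows = []
    for stat in StabilityReport.STATISTICS:
        a, b = ra[stat].to_numpy(), rb[stat].to_numpy()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            rho, pval = float("nan"), float("nan")
        else:
            rho, pval = sps.spearmanr(a, b)
        top_a = set(ra[stat].nsmallest(top_k).index)
        top_b = set(rb[stat].nsmallest(top_k).index)
        rows.append({"statistic": stat, "spearman_rho": float(rho),
                     "p_value": float(pval),
                     f"top{top_k}_overlap": len(top_a & top_b) / top_k})
    return pd.DataFrame(rows).set_index("statistic")
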