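"""Nonparametric multi-model comparison on paired per-patient metrics.

Each metric yields an n_patients x k_models table of paired observations
(every model evaluated on the same patients). Because segmentation metrics
are typically non-Gaussian (checked here with Shapiro-Wilk and QQ data),
model differences are tested with the rank-based Friedman omnibus test

    Q = 12 n / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2

with within-row average ranks for ties and a chi-square reference
distribution on k-1 degrees of freedom, followed by Conover's post-hoc
pairwise comparison of column rank sums on a t distribution with
(n-1)(k-1) degrees of freedom. Pairwise p-values are reported unadjusted
by default (Holm adjustment available as an option).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "MetricTable",
    "ComparisonReport",
    "NormalityResult",
    "normality_check",
    "ci95",
    "friedman_test",
    "conover_posthoc",
    "compare",
    "significance_marks",
]


@dataclass
class MetricTable:
    """n_patients x k_models matrix of one metric's paired observations."""

    values: np.ndarray
    model_names: list[str]
    metric_name: str = ""
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("metric table must be 2-D (patients x models)")
        n, k = vals.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 patients and >= 2 models, got {vals.shape}")
        if len(self.model_names) != k:
            raise ValueError("model_names length must match the number of columns")
        if not np.isfinite(vals).all():
            raise ValueError("metric table must not contain missing cells")
        self.values = vals

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_models(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        metric: str,
        *,
        patient_col: str = "patient_id",
        model_col: str = "model",
    ) -> "MetricTable":
        """Pivot a long per-patient/per-model metric frame into a table.

        Patients with any missing value for this metric are dropped
        row-wise (logged), keeping the design balanced.
        """
        wide = df.pivot(index=patient_col, columns=model_col, values=metric)
        incomplete = wide.index[wide.isna().any(axis=1)]
        if len(incomplete) > 0:
            logger.warning(
                "dropping %d patient(s) with missing %s values: %s",
                len(incomplete), metric, list(incomplete),
            )
            wide = wide.dropna(axis=0)
        return cls(
            values=wide.to_numpy(dtype=float),
            model_names=[str(c) for c in wide.columns],
            metric_name=metric,
            patient_ids=[str(i) for i in wide.index],
        )


@dataclass
class ComparisonReport:
    """Friedman omnibus result plus the Conover pairwise p-value matrix."""

    friedman_statistic: float
    friedman_p: float
    conover_p: pd.DataFrame  # k x k, symmetric, unit diagonal
    alpha: float = 0.05
    metric_name: str = ""


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk result with QQ data for visual inspection."""

    statistic: float
    p_value: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    degenerate: bool = False


def normality_check(values: list[float] | np.ndarray) -> NormalityResult:
    """Shapiro-Wilk normality test plus theoretical-vs-sample QQ pairs.

    A constant vector has no defined test; it is returned flagged
    degenerate with NaN statistic and p-value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("normality check needs at least 3 values")
    (theo, ordered), _ = sps.probplot(arr, dist="norm", fit=True)
    if np.ptp(arr) == 0:
        return NormalityResult(np.nan, np.nan, theo, ordered, degenerate=True)
    stat, p = sps.shapiro(arr)
    return NormalityResult(float(stat), float(p), theo, ordered)


def ci95(values: list[float] | np.ndarray) -> tuple[float, float]:
    """95% dispersion interval: mean +/- 1.96 x sample standard deviation.

    This is the band for individual observations (as drawn around noisy
    per-epoch metric curves), not the standard-error interval on the mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("ci95 needs at least 2 values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return mean - 1.96 * sd, mean + 1.96 * sd


def _row_ranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, axis=1, method="average")


def friedman_test(table: MetricTable | np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test across k >= 3 paired model columns.

    Ties within a patient row receive average ranks; the statistic uses
    the plain (uncorrected) chi-square form with k-1 degrees of freedom,
    so a fully tied table gives Q = 0, p = 1.
    """
    values = table.values if isinstance(table, MetricTable) else np.asarray(table, float)
    n, k = values.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 models")
    ranks = _row_ranks(values)
    mean_ranks = ranks.mean(axis=0)
    q = 12.0 * n / (k * (k + 1)) * float(((mean_ranks - (k + 1) / 2.0) ** 2).sum())
    p = float(sps.chi2.sf(q, df=k - 1))
    return q, p


def conover_posthoc(table: MetricTable | np.ndarray) -> pd.DataFrame:
    """Conover's Friedman post-hoc pairwise p-value matrix (unadjusted).

    For column rank sums R_j, rank-squared total A1 = sum_ij r_ij^2 and
    C1 = n k (k+1)^2 / 4, the pairwise statistic is

        t_ij = |R_i - R_j| / sqrt( 2 n (A1 - C1) / ((n-1)(k-1))
                                   * (1 - T1 / (n (k-1))) )

    where T1 = (k-1) sum_j (R_j - n(k+1)/2)^2 / (A1 - C1) is the
    tie-corrected Friedman statistic, referred to a two-sided t
    distribution on (n-1)(k-1) degrees of freedom. A fully tied table
    yields p = 1 everywhere; perfectly consistent rankings collapse the
    variance and give p = 0 for any unequal pair.
    """
    if isinstance(table, MetricTable):
        values, names = table.values, table.model_names
    else:
        values = np.asarray(table, dtype=float)
        names = [f"model{i}" for i in range(values.shape[1])]
    n, k = values.shape
    if k < 3:
        raise ValueError("Conover post-hoc needs at least 3 models")
    ranks = _row_ranks(values)
    rank_sums = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    df = (n - 1) * (k - 1)
    pmat = np.ones((k, k))
    if a1 - c1 <= 0:  # every row fully tied: no information, no differences
        return pd.DataFrame(pmat, index=names, columns=names)
    t1 = (k - 1) * float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum()) / (a1 - c1)
    var = 2.0 * n * (a1 - c1) / df * (1.0 - t1 / (n * (k - 1)))
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(rank_sums[i] - rank_sums[j])
        if var <= 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / np.sqrt(var)
            p = 2.0 * float(sps.t.sf(t, df=df))
        pmat[i, j] = pmat[j, i] = min(p, 1.0)
    return pd.DataFrame(pmat, index=names, columns=names)


def _holm_adjust(pmat: pd.DataFrame) -> pd.DataFrame:
    k = pmat.shape[0]
    pairs = list(itertools.combinations(range(k), 2))
    raw = np.array([pmat.iloc[i, j] for i, j in pairs])
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adj[idx] = min(1.0, running)
    out = pmat.copy()
    for (i, j), p in zip(pairs, adj):
        out.iloc[i, j] = out.iloc[j, i] = p
    return out


def compare(
    table: MetricTable, alpha: float = 0.05, adjust: str = "none"
) -> ComparisonReport:
    """Friedman omnibus test followed by the Conover pairwise comparison."""
    stat, p = friedman_test(table)
    pmat = conover_posthoc(table)
    if adjust == "holm":
        pmat = _holm_adjust(pmat)
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r} (use 'none' or 'holm')")
    return ComparisonReport(
        friedman_statistic=stat,
        friedman_p=p,
        conover_p=pmat,
        alpha=alpha,
        metric_name=table.metric_name,
    )


def significance_marks(report: ComparisonReport) -> set[tuple[str, str]]:
    """Model pairs with Conover p < alpha, gated on a significant omnibus.

    If the Friedman p-value is not below alpha, no pairwise differences
    are claimed regardless of the pairwise values.
    """
    if not report.friedman_p < report.alpha:
        return set()
    names = list(report.conover_p.columns)
    marks: set[tuple[str, str]] = set()
    for i, j in itertools.combinations(range(len(names)), 2):
        if report.conover_p.iloc[i, j] < report.alpha:
            marks.add((names[i], names[j]))
    return marks
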