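"""Case/control association machinery for the cross-platform validation design.

The validating experiment is deliberately null: a cohort is split at random
into "cases" and "controls", so any genome-wide significant SNP is a false
positive manufactured by differential imputation error.  This module
provides the per-SNP dosage trend test, the genomic inflation factor λ,
QQ-plot coordinates, genome-wide hit counting, and metric-threshold filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PosteriorMatrix, _as_probs

__all__ = [
    "GENOME_WIDE_ALPHA",
    "PhenotypeVector",
    "AssocResult",
    "FilterRule",
    "dosage_trend_test",
    "trend_chi2_batch",
    "genomic_lambda",
    "qq_points",
    "count_genomewide_hits",
    "apply_filter",
]

#: Conventional genome-wide significance threshold (strict inequality).
GENOME_WIDE_ALPHA: float = 5e-8

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1DF_MEDIAN: float = float(stats.chi2.ppf(0.5, df=1))

_METRIC_RANGES = {
    "iqs": (-1.0, 1.0),
    "accuracy": (0.0, 1.0),
    "info_score": (-1.0, 1.0),
    "variance_ratio": (0.0, np.inf),
    "maf": (0.0, 0.5),
    "maf_difference": (0.0, 0.5),
    "p_observed": (0.0, 1.0),
    "p_chance": (0.0, 1.0),
    "efficiency": (0.0, 1.0),
}

_COMPARATORS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


@dataclass(frozen=True)
class PhenotypeVector:
    """Binary case/control labels, 1 = case, 0 = control."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels).astype(np.int8)
        if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
            raise ValueError("phenotype labels must be a 1-D 0/1 sequence")
        if arr.sum() == 0 or arr.sum() == arr.shape[0]:
            raise ValueError("need at least one case and one control")
        object.__setattr__(self, "labels", arr)

    def __len__(self) -> int:
        return self.labels.shape[0]


@dataclass(frozen=True)
class AssocResult:
    """1-df chi-square association result for one SNP."""

    snp_id: str
    statistic: float
    p_value: float
    n_used: int
    degenerate: bool = False


def trend_chi2_batch(dosages: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Score/trend chi-square for many SNPs against one binary phenotype.

    ``statistic = N * r^2`` where ``r`` is the Pearson correlation between
    dosage and phenotype — algebraically identical to the Cochran–Armitage
    trend chi-square with scores (0, 1, 2) when dosages are hard calls.
    Zero-variance dosages yield statistic 0.

    Parameters
    ----------
    dosages : (S, N) or (N,) expected allele-B counts
    y : (N,) 0/1 phenotype
    """
    d = np.atleast_2d(np.asarray(dosages, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if d.shape[1] != n:
        raise ValueError("dosage and phenotype lengths differ")
    yc = y - y.mean()
    dm = d.mean(axis=1, keepdims=True)
    cov = (d - dm) @ yc / n
    var_d = ((d - dm) ** 2).mean(axis=1)
    var_y = (yc**2).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var_d > 0, cov**2 / (var_d * var_y), 0.0)
    return n * r2


def dosage_trend_test(posteriors: PosteriorMatrix | np.ndarray,
                      phenotype: PhenotypeVector | np.ndarray,
                      snp_id: str | None = None) -> AssocResult:
    """1-df trend test on expected dosage between cases and controls.

    Imputation uncertainty enters through the expected dosage
    ``p_AB + 2 p_BB``; for certain genotypes the statistic reduces to the
    classical Cochran–Armitage trend chi-square.  A SNP with zero dosage
    variance (e.g. fully monomorphic posteriors) is flagged degenerate and
    reported with statistic 0, p = 1.
    """
    if isinstance(posteriors, PosteriorMatrix):
        if snp_id is None:
            snp_id = posteriors.snp_id
        dosage = posteriors.dosage
    else:
        probs = _as_probs(posteriors)
        dosage = probs[:, 1] + 2.0 * probs[:, 2]
    pheno = phenotype if isinstance(phenotype, PhenotypeVector) else PhenotypeVector(phenotype)
    if dosage.shape[0] != len(pheno):
        raise ValueError("posterior and phenotype lengths differ")
    stat = float(trend_chi2_batch(dosage, pheno.labels)[0])
    degenerate = np.isclose(dosage.var(), 0.0)
    if degenerate:
        stat = 0.0
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return AssocResult(snp_id or "", stat, p, n_used=dosage.shape[0], degenerate=degenerate)


def _statistics(results) -> np.ndarray:
    if isinstance(results, pd.DataFrame):
        return results["statistic"].to_numpy(dtype=float)
    arr = np.asarray([r.statistic if isinstance(r, AssocResult) else r for r in results],
                     dtype=float)
    return arr


def _p_values(results) -> np.ndarray:
    if isinstance(results, pd.DataFrame):
        return results["p_value"].to_numpy(dtype=float)
    first = results[0] if len(results) else None
    if isinstance(first, AssocResult):
        return np.asarray([r.p_value for r in results], dtype=float)
    return np.asarray(results, dtype=float)


def genomic_lambda(results) -> float:
    """Genomic inflation factor: median chi-square over the null χ²₁ median.

    λ far above 1 signals systematic inflation across many SNPs.  Note that
    a small set of grossly mis-imputed SNPs can produce dramatic genome-wide
    false positives while moving λ only slightly, so λ alone is a weak
    diagnostic for imputation artifacts.
    """
    stat = _statistics(results)
    if stat.size == 0:
        raise ValueError("no association results")
    if stat.size < 100:
        warnings.warn(f"genomic lambda estimated from only {stat.size} SNPs", stacklevel=2)
    return float(np.median(stat) / CHI2_1DF_MEDIAN)


def qq_points(results) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) −log10 p-value pairs for a QQ plot.

    P-values are sorted ascending; rank ``k`` (1-based) of ``m`` is compared
    to the uniform quantile ``(k − 0.5) / m``.
    """
    p = np.sort(_p_values(results))
    if p.size == 0:
        raise ValueError("no association results")
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, 1e-300, None))
    return expected, observed


def count_genomewide_hits(results, alpha: float = GENOME_WIDE_ALPHA) -> int:
    """Number of SNPs with p strictly below ``alpha``."""
    return int((_p_values(results) < alpha).sum())


@dataclass(frozen=True)
class FilterRule:
    """Threshold rule on one per-SNP metric, e.g. ``FilterRule("iqs", ">", 0.9)``.

    SNPs whose metric value is undefined (NaN) never pass.
    """

    metric: str
    comparator: str
    threshold: float

    def __post_init__(self):
        if self.metric not in _METRIC_RANGES:
            raise ValueError(f"unknown metric {self.metric!r}; "
                             f"choose from {sorted(_METRIC_RANGES)}")
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        lo, hi = _METRIC_RANGES[self.metric]
        if not lo <= self.threshold <= hi:
            raise ValueError(
                f"threshold {self.threshold} outside {self.metric} range [{lo}, {hi}]")

    def mask(self, metrics: pd.DataFrame) -> np.ndarray:
        values = metrics[self.metric].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            passed = _COMPARATORS[self.comparator](values, self.threshold)
        return passed & ~np.isnan(values)

    def __str__(self) -> str:
        return f"{self.metric} {self.comparator} {self.threshold:g}"


def apply_filter(metrics: pd.DataFrame,
                 rule: FilterRule | list[FilterRule]) -> tuple[list[str], float]:
    """Apply one rule (or the AND of several) to a per-SNP metrics table.

    Returns the retained SNP ids and the retention proportion.
    """
    rules = [rule] if isinstance(rule, FilterRule) else list(rule)
    if metrics.empty:
        return [], float("nan")
    mask = np.ones(len(metrics), dtype=bool)
    for r in rules:
        mask &= r.mask(metrics)
    retained = metrics.loc[mask, "snp_id"].tolist()
    return retained, len(retained) / len(metrics)
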