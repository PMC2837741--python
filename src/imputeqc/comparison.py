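"""Truth-free imputation-quality statistics used as filtering baselines.

These are the measures practitioners apply when no directly genotyped truth
is available for the imputed SNPs: the dosage variance ratio (MACH's
``rsq_hat``) and the IMPUTE-style information score (the stand-in for
SNPTEST's PROPER_INFO, whose internals are not published), plus the
difference between the estimated and a reference minor allele frequency.
Both information measures equal 1 for certain genotypes at Hardy-Weinberg
counts and fall toward 0 as the posteriors collapse onto their mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PosteriorMatrix, _as_probs

__all__ = [
    "variance_ratio",
    "info_score",
    "maf_difference",
    "ReferenceFrequencyTable",
]


def _dosage(posteriors) -> np.ndarray:
    probs = posteriors.probs if isinstance(posteriors, PosteriorMatrix) else _as_probs(posteriors)
    return probs[:, 1] + 2.0 * probs[:, 2]


def variance_ratio(posteriors: PosteriorMatrix | np.ndarray) -> float:
    """Observed dosage variance over the binomial expectation 2·p̂·(1−p̂).

    ``p̂`` is the allele-B frequency estimated from the mean dosage.  The
    numerator is the population variance of the per-individual expected
    dosage.  A ratio near 0 means the imputed dosages carry almost no
    information (every individual received nearly the same posterior);
    sample noise can push it slightly above 1.  NaN when ``p̂`` is 0 or 1.
    """
    e = _dosage(posteriors)
    if e.shape[0] < 2:
        raise ValueError("variance ratio requires at least 2 individuals")
    p_hat = e.mean() / 2.0
    if p_hat <= 0.0 or p_hat >= 1.0:
        return float("nan")
    return float(e.var() / (2.0 * p_hat * (1.0 - p_hat)))


def info_score(posteriors: PosteriorMatrix | np.ndarray) -> float:
    """IMPUTE-style information score.

    With per-individual ``e_k = p_AB + 2 p_BB`` (expected dosage) and
    ``f_k = p_AB + 4 p_BB`` (expected squared dosage), and the estimated
    allele frequency ``theta = sum(e_k) / 2N``::

        info = 1 - sum(f_k - e_k^2) / (2 N theta (1 - theta))

    ``f_k - e_k^2`` is the posterior dosage variance for individual ``k``,
    zero exactly when the genotype is certain, so the score is 1 for fully
    certain calls and decreases as genotype uncertainty grows.  It can go
    below 0 for very diffuse posteriors at low frequency; such values are
    reported as-is.  NaN when ``theta`` is 0 or 1.
    """
    probs = posteriors.probs if isinstance(posteriors, PosteriorMatrix) else _as_probs(posteriors)
    n = probs.shape[0]
    if n < 2:
        raise ValueError("info score requires at least 2 individuals")
    e = probs[:, 1] + 2.0 * probs[:, 2]
    f = probs[:, 1] + 4.0 * probs[:, 2]
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return float("nan")
    return float(1.0 - (f - e**2).sum() / (2.0 * n * theta * (1.0 - theta)))


def maf_difference(estimated: float, reference: float | None) -> float:
    """Absolute difference between estimated and reference minor allele frequency.

    NaN (metric missing; the SNP then fails any MAF-difference filter) when
    the reference entry is absent.
    """
    if reference is None or (isinstance(reference, float) and np.isnan(reference)):
        return float("nan")
    for name, v in (("estimated", estimated), ("reference", reference)):
        if not 0.0 <= v <= 0.5:
            raise ValueError(f"{name} MAF {v} outside [0, 0.5]")
    return float(abs(estimated - reference))


class ReferenceFrequencyTable:
    """SNP id -> reference minor allele frequency, loaded from a 2-column TSV."""

    def __init__(self, mapping: dict[str, float]):
        for snp, maf in mapping.items():
            if not 0.0 <= maf <= 0.5:
                raise ValueError(f"reference MAF for {snp} outside [0, 0.5]: {maf}")
        self._maf = dict(mapping)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceFrequencyTable":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if df.shape[1] < 2:
            raise ValueError("reference frequency table needs columns (snp_id, maf)")
        ids = df.iloc[:, 0]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique()
            raise ValueError(f"duplicate SNP ids in reference table: {list(dups)[:5]}")
        return cls(dict(zip(ids, df.iloc[:, 1].astype(float))))

    def get(self, snp_id: str) -> float | None:
        return self._maf.get(snp_id)

    def __len__(self) -> int:
        return len(self._maf)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._maf
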