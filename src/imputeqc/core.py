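"""Chance-corrected concordance metrics for imputed genotypes.

The central object is the 3x3 cross-classification of true versus imputed
genotype probability mass for a single biallelic SNP.  Because imputation
programs emit posterior probabilities rather than hard calls, the cells of
this table are nonnegative reals, not integers.  From the table we compute

* ``P_o`` — the observed proportion of agreement (diagonal mass / N),
* ``P_c`` — the agreement expected by chance given the marginals,
* ``IQS`` — the imputation quality score ``(P_o - P_c) / (1 - P_c)``,

the genotype analogue of Cohen's unweighted kappa.  IQS equals 1 only for a
perfect match, is 0 when imputation does no better than calling genotypes at
random with the same marginal rates, and is negative when it does worse.
Unlike raw concordance ("imputation accuracy"), IQS does not inflate as the
minor allele frequency approaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeVector",
    "PosteriorMatrix",
    "ConfusionTable",
    "SNPMetrics",
    "build_confusion",
    "confusion_batch",
    "cross_platform_confusion",
    "observed_agreement",
    "chance_agreement",
    "iqs",
    "iqs_from_tables",
    "accuracy",
    "efficiency",
    "estimated_maf",
    "compute_snp_metrics",
]

#: Sentinel for a missing hard call.
MISSING: int = -1

#: Denominator tolerance below which IQS is reported as undefined (NaN).
IQS_TOL: float = 1e-12

#: SNPs with fewer non-missing individuals than this are flagged low-confidence.
LOW_CONFIDENCE_N: int = 10

_ROW_SUM_TOL = 1e-6


def _as_calls(calls) -> np.ndarray:
    arr = np.asarray(calls)
    if arr.dtype.kind == "f":
        # allow float input with NaN for missing
        out = np.full(arr.shape, MISSING, dtype=np.int8)
        ok = ~np.isnan(arr)
        out[ok] = arr[ok].astype(np.int8)
        arr = out
    else:
        arr = arr.astype(np.int8, copy=False)
    if arr.ndim != 1:
        raise ValueError("genotype calls must be a 1-D sequence")
    bad = ~np.isin(arr, (MISSING, 0, 1, 2))
    if bad.any():
        raise ValueError(f"invalid genotype codes at positions {np.flatnonzero(bad)[:5]}")
    return arr


def _as_probs(probs, tol: float = _ROW_SUM_TOL) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("posterior probabilities must be an N x 3 array")
    if (arr < 0).any():
        raise ValueError("posterior probabilities must be nonnegative")
    sums = arr.sum(axis=1)
    if np.abs(sums - 1.0).max(initial=0.0) > tol:
        k = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"posterior row {k} sums to {sums[k]:.6g}, not 1")
    return arr


@dataclass(frozen=True)
class GenotypeVector:
    """Hard genotype calls for one SNP: 0=AA, 1=AB, 2=BB, -1=missing."""

    snp_id: str
    calls: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "calls", _as_calls(self.calls))

    def __len__(self) -> int:
        return self.calls.shape[0]

    @property
    def n_nonmissing(self) -> int:
        return int((self.calls != MISSING).sum())


@dataclass(frozen=True)
class PosteriorMatrix:
    """Per-individual genotype posterior probabilities, columns (AA, AB, BB)."""

    snp_id: str
    probs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "probs", _as_probs(self.probs))

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def dosage(self) -> np.ndarray:
        """Expected count of allele B per individual, p_AB + 2 p_BB."""
        return self.probs[:, 1] + 2.0 * self.probs[:, 2]


@dataclass(frozen=True)
class ConfusionTable:
    """3x3 true-vs-imputed probability-mass table for one SNP.

    ``n[i, j]`` holds the posterior mass assigned to imputed genotype ``j``
    summed over individuals whose true genotype is ``i`` (0=AA, 1=AB, 2=BB).
    Cells are nonnegative reals; the grand total equals the number of
    individuals that entered the tabulation.
    """

    n: np.ndarray
    snp_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.n, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError("confusion table must be 3x3")
        if (arr < 0).any():
            raise ValueError("confusion table cells must be nonnegative")
        object.__setattr__(self, "n", arr)

    @property
    def total(self) -> float:
        return float(self.n.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.n.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.n.sum(axis=0)


def _truth_onehot(truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mask of non-missing, one-hot (N, 3)) for a call vector."""
    ok = truth != MISSING
    onehot = np.zeros((truth.shape[0], 3))
    onehot[np.arange(truth.shape[0])[ok], truth[ok]] = 1.0
    return ok, onehot


def build_confusion(truth: GenotypeVector | np.ndarray,
                    posteriors: PosteriorMatrix | np.ndarray) -> ConfusionTable:
    """Tabulate true genotypes against imputed posterior mass.

    Individuals with a missing true genotype are excluded; the table total
    then equals the number of non-missing individuals.
    """
    snp_id = getattr(truth, "snp_id", "") or getattr(posteriors, "snp_id", "")
    calls = truth.calls if isinstance(truth, GenotypeVector) else _as_calls(truth)
    probs = posteriors.probs if isinstance(posteriors, PosteriorMatrix) else _as_probs(posteriors)
    if calls.shape[0] != probs.shape[0]:
        raise ValueError(
            f"length mismatch: {calls.shape[0]} truth calls vs {probs.shape[0]} posterior rows"
        )
    ok = calls != MISSING
    if not ok.any():
        raise ValueError("all true genotypes are missing; confusion table undefined")
    table = np.zeros((3, 3))
    np.add.at(table, calls[ok], probs[ok])
    return ConfusionTable(table, snp_id=snp_id)


def confusion_batch(truth: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Vectorised tabulation for many SNPs at once.

    Parameters
    ----------
    truth : (S, N) integer array of calls (no missing values)
    probs : (S, N, 3) posterior array

    Returns
    -------
    (S, 3, 3) array of confusion tables, rows = true genotype.
    """
    onehot = np.zeros(truth.shape + (3,))
    s, n = truth.shape
    onehot[np.arange(s)[:, None], np.arange(n)[None, :], truth] = 1.0
    return np.einsum("ski,skj->sij", onehot, probs)


def cross_platform_confusion(a: PosteriorMatrix | np.ndarray,
                             b: PosteriorMatrix | np.ndarray,
                             *,
                             disjoint: bool = False) -> ConfusionTable:
    """Cross-classify two posterior sets for the same SNP.

    When the same individuals were imputed from two platforms (the default),
    each individual contributes the outer product of their two probability
    triplets: ``n_ij = sum_k a_ik * b_jk``.  With ``disjoint=True`` the two
    cohorts share no individuals and only the marginal product
    ``N * mean(a)_i * mean(b)_j`` is available — a strictly weaker
    comparison, since per-individual agreement is unobservable.
    """
    snp_id = getattr(a, "snp_id", "") or getattr(b, "snp_id", "")
    pa = a.probs if isinstance(a, PosteriorMatrix) else _as_probs(a)
    pb = b.probs if isinstance(b, PosteriorMatrix) else _as_probs(b)
    if disjoint:
        n = 0.5 * (pa.shape[0] + pb.shape[0])
        table = n * np.outer(pa.mean(axis=0), pb.mean(axis=0))
        return ConfusionTable(table, snp_id=snp_id)
    if pa.shape[0] != pb.shape[0]:
        raise ValueError(
            f"length mismatch: {pa.shape[0]} vs {pb.shape[0]} individuals "
            "(use disjoint=True for non-overlapping cohorts)"
        )
    return ConfusionTable(np.einsum("ki,kj->ij", pa, pb), snp_id=snp_id)


def observed_agreement(t: ConfusionTable | np.ndarray) -> float:
    """Observed proportion of agreement P_o: diagonal mass over the total."""
    n = t.n if isinstance(t, ConfusionTable) else np.asarray(t, dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("empty confusion table: P_o undefined")
    return float(np.trace(n) / total)


def chance_agreement(t: ConfusionTable | np.ndarray) -> float:
    """Chance agreement P_c: sum of products of matching marginal frequencies."""
    n = t.n if isinstance(t, ConfusionTable) else np.asarray(t, dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("empty confusion table: P_c undefined")
    return float((n.sum(axis=1) / total) @ (n.sum(axis=0) / total))


def iqs(t: ConfusionTable | np.ndarray, tol: float = IQS_TOL) -> float:
    """Imputation quality score ``(P_o - P_c) / (1 - P_c)``.

    Returns NaN (undefined) when ``1 - P_c <= tol``, which happens when all
    marginal mass sits in a single genotype — e.g. a monomorphic SNP — so the
    score has a vanishing denominator.  Negative values mean imputation
    agreed with truth less often than random calling would.
    """
    po = observed_agreement(t)
    pc = chance_agreement(t)
    denom = 1.0 - pc
    if denom <= tol:
        return float("nan")
    return (po - pc) / denom


def iqs_from_tables(tables: np.ndarray, tol: float = IQS_TOL) -> np.ndarray:
    """Vectorised IQS over an (S, 3, 3) stack of confusion tables."""
    tables = np.asarray(tables, dtype=float)
    total = tables.sum(axis=(-2, -1))
    po = np.trace(tables, axis1=-2, axis2=-1) / total
    rows = tables.sum(axis=-1) / total[..., None]
    cols = tables.sum(axis=-2) / total[..., None]
    pc = (rows * cols).sum(axis=-1)
    denom = 1.0 - pc
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > tol, (po - pc) / denom, np.nan)
    return out


def accuracy(truth: GenotypeVector | np.ndarray,
             posteriors: PosteriorMatrix | np.ndarray) -> float:
    """Raw concordance: fraction of best-guess calls that equal the truth.

    The best guess is the maximum-posterior genotype, ties broken toward the
    lowest genotype index.  Individuals with missing truth are excluded.
    This is the conventional "imputation accuracy"; it is *not* chance
    corrected and approaches 1 for rare SNPs regardless of information.
    """
    calls = truth.calls if isinstance(truth, GenotypeVector) else _as_calls(truth)
    probs = posteriors.probs if isinstance(posteriors, PosteriorMatrix) else _as_probs(posteriors)
    if calls.shape[0] != probs.shape[0]:
        raise ValueError("length mismatch between truth and posteriors")
    ok = calls != MISSING
    if not ok.any():
        raise ValueError("all true genotypes are missing; accuracy undefined")
    best = np.argmax(probs[ok], axis=1)
    return float((best == calls[ok]).mean())


def efficiency(posteriors: PosteriorMatrix | np.ndarray, threshold: float = 0.9) -> float:
    """Fraction of individuals whose maximum posterior exceeds ``threshold``."""
    probs = posteriors.probs if isinstance(posteriors, PosteriorMatrix) else _as_probs(posteriors)
    return float((probs.max(axis=1) > threshold).mean())


def estimated_maf(posteriors: PosteriorMatrix | np.ndarray) -> float:
    """Minor allele frequency estimated from posterior mean dosage (folded)."""
    probs = posteriors.probs if isinstance(posteriors, PosteriorMatrix) else _as_probs(posteriors)
    if probs.shape[0] == 0:
        raise ValueError("no individuals")
    f_b = float((probs[:, 1] + 2.0 * probs[:, 2]).sum() / (2.0 * probs.shape[0]))
    return min(f_b, 1.0 - f_b)


@dataclass
class SNPMetrics:
    """Per-SNP quality record combining agreement and information statistics.

    Undefined values (e.g. IQS at a monomorphic SNP, or a missing reference
    frequency) are stored as NaN and serialised as "NA".
    """

    snp_id: str
    p_observed: float = np.nan
    p_chance: float = np.nan
    iqs: float = np.nan
    accuracy: float = np.nan
    efficiency: float = np.nan
    maf: float = np.nan
    n_effective: int = 0
    variance_ratio: float = np.nan
    info_score: float = np.nan
    maf_difference: float = np.nan
    low_confidence: bool = field(default=False)

    FIELDS = (
        "snp_id", "p_observed", "p_chance", "iqs", "accuracy", "efficiency",
        "maf", "n_effective", "variance_ratio", "info_score", "maf_difference",
    )


def compute_snp_metrics(truth: GenotypeVector,
                        posteriors: PosteriorMatrix,
                        reference_maf: float | None = None) -> SNPMetrics:
    """Compute the full per-SNP metric record against known truth."""
    from . import comparison  # local import to avoid a cycle

    table = build_confusion(truth, posteriors)
    n_eff = truth.n_nonmissing
    maf = estimated_maf(posteriors)
    rec = SNPMetrics(
        snp_id=truth.snp_id or posteriors.snp_id,
        p_observed=observed_agreement(table),
        p_chance=chance_agreement(table),
        iqs=iqs(table),
        accuracy=accuracy(truth, posteriors),
        efficiency=efficiency(posteriors),
        maf=maf,
        n_effective=n_eff,
        variance_ratio=comparison.variance_ratio(posteriors),
        info_score=comparison.info_score(posteriors),
        low_confidence=n_eff < LOW_CONFIDENCE_N,
    )
    if reference_maf is not None:
        rec.maf_difference = comparison.maf_difference(maf, reference_maf)
    return rec
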