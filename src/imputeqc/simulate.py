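"""Seeded synthetic cohorts with controllable imputation error.

The generator draws per-SNP minor allele frequencies, samples Hardy-Weinberg
genotypes, and then corrupts them with one of three error models:

``soft_blend``
    Each posterior row is ``(1-eps) * onehot(truth) + eps * pi`` where ``pi``
    is the realized genotype distribution of the cohort.  This makes IQS
    equal ``1 - eps`` exactly (an algebraic identity) while raw accuracy
    still depends on allele frequency — the cleanest way to separate the two
    statistics.

``random_hardcall``
    With probability ``1-eps`` the true genotype is kept as a certain call;
    otherwise a genotype is drawn at random from ``pi``.  A stochastic
    version of the same error rate, used for sampling-noise studies.

``major_bias``
    ``(1-beta) * onehot(truth) + beta * onehot(major homozygote)``.  This
    mimics the systematic failure mode of cross-platform imputation, where
    hard-to-impute SNPs are dragged toward the major genotype of the
    reference panel.  Applied to cases but not controls it manufactures
    spurious case/control dosage differences — the mechanism behind
    imputation-driven false positives.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` children, so every operation is a pure
function of its config.  No linkage disequilibrium is simulated: every
statistic under study is per-SNP, so independent SNPs suffice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association
from .association import FilterRule, trend_chi2_batch
from .core import GenotypeVector, PosteriorMatrix, confusion_batch, iqs_from_tables

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_truth",
    "emulate_imputation",
    "SplitExperimentReport",
    "run_split_experiment",
    "SplitHalfReport",
    "run_split_half_robustness",
]

_ERROR_MODELS = ("soft_blend", "random_hardcall", "major_bias")
_CHUNK = 1024  # SNPs per processing block; fixed so chunked runs are reproducible


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic cohort and its imputation-error model.

    Parameters
    ----------
    n_individuals, n_snps : cohort dimensions (n_individuals >= 2)
    seed : master seed; mandatory, every random draw derives from it
    maf_range : (low, high) for the per-SNP uniform MAF sampler
    maf_values : explicit per-SNP minor allele frequencies (cycled to
        n_snps); overrides ``maf_range`` when given
    error_model : one of soft_blend | random_hardcall | major_bias
    epsilon : per-SNP error weight for the blend/hardcall models — a float
        for a shared value or a (low, high) tuple for a per-SNP uniform draw
    beta : probability mass moved to the major homozygote under major_bias
    bias_fraction : fraction of SNPs that receive major_bias in the
        split experiment (the rest get soft_blend with ``epsilon``)
    """

    n_individuals: int
    n_snps: int
    seed: int
    maf_range: tuple[float, float] = (0.01, 0.5)
    maf_values: tuple[float, ...] | None = None
    error_model: str = "soft_blend"
    epsilon: float | tuple[float, float] = 0.02
    beta: float = 0.6
    bias_fraction: float = 0.0

    def __post_init__(self):
        if self.n_individuals < 2 or self.n_snps < 1:
            raise ValueError("need n_individuals >= 2 and n_snps >= 1")
        if self.error_model not in _ERROR_MODELS:
            raise ValueError(f"unknown error model {self.error_model!r}")
        if not 0.0 <= self.bias_fraction <= 1.0:
            raise ValueError("bias_fraction must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        eps = self.epsilon
        vals = eps if isinstance(eps, tuple) else (eps,)
        if any(not 0.0 <= e <= 1.0 for e in vals):
            raise ValueError("epsilon values must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= low <= high <= 0.5")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("maf", "truth", "epsilon", "imputation", "imputation2", "split", "bias")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {k: np.random.default_rng(c) for k, c in zip(names, children)}


@dataclass(frozen=True)
class TruthSet:
    """Simulated true genotypes: (n_snps, n_individuals) calls plus true MAFs."""

    genotypes: np.ndarray
    mafs: np.ndarray
    snp_ids: tuple[str, ...]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def genotype_vectors(self):
        """Yield one :class:`~imputeqc.core.GenotypeVector` per SNP."""
        for sid, row in zip(self.snp_ids, self.genotypes):
            yield GenotypeVector(sid, row)


def _draw_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.maf_values is not None:
        reps = -(-config.n_snps // len(config.maf_values))
        return np.tile(np.asarray(config.maf_values, dtype=float), reps)[: config.n_snps]
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def simulate_truth(config: SimConfig) -> TruthSet:
    """Sample HWE genotypes: per SNP, calls ~ Binomial(2, maf) counts of allele B."""
    streams = _streams(config.seed)
    mafs = _draw_mafs(config, streams["maf"])
    geno = streams["truth"].binomial(2, mafs[:, None],
                                     size=(config.n_snps, config.n_individuals)).astype(np.int8)
    ids = tuple(f"snp{k:06d}" for k in range(config.n_snps))
    return TruthSet(geno, mafs, ids)


def _draw_epsilons(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if isinstance(config.epsilon, tuple):
        lo, hi = config.epsilon
        return rng.uniform(lo, hi, size=n)
    return np.full(n, float(config.epsilon))


def _onehot(geno: np.ndarray) -> np.ndarray:
    s, n = geno.shape
    out = np.zeros((s, n, 3))
    out[np.arange(s)[:, None], np.arange(n)[None, :], geno] = 1.0
    return out


def _realized_pi(geno: np.ndarray) -> np.ndarray:
    """Per-SNP realized genotype distribution, shape (S, 3)."""
    s, n = geno.shape
    counts = np.stack([(geno == g).sum(axis=1) for g in range(3)], axis=1)
    return counts / n


def _corrupt(geno: np.ndarray, model: str, weight: np.ndarray,
             rng: np.random.Generator | None) -> np.ndarray:
    """Apply one error model to a (S, N) truth block; weight is eps or beta per SNP."""
    pi = _realized_pi(geno)
    if model == "soft_blend":
        return ((1.0 - weight)[:, None, None] * _onehot(geno)
                + weight[:, None, None] * pi[:, None, :])
    if model == "major_bias":
        major = np.where(pi[:, 2] + 0.5 * pi[:, 1] <= 0.5, 0, 2)
        target = np.zeros((geno.shape[0], 3))
        target[np.arange(geno.shape[0]), major] = 1.0
        return ((1.0 - weight)[:, None, None] * _onehot(geno)
                + weight[:, None, None] * target[:, None, :])
    # random_hardcall
    if rng is None:
        raise ValueError("random_hardcall requires a random generator")
    s, n = geno.shape
    err = rng.random((s, n)) < weight[:, None]
    cum = np.cumsum(pi, axis=1)
    repl = (rng.random((s, n))[:, :, None] >= cum[:, None, :2]).sum(axis=2).astype(np.int8)
    return _onehot(np.where(err, repl, geno))


def emulate_imputation(truth: TruthSet | np.ndarray, config: SimConfig) -> np.ndarray:
    """Produce posterior probabilities (S, N, 3) from truth under the config's model.

    The blend target ``pi`` is the realized genotype distribution of the
    truth block handed in, so downstream identities (IQS = 1 - eps under
    soft_blend) hold exactly for that block.
    """
    geno = truth.genotypes if isinstance(truth, TruthSet) else np.asarray(truth)
    streams = _streams(config.seed)
    weight = (_draw_epsilons(config, streams["epsilon"], geno.shape[0])
              if config.error_model != "major_bias"
              else np.full(geno.shape[0], config.beta))
    return _corrupt(geno, config.error_model, weight, streams["imputation"])


def posterior_matrices(truth: TruthSet, probs: np.ndarray):
    """Yield one :class:`~imputeqc.core.PosteriorMatrix` per SNP."""
    for sid, block in zip(truth.snp_ids, probs):
        yield PosteriorMatrix(sid, block)


# ---------------------------------------------------------------------------
# Experiment protocols
# ---------------------------------------------------------------------------

DEFAULT_FILTERS: tuple[FilterRule, ...] = (
    FilterRule("iqs", ">", 0.9),
    FilterRule("accuracy", ">", 0.99),
    FilterRule("info_score", ">", 0.5),
    FilterRule("variance_ratio", ">", 0.3),
)


@dataclass(frozen=True)
class FilterOutcome:
    rule: str
    n_retained: int
    retention: float
    hits: int
    genomic_lambda: float


@dataclass
class SplitExperimentReport:
    """Outcome of the null cross-platform case/control experiment."""

    metrics: pd.DataFrame
    association: pd.DataFrame
    n_cases: int
    n_controls: int
    n_biased_snps: int
    hits_unfiltered: int
    lambda_unfiltered: float
    filters: dict[str, FilterOutcome] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"filter": "none", "n_retained": len(self.metrics), "retention": 1.0,
                 "hits": self.hits_unfiltered, "genomic_lambda": self.lambda_unfiltered}]
        rows += [{"filter": f.rule, "n_retained": f.n_retained, "retention": f.retention,
                  "hits": f.hits, "genomic_lambda": f.genomic_lambda}
                 for f in self.filters.values()]
        return pd.DataFrame(rows)


def _batch_variance_ratio(probs: np.ndarray) -> np.ndarray:
    e = probs[..., 1] + 2.0 * probs[..., 2]
    p_hat = e.mean(axis=1) / 2.0
    denom = 2.0 * p_hat * (1.0 - p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, e.var(axis=1) / denom, np.nan)


def _batch_info_score(probs: np.ndarray) -> np.ndarray:
    n = probs.shape[1]
    e = probs[..., 1] + 2.0 * probs[..., 2]
    f = probs[..., 1] + 4.0 * probs[..., 2]
    theta = e.sum(axis=1) / (2.0 * n)
    denom = 2.0 * n * theta * (1.0 - theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, 1.0 - (f - e**2).sum(axis=1) / denom, np.nan)


def run_split_experiment(config: SimConfig,
                         fraction_biased_snps: float | None = None,
                         alpha: float = association.GENOME_WIDE_ALPHA,
                         filters: tuple[FilterRule, ...] = DEFAULT_FILTERS,
                         ) -> SplitExperimentReport:
    """Null case/control split with differential imputation error in cases.

    The cohort is halved at random.  Controls keep their true genotypes as
    certain posteriors (they were "genotyped on the denser array"); cases
    are imputed — a random ``fraction_biased_snps`` of SNPs with the
    ``major_bias`` model at ``config.beta`` and the rest with ``soft_blend``
    at ``config.epsilon``.  Because case/control status is random, every
    genome-wide significant SNP is an imputation-driven false positive.
    Per-SNP quality metrics are computed on the imputed (case) half against
    known truth, and each filter rule is scored by the hits and genomic
    lambda among the SNPs it retains.
    """
    if fraction_biased_snps is None:
        fraction_biased_snps = config.bias_fraction
    if not 0.0 <= fraction_biased_snps <= 1.0:
        raise ValueError("fraction_biased_snps must lie in [0, 1]")
    if config.n_individuals < 4:
        raise ValueError("split experiment needs at least 4 individuals")

    streams = _streams(config.seed)
    mafs = _draw_mafs(config, streams["maf"])
    geno = streams["truth"].binomial(2, mafs[:, None],
                                     size=(config.n_snps, config.n_individuals)).astype(np.int8)

    perm = streams["split"].permutation(config.n_individuals)
    n_cases = config.n_individuals // 2
    case_idx, control_idx = perm[:n_cases], perm[n_cases:]
    y = np.zeros(config.n_individuals, dtype=np.int8)
    y[:n_cases] = 1  # dosage blocks are assembled in (cases, controls) order

    n_biased = int(round(fraction_biased_snps * config.n_snps))
    biased = np.zeros(config.n_snps, dtype=bool)
    if n_biased:
        biased[streams["bias"].choice(config.n_snps, size=n_biased, replace=False)] = True
    eps = _draw_epsilons(config, streams["epsilon"], config.n_snps)

    rng_imp = streams["imputation"]
    cols = {k: np.empty(config.n_snps) for k in
            ("p_observed", "p_chance", "iqs", "accuracy", "efficiency", "maf",
             "variance_ratio", "info_score", "statistic")}
    for start in range(0, config.n_snps, _CHUNK):
        sl = slice(start, min(start + _CHUNK, config.n_snps))
        truth_cases = geno[sl][:, case_idx]
        truth_controls = geno[sl][:, control_idx]
        weight = np.where(biased[sl], config.beta, eps[sl])
        model_mask = biased[sl]
        probs = _corrupt(truth_cases, "soft_blend", np.where(model_mask, 0.0, weight), rng_imp)
        if model_mask.any():
            probs_b = _corrupt(truth_cases[model_mask], "major_bias",
                               np.full(model_mask.sum(), config.beta), None)
            probs[model_mask] = probs_b

        tables = confusion_batch(truth_cases, probs)
        total = tables.sum(axis=(1, 2))
        po = np.trace(tables, axis1=1, axis2=2) / total
        rowm = tables.sum(axis=2) / total[:, None]
        colm = tables.sum(axis=1) / total[:, None]
        pc = (rowm * colm).sum(axis=1)
        cols["p_observed"][sl] = po
        cols["p_chance"][sl] = pc
        cols["iqs"][sl] = iqs_from_tables(tables)
        cols["accuracy"][sl] = (np.argmax(probs, axis=2) == truth_cases).mean(axis=1)
        cols["efficiency"][sl] = (probs.max(axis=2) > 0.9).mean(axis=1)
        cols["variance_ratio"][sl] = _batch_variance_ratio(probs)
        cols["info_score"][sl] = _batch_info_score(probs)

        d_cases = probs[..., 1] + 2.0 * probs[..., 2]
        d_controls = truth_controls.astype(float)
        dosage = np.concatenate([d_cases, d_controls], axis=1)
        f_b = dosage.sum(axis=1) / (2.0 * dosage.shape[1])
        cols["maf"][sl] = np.minimum(f_b, 1.0 - f_b)
        cols["statistic"][sl] = trend_chi2_batch(dosage, y)

    from scipy import stats as _st

    snp_ids = [f"snp{k:06d}" for k in range(config.n_snps)]
    statistic = cols.pop("statistic")
    p_values = _st.chi2.sf(statistic, df=1)
    metrics = pd.DataFrame({"snp_id": snp_ids, **cols,
                            "true_maf": mafs, "biased": biased})
    assoc = pd.DataFrame({"snp_id": snp_ids, "statistic": statistic,
                          "p_value": p_values})

    report = SplitExperimentReport(
        metrics=metrics,
        association=assoc,
        n_cases=n_cases,
        n_controls=config.n_individuals - n_cases,
        n_biased_snps=n_biased,
        hits_unfiltered=association.count_genomewide_hits(assoc, alpha),
        lambda_unfiltered=association.genomic_lambda(assoc),
    )
    for rule in filters:
        mask = rule.mask(metrics)
        sub = assoc.loc[mask]
        report.filters[str(rule)] = FilterOutcome(
            rule=str(rule),
            n_retained=int(mask.sum()),
            retention=float(mask.mean()),
            hits=association.count_genomewide_hits(sub, alpha),
            genomic_lambda=(association.genomic_lambda(sub)
                            if mask.sum() else float("nan")),
        )
    return report


@dataclass(frozen=True)
class SplitHalfReport:
    """Per-SNP IQS agreement between two independently imputed cohort halves."""

    correlation: float
    iqs_first: np.ndarray
    iqs_second: np.ndarray
    included: np.ndarray
    epsilons: np.ndarray

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


def run_split_half_robustness(config: SimConfig,
                              maf_floor: float = 0.01) -> SplitHalfReport:
    """Split the cohort in half, impute each half independently, correlate IQS.

    The same per-SNP error level is applied in both halves but with
    independent noise, so a high correlation means IQS is a stable property
    of the SNP rather than of the particular sample.  SNPs with true MAF at
    or below ``maf_floor``, or with undefined IQS in either half, are
    excluded: near-monomorphic SNPs make the score's denominator ``1 - P_c``
    vanish and its value unstable.
    """
    if config.n_individuals < 200:
        raise ValueError("split-half robustness needs at least 200 individuals")
    streams = _streams(config.seed)
    mafs = _draw_mafs(config, streams["maf"])
    geno = streams["truth"].binomial(2, mafs[:, None],
                                     size=(config.n_snps, config.n_individuals)).astype(np.int8)
    perm = streams["split"].permutation(config.n_individuals)
    half = config.n_individuals // 2
    idx_a, idx_b = perm[:half], perm[half : 2 * half]
    eps = _draw_epsilons(config, streams["epsilon"], config.n_snps)

    iqs_halves = []
    for idx, rng in ((idx_a, streams["imputation"]), (idx_b, streams["imputation2"])):
        vals = np.empty(config.n_snps)
        for start in range(0, config.n_snps, _CHUNK):
            sl = slice(start, min(start + _CHUNK, config.n_snps))
            truth = geno[sl][:, idx]
            probs = _corrupt(truth, config.error_model, eps[sl], rng)
            vals[sl] = iqs_from_tables(confusion_batch(truth, probs))
        iqs_halves.append(vals)

    iqs_a, iqs_b = iqs_halves
    included = (mafs > maf_floor) & ~np.isnan(iqs_a) & ~np.isnan(iqs_b)
    if included.sum() < 2:
        raise ValueError("fewer than 2 SNPs with defined IQS in both halves")
    corr = float(np.corrcoef(iqs_a[included], iqs_b[included])[0, 1])
    return SplitHalfReport(corr, iqs_a, iqs_b, included, eps)
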