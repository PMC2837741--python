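"""Readers and writers for genotype-probability formats and metric tables.

Supported formats:

* Oxford GEN/SAMPLE — the native text output of IMPUTE-family programs.
  Five leading columns (snp_id, rsid, position, alleleA, alleleB) followed
  by one (AA, AB, BB) probability triplet per individual, probabilities
  relative to alleleA.
* VCF with GP (genotype probabilities, REF/REF first) and/or GT fields,
  read through cyvcf2.  Biallelic SNPs only; multi-allelic records are
  skipped with a warning.
* Per-SNP metrics and the IQS-database interchange format, both plain TSV
  with "NA" for undefined values.

Gzip-compressed inputs are handled transparently (``.gz`` suffix).
Coordinates are 1-based throughout, as in GEN and VCF.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeVector, PosteriorMatrix, SNPMetrics

__all__ = [
    "VariantRecord",
    "IQSDatabaseRecord",
    "HarmonizationError",
    "read_gen",
    "write_gen",
    "read_sample",
    "write_sample",
    "read_vcf_gp",
    "harmonize_alleles",
    "metrics_frame",
    "write_metrics",
    "read_metrics",
    "write_iqs_database",
    "read_iqs_database",
]

#: Row sums within this distance of 1 are silently renormalised; anything
#: further off marks the record as flagged.
ROW_SUM_SLACK = 1e-3

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantRecord:
    """Identity and allele coding of one biallelic variant (1-based position)."""

    snp_id: str
    position: int
    allele_a: str
    allele_b: str
    chromosome: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if not self.allele_a or not self.allele_b or self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must be non-empty and distinct")

    @property
    def is_strand_ambiguous(self) -> bool:
        """True for A/T and C/G SNPs, whose strand cannot be resolved from alleles."""
        pair = {self.allele_a.upper(), self.allele_b.upper()}
        return pair == {"A", "T"} or pair == {"C", "G"}


class HarmonizationError(ValueError):
    """Raised when two variant records cannot be brought to one allele coding."""

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Oxford GEN / SAMPLE
# ---------------------------------------------------------------------------

def read_sample(path) -> list[str]:
    """Individual ids from an Oxford SAMPLE file (two header lines)."""
    with _open_text(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: SAMPLE file needs two header lines")
    return [row[0] for row in lines[2:]]


def write_sample(path, sample_ids: list[str]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for sid in sample_ids:
            fh.write(f"{sid} {sid} 0\n")


def read_gen(path, sample_path=None):
    """Parse an Oxford GEN file into variant records and posterior matrices.

    Returns ``(variants, posteriors, flagged)`` where ``flagged`` lists the
    snp_ids whose probability rows were too far from summing to one to be
    renormalised.  Rows within ``ROW_SUM_SLACK`` of 1 are renormalised with
    a logged warning.  When ``sample_path`` is given the triplet count of
    every line is checked against the SAMPLE file.
    """
    n_expected = len(read_sample(sample_path)) if sample_path is not None else None
    variants: list[VariantRecord] = []
    posteriors: list[PosteriorMatrix] = []
    flagged: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 8 or (len(fields) - 5) % 3:
                raise ValueError(f"{path}:{lineno}: truncated GEN line "
                                 f"({len(fields)} fields)")
            snp_id, rsid, pos, a, b = fields[:5]
            try:
                probs = np.asarray(fields[5:], dtype=float).reshape(-1, 3)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed probability "
                                 f"value ({exc})") from None
            if n_expected is not None and probs.shape[0] != n_expected:
                raise ValueError(
                    f"{path}:{lineno}: {probs.shape[0]} probability triplets "
                    f"but SAMPLE file lists {n_expected} individuals")
            sums = probs.sum(axis=1)
            if (sums <= 0).any():
                raise ValueError(f"{path}:{lineno}: probability row sums to 0")
            off = np.abs(sums - 1.0)
            if (off > ROW_SUM_SLACK).any():
                # normalised so downstream code can still use the record,
                # but reported so callers can exclude it
                flagged.append(snp_id or rsid)
            elif (off > 1e-9).any():
                warnings.warn(f"{snp_id}: renormalised probability rows "
                              f"(max deviation {off.max():.2g})", stacklevel=2)
            probs = probs / sums[:, None]
            name = snp_id or rsid
            variants.append(VariantRecord(name, int(pos), a, b))
            posteriors.append(PosteriorMatrix(name, probs))
    return variants, posteriors, flagged


def write_gen(path, variants: list[VariantRecord],
              posteriors: list[PosteriorMatrix], precision: int = 6) -> None:
    """Write variants/posteriors as Oxford GEN text (gzip if path ends .gz)."""
    if len(variants) != len(posteriors):
        raise ValueError("variant and posterior lists differ in length")
    fmt = f"{{:.{precision}g}}"
    with _open_text(path, "wt") as fh:
        for var, post in zip(variants, posteriors):
            head = f"{var.snp_id} {var.snp_id} {var.position} {var.allele_a} {var.allele_b}"
            body = " ".join(fmt.format(v) for v in post.probs.ravel())
            fh.write(f"{head} {body}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_gp(path):
    """Read genotype probabilities (GP) and/or hard calls (GT) from a VCF.

    GP triplets are mapped to (AA, AB, BB) with allele A = REF.  Records
    lacking GP but carrying GT are converted to one-hot rows and flagged as
    fallbacks; multi-allelic records are skipped with a warning.

    Returns ``(variants, posteriors, hard_calls, gt_fallback_ids)`` where
    ``hard_calls`` maps snp_id to a :class:`GenotypeVector` for records with
    GT present.
    """
    from cyvcf2 import VCF

    variants: list[VariantRecord] = []
    posteriors: list[PosteriorMatrix] = []
    hard_calls: dict[str, GenotypeVector] = {}
    fallback: list[str] = []
    n_skipped = 0
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                n_skipped += 1
                continue
            snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
            var = VariantRecord(snp_id, rec.POS, rec.REF, rec.ALT[0],
                                chromosome=rec.CHROM)
            gts = None
            if rec.gt_types is not None:
                # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
                gts = np.select([rec.gt_types == 0, rec.gt_types == 1,
                                 rec.gt_types == 3],
                                [0, 1, 2], default=MISSING).astype(np.int8)
                hard_calls[snp_id] = GenotypeVector(snp_id, gts)
            gp = rec.format("GP")
            if gp is not None:
                probs = np.asarray(gp, dtype=float)
                probs = probs / probs.sum(axis=1, keepdims=True)
            elif gts is not None:
                probs = np.zeros((gts.shape[0], 3))
                ok = gts != MISSING
                probs[np.flatnonzero(ok), gts[ok]] = 1.0
                probs[~ok] = 1.0 / 3.0  # uninformative row for missing calls
                fallback.append(snp_id)
            else:
                n_skipped += 1
                continue
            variants.append(var)
            posteriors.append(PosteriorMatrix(snp_id, probs))
    finally:
        vcf.close()
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} record(s) without usable "
                      "biallelic GP/GT", stacklevel=2)
    return variants, posteriors, hard_calls, fallback


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def _complement(allele: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        return allele.upper()


def harmonize_alleles(a: VariantRecord, b: VariantRecord,
                      probs_b: PosteriorMatrix,
                      allow_ambiguous: bool = False):
    """Re-express ``probs_b`` in the allele coding of record ``a``.

    Handles allele swaps (triplet reversed) and strand flips (alleles
    complemented, then compared).  A/T and C/G SNPs are strand-ambiguous —
    a flip is indistinguishable from a swap — and are excluded by default.

    Returns ``(aligned PosteriorMatrix, action)`` with action one of
    ``identical``, ``swap``, ``strand_flip``, ``strand_flip_swap``.
    Raises :class:`HarmonizationError` for ambiguous or incompatible pairs.
    """
    if a.snp_id != b.snp_id and (a.position != b.position):
        raise HarmonizationError(
            f"records {a.snp_id} and {b.snp_id} are different variants",
            reason="identity-mismatch")
    if (a.is_strand_ambiguous or b.is_strand_ambiguous) and not allow_ambiguous:
        raise HarmonizationError(
            f"{a.snp_id}: strand-ambiguous alleles "
            f"({a.allele_a}/{a.allele_b}); excluded",
            reason="strand-ambiguous")
    aa, ab = a.allele_a.upper(), a.allele_b.upper()
    ba, bb = b.allele_a.upper(), b.allele_b.upper()
    if (ba, bb) == (aa, ab):
        action = "identical"
    elif (ba, bb) == (ab, aa):
        action = "swap"
    elif (_complement(ba), _complement(bb)) == (aa, ab):
        action = "strand_flip"
    elif (_complement(ba), _complement(bb)) == (ab, aa):
        action = "strand_flip_swap"
    else:
        raise HarmonizationError(
            f"{a.snp_id}: allele sets {aa}/{ab} vs {ba}/{bb} are incompatible",
            reason="incompatible-alleles")
    probs = probs_b.probs[:, ::-1] if action.endswith("swap") else probs_b.probs
    return PosteriorMatrix(probs_b.snp_id, probs.copy()), action


# ---------------------------------------------------------------------------
# Metrics and IQS-database tables
# ---------------------------------------------------------------------------

def metrics_frame(metrics: list[SNPMetrics]) -> pd.DataFrame:
    """Stack per-SNP metric records into a DataFrame (column order fixed)."""
    return pd.DataFrame([{f: getattr(m, f) for f in SNPMetrics.FIELDS}
                         for m in metrics])


def _check_unique(ids: pd.Series, path, what: str) -> None:
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate {what}: {dups[:10]}")


def write_metrics(metrics, path) -> None:
    """Write a per-SNP metrics table as TSV (undefined values as "NA")."""
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"snp_id": str})
    _check_unique(df["snp_id"], path, "snp_id")
    return df


@dataclass(frozen=True)
class IQSDatabaseRecord:
    """One row of the shared IQS look-up database.

    Records the quality score observed for a SNP when imputing between a
    specific pair of platforms in a specific population, so that future
    studies combining those platforms can filter the SNP without
    re-genotyping.  ``iqs`` may be NaN (undefined, serialised as "NA").
    """

    snp_id: str
    source_platform: str
    target_platform: str
    population: str
    iqs: float
    maf: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"{self.snp_id}: n must be >= 1")
        if not math.isnan(self.iqs) and self.iqs > 1.0:
            raise ValueError(f"{self.snp_id}: iqs {self.iqs} exceeds 1")


_DB_COLUMNS = ("snp_id", "source_platform", "target_platform", "population",
               "iqs", "maf", "n")


def write_iqs_database(records, path) -> None:
    """Write IQS-database rows as a 7-column TSV."""
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, list(_DB_COLUMNS)]
    else:
        df = pd.DataFrame([{c: getattr(r, c) for c in _DB_COLUMNS} for r in records])
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_iqs_database(path) -> list[IQSDatabaseRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     dtype={"snp_id": str, "source_platform": str,
                            "target_platform": str, "population": str})
    missing = set(_DB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    _check_unique(df["snp_id"], path, "snp_id")
    return [IQSDatabaseRecord(row.snp_id, row.source_platform,
                              row.target_platform, row.population,
                              float(row.iqs) if pd.notna(row.iqs) else float("nan"),
                              float(row.maf), int(row.n))
            for row in df.itertuples(index=False)]
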