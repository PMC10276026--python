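"""Genotype matrices: reading, quality control, allele frequencies, imputation.

Dosages count copies of one of the two alleles of a biallelic SNP, so every
call is 0, 1 or 2; missing calls are held as NaN.  The CSV dialect is
individuals as rows and markers as columns, with a header row of marker ids,
the individual id in the first column, and missing cells written ``NA``.
Which allele the dosage counts only flips the sign of the centered codings
downstream; the relationship matrices are invariant to the choice.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ALLOWED = frozenset((0.0, 1.0, 2.0))


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage table with optional missingness.

    Parameters
    ----------
    individual_ids, marker_ids : array-like of str
        Unique ordered labels for rows and columns.
    dosages : ndarray of float, shape (n_individuals, n_markers)
        Entries in {0, 1, 2} with NaN for missing calls.  After mean
        imputation (``imputed=True``) entries may be fractional in [0, 2].
    """

    individual_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    imputed: bool = False

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n != self.individual_ids.size or m != self.marker_ids.size:
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{self.individual_ids.size} individuals x {self.marker_ids.size} markers"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids are not unique")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0.0 or vals.max() > 2.0):
            raise ValueError("dosages must lie in [0, 2]")
        if not self.imputed and vals.size and not set(np.unique(vals)) <= _ALLOWED:
            raise ValueError("non-imputed dosages must be in {0, 1, 2, NA}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.individual_ids, columns=self.marker_ids
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.individual_ids,
            self.marker_ids[keep],
            self.dosages[:, keep],
            imputed=self.imputed,
        )


@dataclass
class QCReport:
    """Per-marker quality-control summary.

    ``percent_reduction`` is 100 * (1 - n_markers_out / n_markers_in), the
    shrinkage of the panel caused by the call-rate and MAF filters.
    """

    n_markers_in: int
    n_markers_out: int
    call_rate_min: float
    maf_min: float
    marker_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    call_rate: np.ndarray = field(default_factory=lambda: np.array([]))
    maf: np.ndarray = field(default_factory=lambda: np.array([]))
    kept: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def percent_reduction(self) -> float:
        if self.n_markers_in == 0:
            return 0.0
        return 100.0 * (1.0 - self.n_markers_out / self.n_markers_in)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "call_rate": self.call_rate,
                "maf": self.maf,
                "kept": self.kept,
            }
        )

    def summary(self) -> str:
        return (
            f"QC call_rate>={self.call_rate_min} maf>={self.maf_min}: "
            f"{self.n_markers_in} -> {self.n_markers_out} markers "
            f"({self.percent_reduction:.2f}% reduction)"
        )


def read_genotypes(path: str | Path, dialect: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from ``csv`` (matrix dialect) or ``vcf``.

    VCF genotype calls are mapped to ALT-allele dosage; multiallelic or
    non-SNP records are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        gm = GenotypeMatrix(
            df.index.astype(str).to_numpy(object),
            df.columns.astype(str).to_numpy(object),
            df.to_numpy(dtype=float),
        )
    elif dialect == "vcf":
        gm = _read_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if gm.n_markers == 0:
        raise ValueError(f"no markers retained from {path}")
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # lazy: only needed for the VCF dialect

    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples, dtype=object)
    cols, ids, skipped = [], [], 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        dos = v.gt_types.astype(float)
        dos[dos == 3] = np.nan
        cols.append(dos)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    vcf.close()
    if skipped:
        logger.info("read_genotypes: skipped %d non-biallelic/non-SNP records", skipped)
    dosages = np.column_stack(cols) if cols else np.empty((samples.size, 0))
    return GenotypeMatrix(samples, np.asarray(ids, dtype=object), dosages)


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the CSV matrix dialect (missing encoded ``NA``)."""
    df = genotypes.to_dataframe()
    if not genotypes.imputed:
        # keep integer look for clean round-trips
        df = df.astype("Int64")
    df.to_csv(path, na_rep="NA")


def allele_frequency(genotypes: GenotypeMatrix) -> np.ndarray:
    """Frequency of the dosage-counted allele per marker, ignoring missing.

    p_j = (sum of dosages at marker j) / (2 x number of non-missing calls).
    All-missing markers get NaN (flagged; they are removed by QC).
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(genotypes.dosages, axis=0) / 2.0
    n_undef = int(np.isnan(p).sum())
    if n_undef:
        logger.warning("allele_frequency: %d markers have no non-missing calls", n_undef)
    return p


def qc_filter(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep markers with call rate >= ``call_rate_min`` and MAF >= ``maf_min``.

    Both comparisons are inclusive.  MAF is min(p, 1-p) computed on
    non-missing calls; markers with undefined frequency are removed.
    """
    for name, t in (("call_rate_min", call_rate_min), ("maf_min", maf_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    call_rate = 1.0 - np.isnan(genotypes.dosages).mean(axis=0)
    p = allele_frequency(genotypes)
    maf = np.minimum(p, 1.0 - p)
    kept = (call_rate >= call_rate_min) & ~np.isnan(maf) & (maf >= maf_min)
    out = genotypes.subset_markers(kept)
    report = QCReport(
        n_markers_in=genotypes.n_markers,
        n_markers_out=out.n_markers,
        call_rate_min=call_rate_min,
        maf_min=maf_min,
        marker_ids=genotypes.marker_ids,
        call_rate=call_rate,
        maf=maf,
        kept=kept,
    )
    logger.info(report.summary())
    if out.n_markers == 0:
        logger.warning("qc_filter: no markers passed quality control")
    return out, report


def impute_missing(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> GenotypeMatrix:
    """Replace missing dosages by the marker mean 2 p_j.

    Mean imputation keeps the centered marker matrix W at exactly zero
    column means when the frequencies come from the same panel.
    """
    if freqs is None:
        freqs = allele_frequency(genotypes)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (genotypes.n_markers,):
        raise ValueError("frequency vector does not match the marker dimension")
    missing = np.isnan(genotypes.dosages)
    bad = missing.any(axis=0) & np.isnan(freqs)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} markers have missing calls but undefined frequency; "
            "run qc_filter first"
        )
    dosages = genotypes.dosages.copy()
    fill = np.broadcast_to(2.0 * freqs, dosages.shape)
    dosages[missing] = fill[missing]
    return GenotypeMatrix(
        genotypes.individual_ids, genotypes.marker_ids, dosages, imputed=True
    )
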