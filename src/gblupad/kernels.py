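"""Genomic relationship matrices for additive and dominance effects.

The additive kernel follows VanRaden's construction

    G = W W' / sum_j 2 p_j (1 - p_j),

where W is the column-centered dosage matrix (dosage minus 2 p_j).  The
dominance kernel follows Vitezica's genotype-class coding

    S_ij = -2 p_j^2          for the homozygote with dosage 0,
            2 p_j (1 - p_j)  for the heterozygote,
           -2 (1 - p_j)^2    for the homozygote with dosage 2,
    D = S S' / (4 sum_j (p_j (1 - p_j))^2).

Both kernels are invariant to which allele the dosage counts, and both have
expected diagonal 1 under Hardy-Weinberg proportions when the frequencies
are estimated from the same panel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, allele_frequency

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass
class RelationshipMatrix:
    """Symmetric n x n kinship kernel with individual labels.

    ``kind`` is one of ``identity`` (no-pedigree BLUP), ``additive`` or
    ``dominance``.
    """

    individual_ids: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = self.individual_ids.size
        if self.values.shape != (n, n):
            raise ValueError("kernel must be square and match the id labels")
        if not np.isfinite(self.values).all():
            raise ValueError("kernel contains non-finite entries")
        scale = max(1.0, np.abs(self.values).max())
        if np.abs(self.values - self.values.T).max() > _SYM_TOL * scale:
            raise ValueError("kernel is not symmetric")
        # enforce exact symmetry for downstream factorizations
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n_individuals(self) -> int:
        return self.individual_ids.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.individual_ids
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str) -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.astype(str).to_numpy(object), df.to_numpy(float), kind)


def identity_kernel(individual_ids) -> RelationshipMatrix:
    """Identity kinship: the no-pedigree BLUP baseline (unrelated individuals)."""
    ids = np.asarray(individual_ids, dtype=object)
    return RelationshipMatrix(ids, np.eye(ids.size), "identity")


def build_W(genotypes: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Centered marker matrix W = dosage - 2 p_j, columnwise.

    Requires a complete (imputed) dosage matrix.  When the frequencies are
    computed from the same panel the column means of W are exactly zero.
    """
    if np.isnan(genotypes.dosages).any():
        raise ValueError("genotypes contain missing calls; impute before building W")
    if freqs is None:
        freqs = allele_frequency(genotypes)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (genotypes.n_markers,):
        raise ValueError("frequency vector does not match the marker dimension")
    return genotypes.dosages - 2.0 * freqs


def build_S(genotypes: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Dominance genotype-class coding matrix S.

    The coding is class-based, not linear in dosage, so it is built from the
    pre-imputation integer dosages; missing calls receive code 0 (their
    count is logged).  Fractional (imputed) dosages are rejected.
    """
    if freqs is None:
        freqs = allele_frequency(genotypes)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (genotypes.n_markers,):
        raise ValueError("frequency vector does not match the marker dimension")
    d = genotypes.dosages
    obs = d[~np.isnan(d)]
    if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
        raise ValueError(
            "dominance coding needs integer genotype classes; pass the "
            "pre-imputation matrix"
        )
    n_missing = int(np.isnan(d).sum())
    if n_missing:
        logger.info("build_S: %d missing calls coded 0 in S", n_missing)
    p = freqs
    q = 1.0 - p
    S = np.zeros_like(d)
    S[d == 0.0] = np.broadcast_to(-2.0 * p**2, d.shape)[d == 0.0]
    S[d == 1.0] = np.broadcast_to(2.0 * p * q, d.shape)[d == 1.0]
    S[d == 2.0] = np.broadcast_to(-2.0 * q**2, d.shape)[d == 2.0]
    return S


def vanraden_G(
    W: np.ndarray, freqs: np.ndarray, individual_ids
) -> RelationshipMatrix:
    """Additive genomic relationship matrix G = WW' / sum 2 p q."""
    freqs = np.asarray(freqs, dtype=float)
    denom = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if denom <= 0.0:
        raise ValueError("degenerate panel: sum 2p(1-p) is zero (all monomorphic)")
    return RelationshipMatrix(individual_ids, (W @ W.T) / denom, "additive")


def vitezica_D(
    S: np.ndarray, freqs: np.ndarray, individual_ids
) -> RelationshipMatrix:
    """Dominance genomic relationship matrix D = SS' / (4 sum (pq)^2)."""
    freqs = np.asarray(freqs, dtype=float)
    pq = freqs * (1.0 - freqs)
    denom = 4.0 * float(np.sum(pq**2))
    if denom <= 0.0:
        raise ValueError("degenerate panel: sum (p(1-p))^2 is zero")
    return RelationshipMatrix(individual_ids, (S @ S.T) / denom, "dominance")


def additive_kernel(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """Convenience chain: W from (imputed) dosages, then VanRaden G."""
    if freqs is None:
        freqs = allele_frequency(genotypes)
    from .genotypes import impute_missing

    gm = impute_missing(genotypes, freqs) if np.isnan(genotypes.dosages).any() else genotypes
    W = build_W(gm, freqs)
    return vanraden_G(W, freqs, genotypes.individual_ids)


def dominance_kernel(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """Convenience chain: S from integer dosages, then Vitezica D."""
    if freqs is None:
        freqs = allele_frequency(genotypes)
    S = build_S(genotypes, freqs)
    return vitezica_D(S, freqs, genotypes.individual_ids)
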