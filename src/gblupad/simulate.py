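"""Synthetic genotypes, genetic effects and multi-year phenotypes.

The generator emulates an unstructured perennial-crop population: unlinked
biallelic SNPs in Hardy-Weinberg proportions, additive and dominance marker
effects drawn on the same centered (W) and genotype-class (S) codings used
by the relationship kernels, and unbalanced year-by-year phenotype records.
Simulating effects directly on the W/S codings makes the configured
variances sigma2_a and sigma2_d the exact estimands of the REML additive and
dominance components, so parameter recovery is a well-posed check.

Deliberately absent (see the package methods note): linkage disequilibrium,
population structure, selection and genotype-by-year interaction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kernels import build_S, build_W

_DEFAULT_YEARS = (2018, 2019, 2021)


@dataclass
class SimulationConfig:
    """Conditions for one simulated trait.

    Defaults mirror the reference population this package emulates: 275
    genotypes scored on a post-QC panel of 8,112 SNPs with allele
    frequencies spread over [0.05, 0.5], phenotyped in three years (four for
    the bunch-count trait; see :mod:`gblupad.study`).  ``records_per_year``
    maps each year either to an inclusion probability in (0, 1] or to an
    integer subset size, modelling the unbalancedness of field campaigns.
    """

    n_individuals: int = 275
    n_markers: int = 8112
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    sigma2_a: float = 0.4
    sigma2_d: float = 0.2
    sigma2_e: float = 0.4
    year_effects: Mapping[int, float] = field(
        default_factory=lambda: {y: 0.0 for y in _DEFAULT_YEARS}
    )
    records_per_year: Mapping[int, float] | None = None
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie inside the open interval (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("sigma2_a", "sigma2_d", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.year_effects:
            raise ValueError("year_effects must name at least one year")
        if self.records_per_year is None:
            self.records_per_year = {y: 1.0 for y in self.year_effects}
        extra = set(self.records_per_year) - set(self.year_effects)
        if extra:
            raise ValueError(f"records_per_year names unknown years: {sorted(extra)}")


@dataclass
class SimulationTruth:
    """Latent quantities of one simulated dataset."""

    individual_ids: np.ndarray
    breeding_values: np.ndarray  # g = W alpha
    dominance_values: np.ndarray  # d = S delta
    marker_additive_effects: np.ndarray
    marker_dominance_effects: np.ndarray
    realized_var_g: float
    realized_var_d: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype_id": self.individual_ids,
                "breeding_value": self.breeding_values,
                "dominance_value": self.dominance_values,
            }
        )


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix  # with missingness, pre-QC view
    phenotypes: pd.DataFrame  # long format: genotype_id, year, trait, value
    truth: SimulationTruth
    freqs: np.ndarray
    config: SimulationConfig


def draw_allele_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw p_j i.i.d. uniform on the configured range (point mass allowed)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.allele_freq_range
    if lo == hi:
        return np.full(config.n_markers, lo)
    return rng.uniform(lo, hi, size=config.n_markers)


def simulate_genotypes(
    freqs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Dosages ~ Binomial(2, p_j) per marker, with MCAR missingness."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("allele frequencies must lie in the open interval (0, 1)")
    dosages = rng.binomial(
        2, freqs[None, :], size=(config.n_individuals, freqs.size)
    ).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    ids = np.array([f"G{i+1:04d}" for i in range(config.n_individuals)], dtype=object)
    mids = np.array([f"M{j+1:05d}" for j in range(freqs.size)], dtype=object)
    return GenotypeMatrix(ids, mids, dosages)


def simulate_effects_and_values(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    freqs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Draw marker effects on the W/S codings and form g and d.

    Additive effects are i.i.d. N(0, sigma2_a / sum 2 p q) and dominance
    effects i.i.d. N(0, sigma2_d / (4 sum (pq)^2)), the scalings under which
    Var(g_i) and Var(d_i) target sigma2_a and sigma2_d exactly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if np.isnan(genotypes.dosages).any():
        raise ValueError("genotypes must be complete (simulate truth before masking)")
    from .genotypes import allele_frequency

    freqs = allele_frequency(genotypes) if freqs is None else np.asarray(freqs, float)
    c_a = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    c_d = 4.0 * float(np.sum((freqs * (1.0 - freqs)) ** 2))
    if c_a <= 0 or c_d <= 0:
        raise ValueError("degenerate panel: all markers monomorphic")
    W = build_W(genotypes, freqs)
    S = build_S(genotypes, freqs)
    m = genotypes.n_markers
    alpha = rng.normal(0.0, np.sqrt(config.sigma2_a / c_a), size=m)
    if config.sigma2_d > 0:
        delta = rng.normal(0.0, np.sqrt(config.sigma2_d / c_d), size=m)
    else:
        delta = np.zeros(m)
    g = W @ alpha
    d = S @ delta
    return SimulationTruth(
        individual_ids=genotypes.individual_ids,
        breeding_values=g,
        dominance_values=d,
        marker_additive_effects=alpha,
        marker_dominance_effects=delta,
        realized_var_g=float(np.var(g, ddof=1)),
        realized_var_d=float(np.var(d, ddof=1)),
    )


def simulate_phenotypes(
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One record per retained (individual, year): year effect + g + d + noise.

    All records of an individual share its g and d; the residual is i.i.d.
    N(0, sigma2_e) per record.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = truth.individual_ids.size
    frames = []
    for year in sorted(config.year_effects):
        spec = config.records_per_year.get(year, 0.0)
        if isinstance(spec, (int, np.integer)) and not isinstance(spec, bool):
            # integer: exact subset size
            take = np.sort(rng.choice(n, size=min(int(spec), n), replace=False))
        else:
            # float: per-individual inclusion probability
            take = np.where(rng.random(n) < float(spec))[0]
        if take.size == 0:
            continue
        eps = rng.normal(0.0, np.sqrt(config.sigma2_e), size=take.size)
        frames.append(
            pd.DataFrame(
                {
                    "genotype_id": truth.individual_ids[take],
                    "year": year,
                    "trait": config.trait,
                    "value": config.year_effects[year]
                    + truth.breeding_values[take]
                    + truth.dominance_values[take]
                    + eps,
                }
            )
        )
    if not frames:
        raise ValueError("empty design: no phenotype records retained")
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full generative chain under one seed; bit-identical across runs.

    The latent truth is computed from the complete dosage matrix; the
    emitted genotype matrix then receives the configured MCAR missingness.
    """
    rng = np.random.default_rng(config.seed)
    freqs = draw_allele_frequencies(config, rng)
    complete_cfg = SimulationConfig(**{**config.__dict__, "missing_rate": 0.0})
    genotypes = simulate_genotypes(freqs, complete_cfg, rng)
    truth = simulate_effects_and_values(genotypes, config, freqs=freqs, rng=rng)
    phenotypes = simulate_phenotypes(truth, config, rng)
    dosages = genotypes.dosages
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan
    observed = GenotypeMatrix(genotypes.individual_ids, genotypes.marker_ids, dosages)
    return SimulatedDataset(observed, phenotypes, truth, freqs, config)
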