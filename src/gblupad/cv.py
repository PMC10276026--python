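"""K-fold cross-validated predictive ability over genotypes.

Folds partition genotypes, never single records: all years of a genotype
are masked together, so no phenotypic information about a validation
genotype leaks into its own prediction.  Within each fold the mixed model is
refit by REML on the training records only (configurable to reuse the
full-data variance components), and validation genotypes are predicted
through the relationship kernel: they stay in the kernel with no records,
so their BLUP is the conditional expectation given the training data.
Predictive ability is the Pearson correlation, per fold, between those
predictions and each validation genotype's across-year phenotype mean.

With an identity kernel no information flows to unphenotyped genotypes:
their predictions are all zero, and by convention such constant-prediction
folds score r = 0 (flagged) rather than NaN.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kernels import RelationshipMatrix
from .reml import GBLUPModel, REMLResults

logger = logging.getLogger(__name__)


@dataclass
class CVPlan:
    """Partition of genotypes into k folds."""

    fold_assignment: pd.Series  # genotype_id -> fold index
    k: int
    seed: int

    def fold_ids(self, fold: int) -> np.ndarray:
        return self.fold_assignment.index[self.fold_assignment == fold].to_numpy(object)


@dataclass
class CVResult:
    """Per-fold and averaged predictive ability for one model."""

    model: str
    per_fold_r: list[float]
    mean_r: float
    se_r: float
    constant_folds: list[int] = field(default_factory=list)
    skipped_folds: list[int] = field(default_factory=list)


def make_folds(individual_ids, k: int = 5, seed: int = 0) -> CVPlan:
    """Uniform random partition into k folds with sizes differing by <= 1."""
    ids = np.asarray(individual_ids, dtype=object)
    n = ids.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of individuals ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    return CVPlan(pd.Series(assignment, index=ids), k, seed)


def predict_masked(
    phenotypes: pd.DataFrame,
    kernels: Sequence[RelationshipMatrix],
    plan: CVPlan,
    fold: int,
    trait: str | None = None,
    fixed_components=None,
    max_iter: int = 200,
) -> tuple[pd.Series, REMLResults]:
    """Refit on training records and predict every individual through the kernel.

    Returns the per-individual genetic predictions (a-hat, g-hat or
    g-hat + d-hat depending on the kernels) and the underlying fit.
    """
    if fold not in range(plan.k):
        raise ValueError(f"fold {fold} not in 0..{plan.k - 1}")
    df = phenotypes
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    val_ids = set(plan.fold_ids(fold))
    missing = val_ids - set(kernels[0].individual_ids)
    if missing:
        raise KeyError(f"validation individuals absent from kernel: {sorted(missing)[:3]}")
    training = df[~df["genotype_id"].isin(val_ids)]
    model = GBLUPModel(training, kernels, trait=None)
    res = model.fit(fixed_components=fixed_components, max_iter=max_iter)
    return res.genetic_values, res


def predictive_ability(
    fold_predictions: Mapping[int, pd.Series],
    phenotypes: pd.DataFrame,
    plan: CVPlan,
    model: str = "",
    trait: str | None = None,
) -> CVResult:
    """Correlate masked predictions with across-year phenotype means, per fold.

    Folds with fewer than 3 validation genotypes holding phenotypes are
    skipped (logged); folds with constant predictions score r = 0 by the
    no-information convention.
    """
    df = phenotypes
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    pheno_mean = df.groupby("genotype_id")["value"].mean()
    rs: list[float] = []
    constant: list[int] = []
    skipped: list[int] = []
    for fold in range(plan.k):
        preds = fold_predictions.get(fold)
        if preds is None:
            skipped.append(fold)
            continue
        val = [g for g in plan.fold_ids(fold) if g in pheno_mean.index]
        if len(val) < 3:
            logger.warning("fold %d skipped: only %d usable validation pairs", fold, len(val))
            skipped.append(fold)
            continue
        x = preds.loc[val].to_numpy(float)
        y = pheno_mean.loc[val].to_numpy(float)
        if np.std(x) <= 1e-12 * (1.0 + np.abs(x).max()):
            rs.append(0.0)
            constant.append(fold)
        else:
            rs.append(float(np.corrcoef(x, y)[0, 1]))
    if not rs:
        raise ValueError("no usable folds")
    mean_r = float(np.mean(rs))
    se_r = float(np.std(rs, ddof=1) / np.sqrt(len(rs))) if len(rs) > 1 else 0.0
    return CVResult(model, rs, mean_r, se_r, constant, skipped)


def cross_validate(
    phenotypes: pd.DataFrame,
    kernels: Sequence[RelationshipMatrix],
    trait: str | None = None,
    k: int = 5,
    seed: int = 0,
    refit: bool = True,
    max_iter: int = 200,
) -> CVResult:
    """Full k-fold loop: partition genotypes, refit, predict, correlate.

    With ``refit=False`` the variance components are estimated once on the
    full data and reused in every fold (only the solutions are recomputed).
    """
    model = GBLUPModel(phenotypes, kernels, trait)
    plan = make_folds(model.design.individual_ids, k=k, seed=seed)
    fixed = None
    if not refit:
        fixed = model.fit(max_iter=max_iter).components.to_numpy()
    preds = {
        fold: predict_masked(
            phenotypes, kernels, plan, fold, trait,
            fixed_components=fixed, max_iter=max_iter,
        )[0]
        for fold in range(plan.k)
    }
    return predictive_ability(preds, phenotypes, plan, model=model.label, trait=trait)
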