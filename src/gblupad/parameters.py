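"""Genetic parameters derived from REML variance components.

Narrow-sense heritability  h2 = sigma2_a / (sigma2_a + sigma2_d + sigma2_e)
Broad-sense heritability   H2 = (sigma2_a + sigma2_d) / (sigma2_a + sigma2_d + sigma2_e)
Dominance fraction         d2 = sigma2_d / (sigma2_a + sigma2_d + sigma2_e)
Additive retention ratio   RL_aa = sigma2_a(AD model) / sigma2_a(A model)
Theoretical accuracy       r = sqrt(1 - PEV / sigma2_g)

For additive-only models sigma2_d = 0, so h2 = H2.  RL_aa well below one
indicates that the additive-only model absorbed dominance variance into its
additive component.  In the accuracy formula sigma2_g is the model's total
genetic variance: sigma2_a for additive-only models, sigma2_a + sigma2_d for
the additive-dominance model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def heritabilities(
    sigma2_a: float, sigma2_d: float, sigma2_e: float
) -> tuple[float, float]:
    """Narrow- and broad-sense heritability from the three components."""
    total = sigma2_a + sigma2_d + sigma2_e
    if total <= 0:
        raise ValueError("total variance must be positive")
    return sigma2_a / total, (sigma2_a + sigma2_d) / total


def dominance_fraction(sigma2_a: float, sigma2_d: float, sigma2_e: float) -> float:
    """d2: share of phenotypic variance due to dominance deviations."""
    total = sigma2_a + sigma2_d + sigma2_e
    if total <= 0:
        raise ValueError("total variance must be positive")
    return sigma2_d / total


def additive_ratio(sigma2_a_ad: float, sigma2_a_a: float) -> float:
    """RL_aa: additive variance with dominance in the model over without."""
    if sigma2_a_a <= 0:
        raise ValueError("additive variance of the additive-only model is zero; "
                         "RL_aa is undefined")
    return sigma2_a_ad / sigma2_a_a


def accuracy(pev_scalar: float, sigma2_g: float) -> float:
    """r = sqrt(1 - PEV / sigma2_g), clipped to 0 when PEV exceeds sigma2_g."""
    if sigma2_g <= 0:
        raise ValueError("sigma2_g must be positive")
    if pev_scalar < 0:
        raise ValueError("PEV must be non-negative")
    ratio = 1.0 - pev_scalar / sigma2_g
    if ratio < 0:
        logger.warning("PEV (%.4g) exceeds sigma2_g (%.4g); accuracy clipped to 0",
                       pev_scalar, sigma2_g)
        return 0.0
    return float(np.sqrt(ratio))


@dataclass
class GeneticParams:
    """Per trait x model bundle of derived genetic parameters."""

    h2_narrow: float
    H2_broad: float
    d2: float
    rl_aa: float | None
    accuracy_r: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.h2_narrow <= self.H2_broad + 1e-12):
            raise ValueError("requires 0 <= h2 <= H2")


def params_from_fit(fit, fit_additive_only=None) -> GeneticParams:
    """Derive the parameter bundle from one REML fit.

    ``fit_additive_only`` (a GBLUP-A fit on the same data) enables RL_aa.
    """
    comps = fit.components
    s_a = float(comps.get("additive", comps.get("identity", 0.0)))
    s_d = float(comps.get("dominance", 0.0))
    s_e = float(comps["residual"])
    h2, H2 = heritabilities(s_a, s_d, s_e)
    d2 = dominance_fraction(s_a, s_d, s_e)
    rl = None
    if fit_additive_only is not None:
        rl = additive_ratio(s_a, float(fit_additive_only.components["additive"]))
    return GeneticParams(h2, H2, d2, rl, fit.accuracy)


def dominance_ratios(fit_ad, fit_a) -> tuple[float, float]:
    """(d2, RL_aa) from an additive-dominance fit and its additive-only pair."""
    comps = fit_ad.components
    d2 = dominance_fraction(
        float(comps["additive"]), float(comps["dominance"]), float(comps["residual"])
    )
    rl = additive_ratio(
        float(comps["additive"]), float(fit_a.components["additive"])
    )
    return d2, rl
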