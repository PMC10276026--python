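"""Reference population: a juçara palm (Euterpe edulis) fruit-production study.

The package's defaults emulate a multi-year field evaluation of a naturally
regenerated, commercially managed juçara palm stand: 275 genotypes of
unknown pedigree phenotyped for 12 fruit-production and fruit/seed
morphometry traits over 2018-2021 (in 2020 only the bunch count NBP was
scored), and genotyped at 44,457 SNPs of which 8,112 survive quality control
(call rate >= 90%, MAF >= 5%, an 81.75% reduction).

This module stores that population's published summary tables — per-year
trait means and standard deviations, REML variance components per model
(BLUP, GBLUP-A, GBLUP-AD), the dominance ratios RL_aa and d2, and the fit /
accuracy criteria — and turns them into simulation configurations.  The
tables play two roles: they parameterize the synthetic-data generator (the
study conditions are the generator's defaults), and they serve as the
arithmetic reference for the derived-parameter formulas, which must
reproduce the tabulated h2, H2, d2, RL_aa, r and AIC from the tabulated
variance components.

Trait abbreviations: NBP number of bunches per plant; FWB fruit weight per
bunch (kg); RL rachis length (cm); NRB number of rachillas per bunch; WF /
WS weight of 25 fruits / seeds (g); AP amount of pulp in 25 fruits (g); PY
pulp yield (%); EDF/LDF equatorial/longitudinal fruit diameter (mm);
EDS/LDS equatorial/longitudinal seed diameter (mm).
"""
from __future__ import annotations

import pandas as pd

from .simulate import SimulationConfig

N_GENOTYPES = 275
N_MARKERS_PRE_QC = 44_457
N_MARKERS_POST_QC = 8_112

TRAITS = ["NBP", "FWB", "RL", "NRB", "WF", "WS", "AP", "PY", "EDF", "LDF", "EDS", "LDS"]
MODELS = ["BLUP", "GBLUP-A", "GBLUP-AD"]

#: trait -> {year: (mean, sd)}; NBP is the only trait scored in 2020
YEAR_SUMMARY: dict[str, dict[int, tuple[float, float]]] = {
    "NBP": {2018: (2.63, 1.54), 2019: (3.28, 1.36), 2020: (3.69, 1.03), 2021: (2.18, 1.36)},
    "FWB": {2018: (3.05, 1.57), 2019: (3.45, 1.49), 2021: (3.68, 1.87)},
    "RL": {2018: (60.6, 14.35), 2019: (62.72, 14.15), 2021: (59.31, 10.39)},
    "NRB": {2018: (107.16, 22.04), 2019: (114.22, 23.46), 2021: (114.52, 21.03)},
    "WF": {2018: (41.04, 8.35), 2019: (38.94, 7.39), 2021: (38.15, 7.1)},
    "WS": {2018: (28.6, 6.34), 2019: (25.04, 5.56), 2021: (26.82, 5.75)},
    "AP": {2018: (12.57, 3.59), 2019: (13.93, 3.07), 2021: (11.31, 2.88)},
    "PY": {2018: (30.55, 6.38), 2019: (35.95, 5.36), 2021: (29.78, 6.07)},
    "EDF": {2018: (14.01, 1.12), 2019: (13.24, 1.08), 2021: (13.31, 1.25)},
    "EDS": {2018: (12.84, 1.15), 2019: (11.48, 1.12), 2021: (11.73, 0.95)},
    "LDF": {2018: (14.66, 1.44), 2019: (13.28, 1.03), 2021: (13.58, 1.2)},
    "LDS": {2018: (12.9, 1.51), 2019: (11.19, 0.92), 2021: (11.12, 0.89)},
}

# (trait, model) -> (sigma2_a, sigma2_d, sigma2_e, h2, H2); sigma2_d and H2
# are only reported for the additive-dominance model
_VC_ROWS = [
    ("NBP", "BLUP", 0.65, None, 1.12, 0.37, None),
    ("NBP", "GBLUP-A", 0.64, None, 1.16, 0.35, None),
    ("NBP", "GBLUP-AD", 0.19, 0.33, 1.13, 0.12, 0.31),
    ("FWB", "BLUP", 1.3, None, 1.27, 0.51, None),
    ("FWB", "GBLUP-A", 1.24, None, 1.31, 0.49, None),
    ("FWB", "GBLUP-AD", 0.39, 0.62, 1.27, 0.17, 0.44),
    ("RL", "BLUP", 59.61, None, 126.49, 0.32, None),
    ("RL", "GBLUP-A", 50.39, None, 129.3, 0.28, None),
    ("RL", "GBLUP-AD", 35.74, 13.7, 126.18, 0.20, 0.28),
    ("NRB", "BLUP", 357.05, None, 151.17, 0.70, None),
    ("NRB", "GBLUP-A", 357.7, None, 153.88, 0.70, None),
    ("NRB", "GBLUP-AD", 248.48, 72.26, 152.11, 0.53, 0.68),
    ("WF", "BLUP", 54.65, None, 9.17, 0.86, None),
    ("WF", "GBLUP-A", 55.45, None, 9.22, 0.86, None),
    ("WF", "GBLUP-AD", 36.32, 11.42, 9.20, 0.64, 0.84),
    ("WS", "BLUP", 30.06, None, 6.59, 0.82, None),
    ("WS", "GBLUP-A", 29.00, None, 6.61, 0.81, None),
    ("WS", "GBLUP-AD", 23.17, 3.55, 6.61, 0.70, 0.80),
    ("AP", "BLUP", 7.07, None, 3.97, 0.64, None),
    ("AP", "GBLUP-A", 6.8, None, 4.00, 0.63, None),
    ("AP", "GBLUP-AD", 4.08, 1.67, 3.99, 0.42, 0.59),
    ("PY", "BLUP", 17.36, None, 17.85, 0.49, None),
    ("PY", "GBLUP-A", 15.26, None, 17.87, 0.46, None),
    ("PY", "GBLUP-AD", 13.13, 1.35, 17.86, 0.41, 0.45),
    ("EDF", "BLUP", 0.91, None, 0.47, 0.66, None),
    ("EDF", "GBLUP-A", 0.92, None, 0.48, 0.66, None),
    ("EDF", "GBLUP-AD", 0.63, 0.18, 0.48, 0.49, 0.63),
    ("LDF", "BLUP", 0.82, None, 0.59, 0.58, None),
    ("LDF", "GBLUP-A", 0.81, None, 0.6, 0.58, None),
    ("LDF", "GBLUP-AD", 0.61, 0.13, 0.6, 0.46, 0.55),
    ("EDS", "BLUP", 0.88, None, 0.41, 0.68, None),
    ("EDS", "GBLUP-A", 0.88, None, 0.41, 0.68, None),
    ("EDS", "GBLUP-AD", 0.68, 0.12, 0.41, 0.56, 0.66),
    ("LDS", "BLUP", 0.7, None, 0.45, 0.61, None),
    ("LDS", "GBLUP-A", 0.63, None, 0.45, 0.58, None),
    ("LDS", "GBLUP-AD", 0.63, 0.0, 0.45, 0.58, 0.58),
]

VARIANCE_COMPONENTS = pd.DataFrame(
    _VC_ROWS, columns=["trait", "model", "sigma2_a", "sigma2_d", "sigma2_e", "h2", "H2"]
)

#: trait -> (RL_aa, d2) for the additive-dominance decomposition
DOMINANCE_RATIOS = pd.DataFrame(
    {
        "NBP": (0.30, 0.20), "FWB": (0.32, 0.27), "RL": (0.71, 0.08),
        "NRB": (0.69, 0.15), "WF": (0.65, 0.20), "WS": (0.80, 0.11),
        "AP": (0.60, 0.17), "PY": (0.86, 0.04), "EDF": (0.69, 0.14),
        "LDF": (0.75, 0.10), "EDS": (0.77, 0.10), "LDS": (1.00, 0.00),
    },
    index=["rl_aa", "d2"],
).T

# (trait, model) -> (PEV, r, LL, AIC, BIC)
_FIT_ROWS = [
    ("NBP", "BLUP", 0.21, 0.82, -345.05, 698.1, 717.82),
    ("NBP", "GBLUP-A", 0.19, 0.83, -348.71, 705.42, 725.14),
    ("NBP", "GBLUP-AD", 0.15, 0.84, -340.83, 689.67, 709.39),
    ("FWB", "BLUP", 0.39, 0.83, -257.97, 521.93, 535.38),
    ("FWB", "GBLUP-A", 0.36, 0.84, -254.04, 514.08, 527.52),
    ("FWB", "GBLUP-AD", 0.30, 0.84, -249.55, 505.1, 518.55),
    ("RL", "BLUP", 28.67, 0.72, -299.72, 605.44, 618.89),
    ("RL", "GBLUP-A", 24.28, 0.72, -291.64, 589.28, 602.73),
    ("RL", "GBLUP-AD", 22.64, 0.74, -290.89, 587.78, 601.23),
    ("NRB", "BLUP", 57.62, 0.92, -181.88, 369.77, 383.21),
    ("NRB", "GBLUP-A", 53.98, 0.92, -171.95, 349.9, 363.35),
    ("NRB", "GBLUP-AD", 91.02, 0.85, -170.75, 347.5, 360.94),
    ("WF", "BLUP", 1.25, 0.99, 599.6, -1193.19, -1175.66),
    ("WF", "GBLUP-A", 1.05, 0.99, 613.54, -1221.08, -1203.55),
    ("WF", "GBLUP-AD", 10.36, 0.88, 616.67, -1227.34, -1209.81),
    ("WS", "BLUP", 0.87, 0.99, 422.77, -839.54, -822.05),
    ("WS", "GBLUP-A", 0.75, 0.99, 443.65, -881.3, -863.81),
    ("WS", "GBLUP-AD", 4.16, 0.92, 444.53, -883.06, -865.57),
    ("AP", "BLUP", 0.47, 0.97, -302.46, 610.93, 628.41),
    ("AP", "GBLUP-A", 0.43, 0.97, -287.92, 581.84, 599.32),
    ("AP", "GBLUP-AD", 1.5, 0.86, -283.82, 573.64, 591.12),
    ("PY", "BLUP", 1.94, 0.94, -467.05, 940.1, 957.58),
    ("PY", "GBLUP-A", 1.76, 0.94, -437.3, 880.6, 898.08),
    ("PY", "GBLUP-AD", 2.81, 0.90, -436.97, 879.94, 897.42),
    ("EDF", "BLUP", 0.06, 0.97, -285.78, 577.56, 595.05),
    ("EDF", "GBLUP-A", 0.06, 0.97, -273.44, 552.88, 570.37),
    ("EDF", "GBLUP-AD", 0.19, 0.88, -271.87, 549.75, 567.24),
    ("LDF", "BLUP", 0.07, 0.95, -262.42, 530.85, 548.34),
    ("LDF", "GBLUP-A", 0.07, 0.96, -247.17, 500.34, 517.84),
    ("LDF", "GBLUP-AD", 0.16, 0.88, -245.88, 497.77, 515.26),
    ("EDS", "BLUP", 0.06, 0.97, -50.26, 106.52, 123.9),
    ("EDS", "GBLUP-A", 0.05, 0.97, -35.53, 77.06, 94.44),
    ("EDS", "GBLUP-AD", 0.16, 0.90, -34.56, 75.11, 92.49),
    ("LDS", "BLUP", 0.06, 0.96, 27.91, -49.82, -32.43),
    ("LDS", "GBLUP-A", 0.05, 0.96, 57.36, -108.72, -91.33),
    ("LDS", "GBLUP-AD", 0.05, 0.96, 57.36, -108.72, -91.33),
]

FIT_CRITERIA = pd.DataFrame(
    _FIT_ROWS, columns=["trait", "model", "pev", "r", "ll", "aic", "bic"]
)


def trait_years(trait: str) -> list[int]:
    """Years in which the trait was scored (2020 only for NBP)."""
    return sorted(YEAR_SUMMARY[trait])


def reference_components(trait: str, model: str = "GBLUP-AD") -> tuple[float, float, float]:
    """(sigma2_a, sigma2_d, sigma2_e) for a trait x model of the reference study."""
    row = VARIANCE_COMPONENTS[
        (VARIANCE_COMPONENTS["trait"] == trait) & (VARIANCE_COMPONENTS["model"] == model)
    ]
    if row.empty:
        raise KeyError(f"no reference components for {trait!r} x {model!r}")
    r = row.iloc[0]
    s_d = 0.0 if pd.isna(r["sigma2_d"]) else float(r["sigma2_d"])
    return float(r["sigma2_a"]), s_d, float(r["sigma2_e"])


def study_simulation_config(
    trait: str,
    n_individuals: int = N_GENOTYPES,
    n_markers: int = N_MARKERS_POST_QC,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimulationConfig:
    """Simulation conditions for one study trait.

    Year effects are the trait's per-year means; the additive, dominance and
    residual variances come from the additive-dominance decomposition.  The
    per-trait-per-year genotype counts were never published, so all
    individuals are phenotyped in every available year by default (the year
    pattern itself — three years per trait, four for NBP — carries the
    unbalancedness across traits).
    """
    if trait not in TRAITS:
        raise KeyError(f"unknown trait {trait!r}; choose from {TRAITS}")
    s_a, s_d, s_e = reference_components(trait, "GBLUP-AD")
    year_effects = {year: mean for year, (mean, _sd) in YEAR_SUMMARY[trait].items()}
    return SimulationConfig(
        n_individuals=n_individuals,
        n_markers=n_markers,
        missing_rate=missing_rate,
        sigma2_a=s_a,
        sigma2_d=s_d,
        sigma2_e=s_e,
        year_effects=year_effects,
        trait=trait,
        seed=seed,
    )
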