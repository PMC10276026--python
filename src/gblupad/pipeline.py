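"""End-to-end analysis pipeline: QC -> kernels -> REML -> parameters -> CV.

``run_analysis`` orchestrates, per trait and model, the whole chain from
raw genotype and phenotype files to four report tables (variance components
and heritabilities; dominance ratios with the likelihood-ratio test; fit and
accuracy criteria; cross-validated predictive ability) plus a QC report and
a JSON manifest of settings and convergence flags.  Failures are isolated
per trait so one ill-behaved trait cannot sink the run.  With fixed seeds
the whole output is byte-identical across reruns.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cv import cross_validate
from .genotypes import allele_frequency, qc_filter, read_genotypes
from .kernels import additive_kernel, dominance_kernel, identity_kernel
from .parameters import dominance_ratios, heritabilities
from .reml import GBLUPModel, fit_dominance_pair, lrt_dominance

logger = logging.getLogger(__name__)

_ALL_MODELS = ("BLUP", "GBLUP-A", "GBLUP-AD")


@dataclass
class AnalysisConfig:
    """Declarative settings for one pipeline run."""

    genotypes_path: str
    phenotypes_path: str
    output_dir: str
    genotype_dialect: str = "csv"
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    traits: list[str] | None = None  # None: every trait in the phenotype table
    models: tuple[str, ...] = _ALL_MODELS
    derive_composite_traits: bool = False
    cv_k: int = 5
    cv_seed: int = 0
    reml_max_iter: int = 200

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(_ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def derive_traits(
    phenotypes: pd.DataFrame,
    fruit_trait: str = "WF",
    seed_trait: str = "WS",
    pulp_trait: str = "AP",
    yield_trait: str = "PY",
) -> pd.DataFrame:
    """Append pulp amount and pulp yield derived from fruit and seed weight.

    For each (genotype, year) holding both the 25-fruit weight WF and the
    25-seed weight WS: AP = WF - WS and PY = AP / WF * 100.  Records with
    WF = 0 are skipped for PY (logged); negative AP is kept but flagged as a
    probable data error.
    """
    wide = (
        phenotypes[phenotypes["trait"].isin([fruit_trait, seed_trait])]
        .pivot_table(index=["genotype_id", "year"], columns="trait", values="value")
        .dropna(subset=[fruit_trait, seed_trait])
        .reset_index()
    )
    if wide.empty:
        return phenotypes
    ap = wide[fruit_trait] - wide[seed_trait]
    n_neg = int((ap < 0).sum())
    if n_neg:
        logger.warning("derive_traits: %d records with negative pulp amount", n_neg)
    ap_records = wide[["genotype_id", "year"]].assign(trait=pulp_trait, value=ap)
    nonzero = wide[fruit_trait] != 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.warning("derive_traits: %d records skipped for %s (WF = 0)", n_zero, yield_trait)
    py_records = wide.loc[nonzero, ["genotype_id", "year"]].assign(
        trait=yield_trait, value=100.0 * ap[nonzero] / wide.loc[nonzero, fruit_trait]
    )
    return pd.concat([phenotypes, ap_records, py_records], ignore_index=True)


def run_analysis(config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Run the full per-trait analysis and write the report tables.

    Outputs in ``config.output_dir``: ``qc_report.csv``, ``G.csv``/``D.csv``,
    ``components_table.csv``, ``dominance_ratios.csv``, ``fit_criteria.csv``,
    ``cv_results.csv`` and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    genotypes = read_genotypes(config.genotypes_path, config.genotype_dialect)
    post_qc, qc_report = qc_filter(genotypes, config.call_rate_min, config.maf_min)
    if post_qc.n_markers == 0:
        raise ValueError("quality control removed every marker")
    qc_report.to_dataframe().to_csv(out / "qc_report.csv", index=False)

    freqs = allele_frequency(post_qc)  # recomputed on the retained panel
    G = additive_kernel(post_qc, freqs)
    D = dominance_kernel(post_qc, freqs)
    I = identity_kernel(post_qc.individual_ids)
    G.to_csv(out / "G.csv")
    D.to_csv(out / "D.csv")

    phenotypes = pd.read_csv(config.phenotypes_path)
    if config.derive_composite_traits:
        phenotypes = derive_traits(phenotypes)
    traits = config.traits or sorted(phenotypes["trait"].unique())

    comp_rows, ratio_rows, crit_rows, cv_rows = [], [], [], []
    failures: dict[str, str] = {}
    convergence: dict[str, dict[str, bool]] = {}

    for trait in traits:
        try:
            fits = {}
            if "BLUP" in config.models:
                fits["BLUP"] = GBLUPModel(phenotypes, [I], trait).fit(
                    max_iter=config.reml_max_iter
                )
            if "GBLUP-AD" in config.models and "GBLUP-A" in config.models:
                fits["GBLUP-A"], fits["GBLUP-AD"] = fit_dominance_pair(
                    phenotypes, G, D, trait, max_iter=config.reml_max_iter
                )
            elif "GBLUP-A" in config.models:
                fits["GBLUP-A"] = GBLUPModel.additive(phenotypes, G, trait).fit(
                    max_iter=config.reml_max_iter
                )
            elif "GBLUP-AD" in config.models:
                fits["GBLUP-AD"] = GBLUPModel.additive_dominance(
                    phenotypes, G, D, trait
                ).fit(max_iter=config.reml_max_iter)

            convergence[trait] = {m: bool(f.converged) for m, f in fits.items()}
            for mname, fit in fits.items():
                comps = fit.components
                s_a = float(comps.get("additive", comps.get("identity", 0.0)))
                s_d = float(comps.get("dominance", 0.0))
                s_e = float(comps["residual"])
                h2, H2 = heritabilities(s_a, s_d, s_e)
                comp_rows.append(
                    dict(trait=trait, model=mname, sigma2_a=s_a, sigma2_d=s_d,
                         sigma2_e=s_e, h2=h2, H2=H2)
                )
                crit_rows.append(
                    dict(trait=trait, model=mname, pev=fit.pev_mean, r=fit.accuracy,
                         ll=fit.loglik, aic=fit.aic, bic=fit.bic,
                         converged=fit.converged)
                )

            if "GBLUP-A" in fits and "GBLUP-AD" in fits:
                d2, rl = dominance_ratios(fits["GBLUP-AD"], fits["GBLUP-A"])
                stat, p = lrt_dominance(fits["GBLUP-A"], fits["GBLUP-AD"])
                ratio_rows.append(
                    dict(trait=trait, rl_aa=rl, d2=d2, lrt_stat=stat, lrt_p=p)
                )

            kernel_sets = {"BLUP": [I], "GBLUP-A": [G], "GBLUP-AD": [G, D]}
            for mname in config.models:
                res = cross_validate(
                    phenotypes, kernel_sets[mname], trait,
                    k=config.cv_k, seed=config.cv_seed,
                    max_iter=config.reml_max_iter,
                )
                for fold, r in enumerate(res.per_fold_r):
                    cv_rows.append(
                        dict(model=mname, trait=trait, fold=fold, r=r,
                             mean_r=res.mean_r, se_r=res.se_r)
                    )
        except Exception as exc:  # isolate per-trait failures
            logger.error("trait %s failed: %s", trait, exc)
            failures[trait] = str(exc)

    reports = {
        "components_table": pd.DataFrame(comp_rows),
        "dominance_ratios": pd.DataFrame(ratio_rows),
        "fit_criteria": pd.DataFrame(crit_rows),
        "cv_results": pd.DataFrame(cv_rows),
    }
    for name, df in reports.items():
        df.to_csv(out / f"{name}.csv", index=False)

    manifest = {
        "gblupad_version": __version__,
        "numpy_version": np.__version__,
        "config": dataclasses.asdict(config),
        "qc": {"n_markers_in": qc_report.n_markers_in,
               "n_markers_out": qc_report.n_markers_out,
               "percent_reduction": qc_report.percent_reduction},
        "convergence": convergence,
        "failures": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    reports["manifest"] = manifest
    return reports
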