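"""Configuration-driven end-to-end analysis pipeline.

Stages, in the order a breeding-program analysis runs them:

1. least-squares ANOVA per trait and selection of significant fixed effects;
2. per-trait REML under the requested subset of the six animal models;
3. AIC comparison and best-model selection;
4. genetic parameters from the best model's components;
5. bivariate REML correlations for requested trait pairs;
6. genetic and phenotypic trends from best-model EBVs;
7. pedigree inbreeding summary.

Every stage writes a CSV table to the output directory and the run
manifest records seeds, versions and convergence of every fit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivariate import bivariate_reml, phenotypic_corr_test
from .engine import REMLOptions
from .fixed_effects import FixedEffectModel, ls_anova, select_fixed_effects
from .genpar import derive_parameters
from .io import read_phenotypes, trait_columns
from .mixedmodel import ModelSpec, fit_all_models, select_best_model
from .pedigree import inbreeding_report, read_pedigree
from .trends import genetic_trend, phenotypic_trend

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    pedigree: str = ""
    phenotypes: str = ""
    outdir: str = "pedigreml_out"
    traits: list = field(default_factory=list)     # default: all columns
    models: list = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    fixed_candidates: list = field(
        default_factory=lambda: ["generation", "hatch"])
    test_interaction: bool = False
    alpha: float = 0.05
    bivariate_pairs: list = field(default_factory=list)
    trend_subset: str = "contributing-females"
    seed: int = 0
    tol_logl: float = 5e-4
    max_iter: int = 200

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory result bundle."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ped = read_pedigree(cfg.pedigree)
    records = read_phenotypes(cfg.phenotypes)
    traits = cfg.traits or trait_columns(records)
    missing = [t for t in traits if t not in records.columns]
    if missing:
        raise ValueError(f"traits not in phenotype file: {missing}")
    options = REMLOptions(tol_logl=cfg.tol_logl, max_iter=cfg.max_iter)
    manifest = {"version": __version__, "seed": cfg.seed, "fits": {}}
    bundle = {"anova": {}, "fits": {}, "best": {}, "params": {},
              "bivariate": {}, "trends": {}, "inbreeding": None}

    # stage 1: fixed effects
    fixed_terms = {}
    anova_rows = []
    fem = FixedEffectModel(tuple(cfg.fixed_candidates),
                           include_interaction=cfg.test_interaction)
    for t in traits:
        res = ls_anova(records, t, fem)
        bundle["anova"][t] = res
        kept = select_fixed_effects(res.pvalues, cfg.alpha)
        fixed_terms[t] = tuple(kept)
        for _, r in res.table.iterrows():
            anova_rows.append({"trait": t, **r.to_dict()})
        for f, df in res.lsm.items():
            df.assign(trait=t, factor=f).to_csv(
                out / f"lsm_{t}_{f}.csv", index=False)
    pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)

    # stages 2-4: univariate models, AIC, parameters
    aic_rows, par_rows = [], []
    for t in traits:
        logger.info("fitting trait %s", t)
        fits = fit_all_models(records, ped, t, models=cfg.models,
                              fixed_terms=fixed_terms[t], options=options)
        bundle["fits"][t] = fits
        best = select_best_model(list(fits.values()))
        bundle["best"][t] = best
        for k, f in sorted(fits.items()):
            aic_rows.append({"trait": t, "model": k, "logL": f.logL,
                             "aic": f.aic, "converged": f.converged,
                             "n_iter": f.n_iter})
            manifest["fits"][f"{t}:model{k}"] = {
                "converged": bool(f.converged), "n_iter": int(f.n_iter),
                "logL": float(f.logL)}
        pars = derive_parameters(best.components)
        bundle["params"][t] = pars
        c = best.components
        par_rows.append({
            "trait": t, "model": best.model.model_number,
            "sigma2_a": c.sigma2_a, "sigma2_m": c.sigma2_m,
            "sigma_am": c.sigma_am, "sigma2_c": c.sigma2_c,
            "sigma2_e": c.sigma2_e, "sigma2_p": c.sigma2_p,
            **pars.as_dict(),
            **{f"se_{k}": v for k, v in pars.se.items()},
        })
        best.ebv.to_csv(out / f"ebv_{t}.csv", index=False)
    pd.DataFrame(aic_rows).to_csv(out / "aic.csv", index=False)
    pd.DataFrame(par_rows).to_csv(out / "parameters.csv", index=False)

    # stage 5: bivariate correlations
    biv_rows = []
    for pair in cfg.bivariate_pairs:
        t1, t2 = pair
        m1 = bundle["best"][t1].model
        m2 = bundle["best"][t2].model
        fit = bivariate_reml(records, ped, t1, t2, m1, m2, options=options)
        bundle["bivariate"][(t1, t2)] = fit
        p_rp = (phenotypic_corr_test(fit.corr["r_p"], fit.n_joint)
                if fit.n_joint >= 3 else float("nan"))
        biv_rows.append({
            "pair": f"{t1}-{t2}", "n_joint": fit.n_joint,
            **{k: fit.corr.get(k, float("nan"))
               for k in ("r_a", "r_m", "r_c", "r_e", "r_p")},
            **{f"se_{k}": fit.corr_se.get(k, float("nan"))
               for k in ("r_a", "r_m", "r_c", "r_e", "r_p")},
            "p_rp": p_rp, "converged": fit.converged})
    if biv_rows:
        pd.DataFrame(biv_rows).to_csv(out / "correlations.csv", index=False)

    # stage 6: trends
    trend_rows = []
    for t in traits:
        gt = genetic_trend(bundle["best"][t].ebv, ped, cfg.trend_subset)
        pt = phenotypic_trend(records, t)
        bundle["trends"][t] = {"genetic": gt, "phenotypic": pt}
        trend_rows.append({"trait": t,
                           "genetic_gain": gt.slope, "genetic_se": gt.slope_se,
                           "genetic_p": gt.p,
                           "phenotypic_gain": pt.slope,
                           "phenotypic_se": pt.slope_se,
                           "phenotypic_p": pt.p})
        gt.by_generation.to_csv(out / f"trend_genetic_{t}.csv", index=False)
        pt.by_generation.to_csv(out / f"trend_phenotypic_{t}.csv", index=False)
    pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)

    # stage 7: inbreeding
    rep = inbreeding_report(ped)
    bundle["inbreeding"] = rep
    rep.per_animal.to_csv(out / "inbreeding_per_animal.csv", index=False)
    rep.by_generation.to_csv(out / "inbreeding_by_generation.csv", index=False)
    manifest["inbreeding"] = {"delta_F_mean": rep.delta_F_mean,
                              "delta_F_mean_parents": rep.delta_F_mean_parents}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return bundle
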