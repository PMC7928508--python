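"""Least-squares ANOVA and least-squares means for fixed effects.

Before any genetic analysis, candidate fixed effects (generation, hatch and
optionally their interaction) are screened by least-squares ANOVA on the
unbalanced record table; only significant terms enter the animal models.
Tests are partial (Type-III style) F tests computed with sum-to-zero
contrasts, and least-squares means are model-adjusted level means —
averages of predicted cell means across the other factors' levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)


@dataclass
class FixedEffectModel:
    factors: tuple = ("generation", "hatch")
    include_interaction: bool = False

    @property
    def terms(self) -> list:
        t = list(self.factors)
        if self.include_interaction and len(self.factors) >= 2:
            t += [":".join(self.factors[:2])]
        return t


@dataclass
class AnovaResult:
    trait: str
    table: pd.DataFrame            # term, F, df_num, df_den, p
    lsm: dict                      # factor -> DataFrame(level, lsm, se, n)
    overall_lsm: float
    overall_se: float
    residual_var: float
    nobs: int
    pvalues: dict = field(default_factory=dict)


def _formula(trait, model: FixedEffectModel) -> str:
    parts = [f"C({f}, Sum)" for f in model.factors]
    if model.include_interaction and len(model.factors) >= 2:
        parts.append(f"C({model.factors[0]}, Sum):C({model.factors[1]}, Sum)")
    return f"Q('{trait}') ~ " + " + ".join(parts)


def ls_anova(records: pd.DataFrame, trait: str,
             model: FixedEffectModel | None = None) -> AnovaResult:
    """Fit the fixed-effect model to one trait and test each term.

    Records with a missing trait value are dropped; each factor needs at
    least two populated levels.  Rank deficiency beyond what sum-to-zero
    coding absorbs (e.g. aliased factors) is fatal.
    """
    model = model or FixedEffectModel()
    rec = records.loc[records[trait].notna()].copy()
    for f in model.factors:
        if rec[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 populated levels")
    ols = smf.ols(_formula(trait, model), data=rec).fit()
    if ols.model.exog.shape[1] > np.linalg.matrix_rank(ols.model.exog):
        raise ValueError(
            f"rank-deficient design for {trait}: aliased terms among "
            f"{model.terms} (empty cells?)")
    at = anova_lm(ols, typ=3)
    rows, pvalues = [], {}
    df_den = float(at.loc["Residual", "df"])
    for term in model.terms:
        if ":" in term:
            key = (f"C({model.factors[0]}, Sum):"
                   f"C({model.factors[1]}, Sum)")
        else:
            key = f"C({term}, Sum)"
        rows.append({
            "term": term,
            "F": float(at.loc[key, "F"]),
            "df_num": float(at.loc[key, "df"]),
            "df_den": df_den,
            "p": float(at.loc[key, "PR(>F)"]),
        })
        pvalues[term] = rows[-1]["p"]
    table = pd.DataFrame(rows)

    design_info = ols.model.data.design_info
    cov = np.asarray(ols.cov_params())
    params = np.asarray(ols.params)

    from patsy import build_design_matrices

    def lsm_rows(grid: pd.DataFrame):
        dm = np.asarray(build_design_matrices([design_info], grid)[0])
        c = dm.mean(axis=0)
        return float(c @ params), float(np.sqrt(c @ cov @ c))

    levels = {f: sorted(rec[f].unique()) for f in model.factors}
    lsm = {}
    for f in model.factors:
        others = [g for g in model.factors if g != f]
        out = []
        for lev in levels[f]:
            grid = pd.DataFrame(
                [dict(zip([f] + others, (lev,) + combo))
                 for combo in product(*(levels[g] for g in others))])
            est, se = lsm_rows(grid)
            out.append({"level": lev, "lsm": est, "se": se,
                        "n": int((rec[f] == lev).sum())})
        lsm[f] = pd.DataFrame(out)
    full_grid = pd.DataFrame(
        [dict(zip(model.factors, combo))
         for combo in product(*(levels[g] for g in model.factors))])
    overall, overall_se = lsm_rows(full_grid)

    return AnovaResult(trait=trait, table=table, lsm=lsm,
                       overall_lsm=overall, overall_se=overall_se,
                       residual_var=float(ols.mse_resid), nobs=int(ols.nobs),
                       pvalues=pvalues)


def select_fixed_effects(pvalues: dict, alpha: float = 0.05) -> list:
    """Terms with p <= alpha, keeping an interaction only when both of its
    main effects are kept (hierarchy rule); empty selection falls back to an
    intercept-only model with a logged warning."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    kept = [t for t, p in pvalues.items() if ":" not in t and p <= alpha]
    for t, p in pvalues.items():
        if ":" in t and p <= alpha:
            if all(m in kept for m in t.split(":")):
                kept.append(t)
    if not kept:
        logger.warning("no significant fixed effect; falling back to "
                       "intercept-only model")
    return kept
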