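"""Two-trait REML: cross-trait covariances and correlations.

The per-trait best univariate models are combined into one bivariate
system: every random term present in both traits' models receives an
unstructured 2x2 cross-trait covariance block (direct genetic always;
maternal genetic and maternal permanent environment when shared), the
residual covariance is estimated from animals recorded on both traits, and
no cross-effect covariances (e.g. direct of one trait with maternal of the
other) are fitted.  Correlations and their delta-method standard errors
are derived from the converged covariances; the phenotypic correlation
uses the summed covariances of the terms present in both models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .engine import REMLOptions, REMLProblem, RandomTerm, Residual
from .mixedmodel import DesignBundle, ModelSpec, VarianceComponents, build_design
from .pedigree import Pedigree

logger = logging.getLogger(__name__)


@dataclass
class BivariateFit:
    traits: tuple
    components: dict               # trait -> VarianceComponents
    cov: dict                      # {"a": cov_a, "m": ..., "c": ..., "e": ...}
    corr: dict                     # {"r_a": ..., "r_m": ..., "r_c": ..., "r_e": ..., "r_p": ...}
    corr_se: dict
    logL: float
    n_joint: int
    converged: bool
    raw: object = None
    param_labels: list = field(default_factory=list)


def _stack_Z(Z, n_before, n_after):
    """Embed a trait-level design matrix into the stacked record space."""
    blocks = []
    if n_before:
        blocks.append(sparse.csr_matrix((n_before, Z.shape[1])))
    blocks.append(Z)
    if n_after:
        blocks.append(sparse.csr_matrix((n_after, Z.shape[1])))
    return sparse.vstack(blocks, format="csr")


def _build_bivariate_problem(d1: DesignBundle, d2: DesignBundle,
                             ped: Pedigree, m1: ModelSpec, m2: ModelSpec,
                             fit_cov: dict | None = None):
    if m1.fit_cov_am or m2.fit_cov_am:
        raise NotImplementedError(
            "bivariate analysis supports models without a direct-maternal "
            "covariance (models 1, 2, 4, 5)")
    fit_cov = dict(fit_cov or {})
    n1, n2 = len(d1.y), len(d2.y)
    y = np.concatenate([d1.y, d2.y])
    X = np.block([
        [d1.X, np.zeros((n1, d2.X.shape[1]))],
        [np.zeros((n2, d1.X.shape[1])), d2.X],
    ])

    terms = []
    # direct genetic effect: present in every model
    terms.append(RandomTerm(
        "a", [_stack_Z(d1.Z_a, 0, n2), _stack_Z(d2.Z_a, n1, 0)],
        ["t1", "t2"], ped=ped, free_cov=fit_cov.get("a", True)))

    # maternal genetic
    if m1.has_maternal_genetic and m2.has_maternal_genetic:
        terms.append(RandomTerm(
            "m", [_stack_Z(d1.Z_m, 0, n2), _stack_Z(d2.Z_m, n1, 0)],
            ["t1", "t2"], ped=ped, free_cov=fit_cov.get("m", True)))
    elif m1.has_maternal_genetic:
        terms.append(RandomTerm("m", [_stack_Z(d1.Z_m, 0, n2)], ["t1"],
                                ped=ped))
    elif m2.has_maternal_genetic:
        terms.append(RandomTerm("m", [_stack_Z(d2.Z_m, n1, 0)], ["t2"],
                                ped=ped))

    # maternal permanent environment: shared dam-level index space
    if m1.has_maternal_pe and m2.has_maternal_pe:
        dams = np.array(sorted(set(d1.pe_dams) | set(d2.pe_dams)))
        lookup = {d: k for k, d in enumerate(dams)}
        def remap(d, Z):
            cmap = np.array([lookup[x] for x in d.pe_dams])
            coo = Z.tocoo()
            return sparse.csr_matrix(
                (coo.data, (coo.row, cmap[coo.col])),
                shape=(Z.shape[0], len(dams)))
        terms.append(RandomTerm(
            "c", [_stack_Z(remap(d1, d1.Z_pe), 0, n2),
                  _stack_Z(remap(d2, d2.Z_pe), n1, 0)],
            ["t1", "t2"], free_cov=fit_cov.get("c", True)))
    elif m1.has_maternal_pe:
        terms.append(RandomTerm("c", [_stack_Z(d1.Z_pe, 0, n2)], ["t1"]))
    elif m2.has_maternal_pe:
        terms.append(RandomTerm("c", [_stack_Z(d2.Z_pe, n1, 0)], ["t2"]))

    # residual: per-animal 2x2 blocks for animals with both records
    a1 = {a: i for i, a in enumerate(d1.records["animal"])}
    pairs = [(a1[a], n1 + j) for j, a in enumerate(d2.records["animal"])
             if a in a1]
    n_joint = len(pairs)
    if n_joint == 0:
        logger.warning("no overlapping records: residual covariance fixed 0")
    residual = Residual.bivariate(
        n1, n2, np.array(pairs, dtype=int).reshape(-1, 2),
        free_cov=fit_cov.get("e", True))
    problem = REMLProblem(y, X, terms, residual)
    return problem, n_joint


def _components_from(theta_map, se_map, trait_tag):
    keys = {
        "sigma2_a": f"a:{trait_tag}", "sigma2_m": f"m:{trait_tag}",
        "sigma2_c": f"c:{trait_tag}", "sigma2_e": f"resid:e{trait_tag[-1]}",
    }
    vals = {c: theta_map.get(k, 0.0) for c, k in keys.items()}
    ses = {c: se_map.get(k, float("nan")) for c, k in keys.items()
           if keys[c] in theta_map}
    return VarianceComponents(
        sigma2_a=vals["sigma2_a"], sigma2_m=vals["sigma2_m"], sigma_am=0.0,
        sigma2_c=vals["sigma2_c"], sigma2_e=vals["sigma2_e"], se=ses)


def bivariate_reml(records: pd.DataFrame, ped: Pedigree,
                   trait1: str, trait2: str,
                   model1: ModelSpec, model2: ModelSpec,
                   options: REMLOptions | None = None,
                   fit_cov: dict | None = None,
                   init_theta: np.ndarray | None = None) -> BivariateFit:
    """Bivariate AI-REML under the two traits' (univariate best) models."""
    d1 = build_design(records, ped, model1, trait1)
    d2 = build_design(records, ped, model2, trait2)
    problem, n_joint = _build_bivariate_problem(d1, d2, ped, model1, model2,
                                                fit_cov)
    if init_theta is None:
        theta0 = _default_init(problem, d1, d2)
    else:
        theta0 = init_theta
    res = problem.fit(theta0, options)

    tm = dict(zip(res.param_labels, res.theta))
    sm = dict(zip(res.param_labels, res.se))
    comps = {
        trait1: _components_from(tm, sm, "t1"),
        trait2: _components_from(tm, sm, "t2"),
    }
    cov = {
        "a": tm.get("a:cov(t1,t2)", np.nan),
        "m": tm.get("m:cov(t1,t2)", np.nan),
        "c": tm.get("c:cov(t1,t2)", np.nan),
        "e": tm.get("resid:cov_e", np.nan),
    }

    def ratios(theta_vec):
        t = dict(zip(res.param_labels, theta_vec))
        out = {}
        for term, rname in (("a", "r_a"), ("m", "r_m"), ("c", "r_c")):
            ck = f"{term}:cov(t1,t2)"
            if ck in t:
                out[rname] = t[ck] / np.sqrt(t[f"{term}:t1"] * t[f"{term}:t2"])
        if "resid:cov_e" in t:
            out["r_e"] = t["resid:cov_e"] / np.sqrt(
                t["resid:e1"] * t["resid:e2"])
        p1 = sum(v for k, v in t.items()
                 if k.endswith(":t1") or k == "resid:e1")
        p2 = sum(v for k, v in t.items()
                 if k.endswith(":t2") or k == "resid:e2")
        cp = sum(t.get(k, 0.0) for k in
                 ("a:cov(t1,t2)", "m:cov(t1,t2)", "c:cov(t1,t2)",
                  "resid:cov_e"))
        out["r_p"] = cp / np.sqrt(p1 * p2)
        return out

    corr = ratios(res.theta)
    corr_se = {}
    if np.isfinite(res.ai_inv).all():
        keys = list(corr)
        J = np.zeros((len(keys), len(res.theta)))
        for j in range(len(res.theta)):
            h = 1e-6 * max(abs(res.theta[j]), 1e-3 * np.var(problem.y))
            up, dn = res.theta.copy(), res.theta.copy()
            up[j] += h
            dn[j] -= h
            r_up, r_dn = ratios(up), ratios(dn)
            for i, k in enumerate(keys):
                J[i, j] = (r_up[k] - r_dn[k]) / (2 * h)
        var = np.einsum("ij,jk,ik->i", J, res.ai_inv, J)
        var[var < 0] = np.nan
        corr_se = dict(zip(keys, np.sqrt(var)))
    return BivariateFit(traits=(trait1, trait2), components=comps, cov=cov,
                        corr=corr, corr_se=corr_se, logL=res.logl,
                        n_joint=n_joint, converged=res.converged, raw=res,
                        param_labels=res.param_labels)


def _default_init(problem, d1, d2):
    theta0 = []
    v = {"t1": np.var(d1.y), "t2": np.var(d2.y)}
    for p in problem.params:
        if p.kind == "resid":
            if p.label.endswith("e1"):
                theta0.append(0.5 * v["t1"])
            elif p.label.endswith("e2"):
                theta0.append(0.5 * v["t2"])
            else:
                theta0.append(0.0)
        elif p.is_variance:
            tag = p.label.split(":")[1]
            nvar = 3.0
            theta0.append(v.get(tag, 1.0) / nvar)
        else:
            theta0.append(0.0)
    return np.array(theta0)


@dataclass
class LRTResult:
    statistic: float
    p: float
    logL_full: float
    logL_reduced: float
    which: str


def lrt_covariance(records, ped, trait1, trait2, model1, model2,
                   full: BivariateFit, which: str,
                   options: REMLOptions | None = None) -> LRTResult:
    """Likelihood-ratio test of one cross-trait covariance against zero.

    ``which`` is ``"cov_a"`` or ``"cov_c"``; the reduced model constrains
    that covariance to zero and the statistic ``2 (logL_full - logL_red)``
    refers to a chi-square with 1 df.
    """
    term = {"cov_a": "a", "cov_c": "c", "cov_m": "m", "cov_e": "e"}[which]
    reduced = bivariate_reml(records, ped, trait1, trait2, model1, model2,
                             options=options, fit_cov={term: False})
    stat = max(0.0, 2.0 * (full.logL - reduced.logL))
    p = float(stats.chi2.sf(stat, df=1)) if reduced.converged else float("nan")
    return LRTResult(statistic=stat, p=p, logL_full=full.logL,
                     logL_reduced=reduced.logL, which=which)


def phenotypic_corr_test(r_p: float, n: int) -> float:
    """Two-sided p-value for H0: correlation = 0 via the exact t transform
    ``t = r sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("need at least 3 joint records")
    if abs(r_p) >= 1:
        return 0.0
    t = r_p * np.sqrt((n - 2) / (1 - r_p ** 2))
    return float(2 * stats.t.sf(abs(t), df=n - 2))
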