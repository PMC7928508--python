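"""Univariate maternal-effects animal models.

Six nested single-trait models are supported, differing in which maternal
components they fit alongside the direct additive effect ``a``:

====== ==================================================
model  random part
====== ==================================================
1      a
2      a + m,          Cov(a, m) = 0
3      a + m,          Cov(a, m) = A sigma_am
4      a + pe
5      a + m + pe,     Cov(a, m) = 0
6      a + m + pe,     Cov(a, m) = A sigma_am
====== ==================================================

``m`` is the maternal additive genetic effect (the dam's genotype acting on
her chick's phenotype, A-structured over the full pedigree) and ``pe`` the
maternal permanent environmental effect (IID per dam).  Variance components
are estimated by AI-REML (see :mod:`pedigreml.engine`); models are compared
by AIC counting only the free (co)variance parameters, since the fixed part
is identical across the six.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .engine import REMLOptions, REMLProblem, RandomTerm, Residual
from .pedigree import Pedigree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Which random effects a single-trait animal model fits."""

    has_maternal_genetic: bool = False
    has_maternal_pe: bool = False
    fit_cov_am: bool = False
    fixed_terms: tuple = ("generation", "hatch")

    def __post_init__(self):
        if self.fit_cov_am and not self.has_maternal_genetic:
            raise ValueError("Cov(a,m) requires the maternal genetic effect")

    @classmethod
    def number(cls, k: int, fixed_terms=("generation", "hatch")) -> "ModelSpec":
        table = {
            1: (False, False, False),
            2: (True, False, False),
            3: (True, False, True),
            4: (False, True, False),
            5: (True, True, False),
            6: (True, True, True),
        }
        if k not in table:
            raise ValueError(f"model number must be 1..6, got {k}")
        m, pe, cov = table[k]
        return cls(m, pe, cov, tuple(fixed_terms))

    @property
    def model_number(self) -> int:
        key = (self.has_maternal_genetic, self.has_maternal_pe, self.fit_cov_am)
        return {
            (False, False, False): 1,
            (True, False, False): 2,
            (True, False, True): 3,
            (False, True, False): 4,
            (True, True, False): 5,
            (True, True, True): 6,
        }[key]

    @property
    def n_vc_params(self) -> int:
        """Free (co)variance parameters: the q of AIC = -2 logL + 2q."""
        return (2 + self.has_maternal_genetic + self.has_maternal_pe
                + self.fit_cov_am)

    @property
    def needs_dam(self) -> bool:
        return self.has_maternal_genetic or self.has_maternal_pe


@dataclass
class VarianceComponents:
    """(Co)variance components of one trait under one model.

    Components not fitted by the model are exactly 0 with SE ``nan``.
    """

    sigma2_a: float
    sigma2_m: float = 0.0
    sigma_am: float = 0.0
    sigma2_c: float = 0.0
    sigma2_e: float = 0.0
    se: dict = field(default_factory=dict)
    #: covariance matrix of the fitted components, order as `component_order`
    cov: np.ndarray = None
    component_order: tuple = ()

    @property
    def sigma2_p(self) -> float:
        return (self.sigma2_a + self.sigma2_m + self.sigma_am
                + self.sigma2_c + self.sigma2_e)

    def as_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a, "sigma2_m": self.sigma2_m,
            "sigma_am": self.sigma_am, "sigma2_c": self.sigma2_c,
            "sigma2_e": self.sigma2_e, "sigma2_p": self.sigma2_p,
        }

    @property
    def se_sigma2_p(self) -> float:
        if self.cov is None or not len(self.component_order):
            return float("nan")
        ones = np.ones(len(self.component_order))
        return float(np.sqrt(ones @ self.cov @ ones))


@dataclass
class DesignBundle:
    """Design matrices of one trait: X, Z_a, Z_m, Z_pe, y and index maps."""

    y: np.ndarray
    X: np.ndarray
    Z_a: sparse.csr_matrix
    Z_m: sparse.csr_matrix | None
    Z_pe: sparse.csr_matrix | None
    records: pd.DataFrame          # rows actually used (after drops)
    pe_dams: np.ndarray | None     # pedigree index per pe column
    n_dropped: int
    fixed_labels: list


@dataclass
class FitResult:
    model: ModelSpec
    components: VarianceComponents
    logL: float
    aic: float
    beta: np.ndarray
    ebv: pd.DataFrame              # animal, generation, ebv[, maternal_ebv]
    pe: pd.DataFrame | None
    n_iter: int
    converged: bool
    n_records: int
    raw: object = None             # engine REMLResult


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _factor_columns(values, prefix):
    """Reference-level dummy coding; returns (matrix, labels)."""
    levels = sorted(pd.unique(values))
    cols, labels = [], []
    for lev in levels[1:]:
        cols.append((values == lev).astype(float))
        labels.append(f"{prefix}[{lev}]")
    return cols, labels, levels


def build_fixed_design(records: pd.DataFrame, terms) -> tuple[np.ndarray, list]:
    """Intercept + reference-coded factor columns for the selected terms.

    ``terms`` may contain ``generation``, ``hatch`` and
    ``generation:hatch``; rank deficiencies (e.g. empty interaction cells)
    are resolved later by pivoted QR in the engine.
    """
    n = len(records)
    cols = [np.ones(n)]
    labels = ["intercept"]
    mains = {}
    for term in terms:
        if ":" in term:
            continue
        c, lab, lev = _factor_columns(records[term].to_numpy(), term)
        cols += c
        labels += lab
        mains[term] = lev
    for term in terms:
        if ":" not in term:
            continue
        f1, f2 = term.split(":")
        v1, v2 = records[f1].to_numpy(), records[f2].to_numpy()
        for l1 in sorted(pd.unique(v1))[1:]:
            for l2 in sorted(pd.unique(v2))[1:]:
                mask = (v1 == l1) & (v2 == l2)
                if mask.any():
                    cols.append(mask.astype(float))
                    labels.append(f"{f1}[{l1}]:{f2}[{l2}]")
    return np.column_stack(cols), labels


def _indicator(rows, col_index, n_cols):
    n = len(rows)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), col_index)), shape=(n, n_cols))


def build_design(records: pd.DataFrame, ped: Pedigree, model: ModelSpec,
                 trait: str) -> DesignBundle:
    """Assemble y, X and the Z matrices of one trait under one model.

    ``Z_a`` and ``Z_m`` have one column per pedigree animal (so BLUP
    solutions exist for non-phenotyped parents); ``Z_pe`` one column per dam
    with records among her offspring.  Records with a missing trait value
    are dropped, and under maternal models records whose animal has an
    unknown dam are dropped with a logged count.
    """
    rec = records.loc[records[trait].notna()].copy()
    missing = [a for a in rec["animal"] if a not in ped.index]
    if missing:
        raise KeyError(
            f"{len(missing)} phenotyped animals absent from pedigree, e.g. "
            f"{missing[:5]}")
    aidx = rec["animal"].map(ped.index).to_numpy()
    dam_idx = ped.dam[aidx]
    n_dropped = 0
    if model.needs_dam:
        keep = dam_idx >= 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning(
                "%s: dropped %d records with unknown dam under model %d",
                trait, n_dropped, model.model_number)
        rec = rec.loc[keep]
        aidx, dam_idx = aidx[keep], dam_idx[keep]

    y = rec[trait].to_numpy(dtype=float)
    X, labels = build_fixed_design(rec, model.fixed_terms)
    Z_a = _indicator(np.arange(len(rec)), aidx, ped.n)
    Z_m = Z_pe = None
    pe_dams = None
    if model.has_maternal_genetic:
        Z_m = _indicator(np.arange(len(rec)), dam_idx, ped.n)
    if model.has_maternal_pe:
        pe_dams = np.array(sorted(set(dam_idx)))
        lookup = {d: k for k, d in enumerate(pe_dams)}
        Z_pe = _indicator(np.arange(len(rec)),
                          np.array([lookup[d] for d in dam_idx]), len(pe_dams))
    return DesignBundle(y=y, X=X, Z_a=Z_a, Z_m=Z_m, Z_pe=Z_pe, records=rec,
                        pe_dams=pe_dams, n_dropped=n_dropped,
                        fixed_labels=labels)


# ---------------------------------------------------------------------------
# REML fit
# ---------------------------------------------------------------------------

def _initial_theta(design: DesignBundle, model: ModelSpec,
                   init: VarianceComponents | None):
    """Equal split of the phenotypic variance across fitted components."""
    if init is not None:
        th = [init.sigma2_a]
        if model.has_maternal_genetic:
            th.append(init.sigma2_m)
        if model.has_maternal_pe:
            th.append(init.sigma2_c)
        if model.fit_cov_am:
            th.append(init.sigma_am)
        th.append(init.sigma2_e)
        return np.array(th, dtype=float)
    k = 2 + model.has_maternal_genetic + model.has_maternal_pe
    v = np.var(design.y) / k
    th = [v] * (k - 1)
    if model.fit_cov_am:
        th.append(0.0)
    th.append(v)
    return np.array(th, dtype=float)


def _build_problem(design: DesignBundle, ped: Pedigree,
                   model: ModelSpec) -> REMLProblem:
    terms = []
    if model.has_maternal_genetic:
        terms.append(RandomTerm("genetic", [design.Z_a, design.Z_m],
                                ["a", "m"], ped=ped,
                                free_cov=model.fit_cov_am))
    else:
        terms.append(RandomTerm("genetic", [design.Z_a], ["a"], ped=ped))
    if model.has_maternal_pe:
        terms.append(RandomTerm("pe", [design.Z_pe], ["pe"]))
    residual = Residual.univariate(len(design.y))
    return REMLProblem(design.y, design.X, terms, residual)


def reml_fit(design: DesignBundle, ped: Pedigree, model: ModelSpec,
             init: VarianceComponents | None = None,
             options: REMLOptions | None = None) -> FitResult:
    """AI-REML estimation of one trait under one model, with BLUP solutions.

    Returns components with SEs from the inverse average-information
    matrix, the restricted log-likelihood, AIC, fixed-effect solutions and
    the per-animal breeding values (direct and, when fitted, maternal).
    """
    problem = _build_problem(design, ped, model)
    theta0 = _initial_theta(design, model, init)
    res = problem.fit(theta0, options)
    if not res.converged:
        logger.warning("model %d did not converge in %d iterations",
                       model.model_number, res.n_iter)

    labels = res.param_labels
    comp_map = {"genetic:a": "sigma2_a", "genetic:m": "sigma2_m",
                "genetic:cov(a,m)": "sigma_am", "pe:pe": "sigma2_c",
                "resid:e": "sigma2_e"}
    values = {comp_map[lab]: float(v) for lab, v in zip(labels, res.theta)}
    ses = {comp_map[lab]: float(s) for lab, s in zip(labels, res.se)}
    order = tuple(comp_map[lab] for lab in labels)
    vc = VarianceComponents(
        sigma2_a=values.get("sigma2_a", 0.0),
        sigma2_m=values.get("sigma2_m", 0.0),
        sigma_am=values.get("sigma_am", 0.0),
        sigma2_c=values.get("sigma2_c", 0.0),
        sigma2_e=values.get("sigma2_e", 0.0),
        se=ses, cov=res.ai_inv, component_order=order)

    gen_sol = res.u["genetic"]
    ebv = pd.DataFrame({
        "animal": ped.ids,
        "generation": ped.generation,
        "ebv": gen_sol[:, 0],
    })
    if model.has_maternal_genetic:
        ebv["maternal_ebv"] = gen_sol[:, 1]
    pe_df = None
    if model.has_maternal_pe:
        pe_df = pd.DataFrame({
            "dam": ped.ids[design.pe_dams],
            "pe": res.u["pe"][:, 0],
        })
    fit = FitResult(model=model, components=vc, logL=res.logl,
                    aic=float("nan"), beta=res.beta, ebv=ebv, pe=pe_df,
                    n_iter=res.n_iter, converged=res.converged,
                    n_records=len(design.y), raw=res)
    fit.aic = aic(fit)
    return fit


def aic(fit: FitResult) -> float:
    """AIC = -2 logL + 2q, with q the free (co)variance parameters only."""
    return -2.0 * fit.logL + 2.0 * fit.model.n_vc_params


def select_best_model(fits) -> "FitResult":
    """Minimum-AIC fit; ties within 1e-6 go to the model with fewer
    parameters.  Non-converged fits are excluded; all non-converged is fatal.
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise RuntimeError("no converged fit to select from")
    best = min(usable,
               key=lambda f: (round(f.aic / 1e-6) * 1e-6,
                              f.model.n_vc_params))
    return best


def select_best_aic(aic_values: dict) -> int:
    """Model selection from a plain {model_number: AIC} mapping (ties to
    fewer parameters).  Useful when only the AIC table is available."""
    def q(k):
        return ModelSpec.number(k).n_vc_params
    items = sorted(aic_values.items(), key=lambda kv: (kv[1], q(kv[0])))
    best, best_aic = items[0]
    for k, v in items[1:]:
        if abs(v - best_aic) <= 1e-6 and q(k) < q(best):
            best = k
    return best


def fit_all_models(records: pd.DataFrame, ped: Pedigree, trait: str,
                   models=(1, 2, 3, 4, 5, 6),
                   fixed_terms=("generation", "hatch"),
                   options: REMLOptions | None = None,
                   common_records: bool = True) -> dict[int, FitResult]:
    """Fit a set of the six models to one trait.

    With ``common_records`` (default) every model is fitted to the record
    set usable under maternal models (known dam), so AIC values are
    comparable across models.
    """
    specs = {k: ModelSpec.number(k, fixed_terms) for k in models}
    needs_dam = common_records and any(s.needs_dam for s in specs.values())
    fits = {}
    for k, spec in specs.items():
        if needs_dam and not spec.needs_dam:
            # force the common record set by dropping unknown-dam records
            spec_tmp = ModelSpec(spec.has_maternal_genetic, True,
                                 spec.fit_cov_am, spec.fixed_terms)
            design = build_design(records, ped, spec_tmp, trait)
            design = DesignBundle(y=design.y, X=design.X, Z_a=design.Z_a,
                                  Z_m=None, Z_pe=None, records=design.records,
                                  pe_dams=None, n_dropped=design.n_dropped,
                                  fixed_labels=design.fixed_labels)
        else:
            design = build_design(records, ped, spec, trait)
        fits[k] = reml_fit(design, ped, spec, options=options)
    return fits
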