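"""Synthetic pedigrees and phenotypes with known truth.

The generator emulates a closed, pedigreed layer-breeding nucleus: discrete
generations, a fixed team of sires and dams per generation (default 50
sires x 250 dams over 7 generations, chicks hatched in up to 8 hatches),
random or sib-avoiding mating, and optional truncation selection of the
next generation's parents.

Phenotypes follow the maternal-effects animal model exactly: founder
direct/maternal genetic values are drawn from the true (co)variance
matrix, non-founders are parent averages plus a Mendelian-sampling
deviation whose variance uses the parents' exact pedigree inbreeding, dams
carry an IID permanent environmental effect, and records add fixed
generation and hatch effects plus residual noise.  Every latent value is
retained in a truth table, so estimators can be validated against known
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, build_pedigree, inbreeding

logger = logging.getLogger(__name__)


@dataclass
class TraitTruth:
    """True simulation parameters of one trait (units of the trait)."""

    sigma2_a: float
    sigma2_e: float
    sigma2_m: float = 0.0
    sigma_am: float = 0.0
    sigma2_c: float = 0.0
    mean: float = 0.0
    gen_trend: float = 0.0       # environmental trend per generation
    hatch_step: float = 0.0      # additive effect per hatch number
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.sigma2_m > 0 or self.sigma_am != 0:
            det = self.sigma2_a * self.sigma2_m - self.sigma_am ** 2
            if det < -1e-12 * max(self.sigma2_a, 1.0):
                raise ValueError("(a, m) covariance block not PSD")


@dataclass
class SimulationConfig:
    """Design of one simulated population."""

    traits: dict = field(default_factory=dict)   # name -> TraitTruth
    n_generations: int = 7
    n_sires: int = 50
    n_dams: int = 250
    progeny_per_dam: int = 15
    n_hatches: int = 8
    mating: str = "random"                 # or "avoid_sibs"
    selection: str = "none"                # "none"|"phenotype"|"true_bv"
    selection_trait: str | None = None
    selected_proportion: float = 1.0
    record_founders: bool = False
    # cross-trait covariances, keyed by (trait1, trait2)
    cov_a: dict = field(default_factory=dict)
    cov_m: dict = field(default_factory=dict)
    cov_c: dict = field(default_factory=dict)
    cov_e: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.selected_proportion <= 1):
            raise ValueError("selected_proportion must be in (0, 1]")
        if self.selection != "none" and self.selection_trait is None:
            if len(self.traits) == 1:
                self.selection_trait = next(iter(self.traits))
            else:
                raise ValueError("selection requires selection_trait")

    @classmethod
    def tiny(cls, traits, **kw) -> "SimulationConfig":
        """Small preset (3 generations x 5 sires x 20 dams x 4 progeny)."""
        base = dict(n_generations=3, n_sires=5, n_dams=20,
                    progeny_per_dam=4, n_hatches=3)
        base.update(kw)
        return cls(traits=traits, **base)


@dataclass
class SimResult:
    pedigree: Pedigree
    phenotypes: pd.DataFrame     # animal, generation, hatch, <trait...>
    truth: pd.DataFrame          # per-animal latent values
    truth_pe: pd.DataFrame       # per-dam permanent environmental values
    config: SimulationConfig


def _genetic_cov_matrix(cfg: SimulationConfig):
    """Covariance of the stacked latent vector [a_t..., m_t...]."""
    names = list(cfg.traits)
    T = len(names)
    S = np.zeros((2 * T, 2 * T))
    for i, t in enumerate(names):
        tr = cfg.traits[t]
        S[i, i] = tr.sigma2_a
        S[T + i, T + i] = tr.sigma2_m
        S[i, T + i] = S[T + i, i] = tr.sigma_am
    for (t1, t2), v in cfg.cov_a.items():
        i, j = names.index(t1), names.index(t2)
        S[i, j] = S[j, i] = v
    for (t1, t2), v in cfg.cov_m.items():
        i, j = names.index(t1), names.index(t2)
        S[T + i, T + j] = S[T + j, T + i] = v
    return names, S


def _block_cov(cfg, names, attr, cross):
    T = len(names)
    S = np.zeros((T, T))
    for i, t in enumerate(names):
        S[i, i] = getattr(cfg.traits[t], attr)
    for (t1, t2), v in cross.items():
        i, j = names.index(t1), names.index(t2)
        S[i, j] = S[j, i] = v
    return S


def _safe_chol(S):
    """Square root of a PSD matrix, tolerating exact zeros on the diagonal."""
    if not S.any():
        return np.zeros_like(S)
    w, V = np.linalg.eigh(S)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("true covariance matrix is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def _assign_mates(rng, sires, dam_list, parent_pairs, mating):
    """Map each dam to a sire; capacity is balanced across sires.

    ``parent_pairs[x]`` is the (sire, dam) tuple of animal ``x`` (or None
    for founders); under ``avoid_sibs`` a dam is not assigned to a sire
    sharing a parent with her, when a non-sib sire has capacity left.
    """
    n_d, n_s = len(dam_list), len(sires)
    cap = np.full(n_s, int(np.ceil(n_d / n_s)))
    order = rng.permutation(n_d)
    assignment = {}
    fell_back = False
    for di in order:
        dam = dam_list[di]
        cands = [k for k in range(n_s) if cap[k] > 0]
        rng.shuffle(cands)
        chosen = None
        if mating == "avoid_sibs":
            dp = parent_pairs.get(dam)
            for k in cands:
                sp = parent_pairs.get(sires[k])
                if dp is None or sp is None or not (set(dp) & set(sp)):
                    chosen = k
                    break
            if chosen is None:
                fell_back = True
        if chosen is None:
            chosen = cands[0]
        cap[chosen] -= 1
        assignment[dam] = sires[chosen]
    if fell_back:
        logger.warning("avoid_sibs infeasible for some dams; "
                       "fell back to random assignment")
    return assignment


def simulate(cfg: SimulationConfig) -> SimResult:
    """Joint pedigree + phenotype simulation (required when selection is on,
    since next-generation parents depend on realised records)."""
    rng = np.random.default_rng(cfg.seed)
    names, S_G = _genetic_cov_matrix(cfg)
    T = len(names)
    L_G = _safe_chol(S_G)
    L_C = _safe_chol(_block_cov(cfg, names, "sigma2_c", cfg.cov_c))
    L_E = _safe_chol(_block_cov(cfg, names, "sigma2_e", cfg.cov_e))

    ids, sire, dam, gen, sex = [], [], [], [], []
    G = []            # per-animal latent [a..., m...]
    F = []            # inbreeding, filled incrementally
    pe_values = {}    # dam index -> per-trait pe vector
    pheno_rows = []

    def new_animal(s, d, g, sx):
        i = len(ids)
        ids.append(f"A{i + 1:06d}")
        sire.append(s)
        dam.append(d)
        gen.append(g)
        sex.append(sx)
        if s == UNKNOWN and d == UNKNOWN:
            F.append(0.0)
            G.append(L_G @ rng.standard_normal(2 * T))
        else:
            pa = np.zeros(2 * T)
            fs = fd = None
            if s != UNKNOWN:
                pa += 0.5 * G[s]
                fs = F[s]
            if d != UNKNOWN:
                pa += 0.5 * G[d]
                fd = F[d]
            if fs is not None and fd is not None:
                dvar = 0.5 - 0.25 * (fs + fd)
                # offspring inbreeding = coancestry (kinship) of its parents
                F.append(_kinship(sire, dam, s, d))
            elif fs is not None or fd is not None:
                dvar = 0.75 - 0.25 * (fs if fs is not None else fd)
                F.append(0.0)
            else:
                dvar = 1.0
                F.append(0.0)
            G.append(pa + np.sqrt(dvar) * (L_G @ rng.standard_normal(2 * T)))
        return i

    def make_record(i, g):
        d = dam[i]
        if d not in pe_values and d != UNKNOWN:
            pe_values[d] = L_C @ rng.standard_normal(T)
        pe = pe_values.get(d, np.zeros(T))
        m_dam = G[d][T:] if d != UNKNOWN else np.zeros(T)
        e = L_E @ rng.standard_normal(T)
        hatch = int(rng.integers(1, cfg.n_hatches + 1))
        row = {"animal": ids[i], "generation": g, "hatch": hatch}
        for k, t in enumerate(names):
            tr = cfg.traits[t]
            val = (tr.mean + tr.gen_trend * g + tr.hatch_step * (hatch - 1)
                   + G[i][k] + m_dam[k] + pe[k] + e[k])
            if tr.missing_rate > 0 and rng.random() < tr.missing_rate:
                val = np.nan
            row[t] = val
            row[f"_e_{t}"] = e[k]
        pheno_rows.append(row)

    # founders
    males = [new_animal(UNKNOWN, UNKNOWN, 0, "M") for _ in range(cfg.n_sires)]
    females = [new_animal(UNKNOWN, UNKNOWN, 0, "F") for _ in range(cfg.n_dams)]
    if cfg.record_founders:
        for i in males + females:
            make_record(i, 0)

    parent_pairs = {}
    for g in range(1, cfg.n_generations + 1):
        assignment = _assign_mates(rng, males, females, parent_pairs,
                                   cfg.mating)
        offspring = []
        for d in females:
            s = assignment[d]
            for j in range(cfg.progeny_per_dam):
                sx = "M" if j % 2 == 0 else "F"
                i = new_animal(s, d, g, sx)
                parent_pairs[i] = (s, d)
                make_record(i, g)
                offspring.append(i)
        if g == cfg.n_generations:
            break
        males = _select(rng, cfg, offspring, "M", cfg.n_sires,
                        pheno_rows, G, names, sex)
        females = _select(rng, cfg, offspring, "F", cfg.n_dams,
                          pheno_rows, G, names, sex)

    ped = Pedigree(
        ids=np.array(ids, dtype=object),
        sire=np.array(sire), dam=np.array(dam),
        generation=np.array(gen), sex=np.array(sex, dtype=object))
    pheno = pd.DataFrame(pheno_rows)
    e_cols = [c for c in pheno.columns if c.startswith("_e_")]
    truth = pd.DataFrame({"animal": ids, "generation": gen})
    for k, t in enumerate(names):
        truth[f"a_{t}"] = [v[k] for v in G]
        truth[f"m_{t}"] = [v[T + k] for v in G]
    truth["F"] = F
    truth_pe = pd.DataFrame(
        {"dam": [ids[d] for d in sorted(pe_values)],
         **{f"pe_{t}": [pe_values[d][k] for d in sorted(pe_values)]
            for k, t in enumerate(names)}})
    residuals = pheno[["animal"] + e_cols].rename(
        columns={c: c.replace("_e_", "e_") for c in e_cols})
    truth = truth.merge(residuals, on="animal", how="left")
    pheno = pheno.drop(columns=e_cols)
    return SimResult(pedigree=ped, phenotypes=pheno, truth=truth,
                     truth_pe=truth_pe, config=cfg)


def _select(rng, cfg, candidates, sx, n_needed, pheno_rows, G, names, sex):
    pool = [i for i in candidates if sex[i] == sx]
    if len(pool) < n_needed:
        raise ValueError(f"not enough {sx} candidates "
                         f"({len(pool)} < {n_needed})")
    if cfg.selection == "none":
        return list(rng.choice(pool, size=n_needed, replace=False))
    ti = names.index(cfg.selection_trait)
    if cfg.selection == "true_bv":
        crit = {i: G[i][ti] for i in pool}
    else:  # phenotype
        recent = {r["animal"]: r.get(cfg.selection_trait, np.nan)
                  for r in pheno_rows}
        crit = {}
        for i in pool:
            v = recent.get(f"A{i + 1:06d}", np.nan)
            crit[i] = -np.inf if v is None or not np.isfinite(v) else v
    ranked = sorted(pool, key=lambda i: crit[i], reverse=True)
    eligible = ranked[: max(n_needed,
                            int(np.ceil(cfg.selected_proportion * len(pool))))]
    chosen = rng.choice(eligible, size=n_needed, replace=False)
    return list(chosen)


def _kinship(sire, dam, x, y, _cache=None):
    """Kinship f(x, y) by recursion on the (partial) pedigree arrays."""
    def f(a, b, memo):
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        if a == b:
            s, d = sire[a], dam[a]
            return 0.5 * (1.0 + f(s, d, memo))
        if a < b:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        v = 0.5 * (f(sire[a], b, memo) + f(dam[a], b, memo))
        memo[key] = v
        return v
    return f(x, y, {})


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Pedigree only.  Runs the joint simulator and discards records, so a
    selection scheme still shapes which animals become parents."""
    return simulate(cfg).pedigree


def simulate_phenotypes(ped: Pedigree, cfg: SimulationConfig,
                        seed: int | None = None):
    """Phenotypes and truth for a *given* pedigree (no selection feedback).

    Founder-generation animals (unknown dam) receive records only when
    ``cfg.record_founders`` is set, mirroring the record-dropping rule of
    maternal-model design construction.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    names, S_G = _genetic_cov_matrix(cfg)
    T = len(names)
    L_G = _safe_chol(S_G)
    L_C = _safe_chol(_block_cov(cfg, names, "sigma2_c", cfg.cov_c))
    L_E = _safe_chol(_block_cov(cfg, names, "sigma2_e", cfg.cov_e))
    F = inbreeding(ped)
    n = ped.n
    G = np.zeros((n, 2 * T))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pa = np.zeros(2 * T)
        if s != UNKNOWN and d != UNKNOWN:
            pa = 0.5 * (G[s] + G[d])
            dvar = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            p = s if s != UNKNOWN else d
            pa = 0.5 * G[p]
            dvar = 0.75 - 0.25 * F[p]
        else:
            dvar = 1.0
        G[i] = pa + np.sqrt(dvar) * (L_G @ rng.standard_normal(2 * T))

    pe_values = {}
    rows = []
    for i in range(n):
        d = ped.dam[i]
        if ped.generation[i] == ped.generation.min() and not cfg.record_founders:
            continue
        if d == UNKNOWN and not cfg.record_founders:
            continue
        if d not in pe_values and d != UNKNOWN:
            pe_values[d] = L_C @ rng.standard_normal(T)
        pe = pe_values.get(d, np.zeros(T))
        m_dam = G[d][T:] if d != UNKNOWN else np.zeros(T)
        e = L_E @ rng.standard_normal(T)
        hatch = int(rng.integers(1, cfg.n_hatches + 1))
        row = {"animal": ped.ids[i], "generation": int(ped.generation[i]),
               "hatch": hatch}
        for k, t in enumerate(names):
            tr = cfg.traits[t]
            val = (tr.mean + tr.gen_trend * ped.generation[i]
                   + tr.hatch_step * (hatch - 1)
                   + G[i][k] + m_dam[k] + pe[k] + e[k])
            if tr.missing_rate > 0 and rng.random() < tr.missing_rate:
                val = np.nan
            row[t] = val
            row[f"e_{t}"] = e[k]
        rows.append(row)
    pheno = pd.DataFrame(rows)
    truth = pd.DataFrame({"animal": ped.ids, "generation": ped.generation})
    for k, t in enumerate(names):
        truth[f"a_{t}"] = G[:, k]
        truth[f"m_{t}"] = G[:, T + k]
    truth["F"] = F
    truth = truth.merge(pheno[["animal"] + [f"e_{t}" for t in names]],
                        on="animal", how="left")
    pheno = pheno.drop(columns=[f"e_{t}" for t in names])
    truth_pe = pd.DataFrame(
        {"dam": [ped.ids[d] for d in sorted(pe_values)],
         **{f"pe_{t}": [pe_values[d][k] for d in sorted(pe_values)]
            for k, t in enumerate(names)}})
    return pheno, truth, truth_pe
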