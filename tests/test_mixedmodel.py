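"""Design construction, REML log-likelihood, AIC selection and BLUP."""

import numpy as np
import pandas as pd
import pytest

from pedigreml.engine import REMLOptions
from pedigreml.mixedmodel import (ModelSpec, VarianceComponents, build_design,
                                  fit_all_models, reml_fit, select_best_aic,
                                  select_best_model, _build_problem,
                                  _initial_theta)
from pedigreml.pedigree import build_pedigree, relationship_matrix
from conftest import random_pedigree


def _records_for(ped, y, gens=None, hatches=None, trait="t"):
    n = len(y)
    return pd.DataFrame({
        "animal": ped.ids[:n] if gens is None else gens.pop("ids"),
        "generation": np.ones(n, dtype=int) if gens is None else gens,
        "hatch": np.ones(n, dtype=int) if hatches is None else hatches,
        trait: y,
    })


def _sim_records(rng, ped, sigma2_a, sigma2_e, trait="t", mu=10.0):
    """Phenotypes for every animal: y = mu + a + e with a ~ N(0, A sigma2_a)."""
    A = relationship_matrix(ped)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(ped.n))
    a = L @ rng.normal(0, np.sqrt(sigma2_a), ped.n)
    y = mu + a + rng.normal(0, np.sqrt(sigma2_e), ped.n)
    return pd.DataFrame({"animal": ped.ids,
                         "generation": ped.generation.clip(min=1),
                         "hatch": rng.integers(1, 3, ped.n),
                         trait: y})


class TestBuildDesign:
    def test_shapes_and_fixed_columns(self, rng):
        ped = random_pedigree(rng, 40, p_unknown=0.0)
        rec = _sim_records(rng, ped, 1.0, 1.0)
        d = build_design(rec, ped, ModelSpec.number(5), "t")
        n = len(d.y)
        assert d.X.shape[0] == n
        # intercept + (levels-1) per factor
        want_cols = 1 + (rec.loc[rec["animal"].isin(d.records["animal"]),
                                 "generation"].nunique() - 1) \
            + (d.records["hatch"].nunique() - 1)
        assert d.X.shape[1] == want_cols
        assert d.Z_a.shape == (n, ped.n)
        assert d.Z_m.shape == (n, ped.n)
        assert d.Z_pe.shape[0] == n
        # one pe column per distinct dam with records
        assert d.Z_pe.shape[1] == d.records["animal"].map(
            lambda a: ped.dam[ped.index[a]]).nunique()

    def test_unknown_dam_records_dropped_under_maternal_models(self, trio):
        rec = pd.DataFrame({"animal": ["s", "d", "x"],
                            "generation": [1, 1, 2], "hatch": [1, 2, 1],
                            "t": [1.0, 2.0, 3.0]})
        d1 = build_design(rec, trio, ModelSpec.number(1), "t")
        d5 = build_design(rec, trio, ModelSpec.number(5), "t")
        assert len(d1.y) == 3 and d1.n_dropped == 0
        # founders s and d have unknown dam
        assert len(d5.y) == 1 and d5.n_dropped == 2

    def test_missing_trait_rows_dropped(self, trio):
        rec = pd.DataFrame({"animal": ["s", "d", "x"],
                            "generation": [1, 1, 2], "hatch": [1, 2, 1],
                            "t": [1.0, np.nan, 3.0]})
        d = build_design(rec, trio, ModelSpec.number(1), "t")
        assert len(d.y) == 2

    def test_unpedigreed_animal_fatal(self, trio):
        rec = pd.DataFrame({"animal": ["ghost"], "generation": [1],
                            "hatch": [1], "t": [1.0]})
        with pytest.raises(KeyError, match="absent from pedigree"):
            build_design(rec, trio, ModelSpec.number(1), "t")


class TestModelSpec:
    def test_numbering_round_trip(self):
        for k in range(1, 7):
            assert ModelSpec.number(k).model_number == k

    def test_vc_param_counts(self):
        assert [ModelSpec.number(k).n_vc_params for k in range(1, 7)] == \
            [2, 3, 4, 3, 4, 5]

    def test_cov_without_maternal_fatal(self):
        with pytest.raises(ValueError):
            ModelSpec(has_maternal_genetic=False, fit_cov_am=True)


class TestLogLikelihoodOracle:
    """MME-based restricted logL against the dense-V textbook formula."""

    def _dense_logl(self, y, X, V):
        n, p = X.shape
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        quad = r @ Vi @ y
        return -0.5 * ((n - p) * np.log(2 * np.pi)
                       + np.linalg.slogdet(V)[1]
                       + np.linalg.slogdet(XtViX)[1] + quad)

    @pytest.mark.parametrize("model_k", [1, 2, 4, 5])
    def test_matches_dense_oracle(self, rng, model_k):
        ped = random_pedigree(rng, 30, p_unknown=0.0)
        rec = _sim_records(rng, ped, 2.0, 3.0)
        spec = ModelSpec.number(model_k)
        d = build_design(rec, ped, spec, "t")
        problem = _build_problem(d, ped, spec)
        theta = _initial_theta(d, spec, VarianceComponents(
            sigma2_a=1.3, sigma2_m=0.7, sigma2_c=0.4, sigma2_e=2.1))

        A = relationship_matrix(ped)
        Za, Zm = d.Z_a.toarray(), None
        V = 1.3 * (Za @ A @ Za.T) + 2.1 * np.eye(len(d.y))
        if spec.has_maternal_genetic:
            Zm = d.Z_m.toarray()
            V += 0.7 * (Zm @ A @ Zm.T)
        if spec.has_maternal_pe:
            V += 0.4 * (d.Z_pe @ d.Z_pe.T).toarray()
        # drop linearly dependent fixed columns as the engine does
        want = self._dense_logl(d.y, _full_rank(d.X), V)
        assert problem.loglik(theta) == pytest.approx(want, abs=1e-8)


def _full_rank(X):
    q, r, piv = __import__("scipy").linalg.qr(X, pivoting=True, mode="economic")
    rank = int((np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0])).sum())
    return X[:, np.sort(piv[:rank])]


class TestAicSelection:
    def test_aic_arithmetic(self):
        # logL = -100: model 1 -> 204, model 4 -> 206, model 6 -> 210
        assert select_best_aic({1: 204.0, 4: 206.0, 6: 210.0}) == 1
        assert select_best_aic({1: 210.0, 5: 205.0, 6: 209.0}) == 5

    def test_tie_goes_to_fewer_parameters(self):
        assert select_best_aic({5: 204.0, 2: 204.0}) == 2
        assert select_best_aic({6: 100.0, 1: 100.0 + 5e-7}) == 1

    def test_select_best_model_skips_nonconverged(self, rng):
        ped = random_pedigree(rng, 25, p_unknown=0.0)
        rec = _sim_records(rng, ped, 1.0, 2.0)
        d = build_design(rec, ped, ModelSpec.number(1), "t")
        good = reml_fit(d, ped, ModelSpec.number(1))
        bad = reml_fit(d, ped, ModelSpec.number(1))
        bad.converged = False
        bad.aic = good.aic - 100.0
        assert select_best_model([good, bad]) is good
        bad2 = reml_fit(d, ped, ModelSpec.number(1))
        bad2.converged = False
        with pytest.raises(RuntimeError):
            select_best_model([bad2])


class TestRemlFit:
    def test_zero_heritability_boundary(self, rng):
        # half-sib families but a pure-noise phenotype: sigma2_a near 0
        n_sires, k = 40, 10
        recs = [(f"s{i}", None, None, 0) for i in range(n_sires)]
        recs += [(f"p{i}_{j}", f"s{i}", None, 1)
                 for i in range(n_sires) for j in range(k)]
        ped = build_pedigree(recs)
        y = rng.normal(5.0, np.sqrt(4.0), n_sires * k)
        rec = pd.DataFrame({"animal": [f"p{i}_{j}" for i in range(n_sires)
                                       for j in range(k)],
                            "generation": 1,
                            "hatch": rng.integers(1, 3, n_sires * k), "t": y})
        d = build_design(rec, ped, ModelSpec.number(1), "t")
        fit = reml_fit(d, ped, ModelSpec.number(1))
        assert fit.converged
        vc = fit.components
        assert vc.sigma2_a <= 0.15 * vc.sigma2_p
        # with sigma2_a at/near zero, sigma2_e tracks the within-family
        # mean square (here slightly above var(y): negative ANOVA estimate)
        msw = np.mean(np.var(y.reshape(n_sires, k), axis=1, ddof=1))
        assert vc.sigma2_e == pytest.approx(msw, rel=0.05)

    def test_halfsib_matches_anova_closed_form(self, rng):
        # balanced half-sib families: sigma2_s = (MSB - MSW)/k, sigma2_a = 4 sigma2_s
        n_sires, k = 60, 10
        recs = [(f"s{i}", None, None, 0) for i in range(n_sires)]
        recs += [(f"p{i}_{j}", f"s{i}", None, 1)
                 for i in range(n_sires) for j in range(k)]
        ped = build_pedigree(recs)
        sires = np.repeat(np.arange(n_sires), k)
        u = rng.normal(0, np.sqrt(0.5), n_sires)
        y = 20.0 + u[sires] + rng.normal(0, np.sqrt(2.0), n_sires * k)
        rec = pd.DataFrame({"animal": [f"p{i}_{j}" for i in range(n_sires)
                                       for j in range(k)],
                            "generation": 1, "hatch": 1, "t": y})
        ym = y.reshape(n_sires, k)
        msb = k * np.var(ym.mean(axis=1), ddof=1)
        msw = np.mean(np.var(ym, axis=1, ddof=1))
        sigma2_s = (msb - msw) / k
        d = build_design(rec, ped, ModelSpec.number(1), "t")
        fit = reml_fit(d, ped, ModelSpec.number(1))
        assert fit.converged
        assert fit.components.sigma2_a == pytest.approx(4 * sigma2_s, rel=1e-4)
        assert fit.components.sigma2_e == pytest.approx(
            msw - 3 * sigma2_s, rel=1e-4)

    def test_ebv_is_shrunken_deviation_for_unrelated_animals(self, rng):
        # single records on unrelated animals: ebv_i = h2_hat (y_i - beta_hat)
        ped = build_pedigree([(f"f{i}", None, None, 1) for i in range(300)])
        y = rng.normal(3.0, 2.0, 300)
        rec = pd.DataFrame({"animal": ped.ids, "generation": 1, "hatch": 1,
                            "t": y})
        d = build_design(rec, ped, ModelSpec.number(1), "t")
        fit = reml_fit(d, ped, ModelSpec.number(1))
        vc = fit.components
        h2 = vc.sigma2_a / (vc.sigma2_a + vc.sigma2_e)
        want = h2 * (y - fit.beta[0])
        assert np.allclose(fit.ebv["ebv"].to_numpy(), want, atol=1e-8)

    def test_fit_all_models_common_records(self, rng):
        ped = random_pedigree(rng, 120, p_unknown=0.15)
        rec = _sim_records(rng, ped, 1.0, 2.0)
        fits = fit_all_models(rec, ped, "t", models=(1, 4),
                              options=REMLOptions(max_iter=60))
        # both models fitted to the known-dam record set -> comparable AIC
        assert fits[1].n_records == fits[4].n_records
        n_known_dam = int((ped.dam >= 0).sum())
        assert fits[1].n_records == n_known_dam
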