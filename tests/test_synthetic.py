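"""Synthetic-data generator: structure, determinism and exact model algebra."""

import numpy as np
import pytest

from pedigreml.pedigree import UNKNOWN, inbreeding
from pedigreml.synthetic import (SimulationConfig, TraitTruth, simulate,
                                 simulate_phenotypes)


def _truth(a=1.0, e=2.0, **kw):
    return TraitTruth(sigma2_a=a, sigma2_e=e, **kw)


def _tiny(seed=0, **kw):
    return SimulationConfig.tiny({"t": _truth()}, seed=seed, **kw)


class TestStructure:
    def test_animal_and_record_counts(self):
        cfg = _tiny()
        res = simulate(cfg)
        n_founders = cfg.n_sires + cfg.n_dams
        n_off = cfg.n_generations * cfg.n_dams * cfg.progeny_per_dam
        assert res.pedigree.n == n_founders + n_off
        # founders unrecorded by default
        assert len(res.phenotypes) == n_off
        assert set(res.phenotypes["generation"]) == {1, 2, 3}
        assert res.phenotypes["hatch"].between(1, cfg.n_hatches).all()

    def test_record_founders_flag(self):
        res = simulate(_tiny(record_founders=True))
        assert (res.phenotypes["generation"] == 0).sum() == 25

    def test_every_offspring_has_both_parents(self):
        ped = simulate(_tiny()).pedigree
        off = ped.generation > 0
        assert (ped.sire[off] != UNKNOWN).all()
        assert (ped.dam[off] != UNKNOWN).all()
        # sires sire, dams bear
        assert all(ped.sex[s] == "M" for s in ped.sire[off])
        assert all(ped.sex[d] == "F" for d in ped.dam[off])

    def test_determinism(self):
        r1, r2 = simulate(_tiny(seed=5)), simulate(_tiny(seed=5))
        assert r1.phenotypes.equals(r2.phenotypes)
        assert np.array_equal(r1.pedigree.sire, r2.pedigree.sire)
        r3 = simulate(_tiny(seed=6))
        assert not r1.phenotypes["t"].equals(r3.phenotypes["t"])

    def test_avoid_sibs_matings_share_no_parent(self):
        cfg = SimulationConfig({"t": _truth()}, n_generations=4, n_sires=8,
                               n_dams=24, progeny_per_dam=4, n_hatches=2,
                               mating="avoid_sibs", seed=3)
        ped = simulate(cfg).pedigree
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s == UNKNOWN or d == UNKNOWN:
                continue
            sp = {ped.sire[s], ped.dam[s]} - {UNKNOWN}
            dp = {ped.sire[d], ped.dam[d]} - {UNKNOWN}
            assert not (sp & dp), f"mating of sibs at animal {i}"


class TestExactAlgebra:
    def test_all_variances_zero_gives_deterministic_cells(self):
        tr = TraitTruth(sigma2_a=0.0, sigma2_e=0.0, mean=7.0,
                        gen_trend=1.5, hatch_step=0.25)
        res = simulate(SimulationConfig.tiny({"t": tr}, seed=1))
        ph = res.phenotypes
        want = 7.0 + 1.5 * ph["generation"] + 0.25 * (ph["hatch"] - 1)
        assert np.allclose(ph["t"], want)

    def test_truth_table_decomposes_phenotype(self):
        tr = TraitTruth(sigma2_a=1.0, sigma2_e=2.0, sigma2_m=0.5,
                        sigma2_c=0.3, mean=10.0, gen_trend=0.5, hatch_step=0.1)
        res = simulate(SimulationConfig.tiny({"t": tr}, seed=2))
        ped, truth = res.pedigree, res.truth.set_index("animal")
        pe = res.truth_pe.set_index("dam")["pe_t"]
        for _, r in res.phenotypes.iterrows():
            i = ped.index[r["animal"]]
            dam = ped.ids[ped.dam[i]]
            want = (10.0 + 0.5 * r["generation"] + 0.1 * (r["hatch"] - 1)
                    + truth.loc[r["animal"], "a_t"]
                    + truth.loc[dam, "m_t"] + pe.loc[dam]
                    + truth.loc[r["animal"], "e_t"])
            assert r["t"] == pytest.approx(want, abs=1e-10)

    def test_inbreeding_truth_matches_pedigree_algebra(self):
        cfg = SimulationConfig({"t": _truth()}, n_generations=5, n_sires=4,
                               n_dams=12, progeny_per_dam=4, n_hatches=2,
                               seed=9)
        res = simulate(cfg)
        assert np.allclose(res.truth["F"].to_numpy(),
                           inbreeding(res.pedigree), atol=1e-12)
        assert res.truth["F"].iloc[-1] > 0  # small closed population inbreeds

    def test_founder_genetic_variance(self):
        cfg = SimulationConfig({"t": _truth(a=4.0)}, n_generations=1,
                               n_sires=2000, n_dams=2000, progeny_per_dam=1,
                               n_hatches=1, seed=4)
        res = simulate(cfg)
        founders = res.truth[res.truth["generation"] == 0]
        assert founders["a_t"].var(ddof=1) == pytest.approx(4.0, rel=0.06)

    def test_offspring_is_parent_average_plus_mendelian_deviation(self):
        # with sigma2_a -> 0 Mendelian noise vanishes; use exact variance law
        cfg = _tiny(seed=8)
        res = simulate(cfg)
        ped, truth = res.pedigree, res.truth
        a = truth["a_t"].to_numpy()
        F = truth["F"].to_numpy()
        dev, dvar = [], []
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s == UNKNOWN or d == UNKNOWN:
                continue
            dev.append(a[i] - 0.5 * (a[s] + a[d]))
            dvar.append(0.5 - 0.25 * (F[s] + F[d]))
        dev, dvar = np.array(dev), np.array(dvar)
        # standardized deviations should be N(0, sigma2_a)
        z = dev / np.sqrt(dvar)
        assert z.var(ddof=1) == pytest.approx(1.0, rel=0.2)
        assert abs(z.mean()) < 0.1


class TestSelection:
    def test_true_bv_selection_raises_mean_breeding_value(self):
        base = dict(n_generations=4, n_sires=10, n_dams=40,
                    progeny_per_dam=6, n_hatches=2, seed=12)
        sel = SimulationConfig({"t": _truth()}, selection="true_bv",
                               selection_trait="t", selected_proportion=0.3,
                               **base)
        none = SimulationConfig({"t": _truth()}, **base)
        rs, rn = simulate(sel), simulate(none)
        def gain(res):
            t = res.truth
            return (t.loc[t["generation"] == 4, "a_t"].mean()
                    - t.loc[t["generation"] == 1, "a_t"].mean())
        assert gain(rs) > gain(rn) + 0.3

    def test_selection_requires_trait_when_ambiguous(self):
        with pytest.raises(ValueError, match="selection_trait"):
            SimulationConfig({"u": _truth(), "v": _truth()},
                             selection="phenotype")

    def test_selected_proportion_validated(self):
        with pytest.raises(ValueError):
            _tiny(selected_proportion=0.0)


class TestSimulatePhenotypesOnFixedPedigree:
    def test_reuses_pedigree_and_skips_founders(self):
        ped = simulate(_tiny(seed=3)).pedigree
        cfg = _tiny(seed=3)
        ph, truth, _ = simulate_phenotypes(ped, cfg, seed=99)
        assert len(ph) == (ped.generation > 0).sum()
        assert len(truth) == ped.n
        ph2, _, _ = simulate_phenotypes(ped, cfg, seed=99)
        assert ph.equals(ph2)
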