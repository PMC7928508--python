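"""Pedigree validation, relationship algebra and inbreeding."""

import numpy as np
import pandas as pd
import pytest

from pedigreml.pedigree import (
    PedigreeError, UNKNOWN, a_inverse, A_matvec, build_pedigree, inbreeding,
    inbreeding_report, logdet_A, read_pedigree, relationship_matrix,
    _gen_summary,
)
from conftest import random_pedigree


# ---------------------------------------------------------------------------
# Wright's path-counting oracle (independent of the tabular recursion)
# ---------------------------------------------------------------------------

def _paths_to_ancestors(ped, i):
    """All directed descent paths from animal i up to each ancestor,
    as (ancestor, frozenset of animals on the path, n_links)."""
    out = [(i, frozenset([i]), 0)]
    stack = [(i, frozenset([i]), 0)]
    while stack:
        node, path, length = stack.pop()
        for p in (ped.sire[node], ped.dam[node]):
            if p != UNKNOWN:
                entry = (p, path | {p}, length + 1)
                out.append(entry)
                stack.append(entry)
    return out


def wright_relationship(ped, i, j, _fmemo=None):
    """Numerator relationship by path counting:
    a_ij = sum over common ancestors A and pairs of paths meeting only at A
    of (1/2)^(L1+L2) (1 + F_A)."""
    fmemo = _fmemo if _fmemo is not None else {}

    def F(x):
        if x in fmemo:
            return fmemo[x]
        s, d = ped.sire[x], ped.dam[x]
        f = 0.0 if (s == UNKNOWN or d == UNKNOWN) else \
            0.5 * wright_relationship(ped, s, d, fmemo)
        fmemo[x] = f
        return f

    if i == j:
        return 1.0 + F(i)
    total = 0.0
    for anc1, set1, l1 in _paths_to_ancestors(ped, i):
        for anc2, set2, l2 in _paths_to_ancestors(ped, j):
            if anc1 == anc2 and set1 & set2 == {anc1}:
                total += 0.5 ** (l1 + l2) * (1.0 + F(anc1))
    return total


# ---------------------------------------------------------------------------
# construction and file reading
# ---------------------------------------------------------------------------

class TestBuildAndRead:
    def test_topological_order_puts_offspring_last(self, tmp_path):
        f = tmp_path / "ped.csv"
        f.write_text("animal,sire,dam\nx,s,d\ns,0,0\nd,0,0\n")
        ped = read_pedigree(f)
        assert len(ped) == 3
        assert ped.ids[-1] == "x"
        assert ped.sire[2] != UNKNOWN and ped.dam[2] != UNKNOWN

    def test_cycle_is_fatal(self, tmp_path):
        f = tmp_path / "ped.csv"
        f.write_text("animal,sire,dam\na,b,0\nb,c,0\nc,a,0\n")
        with pytest.raises(PedigreeError, match="cycle"):
            read_pedigree(f)

    def test_phantom_founder_inserted_and_revalidates(self, tmp_path):
        f = tmp_path / "ped.csv"
        f.write_text("animal,sire,dam,generation\n"
                     "d,0,0,2\nx,s,d,3\ny,s,d,3\n")
        ped = read_pedigree(f)
        assert len(ped) == 4
        i = ped.index["s"]
        assert ped.sire[i] == UNKNOWN and ped.dam[i] == UNKNOWN
        # phantom generation = min generation of its offspring - 1
        assert ped.generation[i] == 2
        # the returned pedigree is itself valid input
        rebuilt = build_pedigree(
            [(a, None if s == UNKNOWN else ped.ids[s],
              None if d == UNKNOWN else ped.ids[d], g, None)
             for a, s, d, g in zip(ped.ids, ped.sire, ped.dam,
                                   ped.generation)])
        assert len(rebuilt) == 4

    def test_undefined_parent_fatal_without_autoinsertion(self):
        with pytest.raises(PedigreeError, match="never defined"):
            build_pedigree([("x", "ghost", None, 1, None)],
                           auto_phantom=False)

    def test_generation_must_postdate_parents(self):
        with pytest.raises(PedigreeError, match="postdate"):
            build_pedigree([("s", None, None, 3), ("x", "s", None, 2)])


# ---------------------------------------------------------------------------
# A, A^-1 and F
# ---------------------------------------------------------------------------

class TestRelationshipMatrix:
    def test_founders_give_identity(self):
        ped = build_pedigree([(f"f{i}", None, None, 0) for i in range(6)])
        assert np.array_equal(relationship_matrix(ped), np.eye(6))
        assert np.allclose(a_inverse(ped).toarray(), np.eye(6))

    def test_trio_closed_form(self, trio):
        A = relationship_matrix(trio)
        assert A[0, 2] == A[1, 2] == 0.5
        assert A[0, 1] == 0.0
        assert A[2, 2] == 1.0
        Ainv = a_inverse(trio).toarray()
        assert np.allclose(np.diag(Ainv), [1.5, 1.5, 2.0])
        assert Ainv[0, 1] == pytest.approx(0.5)
        assert Ainv[0, 2] == Ainv[1, 2] == pytest.approx(-1.0)

    def test_fullsib_mating_offspring(self, fullsib_mating):
        A = relationship_matrix(fullsib_mating)
        F = inbreeding(fullsib_mating)
        assert F[-1] == 0.25
        assert A[-1, -1] == 1.25

    def test_matches_wright_path_counting(self, rng):
        ped = random_pedigree(rng, 30)
        A = relationship_matrix(ped)
        fmemo = {}
        for i in range(30):
            for j in range(i, 30):
                assert A[i, j] == pytest.approx(
                    wright_relationship(ped, i, j, fmemo), abs=1e-12)

    def test_inverse_matches_dense_inversion(self, rng):
        ped = random_pedigree(rng, 30)
        A = relationship_matrix(ped)
        assert np.allclose(a_inverse(ped).toarray(), np.linalg.inv(A),
                           atol=1e-10)

    @pytest.mark.parametrize("n", [50, 120, 200])
    def test_algebra_properties_on_random_pedigrees(self, rng, n):
        ped = random_pedigree(rng, n)
        A = relationship_matrix(ped)
        assert np.allclose(A, A.T)
        assert np.linalg.eigvalsh(A).min() >= -1e-8
        assert np.abs(a_inverse(ped) @ A - np.eye(n)).max() < 1e-8
        F = inbreeding(ped)
        assert np.abs(F - (np.diag(A) - 1)).max() < 1e-12
        v = rng.standard_normal(n)
        assert np.allclose(A_matvec(ped, v), A @ v)
        assert logdet_A(ped) == pytest.approx(np.linalg.slogdet(A)[1])

    def test_diagonal_and_offdiagonal_ranges(self, rng):
        ped = random_pedigree(rng, 100, p_unknown=0.02)
        A = relationship_matrix(ped)
        d = np.diag(A)
        assert ((d >= 1) & (d < 2)).all()
        off = A[~np.eye(100, dtype=bool)]
        assert ((off >= 0) & (off < 2)).all()


class TestInbreedingReport:
    def test_founders_have_zero_F(self):
        ped = build_pedigree([(f"f{i}", None, None, 0) for i in range(4)])
        assert (inbreeding(ped) == 0).all()

    def test_F_equals_diag_A_minus_one_larger(self, rng):
        ped = random_pedigree(rng, 200, p_unknown=0.05)
        A = relationship_matrix(ped)
        assert np.abs(inbreeding(ped) - (np.diag(A) - 1)).max() < 1e-12

    def test_delta_F_arithmetic(self):
        # mean-F sequence (0, 0, 0.007) -> rates (0, 0.007), mean 0.0035
        gen = np.repeat([0, 1, 2], 5)
        F = np.repeat([0.0, 0.0, 0.007], 5)
        g, mean = _gen_summary(gen, F)
        assert g["delta_F"].iloc[1] == pytest.approx(0.0)
        assert g["delta_F"].iloc[2] == pytest.approx(0.007)
        assert mean == pytest.approx(0.0035)

    def test_report_shapes_and_groupings(self, fullsib_mating):
        rep = inbreeding_report(fullsib_mating)
        assert len(rep.per_animal) == 5
        assert set(rep.by_generation.columns) >= {"generation", "n", "F_bar",
                                                  "delta_F"}
        # parents-only grouping excludes the inbred terminal offspring
        assert rep.by_generation_parents["n"].sum() == 4
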