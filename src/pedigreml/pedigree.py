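"""Pedigree data model and relationship algebra.

A pedigree is the substrate of every animal-model analysis: it defines the
numerator relationship matrix ``A`` (expected additive relationships between
animals), its sparse inverse (which enters the mixed-model equations), and
the inbreeding coefficients ``F`` (``diag(A) - 1``).

Animals are stored in topological order (parents before offspring) and
addressed internally by a dense 0-based index; identifiers are opaque
tokens.  Unknown parents are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: Tokens normalised to "unknown parent" when reading pedigree files.
UNKNOWN_CODES = {"", "0", "na", "NA", "nan", ".", "none", "None", "unknown"}

#: Internal sentinel for an unknown parent index.
UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents...)."""


@dataclass
class Pedigree:
    """Validated pedigree in topological (parents-first) order.

    Attributes
    ----------
    ids : ndarray of object
        Animal identifiers, one per animal, in topological order.
    sire, dam : ndarray of int
        Index of the sire/dam of each animal, or ``UNKNOWN`` (-1).
    generation : ndarray of int
        Generation label per animal (founders need not be generation 0).
    sex : ndarray of object
        ``"M"``, ``"F"`` or ``None`` per animal.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    sex: np.ndarray
    index: dict = field(repr=False, default=None)

    def __post_init__(self):
        if self.index is None:
            self.index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self) -> np.ndarray:
        """Boolean mask: both parents unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def parents_of(self, i: int) -> tuple[int, int]:
        return int(self.sire[i]), int(self.dam[i])

    def to_frame(self) -> pd.DataFrame:
        """Pedigree as a DataFrame with identifier columns (unknown -> '0')."""

        def tok(idx):
            return np.where(idx == UNKNOWN, "0", self.ids[np.maximum(idx, 0)])

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": tok(self.sire),
                "dam": tok(self.dam),
                "generation": self.generation,
                "sex": self.sex,
            }
        )


def _toposort(ids, sire_tok, dam_tok):
    """Topologically order animals so parents precede offspring.

    Returns the permutation, raising :class:`PedigreeError` with an
    offending chain if the parent relation is cyclic.
    """
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i, (s, d) in enumerate(zip(sire_tok, dam_tok)):
        for p in (s, d):
            if p is not None:
                children[pos[p]].append(i)
                indeg[i] += 1
    order, queue = [], [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(queue)
    while queue:
        i = heapq.heappop(queue)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(queue, c)
    if len(order) < n:
        stuck = [ids[i] for i in range(n) if indeg[i] > 0]
        raise PedigreeError(
            f"pedigree contains a cycle involving: {', '.join(map(str, stuck[:10]))}"
        )
    return order


def build_pedigree(
    records,
    *,
    auto_phantom: bool = True,
    validate_generations: bool = True,
) -> Pedigree:
    """Build a validated :class:`Pedigree` from raw records.

    Parameters
    ----------
    records : iterable of tuples
        ``(animal, sire, dam[, generation[, sex]])`` with ``None`` for an
        unknown parent / missing field.
    auto_phantom : bool
        Insert phantom founders for parents that never appear as animals
        (generation = min generation of their offspring minus one).  When
        off, such parents are a fatal error.
    validate_generations : bool
        Enforce that each animal's generation exceeds both parents'.
    """
    rows = []
    for rec in records:
        rec = tuple(rec) + (None,) * (5 - len(rec))
        animal, sire, dam, gen, sex = rec[:5]
        rows.append((animal, sire, dam, gen, sex))

    seen = {}
    for animal, *_ in rows:
        if animal in seen:
            raise PedigreeError(f"duplicate animal id {animal!r}")
        seen[animal] = True

    # phantom founders for parents never defined as animals
    parents_only = []
    for _, s, d, *_ in rows:
        for p in (s, d):
            if p is not None and p not in seen:
                if p not in parents_only:
                    parents_only.append(p)
    if parents_only:
        if not auto_phantom:
            raise PedigreeError(
                "parents referenced but never defined: "
                + ", ".join(map(str, parents_only[:10]))
            )
        child_gen = {}
        for a, s, d, g, _ in rows:
            for p in (s, d):
                if p in parents_only and g is not None:
                    child_gen[p] = min(child_gen.get(p, g), g)
        for p in parents_only:
            g = child_gen.get(p)
            rows.insert(0, (p, None, None, None if g is None else g - 1, None))
        logger.info("inserted %d phantom founders", len(parents_only))
        seen.update({p: True for p in parents_only})

    ids = [r[0] for r in rows]
    order = _toposort(ids, [r[1] for r in rows], [r[2] for r in rows])
    rows = [rows[i] for i in order]
    ids = np.array([r[0] for r in rows], dtype=object)
    pos = {a: i for i, a in enumerate(ids)}
    sire = np.array([UNKNOWN if r[1] is None else pos[r[1]] for r in rows])
    dam = np.array([UNKNOWN if r[2] is None else pos[r[2]] for r in rows])
    sex = np.array([r[4] for r in rows], dtype=object)

    gen = np.array([-1 if r[3] is None else int(r[3]) for r in rows])
    if (gen < 0).any():
        # infer missing generations: founders at 0 (or stated), else 1 + max(parent)
        for i in range(len(ids)):
            if gen[i] >= 0:
                continue
            pg = [gen[p] for p in (sire[i], dam[i]) if p != UNKNOWN]
            gen[i] = (max(pg) + 1) if pg else 0

    if validate_generations:
        for i in range(len(ids)):
            for p in (sire[i], dam[i]):
                if p != UNKNOWN and gen[i] <= gen[p]:
                    raise PedigreeError(
                        f"animal {ids[i]!r} (generation {gen[i]}) does not "
                        f"postdate its parent {ids[p]!r} (generation {gen[p]})"
                    )
    return Pedigree(ids=ids, sire=sire, dam=dam, generation=gen, sex=sex)


def read_pedigree(
    path,
    *,
    sep=None,
    auto_phantom: bool = True,
    columns=("animal", "sire", "dam", "generation", "sex"),
) -> Pedigree:
    """Read a delimited pedigree file into a validated :class:`Pedigree`.

    The file must have at least three columns (animal, sire, dam); optional
    generation and sex columns are used when present.  The delimiter is
    sniffed when ``sep`` is None.  Unknown parents may be coded as empty,
    ``0`` or ``NA``.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                     keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 3:
        raise PedigreeError(f"pedigree file {path} has fewer than 3 columns")
    # accept either named columns or positional layout
    lower = [c.lower() for c in cols]
    if "animal" in lower:
        df.columns = lower
    else:
        df.columns = list(columns[: len(cols)])

    def clean(tok):
        tok = str(tok).strip()
        return None if tok in UNKNOWN_CODES else tok

    records = []
    for _, row in df.iterrows():
        gen = row.get("generation")
        gen = None if gen is None or str(gen).strip() in UNKNOWN_CODES else int(float(gen))
        sex = row.get("sex")
        sex = None if sex is None or str(sex).strip() in UNKNOWN_CODES else str(sex).strip().upper()
        records.append((str(row["animal"]).strip(), clean(row["sire"]),
                        clean(row["dam"]), gen, sex))
    return build_pedigree(records, auto_phantom=auto_phantom)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# relationship algebra
# ---------------------------------------------------------------------------

def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Mendelian-sampling variance ``d_i`` per animal (in units of sigma2_a).

    ``d_i = 0.5 - 0.25 (F_s + F_d)`` with both parents known,
    ``0.75 - 0.25 F_p`` with one, and 1 for founders; these are the
    diagonal of ``D`` in the decomposition ``A = T D T'``.
    """
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    d = np.ones(n)
    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and dm != UNKNOWN:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s != UNKNOWN or dm != UNKNOWN:
            p = s if s != UNKNOWN else dm
            d[i] = 0.75 - 0.25 * F[p]
    return d


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix ``A`` by the tabular method.

    ``a_ii = 1 + 0.5 a_(s,d)`` and ``a_ij = 0.5 (a_(j,s) + a_(j,d))`` for
    ``j`` earlier in the topological order; unknown parents contribute 0.
    O(n^2) memory — intended for pedigrees up to a few thousand animals;
    the REML engine itself only ever uses the sparse inverse.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by ancestor tracing.

    Implements the sparse recursive algorithm of Meuwissen & Luo: for each
    non-founder, ``1 + F_i`` is accumulated as ``sum_j L_ij^2 d_j`` over the
    ancestors ``j`` of ``i``, where ``L`` is built by halving contributions
    up the pedigree.  Equals ``diag(A) - 1`` exactly.
    """
    n = ped.n
    F = np.zeros(n)
    d = np.ones(n)  # Mendelian variances filled in pedigree order
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, dm = sire[i], dam[i]
        if s != UNKNOWN and dm != UNKNOWN:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s != UNKNOWN or dm != UNKNOWN:
            d[i] = 0.75 - 0.25 * F[s if s != UNKNOWN else dm]
        if s == UNKNOWN or dm == UNKNOWN:
            F[i] = 0.0
            continue
        # trace ancestors of i, largest index first
        L = {i: 1.0}
        heap = [-i]
        in_heap = {i}
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            in_heap.discard(j)
            aii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    if p not in in_heap:
                        heapq.heappush(heap, -p)
                        in_heap.add(p)
        F[i] = aii - 1.0
    return F


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csc_matrix:
    """Sparse inverse of the numerator relationship matrix.

    Built by Henderson's recursive rules with Quaas' inbreeding adjustment:
    each animal contributes ``alpha = 1/d_i`` to at most 9 cells spanning
    itself and its known parents.
    """
    if F is None:
        F = inbreeding(ped)
    d = mendelian_variances(ped, F)
    n = ped.n
    rows, cols, vals = [], [], []
    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-alpha / 2, -alpha / 2]
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(alpha / 4)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return Ainv


def logdet_A(ped: Pedigree, F: np.ndarray | None = None) -> float:
    """``log|A| = sum_i log d_i`` from the ``A = T D T'`` decomposition."""
    return float(np.sum(np.log(mendelian_variances(ped, F))))


def A_matvec(ped: Pedigree, v: np.ndarray, d: np.ndarray | None = None) -> np.ndarray:
    """O(n) product ``A @ v`` via ``A = T D T'`` without forming ``A``.

    ``T' v`` accumulates halves up the pedigree (reverse order), ``T w``
    accumulates halves down; ``v`` may be a vector or a matrix of columns.
    """
    if d is None:
        d = mendelian_variances(ped)
    u = np.array(v, dtype=float, copy=True)
    sire, dam = ped.sire, ped.dam
    for i in range(ped.n - 1, -1, -1):
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                u[p] += 0.5 * u[i]
    w = (d * u.T).T
    for i in range(ped.n):
        s, dm = sire[i], dam[i]
        if s != UNKNOWN:
            w[i] += 0.5 * w[s]
        if dm != UNKNOWN:
            w[i] += 0.5 * w[dm]
    return w


# ---------------------------------------------------------------------------
# inbreeding report
# ---------------------------------------------------------------------------

@dataclass
class InbreedingReport:
    """Per-animal F plus per-generation means and rates of inbreeding."""

    per_animal: pd.DataFrame      # animal, generation, F
    by_generation: pd.DataFrame   # generation, n, F_bar, delta_F
    delta_F_mean: float
    #: same summary restricted to animals that appear as a parent
    by_generation_parents: pd.DataFrame = None
    delta_F_mean_parents: float = float("nan")


def _gen_summary(gen: np.ndarray, F: np.ndarray) -> tuple[pd.DataFrame, float]:
    df = pd.DataFrame({"generation": gen, "F": F})
    g = df.groupby("generation")["F"].agg(n="size", F_bar="mean").reset_index()
    fbar = g["F_bar"].to_numpy()
    dF = np.full(len(g), np.nan)
    dF[1:] = (fbar[1:] - fbar[:-1]) / (1.0 - fbar[:-1])
    g["delta_F"] = dF
    mean = float(np.nanmean(dF[1:])) if len(g) > 1 else float("nan")
    return g, mean


def inbreeding_report(ped: Pedigree) -> InbreedingReport:
    """Inbreeding coefficients with per-generation means and rates.

    ``delta_F_t = (F_bar_t - F_bar_{t-1}) / (1 - F_bar_{t-1})`` and the mean
    rate is the arithmetic mean over transitions.  Summaries are reported
    both over all animals and over parents only (animals with offspring),
    since selection schemes may differ between the two groups.
    """
    F = inbreeding(ped)
    per_animal = pd.DataFrame(
        {"animal": ped.ids, "generation": ped.generation, "F": F}
    )
    by_gen, mean = _gen_summary(ped.generation, F)
    is_parent = np.zeros(ped.n, dtype=bool)
    for arr in (ped.sire, ped.dam):
        known = arr[arr != UNKNOWN]
        is_parent[known] = True
    if is_parent.any():
        by_gen_p, mean_p = _gen_summary(ped.generation[is_parent], F[is_parent])
    else:
        by_gen_p, mean_p = by_gen.iloc[:0], float("nan")
    return InbreedingReport(
        per_animal=per_animal,
        by_generation=by_gen,
        delta_F_mean=mean,
        by_generation_parents=by_gen_p,
        delta_F_mean_parents=mean_p,
    )
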