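"""Average-information REML engine for pedigree mixed models.

The engine maximises the restricted log-likelihood of a Gaussian mixed
model

    y = X beta + sum_t Z_t u_t + e,

where each random term ``t`` groups ``s`` correlated effect sets (e.g. the
direct and maternal genetic effects of one trait, or the same effect for
two traits) with covariance ``Sigma_t (x) K_t``; ``K_t`` is either the
numerator relationship matrix ``A`` (applied through its sparse inverse and
the ``A = T D T'`` recursion, never formed densely) or an identity.

The restricted log-likelihood is evaluated exactly through the mixed-model
equations (MME):

    -2 logL = (n - p) log 2pi + log|R| + log|G| + log|C| + y'Py,

with ``C`` the full MME coefficient matrix and ``y'Py = y'R^-1 y - sol'rhs``.
Each evaluation is one sparse LU factorisation.  Updates are Newton steps
using the average-information (AI) matrix as curvature, gradients by central
finite differences of the exact likelihood, step halving onto the parameter
space, and monotonicity enforced by accepting a step only when the
likelihood does not decrease.  Standard errors come from the inverse of the
final AI matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .pedigree import Pedigree, logdet_A, mendelian_variances

logger = logging.getLogger(__name__)

#: lower bound on a variance, as a fraction of the phenotypic variance
VARIANCE_FLOOR_FRAC = 1e-6
#: covariances are shrunk so that 2x2 blocks keep |rho| below this
MAX_ABS_CORR = 0.9999


@dataclass
class RandomTerm:
    """One (possibly multi-set) random term of the model.

    ``Zs`` holds one design matrix per correlated effect set, each mapping
    the stacked records to the q levels of the term; the effect sets share
    the level space and have an s x s (co)variance matrix ``Sigma`` with
    ``Var(u) = Sigma (x) K``.
    """

    name: str
    Zs: list                     # list of (n_rec x q) sparse matrices
    labels: list                 # one label per effect set, e.g. ["a", "m"]
    ped: Pedigree | None = None  # K = A when a pedigree is given, else I
    free_cov: bool = False       # fit the off-diagonal(s) of Sigma?

    @property
    def s(self) -> int:
        return len(self.Zs)

    @property
    def q(self) -> int:
        return self.Zs[0].shape[1]


class Residual:
    """Residual covariance structure.

    Represented on a basis of constant sparse n x n pattern matrices so
    that ``R``, ``R^-1`` and the derivative patterns are all linear
    combinations with scalar coefficients.  Univariate: ``R = sigma2_e I``.
    Two-trait: per-animal 2x2 blocks for animals recorded on both traits,
    scalars for the rest.
    """

    def __init__(self, n_rec: int):
        self.n_rec = n_rec

    # -- univariate ---------------------------------------------------------
    @classmethod
    def univariate(cls, n_rec: int) -> "Residual":
        r = cls(n_rec)
        r.kind = "uni"
        r.param_labels = ["e"]
        return r

    # -- two traits ---------------------------------------------------------
    @classmethod
    def bivariate(cls, n1: int, n2: int, pair_idx: np.ndarray,
                  free_cov: bool = True) -> "Residual":
        """``pair_idx``: (k, 2) array of record indices (trait-1, trait-2)
        belonging to the same animal; remaining records are singles."""
        r = cls(n1 + n2)
        r.kind = "biv"
        r.n1, r.n2 = n1, n2
        r.pair1 = pair_idx[:, 0] if len(pair_idx) else np.array([], dtype=int)
        r.pair2 = pair_idx[:, 1] if len(pair_idx) else np.array([], dtype=int)
        paired = np.zeros(r.n_rec, dtype=bool)
        paired[r.pair1] = True
        paired[r.pair2] = True
        slot = np.zeros(r.n_rec, dtype=int)
        slot[n1:] = 1
        r.slot = slot
        r.single1 = np.where(~paired & (slot == 0))[0]
        r.single2 = np.where(~paired & (slot == 1))[0]
        r.free_cov = free_cov and len(r.pair1) > 0
        r.param_labels = ["e1", "e2"] + (["cov_e"] if r.free_cov else [])
        return r

    # parameters: univariate [s2e]; bivariate [s2e1, s2e2, (cov_e)]
    @property
    def n_params(self) -> int:
        return len(self.param_labels)

    def _blocks(self, theta):
        if self.kind == "uni":
            return None
        s11, s22 = theta[0], theta[1]
        s12 = theta[2] if self.free_cov else 0.0
        return s11, s22, s12

    def rinv_coeffs(self, theta):
        """Coefficients of R^-1 on (pair11, pair12, pair22, single1, single2)."""
        s11, s22, s12 = self._blocks(theta)
        det = s11 * s22 - s12 * s12
        return (s22 / det, -s12 / det, s11 / det, 1.0 / s11, 1.0 / s22)

    def rinv_apply(self, theta, v):
        """R^-1 v for a vector or column-stack of vectors."""
        if self.kind == "uni":
            return v / theta[0]
        c11, c12, c22, c1, c2 = self.rinv_coeffs(theta)
        out = np.zeros_like(v, dtype=float)
        p1, p2 = self.pair1, self.pair2
        out[p1] = c11 * v[p1] + c12 * v[p2]
        out[p2] = c12 * v[p1] + c22 * v[p2]
        out[self.single1] = c1 * v[self.single1]
        out[self.single2] = c2 * v[self.single2]
        return out

    def logdet(self, theta) -> float:
        if self.kind == "uni":
            return self.n_rec * np.log(theta[0])
        s11, s22, s12 = self._blocks(theta)
        det = s11 * s22 - s12 * s12
        return (len(self.pair1) * np.log(det)
                + len(self.single1) * np.log(s11)
                + len(self.single2) * np.log(s22))

    def dR_apply(self, j, v):
        """(dR/dtheta_j) v — a pure pattern operation."""
        if self.kind == "uni":
            return v.copy()
        out = np.zeros_like(v, dtype=float)
        if self.param_labels[j] == "e1":
            m = np.concatenate([self.pair1, self.single1])
            out[m] = v[m]
        elif self.param_labels[j] == "e2":
            m = np.concatenate([self.pair2, self.single2])
            out[m] = v[m]
        else:  # cov_e: swap within pairs
            out[self.pair1] = v[self.pair2]
            out[self.pair2] = v[self.pair1]
        return out

    def init_theta(self, y, frac):
        if self.kind == "uni":
            return np.array([frac * np.var(y)])
        v1 = np.var(y[self.slot == 0]) if (self.slot == 0).any() else 1.0
        v2 = np.var(y[self.slot == 1]) if (self.slot == 1).any() else 1.0
        th = [frac * v1, frac * v2]
        if self.free_cov:
            th.append(0.0)
        return np.array(th)


@dataclass
class ParamInfo:
    """Location of one free parameter: which term/residual, which Sigma cell."""
    kind: str          # "term" or "resid"
    term: int          # term index (ignored for resid)
    i: int
    j: int
    label: str
    is_variance: bool


@dataclass
class REMLOptions:
    tol_logl: float = 5e-4        # |delta logL| convergence threshold
    tol_param: float = 1e-4       # relative parameter-change threshold
    max_iter: int = 200
    accept_drop: float = 1e-8     # largest tolerated likelihood decrease
    fd_rel_step: float = 1e-5
    verbose: bool = False


@dataclass
class REMLState:
    theta: np.ndarray
    logl: float
    sol: np.ndarray
    Py: np.ndarray
    lu: object
    rhs: np.ndarray


@dataclass
class REMLResult:
    theta: np.ndarray
    se: np.ndarray
    logl: float
    converged: bool
    n_iter: int
    beta: np.ndarray
    u: dict                       # term name -> (q, s) array of solutions
    param_labels: list
    ai: np.ndarray
    ai_inv: np.ndarray
    at_boundary: np.ndarray


class REMLProblem:
    """Assembled REML problem: data, design, random terms, residual."""

    def __init__(self, y, X, terms: list[RandomTerm], residual: Residual):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        # drop linearly dependent fixed-effect columns (pivoted QR)
        q, r, piv = _qr_colpivot(X)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-8 * max(abs(r[0, 0]), 1)))
        self.x_keep = np.sort(piv[:rank])
        self.X = X[:, self.x_keep]
        self.y = y
        self.n, self.p = self.X.shape
        self.terms = terms
        self.residual = residual

        blocks = [sparse.csr_matrix(self.X)]
        self._slices = []
        off = self.p
        for t in terms:
            sl = []
            for Z in t.Zs:
                blocks.append(sparse.csr_matrix(Z))
                sl.append(slice(off, off + t.q))
                off += t.q
            self._slices.append(sl)
        self.W = sparse.hstack(blocks, format="csc")
        self.dim = off
        self.Wt = self.W.T.tocsr()

        # pedigree constants
        self._ped_cache = {}
        for t in terms:
            if t.ped is not None and id(t.ped) not in self._ped_cache:
                from .pedigree import a_inverse, inbreeding
                F = inbreeding(t.ped)
                d = mendelian_variances(t.ped, F)
                self._ped_cache[id(t.ped)] = {
                    "Ainv": a_inverse(t.ped, F),
                    "logdetA": float(np.sum(np.log(d))),
                    "d": d,
                }

        # free-parameter map
        self.params: list[ParamInfo] = []
        for ti, t in enumerate(terms):
            for i in range(t.s):
                self.params.append(ParamInfo("term", ti, i, i,
                                             f"{t.name}:{t.labels[i]}", True))
            if t.free_cov:
                for i in range(t.s):
                    for j in range(i + 1, t.s):
                        self.params.append(ParamInfo(
                            "term", ti, i, j,
                            f"{t.name}:cov({t.labels[i]},{t.labels[j]})", False))
        for j, lab in enumerate(residual.param_labels):
            self.params.append(ParamInfo("resid", -1, j, j, f"resid:{lab}",
                                         not lab.startswith("cov")))
        self.n_params = len(self.params)
        self.var_floor = VARIANCE_FLOOR_FRAC * float(np.var(y))

    # ------------------------------------------------------------------
    def _split(self, theta):
        """theta -> (list of Sigma matrices per term, residual theta)."""
        sigmas = []
        k = 0
        for t in self.terms:
            S = np.zeros((t.s, t.s))
            for i in range(t.s):
                S[i, i] = theta[k]; k += 1
            if t.free_cov:
                for i in range(t.s):
                    for j in range(i + 1, t.s):
                        S[i, j] = S[j, i] = theta[k]; k += 1
            sigmas.append(S)
        return sigmas, theta[k:]

    def project(self, theta):
        """Clamp variances to the floor and shrink covariances to keep every
        2x2 block comfortably positive definite."""
        theta = np.array(theta, dtype=float)
        for k, p in enumerate(self.params):
            if p.is_variance and theta[k] < self.var_floor:
                theta[k] = self.var_floor
        sigmas, _ = self._split(theta)
        k = 0
        for ti, t in enumerate(self.terms):
            k += t.s
            if t.free_cov:
                S = sigmas[ti]
                for i in range(t.s):
                    for j in range(i + 1, t.s):
                        lim = MAX_ABS_CORR * np.sqrt(S[i, i] * S[j, j])
                        theta[k] = np.clip(theta[k], -lim, lim)
                        k += 1
        # residual block
        r = self.residual
        base = k
        if r.kind == "biv" and r.free_cov:
            lim = MAX_ABS_CORR * np.sqrt(theta[base] * theta[base + 1])
            theta[base + 2] = np.clip(theta[base + 2], -lim, lim)
        return theta

    # ------------------------------------------------------------------
    def _assemble(self, theta):
        sigmas, th_r = self._split(theta)
        Rinv_y = self.residual.rinv_apply(th_r, self.y)
        WtRW = self._wtrw(th_r)
        logdetG = 0.0
        ginv_blocks = [sparse.csr_matrix((self.p, self.p))]
        for ti, t in enumerate(self.terms):
            S = sigmas[ti]
            Sinv = np.linalg.inv(S)
            sign, ld = np.linalg.slogdet(S)
            if sign <= 0:
                raise FloatingPointError("Sigma block not positive definite")
            if t.ped is not None:
                K_inv = self._ped_cache[id(t.ped)]["Ainv"]
                logdetG += t.q * ld + t.s * self._ped_cache[id(t.ped)]["logdetA"]
            else:
                K_inv = sparse.identity(t.q, format="csc")
                logdetG += t.q * ld
            ginv_blocks.append(sparse.kron(sparse.csr_matrix(Sinv), K_inv))
        C = (WtRW + sparse.block_diag(ginv_blocks, format="csc")).tocsc()
        rhs = self.Wt @ Rinv_y
        lu = splu(C, permc_spec="MMD_AT_PLUS_A",
                  options={"SymmetricMode": True})
        sol = lu.solve(rhs)
        logdetC = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        yRy = float(self.y @ Rinv_y)
        yPy = yRy - float(sol @ rhs)
        logdetR = self.residual.logdet(th_r)
        logl = -0.5 * (logdetR + logdetG + logdetC + yPy
                       + (self.n - self.p) * np.log(2 * np.pi))
        resid = self.y - self.W @ sol
        Py = self.residual.rinv_apply(th_r, resid)
        return REMLState(theta=theta, logl=logl, sol=sol, Py=Py, lu=lu, rhs=rhs)

    def _wtrw(self, th_r):
        r = self.residual
        if r.kind == "uni":
            if not hasattr(self, "_WtW"):
                self._WtW = (self.Wt @ self.W).tocsc()
            return self._WtW / th_r[0]
        if not hasattr(self, "_rbasis"):
            n = r.n_rec
            def diagm(idx):
                v = np.zeros(n)
                v[idx] = 1.0
                return sparse.diags(v)
            S = sparse.coo_matrix(
                (np.ones(2 * len(r.pair1)),
                 (np.concatenate([r.pair1, r.pair2]),
                  np.concatenate([r.pair2, r.pair1]))), shape=(n, n))
            basis = [diagm(r.pair1), S.tocsr(), diagm(r.pair2),
                     diagm(r.single1), diagm(r.single2)]
            self._rbasis = [(self.Wt @ B @ self.W).tocsc() for B in basis]
        c = r.rinv_coeffs(th_r)
        return sum(ci * B for ci, B in zip(c, self._rbasis)).tocsc()

    def loglik(self, theta) -> float:
        return self._assemble(theta).logl

    def eval(self, theta) -> REMLState:
        return self._assemble(theta)

    # ------------------------------------------------------------------
    def _K_apply(self, t: RandomTerm, v):
        if t.ped is None:
            return v
        from .pedigree import A_matvec
        return A_matvec(t.ped, v, self._ped_cache[id(t.ped)]["d"])

    def _f_vectors(self, theta, state: REMLState):
        """f_k = (dV/dtheta_k) P y for every free parameter."""
        sigmas, th_r = self._split(theta)
        Py = state.Py
        fs = []
        for p in self.params:
            if p.kind == "term":
                t = self.terms[p.term]
                zi, zj = t.Zs[p.i], t.Zs[p.j]
                f = zi @ self._K_apply(t, zj.T @ Py)
                if p.i != p.j:
                    f = f + zj @ self._K_apply(t, zi.T @ Py)
                fs.append(f)
            else:
                fs.append(self.residual.dR_apply(p.i, Py))
        return fs

    def ai_matrix(self, theta, state: REMLState) -> np.ndarray:
        """Average-information matrix 0.5 F' P F using the stored MME factor."""
        _, th_r = self._split(theta)
        fs = self._f_vectors(theta, state)
        F = np.column_stack(fs)
        RinvF = self.residual.rinv_apply(th_r, F)
        rhs = self.Wt @ RinvF
        sol = np.column_stack([state.lu.solve(rhs[:, k])
                               for k in range(rhs.shape[1])])
        PF = self.residual.rinv_apply(th_r, F - self.W @ sol)
        return 0.5 * (F.T @ PF)

    def gradient(self, theta, state: REMLState, rel_step=1e-5) -> np.ndarray:
        """Central finite-difference gradient of the exact logL."""
        g = np.zeros(self.n_params)
        scale = max(self.var_floor / VARIANCE_FLOOR_FRAC, 1e-12)
        for k in range(self.n_params):
            h = rel_step * max(abs(theta[k]), 1e-3 * scale)
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            tm = self.project(tm)
            tp = self.project(tp)
            denom = tp[k] - tm[k]
            if denom == 0:
                g[k] = 0.0
                continue
            g[k] = (self.loglik(tp) - self.loglik(tm)) / denom
        return g

    # ------------------------------------------------------------------
    def fit(self, theta0, options: REMLOptions | None = None) -> REMLResult:
        opt = options or REMLOptions()
        theta = self.project(np.asarray(theta0, dtype=float))
        state = self.eval(theta)
        converged = False
        it = 0
        ai = np.eye(self.n_params)
        for it in range(1, opt.max_iter + 1):
            g = self.gradient(theta, state, opt.fd_rel_step)
            ai = self.ai_matrix(theta, state)
            # active set: variances pinned at the floor whose gradient pushes
            # them further down are frozen, and the Newton step is taken in
            # the free subspace only
            active = np.array(
                [p.is_variance and theta[k] <= self.var_floor * (1 + 1e-9)
                 and g[k] < 0 for k, p in enumerate(self.params)])
            free = ~active
            step = np.zeros(self.n_params)
            if free.any():
                step[free] = _solve_newton(ai[np.ix_(free, free)], g[free])

            def try_direction(direction):
                lam = 1.0
                for _ in range(30):
                    cand = self.project(theta + lam * direction)
                    try:
                        cand_state = self.eval(cand)
                    except (FloatingPointError, RuntimeError, ValueError):
                        lam *= 0.5
                        continue
                    if cand_state.logl >= state.logl - opt.accept_drop:
                        return cand_state
                    lam *= 0.5
                return None

            new_state = try_direction(step)
            if new_state is None and free.any():
                # fall back to gradient ascent in the free subspace
                gstep = np.where(free, g, 0.0)
                scale = np.max(np.abs(gstep))
                if scale > 0:
                    gstep *= 0.1 * max(np.max(np.abs(theta)),
                                       self.var_floor) / scale
                    new_state = try_direction(gstep)
            if new_state is None:
                logger.debug("REML stalled at iteration %d", it)
                converged = True  # no uphill direction left
                break
            d_logl = new_state.logl - state.logl
            denom = np.maximum(np.abs(theta), self.var_floor)
            d_par = float(np.max(np.abs(new_state.theta - theta) / denom))
            theta, state = new_state.theta, new_state
            if opt.verbose:
                logger.info("iter %3d  logL=%.6f  dlogL=%.2e  dpar=%.2e",
                            it, state.logl, d_logl, d_par)
            if abs(d_logl) < opt.tol_logl and d_par < opt.tol_param:
                converged = True
                break

        ai = self.ai_matrix(theta, state)
        at_boundary = np.array(
            [p.is_variance and theta[k] <= self.var_floor * (1 + 1e-9)
             for k, p in enumerate(self.params)])
        ai_inv, se = _ai_standard_errors(ai, at_boundary)
        beta = state.sol[: self.p]
        u = {}
        for ti, t in enumerate(self.terms):
            u[t.name] = np.column_stack(
                [state.sol[sl] for sl in self._slices[ti]])
        return REMLResult(theta=theta, se=se, logl=state.logl,
                          converged=converged, n_iter=it, beta=beta, u=u,
                          param_labels=[p.label for p in self.params],
                          ai=ai, ai_inv=ai_inv, at_boundary=at_boundary)


def _qr_colpivot(X):
    from scipy.linalg import qr
    return qr(X, mode="economic", pivoting=True)


def _solve_newton(ai, g):
    p = len(g)
    ridge = 1e-8 * (np.trace(ai) / p if p else 1.0)
    for _ in range(12):
        try:
            return np.linalg.solve(ai + ridge * np.eye(p), g)
        except np.linalg.LinAlgError:
            ridge *= 10
    return g / max(np.trace(ai) / p, 1e-12)


def _ai_standard_errors(ai, at_boundary):
    p = len(at_boundary)
    se = np.full(p, np.nan)
    ai_inv = np.full((p, p), np.nan)
    free = ~at_boundary
    if free.any():
        sub = ai[np.ix_(free, free)]
        try:
            inv = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(sub)
        ai_inv[np.ix_(free, free)] = inv
        d = np.diag(inv).copy()
        d[d < 0] = np.nan
        se[free] = np.sqrt(d)
    return ai_inv, se
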