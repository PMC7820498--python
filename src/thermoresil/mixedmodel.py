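"""Sparse mixed-model machinery: REML likelihood, AI updates, BLUP.

The models fitted throughout the package share one algebraic shape,

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, M_k (x) K_k),   e ~ N(0, R),

where each random term k groups observations into levels (animals), every
observation carries an m_k-dimensional design row into its level's
coefficient block (a scalar 1 for a plain animal effect, a Legendre basis
row for a random-regression coefficient vector), ``K_k`` is an
unstructured m_k x m_k covariance to be estimated and ``M_k`` a *known*
correlation structure across levels — identity for i.i.d. animal curves,
the numerator relationship matrix A for pedigree terms (supplied through
its sparse inverse).  The residual is either i.i.d. scalar or, for
multi-trait models, block-diagonal by unit (animal) with an unstructured
trait covariance ``R0`` and missing-trait patterns handled by
sub-matrices.

Estimation is restricted maximum likelihood.  The REML log-likelihood is
evaluated exactly through the mixed-model equations,

    -2 l_R = const + log|R| + log|G| + log|C| + y' P y,

with the coefficient matrix C factorised by sparse LU (its
log-determinant read off the U diagonal; C is symmetric positive
definite).  Updates use the average-information (AI) matrix, computed
exactly from working variates — each parameter's variate costs one
back-solve with the already-factorised C — while the score vector is
obtained by central finite differences of the exact log-likelihood.
Steps that leave the parameter space (a covariance matrix losing positive
definiteness) are halved and, if necessary, projected back by eigenvalue
clipping, which lets variance components settle on the zero boundary
without derailing the iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "RandomTerm",
    "MultiTraitResidual",
    "MixedModelFit",
    "ConvergenceError",
    "fit_reml",
    "design_from_factors",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the log-likelihood trajectory."""

    def __init__(self, message: str, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


# ---------------------------------------------------------------------------
# model specification


@dataclass
class RandomTerm:
    """One random effect: ``u ~ N(0, M (x) K)`` over grouped levels.

    Parameters
    ----------
    name : str
        Label used in reports.
    groups : (n_obs,) int array
        Level index of each observation, in ``0..n_levels-1``.
    design : (n_obs, m) array
        Within-level design row of each observation.
    n_levels : int
        Number of levels (animals).  May exceed ``groups.max()+1`` when
        unphenotyped pedigree animals carry coefficients.
    corr_inv : sparse matrix or None
        ``M^{-1}`` across levels (e.g. the pedigree A-inverse); ``None``
        means identity.
    corr_logdet : float
        ``log|M|`` (0 for identity).
    k_start : (m, m) array or None
        Starting covariance; a default is derived from ``var(y)`` if None.
    """

    name: str
    groups: np.ndarray
    design: np.ndarray
    n_levels: int
    corr_inv: sp.spmatrix | None = None
    corr_logdet: float = 0.0
    k_start: np.ndarray | None = None

    def __post_init__(self):
        self.groups = np.asarray(self.groups, dtype=np.int64)
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.design.shape[0] != self.groups.shape[0]:
            raise ValueError(f"term {self.name}: design rows != n_obs")

    @property
    def m(self) -> int:
        return self.design.shape[1]

    def z_matrix(self) -> sp.csr_matrix:
        n_obs, m = self.design.shape
        rows = np.repeat(np.arange(n_obs), m)
        cols = (self.groups[:, None] * m + np.arange(m)[None, :]).ravel()
        return sp.coo_matrix(
            (self.design.ravel(), (rows, cols)),
            shape=(n_obs, self.n_levels * m),
        ).tocsr()


@dataclass
class MultiTraitResidual:
    """Block-diagonal residual with an unstructured trait covariance.

    Observations sharing ``units[i]`` form one block; ``traits[i]`` indexes
    the row/column of ``R0`` each observation occupies.  An animal
    measured for a subset of traits simply contributes a smaller block
    (the sub-matrix of ``R0`` on its observed traits).
    """

    units: np.ndarray
    traits: np.ndarray
    n_traits: int
    r_start: np.ndarray | None = None

    def __post_init__(self):
        self.units = np.asarray(self.units, dtype=np.int64)
        self.traits = np.asarray(self.traits, dtype=np.int64)
        order = np.lexsort((self.traits, self.units))
        if not np.array_equal(order, np.arange(len(self.units))):
            raise ValueError("observations must be sorted by unit then trait")


# ---------------------------------------------------------------------------
# parameter packing

def _tril_indices(m: int):
    return np.tril_indices(m)


def _pack(mats: list[np.ndarray]) -> np.ndarray:
    out = []
    for k in mats:
        i, j = _tril_indices(k.shape[0])
        out.append(k[i, j])
    return np.concatenate(out)


def _unpack(theta: np.ndarray, dims: list[int]) -> list[np.ndarray]:
    mats, pos = [], 0
    for m in dims:
        nfree = m * (m + 1) // 2
        k = np.zeros((m, m))
        i, j = _tril_indices(m)
        k[i, j] = theta[pos:pos + nfree]
        k[j, i] = k[i, j]
        mats.append(k)
        pos += nfree
    return mats


def _is_pd(k: np.ndarray, floor: float) -> bool:
    try:
        w = np.linalg.eigvalsh(k)
    except np.linalg.LinAlgError:
        return False
    return bool(w.min() >= floor)


def _project_pd(k: np.ndarray, floor: float) -> np.ndarray:
    w, v = np.linalg.eigh(k)
    return (v * np.maximum(w, floor)) @ v.T


# ---------------------------------------------------------------------------
# likelihood engine


class _Engine:
    """Caches the pieces of the MME that do not change with theta."""

    def __init__(self, y, x, terms, residual):
        self.y = np.asarray(y, dtype=float)
        self.n = len(self.y)
        if sp.issparse(x):
            x = x.tocsr()
        else:
            x = sp.csr_matrix(np.atleast_2d(np.asarray(x, dtype=float)))
        self.x = x
        self.p = x.shape[1]
        self.terms = terms
        self.residual = residual
        self.zs = [t.z_matrix() for t in terms]
        self.w = sp.hstack([x] + self.zs, format="csr") if terms else x.tocsr()
        self.dim = self.w.shape[1]
        self.dims = [t.m for t in terms]
        self.scalar_resid = residual is None
        if self.scalar_resid:
            self.wtw = (self.w.T @ self.w).tocsc()
            self.wty = self.w.T @ self.y
            self.yty = float(self.y @ self.y)
        else:
            self._build_blocks()
        # slices of the solution vector
        self.slices, pos = [], self.p
        for t in terms:
            self.slices.append(slice(pos, pos + t.n_levels * t.m))
            pos += t.n_levels * t.m

    def _build_blocks(self):
        r = self.residual
        uniq, starts = np.unique(r.units, return_index=True)
        bounds = np.append(starts, len(r.units))
        self.block_slices = [slice(bounds[i], bounds[i + 1])
                             for i in range(len(uniq))]
        self.block_patterns = [tuple(r.traits[s]) for s in self.block_slices]
        self.uniq_patterns = sorted(set(self.block_patterns))
        # precompute the (row, col) scatter of block-diagonal R^-1 and, per
        # pattern, the positions its inverse values occupy — the sparsity
        # never changes across iterations, only the values do
        rows, cols = [], []
        pat_positions = {p: [] for p in self.uniq_patterns}
        pos = 0
        for s, pat in zip(self.block_slices, self.block_patterns):
            k = s.stop - s.start
            rr, cc = np.meshgrid(np.arange(s.start, s.stop),
                                 np.arange(s.start, s.stop), indexing="ij")
            rows.append(rr.ravel())
            cols.append(cc.ravel())
            pat_positions[pat].append(np.arange(pos, pos + k * k))
            pos += k * k
        self._rinv_rows = np.concatenate(rows)
        self._rinv_cols = np.concatenate(cols)
        self._rinv_npos = pos
        self._pat_positions = {p: np.concatenate(v)
                               for p, v in pat_positions.items()}
        self._pat_counts = {p: len(v) for p, v in pat_positions.items()}

    # -- residual pieces -----------------------------------------------------

    def _rinv(self, r0: np.ndarray):
        """Sparse R^-1 and log|R| for the multi-trait residual."""
        vals = np.empty(self._rinv_npos)
        logdet = 0.0
        for pat in self.uniq_patterns:
            idx = np.asarray(pat)
            sub = r0[np.ix_(idx, idx)]
            sign, ld = np.linalg.slogdet(sub)
            if sign <= 0:
                return None, None
            inv = np.linalg.inv(sub)
            vals[self._pat_positions[pat]] = np.tile(inv.ravel(),
                                                     self._pat_counts[pat])
            logdet += ld * self._pat_counts[pat]
        rinv = sp.coo_matrix(
            (vals, (self._rinv_rows, self._rinv_cols)),
            shape=(self.n, self.n)).tocsr()
        return rinv, logdet

    def _ginv_aug(self, ks: list[np.ndarray]):
        """Augmented G^-1 (zero block for fixed effects) and log|G|."""
        blocks = [sp.csr_matrix((self.p, self.p))]
        logdet = 0.0
        for t, k in zip(self.terms, ks):
            sign, ldk = np.linalg.slogdet(k)
            if sign <= 0:
                return None, None
            kinv = np.linalg.inv(k)
            minv = t.corr_inv if t.corr_inv is not None \
                else sp.identity(t.n_levels, format="csr")
            blocks.append(sp.kron(minv, sp.csr_matrix(kinv), format="csr"))
            logdet += t.m * t.corr_logdet + t.n_levels * ldk
        return sp.block_diag(blocks, format="csc"), logdet

    # -- likelihood ----------------------------------------------------------

    def loglik(self, ks, r0, want_solution=False):
        """REML log-likelihood; optionally also (lu, solution, rinv)."""
        ginv, logdet_g = self._ginv_aug(ks)
        if ginv is None:
            return (-np.inf, None) if want_solution else -np.inf
        if self.scalar_resid:
            s2 = float(r0[0, 0])
            if s2 <= 0:
                return (-np.inf, None) if want_solution else -np.inf
            c = (self.wtw / s2 + ginv).tocsc()
            rhs = self.wty / s2
            ytry = self.yty / s2
            logdet_r = self.n * np.log(s2)
            rinv = None
        else:
            rinv, logdet_r = self._rinv(r0)
            if rinv is None:
                return (-np.inf, None) if want_solution else -np.inf
            rw = rinv @ self.w
            c = (self.w.T @ rw + ginv).tocsc()
            rhs = self.w.T @ (rinv @ self.y)
            ytry = float(self.y @ (rinv @ self.y))
        try:
            # minimum-degree on C + C' suits the symmetric MME structure
            lu = splu(c, permc_spec="MMD_AT_PLUS_A")
        except RuntimeError:
            return (-np.inf, None) if want_solution else -np.inf
        logdet_c = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        sol = lu.solve(rhs)
        ypy = ytry - float(rhs @ sol)
        m2l = ((self.n - self.p) * _LOG2PI + logdet_r + logdet_g
               + logdet_c + ypy)
        ll = -0.5 * m2l
        if not np.isfinite(ll):
            ll = -np.inf
        if want_solution:
            return ll, (lu, sol, rinv)
        return ll

    # -- average information -------------------------------------------------

    def _apply_p(self, f, lu, rinv):
        """P f = R^-1 f - R^-1 W C^-1 W' R^-1 f."""
        g = rinv @ f
        wtg = self.w.T @ g
        return g - rinv @ (self.w @ lu.solve(wtg))

    def working_variates(self, ks, r0, lu, sol, rinv):
        """One column dV/dtheta_i * Py per free parameter."""
        if self.scalar_resid:
            s2 = float(r0[0, 0])
            rinv = sp.identity(self.n, format="csr") / s2
        py = rinv @ (self.y - self.w @ sol)
        cols = []
        for t, k, zsl, z in zip(self.terms, ks, self.slices, self.zs):
            kinv = np.linalg.inv(k)
            u = sol[zsl].reshape(t.n_levels, t.m)
            i_idx, j_idx = _tril_indices(t.m)
            for r, c in zip(i_idx, j_idx):
                de = np.zeros((t.m, t.m))
                de[r, c] = de[c, r] = 1.0
                b = de @ kinv
                v = (u @ b.T)  # per-level transformed coefficients
                cols.append(np.einsum("ij,ij->i", t.design, v[t.groups]))
        if self.scalar_resid:
            cols.append(py.copy())
        else:
            nt = self.residual.n_traits
            i_idx, j_idx = _tril_indices(nt)
            tr = self.residual.traits
            for r, c in zip(i_idx, j_idx):
                f = np.zeros(self.n)
                for s in self.block_slices:
                    t_blk = tr[s]
                    de = ((t_blk[:, None] == r) & (t_blk[None, :] == c)
                          ).astype(float)
                    de = de + de.T if r != c else de
                    f[s] = de @ py[s]
                cols.append(f)
        return np.column_stack(cols), py

    def ai_matrix(self, ks, r0, lu, sol, rinv):
        if self.scalar_resid:
            s2 = float(r0[0, 0])
            rinv = sp.identity(self.n, format="csr") / s2
        fmat, _ = self.working_variates(ks, r0, lu, sol,
                                        rinv if not self.scalar_resid else None)
        pf = np.column_stack([self._apply_p(fmat[:, j], lu, rinv)
                              for j in range(fmat.shape[1])])
        return 0.5 * (fmat.T @ pf)


# ---------------------------------------------------------------------------
# fit result


@dataclass
class MixedModelFit:
    """Converged REML fit: components, solutions, curvature, diagnostics."""

    loglik: float
    k_hats: list[np.ndarray]
    r_hat: np.ndarray
    theta: np.ndarray
    theta_cov: np.ndarray
    fixed: np.ndarray
    random: dict[str, np.ndarray]
    n_iter: int
    converged: bool
    boundary: bool
    trajectory: list[float] = field(default_factory=list)
    n_obs: int = 0
    rank_x: int = 0

    def se_theta(self) -> np.ndarray:
        d = np.diag(self.theta_cov).copy()
        return np.sqrt(np.maximum(d, 0.0))


# ---------------------------------------------------------------------------
# driver


def fit_reml(
    y,
    x,
    terms: list[RandomTerm],
    residual: MultiTraitResidual | None = None,
    max_iter: int = 200,
    ll_tol: float = 1e-8,
    par_tol: float = 1e-6,
    verbose: bool = False,
) -> MixedModelFit:
    """Estimate variance components by AI-REML.

    ``residual=None`` means an i.i.d. scalar residual.  Raises
    :class:`ConvergenceError` if the iteration exhausts ``max_iter``
    without meeting both the log-likelihood and parameter tolerances.
    """
    eng = _Engine(y, x, terms, residual)
    vary = float(np.var(eng.y)) or 1.0
    floor = 1e-8 * vary

    dims = [t.m for t in terms]
    ks = []
    for t in terms:
        if t.k_start is not None:
            ks.append(np.array(t.k_start, dtype=float))
        else:
            ks.append(np.eye(t.m) * (0.5 * vary / max(len(terms), 1) / t.m))
    if residual is None:
        r0 = np.array([[0.5 * vary]])
        rdim = 1
    else:
        rdim = residual.n_traits
        r0 = (np.array(residual.r_start, dtype=float)
              if residual.r_start is not None else np.eye(rdim) * (0.5 * vary))
    all_dims = dims + [rdim]

    theta = _pack(ks + [r0])
    ll = eng.loglik(ks, r0)
    if not np.isfinite(ll):
        raise ConvergenceError("starting values give non-finite likelihood")
    traj = [ll]

    def _ll_of(th):
        mats = _unpack(th, all_dims)
        return eng.loglik(mats[:-1], mats[-1])

    def _score(th, base_ll):
        g = np.zeros_like(th)
        scale = max(vary, np.abs(th).max())
        for i in range(len(th)):
            h = 1e-4 * (abs(th[i]) + 1e-2 * scale)
            tp, tm = th.copy(), th.copy()
            tp[i] += h
            tm[i] -= h
            lp, lm = _ll_of(tp), _ll_of(tm)
            if np.isfinite(lp) and np.isfinite(lm):
                g[i] = (lp - lm) / (2 * h)
            elif np.isfinite(lp):
                g[i] = (lp - base_ll) / h
            elif np.isfinite(lm):
                g[i] = (base_ll - lm) / h
            else:
                g[i] = 0.0
        return g

    converged = False
    n_iter = 0
    tiny_streak = 0
    for n_iter in range(1, max_iter + 1):
        mats = _unpack(theta, all_dims)
        ks_cur, r_cur = mats[:-1], mats[-1]
        ll, (lu, sol, rinv) = eng.loglik(ks_cur, r_cur, want_solution=True)
        ai = eng.ai_matrix(ks_cur, r_cur, lu, sol, rinv)
        score = _score(theta, ll)
        # regularise a (numerically) non-PD AI matrix
        lam = 0.0
        try:
            w_ai = np.linalg.eigvalsh(ai)
            if w_ai.min() <= 0:
                lam = abs(w_ai.min()) + 1e-8 * max(w_ai.max(), 1.0)
        except np.linalg.LinAlgError:
            lam = 1.0
        try:
            delta = np.linalg.solve(ai + lam * np.eye(len(theta)), score)
        except np.linalg.LinAlgError:
            delta = score / max(np.abs(score).max(), 1.0) * 0.1 * vary
        # trust region: a singular AI (degenerate data) can propose absurd
        # steps; cap the move at a few times the current parameter scale
        cap = 5.0 * max(np.abs(theta).max(), vary)
        dmax = np.abs(delta).max()
        if dmax > cap:
            delta = delta * (cap / dmax)

        # AI (Newton) direction first; if a singular AI yields a
        # non-ascent direction, fall back to scaled gradient ascent
        grad_dir = score * (0.1 * max(np.abs(theta).max(), vary)
                            / max(np.abs(score).max(), 1e-12))
        accepted = False
        for delta_try in (delta, grad_dir):
            step = 1.0
            for _ in range(30):
                cand = theta + step * delta_try
                mats_c = _unpack(cand, all_dims)
                mats_c = [_project_pd(k, floor) for k in mats_c]
                cand = _pack(mats_c)
                ll_c = eng.loglik(mats_c[:-1], mats_c[-1])
                if np.isfinite(ll_c) and ll_c >= ll + 1e-10:
                    accepted = True
                    break
                step *= 0.5
            if accepted:
                break
        if not accepted:
            # no uphill step exists: a (possibly boundary) stationary point
            if len(traj) >= 2 and abs(traj[-1] - traj[-2]) < 1e-6 * (
                    1.0 + abs(traj[-1])):
                converged = True
            break

        rel_par = np.max(np.abs(cand - theta) / (np.abs(theta) + 1e-3 * vary))
        rel_ll = abs(ll_c - ll) / (1.0 + abs(ll_c))
        theta = cand
        traj.append(ll_c)
        if verbose:
            print(f"  iter {n_iter:3d}  ll={ll_c:.6f}  dpar={rel_par:.2e}")
        tiny_streak = tiny_streak + 1 if rel_ll < ll_tol else 0
        if rel_ll < ll_tol and rel_par < par_tol:
            converged = True
            break
        if tiny_streak >= 3:  # likelihood flat: accept (boundary plateaus)
            converged = True
            break
    else:
        raise ConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations", traj)

    mats = _unpack(theta, all_dims)
    ks_f, r_f = mats[:-1], mats[-1]
    ll, (lu, sol, rinv) = eng.loglik(ks_f, r_f, want_solution=True)
    ai = eng.ai_matrix(ks_f, r_f, lu, sol, rinv)
    try:
        theta_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        theta_cov = np.linalg.pinv(ai)
    # a component is "at the boundary" when effectively zero relative to
    # the phenotypic scale
    boundary = any(np.linalg.eigvalsh(k).min() <= 1e-4 * vary for k in ks_f)
    random = {t.name: sol[s].reshape(t.n_levels, t.m)
              for t, s in zip(terms, eng.slices)}
    return MixedModelFit(
        loglik=ll, k_hats=ks_f, r_hat=r_f, theta=theta, theta_cov=theta_cov,
        fixed=sol[: eng.p], random=random, n_iter=n_iter, converged=converged,
        boundary=boundary, trajectory=traj, n_obs=eng.n, rank_x=eng.p)


# ---------------------------------------------------------------------------
# fixed-effect design helper


def design_from_factors(
    df: pd.DataFrame,
    factors: list[str] = (),
    covariates: list[str] = (),
    intercept: bool = True,
    drop_confounded: bool = True,
) -> tuple[sp.csr_matrix, list[str]]:
    """Treatment-coded fixed-effect design matrix.

    Each factor's first (sorted) level is absorbed into the reference
    (set-to-zero constraint); covariates enter as-is.  Single-level
    factors contribute nothing.  Returns the sparse matrix and column
    labels.
    """
    n = len(df)
    cols, names = [], []
    if intercept:
        cols.append(sp.csr_matrix(np.ones((n, 1))))
        names.append("intercept")
    for f in factors:
        levels = pd.unique(df[f].sort_values())
        if len(levels) < 2:
            continue
        codes = pd.Categorical(df[f], categories=levels).codes
        keep = np.arange(1, len(levels))
        mask = codes >= 1
        mat = sp.coo_matrix(
            (np.ones(mask.sum()),
             (np.where(mask)[0], codes[mask] - 1)),
            shape=(n, len(keep))).tocsr()
        cols.append(mat)
        names += [f"{f}[{levels[k]}]" for k in keep]
    for c in covariates:
        cols.append(sp.csr_matrix(np.asarray(df[c], dtype=float)[:, None]))
        names.append(c)
    x = sp.hstack(cols, format="csr") if cols else sp.csr_matrix((n, 0))
    if drop_confounded and x.shape[1] > 1:
        from scipy.linalg import qr as _qr

        xd = np.asarray(x.todense())
        _, r, piv = _qr(xd, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(xd.shape) * np.finfo(float).eps * 100
        rank = int((diag > tol).sum())
        if rank < xd.shape[1]:
            keep = np.zeros(xd.shape[1], dtype=bool)
            keep[piv[:rank]] = True
            x = sp.csr_matrix(xd[:, keep])
            names = [nm for nm, k in zip(names, keep) if k]
    return x, names
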