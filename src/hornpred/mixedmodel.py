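"""Linear mixed models on the observed 0/1 scale.

The engine fits ``y = X b + sum_k Z_k u_k + e`` with ``u_k ~ N(0, K_k s2_k)``
and ``e ~ N(0, I s2_e)``.  Variance components are estimated by maximising
the ML or REML log-likelihood; BLUPs and fixed effects come from the
mixed-model equations at the estimates.

Two evaluation paths are used:

* **rotated path** — when at most one random term has an animal-dimensional
  covariance K (a pedigree A or genomic G), the likelihood is evaluated after
  rotating by the eigenvectors of K.  K is eigendecomposed once, block by
  block over the connected components of its sparsity pattern (half-sib
  pedigrees decompose into independent sire families, making n = 4000 fits
  essentially free).  Additional low-dimensional random terms (marker,
  haplotype or group effects) enter through a Woodbury update.
* **dense path** — with two or more animal-dimensional covariances (e.g.
  additive G plus dominance D), V is formed explicitly and factorised per
  likelihood evaluation.

All models here are linear on the observed binary scale; the Pearson
prediction accuracies used downstream are well defined either way, and a
liability-scale heritability is available through the Dempster–Lerner
transform (:func:`observed_to_liability_h2`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import HornpredError
from .kinship import DEFAULT_RIDGE, RelationshipMatrix

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-10
GRAD_TOL = 1e-6
MAX_ITER = 200


# ---------------------------------------------------------------------------
# Eigen-structure of an animal-dimensional covariance
# ---------------------------------------------------------------------------


class KinshipEigen:
    """Blockwise eigendecomposition ``K = U diag(d) U'``.

    The sparsity pattern of K is split into connected components (independent
    families under a pedigree A); each block is eigendecomposed separately so
    rotation costs scale with the largest family, not with n.
    """

    def __init__(self, K: np.ndarray, tol: float = 1e-12):
        K = np.asarray(K, dtype=np.float64)
        n = K.shape[0]
        mask = np.abs(K) > tol
        np.fill_diagonal(mask, True)
        n_comp, labels = connected_components(csr_matrix(mask), directed=False)
        self.n = n
        self.blocks: list[np.ndarray] = []  # original indices per block
        self.Us: list[np.ndarray] = []
        d_parts = []
        for c in range(n_comp):
            idx = np.flatnonzero(labels == c)
            vals, vecs = np.linalg.eigh(K[np.ix_(idx, idx)])
            self.blocks.append(idx)
            self.Us.append(vecs)
            d_parts.append(vals)
        self.order = np.concatenate(self.blocks)
        self.d = np.clip(np.concatenate(d_parts), 0.0, None)

    def rotate(self, M: np.ndarray) -> np.ndarray:
        """Return ``U' M`` (rows of the result are in block order)."""
        M = np.asarray(M, dtype=np.float64)
        out = np.empty_like(M, dtype=np.float64)
        start = 0
        for idx, U in zip(self.blocks, self.Us):
            out[start:start + len(idx)] = U.T @ M[idx]
            start += len(idx)
        return out

    def unrotate(self, M: np.ndarray) -> np.ndarray:
        """Return ``U M`` with rows back in original order."""
        M = np.asarray(M, dtype=np.float64)
        out = np.empty_like(M, dtype=np.float64)
        start = 0
        for idx, U in zip(self.blocks, self.Us):
            out[idx] = U @ M[start:start + len(idx)]
            start += len(idx)
        return out


class _IdentityEigen:
    """Degenerate stand-in when no animal-dimensional K is present."""

    def __init__(self, n: int, d_value: float = 0.0):
        self.n = n
        self.d = np.full(n, d_value)

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return np.asarray(M, dtype=np.float64).copy()

    unrotate = rotate


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass
class RandomTerm:
    """One random term ``Z u`` with ``u ~ N(0, K s2)``.

    ``Z=None`` means the identity (one effect per observation, animal model);
    ``K=None`` means an identity covariance.  K may be an ndarray, a
    :class:`~hornpred.kinship.RelationshipMatrix`, or a precomputed
    :class:`KinshipEigen` (animal-dimensional terms only).
    """

    name: str
    Z: np.ndarray | None = None
    K: object | None = None

    def is_animal_dim(self, n: int) -> bool:
        if self.Z is not None:
            return False
        if isinstance(self.K, KinshipEigen):
            return True
        K = self.K.values if isinstance(self.K, RelationshipMatrix) else self.K
        return K is not None and np.shape(K) == (n, n)


@dataclass
class MixedModelSpec:
    """Response, fixed design and random terms of one linear mixed model."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    random_terms: list[RandomTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match y")
        if len(self.fixed_names) != self.X.shape[1]:
            raise ValueError("fixed_names length does not match X columns")
        for t in self.random_terms:
            if t.Z is not None and np.shape(t.Z)[0] != n:
                raise ValueError(f"random term {t.name}: Z row count does not match y")

    @property
    def n(self) -> int:
        return len(self.y)

    def component_names(self) -> list[str]:
        return [t.name for t in self.random_terms] + ["residual"]


@dataclass
class MMESolution:
    """Solutions of Henderson's mixed-model equations at fixed components."""

    beta: np.ndarray
    fixed_names: list[str]
    u: dict[str, np.ndarray]
    fitted: np.ndarray
    residual_norm: float  # plug-back residual of the MME system


@dataclass
class MixedModelFit:
    """A fitted mixed model: estimates, BLUPs, likelihoods, AIC."""

    fixed_names: list[str]
    beta: np.ndarray
    varcomps: dict[str, float]
    blups: dict[str, np.ndarray]
    contributions: dict[str, np.ndarray]  # Z_k u_k per term, length n
    fitted: np.ndarray
    loglik_ml: float
    loglik_reml: float
    method: str
    n_params: int
    aic: float
    converged: bool
    n_iter: int
    boundary: list[str]
    n_obs: int


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _term_K(term: RandomTerm) -> np.ndarray | None:
    K = term.K
    if isinstance(K, RelationshipMatrix):
        return K.values
    return None if K is None or isinstance(K, KinshipEigen) else np.asarray(K, float)


class _Engine:
    """Pre-processed likelihood evaluator for one model spec."""

    def __init__(self, spec: MixedModelSpec, ridge: float = DEFAULT_RIDGE):
        self.spec = spec
        n = spec.n
        animal_terms = [t for t in spec.random_terms if t.is_animal_dim(n)]
        low_terms = [t for t in spec.random_terms if not t.is_animal_dim(n)]
        self.dense = len(animal_terms) > 1
        self.term_names = [t.name for t in spec.random_terms]

        if self.dense:
            # explicit-V path: keep each covariance contribution as n x n
            self.covs: list[tuple[str, np.ndarray]] = []
            for t in spec.random_terms:
                if t.is_animal_dim(n):
                    if isinstance(t.K, KinshipEigen):
                        raise ValueError(
                            f"term {t.name}: precomputed eigen not usable with >1 "
                            "animal-dimensional covariance"
                        )
                    self.covs.append((t.name, _term_K(t) + ridge * np.eye(n)))
                else:
                    K = _term_K(t)
                    Z = np.asarray(t.Z, float)
                    if Z.ndim == 1:
                        Z = Z[:, None]
                    self.covs.append((t.name, Z @ K @ Z.T if K is not None else Z @ Z.T))
            self.Zs = self._raw_designs()
            return

        # rotated path
        if animal_terms:
            t0 = animal_terms[0]
            self.animal_name = t0.name
            if isinstance(t0.K, KinshipEigen):
                self.eig = t0.K
            else:
                self.eig = KinshipEigen(_term_K(t0))
        else:
            self.animal_name = None
            self.eig = _IdentityEigen(n)
        self.y_r = self.eig.rotate(spec.y[:, None]).ravel()
        self.X_r = self.eig.rotate(spec.X)
        self.low_names: list[str] = []
        self.W_r_parts: list[np.ndarray] = []
        self.Ls: list[np.ndarray | None] = []
        self.Zraw: list[np.ndarray] = []
        for t in low_terms:
            Z = np.asarray(t.Z, float)
            if Z.ndim == 1:
                Z = Z[:, None]
            K = _term_K(t)
            if K is not None:
                L = np.linalg.cholesky(K + ridge * np.eye(K.shape[0]))
                W = Z @ L
            else:
                L = None
                W = Z
            self.low_names.append(t.name)
            self.W_r_parts.append(self.eig.rotate(W))
            self.Ls.append(L)
            self.Zraw.append(Z)
        self.W_r = (
            np.hstack(self.W_r_parts) if self.W_r_parts else np.zeros((n, 0))
        )
        self.col_term = np.concatenate(
            [np.full(W.shape[1], i) for i, W in enumerate(self.W_r_parts)]
        ) if self.W_r_parts else np.zeros(0, dtype=int)

    def _raw_designs(self) -> list[np.ndarray]:
        out = []
        n = self.spec.n
        for t in self.spec.random_terms:
            if t.Z is None:
                out.append(np.eye(n))
            else:
                Z = np.asarray(t.Z, float)
                out.append(Z[:, None] if Z.ndim == 1 else Z)
        return out

    # -- likelihood ---------------------------------------------------------

    def neg_loglik(self, log_s2: np.ndarray, method: str) -> float:
        s2 = np.exp(log_s2)
        try:
            ll = self._loglik(s2, method)
        except np.linalg.LinAlgError:
            return 1e30
        if not np.isfinite(ll):
            return 1e30
        return -ll

    def _loglik(self, s2: np.ndarray, method: str) -> float:
        if self.dense:
            return self._loglik_dense(s2, method)
        return self._loglik_rotated(s2, method)[0]

    def _vinv_pieces(self, s2: np.ndarray):
        """Diagonal base + Woodbury pieces in the rotated basis."""
        s2_terms, s2_e = s2[:-1], s2[-1]
        if self.animal_name is not None:
            i_animal = self.term_names.index(self.animal_name)
            b = s2_terms[i_animal] * self.eig.d + s2_e
        else:
            b = np.full(self.spec.n, s2_e)
        b = np.maximum(b, 1e-30)
        if self.W_r.shape[1] == 0:
            return b, None, None
        sig = np.empty(self.W_r.shape[1])
        for i, name in enumerate(self.low_names):
            sig[self.col_term == i] = s2_terms[self.term_names.index(name)]
        sig = np.maximum(sig, 1e-30)
        Wb = self.W_r / b[:, None]
        Mm = np.diag(1.0 / sig) + self.W_r.T @ Wb
        return b, Wb, (Mm, sig)

    def _loglik_rotated(self, s2: np.ndarray, method: str):
        y, X = self.y_r, self.X_r
        n, p = X.shape
        b, Wb, extra = self._vinv_pieces(s2)

        def vinv(M: np.ndarray) -> np.ndarray:
            base = M / b[:, None]
            if Wb is None:
                return base
            Mm, _ = extra
            return base - Wb @ np.linalg.solve(Mm, self.W_r.T @ base)

        logdet_v = float(np.sum(np.log(b)))
        if Wb is not None:
            Mm, sig = extra
            sign, ld = np.linalg.slogdet(Mm)
            if sign <= 0:
                raise np.linalg.LinAlgError("non-PD Woodbury core")
            logdet_v += ld + float(np.sum(np.log(sig)))

        ViX = vinv(X)
        Viy = vinv(y[:, None]).ravel()
        XtViX = X.T @ ViX
        XtViy = X.T @ Viy
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtViX, XtViy, rcond=None)[0]
        r = y - X @ beta
        Vir = Viy - ViX @ beta
        quad = float(r @ Vir)
        # V is PD, so r' V^-1 r >= 0; a negative value signals catastrophic
        # cancellation in the Woodbury update at extreme variance ratios
        if quad < -1e-6 * max(1.0, float(r @ r)):
            raise np.linalg.LinAlgError("negative quadratic form")
        quad = max(quad, 0.0)
        ll_ml = -0.5 * (n * np.log(2 * np.pi) + logdet_v + quad)
        sign, ld_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            ld_x = np.inf
        ll_reml = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + ld_x + quad)
        ll = ll_ml if method == "ML" else ll_reml
        return ll, beta, Vir, ll_ml, ll_reml

    def _build_v(self, s2: np.ndarray) -> np.ndarray:
        n = self.spec.n
        V = s2[-1] * np.eye(n)
        for (name, C), s in zip(self.covs, s2[:-1]):
            V += s * C
        return V

    def _loglik_dense(self, s2: np.ndarray, method: str) -> float:
        y, X = self.spec.y, self.spec.X
        n, p = X.shape
        V = self._build_v(s2)
        cf = np.linalg.cholesky(V)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf))))
        Vi_yX = np.linalg.solve(V, np.column_stack([y, X]))
        Viy, ViX = Vi_yX[:, 0], Vi_yX[:, 1:]
        XtViX = X.T @ ViX
        beta = np.linalg.solve(XtViX, X.T @ Viy)
        r = y - X @ beta
        Vir = Viy - ViX @ beta
        quad = float(r @ Vir)
        if method == "ML":
            return -0.5 * (n * np.log(2 * np.pi) + logdet_v + quad)
        sign, ld_x = np.linalg.slogdet(XtViX)
        return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + ld_x + quad)

    # -- solutions ----------------------------------------------------------

    def solutions(self, s2: np.ndarray):
        """beta, BLUPs and per-term fitted contributions at components s2."""
        spec = self.spec
        if self.dense:
            V = self._build_v(s2)
            Vi_yX = np.linalg.solve(V, np.column_stack([spec.y, spec.X]))
            Viy, ViX = Vi_yX[:, 0], Vi_yX[:, 1:]
            XtViX = spec.X.T @ ViX
            beta = np.linalg.solve(XtViX, spec.X.T @ Viy)
            Vir = Viy - ViX @ beta
            blups, contribs = {}, {}
            for (name, C), s, Z, t in zip(self.covs, s2[:-1], self.Zs, spec.random_terms):
                contrib = s * (C @ Vir)
                contribs[name] = contrib
                K = _term_K(t)
                if t.Z is None:
                    blups[name] = contrib
                else:
                    Zt = np.asarray(t.Z, float)
                    if Zt.ndim == 1:
                        Zt = Zt[:, None]
                    u = s * ((K @ (Zt.T @ Vir)) if K is not None else Zt.T @ Vir)
                    blups[name] = u
            ll_ml = self._loglik_dense(s2, "ML")
            ll_reml = self._loglik_dense(s2, "REML")
        else:
            _, beta, Vir_r, ll_ml, ll_reml = self._loglik_rotated(s2, "ML")
            blups, contribs = {}, {}
            if self.animal_name is not None:
                i_a = self.term_names.index(self.animal_name)
                u_r = s2[i_a] * (self.eig.d * Vir_r)
                u = self.eig.unrotate(u_r[:, None]).ravel()
                blups[self.animal_name] = u
                contribs[self.animal_name] = u
            for i, name in enumerate(self.low_names):
                s = s2[self.term_names.index(name)]
                W_r = self.W_r_parts[i]
                a = s * (W_r.T @ Vir_r)  # effects in the folded (L) basis
                L = self.Ls[i]
                u = (L @ a) if L is not None else a
                blups[name] = u
                contribs[name] = self.Zraw[i] @ u
        fitted = spec.X @ beta + sum(contribs.values(), np.zeros(spec.n))
        return beta, blups, contribs, fitted, ll_ml, ll_reml


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def solve_mme(
    spec: MixedModelSpec,
    varcomps: dict[str, float],
    ridge: float = DEFAULT_RIDGE,
) -> MMESolution:
    """Solve Henderson's mixed-model equations at given variance components.

    Builds the coefficient matrix explicitly (suitable for moderate n) and
    verifies the solution by plugging it back into the system.
    """
    n = spec.n
    s2_e = varcomps["residual"]
    if s2_e <= 0:
        raise ValueError("residual variance must be strictly positive")
    X = spec.X
    Z_blocks, Ginv_blocks, names = [], [], []
    for t in spec.random_terms:
        s2 = varcomps[t.name]
        if s2 <= 0:
            raise ValueError(f"variance for term {t.name} must be > 0 in the MME")
        Z = np.eye(n) if t.Z is None else np.asarray(t.Z, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        K = _term_K(t)
        if isinstance(t.K, KinshipEigen):
            raise ValueError("solve_mme requires explicit K matrices")
        q = Z.shape[1]
        Kinv = np.eye(q) / s2 if K is None else np.linalg.inv(K + ridge * np.eye(q)) / s2
        Z_blocks.append(Z)
        Ginv_blocks.append(Kinv)
        names.append(t.name)

    Zfull = np.hstack(Z_blocks) if Z_blocks else np.zeros((n, 0))
    p = X.shape[1]
    q = Zfull.shape[1]
    C = np.zeros((p + q, p + q))
    C[:p, :p] = X.T @ X / s2_e
    C[:p, p:] = X.T @ Zfull / s2_e
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Zfull.T @ Zfull / s2_e
    off = 0
    for Kinv in Ginv_blocks:
        k = Kinv.shape[0]
        C[p + off:p + off + k, p + off:p + off + k] += Kinv
        off += k
    rhs = np.concatenate([X.T @ spec.y, Zfull.T @ spec.y]) / s2_e

    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e12:
        # name the confounded fixed columns via the null space of C
        w, v = np.linalg.eigh(C)
        null_vec = np.abs(v[:, 0])
        bad = [spec.fixed_names[i] for i in range(p) if null_vec[i] > 1e-6]
        raise HornpredError(
            f"singular mixed-model equations (cond={cond:.2e}); "
            f"confounded columns include: {bad or ['<random-effect block>']}"
        )
    sol = np.linalg.solve(C, rhs)
    resid = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30))
    beta = sol[:p]
    u: dict[str, np.ndarray] = {}
    off = p
    for name, Z in zip(names, Z_blocks):
        k = Z.shape[1]
        u[name] = sol[off:off + k]
        off += k
    fitted = X @ beta + sum(
        (Z @ u[name] for name, Z in zip(names, Z_blocks)), np.zeros(n)
    )
    return MMESolution(beta=beta, fixed_names=list(spec.fixed_names), u=u,
                       fitted=fitted, residual_norm=resid)


def fit_variance_components(
    spec: MixedModelSpec,
    method: str = "REML",
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = MAX_ITER,
) -> MixedModelFit:
    """Estimate variance components by ML or REML.

    Components are optimised on the log scale with a quasi-Newton method
    (gradient tolerance ``1e-6``); estimates hitting the variance floor are
    reported as boundary (effectively zero) estimates.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    n_comp = len(spec.random_terms) + 1
    if spec.n < spec.X.shape[1] + 2:
        raise HornpredError("too few observations for the fixed structure")
    eng = _Engine(spec, ridge=ridge)
    vy = float(np.var(spec.y))
    if vy <= 0:
        raise HornpredError("response has zero variance")
    start = np.log(np.full(n_comp, vy / n_comp))
    start[-1] = np.log(max(vy / 2, VAR_FLOOR))
    lo = np.log(VAR_FLOOR * vy)
    hi = np.log(1e4 * vy)

    def objective(x: np.ndarray) -> float:
        # keep every evaluation inside the box (the derivative-free fallback
        # has no bound support); excursions are penalised quadratically
        xc = np.clip(x, lo, hi)
        return eng.neg_loglik(xc, method) + 1e3 * float(np.sum((x - xc) ** 2))

    res = optimize.minimize(
        objective,
        start,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * n_comp,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": GRAD_TOL},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        res2 = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
    if not np.isfinite(res.fun):
        raise HornpredError(
            f"variance-component estimation failed to converge: {res.message}"
        )
    s2 = np.exp(np.clip(res.x, lo, hi))
    names = spec.component_names()
    boundary = [nm for nm, v in zip(names, s2) if v <= 1.5 * VAR_FLOOR * vy]
    beta, blups, contribs, fitted, ll_ml, ll_reml = eng.solutions(s2)
    n_params = spec.X.shape[1] + n_comp
    aic = -2.0 * ll_ml + 2.0 * n_params
    return MixedModelFit(
        fixed_names=list(spec.fixed_names),
        beta=beta,
        varcomps=dict(zip(names, s2.tolist())),
        blups=blups,
        contributions=contribs,
        fitted=fitted,
        loglik_ml=ll_ml,
        loglik_reml=ll_reml,
        method=method,
        n_params=n_params,
        aic=aic,
        converged=bool(res.success),
        n_iter=int(getattr(res, "nit", 0)),
        boundary=boundary,
        n_obs=spec.n,
    )


def aic_compare(fits: Sequence[MixedModelFit], labels: Sequence[str] | None = None):
    """Rank fits by AIC (ML likelihoods) with delta-AIC to the first fit.

    The first fit in the list is the declared null model; ``delta_aic`` is
    reported as improvement over it (``AIC_null - AIC_model``, positive =
    better).  The lowest AIC is flagged best; ties go to the earlier entry.
    """
    import pandas as pd

    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1:
        raise HornpredError("fits use different numbers of observations")
    fixed = {tuple(f.fixed_names) for f in fits}
    if any(f.method == "REML" for f in fits) and len(fixed) > 1:
        raise HornpredError(
            "REML likelihoods are not comparable across different fixed structures; "
            "refit with method='ML'"
        )
    labels = list(labels) if labels is not None else [f"model_{i + 1}" for i in range(len(fits))]
    aics = np.array([f.aic for f in fits])
    delta = aics[0] - aics
    best = int(np.argmin(aics + np.arange(len(aics)) * 1e-12))  # stable tie-break
    return pd.DataFrame(
        {
            "model": labels,
            "aic": aics,
            "delta_aic": delta,
            "n_params": [f.n_params for f in fits],
            "best": [i == best for i in range(len(fits))],
        }
    )


def variance_explained_by_marker(
    fit: MixedModelFit,
    y: np.ndarray,
    marker_terms: Sequence[str],
    polygenic_term: str | None = None,
) -> dict[str, float]:
    """Proportion of phenotypic variance explained by the fitted marker term.

    Returns ``{"marker": var(marker fit)/var(y), "marker_plus_polygenic": ...}``
    (the second key only when a polygenic term name is supplied).
    """
    y = np.asarray(y, float)
    vy = float(np.var(y))
    if vy <= 0:
        raise HornpredError("zero phenotypic variance")
    missing = [t for t in marker_terms if t not in fit.contributions]
    if missing:
        raise KeyError(f"fit has no term(s) {missing}")
    marker_fit = sum(fit.contributions[t] for t in marker_terms)
    out = {"marker": float(np.var(marker_fit)) / vy}
    if polygenic_term is not None:
        total = marker_fit + fit.contributions[polygenic_term]
        out["marker_plus_polygenic"] = float(np.var(total)) / vy
    return out


def observed_to_liability_h2(h2_obs: float, prevalence: float) -> float:
    """Dempster–Lerner transform of an observed-scale heritability.

    ``h2_liab = h2_obs * K (1 - K) / z^2`` where K is the prevalence of the
    affected class and z the standard-normal density at the K-quantile.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    if not (0.0 <= h2_obs <= 1.0):
        raise ValueError("h2_obs must be in [0, 1]")
    z = stats.norm.pdf(stats.norm.ppf(prevalence))
    return h2_obs * prevalence * (1.0 - prevalence) / z**2


def liability_to_observed_h2(h2_liab: float, prevalence: float) -> float:
    """Inverse of :func:`observed_to_liability_h2`."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    z = stats.norm.pdf(stats.norm.ppf(prevalence))
    return h2_liab * z**2 / (prevalence * (1.0 - prevalence))
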