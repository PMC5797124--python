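"""Crossed random-effects linear mixed models for pairwise inter-SC values.

Every pairwise Fisher-z value z_ij is modeled as

    z_ij = x_ij' beta + a_i + a_j + e_ij          (within / between models)
    z_ca = x_ca' beta + a_c + b_a + e_ca          (child-to-adult models)

with subject random intercepts a ~ N(0, tau^2) i.i.d. and pair residual
e ~ N(0, sigma^2).  Because each subject appears in N-1 pairs, the entries
of a correlation matrix are not independent; the crossed random effects
absorb exactly that shared-subject covariance, which is what keeps the
type-I error of group tests near nominal where a naive independent-pairs
t-test is anticonservative.

Estimation is profile REML over the variance ratios lambda_k = tau_k^2 /
sigma^2 with the pair covariance assembled from subject incidence:
V = sigma^2 (I + sum_k lambda_k Z_k Z_k').  The Z_k Z_k' matrices are
(jointly) diagonalized once per incidence structure, so per-node fits reduce
to scalar reweighting — the map-wise fits share one eigendecomposition.
Inference uses Satterthwaite denominator degrees of freedom from the REML
information matrix.

The symmetric matrix is listed with both triangles in the reference design;
duplicated rows here are a bookkeeping device only — they are collapsed to
unique unordered pairs before fitting, so doubled and single-triangle inputs
give identical estimates and standard errors (fitting duplicates as
independent data would halve the standard errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .isc import CohortISCMatrix, extract_block

__all__ = [
    "CrossedLMMSpec",
    "CrossedLMMFit",
    "fit_crossed_lmm",
    "satterthwaite_df",
    "within_group_model",
    "group_contrast_model",
    "child_to_adult_age_model",
    "fits_to_frame",
]

_LAM_MAX = 1e4
_BOUNDARY_TOL = 1e-7


@dataclass
class CrossedLMMSpec:
    """A pair table ready for the crossed random-effects fit.

    ``members`` lists, per random factor, an (n_rows, m) integer array of
    subject codes contributing to each row: one factor with two memberships
    per row for within/between models, two crossed one-membership factors
    (child, adult) for child-to-adult models.  ``pair_i``/``pair_j`` identify
    the unordered pair for duplicate collapsing when ``doubling`` is set.
    """

    y: np.ndarray
    X: np.ndarray
    names: list[str]
    members: list[np.ndarray]
    pair_i: np.ndarray | None = None
    pair_j: np.ndarray | None = None
    doubling: bool = False

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n_rows, p) aligned with y")
        self.members = [np.asarray(m, dtype=np.int64) for m in self.members]
        for m in self.members:
            if m.ndim != 2 or m.shape[0] != self.y.size:
                raise ValueError("each member array must be (n_rows, m)")
        if self.pair_i is not None and self.pair_j is not None:
            if np.any(np.asarray(self.pair_i) == np.asarray(self.pair_j)):
                raise ValueError("self-pairs (i == j) are not allowed")


@dataclass
class CrossedLMMFit:
    """Fixed effects, variance components and Satterthwaite inference."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    names: list[str]
    var_subject: np.ndarray  # tau^2 per random factor
    var_resid: float
    loglik: float  # REML log-likelihood, constants included
    converged: bool
    boundary: bool
    n_pairs: int
    n_subjects: int
    node: int | None = None
    _satt: dict = field(default_factory=dict, repr=False)

    @property
    def beta_r(self) -> np.ndarray:
        """Fixed effects mapped back to the correlation scale (tanh)."""
        return np.tanh(self.beta)


# ---------------------------------------------------------------------------
# joint diagonalization of the random-effect Gram matrices
# ---------------------------------------------------------------------------


def _incidence(members: np.ndarray, n_levels: int) -> np.ndarray:
    n = members.shape[0]
    Z = np.zeros((n, n_levels))
    for col in range(members.shape[1]):
        Z[np.arange(n), members[:, col]] += 1.0
    return Z


def _joint_diagonalize(Gs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray] | None:
    """Simultaneously diagonalize commuting symmetric matrices.

    Returns (U, D) with U orthogonal and D[k] = diag(U' G_k U), or None if
    the matrices do not commute (within tolerance).
    """
    n = Gs[0].shape[0]
    scale = max(float(np.abs(G).max()) for G in Gs) or 1.0
    for a in range(len(Gs)):
        for b in range(a + 1, len(Gs)):
            comm = Gs[a] @ Gs[b] - Gs[b] @ Gs[a]
            if np.abs(comm).max() > 1e-8 * scale**2:
                return None
    U = np.eye(n)
    blocks: list[np.ndarray] = [np.arange(n)]
    for G in Gs:
        new_blocks: list[np.ndarray] = []
        for blk in blocks:
            if blk.size == 1:
                new_blocks.append(blk)
                continue
            sub = U[:, blk].T @ G @ U[:, blk]
            w, Q = np.linalg.eigh(sub)
            U[:, blk] = U[:, blk] @ Q
            # split the block by (near-)equal eigenvalues
            start = 0
            for k in range(1, blk.size + 1):
                if k == blk.size or w[k] - w[start] > 1e-9 * (1 + abs(w[start])):
                    new_blocks.append(blk[start:k])
                    start = k
        blocks = new_blocks
    D = np.stack([np.einsum("ij,jk,ki->i", U.T, G, U) for G in Gs])
    # verify off-diagonal leakage
    for k, G in enumerate(Gs):
        resid = U.T @ G @ U - np.diag(D[k])
        if np.abs(resid).max() > 1e-6 * scale:
            return None
    return U, D


class CrossedREMLSolver:
    """Profile-REML solver for one incidence structure, reused across nodes.

    Holds the eigendecomposition of the Z_k Z_k' matrices so that each
    per-node fit costs only scalar reweighting inside a low-dimensional
    optimization over the variance ratios.
    """

    def __init__(self, X: np.ndarray, members: list[np.ndarray]):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n <= p:
            raise ValueError("more fixed-effect columns than rows")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed-effect design is rank deficient")
        self.n, self.p = n, p
        self.q = []
        Gs = []
        for m in members:
            levels, codes = np.unique(m, return_inverse=True)
            codes = codes.reshape(m.shape)
            Z = _incidence(codes, levels.size)
            self.q.append(levels.size)
            Gs.append(Z @ Z.T)
        self.K = len(Gs)
        jd = _joint_diagonalize(Gs)
        if jd is None:
            raise NotImplementedError(
                "random-effect structures do not commute; only jointly "
                "diagonalizable incidence (complete crossed blocks or a "
                "single factor) is supported"
            )
        self.U, self.D = jd  # U (n,n), D (K,n)
        self.Xt = self.U.T @ X

    # -- profiled REML criterion ------------------------------------------

    def _profile(self, lam: np.ndarray, yt: np.ndarray):
        vstar = 1.0 + lam @ self.D  # (n,)
        w = 1.0 / vstar
        Xw = self.Xt * w[:, None]
        M = self.Xt.T @ Xw
        Mc = np.linalg.cholesky(M)
        beta = np.linalg.solve(M, Xw.T @ yt)
        resid = yt - self.Xt @ beta
        rss = float(resid @ (w * resid))
        return vstar, w, M, Mc, beta, rss

    def neg2_reml(self, lam: np.ndarray, yt: np.ndarray) -> float:
        vstar, _, _, Mc, _, rss = self._profile(lam, yt)
        nmp = self.n - self.p
        sigma2 = max(rss / nmp, 1e-300)
        return (
            nmp * (np.log(2.0 * np.pi) + np.log(sigma2) + 1.0)
            + float(np.log(vstar).sum())
            + 2.0 * float(np.log(np.diag(Mc)).sum())
        )

    def _optimize(self, yt: np.ndarray) -> tuple[np.ndarray, bool]:
        if self.K == 1:

            def f(l):
                return self.neg2_reml(np.array([l]), yt)

            res = optimize.minimize_scalar(
                f, bounds=(0.0, _LAM_MAX), method="bounded",
                options={"xatol": 1e-12},
            )
            lam = np.array([res.x])
            if f(0.0) <= res.fun:
                lam = np.array([0.0])
            return lam, True

        def f(l):
            return self.neg2_reml(np.asarray(l), yt)

        best = None
        for start in ([0.1] * self.K, [1.0] * self.K, [1e-3] * self.K):
            r = optimize.minimize(
                f, np.array(start), method="L-BFGS-B",
                bounds=[(0.0, _LAM_MAX)] * self.K,
                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
            )
            if best is None or r.fun < best.fun:
                best = r
        # polish (Nelder-Mead handles the boundary kink gracefully)
        clipped = np.clip(best.x, 0.0, _LAM_MAX)
        r2 = optimize.minimize(
            lambda l: f(np.clip(l, 0.0, _LAM_MAX)), clipped,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 2000},
        )
        lam = np.clip(r2.x if r2.fun <= best.fun else best.x, 0.0, _LAM_MAX)
        lam[lam < _BOUNDARY_TOL] = 0.0
        return lam, bool(best.success or r2.success)

    # -- full fit ----------------------------------------------------------

    def fit(self, y: np.ndarray, names: Sequence[str], node: int | None = None) -> CrossedLMMFit:
        y = np.asarray(y, dtype=float)
        if y.size != self.n:
            raise ValueError("response length mismatch")
        yt = self.U.T @ y
        nmp = self.n - self.p

        if np.ptp(y) < 1e-13:  # constant response: exact intercept, no noise
            beta = np.linalg.lstsq(self.Xt, yt, rcond=None)[0]
            zeros = np.zeros(self.p)
            return CrossedLMMFit(
                beta=beta, se=zeros, t=np.full(self.p, np.inf),
                df=np.full(self.p, float(nmp)), p=zeros, names=list(names),
                var_subject=np.zeros(self.K), var_resid=0.0,
                loglik=np.inf, converged=True, boundary=True,
                n_pairs=self.n, n_subjects=int(sum(self.q)), node=node,
            )

        lam, ok = self._optimize(yt)
        vstar, w, M, Mc, beta, rss = self._profile(lam, yt)
        sigma2 = rss / nmp
        tau2 = lam * sigma2
        covb = sigma2 * np.linalg.inv(M)
        se = np.sqrt(np.diag(covb))
        tvals = beta / se
        loglik = -0.5 * self.neg2_reml(lam, yt)
        boundary = bool((lam <= _BOUNDARY_TOL).any())

        satt = {
            "D": self.D, "Xt": self.Xt, "sigma2": sigma2, "tau2": tau2,
            "covb": covb, "q": self.q, "n": self.n, "p": self.p,
            "boundary": boundary,
        }
        fit = CrossedLMMFit(
            beta=beta, se=se, t=tvals, df=np.empty(self.p), p=np.empty(self.p),
            names=list(names), var_subject=tau2, var_resid=sigma2,
            loglik=loglik, converged=ok, boundary=boundary,
            n_pairs=self.n, n_subjects=int(sum(self.q)), node=node,
            _satt=satt,
        )
        eye = np.eye(self.p)
        for j in range(self.p):
            fit.df[j] = satterthwaite_df(fit, eye[j])
        fit.p = 2.0 * stats.t.sf(np.abs(fit.t), fit.df)
        return fit


def satterthwaite_df(fit: CrossedLMMFit, contrast: np.ndarray) -> float:
    """Satterthwaite denominator degrees of freedom for c'beta.

    df = 2 (c'Cc)^2 / Var(c'Cc), with Var obtained by the delta method from
    the inverse REML information of (sigma^2, tau_1^2, ..).  When a variance
    component is pinned at the zero boundary the information matrix is
    unreliable and the conservative fallback min_k(n_subjects_k) - rank(X)
    is returned.  Always clipped to [1, n_pairs - rank(X)].
    """
    s = fit._satt
    if not s:
        return float(fit.n_pairs - fit.beta.size)
    c = np.asarray(contrast, dtype=float)
    n, p = s["n"], s["p"]
    nmp = n - p
    fallback = float(max(min(s["q"]) - p, 1))
    if s["boundary"]:
        return min(fallback, float(nmp))

    D, Xt = s["D"], s["Xt"]
    u = s["sigma2"] + s["tau2"] @ D  # (n,)
    w = 1.0 / u
    V = np.vstack([np.ones(n), D])  # v_a per theta component, (K+1, n)
    M = Xt.T @ (Xt * w[:, None])
    C = np.linalg.inv(M)
    Cc = C @ c
    phi = float(c @ Cc)

    K1 = V.shape[0]
    XtC = Xt @ C
    qdiag = np.einsum("ij,ij->i", XtC, Xt)  # x_i' C x_i
    A = [Xt.T @ (Xt * (w**2 * V[a])[:, None]) for a in range(K1)]
    g = np.array([float(Cc @ A[a] @ Cc) for a in range(K1)])

    info = np.empty((K1, K1))
    for a in range(K1):
        for b in range(a, K1):
            t1 = float(np.sum(w**2 * V[a] * V[b]))
            t2 = float(np.sum(w**3 * V[a] * V[b] * qdiag))
            t3 = float(np.trace(C @ A[a] @ C @ A[b]))
            info[a, b] = info[b, a] = 0.5 * (t1 - 2.0 * t2 + t3)
    try:
        var_phi = float(g @ np.linalg.solve(info, g))
    except np.linalg.LinAlgError:
        return min(fallback, float(nmp))
    if var_phi <= 0:
        return min(fallback, float(nmp))
    df = 2.0 * phi**2 / var_phi
    return float(np.clip(df, 1.0, nmp))


def fit_crossed_lmm(spec: CrossedLMMSpec, node: int | None = None) -> CrossedLMMFit:
    """Fit the crossed random-effects model for one pair table.

    If ``spec.doubling`` both-triangle rows are collapsed to unique unordered
    pairs first (estimates and standard errors are then identical to the
    single-triangle fit with the correct pair covariance).
    """
    y, X, members = spec.y, spec.X, spec.members
    if spec.doubling:
        if spec.pair_i is None or spec.pair_j is None:
            raise ValueError("doubling requires pair_i/pair_j for collapsing")
        lo = np.minimum(spec.pair_i, spec.pair_j)
        hi = np.maximum(spec.pair_i, spec.pair_j)
        _, first = np.unique(lo * (hi.max() + 1) + hi, return_index=True)
        first = np.sort(first)
        y, X = y[first], X[first]
        members = [m[first] for m in members]
    ok = np.isfinite(y)
    y, X = y[ok], X[ok]
    members = [m[ok] for m in members]
    for m in members:
        if np.unique(m).size < 4:
            raise ValueError("need at least 4 subjects per random factor")
    solver = CrossedREMLSolver(X, members)
    return solver.fit(y, spec.names, node=node)


# ---------------------------------------------------------------------------
# per-node model builders over a CohortISCMatrix
# ---------------------------------------------------------------------------


def _fit_nodes(
    m: CohortISCMatrix,
    pair_i: np.ndarray,
    pair_j: np.ndarray,
    X: np.ndarray,
    names: list[str],
    members: list[np.ndarray],
    nodes: Sequence[int] | None,
) -> list[CrossedLMMFit]:
    flag_rows = m.flagged[pair_i, pair_j]
    node_list = range(m.n_nodes) if nodes is None else nodes
    solvers: dict[bytes, CrossedREMLSolver] = {}
    fits: list[CrossedLMMFit] = []
    for v in node_list:
        y = m.z[v, pair_i, pair_j]
        ok = np.isfinite(y) & ~flag_rows
        key = ok.tobytes()
        if key not in solvers:
            solvers[key] = CrossedREMLSolver(X[ok], [mm[ok] for mm in members])
        fits.append(solvers[key].fit(y[ok], names, node=v))
    return fits


def within_group_model(
    m: CohortISCMatrix,
    group: str | Sequence[str],
    nodes: Sequence[int] | None = None,
) -> list[CrossedLMMFit]:
    """Intercept-only crossed model per node for one group's pairs.

    The intercept is the group-average inter-SC on the Fisher-z scale
    (``fit.beta_r[0]`` gives the correlation-scale value).
    """
    pairs = extract_block(m, group, group)
    i, j = pairs["i"].to_numpy(), pairs["j"].to_numpy()
    if np.unique(np.r_[i, j]).size < 4:
        raise ValueError("need at least 4 subjects in the group")
    X = np.ones((len(pairs), 1))
    members = [np.column_stack([i, j])]
    return _fit_nodes(m, i, j, X, ["intercept"], members, nodes)


def group_contrast_model(
    m: CohortISCMatrix,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    nodes: Sequence[int] | None = None,
    include_between_pairs: bool = False,
) -> list[CrossedLMMFit]:
    """Group-affiliation contrast (A - B) of within-group synchrony per node.

    The default design pools the within-A and within-B pairs only (the
    green-vs-blue blocks of the pairwise matrix); mixed (A, B) pairs may be
    added as a third affiliation level via ``include_between_pairs``, but are
    excluded by default.  The effect ``affiliation`` is the difference in
    mean Fisher-z synchrony, A minus B.
    """
    pa = extract_block(m, group_a, group_a)
    pb = extract_block(m, group_b, group_b)
    tables = [pa, pb]
    affil = [np.full(len(pa), 0.5), np.full(len(pb), -0.5)]
    names = ["intercept", "affiliation"]
    if include_between_pairs:
        pab = extract_block(m, group_a, group_b)
        tables.append(pab)
        affil.append(np.zeros(len(pab)))
    i = np.concatenate([t["i"].to_numpy() for t in tables])
    j = np.concatenate([t["j"].to_numpy() for t in tables])
    X = np.column_stack([np.ones(i.size), np.concatenate(affil)])
    members = [np.column_stack([i, j])]
    for g, p in ((group_a, pa), (group_b, pb)):
        if np.unique(np.r_[p["i"], p["j"]]).size < 4:
            raise ValueError(f"need at least 4 subjects in group {g!r}")
    return _fit_nodes(m, i, j, X, names, members, nodes)


def child_to_adult_age_model(
    m: CohortISCMatrix,
    child_groups: str | Sequence[str] = ("child4", "child6"),
    adult_group: str | Sequence[str] = "adult",
    nodes: Sequence[int] | None = None,
) -> list[CrossedLMMFit]:
    """Child age (months, centered) predicting child-to-adult inter-SC.

    One row per (child, adult) pair with crossed child and adult random
    intercepts; the ``age_months`` slope is the effect of interest.
    """
    pairs = extract_block(m, child_groups, adult_group)
    ci, ai = pairs["i"].to_numpy(), pairs["j"].to_numpy()
    if np.unique(ci).size < 4 or np.unique(ai).size < 4:
        raise ValueError("need at least 4 children and 4 adults")
    age = pairs["age_i"].to_numpy().astype(float)
    if np.ptp(age) == 0:
        raise ValueError("age covariate is constant; slope not estimable")
    X = np.column_stack([np.ones(age.size), age - age.mean()])
    members = [ci[:, None], ai[:, None]]
    return _fit_nodes(m, ci, ai, X, ["intercept", "age_months"], members, nodes)


def fits_to_frame(fits: Sequence[CrossedLMMFit]) -> pd.DataFrame:
    """Tidy per-node fit table: node, effect, beta_z, beta_r, se, t, df, p."""
    rows = []
    for f in fits:
        for k, name in enumerate(f.names):
            rows.append(
                {
                    "node": f.node,
                    "effect": name,
                    "beta_z": f.beta[k],
                    "beta_r": float(np.tanh(f.beta[k])),
                    "se": f.se[k],
                    "t": f.t[k],
                    "df": f.df[k],
                    "p": f.p[k],
                    "var_resid": f.var_resid,
                    "converged": f.converged,
                    "boundary": f.boundary,
                }
            )
    return pd.DataFrame(rows)
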