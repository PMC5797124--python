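"""Independent reference implementations used only to check the package.

These deliberately share no code with iscmix: the REML oracle builds the
dense pair covariance explicitly and uses a generic optimizer; the cluster
oracle is a plain union-find; the correlation oracle is the textbook
covariance/variance loop.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def dense_reml_oracle(y, X, Zs):
    """REML fit via the explicit covariance V = s2*I + sum tau2_k Z_k Z_k'.

    Generic Nelder-Mead over log variance parameters; returns
    (beta, reml_loglik, sigma2, tau2s).  Log-likelihood includes constants:
    l = -0.5 [ log|V| + log|X'V^-1 X| + y'Py + (n-p) log 2pi ].
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    Gs = [Z @ Z.T for Z in Zs]

    def neg2(logth):
        s2 = np.exp(logth[0])
        taus = np.exp(logth[1:])
        V = s2 * np.eye(n) + sum(t * G for t, G in zip(taus, Gs))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        yPy = r @ np.linalg.solve(V, r)
        ld_V = 2.0 * np.log(np.diag(L)).sum()
        ld_M = np.linalg.slogdet(XtViX)[1]
        return ld_V + ld_M + yPy + (n - p) * np.log(2 * np.pi)

    k = 1 + len(Zs)
    best = None
    for start in (
        [np.log(0.05)] * k,
        [np.log(0.5)] * k,
        [np.log(0.005)] + [np.log(0.2)] * (k - 1),
        [np.log(0.05)] + [np.log(1e-6)] * (k - 1),
    ):
        r = optimize.minimize(
            neg2, np.array(start), method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-13, "maxiter": 50000,
                     "maxfev": 50000},
        )
        if best is None or r.fun < best.fun:
            best = r
    s2 = np.exp(best.x[0])
    taus = np.exp(best.x[1:])
    V = s2 * np.eye(n) + sum(t * G for t, G in zip(taus, Gs))
    XtViX = X.T @ np.linalg.solve(V, X)
    beta = np.linalg.solve(XtViX, X.T @ np.linalg.solve(V, y))
    return beta, -0.5 * best.fun, s2, taus


def union_find_components(n_nodes, edges, active):
    """Connected-component labels of the active nodes by plain union-find.

    Returns a dict node -> root label for nodes where active[node] is True.
    """
    parent = list(range(n_nodes))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in edges:
        if active[u] and active[v]:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    return {v: find(v) for v in range(n_nodes) if active[v]}


def pearson_loop(x, y):
    """Textbook Pearson correlation via explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / np.sqrt(sxx * syy)


def atanh_by_log(r):
    """Fisher z via the logarithmic identity, independent of np.arctanh."""
    return 0.5 * np.log((1.0 + r) / (1.0 - r))
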