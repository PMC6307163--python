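"""Convex-hull disjointness by linear programming, and LDA projection.

Two point clouds have intersecting convex hulls iff some convex combination
of one equals a convex combination of the other:

    sum_i lambda_i a_i = sum_j mu_j b_j,   lambda, mu >= 0, each summing to 1.

Feasibility is decided without ever constructing a hull: the equality system
is solved as an LP minimizing the L1 norm of a slack vector; a zero optimum
(within tolerance) yields an intersection certificate (lambda, mu), which is
re-verified by direct substitution before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import linprog
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class HullTestResult:
    """Verdict of the convex-hull intersection LP for two point clouds."""

    disjoint: bool
    tolerance: float
    residual: float
    lambda_: np.ndarray | None = None
    mu: np.ndarray | None = None

    @property
    def certificate(self) -> tuple[np.ndarray, np.ndarray] | None:
        if self.lambda_ is None:
            return None
        return self.lambda_, self.mu


def hulls_disjoint(P: np.ndarray, Q: np.ndarray, tol: float = 1e-7) -> HullTestResult:
    """Test whether conv(P) and conv(Q) are disjoint.

    P, Q are (n_points, d) arrays in the same dimension. The LP minimizes
    ||sum lambda_i p_i - sum mu_j q_j||_1 over the product of simplices; the
    hulls intersect iff the optimum is <= ``tol``. Raises on solver failure
    rather than returning a silent verdict.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape[1] != Q.shape[1]:
        raise ValueError(f"dimension mismatch: {P.shape[1]} vs {Q.shape[1]}")
    if P.shape[0] == 0 or Q.shape[0] == 0:
        raise ValueError("point sets must be nonempty")
    n, m = P.shape[0], Q.shape[0]
    d = P.shape[1]
    # variables: lambda (n), mu (m), s+ (d), s- (d)
    A_eq = np.zeros((d + 2, n + m + 2 * d))
    A_eq[:d, :n] = P.T
    A_eq[:d, n:n + m] = -Q.T
    A_eq[:d, n + m:n + m + d] = np.eye(d)
    A_eq[:d, n + m + d:] = -np.eye(d)
    A_eq[d, :n] = 1.0
    A_eq[d + 1, n:n + m] = 1.0
    b_eq = np.zeros(d + 2)
    b_eq[d] = 1.0
    b_eq[d + 1] = 1.0
    c = np.concatenate([np.zeros(n + m), np.ones(2 * d)])
    bounds = [(0.0, 1.0)] * (n + m) + [(0.0, None)] * (2 * d)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    lam = res.x[:n]
    mu = res.x[n:n + m]
    residual = float(np.linalg.norm(P.T @ lam - Q.T @ mu))
    if res.fun <= tol:
        # certificate must re-verify before we report an intersection
        lam = np.clip(lam, 0.0, 1.0)
        mu = np.clip(mu, 0.0, 1.0)
        lam, mu = lam / lam.sum(), mu / mu.sum()
        residual = float(np.linalg.norm(P.T @ lam - Q.T @ mu))
        if residual > 10 * max(tol, 1e-12) * max(1.0, np.abs(P).max(), np.abs(Q).max()):
            raise RuntimeError(
                f"intersection certificate failed verification (residual {residual:g})"
            )
        return HullTestResult(False, tol, residual, lam, mu)
    return HullTestResult(True, tol, residual)


def pairwise_hull_scan(
    features: pd.DataFrame,
    labels,
    tol: float = 1e-7,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Hull-disjointness verdicts for every unordered pair of label groups.

    Returns a DataFrame (group1, group2, disjoint, residual); the number of
    intersecting pairs is ``(~report["disjoint"]).sum()``.
    """
    labels = np.asarray(labels)
    X = np.asarray(features, dtype=float)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match feature rows")
    groups = {g: X[labels == g] for g in pd.unique(labels)}
    if len(groups) < 2 and pairs is None:
        return pd.DataFrame(columns=["group1", "group2", "disjoint", "residual"])
    if pairs is None:
        pairs = list(combinations(sorted(groups), 2))
    rows = []
    for g1, g2 in pairs:
        r = hulls_disjoint(groups[g1], groups[g2], tol=tol)
        rows.append({"group1": g1, "group2": g2,
                     "disjoint": r.disjoint, "residual": r.residual})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LDAProjection:
    W: np.ndarray              # (d_in, d_out) projection matrix
    projected: np.ndarray      # (n, d_out) projected points
    labels: np.ndarray
    eigenvalues: np.ndarray    # discriminant eigenvalues, descending


class DiscriminantProjector(BaseEstimator, TransformerMixin):
    """Multi-class Fisher LDA projection to ``n_components`` dimensions.

    Solves the generalized eigenproblem S_b v = l S_w v, where S_w is the
    within-class scatter sum_c sum_{x in c} (x - m_c)(x - m_c)^T and S_b the
    between-class scatter sum_c n_c (m - m_c)(m - m_c)^T. With k classes at
    most k - 1 eigenvalues are nonzero; the projection takes the top
    ``n_components`` eigenvectors. A ridge ``reg * tr(S_w)/d * I`` is added
    to S_w when it is singular (with a warning).

    For a two-class 2-D view (a single discriminant direction exists), the
    second axis is the leading within-class principal direction orthogonal to
    the discriminant; ``axis_meaning_`` records this.
    """

    def __init__(self, n_components: int = 2, reg: float = 1e-8):
        self.n_components = n_components
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = pd.unique(y)
        if len(classes) < 2:
            raise ValueError("LDA requires at least two classes")
        d = X.shape[1]
        m = X.mean(axis=0)
        Sw = np.zeros((d, d))
        Sb = np.zeros((d, d))
        for c in classes:
            Xc = X[y == c]
            mc = Xc.mean(axis=0)
            diff = Xc - mc
            Sw += diff.T @ diff
            delta = (mc - m)[:, None]
            Sb += Xc.shape[0] * (delta @ delta.T)
        ridge = self.reg * max(np.trace(Sw) / d, 1.0)
        try:
            evals, evecs = scipy.linalg.eigh(Sb, Sw + ridge * np.eye(d))
        except scipy.linalg.LinAlgError:
            import warnings
            warnings.warn("singular within-class scatter; increasing ridge")
            ridge = 1e-3 * max(np.trace(Sw) / d, 1.0)
            evals, evecs = scipy.linalg.eigh(Sb, Sw + ridge * np.eye(d))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        n_informative = min(len(classes) - 1, d)
        d_out = min(self.n_components, d)
        W = evecs[:, :d_out].copy()
        self.axis_meaning_ = ["discriminant"] * min(d_out, n_informative)
        if d_out > n_informative:
            # augment with leading within-class PC orthogonal to the discriminants
            basis = W[:, :n_informative]
            qb, _ = np.linalg.qr(basis)
            proj = np.eye(d) - qb @ qb.T
            Swp = proj @ Sw @ proj
            pe, pv = np.linalg.eigh(Swp)
            extra = pv[:, ::-1][:, : d_out - n_informative]
            W[:, n_informative:] = extra
            self.axis_meaning_ += ["within_class_pc"] * (d_out - n_informative)
        self.scalings_ = W
        self.eigenvalues_ = evals[:n_informative]
        self.classes_ = classes
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.scalings_


def lda_project(X, labels, d: int = 2) -> LDAProjection:
    """Project a feature matrix to ``d`` dimensions by multi-class LDA."""
    arr = np.asarray(X, dtype=float)
    proj = DiscriminantProjector(n_components=d).fit(arr, labels)
    return LDAProjection(
        W=proj.scalings_,
        projected=proj.transform(arr),
        labels=np.asarray(labels),
        eigenvalues=proj.eigenvalues_,
    )
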