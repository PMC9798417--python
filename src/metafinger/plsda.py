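"""Partial least squares discriminant analysis (PLS-DA) with VIP scores.

Two-class PLS-DA is PLS1 regression of a centered 0/1 group code on the
autoscaled peak matrix.  Components are extracted by NIPALS: each component
has a unit-norm weight vector ``w_a`` maximizing covariance with the
response, scores ``t_a = X w_a``, X-loadings ``p_a`` and a y-loading
``q_a``, after which X is deflated by ``t_a p_a'``.  For a single response
the inner NIPALS loop converges in one pass, but successive components are
still mutually orthogonal in their scores.

Variable importance in projection (VIP) summarizes each feature's
contribution across components, weighted by the response variance each
component explains::

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a )

with ``p`` features and ``SSY_a = q_a^2 t_a' t_a`` the y-variance captured
by component ``a``.  By construction ``mean(VIP^2) = 1``, so VIP > 1 marks
features contributing more than average — the conventional screening
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PLSDA", "PLSDAResults", "vip_scores"]


class PLSDA:
    """PLS-DA model of a two-class response on an autoscaled matrix.

    Parameters
    ----------
    X : array-like, samples x features
        Column-scaled predictor matrix (autoscaled peak intensities).
    y : array-like
        Binary group labels; anything with exactly two distinct values.
    feature_names : sequence of str, optional
        Identifiers carried through to results tables.
    """

    def __init__(self, X, y, feature_names=None):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"y must have exactly two classes, found {classes.size}")
        self.classes_ = classes
        self.y = (y == classes[1]).astype(float)
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"x{j}" for j in range(self.X.shape[1])])
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")

    def fit(self, n_components: int = 2, tol: float = 1e-10,
            max_iter: int = 500) -> "PLSDAResults":
        """Extract ``n_components`` PLS components by NIPALS.

        The sign of each weight vector is fixed so its largest-magnitude
        entry is positive, resolving the inherent sign indeterminacy.
        """
        n, p = self.X.shape
        if not 1 <= n_components <= min(n - 1, p):
            raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
        Xc = self.X - self.X.mean(axis=0)
        yc = self.y - self.y.mean()
        ss_y_total = float(yc @ yc)
        if ss_y_total == 0:
            raise ValueError("response has no variance")

        W = np.zeros((p, n_components))
        P = np.zeros((p, n_components))
        Q = np.zeros(n_components)
        T = np.zeros((n, n_components))
        ssy = np.zeros(n_components)

        Xa, ya = Xc.copy(), yc.copy()
        for a in range(n_components):
            w = Xa.T @ ya
            for _ in range(max_iter):
                norm = np.linalg.norm(w)
                if norm == 0:
                    raise ValueError(f"component {a + 1}: X carries no covariance with y")
                w = w / norm
                t = Xa @ w
                q = float(ya @ t) / float(t @ t)
                w_new = Xa.T @ (ya * q)
                if np.linalg.norm(w_new / np.linalg.norm(w_new) - w) < tol:
                    break
                w = w_new
            # sign convention: largest-|w| entry positive
            lead = np.argmax(np.abs(w))
            if w[lead] < 0:
                w, t, q = -w, -t, -q
            p_a = Xa.T @ t / float(t @ t)
            W[:, a], T[:, a], P[:, a], Q[a] = w, t, p_a, q
            ssy[a] = q * q * float(t @ t)
            Xa = Xa - np.outer(t, p_a)
            ya = ya - q * t

        return PLSDAResults(self, W, P, Q, T, ssy, ss_y_total)


@dataclass
class PLSDAResults:
    """Fitted PLS-DA decomposition with scores, loadings, and VIP."""

    model: PLSDA
    weights: np.ndarray     # p x A, unit-norm columns
    loadings: np.ndarray    # p x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray      # n x A
    ssy: np.ndarray         # y sum-of-squares explained per component
    ss_y_total: float

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def explained_y_variance(self) -> np.ndarray:
        """Fraction of response variance captured by each component."""
        return self.ssy / self.ss_y_total

    def vip(self) -> np.ndarray:
        """Per-feature VIP, cumulative over the fitted components."""
        return vip_scores(self.weights, self.ssy)

    def vip_table(self) -> pd.DataFrame:
        v = self.vip()
        return (pd.DataFrame({"feature": self.model.feature_names, "vip": v})
                .sort_values("vip", ascending=False, ignore_index=True))

    def scores_table(self) -> pd.DataFrame:
        cols = {f"t{a + 1}": self.scores[:, a] for a in range(self.n_components)}
        cols["group"] = np.where(self.model.y == 1,
                                 str(self.model.classes_[1]), str(self.model.classes_[0]))
        return pd.DataFrame(cols)

    def summary(self) -> str:
        lines = [
            "PLS-DA (NIPALS PLS1)",
            f"  samples: {self.scores.shape[0]}   features: {self.weights.shape[0]}",
            f"  classes: {self.model.classes_[0]} (0) vs {self.model.classes_[1]} (1)",
            f"  components: {self.n_components}",
        ]
        for a, frac in enumerate(self.explained_y_variance):
            lines.append(f"    component {a + 1}: R2Y = {frac:.4f}")
        v = self.vip()
        lines.append(f"  VIP > 1.0: {int((v > 1.0).sum())} of {v.size} features")
        return "\n".join(lines)


def vip_scores(weights: np.ndarray, ssy: np.ndarray) -> np.ndarray:
    """VIP from per-component weights and explained y sums-of-squares.

    Weight columns are renormalized defensively; the identity
    ``mean(VIP^2) == 1`` holds exactly.
    """
    W = np.asarray(weights, dtype=float)
    ssy = np.asarray(ssy, dtype=float)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("total explained y variance is zero; VIP undefined")
    p = W.shape[0]
    norms = np.linalg.norm(W, axis=0)
    Wn = W / np.where(norms > 0, norms, 1.0)
    return np.sqrt(p * (Wn ** 2 @ ssy) / total)
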