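"""Partial least squares discriminant analysis (NIPALS PLS2).

PLS-DA here is a diagnostic: it produces the score plots used to inspect
class separation of the fragment feature matrix (tumour vs non-tumour,
HCC vs MFCCC).  Classification proper is done by the SVM/RF pipeline in
:mod:`pesiml.classify`.

The implementation is the classical NIPALS PLS2 algorithm on the
column-mean-centred feature matrix X against a one-hot class-membership
matrix Y: per component, the X-weight vector w is iterated as
``w = X' u / (u' u)`` (normalized), scores ``t = X w``, Y-loadings
``q = Y' t / (t' t)``, ``u = Y q / (q' q)`` until t converges; X is then
deflated by the rank-one approximation ``t p'`` with ``p = X' t/(t' t)``.
The first weight vector equals the dominant left singular vector of
``Xc' Yc``, which the test-suite verifies against an SVD oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FeatureMatrix, ValidationError

__all__ = ["PLSDAModel", "plsda_fit", "scores_table"]


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS2 decomposition with class encoding."""

    n_components: int
    classes: tuple[str, ...]
    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray  # (n_bins, A) X-weights, unit norm
    P: np.ndarray  # (n_bins, A) X-loadings
    Q: np.ndarray  # (n_classes, A) Y-loadings
    T: np.ndarray  # (n_rows, A) X-scores
    explained_x_variance: np.ndarray  # fraction of centred-X SS per component
    row_meta: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        # score columns must be mutually orthogonal (NIPALS with X-deflation)
        G = self.T.T @ self.T
        off = G - np.diag(np.diag(G))
        scale = max(np.abs(np.diag(G)).max(), 1e-30)
        if np.abs(off).max() > 1e-8 * scale:
            raise ValidationError("score columns are not orthogonal")
        if np.any(self.explained_x_variance < -1e-12) or np.any(
            self.explained_x_variance > 1 + 1e-12
        ):
            raise ValidationError("explained X-variance fractions outside [0, 1]")


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    classes = tuple(sorted(set(labels.tolist())))
    Y = np.zeros((labels.size, len(classes)))
    for k, c in enumerate(classes):
        Y[labels == c, k] = 1.0
    return Y, classes


def plsda_fit(
    fm: FeatureMatrix,
    labels: np.ndarray | None = None,
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSDAModel:
    """Fit NIPALS PLS-DA on a feature matrix.

    ``labels`` defaults to ``fm.row_meta['tissue_label']``.  Deterministic:
    the inner iteration for each component starts from the column of the
    (deflated) Y with maximal variance.
    """
    X0 = np.asarray(fm.X, dtype=float)
    if labels is None:
        labels = fm.row_meta["tissue_label"].to_numpy()
    labels = np.asarray(labels)
    if labels.size != X0.shape[0]:
        raise ValidationError("labels length does not match matrix rows")
    Y0, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValidationError("PLS-DA needs at least 2 classes")
    if n_components > min(X0.shape[0] - 1, X0.shape[1]):
        raise ValidationError(
            f"n_components={n_components} exceeds min(rows-1, bins)="
            f"{min(X0.shape[0] - 1, X0.shape[1])}"
        )

    x_mean = X0.mean(axis=0)
    y_mean = Y0.mean(axis=0)
    X = X0 - x_mean
    Y = Y0 - y_mean
    ss_x = float((X ** 2).sum())

    n, p = X.shape
    A = n_components
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((len(classes), A))
    T = np.zeros((n, A))
    expl = np.zeros(A)

    for a in range(A):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        t_old = None
        for it in range(max_iter):
            w = X.T @ u / float(u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValidationError(f"component {a + 1}: degenerate weight vector")
            w /= nw
            t = X @ w
            q = Y.T @ t / float(t @ t)
            u = Y @ q / float(q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise ValidationError(
                f"NIPALS did not converge for component {a + 1} after {max_iter} "
                f"iterations (last step {np.linalg.norm(t - t_old):.3e})"
            )
        p_vec = X.T @ t / float(t @ t)
        X = X - np.outer(t, p_vec)
        Y = Y - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q, t
        expl[a] = float(t @ t) * float(p_vec @ p_vec) / ss_x if ss_x > 0 else 0.0

    return PLSDAModel(
        n_components=A,
        classes=classes,
        x_mean=x_mean,
        y_mean=y_mean,
        W=W,
        P=P,
        Q=Q,
        T=T,
        explained_x_variance=expl,
        row_meta=fm.row_meta.reset_index(drop=True),
        labels=labels,
    )


def scores_table(model: PLSDAModel, component_i: int = 1, component_j: int = 2) -> pd.DataFrame:
    """Per-fragment score-plot table for components i and j (1-based)."""
    for c in (component_i, component_j):
        if not 1 <= c <= model.n_components:
            raise ValidationError(
                f"component {c} not in fitted range 1..{model.n_components}"
            )
    return pd.DataFrame(
        {
            "sample_id": model.row_meta["sample_id"],
            "label": model.labels,
            f"score_{component_i}": model.T[:, component_i - 1],
            f"score_{component_j}": model.T[:, component_j - 1],
        }
    )
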