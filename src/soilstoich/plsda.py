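"""Partial least squares discriminant analysis with VIP scores and k-fold Q².

PLS-DA regresses a centered one-hot class-membership matrix Y on the
preprocessed intensity matrix X by PLS2 (NIPALS).  Model quality is reported
as R² (fraction of class-matrix variance explained by the full fit) and Q²
(1 − PRESS/TSS over stratified k-fold held-out predictions); per-variable
influence as VIP scores, whose squares average to one by construction, with
VIP > 1 the conventional importance threshold.

Exposed in the model/results idiom::

    results = PLSDA(X, y, n_components=2).fit()
    results.vip()            # cumulative VIP over all components
    results.summary()        # text table
    cross_validate(X, y, k=5, n_components=2)   # (R2, Q2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression


def one_hot(y) -> tuple[np.ndarray, list]:
    """Class labels -> indicator matrix (n x k), with the class order used."""
    labels = list(pd.unique(np.asarray(y)))
    Y = np.zeros((len(y), len(labels)))
    for i, v in enumerate(np.asarray(y)):
        Y[i, labels.index(v)] = 1.0
    return Y, labels


class PLSDA:
    """PLS-DA model specification: data plus the number of latent components."""

    def __init__(self, X, y, n_components: int = 2):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x variables)")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("y length must match the number of rows of X")
        if len(pd.unique(self.y)) < 2:
            raise ValueError("PLS-DA needs at least two classes")
        max_comp = min(self.X.shape[0] - 1, self.X.shape[1])
        if not 1 <= n_components <= max_comp:
            raise ValueError(
                f"n_components must be in [1, {max_comp}] for this data"
            )
        self.n_components = n_components

    def fit(self) -> "PLSDAResults":
        Y, classes = one_hot(self.y)
        pls = PLSRegression(n_components=self.n_components, scale=False)
        pls.fit(self.X, Y)
        T = pls.x_scores_.copy()
        W = pls.x_weights_.copy()
        P = pls.x_loadings_.copy()
        Q = pls.y_loadings_.copy()
        # deterministic sign convention: per component, the largest-|w| entry
        # is positive; flipping (w, t, p, q) together leaves the fit invariant
        for a in range(self.n_components):
            j = int(np.argmax(np.abs(W[:, a])))
            if W[j, a] < 0:
                W[:, a] *= -1
                T[:, a] *= -1
                P[:, a] *= -1
                Q[:, a] *= -1
        Yhat = pls.predict(self.X)
        Yc = Y - Y.mean(axis=0)
        tss = float((Yc**2).sum())
        rss = float(((Y - Yhat) ** 2).sum())
        # per-component explained class variance: ssy_a = (t_a·t_a)(q_a·q_a)
        ssy = np.array(
            [T[:, a] @ T[:, a] * (Q[:, a] @ Q[:, a]) for a in range(self.n_components)]
        )
        return PLSDAResults(
            model=self,
            classes=classes,
            scores=T,
            weights=W,
            x_loadings=P,
            y_loadings=Q,
            ssy_per_component=ssy,
            r2=1.0 - rss / tss,
            _sk_model=pls,
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA: scores, weights, explained class variance, R² and VIP."""

    model: PLSDA
    classes: list
    scores: np.ndarray  # T, (n x a)
    weights: np.ndarray  # W, (p x a), unit columns
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    ssy_per_component: np.ndarray
    r2: float
    _sk_model: PLSRegression | None = None

    @property
    def n_components(self) -> int:
        return self.model.n_components

    def vip(self, n_components: int | None = None) -> np.ndarray:
        """Variable importance in projection over the first ``n_components``.

        vip_j = sqrt( p * sum_a ssy_a w_aj^2 / sum_a ssy_a ) with unit-norm
        weight vectors; mean(vip^2) = 1 identically.
        """
        a = self.n_components if n_components is None else n_components
        if not 1 <= a <= self.n_components:
            raise ValueError("n_components out of fitted range")
        W = self.weights[:, :a]
        Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
        ssy = self.ssy_per_component[:a]
        p = W.shape[0]
        return np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())

    def selected_variables(self, threshold: float = 1.0) -> np.ndarray:
        """Indices of variables with VIP above the threshold (default > 1)."""
        return np.nonzero(self.vip() > threshold)[0]

    def predict(self, X) -> np.ndarray:
        return self._sk_model.predict(np.asarray(X, dtype=float))

    def scores_frame(self, n_components: int = 3) -> pd.DataFrame:
        """Score table for external plotting (up to the first 3 components)."""
        a = min(n_components, self.n_components)
        df = pd.DataFrame(
            self.scores[:, :a], columns=[f"component_{i+1}" for i in range(a)]
        )
        df.insert(0, "label", self.model.y)
        return df

    def summary(self) -> str:
        vip = self.vip()
        frac = self.ssy_per_component / self.ssy_per_component.sum()
        lines = [
            "PLS-DA results",
            f"  samples: {self.model.X.shape[0]}  variables: {self.model.X.shape[1]}"
            f"  classes: {len(self.classes)}  components: {self.n_components}",
            f"  R2 (class matrix): {self.r2:.4f}",
            "  explained class-variance share per component: "
            + ", ".join(f"{v:.3f}" for v in frac),
            f"  variables with VIP > 1: {int((vip > 1).sum())} of {len(vip)}",
        ]
        return "\n".join(lines)


def stratified_folds(y, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold indices that tolerate classes smaller than k.

    Each class's members are shuffled and dealt round-robin across folds (the
    deal starts at a random fold per class so small classes do not pile onto
    fold 0).  With class size >= k this is ordinary stratified k-fold; smaller
    classes simply skip some folds, so the training split always retains most
    of every class — the documented graceful degradation.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    y = np.asarray(y)
    if k > len(y):
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    for cls in pd.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        start = int(rng.integers(k))
        fold_of[idx] = (start + np.arange(len(idx))) % k
    folds = []
    for f in range(k):
        test = np.nonzero(fold_of == f)[0]
        if len(test) == 0:
            continue
        folds.append((np.nonzero(fold_of != f)[0], test))
    return folds


def cross_validate(
    X, y, k: int = 5, n_components: int = 2, seed: int = 0
) -> tuple[float, float]:
    """(R², Q²) of a PLS-DA at fixed components under stratified k-fold CV.

    R² comes from the full-data fit.  Q² = 1 − PRESS/TSS, with PRESS pooled
    over held-out predictions of the class matrix across folds and TSS the
    total sum of squares of the centered full class matrix.  Folds are
    stratified by class and seeded; when a class has fewer members than k the
    stratification degrades gracefully (some folds simply lack that class).
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    full = PLSDA(X, y, n_components=n_components).fit()
    Y, classes = one_hot(y)
    press = 0.0
    for train, test in stratified_folds(y, k, seed):
        pls = PLSRegression(
            n_components=min(n_components, len(train) - 1, X.shape[1]), scale=False
        )
        pls.fit(X[train], Y[train])
        press += float(((Y[test] - pls.predict(X[test])) ** 2).sum())
    Yc = Y - Y.mean(axis=0)
    tss = float((Yc**2).sum())
    return full.r2, 1.0 - press / tss
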