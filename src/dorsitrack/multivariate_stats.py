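"""PCA and OPLS-DA with leave-out-p cross-validation and jackknife CIs.

PCA (on mean-centered, unit-variance-scaled columns, the usual convention
of chemometric software) is the exploratory view of the 25-variable
deformation matrix. OPLS-DA separates class-predictive variation from
class-orthogonal variation: orthogonal components, uncorrelated with the
class response, are stripped first, then a single predictive component is
fitted for the two-class problem. Variable-level uncertainty comes from
jackknifing over the cross-validation sub-models: subjects are split into
seven stratified folds (leave-out-p with p of about one seventh of the
subjects), the predictive loadings of the seven sub-models give a
jackknife standard error, and a variable is flagged significant when its
confidence interval excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class Preprocessor:
    """Column centering/scaling parameters with inverse transform."""

    means: np.ndarray
    scales: np.ndarray
    kept: np.ndarray  # indices of retained (non-constant) columns
    n_columns: int
    scale: bool = True

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept]
        return (X - self.means) / self.scales

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        """Inverse map on the retained columns."""
        return Z * self.scales + self.means


def preprocess(X: np.ndarray, scale: bool = True,
               column_names: list[str] | None = None) \
        -> tuple[np.ndarray, Preprocessor]:
    """Mean-center (and by default unit-variance scale) the columns.

    Zero-variance columns carry no information and break scaling; they are
    excluded with a log entry and recorded in the preprocessor.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing values; reject rows upstream")
    sd = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < X.shape[1]:
        dropped = np.flatnonzero(sd == 0)
        names = [column_names[i] for i in dropped] if column_names else dropped.tolist()
        logger.warning("dropping %d zero-variance column(s): %s",
                       len(dropped), names)
    means = X[:, kept].mean(axis=0)
    scales = sd[kept] if scale else np.ones(len(kept))
    pp = Preprocessor(means, scales, kept, X.shape[1], scale)
    return pp.transform(np.asarray(X, dtype=float)[:, :]), pp


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Principal components of the preprocessed matrix."""

    scores: np.ndarray  # (n, c)
    loadings: np.ndarray  # (p, c), orthonormal columns
    explained_variance_fraction: np.ndarray
    preprocessor: Preprocessor

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T


def fit_pca(X: np.ndarray, n_components: int = 2, scale: bool = True) -> PcaModel:
    """PCA by singular-value decomposition of the preprocessed matrix.

    Deterministic sign convention: the largest-magnitude element of each
    loading vector is made positive.
    """
    Z, pp = preprocess(X, scale=scale)
    n, p = Z.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds the matrix rank bound")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt.T[:, :n_components]
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    V = V * flip
    scores = Z @ V
    total_var = np.sum(s**2)
    evf = (s[:n_components] ** 2) / total_var
    return PcaModel(scores, V, evf, pp)


# --------------------------------------------------------------------------
# OPLS-DA
# --------------------------------------------------------------------------

@dataclass
class OplsDaModel:
    """Two-class OPLS-DA with one predictive component.

    ``predictive_loadings`` are on the preprocessed variable scale and
    refer to the retained columns of the preprocessor. Jackknife fields
    are filled by :func:`crossvalidate_jackknife`.
    """

    classes: tuple
    weights: np.ndarray  # predictive w, unit norm
    scores: np.ndarray  # predictive t
    predictive_loadings: np.ndarray  # p
    q: float  # response loading
    ortho_weights: np.ndarray  # (p_vars, n_orth)
    ortho_scores: np.ndarray  # (n, n_orth)
    ortho_loadings: np.ndarray  # (p_vars, n_orth)
    y_mean: float
    preprocessor: Preprocessor
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    significant: np.ndarray | None = None
    cv_predictions: np.ndarray | None = None
    cv_accuracy: float = np.nan
    folds: np.ndarray | None = None

    @property
    def n_orthogonal(self) -> int:
        return self.ortho_scores.shape[1]

    def _filter(self, Z: np.ndarray) -> np.ndarray:
        for j in range(self.n_orthogonal):
            t_o = Z @ self.ortho_weights[:, j]
            Z = Z - np.outer(t_o, self.ortho_loadings[:, j])
        return Z

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Continuous class score for new rows (original column space)."""
        Z = self.preprocessor.transform(np.asarray(X, dtype=float))
        t = self._filter(Z) @ self.weights
        return t * self.q + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard class labels for new rows."""
        yhat = self.decision_values(X)
        return np.where(yhat >= 0, self.classes[1], self.classes[0])


def _dummy_response(labels: np.ndarray) -> tuple[np.ndarray, tuple]:
    classes = tuple(sorted(set(labels)))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y = np.where(np.asarray(labels) == classes[1], 1.0, -1.0)
    return y, classes


def fit_opls_da(X: np.ndarray, labels, n_orthogonal: int = 1,
                scale: bool = True,
                preprocessor: Preprocessor | None = None) -> OplsDaModel:
    """Fit a two-class OPLS-DA model with one predictive component.

    The class response is a centered +/-1 dummy. Orthogonal components are
    extracted iteratively (each is the part of the current X-weight
    structure orthogonal to the predictive direction), then the predictive
    component is computed on the filtered matrix. ``n_orthogonal = 0``
    reduces exactly to a 1-component PLS-DA.
    """
    labels = np.asarray(labels)
    y, classes = _dummy_response(labels)
    counts = [np.sum(labels == c) for c in classes]
    if min(counts) < 3:
        raise ValueError("each class needs >= 3 members")
    if preprocessor is None:
        Z, pp = preprocess(X, scale=scale)
    else:
        pp = preprocessor
        Z = pp.transform(np.asarray(X, dtype=float))
    y_mean = float(y.mean())
    yc = y - y_mean

    p_vars = Z.shape[1]
    W_o = np.zeros((p_vars, n_orthogonal))
    T_o = np.zeros((len(y), n_orthogonal))
    P_o = np.zeros((p_vars, n_orthogonal))
    Zf = Z.copy()
    for j in range(n_orthogonal):
        w = Zf.T @ yc
        w /= np.linalg.norm(w)
        t = Zf @ w
        p = Zf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            logger.warning("orthogonal component %d vanished; stopping", j + 1)
            W_o, T_o, P_o = W_o[:, :j], T_o[:, :j], P_o[:, :j]
            break
        w_o /= nrm
        t_o = Zf @ w_o
        p_o = Zf.T @ t_o / (t_o @ t_o)
        Zf = Zf - np.outer(t_o, p_o)
        W_o[:, j], T_o[:, j], P_o[:, j] = w_o, t_o, p_o

    w = Zf.T @ yc
    w /= np.linalg.norm(w)
    t = Zf @ w
    p = Zf.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    return OplsDaModel(classes=classes, weights=w, scores=t,
                       predictive_loadings=p, q=q, ortho_weights=W_o,
                       ortho_scores=T_o, ortho_loadings=P_o,
                       y_mean=y_mean, preprocessor=pp)


def stratified_folds(labels, n_folds: int = 7,
                     seed: int | None = 0) -> np.ndarray:
    """Fold assignment per row: class-stratified, seeded, sizes within one.

    With n subjects and 7 folds each fold holds about one seventh of the
    subjects (9 or 10 of 68).
    """
    labels = np.asarray(labels)
    if len(labels) < n_folds:
        raise ValueError(f"need at least {n_folds} rows for {n_folds} folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    offset = 0
    for c in sorted(set(labels)):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        # continue the round-robin across classes so fold sizes balance
        folds[idx] = (np.arange(len(idx)) + offset) % n_folds
        offset += len(idx)
    return folds


def crossvalidate_jackknife(X: np.ndarray, labels, n_orthogonal: int = 1,
                            n_folds: int = 7, seed: int | None = 0,
                            scale: bool = True,
                            ci_level: float = 0.95) -> OplsDaModel:
    """OPLS-DA with leave-out-p cross-validation and jackknife CIs.

    The full model is fitted on all rows; each of the ``n_folds``
    sub-models omits one fold. Sub-model predictive loadings (sign-aligned
    to the full model) give a jackknife standard error per variable; the
    CI is the full-model loading +/- t(n_folds - 1) * SE. A variable is
    significant when its CI excludes zero. Held-out class predictions from
    the sub-models are recorded, with the overall held-out accuracy.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    model = fit_opls_da(X, labels, n_orthogonal=n_orthogonal, scale=scale)
    folds = stratified_folds(labels, n_folds=n_folds, seed=seed)

    loadings = np.empty((n_folds, len(model.predictive_loadings)))
    cv_pred = np.empty(len(labels), dtype=object)
    for f in range(n_folds):
        train = folds != f
        sub = fit_opls_da(X[train], labels[train],
                          n_orthogonal=n_orthogonal, scale=scale)
        p_sub = np.full(model.preprocessor.n_columns, 0.0)
        p_sub[sub.preprocessor.kept] = sub.predictive_loadings
        p_sub = p_sub[model.preprocessor.kept]
        if p_sub @ model.predictive_loadings < 0:
            p_sub = -p_sub
        loadings[f] = p_sub
        cv_pred[folds == f] = sub.predict(X[folds == f])

    g = n_folds
    mean_l = loadings.mean(axis=0)
    se = np.sqrt((g - 1) / g * np.sum((loadings - mean_l) ** 2, axis=0))
    tq = stats.t.ppf(0.5 + ci_level / 2, g - 1)
    model.ci_low = model.predictive_loadings - tq * se
    model.ci_high = model.predictive_loadings + tq * se
    model.significant = (model.ci_low > 0) | (model.ci_high < 0)
    model.cv_predictions = cv_pred
    model.cv_accuracy = float(np.mean(cv_pred == labels))
    model.folds = folds
    return model


def loading_table(model: OplsDaModel, column_names: list[str]):
    """Per-variable loading / CI / significance table (pandas DataFrame)."""
    import pandas as pd

    kept = model.preprocessor.kept
    return pd.DataFrame({
        "variable": [column_names[i] for i in kept],
        "loading": model.predictive_loadings,
        "ci_low": model.ci_low,
        "ci_high": model.ci_high,
        "significant": model.significant,
    })
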