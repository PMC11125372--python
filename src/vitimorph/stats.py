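"""Multivariate engine: PCA, stepwise LDA, LOOCV, posterior allocation.

The classifier is the classical multi-group linear discriminant: groups share
a pooled within-group covariance S_w, and the posterior for specimen x and
group g is

    p(g | x)  proportional to  prior_g * exp(-1/2 * D^2(x, mu_g))

with D^2 the Mahalanobis distance under S_w. Variable selection is greedy
stepwise minimization of Wilks' lambda with partial-F thresholds to enter and
remove, the long-standing default of stepwise discriminant analysis in
mainstream statistical packages. Unknown specimens (e.g. fossils) are held
out of fitting and assigned by maximum posterior, optionally subject to a
minimum-posterior threshold below which a specimen stays "unassigned".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA as _SKPCA
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "PCAResult",
    "ClassificationReport",
    "AllocationTable",
    "StepwiseLDA",
    "run_pca",
    "stepwise_select",
    "fit_lda",
    "loocv_classify",
    "classify_unknown",
    "threshold_allocate",
    "round_report",
]

UNKNOWN_LABEL = "unknown"


def round_report(x, decimals: int = 1):
    """Round half away from zero (report formatting convention)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray          # specimens x components
    loadings: np.ndarray        # variables x components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None = None


@dataclass(frozen=True)
class ClassificationReport:
    """Cross-validated classification summary.

    ``confusion_pct`` is a row-percentage confusion matrix (true group by
    predicted group; each row sums to 100); ``correct_pct`` is the overall
    cross-validated correct-classification percentage.
    """

    confusion_pct: pd.DataFrame
    correct_pct: float
    posteriors: pd.DataFrame    # per-specimen posterior probabilities
    predicted: pd.Series


@dataclass(frozen=True)
class AllocationTable:
    """Percentage of the unknown set allocated to each reference group.

    Includes an "unassigned" category when a posterior threshold is applied
    (threshold=None means pure argmax allocation).
    """

    percentages: pd.Series
    counts: pd.Series
    threshold: float | None
    n_unknown: int


def run_pca(X: np.ndarray, center: bool = True, scale: bool = False) -> PCAResult:
    """PCA by eigendecomposition of the covariance (or correlation) matrix.

    Components are ordered by decreasing variance with a deterministic sign
    convention: the largest-magnitude loading of each component is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 specimens and 2 variables")
    sd = None
    Xw = X
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot scale constant variables")
        Xw = (X - X.mean(axis=0)) / sd
    if np.allclose(Xw, Xw.mean(axis=0)):
        raise ValueError("constant matrix has no principal components")
    # sklearn's PCA always centers; `center=False` is not part of the study
    # workflow but kept honest by adding the mean back into the scores.
    pca = _SKPCA(svd_solver="full")
    scores = pca.fit_transform(Xw)
    loadings = pca.components_.T.copy()
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    if not center and not scale:
        scores = (X @ loadings)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=Xw.mean(axis=0) if center else np.zeros(X.shape[1]),
        scale=sd,
    )


# ---------------------------------------------------------------------------
# Wilks' lambda stepwise selection


def _sscp(X: np.ndarray, y: np.ndarray):
    """Within-group and total sum-of-squares-and-cross-products matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    return W, T


def _wilks(W: np.ndarray, T: np.ndarray, idx: list[int]) -> float:
    if not idx:
        return 1.0
    ix = np.ix_(idx, idx)
    sw, ldw = np.linalg.slogdet(W[ix])
    st, ldt = np.linalg.slogdet(T[ix])
    if sw <= 0 or st <= 0:
        return np.nan
    return float(np.exp(ldw - ldt))


def stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_steps: int = 100,
) -> list[int]:
    """Greedy Wilks' lambda stepwise variable selection.

    At each step the candidate with the largest partial F-to-enter joins the
    model if it reaches ``f_enter``; included variables whose partial
    F-to-remove falls below ``f_remove`` are then dropped. ``f_enter`` must
    exceed ``f_remove`` (termination guarantee). Constant variables are never
    selected; ties break toward the lowest column index. An empty selection
    (no variable reaches ``f_enter``) returns ``[]`` with a warning.
    """
    if f_enter <= f_remove:
        raise ValueError("f_enter must be greater than f_remove")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.unique(y)
    g = len(groups)
    n, p = X.shape
    if g < 2:
        raise ValueError("stepwise selection needs at least 2 groups")
    W, T = _sscp(X, y)
    constant = np.isclose(np.diag(T), 0.0, atol=1e-12 * max(1.0, np.trace(T)))
    selected: list[int] = []
    lam_sel = 1.0
    seen = set()
    for _ in range(max_steps):
        state = tuple(selected)
        if state in seen:
            break
        seen.add(state)
        q = len(selected)
        if n - g - q < 1:
            break
        # --- entry scan
        best_j, best_f, best_lam = -1, -np.inf, np.nan
        for j in range(p):
            if j in selected or constant[j]:
                continue
            # tolerance guard: skip candidates (near-)collinear with the
            # current set, as measured on the within-group dispersion
            if selected:
                ix = np.ix_(selected, selected)
                sj, ldj = np.linalg.slogdet(
                    W[np.ix_(selected + [j], selected + [j])]
                )
                ss, lds = np.linalg.slogdet(W[ix])
                if sj <= 0 or ss <= 0:
                    continue
                tol = np.exp(ldj - lds) / W[j, j]
                if tol < 1e-4:
                    continue
            lam_j = _wilks(W, T, selected + [j])
            if not np.isfinite(lam_j) or lam_j <= 0:
                continue
            F = (lam_sel / lam_j - 1.0) * (n - g - q) / (g - 1)
            if F > best_f + 1e-12:
                best_j, best_f, best_lam = j, F, lam_j
        if best_j >= 0 and best_f >= f_enter:
            selected.append(best_j)
            lam_sel = best_lam
        else:
            break
        # --- removal scan
        removed = True
        while removed and len(selected) > 1:
            removed = False
            q = len(selected)
            worst_j, worst_f, worst_lam = -1, np.inf, np.nan
            for j in selected:
                rest = [k for k in selected if k != j]
                lam_rest = _wilks(W, T, rest)
                F = (lam_rest / lam_sel - 1.0) * (n - g - q + 1) / (g - 1)
                if F < worst_f - 1e-12:
                    worst_j, worst_f, worst_lam = j, F, lam_rest
            if worst_j >= 0 and worst_f < f_remove:
                selected.remove(worst_j)
                lam_sel = worst_lam
                removed = True
    if not selected:
        warnings.warn(
            "stepwise selection admitted no variable at "
            f"F-to-enter={f_enter}; caller should fall back to all "
            "non-constant variables",
            stacklevel=2,
        )
    return selected


# ---------------------------------------------------------------------------
# Linear discriminant classifier


class StepwiseLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant analysis with optional stepwise variable selection.

    Parameters
    ----------
    stepwise : bool, default True
        Run Wilks' lambda stepwise selection before fitting. If no variable
        reaches ``f_enter`` the model falls back to all non-constant
        variables.
    f_enter, f_remove : float
        Partial-F thresholds for stepwise entry (default 3.84) and removal
        (default 2.71).
    priors : {"equal", "proportional"}, default "equal"
        Group prior probabilities. Accession sizes are usually sampling
        artifacts, hence equal priors by default.
    variables : sequence of int or None
        Explicit variable subset; overrides stepwise selection.
    ridge : float, default 1e-8
        Relative ridge (times trace/dim) added to a numerically singular
        pooled covariance before giving up.

    Attributes
    ----------
    classes_ : ndarray of group labels (unknowns never included).
    selected_ : list of selected column indices.
    means_ : (n_groups, n_selected) group means on selected variables.
    pooled_cov_ : pooled within-group covariance on selected variables.
    precision_ : its inverse.
    priors_ : group prior probabilities.
    """

    def __init__(
        self,
        stepwise: bool = True,
        f_enter: float = 3.84,
        f_remove: float = 2.71,
        priors: str = "equal",
        variables=None,
        ridge: float = 1e-8,
        max_steps: int = 100,
    ):
        self.stepwise = stepwise
        self.f_enter = f_enter
        self.f_remove = f_remove
        self.priors = priors
        self.variables = variables
        self.ridge = ridge
        self.max_steps = max_steps

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("LDA needs at least 2 groups")
        if np.any(counts < 2):
            bad = classes[counts < 2]
            raise ValueError(f"groups with fewer than 2 specimens: {list(bad)}")
        n, p = X.shape
        if self.variables is not None:
            sel = list(self.variables)
        elif self.stepwise:
            sel = stepwise_select(
                X, y, self.f_enter, self.f_remove, self.max_steps
            )
            if not sel:
                sel = [
                    j for j in range(p)
                    if not np.isclose(np.var(X[:, j]), 0.0)
                ]
        else:
            sel = list(range(p))
        if not sel:
            raise ValueError("no usable (non-constant) variables")
        Xs = X[:, sel]
        means = np.vstack([Xs[y == g].mean(axis=0) for g in classes])
        W = np.zeros((len(sel), len(sel)))
        for g in classes:
            Xg = Xs[y == g] - Xs[y == g].mean(axis=0)
            W += Xg.T @ Xg
        dof = n - len(classes)
        if dof < 1:
            raise ValueError("no within-group degrees of freedom")
        cov = W / dof
        prec = self._invert(cov, sel)
        if self.priors == "equal":
            priors = np.full(len(classes), 1.0 / len(classes))
        elif self.priors == "proportional":
            priors = counts / counts.sum()
        else:
            raise ValueError("priors must be 'equal' or 'proportional'")
        self.classes_ = classes
        self.selected_ = sel
        self.means_ = means
        self.pooled_cov_ = cov
        self.precision_ = prec
        self.priors_ = priors
        self.n_features_in_ = p
        # linear classification functions: score_g(x) = c_g + x . w_g
        self.coef_ = means @ prec
        self.intercept_ = (
            -0.5 * np.einsum("ij,ij->i", means @ prec, means) + np.log(priors)
        )
        return self

    def _invert(self, cov, sel):
        try:
            return np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            pass
        eps = self.ridge * np.trace(cov) / cov.shape[0]
        ridged = cov + eps * np.eye(cov.shape[0])
        try:
            return np.linalg.inv(ridged)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "pooled within-group covariance singular even after ridge; "
                f"offending variables: {sel}"
            ) from err

    def _mahalanobis2(self, X):
        diff = X[:, None, :] - self.means_[None, :, :]
        return np.einsum("sgi,ij,sgj->sg", diff, self.precision_, diff)

    def decision_function(self, X):
        check_is_fitted(self, "classes_")
        X = check_array(X)[:, self.selected_]
        return np.log(self.priors_)[None, :] - 0.5 * self._mahalanobis2(X)

    def predict_proba(self, X):
        """Posterior probabilities p(g | x) under the pooled-covariance model."""
        s = self.decision_function(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        # np.argmax breaks posterior ties toward the lowest group index
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_lda(X, y, variables=None, priors: str = "equal") -> StepwiseLDA:
    """Fit a (non-stepwise) LDA on an explicit variable set.

    ``variables=None`` uses all columns.
    """
    model = StepwiseLDA(stepwise=False, variables=variables, priors=priors)
    return model.fit(X, y)


def loocv_classify(
    X,
    y,
    variables=None,
    priors: str = "equal",
    reselect_per_fold: bool = False,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    ids=None,
) -> ClassificationReport:
    """Leave-one-out cross-validated classification.

    Each specimen is classified by a model refitted on all the others. The
    variable set is fixed across folds by default (selection done once by the
    caller, the conventional stepwise-LDA reporting mode);
    ``reselect_per_fold=True`` reruns stepwise selection inside every fold as
    a sensitivity analysis.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n = len(y)
    if ids is None:
        ids = [str(i) for i in range(n)]
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 3):
        bad = classes[counts < 3]
        raise ValueError(
            f"groups too small for leave-one-out refits: {list(bad)}"
        )
    post = np.empty((n, len(classes)))
    pred = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        if reselect_per_fold:
            model = StepwiseLDA(
                stepwise=True, f_enter=f_enter, f_remove=f_remove,
                priors=priors,
            )
        else:
            model = StepwiseLDA(stepwise=False, variables=variables,
                                priors=priors)
        model.fit(X[mask], y[mask])
        pi = np.zeros(len(classes))
        proba = model.predict_proba(X[i:i + 1])[0]
        for cls, pr in zip(model.classes_, proba):
            pi[list(classes).index(cls)] = pr
        post[i] = pi
        pred[i] = classes[np.argmax(pi)]
        mask[i] = True
    conf = np.zeros((len(classes), len(classes)))
    for i, g in enumerate(y):
        conf[list(classes).index(g), list(classes).index(pred[i])] += 1
    row_pct = 100.0 * conf / conf.sum(axis=1, keepdims=True)
    correct = 100.0 * float(np.trace(conf)) / n
    return ClassificationReport(
        confusion_pct=pd.DataFrame(row_pct, index=classes, columns=classes),
        correct_pct=correct,
        posteriors=pd.DataFrame(post, index=ids, columns=classes),
        predicted=pd.Series(pred, index=ids),
    )


def classify_unknown(model: StepwiseLDA, X_unknown, ids=None):
    """Posteriors for unknown specimens plus their argmax allocation table."""
    check_is_fitted(model, "classes_")
    proba = model.predict_proba(X_unknown)
    if ids is None:
        ids = [str(i) for i in range(len(proba))]
    posteriors = pd.DataFrame(proba, index=ids, columns=model.classes_)
    table = threshold_allocate(posteriors, p_min=None)
    return posteriors, table


def threshold_allocate(
    posteriors: pd.DataFrame, p_min: float | None = 0.90
) -> AllocationTable:
    """Allocate each specimen to its maximum-posterior group, requiring the
    posterior to reach ``p_min`` (inclusive); otherwise "unassigned".

    ``p_min=None`` disables the threshold (pure argmax allocation).
    """
    if p_min is not None and not (0.0 < p_min <= 1.0):
        raise ValueError("p_min must lie in (0, 1]")
    sums = posteriors.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("posterior vectors must each sum to 1")
    groups = list(posteriors.columns)
    n = len(posteriors)
    winners = posteriors.values.argmax(axis=1)
    pmax = posteriors.values.max(axis=1)
    labels = []
    for w, p in zip(winners, pmax):
        if p_min is not None and p < p_min:
            labels.append("unassigned")
        else:
            labels.append(groups[w])
    cats = groups + (["unassigned"] if p_min is not None else [])
    counts = pd.Series(
        [labels.count(c) for c in cats], index=cats, dtype=int
    )
    pct = 100.0 * counts / max(n, 1)
    return AllocationTable(
        percentages=pct, counts=counts, threshold=p_min, n_unknown=n
    )
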