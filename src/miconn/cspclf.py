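"""Sub-band common spatial patterns (CSP) with LDA classification.

CSP finds spatial filters w maximising the variance ratio between two MI
classes: with per-class covariances R1 and R2 the filters solve the
generalised eigenproblem R1 e = lambda R2 e, normalised so that
E^T R2 E = I and E^T R1 E = D (eigenvalues descending). The first filters
maximise class-1 variance relative to class 2 and the last ones the reverse,
so trials are projected on the first m and last m filters and described by
normalised log-variance features. Sub-band CSP repeats this per frequency
band and concatenates features. Classification uses Fisher LDA; evaluation
is stratified k-fold cross-validation repeated with fresh shuffles, CSP
refitted inside each training fold (the only leakage-free protocol).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .preprocess import BandDefinition, TrialSet, filter_band


@dataclass
class CSPModel:
    """Spatial filters (columns, eigenvalue-descending) of one band."""

    filters: np.ndarray  # (n_channels, n_channels)
    eigenvalues: np.ndarray
    band: BandDefinition | None
    class_labels: tuple[str, str]
    channel_labels: list[str]


def _trial_covariances(epochs: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Per-trial covariance S S^T / t, optionally trace-normalised."""
    t = epochs.shape[-1]
    covs = epochs @ epochs.transpose(0, 2, 1) / t
    if normalize:
        traces = np.trace(covs, axis1=1, axis2=2)
        covs = covs / traces[:, None, None]
    return covs


def _class_covariance(epochs: np.ndarray, reg: float = 0.0) -> np.ndarray:
    cov = _trial_covariances(epochs).mean(axis=0)
    if reg > 0:
        cov = cov + reg * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    return cov


def fit_csp(
    class1: TrialSet,
    class2: TrialSet,
    band: BandDefinition | None = None,
    reg: float = 0.0,
) -> CSPModel:
    """Fit CSP filters separating two trial sets.

    Covariances are averaged over trace-normalised per-trial covariances
    (robust to amplitude drift). ``reg`` adds ridge loading for
    rank-deficient covariances.
    """
    if class1.n_trials < 2 or class2.n_trials < 2:
        raise ValueError("need at least 2 trials per class")
    if class1.channel_labels != class2.channel_labels:
        raise ValueError("channel montage differs between classes")
    e1, e2 = class1.epochs, class2.epochs
    if band is not None:
        e1 = filter_band(e1, class1.fs, band)
        e2 = filter_band(e2, class2.fs, band)
    if np.any(e1.var(axis=(0, 2)) == 0) or np.any(e2.var(axis=(0, 2)) == 0):
        raise ValueError("zero-variance channel present; remove it before CSP")
    r1 = _class_covariance(e1, reg)
    r2 = _class_covariance(e2, reg)
    pooled = r1 + r2
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "pooled covariance is rank deficient; refit with reg > 0 (ridge regularization)"
        )
    eigvals, eigvecs = linalg.eigh(r1, r2)  # eigvecs^T R2 eigvecs = I
    order = np.argsort(eigvals)[::-1]
    return CSPModel(
        filters=eigvecs[:, order],
        eigenvalues=eigvals[order],
        band=band,
        class_labels=(class1.condition + "/" + class1.hand, class2.condition + "/" + class2.hand),
        channel_labels=list(class1.channel_labels),
    )


def csp_features(model: CSPModel, trials: TrialSet, m: int) -> np.ndarray:
    """Normalised log-variance features on the first/last m filters.

    Returns (n_trials, 2m): f_i = log(var_i / sum_j var_j) over the 2m
    projected components. When ``model.band`` is set, trials are filtered to
    it first (so the features live in the band the filters were fitted on).
    """
    n_ch = model.filters.shape[0]
    if not (1 <= m <= n_ch // 2):
        raise ValueError(f"m must lie in [1, {n_ch // 2}], got {m}")
    epochs = trials.epochs
    if model.band is not None:
        epochs = filter_band(epochs, trials.fs, model.band)
    w = np.concatenate([model.filters[:, :m], model.filters[:, -m:]], axis=1)
    projected = np.einsum("cf,tcs->tfs", w, epochs)
    var = projected.var(axis=-1)
    var = var / var.sum(axis=1, keepdims=True)
    return np.log(var)


def fit_lda(features: np.ndarray, labels: np.ndarray, shrinkage: bool = False):
    """Fisher linear discriminant on feature vectors.

    With balanced classes and equal covariances the decision boundary sits at
    the midpoint of the projected class means. ``shrinkage`` enables
    Ledoit-Wolf loading for singular within-class scatter.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("LDA here is a two-class discriminant; need both classes present")
    if shrinkage:
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        clf = LinearDiscriminantAnalysis(solver="svd")
    try:
        clf.fit(features, labels)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular within-class scatter; refit with shrinkage=True"
        ) from err
    return clf


def predict(clf, features: np.ndarray) -> np.ndarray:
    return clf.predict(features)


@dataclass
class CVResult:
    """Repeated stratified k-fold accuracies (fractions in [0, 1])."""

    per_repeat: np.ndarray
    m: int
    k: int

    @property
    def mean(self) -> float:
        return float(self.per_repeat.mean())

    @property
    def sd(self) -> float:
        return float(self.per_repeat.std(ddof=1)) if self.per_repeat.size > 1 else 0.0


def cross_validate(
    trials_left: TrialSet,
    trials_right: TrialSet,
    bands,
    m: int = 5,
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
    labels: np.ndarray | None = None,
    shrinkage: bool = False,
) -> CVResult:
    """Repeated stratified k-fold CV of sub-band CSP + LDA.

    CSP filters and the LDA are fitted inside each training fold only; each
    repeat reshuffles the folds from a seed-derived stream, so the same seed
    reproduces the per-repeat accuracies exactly. ``labels`` overrides the
    class labels (e.g. for permutation baselines) but never influences which
    epochs feed the left/right trial sets.
    """
    n_l, n_r = trials_left.n_trials, trials_right.n_trials
    if min(n_l, n_r) < k:
        raise ValueError(f"k={k} exceeds the {min(n_l, n_r)} trials of the smaller class")
    bands = list(bands) or [None]  # no bands: operate on the raw epochs
    fs = trials_left.fs
    # Pre-filter once per band; per-trial covariances make fold refits cheap.
    raw = np.concatenate([trials_left.epochs, trials_right.epochs], axis=0)
    filtered = [
        raw if b is None else
        np.concatenate([filter_band(trials_left.epochs, fs, b),
                        filter_band(trials_right.epochs, fs, b)], axis=0)
        for b in bands
    ]
    y = np.concatenate([np.zeros(n_l, dtype=int), np.ones(n_r, dtype=int)])
    if labels is not None:
        y = np.asarray(labels, dtype=int)
        if y.size != n_l + n_r:
            raise ValueError("labels length must equal total trial count")
    raw_covs = [_trial_covariances(f, normalize=False) for f in filtered]
    norm_covs = [_trial_covariances(f, normalize=True) for f in filtered]
    n_ch = filtered[0].shape[1]
    if not (1 <= m <= n_ch // 2):
        raise ValueError(f"m must lie in [1, {n_ch // 2}], got {m}")

    rng = np.random.default_rng(seed)
    accs = np.empty(repeats)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        correct = total = 0
        for train_idx, test_idx in skf.split(np.zeros(y.size), y):
            feats_tr, feats_te = [], []
            for bi in range(len(bands)):
                c1 = norm_covs[bi][train_idx[y[train_idx] == 0]].mean(axis=0)
                c2 = norm_covs[bi][train_idx[y[train_idx] == 1]].mean(axis=0)
                if shrinkage:
                    c1 = c1 + 1e-6 * np.trace(c1) / n_ch * np.eye(n_ch)
                    c2 = c2 + 1e-6 * np.trace(c2) / n_ch * np.eye(n_ch)
                eigvals, eigvecs = linalg.eigh(c1, c2)
                order = np.argsort(eigvals)[::-1]
                w = np.concatenate(
                    [eigvecs[:, order[:m]], eigvecs[:, order[-m:]]], axis=1
                )
                # var of projected series = w^T C_trial w from cached covariances
                var_all = np.einsum("cf,tcd,df->tf", w, raw_covs[bi], w)
                var_all = var_all / var_all.sum(axis=1, keepdims=True)
                logv = np.log(var_all)
                feats_tr.append(logv[train_idx])
                feats_te.append(logv[test_idx])
            X_tr = np.hstack(feats_tr)
            X_te = np.hstack(feats_te)
            clf = fit_lda(X_tr, y[train_idx], shrinkage=shrinkage)
            correct += int((clf.predict(X_te) == y[test_idx]).sum())
            total += test_idx.size
        accs[rep] = correct / total
    return CVResult(per_repeat=accs, m=m, k=k)


def select_m(
    trials_left: TrialSet,
    trials_right: TrialSet,
    bands,
    m_range=range(1, 9),
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Sweep the CSP component count m, returning (best m, mean accuracy per m).

    Ties break toward smaller m.
    """
    acc_per_m: dict[int, float] = {}
    for m in m_range:
        acc_per_m[m] = cross_validate(
            trials_left, trials_right, bands, m=m, k=k, repeats=repeats, seed=seed
        ).mean
    best = min(acc_per_m, key=lambda m: (-acc_per_m[m], m))
    return best, acc_per_m
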