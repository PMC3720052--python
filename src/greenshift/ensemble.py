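"""Climatic-niche model ensemble with TSS-optimal binarization.

A pluggable suitability-model interface: a rectilinear climate envelope
and a class-weighted logistic regression are implemented in-repo;
additional learners (random forest, gradient boosting, quadratic
logistic) are thin adapters over scikit-learn.  Presences and
pseudo-absences are weighted to contribute equally to every fit.
Evaluation follows an 80/20 calibration/validation split with AUC, the
true skill statistic (TSS = sensitivity + specificity − 1) and
sensitivity, binarizing continuous suitability scores at the
TSS-optimal threshold.  Binary projections from K models are summed
into agreement counts; a cell is ensemble-suitable when at least
``majority`` models (default 3) agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# weights, thresholding, metrics
# ---------------------------------------------------------------------------

def balanced_weights(labels: np.ndarray) -> np.ndarray:
    """Per-record weights making total presence weight equal total absence.

    Presences get weight 1; each absence gets n_presence / n_absence.
    """
    labels = np.asarray(labels).astype(bool)
    n_p, n_a = int(labels.sum()), int((~labels).sum())
    if n_p == 0 or n_a == 0:
        raise ValueError("both classes must be non-empty")
    w = np.ones(labels.size)
    w[~labels] = n_p / n_a
    return w


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Mid-points between adjacent distinct scores, plus the extremes."""
    u = np.unique(scores)
    if u.size == 1:
        return u
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0]], mids, [u[-1]]])


def weighted_confusion(scores, labels, weights, threshold):
    """Weighted (sensitivity, specificity) with prediction = score ≥ threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    weights = np.asarray(weights, float)
    pred = scores >= threshold
    wp = weights[labels].sum()
    wa = weights[~labels].sum()
    sens = weights[labels & pred].sum() / wp if wp > 0 else np.nan
    spec = weights[~labels & ~pred].sum() / wa if wa > 0 else np.nan
    return sens, spec


def tss_threshold(scores, labels, weights=None) -> tuple[float, float]:
    """Threshold maximizing weighted TSS; ties go to the lowest threshold.

    Candidates are the mid-points of adjacent distinct scores plus the
    extremes.  Returns (threshold, tss_at_threshold).  A degenerate
    all-equal score set yields its single candidate with TSS 0.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if weights is None:
        weights = np.ones(scores.size)
    weights = np.asarray(weights, float)
    cands = _candidate_thresholds(scores)
    if cands.size == 1:
        warnings.warn("degenerate score set: all scores equal", stacklevel=2)
        return float(cands[0]), 0.0
    # vectorized weighted TSS over all candidates
    pred = scores[None, :] >= cands[:, None]            # (c, n)
    wp = weights[labels].sum()
    wa = weights[~labels].sum()
    sens = (pred[:, labels] * weights[labels]).sum(axis=1) / wp
    spec = ((~pred)[:, ~labels] * weights[~labels]).sum(axis=1) / wa
    tss = sens + spec - 1.0
    best = np.flatnonzero(tss == tss.max())[0]          # lowest threshold wins
    return float(cands[best]), float(tss[best])


def weighted_auc(scores, labels, weights=None) -> float:
    """Weighted AUC (rank statistic, ties averaged) via scikit-learn."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(np.asarray(labels).astype(int), scores,
                               sample_weight=weights))


# ---------------------------------------------------------------------------
# suitability models
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted suitability model with its evaluation record."""

    algorithm: str
    parameters: dict
    threshold: float = float("nan")
    auc: float = float("nan")
    tss: float = float("nan")
    sensitivity: float = float("nan")
    weight_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "parameters": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in self.parameters.items()},
            "threshold": self.threshold, "auc": self.auc, "tss": self.tss,
            "sensitivity": self.sensitivity,
            "weight_summary": self.weight_summary,
        }


class EnvelopeModel:
    """Rectilinear climate envelope (bioclim-style).

    Bounds are the [q, 1−q] quantiles of the presence predictor values
    (q=0 gives the literal min/max box).  The continuous score of a point
    is the fraction of predictors inside their bounds; the point is
    binary-suitable only inside all bounds.
    """

    name = "envelope"

    def __init__(self, quantile_trim: float = 0.05):
        if not 0.0 <= quantile_trim < 0.5:
            raise ValueError("quantile trim must be in [0, 0.5)")
        self.q = quantile_trim
        self.lower = self.upper = None

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, float)
        pres = X[np.asarray(y).astype(bool)]
        if pres.shape[0] < 2:
            raise ValueError("at least 2 presences required for an envelope")
        self.lower = np.quantile(pres, self.q, axis=0)
        self.upper = np.quantile(pres, 1.0 - self.q, axis=0)
        return self

    def predict_score(self, X):
        X = np.asarray(X, float)
        inside = (X >= self.lower) & (X <= self.upper)
        return inside.mean(axis=1)

    @property
    def bounds(self):
        return {"lower": self.lower, "upper": self.upper}


def fit_envelope(presence_values: np.ndarray,
                 quantile_trim: float = 0.05) -> ModelFit:
    """Fit a rectilinear envelope to presence predictor values only."""
    X = np.asarray(presence_values, float)
    m = EnvelopeModel(quantile_trim).fit(X, np.ones(X.shape[0], bool))
    return ModelFit(algorithm="envelope",
                    parameters={"lower": m.lower, "upper": m.upper,
                                "quantile_trim": quantile_trim})


class WeightedLogisticModel:
    """Logistic regression maximizing a weighted binomial likelihood.

    Predictors are standardized internally.  The weighted likelihood is
    maximized by iteratively reweighted least squares (statsmodels GLM
    with variance weights), so scaling the weight of a duplicated record
    leaves the fit unchanged.  Complete separation (or non-convergence)
    triggers a warning and a small-ridge penalized fallback.
    """

    name = "weighted_logistic"

    def __init__(self, ridge_on_separation: float = 1e-4):
        self.ridge = ridge_on_separation
        self.coef_ = None           # on standardized predictors, [intercept, ...]
        self._mean = self._std = None

    def _standardize(self, X):
        return (np.asarray(X, float) - self._mean) / self._std

    def fit(self, X, y, sample_weight=None):
        import statsmodels.api as sm

        X = np.asarray(X, float)
        y = np.asarray(y).astype(float)
        w = np.ones(X.shape[0]) if sample_weight is None else np.asarray(
            sample_weight, float)
        # weight-aware standardization keeps the fit invariant under
        # record duplication with compensating weights
        self._mean = np.average(X, axis=0, weights=w)
        var = np.average((X - self._mean) ** 2, axis=0, weights=w)
        self._std = np.where(var > 0, np.sqrt(var), 1.0)
        Xs = sm.add_constant(self._standardize(X), has_constant="add")
        try:
            from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                                         PerfectSeparationWarning)

            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                warnings.simplefilter("error", ConvergenceWarning)
                res = sm.GLM(y, Xs, family=sm.families.Binomial(),
                             var_weights=w).fit()
            if not np.all(np.isfinite(res.params)) or np.any(
                    np.abs(res.params) > 1e4):
                raise ValueError("diverging coefficients")
            self.coef_ = np.asarray(res.params)
        except Exception:
            warnings.warn("separation or non-convergence in logistic fit; "
                          "falling back to a small ridge penalty", stacklevel=2)
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1.0 / self.ridge, solver="lbfgs",
                                    max_iter=1000)
            lr.fit(self._standardize(X), y.astype(int), sample_weight=w)
            self.coef_ = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        return self

    def predict_score(self, X):
        Xs = np.column_stack([np.ones(len(X)), self._standardize(X)])
        z = Xs @ self.coef_
        return 1.0 / (1.0 + np.exp(-z))


def fit_weighted_logistic(presences: np.ndarray, pseudo_absences: np.ndarray,
                          weights: np.ndarray | None = None) -> ModelFit:
    """Weighted logistic fit from presence and pseudo-absence predictors.

    When ``weights`` is None the classes are balanced so presences and
    absences contribute equally to the likelihood.
    """
    X = np.vstack([presences, pseudo_absences])
    y = np.concatenate([np.ones(len(presences)), np.zeros(len(pseudo_absences))])
    w = balanced_weights(y) if weights is None else np.asarray(weights, float)
    m = WeightedLogisticModel().fit(X, y, sample_weight=w)
    return ModelFit(algorithm="weighted_logistic",
                    parameters={"coef": m.coef_,
                                "mean": m._mean, "std": m._std},
                    weight_summary={"presence_weight": float(w[y == 1].sum()),
                                    "absence_weight": float(w[y == 0].sum())})


class SklearnAdapter:
    """Wrap any scikit-learn classifier with predict_proba as a model."""

    def __init__(self, estimator, name: str):
        self.estimator = estimator
        self.name = name

    def fit(self, X, y, sample_weight=None):
        from sklearn.pipeline import Pipeline

        X = np.asarray(X, float)
        y = np.asarray(y).astype(int)
        if isinstance(self.estimator, Pipeline):
            # route weights to the final estimator step
            params = {}
            if sample_weight is not None:
                last = self.estimator.steps[-1][0]
                params[f"{last}__sample_weight"] = sample_weight
            self.estimator.fit(X, y, **params)
        else:
            self.estimator.fit(X, y, sample_weight=sample_weight)
        return self

    def predict_score(self, X):
        return self.estimator.predict_proba(np.asarray(X, float))[:, 1]


def default_model_suite(seed: int = 0, quantile_trim: float = 0.05) -> list:
    """Five suitability models: envelope, weighted logistic, three learners."""
    from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import PolynomialFeatures, StandardScaler

    quad = make_pipeline(StandardScaler(), PolynomialFeatures(degree=2),
                         LogisticRegression(max_iter=1000))
    return [
        EnvelopeModel(quantile_trim),
        WeightedLogisticModel(),
        SklearnAdapter(RandomForestClassifier(n_estimators=100,
                                              random_state=seed),
                       "random_forest"),
        SklearnAdapter(HistGradientBoostingClassifier(random_state=seed),
                       "gradient_boosting"),
        SklearnAdapter(quad, "quadratic_logistic"),
    ]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _stratified_split(labels, calibration_fraction, rng):
    labels = np.asarray(labels).astype(bool)
    cal = np.zeros(labels.size, bool)
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_cal = max(1, int(round(calibration_fraction * idx.size)))
        n_cal = min(n_cal, idx.size - 1) if idx.size > 1 else idx.size
        cal[idx[:n_cal]] = True
    return cal


def evaluate_split(model, X, labels, weights=None,
                   calibration_fraction: float = 0.8, seed: int = 0,
                   max_retries: int = 20) -> ModelFit:
    """Fit on a stratified 80% calibration split, score the 20% hold-out.

    The TSS-optimal threshold is chosen on the calibration scores and
    applied to the hold-out; AUC, TSS and sensitivity are reported on the
    hold-out, respecting record weights throughout.  The split is redrawn
    (up to ``max_retries``) if either partition lacks a class.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels).astype(bool)
    w = balanced_weights(labels) if weights is None else np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        cal = _stratified_split(labels, calibration_fraction, rng)
        if (labels[cal].any() and (~labels)[cal].any()
                and labels[~cal].any() and (~labels)[~cal].any()):
            break
    else:
        raise ValueError("could not produce a split with both classes in "
                         "both partitions")
    model.fit(X[cal], labels[cal], sample_weight=w[cal])
    cal_scores = model.predict_score(X[cal])
    thr, _ = tss_threshold(cal_scores, labels[cal], w[cal])
    val_scores = model.predict_score(X[~cal])
    sens, spec = weighted_confusion(val_scores, labels[~cal], w[~cal], thr)
    auc = weighted_auc(val_scores, labels[~cal], w[~cal])
    name = getattr(model, "name", type(model).__name__)
    return ModelFit(algorithm=name, parameters={}, threshold=float(thr),
                    auc=auc, tss=float(sens + spec - 1.0),
                    sensitivity=float(sens))


# ---------------------------------------------------------------------------
# ensembles and richness
# ---------------------------------------------------------------------------

@dataclass
class EnsembleProjection:
    """Per-cell model-agreement count and its majority binarization."""

    count: np.ndarray
    n_models: int
    majority: int = 3
    species: str = ""
    label: str = ""

    def __post_init__(self):
        self.count = np.asarray(self.count, int)
        if self.count.max(initial=0) > self.n_models:
            raise ValueError("agreement count exceeds the number of models")

    @property
    def majority_layer(self) -> np.ndarray:
        return self.count >= self.majority


def ensemble_project(binary_layers: list[np.ndarray], majority: int = 3,
                     species: str = "", label: str = "") -> EnsembleProjection:
    """Sum K binary model projections into an agreement count + majority."""
    if not binary_layers:
        raise ValueError("at least one projection layer required")
    stack = np.stack([np.asarray(l, bool) for l in binary_layers])
    return EnsembleProjection(count=stack.sum(axis=0),
                              n_models=len(binary_layers), majority=majority,
                              species=species, label=label)


def project_suite(models: list, bioclim, region_mask: np.ndarray,
                  thresholds: list[float], majority: int = 3,
                  species: str = "", label: str = "") -> EnsembleProjection:
    """Project fitted models onto a grid and take the majority ensemble.

    Models are projected only onto cells where ``region_mask`` is True
    (land in the study region); everywhere else is unsuitable.
    """
    region_mask = np.asarray(region_mask, bool)
    rows, cols = np.nonzero(region_mask)
    X = bioclim.values_at(rows, cols)
    layers = []
    for model, thr in zip(models, thresholds):
        scores = model.predict_score(X)
        layer = np.zeros(region_mask.shape, bool)
        layer[rows, cols] = scores >= thr
        layers.append(layer)
    return ensemble_project(layers, majority=majority, species=species,
                            label=label)


def richness_stack(majority_layers: list[np.ndarray]) -> np.ndarray:
    """Per-cell potential species richness from per-species majority layers."""
    if not majority_layers:
        raise ValueError("at least one species layer required")
    return np.stack([np.asarray(l, bool) for l in majority_layers]
                    ).sum(axis=0).astype(int)


def richness_diff(future: np.ndarray, current: np.ndarray) -> np.ndarray:
    """Signed richness change, future minus current."""
    return np.asarray(future, int) - np.asarray(current, int)
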