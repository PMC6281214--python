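"""Per-chromosome max-margin classification and the correction workflow.

One classifier is trained per target chromosome on the samples the
one-Z-test rule could call confidently (triage groups N and P), then
applied to the samples it could not (the grey zone and, optionally, the
QC-filtered group).  Training solves the soft-margin problem

    argmin_{w,b}  1/2 ||w||^2 + C * sum_i eps_i
    s.t.          y_i (w . phi(x_i) + b) >= 1 - eps_i,  eps_i >= 0

through its dual (solved by libsvm via scikit-learn), with either a
linear kernel or the RBF kernel k(x, x') = exp(-gamma ||x - x'||^2).
Class imbalance (thousands of negatives, a handful of trisomies) is
countered with per-class penalties inversely proportional to class size.
C and gamma are chosen by cross-validated grid search: a coarse pass over
log2 C in [-5, 15] and log2 gamma in [-15, 3], then a 0.1-step refinement
around the best cell, with ties broken toward smaller C then smaller
gamma to avoid needlessly hard margins.

Closed-form linear and quadratic discriminant analysis are provided as
baselines, and a config hook accepts any additional sklearn-style
estimator for further comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .depth_io import ResultRow, SampleRecord, TARGET_CHROMS
from .errors import NiptError, ParameterError
from .normalize import MergedProfile
from .triage_features import (FeatureScaler, FeatureVector, GROUP_N, GROUP_P,
                              GROUP_QC_FILTERED, GROUP_UNCLASSIFIED,
                              assemble_features, fit_scaler, qc_filter, run_z,
                              triage)
from .zstats import ReferencePanel, compute_z_vector

logger = logging.getLogger(__name__)


@dataclass
class SvmConfig:
    """Hyper-parameter search space and training options."""

    kernel: str = "rbf"  # "linear" | "rbf"
    class_weight_mode: str = "inverse"  # "none" | "inverse"
    cv_folds: int = 5
    log2c_range: tuple[float, float] = (-5.0, 15.0)
    log2g_range: tuple[float, float] = (-15.0, 3.0)
    coarse_step: float = 1.0
    fine_step: float = 0.1
    fine_span: float = 1.0  # refine +/- this around the coarse optimum
    probability: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ParameterError(f"unknown kernel {self.kernel!r}")
        if self.class_weight_mode not in ("none", "inverse"):
            raise ParameterError("class_weight_mode must be 'none' or 'inverse'")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if self.coarse_step <= 0 or self.fine_step <= 0:
            raise ParameterError("grid steps must be > 0")
        for lo, hi in (self.log2c_range, self.log2g_range):
            if hi < lo:
                raise ParameterError("degenerate grid range")


def class_weights(labels: Sequence[int]) -> dict[int, float]:
    """Per-class penalty multipliers inversely proportional to class size.

    ``w_k = n_total / (2 * n_k)``, so the minority class's misclassification
    costs proportionally more and a balanced problem gets weights (1, 1).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ParameterError("class weights need both classes present")
    n = y.size
    return {int(c): n / (2 * k) for c, k in zip(classes, counts)}


@dataclass
class SvmModel:
    """A trained per-chromosome classifier with its scaler state."""

    svc: SVC
    scaler: FeatureScaler
    chrom: str
    config: SvmConfig
    c: float
    gamma: float | None
    cv_accuracy: float
    train_counts: dict[int, int]
    weights: dict[int, float] | None

    # -- dual solution views ---------------------------------------------
    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def dual_weights(self) -> np.ndarray:
        """alpha_i * y_i for each support vector."""
        return self.svc.dual_coef_.ravel()

    @property
    def offset(self) -> float:
        return float(self.svc.intercept_[0])

    def decision_value(self, x: np.ndarray) -> float:
        return float(self.svc.decision_function(np.atleast_2d(x))[0])

    def dual_feasibility(self) -> tuple[float, float]:
        """(|sum alpha_i y_i|, max box-constraint violation) of the dual."""
        balance = abs(float(self.dual_weights.sum()))
        w = self.weights or {-1: 1.0, 1: 1.0}
        sv_y = np.sign(self.dual_weights)
        caps = np.array([self.c * w[int(s)] for s in sv_y])
        violation = float(np.max(np.abs(self.dual_weights) - caps, initial=0.0))
        return balance, violation


def _cv_accuracy(X: np.ndarray, y: np.ndarray, c: float, gamma: float | None,
                 cfg: SvmConfig, weights: dict[int, float] | None,
                 folds: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    correct = 0
    for tr, te in skf.split(X, y):
        svc = SVC(kernel=cfg.kernel, C=c,
                  gamma=gamma if gamma is not None else "scale",
                  class_weight=weights)
        svc.fit(X[tr], y[tr])
        correct += int((svc.predict(X[te]) == y[te]).sum())
    return correct / y.size


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def grid_search_train(train: Sequence[FeatureVector], cfg: SvmConfig,
                      scaler: FeatureScaler | None = None,
                      chrom: str = "") -> SvmModel:
    """Select (C, gamma) by cross-validated grid search and refit.

    ``train`` must already be on the classifier scale (Z features raw,
    D7-D10 mapped to [0, 3]).  Accuracy ties break toward smaller C, then
    smaller gamma.  Fold assignment is stratified and seeded; if a class
    has fewer members than ``cv_folds`` the fold count drops to that size.
    """
    labeled = [v for v in train if v.label in (-1, 1)]
    if not labeled:
        raise ParameterError("training set has no labeled vectors")
    X = np.array([v.values for v in labeled], float)
    y = np.array([v.label for v in labeled])
    if np.any(~np.isfinite(X)):
        raise ParameterError("training refuses missing/non-finite features")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ParameterError("training needs both classes present")
    weights = class_weights(y) if cfg.class_weight_mode == "inverse" else None
    folds = min(cfg.cv_folds, int(counts.min()))
    if folds < cfg.cv_folds:
        logger.warning("chromosome %s: minority class of %d limits CV to "
                       "%d folds", chrom, counts.min(), folds)
    if folds < 2:
        raise ParameterError("need >= 2 members per class for cross-validation")

    c_grid = _grid(*cfg.log2c_range, cfg.coarse_step)
    g_grid = (_grid(*cfg.log2g_range, cfg.coarse_step)
              if cfg.kernel == "rbf" else np.array([math.nan]))

    def search(cs: np.ndarray, gs: np.ndarray) -> tuple[float, float, float]:
        best = (-1.0, math.inf, math.inf)
        for lc in cs:
            for lg in gs:
                gamma = None if math.isnan(lg) else 2.0 ** lg
                acc = _cv_accuracy(X, y, 2.0 ** lc, gamma, cfg, weights, folds)
                key = (acc, -lc, -lg if not math.isnan(lg) else 0.0)
                if key > (best[0], -best[1], -best[2]):
                    best = (acc, lc, lg)
        return best

    acc, lc, lg = search(c_grid, g_grid)
    fine_c = np.clip(_grid(lc - cfg.fine_span, lc + cfg.fine_span, cfg.fine_step),
                     *cfg.log2c_range)
    if cfg.kernel == "rbf":
        fine_g = np.clip(_grid(lg - cfg.fine_span, lg + cfg.fine_span,
                               cfg.fine_step), *cfg.log2g_range)
    else:
        fine_g = np.array([math.nan])
    acc, lc, lg = max((acc, lc, lg), search(np.unique(fine_c), np.unique(fine_g)),
                      key=lambda t: (t[0], -t[1], -t[2]))

    c = 2.0 ** lc
    gamma = None if math.isnan(lg) else 2.0 ** lg
    svc = SVC(kernel=cfg.kernel, C=c, gamma=gamma if gamma is not None else "scale",
              class_weight=weights, probability=cfg.probability,
              random_state=cfg.seed)
    svc.fit(X, y)
    logger.info("chromosome %s: %s kernel, CV accuracy %.4f at "
                "log2C=%.1f log2gamma=%s", chrom, cfg.kernel, acc, lc,
                f"{lg:.1f}" if not math.isnan(lg) else "n/a")
    return SvmModel(svc=svc, scaler=scaler, chrom=chrom, config=cfg, c=c,
                    gamma=gamma, cv_accuracy=acc,
                    train_counts={int(k): int(v)
                                  for k, v in zip(classes, counts)},
                    weights=weights)


def predict(model: SvmModel,
            v: FeatureVector) -> tuple[int, float, float]:
    """(class, probability_negative, probability_positive) for one vector.

    The saved training scaler is applied first.  The class is the sign of
    the decision value, with an exact zero assigned to -1 (flagged in the
    log); probabilities come from the Platt-style sigmoid fitted at
    training time and always sum to 1.
    """
    if model.scaler is not None:
        v = model.scaler.transform(v)
    x = np.asarray(v.values, float)
    if np.any(~np.isfinite(x)):
        raise ParameterError(f"{v.sample_id}: non-finite features at prediction")
    f = model.decision_value(x)
    if f == 0.0:
        logger.warning("%s %s: decision value exactly 0; assigning -1",
                       v.sample_id, model.chrom)
    cls = 1 if f > 0 else -1
    if model.config.probability:
        proba = model.svc.predict_proba(x[None, :])[0]
        by_class = dict(zip(model.svc.classes_, proba))
        p_neg, p_pos = float(by_class[-1]), float(by_class[1])
        s = p_neg + p_pos
        p_neg, p_pos = p_neg / s, p_pos / s
    else:
        p_neg = p_pos = float("nan")
    return cls, p_neg, p_pos


# ---------------------------------------------------------------------------
# closed-form discriminant baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineModel:
    """Gaussian discriminant classifier (shared or per-class covariance)."""

    kind: str  # "LDA" | "QDA"
    classes: tuple[int, ...]
    priors: dict[int, float]
    means: dict[int, np.ndarray]
    # LDA: one pooled matrix under key 0; QDA: one per class
    covariances: dict[int, np.ndarray]
    _inv: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _logdet: dict[int, float] = field(default_factory=dict, repr=False)

    def discriminants(self, x: np.ndarray) -> dict[int, float]:
        x = np.asarray(x, float)
        out = {}
        for k in self.classes:
            mu = self.means[k]
            if self.kind == "LDA":
                inv = self._inv[0]
                out[k] = float(x @ inv @ mu - 0.5 * mu @ inv @ mu
                               + math.log(self.priors[k]))
            else:
                inv = self._inv[k]
                d = x - mu
                out[k] = float(-0.5 * self._logdet[k] - 0.5 * d @ inv @ d
                               + math.log(self.priors[k]))
        return out


def _safe_inverse(cov: np.ndarray, ridge: float = 1e-8):
    """(inverse, log-determinant), adding a small ridge if singular."""
    for bump in (0.0, ridge):
        mat = cov + bump * np.eye(cov.shape[0])
        sign, logdet = np.linalg.slogdet(mat)
        if sign > 0 and np.isfinite(logdet):
            try:
                return np.linalg.inv(mat), float(logdet)
            except np.linalg.LinAlgError:
                continue
    raise NiptError("covariance matrix singular even after ridge")


def train_baseline(train: Sequence[FeatureVector], kind: str) -> BaselineModel:
    """Fit LDA (pooled covariance) or QDA (per-class covariance) in closed
    form: class means, empirical priors, and covariance(s)."""
    if kind not in ("LDA", "QDA"):
        raise ParameterError("kind must be 'LDA' or 'QDA'")
    labeled = [v for v in train if v.label in (-1, 1)]
    X = np.array([v.values for v in labeled], float)
    y = np.array([v.label for v in labeled])
    classes = tuple(int(c) for c in np.unique(y))
    if len(classes) < 2:
        raise ParameterError("baseline training needs both classes")
    priors = {k: float((y == k).mean()) for k in classes}
    means = {k: X[y == k].mean(axis=0) for k in classes}
    model = BaselineModel(kind, classes, priors, means, {})
    if kind == "LDA":
        pooled = np.zeros((X.shape[1], X.shape[1]))
        for k in classes:
            d = X[y == k] - means[k]
            pooled += d.T @ d
        pooled /= max(len(y) - len(classes), 1)
        model.covariances[0] = pooled
        model._inv[0], model._logdet[0] = _safe_inverse(pooled)
    else:
        for k in classes:
            d = X[y == k] - means[k]
            cov = d.T @ d / max((y == k).sum() - 1, 1)
            model.covariances[k] = cov
            model._inv[k], model._logdet[k] = _safe_inverse(cov)
    return model


def baseline_predict(model: BaselineModel, v: FeatureVector | np.ndarray) -> int:
    x = v.values if isinstance(v, FeatureVector) else v
    d = model.discriminants(np.asarray(x, float))
    return max(sorted(d), key=lambda k: d[k])


def extra_baseline(estimator, train: Sequence[FeatureVector],
                   test: Sequence[FeatureVector]) -> np.ndarray:
    """Hook for additional comparison classifiers (trees, boosting, ...).

    Fits any sklearn-style estimator (``fit``/``predict``) on the labeled
    training vectors and returns its predictions on ``test``.  The hook
    makes no correctness claims for the estimator itself.
    """
    labeled = [v for v in train if v.label in (-1, 1)]
    X = np.array([v.values for v in labeled], float)
    y = np.array([v.label for v in labeled])
    estimator.fit(X, y)
    return np.asarray(estimator.predict(
        np.array([v.values for v in test], float)))


# ---------------------------------------------------------------------------
# end-to-end correction workflow
# ---------------------------------------------------------------------------

@dataclass
class CorrectionResult:
    """Outputs of the per-chromosome train-then-correct workflow."""

    rows: list[ResultRow]
    models: dict[str, SvmModel]
    scalers: dict[str, FeatureScaler]
    groups: dict[tuple[str, str], str]  # (sample_id, chrom) -> triage group


def correction_workflow(profiles: Sequence[MergedProfile],
                        records: Mapping[str, SampleRecord],
                        panel: ReferencePanel,
                        cfg: SvmConfig | None = None,
                        train_ids: Iterable[str] | None = None,
                        use_true_labels: bool = False,
                        chroms: Iterable[str] = TARGET_CHROMS
                        ) -> CorrectionResult:
    """Triage a cohort and correct its uncallable samples per chromosome.

    For each target chromosome: QC-filter and triage every sample on its
    run Z; fit the 0-3 scaler and a class-weighted SVM on the triage-N/P
    samples (restricted to ``train_ids`` when given, so held-out arms are
    never trained on); predict *every* sample, which gives internal
    validation on the training groups and corrections for the
    Unclassified and QC-filtered groups.  Labels come from the triage
    groups (P -> +1, N -> -1) unless ``use_true_labels`` asks for
    confirmed states.
    """
    cfg = cfg or SvmConfig()
    train_ids = set(train_ids) if train_ids is not None else None
    zvecs, qc, fvs, groups = {}, {}, {}, {}
    for p in profiles:
        rec = records[p.sample_id]
        zv = compute_z_vector(p, panel, rec, chroms)
        qc[p.sample_id] = qc_filter(rec)
        for c, z in zv.items():
            zvecs[(p.sample_id, c)] = z
            groups[(p.sample_id, c)] = triage(run_z(z, rec, c), qc[p.sample_id])
            fvs[(p.sample_id, c)] = assemble_features(z, rec, c)

    rows: list[ResultRow] = []
    models: dict[str, SvmModel] = {}
    scalers: dict[str, FeatureScaler] = {}
    for c in chroms:
        train = []
        for p in profiles:
            sid = p.sample_id
            if train_ids is not None and sid not in train_ids:
                continue
            g = groups[(sid, c)]
            if g not in (GROUP_N, GROUP_P):
                continue
            v = fvs[(sid, c)]
            label = (records[sid].real_state.get(c) if use_true_labels
                     else (1 if g == GROUP_P else -1))
            if label is None:
                continue
            train.append(FeatureVector(v.sample_id, v.chrom, v.values, label))
        if not any(v.label == 1 for v in train):
            raise NiptError(
                f"chromosome {c}: no positive training samples in groups N/P; "
                "augment the cohort (e.g. simulate additional trisomies)")
        scaler = fit_scaler(train)
        model = grid_search_train(scaler.transform_all(train), cfg,
                                  scaler=scaler, chrom=c)
        models[c], scalers[c] = model, scaler
        for p in profiles:
            sid = p.sample_id
            v = fvs[(sid, c)]
            cls, p_neg, p_pos = predict(model, v)
            rows.append(ResultRow(
                sample_id=sid, chrom=c, features=v.values,
                qc_flag=qc[sid], triage_group=groups[(sid, c)],
                predicted_class=cls,
                probability_negative=None if math.isnan(p_neg) else p_neg,
                probability_positive=None if math.isnan(p_pos) else p_pos))
    return CorrectionResult(rows, models, scalers, groups)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def save_model(model: SvmModel, path) -> None:
    """Persist a trained model (joblib archive, format-versioned)."""
    import joblib

    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> SvmModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise NiptError(f"unsupported model format: {payload.get('format_version')}")
    return payload["model"]
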