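"""Evaluation protocol: target mapping, MSE monitoring, imbalance-aware
10-fold cross-validation, the eight-metric confusion-matrix suite and
confusion-matrix reconstruction from printed (accuracy, F1) pairs.

Adenocarcinoma is the positive class throughout: TP = a subject correctly
labelled Adeno, TN = correctly labelled Meso.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import TrainedClassifier, fit_classifier
from .errors import AmbiguityError, ConstraintError, InputError, StratificationError
from .feature_selection import SelectionMask, select_features
from .io_formats import ADENO, MESO, RunConfig


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InputError(f"{name} must be a non-negative integer (got {v})")
            setattr(self, name, int(v))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricsRecord:
    """The eight-metric suite: percentages on 0-100, MCC/kappa as ratios."""

    acc: float
    f1: float
    mcc: float
    er: float
    ji: float
    csi: float
    gmean: float
    kappa: float
    undefined: tuple = ()
    dr_method: str = ""
    fsel_method: str = ""
    classifier: str = ""


@dataclass
class TargetMap:
    """Unit-interval regression targets for the two classes."""

    t_meso: float = 0.1
    t_adeno: float = 0.95


def validate_targets(t_meso: float, t_adeno: float,
                     class_feature_means: dict | None = None) -> TargetMap:
    """Check the target-mapping constraints and return a TargetMap.

    The Adeno target must be the upper one, both must lie in (0, 1), their
    separation must be at least 0.5, and (when normalized class feature
    means are supplied) each class mean must not exceed its target.
    """
    for name, v in (("t_meso", t_meso), ("t_adeno", t_adeno)):
        if not 0 < v < 1:
            raise ConstraintError(f"{name}={v} must lie strictly inside (0, 1)")
    if t_adeno <= t_meso:
        raise ConstraintError(
            "t_adeno must be the upper target (Adeno maps near the upper bound)"
        )
    if abs(t_adeno - t_meso) < 0.5:
        raise ConstraintError(
            f"target separation |t_adeno - t_meso| = {abs(t_adeno - t_meso):.3g} < 0.5"
        )
    if class_feature_means is not None:
        if class_feature_means.get(MESO, -math.inf) > t_meso:
            raise ConstraintError("mean Meso feature level exceeds the Meso target bound")
        if class_feature_means.get(ADENO, -math.inf) > t_adeno:
            raise ConstraintError("mean Adeno feature level exceeds the Adeno target bound")
    return TargetMap(t_meso=t_meso, t_adeno=t_adeno)


def mse(observed, targets) -> float:
    """Mean squared error (1/N) sum (O_j - T_j)^2."""
    o = np.asarray(observed, dtype=float).ravel()
    t = np.asarray(targets, dtype=float).ravel()
    if o.size != t.size:
        raise InputError(f"length mismatch: {o.size} observed vs {t.size} targets")
    if o.size == 0:
        raise InputError("mse needs at least one observation")
    return float(np.mean((o - t) ** 2))


# ---------------------------------------------------------------------------
# metric suite


def compute_metrics(cm: ConfusionMatrix) -> MetricsRecord:
    """All eight metrics from one confusion matrix.

    Metrics whose denominator vanishes are reported as NaN and listed in
    ``undefined`` rather than silently zeroed.  Kappa is standard Cohen's
    kappa on proportions with chance agreement from the marginals.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    n = cm.n
    if n < 1:
        raise InputError("empty confusion matrix")
    undefined = []

    def guard(name, num, den):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    acc = 100.0 * (tp + tn) / n
    er = 100.0 * (fp + fn) / n
    f1 = 100.0 * guard("f1", 2 * tp, 2 * tp + fp + fn)
    ji = 100.0 * guard("ji", tp, tp + fp + fn)
    precision = guard("csi", tp, tp + fp)
    sensitivity = guard("csi", tp, tp + fn)
    specificity = guard("gmean", tn, tn + fp)
    csi = 100.0 * precision + 100.0 * sensitivity - 100.0
    gmean = (100.0 * math.sqrt(sensitivity * specificity)
             if not (math.isnan(sensitivity) or math.isnan(specificity)) else math.nan)
    if math.isnan(sensitivity):
        undefined.append("gmean")

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / mcc_den

    po = (tp + tn) / n
    pe = ((tp + fp) / n) * ((tp + fn) / n) + ((tn + fp) / n) * ((tn + fn) / n)
    if pe == 1.0:
        kappa = 1.0 if po == 1.0 else math.nan
        if po != 1.0:
            undefined.append("kappa")
    else:
        kappa = (po - pe) / (1.0 - pe)

    return MetricsRecord(acc=acc, f1=f1, mcc=mcc, er=er, ji=ji, csi=csi,
                         gmean=gmean, kappa=kappa,
                         undefined=tuple(dict.fromkeys(undefined)))


def _printed_match(value: np.ndarray, printed: float) -> np.ndarray:
    """True where ``value`` prints as ``printed`` at two decimals, by
    rounding or by truncation (published tables mix both)."""
    rounded = np.round(value, 2)
    truncated = np.floor(value * 100.0 + 1e-9) / 100.0
    return (np.abs(rounded - printed) < 1e-6) | (np.abs(truncated - printed) < 1e-6)


def reconstruct_confusion_matrix(acc: float, f1: float, n: int,
                                 n_pos: int, n_neg: int) -> ConfusionMatrix:
    """Exhaustively recover the integer confusion matrix behind printed
    (accuracy %, F1 %) at two-decimal precision.

    Searches all tp in [0, n_pos], fp in [0, n_neg]; raises AmbiguityError
    (listing the candidates) unless exactly one matrix matches.
    """
    if n_pos + n_neg != n:
        raise InputError("n_pos + n_neg must equal n")
    tp = np.arange(n_pos + 1)[:, None]
    fp = np.arange(n_neg + 1)[None, :]
    fn = n_pos - tp
    tn = n_neg - fp
    acc_grid = 100.0 * (tp + tn) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        f1_grid = 100.0 * (2 * tp) / (2 * tp + fp + fn)
    ok = _printed_match(acc_grid, acc) & _printed_match(f1_grid, f1)
    ok &= np.isfinite(f1_grid)
    hits = np.argwhere(ok)
    candidates = [ConfusionMatrix(int(t), int(f), int(n_pos - t), int(n_neg - f))
                  for t, f in hits]
    if len(candidates) != 1:
        raise AmbiguityError(
            f"(acc={acc}, f1={f1}) matched {len(candidates)} matrices",
            candidates=candidates,
        )
    return candidates[0]


def aggregate_mean(values) -> float:
    """Arithmetic mean of metric cells gathered across result tables."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InputError("aggregate_mean needs at least one value")
    return float(v.mean())


# ---------------------------------------------------------------------------
# cross-validation with the two-model argmax imbalance scheme


@dataclass
class FoldModels:
    """Everything fitted from one fold's training partition only."""

    mask: SelectionMask | None
    model_adeno: TrainedClassifier     # model I: scores Adeno membership (A0)
    model_meso: TrainedClassifier      # model II: scores Meso membership (M0)

    def feature_view(self, X: np.ndarray) -> np.ndarray:
        return X if self.mask is None else X[:, self.mask.selected]


@dataclass
class CvResult:
    confusion: ConfusionMatrix
    fold_records: list = field(default_factory=list)
    predictions: np.ndarray | None = None
    monitor_mse: float = math.nan


def fit_fold(X_tr: np.ndarray, y_tr, config: RunConfig, fold_seed: int) -> FoldModels:
    """Fit the fold's optional feature selection and both models.

    A pure function of the training partition: nothing from the test fold
    can reach the fitted parameters.
    """
    y_tr = np.asarray(y_tr)
    if len(set(y_tr.tolist())) < 2:
        raise StratificationError("training partition lost a class")
    mask = None
    X_fit = X_tr
    if config.fsel_method != "none":
        mask = select_features(config.fsel_method, X_tr, y_tr, config, seed=fold_seed)
        X_fit = X_tr[:, mask.selected]
    m1 = fit_classifier(config.classifier, X_fit, y_tr, config,
                        positive=ADENO, seed=fold_seed)
    m2 = fit_classifier(config.classifier, X_fit, y_tr, config,
                        positive=MESO, seed=fold_seed + 1)
    return FoldModels(mask=mask, model_adeno=m1, model_meso=m2)


def predict_fold(models: FoldModels, X_te: np.ndarray) -> np.ndarray:
    """argmax(A0, M0): Adeno wherever the Adeno-membership score wins."""
    Xv = models.feature_view(X_te)
    a0 = models.model_adeno.score_continuous(Xv)
    m0 = models.model_meso.score_continuous(Xv)
    return np.where(a0 >= m0, ADENO, MESO)


def tenfold_cv_imbalanced(features, labels=None, config: RunConfig | None = None) -> CvResult:
    """Stratified k-fold CV with per-class models combined by argmax.

    ``features`` is a ReducedFeatureMatrix (labels taken from it) or a plain
    (n_samples, n_features) array with ``labels`` given separately.  Feature
    selection, when configured, runs inside each training partition
    (leak-free) unless ``config.fsel_global_mode`` is set.  Fold confusions
    are summed into a single pooled ConfusionMatrix.
    """
    config = config or RunConfig()
    if hasattr(features, "values") and labels is None:
        X = features.values
        y = np.asarray(features.labels)
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels)
    counts = {c: int(np.sum(y == c)) for c in (ADENO, MESO)}
    if min(counts.values()) < config.folds:
        raise StratificationError(
            f"minority class has {min(counts.values())} samples; cannot stratify "
            f"{config.folds} folds with both classes present"
        )

    global_mask = None
    cfg = config
    if config.fsel_method != "none" and config.fsel_global_mode:
        global_mask = select_features(config.fsel_method, X, y, config, seed=config.seed)
        X = X[:, global_mask.selected]
        cfg = _without_fsel(config)

    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    rng = np.random.default_rng(config.seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=config.folds)

    total = ConfusionMatrix(0, 0, 0, 0)
    fold_records = []
    predictions = np.empty(y.size, dtype=object)
    scores = np.empty(y.size, dtype=float)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        models = fit_fold(X[tr], y[tr], cfg, int(fold_seeds[k]))
        pred = predict_fold(models, X[te])
        predictions[te] = pred
        scores[te] = models.model_adeno.score_continuous(models.feature_view(X[te]))
        cm = ConfusionMatrix(
            tp=int(np.sum((pred == ADENO) & (y[te] == ADENO))),
            fp=int(np.sum((pred == ADENO) & (y[te] == MESO))),
            fn=int(np.sum((pred == MESO) & (y[te] == ADENO))),
            tn=int(np.sum((pred == MESO) & (y[te] == MESO))),
        )
        total = total + cm
        fold_records.append({"fold": k, "confusion": cm, "mask": models.mask,
                             "test_indices": te, "seed": int(fold_seeds[k])})

    targets = np.where(y == ADENO, config.t_adeno, config.t_meso)
    result = CvResult(confusion=total, fold_records=fold_records,
                      predictions=predictions, monitor_mse=mse(scores, targets))
    if global_mask is not None:
        for rec in result.fold_records:
            rec["global_mask"] = global_mask
    return result


def _without_fsel(config: RunConfig) -> RunConfig:
    import dataclasses

    return dataclasses.replace(config, fsel_method="none")
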