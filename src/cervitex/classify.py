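"""Feed-forward neural-network classification and evaluation.

A standard fully connected back-propagation network separates normal from
abnormal feature vectors.  Features are standardized with parameters frozen
at training time.  Evaluation follows the screening convention: per-fold
misclassification error under stratified k-fold cross-validation, the mean
cross-validation error mu = (1/k) * sum C(k), and the full 2x2
confusion-matrix metric suite (sensitivity, specificity, accuracy, predictive
values, likelihood ratios).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

__all__ = [
    "TrainConfig",
    "CervixClassifier",
    "ConfusionMetrics",
    "train",
    "metrics_from_counts",
    "kfold_cv",
]

LABEL_MAP = {0: "normal", 1: "abnormal"}


@dataclass(frozen=True)
class TrainConfig:
    """Network architecture and optimization settings.

    ``hidden`` of None selects max(8, n_features // 2) units in the single
    hidden layer.  ``weight_decay`` is the L2 penalty; the default of 1.0 is
    deliberately strong because the assembled feature vector (hundreds of
    ridgelet statistics) is usually much wider than the training set.
    """

    hidden: int | None = None
    epochs: int = 500
    learning_rate: float = 0.01
    weight_decay: float = 1.0
    seed: int = 0

    def resolve_hidden(self, n_features: int) -> int:
        return self.hidden if self.hidden is not None else max(8, n_features // 2)


@dataclass
class CervixClassifier:
    """Frozen feed-forward network plus its standardization parameters.

    Prediction is an explicit forward pass through the stored weights
    (logistic activations), so a serialized model reproduces its scores
    bit-for-bit without the training backend.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    train_config: TrainConfig
    feature_names: list[str] | None = None
    degenerate: bool = False
    label_map: dict[int, str] = field(default_factory=lambda: dict(LABEL_MAP))

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Abnormality score in [0, 1] per sample."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) features, got shape {X.shape}"
            )
        a = (X - self.scaler_mean) / self.scaler_scale
        for W, b in zip(self.weights, self.biases):
            z = a @ W + b
            a = 1.0 / (1.0 + np.exp(-z))
        return a.ravel()

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, scores); score >= 0.5 is called abnormal (screening tie-break)."""
        scores = self.decision_scores(X)
        return (scores >= 0.5).astype(int), scores

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "train_config": asdict(self.train_config),
            "feature_names": self.feature_names,
            "degenerate": self.degenerate,
            "label_map": {str(k): v for k, v in self.label_map.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CervixClassifier":
        d = json.loads(text)
        return cls(
            weights=[np.array(W) for W in d["weights"]],
            biases=[np.array(b) for b in d["biases"]],
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_scale=np.array(d["scaler_scale"]),
            train_config=TrainConfig(**d["train_config"]),
            feature_names=d.get("feature_names"),
            degenerate=d.get("degenerate", False),
            label_map={int(k): v for k, v in d.get("label_map", {}).items()} or dict(LABEL_MAP),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "CervixClassifier":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    feature_names: list[str] | None = None,
) -> CervixClassifier:
    """Train the network by gradient back-propagation with a fixed seed.

    Requires both classes present and at least two samples per class.  A
    training set with no usable signal (all features constant) still returns
    a model, flagged ``degenerate``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"feature/label shape mismatch: {X.shape} vs {y.shape}")
    if np.isnan(X).any():
        raise ValueError("NaN values in feature matrix")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if not np.isin(classes, [0, 1]).all():
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    scaler = StandardScaler().fit(X)
    scaler.scale_[scaler.scale_ == 0] = 1.0  # constant columns carry no signal
    Xs = scaler.transform(X)
    degenerate = bool(np.all(X == X[0]))

    net = MLPClassifier(
        hidden_layer_sizes=(config.resolve_hidden(X.shape[1]),),
        activation="logistic",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        random_state=config.seed,
        alpha=config.weight_decay,
        tol=0.0,  # run the configured epoch budget deterministically
        n_iter_no_change=config.epochs,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        net.fit(Xs, y)

    return CervixClassifier(
        weights=[np.asarray(W) for W in net.coefs_],
        biases=[np.asarray(b) for b in net.intercepts_],
        scaler_mean=np.asarray(scaler.mean_),
        scaler_scale=np.asarray(scaler.scale_),
        train_config=config,
        feature_names=feature_names,
        degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class ConfusionMetrics:
    """2x2 confusion counts and all derived screening metrics.

    Undefined ratios (division by zero) are reported as NaN, never raised.
    ``fold_errors`` and ``cv_error`` are populated by cross-validation.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    precision: float
    lr_pos: float
    lr_neg: float
    fold_errors: list[float] = field(default_factory=list)
    cv_error: float = math.nan

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        lines = [
            f"TP={self.tp}  TN={self.tn}  FP={self.fp}  FN={self.fn}",
            f"sensitivity : {self.sensitivity:.4f}",
            f"specificity : {self.specificity:.4f}",
            f"accuracy    : {self.accuracy:.4f}",
            f"PPV         : {self.ppv:.4f}",
            f"NPV         : {self.npv:.4f}",
            f"precision   : {self.precision:.4f}",
            f"LR+         : {self.lr_pos:.4f}",
            f"LR-         : {self.lr_neg:.4f}",
        ]
        if self.fold_errors:
            folds = ", ".join(f"{e:.4f}" for e in self.fold_errors)
            lines.append(f"fold errors : [{folds}]")
            lines.append(f"cv error mu : {self.cv_error:.4f}")
        return "\n".join(lines)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """Derive the full metric suite from confusion counts."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    return ConfusionMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        accuracy=(tp + tn) / total,
        ppv=ppv,
        npv=_ratio(tn, tn + fn),
        precision=ppv,
        lr_pos=_ratio(sens, 1 - spec) if not math.isnan(spec) else math.nan,
        lr_neg=_ratio(1 - sens, spec) if not math.isnan(sens) else math.nan,
    )


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 2,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> ConfusionMetrics:
    """Stratified k-fold cross-validation of the network.

    Per-fold error C(k) is the misclassification fraction on the held-out
    fold; mu is their mean.  Confusion counts are pooled over all held-out
    predictions.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int).ravel()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > y.size:
        raise ValueError(f"k={k} exceeds the {y.size} available samples")
    config = config or TrainConfig(seed=seed)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_errors: list[float] = []
    tp = tn = fp = fn = 0
    for train_idx, test_idx in splitter.split(X, y):
        model = train(X[train_idx], y[train_idx], config)
        pred, _ = model.predict(X[test_idx])
        truth = y[test_idx]
        fold_errors.append(float(np.mean(pred != truth)))
        tp += int(np.sum((pred == 1) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    metrics = metrics_from_counts(tp, tn, fp, fn)
    metrics.fold_errors = fold_errors
    metrics.cv_error = float(np.mean(fold_errors))
    return metrics
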