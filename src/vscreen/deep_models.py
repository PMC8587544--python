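"""The two screening classifiers and their evaluation metrics.

* ``ecfp_dense`` — a feedforward network (ReLU hidden layers, sigmoid output)
  on circular-fingerprint bit vectors, trained with Adam, binary cross-entropy,
  L2 weight decay, inverted dropout and early stopping on validation loss.
* ``nfp_graphconv`` — a graph-convolutional neural-fingerprint encoder (atom
  states updated from neighbor atom and bond features over a fixed number of
  rounds, per-layer softmax-pooled into a dense fingerprint) feeding the same
  dense head. Predictions are invariant to atom input order because pooling is
  a sum over atoms.

Everything is pure NumPy: training is deterministic for a fixed seed, needs no
GPU, and runs at desk scale in seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

from .fingerprints import (
    ATOM_FEATURE_DIM,
    BOND_FEATURE_DIM,
    BitFingerprint,
    GraphEncoding,
)

__all__ = [
    "ClassifierConfig",
    "ConfusionCounts",
    "EvalReport",
    "TrainedClassifier",
    "train_dense_classifier",
    "train_nfp_classifier",
    "predict",
    "classify",
    "confusion",
    "metrics",
    "auc_score",
    "batch_size_sweep",
    "save_classifier",
    "load_classifier",
    "write_sweep_tsv",
]


class TrainingError(RuntimeError):
    """Raised for untrainable inputs (e.g. single-class training sets)."""


@dataclass(frozen=True)
class ClassifierConfig:
    learning_rate: float = 0.001
    batch_size: int = 300
    l2: float = 0.0001
    dropout_rate: float = 0.25
    hidden_widths: tuple[int, ...] = (512, 128)
    nfp_depth: int = 2
    nfp_fp_length: int = 128
    nfp_hidden_dim: int = 32
    epochs: int = 200
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass(frozen=True)
class EvalReport:
    """Six classification indicators; undefined values are NaN, never 0."""

    SE: float
    SP: float
    Qplus: float
    Qminus: float
    MCC: float
    AUC: float


# ---------------------------------------------------------------------------
# NumPy MLP with Adam, BCE + L2, inverted dropout


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _MLP:
    """Minimal feedforward binary classifier trained with Adam."""

    def __init__(self, layer_sizes: list[int], rng: np.random.Generator):
        self.sizes = list(layer_sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes, layer_sizes[1:]):
            scale = math.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(
        self,
        X: np.ndarray,
        dropout_rate: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Return (probabilities, cache). Dropout is applied to hidden
        activations only when a generator is supplied (training mode)."""
        h = X
        cache = [(h, None)]
        n_layers = len(self.W)
        for li in range(n_layers - 1):
            z = h @ self.W[li] + self.b[li]
            h = np.maximum(z, 0.0)
            mask = None
            if rng is not None and dropout_rate > 0.0:
                mask = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
                h = h * mask
            cache.append((h, mask))
        logits = h @ self.W[-1] + self.b[-1]
        p = _sigmoid(logits)[:, 0]
        return p, cache

    def gradients(self, X, y, dropout_rate, rng, l2):
        p, cache = self.forward(X, dropout_rate, rng)
        n = X.shape[0]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = ((p - y) / n)[:, None]  # d BCE / d logits
        for li in range(len(self.W) - 1, -1, -1):
            h_prev = cache[li][0]
            gW[li] = h_prev.T @ delta + 2.0 * l2 * self.W[li]
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.W[li].T
                mask = cache[li][1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * (cache[li][0] > 0)
        return gW, gb

    def loss(self, X, y, l2):
        p, _ = self.forward(X)
        eps = 1e-12
        bce = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        reg = l2 * sum(float(np.sum(w * w)) for w in self.W)
        return bce + reg

    def state(self) -> dict:
        return {
            "sizes": self.sizes,
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_state(cls, state: dict) -> "_MLP":
        obj = cls.__new__(cls)
        obj.sizes = list(state["sizes"])
        obj.W = [np.array(w, dtype=np.float64) for w in state["W"]]
        obj.b = [np.array(b, dtype=np.float64) for b in state["b"]]
        return obj


def _train_mlp(
    mlp: _MLP,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ClassifierConfig,
    rng: np.random.Generator,
) -> dict:
    """Adam training loop with early stopping on validation loss. Returns a
    small history dict; the best-validation weights are restored in place."""
    mW = [np.zeros_like(w) for w in mlp.W]
    vW = [np.zeros_like(w) for w in mlp.W]
    mb = [np.zeros_like(b) for b in mlp.b]
    vb = [np.zeros_like(b) for b in mlp.b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_val = math.inf
    best_state = mlp.state()
    patience_left = config.early_stop_patience
    history = {"val_loss": [], "stopped_epoch": config.epochs}
    n = X_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            gW, gb = mlp.gradients(
                X_train[idx], y_train[idx], config.dropout_rate, rng, config.l2
            )
            t += 1
            for li in range(len(mlp.W)):
                mW[li] = beta1 * mW[li] + (1 - beta1) * gW[li]
                vW[li] = beta2 * vW[li] + (1 - beta2) * gW[li] ** 2
                mb[li] = beta1 * mb[li] + (1 - beta1) * gb[li]
                vb[li] = beta2 * vb[li] + (1 - beta2) * gb[li] ** 2
                mhat = mW[li] / (1 - beta1**t)
                vhat = vW[li] / (1 - beta2**t)
                mlp.W[li] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
                mhatb = mb[li] / (1 - beta1**t)
                vhatb = vb[li] / (1 - beta2**t)
                mlp.b[li] -= config.learning_rate * mhatb / (np.sqrt(vhatb) + eps)
        val_loss = mlp.loss(X_val, y_val, config.l2)
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = mlp.state()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                history["stopped_epoch"] = epoch + 1
                break
    restored = _MLP.from_state(best_state)
    mlp.W, mlp.b = restored.W, restored.b
    return history


# ---------------------------------------------------------------------------
# Graph neural-fingerprint encoder

@dataclass
class _NFPEncoder:
    """Fixed random-weight graph-convolution encoder.

    Atom hidden states are updated over ``depth`` rounds from the states of
    neighboring atoms plus incident bond features; after every round each
    atom's softmax-hashed contribution is summed into a dense fingerprint.
    Summation over atoms makes the output permutation invariant. The
    convolution weights are drawn once from the seed and frozen; only the
    dense head on top is trained (large random graph-convolution weights are a
    well-behaved stand-in for learned ones at this scale).
    """

    depth: int
    fp_length: int
    hidden_dim: int
    seed: int
    W_in: np.ndarray = field(init=False)
    W_self: list[np.ndarray] = field(init=False)
    W_nbr: list[np.ndarray] = field(init=False)
    W_bond: list[np.ndarray] = field(init=False)
    W_out: list[np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        d = self.hidden_dim

        def mat(shape):
            return rng.normal(0.0, math.sqrt(2.0 / shape[0]), size=shape)

        self.W_in = mat((ATOM_FEATURE_DIM, d))
        self.W_self = [mat((d, d)) for _ in range(self.depth)]
        self.W_nbr = [mat((d, d)) for _ in range(self.depth)]
        self.W_bond = [mat((BOND_FEATURE_DIM, d)) for _ in range(self.depth)]
        self.W_out = [mat((d, self.fp_length)) for _ in range(self.depth + 1)]

    def embed(self, graph: GraphEncoding) -> np.ndarray:
        """Dense fingerprint of shape (fp_length,)."""
        h = np.maximum(graph.atom_features @ self.W_in, 0.0)
        adj = graph.adjacency()
        bsum = graph.bond_sums()
        fp = self._pool(h, self.W_out[0])
        for layer in range(self.depth):
            h = np.maximum(
                h @ self.W_self[layer]
                + adj @ h @ self.W_nbr[layer]
                + bsum @ self.W_bond[layer],
                0.0,
            )
            fp += self._pool(h, self.W_out[layer + 1])
        return fp

    @staticmethod
    def _pool(h: np.ndarray, w_out: np.ndarray) -> np.ndarray:
        z = h @ w_out
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        sm = ez / ez.sum(axis=1, keepdims=True)
        return sm.sum(axis=0)

    def params(self) -> dict:
        return {
            "depth": self.depth,
            "fp_length": self.fp_length,
            "hidden_dim": self.hidden_dim,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Public training / prediction API


@dataclass
class TrainedClassifier:
    architecture: str  # "ecfp_dense" | "nfp_graphconv"
    mlp: _MLP
    config: ClassifierConfig
    decision_threshold: float = 0.5
    encoder: _NFPEncoder | None = None
    history: dict = field(default_factory=dict)


def _dense_matrix(items: list[BitFingerprint]) -> np.ndarray:
    if not items:
        return np.zeros((0, 0))
    if not isinstance(items[0], BitFingerprint):
        raise TypeError("ecfp_dense classifier expects BitFingerprint inputs")
    length = items[0].length
    X = np.zeros((len(items), length), dtype=np.float64)
    for i, fp in enumerate(items):
        if not isinstance(fp, BitFingerprint):
            raise TypeError("ecfp_dense classifier expects BitFingerprint inputs")
        if fp.length != length:
            raise ValueError("inconsistent fingerprint lengths")
        if fp.on_bits:
            X[i, sorted(fp.on_bits)] = 1.0
    return X


def _check_labels(y: np.ndarray) -> None:
    classes = set(np.unique(y).tolist())
    if not classes <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(classes) < 2:
        raise TrainingError("training set contains a single class")


def train_dense_classifier(
    train_set: list[tuple[BitFingerprint, int]],
    validation_set: list[tuple[BitFingerprint, int]],
    config: ClassifierConfig = ClassifierConfig(),
) -> TrainedClassifier:
    """Train the feedforward classifier on fingerprint/label pairs."""
    X_train = _dense_matrix([fp for fp, _ in train_set])
    y_train = np.array([float(y) for _, y in train_set])
    X_val = _dense_matrix([fp for fp, _ in validation_set])
    y_val = np.array([float(y) for _, y in validation_set])
    _check_labels(y_train)
    rng = np.random.default_rng(config.seed)
    mlp = _MLP([X_train.shape[1], *config.hidden_widths, 1], rng)
    history = _train_mlp(mlp, X_train, y_train, X_val, y_val, config, rng)
    history["batch_size"] = config.batch_size
    return TrainedClassifier(
        architecture="ecfp_dense", mlp=mlp, config=config, history=history
    )


def train_nfp_classifier(
    train_set: list[tuple[GraphEncoding, int]],
    validation_set: list[tuple[GraphEncoding, int]],
    config: ClassifierConfig = ClassifierConfig(batch_size=350),
) -> TrainedClassifier:
    """Train the graph-convolutional neural-fingerprint classifier."""
    encoder = _NFPEncoder(
        depth=config.nfp_depth,
        fp_length=config.nfp_fp_length,
        hidden_dim=config.nfp_hidden_dim,
        seed=config.seed,
    )
    X_train = np.stack([encoder.embed(g) for g, _ in train_set])
    y_train = np.array([float(y) for _, y in train_set])
    X_val = np.stack([encoder.embed(g) for g, _ in validation_set])
    y_val = np.array([float(y) for _, y in validation_set])
    _check_labels(y_train)
    rng = np.random.default_rng(config.seed)
    head_widths = config.hidden_widths if config.hidden_widths else (64,)
    mlp = _MLP([config.nfp_fp_length, *head_widths, 1], rng)
    history = _train_mlp(mlp, X_train, y_train, X_val, y_val, config, rng)
    history["batch_size"] = config.batch_size
    return TrainedClassifier(
        architecture="nfp_graphconv",
        mlp=mlp,
        config=config,
        encoder=encoder,
        history=history,
    )


def predict(classifier: TrainedClassifier, items: list) -> np.ndarray:
    """Predicted probabilities for fingerprints (dense) or graphs (NFP)."""
    if not items:
        return np.zeros(0)
    if classifier.architecture == "ecfp_dense":
        X = _dense_matrix(items)
        if X.shape[1] != classifier.mlp.sizes[0]:
            raise ValueError(
                f"fingerprint length {X.shape[1]} does not match model input "
                f"{classifier.mlp.sizes[0]}"
            )
    elif classifier.architecture == "nfp_graphconv":
        for g in items:
            if not isinstance(g, GraphEncoding):
                raise TypeError("nfp_graphconv classifier expects GraphEncoding inputs")
        X = np.stack([classifier.encoder.embed(g) for g in items])
    else:
        raise ValueError(f"unknown architecture {classifier.architecture!r}")
    p, _ = classifier.mlp.forward(X)
    return p


def classify(classifier: TrainedClassifier, items: list) -> np.ndarray:
    """Hard 0/1 labels at the classifier's decision threshold."""
    return (predict(classifier, items) >= classifier.decision_threshold).astype(int)


# ---------------------------------------------------------------------------
# Evaluation


def confusion(labels, predictions) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (set(np.unique(labels)) | set(np.unique(predictions))) <= {0, 1}:
        raise ValueError("labels and predictions must be binary")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    return ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def auc_score(labels, scores) -> float:
    """ROC area by the rank statistic; ties receive average ranks."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    r = rankdata(scores, method="average")
    return (float(r[labels].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def metrics(
    counts: ConfusionCounts,
    scores=None,
    labels=None,
) -> EvalReport:
    """Sensitivity, specificity, predictive values, MCC, and (when scores are
    given) the ROC AUC. Any zero denominator yields NaN."""
    tp, fn, tn, fp = counts.TP, counts.FN, counts.TN, counts.FP
    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    qp = _ratio(tp, tp + fp)
    qm = _ratio(tn, tn + fn)
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fn * fp) / math.sqrt(denom) if denom > 0 else math.nan
    auc = auc_score(labels, scores) if scores is not None and labels is not None else math.nan
    return EvalReport(SE=se, SP=sp, Qplus=qp, Qminus=qm, MCC=mcc, AUC=auc)


def evaluate_classifier(
    classifier: TrainedClassifier, items: list, labels
) -> EvalReport:
    scores = predict(classifier, items)
    preds = (scores >= classifier.decision_threshold).astype(int)
    return metrics(confusion(labels, preds), scores=scores, labels=labels)


@dataclass(frozen=True)
class SweepRow:
    model: str
    batch_size: int
    report: EvalReport


def batch_size_sweep(
    train_set,
    test_set,
    sizes: list[int],
    architecture: str = "ecfp_dense",
    validation_set=None,
    base_config: ClassifierConfig | None = None,
) -> tuple[list[SweepRow], int]:
    """Train one model per batch size; return the rows and the index of the
    best row (highest AUC, ties broken by MCC)."""
    if not sizes:
        raise ValueError("sizes must be nonempty")
    base = base_config or ClassifierConfig()
    val = validation_set if validation_set is not None else test_set
    trainer = (
        train_dense_classifier if architecture == "ecfp_dense" else train_nfp_classifier
    )
    prefix = "Model_D" if architecture == "ecfp_dense" else "Model_C"
    rows: list[SweepRow] = []
    test_items = [x for x, _ in test_set]
    test_labels = [y for _, y in test_set]
    for i, size in enumerate(sizes, start=1):
        cfg_dict = asdict(base)
        cfg_dict["batch_size"] = size
        cfg_dict["hidden_widths"] = tuple(cfg_dict["hidden_widths"])
        cfg = ClassifierConfig(**cfg_dict)
        clf = trainer(train_set, val, cfg)
        rows.append(SweepRow(f"{prefix}{i}", size, evaluate_classifier(clf, test_items, test_labels)))

    def sort_key(i: int):
        rep = rows[i].report
        auc = rep.AUC if not math.isnan(rep.AUC) else -math.inf
        mcc = rep.MCC if not math.isnan(rep.MCC) else -math.inf
        return (auc, mcc)

    best = max(range(len(rows)), key=sort_key)
    return rows, best


def write_sweep_tsv(path, rows: list[SweepRow]) -> None:
    """Metrics table in (model, batch size, SE, SP, Q+, Q-, MCC, AUC) order."""
    with open(path, "w") as fh:
        fh.write("model\tbatch_size\tSE\tSP\tQ+\tQ-\tMCC\tAUC\n")
        for row in rows:
            r = row.report
            fh.write(
                f"{row.model}\t{row.batch_size}\t{r.SE:.3f}\t{r.SP:.3f}\t"
                f"{r.Qplus:.3f}\t{r.Qminus:.3f}\t{r.MCC:.3f}\t{r.AUC:.3f}\n"
            )


# ---------------------------------------------------------------------------
# Checkpointing (single JSON archive: weights + config + encoder params)


def save_classifier(classifier: TrainedClassifier, path) -> None:
    payload = {
        "architecture": classifier.architecture,
        "decision_threshold": classifier.decision_threshold,
        "config": asdict(classifier.config),
        "mlp": classifier.mlp.state(),
        "encoder": classifier.encoder.params() if classifier.encoder else None,
        "history": classifier.history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_classifier(path) -> TrainedClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = dict(payload["config"])
    cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
    config = ClassifierConfig(**cfg)
    encoder = None
    if payload["encoder"] is not None:
        encoder = _NFPEncoder(**payload["encoder"])
    return TrainedClassifier(
        architecture=payload["architecture"],
        mlp=_MLP.from_state(payload["mlp"]),
        config=config,
        decision_threshold=payload["decision_threshold"],
        encoder=encoder,
        history=payload.get("history", {}),
    )
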