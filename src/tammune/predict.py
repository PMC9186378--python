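"""Neural-network prediction of immune-checkpoint-blockade response.

The predictor is a small fully connected network on 7 per-sample
features — the ssGSEA grades of CXCL9, CXCL10, CXCL11 and CCL5 plus the
deconvolved fractions of M1 macrophages, CD8 T cells and activated-memory
CD4 T cells — with layer sizes [7, 20, 5, 1], the logistic sigmoid
1/(1+e^-x) at every layer, inverted dropout on the two hidden layers
during training, and mean binary cross-entropy loss
(1/N) sum -(y log p + (1-y) log(1-p)) minimized by full-batch gradient
descent. Response is coded 1 for CR/PR and 0 for SD/PD. Evaluation
reports the ROC curve, trapezoidal AUC and the confusion matrix at
threshold 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .matrix import ExpressionMatrix
from .score import ssgsea
from .synth import CHEMOKINES, KEY_CELL_TYPES

__all__ = [
    "FEATURE_COLUMNS",
    "build_features",
    "MlpModel",
    "train_mlp",
    "predict_proba",
    "evaluate",
    "RocResult",
]

FEATURE_COLUMNS = tuple(CHEMOKINES) + tuple(KEY_CELL_TYPES)


def build_features(
    expr: ExpressionMatrix,
    fractions: pd.DataFrame,
    labels: pd.Series,
    chemokine_sets: dict[str, list[str]] | None = None,
    fraction_columns: tuple[str, ...] = KEY_CELL_TYPES,
) -> pd.DataFrame:
    """Assemble the 7-feature table (plus the 0/1 ``response`` column).

    Chemokine grades are per-gene ssGSEA scores (single-gene sets by
    default); the three fraction columns are taken from the deconvolution
    output. Features are z-scored per column.
    """
    if chemokine_sets is None:
        chemokine_sets = {g: [g] for g in CHEMOKINES}
    samples = list(expr.sample_ids)
    missing = [s for s in samples if s not in set(fractions.index)]
    if missing:
        raise ValueError(f"samples missing from fractions: {missing[:5]}")
    missing = [s for s in samples if s not in set(labels.index)]
    if missing:
        raise ValueError(f"samples missing from labels: {missing[:5]}")
    absent = [c for c in fraction_columns if c not in fractions.columns]
    if absent:
        raise ValueError(f"missing cell-type column(s): {absent}")

    grades = ssgsea(expr, chemokine_sets)
    ft = pd.concat(
        [grades.loc[samples], fractions.loc[samples, list(fraction_columns)]], axis=1
    )
    sd = ft.std(axis=0, ddof=0)
    flat = sd.index[sd == 0].tolist()
    if flat:
        raise ValueError(
            f"constant feature(s) {flat}: z-scoring undefined; drop the column "
            "or check the upstream scores"
        )
    ft = (ft - ft.mean(axis=0)) / sd
    ft["response"] = labels.loc[samples].astype(int)
    return ft


# ======================================================================


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class MlpModel:
    """[7, 20, 5, 1] sigmoid network with stored training configuration."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_columns: list[str]
    dropout_rate: float
    learning_rate: float
    epochs: int
    seed: int
    loss_trace: list[float] = field(default_factory=list)

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[1]] + [w.shape[0] for w in self.weights]

    # -- forward -------------------------------------------------------
    def forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None,
        dropout: bool = False,
    ) -> tuple[list[np.ndarray], list[np.ndarray | None]]:
        """Layer activations (input first); dropout masks when training."""
        acts = [X]
        masks: list[np.ndarray | None] = []
        a = X
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = _sigmoid(a @ W.T + b)
            hidden = li < len(self.weights) - 1
            if hidden and dropout and self.dropout_rate > 0:
                keep = 1.0 - self.dropout_rate
                m = (rng.uniform(size=a.shape) < keep) / keep  # inverted dropout
                a = a * m
                masks.append(m)
            else:
                masks.append(None)
            acts.append(a)
        return acts, masks

    # -- serialization -------------------------------------------------
    def save(self, path: str | Path) -> None:
        blob = {
            "layer_sizes": self.layer_sizes,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_columns": self.feature_columns,
            "dropout_rate": self.dropout_rate,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "MlpModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            weights=[np.asarray(w, dtype=float) for w in blob["weights"]],
            biases=[np.asarray(b, dtype=float) for b in blob["biases"]],
            feature_columns=list(blob["feature_columns"]),
            dropout_rate=blob["dropout_rate"],
            learning_rate=blob["learning_rate"],
            epochs=blob["epochs"],
            seed=blob["seed"],
        )


def _loss_and_grads(
    model: MlpModel, X: np.ndarray, y: np.ndarray,
    rng: np.random.Generator | None = None, dropout: bool = False,
    pos_weight: float = 1.0,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean binary cross-entropy and its gradients by backpropagation."""
    acts, masks = model.forward(X, rng=rng, dropout=dropout)
    p = acts[-1][:, 0]
    eps = 1e-12
    w_samp = np.where(y == 1, pos_weight, 1.0)
    n = len(y)
    loss = float(
        np.sum(-w_samp * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))) / n
    )
    # output layer: d(loss)/d(z_out) for sigmoid + cross-entropy
    delta = ((p - y) * w_samp / n)[:, None]
    gW: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    gb: list[np.ndarray] = [None] * len(model.biases)   # type: ignore[list-item]
    for li in range(len(model.weights) - 1, -1, -1):
        a_prev = acts[li]
        gW[li] = delta.T @ a_prev
        gb[li] = delta.sum(axis=0)
        if li > 0:
            back = delta @ model.weights[li]
            m = masks[li - 1]
            a = acts[li]
            if m is not None:
                back = back * m
                # pre-dropout sigmoid output for the derivative; dropped
                # units have back == 0, so their value is irrelevant
                a = a / np.where(m > 0, m, 1.0)
            delta = back * a * (1.0 - a)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss; lower the learning rate")
    return loss, gW, gb


def train_mlp(
    ft: pd.DataFrame,
    lr: float = 0.1,
    epochs: int = 2000,
    dropout_rate: float = 0.2,
    seed: int = 0,
    hidden_sizes: tuple[int, int] = (20, 5),
    pos_weight: float = 1.0,
) -> MlpModel:
    """Train the response network by full-batch gradient descent.

    ``ft`` is a feature table from :func:`build_features` (z-scored
    feature columns plus ``response``). Weights start uniform(-0.5, 0.5)
    under the seed; training is deterministic for a fixed seed.
    """
    if "response" not in ft.columns:
        raise ValueError("feature table must contain a 'response' column")
    y = ft["response"].to_numpy(dtype=float)
    X = ft.drop(columns="response").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(y) < 20:
        raise ValueError(f"need >= 20 samples to train, got {len(y)}")

    rng = np.random.default_rng(seed)
    sizes = [X.shape[1], *hidden_sizes, 1]
    weights = [
        rng.uniform(-0.5, 0.5, size=(sizes[i + 1], sizes[i]))
        for i in range(len(sizes) - 1)
    ]
    biases = [rng.uniform(-0.5, 0.5, size=sizes[i + 1]) for i in range(len(sizes) - 1)]
    model = MlpModel(
        weights=weights,
        biases=biases,
        feature_columns=[c for c in ft.columns if c != "response"],
        dropout_rate=dropout_rate,
        learning_rate=lr,
        epochs=epochs,
        seed=seed,
    )
    for _ in range(epochs):
        loss, gW, gb = _loss_and_grads(
            model, X, y, rng=rng, dropout=dropout_rate > 0, pos_weight=pos_weight
        )
        model.loss_trace.append(loss)
        for li in range(len(model.weights)):
            model.weights[li] -= lr * gW[li]
            model.biases[li] -= lr * gb[li]
    return model


def predict_proba(model: MlpModel, ft: pd.DataFrame) -> pd.Series:
    """Response probabilities (dropout disabled)."""
    cols = [c for c in ft.columns if c != "response"]
    if cols != model.feature_columns:
        raise ValueError(
            f"feature columns {cols} do not match training schema "
            f"{model.feature_columns}"
        )
    X = ft[cols].to_numpy(dtype=float)
    acts, _ = model.forward(X, dropout=False)
    return pd.Series(acts[-1][:, 0], index=ft.index, name="probability")


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    confusion: pd.DataFrame  # at threshold 0.5


def evaluate(probabilities: pd.Series, labels: pd.Series) -> RocResult:
    """ROC curve, trapezoidal AUC and the 0.5-threshold confusion matrix."""
    p = pd.Series(probabilities).astype(float)
    y = pd.Series(labels).loc[p.index].astype(int)
    if y.nunique() < 2:
        raise ValueError("evaluation requires both classes")
    fpr, tpr, thr = roc_curve(y, p)
    auc = float(roc_auc_score(y, p))
    pred = (p.to_numpy() >= 0.5).astype(int)
    yv = y.to_numpy()
    conf = pd.DataFrame(
        [
            [int(((pred == 1) & (yv == 1)).sum()), int(((pred == 1) & (yv == 0)).sum())],
            [int(((pred == 0) & (yv == 1)).sum()), int(((pred == 0) & (yv == 0)).sum())],
        ],
        index=["pred_pos", "pred_neg"],
        columns=["true_pos_class", "true_neg_class"],
    )
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc, confusion=conf)
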