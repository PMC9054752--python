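"""Neural Networks on Dictionaries (NNoD): multi-label decoding models.

The model family is a fully connected network with 0 to 3 hidden layers on
top of dictionary loadings x in R^p.  With no hidden layers the score is the
logistic-regression form

    f_theta(x) = W x + b,        theta = {W, b},

otherwise each hidden affine map is followed by the configured activation
(identity or the rectifier z -> max(z, 0)).  Two output formulations are
supported:

* binary — each label is an independent Bernoulli task, sigmoid outputs and
  a summed per-label cross-entropy;
* multinomial — labels compete through a softmax, and the target is the
  label-sum-normalized vector y / sum_k y^k.

Both losses add an elastic-net penalty R(theta) on the weights (biases
excluded); dropout with inverted scaling is applied to the input and hidden
activations during training.  Everything is plain NumPy: training is
mini-batch gradient descent with adaptive moments (Adam), deterministic
given the config seed.

Usage follows the statsmodels convention: build a :class:`ConceptDecoder`
from data, call ``fit`` to obtain :class:`DecoderResults` carrying the
parameters, training history, prediction methods and a ``summary`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

EPS = 1e-7
ACTIVATIONS = ("identity", "rectifier")
OUTPUT_MODES = ("binary", "multinomial")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and regularization of one NNoD model."""

    input_dim: int
    n_labels: int
    n_hidden: int = 1
    hidden_width: int = 300
    activation: str = "rectifier"
    output_mode: str = "binary"
    l1_weight: float = 1e-3
    l2_weight: float = 1e-3
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.n_labels < 1:
            raise ValueError("input_dim and n_labels must be positive")
        if self.n_hidden not in (0, 1, 2, 3):
            raise ValueError("n_hidden must be in {0, 1, 2, 3}")
        if self.n_hidden >= 1 and self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1 with hidden layers")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.output_mode not in OUTPUT_MODES:
            raise ValueError(f"output_mode must be one of {OUTPUT_MODES}")
        if self.l1_weight < 0 or self.l2_weight < 0:
            raise ValueError("penalty weights must be non-negative")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def layer_dims(self) -> list[int]:
        return [self.input_dim] + [self.hidden_width] * self.n_hidden + [self.n_labels]


def reference_config(input_dim: int, n_labels: int, seed: int = 0) -> ModelConfig:
    """The selected configuration: one rectifier hidden layer of width 300,
    dropout 0.2, and an elastic-net penalty of 0.001 on both norms."""
    return ModelConfig(input_dim=input_dim, n_labels=n_labels, seed=seed)


# ---------------------------------------------------------------------------
# parameters and forward pass
# ---------------------------------------------------------------------------

Params = list[tuple[np.ndarray, np.ndarray]]  # [(W: out x in, b: out), ...]


def init_params(config: ModelConfig) -> Params:
    # symmetric uniform scaled by fan-in
    rng = np.random.default_rng(config.seed)
    dims = config.layer_dims
    params: Params = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(1.0 / d_in)
        W = rng.uniform(-bound, bound, size=(d_out, d_in))
        b = np.zeros(d_out)
        params.append((W, b))
    return params


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "rectifier":
        return np.maximum(z, 0.0)
    return z


def _forward_logits(params: Params, x: np.ndarray, activation: str) -> np.ndarray:
    h = x
    for W, b in params[:-1]:
        h = _activate(h @ W.T + b, activation)
    W, b = params[-1]
    return h @ W.T + b


def _as_input(x, input_dim: int) -> tuple[np.ndarray, bool]:
    """Coerce an Embedding / vector / batch to a 2-D array."""
    if hasattr(x, "loadings"):
        x = x.loadings
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != input_dim:
        raise ValueError(f"input has {x.shape[1]} features, model expects {input_dim}")
    return x, single


def forward(model: "DecoderResults", x) -> np.ndarray:
    """Pre-activation output scores (logits); no output activation applied."""
    xb, single = _as_input(x, model.config.input_dim)
    z = _forward_logits(model.params, xb, model.config.activation)
    return z[0] if single else z


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)  # max-subtraction for stability
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def predict_binary(model: "DecoderResults", x) -> np.ndarray:
    """Elementwise sigmoid of the scores (independent Bernoulli labels)."""
    if model.config.output_mode != "binary":
        raise ValueError("model is not in binary output mode")
    return _sigmoid(forward(model, x))


def predict_multinomial(model: "DecoderResults", x) -> np.ndarray:
    """Softmax of the scores (categorical distribution over labels)."""
    if model.config.output_mode != "multinomial":
        raise ValueError("model is not in multinomial output mode")
    return _softmax(forward(model, x))


# ---------------------------------------------------------------------------
# losses and penalty
# ---------------------------------------------------------------------------

def regularization(params_or_model, l1_weight: float, l2_weight: float) -> float:
    """Elastic net on the weight matrices of every layer; biases excluded."""
    params = getattr(params_or_model, "params", params_or_model)
    r = 0.0
    for W, _ in params:
        r += l1_weight * np.abs(W).sum() + l2_weight * (W ** 2).sum()
    return float(r)


def _penalty_of(model: "DecoderResults | None") -> float:
    if model is None:
        return 0.0
    return regularization(model.params, model.config.l1_weight, model.config.l2_weight)


def loss_binary(y: np.ndarray, y_hat: np.ndarray, model: "DecoderResults | None" = None) -> float:
    """Summed per-label cross-entropy plus the model's elastic-net penalty."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("label and prediction lengths differ")
    p = np.clip(y_hat, EPS, 1.0 - EPS)
    ce = -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(ce + _penalty_of(model))


def loss_multinomial(y: np.ndarray, y_hat: np.ndarray, model: "DecoderResults | None" = None) -> float:
    """Categorical cross-entropy with label-sum-normalized targets."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("label and prediction lengths differ")
    total = y.sum()
    if total <= 0:
        raise ValueError("multinomial loss undefined for an all-zero label vector")
    p = np.clip(y_hat, EPS, 1.0 - EPS)
    ce = -np.sum((y / total) * np.log(p))
    return float(ce + _penalty_of(model))


# ---------------------------------------------------------------------------
# training internals
# ---------------------------------------------------------------------------

def _targets(Y: np.ndarray, output_mode: str) -> np.ndarray:
    if output_mode == "binary":
        return Y
    sums = Y.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("multinomial mode requires at least one positive label per row")
    return Y / sums


def _batch_objective(params: Params, X, T, config: ModelConfig) -> float:
    """Mean per-sample data loss plus the penalty (the trained objective)."""
    z = _forward_logits(params, X, config.activation)
    if config.output_mode == "binary":
        p = np.clip(_sigmoid(z), EPS, 1.0 - EPS)
        data = -np.sum(T * np.log(p) + (1.0 - T) * np.log(1.0 - p)) / X.shape[0]
    else:
        p = np.clip(_softmax(z), EPS, 1.0 - EPS)
        data = -np.sum(T * np.log(p)) / X.shape[0]
    return float(data + regularization(params, config.l1_weight, config.l2_weight))


def _batch_gradients(
    params: Params,
    X: np.ndarray,
    T: np.ndarray,
    config: ModelConfig,
    dropout_masks: list[np.ndarray] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Analytic gradients of the batch objective by backpropagation.

    `dropout_masks` are inverted-scaled keep masks for the input and each
    hidden activation (None during evaluation-mode gradient checks).
    """
    n = X.shape[0]
    activations = []
    pre: list[np.ndarray] = []
    h = X if dropout_masks is None else X * dropout_masks[0]
    activations.append(h)
    for li, (W, b) in enumerate(params[:-1]):
        z = h @ W.T + b
        pre.append(z)
        h = _activate(z, config.activation)
        if dropout_masks is not None:
            h = h * dropout_masks[li + 1]
        activations.append(h)
    W_out, b_out = params[-1]
    z_out = h @ W_out.T + b_out
    probs = _sigmoid(z_out) if config.output_mode == "binary" else _softmax(z_out)
    delta = (probs - T) / n
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params)  # type: ignore[list-item]
    for li in range(len(params) - 1, -1, -1):
        W, _ = params[li]
        gW = delta.T @ activations[li]
        gW = gW + config.l1_weight * np.sign(W) + 2.0 * config.l2_weight * W
        gb = delta.sum(axis=0)
        grads[li] = (gW, gb)
        if li > 0:
            delta = delta @ W
            if dropout_masks is not None:
                delta = delta * dropout_masks[li]
            if config.activation == "rectifier":
                delta = delta * (pre[li - 1] > 0)
    return grads


def _coerce_xy(X, Y) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    label_names = None
    if hasattr(Y, "frame"):  # LabelMatrix
        label_names = list(Y.frame.columns)
        Y = Y.frame.to_numpy()
    elif isinstance(Y, pd.DataFrame):
        label_names = list(Y.columns)
        Y = Y.to_numpy()
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X rows must align with Y rows")
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    return X, Y, label_names


def train(
    config: ModelConfig,
    X,
    Y,
    epochs: int = 100,
    batch_size: int = 256,
    learning_rate: float = 1e-3,
) -> "DecoderResults":
    """Fit one NNoD model by Adam mini-batch descent (seeded, deterministic)."""
    X, Y, label_names = _coerce_xy(X, Y)
    if config.input_dim != X.shape[1] or config.n_labels != Y.shape[1]:
        raise ValueError("config dimensions do not match the data")
    T = _targets(Y, config.output_mode)
    params = init_params(config)
    rng = np.random.default_rng([config.seed, 1])
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = X.shape[0]
    keep = 1.0 - config.dropout_rate
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Xb, Tb = X[idx], T[idx]
            masks = None
            if config.dropout_rate > 0:
                masks = [
                    (rng.random((Xb.shape[0], d)) < keep).astype(float) / keep
                    for d in config.layer_dims[:-1]
                ]
            grads = _batch_gradients(params, Xb, Tb, config, masks)
            step += 1
            new_params = []
            for li, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
                mW, mb = m[li]
                vW, vb = v[li]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW ** 2
                vb = beta2 * vb + (1 - beta2) * gb ** 2
                m[li] = (mW, mb)
                v[li] = (vW, vb)
                mW_hat = mW / (1 - beta1 ** step)
                mb_hat = mb / (1 - beta1 ** step)
                vW_hat = vW / (1 - beta2 ** step)
                vb_hat = vb / (1 - beta2 ** step)
                new_params.append(
                    (
                        W - learning_rate * mW_hat / (np.sqrt(vW_hat) + eps),
                        b - learning_rate * mb_hat / (np.sqrt(vb_hat) + eps),
                    )
                )
            params = new_params
            epoch_losses.append(_batch_objective(params, Xb, Tb, config))
        history.append(float(np.mean(epoch_losses)))
    return DecoderResults(params=params, config=config, label_names=label_names, history=history)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class ConceptDecoder:
    """A multi-label concept decoder bound to one feature/label dataset.

    Parameters
    ----------
    X : (n, p) array or DataFrame of dictionary loadings
    Y : (n, L) binary array, DataFrame or LabelMatrix
    config : ModelConfig, defaults to the reference configuration
    """

    def __init__(self, X, Y, config: ModelConfig | None = None):
        self.X, self.Y, self.label_names = _coerce_xy(X, Y)
        if config is None:
            config = reference_config(self.X.shape[1], self.Y.shape[1])
        if config.input_dim != self.X.shape[1] or config.n_labels != self.Y.shape[1]:
            raise ValueError("config dimensions do not match the data")
        self.config = config

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, labels, config: ModelConfig | None = None):
        """Align a feature table with a LabelMatrix on map_id and build the model."""
        frame = labels.frame if hasattr(labels, "frame") else labels
        common = [i for i in frame.index if i in set(features.index)]
        return cls(features.loc[common], frame.loc[common], config)

    def fit(
        self,
        epochs: int = 100,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
    ) -> "DecoderResults":
        res = train(
            self.config, self.X, self.Y,
            epochs=epochs, batch_size=batch_size, learning_rate=learning_rate,
        )
        if res.label_names is None:
            res = replace(res, label_names=self.label_names)
        res.model = self
        return res


@dataclass
class DecoderResults:
    """Fitted NNoD parameters with prediction, evaluation and persistence."""

    params: Params
    config: ModelConfig
    label_names: list[str] | None = None
    history: list[float] = field(default_factory=list)
    model: ConceptDecoder | None = None

    @property
    def n_parameters(self) -> int:
        return int(sum(W.size + b.size for W, b in self.params))

    def decision_function(self, X) -> np.ndarray:
        return forward(self, X)

    def predict(self, X) -> np.ndarray:
        """Label probabilities under the configured output model."""
        if self.config.output_mode == "binary":
            return predict_binary(self, X)
        return predict_multinomial(self, X)

    predict_proba = predict

    def label_index(self, label: str) -> int:
        if self.label_names is None:
            raise ValueError("results carry no label names")
        try:
            return self.label_names.index(label)
        except ValueError as err:
            raise KeyError(f"unknown label {label!r}") from err

    def evaluate(self, X, Y, k: int = 10):
        """EvalReport (macro AUC, WR@k, per-label AUCs) on held-out data."""
        from .metrics import evaluate_scores

        frame = Y.frame if hasattr(Y, "frame") else Y
        names = list(frame.columns) if isinstance(frame, pd.DataFrame) else self.label_names
        Yv = frame.to_numpy() if isinstance(frame, pd.DataFrame) else np.asarray(frame)
        scores = self.decision_function(X)
        return evaluate_scores(Yv, scores, label_names=names, k=k)

    def input_gradient(self, X, label_index: int) -> np.ndarray:
        """d score_l / d x for each row of X (evaluation mode, no dropout)."""
        Xb, single = _as_input(X, self.config.input_dim)
        activations = [Xb]
        pre = []
        h = Xb
        for W, b in self.params[:-1]:
            z = h @ W.T + b
            pre.append(z)
            h = _activate(z, self.config.activation)
            activations.append(h)
        W_out, _ = self.params[-1]
        delta = np.repeat(W_out[label_index][None, :], Xb.shape[0], axis=0)
        for li in range(len(self.params) - 2, -1, -1):
            if self.config.activation == "rectifier":
                delta = delta * (pre[li] > 0)
            delta = delta @ self.params[li][0]
        return delta[0] if single else delta

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "NNoD decoder results",
            "=" * 44,
            f"output mode     : {cfg.output_mode}",
            f"hidden layers   : {cfg.n_hidden} x {cfg.hidden_width if cfg.n_hidden else '-'}"
            f" ({cfg.activation})",
            f"layer dims      : {' -> '.join(map(str, cfg.layer_dims))}",
            f"parameters      : {self.n_parameters}",
            f"l1 / l2 penalty : {cfg.l1_weight:g} / {cfg.l2_weight:g}",
            f"dropout rate    : {cfg.dropout_rate:g}",
            f"labels          : {cfg.n_labels}",
        ]
        if self.history:
            lines.append(f"final objective : {self.history[-1]:.4f} "
                         f"(epoch 1: {self.history[0]:.4f}, {len(self.history)} epochs)")
        return "\n".join(lines)

    # --- persistence: JSON config + npz weight arrays ---------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cfg = {k: getattr(self.config, k) for k in self.config.__dataclass_fields__}
        (path / "config.json").write_text(
            json.dumps({"config": cfg, "label_names": self.label_names,
                        "history": self.history})
        )
        arrays = {}
        for li, (W, b) in enumerate(self.params):
            arrays[f"W{li}"] = W
            arrays[f"b{li}"] = b
        np.savez(path / "weights.npz", **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DecoderResults":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        config = ModelConfig(**meta["config"])
        data = np.load(path / "weights.npz")
        params = [
            (data[f"W{li}"], data[f"b{li}"])
            for li in range(len(config.layer_dims) - 1)
        ]
        return cls(params=params, config=config,
                   label_names=meta.get("label_names"), history=meta.get("history", []))


def grid_search(
    configs: list[ModelConfig],
    X_train,
    Y_train,
    X_val,
    Y_val,
    epochs: int = 100,
    batch_size: int = 256,
    learning_rate: float = 1e-3,
) -> tuple[ModelConfig, DecoderResults, pd.DataFrame]:
    """Train every config and select the best validation macro AUC.

    Ties break toward the earlier position in `configs`.
    """
    from .metrics import evaluate_scores

    if not configs:
        raise ValueError("grid_search needs at least one config")
    Xv, Yv, _ = _coerce_xy(X_val, Y_val)
    rows = []
    best: tuple[float, int, DecoderResults] | None = None
    for ci, cfg in enumerate(configs):
        res = train(cfg, X_train, Y_train, epochs=epochs,
                    batch_size=batch_size, learning_rate=learning_rate)
        report = evaluate_scores(Yv, res.decision_function(Xv), k=min(10, cfg.n_labels))
        auc = report.macro_auc
        rows.append({
            "config_index": ci, "n_hidden": cfg.n_hidden,
            "hidden_width": cfg.hidden_width, "activation": cfg.activation,
            "output_mode": cfg.output_mode, "l1_weight": cfg.l1_weight,
            "l2_weight": cfg.l2_weight, "dropout_rate": cfg.dropout_rate,
            "val_macro_auc": auc,
        })
        if best is None or auc > best[0]:
            best = (auc, ci, res)
    assert best is not None
    table = pd.DataFrame(rows)
    return configs[best[1]], best[2], table
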