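"""The bipartite graph convolutional network classifier ``f(P, A)``.

Respondent nodes start with zero features, so one propagation step moves
answer-weighted information from respondents to item nodes and a second
step returns it; the number of graph-convolution layers must therefore
be EVEN for respondent representations to be populated.  The default
architecture is two convolutions (hidden widths 80 then 30) with
inverted dropout (p = 0.5) between them, a dense softmax head on the
respondent rows, and full-batch Adam (lr 1e-2) minimizing the negative
log-likelihood of the labeled respondents.

Prediction is inductive: unseen respondents are attached to the item
nodes of a fresh bipartite graph built from their own standardized
answers, and the frozen trained parameters are applied in eval mode.

Everything is plain float64 numpy; gradients are written by hand and
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from . import bipartite_graph as bg
from .evaluation import confusion_and_metrics
from .instruments import AnswerMatrix, InstrumentBank

__all__ = [
    "BGCNConfig",
    "BGCNParams",
    "GraphTensors",
    "ConfigurationError",
    "graph_tensors",
    "init_bgcn",
    "gcn_layer",
    "forward",
    "nll_loss",
    "loss_and_gradients",
    "train",
    "predict",
    "PredictionResult",
    "save_checkpoint",
    "load_checkpoint",
    "write_history_tsv",
]

CHECKPOINT_VERSION = 1


class ConfigurationError(ValueError):
    """Raised for invalid model configurations (e.g. odd convolution depth)."""


@dataclass(frozen=True)
class BGCNConfig:
    """Hyperparameters of the BGCN classifier.

    ``hidden_dims`` lists the output width of each graph-convolution
    layer; its length is the convolution depth and must be even.
    ``class_weight=None`` trains unweighted despite class imbalance;
    ``"balanced"`` applies inverse-frequency sample weights.
    """

    hidden_dims: tuple[int, ...] = (80, 30)
    dropout_p: float = 0.5
    learning_rate: float = 1e-2
    optimizer: str = "adam"
    epochs: int = 200
    seed: int = 0
    class_weight: str | None = None
    n_classes: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_dims", tuple(int(d) for d in self.hidden_dims))
        if len(self.hidden_dims) == 0 or len(self.hidden_dims) % 2 != 0:
            raise ConfigurationError(
                "even number of graph-convolution layers required "
                f"(got {len(self.hidden_dims)}): respondent nodes start with zero "
                "features and information must return to them through item nodes"
            )
        if any(d < 1 for d in self.hidden_dims):
            raise ConfigurationError("hidden dims must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError("dropout_p must be in [0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.n_classes != 2:
            raise ConfigurationError("binary crisis screening: n_classes must be 2")
        if self.class_weight not in (None, "balanced"):
            raise ConfigurationError("class_weight must be None or 'balanced'")

    def to_dict(self) -> dict:
        return {
            "hidden_dims": list(self.hidden_dims),
            "dropout_p": self.dropout_p,
            "learning_rate": self.learning_rate,
            "optimizer": self.optimizer,
            "epochs": self.epochs,
            "seed": self.seed,
            "class_weight": self.class_weight,
            "n_classes": self.n_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BGCNConfig":
        d = dict(d)
        d["hidden_dims"] = tuple(d.get("hidden_dims", (80, 30)))
        return cls(**d)


@dataclass
class BGCNParams:
    """Trainable parameters: per-layer convolution weights and the softmax head."""

    conv_weights: list[np.ndarray]
    out_weight: np.ndarray
    out_bias: np.ndarray
    config: BGCNConfig
    init_scheme: str = "glorot_uniform"
    init_seed: int = 0

    @property
    def n_features(self) -> int:
        """Input feature width (= item count k for the bipartite model)."""
        return self.conv_weights[0].shape[0]

    def tensors(self) -> list[np.ndarray]:
        return [*self.conv_weights, self.out_weight, self.out_bias]

    def copy(self) -> "BGCNParams":
        return BGCNParams(
            conv_weights=[w.copy() for w in self.conv_weights],
            out_weight=self.out_weight.copy(),
            out_bias=self.out_bias.copy(),
            config=self.config,
            init_scheme=self.init_scheme,
            init_seed=self.init_seed,
        )


class GraphTensors(NamedTuple):
    """Dense tensors a forward pass needs: normalized adjacency, features, and
    the node ids of the respondent rows (in respondent order)."""

    a_hat: np.ndarray
    features: np.ndarray
    respondent_rows: np.ndarray


def graph_tensors(graph: Union[bg.BipartiteGraph, GraphTensors]) -> GraphTensors:
    """Normalize a :class:`~bgcn_screen.bipartite_graph.BipartiteGraph` (or pass
    through ready-made tensors)."""
    if isinstance(graph, GraphTensors):
        return graph
    return GraphTensors(
        a_hat=bg.normalize_adjacency(graph),
        features=graph.features,
        respondent_rows=graph.respondent_nodes,
    )


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_bgcn(config: BGCNConfig, n_features: int, seed: int | None = None) -> BGCNParams:
    """Glorot-uniform parameter initialization; deterministic for a fixed seed.

    ``n_features`` is the width of the node feature matrix — the item
    count ``k`` for the bipartite model, since item features are ``I_k``.
    """
    if n_features < 1:
        raise ConfigurationError("n_features must be positive")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    dims = (n_features, *config.hidden_dims)
    conv = [_glorot_uniform(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
    out_w = _glorot_uniform(rng, dims[-1], config.n_classes)
    out_b = np.zeros(config.n_classes)
    return BGCNParams(
        conv_weights=conv,
        out_weight=out_w,
        out_bias=out_b,
        config=config,
        init_seed=seed,
    )


_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "relu": lambda z: np.maximum(z, 0.0),
    "identity": lambda z: z,
}


def gcn_layer(a_hat, h, theta, activation="relu") -> np.ndarray:
    """One graph-convolution step: ``activation(A_hat @ H @ Theta)``."""
    a_hat = np.asarray(a_hat, dtype=float)
    h = np.asarray(h, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if a_hat.shape[1] != h.shape[0] or h.shape[1] != theta.shape[0]:
        raise ValueError(
            f"shape mismatch: A_hat {a_hat.shape}, H {h.shape}, Theta {theta.shape}"
        )
    act = _ACTIVATIONS[activation] if isinstance(activation, str) else activation
    return act(a_hat @ (h @ theta))


def _forward_cached(params: BGCNParams, gt: GraphTensors, mode: str, rng):
    """Forward pass keeping intermediates for backprop.

    Matmuls are ordered ``A_hat @ (H @ Theta)`` so the large adjacency
    multiplies a thin matrix.
    """
    p = params.config.dropout_p
    n_layers = len(params.conv_weights)
    h = gt.features
    cache = []
    for i, theta in enumerate(params.conv_weights):
        ah_theta_in = h  # input to this layer
        z = gt.a_hat @ (h @ theta)
        h_act = np.maximum(z, 0.0)
        mask = None
        if mode == "train" and p > 0.0 and i < n_layers - 1:
            mask = (rng.random(h_act.shape) >= p).astype(float)
            h_out = h_act * mask / (1.0 - p)
        else:
            h_out = h_act
        cache.append((ah_theta_in, z, mask))
        h = h_out
    rows = gt.respondent_rows
    logits = h[rows] @ params.out_weight + params.out_bias
    log_probs = logits - logsumexp(logits, axis=1, keepdims=True)
    return log_probs, h, cache


def forward(
    params: BGCNParams,
    graph: Union[bg.BipartiteGraph, GraphTensors],
    mode: str = "eval",
    dropout_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-respondent class log-probabilities, shape (n_respondents, 2).

    ``mode="train"`` applies inverted dropout between convolutions and
    requires ``dropout_rng``; ``mode="eval"`` is deterministic.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "train" and params.config.dropout_p > 0.0 and dropout_rng is None:
        raise ValueError("mode='train' requires a dropout_rng")
    gt = graph_tensors(graph)
    if gt.features.shape[1] != params.n_features:
        raise ValueError(
            f"graph feature width {gt.features.shape[1]} != model input "
            f"width {params.n_features}"
        )
    log_probs, _, _ = _forward_cached(params, gt, mode, dropout_rng)
    return log_probs


def nll_loss(log_probs, labels, sample_weight=None) -> float:
    """Mean negative log-likelihood of the true class.

    Minimizing this over softmax outputs is maximum-likelihood fitting of
    the class-membership probabilities.
    """
    log_probs = np.asarray(log_probs, dtype=float)
    labels = np.asarray(labels, dtype=int).ravel()
    if log_probs.shape[0] != labels.shape[0]:
        raise ValueError("log_probs and labels must have equal length")
    if labels.size and not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be in {0, 1}")
    picked = log_probs[np.arange(labels.size), labels]
    if sample_weight is None:
        return float(-picked.mean())
    w = np.asarray(sample_weight, dtype=float).ravel()
    return float(-(w * picked).sum() / w.sum())


def loss_and_gradients(params, graph, labels, train_mask=None):
    """NLL loss and analytic gradients for one dropout-free full-batch step.

    Returns ``(loss, grads)`` where ``grads`` lists gradients in tensor
    order (conv layers, output weight, output bias).  Used for gradient
    checking and diagnostics; :func:`train` applies the same backward
    pass with dropout.
    """
    gt = graph_tensors(graph)
    labels = np.asarray(labels, dtype=int).ravel()
    n = gt.respondent_rows.size
    train_idx = np.arange(n) if train_mask is None else np.asarray(train_mask)
    if train_idx.dtype == bool:
        train_idx = np.flatnonzero(train_idx)
    y = labels[train_idx]

    log_probs, h_final, cache = _forward_cached(params, gt, "eval", None)
    lp = log_probs[train_idx]
    loss = nll_loss(lp, y)

    onehot = np.zeros((y.size, params.config.n_classes))
    onehot[np.arange(y.size), y] = 1.0
    dlogits = np.zeros_like(log_probs)
    dlogits[train_idx] = (np.exp(lp) - onehot) / y.size
    grads_conv, d_out_w, d_out_b = _backward(params, gt, cache, h_final, dlogits)
    return loss, [*grads_conv, d_out_w, d_out_b]


def _backward(params, gt, cache, h_final, dlogits):
    """Gradients of the weighted NLL w.r.t. every parameter tensor.

    ``dlogits`` is dL/dlogits on the respondent rows (already divided by
    the weight normalizer); ``A_hat`` is symmetric so its transpose is
    itself.
    """
    rows = gt.respondent_rows
    p = params.config.dropout_p
    grads_conv = [None] * len(params.conv_weights)

    d_out_w = h_final[rows].T @ dlogits
    d_out_b = dlogits.sum(axis=0)

    dh = np.zeros_like(h_final)
    dh[rows] = dlogits @ params.out_weight.T

    n_layers = len(params.conv_weights)
    for i in range(n_layers - 1, -1, -1):
        h_in, z, mask = cache[i]
        if mask is not None:
            dh = dh * mask / (1.0 - p)
        dz = dh * (z > 0.0)
        a_dz = gt.a_hat @ dz  # A_hat symmetric
        grads_conv[i] = h_in.T @ a_dz
        if i > 0:
            dh = a_dz @ params.conv_weights[i].T
    return grads_conv, d_out_w, d_out_b


class _Adam:
    """Standard Adam update (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, tensors, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t) for t in tensors]
        self.v = [np.zeros_like(t) for t in tensors]
        self.t = 0

    def step(self, tensors, grads):
        self.t += 1
        for i, (tns, g) in enumerate(zip(tensors, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            tns -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class _SGD:
    def __init__(self, tensors, lr):
        self.lr = lr

    def step(self, tensors, grads):
        for tns, g in zip(tensors, grads):
            tns -= self.lr * g


def train(
    params: BGCNParams,
    graph: Union[bg.BipartiteGraph, GraphTensors],
    labels,
    train_mask=None,
    config: BGCNConfig | None = None,
):
    """Full-batch training on the labeled respondents of one graph.

    Parameters
    ----------
    params
        Initialized parameters (consumed as the starting point; a trained
        copy is returned, the input is not mutated).
    labels
        0/1 crisis labels aligned with the graph's respondent order.
    train_mask
        Boolean mask (or integer index array) over respondents selecting
        the labeled training nodes; default all.
    config
        Overrides ``params.config`` if given.

    Returns
    -------
    (BGCNParams, list[dict])
        Trained parameters and a per-epoch history of
        ``{"epoch", "loss", "accuracy", "f1"}`` computed on the training
        nodes (supports loss/metric-vs-epoch curves).
    """
    cfg = config or params.config
    gt = graph_tensors(graph)
    labels = np.asarray(labels, dtype=int).ravel()
    n = gt.respondent_rows.size
    if labels.size != n:
        raise ValueError(f"{labels.size} labels for {n} respondents")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be in {0, 1}")

    if train_mask is None:
        mask = np.ones(n, dtype=bool)
    else:
        tm = np.asarray(train_mask)
        if tm.dtype == bool:
            if tm.size != n:
                raise ValueError("boolean train_mask length must equal respondent count")
            mask = tm
        else:
            mask = np.zeros(n, dtype=bool)
            mask[tm] = True
    if mask.sum() == 0:
        raise ValueError("train_mask selects no labeled respondents")

    train_idx = np.flatnonzero(mask)
    y_train = labels[train_idx]

    if cfg.class_weight == "balanced":
        counts = np.bincount(y_train, minlength=2).astype(float)
        counts[counts == 0] = 1.0
        cw = y_train.size / (2.0 * counts)
        weights = cw[y_train]
    else:
        weights = np.ones(y_train.size)
    w_sum = weights.sum()

    out = params.copy()
    out.config = cfg
    tensors = out.tensors()
    opt = _Adam(tensors, cfg.learning_rate) if cfg.optimizer == "adam" else _SGD(
        tensors, cfg.learning_rate
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))

    history: list[dict] = []
    onehot = np.zeros((y_train.size, cfg.n_classes))
    onehot[np.arange(y_train.size), y_train] = 1.0

    for epoch in range(cfg.epochs):
        log_probs, h_final, cache = _forward_cached(out, gt, "train", rng)
        lp_train = log_probs[train_idx]
        loss = nll_loss(lp_train, y_train, weights)

        probs = np.exp(lp_train)
        dlogits_train = (probs - onehot) * (weights[:, None] / w_sum)
        dlogits = np.zeros_like(log_probs)
        dlogits[train_idx] = dlogits_train

        grads_conv, d_out_w, d_out_b = _backward(out, gt, cache, h_final, dlogits)
        opt.step(tensors, [*grads_conv, d_out_w, d_out_b])

        pred = (lp_train[:, 1] > lp_train[:, 0]).astype(int)
        rep = confusion_and_metrics(pred, y_train)
        history.append(
            {"epoch": epoch, "loss": loss, "accuracy": rep.accuracy, "f1": rep.f1}
        )
    return out, history


@dataclass(frozen=True)
class PredictionResult:
    """Inductive predictions: hard labels, class probabilities, log-probabilities."""

    labels: np.ndarray
    probabilities: np.ndarray
    log_probabilities: np.ndarray
    respondent_ids: list[str] | None = None


def predict(
    params: BGCNParams,
    standardizer: bg.ItemStandardizer,
    bank: InstrumentBank,
    new_responses: AnswerMatrix,
) -> PredictionResult:
    """Classify unseen respondents with frozen trained parameters.

    A new bipartite graph is built from the test respondents alone (same
    item nodes, edge weights from the *training* standardizer) and run in
    eval mode.  Exact probability ties resolve to label 0 (healthy), the
    conservative screening default.

    Note the inductive caveat: item-node degrees depend on the batch of
    respondents present in the graph, so predictions can differ slightly
    across batch compositions.
    """
    if new_responses.bank is not None and new_responses.bank.item_ids != bank.item_ids:
        raise ValueError("response matrix bank does not match the model bank")
    if len(bank) != params.n_features:
        raise ValueError(
            f"bank has {len(bank)} items but model expects {params.n_features}"
        )
    a_star = bg.apply_standardizer(standardizer, new_responses)
    graph = bg.build_bipartite_graph(a_star)
    log_probs = forward(params, graph, mode="eval")
    probs = np.exp(log_probs)
    labels = (probs[:, 1] > probs[:, 0]).astype(int)  # tie -> healthy
    return PredictionResult(
        labels=labels,
        probabilities=probs,
        log_probabilities=log_probs,
        respondent_ids=list(new_responses.respondent_ids),
    )


def _bank_hash(bank: InstrumentBank) -> str:
    return hashlib.sha256(bank.to_json().encode()).hexdigest()


def save_checkpoint(
    path,
    params: BGCNParams,
    standardizer: bg.ItemStandardizer,
    bank: InstrumentBank,
) -> None:
    """Write a single-file JSON checkpoint: config header + named arrays.

    The header records the checkpoint version, the config, the
    initialization scheme/seed, and a hash of the bank so mismatched
    schemas are caught at load time.
    """
    obj = {
        "format": "bgcn-checkpoint",
        "version": CHECKPOINT_VERSION,
        "config": params.config.to_dict(),
        "init": {"scheme": params.init_scheme, "seed": params.init_seed},
        "bank_hash": _bank_hash(bank),
        "bank": json.loads(bank.to_json()),
        "standardizer": json.loads(standardizer.to_json()),
        "arrays": {
            **{f"conv_{i}": w.tolist() for i, w in enumerate(params.conv_weights)},
            "out_weight": params.out_weight.tolist(),
            "out_bias": params.out_bias.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_checkpoint(path):
    """Load a checkpoint; returns ``(params, standardizer, bank)``."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("format") != "bgcn-checkpoint":
        raise ValueError(f"{path}: not a BGCN checkpoint")
    if obj.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"{path}: unsupported checkpoint version {obj.get('version')}")
    cfg = BGCNConfig.from_dict(obj["config"])
    bank = InstrumentBank.from_json(obj["bank"])
    if _bank_hash(bank) != obj["bank_hash"]:
        raise ValueError(f"{path}: bank hash mismatch")
    std = bg.ItemStandardizer.from_json(obj["standardizer"])
    arrays = obj["arrays"]
    n_conv = len(cfg.hidden_dims)
    params = BGCNParams(
        conv_weights=[np.array(arrays[f"conv_{i}"], dtype=float) for i in range(n_conv)],
        out_weight=np.array(arrays["out_weight"], dtype=float),
        out_bias=np.array(arrays["out_bias"], dtype=float),
        config=cfg,
        init_scheme=obj["init"]["scheme"],
        init_seed=obj["init"]["seed"],
    )
    return params, std, bank


def write_history_tsv(history: Sequence[dict], path) -> None:
    """Training history as TSV (epoch, loss, accuracy, f1) for curve plots."""
    with open(path, "w") as fh:
        fh.write("epoch\tloss\taccuracy\tf1\n")
        for rec in history:
            fh.write(
                f"{rec['epoch']}\t{rec['loss']:.6f}\t{rec['accuracy']:.6f}\t"
                f"{rec['f1']:.6f}\n"
            )
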