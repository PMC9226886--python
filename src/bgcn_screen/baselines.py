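"""Reference classifiers the bipartite GCN is compared against.

All baselines consume rows of the standardized answer matrix as feature
vectors:

- ``lr``: L2-regularized logistic regression trained by stochastic
  gradient descent (learning rate 1e-3).
- ``svm``: RBF-kernel support vector machine, C = 1, kernel coefficient
  gamma = 0.007.
- ``ann``: dense network with two hidden layers (80, 30), Adam.
- ``cnn``: the comparison study's "CNN" — described only as a 4-layer
  network with hidden sizes 80 and 30, cross-entropy and SGD (lr 1e-3),
  i.e. no convolution geometry; implemented as the dense net it
  describes.
- ``similarity_gcn``: transductive two-layer graph convolution on a
  respondent-only cosine k-nearest-neighbour similarity graph; test
  respondents are present (unlabeled) in the training graph, so unlike
  the bipartite model it cannot classify respondents unseen at training
  time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import SGDClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import bgcn_model as bm
from .bipartite_graph import apply_standardizer, fit_standardizer, normalize_adjacency
from .evaluation import MetricsReport, confusion_and_metrics
from .instruments import AnswerMatrix

__all__ = ["BaselineConfig", "BASELINE_NAMES", "run_baseline", "build_similarity_graph"]

BASELINE_NAMES = ("lr", "svm", "ann", "cnn", "similarity_gcn")


@dataclass(frozen=True)
class BaselineConfig:
    """Name + hyperparameters of one baseline; defaults are the study settings."""

    name: str
    seed: int = 0
    learning_rate: float = 1e-3  # lr / cnn SGD step size
    svm_c: float = 1.0
    svm_gamma: float = 0.007
    hidden_dims: tuple[int, int] = (80, 30)
    max_iter: int = 300
    k_neighbors: int = 10  # similarity_gcn
    gcn_epochs: int = 200
    gcn_learning_rate: float = 1e-2
    gcn_dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(
                f"unknown baseline {self.name!r}; expected one of {BASELINE_NAMES}"
            )


def _as_features(data):
    """(X, y, fitted-standardizer-or-None) from (AnswerMatrix | ndarray, labels)."""
    x, y = data
    return x, np.asarray(y, dtype=int).ravel()


def build_similarity_graph(a_star, k_neighbors: int) -> np.ndarray:
    """Symmetric cosine k-NN similarity graph over respondents.

    Edge weight is the cosine similarity of standardized answer rows,
    clipped at 0 (dissimilar pairs get no edge); each respondent is
    linked to its ``k_neighbors`` most similar others and the edge set is
    symmetrized by union.  Diagonal is zero.
    """
    x = np.asarray(a_star, dtype=float)
    n = x.shape[0]
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} requires more than {n} respondents")
    norms = np.linalg.norm(x, axis=1)
    norms[norms == 0] = 1.0
    xn = x / norms[:, None]
    sim = np.clip(xn @ xn.T, 0.0, None)
    np.fill_diagonal(sim, 0.0)
    w = np.zeros_like(sim)
    for i in range(n):
        nbrs = np.argsort(sim[i])[::-1][:k_neighbors]
        w[i, nbrs] = sim[i, nbrs]
    w = np.maximum(w, w.T)  # union symmetrization
    return w


def _run_similarity_gcn(config, x_train, y_train, x_test) -> np.ndarray:
    """Transductive GCN: one graph over train+test rows, loss on train only."""
    x_all = np.vstack([x_train, x_test])
    n_train = x_train.shape[0]
    w = build_similarity_graph(x_all, config.k_neighbors)
    gt = bm.GraphTensors(
        a_hat=normalize_adjacency(w),
        features=x_all,
        respondent_rows=np.arange(x_all.shape[0]),
    )
    gcn_cfg = bm.BGCNConfig(
        hidden_dims=config.hidden_dims,
        dropout_p=config.gcn_dropout,
        learning_rate=config.gcn_learning_rate,
        epochs=config.gcn_epochs,
        seed=config.seed,
    )
    params = bm.init_bgcn(gcn_cfg, n_features=x_all.shape[1])
    labels_all = np.zeros(x_all.shape[0], dtype=int)
    labels_all[:n_train] = y_train
    trained, _ = bm.train(params, gt, labels_all, train_mask=np.arange(n_train))
    log_probs = bm.forward(trained, gt, mode="eval")
    lp_test = log_probs[n_train:]
    return (lp_test[:, 1] > lp_test[:, 0]).astype(int)


def run_baseline(config: BaselineConfig, train, test) -> MetricsReport:
    """Fit one baseline on the training set and score it on the test set.

    ``train`` and ``test`` are ``(AnswerMatrix-or-array, labels)`` pairs
    sharing one instrument bank.  When answer matrices are given, a
    z-score standardizer is fitted on the training matrix only and
    applied to both (the same preprocessing the bipartite model uses).
    Deterministic for a fixed config seed.
    """
    x_train_raw, y_train = _as_features(train)
    x_test_raw, y_test = _as_features(test)
    if isinstance(x_train_raw, AnswerMatrix):
        std = fit_standardizer(x_train_raw, mode="zscore")
        x_train = apply_standardizer(std, x_train_raw)
        x_test = apply_standardizer(std, x_test_raw)
    else:
        x_train = np.asarray(x_train_raw, dtype=float)
        x_test = np.asarray(x_test_raw, dtype=float)

    if config.name == "lr":
        model = SGDClassifier(
            loss="log_loss",
            penalty="l2",
            learning_rate="constant",
            eta0=config.learning_rate,
            max_iter=1000,
            tol=1e-4,
            random_state=config.seed,
        )
    elif config.name == "svm":
        model = SVC(
            C=config.svm_c,
            kernel="rbf",
            gamma=config.svm_gamma,
            random_state=config.seed,
        )
    elif config.name == "ann":
        model = MLPClassifier(
            hidden_layer_sizes=config.hidden_dims,
            solver="adam",
            max_iter=config.max_iter,
            random_state=config.seed,
        )
    elif config.name == "cnn":
        model = MLPClassifier(
            hidden_layer_sizes=config.hidden_dims,
            solver="sgd",
            learning_rate="constant",
            learning_rate_init=config.learning_rate,
            max_iter=config.max_iter,
            random_state=config.seed,
        )
    elif config.name == "similarity_gcn":
        pred = _run_similarity_gcn(config, x_train, y_train, x_test)
        return confusion_and_metrics(pred, y_test)
    else:  # pragma: no cover - guarded by BaselineConfig
        raise ValueError(f"unknown baseline {config.name!r}")

    model.fit(x_train, y_train)
    pred = model.predict(x_test)
    return confusion_and_metrics(pred, y_test)
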