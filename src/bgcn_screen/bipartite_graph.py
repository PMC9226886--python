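"""Standardization of the answer matrix and respondent-item bipartite graph.

The encoded answer matrix ``A`` (respondents x items) is standardized
per item — z-score by default, min-max as an alternative — into the
weight matrix ``A*`` whose entries become the edge weights of an
undirected bipartite graph: item nodes on one side, respondent nodes on
the other, one edge per (respondent, item) pair.

Node features follow the convention that item nodes carry the
``k``-dimensional identity (``Q = I_k``) and respondent nodes start at
zero, so all respondent information enters through propagation along
answer-weighted edges.

Standardizers are fitted on training data only and reused unchanged on
unseen respondents (the inductive contract).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

import numpy as np

from .instruments import AnswerMatrix

__all__ = [
    "ItemStandardizer",
    "BipartiteGraph",
    "fit_standardizer",
    "apply_standardizer",
    "build_bipartite_graph",
    "normalize_adjacency",
    "write_edge_list",
]


def _as_codes(m) -> np.ndarray:
    if isinstance(m, AnswerMatrix):
        return np.asarray(m.codes, dtype=float)
    return np.asarray(m, dtype=float)


@dataclass
class ItemStandardizer:
    """Per-item affine map ``(code - center) / scale`` learned from training data.

    In ``zscore`` mode center/scale are the training mean and population
    standard deviation; in ``minmax`` mode they are the training minimum
    and range, and transformed values are clipped to ``[0, 1]`` so unseen
    out-of-range codes stay bounded.  Degenerate (constant) training
    columns get scale 1, so uninformative items map to constant zero
    weight.
    """

    mode: str
    centers: np.ndarray
    scales: np.ndarray
    item_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("zscore", "minmax"):
            raise ValueError(f"unknown standardization mode {self.mode!r}")
        self.centers = np.asarray(self.centers, dtype=float).ravel()
        self.scales = np.asarray(self.scales, dtype=float).ravel()
        if self.centers.shape != self.scales.shape:
            raise ValueError("centers and scales must have equal length")
        if not (self.scales > 0).all():
            raise ValueError("all scales must be strictly positive")

    @property
    def n_items(self) -> int:
        return self.centers.shape[0]

    def to_json(self, path=None) -> str:
        obj = {
            "mode": self.mode,
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
        }
        if self.item_ids is not None:
            obj["item_ids"] = list(self.item_ids)
        text = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ItemStandardizer":
        if isinstance(source, dict):
            obj = source
        else:
            text = str(source)
            if "\n" not in text and not text.lstrip().startswith("{"):
                with open(text) as fh:
                    obj = json.load(fh)
            else:
                obj = json.loads(text)
        return cls(
            mode=obj["mode"],
            centers=np.array(obj["centers"], dtype=float),
            scales=np.array(obj["scales"], dtype=float),
            item_ids=obj.get("item_ids"),
        )


def fit_standardizer(train, mode: str = "zscore") -> ItemStandardizer:
    """Learn per-item center and scale from a training answer matrix.

    Parameters
    ----------
    train
        :class:`~bgcn_screen.instruments.AnswerMatrix` or plain 2-D array.
    mode
        ``"zscore"`` (center = mean, scale = population SD) or
        ``"minmax"`` (center = min, scale = range).
    """
    codes = _as_codes(train)
    if codes.ndim != 2 or codes.shape[0] == 0:
        raise ValueError("training matrix must be non-empty and 2-D")
    if mode == "zscore":
        centers = codes.mean(axis=0)
        scales = codes.std(axis=0, ddof=0)
    elif mode == "minmax":
        centers = codes.min(axis=0)
        scales = codes.max(axis=0) - centers
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    scales = np.where(scales > 0, scales, 1.0)  # degenerate-column rule
    item_ids = train.bank.item_ids if isinstance(train, AnswerMatrix) and train.bank else None
    return ItemStandardizer(mode=mode, centers=centers, scales=scales, item_ids=item_ids)


def apply_standardizer(std: ItemStandardizer, m) -> np.ndarray:
    """Map an answer matrix to the standardized weight matrix ``A*`` (n x k, float).

    Uses only the statistics stored in ``std`` — never the data being
    transformed — so train and test respondents pass through the same map.
    """
    codes = _as_codes(m)
    if codes.ndim != 2 or codes.shape[1] != std.n_items:
        raise ValueError(
            f"matrix has {codes.shape[1] if codes.ndim == 2 else '?'} items, "
            f"standardizer expects {std.n_items}"
        )
    if isinstance(m, AnswerMatrix) and m.bank is not None and std.item_ids is not None:
        if m.bank.item_ids != list(std.item_ids):
            raise ValueError("answer matrix items do not match the standardizer's items")
    out = (codes - std.centers[None, :]) / std.scales[None, :]
    if std.mode == "minmax":
        out = np.clip(out, 0.0, 1.0)
    return out


@dataclass
class BipartiteGraph:
    """Undirected respondent-item bipartite graph with node features.

    Node ordering is items first (ids ``0 .. k-1``) then respondents
    (``k .. k+n-1``); every downstream index depends on this.  The
    weighted adjacency has block structure ``[[0, A*^T], [A*, 0]]``
    (edges only between node types) and the feature matrix ``P`` stacks
    the item identity block over zero respondent rows.
    """

    weights: np.ndarray  # standardized A*, n x k
    n_items: int
    n_respondents: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_respondents, self.n_items):
            raise ValueError(
                f"weights shape {self.weights.shape} != "
                f"({self.n_respondents}, {self.n_items})"
            )

    @property
    def n_nodes(self) -> int:
        return self.n_items + self.n_respondents

    @property
    def item_nodes(self) -> np.ndarray:
        return np.arange(self.n_items)

    @property
    def respondent_nodes(self) -> np.ndarray:
        return np.arange(self.n_items, self.n_nodes)

    @property
    def adjacency(self) -> np.ndarray:
        """Dense symmetric (k+n) x (k+n) weighted adjacency with zero diagonal blocks."""
        k, n = self.n_items, self.n_respondents
        w = np.zeros((k + n, k + n))
        w[:k, k:] = self.weights.T
        w[k:, :k] = self.weights
        return w

    @property
    def features(self) -> np.ndarray:
        """Node feature matrix ``P``: item rows = I_k, respondent rows = 0."""
        p = np.zeros((self.n_nodes, self.n_items))
        p[: self.n_items, : self.n_items] = np.eye(self.n_items)
        return p


def build_bipartite_graph(a_star, n_items: int | None = None) -> BipartiteGraph:
    """Wrap a standardized weight matrix ``A*`` (n x k) as a bipartite graph."""
    a_star = np.asarray(a_star, dtype=float)
    if a_star.ndim != 2:
        raise ValueError("A* must be 2-D (respondents x items)")
    n, k = a_star.shape
    if n_items is not None and n_items != k:
        raise ValueError(f"A* has {k} item columns, expected {n_items}")
    return BipartiteGraph(weights=a_star, n_items=k, n_respondents=n)


def normalize_adjacency(
    g: Union[BipartiteGraph, np.ndarray], degree: str = "mean"
) -> np.ndarray:
    """Symmetric degree-normalized adjacency with unit self-loops.

    Computes ``A_hat = D^{-1/2} (W + I) D^{-1/2}``.  Absolute edge
    weights enter the degrees so they stay strictly positive even when
    z-scored weights are negative, and the +1 accounts for the
    self-loop.  Two degree conventions:

    - ``degree="mean"`` (default): ``D_vv = 1 + mean_u |W[v, u]|`` where
      the mean runs over the nodes of the opposite type (respondents for
      an item node, items for a respondent node; all other nodes for a
      generic graph).  Item-node degrees are then independent of how
      many respondents the graph contains, so a model trained on a large
      cohort sees the same propagation scale on a small test-only graph
      — the property inductive prediction relies on.
    - ``degree="sum"``: the classic ``D_vv = 1 + sum_u |W[v, u]|``.
      Here item degrees grow linearly with the respondent count and
      hidden activations shrink like ``n^{-3/2}``, which couples the
      model to the training-graph size.

    Accepts a :class:`BipartiteGraph` or any symmetric weight matrix
    (used by the transductive respondent-similarity baseline).
    """
    if degree not in ("mean", "sum"):
        raise ValueError(f"unknown degree convention {degree!r}")
    w = g.adjacency if isinstance(g, BipartiteGraph) else np.asarray(g, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isfinite(w).all():
        raise ValueError("adjacency contains non-finite weights")
    abs_deg = np.abs(w).sum(axis=1)
    if degree == "mean":
        if isinstance(g, BipartiteGraph):
            k, n = g.n_items, g.n_respondents
            denom = np.concatenate(
                [np.full(k, max(n, 1), dtype=float), np.full(n, max(k, 1), dtype=float)]
            )
        else:
            denom = float(max(w.shape[0] - 1, 1))
        abs_deg = abs_deg / denom
    deg = 1.0 + abs_deg
    inv_sqrt = 1.0 / np.sqrt(deg)
    a_hat = (w + np.eye(w.shape[0])) * inv_sqrt[:, None] * inv_sqrt[None, :]
    return a_hat


def write_edge_list(g: BipartiteGraph, path, respondent_ids=None, item_ids=None) -> None:
    """Export the bipartite edges as TSV (node_u, node_v, weight) for inspection."""
    k = g.n_items
    with open(path, "w") as fh:
        fh.write("node_u\tnode_v\tweight\n")
        for i in range(g.n_respondents):
            rname = respondent_ids[i] if respondent_ids is not None else f"resp_{i}"
            for j in range(k):
                iname = item_ids[j] if item_ids is not None else f"item_{j}"
                fh.write(f"{iname}\t{rname}\t{g.weights[i, j]:.10g}\n")
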