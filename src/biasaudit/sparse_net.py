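"""Masked feed-forward networks whose hidden nodes are biological entities.

Each hidden layer corresponds to a layer of the knowledge DAG (genes, then
pathways); weights are element-wise masked by the DAG's connectivity so a
hidden node only receives input from its known biological parents.  A
single sigmoid prediction head follows the last hidden layer (an
auxiliary-head hook is left in the layer API but not used).  Training is
plain minibatch Adam on binary cross-entropy with early stopping that
restores the best-validation weights; all randomness flows from exactly
two named seeds (split_seed for the partition, init_seed for the weights),
so a run is fully reproducible.

The networks in scope are small (thousands of weights), so the forward,
backward and update passes are implemented directly on numpy arrays; this
keeps every arithmetic step visible to the attribution code, which must
walk the same graph backwards.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics

from .cohort_io import Cohort, SplitAssignment, assemble_inputs
from .graphkit import LayeredDAG, build_masks


class DivergenceError(RuntimeError):
    pass


class UndefinedROCError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Training hyperparameters; recorded verbatim into every artifact."""

    hidden_activation: str = "tanh"
    output_activation: str = "sigmoid"
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 0.01
    optimizer: str = "adam"
    weight_decay: float = 0.0
    patience: int = 15
    init_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.hidden_activation != "tanh":
            raise ValueError("only tanh hidden activation is implemented")
        if self.optimizer != "adam":
            raise ValueError("only adam is implemented")

    def with_seed(self, init_seed: int) -> "NetworkConfig":
        return replace(self, init_seed=init_seed)


@dataclass
class TrainedNetwork:
    """Masked weights plus the provenance needed to reproduce them.

    ``weights[l]`` maps layer ``l`` activations to layer ``l+1``
    pre-activations; the final element is the prediction head (fan-in =
    last hidden layer, fan-out = 1, unmasked).  ``masks`` mirrors
    ``weights`` with an all-ones mask for the head.
    """

    dag: LayeredDAG
    config: NetworkConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    masks: list[np.ndarray]
    layer_orders: list[list[str]]  # node ids per layer, canonical order
    init_seed: int
    split_seed: int | None = None
    setup: str = "original"
    metrics: dict = field(default_factory=dict)

    @property
    def n_transitions(self) -> int:
        return len(self.weights)

    def forward(self, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Return per-layer activations [a_0 .. a_L] and output probability."""
        acts = [np.asarray(x, dtype=float)]
        a = acts[0]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w + b)
            acts.append(a)
        z_out = a @ self.weights[-1] + self.biases[-1]
        p = _sigmoid(z_out)
        return acts, p.ravel()

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[1]

    def feature_matrix(self, cohort: Cohort) -> pd.DataFrame:
        return assemble_inputs(cohort, self.layer_orders[0])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_network(dag: LayeredDAG, config: NetworkConfig) -> TrainedNetwork:
    """Initialize masked weights from ``config.init_seed`` only.

    Weights are uniform on +/- 1/sqrt(fan_in), where fan_in is each unit's
    *masked* in-degree (at least 1); masked entries are exactly zero and
    biases start at zero.
    """
    masks = [m.astype(float) for m in build_masks(dag)]
    orders = [dag.layer_nodes(layer) for layer in range(dag.n_layers)]
    masks.append(np.ones((len(orders[-1]), 1)))  # prediction head
    rng = np.random.default_rng(config.init_seed)
    weights, biases = [], []
    for m in masks:
        fan_in = np.maximum(m.sum(axis=0), 1.0)
        scale = 1.0 / np.sqrt(fan_in)
        w = rng.uniform(-1.0, 1.0, size=m.shape) * scale[None, :]
        weights.append(w * m)
        biases.append(np.zeros(m.shape[1]))
    return TrainedNetwork(
        dag=dag, config=config, weights=weights, biases=biases, masks=masks,
        layer_orders=orders, init_seed=config.init_seed,
    )


def _bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _backward(net: TrainedNetwork, x: np.ndarray, y: np.ndarray):
    """Gradients of mean BCE w.r.t. every weight and bias (masked)."""
    acts, p = net.forward(x)
    n = len(y)
    grads_w, grads_b = [None] * net.n_transitions, [None] * net.n_transitions
    delta = ((p - y) / n)[:, None]  # dL/dz_out, BCE + sigmoid
    for l in range(net.n_transitions - 1, -1, -1):
        grads_w[l] = (acts[l].T @ delta) * net.masks[l]
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ net.weights[l].T) * (1.0 - acts[l] ** 2)  # tanh'
    return grads_w, grads_b


def train(
    net: TrainedNetwork,
    cohort: Cohort,
    split: SplitAssignment,
    config: NetworkConfig | None = None,
) -> TrainedNetwork:
    """Fit the masked network; returns the same object, trained in place.

    Minimizes binary cross-entropy on the train partition with Adam; early
    stopping monitors validation loss and restores the best-validation
    weights.  Masks are re-applied after every update, so masked entries
    stay exactly zero.  Populates train/validation/test losses and the
    test ROC/AUC in ``net.metrics``.
    """
    config = config or net.config
    x_all = net.feature_matrix(cohort)
    y_all = cohort.labels

    def part(name):
        ids = split.samples(name)
        return x_all.loc[ids].values, y_all.loc[ids].values.astype(float)

    x_tr, y_tr = part("train")
    x_va, y_va = part("validation")
    x_te, y_te = part("test")

    rng = np.random.default_rng(config.init_seed + 1)  # minibatch order
    m_w = [np.zeros_like(w) for w in net.weights]
    v_w = [np.zeros_like(w) for w in net.weights]
    m_b = [np.zeros_like(b) for b in net.biases]
    v_b = [np.zeros_like(b) for b in net.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_val = np.inf
    best = None
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(y_tr))
        for start in range(0, len(y_tr), config.batch_size):
            idx = order[start:start + config.batch_size]
            gw, gb = _backward(net, x_tr[idx], y_tr[idx])
            if config.weight_decay:
                for l in range(net.n_transitions):
                    gw[l] = gw[l] + config.weight_decay * net.weights[l]
            t += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
            for l in range(net.n_transitions):
                m_w[l] = beta1 * m_w[l] + (1 - beta1) * gw[l]
                v_w[l] = beta2 * v_w[l] + (1 - beta2) * gw[l] ** 2
                net.weights[l] -= lr_t * m_w[l] / (np.sqrt(v_w[l]) + eps)
                net.weights[l] *= net.masks[l]
                m_b[l] = beta1 * m_b[l] + (1 - beta1) * gb[l]
                v_b[l] = beta2 * v_b[l] + (1 - beta2) * gb[l] ** 2
                net.biases[l] -= lr_t * m_b[l] / (np.sqrt(v_b[l]) + eps)
        val_loss = _bce(net.predict(x_va), y_va)
        if not np.isfinite(val_loss):
            raise DivergenceError(
                f"non-finite validation loss at epoch {epoch} "
                f"(learning rate {config.learning_rate})"
            )
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best = ([w.copy() for w in net.weights], [b.copy() for b in net.biases])
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break

    if best is not None:
        net.weights, net.biases = best
    net.split_seed = split.split_seed
    roc, auc = roc_curve_from_scores(net.predict(x_te), y_te)
    net.metrics = {
        "train_loss": _bce(net.predict(x_tr), y_tr),
        "validation_loss": _bce(net.predict(x_va), y_va),
        "test_loss": _bce(net.predict(x_te), y_te),
        "test_auc": auc,
        "epochs_run": epoch + 1,
    }
    net.metrics["roc"] = roc
    return net


def roc_curve_from_scores(scores: np.ndarray, y: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC by threshold sweep over unique scores; AUC by trapezoid."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise UndefinedROCError("ROC undefined: partition contains a single class")
    fpr, tpr, _ = _skmetrics.roc_curve(y, scores, drop_intermediate=False)
    auc = float(_skmetrics.auc(fpr, tpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc


def roc_curve(net: TrainedNetwork, cohort: Cohort, split: SplitAssignment,
              partition: str = "test") -> tuple[pd.DataFrame, float]:
    """ROC points and AUC of a trained network on one partition."""
    ids = split.samples(partition)
    x = net.feature_matrix(cohort).loc[ids].values
    y = cohort.labels.loc[ids].values
    return roc_curve_from_scores(net.predict(x), y)


# -- model artifact ------------------------------------------------------
#
# A saved network is a directory: the hierarchy file (so the artifact is
# self-contained), one npz with weights/biases/masks, a JSON manifest with
# seeds, config, setup tag and metrics, and the test ROC as CSV.


def save_network(net: TrainedNetwork, outdir) -> None:
    from .graphkit import write_hierarchy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_hierarchy(net.dag, outdir / "hierarchy.tsv")
    arrays = {}
    for l, (w, b, m) in enumerate(zip(net.weights, net.biases, net.masks)):
        arrays[f"w{l}"], arrays[f"b{l}"], arrays[f"m{l}"] = w, b, m
    np.savez(outdir / "arrays.npz", **arrays)
    metrics = {k: v for k, v in net.metrics.items() if k != "roc"}
    manifest = {
        "init_seed": net.init_seed,
        "split_seed": net.split_seed,
        "setup": net.setup,
        "config": asdict(net.config),
        "metrics": metrics,
        "n_transitions": net.n_transitions,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if "roc" in net.metrics:
        net.metrics["roc"].to_csv(outdir / "roc.csv", index=False)


def load_network(outdir) -> TrainedNetwork:
    from .graphkit import read_hierarchy

    outdir = Path(outdir)
    dag = read_hierarchy(outdir / "hierarchy.tsv")
    manifest = json.loads((outdir / "manifest.json").read_text())
    config = NetworkConfig(**manifest["config"])
    with np.load(outdir / "arrays.npz") as data:
        n = manifest["n_transitions"]
        weights = [data[f"w{l}"] for l in range(n)]
        biases = [data[f"b{l}"] for l in range(n)]
        masks = [data[f"m{l}"] for l in range(n)]
    net = TrainedNetwork(
        dag=dag, config=config, weights=weights, biases=biases, masks=masks,
        layer_orders=[dag.layer_nodes(layer) for layer in range(dag.n_layers)],
        init_seed=manifest["init_seed"], split_seed=manifest["split_seed"],
        setup=manifest["setup"], metrics=manifest["metrics"],
    )
    roc_path = outdir / "roc.csv"
    if roc_path.exists():
        net.metrics["roc"] = pd.read_csv(roc_path)
    return net
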