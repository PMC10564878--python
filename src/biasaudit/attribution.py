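"""Hidden-node importance via DeepLIFT-style rescale attribution.

The rescale rule assigns each nonlinearity a multiplier
``(f(z) - f(z0)) / (z - z0)`` — the secant slope between the actual
pre-activation and a reference pre-activation — substituting the gradient
``f'(z)`` when the denominator is nearly zero.  Multipliers are chained
backwards from the output through the masked linear layers, and each
hidden node's per-sample contribution is its activation delta times its
multiplier to the output.  Because linear layers propagate deltas exactly,
the contributions of any single layer sum to the output delta
(completeness), which every computation here is tested against.

The reference input defaults to all zeros — no mutation, neutral copy
number — i.e. a wild-type sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_io import Cohort, SplitAssignment
from .graphkit import LayeredDAG, degrees
from .sparse_net import TrainedNetwork, _sigmoid

#: below this pre-activation delta the secant slope degenerates and the
#: gradient is substituted
EPSILON = 1e-7

AGGREGATION_MODES = ("mean_abs", "signed_mean", "sum_abs")


def rescale_multipliers(
    net: TrainedNetwork,
    input_batch: np.ndarray,
    reference_input: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Per-sample, per-node contributions of every layer to the output.

    Returns ``{layer: contributions}`` with one (samples x nodes) array per
    network layer (0 = input features, 1.. = hidden).  Each layer's
    contributions sum (over nodes) to ``output(x) - output(reference)``.
    """
    x = np.atleast_2d(np.asarray(input_batch, dtype=float))
    if reference_input is None:
        x0 = np.zeros((1, x.shape[1]))
    else:
        x0 = np.atleast_2d(np.asarray(reference_input, dtype=float))
    if x0.shape[1] != x.shape[1]:
        raise ValueError(
            f"reference has {x0.shape[1]} features, inputs have {x.shape[1]}"
        )

    # forward both passes keeping pre-activations
    def fwd(a):
        acts, pres = [a], []
        for w, b in zip(net.weights[:-1], net.biases[:-1]):
            z = acts[-1] @ w + b
            pres.append(z)
            acts.append(np.tanh(z))
        z_out = acts[-1] @ net.weights[-1] + net.biases[-1]
        pres.append(z_out)
        return acts, pres, _sigmoid(z_out)

    acts, pres, p = fwd(x)
    acts0, pres0, p0 = fwd(x0)

    def secant(dz, df, deriv):
        slope = np.where(np.abs(dz) < EPSILON, deriv, df / np.where(np.abs(dz) < EPSILON, 1.0, dz))
        return slope

    n_hidden_layers = len(net.weights) - 1
    # output nonlinearity multiplier (samples x 1)
    dz_out = pres[-1] - pres0[-1]
    m = secant(dz_out, p - p0, p * (1.0 - p))
    # multiplier of last hidden activations to the output
    m_act = m @ net.weights[-1].T

    contributions: dict[int, np.ndarray] = {}
    for layer in range(n_hidden_layers, 0, -1):
        da = acts[layer] - acts0[layer]
        contributions[layer] = da * m_act
        dz = pres[layer - 1] - pres0[layer - 1]
        deriv = 1.0 - acts[layer] ** 2  # tanh'
        m_pre = secant(dz, da, deriv) * m_act
        m_act = m_pre @ net.weights[layer - 1].T
    contributions[0] = (x - acts0[0]) * m_act
    return contributions


def aggregate_importance(
    contributions: dict[int, np.ndarray],
    net: TrainedNetwork,
    mode: str = "mean_abs",
) -> pd.Series:
    """Collapse per-sample contributions into one score per hidden node.

    ``mean_abs`` (default): mean over samples of the absolute contribution
    — robust to the sign flips replicate networks commonly show.
    ``signed_mean`` and ``sum_abs`` are alternatives; the mode is recorded
    in the result's name.
    """
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    scores: dict[str, float] = {}
    for layer in sorted(contributions):
        if layer == 0:
            continue  # importance is reported for hidden nodes only
        c = contributions[layer]
        if c.shape[0] == 0:
            raise ValueError("empty sample selection")
        if mode == "mean_abs":
            vals = np.abs(c).mean(axis=0)
        elif mode == "signed_mean":
            vals = c.mean(axis=0)
        else:
            vals = np.abs(c).sum(axis=0)
        for node, v in zip(net.layer_orders[layer], vals):
            scores[node] = float(v)
    out = pd.Series(scores, name=mode)
    return out


def degree_normalize(scores: pd.Series, dag: LayeredDAG, mode: str = "degree") -> pd.Series:
    """Attenuate hub scores by dividing by total degree (in + out).

    Mirrors the degree normalization biology-inspired models apply to damp
    highly connected nodes; note this is a *local* correction and does not
    remove global (reachability-driven) biases.  ``mode="off"`` is the
    identity.
    """
    if mode == "off":
        return scores.copy()
    if mode != "degree":
        raise ValueError(f"unknown normalization mode {mode!r}")
    indeg, outdeg = degrees(dag)
    total = {}
    for node in scores.index:
        if node not in dag.nodes:
            raise KeyError(f"scored node {node!r} not in dag")
        d = indeg[node] + outdeg[node]
        if d == 0:
            raise ZeroDivisionError(f"node {node!r} has total degree 0")
        total[node] = d
    out = scores / pd.Series(total)
    out.name = scores.name
    return out


def compute_importance(
    net: TrainedNetwork,
    cohort: Cohort,
    split: SplitAssignment | None = None,
    partition: str = "test",
    reference: np.ndarray | None = None,
    mode: str = "mean_abs",
    normalize: str = "degree",
) -> pd.Series:
    """Importance of every hidden node for one trained network.

    By default contributions are computed on the held-out test partition
    (pass ``partition="all"`` or ``split=None`` to use every sample),
    aggregated as mean absolute contribution, and degree-normalized.
    """
    x = net.feature_matrix(cohort)
    if split is not None and partition != "all":
        x = x.loc[split.samples(partition)]
    contribs = rescale_multipliers(net, x.values, reference)
    scores = aggregate_importance(contribs, net, mode=mode)
    return degree_normalize(scores, net.dag, mode=normalize)
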