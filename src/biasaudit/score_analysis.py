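"""Cross-setup comparison and bias-corrected differential importance.

The correction recipe: quantile-normalize the importance columns of the
original setup together with those of a control setup (shuffled labels by
default), average replicate columns per node within each setup, and
subtract the control mean from the original mean.  A positive differential
marks a node that is more important than the network's structural biases
alone predict; a negative one marks importance driven by those biases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, rankdata, spearmanr


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common (row-mean) quantile profile.

    Each column is replaced by the row-wise mean of the column-sorted
    input, mapped back by rank; tied entries within a column receive the
    mean of the normalized values their ranks span.  Matches the limma
    ``normalizeQuantiles(..., ties=TRUE)`` semantics for complete
    matrices.
    """
    if matrix.isna().any().any():
        raise ValueError("missing entries are not allowed")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")  # 1-based, ties averaged
        # fractional ranks interpolate between adjacent order statistics
        idx = ranks - 1.0
        lo = np.floor(idx).astype(int)
        hi = np.ceil(idx).astype(int)
        frac = idx - lo
        out[:, j] = mean_sorted[lo] * (1.0 - frac) + mean_sorted[hi] * frac
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def differential_scores(
    original: pd.DataFrame,
    control: pd.DataFrame,
    layers: pd.Series | None = None,
) -> pd.DataFrame:
    """Bias-corrected per-node scores: normalized original minus control.

    Both matrices are node x replicate; they are concatenated, jointly
    quantile-normalized, averaged per node within each setup, and
    subtracted.  Rows are every node shared by both inputs; ``layers``
    (node -> layer) adds a per-layer rank of the differential (rank 1 =
    largest).
    """
    if set(original.index) != set(control.index):
        raise ValueError("node sets of original and control matrices differ")
    control = control.loc[original.index]
    joint = pd.concat(
        [original.add_prefix("orig::"), control.add_prefix("ctrl::")], axis=1
    )
    normed = quantile_normalize(joint)
    mean_orig = normed.filter(like="orig::").mean(axis=1)
    mean_ctrl = normed.filter(like="ctrl::").mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_original": mean_orig,
            "mean_control": mean_ctrl,
            "differential": mean_orig - mean_ctrl,
        }
    )
    if layers is not None:
        table["layer"] = layers.loc[table.index]
        table["layer_rank"] = table.groupby("layer")["differential"].rank(
            ascending=False, method="average"
        )
    table.index.name = "node_id"
    return table


def cross_setup_correlation(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Pearson correlation between importance columns + complete-linkage order.

    ``matrix`` is node x column with columns labeled ``setup:seed`` across
    setups.  Returns (correlation matrix, dendrogram leaf order, scipy
    linkage) where clustering uses distance ``1 - r`` with complete
    linkage.
    """
    if (matrix.std(axis=0) == 0).any():
        bad = matrix.columns[matrix.std(axis=0) == 0].tolist()
        raise ValueError(f"zero-variance columns: {bad}")
    corr = matrix.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    if len(corr) > 1:
        link = _hier.linkage(squareform(dist, checks=False), method="complete")
        order = [corr.columns[i] for i in _hier.leaves_list(link)]
    else:
        link = np.empty((0, 4))
        order = list(corr.columns)
    return corr, order, link


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a newick string (branch lengths
    from merge heights).  Labels are single-quoted so that column names
    like ``setup:seed`` survive newick's special characters."""

    def quote(label: str) -> str:
        return "'" + label.replace("'", "''") + "'"

    n = len(labels)
    if link.shape[0] == 0:
        return f"({quote(labels[0])});" if n == 1 else ";"
    heights = {i: 0.0 for i in range(n)}

    def node_repr(i: int) -> str:
        if i < n:
            return quote(labels[i])
        a, b, h, _ = link[i - n]
        parts = []
        for child in (int(a), int(b)):
            bl = h - heights[child]
            parts.append(f"{node_repr(child)}:{bl:.6g}")
        heights[i] = h
        return "(" + ",".join(parts) + ")"

    # post-order: fill heights bottom-up
    for k in range(link.shape[0]):
        heights[n + k] = link[k, 2]
    return node_repr(n + link.shape[0] - 1) + ";"


def centrality_correlation(
    importance: pd.DataFrame | pd.Series,
    centrality: pd.DataFrame,
    measures: tuple[str, ...] = ("indegree", "outdegree", "reachability", "betweenness"),
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-(layer, measure) correlation of mean importance with centrality.

    ``importance`` is node x replicate (averaged across columns first) or
    an already-averaged Series.  A measure that is constant within a layer
    yields an explicit missing value (NaN) — the "gray cells" — never
    zero.  ``method`` may be "pearson" (default) or "spearman" as a
    diagnostic.
    """
    if isinstance(importance, pd.DataFrame):
        mean_imp = importance.mean(axis=1)
    else:
        mean_imp = importance
    cent = centrality.loc[centrality.index.intersection(mean_imp.index)]
    rows = []
    for layer, sub in cent.groupby("layer"):
        row: dict = {"layer": layer}
        imp = mean_imp.loc[sub.index]
        for meas in measures:
            vals = sub[meas].astype(float)
            if vals.nunique() < 2 or imp.nunique() < 2 or len(sub) < 3:
                row[meas] = np.nan
            else:
                fn = pearsonr if method == "pearson" else spearmanr
                row[meas] = float(fn(imp.values, vals.values)[0])
        rows.append(row)
    return pd.DataFrame(rows).set_index("layer")
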