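"""Reading, validating, splitting and writing sample-level omics matrices.

The on-disk layout mirrors the common patient-genomics CSV convention:
one file per feature type with sample ids in the first column and gene ids
in the header row, plus a labels CSV with a single binary outcome column
(1 = positive class, e.g. metastatic; 0 = negative).  Copy-number matrices
are real-valued and are expanded into binary amplification / deletion
indicator blocks at cutoffs +1.5 / -1.5 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

#: which feature block feeds which layer-0 suffix of the knowledge DAG
DEFAULT_BLOCK_SUFFIXES = {"mutation": "mut", "amplification": "amp", "deletion": "del"}

DEFAULT_CUTOFFS = (1.5, -1.5)


class CohortValidationError(ValueError):
    pass


@dataclass
class Cohort:
    """Per-feature-type sample x gene matrices plus binary labels.

    All blocks are inner-joined on sample ids at construction; labels must
    cover every sample and contain both classes.
    """

    feature_blocks: dict[str, pd.DataFrame]
    labels: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.feature_blocks:
            raise CohortValidationError("no feature blocks")
        common = None
        for name, block in self.feature_blocks.items():
            if not np.issubdtype(np.asarray(block).dtype, np.number):
                raise CohortValidationError(f"block {name!r} contains non-numeric cells")
            ids = set(block.index)
            common = ids if common is None else common & ids
        if not common:
            raise CohortValidationError("no overlapping samples across blocks")
        missing = common - set(self.labels.index)
        if missing:
            raise CohortValidationError(f"labels missing for samples: {sorted(missing)[:5]}")
        order = sorted(common)
        self.feature_blocks = {k: v.loc[order] for k, v in self.feature_blocks.items()}
        self.labels = self.labels.loc[order].astype(int)
        if set(self.labels.unique()) - {0, 1}:
            raise CohortValidationError("labels must be binary 0/1")
        if self.labels.nunique() < 2:
            raise CohortValidationError("labels contain a single class")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def replace(self, *, feature_blocks=None, labels=None, metadata=None) -> "Cohort":
        return Cohort(
            feature_blocks={k: v.copy() for k, v in (feature_blocks or self.feature_blocks).items()},
            labels=(self.labels if labels is None else labels).copy(),
            metadata=dict(self.metadata if metadata is None else metadata),
        )


@dataclass(frozen=True)
class SplitAssignment:
    """Per-sample partition tag in {train, validation, test}."""

    assignment: pd.Series  # index: sample id, values: partition tag
    split_seed: int
    fractions: tuple[float, float, float]

    def samples(self, partition: str) -> list[str]:
        return list(self.assignment.index[self.assignment == partition])


def threshold_expand(
    cohort: Cohort,
    block: str = "cna",
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
) -> Cohort:
    """Expand a real-valued copy-number block into binary indicator blocks.

    Values above ``cutoffs[0]`` mark amplification, values below
    ``cutoffs[1]`` mark deletion; everything in between is neutral.
    """
    if block not in cohort.feature_blocks:
        raise CohortValidationError(f"no block named {block!r}")
    hi, lo = cutoffs
    if hi <= lo:
        raise CohortValidationError("amplification cutoff must exceed deletion cutoff")
    cna = cohort.feature_blocks[block]
    if not np.isfinite(np.asarray(cna)).all():
        raise CohortValidationError(f"block {block!r} contains non-finite values")
    blocks = {k: v for k, v in cohort.feature_blocks.items() if k != block}
    blocks["amplification"] = (cna > hi).astype(float)
    blocks["deletion"] = (cna < lo).astype(float)
    return Cohort(feature_blocks=blocks, labels=cohort.labels, metadata=dict(cohort.metadata))


def align_to_genes(cohort: Cohort, genes: list[str]) -> Cohort:
    """Restrict every block to ``genes``, zero-filling absent columns.

    Mirrors the tolerance of knowledge-primed pipelines for differing gene
    universes between matrices and the knowledge graph; a warning reports
    how many columns were filled.
    """
    blocks = {}
    filled = 0
    for name, block in cohort.feature_blocks.items():
        missing = [g for g in genes if g not in block.columns]
        filled += len(missing)
        out = block.reindex(columns=genes, fill_value=0.0).astype(float)
        blocks[name] = out
    if filled:
        warnings.warn(f"zero-filled {filled} gene columns absent from input matrices",
                      stacklevel=2)
    meta = dict(cohort.metadata)
    meta["zero_filled_columns"] = filled
    return Cohort(feature_blocks=blocks, labels=cohort.labels, metadata=meta)


def load_cohort(
    block_paths: dict[str, str | Path],
    labels_path: str | Path,
    thresholds: dict[str, tuple[float, float]] | None = None,
    genes: list[str] | None = None,
) -> Cohort:
    """Load feature blocks and labels from CSV; threshold real blocks.

    ``thresholds`` maps a block name to (amplification, deletion) cutoffs;
    each such block is expanded into indicator blocks.  If ``genes`` is
    given, all blocks are aligned to that universe (absent genes
    zero-filled with a warning).
    """
    blocks = {}
    for name, path in block_paths.items():
        try:
            df = pd.read_csv(path, index_col=0)
            df = df.astype(float)
        except ValueError as exc:
            raise CohortValidationError(f"block {name!r}: non-numeric cell ({exc})") from exc
        df.index = df.index.astype(str)
        blocks[name] = df
    labels_df = pd.read_csv(labels_path, index_col=0)
    labels = labels_df.iloc[:, 0]
    labels.index = labels.index.astype(str)
    cohort = Cohort(feature_blocks=blocks, labels=labels)
    for name, cutoffs in (thresholds or {}).items():
        cohort = threshold_expand(cohort, block=name, cutoffs=cutoffs)
    if genes is not None:
        cohort = align_to_genes(cohort, genes)
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write each block and the labels as CSV; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, block in cohort.feature_blocks.items():
        p = outdir / f"{name}.csv"
        block.to_csv(p, float_format="%.17g")
        paths[name] = p
    p = outdir / "labels.csv"
    cohort.labels.to_frame().to_csv(p)
    paths["labels"] = p
    return paths


def make_split(
    cohort: Cohort,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    split_seed: int = 0,
    stratify: bool = True,
) -> SplitAssignment:
    """Partition samples into train / validation / test.

    Stratified by label by default so each partition keeps the global
    class frequency to within one sample; a pure function of the sample
    set, fractions and ``split_seed``.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    n = cohort.n_samples
    sizes = _partition_sizes(n, fractions)
    if min(sizes) < 1:
        raise ValueError("every partition needs at least one sample")
    ids = np.array(cohort.sample_ids)
    y = cohort.labels.values
    strat = y if stratify else None
    rest_ids, test_ids = train_test_split(
        ids, test_size=sizes[2], random_state=split_seed,
        stratify=strat, shuffle=True,
    )
    strat_rest = cohort.labels.loc[rest_ids].values if stratify else None
    train_ids, val_ids = train_test_split(
        rest_ids, test_size=sizes[1], random_state=split_seed,
        stratify=strat_rest, shuffle=True,
    )
    if stratify:
        for part_ids, part in ((train_ids, "train"), (val_ids, "validation"), (test_ids, "test")):
            sub = cohort.labels.loc[part_ids]
            if sub.nunique() < 2:
                raise ValueError(f"stratification error: a class is absent from {part}")
    assignment = pd.Series("train", index=cohort.sample_ids, name="partition")
    assignment.loc[val_ids] = "validation"
    assignment.loc[test_ids] = "test"
    return SplitAssignment(assignment=assignment, split_seed=split_seed,
                           fractions=tuple(fractions))


def _partition_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment: sizes sum to n, each within one
    sample of n * fraction."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for k in range(rem):
        base[order[k]] += 1
    return tuple(base)


def assemble_inputs(
    cohort: Cohort,
    feature_nodes: list[str],
    block_suffixes: dict[str, str] = DEFAULT_BLOCK_SUFFIXES,
) -> pd.DataFrame:
    """Build the sample x feature-node input matrix for a layered network.

    Each layer-0 node id is ``<gene>_<suffix>``; the suffix selects the
    feature block and the gene selects its column.
    """
    suffix_to_block = {v: k for k, v in block_suffixes.items()}
    cols = {}
    for node in feature_nodes:
        gene, _, suffix = node.rpartition("_")
        if suffix not in suffix_to_block:
            raise CohortValidationError(f"feature node {node!r}: unknown suffix {suffix!r}")
        block = suffix_to_block[suffix]
        if block not in cohort.feature_blocks:
            raise CohortValidationError(
                f"feature node {node!r} needs block {block!r}; "
                f"have {sorted(cohort.feature_blocks)}"
            )
        if gene not in cohort.feature_blocks[block].columns:
            raise CohortValidationError(f"gene {gene!r} absent from block {block!r}")
        cols[node] = cohort.feature_blocks[block][gene].astype(float)
    return pd.DataFrame(cols, index=cohort.sample_ids)[feature_nodes]
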