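"""Control setups for auditing interpretation bias.

Two complementary controls bracket the prediction-accuracy spectrum:

* **deterministic control inputs** — every input feature is set to a
  class-determined constant, so every single feature perfectly predicts
  the label; any remaining differences in node importance are driven by
  network structure alone (bias under high accuracy).
* **shuffled labels** — samples are randomly re-labeled at equal class
  frequency, so supervision is uninformative and learned importance again
  reflects structure-driven bias (bias under low accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import Cohort

#: class-determined fill values per feature block for the positive class;
#: negatives receive wild-type zeros everywhere.  Mutation presence is 1 and
#: copy-number amplification 2 (above the +1.5 cutoff) by convention; on an
#: already-thresholded cohort the amplification indicator is 1 and the
#: deletion indicator stays wild-type (positives are mutated + amplified).
DEFAULT_FILL_VALUES = {"mutation": 1.0, "cna": 2.0, "amplification": 1.0, "deletion": 0.0}


@dataclass(frozen=True)
class ControlSpec:
    kind: str  # "deterministic" | "shuffled"
    fill_values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FILL_VALUES))
    shuffle_seed: int = 0
    positive_frequency: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("deterministic", "shuffled"):
            raise ValueError(f"unknown control kind {self.kind!r}")
        if not all(np.isfinite(v) for v in self.fill_values.values()):
            raise ValueError("fill values must be finite")
        if not 0.0 < self.positive_frequency < 1.0:
            raise ValueError("positive_frequency must be in (0, 1)")


def make_deterministic_inputs(cohort: Cohort, spec: ControlSpec | None = None) -> Cohort:
    """Replace every feature by a class-determined constant; labels unchanged.

    Positive-class samples receive the per-block fill value in every gene
    (default: mutation = 1, copy-number = 2); negative-class samples
    receive wild-type zeros.  Each feature alone then separates the
    classes perfectly.  Idempotent and label-preserving.
    """
    spec = spec or ControlSpec(kind="deterministic")
    y = cohort.labels.values.astype(float)
    blocks = {}
    for name, block in cohort.feature_blocks.items():
        fill = spec.fill_values.get(name, 1.0)
        values = np.where(y[:, None] == 1.0, fill, 0.0) * np.ones((1, block.shape[1]))
        blocks[name] = pd.DataFrame(values, index=block.index, columns=block.columns)
    return Cohort(feature_blocks=blocks, labels=cohort.labels.copy(),
                  metadata={**cohort.metadata, "control": "deterministic"})


def shuffle_labels(
    labels: pd.Series,
    shuffle_seed: int,
    mode: str = "relabel",
) -> pd.Series:
    """Draw an uninformative labeling of the samples.

    ``mode="relabel"`` (default) discards the original labels and draws a
    fresh labeling with equal class frequency: floor(n/2) negatives and
    ceil(n/2) positives (the positive class takes the extra sample for odd
    n), uniformly over all such labelings.  ``mode="permute"`` instead
    permutes the original labels, preserving the original class ratio —
    useful under strong class imbalance.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples to shuffle")
    rng = np.random.default_rng(shuffle_seed)
    if mode == "relabel":
        n_pos = (n + 1) // 2  # odd n: positive class receives the extra sample
        new = np.zeros(n, dtype=int)
        new[rng.choice(n, size=n_pos, replace=False)] = 1
    elif mode == "permute":
        new = rng.permutation(labels.values.astype(int))
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return pd.Series(new, index=labels.index, name=labels.name)


def apply_control(cohort: Cohort, kind: str, shuffle_seed: int = 0,
                  spec: ControlSpec | None = None) -> Cohort:
    """Dispatch a setup tag to its cohort transform; 'original' is identity."""
    if kind == "original":
        return cohort
    if kind == "deterministic":
        return make_deterministic_inputs(cohort, spec)
    if kind == "shuffled":
        labels = shuffle_labels(cohort.labels, shuffle_seed)
        return cohort.replace(labels=labels,
                              metadata={**cohort.metadata, "control": "shuffled"})
    raise ValueError(f"unknown setup {kind!r}")
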