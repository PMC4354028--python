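"""Maximum-margin linear classifier over many separator CpGs.

Comparator for the 2-CpG score: a linear support-vector machine trained on
all CpGs that perfectly separate pluripotent from somatic training samples.
With separable training data and a large regularisation constant the fit is
effectively hard-margin, so training error is zero by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from sklearn.svm import SVC

from .exceptions import EpiPluriError, SelectionError
from .io import BetaMatrix, SampleAnnotation
from .scoring import NON_PLURIPOTENT, PLURIPOTENT

logger = logging.getLogger(__name__)

#: Near-hard-margin default; exposed because the ideal value is data-bound.
DEFAULT_C = 1e6


@dataclass(frozen=True)
class LinearMarginClassifier:
    """A separating hyperplane over beta-values of selected CpGs.

    The decision value of a sample is ``sum(weights * beta) + bias``;
    positive values are called pluripotent, zero or negative values
    non-pluripotent (zero logs a boundary warning, matching the score's
    tie rule).
    """

    cpg_ids: tuple[str, ...]
    weights: tuple[float, ...]
    bias: float

    def __post_init__(self) -> None:
        if len(self.cpg_ids) != len(self.weights):
            raise EpiPluriError("one weight per CpG feature required")
        if not self.cpg_ids:
            raise EpiPluriError("classifier needs at least one CpG feature")

    def decision_values(self, matrix: BetaMatrix) -> dict[str, float]:
        missing = [c for c in self.cpg_ids if c not in matrix.data.index]
        if missing:
            raise EpiPluriError(f"feature CpGs absent from matrix: {missing[:5]}")
        x = matrix.data.loc[list(self.cpg_ids)].to_numpy(dtype=float)
        if np.isnan(x).any():
            i, j = np.argwhere(np.isnan(x))[0]
            raise EpiPluriError(
                f"missing beta-value at feature CpG {self.cpg_ids[i]!r}, "
                f"sample {matrix.sample_ids[j]!r}"
            )
        d = np.asarray(self.weights, dtype=float) @ x + self.bias
        return dict(zip(matrix.sample_ids, map(float, d)))

    def predict(self, matrix: BetaMatrix) -> dict[str, str]:
        calls = {}
        for sample, d in self.decision_values(matrix).items():
            if d == 0:
                logger.warning(
                    "sample %s sits exactly on the decision boundary; "
                    "calling non_pluripotent", sample,
                )
            calls[sample] = PLURIPOTENT if d > 0 else NON_PLURIPOTENT
        return calls

    # -- serialisation ---------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "cpg_ids": list(self.cpg_ids),
                "weights": list(self.weights),
                "bias": self.bias,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LinearMarginClassifier":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(tuple(blob["cpg_ids"]),
                   tuple(float(w) for w in blob["weights"]),
                   float(blob["bias"]))


def train_max_margin(
    matrix: BetaMatrix,
    annotations: Iterable[SampleAnnotation],
    group1_label: str = "pluripotent",
    group2_label: str = "somatic",
    C: float = DEFAULT_C,
) -> LinearMarginClassifier:
    """Fit the maximum-margin hyperplane on the given feature matrix.

    The matrix should already be restricted to the intended feature CpGs
    (typically the output of ``enumerate_perfect_separators``).  ``C`` is
    the soft-margin constant; the large default approximates a hard margin
    and only matters when the classes are not linearly separable.
    """
    annotations = list(annotations)
    ids1 = [a.sample_id for a in annotations if a.label == group1_label]
    ids2 = [a.sample_id for a in annotations if a.label == group2_label]
    if not ids1 or not ids2:
        raise SelectionError("both classes need at least one sample")
    if matrix.shape[0] == 0:
        raise SelectionError("empty feature set")
    cols = ids1 + ids2
    x = matrix.data[cols].to_numpy(dtype=float).T
    if np.isnan(x).any():
        raise EpiPluriError("training matrix contains missing beta-values")
    y = np.array([1] * len(ids1) + [-1] * len(ids2))
    if len(ids1) + len(ids2) < 2:
        raise SelectionError("need at least two training samples")
    svc = SVC(kernel="linear", C=C)
    svc.fit(x, y)
    # sklearn orders classes ascending, so coef_ points toward class +1
    return LinearMarginClassifier(
        cpg_ids=tuple(matrix.cpg_ids),
        weights=tuple(float(w) for w in svc.coef_[0]),
        bias=float(svc.intercept_[0]),
    )
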