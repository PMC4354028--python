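"""The published scores and per-sample class calls.

Epi-Pluri-Score
    ``beta(cg23737055, ANKRD46) - beta(cg22247240, C14orf115)``, bounded in
    [-1, 1].  cg23737055 is methylated in pluripotent cells and cg22247240 is
    unmethylated, so pluripotent samples score close to +1 and somatic
    samples close to -1.  Positive scores are called pluripotent, negative
    (and exactly zero, conservatively) non-pluripotent.

POU5F1 complement
    The beta-value at cg13083810 (*POU5F1*/OCT4) rises early in
    differentiation, before the two score CpGs move, so exceeding a
    training-derived cutoff flags incipient differentiation while the
    Epi-Pluri-Score is still positive.

Parthenogenic-Score
    ``beta(cg18506672, SNURF) - beta(cg17769238, H19) - 0.2``; the 0.2
    offset shifts the classification cutoff to zero.  Parthenogenic ESCs
    (two maternal genomes) hypermethylate the maternally imprinted
    SNURF site and hypomethylate the H19 site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import EpiPluriError
from .io import BetaMatrix

logger = logging.getLogger(__name__)

#: Published probe ids of the three pluripotency CpGs.
ANKRD46_CPG = "cg23737055"
C14ORF115_CPG = "cg22247240"
POU5F1_CPG = "cg13083810"

#: Published probe ids of the two imprinting CpGs.
SNURF_CPG = "cg18506672"
H19_CPG = "cg17769238"

#: Cutoff shift of the Parthenogenic-Score.
PARTHENO_OFFSET = 0.2

PLURIPOTENT = "pluripotent"
NON_PLURIPOTENT = "non_pluripotent"


def _check_beta(value: float, name: str) -> float:
    v = float(value)
    if math.isnan(v):
        raise EpiPluriError(f"{name} is missing")
    if v < 0.0 or v > 1.0:
        raise EpiPluriError(f"{name} = {value} outside [0, 1]")
    return v


def epi_pluri_score(beta_ankrd46: float, beta_c14orf115: float) -> float:
    """Difference of the two marker beta-values; lies in [-1, 1]."""
    a = _check_beta(beta_ankrd46, "beta_ankrd46")
    b = _check_beta(beta_c14orf115, "beta_c14orf115")
    return a - b


def classify(score: float) -> str:
    """Sign rule: positive -> pluripotent, otherwise non-pluripotent.

    A score of exactly zero is on the decision boundary; it is called
    non-pluripotent (the conservative call for a pluripotency claim) and a
    warning is logged.
    """
    if score > 0:
        return PLURIPOTENT
    if score == 0:
        logger.warning("score is exactly 0: boundary case, calling non_pluripotent")
    return NON_PLURIPOTENT


def pou5f1_flag(beta_pou5f1: float, cutoff: float) -> bool:
    """True iff the POU5F1 CpG is methylated beyond the cutoff.

    Hypermethylation of cg13083810 precedes the score CpGs during
    differentiation, so a ``True`` flag suggests early differentiation even
    when the Epi-Pluri-Score is still positive.
    """
    if not (0.0 < cutoff < 1.0):
        raise EpiPluriError(f"POU5F1 cutoff {cutoff} outside (0, 1)")
    b = _check_beta(beta_pou5f1, "beta_pou5f1")
    return b > cutoff


@dataclass(frozen=True)
class ScoreResult:
    """Epi-Pluri-Score of one sample."""

    sample_id: str
    beta_ankrd46: float
    beta_c14orf115: float
    epi_pluri_score: float
    call: str
    beta_pou5f1: float | None = None
    pou5f1_flag: bool | None = None


@dataclass(frozen=True)
class ParthenoResult:
    """Parthenogenic-Score of one sample.

    The direction of the call is an assumption of this implementation:
    positive scores (SNURF hypermethylated / H19 hypomethylated, as expected
    with two maternal genomes) are called parthenogenic-like.
    """

    sample_id: str
    beta_snurf: float
    beta_h19: float
    partheno_score: float
    call: str


def parthenogenic_score(
    beta_snurf: float, beta_h19: float, sample_id: str = ""
) -> ParthenoResult:
    """SNURF minus H19 beta-value, shifted by -0.2 so the cutoff sits at zero."""
    s = _check_beta(beta_snurf, "beta_snurf")
    h = _check_beta(beta_h19, "beta_h19")
    score = s - h - PARTHENO_OFFSET
    call = "parthenogenic_like" if score > 0 else "normal_pluripotent"
    return ParthenoResult(sample_id, s, h, score, call)


@dataclass(frozen=True)
class UnscorableSample:
    sample_id: str
    reason: str


@dataclass(frozen=True)
class ScoringReport:
    """Per-sample score results plus the samples that could not be scored."""

    results: list[ScoreResult]
    unscorable: list[UnscorableSample]

    def calls(self) -> dict[str, str]:
        return {r.sample_id: r.call for r in self.results}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tbeta_ankrd46\tbeta_c14orf115\tbeta_pou5f1\t"
                     "epi_pluri_score\tcall\tpou5f1_flag\n")
            for r in self.results:
                pou = "" if r.beta_pou5f1 is None else repr(r.beta_pou5f1)
                flag = "" if r.pou5f1_flag is None else str(r.pou5f1_flag)
                fh.write(f"{r.sample_id}\t{r.beta_ankrd46!r}\t"
                         f"{r.beta_c14orf115!r}\t{pou}\t"
                         f"{r.epi_pluri_score!r}\t{r.call}\t{flag}\n")
            for u in self.unscorable:
                fh.write(f"{u.sample_id}\tNA\tNA\tNA\tNA\tunscorable\t\n")


def score_samples(
    matrix: BetaMatrix,
    marker_ids: Sequence[str] = (ANKRD46_CPG, C14ORF115_CPG, POU5F1_CPG),
    pou5f1_cutoff: float | None = None,
) -> ScoringReport:
    """Score every sample of a matrix with the 2-CpG score (+ POU5F1 flag).

    ``marker_ids`` is ``(ankrd46_like, c14orf115_like[, pou5f1_like])``; the
    default is the published probe triple.  The two score CpGs must be rows
    of the matrix; the POU5F1 CpG is optional (pass a 2-tuple or ``None`` in
    third position to skip it).  Samples with a missing required beta-value
    are reported as unscorable rather than dropped or imputed.
    """
    if len(marker_ids) == 2:
        ankrd46_id, c14_id, pou_id = *marker_ids, None
    elif len(marker_ids) == 3:
        ankrd46_id, c14_id, pou_id = marker_ids
    else:
        raise EpiPluriError("marker_ids must hold two or three CpG ids")
    for required in (ankrd46_id, c14_id):
        if required not in matrix.data.index:
            raise EpiPluriError(f"required CpG {required!r} absent from matrix")
    if pou_id is not None and pou_id not in matrix.data.index:
        raise EpiPluriError(f"POU5F1 CpG {pou_id!r} absent from matrix")

    results: list[ScoreResult] = []
    unscorable: list[UnscorableSample] = []
    for sample in matrix.sample_ids:
        a = matrix.get(ankrd46_id, sample)
        c = matrix.get(c14_id, sample)
        missing = [cpg for cpg, v in ((ankrd46_id, a), (c14_id, c))
                   if np.isnan(v)]
        if missing:
            unscorable.append(UnscorableSample(
                sample, f"missing beta at {', '.join(missing)}"
            ))
            continue
        score = epi_pluri_score(a, c)
        pou_beta: float | None = None
        flag: bool | None = None
        if pou_id is not None:
            v = matrix.get(pou_id, sample)
            if not np.isnan(v):
                pou_beta = v
                if pou5f1_cutoff is not None:
                    flag = pou5f1_flag(v, pou5f1_cutoff)
        results.append(ScoreResult(
            sample_id=sample,
            beta_ankrd46=a,
            beta_c14orf115=c,
            epi_pluri_score=score,
            call=classify(score),
            beta_pou5f1=pou_beta,
            pou5f1_flag=flag,
        ))
    return ScoringReport(results, unscorable)
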