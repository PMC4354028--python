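"""Maximum-margin CpG biomarker selection.

Two derivation criteria are implemented:

*Criterion 1 (margin).*  For one CpG and two sample groups the margin is the
gap between the groups' beta-value ranges::

    m_hypo  = min(group2) - max(group1)   # CpG hypomethylated in group 1
    m_hyper = min(group1) - max(group2)   # CpG hypermethylated in group 1

The reported margin is the larger of the two, with the matching direction.
A positive margin means the ranges do not overlap, i.e. a threshold placed
at the gap midpoint separates the training groups without error; a negative
margin quantifies the overlap.

*Criterion 2 (differentiated-sample classification).*  Among CpGs whose
margins are similar, prefer the one whose gap-midpoint threshold pushes the
largest fraction of in-vitro differentiated samples onto the non-pluripotent
side.  Differentiated cells still carry a largely pluripotent methylome, so
this criterion rewards CpGs that respond early to differentiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import MissingValueError, SelectionError
from .io import BetaMatrix, SampleAnnotation, annotations_by_label

logger = logging.getLogger(__name__)

#: CpG hypomethylated in group 1 (lower betas than every group-2 sample).
HYPO = "hypo_in_group1"
#: CpG hypermethylated in group 1.
HYPER = "hyper_in_group1"


@dataclass(frozen=True)
class MarkerCandidate:
    """One CpG evaluated as a two-group separator.

    Attributes
    ----------
    cpg_id
        Probe identifier.
    direction
        ``hypo_in_group1`` or ``hyper_in_group1`` — which group sits on the
        low-methylation side.
    margin
        Signed range gap in [-1, 1]; positive iff the CpG perfectly
        separates the groups.
    cutoff
        Gap midpoint (mean of the two boundary beta-values); ``None`` when
        the margin is not positive, since no error-free threshold exists.
    criterion2_fraction
        Fraction of differentiated samples classified as non-pluripotent by
        the cutoff; filled in by :func:`criterion2_fraction`.
    """

    cpg_id: str
    direction: str
    margin: float
    cutoff: float | None
    criterion2_fraction: float | None = None


def _as_clean_array(values, group_name: str, sample_ids=None) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise SelectionError(f"{group_name} group is empty")
    bad = np.isnan(arr)
    if bad.any():
        idx = int(np.argmax(bad))
        who = sample_ids[idx] if sample_ids is not None else f"position {idx}"
        raise MissingValueError(
            f"missing beta-value in {group_name} group (sample {who})"
        )
    return arr


def compute_margin(
    group1_values,
    group2_values,
    cpg_id: str = "",
    group1_sample_ids: Sequence[str] | None = None,
    group2_sample_ids: Sequence[str] | None = None,
) -> MarkerCandidate:
    """Criterion-1 margin of one CpG between two sample groups.

    Returns the larger of the hypo-/hyper-direction margins together with
    the direction and the gap-midpoint cutoff (``None`` unless margin > 0).
    """
    g1 = _as_clean_array(group1_values, "group1", group1_sample_ids)
    g2 = _as_clean_array(group2_values, "group2", group2_sample_ids)
    m_hypo = float(g2.min() - g1.max())
    m_hyper = float(g1.min() - g2.max())
    if m_hypo >= m_hyper:
        margin, direction = m_hypo, HYPO
        cutoff = (g1.max() + g2.min()) / 2.0
    else:
        margin, direction = m_hyper, HYPER
        cutoff = (g1.min() + g2.max()) / 2.0
    return MarkerCandidate(
        cpg_id=cpg_id,
        direction=direction,
        margin=margin,
        cutoff=float(cutoff) if margin > 0 else None,
    )


def _group_columns(
    matrix: BetaMatrix,
    annotations: Iterable[SampleAnnotation],
    label: str,
) -> list[str]:
    ids = [a.sample_id for a in annotations if a.label == label]
    if not ids:
        raise SelectionError(f"no samples with label {label!r}")
    missing = [s for s in ids if s not in matrix.data.columns]
    if missing:
        raise SelectionError(
            f"annotated samples absent from matrix: {missing[:5]}"
        )
    return ids


def _directional_margins(
    matrix: BetaMatrix,
    annotations: Iterable[SampleAnnotation],
    group1_label: str,
    group2_label: str,
    allow_missing: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-CpG margins in both directions.

    Returns (m_hypo, m_hyper, max_g1/min_g2 boundary pairs) as arrays over
    matrix rows.  With ``allow_missing`` NaNs are dropped per CpG; otherwise
    any NaN in an addressed cell raises, naming the sample.
    """
    annotations = list(annotations)
    cols1 = _group_columns(matrix, annotations, group1_label)
    cols2 = _group_columns(matrix, annotations, group2_label)
    v1 = matrix.data[cols1].to_numpy(dtype=float)
    v2 = matrix.data[cols2].to_numpy(dtype=float)
    for name, cols, v in (("group1", cols1, v1), ("group2", cols2, v2)):
        nan_mask = np.isnan(v)
        if nan_mask.any():
            if not allow_missing:
                i, j = np.argwhere(nan_mask)[0]
                raise MissingValueError(
                    f"missing beta-value at CpG {matrix.cpg_ids[i]!r}, "
                    f"sample {cols[j]!r}; pass allow_missing=True to drop "
                    f"missing samples per CpG"
                )
            if nan_mask.all(axis=1).any():
                i = int(np.argmax(nan_mask.all(axis=1)))
                raise MissingValueError(
                    f"CpG {matrix.cpg_ids[i]!r} has no non-missing value in {name}"
                )
    if allow_missing:
        max1, min1 = np.nanmax(v1, axis=1), np.nanmin(v1, axis=1)
        max2, min2 = np.nanmax(v2, axis=1), np.nanmin(v2, axis=1)
    else:
        max1, min1 = v1.max(axis=1), v1.min(axis=1)
        max2, min2 = v2.max(axis=1), v2.min(axis=1)
    m_hypo = min2 - max1
    m_hyper = min1 - max2
    return m_hypo, m_hyper, (max1, min2), (min1, max2)


def _candidates_from_margins(
    cpg_ids: Sequence[str],
    m_hypo: np.ndarray,
    m_hyper: np.ndarray,
    hypo_bounds: tuple[np.ndarray, np.ndarray],
    hyper_bounds: tuple[np.ndarray, np.ndarray],
) -> list[MarkerCandidate]:
    take_hypo = m_hypo >= m_hyper
    margins = np.where(take_hypo, m_hypo, m_hyper)
    cut_hypo = (hypo_bounds[0] + hypo_bounds[1]) / 2.0
    cut_hyper = (hyper_bounds[0] + hyper_bounds[1]) / 2.0
    cutoffs = np.where(take_hypo, cut_hypo, cut_hyper)
    out = []
    for k, cpg in enumerate(cpg_ids):
        margin = float(margins[k])
        out.append(MarkerCandidate(
            cpg_id=cpg,
            direction=HYPO if take_hypo[k] else HYPER,
            margin=margin,
            cutoff=float(cutoffs[k]) if margin > 0 else None,
        ))
    return out


def rank_by_margin(
    matrix: BetaMatrix,
    annotations: Iterable[SampleAnnotation],
    group1_label: str = "pluripotent",
    group2_label: str = "somatic",
    allow_missing: bool = False,
) -> list[MarkerCandidate]:
    """One criterion-1 candidate per CpG, sorted by margin descending.

    Ties are broken lexicographically on CpG id so the ranking is fully
    deterministic.
    """
    m_hypo, m_hyper, hb, yb = _directional_margins(
        matrix, annotations, group1_label, group2_label, allow_missing
    )
    candidates = _candidates_from_margins(matrix.cpg_ids, m_hypo, m_hyper, hb, yb)
    candidates.sort(key=lambda c: (-c.margin, c.cpg_id))
    return candidates


def criterion2_fraction(
    candidate: MarkerCandidate,
    diff_values,
    diff_sample_ids: Sequence[str] | None = None,
) -> float:
    """Fraction of differentiated samples landing on the non-pluripotent side.

    The candidate must have a positive margin (group 1 = pluripotent).  A
    differentiated sample counts as correctly classified when its beta-value
    is strictly beyond the cutoff, on the side occupied by the somatic
    training group.
    """
    if candidate.margin <= 0 or candidate.cutoff is None:
        raise SelectionError(
            f"criterion 2 needs a perfectly separating CpG "
            f"(margin {candidate.margin} for {candidate.cpg_id!r})"
        )
    values = _as_clean_array(diff_values, "differentiated", diff_sample_ids)
    if candidate.direction == HYPO:
        # pluripotent cells sit low; non-pluripotent side is above the cutoff
        correct = int((values > candidate.cutoff).sum())
    else:
        correct = int((values < candidate.cutoff).sum())
    return correct / values.size


def select_score_pair(
    matrix: BetaMatrix,
    annotations: Iterable[SampleAnnotation],
    margin_tolerance: float = 0.05,
    pluripotent_label: str = "pluripotent",
    somatic_label: str = "somatic",
    differentiated_label: str = "differentiated",
    allow_missing: bool = False,
) -> tuple[MarkerCandidate, MarkerCandidate]:
    """Select the two score CpGs: (hypo-in-pluripotent, hyper-in-pluripotent).

    The hypo marker is pure criterion-1 margin maximisation.  For the hyper
    direction several CpGs typically perform similarly well, so among the
    candidates within ``margin_tolerance`` of the best hyper margin the one
    maximising the criterion-2 fraction is chosen (ties: larger margin, then
    CpG id).  Both returned candidates carry their criterion-2 fraction.
    """
    annotations = list(annotations)
    groups = annotations_by_label(annotations)
    if differentiated_label not in groups:
        raise SelectionError(
            f"criterion 2 requires samples labelled {differentiated_label!r}"
        )
    ranked = rank_by_margin(
        matrix, annotations, pluripotent_label, somatic_label, allow_missing
    )
    diff_ids = _group_columns(matrix, annotations, differentiated_label)

    def _with_c2(c: MarkerCandidate) -> MarkerCandidate:
        vals = matrix.data.loc[c.cpg_id, diff_ids].to_numpy(dtype=float)
        if allow_missing:
            keep = ~np.isnan(vals)
            vals, ids = vals[keep], [d for d, k in zip(diff_ids, keep) if k]
        else:
            ids = diff_ids
        return replace(c, criterion2_fraction=criterion2_fraction(c, vals, ids))

    hypo = [c for c in ranked if c.direction == HYPO and c.margin > 0]
    hyper = [c for c in ranked if c.direction == HYPER and c.margin > 0]
    if not hypo:
        raise SelectionError("no CpG with positive hypo-in-pluripotent margin")
    if not hyper:
        raise SelectionError("no CpG with positive hyper-in-pluripotent margin")
    best_hypo = _with_c2(hypo[0])
    floor = hyper[0].margin - margin_tolerance
    shortlist = [_with_c2(c) for c in hyper if c.margin >= floor]
    shortlist.sort(key=lambda c: (-c.criterion2_fraction, -c.margin, c.cpg_id))
    return best_hypo, shortlist[0]


def best_cpg_in_genes(
    matrix: BetaMatrix,
    annotations: Iterable[SampleAnnotation],
    gene_map: Mapping[str, str],
    genes: Sequence[str],
    group1_label: str = "pluripotent",
    group2_label: str = "somatic",
    allow_missing: bool = False,
) -> dict[str, MarkerCandidate | None]:
    """Best-margin CpG per gene, restricted to each gene's mapped CpGs.

    ``gene_map`` maps CpG id -> gene symbol.  A gene with no mapped CpG in
    the matrix is reported as ``None`` (and logged), not raised.
    """
    annotations = list(annotations)
    by_gene: dict[str, list[str]] = {g: [] for g in genes}
    for cpg, gene in gene_map.items():
        if gene in by_gene and cpg in matrix.data.index:
            by_gene[gene].append(cpg)
    result: dict[str, MarkerCandidate | None] = {}
    for gene in genes:
        cpgs = sorted(by_gene[gene])
        if not cpgs:
            logger.warning("gene %s has no mapped CpG in the matrix", gene)
            result[gene] = None
            continue
        ranked = rank_by_margin(
            matrix.subset_cpgs(cpgs), annotations,
            group1_label, group2_label, allow_missing,
        )
        result[gene] = ranked[0]
    return result


def enumerate_perfect_separators(
    matrix: BetaMatrix,
    annotations: Iterable[SampleAnnotation],
    group1_label: str = "pluripotent",
    group2_label: str = "somatic",
    allow_missing: bool = False,
) -> list[MarkerCandidate]:
    """All CpGs whose group ranges do not overlap (margin strictly > 0)."""
    ranked = rank_by_margin(
        matrix, annotations, group1_label, group2_label, allow_missing
    )
    return [c for c in ranked if c.margin > 0]


def select_parthenogenic_pair(
    matrix: BetaMatrix,
    annotations: Iterable[SampleAnnotation],
    parthenogenic_label: str = "parthenogenic",
    pluripotent_label: str = "pluripotent",
    allow_missing: bool = False,
) -> tuple[MarkerCandidate, MarkerCandidate]:
    """Best criterion-1 CpG in each direction, parthenogenic vs. ESC/iPSC.

    Parthenogenic ESCs carry two maternal genomes, so imprinted loci shift:
    maternally methylated sites (SNURF-like) go up, paternally methylated
    sites (H19-like) go down.  Returns ``(cpg_up, cpg_down)`` — the CpG
    hypermethylated and the CpG hypomethylated in the parthenogenic group.
    """
    m_hypo, m_hyper, hb, yb = _directional_margins(
        matrix, annotations, parthenogenic_label, pluripotent_label,
        allow_missing,
    )
    cpgs = matrix.cpg_ids

    def _best(margins: np.ndarray, direction: str, bounds) -> MarkerCandidate:
        order = sorted(range(len(cpgs)), key=lambda k: (-margins[k], cpgs[k]))
        k = order[0]
        if margins[k] <= 0:
            raise SelectionError(
                f"no CpG with positive {direction} margin for the "
                f"parthenogenic comparison"
            )
        cutoff = (bounds[0][k] + bounds[1][k]) / 2.0
        return MarkerCandidate(cpgs[k], direction, float(margins[k]), float(cutoff))

    cpg_up = _best(m_hyper, HYPER, yb)
    cpg_down = _best(m_hypo, HYPO, hb)
    return cpg_up, cpg_down


def candidates_to_tsv(candidates: Iterable[MarkerCandidate], path) -> None:
    """Write candidates as TSV (cpg_id, direction, margin, cutoff, c2 fraction)."""
    with open(path, "w") as fh:
        fh.write("cpg_id\tdirection\tmargin\tcutoff\tcriterion2_fraction\n")
        for c in candidates:
            cut = "" if c.cutoff is None else repr(float(c.cutoff))
            c2 = "" if c.criterion2_fraction is None else repr(float(c.criterion2_fraction))
            fh.write(f"{c.cpg_id}\t{c.direction}\t{c.margin!r}\t{cut}\t{c2}\n")
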