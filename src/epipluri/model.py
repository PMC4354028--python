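"""Model/Results interface over the marker-derivation pipeline.

``EpiPluriModel`` holds a labelled training cohort (beta matrix plus sample
annotations); ``fit()`` runs the two-criterion derivation and returns an
``EpiPluriResults`` carrying the selected marker pair, all perfect
separators, the training-derived POU5F1-style cutoff, and — when
parthenogenic samples are present — the imprinting marker pair.  Scoring of
new cohorts, the multi-CpG comparator and plotting hang off the results
object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import markers as mk
from .classifier import DEFAULT_C, LinearMarginClassifier, train_max_margin
from .exceptions import EpiPluriError, SelectionError
from .io import (
    BetaMatrix, SampleAnnotation, annotations_by_label,
    intersect_platforms, read_annotations, read_beta_matrix, read_manifest,
)
from .scoring import POU5F1_CPG, ScoringReport, score_samples
from .validation import confusion, metrics_json


class EpiPluriModel:
    """Two-criterion maximum-margin marker derivation on a labelled cohort.

    Parameters
    ----------
    betas
        Training beta matrix (CpGs x samples).
    annotations
        One annotation per training sample; pluripotent, somatic and
        differentiated samples must all be present for a full fit.
    margin_tolerance
        Hyper-direction candidates within this margin of the best are
        considered "similarly good" and re-ranked by criterion 2.
    pou5f1_cpg
        CpG whose training gap midpoint becomes the early-differentiation
        cutoff; ``None`` disables the complement.
    allow_missing
        Drop missing beta-values per CpG instead of raising.
    """

    def __init__(
        self,
        betas: BetaMatrix,
        annotations: Iterable[SampleAnnotation],
        margin_tolerance: float = 0.05,
        pou5f1_cpg: str | None = POU5F1_CPG,
        allow_missing: bool = False,
    ) -> None:
        self.betas = betas
        self.annotations = list(annotations)
        self.margin_tolerance = float(margin_tolerance)
        self.pou5f1_cpg = pou5f1_cpg
        self.allow_missing = allow_missing
        unknown = [a.sample_id for a in self.annotations
                   if a.sample_id not in betas.data.columns]
        if unknown:
            raise EpiPluriError(
                f"annotated samples absent from matrix: {unknown[:5]}"
            )

    @classmethod
    def from_files(
        cls,
        betas_path,
        annotations_path,
        manifest_path=None,
        **kwargs,
    ) -> "EpiPluriModel":
        """Build a model from the TSV conventions of :mod:`epipluri.io`."""
        betas = read_beta_matrix(betas_path)
        if manifest_path is not None:
            betas = intersect_platforms(betas, read_manifest(manifest_path))
        return cls(betas, read_annotations(annotations_path), **kwargs)

    def fit(
        self,
        gene_map: Mapping[str, str] | None = None,
        genes: Sequence[str] | None = None,
    ) -> "EpiPluriResults":
        """Run both derivation criteria and collect the results.

        When ``gene_map``/``genes`` are given, the best CpG per gene is
        derived as well (gene-restricted criterion 1).  When parthenogenic
        samples are annotated, the imprinting marker pair is derived from
        the parthenogenic-vs-pluripotent comparison.
        """
        hypo, hyper = mk.select_score_pair(
            self.betas, self.annotations, self.margin_tolerance,
            allow_missing=self.allow_missing,
        )
        separators = mk.enumerate_perfect_separators(
            self.betas, self.annotations, allow_missing=self.allow_missing,
        )
        pou5f1_candidate = None
        if (self.pou5f1_cpg is not None
                and self.pou5f1_cpg in self.betas.data.index):
            ranked = mk.rank_by_margin(
                self.betas.subset_cpgs([self.pou5f1_cpg]), self.annotations,
                allow_missing=self.allow_missing,
            )
            pou5f1_candidate = ranked[0]
        gene_best = None
        if gene_map is not None and genes is not None:
            gene_best = mk.best_cpg_in_genes(
                self.betas, self.annotations, gene_map, genes,
                allow_missing=self.allow_missing,
            )
        partheno_pair = None
        if "parthenogenic" in annotations_by_label(self.annotations):
            partheno_pair = mk.select_parthenogenic_pair(
                self.betas, self.annotations,
                allow_missing=self.allow_missing,
            )
        return EpiPluriResults(
            model=self,
            hypo_marker=hypo,
            hyper_marker=hyper,
            separators=separators,
            pou5f1_candidate=pou5f1_candidate,
            gene_best=gene_best,
            partheno_pair=partheno_pair,
        )


@dataclass(frozen=True)
class EpiPluriResults:
    """Derived markers plus scoring / comparator / plotting helpers."""

    model: EpiPluriModel
    hypo_marker: mk.MarkerCandidate
    hyper_marker: mk.MarkerCandidate
    separators: list[mk.MarkerCandidate]
    pou5f1_candidate: mk.MarkerCandidate | None = None
    gene_best: dict[str, mk.MarkerCandidate | None] | None = None
    partheno_pair: tuple[mk.MarkerCandidate, mk.MarkerCandidate] | None = None

    # -- derived quantities ----------------------------------------------
    @property
    def marker_ids(self) -> tuple[str, str, str | None]:
        """(hyper, hypo, pou5f1) CpG ids in score_samples order."""
        pou = (self.pou5f1_candidate.cpg_id
               if self.pou5f1_candidate is not None else None)
        return self.hyper_marker.cpg_id, self.hypo_marker.cpg_id, pou

    @property
    def pou5f1_cutoff(self) -> float | None:
        """Training gap midpoint of the early-differentiation CpG."""
        if self.pou5f1_candidate is None:
            return None
        return self.pou5f1_candidate.cutoff

    # -- scoring ----------------------------------------------------------
    def score(self, matrix: BetaMatrix | None = None) -> ScoringReport:
        """Score a cohort with the derived marker pair (default: training)."""
        if matrix is None:
            matrix = self.model.betas
        hyper_id, hypo_id, pou_id = self.marker_ids
        ids = (hyper_id, hypo_id) if pou_id is None else (hyper_id, hypo_id, pou_id)
        return score_samples(matrix, ids, pou5f1_cutoff=self.pou5f1_cutoff)

    def validate(self, matrix: BetaMatrix,
                 annotations: Iterable[SampleAnnotation]) -> dict:
        """Score a cohort and return confusion counts plus sens/spec."""
        report = self.score(matrix)
        truth = {a.sample_id: a.label for a in annotations}
        return metrics_json(confusion(report.calls(), truth))

    # -- multi-CpG comparator ---------------------------------------------
    def fit_multi_cpg(self, C: float = DEFAULT_C) -> LinearMarginClassifier:
        """Maximum-margin linear classifier over all perfect separators."""
        if not self.separators:
            raise SelectionError("no perfect separators to train on")
        feature_matrix = self.model.betas.subset_cpgs(
            [c.cpg_id for c in self.separators]
        )
        return train_max_margin(feature_matrix, self.model.annotations, C=C)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        by_label = annotations_by_label(self.model.annotations)
        lines = [
            "Epi-Pluri marker derivation",
            "=" * 61,
            "training samples: " + ", ".join(
                f"{len(v)} {k}" for k, v in sorted(by_label.items())
            ),
            f"CpGs evaluated:   {self.model.betas.shape[0]}",
            f"perfect separators (margin > 0): {len(self.separators)}",
            "-" * 61,
            f"{'role':<22}{'CpG':<14}{'margin':>8}{'cutoff':>8}{'crit.2':>8}",
        ]

        def _row(role: str, c: mk.MarkerCandidate | None) -> str:
            if c is None:
                return f"{role:<22}{'-':<14}"
            cut = f"{c.cutoff:.3f}" if c.cutoff is not None else "-"
            c2 = (f"{c.criterion2_fraction:.3f}"
                  if c.criterion2_fraction is not None else "-")
            return f"{role:<22}{c.cpg_id:<14}{c.margin:>8.3f}{cut:>8}{c2:>8}"

        lines.append(_row("hypo in pluripotent", self.hypo_marker))
        lines.append(_row("hyper in pluripotent", self.hyper_marker))
        lines.append(_row("early-diff complement", self.pou5f1_candidate))
        if self.partheno_pair is not None:
            up, down = self.partheno_pair
            lines.append(_row("hyper in parthenog.", up))
            lines.append(_row("hypo in parthenog.", down))
        if self.gene_best:
            lines.append("-" * 61)
            lines.append("best CpG per gene:")
            for gene, cand in self.gene_best.items():
                lines.append(_row(f"  {gene}", cand))
        lines.append("=" * 61)
        lines.append(
            "score = beta[hyper marker] - beta[hypo marker]; "
            "positive => pluripotent"
        )
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------
    def plot_margins(self, ax=None):
        """Rank plot of per-CpG margins (negative = overlapping ranges)."""
        import matplotlib.pyplot as plt

        ranked = mk.rank_by_margin(
            self.model.betas, self.model.annotations,
            allow_missing=self.model.allow_missing,
        )
        if ax is None:
            _, ax = plt.subplots()
        ax.plot([c.margin for c in ranked], lw=1)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("CpG rank")
        ax.set_ylabel("margin between group ranges")
        return ax

    def plot_scores(self, matrix: BetaMatrix | None = None, ax=None):
        """Scatter of Epi-Pluri-Score vs the early-differentiation beta."""
        import matplotlib.pyplot as plt

        report = self.score(matrix)
        if ax is None:
            _, ax = plt.subplots()
        xs = [r.epi_pluri_score for r in report.results]
        ys = [r.beta_pou5f1 if r.beta_pou5f1 is not None else float("nan")
              for r in report.results]
        ax.scatter(xs, ys, s=12)
        ax.axvline(0.0, color="grey", lw=0.8)
        if self.pou5f1_cutoff is not None:
            ax.axhline(self.pou5f1_cutoff, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("Epi-Pluri-Score")
        ax.set_ylabel("beta at early-differentiation CpG")
        return ax
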