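"""Seeded simulator of methylation-array cohorts.

Generates beta-value matrices with the statistical structure the marker
derivation assumes: a handful of planted marker CpGs whose class-conditional
beta distributions are cleanly separated, a large background of uninformative
CpGs whose distribution is shared across classes, differentiated samples
whose marker means travel from the pluripotent toward the somatic level
along a logistic time course, and optional parthenogenic and partially
reprogrammed samples.

Beta-values are drawn from beta distributions parameterised by
``(mean, precision)`` — shape parameters ``a = mean * precision`` and
``b = (1 - mean) * precision`` — which keeps draws in [0, 1] and makes the
spread interpretable (variance = mean (1-mean) / (1 + precision)).

Identical ``SimulationConfig`` (including its seed) yields bit-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import EpiPluriError
from .io import BetaMatrix, SampleAnnotation
from .scoring import (
    ANKRD46_CPG, C14ORF115_CPG, H19_CPG, POU5F1_CPG, SNURF_CPG,
)

_MEAN_EPS = 1e-6


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class MarkerSpec:
    """Class-conditional beta distribution of one planted marker CpG.

    ``mean_parthenogenic`` defaults to the pluripotent mean (parthenogenic
    ESCs look pluripotent at non-imprinted loci).  ``t50``/``tau`` place the
    logistic transition of differentiated samples: the mean beta at day t is
    ``mean_pluripotent + (mean_somatic - mean_pluripotent) *
    logistic((t - t50) / tau)``.
    """

    cpg_id: str
    mean_pluripotent: float
    mean_somatic: float
    mean_parthenogenic: float | None = None
    precision: float = 50.0
    t50: float = 15.0
    tau: float = 2.0

    def __post_init__(self) -> None:
        for name in ("mean_pluripotent", "mean_somatic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise EpiPluriError(f"{self.cpg_id}: {name} {v} outside [0, 1]")
        if self.mean_parthenogenic is not None and not (
            0.0 <= self.mean_parthenogenic <= 1.0
        ):
            raise EpiPluriError(f"{self.cpg_id}: parthenogenic mean outside [0, 1]")
        if self.precision <= 0 or self.tau <= 0:
            raise EpiPluriError(f"{self.cpg_id}: precision and tau must be > 0")

    def mean_for_day(self, day: float) -> float:
        frac = float(_logistic((day - self.t50) / self.tau))
        return self.mean_pluripotent + (self.mean_somatic - self.mean_pluripotent) * frac

    @property
    def direction_in_pluripotent(self) -> str:
        """'hypo' if the CpG is hypomethylated in pluripotent cells."""
        return "hypo" if self.mean_pluripotent < self.mean_somatic else "hyper"


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort sizes, planted markers, noise model and seed of one simulation.

    Defaults mirror the scale of the published training set: 63 pluripotent,
    177 somatic and 18 in-vitro differentiated profiles, plus 6
    parthenogenic lines, against a background of 1,000 uninformative CpGs.
    """

    n_pluripotent: int = 63
    n_somatic: int = 177
    n_differentiated: int = 18
    n_parthenogenic: int = 6
    n_partial: int = 0
    n_noise_cpgs: int = 1000
    markers: tuple[MarkerSpec, ...] = ()
    differentiation_days: tuple[float, ...] = (3.0, 8.0, 11.0, 15.0, 20.0, 25.0)
    mixture_fraction: float | None = None
    noise_precision: float = 8.0
    noise_mean_low: float = 0.05
    noise_mean_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_pluripotent, self.n_somatic, self.n_differentiated,
                  self.n_parthenogenic, self.n_partial, self.n_noise_cpgs)
        if min(counts) < 0:
            raise EpiPluriError("cohort sizes must be non-negative")
        if self.mixture_fraction is not None and not (
            0.0 <= self.mixture_fraction <= 1.0
        ):
            raise EpiPluriError("mixture_fraction outside [0, 1]")
        if self.n_partial > 0 and self.mixture_fraction is None:
            raise EpiPluriError("n_partial > 0 requires mixture_fraction")
        if self.noise_precision <= 0:
            raise EpiPluriError("noise_precision must be > 0")
        if not 0.0 <= self.noise_mean_low <= self.noise_mean_high <= 1.0:
            raise EpiPluriError("noise mean range must satisfy 0 <= low <= high <= 1")
        if self.n_differentiated > 0 and not self.differentiation_days:
            raise EpiPluriError("differentiated samples need differentiation_days")
        ids = [m.cpg_id for m in self.markers]
        if len(ids) != len(set(ids)):
            raise EpiPluriError("duplicate marker CpG ids")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_json(self, path) -> None:
        blob = dataclasses.asdict(self)
        blob["markers"] = [dataclasses.asdict(m) for m in self.markers]
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            blob = json.load(fh)
        blob["markers"] = tuple(MarkerSpec(**m) for m in blob.get("markers", []))
        for key in ("differentiation_days",):
            if key in blob:
                blob[key] = tuple(blob[key])
        return cls(**blob)


def default_config(seed: int = 0) -> SimulationConfig:
    """The reference simulation: three pluripotency markers, two imprinting
    markers, published-scale class sizes.

    The planted pluripotency markers emulate the published triple:

    * a C14orf115-like CpG, unmethylated in pluripotent cells (mean 0.05)
      and methylated in somatic cells (0.85), shifting around day 15;
    * an ANKRD46-like CpG, methylated in pluripotent cells (0.90) and
      unmethylated in somatic cells (0.10), shifting around day 20;
    * a POU5F1-like CpG (0.10 vs 0.80, noisier, hence a smaller margin
      than the two score CpGs) that shifts early (around day 7), so it
      flags differentiation while the score CpGs still look pluripotent.

    The imprinting markers sit at ~0.45 in normal cells and move to 0.90
    (SNURF-like, maternally methylated) and 0.05 (H19-like) in
    parthenogenic samples.
    """
    markers = (
        MarkerSpec(C14ORF115_CPG, mean_pluripotent=0.05, mean_somatic=0.85,
                   precision=50.0, t50=15.0, tau=2.5),
        MarkerSpec(ANKRD46_CPG, mean_pluripotent=0.90, mean_somatic=0.10,
                   precision=50.0, t50=20.0, tau=2.5),
        MarkerSpec(POU5F1_CPG, mean_pluripotent=0.10, mean_somatic=0.80,
                   precision=25.0, t50=7.0, tau=1.5),
        MarkerSpec(SNURF_CPG, mean_pluripotent=0.45, mean_somatic=0.45,
                   mean_parthenogenic=0.90, precision=60.0, t50=15.0, tau=2.5),
        MarkerSpec(H19_CPG, mean_pluripotent=0.45, mean_somatic=0.45,
                   mean_parthenogenic=0.05, precision=60.0, t50=15.0, tau=2.5),
    )
    return SimulationConfig(markers=markers, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: per-sample class/day and marker geometry."""

    classes: dict[str, str]
    days: dict[str, float]
    marker_directions: dict[str, str]  # cpg -> 'hypo'/'hyper' in pluripotent
    marker_means: dict[str, dict[str, float]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _draw_beta(rng: np.random.Generator, mean: float, precision: float,
               size: int) -> np.ndarray:
    m = min(max(mean, _MEAN_EPS), 1.0 - _MEAN_EPS)
    return rng.beta(m * precision, (1.0 - m) * precision, size=size)


def simulate(
    config: SimulationConfig,
) -> tuple[BetaMatrix, list[SampleAnnotation], GroundTruth]:
    """Draw one cohort from the seeded generator.

    Returns the beta matrix (marker CpGs first, then noise CpGs), the sample
    annotations, and the planted ground truth.  All randomness comes from
    ``numpy.random.default_rng(config.seed)``, so identical configs give
    bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)

    samples: list[SampleAnnotation] = []
    samples += [SampleAnnotation(f"pluri_{i:04d}", "pluripotent")
                for i in range(config.n_pluripotent)]
    samples += [SampleAnnotation(f"soma_{i:04d}", "somatic")
                for i in range(config.n_somatic)]
    days = [config.differentiation_days[i % len(config.differentiation_days)]
            for i in range(config.n_differentiated)]
    samples += [SampleAnnotation(f"diff_{i:04d}", "differentiated", float(d))
                for i, d in enumerate(days)]
    samples += [SampleAnnotation(f"pesc_{i:04d}", "parthenogenic")
                for i in range(config.n_parthenogenic)]
    samples += [SampleAnnotation(f"partial_{i:04d}", "unknown")
                for i in range(config.n_partial)]
    sample_ids = [s.sample_id for s in samples]
    n_samples = len(sample_ids)
    if n_samples == 0:
        raise EpiPluriError("simulation needs at least one sample")

    rows: list[np.ndarray] = []
    cpg_ids: list[str] = []
    f = config.mixture_fraction
    for spec in config.markers:
        pesc_mean = (spec.mean_parthenogenic
                     if spec.mean_parthenogenic is not None
                     else spec.mean_pluripotent)
        row = np.empty(n_samples)
        k = 0
        for mean, count in (
            (spec.mean_pluripotent, config.n_pluripotent),
            (spec.mean_somatic, config.n_somatic),
        ):
            row[k:k + count] = _draw_beta(rng, mean, spec.precision, count)
            k += count
        for d in days:
            row[k] = _draw_beta(rng, spec.mean_for_day(d), spec.precision, 1)[0]
            k += 1
        row[k:k + config.n_parthenogenic] = _draw_beta(
            rng, pesc_mean, spec.precision, config.n_parthenogenic)
        k += config.n_parthenogenic
        if config.n_partial:
            mix = f * spec.mean_pluripotent + (1.0 - f) * spec.mean_somatic
            row[k:k + config.n_partial] = _draw_beta(
                rng, mix, spec.precision, config.n_partial)
        rows.append(row)
        cpg_ids.append(spec.cpg_id)

    # uninformative background: one class-independent distribution per CpG
    noise_means = rng.uniform(config.noise_mean_low, config.noise_mean_high,
                              size=config.n_noise_cpgs)
    for i, mean in enumerate(noise_means):
        rows.append(_draw_beta(rng, float(mean), config.noise_precision,
                               n_samples))
        cpg_ids.append(f"cgn{i:07d}")

    if not rows:
        raise EpiPluriError("simulation needs at least one CpG")
    matrix = BetaMatrix(pd.DataFrame(
        np.vstack(rows), index=cpg_ids, columns=sample_ids, dtype=float,
    ))

    classes = {s.sample_id: ("partial" if s.sample_id.startswith("partial_")
                             else s.label) for s in samples}
    truth = GroundTruth(
        classes=classes,
        days={s.sample_id: s.day for s in samples if s.day is not None},
        marker_directions={m.cpg_id: m.direction_in_pluripotent
                           for m in config.markers},
        marker_means={m.cpg_id: {
            "pluripotent": m.mean_pluripotent,
            "somatic": m.mean_somatic,
            "parthenogenic": (m.mean_parthenogenic
                              if m.mean_parthenogenic is not None
                              else m.mean_pluripotent),
        } for m in config.markers},
    )
    return matrix, samples, truth


def simulate_validation_cohort(
    config: SimulationConfig, seed: int,
    n_pluripotent: int | None = None,
    n_somatic: int | None = None,
) -> tuple[BetaMatrix, list[SampleAnnotation], GroundTruth]:
    """A fresh pluripotent/somatic cohort from the same marker geometry.

    Convenience for train-on-one-cohort, validate-on-another experiments;
    only the seed (and optionally the class sizes) differ from ``config``.
    """
    changes = {"seed": seed, "n_differentiated": 0, "n_parthenogenic": 0,
               "n_partial": 0, "mixture_fraction": None}
    if n_pluripotent is not None:
        changes["n_pluripotent"] = n_pluripotent
    if n_somatic is not None:
        changes["n_somatic"] = n_somatic
    return simulate(config.replace(**changes))
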