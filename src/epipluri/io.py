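"""Reading and writing beta-value matrices, sample annotations and CpG manifests.

The on-disk conventions follow GEO series-matrix practice: a tab-separated
table with CpG probe identifiers in the first column, one column per sample,
and methylation fractions (beta-values) in [0, 1].  Missing measurements are
written as the literal ``NA`` and kept as missing in memory — they are never
silently imputed or zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import BetaParseError, EpiPluriError

#: Closed vocabulary of sample class labels.
LABELS = ("pluripotent", "somatic", "differentiated", "parthenogenic", "unknown")

#: Labels that may carry a differentiation day.
_DAY_LABELS = ("differentiated", "unknown")


@dataclass(frozen=True)
class BetaMatrix:
    """A CpG x sample matrix of methylation beta-values.

    Parameters
    ----------
    data
        Float DataFrame indexed by CpG id with one column per sample id.
        Values lie in [0, 1]; missing measurements are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise BetaParseError(f"duplicate CpG id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise BetaParseError(f"duplicate sample id {dup!r}")
        values = df.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BetaParseError(
                f"beta-value {values[i, j]} outside [0, 1] at "
                f"CpG {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, cpg_id: str) -> pd.Series:
        """Beta-values of one CpG across all samples."""
        if cpg_id not in self.data.index:
            raise EpiPluriError(f"CpG {cpg_id!r} not present in matrix")
        return self.data.loc[cpg_id]

    def get(self, cpg_id: str, sample_id: str) -> float:
        return float(self.data.at[cpg_id, sample_id])

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        missing = [c for c in cpg_ids if c not in self.data.index]
        if missing:
            raise EpiPluriError(f"CpGs not present in matrix: {missing[:5]}")
        return BetaMatrix(self.data.loc[list(cpg_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise EpiPluriError(f"samples not present in matrix: {missing[:5]}")
        return BetaMatrix(self.data[list(sample_ids)])


@dataclass(frozen=True)
class SampleAnnotation:
    """Class label (and optional differentiation day) of one sample."""

    sample_id: str
    label: str
    day: float | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise BetaParseError(
                f"unknown label {self.label!r} for sample {self.sample_id!r}; "
                f"allowed labels: {', '.join(LABELS)}"
            )
        if self.day is not None:
            if self.label not in _DAY_LABELS:
                raise BetaParseError(
                    f"sample {self.sample_id!r}: day given but label is "
                    f"{self.label!r} (day is only meaningful for "
                    f"{' or '.join(_DAY_LABELS)})"
                )
            if not math.isfinite(self.day) or self.day < 0:
                raise BetaParseError(
                    f"sample {self.sample_id!r}: day must be a non-negative number"
                )


@dataclass(frozen=True)
class PlatformManifest:
    """The CpG content of one array platform (or a platform intersection)."""

    name: str
    cpg_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.cpg_ids:
            raise BetaParseError(f"manifest {self.name!r} contains no CpG ids")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_beta_matrix(path) -> BetaMatrix:
    """Read a tab-separated beta-value matrix (CpG rows x sample columns).

    Cells must be decimal numbers in [0, 1] (scientific notation accepted)
    or the literal ``NA`` for missing.  Malformed cells are reported with
    their CpG and sample ids.
    """
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise BetaParseError(f"{path}: no CpG rows")
    sample_ids = header.rstrip("\n").split("\t")[1:]
    if len(sample_ids) != len(set(sample_ids)):
        # checked on the raw header because pandas silently renames
        # duplicate columns
        dup = next(s for i, s in enumerate(sample_ids) if s in sample_ids[:i])
        raise BetaParseError(f"{path}: duplicate sample id {dup!r}")
    try:
        raw = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str,
            keep_default_na=False, na_values=[],
        )
    except pd.errors.EmptyDataError:
        raise BetaParseError(f"{path}: no CpG rows") from None
    raw.columns = sample_ids
    if raw.shape[0] == 0:
        raise BetaParseError(f"{path}: no CpG rows")
    if raw.shape[1] == 0:
        raise BetaParseError(f"{path}: header holds no sample ids")
    raw = raw.where(raw != "NA")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    unparsable = numeric.isna() & raw.notna()
    if unparsable.to_numpy().any():
        i, j = np.argwhere(unparsable.to_numpy())[0]
        raise BetaParseError(
            f"{path}: cell {raw.iat[i, j]!r} at CpG {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} is not a number or NA"
        )
    # pandas' fast float parser is not round-trip exact; Python's float() is
    exact = raw.astype(float)
    exact.index = exact.index.astype(str)
    exact.columns = exact.columns.astype(str)
    return BetaMatrix(exact)


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    """Write a beta-value matrix as TSV; missing cells become ``NA``.

    Uses shortest round-trip float formatting, so write -> read reproduces
    values bit-identically.
    """
    df = matrix.data.copy()
    df.index.name = df.index.name or "cpg_id"
    with open(path, "w") as fh:
        fh.write(df.index.name + "\t" + "\t".join(map(str, df.columns)) + "\n")
        values = df.to_numpy(dtype=float)
        for cpg, row in zip(df.index, values):
            cells = ("NA" if np.isnan(v) else repr(float(v)) for v in row)
            fh.write(str(cpg) + "\t" + "\t".join(cells) + "\n")


def read_annotations(path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV with header ``sample_id  label  [day]``."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str,
                         keep_default_na=False, na_values=[])
    except pd.errors.EmptyDataError:
        raise BetaParseError(f"{path}: empty annotation file") from None
    required = {"sample_id", "label"}
    if not required.issubset(df.columns):
        raise BetaParseError(
            f"{path}: annotation header must contain columns "
            f"'sample_id' and 'label' (optional 'day'); got {list(df.columns)}"
        )
    annotations: list[SampleAnnotation] = []
    seen: set[str] = set()
    for _, rec in df.iterrows():
        sid = rec["sample_id"]
        if sid in seen:
            raise BetaParseError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)
        day_txt = rec.get("day", "")
        day: float | None = None
        if day_txt not in ("", "NA", None):
            try:
                day = float(day_txt)
            except ValueError:
                raise BetaParseError(
                    f"{path}: day {day_txt!r} for sample {sid!r} is not a number"
                ) from None
        annotations.append(SampleAnnotation(sid, rec["label"], day))
    return annotations


def write_annotations(annotations: Iterable[SampleAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\tday\n")
        for ann in annotations:
            day = "" if ann.day is None else repr(float(ann.day))
            fh.write(f"{ann.sample_id}\t{ann.label}\t{day}\n")


def read_manifest(path, name: str | None = None) -> PlatformManifest:
    """Read a platform manifest: one CpG id per line, blanks ignored."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(ids) != len(set(ids)):
        raise BetaParseError(f"{path}: manifest contains duplicate CpG ids")
    return PlatformManifest(name or str(path), frozenset(ids))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def intersect_platforms(matrix: BetaMatrix, manifest: PlatformManifest) -> BetaMatrix:
    """Restrict a matrix to the CpGs present in a platform manifest.

    Mirrors the cross-platform step of restricting HumanMethylation450
    training data to the probes shared with the HumanMethylation27 chip so
    that classifiers transfer between the platforms.  Row order is preserved;
    samples are untouched.
    """
    keep = [c for c in matrix.cpg_ids if c in manifest.cpg_ids]
    if not keep:
        raise EpiPluriError(
            f"no CpGs shared between matrix and manifest {manifest.name!r}"
        )
    return BetaMatrix(matrix.data.loc[keep])


def pyro_to_beta(percent: float) -> float:
    """Convert a pyrosequencing percent-methylation readout to a beta-value."""
    p = float(percent)
    if not math.isfinite(p) or p < 0.0 or p > 100.0:
        raise EpiPluriError(
            f"percent methylation {percent!r} outside [0, 100]"
        )
    return p / 100.0


def annotations_by_label(
    annotations: Iterable[SampleAnnotation],
) -> dict[str, list[SampleAnnotation]]:
    """Group annotations by class label (labels without samples are absent)."""
    groups: dict[str, list[SampleAnnotation]] = {}
    for ann in annotations:
        groups.setdefault(ann.label, []).append(ann)
    return groups
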