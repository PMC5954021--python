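"""Small quantitative readout metrics: IHC score, tumor volume, MFI fold.

The IHC quantitative score multiplies the percentage of immunopositive
cells (0–100) by an ordinal staining-intensity grade (0 negative, 1 low,
2 medium, 3 high), range 0–300. Tumor volume uses the caliper ellipsoid
approximation l × w² / 2 (longest × shortest diameter). MFI fold change
is the plain ratio of treated to control mean fluorescence intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd
from scipy import stats

from .emt import CorrelationResult, correlate
from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "IHCRecord",
    "TumorMeasurement",
    "MFIPair",
    "ihc_score",
    "tumor_volume",
    "mfi_fold_change",
    "correlate_markers",
]


def ihc_score(percent_positive: float, intensity: int) -> float:
    """Quantitative IHC score: percent positive × intensity grade."""
    if not 0 <= percent_positive <= 100:
        raise InvalidInputError(
            f"percent_positive must be in [0, 100], got {percent_positive}"
        )
    if isinstance(intensity, bool) or intensity != int(intensity):
        raise InvalidInputError(f"intensity must be an integer grade, got {intensity}")
    if int(intensity) not in (0, 1, 2, 3):
        raise InvalidInputError(f"intensity must be in {{0,1,2,3}}, got {intensity}")
    return float(percent_positive) * int(intensity)


def tumor_volume(l: float, w: float) -> float:
    """Caliper tumor volume l × w × w / 2 (mm³), l the longest diameter.

    If w > l the arguments are swapped with a warning rather than
    rejected, so the longest diameter is always cubed-down correctly.
    """
    if l <= 0 or w <= 0:
        raise InvalidInputError(f"diameters must be positive, got l={l}, w={w}")
    if w > l:
        warnings.warn(
            f"w={w} exceeds l={l}; swapping so l is the longest diameter",
            stacklevel=2,
        )
        l, w = w, l
    return l * w * w / 2.0


def mfi_fold_change(mfi_treated: float, mfi_control: float) -> float:
    """Fold induction of mean fluorescence intensity: treated / control."""
    if mfi_control <= 0:
        raise InvalidInputError(f"mfi_control must be positive, got {mfi_control}")
    if mfi_treated <= 0:
        raise InvalidInputError(f"mfi_treated must be positive, got {mfi_treated}")
    return mfi_treated / mfi_control


@dataclass(frozen=True)
class IHCRecord:
    """One specimen × marker IHC readout with its derived score."""

    specimen_id: str
    marker: str
    percent_positive: float
    intensity: int

    @property
    def score(self) -> float:
        return ihc_score(self.percent_positive, self.intensity)


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper diameters (mm) with the derived ellipsoid volume (mm³)."""

    l: float
    w: float

    @property
    def volume(self) -> float:
        return tumor_volume(self.l, self.w)


@dataclass(frozen=True)
class MFIPair:
    """Treated/control MFI pair with the derived fold change."""

    mfi_treated: float
    mfi_control: float

    @property
    def fold(self) -> float:
        return mfi_fold_change(self.mfi_treated, self.mfi_control)


def correlate_markers(
    table: Sequence[IHCRecord] | pd.DataFrame,
    marker_a: str,
    marker_b: str,
    method: Literal["pearson", "spearman"] = "pearson",
) -> CorrelationResult:
    """Correlate two markers' IHC scores across specimens.

    Specimens are matched by id; at least 3 paired specimens are
    required. Pearson on raw scores by default; Spearman rank
    correlation is available as an alternative.
    """
    if isinstance(table, pd.DataFrame):
        records = [
            IHCRecord(
                specimen_id=str(row["specimen_id"]),
                marker=str(row["marker"]),
                percent_positive=float(row["percent_positive"]),
                intensity=int(row["intensity"]),
            )
            for _, row in table.iterrows()
        ]
    else:
        records = list(table)
    scores: dict[str, dict[str, float]] = {}
    for rec in records:
        scores.setdefault(rec.specimen_id, {})[rec.marker] = rec.score
    paired = [
        (v[marker_a], v[marker_b])
        for v in scores.values()
        if marker_a in v and marker_b in v
    ]
    if len(paired) < 3:
        raise InsufficientDataError(
            f"only {len(paired)} specimens have both {marker_a!r} and {marker_b!r}"
        )
    a, b = zip(*paired)
    if method == "pearson":
        return correlate(a, b)
    if method == "spearman":
        res = stats.spearmanr(a, b)
        return CorrelationResult(
            r=float(res.statistic), p_value=float(res.pvalue), n=len(paired)
        )
    raise InvalidInputError(f"unknown correlation method {method!r}")
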