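"""N-glycan site-occupancy quantification from peptide-ion intensities.

The core quantity is the percent occupancy of an N-glycosylation sequon,
estimated from three normalized peptide intensities:

* ``IN``  — the native (Asn-containing, N×T) peptide after PNGase F;
* ``INF`` — the de-glycosylated (Asp-containing, D×T) peptide after
  PNGase F, whose Asn was converted to Asp by enzymatic glycan release;
* ``IND`` — the D×T peptide from a control run without PNGase F, which
  measures spontaneous (non-enzymatic) deamidation.

Occupancy is ``(INF − IND) / (IN + INF) × 100``: the enzymatically
produced Asp signal, corrected for spontaneous deamidation, over the
total de-glycosylated plus never-glycosylated pool. Full occupancy means
no native peptide survives PNGase F (``IN = 0``) and no spontaneous
deamidation is seen (``IND = 0``), giving exactly 100%.

Species are resolved by extracted ion chromatograms (XICs) in a narrow
parts-per-million window around the calculated accurate m/z; the Asn→Asp
shift is the exact monoisotopic deamidation delta (0.984016 Da), which a
10 ppm window separates cleanly at tryptic-peptide masses. Protein
amounts are equalized across samples with two non-glycosylated reference
peptides before the occupancy formula is applied.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEAMIDATION_DELTA,
    DEFAULT_PPM_TOL,
    PROTON_MASS,
    REFERENCE_PEPTIDES,
    RESIDUE_MONO_MASS,
    WATER_MONO_MASS,
)
from .errors import InvalidInputError, MissingReferenceError, ZeroReferenceError

__all__ = [
    "Variant",
    "RunCondition",
    "PeptideIon",
    "Scan",
    "SpectrumSet",
    "XICTrace",
    "PeakMeasurement",
    "NormalizationResult",
    "OccupancyResult",
    "monoisotopic_mass",
    "ion_mz",
    "apply_deamidation",
    "mz_window",
    "extract_xic",
    "integrate_trace",
    "normalize_to_reference",
    "compute_site_occupancy",
    "occupancy_table",
]

# Fraction of the baseline reference mean below which IN + INF is
# considered too weak to quantify reliably.
DEFAULT_LOW_SIGNAL_FRACTION = 1e-6


class Variant(str, enum.Enum):
    """Peptide form: native sequon (N×T), deamidated (D×T), or reference."""

    NATIVE = "native"
    DEAMIDATED = "deamidated"
    REFERENCE = "reference"


class RunCondition(str, enum.Enum):
    """MS run condition: PNGase F treated, or the no-enzyme control."""

    PNGASEF = "pngasef"
    CONTROL = "control"


def monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic mass (Da) of a peptide: residue sum plus one water.

    The empty string returns the mass of water. Raises
    :class:`InvalidInputError` naming the offending character and its
    1-based position for any non-standard residue.
    """
    total = WATER_MONO_MASS
    for pos, aa in enumerate(sequence, start=1):
        try:
            total += RESIDUE_MONO_MASS[aa]
        except KeyError:
            raise InvalidInputError(
                f"unknown residue {aa!r} at position {pos} in {sequence!r}"
            ) from None
    return total


def ion_mz(mass: float, charge: int) -> float:
    """m/z of the ``[M + zH]^z+`` ion: ``(mass + z·m_proton) / z``."""
    if charge < 1:
        raise InvalidInputError(f"charge must be >= 1, got {charge}")
    if mass <= 0:
        raise InvalidInputError(f"mass must be positive, got {mass}")
    return (mass + charge * PROTON_MASS) / charge


def mz_window(target_mz: float, ppm_tol: float) -> tuple[float, float]:
    """Closed m/z interval ``target × (1 ± ppm_tol·1e-6)``."""
    if target_mz <= 0:
        raise InvalidInputError(f"target_mz must be positive, got {target_mz}")
    if ppm_tol < 0:
        raise InvalidInputError(f"ppm_tol must be >= 0, got {ppm_tol}")
    half = target_mz * ppm_tol * 1e-6
    return (target_mz - half, target_mz + half)


@dataclass(frozen=True)
class PeptideIon:
    """A tryptic peptide with charge state and sequon variant.

    ``deamidation_positions`` are 1-based indices into the *native*
    sequence; they must point at Asn residues and are non-empty exactly
    when ``variant`` is deamidated.
    """

    sequence: str
    charge: int
    variant: Variant = Variant.NATIVE
    deamidation_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError("peptide sequence must be non-empty")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in RESIDUE_MONO_MASS:
                raise InvalidInputError(
                    f"unknown residue {aa!r} at position {pos} in {self.sequence!r}"
                )
        if self.charge < 1:
            raise InvalidInputError(f"charge must be >= 1, got {self.charge}")
        object.__setattr__(self, "variant", Variant(self.variant))
        object.__setattr__(
            self, "deamidation_positions", tuple(self.deamidation_positions)
        )
        if (self.variant is Variant.DEAMIDATED) != bool(self.deamidation_positions):
            raise InvalidInputError(
                "deamidation_positions must be non-empty iff variant is deamidated"
            )
        for pos in self.deamidation_positions:
            if not 1 <= pos <= len(self.sequence):
                raise InvalidInputError(f"deamidation position {pos} out of range")
            if self.sequence[pos - 1] != "N":
                raise InvalidInputError(
                    f"residue at position {pos} is {self.sequence[pos - 1]!r}, not N"
                )

    @property
    def mass(self) -> float:
        """Monoisotopic mass including the deamidation shift(s)."""
        return monoisotopic_mass(self.sequence) + len(
            self.deamidation_positions
        ) * DEAMIDATION_DELTA

    @property
    def mz(self) -> float:
        return ion_mz(self.mass, self.charge)


def apply_deamidation(ion: PeptideIon, position: int) -> PeptideIon:
    """Deamidate the Asn at ``position`` (1-based), returning the D×T form.

    The sequence keeps its native residues; the shift is tracked through
    ``deamidation_positions`` so the exact monoisotopic delta (0.984016 Da
    per site) enters the mass. Applying twice at one site is an error.
    """
    if not 1 <= position <= len(ion.sequence):
        raise InvalidInputError(f"position {position} out of range")
    if position in ion.deamidation_positions:
        raise InvalidInputError(f"position {position} is already deamidated")
    if ion.sequence[position - 1] != "N":
        raise InvalidInputError(
            f"residue at position {position} is {ion.sequence[position - 1]!r}, not N"
        )
    return replace(
        ion,
        variant=Variant.DEAMIDATED,
        deamidation_positions=tuple(sorted(ion.deamidation_positions + (position,))),
    )


@dataclass(frozen=True)
class Scan:
    """One centroided scan: retention time (min) plus aligned m/z and
    intensity arrays, m/z sorted ascending."""

    retention_time: float
    mz_values: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz_values, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise InvalidInputError("mz_values and intensities must be aligned 1-D")
        if np.any(np.diff(mz) < 0):
            raise InvalidInputError("mz_values must be sorted ascending")
        if np.any(inten < 0):
            raise InvalidInputError("intensities must be non-negative")
        object.__setattr__(self, "mz_values", mz)
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class SpectrumSet:
    """An ordered set of centroided scans with strictly increasing RT."""

    scans: tuple[Scan, ...]

    def __post_init__(self) -> None:
        scans = tuple(self.scans)
        rts = [s.retention_time for s in scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise InvalidInputError("retention times must be strictly increasing")
        object.__setattr__(self, "scans", scans)

    def total_intensity(self) -> float:
        return float(sum(s.intensities.sum() for s in self.scans))


@dataclass(frozen=True)
class XICTrace:
    """Per-scan summed intensity around a target m/z."""

    target_mz: float
    ppm_tol: float
    points: tuple[tuple[float, float], ...]  # (retention_time, intensity)


def extract_xic(
    spectra: SpectrumSet, target_mz: float, ppm_tol: float = DEFAULT_PPM_TOL
) -> XICTrace:
    """Extracted ion chromatogram: one point per scan, summing centroid
    intensities whose m/z falls inside the closed ppm window (bounds
    inclusive). Scans with no matching centroid contribute 0."""
    lo, hi = mz_window(target_mz, ppm_tol)
    points = []
    for scan in spectra.scans:
        i = np.searchsorted(scan.mz_values, lo, side="left")
        j = np.searchsorted(scan.mz_values, hi, side="right")
        points.append((scan.retention_time, float(scan.intensities[i:j].sum())))
    return XICTrace(target_mz=target_mz, ppm_tol=ppm_tol, points=tuple(points))


def integrate_trace(trace: XICTrace) -> float:
    """Trapezoidal area of the trace in intensity × minutes.

    Degenerate conventions: an empty trace integrates to 0 and a
    single-point trace returns that point's intensity.
    """
    if not trace.points:
        return 0.0
    rts = np.array([p[0] for p in trace.points])
    vals = np.array([p[1] for p in trace.points])
    if len(trace.points) == 1:
        return float(vals[0])
    if np.any(np.diff(rts) < 0):
        raise InvalidInputError("trace points must be sorted by retention time")
    return float(np.trapezoid(vals, rts))


@dataclass
class PeakMeasurement:
    """A quantified peptide-ion intensity for one sample and run."""

    sample_id: str
    run_condition: RunCondition
    ion: PeptideIon
    intensity: float
    site_id: str = ""
    normalized_intensity: float | None = None

    def __post_init__(self) -> None:
        self.run_condition = RunCondition(self.run_condition)
        if self.intensity < 0:
            raise InvalidInputError(
                f"intensity must be non-negative, got {self.intensity}"
            )


@dataclass
class NormalizationResult:
    """Normalized measurements plus the per-sample scale factors used."""

    measurements: list[PeakMeasurement]
    scale_factors: dict[str, float]
    baseline_sample: str
    baseline_reference_mean: float


def normalize_to_reference(
    measurements: Sequence[PeakMeasurement],
    reference_sequences: Sequence[str] = tuple(REFERENCE_PEPTIDES),
    baseline_sample: str | None = None,
) -> NormalizationResult:
    """Equalize protein amount across samples via reference peptides.

    Each sample's scale factor is ``mean(reference intensities in the
    baseline sample) / mean(reference intensities in the sample)``; all
    of the sample's intensities (both run conditions) are multiplied by
    it. The baseline defaults to the first sample in input order.
    """
    if not measurements:
        raise InvalidInputError("no measurements to normalize")
    order: list[str] = []
    for m in measurements:
        if m.sample_id not in order:
            order.append(m.sample_id)
    if baseline_sample is None:
        baseline_sample = order[0]
    if baseline_sample not in order:
        raise InvalidInputError(f"baseline sample {baseline_sample!r} not in input")

    ref_means: dict[str, float] = {}
    for sample in order:
        per_ref: dict[str, list[float]] = {seq: [] for seq in reference_sequences}
        for m in measurements:
            if (
                m.sample_id == sample
                and m.ion.variant is Variant.REFERENCE
                and m.ion.sequence in per_ref
            ):
                per_ref[m.ion.sequence].append(m.intensity)
        for seq, vals in per_ref.items():
            if not vals:
                raise MissingReferenceError(
                    f"sample {sample!r} has no intensity for reference {seq!r}"
                )
        pooled = [v for vals in per_ref.values() for v in vals]
        mean = float(np.mean(pooled))
        if mean == 0:
            raise ZeroReferenceError(
                f"sample {sample!r} has zero mean reference intensity"
            )
        ref_means[sample] = mean

    baseline_mean = ref_means[baseline_sample]
    factors = {s: baseline_mean / ref_means[s] for s in order}
    normalized = [
        replace(m, normalized_intensity=m.intensity * factors[m.sample_id])
        for m in measurements
    ]
    return NormalizationResult(
        measurements=normalized,
        scale_factors=factors,
        baseline_sample=baseline_sample,
        baseline_reference_mean=baseline_mean,
    )


@dataclass(frozen=True)
class OccupancyResult:
    """Percent N-glycan site occupancy with QC flags.

    ``occupancy_percent`` is the raw value clamped to [0, 100]; it is
    ``None`` when the denominator ``IN + INF`` is zero. Flags record any
    clamping (``negative_raw``), an undefined ratio (``zero_denominator``)
    and weak total signal (``low_signal``).
    """

    site_id: str
    IN: float
    INF: float
    IND: float
    raw_percent: float
    occupancy_percent: float | None
    flags: frozenset[str] = field(default_factory=frozenset)


def compute_site_occupancy(
    IN: float,
    INF: float,
    IND: float,
    site_id: str = "",
    low_signal_floor: float | None = None,
) -> OccupancyResult:
    """Percent occupancy ``(INF − IND) / (IN + INF) × 100``.

    ``IND > INF`` (spontaneous deamidation exceeding the enzymatic
    signal) yields a negative raw value, clamped to 0 and flagged rather
    than dropped. ``IN + INF = 0`` is flagged ``zero_denominator`` and
    leaves the occupancy unset. ``low_signal`` is raised when
    ``IN + INF`` falls below ``low_signal_floor``.
    """
    for name, val in (("IN", IN), ("INF", INF), ("IND", IND)):
        if val < 0 or not math.isfinite(val):
            raise InvalidInputError(f"{name} must be finite and >= 0, got {val}")
    flags: set[str] = set()
    denom = IN + INF
    if denom == 0:
        return OccupancyResult(
            site_id=site_id,
            IN=IN,
            INF=INF,
            IND=IND,
            raw_percent=float("nan"),
            occupancy_percent=None,
            flags=frozenset({"zero_denominator"}),
        )
    if low_signal_floor is not None and denom < low_signal_floor:
        flags.add("low_signal")
    raw = (INF - IND) / denom * 100.0
    clamped = raw
    if raw < 0:
        clamped = 0.0
        flags.add("negative_raw")
    return OccupancyResult(
        site_id=site_id,
        IN=IN,
        INF=INF,
        IND=IND,
        raw_percent=raw,
        occupancy_percent=clamped,
        flags=frozenset(flags),
    )


def _gather(measurements: Iterable[PeakMeasurement]) -> dict:
    """Sum normalized intensities per (site, sample, variant, run)."""
    acc: dict[tuple[str, str, Variant, RunCondition], float] = {}
    for m in measurements:
        if m.ion.variant is Variant.REFERENCE:
            continue
        if m.normalized_intensity is None:
            raise InvalidInputError("measurements must be normalized first")
        key = (m.site_id, m.sample_id, m.ion.variant, m.run_condition)
        acc[key] = acc.get(key, 0.0) + m.normalized_intensity
    return acc


def occupancy_table(
    normalization: NormalizationResult,
    low_signal_fraction: float = DEFAULT_LOW_SIGNAL_FRACTION,
) -> pd.DataFrame:
    """Assemble IN/INF/IND per glycosite × sample and compute occupancy.

    IN is the native-peptide intensity from the PNGase F run, INF the
    deamidated-peptide intensity from the PNGase F run, and IND the
    deamidated-peptide intensity from the no-enzyme control. A missing
    species contributes 0. Returns a tidy frame sorted by site then
    sample, one row per combination.
    """
    acc = _gather(normalization.measurements)
    floor = low_signal_fraction * normalization.baseline_reference_mean
    combos = sorted({(site, sample) for site, sample, _, _ in acc})
    rows = []
    for site, sample in combos:
        IN = acc.get((site, sample, Variant.NATIVE, RunCondition.PNGASEF), 0.0)
        INF = acc.get((site, sample, Variant.DEAMIDATED, RunCondition.PNGASEF), 0.0)
        IND = acc.get((site, sample, Variant.DEAMIDATED, RunCondition.CONTROL), 0.0)
        res = compute_site_occupancy(
            IN, INF, IND, site_id=site, low_signal_floor=floor
        )
        rows.append(
            {
                "site_id": site,
                "sample_id": sample,
                "IN": IN,
                "INF": INF,
                "IND": IND,
                "raw_percent": res.raw_percent,
                "occupancy_percent": res.occupancy_percent,
                "flags": ";".join(sorted(res.flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "sample_id",
            "IN",
            "INF",
            "IND",
            "raw_percent",
            "occupancy_percent",
            "flags",
        ],
    )
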