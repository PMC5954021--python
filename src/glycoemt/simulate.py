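"""Synthetic-data generators with known ground truth for every stage.

Occupancy runs are generated from a two-parameter latent model: a true
site-occupancy fraction ``theta`` and a spontaneous-deamidation fraction
``d``. With per-sample abundance ``A`` the expected intensities are

* ``IN  = A (1 − theta)(1 − d)``   (native peptide, PNGase F run)
* ``INF = A (theta + (1 − theta) d)``  (Asp peptide, PNGase F run)
* ``IND = A (1 − theta) d``        (Asp peptide, no-enzyme control)

so the occupancy formula recovers ``100·theta`` exactly in the absence
of noise, for any abundance and deamidation rate. Measurement noise is
multiplicative log-normal with a chosen coefficient of variation,
applied independently per intensity (MS peak intensities are positive
and roughly CV-stable). Reference peptides scale with abundance and
carry the same noise, so reference normalization is genuinely exercised.

Expression matrices have an epithelial/mesenchymal two-group structure:
mesenchymal-arm genes shift up (and epithelial-arm genes down) by
``effect`` log2 units in the mesenchymal group, optional linked genes
correlate with group membership at a requested level, and everything is
exponentiated back to a raw RSEM-like scale.

IHC tables draw a latent equicorrelated multivariate normal per
specimen and map it monotonically to percent positive (0–100) and an
intensity grade (0–3) via fixed latent-quantile cuts {0.25, 0.5, 0.75}.

These generators emulate structure, not realism: no isotope envelopes,
no retention-time drift, no real TCGA marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import REFERENCE_PEPTIDES
from .errors import InvalidInputError
from .glyco import (
    PeakMeasurement,
    PeptideIon,
    RunCondition,
    Scan,
    SpectrumSet,
    Variant,
    apply_deamidation,
    extract_xic,
    integrate_trace,
)
from .emt import EMTSignature, ExpressionMatrix

__all__ = [
    "OccupancySimParams",
    "ExpressionSimParams",
    "ExpressionSim",
    "DEFAULT_GLYCOPEPTIDES",
    "simulate_occupancy_runs",
    "simulate_spectra",
    "requantify_from_spectra",
    "simulate_expression",
    "simulate_ihc",
]

# Synthetic sequon-bearing tryptic peptides: site -> (sequence, charge,
# 1-based Asn position of the N-X-S/T sequon). Site ids are opaque labels.
DEFAULT_GLYCOPEPTIDES: dict[str, tuple[str, int, int]] = {
    "site1": ("LFNVTSTLR", 2, 3),
}

_IHC_GRADE_CUTS = (0.25, 0.5, 0.75)  # latent-quantile cuts for grades 0-3


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class OccupancySimParams:
    """Latent generative parameters for MS occupancy runs.

    ``theta`` and ``d`` are the generator's own parameters; only the
    intensities they induce correspond to observable quantities.
    """

    theta: float
    d: float = 0.1
    abundance: float | Sequence[float] = 1.0
    noise_cv: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    sites: Mapping[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_GLYCOPEPTIDES)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise InvalidInputError(f"theta must be in [0, 1], got {self.theta}")
        if not 0.0 <= self.d < 1.0:
            raise InvalidInputError(f"d must be in [0, 1), got {self.d}")
        if self.noise_cv < 0:
            raise InvalidInputError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        abund = self.abundance
        if np.isscalar(abund):
            abund = tuple([float(abund)] * self.n_replicates)  # type: ignore[list-item]
        else:
            abund = tuple(float(a) for a in abund)  # type: ignore[union-attr]
            if len(abund) != self.n_replicates:
                raise InvalidInputError("abundance length must equal n_replicates")
        if any(a <= 0 for a in abund):
            raise InvalidInputError("abundance must be positive")
        object.__setattr__(self, "abundance", abund)


def simulate_occupancy_runs(params: OccupancySimParams) -> list[PeakMeasurement]:
    """Generate a peak table for both run conditions, references included.

    One sample per replicate (``rep1`` …), each carrying the native and
    deamidated glycopeptide ions and both reference peptides in both the
    PNGase F and control runs. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    theta, d = params.theta, params.d
    rows: list[PeakMeasurement] = []
    ref_ions = [
        PeptideIon(sequence=seq, charge=z, variant=Variant.REFERENCE)
        for seq, z in REFERENCE_PEPTIDES.items()
    ]
    site_ions = {}
    for site_id, (seq, charge, n_pos) in params.sites.items():
        native = PeptideIon(sequence=seq, charge=charge, variant=Variant.NATIVE)
        site_ions[site_id] = (native, apply_deamidation(native, n_pos))

    for rep, A in enumerate(params.abundance, start=1):
        sample = f"rep{rep}"
        for run in (RunCondition.PNGASEF, RunCondition.CONTROL):
            for site_id, (native, deamid) in site_ions.items():
                if run is RunCondition.PNGASEF:
                    native_i = A * (1 - theta) * (1 - d)
                    deamid_i = A * (theta + (1 - theta) * d)
                else:
                    native_i = A * (1 - theta) * (1 - d)
                    deamid_i = A * (1 - theta) * d
                noise = _lognormal_factors(rng, params.noise_cv, 2)
                rows.append(
                    PeakMeasurement(
                        sample_id=sample,
                        run_condition=run,
                        ion=native,
                        intensity=native_i * noise[0],
                        site_id=site_id,
                    )
                )
                rows.append(
                    PeakMeasurement(
                        sample_id=sample,
                        run_condition=run,
                        ion=deamid,
                        intensity=deamid_i * noise[1],
                        site_id=site_id,
                    )
                )
            noise = _lognormal_factors(rng, params.noise_cv, len(ref_ions))
            for ion, nf in zip(ref_ions, noise):
                rows.append(
                    PeakMeasurement(
                        sample_id=sample,
                        run_condition=run,
                        ion=ion,
                        intensity=A * nf,
                        site_id="",
                    )
                )
    return rows


def simulate_spectra(
    peak_table: Sequence[PeakMeasurement],
    rt_center: float = 10.0,
    rt_sigma: float = 0.5,
    mz_jitter_ppm: float = 0.0,
    n_scans: int = 50,
    seed: int = 0,
) -> dict[tuple[str, str], SpectrumSet]:
    """Render a peak table as Gaussian elution profiles in centroid scans.

    Each (sample, run) pair becomes one :class:`SpectrumSet` whose scans
    span ``rt_center ± 4·rt_sigma``. Every ion contributes a Gaussian
    profile whose trapezoidal area equals its table intensity; centroid
    m/z is the ion's theoretical value perturbed by Gaussian jitter of
    scale ``mz_jitter_ppm``. Deterministic under a fixed seed.
    """
    if n_scans < 3:
        raise InvalidInputError("n_scans must be >= 3")
    rng = np.random.default_rng(seed)
    rts = np.linspace(rt_center - 4 * rt_sigma, rt_center + 4 * rt_sigma, n_scans)
    groups: dict[tuple[str, str], list[PeakMeasurement]] = {}
    for m in peak_table:
        groups.setdefault((m.sample_id, m.run_condition.value), []).append(m)

    out: dict[tuple[str, str], SpectrumSet] = {}
    for key in sorted(groups):
        members = groups[key]
        profile = stats.norm.pdf(rts, loc=rt_center, scale=rt_sigma)
        # intensity matrix: ions × scans
        inten = np.array([m.intensity for m in members])[:, None] * profile[None, :]
        base_mz = np.array([m.ion.mz for m in members])
        jitter = rng.normal(0.0, mz_jitter_ppm * 1e-6, size=(len(members), n_scans))
        mz = base_mz[:, None] * (1.0 + jitter)
        scans = []
        for k, rt in enumerate(rts):
            order = np.argsort(mz[:, k], kind="stable")
            scans.append(
                Scan(
                    retention_time=float(rt),
                    mz_values=mz[order, k],
                    intensities=inten[order, k],
                )
            )
        out[key] = SpectrumSet(scans=tuple(scans))
    return out


def requantify_from_spectra(
    peak_table: Sequence[PeakMeasurement],
    spectra: Mapping[tuple[str, str], SpectrumSet],
    ppm_tol: float = 10.0,
) -> list[PeakMeasurement]:
    """Re-quantify every table ion from the spectra via XIC integration.

    Returns a new peak table whose intensities are integrated XIC areas
    at each ion's theoretical m/z, i.e. the full extraction path rather
    than the generator's ground-truth intensities.
    """
    out = []
    for m in peak_table:
        spectrum_set = spectra[(m.sample_id, m.run_condition.value)]
        trace = extract_xic(spectrum_set, m.ion.mz, ppm_tol)
        out.append(replace(m, intensity=integrate_trace(trace)))
    return out


@dataclass(frozen=True)
class ExpressionSimParams:
    """Two-group expression-matrix generative parameters."""

    n_epithelial: int = 50
    n_mesenchymal: int = 50
    effect: float = 1.0
    noise_sd: float = 0.5
    linked_genes: Mapping[str, float] = field(default_factory=dict)
    n_background: int = 20
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epithelial < 2 or self.n_mesenchymal < 2:
            raise InvalidInputError("group sizes must be >= 2")
        if self.noise_sd <= 0:
            raise InvalidInputError("noise_sd must be positive")
        for gene, rho in self.linked_genes.items():
            if not abs(rho) < 1:
                raise InvalidInputError(
                    f"linked-gene correlation for {gene!r} must satisfy |rho| < 1"
                )


@dataclass(frozen=True)
class ExpressionSim:
    """Simulated matrix plus the true per-sample group labels."""

    matrix: ExpressionMatrix
    groups: pd.Series  # 'epithelial' or 'mesenchymal' per sample


def simulate_expression(
    params: ExpressionSimParams, signature: EMTSignature
) -> ExpressionSim:
    """Simulate a raw-space gene × sample matrix with EMT group structure.

    Per-gene baselines are drawn once; mesenchymal-arm genes gain
    ``+effect`` and epithelial-arm genes ``−effect`` log2 units in the
    mesenchymal group; linked genes are tied to the group label at the
    requested point-biserial correlation; independent Gaussian noise of
    ``noise_sd`` log2 units is added everywhere, then values return to
    raw space as powers of two. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_epithelial + params.n_mesenchymal
    labels = np.r_[
        np.zeros(params.n_epithelial, dtype=int),
        np.ones(params.n_mesenchymal, dtype=int),
    ]
    sample_ids = [
        f"EPI{i + 1:03d}" for i in range(params.n_epithelial)
    ] + [f"MES{i + 1:03d}" for i in range(params.n_mesenchymal)]

    arm_shift: dict[str, float] = {}
    for g in signature.mesenchymal_genes:
        arm_shift[g] = params.effect
    for g in signature.epithelial_genes:
        arm_shift[g] = -params.effect

    linked = dict(params.linked_genes)
    collisions = set(linked) & set(arm_shift)
    if collisions:
        import warnings

        warnings.warn(
            f"linked genes override signature membership: {sorted(collisions)}",
            stacklevel=2,
        )
        for g in collisions:
            del arm_shift[g]

    genes = (
        list(signature.mesenchymal_genes)
        + list(signature.epithelial_genes)
        + [g for g in linked if g not in arm_shift]
        + [f"BG{i + 1:03d}" for i in range(params.n_background)]
    )
    genes = list(dict.fromkeys(genes))

    z_label = (labels - labels.mean()) / labels.std()
    log2 = np.empty((len(genes), n))
    for i, gene in enumerate(genes):
        baseline = rng.normal(params.baseline_mean, params.baseline_sd)
        row = baseline + rng.normal(0.0, params.noise_sd, size=n)
        if gene in arm_shift:
            row = row + arm_shift[gene] * labels
        if gene in linked:
            rho = linked[gene]
            beta = params.noise_sd * rho / math.sqrt(1.0 - rho * rho)
            row = row + beta * z_label
        log2[i] = row
    raw = np.power(2.0, log2)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(raw, index=genes, columns=sample_ids), space="raw"
    )
    groups = pd.Series(
        np.where(labels == 1, "mesenchymal", "epithelial"),
        index=sample_ids,
        name="group",
    )
    return ExpressionSim(matrix=matrix, groups=groups)


def simulate_ihc(
    n: int,
    rho: float,
    markers: Sequence[str] = ("STT3A", "PDL1"),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format IHC table with latent marker co-expression.

    Each specimen draws a latent equicorrelated multivariate normal
    across markers; percent positive is ``100·Φ(z)`` and the intensity
    grade cuts the latent quantile at {0.25, 0.5, 0.75}. Deterministic
    under a fixed seed.
    """
    if n < 3:
        raise InvalidInputError("need at least 3 specimens")
    if not abs(rho) < 1:
        raise InvalidInputError(f"|rho| must be < 1, got {rho}")
    if len(markers) < 2:
        raise InvalidInputError("need at least 2 markers")
    rng = np.random.default_rng(seed)
    k = len(markers)
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    u = stats.norm.cdf(z)
    grade = np.searchsorted(_IHC_GRADE_CUTS, u)
    rows = []
    for i in range(n):
        for j, marker in enumerate(markers):
            rows.append(
                {
                    "specimen_id": f"spec{i + 1:04d}",
                    "marker": marker,
                    "percent_positive": round(100.0 * u[i, j], 1),
                    "intensity": int(grade[i, j]),
                }
            )
    return pd.DataFrame(rows)
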