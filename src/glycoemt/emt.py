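"""EMT signature scoring of gene × sample expression matrices.

The score follows the two-arm mean-difference convention: transform the
raw matrix to gene-wise log2 ratios (0 = unchanged for that gene), then
per sample take the mean log ratio over the mesenchymal-arm genes minus
the mean over the epithelial-arm genes. Higher scores are more
mesenchymal-like. Gene–score and gene–gene association use Pearson
correlation with a two-sided p-value.

Heatmap colors mirror the usual clustering-viewer conventions: for
expression, 0 is black ramping to red (positive) or green (negative);
for the EMT score, 0 is gray ramping to yellow (mesenchymal) or blue
(epithelial), with intensity scaling with magnitude up to ``vmax``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidInputError,
    UndefinedCorrelationError,
    UnusableSignatureError,
)

__all__ = [
    "ExpressionMatrix",
    "EMTSignature",
    "EMTScores",
    "CorrelationResult",
    "load_signature",
    "log_ratio_transform",
    "emt_score",
    "correlate",
    "heatmap_colors",
]

_ZERO_COLORS = {"expression": (0, 0, 0), "emt_score": (128, 128, 128)}
_POS_COLORS = {"expression": (255, 0, 0), "emt_score": (255, 255, 0)}
_NEG_COLORS = {"expression": (0, 255, 0), "emt_score": (0, 0, 255)}
DEFAULT_VMAX = {"expression": 3.0, "emt_score": 1.0}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene × sample expression values in ``raw`` or ``log_ratio`` space."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    space: Literal["raw", "log_ratio"] = "raw"

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise InvalidInputError("duplicate gene identifiers")
        if df.columns.has_duplicates:
            raise InvalidInputError("duplicate sample identifiers")
        if self.space not in ("raw", "log_ratio"):
            raise InvalidInputError(f"unknown space {self.space!r}")
        if self.space == "raw" and (df.to_numpy() < 0).any():
            raise InvalidInputError("raw-space values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class EMTSignature:
    """Two-arm EMT gene signature (disjoint, non-empty arms)."""

    mesenchymal_genes: tuple[str, ...]
    epithelial_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        mes = tuple(g.strip() for g in self.mesenchymal_genes)
        epi = tuple(g.strip() for g in self.epithelial_genes)
        if not mes or not epi:
            raise InvalidInputError("both signature arms must be non-empty")
        if set(mes) & set(epi):
            raise InvalidInputError("signature arms must be disjoint")
        object.__setattr__(self, "mesenchymal_genes", mes)
        object.__setattr__(self, "epithelial_genes", epi)

    def swapped(self) -> "EMTSignature":
        return EMTSignature(self.epithelial_genes, self.mesenchymal_genes)

    def __len__(self) -> int:
        return len(self.mesenchymal_genes) + len(self.epithelial_genes)


@dataclass(frozen=True)
class EMTScores:
    """Per-sample EMT scores with per-arm signature coverage."""

    scores: pd.Series  # index = sample ids
    coverage_mesenchymal: float
    coverage_epithelial: float
    genes_used_mesenchymal: tuple[str, ...]
    genes_used_epithelial: tuple[str, ...]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-sided p-value and the sample count used."""

    r: float
    p_value: float
    n: int


def load_signature(path: str | None = None) -> EMTSignature:
    """Load a two-arm signature from TSV (columns ``gene``, ``arm``).

    With no path, loads the packaged 37-gene fixture
    (``emt_signature_synthetic.tsv``): a synthetic stand-in carrying 20
    canonical mesenchymal and 17 canonical epithelial gene symbols with
    the two-arm structure the scorer expects.
    """
    if path is None:
        ref = resources.files("glycoemt.data") / "emt_signature_synthetic.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("gene", "arm"):
        if col not in df.columns:
            raise InvalidInputError(f"signature file missing column {col!r}")
    bad = set(df["arm"]) - {"mesenchymal", "epithelial"}
    if bad:
        raise InvalidInputError(f"unknown signature arm(s): {sorted(bad)}")
    return EMTSignature(
        mesenchymal_genes=tuple(df.loc[df["arm"] == "mesenchymal", "gene"]),
        epithelial_genes=tuple(df.loc[df["arm"] == "epithelial", "gene"]),
    )


def log_ratio_transform(
    matrix: ExpressionMatrix,
    pseudocount: float = 1.0,
    center: Literal["median", "mean"] = "median",
) -> ExpressionMatrix:
    """log2(x + pseudocount), then gene-wise centering across samples.

    After centering, 0 means "unchanged relative to this gene's typical
    level". Centering statistic is the median by default (mean exposed
    for comparison). A zero value with pseudocount 0 is a domain error.
    """
    if matrix.space != "raw":
        raise InvalidInputError("log_ratio_transform expects a raw-space matrix")
    if pseudocount < 0:
        raise InvalidInputError("pseudocount must be >= 0")
    vals = matrix.values.to_numpy(dtype=float)
    if pseudocount == 0 and (vals == 0).any():
        raise InvalidInputError(
            "matrix contains zeros; use a positive pseudocount"
        )
    logged = np.log2(vals + pseudocount)
    if center == "median":
        centers = np.median(logged, axis=1, keepdims=True)
    elif center == "mean":
        centers = logged.mean(axis=1, keepdims=True)
    else:
        raise InvalidInputError(f"unknown centering {center!r}")
    out = pd.DataFrame(
        logged - centers, index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(values=out, space="log_ratio")


def emt_score(matrix: ExpressionMatrix, signature: EMTSignature) -> EMTScores:
    """Mean mesenchymal-arm log ratio minus mean epithelial-arm log ratio.

    Signature genes absent from the matrix are dropped with a warning;
    an arm with no matching genes at all is fatal.
    """
    if matrix.space != "log_ratio":
        raise InvalidInputError("emt_score expects a log_ratio-space matrix")
    present = set(matrix.values.index)
    used = {}
    for arm_name, genes in (
        ("mesenchymal", signature.mesenchymal_genes),
        ("epithelial", signature.epithelial_genes),
    ):
        found = tuple(g for g in genes if g in present)
        missing = [g for g in genes if g not in present]
        if not found:
            raise UnusableSignatureError(
                f"no {arm_name}-arm signature genes found in the matrix"
            )
        if missing:
            warnings.warn(
                f"{len(missing)} {arm_name}-arm gene(s) absent from matrix: "
                f"{missing}",
                stacklevel=2,
            )
        used[arm_name] = found
    mes_mean = matrix.values.loc[list(used["mesenchymal"])].mean(axis=0)
    epi_mean = matrix.values.loc[list(used["epithelial"])].mean(axis=0)
    scores = (mes_mean - epi_mean).rename("emt_score")
    return EMTScores(
        scores=scores,
        coverage_mesenchymal=len(used["mesenchymal"])
        / len(signature.mesenchymal_genes),
        coverage_epithelial=len(used["epithelial"]) / len(signature.epithelial_genes),
        genes_used_mesenchymal=used["mesenchymal"],
        genes_used_epithelial=used["epithelial"],
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with two-sided p-value (requires n ≥ 3)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidInputError("x and y must be 1-D vectors of equal length")
    n = len(xa)
    if n < 3:
        raise InvalidInputError(f"need at least 3 observations, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def heatmap_colors(
    values: Sequence[float],
    kind: Literal["expression", "emt_score"],
    vmax: float | None = None,
) -> list[tuple[int, int, int]]:
    """Map values to RGB triples by a linear two-hue ramp around zero.

    Zero maps to the neutral color (black for expression, gray for the
    EMT score); magnitudes ramp linearly to the full positive/negative
    hue at ``|value| >= vmax``.
    """
    if kind not in _ZERO_COLORS:
        raise InvalidInputError(f"unknown heatmap kind {kind!r}")
    if vmax is None:
        vmax = DEFAULT_VMAX[kind]
    if vmax <= 0:
        raise InvalidInputError("vmax must be positive")
    zero = np.array(_ZERO_COLORS[kind], dtype=float)
    out = []
    for v in np.asarray(values, dtype=float):
        hue = np.array(_POS_COLORS[kind] if v >= 0 else _NEG_COLORS[kind], float)
        t = min(abs(v) / vmax, 1.0)
        rgb = np.rint(zero + t * (hue - zero)).astype(int)
        out.append((int(rgb[0]), int(rgb[1]), int(rgb[2])))
    return out
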