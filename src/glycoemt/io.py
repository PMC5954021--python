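"""Readers/writers for the pipeline's table formats and run logs.

Tables are plain CSV/TSV with header rows. Centroided spectra use a
compact mzML 1.1 reader/writer pair implemented here: the reader walks
the document with the stdlib XML parser and decodes base64 binary
arrays (32/64-bit floats, plain or zlib-compressed); the writer emits
uncompressed 64-bit arrays. Only MS1 centroid data and scan start times
are interpreted — enough for XIC extraction.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from pathlib import Path
from typing import Mapping, Sequence
from xml.sax.saxutils import escape

import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

from . import __version__
from .constants import constants_hash
from .errors import InvalidInputError
from .glyco import (
    PeakMeasurement,
    PeptideIon,
    RunCondition,
    Scan,
    SpectrumSet,
    Variant,
)

PEAK_COLUMNS = ["sample_id", "run_condition", "peptide", "variant", "site_id", "intensity"]


def _ion_from_fields(
    peptide: str,
    variant: str,
    charge: int,
    deamidation_positions: str | None,
    line_no: int,
) -> PeptideIon:
    variant = Variant(variant)
    positions: tuple[int, ...] = ()
    if variant is Variant.DEAMIDATED:
        if deamidation_positions:
            positions = tuple(
                int(p) for p in str(deamidation_positions).split(";") if p
            )
        else:
            # default: the first Asn of the sequence is the sequon site
            idx = peptide.find("N")
            if idx < 0:
                raise InvalidInputError(
                    f"line {line_no}: deamidated peptide {peptide!r} has no Asn"
                )
            positions = (idx + 1,)
    return PeptideIon(
        sequence=peptide,
        charge=charge,
        variant=variant,
        deamidation_positions=positions,
    )


def read_peak_table(path: str | Path, default_charge: int = 2) -> list[PeakMeasurement]:
    """Read a peak-intensity CSV into measurements.

    Required columns: sample_id, run_condition, peptide, variant,
    site_id, intensity. Optional: charge, deamidation_positions
    (semicolon-separated 1-based indices; defaults to the first Asn).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed file
        raise InvalidInputError(f"cannot parse peak table {path}: {exc}") from exc
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"peak table {path} missing column(s) {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            charge = int(d.get("charge") or default_charge)
            ion = _ion_from_fields(
                d["peptide"], d["variant"], charge, d.get("deamidation_positions"), i
            )
            out.append(
                PeakMeasurement(
                    sample_id=d["sample_id"],
                    run_condition=RunCondition(d["run_condition"]),
                    ion=ion,
                    intensity=float(d["intensity"]),
                    site_id=d["site_id"],
                )
            )
        except (ValueError, KeyError) as exc:
            raise InvalidInputError(f"line {i} of {path}: {exc}") from exc
    return out


def write_peak_table(measurements: Sequence[PeakMeasurement], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "run_condition": m.run_condition.value,
            "peptide": m.ion.sequence,
            "variant": m.ion.variant.value,
            "site_id": m.site_id,
            "intensity": f"{m.intensity:.10g}",
            "charge": m.ion.charge,
            "deamidation_positions": ";".join(
                str(p) for p in m.ion.deamidation_positions
            ),
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_peptide_definitions(path: str | Path) -> dict[str, list[PeptideIon]]:
    """Read a TSV of site_id, sequence, charge, variant (+ optional
    deamidation_positions) into per-site ion lists for mzML extraction."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("site_id", "sequence", "charge", "variant"):
        if col not in df.columns:
            raise InvalidInputError(f"peptide definitions missing column {col!r}")
    defs: dict[str, list[PeptideIon]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        ion = _ion_from_fields(
            d["sequence"], d["variant"], int(d["charge"]),
            d.get("deamidation_positions"), i,
        )
        defs.setdefault(d["site_id"], []).append(ion)
    return defs


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Gene × sample TSV: first column gene ids, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    return df


# ---------------------------------------------------------------------------
# mzML


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem: ET.Element) -> dict[str, str]:
    return {
        child.get("accession", ""): child.get("value", "")
        for child in elem
        if _local(child.tag) == "cvParam"
    }


def _decode_binary_array(bda: ET.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind accession, values)."""
    params: dict[str, str] = {}
    binary_text = ""
    for child in bda.iter():
        if _local(child.tag) == "cvParam":
            params[child.get("accession", "")] = child.get("value", "")
        elif _local(child.tag) == "binary":
            binary_text = child.text or ""
    raw = base64.b64decode(binary_text)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # 32- vs 64-bit float
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = next(
        (acc for acc in ("MS:1000514", "MS:1000515") if acc in params), None
    )
    return kind, values


def read_mzml(path: str | Path) -> SpectrumSet:
    """Read centroided MS1 scans from an mzML file into a SpectrumSet.

    Understands plain or zlib-compressed 32/64-bit float arrays; scan
    start times recorded in seconds are converted to minutes.
    """
    scans = []
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        top_params = _cv_params(elem)
        if top_params.get("MS:1000511", "1") not in ("", "1"):
            elem.clear()
            continue
        rt_min = None
        for sub in elem.iter():
            if _local(sub.tag) == "scan":
                for p in sub:
                    if (
                        _local(p.tag) == "cvParam"
                        and p.get("accession") == "MS:1000016"
                    ):
                        rt = float(p.get("value", "0"))
                        unit = p.get("unitName", "minute")
                        rt_min = rt / 60.0 if unit.startswith("second") else rt
        arrays: dict[str, np.ndarray] = {}
        for sub in elem.iter():
            if _local(sub.tag) == "binaryDataArray":
                kind, values = _decode_binary_array(sub)
                if kind:
                    arrays[kind] = values
        if rt_min is None or "MS:1000514" not in arrays:
            raise InvalidInputError(
                f"{path}: spectrum without scan start time or m/z array"
            )
        mz = arrays["MS:1000514"]
        inten = arrays.get("MS:1000515", np.zeros_like(mz))
        order = np.argsort(mz, kind="stable")
        scans.append(
            Scan(retention_time=rt_min, mz_values=mz[order], intensities=inten[order])
        )
        elem.clear()
    scans.sort(key=lambda s: s.retention_time)
    return SpectrumSet(scans=tuple(scans))


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode()


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{length}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(spectra: SpectrumSet, path: str | Path, run_id: str = "run1") -> None:
    """Serialize a SpectrumSet as minimal centroided mzML 1.1."""
    parts = [_MZML_HEADER.format(run_id=escape(run_id), count=len(spectra.scans))]
    for i, scan in enumerate(spectra.scans):
        mz_b64 = _b64_doubles(scan.mz_values)
        int_b64 = _b64_doubles(scan.intensities)
        parts.append(
            _MZML_SPECTRUM.format(
                index=i,
                scan=i + 1,
                length=len(scan.mz_values),
                rt=scan.retention_time,
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


# ---------------------------------------------------------------------------
# run logs


def write_run_log(
    path: str | Path,
    subcommand: str,
    inputs: Mapping[str, object],
    parameters: Mapping[str, object],
) -> None:
    """JSON run log: inputs, parameters, tool version, constants hash.

    Content is deterministic (no timestamps) so identical runs produce
    byte-identical logs.
    """
    log = {
        "tool": "glycoemt",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": dict(inputs),
        "parameters": dict(parameters),
        "constants_hash": constants_hash(),
    }
    Path(path).write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
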