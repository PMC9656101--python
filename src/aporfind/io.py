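"""Spectral file I/O (MGF, minimal mzML), report writing, run configuration.

MGF and mzML parsing is delegated to pyteomics; this module maps its records
onto :class:`~aporfind.spectrum.Spectrum` and enforces the package's
conventions: retention time in minutes internally (MGF RTINSECONDS is
converted on read), peak m/z serialized at 4 decimals, intensities as
integers, reports byte-stable for identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .annotate import RunReport
from .spectrum import Spectrum

__all__ = [
    "RunConfig",
    "read_mgf",
    "read_mzml",
    "write_mgf",
    "write_report",
    "write_manifest",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline settings; serializable to/from a YAML file.

    Defaults mirror the acquisition/processing settings of the alkaloid
    screen: 5/10 ppm MS1/MS2 tolerances, 1.5-mDa absolute floor, minimum
    peak intensity 10,000, 3.0 m/z isolation window, element bounds
    C30/H60/N10/O20.
    """

    ms1_ppm: float = 5.0
    ms2_ppm: float = 10.0
    floor_mda: float = 1.5
    min_intensity: float = 10_000.0
    rt_window_min: float | None = None
    isolation_window_mz: float = 3.0
    element_bounds: dict = field(
        default_factory=lambda: {"C": 30, "H": 60, "N": 10, "O": 20}
    )
    library: str = "builtin"
    output: str = "report.csv"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _spectrum_from_record(
    rec: dict, fallback_id: str
) -> Spectrum | None:
    params = rec.get("params", {})
    pepmass = params.get("pepmass")
    if not pepmass or pepmass[0] is None:
        logger.warning("block %s: missing PEPMASS, skipped", fallback_id)
        return None
    rt = None
    if "rtinseconds" in params:
        rt = float(params["rtinseconds"]) / 60.0
    title = str(params.get("title", fallback_id))
    peaks = tuple(
        (float(mz), float(inten))
        for mz, inten in zip(rec["m/z array"], rec["intensity array"])
    )
    meta = tuple(
        (k, str(v))
        for k, v in params.items()
        if k not in ("pepmass", "rtinseconds", "title", "charge")
    )
    return Spectrum(
        spectrum_id=title,
        precursor_mz=float(pepmass[0]),
        peaks=peaks,
        rt=rt,
        metadata=meta,
    )


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read a Mascot generic format file into Spectrum records.

    The first PEPMASS token is the precursor m/z; RTINSECONDS is converted
    to minutes; blocks without PEPMASS are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, rec in enumerate(reader):
            spec = _spectrum_from_record(rec, f"spectrum_{i}")
            if spec is not None:
                spectra.append(spec)
    return spectra


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, tuple[str, str]]:
    """accession -> (value, unitName) for the element's direct cvParams."""
    out = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = (
                child.get("value", ""),
                child.get("unitName", ""),
            )
    return out


def _decode_binary_array(array_element) -> tuple[str, "list[float]"]:
    """Decode one <binaryDataArray>: returns (kind, values).

    Supports 64/32-bit floats, optionally zlib-compressed — the minimal
    read contract for converter-produced centroid mzML.
    """
    import base64
    import struct
    import zlib

    params = _cv_params(array_element)
    kind = (
        "mz" if "MS:1000514" in params
        else "intensity" if "MS:1000515" in params
        else "other"
    )
    fmt = "f" if "MS:1000521" in params else "d"
    binary = next(
        (c for c in array_element if _local(c.tag) == "binary"), None
    )
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    width = 4 if fmt == "f" else 8
    values = list(struct.unpack(f"<{len(raw) // width}{fmt}", raw))
    return kind, values


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read MS2 spectra from an mzML file (minimal, read-only contract).

    Non-MS2 scans are ignored.  The selected-ion m/z is the precursor; scan
    start time is converted to minutes when expressed in seconds.  Malformed
    XML raises with the parser's line/column position.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    for _, element in ET.iterparse(str(path), events=("end",)):
        if _local(element.tag) != "spectrum":
            continue
        params = _cv_params(element)
        if params.get("MS:1000511", ("",))[0] != "2":
            element.clear()
            continue
        precursor = None
        rt = None
        mzs: list[float] = []
        intens: list[float] = []
        for node in element.iter():
            tag = _local(node.tag)
            if tag == "selectedIon":
                ion_params = _cv_params(node)
                if "MS:1000744" in ion_params:
                    precursor = float(ion_params["MS:1000744"][0])
            elif tag == "scan":
                scan_params = _cv_params(node)
                if "MS:1000016" in scan_params:
                    value, unit = scan_params["MS:1000016"]
                    rt = float(value) / 60.0 if unit == "second" else float(value)
            elif tag == "binaryDataArray":
                kind, values = _decode_binary_array(node)
                if kind == "mz":
                    mzs = values
                elif kind == "intensity":
                    intens = values
        if precursor is None:
            logger.warning(
                "scan %s: no selected ion m/z, skipped", element.get("id")
            )
            element.clear()
            continue
        spectra.append(
            Spectrum(
                spectrum_id=str(element.get("id", f"scan={len(spectra)}")),
                precursor_mz=precursor,
                peaks=tuple(zip(mzs, intens)),
                rt=rt,
            )
        )
        element.clear()
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF: peak m/z at 4 decimals, integer intensities.

    Output is bit-stable for identical inputs.
    """
    lines: list[str] = []
    for spec in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={spec.spectrum_id}")
        lines.append(f"PEPMASS={spec.precursor_mz:.4f}")
        if spec.rt is not None:
            lines.append(f"RTINSECONDS={spec.rt * 60.0:.4f}")
        for key, value in spec.metadata:
            lines.append(f"{key.upper()}={value}")
        for mz, inten in spec.peaks:
            lines.append(f"{mz:.4f} {int(round(inten))}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


_REPORT_FORMATS = {
    "rt_min": "{:.2f}",
    "experimental_mz": "{:.4f}",
    "theoretical_mz": "{:.4f}",
    "ppm_error": "{:.2f}",
}


def write_report(report: RunReport | pd.DataFrame, path: str | Path) -> None:
    """Write an annotation report CSV with fixed column order and formatting.

    m/z columns carry 4 decimals and ppm errors 2; an empty annotation set
    yields a header-only CSV.  Identical inputs produce byte-identical files.
    """
    table = report.table if isinstance(report, RunReport) else report
    out = table.copy()
    for col, fmt in _REPORT_FORMATS.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v, f=fmt: "" if pd.isna(v) else f.format(v)
            )
    out.to_csv(path, index=False, lineterminator="\n")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    """Write a fixture manifest CSV (stable ordering and formatting)."""
    manifest.to_csv(path, index=False, lineterminator="\n")
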