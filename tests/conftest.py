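"""Shared fixtures: curated library, fixture spectra, minimal mzML writer."""

from __future__ import annotations

import base64
import struct

import pytest

from aporfind import build_fixture_set, load_curated_library
from aporfind.spectrum import Spectrum


@pytest.fixture(scope="session")
def library():
    return load_curated_library()


@pytest.fixture(scope="session")
def fixture_set():
    return build_fixture_set()


@pytest.fixture(scope="session")
def fixture_spectra(fixture_set):
    return fixture_set[0]


@pytest.fixture(scope="session")
def manifest(fixture_set):
    return fixture_set[1]


def _b64_doubles(values) -> str:
    return base64.b64encode(
        struct.pack(f"<{len(values)}d", *values)
    ).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="UNIT-ONTOLOGY" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="{sid}" defaultArrayLength="{npeaks}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{mslevel}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_s}" unitAccession="UO:0000010" unitName="second" unitCvRef="UO"/>
          </scan>
        </scanList>
{precursor}        <binaryDataArrayList count="2">
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

_MZML_PRECURSOR = """        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{mz}"/>
              </selectedIon>
            </selectedIonList>
          </precursor>
        </precursorList>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_minimal_mzml(spectra: list[Spectrum], path, ms_level: int = 2) -> None:
    """Serialize spectra as a minimal uncompressed mzML (test-only helper)."""
    parts = [_MZML_HEADER.format(count=len(spectra))]
    for i, spec in enumerate(spectra):
        mzs = [mz for mz, _ in spec.peaks]
        intens = [inten for _, inten in spec.peaks]
        mz_b64, int_b64 = _b64_doubles(mzs), _b64_doubles(intens)
        precursor = (
            _MZML_PRECURSOR.format(mz=f"{spec.precursor_mz:.4f}")
            if ms_level == 2
            else ""
        )
        parts.append(
            _MZML_SPECTRUM.format(
                index=i,
                sid=spec.spectrum_id,
                npeaks=len(mzs),
                mslevel=ms_level,
                rt_s=f"{(spec.rt or 0.0) * 60.0:.4f}",
                precursor=precursor,
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    path.write_text("".join(parts))
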