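"""In-paper fixture spectra and randomized synthetic variants.

The study's raw data were never deposited, so the packaged fixture set
re-creates each of the 70 identifications from what the publication prints:
the experimental precursor m/z and retention time of every peak, and the
per-compound (or isomer-group) fragment m/z list from the identification
text.  Fragment intensities are synthetic — the paper prints only a handful
of relative abundances (used where given, for the lirinidine group);
elsewhere a rank-decreasing geometric profile is assigned, always at or
above the 10,000-count intensity floor so that intensity filtering never
removes fixture evidence.

Randomized variants (seeded ppm jitter, decoy precursors) provide the
robustness and negative-control harnesses; all are pure functions of their
parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formula import ppm_error
from .library import CandidateCompound, load_curated_library
from .rules import NitrogenClass
from .spectrum import Spectrum

__all__ = [
    "build_fixture_set",
    "jitter_spectra",
    "make_decoy_spectra",
]

#: relative abundances printed for the lirinidine isomer group, e.g.
#: "237.0911(100)"; every other fixture intensity is synthetic.
_PRINTED_ABUNDANCE = {
    (58.0660, "lirinidine"): 90,
    (191.0855, "lirinidine"): 5,
    (219.0806, "lirinidine"): 23,
    (237.0911, "lirinidine"): 100,
}

INTENSITY_FLOOR = 10_000.0


def _intensities(entry: CandidateCompound) -> tuple[float, ...]:
    group = "lirinidine" if entry.name.startswith("lirinidine") else ""
    out = []
    for i, frag in enumerate(entry.reference_fragments):
        printed = _PRINTED_ABUNDANCE.get((frag, group))
        if printed is not None:
            out.append(INTENSITY_FLOOR + printed * INTENSITY_FLOOR)
        else:
            out.append(max(float(round(1_000_000.0 * 0.6**i)), INTENSITY_FLOOR))
    return tuple(out)


def build_fixture_set() -> tuple[list[Spectrum], pd.DataFrame]:
    """The 70 fixture spectra plus their manifest.

    Each spectrum's precursor is the recorded *experimental* mass and its RT
    the recorded retention time.  The manifest carries, per peak: the
    expected identification and nitrogen class, the class its printed
    fragment list actually supports (``fragment_class``), whether the two
    agree (``class_consistent``), and the curation errata note.  A
    mass-inconsistent entry raises naming the peak.
    """
    spectra: list[Spectrum] = []
    rows = []
    for entry in load_curated_library():
        err = ppm_error(entry.experimental_mz, entry.theoretical_mz)
        if abs(err) > 5.0:
            raise ValueError(
                f"fixture peak {entry.peak_id}: experimental mass is "
                f"{err:+.2f} ppm from theory"
            )
        peaks = tuple(
            zip(entry.reference_fragments, _intensities(entry))
        )
        spectra.append(
            Spectrum(
                spectrum_id=f"peak_{int(entry.peak_id):02d}",
                precursor_mz=entry.experimental_mz,
                peaks=peaks,
                rt=entry.reference_rt,
            )
        )
        expected = (
            NitrogenClass.N_ACYL_OR_OXO
            if entry.n_acyl_or_oxo
            else entry.nitrogen_class
        )
        rows.append(
            {
                "peak_id": entry.peak_id,
                "rt_min": entry.reference_rt,
                "precursor_mz": entry.experimental_mz,
                "fragments": ";".join(
                    f"{f:.4f}" for f in entry.reference_fragments
                ),
                "expected_identification": entry.name,
                "expected_class": entry.nitrogen_class.value,
                "n_acyl_or_oxo": entry.n_acyl_or_oxo,
                "fragment_class": entry.fragment_class.value,
                "class_consistent": entry.fragment_class == expected,
                "errata": entry.errata_note,
            }
        )
    return spectra, pd.DataFrame(rows)


def jitter_spectra(
    spectra: list[Spectrum], ppm_sd: float, seed: int
) -> list[Spectrum]:
    """Multiply every m/z by ``1 + eps/1e6`` with eps ~ N(0, ppm_sd).

    Deterministic given the seed; ``ppm_sd = 0`` returns identical spectra.
    """
    if ppm_sd < 0:
        raise ValueError("ppm_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for spec in spectra:
        eps = rng.normal(0.0, ppm_sd, size=1 + len(spec.peaks))
        out.append(
            Spectrum(
                spectrum_id=spec.spectrum_id,
                precursor_mz=spec.precursor_mz * (1 + eps[0] * 1e-6),
                peaks=tuple(
                    (mz * (1 + e * 1e-6), inten)
                    for (mz, inten), e in zip(spec.peaks, eps[1:])
                ),
                rt=spec.rt,
                metadata=spec.metadata,
            )
        )
    return out


def make_decoy_spectra(n: int, seed: int) -> list[Spectrum]:
    """Negative controls: precursors in m/z 120-1000 away from any library ion.

    Decoy precursors are rejected while they fall within
    ``max(10 ppm, 3 mDa)`` of a curated ion m/z, so by construction they
    never annotate against the curated library at 5 ppm with the 1.5-mDa
    floor.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    ions = np.array([c.theoretical_mz for c in load_curated_library()])
    guard = np.maximum(ions * 10e-6, 0.003)
    out: list[Spectrum] = []
    while len(out) < n:
        mz = float(rng.uniform(120.0, 1000.0))
        if np.any(np.abs(ions - mz) <= guard):
            continue
        frags = np.sort(rng.uniform(60.0, mz - 10.0, size=3))
        peaks = tuple(
            (float(f), float(rng.uniform(2e4, 1e6))) for f in frags
        )
        out.append(
            Spectrum(
                spectrum_id=f"decoy_{len(out):03d}",
                precursor_mz=mz,
                peaks=peaks,
                rt=float(rng.uniform(1.0, 20.0)),
            )
        )
    return out
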