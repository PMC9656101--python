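"""End-to-end annotation: spectra versus the candidate library.

For each MS2 spectrum, candidates whose ion m/z lies within the precursor
(MS1) tolerance are retained — optionally also gated on retention-time
proximity — then scored on how many of their reference fragments appear in
the spectrum (MS2 tolerance) and classified from their neutral losses.
Candidates are ranked by matched fragment evidence, then |ppm error|, then
RT proximity (the only handle the study has on positional isomers), then
name.  The run-level report is one row per spectrum x retained candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .decompose import ToleranceSpec
from .library import CandidateCompound
from .formula import ppm_error, round_mz
from .rules import ClassEvidence, classify_spectrum
from .spectrum import Spectrum

__all__ = [
    "Annotation",
    "DEFAULT_MIN_INTENSITY",
    "annotate_spectrum",
    "annotate_run",
    "RunReport",
]

logger = logging.getLogger(__name__)

#: default absolute peak-intensity floor applied before any matching
DEFAULT_MIN_INTENSITY = 10_000.0

MS1_TOL = ToleranceSpec(ppm=5.0)
MS2_TOL = ToleranceSpec(ppm=10.0)


@dataclass(frozen=True)
class Annotation:
    spectrum_id: str
    candidate: CandidateCompound
    theoretical_mz: float
    ppm_error: float
    class_evidence: ClassEvidence
    matched_reference_fragments: int
    rank: int


def _fragment_matches(
    spectrum: Spectrum, candidate: CandidateCompound, ms2_tol: ToleranceSpec
) -> int:
    count = 0
    for ref in candidate.reference_fragments:
        window = ms2_tol.window(ref)
        if any(abs(mz - ref) <= window for mz in spectrum.fragment_mzs):
            count += 1
    return count


def annotate_spectrum(
    spectrum: Spectrum,
    library: tuple[CandidateCompound, ...] | list[CandidateCompound],
    ms1_tol: ToleranceSpec = MS1_TOL,
    ms2_tol: ToleranceSpec = MS2_TOL,
    rt_window: float | None = None,
    min_intensity: float = DEFAULT_MIN_INTENSITY,
) -> list[Annotation]:
    """All library matches for one spectrum, best first.

    The intensity floor is applied before matching; a spectrum left with no
    peaks still receives precursor-only annotations with empty evidence.
    ``rt_window`` (minutes) filters candidates only when both the spectrum
    and the candidate carry a retention time; RT *proximity* additionally
    breaks ranking ties among same-mass isomers whenever RTs are available,
    regardless of the filter setting.
    """
    if not library:
        raise ValueError("candidate library must not be empty")
    filtered = spectrum.filter_intensity(min_intensity)
    evidence = classify_spectrum(filtered, ms2_tol)

    retained: list[tuple[CandidateCompound, float, int]] = []
    for cand in library:
        theo = cand.theoretical_mz
        if abs(spectrum.precursor_mz - theo) > ms1_tol.window(theo):
            continue
        if (
            rt_window is not None
            and spectrum.rt is not None
            and cand.reference_rt is not None
            and abs(spectrum.rt - cand.reference_rt) > rt_window
        ):
            continue
        err = ppm_error(spectrum.precursor_mz, theo)
        nmatch = _fragment_matches(filtered, cand, ms2_tol)
        retained.append((cand, err, nmatch))

    def sort_key(item: tuple[CandidateCompound, float, int]):
        cand, err, nmatch = item
        rt_dist = (
            abs(spectrum.rt - cand.reference_rt)
            if spectrum.rt is not None and cand.reference_rt is not None
            else float("inf")
        )
        return (-nmatch, abs(err), rt_dist, cand.name)

    retained.sort(key=sort_key)
    return [
        Annotation(
            spectrum_id=spectrum.spectrum_id,
            candidate=cand,
            theoretical_mz=cand.theoretical_mz,
            ppm_error=err,
            class_evidence=evidence,
            matched_reference_fragments=nmatch,
            rank=i + 1,
        )
        for i, (cand, err, nmatch) in enumerate(retained)
    ]


@dataclass(frozen=True)
class RunReport:
    """Tabular result of annotating a whole run, plus summary counters."""

    table: pd.DataFrame
    n_spectra: int
    n_annotated: int
    warnings: tuple[str, ...] = ()

    @property
    def summary(self) -> str:
        return (
            f"{self.n_annotated} of {self.n_spectra} spectra received "
            f">=1 annotation"
        )


REPORT_COLUMNS = [
    "spectrum_id", "rt_min", "experimental_mz", "species", "ion_formula",
    "theoretical_mz", "ppm_error", "identification", "nitrogen_class",
    "evidence", "family_ion", "matched_fragments", "rank",
]


def annotate_run(
    spectra: list[Spectrum],
    library: tuple[CandidateCompound, ...] | list[CandidateCompound],
    ms1_tol: ToleranceSpec = MS1_TOL,
    ms2_tol: ToleranceSpec = MS2_TOL,
    rt_window: float | None = None,
    min_intensity: float = DEFAULT_MIN_INTENSITY,
) -> RunReport:
    """Annotate every spectrum; one report row per spectrum x candidate.

    Unreadable/invalid spectra are skipped and counted in the warnings.
    Rows are ordered by RT (missing RT last), then precursor m/z; the
    summary counts spectra (duplicates included), not distinct compounds.
    """
    rows = []
    warnings: list[str] = []
    n_annotated = 0
    n_spectra = 0
    for spec in spectra:
        n_spectra += 1
        try:
            anns = annotate_spectrum(
                spec, library, ms1_tol, ms2_tol, rt_window, min_intensity
            )
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            warnings.append(f"{spec.spectrum_id}: {exc}")
            continue
        if anns:
            n_annotated += 1
        for ann in anns:
            cand = ann.candidate
            ev = ann.class_evidence
            rows.append(
                {
                    "spectrum_id": ann.spectrum_id,
                    "rt_min": spec.rt,
                    "experimental_mz": round_mz(spec.precursor_mz),
                    "species": cand.species.kind.value,
                    "ion_formula": cand.ion_formula.hill(),
                    "theoretical_mz": round_mz(ann.theoretical_mz),
                    "ppm_error": round(ann.ppm_error, 2),
                    "identification": cand.name,
                    "nitrogen_class": ev.assigned_class.value,
                    "evidence": ";".join(
                        m.rule_label for m in ev.matched_rules
                    ),
                    "family_ion": ev.family_ion_present,
                    "matched_fragments": ann.matched_reference_fragments,
                    "rank": ann.rank,
                }
            )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if not table.empty:
        table = table.sort_values(
            ["rt_min", "experimental_mz", "spectrum_id", "rank"],
            na_position="last", kind="stable",
        ).reset_index(drop=True)
    return RunReport(
        table=table,
        n_spectra=n_spectra,
        n_annotated=n_annotated,
        warnings=tuple(warnings),
    )
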