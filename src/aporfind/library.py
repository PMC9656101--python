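"""Curated reference library and scaffold-based candidate enumeration.

The curated library holds the 70 aporphine alkaloids identified in the
*Sabia schumanniana* stem extract, transcribed from the published table and
identification text with a documented errata column (formula corrections,
truncated printed masses, the one row restored from the running text).  It
is the annotator's default target set.

Candidate *generation* serves prospective screening: starting from the two
template scaffolds (magnoflorine, an intact N,N-dimethyl quaternary cation,
and roemerine, a neutral tertiary amine measured as [M+H]+), a list of
substituent transformations (+/-CH3, +/-OH, +/-OCH3, C=O, -OCH2O-, plus the
acetyl/glucosyl/2H extensions the identifications require) is applied up to
a configurable depth, and the deduplicated products become a PRM inclusion
list of target m/z values with a fixed isolation window.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

from .formula import (
    Formula,
    FormulaError,
    IonKind,
    IonSpecies,
    monoisotopic_mz,
    parse_formula,
    ppm_error,
    round_mz,
)
from .rules import NitrogenClass

__all__ = [
    "CandidateCompound",
    "Transformation",
    "Scaffold",
    "DEFAULT_TRANSFORMATIONS",
    "MAGNOFLORINE",
    "ROEMERINE",
    "load_curated_library",
    "enumerate_candidates",
    "build_inclusion_list",
]

#: precursor-level consistency bound for the packaged library, ppm
LIBRARY_SELF_CHECK_PPM = 5.0


class LibraryError(RuntimeError):
    """Packaged library data failed its mass-consistency self-check."""


@dataclass(frozen=True)
class CandidateCompound:
    """One annotation target: a named ion with provenance and reference data.

    ``fragment_class`` records the nitrogen class that the compound's printed
    fragment list actually supports under the loss rules (hand-derived during
    curation); where it differs from ``nitrogen_class`` (section membership)
    the discrepancy is thereby enumerated rather than hidden.
    """

    peak_id: int | str
    name: str
    species: IonSpecies
    nitrogen_class: NitrogenClass
    n_acyl_or_oxo: bool = False
    reference_rt: float | None = None
    reference_fragments: tuple[float, ...] = ()
    novel_flag: bool = True
    experimental_mz: float | None = None
    theoretical_mz_printed: float | None = None
    fragment_class: NitrogenClass | None = None
    errata_note: str = ""
    provenance: str = ""

    @property
    def theoretical_mz(self) -> float:
        """Exact (unrounded) ion m/z computed from the ion formula."""
        return self.species.mz

    @property
    def ion_formula(self) -> Formula:
        return self.species.ion_formula


@dataclass(frozen=True)
class Transformation:
    """A substituent mass shift, applied to a composition element-wise."""

    label: str
    delta: tuple[tuple[str, int], ...]

    def apply(self, formula: Formula) -> Formula | None:
        """Shifted formula, or None when a count would go negative."""
        counts = formula.as_dict()
        for sym, d in self.delta:
            counts[sym] = counts.get(sym, 0) + d
            if counts[sym] < 0:
                return None
        if not any(n > 0 for n in counts.values()):
            return None
        return Formula.from_counts(counts, formula.charge)

    def inverse(self) -> "Transformation":
        return Transformation(
            f"-({self.label})", tuple((s, -d) for s, d in self.delta)
        )


def _t(label: str, **delta: int) -> Transformation:
    return Transformation(label, tuple(sorted(delta.items())))


DEFAULT_TRANSFORMATIONS: tuple[Transformation, ...] = (
    _t("methylation", C=1, H=2),
    _t("demethylation", C=-1, H=-2),
    _t("hydroxylation", O=1),
    _t("dehydroxylation", O=-1),
    _t("methoxylation", C=1, H=2, O=1),
    _t("demethoxylation", C=-1, H=-2, O=-1),
    _t("methylene_to_ketone", O=1, H=-2),
    _t("methylenedioxy_formation", H=-2),
    _t("acetylation", C=2, H=2, O=1),
    _t("glucosylation", C=6, H=10, O=5),
    _t("hydrogenation", H=2),
    _t("dehydrogenation", H=-2),
)


@dataclass(frozen=True)
class Scaffold:
    """A template compound from which derivatives are enumerated."""

    name: str
    species: IonSpecies
    nitrogen_class: NitrogenClass


MAGNOFLORINE = Scaffold(
    "magnoflorine",
    IonSpecies.m_plus(parse_formula("C20H24NO4")),
    NitrogenClass.QUATERNARY,
)
ROEMERINE = Scaffold(
    "roemerine",
    IonSpecies.m_plus_h(parse_formula("C18H17NO2")),
    NitrogenClass.TERTIARY,
)


def _species_from_row(ion_formula: str, species: str) -> IonSpecies:
    ion = parse_formula(ion_formula, charge=1)
    if species == "[M]+":
        return IonSpecies.m_plus(ion)
    if species == "[M+H]+":
        neutral = parse_formula(ion_formula)
        neutral = Formula.from_counts(
            {**neutral.as_dict(), "H": neutral.as_dict().get("H", 0) - 1}
        )
        return IonSpecies.m_plus_h(neutral)
    raise LibraryError(f"unknown species notation {species!r}")


@lru_cache(maxsize=None)
def load_curated_library() -> tuple[CandidateCompound, ...]:
    """The packaged 70-entry curated library, mass-self-checked on load.

    Every entry's computed theoretical m/z must agree with its recorded
    experimental m/z to within 5 ppm; a failing row raises
    :class:`LibraryError` naming the peak.
    """
    path = resources.files("aporfind.data").joinpath("curated_library.csv")
    entries: list[CandidateCompound] = []
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            peak_id = int(row["peak_id"])
            try:
                species = _species_from_row(row["ion_formula"], row["species"])
            except FormulaError as exc:
                raise LibraryError(f"peak {peak_id}: {exc}") from exc
            entry = CandidateCompound(
                peak_id=peak_id,
                name=row["name"],
                species=species,
                nitrogen_class=NitrogenClass(row["nitrogen_class"]),
                n_acyl_or_oxo=row["n_acyl_or_oxo"] == "1",
                reference_rt=float(row["rt_min"]),
                reference_fragments=tuple(
                    float(x) for x in row["fragments"].split(";") if x
                ),
                novel_flag=row["novel"] == "1",
                experimental_mz=float(row["experimental_mz"]),
                theoretical_mz_printed=(
                    float(row["theoretical_mz_printed"])
                    if row["theoretical_mz_printed"]
                    else None
                ),
                fragment_class=NitrogenClass(row["fragment_class"]),
                errata_note=row["errata"],
                provenance="curated",
            )
            err = ppm_error(entry.experimental_mz, entry.theoretical_mz)
            if abs(err) > LIBRARY_SELF_CHECK_PPM:
                raise LibraryError(
                    f"peak {peak_id}: experimental {entry.experimental_mz} is "
                    f"{err:+.2f} ppm from computed {entry.theoretical_mz:.4f}"
                )
            entries.append(entry)
    if len(entries) != 70:
        raise LibraryError(f"expected 70 curated entries, found {len(entries)}")
    return tuple(entries)


def enumerate_candidates(
    scaffolds: tuple[Scaffold, ...] = (MAGNOFLORINE, ROEMERINE),
    transforms: tuple[Transformation, ...] = DEFAULT_TRANSFORMATIONS,
    max_depth: int = 2,
) -> list[CandidateCompound]:
    """Breadth-first derivative enumeration, deduplicated by (ion, species).

    Each candidate keeps its provenance (scaffold name plus the ordered
    transformation labels along the first/shortest route found).  Infeasible
    branches (negative element counts) are skipped silently.  Output order is
    deterministic: ion mass ascending, then provenance string.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    seen: dict[tuple[str, IonKind], str] = {}
    queue: deque[tuple[Scaffold, Formula, int, str]] = deque()
    for sc in scaffolds:
        base = (
            sc.species.ion_formula
            if sc.species.kind is IonKind.M_PLUS
            else sc.species.neutral_formula
        )
        key = (sc.species.ion_formula.hill(), sc.species.kind)
        if key not in seen:
            seen[key] = sc.name
            queue.append((sc, base, 0, sc.name))
    results: list[CandidateCompound] = []

    def to_candidate(sc: Scaffold, formula: Formula, prov: str) -> CandidateCompound:
        if sc.species.kind is IonKind.M_PLUS:
            species = IonSpecies.m_plus(formula)
        else:
            species = IonSpecies.m_plus_h(formula)
        return CandidateCompound(
            peak_id=prov,
            name=prov,
            species=species,
            nitrogen_class=sc.nitrogen_class,
            provenance=prov,
        )

    while queue:
        sc, formula, depth, prov = queue.popleft()
        results.append(to_candidate(sc, formula, prov))
        if depth >= max_depth:
            continue
        for tr in transforms:
            nxt = tr.apply(formula)
            if nxt is None:
                continue
            if sc.species.kind is IonKind.M_PLUS:
                ion_hill = nxt.hill()
            else:
                ion_hill = Formula.from_counts(
                    {**nxt.as_dict(), "H": nxt.as_dict().get("H", 0) + 1}
                ).hill()
            key = (ion_hill, sc.species.kind)
            if key in seen:
                continue
            child_prov = f"{prov} + {tr.label}"
            seen[key] = child_prov
            queue.append((sc, nxt, depth + 1, child_prov))

    results.sort(key=lambda c: (c.theoretical_mz, c.provenance))
    return results


def build_inclusion_list(
    candidates: list[CandidateCompound] | tuple[CandidateCompound, ...],
    window_mz: float = 3.0,
) -> pd.DataFrame:
    """PRM inclusion-list table: one target row per candidate, m/z ascending.

    ``window_mz`` is the isolation window handed to the instrument method
    (default 3.0 m/z).  An empty candidate list yields a header-only table.
    """
    if window_mz <= 0:
        raise ValueError("isolation window must be positive")
    rows = [
        {
            "mz": round_mz(c.theoretical_mz),
            "species": c.species.kind.value,
            "window_mz": window_mz,
            "name": c.name,
            "provenance": c.provenance,
        }
        for c in candidates
    ]
    df = pd.DataFrame(rows, columns=["mz", "species", "window_mz", "name",
                                     "provenance"])
    return df.sort_values("mz", kind="stable").reset_index(drop=True)
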