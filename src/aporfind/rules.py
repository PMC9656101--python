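"""Neutral-loss and diagnostic-ion rules for nitrogen-class typing.

Aporphine alkaloids betray the substitution state of their nitrogen through
the amine-containing neutral loss between precursor and fragment ions:

* ``C2H7N`` (45.0578 u) — ring opening ejecting N plus both methyls;
  characteristic of quaternary N,N-dimethyl alkaloids,
* ``CH3NH2`` (31.0422 u) — methylamine, from tertiary N-methyl alkaloids,
* ``NH3`` (17.0265 u) — ammonia, from secondary (NH) alkaloids,
* ``NH`` / ``C2H5NO`` — losses seen for N-oxo / N-acyl variants,

plus a set of generic (class-neutral) losses (CH3OH, CH3O, CO, H2O, CH3, and
their cumulative combinations) and the m/z 58.0651 ``C3H8N+`` iminium family
ion that flags the aporphine skeleton as a whole.

Class assignment prefers the most hydrogen-rich amine loss: tertiary
N-methyl alkaloids also undergo the C2H7N ring-opening loss (the lirinidine
reference spectrum shows both), whereas a quaternary nitrogen cannot shed
CH3NH2 or NH3, so the smaller amine loss is the informative one.  All
matching is on exact mass — the exact masses disambiguate the nominal-31
pair CH3NH2 (31.0422) versus CH3O (31.0184) — inside a window of
``max(ppm x precursor m/z, 1.5 mDa)``: a neutral loss is the difference of
two measured ion masses, so its uncertainty scales with the precursor.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources

from .decompose import ToleranceSpec
from .formula import Formula, monoisotopic_mz, parse_formula
from .spectrum import Spectrum

__all__ = [
    "NitrogenClass",
    "NeutralLossRule",
    "DiagnosticIonRule",
    "FAMILY_ION",
    "ClassEvidence",
    "load_rules",
    "extract_neutral_losses",
    "match_loss",
    "classify_spectrum",
]

logger = logging.getLogger(__name__)


class NitrogenClass(str, Enum):
    QUATERNARY = "quaternary"
    TERTIARY = "tertiary"
    SECONDARY = "secondary"
    N_ACYL_OR_OXO = "N_acyl_or_oxo"
    GENERIC = "generic"
    UNKNOWN = "unknown"


# Most informative first: an H-richer amine loss requires more H on/next to N,
# which a more substituted nitrogen cannot provide.
CLASS_PRECEDENCE = (
    NitrogenClass.SECONDARY,
    NitrogenClass.TERTIARY,
    NitrogenClass.QUATERNARY,
    NitrogenClass.N_ACYL_OR_OXO,
)


@dataclass(frozen=True)
class NeutralLossRule:
    label: str
    composition: Formula
    implication: NitrogenClass

    @property
    def exact_mass(self) -> float:
        return monoisotopic_mz(self.composition)

    @property
    def nominal_mass(self) -> int:
        return self.composition.nominal_mass


@dataclass(frozen=True)
class DiagnosticIonRule:
    """A diagnostic fragment ion matched directly against peak m/z values."""

    label: str
    ion: Formula

    @property
    def mz(self) -> float:
        return monoisotopic_mz(self.ion)


FAMILY_ION = DiagnosticIonRule("aporphine family ion", parse_formula("C3H8N", 1))


@lru_cache(maxsize=None)
def load_rules() -> tuple[NeutralLossRule, ...]:
    """Load the packaged neutral-loss rule table (editable CSV resource)."""
    text = resources.files("aporfind.data").joinpath("neutral_loss_rules.csv")
    rules = []
    with text.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rules.append(
                NeutralLossRule(
                    label=row["label"],
                    composition=parse_formula(row["composition"]),
                    implication=NitrogenClass(row["implication"]),
                )
            )
    return tuple(rules)


@dataclass(frozen=True)
class MatchedRule:
    rule_label: str
    implication: NitrogenClass
    fragment_mz: float
    loss_mass: float
    deviation_mda: float


@dataclass(frozen=True)
class ClassEvidence:
    """The outcome of classifying one spectrum."""

    assigned_class: NitrogenClass
    matched_rules: tuple[MatchedRule, ...]
    family_ion_present: bool
    family_ion_mz: float | None = None

    @property
    def class_bearing(self) -> tuple[MatchedRule, ...]:
        return tuple(
            m for m in self.matched_rules
            if m.implication in CLASS_PRECEDENCE
        )


def extract_neutral_losses(spectrum: Spectrum) -> list[tuple[float, float]]:
    """Precursor-relative losses: one ``(fragment m/z, loss mass)`` per peak.

    Sequential multi-step losses appear only as their cumulative sum.
    Fragments at or above the precursor are skipped with a logged note.
    """
    out = []
    for mz in spectrum.fragment_mzs:
        if mz >= spectrum.precursor_mz:
            logger.info(
                "spectrum %s: fragment %.4f >= precursor %.4f, skipped",
                spectrum.spectrum_id, mz, spectrum.precursor_mz,
            )
            continue
        out.append((mz, spectrum.precursor_mz - mz))
    return out


def match_loss(
    loss_mass: float,
    tol: ToleranceSpec = ToleranceSpec(ppm=10.0),
    reference_mz: float | None = None,
    nominal: bool = False,
) -> NeutralLossRule | None:
    """Best-matching rule for a neutral-loss mass, or None.

    The ppm component of the window is taken on ``reference_mz`` (normally
    the precursor) when given, else on the loss mass itself.  ``nominal``
    switches to integer-mass matching for exploratory use.
    """
    if loss_mass <= 0:
        raise ValueError("loss mass must be positive")
    if nominal:
        target = round(loss_mass)
        hits = [r for r in load_rules() if r.nominal_mass == target]
        return min(hits, key=lambda r: abs(r.exact_mass - loss_mass), default=None)
    window = tol.window(reference_mz if reference_mz is not None else loss_mass)
    best: NeutralLossRule | None = None
    best_dev = window
    for rule in load_rules():
        dev = abs(loss_mass - rule.exact_mass)
        if dev <= best_dev:
            best, best_dev = rule, dev
    return best


def classify_spectrum(
    spectrum: Spectrum,
    tol: ToleranceSpec = ToleranceSpec(ppm=10.0),
    nominal: bool = False,
) -> ClassEvidence:
    """Assign the nitrogen class of a spectrum from its neutral losses.

    Class-bearing losses are matched by exact mass within
    ``max(ppm x precursor, floor)``; the evidence records every matched rule
    (generic losses included) and whether the m/z 58 family ion is present.
    A spectrum with no class-bearing loss is ``unknown``, never an error.
    """
    matched: list[MatchedRule] = []
    for frag_mz, loss in extract_neutral_losses(spectrum):
        rule = match_loss(loss, tol, reference_mz=spectrum.precursor_mz,
                          nominal=nominal)
        if rule is not None:
            matched.append(
                MatchedRule(
                    rule_label=rule.label,
                    implication=rule.implication,
                    fragment_mz=frag_mz,
                    loss_mass=loss,
                    deviation_mda=(loss - rule.exact_mass) * 1e3,
                )
            )
    family_mz = None
    for mz in spectrum.fragment_mzs:
        # diagnostic ion matched with the absolute floor (ppm at m/z 58 is
        # far tighter than real calibration there)
        if abs(mz - FAMILY_ION.mz) <= max(tol.absolute_floor, 1e-12):
            family_mz = mz
            break
    implied = {m.implication for m in matched}
    assigned = next(
        (c for c in CLASS_PRECEDENCE if c in implied), NitrogenClass.UNKNOWN
    )
    return ClassEvidence(
        assigned_class=assigned,
        matched_rules=tuple(matched),
        family_ion_present=family_mz is not None,
        family_ion_mz=family_mz,
    )
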