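"""Neutral-loss matching and nitrogen-class assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aporfind.decompose import ToleranceSpec
from aporfind.formula import monoisotopic_mz
from aporfind.rules import (
    CLASS_PRECEDENCE,
    FAMILY_ION,
    NitrogenClass,
    classify_spectrum,
    extract_neutral_losses,
    load_rules,
    match_loss,
)
from aporfind.spectrum import Spectrum

TOL = ToleranceSpec(ppm=10.0)


def test_rule_masses_internally_consistent():
    """Each rule's exact mass must equal the mass of its composition."""
    for rule in load_rules():
        assert rule.exact_mass == monoisotopic_mz(rule.composition)


@pytest.mark.parametrize(
    "label,nominal",
    [("C2H7N", 45), ("CH3NH2", 31), ("NH3", 17), ("NH", 15),
     ("C2H5NO", 59), ("CH3OH", 32), ("CH3O", 31), ("CO", 28), ("H2O", 18),
     ("CH3", 15)],
)
def test_nominal_masses(label, nominal):
    rule = next(r for r in load_rules() if r.label == label)
    assert rule.nominal_mass == nominal


def test_family_ion_mass():
    assert round(FAMILY_ION.mz, 5) == 58.06513


@pytest.mark.parametrize(
    "loss,expected_label",
    [
        (31.0422, "CH3NH2"),  # exact mass splits the nominal-31 pair
        (31.0184, "CH3O"),
        (45.0578, "C2H7N"),
        (17.0266, "NH3"),
        (10.0, None),
    ],
)
def test_match_loss(loss, expected_label):
    rule = match_loss(loss, TOL)
    assert (rule.label if rule else None) == expected_label


def test_match_loss_rejects_nonpositive():
    with pytest.raises(ValueError):
        match_loss(0.0, TOL)


def test_match_loss_nominal_mode():
    assert match_loss(45.2, TOL, nominal=True).label == "C2H7N"


def test_extract_neutral_losses_magnoflorine():
    spec = Spectrum("s", 342.1703, ((297.1123, 1e5),))
    (frag, loss), = extract_neutral_losses(spec)
    assert frag == 297.1123
    assert loss == pytest.approx(45.0580, abs=1e-4)


def test_extract_neutral_losses_skips_superprecursor_peaks():
    spec = Spectrum("s", 200.0, ((150.0, 1e5), (250.0, 1e5)))
    assert [f for f, _ in extract_neutral_losses(spec)] == [150.0]


def test_extract_neutral_losses_empty():
    assert extract_neutral_losses(Spectrum("s", 200.0)) == []


STANDARDS = {
    # reference-standard spectra as printed: fragments and precursor
    "magnoflorine": (
        342.1703,
        (58.0658, 237.0905, 265.0852, 282.0877, 297.1123),
        NitrogenClass.QUATERNARY,
        True,
    ),
    "lirinidine": (
        282.1495,
        (58.0660, 191.0855, 219.0806, 237.0911, 251.1063),
        NitrogenClass.TERTIARY,
        True,
    ),
    "roemerine": (
        280.1336,
        (191.0856, 219.0805, 249.0912),
        NitrogenClass.TERTIARY,
        False,
    ),
    "N-nornuciferine": (
        282.1493,
        (234.1041, 250.0990, 265.1224),
        NitrogenClass.SECONDARY,
        False,
    ),
}


@pytest.mark.parametrize("name", list(STANDARDS))
def test_reference_standards_classify(name):
    precursor, frags, expected, family = STANDARDS[name]
    spec = Spectrum(name, precursor, tuple((f, 1e5) for f in frags))
    ev = classify_spectrum(spec, TOL)
    assert ev.assigned_class is expected
    assert ev.family_ion_present is family


def test_lirinidine_shows_both_amine_losses():
    """The tertiary standard also ring-opens (C2H7N); the H-richer CH3NH2
    loss must take precedence."""
    precursor, frags, _, _ = STANDARDS["lirinidine"]
    spec = Spectrum("lirinidine", precursor, tuple((f, 1e5) for f in frags))
    labels = {m.rule_label for m in classify_spectrum(spec, TOL).matched_rules}
    assert {"CH3NH2", "C2H7N"} <= labels


def test_secondary_via_ammonia_loss():
    spec = Spectrum("nnn", 282.1493, ((265.1224, 1e5),))
    ev = classify_spectrum(spec, TOL)
    assert ev.assigned_class is NitrogenClass.SECONDARY
    assert ev.matched_rules[0].rule_label == "NH3"


def test_generic_loss_alone_gives_unknown():
    spec = Spectrum("co", 300.0, ((300.0 - 27.9949, 1e5),))
    ev = classify_spectrum(spec, TOL)
    assert ev.assigned_class is NitrogenClass.UNKNOWN
    assert [m.rule_label for m in ev.matched_rules] == ["CO"]


def test_acyl_class_from_acetamide_loss():
    # N-acetylanonaine: 308.1281 -> 249.0914 is the C2H5NO loss
    spec = Spectrum("naa", 308.1281, ((249.0914, 1e5),))
    ev = classify_spectrum(spec, TOL)
    assert ev.assigned_class is NitrogenClass.N_ACYL_OR_OXO


def test_precedence_order():
    assert CLASS_PRECEDENCE.index(NitrogenClass.SECONDARY) < \
        CLASS_PRECEDENCE.index(NitrogenClass.TERTIARY) < \
        CLASS_PRECEDENCE.index(NitrogenClass.QUATERNARY)


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.floats(60.0, 200.0), max_size=5))
def test_unmatched_noise_never_changes_class(extra):
    """Adding fragments that match no rule leaves the class unchanged."""
    precursor, frags, expected, _ = STANDARDS["magnoflorine"]
    base = Spectrum("m", precursor, tuple((f, 1e5) for f in frags))
    # keep noise away from every rule window relative to this precursor
    window = TOL.window(precursor)
    safe = []
    for mz in extra:
        loss = precursor - mz
        if all(
            abs(loss - r.exact_mass) > 2 * window for r in load_rules()
        ) and abs(mz - FAMILY_ION.mz) > 2 * window:
            safe.append(mz)
    noisy = Spectrum(
        "m", precursor, base.peaks + tuple((mz, 1e5) for mz in safe)
    )
    assert classify_spectrum(noisy, TOL).assigned_class is expected
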