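# Methods

## Scope and model

`aporfind` reproduces the computational side of a targeted aporphine
alkaloid screen: given centroided positive-mode MS2 spectra with accurate
precursor masses, it (i) proposes elemental compositions for observed
m/z values, (ii) matches precursors against a curated reference library,
(iii) infers the nitrogen substitution class from neutral losses, and
(iv) generates PRM inclusion lists from scaffold-derivative enumeration.
Everything instrument-side — chromatography, acquisition, peak picking
from profile data — is out of scope; spectra enter the package already
centroided.

## Mass arithmetic

Monoisotopic atomic masses (H 1.00782503207, C 12 exact, N 14.0030740048,
O 15.9949146196 u) and the electron mass (0.00054857990907 u) are pinned
in `formula.py` to more than ten significant figures (CODATA/IUPAC
values). A +1 ion's m/z is the summed atomic mass minus one electron mass;
only charges 0 and +1 are supported because the analyte family produces
exclusively singly charged positive ions. Quaternary alkaloids are intact
cations (`[M]+`); all others are protonated neutrals (`[M+H]+`).

Reported m/z values are rounded half-away-from-zero to 4 decimals. That
convention reproduces the published boundary values (e.g. 282.14886 →
282.1489 and 266.11756 → 266.1176); the handful of published entries that
were evidently truncated instead of rounded are recorded in the library's
errata column and excluded from 4-decimal equality tests.

## Formula decomposition

`decompose` enumerates all compositions within a tolerance window of an
observed m/z under per-element count bounds (defaults C≤30, H≤60, N≤10,
O≤20, the formula-predictor settings of the screen). The window is
`max(ppm·m/10⁶, floor)` with a 1.5-mDa default floor: the m/z 58.065
iminium family ion is routinely measured 12–15 ppm high, so a pure ppm
window at low mass would reject the screen's own diagnostic ion. The
search is a depth-first scan over elements in decreasing mass with
residual-mass pruning (each branch is cut when the remaining elements
cannot reach the target window even at their bounds). Correctness is
defined by `brute_force_decompose`, a vectorised enumeration of the whole
bound grid, and the test suite asserts exact agreement on a thousand
randomized instances. No valence/RDBE filter is applied by default (the
source workflow states none); an even-electron plausibility filter is
available behind a flag.

## Curated library and errata policy

`data/curated_library.csv` transcribes the 70 identifications: retention
time, printed theoretical and experimental m/z, ion formula, species,
identification, nitrogen class (by the section of the identification text
each compound appears in), per-compound fragment list, and an errata note.
Curation rules, applied openly rather than silently:

* printed masses win over formula notation when the two conflict (the
  "+H" suffix sometimes already includes the proton, e.g. roemerine's
  280.1332 matches C₁₈H₁₈NO₂⁺, the protonated C₁₈H₁₇NO₂ molecule);
* the identification text wins over the table where both give a formula
  and the mass agrees with the text (one row);
* one compound (N-acetylanonaine, m/z 308.1281) is absent from the
  printed table and is restored from the running text;
* the single previously known constituent is taken to be magnoflorine,
  the reference-standard template compound, so that exactly 69 of 70
  entries carry the first-report flag.

On every load the library verifies that each recorded experimental mass
lies within 5 ppm of the mass recomputed from the corrected ion formula
(worst row ≈ 2.5 ppm); a failing row aborts the load naming the peak.

## Neutral-loss classification

The rulebase (`data/neutral_loss_rules.csv`, editable) holds class-bearing
losses — C₂H₇N → quaternary, CH₃NH₂ → tertiary, NH₃ → secondary, NH and
C₂H₅NO → N-acyl/N-oxo — plus generic losses and their narrated cumulative
combinations (e.g. C₂H₇N+CH₃OH+CO). Matching is on exact mass; the exact
values split the nominal-31 pair CH₃NH₂/CH₃O cleanly. The window is
`max(ppm·precursor/10⁶, 1.5 mDa)`: a neutral loss is the difference of two
measured ion masses, so its uncertainty scales with the precursor rather
than with the (often small) loss itself.

When several class-bearing losses match, the most hydrogen-rich amine loss
wins (NH₃ > CH₃NH₂ > C₂H₇N > N-acyl). The ordering is forced by the data:
tertiary N-methyl alkaloids also undergo the C₂H₇N ring-opening loss (the
lirinidine standard shows both 31.04 and 45.06 losses, with the C₂H₇N
product as base peak), whereas a quaternary N,N-dimethyl nitrogen carries
no N–H and cannot shed CH₃NH₂ or NH₃; across all 70 fixtures no
quaternary spectrum shows a smaller amine loss. A spectrum with no
class-bearing loss is reported `unknown`, never guessed.

The curated CSV also freezes, per compound, the class its printed fragment
list actually supports (`fragment_class`, hand-derived from the printed
losses during curation). For 43 of 70 entries this agrees with the
section-membership class; the rest are enumerated discrepancies — either
the printed list contains no class-bearing loss at all, or (for several
tertiary groups) only the ring-opening C₂H₇N loss was printed. Tests
assert the classifier reproduces the frozen column for all 70 and that the
consistent subset matches its section class.

## Annotation and isomer ranking

Candidates within the MS1 window of a precursor are retained, scored by
the number of reference fragments found within the MS2 window, and ranked
by (matched fragments desc, |ppm| asc, RT proximity, name). Positional
isomers share ion formula, exact mass and — in this data set — fragment
list, so retention time is the only discriminator, exactly as in the
source study; RT proximity therefore acts as a ranking tie-break whenever
both sides carry an RT, independent of the optional hard RT-window
*filter* (off by default). The intensity floor (default 10 000 counts) is
applied before any matching; a spectrum emptied by the filter still
receives precursor-only annotations with empty evidence.

## Fixture generator

`build_fixture_set` reconstructs all 70 spectra from the published
numbers: precursor = recorded experimental m/z, RT as recorded, fragment
m/z lists as printed per compound or isomer group (groups share one
printed list). Intensities are synthetic — the publication prints only a
few relative abundances (used where given, for the lirinidine group);
otherwise a rank-decreasing geometric profile is assigned, always at or
above the intensity floor so filtering never removes fixture evidence.
What passing fixture tests therefore demonstrate is the correctness of the
mass arithmetic, matching, ranking and classification logic — not
robustness to real-world intensity variation, isotope envelopes,
chimeric spectra or chromatographic noise, none of which the generator
emulates.

Randomized harnesses are pure functions of their seed: `jitter_spectra`
multiplies every m/z by `1 + ε/10⁶` with ε ~ N(0, sd); at the 1.5-ppm sd
used in tests, at least 95 % of fixtures remain annotated (the worst
library row sits 2.5 ppm from theory, leaving ≥ 2.5 ppm of headroom).
`make_decoy_spectra` draws precursors uniformly from m/z 120–1000,
rejecting anything within `max(10 ppm, 3 mDa)` of a library ion, so decoys
cannot annotate at 5 ppm by construction.

## Numerical choices and degenerate inputs

* Rounding: half-away-from-zero, `decimal`-based, applied only at the
  reporting layer; all matching uses unrounded masses.
* ppm errors are computed against unrounded theoretical masses; the
  published error column is informative only (it is not reproducible from
  the rounded printed masses).
* Decomposition with a zero window returns an empty list; empty bounds or
  non-positive m/z raise.
* Fragments at or above the precursor are skipped with a logged note.
* Enumeration branches that would drive an element count negative are
  dropped silently (infeasible chemistry, not an error); deduplication is
  by (ion formula, species) keeping the shortest provenance.
* Report writing is byte-stable for identical inputs: fixed column order,
  m/z at 4 decimals, ppm at 2, `\n` line endings.

## Problem sizes

The test suite and the acceptance script run entirely on generated or
packaged data: 70 fixture spectra, a 70-entry library, 100 decoys, 1,000
randomized decomposition instances under reduced bounds (C≤15, H≤25, N≤3,
O≤6), and property tests at 60–200 examples each. The full suite completes
in a few seconds on one core.

## Known limitations

* Only C/H/N/O are in the element table by default; it is extensible but
  extensions are untested.
* Negative mode, multiple charging, isotope patterns and average masses
  are out of scope.
* The scaffold-derivative enumerator cannot reach every curated
  identification (ring-opening +2H products, glucosides at depth 1 from
  non-scaffold parents), which is why the curated library — not the
  generator — is the annotator's default target set; generation exists
  for prospective inclusion-list design.
* mzML support is a minimal read-only contract (centroided MS2 with
  selected-ion m/z and scan start time, 32/64-bit float arrays, optional
  zlib); vendor raw formats and profile data are unsupported.
* No structural (SMILES/2-D) reasoning: positional isomers are
  distinguished by retention time alone, as in the source study.
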