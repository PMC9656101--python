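# aporfind

Accurate-mass annotation and nitrogen-class typing of **aporphine
alkaloids** from high-resolution LC-MS/MS data.

Aporphine alkaloids are tetracyclic isoquinoline natural products found in
medicinal plants such as *Sabia schumanniana* Diels. A targeted screen of
such an extract produces centroided MS2 spectra whose annotation rests on
three desk-side computations, all implemented here:

1. **Exact ion-mass arithmetic.** Every composition `CcHhNnOo` has a
   monoisotopic mass `Σ count·m(isotope)`; a singly charged cation weighs
   one electron less. Quaternary alkaloids fly as intact cations `[M]+`,
   all others as protonated molecules `[M+H]+`. Agreement between observed
   and theoretical mass is scored in ppm:
   `δ = (m_obs − m_theo)/m_theo × 10⁶`.
2. **Formula decomposition.** All compositions within
   `max(ppm·m/10⁶, 1.5 mDa)` of an observed m/z under element bounds
   C≤30, H≤60, N≤10, O≤20 (depth-first search with residual-mass pruning,
   verified against full-grid enumeration).
3. **Neutral-loss classification.** The amine-containing neutral loss
   between precursor and fragment identifies the nitrogen substitution
   state — C₂H₇N (45.0578 u) for quaternary, CH₃NH₂ (31.0422 u) for
   tertiary, NH₃ (17.0265 u) for secondary, NH / C₂H₅NO for N-oxo/N-acyl
   variants — alongside generic losses (CH₃OH, CH₃O, CO, H₂O, CH₃, …) and
   the m/z 58.0651 C₃H₈N⁺ iminium ion diagnostic of the aporphine skeleton.

On top sit a curated 70-compound reference library (with a documented
errata column), a scaffold-derivative enumerator that turns template
compounds (magnoflorine, roemerine) plus substituent shifts into PRM
inclusion lists, an annotator that matches spectra against the library
(5 ppm MS1, 10 ppm MS2, intensity floor 10 000, optional RT window), and a
fixture generator that rebuilds all 70 published spectra from the printed
masses so that the whole pipeline is testable without any instrument data.

## Worked example

```python
>>> import aporfind as ap
>>> f = ap.parse_formula("C20H24NO4", charge=1)   # magnoflorine cation
>>> ap.round_mz(ap.monoisotopic_mz(f))
342.17
>>> round(ap.ppm_error(342.1703, 342.1700), 2)    # observed vs printed mass
0.88
>>> [g.hill() for g in ap.decompose(58.0658, 1, ap.ToleranceSpec(ppm=10))]
['C3H8N']
>>> spectra, manifest = ap.build_fixture_set()
>>> report = ap.annotate_run(spectra, ap.load_curated_library())
>>> report.summary
'70 of 70 spectra received >=1 annotation'
>>> ann = ap.annotate_spectrum(spectra[26], ap.load_curated_library())[0]
>>> ann.candidate.name, ann.class_evidence.assigned_class.value
('magnoflorine', 'quaternary')
```

The first numbers are the theoretical m/z of the intact magnoflorine
cation (342.1700 at 4 decimals) and its +0.88 ppm deviation from the
observed 342.1703; the decomposition shows that within 10 ppm (plus the
1.5-mDa low-mass floor) only C₃H₈N⁺ explains the m/z 58.0658 family ion;
the final lines annotate the packaged fixture spectra — all 70 match their
library entries, and the magnoflorine spectrum classifies as a quaternary
alkaloid from its C₂H₇N neutral loss.

The same operations are exposed on the command line:

```sh
aporfind decompose 342.1703 --ppm 5
aporfind fixtures --out fx/ --decoys 100
aporfind annotate fx/fixtures.mgf --out report.csv
aporfind classify fx/fixtures.mgf --out classes.csv
aporfind enumerate --scaffold magnoflorine --depth 2 --out targets.csv
```

## Layout

- `src/aporfind/formula.py` — compositions, ion species, exact masses, ppm
- `src/aporfind/decompose.py` — bounded formula decomposition + oracle
- `src/aporfind/library.py` — curated library, derivative enumeration,
  inclusion lists (`data/curated_library.csv` is the versioned resource)
- `src/aporfind/rules.py` — neutral-loss rulebase and classifier
  (`data/neutral_loss_rules.csv`)
- `src/aporfind/annotate.py` — spectrum-versus-library annotation
- `src/aporfind/io.py` — MGF/mzML reading, MGF and report writing, config
- `src/aporfind/fixtures.py` — fixture spectra, seeded jitter, decoys
- `docs/methods.md` — model, assumptions, parameter choices, limitations
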