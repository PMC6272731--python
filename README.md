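# flavohunt

Biosynthesis-guided flavonoid hunting in untargeted LC-MS data.

Plants assemble their flavonoids from a handful of skeletons — flavanonols
via naringenin (C15H12O5), flavanols via catechin (C15H14O6) — decorated by
a limited vocabulary of enzymatic modifications: hydroxylation (+O),
methylation (+CH2), O-glycosylations (hexosyl +C6H10O5, rhamnosyl +C6H10O4,
pentosyl +C5H8O4, glucuronyl +C6H8O6), acylations, prenylation, and C-C
conjugations with phenylpropanoid or flavan units.  `flavohunt` turns that
biosynthetic logic into a screening tool for negative-mode Q-TOF data:

1. **Predict** — apply 1-8 modifiers combinatorially to a parent skeleton
   and tabulate every candidate formula with its exact [M-H]⁻ m/z
   (m/z = monoisotopic mass − 1.00727645 Da).
2. **Match** — screen a centroided feature table (m/z, RT, height, isotope
   cluster) against the candidates.  A candidate is in play when its
   theoretical m/z lies within **2.0 mDa + 5.6 ppm** of the observed ion;
   it is accepted when the weighted relevance score

   R = (40·S_mass + 35·S_isotope + 15·S_defect + 10·S_msms) / Σw ≥ 75 %

   with S_mass a linear taper over the tolerance window, S_isotope the
   mean agreement of observed vs. computed isotopologue abundances
   (7.5 % relative tolerance), S_defect a 25 mDa mass-defect gate, and
   the MS/MS term dropped (weights renormalised) when no spectra are given.
3. **Annotate** — explain MS/MS fragments as the precursor minus multisets
   of diagnostic neutral losses (146 Da rhamnosyl, 164 Da rhamnose,
   110 Da dihydroxybenzene, 234 Da combined dihydroxytoluene elimination,
   CO/CO₂/H₂O, …) and apply deterministic rules to call substructures
   (3-*O*-rhamnoside, phenylpropanoid conjugation, bis-substitution, …).

Intended users: natural-product and metabolomics researchers profiling
flavonoid-rich plant extracts who want candidate structures, not just
formulas, from MS1 + MS/MS evidence.

## Worked example

Astilbin, the major flavonoid of *Smilax glabra* rhizomes, is a
2×hydroxylation + rhamnosylation derivative of naringenin.  Screening a
feature observed at m/z 449.1107 (RT 10.6 min) against the full flavanonol
database:

```python
from flavohunt import *

nar = builtin_parents()[0]                       # naringenin, C15H12O5
groups = group_by_formula(enumerate_candidates(nar, builtin_modifier_table()))

pat = isotope_pattern(parse_formula("C21H22O11"), ion=IonSpec(), n_peaks=4)
feature = Feature(mz=449.1107, rt=10.6, height=5e5,
                  isotope_peaks=tuple(pat.peaks[1:]))
hit = match_features([feature], groups)[0]
print(hit.formula, f"{hit.calculated_mz:.4f}", f"{hit.error_ppm:+.2f} ppm",
      f"relevance {hit.relevance:.1f}%")
```

prints

```
C21H22O11 449.1089 +3.93 ppm relevance 82.6%
```

i.e. the observed ion matches the astilbin formula C21H22O11 (theoretical
[M-H]⁻ 449.1089) with a +3.93 ppm mass error, and the combined
mass/isotope/defect evidence scores 82.6 %, above the 75 % acceptance
threshold.  The same pipeline from the shell:

```bash
flavohunt build-db --parent naringenin --out db.csv
flavohunt match --db db.csv --features features.csv --out results.csv
flavohunt annotate --mgf spectra.mgf --out annotations.csv
```

`flavohunt simulate` generates seeded synthetic feature tables (and MGF
spectra) with ground truth for benchmarking recall and precision.

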