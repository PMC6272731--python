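# Methods

## Model

`flavohunt` implements a biosynthesis-guided annotation model for
negative-mode LC-MS profiling of plant flavonoids.  The central assumption
is that the metabolite space of a flavonoid-rich tissue is well covered by
a parent skeleton plus a multiset of additive biotransformations, so that
candidate *elemental formulas* (and hence exact [M-H]⁻ masses) can be
enumerated exhaustively in advance.  Identification then reduces to scoring
observed features against that finite candidate set, with MS/MS neutral
losses supplying substructure evidence.  The model deliberately stops at
the formula + substructure level: positional isomers and stereochemistry
are not distinguishable from mass spectra and are out of scope.

## Mass and isotope arithmetic

* Atomic masses and abundances are pinned in `data/isotopes.csv`
  (AME atomic masses, IUPAC 2013 representative isotopic abundances) so
  results are reproducible offline and independent of any external library
  version.
* Ion m/z uses the ionic-mass convention: [M-H]⁻ = M − 1.00727645 Da
  (hydrogen atom minus the retained electron).  This matches the 4-decimal
  reference values for flavonoid standards (e.g. catechin C15H13O6⁻ at
  289.0718) to 0.1 mDa; omitting the electron term would miss by ~0.5 mDa.
* Isotopologue patterns are computed by exact sequential convolution of
  per-element extra-neutron distributions, tracking per-cluster probability
  and probability-weighted mass.  Clusters are aggregated per nominal mass
  unit and reported at their abundance-weighted centroid, which is what a
  unit-resolving TOF records as one "isotopic ion" per +1 Da.  For the
  deprotonated ion the pattern is computed on the composition minus one H,
  shifted by the electron mass.  The convolution carries 6 clusters of
  headroom beyond the requested peaks so truncation cannot bias retained
  abundances; the test suite checks equivalence with a brute-force
  enumeration of all isotopologues (polynomial expansion) to 1e-6 relative
  abundance and 1e-5 Da for formulas up to 25 atoms.
* Fine isotope structure (separating ¹³C from ²H within a cluster) is not
  resolved, by design; only centroids are reported.

## Candidate database

* The modifier vocabulary ships as an editable CSV with 14 distinct
  elemental deltas.  Glycosyl and acyl deltas follow condensation
  chemistry (sugar − H₂O, acid − H₂O); the C-C conjugation deltas
  (+C9H6O3 dihydroxyphenylpropanoid, +C9H8O4 dihydroxyphenylpropanoic
  acid, +C15H12O6 catechin unit, +C15H12O5 tetrahydroxyflavanol unit) are
  back-derived from the formula pairs of the cinchonain, procyanidin and
  related families they generate.  Sugars isobaric to MS
  (glucose/galactose; apiose/arabinose) collapse to one delta with
  aliases.  The butyl modifier is shipped as +C4H8; a butenyl variant
  (+C4H6) can be supplied via a custom table.
* Enumeration covers all multisets of 1-8 modifiers subject to each
  modifier's own cap and per-class caps (glycosylation ≤ 3, acylation ≤ 2,
  conjugation ≤ 2 by default).  Uncapped enumeration over 14 modifiers
  would exceed 2×10⁵ combinations dominated by biologically implausible
  stacks; the caps keep the default flavanonol database at 121,400 entries
  (14,813 distinct formulas) while retaining every compound family the
  annotation rules recognise.  Caps are overridable per call.
* Distinct combos can collide on one formula (2×methyl = +C2H4); matching
  therefore operates on formula groups, and every report lists all combos
  of a group.

## Matching and relevance scoring

* Pre-filter: RT within [4, 50] min and m/z within [200, 1000] (closed
  intervals), height strictly over 200 counts ("over" read as strict).
* Mass window: half-width 2.0 mDa + 5.6 ppm of the theoretical m/z,
  symmetric.  This is the expected-variation bound of a calibrated Q-TOF;
  the window is the union of an absolute term (detector/centroiding floor)
  and a relative term (calibration drift).
* Component scores, each 0-100: mass accuracy = linear taper of |error|
  across the window; isotope agreement = mean over recorded clusters of a
  linear taper of the relative abundance error across 7.5 %; mass defect =
  pass/fail gate at 25 mDa after aligning nominal masses; MS/MS = caller-
  supplied fragment-support score.
* Relevance = weighted mean with weights 40/35/15/10
  (mass/isotope/defect/MS/MS).  The weights of the commercial package this
  workflow descends from are unpublished; these defaults put the majority
  weight on mass evidence, mirroring the criterion order of that workflow.
  **Missing evidence is excluded, not zeroed**: with no MS/MS spectra the
  remaining weights are renormalised, and a feature without recorded
  isotope peaks receives a neutral isotope score of 50.  Zeroing instead
  would make the 75 % acceptance threshold unreachable for genuine
  identifications with ~4 ppm mass error in an MS1-only run.
* Accepted results (relevance ≥ 75 %) are ranked per feature by relevance,
  then |ppm error|, then formula string — a total, deterministic order.
* A retention-time tolerance applies only when comparing a sample against
  authentic standards, not to database matching: the database predicts
  masses, not retention times.

## MS/MS annotation

* Each fragment is explained as precursor − (multiset of ≤ `max_depth`
  table losses); multisets one deeper are admitted when they include a
  conjugation-scale loss (≥ 150 Da), covering chains like substituent +
  rhamnose + water.  Fragment tolerance defaults to 5 mDa + 10 ppm, looser
  than MS1 because product ions calibrate less accurately.
* All fitting explanations are kept, ranked by |error| then parsimony
  (fewest losses).  Classification uses only the top-ranked explanation
  per fragment.
* Some loss multisets are exactly mass-degenerate (rhamnosyl + H₂O ≡
  rhamnose, both C6H12O5 in total), so "recovering the generating losses"
  is only well-defined up to total loss mass; ranking prefers the
  single-loss reading on exact ties, and the simulation round-trip tests
  assert mass identity, not multiset identity.
* Rules are conjunctions over diagnostic tags (per-loss tags plus
  multiset-level tags such as "two C6H6O2 units in one explanation" or
  "CO alongside a substituent loss").  The shipped rules call:
  3-*O*-rhamnoside (146 & 164 Da), dihydroxyphenylpropanoid substituent
  (110 Da), cinchonain-type conjugate (combined 234 Da), tetrahydroxy-
  flavanol upper unit (C8H10O3 ring-B fission), C-4 carbonyl (CO after a
  substituent loss), bis-substitution (single and double 110 Da events),
  and dihydroxyphenylpropanoic-acid substituent (180 Da).  The m/z
  177.0190 ion that localises the acid substituent to C-6/C-8 is recorded
  as a diagnostic constant, not a derived loss, because its composition is
  not established.
* Intensities are carried but never scored; presence of a diagnostic loss
  is the evidence unit.

## Synthetic data

The generator draws true features from database formulas (seeded Gaussian
mass error, default σ = 1 ppm; isotope clusters from theory with 2 %
relative abundance noise, matching the 0-2.5 % agreement a tuned
instrument achieves; RT uniform on 4-50 min; log-uniform heights
10³-10⁶) and decoys uniformly in m/z with a guard band of three tolerance-
window widths around every database mass, so recall and precision are
well defined.  MS/MS spectra are built by applying the loss table exactly.
Not emulated: chromatographic peak shape, co-elution, in-source
fragmentation, adducts other than [M-H]⁻, detector saturation, calibration
drift.  Perfect recall on clean synthetic data therefore validates the
matching logic and thresholds, not instrument-grade performance on real
extracts; on dense candidate databases, borderline draws (≈2.5σ mass error
plus unfavourable isotope noise) can fall just below the 75 % threshold,
which is the intended behaviour of the threshold rather than a failure of
the matcher.

## Problem sizes and determinism

The default test and acceptance workloads use the full flavanonol database
(121,400 entries) for matching, 50 true + 50 decoy features, and 20
simulated MS/MS spectra — sizes at which the whole suite completes in well
under a minute.  All randomness flows through a single integer seed
(numpy `default_rng`); reruns with the same seed and config are
byte-identical, and every CLI command emits a JSON manifest (inputs,
config hash, version) alongside its output.

## Known limitations

* Addition-only modifiers: no demethylation/dehydration of parents.
* Negative mode, singly charged [M-H]⁻ only; no adduct inference.
* No chromatographic peak picking — the tool consumes centroided feature
  tables produced upstream.
* Formula-level identification only; isobaric formulas within the mass
  window are inherently ambiguous and are all reported, ranked.
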