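"""Neutral-loss annotation and substructure classification of negative-mode
MS/MS spectra of flavonoids.

Flavonoid glycosides and phenylpropanoid conjugates fragment by losing
whole neutral moieties: a rhamnosyl residue leaves as 146 Da (C6H10O4) or,
with its glycosidic water, 164 Da (C6H12O5); a dihydroxyphenylpropanoid
substituent announces itself by a 110 Da (C6H6O2, dihydroxybenzene) loss;
cinchonain-type catechin conjugates additionally eliminate dihydroxytoluene
(C7H8O2, giving a combined 234 Da loss); A-/C-ring chemistry shows up as
CO, CO2 and H2O losses.  Each fragment is therefore explained as the
precursor minus a small multiset of table losses, and deterministic rules
over the diagnostic tags those losses carry turn annotations into
substructure conclusions (e.g. losses of both 146 and 164 Da indicate a
rhamnose at the 3-OH).

Fragment intensity is carried through but not used for scoring: the
classification logic reasons on the presence of diagnostic losses, not on
their intensity.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from pyteomics import mgf as _mgf

from .formula_engine import Composition, monoisotopic_mass, parse_formula

__all__ = [
    "Ms2Spectrum",
    "NeutralLossDef",
    "FragmentAnnotation",
    "AnnotationReport",
    "ClassificationRule",
    "Conclusion",
    "builtin_loss_table",
    "builtin_rules",
    "annotate_spectrum",
    "classify",
    "read_mgf",
    "write_mgf",
    "export_annotations",
    "DIAGNOSTIC_MZ_A_RING_SUBSTITUTION",
]

#: fragment anion whose appearance places a dihydroxyphenylpropanoic-acid
#: group on the A ring (C-6 or C-8); recorded as an observed diagnostic
#: constant because its elemental composition is not established
DIAGNOSTIC_MZ_A_RING_SUBSTITUTION = 177.0190


@dataclass(frozen=True)
class Ms2Spectrum:
    """A centroided MS/MS spectrum of one [M-H]- precursor."""

    precursor_mz: float
    fragments: Tuple[Tuple[float, float], ...]  # (m/z, intensity), ascending m/z
    collision_energy: float = 30.0
    title: str = ""

    def __post_init__(self) -> None:
        mzs = [m for m, _ in self.fragments]
        if mzs != sorted(mzs):
            object.__setattr__(
                self, "fragments", tuple(sorted(self.fragments))
            )
        if any(m >= self.precursor_mz + 0.01 for m, _ in self.fragments):
            raise ValueError("fragment m/z above precursor")


@dataclass(frozen=True)
class NeutralLossDef:
    """A named neutral loss with the substructure it diagnoses."""

    name: str
    composition: Composition
    diagnostic: str

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.composition)

    @property
    def nominal(self) -> int:
        return round(self.mass)


def builtin_loss_table() -> List[NeutralLossDef]:
    """Diagnostic neutral losses of flavonoid glycosides and conjugates."""
    rows = [
        ("water", "H2O", "dehydration"),
        ("carbon monoxide", "CO", "carbonyl"),
        ("carbon dioxide", "CO2", "carboxyl"),
        ("rhamnosyl", "C6H10O4", "rhamnosyl"),
        ("rhamnose", "C6H12O5", "rhamnose+water"),
        ("hexosyl", "C6H10O5", "hexosyl"),
        ("dihydroxybenzene", "C6H6O2", "dihydroxybenzene"),
        ("dihydroxytoluene", "C7H8O2", "dihydroxytoluene"),
        ("dihydroxyphenylpropanoic acid", "C9H8O4", "dihydroxyphenylpropanoic-acid"),
        ("dihydroxyphenylpropanoid", "C9H6O3", "dihydroxyphenylpropanoid"),
        ("upper-unit ring-B fission", "C8H10O3", "ring-B-fission-upper-unit"),
        ("interflavan cleavage", "C15H14O6", "interflavan-cleavage"),
    ]
    return [NeutralLossDef(n, parse_formula(f), d) for n, f, d in rows]


@dataclass(frozen=True)
class FragmentAnnotation:
    """One explanation of a fragment as precursor minus a loss multiset."""

    fragment_mz: float
    intensity: float
    losses: Tuple[NeutralLossDef, ...]  # empty tuple = precursor survivor ion
    expected_mz: float
    error_mda: float
    error_ppm: float
    tags: Tuple[str, ...]

    @property
    def loss_names(self) -> Tuple[str, ...]:
        return tuple(l.name for l in self.losses)


@dataclass(frozen=True)
class AnnotationReport:
    """All annotations of one spectrum plus the fragments left unexplained."""

    spectrum: Ms2Spectrum
    annotations: Tuple[FragmentAnnotation, ...]
    unexplained: Tuple[float, ...]

    def top_annotations(self) -> List[FragmentAnnotation]:
        """Best-ranked explanation per fragment (annotation order is already
        ranked within each fragment)."""
        seen = set()
        out = []
        for a in self.annotations:
            if a.fragment_mz not in seen:
                seen.add(a.fragment_mz)
                out.append(a)
        return out


def _combo_tags(losses: Sequence[NeutralLossDef]) -> Tuple[str, ...]:
    """Per-loss diagnostics plus multiset-level combination tags."""
    tags = [l.diagnostic for l in losses]
    diags = [l.diagnostic for l in losses]
    if diags.count("dihydroxybenzene") >= 2:
        tags.append("2x-dihydroxybenzene")
    if "dihydroxybenzene" in diags and "dihydroxytoluene" in diags:
        tags.append("dihydroxybenzene+dihydroxytoluene")
    if "carbonyl" in diags and any(l.mass > 100.0 for l in losses):
        tags.append("CO-after-substituent")
    return tuple(dict.fromkeys(tags))


def annotate_spectrum(
    spectrum: Ms2Spectrum,
    losses: Optional[Sequence[NeutralLossDef]] = None,
    max_depth: int = 2,
    frag_tol_mda: float = 5.0,
    frag_tol_ppm: float = 10.0,
) -> AnnotationReport:
    """Explain each fragment as the precursor minus <= ``max_depth`` losses.

    Multisets one deeper than ``max_depth`` are also admitted when they
    contain a conjugation-scale loss (>= 150 Da), covering chains such as
    substituent + rhamnose + water.  All fitting explanations are returned,
    ranked per fragment by absolute error then by fewest losses; fragments
    with no explanation (the zero-loss identity annotation excepted) are
    listed in ``unexplained``.

    The tolerance window half-width is ``frag_tol_mda`` mDa +
    ``frag_tol_ppm`` ppm of the expected fragment m/z — looser than MS1
    screening, as fragment ions calibrate less accurately.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    table = builtin_loss_table() if losses is None else list(losses)

    multisets: List[Tuple[Tuple[NeutralLossDef, ...], float]] = [((), 0.0)]
    for depth in range(1, max_depth + 2):
        for combo in itertools.combinations_with_replacement(table, depth):
            if depth > max_depth and not any(l.mass >= 150.0 for l in combo):
                continue
            multisets.append((combo, sum(l.mass for l in combo)))

    annotations: List[FragmentAnnotation] = []
    unexplained: List[float] = []
    for frag_mz, intensity in spectrum.fragments:
        fits: List[FragmentAnnotation] = []
        for combo, loss_mass in multisets:
            expected = spectrum.precursor_mz - loss_mass
            if expected <= 0:
                continue
            tol = frag_tol_mda * 1e-3 + frag_tol_ppm * 1e-6 * expected
            err = frag_mz - expected
            if abs(err) <= tol:
                fits.append(
                    FragmentAnnotation(
                        fragment_mz=frag_mz,
                        intensity=intensity,
                        losses=combo,
                        expected_mz=expected,
                        error_mda=err * 1e3,
                        error_ppm=err / expected * 1e6,
                        tags=_combo_tags(combo),
                    )
                )
        fits.sort(key=lambda a: (abs(a.error_mda), len(a.losses)))
        if fits:
            annotations.extend(fits)
        else:
            unexplained.append(frag_mz)
    return AnnotationReport(
        spectrum=spectrum,
        annotations=tuple(annotations),
        unexplained=tuple(unexplained),
    )


@dataclass(frozen=True)
class ClassificationRule:
    """Conclude a substructure when every required tag has been observed."""

    rule_id: str
    required_tags: frozenset
    label: str
    description: str = ""


@dataclass(frozen=True)
class Conclusion:
    label: str
    rule_id: str
    evidence: Tuple[FragmentAnnotation, ...]


def builtin_rules() -> List[ClassificationRule]:
    """Substructure inference rules for flavanonol/flavanol conjugates."""
    return [
        ClassificationRule(
            "R1",
            frozenset({"rhamnosyl", "rhamnose+water"}),
            "3-O-rhamnoside",
            "paired 146/164 Da losses place a rhamnose on the 3-OH",
        ),
        ClassificationRule(
            "R2",
            frozenset({"dihydroxybenzene"}),
            "dihydroxyphenylpropanoid substituent",
            "a 110 Da C6H6O2 loss reveals a dihydroxyphenyl group",
        ),
        ClassificationRule(
            "R3",
            frozenset({"dihydroxybenzene+dihydroxytoluene"}),
            "cinchonain-type phenylpropanoid-catechin",
            "joint C6H6O2 + C7H8O2 (234 Da) elimination of dihydroxytoluene",
        ),
        ClassificationRule(
            "R4",
            frozenset({"ring-B-fission-upper-unit"}),
            "tetrahydroxyflavanol upper unit",
            "C8H10O3 ring-B fission of the upper flavan unit",
        ),
        ClassificationRule(
            "R5",
            frozenset({"CO-after-substituent"}),
            "C-4 carbonyl (flavanonol skeleton)",
            "CO loss accompanying a substituent loss requires a 4-keto group",
        ),
        ClassificationRule(
            "R6",
            frozenset({"dihydroxybenzene", "2x-dihydroxybenzene"}),
            "bis-dihydroxyphenylpropanoid substitution",
            "single and double C6H6O2 loss events require two substituents",
        ),
        ClassificationRule(
            "R7",
            frozenset({"dihydroxyphenylpropanoic-acid"}),
            "dihydroxyphenylpropanoic-acid substituent",
            "a 180 Da C9H8O4 loss releases the intact acid side chain",
        ),
    ]


def classify(
    report: AnnotationReport, rules: Optional[Sequence[ClassificationRule]] = None
) -> List[Conclusion]:
    """Evaluate substructure rules over the top annotation of each fragment.

    A rule fires only when all its required tags are present in the union
    of tags over top-ranked annotations; the conclusion carries the
    annotations that contributed those tags.  Pure function of its inputs.
    """
    rules = builtin_rules() if rules is None else list(rules)
    top = report.top_annotations()
    tag_sources: Dict[str, List[FragmentAnnotation]] = {}
    for ann in top:
        for tag in ann.tags:
            tag_sources.setdefault(tag, []).append(ann)
    conclusions: List[Conclusion] = []
    for rule in rules:
        if rule.required_tags <= set(tag_sources):
            evidence = tuple(
                dict.fromkeys(
                    ann for tag in sorted(rule.required_tags) for ann in tag_sources[tag]
                )
            )
            conclusions.append(Conclusion(rule.label, rule.rule_id, evidence))
    return conclusions


# ---------------------------------------------------------------------------
# MGF I/O
# ---------------------------------------------------------------------------

def read_mgf(path) -> List[Ms2Spectrum]:
    """Read MGF spectra (negative mode assumed; charge sign ignored)."""
    spectra: List[Ms2Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, spec in enumerate(reader):
            params = spec.get("params", {})
            if "pepmass" not in params:
                raise ValueError(f"{path}: spectrum block {i} lacks PEPMASS")
            precursor = float(params["pepmass"][0])
            frags = tuple(
                (float(mz), float(inten))
                for mz, inten in zip(spec["m/z array"], spec["intensity array"])
            )
            ce = params.get("collision_energy", 30.0)
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=precursor,
                    fragments=frags,
                    collision_energy=float(ce),
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Ms2Spectrum], path) -> None:
    """Write spectra as MGF blocks with PEPMASS and CHARGE 1-."""
    records = []
    for i, s in enumerate(spectra):
        records.append(
            {
                "m/z array": [m for m, _ in s.fragments],
                "intensity array": [x for _, x in s.fragments],
                "params": {
                    "title": s.title or f"spectrum_{i}",
                    "pepmass": s.precursor_mz,
                    "charge": "1-",
                },
            }
        )
    _mgf.write(records, str(path), file_mode="w")


def export_annotations(reports: Sequence[AnnotationReport], path) -> None:
    """Write one CSV row per top-ranked fragment annotation."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["precursor_mz", "fragment_mz", "intensity", "losses", "expected_mz",
             "error_mda", "tags"]
        )
        for rep in reports:
            for ann in rep.top_annotations():
                writer.writerow(
                    [
                        f"{rep.spectrum.precursor_mz:.4f}",
                        f"{ann.fragment_mz:.4f}",
                        f"{ann.intensity:.0f}",
                        " + ".join(ann.loss_names) or "(precursor)",
                        f"{ann.expected_mz:.4f}",
                        f"{ann.error_mda:.2f}",
                        ";".join(ann.tags),
                    ]
                )
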