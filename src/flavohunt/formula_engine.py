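"""Exact-mass and isotopologue arithmetic on elemental compositions.

This module is the numeric foundation of the package.  It provides an
immutable elemental-composition type with element-wise algebra, Hill-notation
parsing/formatting, monoisotopic masses, deprotonated ([M-H]-) m/z values,
and unit-resolution isotopologue patterns for the small CHNOPS molecules
that flavonoid chemistry lives in.

Atomic masses and isotopic abundances are shipped as a versioned CSV
resource (``data/isotopes.csv``; AME atomic masses, IUPAC 2013 representative
abundances) so that every number the package produces is reproducible from
the repository alone.

Conventions
-----------
* Ion m/z values are true ionic masses: deprotonation removes a hydrogen
  *atom* and keeps the extra electron, i.e. the [M-H]- m/z equals the
  neutral monoisotopic mass minus 1.00727645 Da (proton mass).  Q-TOF
  instruments are calibrated on ionic masses, and the 4-decimal m/z values
  quoted for flavonoid reference ions (e.g. 289.0718 for the catechin
  [M-H]- ion, C15H13O6-) match this convention to 0.1 mDa.
* Isotope patterns are aggregated per nominal-mass unit (A, A+1, A+2, ...),
  each cluster reported at its abundance-weighted centroid m/z, because
  unit-resolution clusters are what a TOF instrument reports as "isotopic
  ions" at this resolving power.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterator, Mapping, Optional, Tuple

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Composition",
    "IonSpec",
    "IsotopePattern",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "deprotonated_mz",
    "isotope_pattern",
    "ppm_error",
]

ELECTRON_MASS = 0.00054857990907
#: mass of a hydrogen atom minus one electron; [M-H]- = M - PROTON_MASS
PROTON_MASS = 1.00782503207 - ELECTRON_MASS


def _load_isotopes() -> Dict[str, Tuple[Tuple[float, float], ...]]:
    table: Dict[str, list] = {}
    res = resources.files("flavohunt.data").joinpath("isotopes.csv")
    with res.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table.setdefault(row["element"], []).append(
                (float(row["mass"]), float(row["abundance"]))
            )
    return {el: tuple(sorted(iso)) for el, iso in table.items()}


#: element -> ((isotope mass, abundance), ...) sorted by ascending mass
ISOTOPES: Dict[str, Tuple[Tuple[float, float], ...]] = _load_isotopes()

#: element -> lightest-isotope (monoisotopic) mass in Da
MONOISOTOPIC_MASS: Dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Composition(Mapping[str, int]):
    """Immutable map from element symbol to a positive integer count.

    Supports element-wise ``+`` and ``-`` (subtraction below zero raises)
    and integer scaling, the algebra behind modifier application and
    neutral-loss arithmetic.  Zero counts are never stored.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Optional[Mapping[str, int]] = None, **kwargs: int):
        merged: Dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for el, n in source.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
        object.__setattr__(self, "_counts", {el: n for el, n in merged.items() if n})

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, el: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(el, default)

    # algebra --------------------------------------------------------------
    def __add__(self, other: "Composition") -> "Composition":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return Composition(out)

    def __sub__(self, other: "Composition") -> "Composition":
        out = dict(self._counts)
        for el, n in other.items():
            new = out.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count "
                    f"({out.get(el, 0)} - {n})"
                )
            out[el] = new
        return Composition(out)

    def __mul__(self, k: int) -> "Composition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("composition scaling requires a non-negative integer")
        return Composition({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Composition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {el: n for el, n in other.items() if n}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"Composition({self._counts!r})"

    @property
    def formula(self) -> str:
        return format_formula(self)

    @property
    def n_atoms(self) -> int:
        return sum(self._counts.values())


@dataclass(frozen=True)
class IonSpec:
    """Ionisation mode.  Only singly deprotonated negative ions ([M-H]-)
    are supported, the mode of choice for flavonoids."""

    polarity: str = "negative"
    adduct: str = "[M-H]-"
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity != "negative" or self.adduct != "[M-H]-" or self.charge != 1:
            raise NotImplementedError(
                "only singly charged [M-H]- ions are supported"
            )


@dataclass(frozen=True)
class IsotopePattern:
    """Unit-resolution isotopologue clusters.

    ``peaks`` is a tuple of ``(centroid m/z, relative abundance %)`` sorted
    by ascending m/z; the base (most abundant) cluster has abundance 100,
    and for CHNOPS formulas of this size that is always the monoisotopic
    A cluster.
    """

    peaks: Tuple[Tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.peaks)

    def mz(self, i: int) -> float:
        return self.peaks[i][0]

    def abundance(self, i: int) -> float:
        return self.peaks[i][1]


def parse_formula(text: str) -> Composition:
    """Parse a flat Hill-notation formula string such as ``"C21H22O11"``.

    No parentheses, charges, hydrates or isotope labels; counts must be
    positive integers (an omitted count means 1).
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPES:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        n = int(num) if num else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return Composition(counts)


def format_formula(c: Composition) -> str:
    """Format a composition in Hill notation.

    With carbon present: C first, H second, then the rest alphabetically.
    Without carbon all elements are alphabetical.  Unit counts are omitted.
    """
    if len(c) == 0:
        raise ValueError("cannot format an empty composition")
    symbols = sorted(c)
    if "C" in c:
        head = ["C"] + (["H"] if "H" in c else [])
        symbols = head + [el for el in symbols if el not in ("C", "H")]
    return "".join(el + (str(c[el]) if c[el] != 1 else "") for el in symbols)


def monoisotopic_mass(c: Composition) -> float:
    """Monoisotopic (all-lightest-isotope) mass in Da."""
    try:
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in c.items())
    except KeyError as exc:
        raise ValueError(f"element {exc.args[0]!r} missing from mass table") from None


def deprotonated_mz(c: Composition) -> float:
    """Theoretical [M-H]- m/z (singly charged) of a neutral composition."""
    if c.get("H", 0) < 1:
        raise ValueError(f"{format_formula(c)} has no hydrogen to remove")
    return monoisotopic_mass(c) - PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# isotopologue patterns
# ---------------------------------------------------------------------------

# shift distribution: extra-neutron count -> (probability, probability-weighted
# mass sum).  Convolution of two such distributions is exact because masses
# add over independent subunits.
_ShiftDist = Dict[int, Tuple[float, float]]

_PRUNE = 1e-15


def _convolve(a: _ShiftDist, b: _ShiftDist, max_shift: int) -> _ShiftDist:
    out: Dict[int, list] = {}
    for s1, (p1, m1) in a.items():
        for s2, (p2, m2) in b.items():
            s = s1 + s2
            if s > max_shift:
                continue
            acc = out.setdefault(s, [0.0, 0.0])
            acc[0] += p1 * p2
            acc[1] += p1 * m2 + p2 * m1
    return {s: (p, m) for s, (p, m) in out.items() if p > _PRUNE}


def _element_dist(el: str, n: int, max_shift: int) -> _ShiftDist:
    iso = ISOTOPES[el]
    base = iso[0][0]
    single: _ShiftDist = {}
    for mass, ab in iso:
        shift = round(mass - base)
        p, m = single.get(shift, (0.0, 0.0))
        single[shift] = (p + ab, m + ab * mass)
    dist: _ShiftDist = {0: (1.0, 0.0)}
    for _ in range(n):
        dist = _convolve(dist, single, max_shift)
    return dist


def isotope_pattern(
    c: Composition,
    ion: Optional[IonSpec] = None,
    n_peaks: int = 4,
    prune_threshold: float = 0.0,
) -> IsotopePattern:
    """Unit-resolution isotopologue pattern of a neutral molecule or its
    [M-H]- ion.

    Parameters
    ----------
    c
        Neutral elemental composition.
    ion
        ``None`` for the neutral molecule; an :class:`IonSpec` for the
        deprotonated ion, in which case the pattern is computed for the
        composition with one H removed and shifted by the electron mass.
    n_peaks
        Number of clusters to report, starting at the monoisotopic A peak.
    prune_threshold
        Clusters with relative abundance below this fraction of the base
        peak are dropped.  Must lie in [0, 1).

    Returns
    -------
    IsotopePattern
        Clusters at abundance-weighted centroid m/z, base peak scaled
        to 100 %.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if not 0.0 <= prune_threshold < 1.0:
        raise ValueError("prune_threshold must lie in [0, 1)")
    if len(c) == 0:
        raise ValueError("empty composition has no isotope pattern")

    mass_offset = 0.0
    if ion is not None:
        if c.get("H", 0) < 1:
            raise ValueError("no hydrogen to remove for [M-H]-")
        c = c - Composition(H=1)
        mass_offset = ELECTRON_MASS
        if len(c) == 0:
            raise ValueError("deprotonation leaves an empty composition")

    max_shift = n_peaks + 6  # headroom so truncation cannot bias retained peaks
    dist: _ShiftDist = {0: (1.0, 0.0)}
    for el, n in c.items():
        if el not in ISOTOPES:
            raise ValueError(f"no isotope data for element {el!r}")
        dist = _convolve(dist, _element_dist(el, n, max_shift), max_shift)

    clusters = sorted(dist.items())[:n_peaks]
    base = max(p for p, _ in dist.values())
    peaks = []
    for _, (p, msum) in clusters:
        rel = p / base
        if rel < prune_threshold:
            continue
        peaks.append((msum / p + mass_offset, 100.0 * rel))
    return IsotopePattern(peaks=tuple(peaks))
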