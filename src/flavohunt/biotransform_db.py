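"""Combinatorial biotransformation candidate database.

Plant flavonoids arise from a small number of parent skeletons (here the
flavanonol route via naringenin and the flavanol route via catechin) that
are decorated by a limited vocabulary of biosynthetic modifications:
hydroxylation, methylation and other alkylations, O-glycosylations,
acylations, and C-C conjugations with phenylpropanoid or flavanol units.
Applying 1-8 such modifiers combinatorially to a parent predicts the
elemental formula — and hence the exact [M-H]- m/z — of every plausible
metabolite, which is the search space the LC-MS matcher screens.

Each modifier is a strictly additive elemental-composition delta.  The
deltas follow standard condensation chemistry (a glycosyl residue is the
sugar minus H2O; an acyl group the acid minus H2O) and, for the C-C
conjugations, are back-derived from characteristic formula pairs of the
compound families involved (e.g. catechin C15H14O6 + C9H6O3 gives the
cinchonain formula C24H20O9).  Isomeric sugars that MS cannot distinguish
(glucose/galactose, apiose/arabinose) collapse to a single delta with an
alias list.

The default table ships as a user-editable CSV resource
(``data/modifiers.csv``) with columns ``name,delta_formula,class,
max_count,aliases``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .formula_engine import (
    Composition,
    deprotonated_mz,
    format_formula,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "MODIFIER_CLASSES",
    "DEFAULT_CLASS_CAPS",
    "ModifierDef",
    "ParentCompound",
    "ModifierCombo",
    "CandidateEntry",
    "builtin_modifier_table",
    "builtin_parents",
    "load_modifier_table",
    "lookup_modifier",
    "enumerate_candidates",
    "group_by_formula",
    "export_db",
    "import_db",
]

MODIFIER_CLASSES = ("oxidation", "glycosylation", "acylation", "alkylation", "conjugation")

#: default per-class combination caps; they contain the combinatorial growth
#: of an uncapped 1-8 enumeration while keeping every compound family the
#: matcher needs to recognise (triglycosides, diacyl esters, bis-conjugates)
DEFAULT_CLASS_CAPS: Dict[str, int] = {
    "glycosylation": 3,
    "acylation": 2,
    "conjugation": 2,
}


@dataclass(frozen=True)
class ModifierDef:
    """A named, strictly additive biotransformation delta."""

    name: str
    delta: Composition
    mod_class: str
    max_count: int = 8
    aliases: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.delta) == 0:
            raise ValueError(f"modifier {self.name!r} has an empty delta")
        if self.mod_class not in MODIFIER_CLASSES:
            raise ValueError(f"unknown modifier class {self.mod_class!r}")
        if self.max_count < 1:
            raise ValueError(f"modifier {self.name!r} max_count must be >= 1")

    @property
    def delta_mass(self) -> float:
        return monoisotopic_mass(self.delta)


@dataclass(frozen=True)
class ParentCompound:
    """A parent skeleton that modifiers are applied to."""

    name: str
    formula: Composition
    skeleton_class: str = "flavanonol"

    def __post_init__(self) -> None:
        if self.formula.get("H", 0) < 1:
            raise ValueError(f"parent {self.name!r} must contain hydrogen")


#: a modifier multiset: ((ModifierDef, count), ...) sorted by modifier name
ModifierCombo = Tuple[Tuple[ModifierDef, int], ...]


@dataclass(frozen=True)
class CandidateEntry:
    """One predicted metabolite: parent + modifier multiset."""

    name: str
    parent: ParentCompound
    combo: ModifierCombo
    result_formula: Composition
    result_neutral_mass: float
    result_deprotonated_mz: float

    @property
    def total_modifiers(self) -> int:
        return sum(n for _, n in self.combo)

    @property
    def combo_string(self) -> str:
        return _combo_string(self.combo)


def _combo_string(combo: ModifierCombo) -> str:
    return " + ".join(f"{n}*{mod.name}" for mod, n in combo)


def _normalize(name: str) -> str:
    return name.strip().lower().replace(" ", "-").replace("_", "-")


def load_modifier_table(path) -> List[ModifierDef]:
    """Read a modifier table CSV (``name,delta_formula,class,max_count,aliases``).

    ``aliases`` is a semicolon-separated list and may be empty or absent.
    """
    mods: List[ModifierDef] = []
    seen = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "delta_formula", "class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"modifier table {path} lacks columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            name = row["name"].strip()
            if not name:
                raise ValueError(f"{path}:{i}: empty modifier name")
            if name in seen:
                raise ValueError(f"{path}:{i}: duplicate modifier name {name!r}")
            seen.add(name)
            aliases = tuple(
                a.strip() for a in (row.get("aliases") or "").split(";") if a.strip()
            )
            mods.append(
                ModifierDef(
                    name=name,
                    delta=parse_formula(row["delta_formula"]),
                    mod_class=row["class"].strip(),
                    max_count=int(row.get("max_count") or 8),
                    aliases=aliases,
                )
            )
    if not mods:
        raise ValueError(f"modifier table {path} is empty")
    return mods


def builtin_modifier_table() -> List[ModifierDef]:
    """The default biosynthetic modifier vocabulary (14 distinct deltas)."""
    res = resources.files("flavohunt.data").joinpath("modifiers.csv")
    with resources.as_file(res) as path:
        return load_modifier_table(path)


def builtin_parents() -> List[ParentCompound]:
    """Naringenin (flavanonol route) and catechin (flavanol route)."""
    return [
        ParentCompound("naringenin", parse_formula("C15H12O5"), "flavanonol"),
        ParentCompound("catechin", parse_formula("C15H14O6"), "flavanol"),
    ]


def lookup_modifier(name: str, table: Optional[Sequence[ModifierDef]] = None) -> ModifierDef:
    """Find a modifier by canonical name or alias (case/spacing-insensitive)."""
    table = builtin_modifier_table() if table is None else table
    key = _normalize(name)
    for mod in table:
        if _normalize(mod.name) == key or any(_normalize(a) == key for a in mod.aliases):
            return mod
    raise KeyError(f"no modifier named {name!r}")


def enumerate_candidates(
    parent: ParentCompound,
    modifiers: Sequence[ModifierDef],
    min_total: int = 1,
    max_total: int = 8,
    per_class_caps: Optional[Mapping[str, int]] = None,
) -> List[CandidateEntry]:
    """Enumerate every distinct modifier multiset on a parent.

    One entry per multiset with ``min_total <= total count <= max_total``,
    respecting each modifier's ``max_count`` and the per-class caps
    (:data:`DEFAULT_CLASS_CAPS` when ``per_class_caps`` is None; pass ``{}``
    to disable).  Output order is deterministic: ascending total count,
    then entry name.
    """
    if not modifiers:
        raise ValueError("modifier list is empty")
    if min_total < 1 or max_total < min_total:
        raise ValueError("require max_total >= min_total >= 1")
    caps = DEFAULT_CLASS_CAPS if per_class_caps is None else dict(per_class_caps)

    mods = sorted(modifiers, key=lambda m: m.name)
    reachable = sum(
        min(m.max_count, caps.get(m.mod_class, max_total), max_total) for m in mods
    )
    if reachable < min_total:
        raise ValueError(
            f"caps allow at most {reachable} modifiers, below min_total={min_total}"
        )

    entries: List[CandidateEntry] = []
    counts: List[int] = [0] * len(mods)

    def recurse(idx: int, total: int, used: Dict[str, int]) -> None:
        if idx == len(mods):
            if total >= min_total:
                combo = tuple(
                    (mods[i], counts[i]) for i in range(len(mods)) if counts[i]
                )
                entries.append(_make_entry(parent, combo))
            return
        mod = mods[idx]
        cap = min(
            mod.max_count,
            max_total - total,
            caps.get(mod.mod_class, max_total) - used.get(mod.mod_class, 0),
        )
        for k in range(0, max(cap, 0) + 1):
            counts[idx] = k
            if k:
                used[mod.mod_class] = used.get(mod.mod_class, 0) + k
            recurse(idx + 1, total + k, used)
            if k:
                used[mod.mod_class] -= k
        counts[idx] = 0

    recurse(0, 0, {})
    entries.sort(key=lambda e: (e.total_modifiers, e.name))
    return entries


def _make_entry(parent: ParentCompound, combo: ModifierCombo) -> CandidateEntry:
    delta = Composition()
    for mod, n in combo:
        delta = delta + mod.delta * n
    result = parent.formula + delta
    name = f"{_combo_string(combo)} of {parent.name}"
    return CandidateEntry(
        name=name,
        parent=parent,
        combo=combo,
        result_formula=result,
        result_neutral_mass=monoisotopic_mass(result),
        result_deprotonated_mz=deprotonated_mz(result),
    )


def group_by_formula(entries: Iterable[CandidateEntry]) -> Dict[str, List[CandidateEntry]]:
    """Group candidate entries by Hill formula string.

    Distinct modifier multisets can yield identical formulas (e.g. two
    methylations coincide with one +C2H4 alkylation); the matcher scores
    formulas, so colliding combos must be reported together.
    """
    groups: Dict[str, List[CandidateEntry]] = {}
    for entry in entries:
        groups.setdefault(format_formula(entry.result_formula), []).append(entry)
    return groups


_DB_COLUMNS = [
    "parent",
    "parent_formula",
    "skeleton_class",
    "combo",
    "result_formula",
    "neutral_mass",
    "deprotonated_mz",
]


def export_db(entries: Sequence[CandidateEntry], path) -> None:
    """Write a candidate database CSV (masses printed to 6 decimal places)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DB_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.parent.name,
                    format_formula(e.parent.formula),
                    e.parent.skeleton_class,
                    e.combo_string,
                    format_formula(e.result_formula),
                    f"{e.result_neutral_mass:.6f}",
                    f"{e.result_deprotonated_mz:.6f}",
                ]
            )


def import_db(
    path, modifiers: Optional[Sequence[ModifierDef]] = None
) -> List[CandidateEntry]:
    """Read a candidate database CSV written by :func:`export_db`.

    Modifier names in the combo column are resolved against ``modifiers``
    (default: the built-in table).  Masses are recomputed from the formula
    at full precision; a row whose printed mass is negative or inconsistent
    with its formula is rejected with its line number.
    """
    table = builtin_modifier_table() if modifiers is None else list(modifiers)
    entries: List[CandidateEntry] = []
    parents_cache: Dict[Tuple[str, str, str], ParentCompound] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_DB_COLUMNS).issubset(reader.fieldnames):
            raise ValueError(f"{path}: missing database columns {_DB_COLUMNS}")
        for i, row in enumerate(reader, start=2):
            try:
                pkey = (row["parent"], row["parent_formula"], row["skeleton_class"])
                parent = parents_cache.get(pkey)
                if parent is None:
                    parent = ParentCompound(
                        pkey[0], parse_formula(pkey[1]), pkey[2]
                    )
                    parents_cache[pkey] = parent
                combo_parts = []
                for part in row["combo"].split(" + "):
                    count_str, mod_name = part.split("*", 1)
                    combo_parts.append((lookup_modifier(mod_name, table), int(count_str)))
                combo: ModifierCombo = tuple(
                    sorted(combo_parts, key=lambda cn: cn[0].name)
                )
                entry = _make_entry(parent, combo)
                for col in ("neutral_mass", "deprotonated_mz"):
                    printed = float(row[col])
                    if printed <= 0:
                        raise ValueError(f"non-positive {col} {printed}")
                recorded = parse_formula(row["result_formula"])
                if recorded != entry.result_formula:
                    raise ValueError(
                        f"formula {row['result_formula']} inconsistent with combo"
                    )
                if abs(float(row["neutral_mass"]) - entry.result_neutral_mass) > 5e-6:
                    raise ValueError("neutral_mass inconsistent with formula")
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from None
            entries.append(entry)
    return entries
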