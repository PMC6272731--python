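"""Screen centroided LC-MS feature tables against a candidate database.

A feature is a centroided negative-mode peak (m/z, retention time, height,
area, optionally its isotope cluster).  Matching follows the screening
criteria of the underlying Q-TOF workflow:

* features are pre-filtered to retention times of 4-50 min, heights over
  200 counts and m/z 200-1000;
* a candidate formula is in play when its theoretical [M-H]- m/z lies
  within a symmetric window of half-width ``2.0 mDa + 5.6 ppm`` of the
  observed m/z;
* candidates are then scored on four weighted criteria — mass accuracy,
  isotope-abundance agreement (7.5 % relative tolerance), mass-defect
  proximity, and (when MS/MS evidence is supplied) fragment support — and
  accepted when the total relevance reaches 75 %.

The relevance weights of the commercial software this emulates are not
public; the defaults here put the majority weight on mass evidence
(mass 40, isotopes 35, defect 15, MS/MS 10).  When a criterion has no data
(no MS/MS spectra supplied), its weight is dropped and the remaining
weights renormalised, so relevance always refers to the evidence actually
available.  Features lacking recorded isotope peaks receive the neutral
isotope score of 50.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .biotransform_db import CandidateEntry
from .formula_engine import (
    IonSpec,
    IsotopePattern,
    deprotonated_mz,
    isotope_pattern,
    parse_formula,
    ppm_error,
)

__all__ = [
    "Feature",
    "MatchConfig",
    "MatchResult",
    "load_feature_table",
    "write_feature_table",
    "filter_features",
    "mass_tolerance_window",
    "score_isotopes",
    "mass_defect_filter",
    "match_features",
    "export_results",
]


@dataclass(frozen=True)
class Feature:
    """One centroided LC-MS feature, assumed to be an [M-H]- ion."""

    mz: float
    rt: float
    height: float
    area: float = 0.0
    isotope_peaks: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")
        if self.height < 0:
            raise ValueError("feature height must be non-negative")
        mzs = [m for m, _ in self.isotope_peaks]
        if mzs != sorted(mzs) or any(m <= self.mz for m in mzs):
            raise ValueError("isotope peaks must ascend and exceed the A-peak m/z")


@dataclass(frozen=True)
class MatchConfig:
    """Screening and scoring parameters.

    Tolerances default to the Q-TOF acquisition they model: expected mass
    variation 2.0 mDa + 5.6 ppm, isotope-abundance variation 7.5 %,
    features kept for RT 4-50 min, heights over 200 counts and m/z
    200-1000, identifications at >= 75 % total relevance.
    """

    mass_tol_mda: float = 2.0
    mass_tol_ppm: float = 5.6
    isotope_abund_tol: float = 7.5  # % relative abundance error for a zero score
    rt_window: Tuple[float, float] = (4.0, 50.0)
    min_height: float = 200.0
    mz_range: Tuple[float, float] = (200.0, 1000.0)
    relevance_threshold: float = 75.0
    defect_tol_mda: float = 25.0
    neutral_isotope_score: float = 50.0
    n_isotope_peaks: int = 4
    weights: Mapping[str, float] = field(
        default_factory=lambda: {"mass": 40.0, "isotope": 35.0, "defect": 15.0, "msms": 10.0}
    )

    def __post_init__(self) -> None:
        if abs(sum(self.weights.values()) - 100.0) > 1e-9:
            raise ValueError("relevance weights must sum to 100")
        for name in ("mass_tol_mda", "mass_tol_ppm", "isotope_abund_tol", "defect_tol_mda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MatchResult:
    """A scored candidate-formula <-> feature link."""

    feature: Feature
    formula: str
    combos: Tuple[str, ...]
    calculated_mz: float
    error_mda: float
    error_ppm: float
    mass_score: float
    isotope_score: float
    mass_defect_pass: bool
    msms_score: Optional[float]
    relevance: float
    rank: int = 0


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------

def load_feature_table(path) -> List[Feature]:
    """Read a feature CSV with header ``mz,rt,height[,area][,isoK_mz,isoK_ab...]``.

    Isotope columns come in pairs ``iso1_mz,iso1_ab``, ``iso2_mz,iso2_ab``,
    ... giving each +K cluster's centroid m/z and abundance as % of the
    A peak; blank cells mean the cluster was not recorded.  Malformed rows
    raise with their line number; row order is preserved.
    """
    features: List[Feature] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"mz", "rt", "height"}.issubset(reader.fieldnames):
            raise ValueError(f"{path}: feature table requires columns mz,rt,height")
        iso_cols = []
        k = 1
        while f"iso{k}_mz" in reader.fieldnames and f"iso{k}_ab" in reader.fieldnames:
            iso_cols.append((f"iso{k}_mz", f"iso{k}_ab"))
            k += 1
        for i, row in enumerate(reader, start=2):
            try:
                iso = []
                for mz_col, ab_col in iso_cols:
                    if (row.get(mz_col) or "").strip() and (row.get(ab_col) or "").strip():
                        iso.append((float(row[mz_col]), float(row[ab_col])))
                features.append(
                    Feature(
                        mz=float(row["mz"]),
                        rt=float(row["rt"]),
                        height=float(row["height"]),
                        area=float(row["area"]) if (row.get("area") or "").strip() else 0.0,
                        isotope_peaks=tuple(iso),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from None
    return features


def write_feature_table(features: Sequence[Feature], path) -> None:
    """Write features in the CSV schema :func:`load_feature_table` reads."""
    n_iso = max((len(f.isotope_peaks) for f in features), default=0)
    header = ["mz", "rt", "height", "area"]
    for k in range(1, n_iso + 1):
        header += [f"iso{k}_mz", f"iso{k}_ab"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for f in features:
            row = [f"{f.mz:.6f}", f"{f.rt:.3f}", f"{f.height:.1f}", f"{f.area:.1f}"]
            for k in range(n_iso):
                if k < len(f.isotope_peaks):
                    mz_k, ab_k = f.isotope_peaks[k]
                    row += [f"{mz_k:.6f}", f"{ab_k:.4f}"]
                else:
                    row += ["", ""]
            writer.writerow(row)


def filter_features(features: Sequence[Feature], cfg: MatchConfig) -> List[Feature]:
    """Apply the acquisition-window pre-filter.

    RT and m/z intervals are closed on both ends; height is a strict
    'over' threshold.  Idempotent by construction.
    """
    lo_rt, hi_rt = cfg.rt_window
    lo_mz, hi_mz = cfg.mz_range
    return [
        f
        for f in features
        if lo_rt <= f.rt <= hi_rt and f.height > cfg.min_height and lo_mz <= f.mz <= hi_mz
    ]


# ---------------------------------------------------------------------------
# scoring components
# ---------------------------------------------------------------------------

def mass_tolerance_window(theoretical_mz: float, cfg: MatchConfig) -> Tuple[float, float]:
    """Symmetric acceptance window around a theoretical m/z.

    Half-width = ``mass_tol_mda`` mDa + ``mass_tol_ppm`` ppm of the
    theoretical value.
    """
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    half = cfg.mass_tol_mda * 1e-3 + cfg.mass_tol_ppm * 1e-6 * theoretical_mz
    return (theoretical_mz - half, theoretical_mz + half)


def _mass_score(error_da: float, theoretical_mz: float, cfg: MatchConfig) -> float:
    half = cfg.mass_tol_mda * 1e-3 + cfg.mass_tol_ppm * 1e-6 * theoretical_mz
    return 100.0 * max(0.0, 1.0 - abs(error_da) / half)


def score_isotopes(
    feature: Feature, pattern: IsotopePattern, cfg: MatchConfig
) -> float:
    """Score agreement between observed and theoretical isotope abundances.

    For each recorded +K cluster the relative abundance error (in % of the
    theoretical value) is mapped linearly to a per-cluster score of
    ``max(0, 1 - error/tol)``; the result is 100 x the mean over compared
    clusters.  A feature with no recorded isotope peaks returns the
    configured neutral score.
    """
    if not feature.isotope_peaks:
        return cfg.neutral_isotope_score
    if len(pattern) < 2:
        return cfg.neutral_isotope_score
    scores = []
    for k, (_, obs_ab) in enumerate(feature.isotope_peaks, start=1):
        if k >= len(pattern):
            break
        theo_ab = pattern.abundance(k)
        rel_err_pct = abs(obs_ab - theo_ab) / theo_ab * 100.0
        scores.append(max(0.0, 1.0 - rel_err_pct / cfg.isotope_abund_tol))
    if not scores:
        return cfg.neutral_isotope_score
    return 100.0 * sum(scores) / len(scores)


def mass_defect_filter(
    feature: Feature, candidate_mz: float, cfg: Optional[MatchConfig] = None
) -> bool:
    """True when observed and candidate mass defects agree.

    The defect is the fractional part of the m/z; the difference is wrapped
    to [-0.5, 0.5) so nominal masses align before comparison.
    """
    cfg = cfg or MatchConfig()
    diff = (feature.mz - candidate_mz + 0.5) % 1.0 - 0.5
    return abs(diff) <= cfg.defect_tol_mda * 1e-3


def _relevance(components: Mapping[str, float], cfg: MatchConfig) -> float:
    """Weighted mean over the evidence actually present, as a percentage."""
    wsum = sum(cfg.weights[k] for k in components)
    return sum(cfg.weights[k] * v for k, v in components.items()) / wsum


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_features(
    features: Sequence[Feature],
    groups: Mapping[str, Sequence[CandidateEntry]],
    cfg: Optional[MatchConfig] = None,
    msms_scores: Optional[Mapping[int, float]] = None,
) -> List[MatchResult]:
    """Score every filtered feature against every in-window candidate formula.

    ``groups`` maps Hill formula -> candidate entries (see
    :func:`flavohunt.biotransform_db.group_by_formula`).  ``msms_scores``
    optionally maps an index into ``features`` to a 0-100 MS/MS support
    score for that feature; absent evidence drops the MS/MS weight.

    Results with relevance >= the threshold are returned sorted per feature
    by relevance descending, ties broken by \\|ppm error\\| ascending then
    formula string; ``rank`` is 1-based within each feature.
    """
    if not groups:
        raise ValueError("candidate database is empty")
    cfg = cfg or MatchConfig()
    msms_scores = msms_scores or {}

    formulas = list(groups)
    theo_mz = np.array([deprotonated_mz(parse_formula(f)) for f in formulas])
    order = np.argsort(theo_mz)
    theo_sorted = theo_mz[order]

    pattern_cache: Dict[str, IsotopePattern] = {}
    feature_index = {id(f): i for i, f in enumerate(features)}

    results: List[MatchResult] = []
    for feat in filter_features(features, cfg):
        # conservative bracket, then exact per-candidate window check
        max_half = cfg.mass_tol_mda * 1e-3 + cfg.mass_tol_ppm * 1e-6 * (feat.mz + 0.01)
        lo = np.searchsorted(theo_sorted, feat.mz - max_half, side="left")
        hi = np.searchsorted(theo_sorted, feat.mz + max_half, side="right")
        feat_results: List[MatchResult] = []
        for j in range(lo, hi):
            idx = int(order[j])
            formula = formulas[idx]
            t = float(theo_mz[idx])
            low, high = mass_tolerance_window(t, cfg)
            if not (low <= feat.mz <= high):
                continue
            err = feat.mz - t
            if formula not in pattern_cache:
                pattern_cache[formula] = isotope_pattern(
                    parse_formula(formula), ion=IonSpec(), n_peaks=cfg.n_isotope_peaks
                )
            iso_score = score_isotopes(feat, pattern_cache[formula], cfg)
            defect_ok = mass_defect_filter(feat, t, cfg)
            components = {
                "mass": _mass_score(err, t, cfg),
                "isotope": iso_score,
                "defect": 100.0 if defect_ok else 0.0,
            }
            msms = msms_scores.get(feature_index[id(feat)])
            if msms is not None:
                components["msms"] = float(msms)
            relevance = _relevance(components, cfg)
            if relevance < cfg.relevance_threshold:
                continue
            feat_results.append(
                MatchResult(
                    feature=feat,
                    formula=formula,
                    combos=tuple(e.combo_string for e in groups[formula]),
                    calculated_mz=t,
                    error_mda=err * 1e3,
                    error_ppm=ppm_error(feat.mz, t),
                    mass_score=components["mass"],
                    isotope_score=iso_score,
                    mass_defect_pass=defect_ok,
                    msms_score=msms,
                    relevance=relevance,
                )
            )
        feat_results.sort(key=lambda r: (-r.relevance, abs(r.error_ppm), r.formula))
        results.extend(
            replace(r, rank=k) for k, r in enumerate(feat_results, start=1)
        )
    return results


_RESULT_COLUMNS = [
    "calculated_mz",
    "observed_mz",
    "error_mda",
    "error_ppm",
    "isotope_score",
    "relevance",
    "rank",
    "rt",
    "height",
    "formula",
    "combos",
]


def export_results(results: Sequence[MatchResult], path) -> None:
    """Write the scored result table as CSV (m/z to 4 decimal places)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RESULT_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    f"{r.calculated_mz:.4f}",
                    f"{r.feature.mz:.4f}",
                    f"{r.error_mda:.2f}",
                    f"{r.error_ppm:.2f}",
                    f"{r.isotope_score:.1f}",
                    f"{r.relevance:.1f}",
                    r.rank,
                    f"{r.feature.rt:.2f}",
                    f"{r.feature.height:.0f}",
                    r.formula,
                    " | ".join(r.combos),
                ]
            )
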