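"""Feature filtering, tolerance windows, scoring and matching."""

import csv

import pytest
from hypothesis import given, settings, strategies as st

from flavohunt.feature_matcher import (
    Feature,
    MatchConfig,
    export_results,
    filter_features,
    load_feature_table,
    mass_defect_filter,
    mass_tolerance_window,
    match_features,
    score_isotopes,
    write_feature_table,
)
from flavohunt.formula_engine import (
    IonSpec,
    deprotonated_mz,
    isotope_pattern,
    parse_formula,
)


CFG = MatchConfig()


def _astilbin_feature(exact_isotopes=True, mz=449.1107):
    pat = isotope_pattern(parse_formula("C21H22O11"), ion=IonSpec(), n_peaks=4)
    iso = tuple(pat.peaks[1:]) if exact_isotopes else ()
    return Feature(mz=mz, rt=10.6, height=5e5, isotope_peaks=iso)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_load_feature_table(tmp_path):
    path = tmp_path / "f.csv"
    path.write_text(
        "mz,rt,height,area,iso1_mz,iso1_ab\n"
        "449.1107,10.6,500000,1e6,450.1139,22.9\n"
        "289.0718,3.8,1200,,,\n"
        "611.1388,21.9,900,,612.1419,33.1\n"
    )
    feats = load_feature_table(path)
    assert len(feats) == 3
    assert feats[0].rt == 10.6
    assert feats[0].isotope_peaks == ((450.1139, 22.9),)
    assert feats[1].isotope_peaks == ()


def test_load_feature_table_reports_bad_row(tmp_path):
    path = tmp_path / "f.csv"
    path.write_text("mz,rt,height\n449.1107,10.6,5e5\n,11.0,100\n")
    with pytest.raises(ValueError, match="line 3"):
        load_feature_table(path)


def test_load_feature_table_requires_columns(tmp_path):
    path = tmp_path / "f.csv"
    path.write_text("mz,rt\n449.1,10.6\n")
    with pytest.raises(ValueError, match="mz,rt,height"):
        load_feature_table(path)


def test_feature_table_round_trip(tmp_path):
    feats = [
        _astilbin_feature(),
        Feature(mz=289.0718, rt=3.8, height=1200.0),
    ]
    path = tmp_path / "out.csv"
    write_feature_table(feats, path)
    back = load_feature_table(path)
    assert len(back) == 2
    assert back[0].mz == pytest.approx(feats[0].mz, abs=1e-6)
    assert len(back[0].isotope_peaks) == 3


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mz,rt,height,kept",
    [
        (449.1, 3.0, 1000, False),   # before the 4 min window
        (449.1, 4.0, 1000, True),    # window closed at both ends
        (449.1, 50.0, 1000, True),
        (449.1, 50.1, 1000, False),
        (449.1, 10.0, 200, False),   # "over 200 counts" is strict
        (449.1, 10.0, 201, True),
        (1500.0, 10.0, 1000, False),  # outside m/z range
        (200.0, 10.0, 1000, True),
        (150.0, 10.0, 1000, False),
    ],
)
def test_filter_feature_boundaries(mz, rt, height, kept):
    feats = [Feature(mz=mz, rt=rt, height=height)]
    assert (len(filter_features(feats, CFG)) == 1) is kept


def test_filter_is_idempotent():
    feats = [
        Feature(mz=300.0, rt=3.0, height=1e4),
        Feature(mz=300.0, rt=30.0, height=1e4),
        Feature(mz=300.0, rt=30.0, height=100),
    ]
    once = filter_features(feats, CFG)
    assert filter_features(once, CFG) == once


# ---------------------------------------------------------------------------
# tolerance window and component scores
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "theo,half",
    [(449.1089, 4.515e-3), (629.1512, 5.523e-3)],
)
def test_mass_tolerance_window_half_width(theo, half):
    lo, hi = mass_tolerance_window(theo, CFG)
    assert (hi - lo) / 2 == pytest.approx(half, abs=2e-6)
    assert (hi + lo) / 2 == pytest.approx(theo, abs=1e-12)


def test_mass_tolerance_window_requires_positive_mz():
    with pytest.raises(ValueError):
        mass_tolerance_window(0.0, CFG)


def test_score_isotopes_exact_and_limit():
    pat = isotope_pattern(parse_formula("C21H22O11"), ion=IonSpec(), n_peaks=4)
    exact = Feature(mz=449.1107, rt=10.0, height=1e4, isotope_peaks=tuple(pat.peaks[1:]))
    assert score_isotopes(exact, pat, CFG) == pytest.approx(100.0)
    # every cluster off by exactly the 7.5 % relative tolerance scores zero
    off = Feature(
        mz=449.1107, rt=10.0, height=1e4,
        isotope_peaks=tuple((mz, ab * 1.075) for mz, ab in pat.peaks[1:]),
    )
    assert score_isotopes(off, pat, CFG) == pytest.approx(0.0, abs=1e-9)
    # 2.5 % relative error -> at least 66.7
    mid = Feature(
        mz=449.1107, rt=10.0, height=1e4,
        isotope_peaks=tuple((mz, ab * 1.025) for mz, ab in pat.peaks[1:]),
    )
    assert score_isotopes(mid, pat, CFG) >= 66.6


def test_score_isotopes_neutral_when_absent():
    pat = isotope_pattern(parse_formula("C21H22O11"), ion=IonSpec(), n_peaks=4)
    bare = Feature(mz=449.1107, rt=10.0, height=1e4)
    assert score_isotopes(bare, pat, CFG) == CFG.neutral_isotope_score


@pytest.mark.parametrize(
    "obs,cand,passes",
    [
        (449.1107, 449.1089, True),   # 1.8 mDa defect gap
        (449.40, 449.1089, False),    # 0.29 Da defect gap
        (449.1089, 449.1089, True),
        (450.1107, 449.1089, True),   # nominal masses aligned before compare
    ],
)
def test_mass_defect_filter(obs, cand, passes):
    feat = Feature(mz=obs, rt=10.0, height=1e4)
    assert mass_defect_filter(feat, cand, CFG) is passes


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_astilbin_top_hit_against_full_db(flavanonol_groups):
    """A feature at the astilbin ion with theory-matching isotopes must
    rank C21H22O11 first across the whole flavanonol database."""
    res = match_features([_astilbin_feature()], flavanonol_groups, CFG)
    assert res and res[0].rank == 1
    assert res[0].formula == "C21H22O11"
    assert any("rhamnosylation" in c for c in res[0].combos)
    assert res[0].relevance >= CFG.relevance_threshold


def test_no_hit_when_tolerance_shrunk(flavanonol_groups):
    tight = MatchConfig(mass_tol_mda=1e-6, mass_tol_ppm=1.0)
    res = match_features([_astilbin_feature()], flavanonol_groups, tight)
    assert res == []


def test_empty_db_rejected():
    with pytest.raises(ValueError):
        match_features([_astilbin_feature()], {}, CFG)


@given(st.floats(min_value=200.0, max_value=1000.0))
@settings(derandomize=True, max_examples=80, deadline=None)
def test_window_membership_matches_linear_scan(small_groups, obs_mz):
    """A candidate is scored iff |obs - theo| <= 2.0 mDa + 5.6 ppm x theo,
    verified against a brute-force scan over every database formula."""
    cfg = MatchConfig(relevance_threshold=0.0)
    feat = Feature(mz=obs_mz, rt=25.0, height=1e4)
    res = match_features([feat], small_groups, cfg)
    got = {r.formula for r in res}
    expected = set()
    for formula in small_groups:
        theo = deprotonated_mz(parse_formula(formula))
        if abs(obs_mz - theo) <= 0.002 + 5.6e-6 * theo:
            expected.add(formula)
    assert got == expected


def test_relevance_monotone_in_mass_error(flavanonol_groups):
    theo = 449.1089
    rels = []
    for offset in (0.0, 1.0e-3, 2.0e-3, 3.0e-3):
        feat = _astilbin_feature(mz=theo + offset)
        res = [r for r in match_features([feat], flavanonol_groups,
                                         MatchConfig(relevance_threshold=0.0))
               if r.formula == "C21H22O11"]
        rels.append(res[0].relevance)
    assert all(a >= b for a, b in zip(rels, rels[1:]))


def test_relevance_monotone_in_isotope_error(flavanonol_groups):
    pat = isotope_pattern(parse_formula("C21H22O11"), ion=IonSpec(), n_peaks=4)
    rels = []
    for scale in (1.0, 1.02, 1.05, 1.074):
        feat = Feature(
            mz=449.1089, rt=10.6, height=5e5,
            isotope_peaks=tuple((mz, ab * scale) for mz, ab in pat.peaks[1:]),
        )
        res = [r for r in match_features([feat], flavanonol_groups,
                                         MatchConfig(relevance_threshold=0.0))
               if r.formula == "C21H22O11"]
        rels.append(res[0].relevance)
    assert all(a >= b for a, b in zip(rels, rels[1:]))


def test_export_results(tmp_path, flavanonol_groups):
    res = match_features([_astilbin_feature()], flavanonol_groups, CFG)
    path = tmp_path / "results.csv"
    export_results(res, path)
    rows = list(csv.DictReader(path.open()))
    assert len(rows) == len(res)
    top = rows[0]
    assert top["calculated_mz"] == "449.1089"
    assert top["observed_mz"] == "449.1107"
    export_results([], tmp_path / "empty.csv")
    assert (tmp_path / "empty.csv").read_text().count("\n") == 1


def test_weights_must_sum_to_100():
    with pytest.raises(ValueError):
        MatchConfig(weights={"mass": 50.0, "isotope": 30.0, "defect": 10.0, "msms": 5.0})
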