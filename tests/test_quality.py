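"""DIAAR/DIAAS scoring, limiting amino acid, product comparison."""

import pytest

from nutriferm.aa import AaMeasurement, AminoAcidProfile
from nutriferm.digestibility import DigestionRecord, aa_digestibility
from nutriferm.quality import (
    AGE_GROUPS,
    SCORING_UNITS,
    ProteinQualityResult,
    ReferencePattern,
    compare_products,
    diaar,
    diaas,
    load_reference_pattern,
    score_product,
)

UNIFORM = ReferencePattern(
    age_group="older_child_adolescent_adult",
    requirements=dict.fromkeys(SCORING_UNITS, 48.0),
)


def full_content(value=48.0, **overrides):
    out = dict.fromkeys(SCORING_UNITS, value)
    out.update(overrides)
    return out


def test_diaar_self_referential_requirement():
    out = diaar(full_content(48.0), dict.fromkeys(SCORING_UNITS, 80.0), UNIFORM)
    assert all(v == pytest.approx(80.0) for v in out.values())


def test_diaar_zero_digestibility():
    out = diaar(full_content(), dict.fromkeys(SCORING_UNITS, 0.0), UNIFORM)
    assert all(v == 0.0 for v in out.values())


def test_diaar_hand_chain():
    # Lys 43.5 mg/g (0.87 g/100 g at 20 % protein), 90 % digestible, req 48
    out = diaar(full_content(Lys=43.5), dict.fromkeys(SCORING_UNITS, 90.0), UNIFORM)
    assert out["Lys"] == pytest.approx(43.5 * 0.9 / 48 * 100)  # 81.5625


def test_diaar_missing_unit_error():
    content = full_content()
    del content["Val"]
    with pytest.raises(ValueError, match="Val"):
        diaar(content, dict.fromkeys(SCORING_UNITS, 80.0), UNIFORM)


def test_diaas_minimum_and_tie():
    assert diaas({"Lys": 90, "Val": 70, "SAA": 85}) == (70, "Val", False)
    value, unit, tie = diaas(dict.fromkeys(SCORING_UNITS, 100.0))
    assert (value, unit, tie) == (100.0, "His", True)
    with pytest.raises(ValueError):
        diaas({})


def test_diaas_never_exceeds_any_diaar_and_nonlimiting_removal():
    ratios = {"His": 91.0, "Val": 70.0, "Lys": 85.0}
    value, limiting, _ = diaas(ratios)
    assert all(value <= v for v in ratios.values())
    without = {u: v for u, v in ratios.items() if u != "His"}
    assert diaas(without)[0] == value


def test_diaar_linear_in_digestibility():
    low = diaar(full_content(), dict.fromkeys(SCORING_UNITS, 40.0), UNIFORM)
    high = diaar(full_content(), dict.fromkeys(SCORING_UNITS, 80.0), UNIFORM)
    for unit in SCORING_UNITS:
        assert high[unit] == pytest.approx(2 * low[unit])


@pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
def test_requirement_scaling_inverts_scores(k):
    scaled = ReferencePattern(
        age_group=UNIFORM.age_group,
        requirements={u: r * k for u, r in UNIFORM.requirements.items()},
    )
    base = diaar(full_content(Lys=30.0), dict.fromkeys(SCORING_UNITS, 75.0), UNIFORM)
    out = diaar(full_content(Lys=30.0), dict.fromkeys(SCORING_UNITS, 75.0), scaled)
    for unit in SCORING_UNITS:
        assert out[unit] == pytest.approx(base[unit] / k)
    assert diaas(out)[0] == pytest.approx(diaas(base)[0] / k)


def test_reference_pattern_file():
    for age_group in AGE_GROUPS:
        pattern = load_reference_pattern(age_group)
        assert set(pattern.requirements) == set(SCORING_UNITS)
        assert all(v > 0 for v in pattern.requirements.values())
    with pytest.raises(FileNotFoundError):
        load_reference_pattern(path="does/not/exist.yaml")
    with pytest.raises(ValueError):
        load_reference_pattern("toddlers")


def test_degraded_saa_becomes_limiting(published_profiles):
    """A product whose Met/Cys digestibility is knocked down scores SAA as
    its limiting amino acid, mirroring the standard products' behaviour."""
    profile = published_profiles["ST"]
    pattern = load_reference_pattern()
    food = {c: profile.contents[c].mean * 1000 for c in profile.contents}

    def records(saa_d):
        d = {c: 0.9 for c in food}
        d.update(Met=saa_d, Cys=saa_d)
        pellet = {c: food[c] * (1 - d[c]) for c in food if c != "Trp"}
        return DigestionRecord(
            product_id="ST", food_content=food, pellet_content=pellet,
            trp_supernatant=food["Trp"] * 0.9,
        )

    degraded = score_product(profile, aa_digestibility(records(0.2)), pattern)
    intact = score_product(profile, aa_digestibility(records(0.9)), pattern)
    assert degraded.limiting == "SAA"
    assert intact.limiting != "SAA"
    assert degraded.diaas < intact.diaas


def qresult(product, value, limiting="SAA", age_group="older_child_adolescent_adult"):
    return ProteinQualityResult(
        product_id=product, diaar={}, diaas=value, limiting=limiting, age_group=age_group
    )


def test_compare_products_published_deltas():
    turkey = compare_products(qresult("ST", 66.68), qresult("RT", 86.24, "Val"))
    assert turkey["diaas_diff"] == pytest.approx(19.56)
    assert turkey["limiting_shifted"]
    ham = compare_products(qresult("SH", 57.14), qresult("RH", 90.05, "Val"))
    assert ham["diaas_diff"] == pytest.approx(32.91)


def test_compare_products_identity_and_mismatch():
    a = qresult("X", 80.0)
    same = compare_products(a, qresult("X", 80.0))
    assert same["diaas_diff"] == 0.0
    assert not same["limiting_shifted"]
    with pytest.raises(ValueError, match="age-group mismatch"):
        compare_products(a, qresult("Y", 70.0, age_group="infant"))


def test_score_product_replicate_sd_propagation(simple_profile):
    profile = AminoAcidProfile(
        "rep",
        {code: AaMeasurement(0.5) for code in
         ("His", "Ile", "Leu", "Lys", "Met", "Cys", "Phe", "Tyr", "Thr", "Trp", "Val")},
        protein_pct=20.0,
    )
    pattern = load_reference_pattern()
    food = {c: 500.0 for c in profile.contents}

    def rec(d):
        pellet = {c: food[c] * (1 - d) for c in food if c != "Trp"}
        return DigestionRecord(product_id="rep", food_content=food,
                               pellet_content=pellet, trp_supernatant=food["Trp"] * d)

    per_rep = [aa_digestibility(rec(0.7)), aa_digestibility(rec(0.9))]
    res = score_product(profile, per_rep, pattern)
    mid = score_product(profile, aa_digestibility(rec(0.8)), pattern)
    assert res.diaas == pytest.approx(mid.diaas)
    assert res.diaas_sd > 0


def test_truncate_flag_caps_at_100(published_profiles):
    profile = published_profiles["ST"]
    food = {c: profile.contents[c].mean * 1000 for c in profile.contents}
    rec = DigestionRecord(
        product_id="ST", food_content=food,
        pellet_content={c: 0.0 for c in food if c != "Trp"},
        trp_supernatant=food["Trp"],
    )
    pattern = load_reference_pattern()
    raw = score_product(profile, aa_digestibility(rec), pattern)
    capped = score_product(profile, aa_digestibility(rec), pattern, truncate=True)
    assert max(m for m, _ in raw.diaar.values()) > 100.0
    assert max(m for m, _ in capped.diaar.values()) <= 100.0
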