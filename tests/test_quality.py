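"""Quality criteria: per-relative rule, per-pedigree scoring, threshold
sweep and no-data analysis."""

import itertools
import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from famhx import (
    Cohort,
    ConditionRecord,
    CriterionId,
    Pedigree,
    RelationCode,
    assess_pedigree,
    hq_sweep,
    no_data_analysis,
    relative_is_high_quality,
)
from conftest import rel, small_pedigree

R = RelationCode


def enumerate_relative_variants():
    """All small attribute combinations for one relative: reporting state x
    gender x affection/onset pattern x vital status x death-field pattern."""
    affection = {
        "unaffected": [],
        "one_no_onset": [ConditionRecord("diabetes")],
        "one_with_onset": [ConditionRecord("diabetes", 50.0)],
        "two_one_onset": [ConditionRecord("breast_cancer", 42.0), ConditionRecord("thrombosis")],
        "two_no_onset": [ConditionRecord("breast_cancer"), ConditionRecord("thrombosis")],
    }
    for data, gender, (aff_key, conds), vital, aod, cod in itertools.product(
        [True, False],
        ["female", "male", "unknown"],
        affection.items(),
        ["alive", "deceased"],
        [None, 80.0],
        [None, "heart_attack"],
    ):
        if vital == "alive" and (aod is not None or cod is not None):
            continue  # invariant: death fields only on deceased
        if not data and (conds or aod is not None or cod is not None):
            continue  # invariant: no-data relatives carry no fields
        yield data, gender, aff_key, conds, vital, aod, cod


def oracle_high_quality(data, gender, aff_key, vital, aod, cod):
    """Exhaustive hand-specified truth table, case by case."""
    if not data:
        return False
    if gender == "unknown":
        return False
    if vital == "deceased":
        if aod is None or cod is None:
            return False
    # onset criterion: affected relatives need at least one onset age
    if aff_key in ("one_no_onset", "two_no_onset"):
        return False
    return True  # unaffected, or count-once onset satisfied


def test_high_quality_matches_exhaustive_truth_table():
    n = 0
    for data, gender, aff_key, conds, vital, aod, cod in enumerate_relative_variants():
        r = rel("x", R.MOTHER, gender=gender, vital=vital, aod=aod, cod=cod,
                conditions=[ConditionRecord(c.disease, c.age_of_onset) for c in conds],
                data=data)
        expected = oracle_high_quality(data, gender, aff_key, vital, aod, cod)
        assert relative_is_high_quality(r) == expected, (
            data, gender, aff_key, vital, aod, cod)
        n += 1
    # reported: 3 genders x 5 affection patterns x (1 alive + 4 deceased
    # field patterns) = 75; no-data: 3 genders x 2 vital states = 6
    assert n == 81


def test_high_quality_rejects_proband():
    with pytest.raises(ValueError):
        relative_is_high_quality(rel("p", R.PROBAND))


def test_unaffected_living_reported_relative_is_high_quality():
    """Vacuous satisfaction: nothing applicable to fail."""
    assert relative_is_high_quality(rel("a", R.SISTER, "female"))


def test_affected_relative_needs_onset_for_only_one_disease():
    aunt = rel("a", R.MATERNAL_AUNT, "female",
               conditions=[ConditionRecord("breast_cancer", 42.0), ConditionRecord("thrombosis")])
    assert relative_is_high_quality(aunt)


def test_deceased_relative_needs_both_age_and_cause():
    gf = rel("g", R.MATERNAL_GRANDFATHER, "male", "deceased", aod=80)
    assert not relative_is_high_quality(gf)
    gf.cause_of_death = "heart_attack"
    assert relative_is_high_quality(gf)


def _death_pedigree(n_dead, n_age, n_cause, n_both):
    """Pedigree with n_dead deceased brothers carrying the given numbers of
    age/cause fields (the first n_both carry both)."""
    rels = [rel("m", R.MOTHER, "female"), rel("gm", R.MATERNAL_GRANDMOTHER, "female")]
    for i in range(n_dead):
        aod = 70.0 if i < n_age else None
        cod = "cancer" if (i < n_both or n_age <= i < n_age + (n_cause - n_both)) else None
        rels.append(rel(f"d{i}", R.BROTHER, "male", "deceased", aod=aod, cod=cod))
    return Pedigree("D", rel("p", R.PROBAND, "female"), rels)


def test_death_reporting_proportions():
    ped = _death_pedigree(n_dead=10, n_age=9, n_cause=3, n_both=2)
    q = assess_pedigree(ped)
    assert q.prop_age_of_death == pytest.approx(0.9)
    assert q.prop_cause_of_death == pytest.approx(0.3)
    assert q.prop_age_and_cause == pytest.approx(0.2)
    assert q.prop_age_and_cause <= min(q.prop_cause_of_death, q.prop_age_of_death)

    ped4 = _death_pedigree(n_dead=4, n_age=4, n_cause=1, n_both=1)
    assert assess_pedigree(ped4).prop_age_and_cause == pytest.approx(0.25)


def test_death_criteria_not_applicable_without_deceased():
    ped = Pedigree("A", rel("p", R.PROBAND), [rel("m", R.MOTHER, "female")])
    q = assess_pedigree(ped)
    assert q.criterion_met[CriterionId.C6_CAUSE_OF_DEATH] is None
    assert q.criterion_met[CriterionId.C7_AGE_OF_DEATH] is None
    assert math.isnan(q.prop_cause_of_death)


def test_onset_denominator_modes():
    rels = [
        rel("a", R.MOTHER, "female", conditions=[ConditionRecord("diabetes", 50.0)]),
        rel("b", R.SISTER, "female", conditions=[ConditionRecord("asthma")]),
        rel("c", R.BROTHER, "male"),
        rel("d", R.FATHER, "male"),
    ]
    ped = Pedigree("O", rel("p", R.PROBAND), rels)
    assert assess_pedigree(ped, "affected").prop_onset == pytest.approx(0.5)
    assert assess_pedigree(ped, "all").prop_onset == pytest.approx(0.25)
    with pytest.raises(ValueError):
        assess_pedigree(ped, "bogus")


def test_assessment_invariant_to_relative_order():
    ped = _death_pedigree(n_dead=5, n_age=4, n_cause=2, n_both=1)
    base = assess_pedigree(ped)
    rng = random.Random(3)
    for _ in range(5):
        rng.shuffle(ped.relatives)
        q = assess_pedigree(ped)
        assert q.criterion_met == base.criterion_met
        assert q.n_hq_relatives == base.n_hq_relatives
        assert q.prop_age_of_death == base.prop_age_of_death


def test_all_high_quality_pedigree_meets_applicable_criteria():
    ped = small_pedigree()
    ped.relatives.append(
        rel("P1-5", R.MATERNAL_AUNT, "female", conditions=[ConditionRecord("diabetes", 48.0)])
    )
    q = assess_pedigree(ped)
    assert all(relative_is_high_quality(r) for r in ped.relatives)
    for cid in (CriterionId.C2_LINEAGE, CriterionId.C3_GENDER, CriterionId.C5_AGE_OF_ONSET,
                CriterionId.C6_CAUSE_OF_DEATH, CriterionId.C7_AGE_OF_DEATH):
        assert q.criterion_met[cid] is True


def ped_with_fraction(pid, n_hq, n_rel):
    """Pedigree whose fraction of high-quality relatives is n_hq/n_rel
    (unknown gender disqualifies the remainder)."""
    rels = [rel(f"{pid}-{i}", R.SISTER, "female" if i < n_hq else "unknown")
            for i in range(n_rel)]
    return Pedigree(pid, rel(f"{pid}-0", R.PROBAND), rels)


def test_hq_sweep_examples_and_monotonicity():
    cohort = Cohort([
        ped_with_fraction("a", 2, 10),   # 0.2
        ped_with_fraction("b", 5, 10),   # 0.5
        ped_with_fraction("c", 9, 10),   # 0.9
    ])
    curve = dict(hq_sweep(cohort, [0.0, 0.4, 0.95]))
    assert curve[0.0] == 1.0
    assert curve[0.4] == pytest.approx(2 / 3)
    assert curve[0.95] == 0.0

    full = hq_sweep(cohort)
    props = [p for _, p in full]
    assert full[0] == (0.0, 1.0)
    assert all(a >= b for a, b in zip(props, props[1:]))

    with pytest.raises(ValueError):
        hq_sweep(Cohort([]))
    with pytest.raises(ValueError):
        hq_sweep(cohort, [1.5])


@given(st.lists(
    st.tuples(st.integers(0, 8), st.integers(1, 8)),
    min_size=1, max_size=15,
))
@settings(deadline=None, derandomize=True, max_examples=40)
def test_hq_sweep_monotone_for_arbitrary_hq_fractions(specs):
    """Property: for any mix of pedigree HQ fractions the sweep starts at
    exactly 1.0 and is monotone non-increasing."""
    cohort = Cohort([
        ped_with_fraction(f"h{i}", min(a, b), b) for i, (a, b) in enumerate(specs)
    ])
    curve = hq_sweep(cohort)
    assert curve[0] == (0.0, 1.0)
    props = [p for _, p in curve]
    assert all(0.0 <= p <= 1.0 for p in props)
    assert all(a >= b for a, b in zip(props, props[1:]))


def test_no_data_analysis_ratios_and_marginalization():
    # 4 FDR all reported, 8 SDR of which 2 no-data, plus deceased gm
    rels = [rel(f"f{i}", R.SISTER, "female") for i in range(4)]
    rels += [rel(f"s{i}", R.MATERNAL_AUNT, "female", data=(i >= 2)) for i in range(8)]
    rels += [rel(f"g{i}", R.MATERNAL_GRANDMOTHER, "female") for i in range(1)]
    rels += [rel(f"h{i}", R.PATERNAL_UNCLE, "male") for i in range(7)]
    ped = Pedigree("N", rel("p", R.PROBAND), rels)  # 20 relatives
    out = no_data_analysis(Cohort([ped]))
    assert out["fdr"].mean_prop_all == 0.0
    assert out["sdr"].mean_prop_all == pytest.approx(2 / 16)
    assert out["all"].mean_prop_all == pytest.approx(0.10)
    assert out["grandparents"].mean_prop_all == 0.0
    # marginalization: stratum totals add up to the cohort-wide count
    assert out["all"].total_no_data == 2
    assert out["fdr"].total_no_data + out["sdr"].total_no_data == 2


def test_no_data_analysis_all_reported_means_zero_and_empty_subgroup():
    out = no_data_analysis(Cohort([small_pedigree()]))
    assert out["all"].mean_prop_all == 0.0
    assert out["all"].n_pedigrees_with_nodata == 0
    assert math.isnan(out["all"].mean_prop_subgroup)
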