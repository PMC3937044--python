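"""Cohort statistics: prevalence, aggregation modes, deceased summary,
contact effect, sibling recurrence-risk ratio."""

import copy
import math

import pytest

from famhx import (
    ANY_DISEASE,
    AggregationMode,
    Cohort,
    ConditionRecord,
    DenominatorRule,
    GeneratorConfig,
    Pedigree,
    ProbandCovariates,
    RelationCode,
    contact_effect,
    criterion_summary,
    deceased_summary,
    generate,
    prevalence,
    sibling_lambda,
)
from conftest import rel, small_pedigree

R = RelationCode


def _ped(pid, proband_conds=(), sibs=(), talked=False, extra=()):
    """Pedigree with a proband, given sibling (gender, conditions) pairs
    and any extra relatives."""
    rels = [rel(f"{pid}-s{i}", R.SISTER if g == "female" else R.BROTHER, g,
                conditions=[ConditionRecord(d, 50.0) for d in conds])
            for i, (g, conds) in enumerate(sibs)]
    rels += list(extra)
    if not rels:
        rels = [rel(f"{pid}-m", R.MOTHER, "female")]
    return Pedigree(
        pid,
        rel(f"{pid}-0", R.PROBAND, "female",
            conditions=[ConditionRecord(d, 55.0) for d in proband_conds]),
        rels,
        ProbandCovariates(gender="female", talked_to_relatives=talked),
    )


# ----------------------------------------------------------------- prevalence

def test_prevalence_counts_each_person_once_per_disease():
    ped = _ped("A", proband_conds=["diabetes"],
               sibs=[("female", ["diabetes", "diabetes"]), ("male", [])])
    res = prevalence(Cohort([ped]), "diabetes")
    assert (res.numerator, res.denominator) == (2, 3)
    any_res = prevalence(Cohort([ped]), ANY_DISEASE)
    assert any_res.numerator == 2  # multi-condition person counts once overall


def test_prevalence_denominator_rules():
    ped = _ped("A", proband_conds=["breast_cancer"],
               sibs=[("female", ["breast_cancer"]), ("male", [])])
    c = Cohort([ped])
    females = prevalence(c, "breast_cancer", denominator_rule=DenominatorRule.FEMALES_ONLY)
    assert (females.numerator, females.denominator) == (2, 2)
    probands = prevalence(c, "breast_cancer", denominator_rule=DenominatorRule.PROBANDS_ONLY)
    assert (probands.numerator, probands.denominator) == (1, 1)
    absent = prevalence(c, "dementia")
    assert absent.value == 0.0


def test_no_data_relatives_in_denominator_never_numerator():
    ped = _ped("A", proband_conds=["diabetes"])
    ped.relatives.append(rel("A-x", R.MATERNAL_AUNT, "female", data=False))
    res = prevalence(Cohort([ped]), "diabetes")
    assert (res.numerator, res.denominator) == (1, 3)


def test_prevalence_additive_over_cohort_partition():
    cohort, _ = generate(GeneratorConfig(n_pedigrees=60, seed=11))
    half1, half2 = Cohort(cohort.pedigrees[:30]), Cohort(cohort.pedigrees[30:])
    full = prevalence(cohort, "diabetes")
    a, b = prevalence(half1, "diabetes"), prevalence(half2, "diabetes")
    assert full.numerator == a.numerator + b.numerator
    assert full.denominator == a.denominator + b.denominator


def test_aggregation_modes_collapse_on_identical_pedigrees():
    """by_proband and by_individual agree exactly when every pedigree is
    an identical copy (equal within-pedigree denominators)."""
    base = _ped("A", proband_conds=["diabetes"], sibs=[("male", []), ("female", [])])
    peds = []
    for i in range(5):
        p = copy.deepcopy(base)
        p.pedigree_id = f"A{i}"
        peds.append(p)
    c = Cohort(peds)
    by_ind = prevalence(c, "diabetes", AggregationMode.BY_INDIVIDUAL)
    by_pro = prevalence(c, "diabetes", AggregationMode.BY_PROBAND)
    assert by_pro.value == pytest.approx(by_ind.value)


def test_empty_denominator_flagged_undefined():
    ped = _ped("A")  # proband female; no males at all
    res = prevalence(Cohort([ped]), "diabetes",
                     denominator_rule=DenominatorRule.FEMALE_PROBANDS_ONLY)
    assert res.defined
    allmale = Cohort([Pedigree("B", rel("B-0", R.PROBAND, "male"),
                               [rel("B-1", R.FATHER, "male")])])
    res2 = prevalence(allmale, "diabetes", denominator_rule=DenominatorRule.FEMALES_ONLY)
    assert not res2.defined


# ----------------------------------------------------------- deceased summary

def test_deceased_summary_counts_and_shares():
    rels = [
        rel("d-m", R.MOTHER, "female", "deceased", aod=80),
        rel("d-f", R.FATHER, "male", "deceased", aod=82),
        rel("d-gm", R.MATERNAL_GRANDMOTHER, "female", "deceased"),
        rel("d-s", R.SISTER, "female"),
    ] + [rel(f"d-a{i}", R.MATERNAL_AUNT, "female") for i in range(5)]
    ped = Pedigree("D", rel("d-0", R.PROBAND, "female"), rels)  # 10 members, 3 deceased
    s = deceased_summary(Cohort([ped]))
    assert s.mean_prop == pytest.approx(0.3)
    assert s.prevalence_individuals == pytest.approx(0.3)
    assert s.fdr_share == pytest.approx(2 / 3)
    assert s.sdr_share == pytest.approx(1 / 3)
    assert s.grandparent_share_of_sdr == pytest.approx(1.0)
    assert s.fdr_share + s.sdr_share <= 1.0 + 1e-12


def test_deceased_summary_no_deceased():
    ped = _ped("A", sibs=[("male", [])])
    s = deceased_summary(Cohort([ped]))
    assert s.n_deceased == 0
    assert s.prevalence_individuals == 0.0
    assert math.isnan(s.fdr_share)
    assert s.n_pedigrees_no_deceased == 1


# ------------------------------------------------------------- contact effect

def test_contact_effect_symmetry_and_complete_rate():
    talk = _ped("T", sibs=[("female", [])], talked=True)
    silent = _ped("S", sibs=[("female", [])], talked=False)
    eff = contact_effect(Cohort([talk, silent]))
    assert eff.mean_nodata_talked == eff.mean_nodata_not_talked == 0.0
    assert eff.complete_rate_talked == 1.0

    silent.relatives.append(rel("S-x", R.MATERNAL_AUNT, "female", data=False))
    eff2 = contact_effect(Cohort([talk, silent]))
    assert eff2.mean_nodata_talked == 0.0
    assert eff2.mean_nodata_not_talked == pytest.approx(0.5)
    assert eff2.complete_rate_not_talked == 0.0


def test_contact_effect_empty_group_flagged():
    eff = contact_effect(Cohort([_ped("T", talked=True)]))
    assert math.isnan(eff.mean_nodata_not_talked)
    assert eff.n_not_talked == 0


# -------------------------------------------------------------- sibling lambda

def toy_lambda_cohort():
    """4 pedigrees: 2 affected probands with 2 siblings each (3 of the 4
    siblings affected); 2 unaffected probands."""
    return Cohort([
        _ped("L1", proband_conds=["diabetes"],
             sibs=[("male", ["diabetes"]), ("female", ["diabetes"])]),
        _ped("L2", proband_conds=["diabetes"],
             sibs=[("male", ["diabetes"]), ("female", [])]),
        _ped("L3", sibs=[("male", [])]),
        _ped("L4", sibs=[("female", [])]),
    ])


def brute_force_lambda(cohort, disease):
    """Independent oracle: raw counting loops straight off the data model."""
    probands = [p.proband for p in cohort.pedigrees]
    aff = [p for p in cohort.pedigrees
           if any(c.disease == disease for c in p.proband.conditions)]
    prev = len(aff) / len(probands)
    sibs = [r for p in aff for r in p.relatives
            if r.relation in (R.SISTER, R.BROTHER)]
    aff_sibs = [s for s in sibs if any(c.disease == disease for c in s.conditions)]
    return (len(aff_sibs) / len(sibs)) / prev


def test_sibling_lambda_toy_cohort_hand_enumerated():
    c = toy_lambda_cohort()
    est = sibling_lambda(c, "diabetes", n_bootstrap=10, seed=0)
    # prevalence 2/4, sibling risk 3/4 -> lambda = (3/4)/(1/2) = 1.5
    assert est.lam == pytest.approx(1.5)
    assert est.lam == pytest.approx(brute_force_lambda(c, "diabetes"))
    assert est.n_affected_probands == 2
    assert est.n_siblings_of_affected == 4
    assert est.n_affected_siblings == 3


def test_sibling_lambda_sex_restriction():
    c = toy_lambda_cohort()
    est = sibling_lambda(c, "diabetes", sex_restrict=True, susceptible_sex="female",
                         n_bootstrap=10, seed=0)
    # female probands: 4, affected 2; female sibs of affected: 2, affected 1
    assert est.n_eligible_probands == 4
    assert est.n_siblings_of_affected == 2
    assert est.lam == pytest.approx((1 / 2) / (2 / 4))


def test_sibling_lambda_undefined_cases_flagged_not_raised():
    no_aff = Cohort([_ped("X", sibs=[("male", [])])])
    est = sibling_lambda(no_aff, "diabetes", n_bootstrap=5, seed=0)
    assert not est.defined
    # affected proband but no siblings
    only_mother = Cohort([_ped("Y", proband_conds=["diabetes"])])
    est2 = sibling_lambda(only_mother, "diabetes", n_bootstrap=5, seed=0)
    assert not est2.defined


def test_sibling_lambda_order_and_seed_invariance_of_point_estimate():
    c = toy_lambda_cohort()
    a = sibling_lambda(c, "diabetes", n_bootstrap=50, seed=1)
    reordered = Cohort(list(reversed(c.pedigrees)))
    b = sibling_lambda(reordered, "diabetes", n_bootstrap=50, seed=99)
    assert a.lam == b.lam


def test_bootstrap_reproducible_and_brackets_estimate():
    cohort, _ = generate(GeneratorConfig(n_pedigrees=400, seed=7))
    e1 = sibling_lambda(cohort, "diabetes", n_bootstrap=300, seed=42)
    e2 = sibling_lambda(cohort, "diabetes", n_bootstrap=300, seed=42)
    assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)
    assert 0.0 <= e1.ci_low <= e1.ci_high
    assert e1.ci_low <= e1.lam <= e1.ci_high


def test_ci_width_shrinks_with_cohort_size():
    widths = []
    for n, seed in [(100, 3), (400, 3), (1600, 3)]:
        cohort, _ = generate(GeneratorConfig(n_pedigrees=n, seed=seed))
        e = sibling_lambda(cohort, "diabetes", n_bootstrap=400, seed=5)
        widths.append(e.ci_high - e.ci_low)
    assert widths[0] > widths[1] > widths[2]


# ----------------------------------------------------------- criterion summary

def test_criterion_summary_all_complete_cohort():
    peds = []
    for i in range(4):
        p = small_pedigree(f"C{i}")
        p.relatives.append(
            rel(f"C{i}-a", R.MATERNAL_AUNT, "female",
                conditions=[ConditionRecord("diabetes", 48.0)]))
        peds.append(p)
    s = criterion_summary(Cohort(peds))
    assert all(pct == 100.0 for pct in s.criterion_pct.values())
    assert s.high_quality_pct == 100.0
    assert s.proportions["age_of_death"].mean_all == 1.0
    assert s.proportions["onset"].mean_all == 1.0
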