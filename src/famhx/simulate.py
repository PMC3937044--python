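"""Synthetic family-health-history cohorts.

Two constructors live here:

* :func:`generate` draws stochastic cohorts with the statistical structure
  the analysis assumes — three-generation pedigrees of realistic size,
  per-disease prevalence, familial clustering with a *tunable sibling
  recurrence-risk ratio*, generation-dependent mortality, and a
  missing-data process concentrated in second-degree relatives and
  attenuated when the proband talked to relatives.

* :func:`make_fixture` deterministically builds a minimal cohort hitting
  exact requested counts (how many pedigrees meet each criterion, disease
  numerators/denominators, ...), so printed summary tables can be
  reproduced without the original data.

Familial clustering uses a two-point family frailty: with probability
``1/lambda`` a family is "at risk" and each member is affected
independently with probability ``lambda * p``; otherwise nobody is.  The
marginal prevalence is then exactly ``p`` and the induced sibling
recurrence-risk ratio exactly ``lambda`` — the calibration is closed-form
and requires only ``lambda >= 1`` and ``lambda * p <= 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .pedigree import (
    Cohort,
    ConditionRecord,
    GRANDPARENT_CODES,
    Pedigree,
    ProbandCovariates,
    Relative,
    RelationCode,
    Degree,
    degree_of,
)
from .stats import SEX_LIMITED_DISEASES

R = RelationCode


@dataclass
class DiseaseSpec:
    """One disease in the generator's disease table."""

    label: str
    base_prevalence: float
    sibling_lambda: float = 1.0
    sex_limited: Optional[str] = None  # None, "female" or "male"
    onset_mean: float = 55.0
    onset_sd: float = 12.0


def default_disease_table() -> list[DiseaseSpec]:
    """Disease table emulating the study cohort.

    Prevalences are the cohort's across-individuals rates; the sibling
    recurrence-risk ratios are the cohort estimates where available and
    field-typical values for the remaining diseases.
    """
    return [
        DiseaseSpec("breast_cancer", 0.0471, 2.61, sex_limited="female", onset_mean=61, onset_sd=12),
        DiseaseSpec("ovarian_cancer", 0.0097, 3.0, sex_limited="female", onset_mean=60, onset_sd=12),
        DiseaseSpec("colon_cancer", 0.0137, 27.86, onset_mean=65, onset_sd=12),
        DiseaseSpec("hereditary_cancer_syndromes", 0.0091, 5.0, onset_mean=50, onset_sd=14),
        DiseaseSpec("thrombosis", 0.0176, 2.0, onset_mean=55, onset_sd=15),
        DiseaseSpec("heart_attack", 0.0876, 5.89, onset_mean=60, onset_sd=13),
        DiseaseSpec("diabetes", 0.0636, 2.49, onset_mean=52, onset_sd=14),
        DiseaseSpec("asthma", 0.0282, 2.0, onset_mean=15, onset_sd=12),
        DiseaseSpec("dementia", 0.0360, 2.0, onset_mean=78, onset_sd=8),
    ]


@dataclass
class MissingDataConfig:
    """Per-relative no-data probabilities by stratum (rates for probands
    who did not contact relatives) and the contact attenuation factor."""

    p_nodata_fdr: float = 0.014
    p_nodata_sdr: float = 0.13
    p_nodata_grandparent: float = 0.22
    contact_reduction_factor: float = 0.46
    knowledge_beta: float = -0.15  # log-rate slope per Likert point


@dataclass
class FieldCompleteness:
    """Probability each detail field is filled when applicable."""

    p_onset_given_affected: float = 0.30
    p_cause_given_deceased: float = 0.12
    p_agedeath_given_deceased: float = 0.88


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_pedigrees: int = 1184
    seed: int = 0
    size_median: float = 21.0
    size_sigma: float = 0.35
    size_min: int = 8
    size_max: int = 71
    disease_table: list[DiseaseSpec] = field(default_factory=default_disease_table)
    deceased_rate_by_generation: dict[int, float] = field(
        default_factory=lambda: {-2: 0.97, -1: 0.65, 0: 0.22, 1: 0.03, 2: 0.01}
    )
    missing_data: MissingDataConfig = field(default_factory=MissingDataConfig)
    field_completeness: FieldCompleteness = field(default_factory=FieldCompleteness)
    p_talked: float = 0.5389
    mean_contacted: float = 2.89
    p_female_proband: float = 0.586
    proband_age_mean: float = 58.8
    proband_age_sd: float = 11.8
    ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: {"white": 0.818, "black": 0.135, "other": 0.047}
    )
    education_probs: tuple[float, float, float, float] = (0.133, 0.207, 0.389, 0.270)
    knowledge_mean: float = 4.30
    knowledge_sd: float = 1.30


def config_from_dict(data: dict) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a (YAML-loaded) mapping.

    Nested sections ``disease_table`` (list of mappings), ``missing_data``
    and ``field_completeness`` are converted to their dataclasses; unknown
    keys are rejected.
    """
    data = dict(data)
    kwargs: dict = {}
    if "disease_table" in data:
        kwargs["disease_table"] = [DiseaseSpec(**d) for d in data.pop("disease_table")]
    if "missing_data" in data:
        kwargs["missing_data"] = MissingDataConfig(**data.pop("missing_data"))
    if "field_completeness" in data:
        kwargs["field_completeness"] = FieldCompleteness(**data.pop("field_completeness"))
    if "deceased_rate_by_generation" in data:
        raw = data.pop("deceased_rate_by_generation")
        kwargs["deceased_rate_by_generation"] = {int(k): float(v) for k, v in raw.items()}
    valid = {f for f in GeneratorConfig.__dataclass_fields__}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
    kwargs.update(data)
    return GeneratorConfig(**kwargs)


@dataclass
class GeneratorTruth:
    """Ground-truth parameters realized by :func:`generate`: everything
    needed to compute the expected value of each downstream statistic."""

    n_pedigrees: int
    seed: int
    disease_truth: dict[str, dict[str, float]]
    config: dict


def _validate_config(cfg: GeneratorConfig) -> None:
    if cfg.n_pedigrees < 1:
        raise ValueError("n_pedigrees must be >= 1")
    for d in cfg.disease_table:
        if not (0.0 <= d.base_prevalence <= 1.0):
            raise ValueError(f"disease {d.label!r}: base_prevalence outside [0, 1]")
        if d.sibling_lambda < 1.0:
            raise ValueError(
                f"disease {d.label!r}: sibling_lambda {d.sibling_lambda} < 1 is not "
                "representable by a shared-frailty model"
            )
        if d.sibling_lambda * d.base_prevalence > 1.0:
            raise ValueError(
                f"disease {d.label!r}: infeasible calibration "
                f"(lambda {d.sibling_lambda} x prevalence {d.base_prevalence} > 1)"
            )
    md = cfg.missing_data
    for name in ("p_nodata_fdr", "p_nodata_sdr", "p_nodata_grandparent", "contact_reduction_factor"):
        v = getattr(md, name)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"missing_data.{name} outside [0, 1]")


# Composition of the non-fixed part of a pedigree (beyond proband, two
# parents and four grandparents): siblings, aunts/uncles, children,
# nieces/nephews, grandchildren.
_COMP_WEIGHTS = np.array([0.25, 0.35, 0.25, 0.10, 0.05])
_AUNT_UNCLE = [R.MATERNAL_AUNT, R.MATERNAL_UNCLE, R.PATERNAL_AUNT, R.PATERNAL_UNCLE]

_FIXED_CODES = [
    R.MOTHER,
    R.FATHER,
    R.MATERNAL_GRANDMOTHER,
    R.MATERNAL_GRANDFATHER,
    R.PATERNAL_GRANDMOTHER,
    R.PATERNAL_GRANDFATHER,
]

_CODE_GENDER = {
    R.MOTHER: "female",
    R.FATHER: "male",
    R.SISTER: "female",
    R.BROTHER: "male",
    R.DAUGHTER: "female",
    R.SON: "male",
    R.MATERNAL_GRANDMOTHER: "female",
    R.MATERNAL_GRANDFATHER: "male",
    R.PATERNAL_GRANDMOTHER: "female",
    R.PATERNAL_GRANDFATHER: "male",
    R.MATERNAL_AUNT: "female",
    R.MATERNAL_UNCLE: "male",
    R.PATERNAL_AUNT: "female",
    R.PATERNAL_UNCLE: "male",
    R.NIECE: "female",
    R.NEPHEW: "male",
}

_OFFSETS = {
    R.MOTHER: -1, R.FATHER: -1,
    R.MATERNAL_GRANDMOTHER: -2, R.MATERNAL_GRANDFATHER: -2,
    R.PATERNAL_GRANDMOTHER: -2, R.PATERNAL_GRANDFATHER: -2,
    R.MATERNAL_AUNT: -1, R.MATERNAL_UNCLE: -1,
    R.PATERNAL_AUNT: -1, R.PATERNAL_UNCLE: -1,
    R.SISTER: 0, R.BROTHER: 0, R.DAUGHTER: 1, R.SON: 1,
    R.NIECE: 1, R.NEPHEW: 1, R.GRANDCHILD: 2,
}


def _draw_size(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    raw = math.exp(rng.normal(math.log(cfg.size_median), cfg.size_sigma))
    return int(min(max(round(raw), cfg.size_min), cfg.size_max))


def _relative_codes(cfg: GeneratorConfig, size: int, rng: np.random.Generator) -> list[RelationCode]:
    codes = list(_FIXED_CODES)
    rem = size - 1 - len(codes)
    if rem > 0:
        n_sib, n_au, n_child, n_nn, n_gc = rng.multinomial(rem, _COMP_WEIGHTS)
        for _ in range(n_sib):
            codes.append(R.SISTER if rng.random() < 0.5 else R.BROTHER)
        for _ in range(n_au):
            codes.append(_AUNT_UNCLE[rng.integers(0, 4)])
        for _ in range(n_child):
            codes.append(R.DAUGHTER if rng.random() < 0.5 else R.SON)
        for _ in range(n_nn):
            codes.append(R.NIECE if rng.random() < 0.5 else R.NEPHEW)
        codes.extend([R.GRANDCHILD] * int(n_gc))
    return codes


def _nodata_base(code: RelationCode, md: MissingDataConfig) -> float:
    if code in GRANDPARENT_CODES:
        return md.p_nodata_grandparent
    return md.p_nodata_fdr if degree_of(code) is Degree.FIRST else md.p_nodata_sdr


def generate(cfg: GeneratorConfig) -> tuple[Cohort, GeneratorTruth]:
    """Draw a cohort from the generator; fully reproducible from the seed.

    Returns the cohort together with a :class:`GeneratorTruth` echoing the
    realized per-disease frailty parameters (at-risk family probability
    ``1/lambda`` and within-family risk ``lambda * p``).
    """
    _validate_config(cfg)
    rng = np.random.default_rng(cfg.seed)
    diseases = cfg.disease_table
    p_high = np.array([1.0 / d.sibling_lambda for d in diseases])
    p_aff_high = np.array([d.sibling_lambda * d.base_prevalence for d in diseases])
    md, fc = cfg.missing_data, cfg.field_completeness
    eth_labels = list(cfg.ethnicity_probs)
    eth_p = np.array([cfg.ethnicity_probs[k] for k in eth_labels])
    eth_p = eth_p / eth_p.sum()
    edu_p = np.asarray(cfg.education_probs) / sum(cfg.education_probs)

    pedigrees: list[Pedigree] = []
    for i in range(cfg.n_pedigrees):
        ped_id = f"S{i:05d}"
        size = _draw_size(cfg, rng)
        codes = _relative_codes(cfg, size, rng)
        n = len(codes)

        # --- proband covariates -------------------------------------
        pro_gender = "female" if rng.random() < cfg.p_female_proband else "male"
        pro_age = float(np.clip(rng.normal(cfg.proband_age_mean, cfg.proband_age_sd), 18, 92))
        talked = bool(rng.random() < cfg.p_talked)
        n_contacted = int(1 + rng.poisson(max(cfg.mean_contacted - 1.0, 0.0))) if talked else 0
        knowledge = int(np.clip(round(rng.normal(cfg.knowledge_mean, cfg.knowledge_sd)), 1, 7))
        cov = ProbandCovariates(
            age=round(pro_age),
            gender=pro_gender,
            ethnicity=eth_labels[int(rng.choice(len(eth_labels), p=eth_p))],
            education=int(rng.choice(4, p=edu_p)) + 1,
            talked_to_relatives=talked,
            n_relatives_contacted=n_contacted,
            fhh_knowledge=knowledge,
        )

        # --- family frailty and per-member affection ----------------
        at_risk = rng.random(len(diseases)) < p_high
        p_eff = np.where(at_risk, p_aff_high, 0.0)
        genders = [
            _CODE_GENDER.get(code) or ("female" if rng.random() < 0.5 else "male")
            for code in codes
        ]
        all_genders = [pro_gender] + genders
        aff = rng.random((n + 1, len(diseases))) < p_eff[None, :]
        for j, d in enumerate(diseases):
            if d.sex_limited is not None:
                sex_ok = np.array([g == d.sex_limited for g in all_genders])
                aff[:, j] &= sex_ok

        onset_present = rng.random((n + 1, len(diseases))) < fc.p_onset_given_affected
        onset_age = np.clip(
            rng.normal(
                [d.onset_mean for d in diseases], [d.onset_sd for d in diseases], (n + 1, len(diseases))
            ),
            1,
            100,
        )

        # --- mortality, ages, missingness ---------------------------
        offsets = np.array([_OFFSETS[c] for c in codes])
        p_dec = np.array([cfg.deceased_rate_by_generation.get(int(o), 0.0) for o in offsets])
        deceased = rng.random(n) < p_dec
        cur_age = np.clip(pro_age - 27.5 * offsets + rng.normal(0, 5, n), 0, 100)
        death_age = np.clip(rng.normal(74, 13, n), 1, 110)
        has_cause = rng.random(n) < fc.p_cause_given_deceased
        has_agedeath = rng.random(n) < fc.p_agedeath_given_deceased

        contact_factor = md.contact_reduction_factor if talked else 1.0
        know_factor = math.exp(md.knowledge_beta * (knowledge - cfg.knowledge_mean))
        p_nodata = np.clip(
            np.array([_nodata_base(c, md) for c in codes]) * contact_factor * know_factor, 0, 1
        )
        nodata = rng.random(n) < p_nodata

        # --- materialize --------------------------------------------
        def conditions_for(row: int) -> list[ConditionRecord]:
            out = []
            for j, d in enumerate(diseases):
                if aff[row, j]:
                    onset = round(float(onset_age[row, j])) if onset_present[row, j] else None
                    out.append(ConditionRecord(d.label, onset))
            return out

        proband = Relative(
            person_id=f"{ped_id}-0",
            relation=R.PROBAND,
            gender=pro_gender,
            vital_status="alive",
            current_age=round(pro_age),
            conditions=conditions_for(0),
            data_reported=True,
        )
        relatives: list[Relative] = []
        for k, code in enumerate(codes):
            if nodata[k]:
                relatives.append(
                    Relative(
                        person_id=f"{ped_id}-{k + 1}",
                        relation=code,
                        gender=genders[k],
                        vital_status="deceased" if deceased[k] else "alive",
                        data_reported=False,
                    )
                )
                continue
            is_dec = bool(deceased[k])
            conds = conditions_for(k + 1)
            cause = None
            if is_dec and has_cause[k]:
                cause = conds[0].disease if conds else "natural_causes"
            relatives.append(
                Relative(
                    person_id=f"{ped_id}-{k + 1}",
                    relation=code,
                    gender=genders[k],
                    vital_status="deceased" if is_dec else "alive",
                    current_age=None if is_dec else round(float(cur_age[k])),
                    age_at_death=round(float(death_age[k])) if (is_dec and has_agedeath[k]) else None,
                    cause_of_death=cause,
                    conditions=conds,
                    data_reported=True,
                )
            )
        pedigrees.append(Pedigree(ped_id, proband, relatives, cov))

    truth = GeneratorTruth(
        n_pedigrees=cfg.n_pedigrees,
        seed=cfg.seed,
        disease_truth={
            d.label: {
                "base_prevalence": d.base_prevalence,
                "sibling_lambda": d.sibling_lambda,
                "p_at_risk_family": 1.0 / d.sibling_lambda,
                "p_affected_at_risk": d.sibling_lambda * d.base_prevalence,
            }
            for d in diseases
        },
        config=asdict(cfg),
    )
    return Cohort(pedigrees), truth


# ---------------------------------------------------------------------
# Deterministic fixtures with exact counts
# ---------------------------------------------------------------------

#: Neutral disease label used for criterion-quota relatives so fixture
#: quality counts never collide with named-disease prevalence counts.
FIXTURE_CONDITION = "fixture_condition"

#: Summary counts of the primary-care FHH cohort whose structure the
#: generator defaults emulate: 1,184 enrolled probands, 27,406 recorded
#: individuals, pedigree-level criterion counts and per-disease affected
#: counts.  Feeding these to :func:`make_fixture` rebuilds a cohort on
#: which the pipeline returns the published summary percentages.
STUDY_SUMMARY_COUNTS: dict = dict(
    n_pedigrees=1184,
    n_individuals=27406,
    n_females=13659,
    n_deceased=12264,
    n_with_deceased=1179,
    n_with_onset=854,
    n_with_cause=695,
    n_with_agedeath=1156,
    n_with_both=479,
    n_high_quality=1182,
    n_female_probands=694,
    n_talked=638,
    proband_disease_counts={
        "breast_cancer": 45,
        "colon_cancer": 5,
        "diabetes": 110,
        "heart_attack": 36,
    },
    female_disease_counts={"breast_cancer": 644, "ovarian_cancer": 133},
    disease_counts={
        "colon_cancer": 376,
        "hereditary_cancer_syndromes": 250,
        "thrombosis": 482,
        "heart_attack": 2400,
        "diabetes": 1744,
        "asthma": 744,
        "dementia": 987,
    },
)


def study_fixture() -> Cohort:
    """The deterministic cohort built from :data:`STUDY_SUMMARY_COUNTS`."""
    return make_fixture(**STUDY_SUMMARY_COUNTS)


def make_fixture(
    n_pedigrees: int,
    *,
    n_individuals: Optional[int] = None,
    n_females: Optional[int] = None,
    n_deceased: Optional[int] = None,
    n_with_deceased: Optional[int] = None,
    n_with_onset: int = 0,
    n_with_cause: int = 0,
    n_with_agedeath: int = 0,
    n_with_both: Optional[int] = None,
    n_high_quality: Optional[int] = None,
    n_female_probands: int = 0,
    n_talked: int = 0,
    proband_disease_counts: Optional[dict[str, int]] = None,
    disease_counts: Optional[dict[str, int]] = None,
    female_disease_counts: Optional[dict[str, int]] = None,
) -> Cohort:
    """Deterministically build a cohort hitting exact summary counts.

    Parameters give pedigree-level quota counts (pedigrees with >= 1
    onset-reported affected relative, >= 1 deceased relative with cause /
    age of death / both, >= 1 high-quality relative, >= 1 deceased) and
    cohort-level totals (individuals, females, deceased, per-disease
    affected counts overall / among females / among probands).  Totals
    include probands.  Contradictory quotas raise ``ValueError``.

    Each pedigree starts from a three-generation core (proband, mother,
    father, maternal grandmother); quota carriers and padding relatives
    are added on top.  Non-high-quality pedigrees are realized by making
    every relative affected without an onset age, with the
    pertinent-negatives flag asserted structurally.
    """
    if n_pedigrees < 1:
        raise ValueError("n_pedigrees must be >= 1")
    n_both = min(n_with_cause, n_with_agedeath) if n_with_both is None else n_with_both
    need_deceased_peds = max(n_with_cause, n_with_agedeath, n_both)
    if n_with_deceased is None:
        n_with_deceased = n_pedigrees if (need_deceased_peds or n_deceased) else 0
    n_hq = n_pedigrees if n_high_quality is None else n_high_quality
    proband_disease_counts = dict(proband_disease_counts or {})
    disease_counts = dict(disease_counts or {})
    female_disease_counts = dict(female_disease_counts or {})

    for name, quota, cap in [
        ("n_with_onset", n_with_onset, n_hq),
        ("n_with_cause", n_with_cause, n_with_deceased),
        ("n_with_agedeath", n_with_agedeath, n_with_deceased),
        ("n_with_both", n_both, min(n_with_cause, n_with_agedeath, n_hq if n_high_quality is not None else n_with_cause)),
        ("n_with_deceased", n_with_deceased, n_pedigrees),
        ("n_high_quality", n_hq, n_pedigrees),
        ("n_female_probands", n_female_probands, n_pedigrees),
        ("n_talked", n_talked, n_pedigrees),
    ]:
        if quota > cap:
            raise ValueError(f"{name}={quota} exceeds its maximum of {cap}")

    pedigrees: list[Pedigree] = []
    onset50 = 50.0
    for i in range(n_pedigrees):
        ped_id = f"F{i:05d}"
        hq_ped = i < n_hq
        pro_gender = "female" if i < n_female_probands else "male"
        proband = Relative(f"{ped_id}-0", R.PROBAND, pro_gender, "alive", current_age=58)
        cov = ProbandCovariates(
            age=58,
            gender=pro_gender,
            ethnicity="white",
            education=3,
            talked_to_relatives=i < n_talked,
            n_relatives_contacted=3 if i < n_talked else 0,
            fhh_knowledge=4,
        )
        # In a non-HQ pedigree every relative must fail the high-quality
        # rule; affected-without-onset does that without touching any
        # criterion quota.
        core_conditions = [] if hq_ped else [ConditionRecord(FIXTURE_CONDITION)]
        rels = [
            Relative(f"{ped_id}-m", R.MOTHER, "female", "alive", current_age=84,
                     conditions=list(core_conditions)),
            Relative(f"{ped_id}-f", R.FATHER, "male", "alive", current_age=86,
                     conditions=list(core_conditions)),
            Relative(f"{ped_id}-mgm", R.MATERNAL_GRANDMOTHER, "female", "alive", current_age=99,
                     conditions=list(core_conditions)),
        ]
        if i < n_with_onset:
            rels.append(
                Relative(f"{ped_id}-aunt", R.MATERNAL_AUNT, "female", "alive", current_age=80,
                         conditions=[ConditionRecord(FIXTURE_CONDITION, onset50)])
            )
        if i < n_with_deceased:
            if i < n_both:
                rels.append(
                    Relative(f"{ped_id}-mgf", R.MATERNAL_GRANDFATHER, "male", "deceased",
                             age_at_death=80, cause_of_death=FIXTURE_CONDITION)
                )
            else:
                if i < n_with_agedeath:
                    rels.append(
                        Relative(f"{ped_id}-mgf", R.MATERNAL_GRANDFATHER, "male", "deceased",
                                 age_at_death=80)
                    )
                if i < n_with_cause:
                    rels.append(
                        Relative(f"{ped_id}-pgf", R.PATERNAL_GRANDFATHER, "male", "deceased",
                                 cause_of_death=FIXTURE_CONDITION)
                    )
                if not (i < n_with_agedeath or i < n_with_cause):
                    rels.append(
                        Relative(f"{ped_id}-mgf", R.MATERNAL_GRANDFATHER, "male", "deceased")
                    )
        pedigrees.append(
            Pedigree(ped_id, proband, rels, cov, pertinent_negatives_override=True if not hq_ped else None)
        )

    # --- proband disease assignment ---------------------------------
    female_idx = list(range(n_female_probands))
    other_idx = list(range(n_female_probands, n_pedigrees)) + female_idx
    cursors = {"female": 0, "other": 0}
    for disease, count in proband_disease_counts.items():
        pool_name = "female" if SEX_LIMITED_DISEASES.get(disease) == "female" else "other"
        pool = female_idx if pool_name == "female" else other_idx
        cur = cursors[pool_name]
        if cur + count > len(pool):
            raise ValueError(f"not enough probands for proband_disease_counts[{disease!r}]")
        for k in range(count):
            pedigrees[pool[cur + k]].proband.conditions.append(ConditionRecord(disease, onset50))
        cursors[pool_name] = cur + count

    # --- padding to cohort totals ------------------------------------
    def count_members(pred) -> int:
        return sum(1 for p in pedigrees for m in p.members if pred(m))

    def deficit(target: Optional[int], current: int, what: str) -> int:
        if target is None:
            return 0
        if target < current:
            raise ValueError(f"{what}: target {target} below structural count {current}")
        return target - current

    n_pads = deficit(n_individuals, sum(p.size for p in pedigrees), "n_individuals")
    pad_female = deficit(n_females, count_members(lambda m: m.gender == "female"), "n_females")
    pad_deceased = deficit(n_deceased, count_members(lambda m: m.is_deceased), "n_deceased")
    if n_individuals is None:
        n_pads = max(pad_female, pad_deceased)
    if pad_female > n_pads or pad_deceased > n_pads:
        raise ValueError("female/deceased targets exceed the individual budget")
    if pad_deceased and n_with_deceased == 0:
        raise ValueError("n_deceased > 0 requires n_with_deceased > 0")

    # Attribute layout over the pad list: females at the front, deceased
    # packed at the back (overlap is fine), sex-limited diseases assigned
    # to female pads, other diseases to the rest.
    pad_gender = ["female"] * pad_female + ["male"] * (n_pads - pad_female)
    pad_dead = [False] * (n_pads - pad_deceased) + [True] * pad_deceased
    pad_disease: list[Optional[str]] = [None] * n_pads
    fcur = 0
    for disease, count in female_disease_counts.items():
        have = count_members(lambda m: m.gender == "female" and m.has_condition(disease))
        need = deficit(count, have, f"female_disease_counts[{disease!r}]")
        if fcur + need > pad_female:
            raise ValueError(f"not enough female padding for {disease!r}")
        for k in range(need):
            pad_disease[fcur + k] = disease
        fcur += need
    ocur = pad_female
    for disease, count in disease_counts.items():
        have = count_members(lambda m: m.has_condition(disease))
        need = deficit(count, have, f"disease_counts[{disease!r}]")
        if ocur + need > n_pads:
            raise ValueError(f"not enough padding for {disease!r}")
        for k in range(need):
            pad_disease[ocur + k] = disease
        ocur += need

    # Alive pads must avoid non-HQ pedigrees (an unaffected reported
    # relative would be high quality); deceased pads must land in
    # pedigrees that already contain a deceased relative.
    alive_targets = list(range(min(n_hq, n_pedigrees))) or [0]
    dead_targets = list(range(min(n_with_deceased, n_hq))) or None
    a_i = d_i = 0
    for k in range(n_pads):
        if pad_dead[k]:
            if dead_targets is None:
                raise ValueError("deceased padding requested but no eligible pedigree")
            ped = pedigrees[dead_targets[d_i % len(dead_targets)]]
            d_i += 1
        else:
            ped = pedigrees[alive_targets[a_i % len(alive_targets)]]
            a_i += 1
        disease = pad_disease[k]
        code = R.SISTER if pad_gender[k] == "female" else R.BROTHER
        if disease is not None:
            conds = [ConditionRecord(disease)]
        elif not pad_dead[k] and n_hq == 0:
            # an unaffected reported living relative would be high quality;
            # with zero HQ pedigrees allowed, mark the pad affected without
            # an onset age instead.
            conds = [ConditionRecord(FIXTURE_CONDITION)]
        else:
            conds = []
        ped.relatives.append(
            Relative(
                person_id=f"{ped.pedigree_id}-pad{k}",
                relation=code,
                gender=pad_gender[k],
                vital_status="deceased" if pad_dead[k] else "alive",
                current_age=None if pad_dead[k] else 55,
                conditions=conds,
                data_reported=True,
            )
        )

    return Cohort(pedigrees)
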