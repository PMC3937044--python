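"""Cohort-level statistics over family-health-history pedigrees.

Two aggregation semantics are used throughout, and every statistic
declares which one it follows:

* **by_proband** — compute the quantity within each pedigree, then
  summarize its distribution across pedigrees ("proportion within
  pedigree");
* **by_individual** — pool every person in the cohort and ignore pedigree
  membership ("prevalence across individuals").

The sibling recurrence-risk ratio for a disease,

    lambda_s = P(sibling affected | proband affected) / P(proband affected),

compares familial risk to the risk in the enrolled population (the
probands).  The numerator pools full siblings of affected probands; the
confidence interval is a percentile bootstrap that resamples whole
pedigrees with replacement, truncated below at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .pedigree import (
    Cohort,
    Degree,
    Pedigree,
    Relative,
    SIBLING_CODES,
    degree_of,
    is_grandparent,
)
from .quality import (
    CriterionId,
    DECEASED_CRITERIA,
    PedigreeQuality,
    assess_cohort,
)

#: Sentinel disease label meaning "any disease" (count a person once
#: regardless of how many diseases they have).
ANY_DISEASE = "__any__"

#: Diseases whose prevalence is conventionally computed among one sex.
SEX_LIMITED_DISEASES: dict[str, str] = {
    "breast_cancer": "female",
    "ovarian_cancer": "female",
}


class AggregationMode(str, Enum):
    BY_PROBAND = "by_proband"
    BY_INDIVIDUAL = "by_individual"


class DenominatorRule(str, Enum):
    ALL_INDIVIDUALS = "all_individuals"
    FEMALES_ONLY = "females_only"
    PROBANDS_ONLY = "probands_only"
    FEMALE_PROBANDS_ONLY = "female_probands_only"


@dataclass
class PrevalenceResult:
    """Disease frequency under one aggregation mode and denominator rule.

    For by_individual, ``value = numerator / denominator`` over the pooled
    persons.  For by_proband, ``value`` is the mean within-pedigree
    proportion and ``dist_*`` describe its distribution; numerator and
    denominator then hold the pooled counts for reference.
    """

    disease: str
    mode: AggregationMode
    denominator_rule: DenominatorRule
    numerator: int
    denominator: int
    value: float
    dist_sd: float = math.nan
    dist_min: float = math.nan
    dist_max: float = math.nan

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def _in_denominator(ped: Pedigree, r: Relative, rule: DenominatorRule) -> bool:
    if rule in (DenominatorRule.PROBANDS_ONLY, DenominatorRule.FEMALE_PROBANDS_ONLY):
        if r is not ped.proband:
            return False
    if rule in (DenominatorRule.FEMALES_ONLY, DenominatorRule.FEMALE_PROBANDS_ONLY):
        if r.gender != "female":
            return False
    return True


def _counts_disease(ped: Pedigree, disease: str, rule: DenominatorRule) -> tuple[int, int]:
    num = den = 0
    for r in ped.members:
        if not _in_denominator(ped, r, rule):
            continue
        den += 1
        if disease == ANY_DISEASE:
            affected = r.is_affected
        else:
            affected = r.has_condition(disease)
        if affected:
            num += 1  # count-once per disease (and once overall for ANY)
    return num, den


def prevalence(
    c: Cohort,
    disease: str,
    mode: AggregationMode = AggregationMode.BY_INDIVIDUAL,
    denominator_rule: DenominatorRule = DenominatorRule.ALL_INDIVIDUALS,
) -> PrevalenceResult:
    """Disease frequency in a cohort.

    No-data relatives sit in the denominator and can never be in the
    numerator (their condition list is empty by invariant); a person with
    several records of the same disease counts once.
    """
    mode = AggregationMode(mode)
    rule = DenominatorRule(denominator_rule)
    per_ped = [_counts_disease(p, disease, rule) for p in c.pedigrees]
    num = sum(n for n, _ in per_ped)
    den = sum(d for _, d in per_ped)
    if mode is AggregationMode.BY_INDIVIDUAL:
        value = num / den if den else math.nan
        return PrevalenceResult(disease, mode, rule, num, den, value)
    props = [n / d for n, d in per_ped if d > 0]
    if not props:
        return PrevalenceResult(disease, mode, rule, num, den, math.nan)
    arr = np.asarray(props)
    return PrevalenceResult(
        disease,
        mode,
        rule,
        num,
        den,
        float(arr.mean()),
        dist_sd=float(arr.std(ddof=1)) if len(arr) > 1 else math.nan,
        dist_min=float(arr.min()),
        dist_max=float(arr.max()),
    )


@dataclass
class DeceasedSummary:
    """Vital-status summary: within-pedigree distribution, pooled
    prevalence, and degree-class composition of the deceased."""

    mean_prop: float
    sd_prop: float
    min_prop: float
    max_prop: float
    prevalence_individuals: float
    n_deceased: int
    n_individuals: int
    fdr_share: float
    sdr_share: float
    grandparent_share_of_sdr: float
    n_pedigrees_no_deceased: int


def deceased_summary(c: Cohort) -> DeceasedSummary:
    """Summarize deceased relatives both by proband and by individual.

    Shares are composition fractions of the deceased: what fraction were
    first-degree relatives, second-degree relatives, and (within SDR
    deceased) grandparents.  Probands are members of the individual pool
    but, being enrolled patients, are alive in practice.
    """
    props: list[float] = []
    n_dec = n_all = 0
    dec_fdr = dec_sdr = dec_gp = 0
    n_no_dec = 0
    for p in c.pedigrees:
        ped_dec = sum(1 for m in p.members if m.is_deceased)
        props.append(ped_dec / p.size)
        if ped_dec == 0:
            n_no_dec += 1
        n_dec += ped_dec
        n_all += p.size
        for r in p.relatives:
            if not r.is_deceased:
                continue
            deg = degree_of(r.relation)
            if deg is Degree.FIRST:
                dec_fdr += 1
            elif deg is Degree.SECOND:
                dec_sdr += 1
                if is_grandparent(r.relation):
                    dec_gp += 1
    arr = np.asarray(props) if props else np.asarray([math.nan])
    return DeceasedSummary(
        mean_prop=float(arr.mean()),
        sd_prop=float(arr.std(ddof=1)) if len(arr) > 1 else math.nan,
        min_prop=float(arr.min()),
        max_prop=float(arr.max()),
        prevalence_individuals=n_dec / n_all if n_all else math.nan,
        n_deceased=n_dec,
        n_individuals=n_all,
        fdr_share=dec_fdr / n_dec if n_dec else math.nan,
        sdr_share=dec_sdr / n_dec if n_dec else math.nan,
        grandparent_share_of_sdr=dec_gp / dec_sdr if dec_sdr else math.nan,
        n_pedigrees_no_deceased=n_no_dec,
    )


@dataclass
class ContactEffect:
    """Group means of the no-data proportion and complete-pedigree rate,
    split by whether the proband talked to relatives before reporting."""

    mean_nodata_talked: float
    mean_nodata_not_talked: float
    complete_rate_talked: float
    complete_rate_not_talked: float
    n_talked: int
    n_not_talked: int


def contact_effect(c: Cohort) -> ContactEffect:
    """Compare no-data rates between probands who did and did not contact
    relatives; a pedigree is *complete* when every relative has data."""
    groups: dict[bool, list[tuple[float, bool]]] = {True: [], False: []}
    for p in c.pedigrees:
        n = len(p.relatives)
        if n == 0:
            continue
        nodata = sum(1 for r in p.relatives if not r.data_reported)
        groups[p.proband_covariates.talked_to_relatives].append((nodata / n, nodata == 0))

    def mean_of(group: list, idx: int) -> float:
        if not group:
            return math.nan
        return sum(g[idx] for g in group) / len(group)

    return ContactEffect(
        mean_nodata_talked=mean_of(groups[True], 0),
        mean_nodata_not_talked=mean_of(groups[False], 0),
        complete_rate_talked=mean_of(groups[True], 1),
        complete_rate_not_talked=mean_of(groups[False], 1),
        n_talked=len(groups[True]),
        n_not_talked=len(groups[False]),
    )


@dataclass
class LambdaEstimate:
    """Sibling recurrence-risk ratio for one disease, with the counts it
    was built from and a pedigree-resampling bootstrap CI."""

    disease: str
    lam: float
    ci_low: float
    ci_high: float
    n_eligible_probands: int
    n_affected_probands: int
    n_siblings_of_affected: int
    n_affected_siblings: int
    proband_prevalence: float
    sibling_risk: float
    n_bootstrap: int
    seed: Optional[int]

    @property
    def defined(self) -> bool:
        return not math.isnan(self.lam)


def _lambda_counts(
    ped: Pedigree, disease: str, sex_restrict: bool, susceptible_sex: str
) -> tuple[int, int, int, int]:
    """Per-pedigree counts: (eligible proband, affected proband,
    siblings of affected proband, affected siblings)."""
    pro = ped.proband
    eligible = 1
    if sex_restrict and pro.gender != susceptible_sex:
        eligible = 0
    affected_pro = eligible and pro.has_condition(disease)
    n_sibs = n_aff_sibs = 0
    if affected_pro:
        for r in ped.relatives:
            if r.relation not in SIBLING_CODES:
                continue
            if sex_restrict and r.gender != susceptible_sex:
                continue
            n_sibs += 1
            if r.has_condition(disease):
                n_aff_sibs += 1
    return eligible, int(affected_pro), n_sibs, n_aff_sibs


def _lambda_from_totals(tot: np.ndarray) -> float:
    eligible, aff_pro, sibs, aff_sibs = (float(x) for x in tot)
    if eligible == 0 or aff_pro == 0 or sibs == 0:
        return math.nan
    return (aff_sibs / sibs) / (aff_pro / eligible)


def sibling_lambda(
    c: Cohort,
    disease: str,
    sex_restrict: bool = False,
    susceptible_sex: str = "female",
    n_bootstrap: int = 2000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
) -> LambdaEstimate:
    """Estimate the sibling recurrence-risk ratio for a disease.

    Point estimate: (affected siblings / siblings of affected probands)
    divided by the proband prevalence (affected probands / eligible
    probands).  ``sex_restrict`` limits both the proband denominator and
    the sibling pool to ``susceptible_sex`` (the convention for breast and
    ovarian cancer).  The CI resamples pedigrees with replacement
    (percentile method, truncated below at 0); undefined resamples are
    dropped.  The estimate is undefined — returned flagged, not raised —
    when there are no eligible or no affected probands, zero proband
    prevalence, or no siblings of affected probands.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    counts = np.asarray(
        [_lambda_counts(p, disease, sex_restrict, susceptible_sex) for p in c.pedigrees],
        dtype=np.int64,
    )
    if counts.size == 0:
        counts = np.zeros((0, 4), dtype=np.int64)
    tot = counts.sum(axis=0)
    lam = _lambda_from_totals(tot)
    eligible, aff_pro, sibs, aff_sibs = (int(x) for x in tot)
    prev = aff_pro / eligible if eligible else math.nan
    risk = aff_sibs / sibs if sibs else math.nan

    ci_low = ci_high = math.nan
    if not math.isnan(lam):
        rng = np.random.default_rng(seed)
        n = counts.shape[0]
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        boots = counts[idx].sum(axis=1)  # (n_bootstrap, 4)
        with np.errstate(divide="ignore", invalid="ignore"):
            b_prev = boots[:, 1] / boots[:, 0]
            b_risk = boots[:, 3] / boots[:, 2]
            b_lam = b_risk / b_prev
        b_lam = b_lam[np.isfinite(b_lam)]
        if b_lam.size:
            alpha = (1.0 - ci_level) / 2.0
            ci_low = max(0.0, float(np.quantile(b_lam, alpha)))
            ci_high = float(np.quantile(b_lam, 1.0 - alpha))

    return LambdaEstimate(
        disease=disease,
        lam=lam,
        ci_low=ci_low,
        ci_high=ci_high,
        n_eligible_probands=eligible,
        n_affected_probands=aff_pro,
        n_siblings_of_affected=sibs,
        n_affected_siblings=aff_sibs,
        proband_prevalence=prev,
        sibling_risk=risk,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


@dataclass
class ProportionSummary:
    """Distribution of a within-pedigree proportion, over all pedigrees
    with a defined denominator and over the subgroup with >= 1 qualifying
    relative."""

    name: str
    mean_all: float
    sd_all: float
    min_all: float
    max_all: float
    n_all: int
    n_subgroup: int
    subgroup_share: float
    mean_subgroup: float
    sd_subgroup: float
    min_subgroup: float
    max_subgroup: float


@dataclass
class CriterionSummary:
    """Cohort-level criterion report: per-criterion counts/percentages
    plus the reporting-proportion distributions."""

    n_pedigrees: int
    n_pedigrees_with_deceased: int
    n_high_quality: int
    criterion_n: dict[CriterionId, int]
    criterion_pct: dict[CriterionId, float]
    proportions: dict[str, ProportionSummary]
    onset_denominator: str

    @property
    def high_quality_pct(self) -> float:
        return 100.0 * self.n_high_quality / self.n_pedigrees if self.n_pedigrees else math.nan


def _prop_summary(
    name: str, values: Sequence[float], share_n: Optional[int] = None
) -> ProportionSummary:
    """``share_n`` is the denominator for the subgroup share; default is
    the number of pedigrees where the proportion is defined (the right
    choice for death proportions, whose denominator is the
    deceased-containing pedigrees; the onset share is conventionally
    quoted out of all pedigrees)."""
    vals = [v for v in values if not math.isnan(v)]
    sub = [v for v in vals if v > 0]

    def stats(xs: Sequence[float]) -> tuple[float, float, float, float]:
        if not xs:
            return (math.nan,) * 4
        arr = np.asarray(xs)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else math.nan
        return float(arr.mean()), sd, float(arr.min()), float(arr.max())

    m, s, lo, hi = stats(vals)
    ms, ss, los, his = stats(sub)
    return ProportionSummary(
        name=name,
        mean_all=m,
        sd_all=s,
        min_all=lo,
        max_all=hi,
        n_all=len(vals),
        n_subgroup=len(sub),
        subgroup_share=len(sub) / (share_n if share_n else len(vals)) if vals else math.nan,
        mean_subgroup=ms,
        sd_subgroup=ss,
        min_subgroup=los,
        max_subgroup=his,
    )


def criterion_summary(
    c: Cohort,
    onset_denominator: str = "affected",
    assessments: Optional[list[PedigreeQuality]] = None,
) -> CriterionSummary:
    """Tabulate how many pedigrees meet each quality criterion.

    The death-related criteria use the pedigrees containing at least one
    deceased relative as their denominator; the others use all pedigrees.
    Reporting proportions (onset, cause of death, age of death, both) are
    summarized over all pedigrees with a defined denominator and over the
    subgroup with at least one qualifying relative.
    """
    if assessments is None:
        assessments = assess_cohort(c, onset_denominator)
    n = len(assessments)
    n_dec = sum(1 for q in assessments if q.has_deceased)
    crit_n: dict[CriterionId, int] = {}
    crit_pct: dict[CriterionId, float] = {}
    for cid in CriterionId:
        met = sum(1 for q in assessments if q.criterion_met[cid] is True)
        den = n_dec if cid in DECEASED_CRITERIA else n
        crit_n[cid] = met
        crit_pct[cid] = 100.0 * met / den if den else math.nan
    props = {
        "onset": _prop_summary("onset", [q.prop_onset for q in assessments], share_n=n),
        "cause_of_death": _prop_summary(
            "cause_of_death", [q.prop_cause_of_death for q in assessments]
        ),
        "age_of_death": _prop_summary(
            "age_of_death", [q.prop_age_of_death for q in assessments]
        ),
        "age_and_cause": _prop_summary(
            "age_and_cause", [q.prop_age_and_cause for q in assessments]
        ),
    }
    return CriterionSummary(
        n_pedigrees=n,
        n_pedigrees_with_deceased=n_dec,
        n_high_quality=sum(1 for q in assessments if q.is_high_quality),
        criterion_n=crit_n,
        criterion_pct=crit_pct,
        proportions=props,
        onset_denominator=onset_denominator,
    )
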