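"""Pedigree quality scoring against the Bennett completeness criteria.

Seven criteria are scored per pedigree (the "up to date" criterion of the
original eight is structural for prospectively collected histories and is
not scored):

====  =========================================================
C1    three generations of relatives present
C2    relatives' lineage (maternal/paternal side) recorded
C3    relatives' gender known
C4    pertinent negatives representable (unaffected != unknown)
C5    age of disease onset recorded for an affected relative
C6    cause of death recorded for a deceased relative
C7    age of death recorded for a deceased relative
====  =========================================================

A relative is *high quality* when every criterion that applies to them
personally is met: any data at all reported, gender known, lineage
derivable, at least one onset age if affected, and both age and cause of
death if deceased.  Criteria that do not apply (living relatives and the
death criteria, unaffected relatives and the onset criterion) are
vacuously satisfied, so an unaffected living relative with reported data
and known gender is high quality.  A pedigree is *high quality* when it
contains at least one high-quality relative.

Criteria C2–C7 and the high-quality rule are evaluated over relatives
only: the proband's self-report is complete by construction and would make
the rule vacuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .pedigree import (
    Cohort,
    Degree,
    Pedigree,
    Relative,
    RelationCode,
    degree_of,
    generation_span,
    is_grandparent,
    lineage_of,
)


class CriterionId(str, Enum):
    """The seven scored pedigree-completeness criteria, in report order."""

    C1_THREE_GENERATIONS = "three_generations"
    C2_LINEAGE = "lineage"
    C3_GENDER = "gender"
    C4_PERTINENT_NEGATIVES = "pertinent_negatives"
    C5_AGE_OF_ONSET = "age_of_onset"
    C6_CAUSE_OF_DEATH = "cause_of_death"
    C7_AGE_OF_DEATH = "age_of_death"


#: Criteria that only apply to pedigrees containing a deceased relative.
DECEASED_CRITERIA = (CriterionId.C6_CAUSE_OF_DEATH, CriterionId.C7_AGE_OF_DEATH)


def _has_onset(r: Relative) -> bool:
    return any(c.age_of_onset is not None for c in r.conditions)


def relative_is_high_quality(r: Relative) -> bool:
    """True iff every criterion applicable to this relative is met.

    Count-once rule: an affected relative needs an onset age for only one
    of their diseases.  Inapplicable criteria are vacuously satisfied.
    """
    if r.relation is RelationCode.PROBAND:
        raise ValueError("high-quality assessment applies to relatives, not the proband")
    if not r.data_reported:
        return False
    if r.gender not in ("female", "male"):
        return False
    # lineage_of is total over valid codes, so the lineage criterion can
    # only fail on an invalid record; evaluate for symmetry with C2.
    lineage_of(r.relation)
    if r.is_affected and not _has_onset(r):
        return False
    if r.is_deceased and (r.age_at_death is None or r.cause_of_death is None):
        return False
    return True


@dataclass
class PedigreeQuality:
    """Quality assessment of a single pedigree.

    Proportions use NaN when the denominator is empty (e.g. the death
    proportions in a pedigree with no deceased relative); the matching
    criterion flags are then None ("not applicable").
    """

    pedigree_id: str
    criterion_met: dict[CriterionId, Optional[bool]]
    prop_onset: float
    prop_cause_of_death: float
    prop_age_of_death: float
    prop_age_and_cause: float
    n_relatives: int
    n_hq_relatives: int
    hq_fraction: float
    is_high_quality: bool
    n_deceased: int
    n_affected: int
    n_no_data: int

    @property
    def has_deceased(self) -> bool:
        return self.n_deceased > 0


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def assess_pedigree(p: Pedigree, onset_denominator: str = "affected") -> PedigreeQuality:
    """Score one pedigree against all seven criteria.

    Parameters
    ----------
    p:
        A validated pedigree with at least one relative.
    onset_denominator:
        ``"affected"`` (default) computes the onset-reporting proportion
        over affected relatives; ``"all"`` over all relatives.
    """
    if not p.relatives:
        raise ValueError(f"pedigree {p.pedigree_id!r} has no relatives to assess")
    if onset_denominator not in ("affected", "all"):
        raise ValueError(f"onset_denominator must be 'affected' or 'all', got {onset_denominator!r}")

    rels = p.relatives
    affected = [r for r in rels if r.is_affected]
    deceased = [r for r in rels if r.is_deceased]
    n_onset = sum(1 for r in affected if _has_onset(r))
    n_cause = sum(1 for r in deceased if r.cause_of_death is not None)
    n_agedeath = sum(1 for r in deceased if r.age_at_death is not None)
    n_both = sum(1 for r in deceased if r.cause_of_death is not None and r.age_at_death is not None)

    if p.pertinent_negatives_override is not None:
        c4 = p.pertinent_negatives_override
    else:
        # The record format distinguishes "no disease reported" from "no
        # data" whenever some unaffected relative has data reported.
        c4 = any(r.data_reported and not r.is_affected for r in rels)

    met: dict[CriterionId, Optional[bool]] = {
        CriterionId.C1_THREE_GENERATIONS: generation_span(p) >= 3,
        CriterionId.C2_LINEAGE: True,  # lineage_of is total over valid codes
        CriterionId.C3_GENDER: all(r.gender in ("female", "male") for r in rels),
        CriterionId.C4_PERTINENT_NEGATIVES: c4,
        CriterionId.C5_AGE_OF_ONSET: n_onset >= 1,
        CriterionId.C6_CAUSE_OF_DEATH: (n_cause >= 1) if deceased else None,
        CriterionId.C7_AGE_OF_DEATH: (n_agedeath >= 1) if deceased else None,
    }

    onset_den = len(affected) if onset_denominator == "affected" else len(rels)
    hq = sum(1 for r in rels if relative_is_high_quality(r))
    return PedigreeQuality(
        pedigree_id=p.pedigree_id,
        criterion_met=met,
        prop_onset=_ratio(n_onset, onset_den),
        prop_cause_of_death=_ratio(n_cause, len(deceased)),
        prop_age_of_death=_ratio(n_agedeath, len(deceased)),
        prop_age_and_cause=_ratio(n_both, len(deceased)),
        n_relatives=len(rels),
        n_hq_relatives=hq,
        hq_fraction=hq / len(rels),
        is_high_quality=hq >= 1,
        n_deceased=len(deceased),
        n_affected=len(affected),
        n_no_data=sum(1 for r in rels if not r.data_reported),
    )


def assess_cohort(c: Cohort, onset_denominator: str = "affected") -> list[PedigreeQuality]:
    """Score every pedigree in a cohort (see :func:`assess_pedigree`)."""
    return [assess_pedigree(p, onset_denominator) for p in c.pedigrees]


def hq_sweep(
    c: Cohort,
    thresholds: Optional[Sequence[float]] = None,
    assessments: Optional[list[PedigreeQuality]] = None,
) -> list[tuple[float, float]]:
    """High-quality pedigree rate as the required HQ-relative fraction grows.

    For each threshold t, returns the proportion of pedigrees whose
    fraction of high-quality relatives is at least t.  At t = 0 every
    pedigree qualifies (proportion exactly 1.0) and the curve is monotone
    non-increasing in t.
    """
    if not c.pedigrees:
        raise ValueError("hq_sweep requires a non-empty cohort")
    if thresholds is None:
        thresholds = [round(0.05 * i, 2) for i in range(21)]
    for t in thresholds:
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"threshold {t} outside [0, 1]")
    if assessments is None:
        assessments = assess_cohort(c)
    fracs = [q.hq_fraction for q in assessments]
    n = len(fracs)
    return [(float(t), sum(1 for f in fracs if f >= t) / n) for t in thresholds]


@dataclass
class NoDataStats:
    """No-data summary for one stratum of relatives.

    ``mean_prop_all`` averages the within-pedigree no-data proportion over
    every pedigree that has relatives in the stratum; ``mean_prop_subgroup``
    over the subgroup of pedigrees with at least one no-data relative in
    the stratum.  Counts are per-pedigree averages of no-data relatives.
    """

    stratum: str
    mean_prop_all: float
    sd_prop_all: float
    min_prop_all: float
    max_prop_all: float
    mean_count_all: float
    n_pedigrees_with_stratum: int
    n_pedigrees_with_nodata: int
    mean_prop_subgroup: float
    mean_count_subgroup: float
    total_no_data: int


def _stratum_members(p: Pedigree, stratum: str) -> list[Relative]:
    if stratum == "all":
        return p.relatives
    if stratum == "fdr":
        return [r for r in p.relatives if degree_of(r.relation) is Degree.FIRST]
    if stratum == "sdr":
        return [r for r in p.relatives if degree_of(r.relation) is Degree.SECOND]
    if stratum == "grandparents":
        return [r for r in p.relatives if is_grandparent(r.relation)]
    raise ValueError(f"unknown stratum {stratum!r}")


NO_DATA_STRATA = ("all", "fdr", "sdr", "grandparents")


def no_data_analysis(c: Cohort) -> dict[str, NoDataStats]:
    """Summarize relatives with no reported data, overall and by stratum.

    Strata: all relatives, first-degree (FDR), second-degree (SDR), and
    grandparents.  Within-pedigree proportions use the stratum size as
    denominator; pedigrees with no relatives in a stratum do not
    contribute to that stratum's proportion average.
    """
    out: dict[str, NoDataStats] = {}
    for stratum in NO_DATA_STRATA:
        props: list[float] = []
        counts: list[int] = []
        sub_props: list[float] = []
        sub_counts: list[int] = []
        total = 0
        for p in c.pedigrees:
            members = _stratum_members(p, stratum)
            if not members:
                continue
            n_nodata = sum(1 for r in members if not r.data_reported)
            total += n_nodata
            props.append(n_nodata / len(members))
            counts.append(n_nodata)
            if n_nodata > 0:
                sub_props.append(n_nodata / len(members))
                sub_counts.append(n_nodata)
        out[stratum] = NoDataStats(
            stratum=stratum,
            mean_prop_all=_mean(props),
            sd_prop_all=_sd(props),
            min_prop_all=min(props) if props else math.nan,
            max_prop_all=max(props) if props else math.nan,
            mean_count_all=_mean(counts),
            n_pedigrees_with_stratum=len(props),
            n_pedigrees_with_nodata=len(sub_props),
            mean_prop_subgroup=_mean(sub_props),
            mean_count_subgroup=_mean(sub_counts),
            total_no_data=total,
        )
    return out


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs) if xs else math.nan


def _sd(xs: Sequence[float]) -> float:
    if len(xs) < 2:
        return math.nan
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))
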