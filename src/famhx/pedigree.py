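"""Relation-coded pedigree data model.

A pedigree here is the structure a patient-facing family-health-history
tool collects: one proband (the enrolled patient) plus relatives tagged by
their relationship to the proband (``mother``, ``maternal_aunt``, ...).
No parent-child links are stored; degree of relatedness, lineage (maternal
vs. paternal side) and generation are all derived from the relation code,
which is sufficient for every statistic this package computes.

Degree classes follow the standard genetic convention: first-degree
relatives (parents, full siblings, children) share half their genome with
the proband; second-degree relatives (grandparents, aunts/uncles,
nieces/nephews, grandchildren, half-siblings) a quarter; cousins are
third-degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional


class RelationCode(str, Enum):
    """Controlled vocabulary of relationships to the proband."""

    PROBAND = "proband"
    MOTHER = "mother"
    FATHER = "father"
    SISTER = "sister"
    BROTHER = "brother"
    DAUGHTER = "daughter"
    SON = "son"
    MATERNAL_GRANDMOTHER = "maternal_grandmother"
    MATERNAL_GRANDFATHER = "maternal_grandfather"
    PATERNAL_GRANDMOTHER = "paternal_grandmother"
    PATERNAL_GRANDFATHER = "paternal_grandfather"
    MATERNAL_AUNT = "maternal_aunt"
    MATERNAL_UNCLE = "maternal_uncle"
    PATERNAL_AUNT = "paternal_aunt"
    PATERNAL_UNCLE = "paternal_uncle"
    NIECE = "niece"
    NEPHEW = "nephew"
    GRANDCHILD = "grandchild"
    HALF_SIBLING = "half_sibling"
    COUSIN = "cousin"


class Degree(str, Enum):
    FIRST = "FIRST"
    SECOND = "SECOND"
    THIRD = "THIRD"


class Lineage(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BOTH = "both"
    NOT_APPLICABLE = "not_applicable"


R = RelationCode

_DEGREE: dict[RelationCode, Degree] = {
    R.MOTHER: Degree.FIRST,
    R.FATHER: Degree.FIRST,
    R.SISTER: Degree.FIRST,
    R.BROTHER: Degree.FIRST,
    R.DAUGHTER: Degree.FIRST,
    R.SON: Degree.FIRST,
    R.MATERNAL_GRANDMOTHER: Degree.SECOND,
    R.MATERNAL_GRANDFATHER: Degree.SECOND,
    R.PATERNAL_GRANDMOTHER: Degree.SECOND,
    R.PATERNAL_GRANDFATHER: Degree.SECOND,
    R.MATERNAL_AUNT: Degree.SECOND,
    R.MATERNAL_UNCLE: Degree.SECOND,
    R.PATERNAL_AUNT: Degree.SECOND,
    R.PATERNAL_UNCLE: Degree.SECOND,
    R.NIECE: Degree.SECOND,
    R.NEPHEW: Degree.SECOND,
    R.GRANDCHILD: Degree.SECOND,
    R.HALF_SIBLING: Degree.SECOND,
    R.COUSIN: Degree.THIRD,
}

# Generation offset relative to the proband: grandparents -2, parents'
# generation -1, proband's generation 0, children +1, grandchildren +2.
_GENERATION_OFFSET: dict[RelationCode, int] = {
    R.PROBAND: 0,
    R.MOTHER: -1,
    R.FATHER: -1,
    R.SISTER: 0,
    R.BROTHER: 0,
    R.DAUGHTER: 1,
    R.SON: 1,
    R.MATERNAL_GRANDMOTHER: -2,
    R.MATERNAL_GRANDFATHER: -2,
    R.PATERNAL_GRANDMOTHER: -2,
    R.PATERNAL_GRANDFATHER: -2,
    R.MATERNAL_AUNT: -1,
    R.MATERNAL_UNCLE: -1,
    R.PATERNAL_AUNT: -1,
    R.PATERNAL_UNCLE: -1,
    R.NIECE: 1,
    R.NEPHEW: 1,
    R.GRANDCHILD: 2,
    R.HALF_SIBLING: 0,
    R.COUSIN: 0,
}

# Ascending relatives carry the side of the family they sit on; full and
# half siblings share the proband's ancestry on both sides (a half-sibling
# shares one, but the unqualified code cannot say which); descendants and
# unqualified cousins carry no proband-side lineage.
_LINEAGE: dict[RelationCode, Lineage] = {
    R.MOTHER: Lineage.MATERNAL,
    R.FATHER: Lineage.PATERNAL,
    R.SISTER: Lineage.BOTH,
    R.BROTHER: Lineage.BOTH,
    R.HALF_SIBLING: Lineage.BOTH,
    R.DAUGHTER: Lineage.NOT_APPLICABLE,
    R.SON: Lineage.NOT_APPLICABLE,
    R.MATERNAL_GRANDMOTHER: Lineage.MATERNAL,
    R.MATERNAL_GRANDFATHER: Lineage.MATERNAL,
    R.PATERNAL_GRANDMOTHER: Lineage.PATERNAL,
    R.PATERNAL_GRANDFATHER: Lineage.PATERNAL,
    R.MATERNAL_AUNT: Lineage.MATERNAL,
    R.MATERNAL_UNCLE: Lineage.MATERNAL,
    R.PATERNAL_AUNT: Lineage.PATERNAL,
    R.PATERNAL_UNCLE: Lineage.PATERNAL,
    R.NIECE: Lineage.NOT_APPLICABLE,
    R.NEPHEW: Lineage.NOT_APPLICABLE,
    R.GRANDCHILD: Lineage.NOT_APPLICABLE,
    R.COUSIN: Lineage.NOT_APPLICABLE,
}

GRANDPARENT_CODES = frozenset(
    {
        R.MATERNAL_GRANDMOTHER,
        R.MATERNAL_GRANDFATHER,
        R.PATERNAL_GRANDMOTHER,
        R.PATERNAL_GRANDFATHER,
    }
)

SIBLING_CODES = frozenset({R.SISTER, R.BROTHER})


def _coerce(relation: "RelationCode | str") -> RelationCode:
    if isinstance(relation, RelationCode):
        return relation
    try:
        return RelationCode(relation)
    except ValueError:
        raise ValueError(f"unknown relation code: {relation!r}") from None


def degree_of(relation: "RelationCode | str") -> Degree:
    """Degree of relatedness of a relative to the proband.

    Parents, siblings and children are FIRST degree; grandparents,
    aunts/uncles, nieces/nephews, grandchildren and half-siblings SECOND;
    cousins THIRD.  The proband itself has no degree.
    """
    code = _coerce(relation)
    if code is R.PROBAND:
        raise ValueError("degree_of is undefined for the proband")
    return _DEGREE[code]


def generation_offset(relation: "RelationCode | str") -> int:
    """Generation of a relative, relative to the proband (in -2..+2)."""
    return _GENERATION_OFFSET[_coerce(relation)]


def lineage_of(relation: "RelationCode | str") -> Lineage:
    """Side of the family a relative belongs to (maternal/paternal/both)."""
    code = _coerce(relation)
    if code is R.PROBAND:
        return Lineage.BOTH
    return _LINEAGE[code]


@dataclass
class ConditionRecord:
    """One reported disease for one person, with optional age of onset."""

    disease: str
    age_of_onset: Optional[float] = None


@dataclass
class Relative:
    """One individual in a pedigree (the proband is also a Relative).

    ``data_reported`` is True iff the informant supplied any health
    information for this person; a "no data" relative is structurally
    present (their relation code is known) but carries no conditions, no
    age and no death details.
    """

    person_id: str
    relation: RelationCode
    gender: str = "unknown"  # female | male | unknown
    vital_status: str = "unknown"  # alive | deceased | unknown
    current_age: Optional[float] = None
    age_at_death: Optional[float] = None
    cause_of_death: Optional[str] = None
    conditions: list[ConditionRecord] = field(default_factory=list)
    data_reported: bool = True

    @property
    def is_affected(self) -> bool:
        return len(self.conditions) > 0

    @property
    def is_deceased(self) -> bool:
        return self.vital_status == "deceased"

    def has_condition(self, disease: str) -> bool:
        return any(c.disease == disease for c in self.conditions)


@dataclass
class ProbandCovariates:
    """Survey covariates of the enrolled patient."""

    age: Optional[float] = None
    gender: str = "unknown"
    ethnicity: str = "other"  # white | black | other
    education: Optional[int] = None  # 1=HS or less .. 4=any graduate
    talked_to_relatives: bool = False
    n_relatives_contacted: int = 0
    fhh_knowledge: Optional[int] = None  # Likert 1..7


@dataclass
class Pedigree:
    """A proband plus relation-coded relatives; the unit of quality scoring.

    ``pertinent_negatives_override`` lets chart-review-style inputs state
    explicitly whether the record format distinguishes "no disease
    reported" from "no data"; when None the distinction is inferred from
    the data (see quality scoring).
    """

    pedigree_id: str
    proband: Relative
    relatives: list[Relative] = field(default_factory=list)
    proband_covariates: ProbandCovariates = field(default_factory=ProbandCovariates)
    pertinent_negatives_override: Optional[bool] = None

    @property
    def members(self) -> list[Relative]:
        return [self.proband] + self.relatives

    @property
    def size(self) -> int:
        return 1 + len(self.relatives)


@dataclass
class Cohort:
    """A collection of pedigrees; the unit of aggregation."""

    pedigrees: list[Pedigree] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pedigrees)

    def iter_members(self) -> Iterator[tuple[Pedigree, Relative]]:
        for ped in self.pedigrees:
            for rel in ped.members:
                yield ped, rel

    @property
    def n_individuals(self) -> int:
        return sum(p.size for p in self.pedigrees)


@dataclass
class Violation:
    """One invariant violation, as data rather than an exception."""

    pedigree_id: str
    person_id: Optional[str]
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        who = self.person_id or "<pedigree>"
        return f"[{self.pedigree_id}/{who}] {self.rule}"


_GENDERS = {"female", "male", "unknown"}
_VITAL = {"alive", "deceased", "unknown"}


def _relative_violations(ped_id: str, r: Relative) -> list[Violation]:
    out: list[Violation] = []

    def bad(rule: str) -> None:
        out.append(Violation(ped_id, r.person_id, rule))

    if r.gender not in _GENDERS:
        bad(f"invalid gender {r.gender!r}")
    if r.vital_status not in _VITAL:
        bad(f"invalid vital_status {r.vital_status!r}")
    if r.vital_status != "deceased":
        if r.age_at_death is not None:
            bad("age_at_death set on a non-deceased individual")
        if r.cause_of_death is not None:
            bad("cause_of_death set on a non-deceased individual")
    for c in r.conditions:
        if c.age_of_onset is not None and not (0 <= c.age_of_onset <= 120):
            bad(f"age_of_onset {c.age_of_onset} outside [0, 120] for {c.disease}")
    if not r.data_reported:
        if r.conditions:
            bad("conditions present on a no-data relative")
        if r.age_at_death is not None or r.cause_of_death is not None:
            bad("death details present on a no-data relative")
    for age in (r.current_age, r.age_at_death):
        if age is not None and not (0 <= age <= 120):
            bad(f"age {age} outside [0, 120]")
    return out


def validate_pedigree(p: Pedigree) -> list[Violation]:
    """Check every structural invariant; returns violations (empty = valid)."""
    out: list[Violation] = []
    pid = p.pedigree_id
    if p.proband.relation is not R.PROBAND:
        out.append(Violation(pid, p.proband.person_id, "proband slot has non-proband relation"))
    n_probands = sum(1 for m in p.members if m.relation is R.PROBAND)
    if n_probands != 1:
        out.append(Violation(pid, None, f"multiple probands ({n_probands})" if n_probands > 1 else "no proband"))
    seen: set[str] = set()
    for m in p.members:
        if m.person_id in seen:
            out.append(Violation(pid, m.person_id, "duplicate person_id"))
        seen.add(m.person_id)
    if p.size < 2:
        out.append(Violation(pid, None, "pedigree has fewer than 2 members"))
    cov = p.proband_covariates
    if cov.n_relatives_contacted > 0 and not cov.talked_to_relatives:
        out.append(Violation(pid, p.proband.person_id, "n_relatives_contacted > 0 but talked_to_relatives is false"))
    if cov.fhh_knowledge is not None and cov.fhh_knowledge not in range(1, 8):
        out.append(Violation(pid, p.proband.person_id, f"fhh_knowledge {cov.fhh_knowledge} outside 1..7"))
    for m in p.members:
        out.extend(_relative_violations(pid, m))
    return out


def validate_cohort(c: Cohort) -> list[Violation]:
    """Validate every pedigree plus cohort-level uniqueness of pedigree ids."""
    out: list[Violation] = []
    seen: set[str] = set()
    for p in c.pedigrees:
        if p.pedigree_id in seen:
            out.append(Violation(p.pedigree_id, None, "duplicate pedigree_id"))
        seen.add(p.pedigree_id)
        out.extend(validate_pedigree(p))
    return out


def generation_span(p: Pedigree) -> int:
    """Number of distinct generations present in a pedigree.

    A pedigree with grandparents, the parental generation, and the
    proband's own generation spans (at least) three generations — the
    classic completeness bar for a family history.
    """
    return len({generation_offset(m.relation) for m in p.members})


def is_grandparent(relation: "RelationCode | str") -> bool:
    return _coerce(relation) in GRANDPARENT_CODES
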