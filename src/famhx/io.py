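"""Readers, writers and report rendering.

The on-disk cohort format is a flat CSV, one row per individual, with the
proband's survey covariates carried on the proband row only.  Conditions
are encoded as semicolon-separated ``disease@onset`` tokens with the
``@onset`` part optional (``"breast_cancer@42;thrombosis"``).  Empty
string means missing; ages are integer years.

A linkage-format PED export (family, individual, father, mother, sex,
phenotype) is derived from the relation codes, inserting placeholder
founders (e.g. an aunt's spouse) where the pedigree has no explicit row
for a structural parent.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .pedigree import (
    Cohort,
    ConditionRecord,
    Pedigree,
    ProbandCovariates,
    Relative,
    RelationCode,
    lineage_of,
    validate_cohort,
)
from .quality import CriterionId, NoDataStats
from .stats import CriterionSummary, LambdaEstimate, PrevalenceResult

CSV_COLUMNS = [
    "pedigree_id",
    "person_id",
    "relation",
    "gender",
    "lineage",
    "vital_status",
    "current_age",
    "age_at_death",
    "cause_of_death",
    "conditions",
    "data_reported",
    "talked_to_relatives",
    "n_relatives_contacted",
    "fhh_knowledge",
    "age",
    "ethnicity",
    "education",
]

PathLike = Union[str, Path]


def _encode_conditions(conditions: list[ConditionRecord]) -> str:
    toks = []
    for c in conditions:
        if c.age_of_onset is None:
            toks.append(c.disease)
        else:
            onset = c.age_of_onset
            toks.append(f"{c.disease}@{int(onset) if float(onset).is_integer() else onset}")
    return ";".join(toks)


def _parse_conditions(raw: str, where: str) -> list[ConditionRecord]:
    out: list[ConditionRecord] = []
    for tok in raw.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        if tok.count("@") > 1:
            raise ValueError(f"{where}: malformed condition token {tok!r}")
        if "@" in tok:
            disease, onset_s = tok.split("@")
            if not disease:
                raise ValueError(f"{where}: malformed condition token {tok!r}")
            try:
                onset = float(onset_s)
            except ValueError:
                raise ValueError(f"{where}: malformed condition token {tok!r}") from None
            out.append(ConditionRecord(disease, onset))
        else:
            out.append(ConditionRecord(tok))
    return out


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and float(value).is_integer():
        return str(int(value))
    return str(value)


def write_cohort(c: Cohort, path: PathLike) -> None:
    """Write a cohort in the flat pedigree CSV dialect."""
    rows = []
    for ped in c.pedigrees:
        for r in ped.members:
            row = {
                "pedigree_id": ped.pedigree_id,
                "person_id": r.person_id,
                "relation": r.relation.value,
                "gender": r.gender,
                "lineage": lineage_of(r.relation).value,
                "vital_status": r.vital_status,
                "current_age": _fmt(r.current_age),
                "age_at_death": _fmt(r.age_at_death),
                "cause_of_death": _fmt(r.cause_of_death),
                "conditions": _encode_conditions(r.conditions),
                "data_reported": _fmt(r.data_reported),
                "talked_to_relatives": "",
                "n_relatives_contacted": "",
                "fhh_knowledge": "",
                "age": "",
                "ethnicity": "",
                "education": "",
            }
            if r.relation is RelationCode.PROBAND:
                cov = ped.proband_covariates
                row.update(
                    talked_to_relatives=_fmt(cov.talked_to_relatives),
                    n_relatives_contacted=_fmt(cov.n_relatives_contacted),
                    fhh_knowledge=_fmt(cov.fhh_knowledge),
                    age=_fmt(cov.age),
                    ethnicity=cov.ethnicity,
                    education=_fmt(cov.education),
                )
            rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def _opt_float(v: str) -> Optional[float]:
    return float(v) if v != "" else None


def _opt_int(v: str) -> Optional[int]:
    return int(float(v)) if v != "" else None


def _bool(v: str, where: str) -> bool:
    low = v.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no", ""):
        return False
    raise ValueError(f"{where}: cannot parse boolean {v!r}")


def read_cohort(path: PathLike, validate: bool = True) -> Cohort:
    """Read a cohort CSV; raises on malformed rows (naming file:line) and,
    when ``validate``, on any structural invariant violation."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    peds: dict[str, Pedigree] = {}
    order: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        where = f"{path}:{idx}"
        try:
            relation = RelationCode(row.relation)
        except ValueError:
            raise ValueError(f"{where}: unknown relation code {row.relation!r}") from None
        if row.lineage and row.lineage != lineage_of(relation).value:
            raise ValueError(
                f"{where}: lineage {row.lineage!r} disagrees with relation "
                f"{relation.value!r} (expected {lineage_of(relation).value!r})"
            )
        rel = Relative(
            person_id=row.person_id,
            relation=relation,
            gender=row.gender or "unknown",
            vital_status=row.vital_status or "unknown",
            current_age=_opt_float(row.current_age),
            age_at_death=_opt_float(row.age_at_death),
            cause_of_death=row.cause_of_death or None,
            conditions=_parse_conditions(row.conditions, where),
            data_reported=_bool(row.data_reported, where) if row.data_reported else True,
        )
        ped_id = row.pedigree_id
        if ped_id not in peds:
            order.append(ped_id)
            peds[ped_id] = Pedigree(ped_id, proband=None, relatives=[])  # type: ignore[arg-type]
        ped = peds[ped_id]
        if relation is RelationCode.PROBAND:
            if ped.proband is not None:
                raise ValueError(f"{where}: second proband row for pedigree {ped_id!r}")
            ped.proband = rel
            ped.proband_covariates = ProbandCovariates(
                age=_opt_float(row.age),
                gender=row.gender or "unknown",
                ethnicity=row.ethnicity or "other",
                education=_opt_int(row.education),
                talked_to_relatives=_bool(row.talked_to_relatives, where),
                n_relatives_contacted=_opt_int(row.n_relatives_contacted) or 0,
                fhh_knowledge=_opt_int(row.fhh_knowledge),
            )
        else:
            ped.relatives.append(rel)

    for ped_id, ped in peds.items():
        if ped.proband is None:
            raise ValueError(f"{path}: pedigree {ped_id!r} has no proband row")
    cohort = Cohort([peds[k] for k in order])
    if validate:
        violations = validate_cohort(cohort)
        if violations:
            head = "; ".join(str(v) for v in violations[:5])
            raise ValueError(f"{path}: {len(violations)} invariant violation(s): {head}")
    return cohort


# ---------------------------------------------------------------------
# Linkage PED export
# ---------------------------------------------------------------------

_SEX_CODE = {"male": "1", "female": "2", "unknown": "0"}


def write_ped(c: Cohort, path: PathLike) -> None:
    """Export a cohort as a 6-column linkage PED file.

    Parent links are derived from relation codes; placeholder founders
    (ids ending in ``_sp``/``_x``) are synthesized where a structural
    parent has no explicit row (aunt's spouse, parents of nieces when no
    sibling is listed, ...).  Phenotype is affected-by-any-disease
    (1 = unaffected, 2 = affected, 0 = missing/no data).
    """
    R = RelationCode
    lines: list[str] = []
    for ped in c.pedigrees:
        fid = ped.pedigree_id
        by_code: dict[RelationCode, list[Relative]] = {}
        for m in ped.members:
            by_code.setdefault(m.relation, []).append(m)

        placeholders: dict[str, str] = {}  # placeholder id -> sex code

        def placeholder(tag: str, sex: str) -> str:
            pid = f"{fid}_{tag}"
            placeholders.setdefault(pid, _SEX_CODE[sex])
            return pid

        def first_id(code: RelationCode, tag: str, sex: str) -> str:
            if by_code.get(code):
                return by_code[code][0].person_id
            return placeholder(tag, sex)

        def parents_of(m: Relative) -> tuple[str, str]:
            code = m.relation
            if code in (R.PROBAND, R.SISTER, R.BROTHER):
                return (first_id(R.FATHER, "father_x", "male"), first_id(R.MOTHER, "mother_x", "female"))
            if code is R.HALF_SIBLING:
                # shares the mother by convention; other parent unknown
                return (placeholder("hs_father_x", "male"), first_id(R.MOTHER, "mother_x", "female"))
            if code in (R.MOTHER, R.MATERNAL_AUNT, R.MATERNAL_UNCLE):
                return (
                    first_id(R.MATERNAL_GRANDFATHER, "mgf_x", "male"),
                    first_id(R.MATERNAL_GRANDMOTHER, "mgm_x", "female"),
                )
            if code in (R.FATHER, R.PATERNAL_AUNT, R.PATERNAL_UNCLE):
                return (
                    first_id(R.PATERNAL_GRANDFATHER, "pgf_x", "male"),
                    first_id(R.PATERNAL_GRANDMOTHER, "pgm_x", "female"),
                )
            if code in (R.DAUGHTER, R.SON):
                pro = ped.proband
                if pro.gender == "female":
                    return (placeholder("pro_sp", "male"), pro.person_id)
                return (pro.person_id, placeholder("pro_sp", "female"))
            if code in (R.NIECE, R.NEPHEW):
                sib = (by_code.get(R.SISTER) or by_code.get(R.BROTHER) or [None])[0]
                if sib is None:
                    return (placeholder("sib_x", "male"), placeholder("sib_sp_x", "female"))
                if sib.gender == "female":
                    return (placeholder("sib_sp", "male"), sib.person_id)
                return (sib.person_id, placeholder("sib_sp", "female"))
            if code is R.GRANDCHILD:
                child = (by_code.get(R.DAUGHTER) or by_code.get(R.SON) or [None])[0]
                if child is None:
                    return (placeholder("child_x", "male"), placeholder("child_sp_x", "female"))
                if child.gender == "female":
                    return (placeholder("child_sp", "male"), child.person_id)
                return (child.person_id, placeholder("child_sp", "female"))
            if code is R.COUSIN:
                au = next((by_code[c][0] for c in (R.MATERNAL_AUNT, R.MATERNAL_UNCLE,
                                                   R.PATERNAL_AUNT, R.PATERNAL_UNCLE)
                           if by_code.get(c)), None)
                if au is None:
                    return (placeholder("au_x", "male"), placeholder("au_sp_x", "female"))
                if au.gender == "female":
                    return (placeholder("au_sp", "male"), au.person_id)
                return (au.person_id, placeholder("au_sp", "female"))
            # founders: grandparents
            return ("0", "0")

        for m in ped.members:
            father, mother = parents_of(m)
            if not m.data_reported:
                pheno = "0"
            else:
                pheno = "2" if m.is_affected else "1"
            lines.append(
                " ".join([fid, m.person_id, father, mother, _SEX_CODE.get(m.gender, "0"), pheno])
            )
        for pid, sex in placeholders.items():
            lines.append(" ".join([fid, pid, "0", "0", sex, "0"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------

CRITERION_LABELS = {
    CriterionId.C1_THREE_GENERATIONS: "1. 3 generations of relatives",
    CriterionId.C2_LINEAGE: "2. Relatives' lineage",
    CriterionId.C3_GENDER: "3. Relatives' gender",
    CriterionId.C4_PERTINENT_NEGATIVES: "4. Pertinent negatives noted",
    CriterionId.C5_AGE_OF_ONSET: "5. Age of disease onset",
    CriterionId.C6_CAUSE_OF_DEATH: "6. Cause of death",
    CriterionId.C7_AGE_OF_DEATH: "7. Age of death",
}


def _num(x: float) -> Optional[float]:
    return None if (isinstance(x, float) and math.isnan(x)) else x


def summaries_to_dict(
    quality: CriterionSummary,
    prevalences: Optional[list[PrevalenceResult]] = None,
    lambdas: Optional[list[LambdaEstimate]] = None,
    no_data: Optional[dict[str, NoDataStats]] = None,
    hq_sweep_curve: Optional[list[tuple[float, float]]] = None,
) -> dict:
    """Assemble computed summaries into one JSON-serializable report dict."""
    report: dict = {
        "criteria": {
            "n_pedigrees": quality.n_pedigrees,
            "n_pedigrees_with_deceased": quality.n_pedigrees_with_deceased,
            "n_high_quality": quality.n_high_quality,
            "high_quality_pct": _num(quality.high_quality_pct),
            "onset_denominator": quality.onset_denominator,
            "rows": [
                {
                    "criterion": cid.value,
                    "label": CRITERION_LABELS[cid],
                    "n_met": quality.criterion_n[cid],
                    "pct": _num(quality.criterion_pct[cid]),
                }
                for cid in CriterionId
            ],
            "proportions": {
                name: {k: _num(v) if isinstance(v, float) else v for k, v in vars(ps).items()}
                for name, ps in quality.proportions.items()
            },
        }
    }
    if prevalences is not None:
        report["prevalence"] = [
            {
                "disease": p.disease,
                "mode": p.mode.value,
                "denominator_rule": p.denominator_rule.value,
                "numerator": p.numerator,
                "denominator": p.denominator,
                "value": _num(p.value),
            }
            for p in prevalences
        ]
    if lambdas is not None:
        report["sibling_lambda"] = [
            {
                "disease": e.disease,
                "lambda": _num(e.lam),
                "ci_low": _num(e.ci_low),
                "ci_high": _num(e.ci_high),
                "n_eligible_probands": e.n_eligible_probands,
                "n_affected_probands": e.n_affected_probands,
                "n_siblings_of_affected": e.n_siblings_of_affected,
                "n_affected_siblings": e.n_affected_siblings,
                "n_bootstrap": e.n_bootstrap,
            }
            for e in lambdas
        ]
    if no_data is not None:
        report["no_data"] = {
            name: {k: _num(v) if isinstance(v, float) else v for k, v in vars(s).items()}
            for name, s in no_data.items()
        }
    if hq_sweep_curve is not None:
        report["hq_sweep"] = [{"threshold": t, "proportion": p} for t, p in hq_sweep_curve]
    return report


def render_report(report: dict, path: PathLike) -> None:
    """Write a report dict as ``<path>.json`` and ``<path>.md`` (plus the
    HQ-threshold sweep as ``<path>_hq_sweep.csv`` when present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(".json").write_text(json.dumps(report, indent=2) + "\n")

    lines: list[str] = ["# Family health history quality report", ""]
    crit = report["criteria"]
    lines += [
        f"Pedigrees: {crit['n_pedigrees']} "
        f"({crit['n_pedigrees_with_deceased']} with >=1 deceased relative)",
        "",
        f"High-quality pedigrees (>=1 high-quality relative): "
        f"{crit['n_high_quality']} ({_pct(crit['high_quality_pct'])})",
        "",
        "| Quality criterion | N met | % |",
        "|---|---|---|",
    ]
    for row in crit["rows"]:
        lines.append(f"| {row['label']} | {row['n_met']} | {_pct(row['pct'])} |")
    lines.append("")

    if "prevalence" in report:
        lines += ["## Disease frequency", "", "| Disease | Mode | N | Denominator | % |", "|---|---|---|---|---|"]
        for p in report["prevalence"]:
            pct = _pct(100 * p["value"]) if p["value"] is not None else "undefined"
            lines.append(
                f"| {p['disease']} | {p['mode']} ({p['denominator_rule']}) "
                f"| {p['numerator']} | {p['denominator']} | {pct} |"
            )
        lines.append("")

    lines.append("## Sibling recurrence-risk ratios")
    lines.append("")
    if report.get("sibling_lambda"):
        lines += ["| Disease | lambda | 95% CI | affected sibs / sibs | proband N |", "|---|---|---|---|---|"]
        for e in report["sibling_lambda"]:
            if e["lambda"] is None:
                lines.append(f"| {e['disease']} | undefined | - | - | - |")
            else:
                lines.append(
                    f"| {e['disease']} | {e['lambda']:.2f} | {e['ci_low']:.2f}-{e['ci_high']:.2f} "
                    f"| {e['n_affected_siblings']}/{e['n_siblings_of_affected']} "
                    f"| {e['n_affected_probands']}/{e['n_eligible_probands']} |"
                )
    else:
        lines.append("not estimated")
    lines.append("")

    if "no_data" in report:
        lines += ["## Relatives with no reported data", "", "| Stratum | mean % (all) | mean % (subgroup) | pedigrees w/ no-data |", "|---|---|---|---|"]
        for name, s in report["no_data"].items():
            lines.append(
                f"| {name} | {_pct(100 * s['mean_prop_all'] if s['mean_prop_all'] is not None else None)} "
                f"| {_pct(100 * s['mean_prop_subgroup'] if s['mean_prop_subgroup'] is not None else None)} "
                f"| {s['n_pedigrees_with_nodata']} |"
            )
        lines.append("")

    path.with_suffix(".md").write_text("\n".join(lines))

    if "hq_sweep" in report:
        pd.DataFrame(report["hq_sweep"]).to_csv(
            path.parent / (path.stem + "_hq_sweep.csv"), index=False
        )


def _pct(x: Optional[float]) -> str:
    return "n/a" if x is None else f"{x:.1f}%"


def load_config(path: PathLike) -> dict:
    """Load a YAML generator/analysis configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top-level config must be a mapping")
    return data
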