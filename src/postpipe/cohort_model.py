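"""Domain types and CSV schema for cohort, expert-panel and rater-label inputs.

Conventions
-----------
* Missing values are encoded as empty cells; ``0`` is a legal value and never
  means "missing".
* Headache laterality is stored *relative to the treated aneurysm side*
  (``ipsilateral`` / ``contralateral`` / ``bilateral`` / ``unknown``);
  :func:`relative_laterality` converts absolute sides.
* The cohort CSV carries a leading comment line ``# postpipe-cohort <version>``
  guarding against silent column drift.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

from .errors import CohortValidationError, SchemaError

SCHEMA_VERSION = "v1"
_SCHEMA_TAG = "# postpipe-cohort"


class Laterality(str, Enum):
    IPSILATERAL = "ipsilateral"
    CONTRALATERAL = "contralateral"
    BILATERAL = "bilateral"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class PriorDiagnosis(str, Enum):
    NONE = "none"
    MIGRAINE = "migraine"
    TENSION_TYPE = "tension_type"
    SECONDARY_TO_ANEURYSM = "secondary_to_aneurysm"


class ReportedDirection(str, Enum):
    IMPROVED = "improved"
    SAME = "same"
    WORSE = "worse"
    NOT_APPLICABLE = "not_applicable"


SYMPTOMS = frozenset(
    {"nausea", "vomiting", "photophobia", "phonophobia", "visual_disturbances"}
)

#: Controlled vocabulary of aneurysm locations (Table-2-style topography).
ANEURYSM_LOCATIONS = (
    "vertebral_basilar",
    "vertebral_pica",
    "basilar_p1",
    "aca_a1_a2",
    "acom",
    "a2_a3",
    "ica_cervical",
    "petrous",
    "cavernous",
    "ophthalmic",
    "choroidal",
    "pcom",
    "a1",
    "m1",
    "mca_m1_m2",
    "pca_p1_pcom",
    "p2_p3",
)

#: Locations in the posterior circulation (the anterior flag is still an
#: independent input field; this set only backs the default assignment).
POSTERIOR_LOCATIONS = frozenset(
    {"vertebral_basilar", "vertebral_pica", "basilar_p1", "pca_p1_pcom", "p2_p3"}
)


def relative_laterality(headache_side: str, aneurysm_side: str) -> Laterality:
    """Convert an absolute headache side to aneurysm-relative laterality.

    ``headache_side`` in {left, right, bilateral, unknown};
    ``aneurysm_side`` in {left, right}.
    """
    if headache_side == "bilateral":
        return Laterality.BILATERAL
    if headache_side == "unknown":
        return Laterality.UNKNOWN
    if headache_side not in ("left", "right"):
        raise ValueError(f"unknown headache side {headache_side!r}")
    if aneurysm_side not in ("left", "right"):
        raise ValueError(f"unknown aneurysm side {aneurysm_side!r}")
    return (
        Laterality.IPSILATERAL
        if headache_side == aneurysm_side
        else Laterality.CONTRALATERAL
    )


@dataclass(frozen=True)
class HeadacheProfile:
    """Headache phenotype in one epoch (pre- or post-procedural).

    Numeric fields may be ``None`` when not collected; a criterion needing a
    missing field fails loudly at scoring time rather than scoring zero.
    """

    present: bool
    nrs_intensity: Optional[float] = None
    monthly_headache_days: Optional[float] = None
    attack_duration_hours: Optional[float] = None
    laterality: Optional[Laterality] = None
    symptoms: frozenset = frozenset()
    analgesic_count: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))

    def validate(self, patient_id="?", prefix=""):
        def err(fieldname, msg):
            raise CohortValidationError(patient_id, prefix + fieldname, msg)

        bad = self.symptoms - SYMPTOMS
        if bad:
            err("symptoms", f"unknown symptoms {sorted(bad)}")
        if not self.present:
            for name in (
                "nrs_intensity",
                "monthly_headache_days",
                "attack_duration_hours",
            ):
                v = getattr(self, name)
                if v not in (None, 0, 0.0):
                    err(name, "must be absent/zero when no headache is present")
            if self.symptoms:
                err("symptoms", "must be empty when no headache is present")
            if self.laterality is not None:
                err("laterality", "must be absent when no headache is present")
            return
        if self.nrs_intensity is not None and not 0 <= self.nrs_intensity <= 10:
            err("nrs_intensity", "0 <= nrs_intensity <= 10")
        if self.monthly_headache_days is not None and not (
            0 <= self.monthly_headache_days <= 31
        ):
            err("monthly_headache_days", "0 <= monthly_headache_days <= 31")
        if self.attack_duration_hours is not None and self.attack_duration_hours <= 0:
            err("attack_duration_hours", "attack_duration_hours > 0")
        if self.analgesic_count is not None and self.analgesic_count < 0:
            err("analgesic_count", "analgesic_count >= 0")

    @classmethod
    def absent(cls) -> "HeadacheProfile":
        return cls(present=False)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    sex: Sex
    prior_headache_diagnosis: PriorDiagnosis
    aneurysm_location: str
    anterior_circulation: bool
    neck_mm: float
    dome_mm: float
    aspect_ratio: float
    pre_profile: HeadacheProfile
    post_profile_3m: HeadacheProfile
    criterion_A_met: bool
    criterion_D_met: bool
    patient_reported_direction: ReportedDirection
    post_profile_12m: Optional[HeadacheProfile] = None
    similarity_rating: Optional[float] = None
    coils_used: Optional[bool] = None
    dapt_months: Optional[float] = None
    mapt_used: Optional[bool] = None
    mapt_months: Optional[float] = None
    steroids_postop: Optional[bool] = None
    reintervention: Optional[bool] = None
    partial_thrombosis: Optional[bool] = None
    row_number: Optional[int] = field(default=None, compare=False)

    def validate(self):
        pid = self.patient_id

        def err(fieldname, msg):
            raise CohortValidationError(pid, fieldname, msg)

        if self.age < 18:
            err("age", "age >= 18")
        if self.aneurysm_location not in ANEURYSM_LOCATIONS:
            err("aneurysm_location", f"unknown location {self.aneurysm_location!r}")
        for name in ("neck_mm", "dome_mm", "aspect_ratio"):
            if getattr(self, name) <= 0:
                err(name, f"{name} > 0")
        for name in ("dapt_months", "mapt_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                err(name, f"{name} >= 0")
        self.pre_profile.validate(pid, "pre_")
        self.post_profile_3m.validate(pid, "post3m_")
        if self.post_profile_12m is not None:
            self.post_profile_12m.validate(pid, "post12m_")
        naive = self.prior_headache_diagnosis is PriorDiagnosis.NONE
        if naive and self.pre_profile.present:
            err("pre_present", "prior_headache_diagnosis=none requires absent pre-profile")
        if not naive and not self.pre_profile.present:
            err("pre_present", "a prior headache diagnosis requires a pre-profile")
        if self.similarity_rating is not None:
            if not (self.pre_profile.present and self.post_profile_3m.present):
                err(
                    "similarity_rating",
                    "similarity_rating requires both pre and post headaches",
                )
            if not 0 <= self.similarity_rating <= 10:
                err("similarity_rating", "0 <= similarity_rating <= 10")
        return self


@dataclass(frozen=True)
class ExpertRating:
    """One expert's relevance/clarity judgment of one score item."""

    rater_id: str
    item_id: str
    relevance: int
    clarity: int

    ITEMS = ("A", "B", "C1", "C2", "C3", "C4", "C5", "C6", "D", "threshold")

    def validate(self):
        if self.item_id not in self.ITEMS:
            raise CohortValidationError(self.rater_id, "item_id", f"unknown item {self.item_id!r}")
        for name in ("relevance", "clarity"):
            if getattr(self, name) not in (1, 2, 3, 4):
                raise CohortValidationError(self.rater_id, name, "Likert value must be in 1..4")
        return self


@dataclass(frozen=True)
class RaterLabel:
    """One external rater's binary post-pipeline classification of one patient."""

    rater_id: str
    patient_id: str
    label: bool


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

_PROFILE_FIELDS = (
    "present",
    "nrs_intensity",
    "monthly_headache_days",
    "attack_duration_hours",
    "laterality",
    "symptoms",
    "analgesic_count",
)

_SCALAR_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "prior_headache_diagnosis",
    "aneurysm_location",
    "anterior_circulation",
    "neck_mm",
    "dome_mm",
    "aspect_ratio",
    "coils_used",
    "dapt_months",
    "mapt_used",
    "mapt_months",
    "steroids_postop",
    "reintervention",
    "partial_thrombosis",
    "criterion_A_met",
    "criterion_D_met",
    "patient_reported_direction",
    "similarity_rating",
)

COHORT_COLUMNS = _SCALAR_COLUMNS + tuple(
    f"{prefix}_{f}" for prefix in ("pre", "post3m", "post12m") for f in _PROFILE_FIELDS
)


def _fmt_bool(v):
    return "" if v is None else ("true" if v else "false")


def _fmt_num(v):
    if v is None:
        return ""
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def _parse_bool(s, ctx):
    if s == "true":
        return True
    if s == "false":
        return False
    raise SchemaError(f"{ctx}: expected true/false, got {s!r}")


def _parse_opt_bool(s, ctx):
    return None if s == "" else _parse_bool(s, ctx)


def _parse_opt_float(s, ctx):
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise SchemaError(f"{ctx}: expected a number, got {s!r}")


def _profile_to_cells(profile: Optional[HeadacheProfile]) -> dict:
    if profile is None:
        return {f: "" for f in _PROFILE_FIELDS}
    return {
        "present": _fmt_bool(profile.present),
        "nrs_intensity": _fmt_num(profile.nrs_intensity),
        "monthly_headache_days": _fmt_num(profile.monthly_headache_days),
        "attack_duration_hours": _fmt_num(profile.attack_duration_hours),
        "laterality": profile.laterality.value if profile.laterality else "",
        "symptoms": ";".join(sorted(profile.symptoms)),
        "analgesic_count": _fmt_num(profile.analgesic_count),
    }


def _profile_from_cells(cells: dict, ctx: str, optional: bool) -> Optional[HeadacheProfile]:
    if cells["present"] == "":
        if optional:
            return None
        raise SchemaError(f"{ctx}: 'present' flag is mandatory")
    lat = cells["laterality"]
    symptoms = frozenset(s for s in cells["symptoms"].split(";") if s)
    return HeadacheProfile(
        present=_parse_bool(cells["present"], ctx),
        nrs_intensity=_parse_opt_float(cells["nrs_intensity"], ctx),
        monthly_headache_days=_parse_opt_float(cells["monthly_headache_days"], ctx),
        attack_duration_hours=_parse_opt_float(cells["attack_duration_hours"], ctx),
        laterality=Laterality(lat) if lat else None,
        symptoms=symptoms,
        analgesic_count=_parse_opt_float(cells["analgesic_count"], ctx),
    )


def record_to_row(record: PatientRecord) -> dict:
    row = {
        "patient_id": record.patient_id,
        "age": _fmt_num(record.age),
        "sex": record.sex.value,
        "prior_headache_diagnosis": record.prior_headache_diagnosis.value,
        "aneurysm_location": record.aneurysm_location,
        "anterior_circulation": _fmt_bool(record.anterior_circulation),
        "neck_mm": _fmt_num(record.neck_mm),
        "dome_mm": _fmt_num(record.dome_mm),
        "aspect_ratio": _fmt_num(record.aspect_ratio),
        "coils_used": _fmt_bool(record.coils_used),
        "dapt_months": _fmt_num(record.dapt_months),
        "mapt_used": _fmt_bool(record.mapt_used),
        "mapt_months": _fmt_num(record.mapt_months),
        "steroids_postop": _fmt_bool(record.steroids_postop),
        "reintervention": _fmt_bool(record.reintervention),
        "partial_thrombosis": _fmt_bool(record.partial_thrombosis),
        "criterion_A_met": _fmt_bool(record.criterion_A_met),
        "criterion_D_met": _fmt_bool(record.criterion_D_met),
        "patient_reported_direction": record.patient_reported_direction.value,
        "similarity_rating": _fmt_num(record.similarity_rating),
    }
    for prefix, profile in (
        ("pre", record.pre_profile),
        ("post3m", record.post_profile_3m),
        ("post12m", record.post_profile_12m),
    ):
        for k, v in _profile_to_cells(profile).items():
            row[f"{prefix}_{k}"] = v
    return row


def record_from_row(row: dict, row_number: int) -> PatientRecord:
    pid = row.get("patient_id", "")
    ctx = f"row {row_number} (patient {pid!r})"
    try:
        record = PatientRecord(
            patient_id=pid,
            age=float(row["age"]),
            sex=Sex(row["sex"]),
            prior_headache_diagnosis=PriorDiagnosis(row["prior_headache_diagnosis"]),
            aneurysm_location=row["aneurysm_location"],
            anterior_circulation=_parse_bool(row["anterior_circulation"], ctx),
            neck_mm=float(row["neck_mm"]),
            dome_mm=float(row["dome_mm"]),
            aspect_ratio=float(row["aspect_ratio"]),
            coils_used=_parse_opt_bool(row["coils_used"], ctx),
            dapt_months=_parse_opt_float(row["dapt_months"], ctx),
            mapt_used=_parse_opt_bool(row["mapt_used"], ctx),
            mapt_months=_parse_opt_float(row["mapt_months"], ctx),
            steroids_postop=_parse_opt_bool(row["steroids_postop"], ctx),
            reintervention=_parse_opt_bool(row["reintervention"], ctx),
            partial_thrombosis=_parse_opt_bool(row["partial_thrombosis"], ctx),
            criterion_A_met=_parse_bool(row["criterion_A_met"], ctx),
            criterion_D_met=_parse_bool(row["criterion_D_met"], ctx),
            patient_reported_direction=ReportedDirection(row["patient_reported_direction"]),
            similarity_rating=_parse_opt_float(row["similarity_rating"], ctx),
            pre_profile=_profile_from_cells(
                {f: row[f"pre_{f}"] for f in _PROFILE_FIELDS}, ctx, optional=False
            ),
            post_profile_3m=_profile_from_cells(
                {f: row[f"post3m_{f}"] for f in _PROFILE_FIELDS}, ctx, optional=False
            ),
            post_profile_12m=_profile_from_cells(
                {f: row[f"post12m_{f}"] for f in _PROFILE_FIELDS}, ctx, optional=True
            ),
            row_number=row_number,
        )
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"{ctx}: {exc}") from exc
    return record.validate()


def read_cohort(path, schema_version: str = SCHEMA_VERSION) -> list[PatientRecord]:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` on header problems and
    :class:`CohortValidationError` on invariant violations (with patient id
    and field name).
    """
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.startswith(_SCHEMA_TAG):
            raise SchemaError(
                f"{path}: missing schema comment line '{_SCHEMA_TAG} <version>'"
            )
        found_version = first[len(_SCHEMA_TAG):].strip()
        if found_version != schema_version:
            raise SchemaError(
                f"{path}: schema version {found_version!r} != expected {schema_version!r}"
            )
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(reader, start=2):
            records.append(record_from_row(row, row_number=i))
    return records


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write a cohort CSV such that ``read_cohort`` round-trips losslessly."""
    rows = []
    for r in records:
        r.validate()
        rows.append(record_to_row(r))
    buf = io.StringIO()
    buf.write(f"{_SCHEMA_TAG} {SCHEMA_VERSION}\n")
    writer = csv.DictWriter(buf, fieldnames=list(COHORT_COLUMNS), lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def read_panel(path) -> list[ExpertRating]:
    """Read a long-format expert-panel CSV (rater_id,item_id,relevance,clarity)."""
    ratings = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for col in ("rater_id", "item_id", "relevance", "clarity"):
            if col not in (reader.fieldnames or []):
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        for row in reader:
            ratings.append(
                ExpertRating(
                    rater_id=row["rater_id"],
                    item_id=row["item_id"],
                    relevance=int(row["relevance"]),
                    clarity=int(row["clarity"]),
                ).validate()
            )
    return ratings


def write_panel(ratings: Iterable[ExpertRating], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["rater_id", "item_id", "relevance", "clarity"])
        for r in ratings:
            writer.writerow([r.rater_id, r.item_id, r.relevance, r.clarity])


def read_rater_labels(path) -> list[RaterLabel]:
    """Read rater-label CSV (rater_id,patient_id,label); duplicates rejected."""
    labels = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for col in ("rater_id", "patient_id", "label"):
            if col not in (reader.fieldnames or []):
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        for i, row in enumerate(reader, start=2):
            key = (row["rater_id"], row["patient_id"])
            if key in seen:
                raise SchemaError(f"{path} row {i}: duplicate label for {key}")
            seen.add(key)
            labels.append(
                RaterLabel(
                    rater_id=row["rater_id"],
                    patient_id=row["patient_id"],
                    label=_parse_bool(row["label"], f"row {i}"),
                )
            )
    return labels


def write_rater_labels(labels: Iterable[RaterLabel], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["rater_id", "patient_id", "label"])
        for lab in labels:
            writer.writerow([lab.rater_id, lab.patient_id, _fmt_bool(lab.label)])
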