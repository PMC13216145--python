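"""Composite post-procedural headache score and five-way outcome classification.

Two diagnostic pathways exist. Headache-naive patients who develop a new,
persistent headache (pathway B) are diagnostic by construction. Patients with
a pre-existing headache disorder (pathway C) accumulate points across six
change criteria (intensity, lateralization, attack duration, associated
symptoms, frequency, subjective dissimilarity) and qualify at a configurable
threshold (default >= 9), always conditional on the clinician-supplied
criteria A (persistence >= 3 months) and D (no better alternative diagnosis).

A pre-existing headache that worsens but stays below threshold is treated as
normal fluctuation of the primary disorder and classified "no change".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .cohort_model import HeadacheProfile, Laterality, PatientRecord, PriorDiagnosis, ReportedDirection, SYMPTOMS
from .config import ScoringConfig
from .errors import InsufficientDataError, UnclassifiedTransientError

DEFAULT_CONFIG = ScoringConfig()


class Pathway(str, Enum):
    NEW_ONSET_B = "new_onset_B"
    PREEXISTING_C = "preexisting_C"
    NOT_APPLICABLE = "not_applicable"


class OutcomeCategory(str, Enum):
    NEVER = "never"
    NEW_ONSET = "new_onset"
    IMPROVEMENT = "improvement"
    NO_CHANGE = "no_change"
    WORSENING = "worsening"


@dataclass(frozen=True)
class ScoreBreakdown:
    patient_id: str
    c1_intensity: int
    c2_lateralization: int
    c3_duration: int
    c4_symptoms: int
    c5_frequency: int
    c6_dissimilarity: int
    b_naive: int
    total: int
    criterion_A: bool
    criterion_D: bool
    pathway: Pathway
    is_post_pipeline: bool

    @property
    def c_total(self) -> int:
        return (
            self.c1_intensity
            + self.c2_lateralization
            + self.c3_duration
            + self.c4_symptoms
            + self.c5_frequency
            + self.c6_dissimilarity
        )


def duration_category(hours: float, config: ScoringConfig = DEFAULT_CONFIG) -> int:
    """Attack-duration category: 0 (<4 h), 1 (4-24 h), 2 (24-72 h), 3 (>72 h).

    Touching band labels are resolved by assigning the boundary to the lower
    band (24 h -> category 1, 72 h -> category 2).
    """
    if hours is None or hours <= 0:
        raise ValueError(f"attack duration must be positive, got {hours!r}")
    e1, e2, e3 = config.duration_edges
    if hours < e1:
        return 0
    if hours <= e2:
        return 1
    if hours <= e3:
        return 2
    return 3


def score_intensity_change(
    pre_nrs: float, post_nrs: float, config: ScoringConfig = DEFAULT_CONFIG
) -> int:
    """C1: points for an increase in mean pain intensity on the 0-10 NRS.

    +2 for an increase of 2 to <4 points, +4 for >= 4 points (the >=4 band
    wins at the overlapping boundary). Decreases score 0.
    """
    for v, name in ((pre_nrs, "pre"), (post_nrs, "post")):
        if v is None or not 0 <= v <= 10:
            raise ValueError(f"{name} NRS out of range [0, 10]: {v!r}")
    d = post_nrs - pre_nrs
    if d >= config.c1_major_delta:
        return config.c1_major_points
    if d >= config.c1_moderate_delta:
        return config.c1_moderate_points
    return 0


def score_lateralization(
    pre_lat: Laterality, post_lat: Laterality, config: ScoringConfig = DEFAULT_CONFIG
) -> int:
    """C2: points for a lateralization shift relative to the aneurysm side.

    Strict reading: only contralateral -> ipsilateral scores. With
    ``lenient_lateralization`` any non-ipsilateral -> ipsilateral shift
    scores (prose variant "toward the aneurysm side").
    """
    pre_lat = Laterality(pre_lat)
    post_lat = Laterality(post_lat)
    if post_lat is Laterality.IPSILATERAL:
        if pre_lat is Laterality.CONTRALATERAL:
            return config.c2_points
        if config.lenient_lateralization and pre_lat in (
            Laterality.BILATERAL,
            Laterality.UNKNOWN,
        ):
            return config.c2_points
    return 0


def score_duration_change(
    pre_hours: float, post_hours: float, config: ScoringConfig = DEFAULT_CONFIG
) -> int:
    """C3: +1 for one upward duration-category transition, +4 (configurable)
    for two or more. Shortening scores 0."""
    k = duration_category(post_hours, config) - duration_category(pre_hours, config)
    if k <= 0:
        return 0
    if k == 1:
        return config.c3_single_jump_points
    return config.c3_multi_jump_points


def score_symptom_change(
    pre_symptoms: Iterable[str],
    post_symptoms: Iterable[str],
    config: ScoringConfig = DEFAULT_CONFIG,
) -> int:
    """C4: new-onset associated symptoms; +1 each, nausea +2; lost symptoms 0."""
    pre = frozenset(pre_symptoms)
    post = frozenset(post_symptoms)
    bad = (pre | post) - SYMPTOMS
    if bad:
        raise ValueError(f"unknown symptom token(s): {sorted(bad)}")
    points = 0
    for s in post - pre:
        points += config.c4_nausea_points if s == "nausea" else config.c4_symptom_points
    return points


def score_frequency_change(
    pre_mhd: float, post_mhd: float, config: ScoringConfig = DEFAULT_CONFIG
) -> int:
    """C5: +4 for a >= 50% frequency increase with at least 5 extra days/month.

    A pre-frequency of 0 (episodic patient headache-free in the reference
    window) satisfies the relative condition; the absolute floor still applies.
    """
    for v, name in ((pre_mhd, "pre"), (post_mhd, "post")):
        if v is None or v < 0:
            raise ValueError(f"{name} monthly headache days must be >= 0, got {v!r}")
    extra = post_mhd - pre_mhd
    if extra < config.c5_min_extra_days:
        return 0
    if pre_mhd > 0 and extra / pre_mhd < config.c5_min_relative_increase:
        return 0
    return config.c5_points


def score_dissimilarity(
    rating: float, scale: str = "dissimilarity", config: ScoringConfig = DEFAULT_CONFIG
) -> int:
    """C6: patient-reported dissimilarity of the post headache from baseline.

    ``scale="similarity"`` accepts the interview scale (0 = very different,
    10 = identical) and converts internally; the score bands apply to the
    dissimilarity direction: >= 8 -> +4, 6 to <8 -> +2, < 6 -> 0.
    """
    if rating is None or not 0 <= rating <= 10:
        raise ValueError(f"rating out of range [0, 10]: {rating!r}")
    if scale == "similarity":
        d = 10 - rating
    elif scale == "dissimilarity":
        d = rating
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if d >= config.c6_major_edge:
        return config.c6_major_points
    if d >= config.c6_moderate_edge:
        return config.c6_moderate_points
    return 0


def _require_fields(record: PatientRecord, pairs):
    missing = [name for name, value in pairs if value is None]
    if missing:
        raise InsufficientDataError(record.patient_id, missing)


def compute_score(
    record: PatientRecord, config: ScoringConfig = DEFAULT_CONFIG
) -> ScoreBreakdown:
    """Score one patient at the 3-month assessment.

    Raises :class:`InsufficientDataError` listing the missing fields if any
    applicable criterion lacks its inputs; a criterion is never silently
    scored zero.
    """
    pre = record.pre_profile
    post = record.post_profile_3m
    A = record.criterion_A_met
    D = record.criterion_D_met
    zero = dict(
        c1_intensity=0,
        c2_lateralization=0,
        c3_duration=0,
        c4_symptoms=0,
        c5_frequency=0,
        c6_dissimilarity=0,
    )

    if not post.present:
        return ScoreBreakdown(
            patient_id=record.patient_id,
            **zero,
            b_naive=0,
            total=0,
            criterion_A=A,
            criterion_D=D,
            pathway=Pathway.NOT_APPLICABLE,
            is_post_pipeline=False,
        )

    naive = record.prior_headache_diagnosis is PriorDiagnosis.NONE
    if naive:
        b = config.b_naive_points
        return ScoreBreakdown(
            patient_id=record.patient_id,
            **zero,
            b_naive=b,
            total=b,
            criterion_A=A,
            criterion_D=D,
            pathway=Pathway.NEW_ONSET_B,
            is_post_pipeline=A and D,
        )

    _require_fields(
        record,
        [
            ("pre_nrs_intensity", pre.nrs_intensity),
            ("post3m_nrs_intensity", post.nrs_intensity),
            ("pre_laterality", pre.laterality),
            ("post3m_laterality", post.laterality),
            ("pre_attack_duration_hours", pre.attack_duration_hours),
            ("post3m_attack_duration_hours", post.attack_duration_hours),
            ("pre_monthly_headache_days", pre.monthly_headache_days),
            ("post3m_monthly_headache_days", post.monthly_headache_days),
            ("similarity_rating", record.similarity_rating),
        ],
    )

    c1 = score_intensity_change(pre.nrs_intensity, post.nrs_intensity, config)
    c2 = score_lateralization(pre.laterality, post.laterality, config)
    c3 = score_duration_change(pre.attack_duration_hours, post.attack_duration_hours, config)
    c4 = score_symptom_change(pre.symptoms, post.symptoms, config)
    c5 = score_frequency_change(pre.monthly_headache_days, post.monthly_headache_days, config)
    c6 = score_dissimilarity(record.similarity_rating, scale="similarity", config=config)
    total = c1 + c2 + c3 + c4 + c5 + c6
    return ScoreBreakdown(
        patient_id=record.patient_id,
        c1_intensity=c1,
        c2_lateralization=c2,
        c3_duration=c3,
        c4_symptoms=c4,
        c5_frequency=c5,
        c6_dissimilarity=c6,
        b_naive=0,
        total=total,
        criterion_A=A,
        criterion_D=D,
        pathway=Pathway.PREEXISTING_C,
        is_post_pipeline=A and D and total >= config.threshold,
    )


def classify_outcome(record: PatientRecord, breakdown: ScoreBreakdown) -> OutcomeCategory:
    """Five-way post-procedural outcome.

    * no pre, no post -> ``never``
    * no pre, post, diagnostic -> ``new_onset``
    * pre, patient reports improvement -> ``improvement`` (regardless of
      feature changes)
    * pre, reports worsening and diagnostic -> ``worsening``
    * pre, reports no difference, or sub-threshold worsening -> ``no_change``

    A naive patient with a non-diagnostic post headache has no bucket and
    raises :class:`UnclassifiedTransientError` for manual review.
    """
    pre = record.pre_profile.present
    post = record.post_profile_3m.present
    direction = record.patient_reported_direction
    if not pre:
        if not post:
            return OutcomeCategory.NEVER
        if breakdown.is_post_pipeline:
            return OutcomeCategory.NEW_ONSET
        raise UnclassifiedTransientError(record.patient_id)
    if direction is ReportedDirection.IMPROVED:
        return OutcomeCategory.IMPROVEMENT
    if direction is ReportedDirection.WORSE:
        return (
            OutcomeCategory.WORSENING
            if breakdown.is_post_pipeline
            else OutcomeCategory.NO_CHANGE
        )
    if direction is ReportedDirection.SAME:
        return OutcomeCategory.NO_CHANGE
    raise ValueError(
        f"patient {record.patient_id!r}: direction {direction.value!r} is not "
        "classifiable for a patient with a pre-existing headache"
    )


def score_cohort(
    records: Iterable[PatientRecord], config: ScoringConfig = DEFAULT_CONFIG
) -> tuple[dict[str, ScoreBreakdown], dict[str, OutcomeCategory]]:
    """Score and classify every record; returns (breakdowns, outcomes) by id."""
    breakdowns: dict[str, ScoreBreakdown] = {}
    outcomes: dict[str, OutcomeCategory] = {}
    for record in records:
        bd = compute_score(record, config)
        breakdowns[record.patient_id] = bd
        outcomes[record.patient_id] = classify_outcome(record, bd)
    return breakdowns, outcomes
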