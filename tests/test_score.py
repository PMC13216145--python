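import dataclasses

import numpy as np
import pytest

from postpipe.cohort_model import (
    HeadacheProfile,
    Laterality,
    PatientRecord,
    PriorDiagnosis,
    ReportedDirection,
    Sex,
)
from postpipe.config import ScoringConfig
from postpipe.errors import InsufficientDataError, UnclassifiedTransientError
from postpipe.score import (
    OutcomeCategory,
    Pathway,
    classify_outcome,
    compute_score,
    duration_category,
    score_dissimilarity,
    score_duration_change,
    score_frequency_change,
    score_intensity_change,
    score_lateralization,
    score_symptom_change,
)
from oracles import oracle_pre_existing_total

L = Laterality


def make_record(
    pre=None,
    post=None,
    prior=PriorDiagnosis.MIGRAINE,
    similarity=None,
    A=True,
    D=True,
    direction=ReportedDirection.WORSE,
    pid="P1",
):
    return PatientRecord(
        patient_id=pid,
        age=50.0,
        sex=Sex.FEMALE,
        prior_headache_diagnosis=prior,
        aneurysm_location="ophthalmic",
        anterior_circulation=True,
        neck_mm=5.0,
        dome_mm=10.0,
        aspect_ratio=2.0,
        pre_profile=pre if pre is not None else HeadacheProfile.absent(),
        post_profile_3m=post if post is not None else HeadacheProfile.absent(),
        criterion_A_met=A,
        criterion_D_met=D,
        patient_reported_direction=direction,
        similarity_rating=similarity,
    )


def profile(nrs=5, mhd=5, hours=12, lat=L.IPSILATERAL, symptoms=()):
    return HeadacheProfile(
        present=True,
        nrs_intensity=float(nrs),
        monthly_headache_days=float(mhd),
        attack_duration_hours=float(hours),
        laterality=lat,
        symptoms=frozenset(symptoms),
    )


class TestDurationCategory:
    @pytest.mark.parametrize(
        "hours,expected",
        [(2, 0), (3.99, 0), (4, 1), (24, 1), (24.5, 2), (72, 2), (72.1, 3), (100, 3)],
    )
    def test_bands(self, hours, expected):
        assert duration_category(hours) == expected

    @pytest.mark.parametrize("hours", [0, -1])
    def test_nonpositive_rejected(self, hours):
        with pytest.raises(ValueError):
            duration_category(hours)


class TestIntensityChange:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(5, 5, 0), (4, 7, 2), (3, 8, 4), (5, 9, 4), (5, 7, 2), (8, 3, 0), (5, 6.9, 0)],
    )
    def test_bands(self, pre, post, expected):
        assert score_intensity_change(pre, post) == expected

    def test_boundary_difference_of_exactly_4_scores_4(self):
        assert score_intensity_change(3, 7) == 4

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_intensity_change(5, 11)


class TestLateralization:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (L.CONTRALATERAL, L.IPSILATERAL, 2),
            (L.IPSILATERAL, L.IPSILATERAL, 0),
            (L.IPSILATERAL, L.CONTRALATERAL, 0),
            (L.CONTRALATERAL, L.CONTRALATERAL, 0),
            (L.BILATERAL, L.IPSILATERAL, 0),
            (L.UNKNOWN, L.IPSILATERAL, 0),
            (L.CONTRALATERAL, L.BILATERAL, 0),
        ],
    )
    def test_strict_table(self, pre, post, expected):
        assert score_lateralization(pre, post) == expected

    def test_lenient_variant_scores_any_shift_toward_aneurysm(self):
        cfg = ScoringConfig(lenient_lateralization=True)
        assert score_lateralization(L.BILATERAL, L.IPSILATERAL, cfg) == 2
        assert score_lateralization(L.IPSILATERAL, L.IPSILATERAL, cfg) == 0


class TestDurationChange:
    @pytest.mark.parametrize(
        "pre,post,expected", [(12, 12, 0), (12, 48, 1), (2, 100, 4), (48, 12, 0), (2, 12, 1)]
    )
    def test_jumps(self, pre, post, expected):
        assert score_duration_change(pre, post) == expected

    def test_multi_jump_points_configurable(self):
        cfg = ScoringConfig(c3_multi_jump_points=5)
        assert score_duration_change(2, 100, cfg) == 5


class TestSymptomChange:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (set(), {"nausea"}, 2),
            ({"photophobia"}, {"photophobia"}, 0),
            ({"nausea"}, {"vomiting", "photophobia"}, 2),
            (set(), {"nausea", "vomiting", "photophobia", "phonophobia", "visual_disturbances"}, 6),
            ({"nausea"}, set(), 0),
        ],
    )
    def test_new_symptoms(self, pre, post, expected):
        assert score_symptom_change(pre, post) == expected

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError):
            score_symptom_change(set(), {"dizziness"})


class TestFrequencyChange:
    @pytest.mark.parametrize(
        "pre,post,expected", [(4, 10, 4), (10, 14, 0), (0, 6, 4), (0, 4, 0), (10, 15, 4), (20, 26, 0)]
    )
    def test_bands(self, pre, post, expected):
        assert score_frequency_change(pre, post) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            score_frequency_change(-1, 5)


class TestDissimilarity:
    @pytest.mark.parametrize(
        "rating,scale,expected",
        [
            (9, "dissimilarity", 4),
            (3, "dissimilarity", 0),
            (3, "similarity", 2),  # 10-3=7 falls in the 6-8 band
            (8, "dissimilarity", 4),
            (6, "dissimilarity", 2),
            (5.9, "dissimilarity", 0),
            (0, "similarity", 4),
        ],
    )
    def test_bands(self, rating, scale, expected):
        assert score_dissimilarity(rating, scale) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            score_dissimilarity(11, "dissimilarity")


class TestComputeScore:
    def test_naive_path_diagnostic(self):
        rec = make_record(
            post=profile(), prior=PriorDiagnosis.NONE, A=True, D=True,
            direction=ReportedDirection.NOT_APPLICABLE,
        )
        bd = compute_score(rec)
        assert bd.pathway is Pathway.NEW_ONSET_B
        assert bd.b_naive == 9 and bd.total == 9
        assert bd.is_post_pipeline

    def test_naive_path_requires_A_and_D(self):
        rec = make_record(
            post=profile(), prior=PriorDiagnosis.NONE, A=True, D=False,
            direction=ReportedDirection.NOT_APPLICABLE,
        )
        assert not compute_score(rec).is_post_pipeline

    def test_preexisting_hand_summed_example(self):
        # NRS 4->7, contralateral->ipsilateral, 12->48 h, new nausea,
        # MHD 4->10, dissimilarity 7 -> components (2,2,1,2,4,2), total 13
        rec = make_record(
            pre=profile(nrs=4, mhd=4, hours=12, lat=L.CONTRALATERAL),
            post=profile(nrs=7, mhd=10, hours=48, lat=L.IPSILATERAL, symptoms={"nausea"}),
            similarity=3.0,  # dissimilarity 7
        )
        bd = compute_score(rec)
        assert (
            bd.c1_intensity,
            bd.c2_lateralization,
            bd.c3_duration,
            bd.c4_symptoms,
            bd.c5_frequency,
            bd.c6_dissimilarity,
        ) == (2, 2, 1, 2, 4, 2)
        assert bd.total == 13
        assert bd.is_post_pipeline

    def test_preexisting_all_below_floors(self):
        rec = make_record(
            pre=profile(nrs=5), post=profile(nrs=6), similarity=7.0  # dissimilarity 3
        )
        bd = compute_score(rec)
        assert bd.total == 0
        assert not bd.is_post_pipeline

    def test_no_post_headache(self):
        rec = make_record(
            pre=profile(), post=HeadacheProfile.absent(),
            direction=ReportedDirection.IMPROVED,
        )
        bd = compute_score(rec)
        assert bd.pathway is Pathway.NOT_APPLICABLE
        assert bd.total == 0 and not bd.is_post_pipeline

    def test_missing_fields_raise_insufficient_data(self):
        rec = make_record(
            pre=profile(),
            post=HeadacheProfile(present=True, nrs_intensity=7.0),
            similarity=None,
        )
        with pytest.raises(InsufficientDataError) as exc:
            compute_score(rec)
        assert "similarity_rating" in exc.value.missing_fields
        assert "post3m_monthly_headache_days" in exc.value.missing_fields

    def test_threshold_configurable(self):
        rec = make_record(
            pre=profile(nrs=3, mhd=4), post=profile(nrs=8, mhd=10), similarity=8.0
        )
        assert compute_score(rec).total == 8
        assert not compute_score(rec).is_post_pipeline
        assert compute_score(rec, ScoringConfig(threshold=8)).is_post_pipeline


class TestClassifyOutcome:
    def classify(self, rec):
        return classify_outcome(rec, compute_score(rec))

    def test_never(self):
        rec = make_record(prior=PriorDiagnosis.NONE, A=False, D=False,
                          direction=ReportedDirection.NOT_APPLICABLE)
        assert self.classify(rec) is OutcomeCategory.NEVER

    def test_new_onset(self):
        rec = make_record(post=profile(), prior=PriorDiagnosis.NONE,
                          direction=ReportedDirection.NOT_APPLICABLE)
        assert self.classify(rec) is OutcomeCategory.NEW_ONSET

    def test_improvement_regardless_of_feature_changes(self):
        # a new symptom appears, yet the patient reports improvement
        rec = make_record(
            pre=profile(nrs=7), post=profile(nrs=4, symptoms={"phonophobia"}),
            similarity=8.0, direction=ReportedDirection.IMPROVED,
        )
        assert self.classify(rec) is OutcomeCategory.IMPROVEMENT

    def test_minimal_worsening_is_no_change(self):
        rec = make_record(
            pre=profile(nrs=5), post=profile(nrs=6), similarity=8.0,
            direction=ReportedDirection.WORSE,
        )
        assert self.classify(rec) is OutcomeCategory.NO_CHANGE

    def test_worsening_above_threshold(self):
        rec = make_record(
            pre=profile(nrs=3, mhd=4, hours=12),
            post=profile(nrs=8, mhd=10, hours=48),
            similarity=3.0, direction=ReportedDirection.WORSE,
        )
        assert self.classify(rec) is OutcomeCategory.WORSENING

    def test_same_is_no_change(self):
        rec = make_record(pre=profile(), post=profile(), similarity=9.0,
                          direction=ReportedDirection.SAME)
        assert self.classify(rec) is OutcomeCategory.NO_CHANGE

    def test_transient_new_headache_flagged(self):
        rec = make_record(post=profile(), prior=PriorDiagnosis.NONE, A=False,
                          direction=ReportedDirection.NOT_APPLICABLE)
        with pytest.raises(UnclassifiedTransientError):
            self.classify(rec)


# ---------------------------------------------------------------------------
# Randomized oracle equivalence and structural properties
# ---------------------------------------------------------------------------


def random_preexisting_record(rng, pid="R"):
    lats = list(Laterality)
    syms = ["nausea", "vomiting", "photophobia", "phonophobia", "visual_disturbances"]
    pre_sym = frozenset(rng.choice(syms, size=rng.integers(0, 4), replace=False))
    post_sym = frozenset(rng.choice(syms, size=rng.integers(0, 4), replace=False))
    pre = profile(
        nrs=int(rng.integers(0, 11)),
        mhd=int(rng.integers(0, 29)),
        hours=float(rng.choice([1, 3, 4, 12, 24, 36, 48, 72, 96, 200])),
        lat=lats[rng.integers(0, 4)],
        symptoms=pre_sym,
    )
    post = profile(
        nrs=int(rng.integers(0, 11)),
        mhd=int(rng.integers(0, 29)),
        hours=float(rng.choice([1, 3, 4, 12, 24, 36, 48, 72, 96, 200])),
        lat=lats[rng.integers(0, 4)],
        symptoms=post_sym,
    )
    return make_record(
        pre=pre, post=post, similarity=float(rng.integers(0, 11)),
        A=bool(rng.integers(0, 2)), D=bool(rng.integers(0, 2)), pid=pid,
    )


def test_oracle_equivalence_on_random_records():
    rng = np.random.default_rng(42)
    for i in range(10_000):
        rec = random_preexisting_record(rng, pid=f"R{i}")
        bd = compute_score(rec)
        expected = oracle_pre_existing_total(
            rec.pre_profile.nrs_intensity,
            rec.post_profile_3m.nrs_intensity,
            rec.pre_profile.laterality.value,
            rec.post_profile_3m.laterality.value,
            rec.pre_profile.attack_duration_hours,
            rec.post_profile_3m.attack_duration_hours,
            rec.pre_profile.symptoms,
            rec.post_profile_3m.symptoms,
            rec.pre_profile.monthly_headache_days,
            rec.post_profile_3m.monthly_headache_days,
            rec.similarity_rating,
        )
        assert bd.total == expected, rec


def test_monotonicity_in_each_delta():
    rng = np.random.default_rng(7)
    for i in range(400):
        rec = random_preexisting_record(rng)
        base = compute_score(rec).total
        post = rec.post_profile_3m
        # raise intensity
        if post.nrs_intensity < 10:
            bumped = dataclasses.replace(post, nrs_intensity=post.nrs_intensity + 1)
            assert compute_score(dataclasses.replace(rec, post_profile_3m=bumped)).total >= base
        # raise frequency
        if post.monthly_headache_days < 30:
            bumped = dataclasses.replace(
                post, monthly_headache_days=post.monthly_headache_days + 1
            )
            assert compute_score(dataclasses.replace(rec, post_profile_3m=bumped)).total >= base
        # lengthen attacks
        bumped = dataclasses.replace(
            post, attack_duration_hours=post.attack_duration_hours * 3
        )
        assert compute_score(dataclasses.replace(rec, post_profile_3m=bumped)).total >= base
        # add a symptom
        missing = {"nausea", "vomiting"} - post.symptoms
        if missing:
            bumped = dataclasses.replace(post, symptoms=post.symptoms | {missing.pop()})
            assert compute_score(dataclasses.replace(rec, post_profile_3m=bumped)).total >= base
        # more dissimilar (lower similarity rating)
        if rec.similarity_rating > 0:
            assert (
                compute_score(
                    dataclasses.replace(rec, similarity_rating=rec.similarity_rating - 1)
                ).total
                >= base
            )


def test_total_bounds_and_pathway_exclusivity(default_config):
    rng = np.random.default_rng(11)
    max_total = default_config.max_total
    assert max_total == 24
    for i in range(2000):
        rec = random_preexisting_record(rng)
        bd = compute_score(rec)
        assert 0 <= bd.total <= max_total
        assert bd.b_naive == 0  # pre-existing path
        assert bd.total == bd.c_total
    naive = make_record(post=profile(), prior=PriorDiagnosis.NONE,
                        direction=ReportedDirection.NOT_APPLICABLE)
    bd = compute_score(naive)
    assert bd.total in (0, 9) and bd.c_total == 0  # B and C mutually exclusive


def test_diagnosis_implies_A_D_and_threshold(scored_fixture, default_config):
    breakdowns, outcomes = scored_fixture
    for pid, bd in breakdowns.items():
        if bd.is_post_pipeline:
            assert bd.criterion_A and bd.criterion_D
            assert bd.pathway is Pathway.NEW_ONSET_B or bd.total >= default_config.threshold
            assert outcomes[pid] in (OutcomeCategory.NEW_ONSET, OutcomeCategory.WORSENING)
        else:
            assert outcomes[pid] not in (
                OutcomeCategory.NEW_ONSET, OutcomeCategory.WORSENING
            )


def test_exactly_one_category_per_record(scored_fixture):
    _, outcomes = scored_fixture
    assert len(outcomes) == 137
    assert sum(1 for _ in outcomes.values()) == 137
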