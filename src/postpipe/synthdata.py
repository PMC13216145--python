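"""Synthetic cohorts, a deterministic fixture cohort, simulated raters and
expert panels.

Patient-level study data are not public. Two generators stand in for them:

* :func:`simulate_cohort` draws stochastic cohorts with the statistical
  structure the analysis assumes (lognormal aneurysm dimensions, a logistic
  neck-size -> outcome model, phenotype-change templates conditional on the
  outcome), reproducible from a seed.
* :func:`make_fixture_cohort` builds, with no randomness, a 137-record cohort
  whose derived categorical marginals reproduce the published counts exactly
  once run through the real scoring and classification code.

Only categorical counts are promised exactly by the fixture; continuous
fields carry deterministic values placed near the published group means
(record-level continuous data are unrecoverable from mean +/- SD).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .cohort_model import (
    ANEURYSM_LOCATIONS,
    POSTERIOR_LOCATIONS,
    ExpertRating,
    HeadacheProfile,
    Laterality,
    PatientRecord,
    PriorDiagnosis,
    RaterLabel,
    ReportedDirection,
    Sex,
)
from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# Phenotype-change templates
# ---------------------------------------------------------------------------
# Each worsening template is (pre_profile_kwargs, post_profile_kwargs,
# similarity_rating) chosen so the scoring rules award a known total.
# Component arithmetic, with defaults:
#   NRS 3->8            -> +4      MHD 4->10          -> +4
#   duration 12->48 h   -> +1      contralateral->ipsilateral -> +2
#   new nausea          -> +2      similarity 3 (dissimilarity 7) -> +2

def _profile(nrs, mhd, hours, lat, symptoms=(), amn=2.0):
    return HeadacheProfile(
        present=True,
        nrs_intensity=nrs,
        monthly_headache_days=mhd,
        attack_duration_hours=hours,
        laterality=lat,
        symptoms=frozenset(symptoms),
        analgesic_count=amn,
    )


_L = Laterality

#: total -> (pre, post, similarity_rating); totals checked by the test suite
WORSENING_TEMPLATES: dict[int, tuple[HeadacheProfile, HeadacheProfile, float]] = {
    9: (
        _profile(3, 4, 12, _L.IPSILATERAL, {"photophobia"}),
        _profile(8, 10, 48, _L.IPSILATERAL, {"photophobia"}, amn=6.0),
        8.0,
    ),
    10: (
        _profile(3, 4, 12, _L.IPSILATERAL, {"photophobia"}),
        _profile(8, 10, 12, _L.IPSILATERAL, {"photophobia"}, amn=6.0),
        3.0,
    ),
    11: (
        _profile(3, 4, 12, _L.IPSILATERAL, {"photophobia"}),
        _profile(8, 10, 48, _L.IPSILATERAL, {"photophobia"}, amn=7.0),
        3.0,
    ),
    12: (
        _profile(3, 4, 12, _L.CONTRALATERAL, {"photophobia"}),
        _profile(8, 10, 12, _L.IPSILATERAL, {"photophobia"}, amn=7.0),
        3.0,
    ),
    13: (
        _profile(3, 4, 12, _L.IPSILATERAL, {"photophobia"}),
        _profile(8, 10, 48, _L.IPSILATERAL, {"photophobia", "nausea"}, amn=8.0),
        3.0,
    ),
}

#: Sub-threshold "minimal worsening" templates (total, pre, post, similarity).
MINIMAL_WORSENING_TEMPLATES = (
    (0, _profile(5, 6, 12, _L.BILATERAL), _profile(6, 6, 12, _L.BILATERAL), 8.0),
    (2, _profile(5, 6, 12, _L.BILATERAL), _profile(7, 8, 12, _L.BILATERAL), 8.0),
)

_UNCHANGED_PRE = _profile(5, 6, 12, _L.BILATERAL, {"phonophobia"})
_IMPROVED_PRE = _profile(7, 8, 24, _L.BILATERAL, {"photophobia"})
_IMPROVED_POST = _profile(4, 4, 12, _L.BILATERAL, {"photophobia"}, amn=1.0)
# improvement despite one technically-worsened feature (new symptom)
_IMPROVED_POST_MIXED = _profile(4, 4, 12, _L.BILATERAL, {"photophobia", "phonophobia"}, amn=1.0)
_NEW_ONSET_POST = _profile(6, 8, 24, _L.IPSILATERAL, {"photophobia"}, amn=4.0)


# ---------------------------------------------------------------------------
# Deterministic fixture cohort (n = 137)
# ---------------------------------------------------------------------------

#: Published worsening-group score totals are summarized as 10.82 +/- 1.94;
#: these 17 template totals average 10.82.
_FIXTURE_WORSENING_TOTALS = (9, 9, 9, 9, 10, 10, 10, 10, 11, 11, 11, 12, 12, 12, 13, 13, 13)

# Aneurysm topography by eventual diagnostic group, matching the published
# per-group level counts.
_FIXTURE_LOCATIONS_POS = (
    ["ophthalmic"] * 16
    + ["pcom"] * 4
    + ["cavernous"] * 3
    + ["a2_a3"] * 2
    + ["vertebral_basilar", "basilar_p1", "a1", "mca_m1_m2"]
)
_FIXTURE_LOCATIONS_NEG = (
    ["ophthalmic"] * 52
    + ["pcom"] * 14
    + ["vertebral_basilar"] * 13
    + ["cavernous"] * 10
    + ["acom"] * 4
    + ["a2_a3"] * 3
    + ["vertebral_pica"] * 2
    + [
        "aca_a1_a2",
        "ica_cervical",
        "petrous",
        "choroidal",
        "a1",
        "m1",
        "mca_m1_m2",
        "pca_p1_pcom",
        "p2_p3",
        "basilar_p1",
    ]
)

# Continuous fixture fields come from irrational-rotation (low-discrepancy)
# sequences: fully deterministic and RNG-free, but irregular enough that the
# two diagnostic groups overlap in every covariate (regular cyclic grids make
# the groups linearly separable and break the regression stage).
_ALPHA_NECK = 0.6180339887498949  # frac(golden ratio)
_ALPHA_DOME = 0.4142135623730951  # frac(sqrt 2)
_ALPHA_AGE = 0.7320508075688772  # frac(sqrt 3)
_ALPHA_DAPT = 0.2360679774997896  # frac(sqrt 5)
_ALPHA_MAPT = 0.6457513110645906  # frac(sqrt 7)


def _rot(i: int, alpha: float, phase: float = 0.0) -> float:
    """i-th point of an irrational rotation on [0, 1)."""
    return ((i + 1) * alpha + phase) % 1.0


def _fixture_continuous(i: int, post_pipeline: bool):
    """Deterministic neck/dome/age values near the published group means."""
    if post_pipeline:
        neck = 6.03 + 5.0 * (_rot(i, _ALPHA_NECK) - 0.5)
        dome = 13.68 + 10.0 * (_rot(i, _ALPHA_DOME) - 0.5)
    else:
        neck = 4.83 + 4.0 * (_rot(i, _ALPHA_NECK, 0.31) - 0.5)
        dome = 10.14 + 8.0 * (_rot(i, _ALPHA_DOME, 0.17) - 0.5)
    age = 58.3 + 28.0 * (_rot(i, _ALPHA_AGE) - 0.5)
    return round(neck, 2), round(dome, 2), round(age, 1)


def _fixture_treatment(i: int):
    """Deterministic treatment details; a few deliberate missing values
    exercise the optional-field conventions."""
    mapt_used = i % 6 != 5
    return dict(
        coils_used=None if i % 13 == 7 else (i % 5 == 0),
        dapt_months=round(3.8 + 3.0 * (_rot(i, _ALPHA_DAPT) - 0.5), 1),
        mapt_used=mapt_used,
        mapt_months=round(5.4 + 4.0 * (_rot(i, _ALPHA_MAPT) - 0.5), 1) if mapt_used else None,
        steroids_postop=i % 3 != 2,
        reintervention=i % 34 == 0,
        partial_thrombosis=i % 10 == 0,
    )


def make_fixture_cohort() -> list[PatientRecord]:
    """Deterministic 137-record cohort reproducing the published marginals.

    Derived counts under the default scoring configuration:
    improvement 41, no-change 30, worsening 17, new-onset 12, never 37;
    prior-headache split 88/49; suspected-secondary subgroup 18 with 3
    worseners; 26 males split 23/3 and anterior circulation 118 split 91/27
    by diagnostic group.
    """
    records: list[PatientRecord] = []
    pos_locations = list(_FIXTURE_LOCATIONS_POS)
    neg_locations = list(_FIXTURE_LOCATIONS_NEG)
    # The published anterior-circulation count (118, split 91/27) exceeds by
    # one what the topography level counts imply (117, split 90/27); the flag
    # is an independent input field, so one posterior-location record carries
    # anterior_circulation=True to reproduce both printed marginals.
    anterior_override = {"I37"}  # a vertebral-basilar record, see pop order below

    def add(pid, prior, pre, post, direction, A, D, similarity, post12m, post_pipeline, male):
        i = len(records)
        if post_pipeline:
            location = pos_locations.pop(0)
        else:
            location = neg_locations.pop(0)
        neck, dome, age = _fixture_continuous(i, post_pipeline)
        anterior = location not in POSTERIOR_LOCATIONS or pid in anterior_override
        records.append(
            PatientRecord(
                patient_id=pid,
                age=age,
                sex=Sex.MALE if male else Sex.FEMALE,
                prior_headache_diagnosis=prior,
                aneurysm_location=location,
                anterior_circulation=anterior,
                neck_mm=neck,
                dome_mm=dome,
                aspect_ratio=round(dome / neck, 2),
                pre_profile=pre,
                post_profile_3m=post,
                post_profile_12m=post12m,
                criterion_A_met=A,
                criterion_D_met=D,
                patient_reported_direction=direction,
                similarity_rating=similarity,
                **_fixture_treatment(i),
            ).validate()
        )

    # --- worsening (17): 3 suspected-secondary + 10 migraine + 4 tension ----
    worsening_priors = (
        [PriorDiagnosis.SECONDARY_TO_ANEURYSM] * 3
        + [PriorDiagnosis.MIGRAINE] * 10
        + [PriorDiagnosis.TENSION_TYPE] * 4
    )
    for k, (total, prior) in enumerate(zip(_FIXTURE_WORSENING_TOTALS, worsening_priors)):
        pre, post, sim = WORSENING_TEMPLATES[total]
        add(
            f"W{k + 1:02d}",
            prior,
            pre,
            post,
            ReportedDirection.WORSE,
            A=True,
            D=True,
            similarity=sim,
            post12m=post if k < 7 else None,
            post_pipeline=True,
            male=(k == 0),
        )

    # --- no change (30): 24 report "same", 6 minimal worsening below threshold
    nochange_priors = [PriorDiagnosis.MIGRAINE] * 18 + [PriorDiagnosis.TENSION_TYPE] * 12
    for k, prior in enumerate(nochange_priors):
        if k < 24:
            pre = post = _UNCHANGED_PRE
            direction, A = ReportedDirection.SAME, False
            sim = 9.0
        else:
            _, pre, post, sim = MINIMAL_WORSENING_TEMPLATES[k % 2]
            direction, A = ReportedDirection.WORSE, True
        add(
            f"N{k + 1:02d}",
            prior,
            pre,
            post,
            direction,
            A=A,
            D=True,
            similarity=sim,
            post12m=None,
            post_pipeline=False,
            male=(k < 7),
        )

    # --- improvement (41): 15 suspected-secondary + 18 migraine + 8 tension -
    improvement_priors = (
        [PriorDiagnosis.SECONDARY_TO_ANEURYSM] * 15
        + [PriorDiagnosis.MIGRAINE] * 18
        + [PriorDiagnosis.TENSION_TYPE] * 8
    )
    for k, prior in enumerate(improvement_priors):
        if k >= 31:  # headache resolved entirely
            post, sim = HeadacheProfile.absent(), None
        elif k == 15:  # improved overall despite one new symptom
            post, sim = _IMPROVED_POST_MIXED, 8.0
        else:
            post, sim = _IMPROVED_POST, 8.0
        add(
            f"I{k + 1:02d}",
            prior,
            _IMPROVED_PRE,
            post,
            ReportedDirection.IMPROVED,
            A=False,
            D=True,
            similarity=sim,
            post12m=None,
            post_pipeline=False,
            male=(k < 9),
        )

    # --- new onset (12) ----------------------------------------------------
    for k in range(12):
        add(
            f"O{k + 1:02d}",
            PriorDiagnosis.NONE,
            HeadacheProfile.absent(),
            _NEW_ONSET_POST,
            ReportedDirection.NOT_APPLICABLE,
            A=True,
            D=True,
            similarity=None,
            post12m=_NEW_ONSET_POST if k < 5 else None,
            post_pipeline=True,
            male=(k < 2),
        )

    # --- never (37) --------------------------------------------------------
    for k in range(37):
        add(
            f"V{k + 1:02d}",
            PriorDiagnosis.NONE,
            HeadacheProfile.absent(),
            HeadacheProfile.absent(),
            ReportedDirection.NOT_APPLICABLE,
            A=False,
            D=False,
            similarity=None,
            post12m=None,
            post_pipeline=False,
            male=(k < 7),
        )

    assert len(records) == 137 and not pos_locations and not neg_locations
    return records


# ---------------------------------------------------------------------------
# Stochastic cohort simulation
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the stochastic cohort generator.

    Defaults follow the published cohort: age 58.29 +/- 12.70, 19.0% male,
    prior-headache prevalence 88/137, neck 5.09 +/- 2.53 mm and dome
    10.90 +/- 6.62 mm (lognormal, moment-matched), and a logistic outcome
    model logit P = beta0 + beta_neck * neck with beta_neck = 0.388 and
    beta0 calibrated to a marginal prevalence of 0.212.
    """

    n_patients: int = 137
    seed: int = 0
    age_mean: float = 58.29
    age_sd: float = 12.70
    p_male: float = 0.19
    p_prior_headache: float = 88 / 137
    prior_mix: tuple[float, float, float] = (46 / 88, 24 / 88, 18 / 88)  # migraine, tension, secondary
    neck_mean_mm: float = 5.09
    neck_sd_mm: float = 2.53
    dome_mean_mm: float = 10.90
    dome_sd_mm: float = 6.62
    beta_neck: float = 0.388
    beta0: Optional[float] = None  # None -> calibrated to target_prevalence
    target_prevalence: float = 0.212
    p_signal: float = 1.0
    scoring_threshold: int = 9
    p_improved_given_benign: float = 41 / 71
    p_dapt_mean: float = 3.77
    p_dapt_sd: float = 1.99
    p_mapt_used: float = 0.81
    mapt_mean: float = 5.35
    mapt_sd: float = 3.61
    p_steroids: float = 0.64
    p_coils: float = 0.22
    p_reintervention: float = 0.042
    p_partial_thrombosis: float = 0.10

    def __post_init__(self):
        for name in (
            "p_male",
            "p_prior_headache",
            "p_signal",
            "p_improved_given_benign",
            "target_prevalence",
            "p_mapt_used",
            "p_steroids",
            "p_coils",
            "p_reintervention",
            "p_partial_thrombosis",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.prior_mix) - 1.0) > 1e-9:
            raise ConfigurationError("prior_mix must sum to 1")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if self.p_signal > 0 and self.scoring_threshold > max(WORSENING_TEMPLATES):
            raise ConfigurationError(
                f"scoring_threshold {self.scoring_threshold} exceeds the largest "
                f"achievable template total {max(WORSENING_TEMPLATES)}"
            )


def calibrate_intercept(config: SimConfig, n_draws: int = 50000) -> float:
    """Intercept beta0 such that the marginal outcome prevalence matches the
    configured target under the lognormal neck distribution (deterministic
    internal Monte-Carlo + bisection)."""
    from scipy.optimize import brentq
    from scipy.special import expit

    mu, sigma = _lognormal_params(config.neck_mean_mm, config.neck_sd_mm)
    rng = np.random.default_rng(987654321)  # fixed: calibration, not simulation
    neck = rng.lognormal(mu, sigma, size=n_draws)

    def gap(b0):
        return expit(b0 + config.beta_neck * neck).mean() - config.target_prevalence

    return float(brentq(gap, -40.0, 40.0, xtol=1e-10))


_TEMPLATE_TOTALS = tuple(sorted(WORSENING_TEMPLATES))
_TEMPLATE_WEIGHTS = np.array([4, 4, 3, 3, 3], dtype=float) / 17.0  # fixture mix


def simulate_cohort(config: SimConfig) -> tuple[list[PatientRecord], dict[str, bool]]:
    """Draw a reproducible synthetic cohort.

    Returns ``(records, truth)`` where ``truth`` maps patient id to the
    generative post-pipeline outcome flag. The truth travels separately from
    the records so pipeline stages cannot read it by accident.
    """
    rng = np.random.default_rng(config.seed)
    beta0 = config.beta0 if config.beta0 is not None else calibrate_intercept(config)
    neck_mu, neck_sigma = _lognormal_params(config.neck_mean_mm, config.neck_sd_mm)
    dome_mu, dome_sigma = _lognormal_params(config.dome_mean_mm, config.dome_sd_mm)
    from scipy.special import expit

    location_pool = np.array(ANEURYSM_LOCATIONS)
    # published overall topography frequencies
    location_weights = np.array([14, 2, 2, 1, 4, 5, 1, 1, 13, 68, 1, 18, 2, 1, 2, 1, 1], dtype=float)
    location_weights /= location_weights.sum()

    records: list[PatientRecord] = []
    truth: dict[str, bool] = {}
    n_digits = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"S{i + 1:0{n_digits}d}"
        age = float(np.round(max(18.0, rng.normal(config.age_mean, config.age_sd)), 1))
        male = rng.random() < config.p_male
        neck = float(np.round(rng.lognormal(neck_mu, neck_sigma), 2))
        dome = float(np.round(rng.lognormal(dome_mu, dome_sigma), 2))
        location = str(rng.choice(location_pool, p=location_weights))
        has_prior = rng.random() < config.p_prior_headache
        if has_prior:
            prior = (
                PriorDiagnosis.MIGRAINE,
                PriorDiagnosis.TENSION_TYPE,
                PriorDiagnosis.SECONDARY_TO_ANEURYSM,
            )[rng.choice(3, p=np.asarray(config.prior_mix))]
        else:
            prior = PriorDiagnosis.NONE
        is_pp = bool(rng.random() < expit(beta0 + config.beta_neck * neck))
        truth[pid] = is_pp

        if prior is PriorDiagnosis.NONE:
            if is_pp:
                pre, post = HeadacheProfile.absent(), _NEW_ONSET_POST
                direction, A, D, sim = ReportedDirection.NOT_APPLICABLE, True, True, None
            else:
                pre = post = HeadacheProfile.absent()
                direction, A, D, sim = ReportedDirection.NOT_APPLICABLE, False, False, None
        elif is_pp:
            if config.p_signal >= 1.0 or rng.random() < config.p_signal:
                total = int(rng.choice(_TEMPLATE_TOTALS, p=_TEMPLATE_WEIGHTS))
                pre, post, sim = WORSENING_TEMPLATES[total]
            else:
                _, pre, post, sim = MINIMAL_WORSENING_TEMPLATES[int(rng.integers(2))]
            direction, A, D = ReportedDirection.WORSE, True, True
        else:
            if rng.random() < config.p_improved_given_benign:
                pre, post, sim = _IMPROVED_PRE, _IMPROVED_POST, 8.0
                direction = ReportedDirection.IMPROVED
            else:
                pre = post = _UNCHANGED_PRE
                sim = 9.0
                direction = ReportedDirection.SAME
            A, D = False, True

        mapt_used = bool(rng.random() < config.p_mapt_used)
        records.append(
            PatientRecord(
                patient_id=pid,
                age=age,
                sex=Sex.MALE if male else Sex.FEMALE,
                prior_headache_diagnosis=prior,
                aneurysm_location=location,
                anterior_circulation=location not in POSTERIOR_LOCATIONS,
                neck_mm=neck,
                dome_mm=dome,
                aspect_ratio=round(dome / neck, 2),
                pre_profile=pre,
                post_profile_3m=post,
                post_profile_12m=None,
                criterion_A_met=A,
                criterion_D_met=D,
                patient_reported_direction=direction,
                similarity_rating=sim,
                coils_used=bool(rng.random() < config.p_coils),
                dapt_months=float(np.round(max(0.5, rng.normal(config.p_dapt_mean, config.p_dapt_sd)), 1)),
                mapt_used=mapt_used,
                mapt_months=(
                    float(np.round(max(0.5, rng.normal(config.mapt_mean, config.mapt_sd)), 1))
                    if mapt_used
                    else None
                ),
                steroids_postop=bool(rng.random() < config.p_steroids),
                reintervention=bool(rng.random() < config.p_reintervention),
                partial_thrombosis=bool(rng.random() < config.p_partial_thrombosis),
            ).validate()
        )
    return records, truth


# ---------------------------------------------------------------------------
# Simulated external raters and expert panel
# ---------------------------------------------------------------------------


def simulate_raters(
    truth: Mapping[str, bool],
    fn_rate: float = 0.16,
    fp_rate: float = 0.02,
    seed: int = 0,
    rater_ids: Sequence[str] = ("R1", "R2", "R3"),
) -> list[RaterLabel]:
    """Noisy binary raters: each label is the truth flipped independently
    with class-conditional error probabilities (false-negative rate on true
    positives, false-positive rate on true negatives)."""
    for name, v in (("fn_rate", fn_rate), ("fp_rate", fp_rate)):
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = []
    for rater_id in rater_ids:
        for pid in sorted(truth):
            t = truth[pid]
            flip = rng.random() < (fn_rate if t else fp_rate)
            labels.append(RaterLabel(rater_id=rater_id, patient_id=pid, label=t ^ flip))
    return labels


@dataclass(frozen=True)
class PanelConfig:
    """Expert-panel simulation: Likert draws per (rater, item, dimension)."""

    n_raters: int = 11
    seed: int = 0
    # P(rating = 1..4); default puts 0.96 mass on endorsement (>= 3)
    likert_probs: tuple[float, float, float, float] = (0.01, 0.03, 0.31, 0.65)

    def __post_init__(self):
        if self.n_raters < 2:
            raise ConfigurationError("n_raters must be >= 2")
        if abs(sum(self.likert_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.likert_probs):
            raise ConfigurationError("likert_probs must be a probability vector")


def simulate_panel(config: PanelConfig) -> list[ExpertRating]:
    """Seeded Likert panel over all score items."""
    rng = np.random.default_rng(config.seed)
    p = np.asarray(config.likert_probs)
    ratings = []
    for r in range(config.n_raters):
        for item in ExpertRating.ITEMS:
            rel, cla = rng.choice([1, 2, 3, 4], size=2, p=p)
            ratings.append(
                ExpertRating(
                    rater_id=f"E{r + 1:02d}",
                    item_id=item,
                    relevance=int(rel),
                    clarity=int(cla),
                ).validate()
            )
    return ratings
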