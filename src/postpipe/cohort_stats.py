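"""Descriptive summaries and group-comparison tests.

The comparison machinery mirrors the study's analysis plan: Fisher's exact
test for categorical variables (probability-mass two-sided convention), the
Mann-Whitney U test for continuous/ordinal variables (exact when feasible,
tie-corrected normal approximation with continuity correction otherwise), a
Monte-Carlo conditional exact test for multi-level tables, and Shapiro-Wilk
reported as metadata for the normality gate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from scipy.stats import shapiro as _scipy_shapiro

from .cohort_model import ANEURYSM_LOCATIONS, PatientRecord, Sex
from .errors import ConfigurationError
from .score import ScoreBreakdown

#: Relative tolerance on the "at most as probable" comparison, so that exact
#: ties survive floating-point evaluation of the hypergeometric pmf.
_FISHER_REL_TOL = 1e-7

#: Largest n_x * n_y for which the exact Mann-Whitney null distribution is used.
_MW_EXACT_LIMIT = 400


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value (AS R94, via scipy). Requires 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk supports at most 5000 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = _scipy_shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _hypergeom_pmf_support(n_total: int, r1: int, c1: int):
    """Support and pmf of the table count a given fixed margins (vectorized)."""
    lo = max(0, r1 + c1 - n_total)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(n_total - r1 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(n_total - r1 - c1 + k + 1)
        - (gammaln(n_total + 1) - gammaln(c1 + 1) - gammaln(n_total - c1 + 1))
    )
    return k, np.exp(logpmf)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Probability-mass convention: the p-value sums the hypergeometric
    probabilities of every table with the same margins whose probability does
    not exceed that of the observed table (relative tolerance 1e-7 on the
    comparison). A zero margin makes the table degenerate: p = 1 with a
    warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact_2x2 expects a 2x2 table of non-negative counts")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n_total = int(t.sum())
    if 0 in (r1, c1, n_total - r1, n_total - c1):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    k, pmf = _hypergeom_pmf_support(n_total, r1, c1)
    p_obs = pmf[a - k[0]]
    p = pmf[pmf <= p_obs * (1.0 + _FISHER_REL_TOL)].sum()
    return float(min(1.0, p))


def fisher_exact_rxc(table, n_mc: int = 20000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo conditional exact test for an r x c table.

    Samples tables with the observed margins by permuting column labels
    against row labels; the test statistic is the conditional
    (multivariate-hypergeometric) likelihood, and the p-value is the
    add-one-smoothed proportion of sampled tables at most as likely as the
    observed one. Returns ``(p, standard_error)``; bit-reproducible per seed.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("expected a 2-D table of non-negative counts")
    if t.size <= 4:
        raise ValueError("use fisher_exact_2x2 for 2x2 tables")
    if n_mc < 1000:
        raise ConfigurationError("n_mc must be at least 1000")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n_total = int(t.sum())
    if n_total == 0:
        warnings.warn("empty table; p = 1", stacklevel=2)
        return 1.0, 0.0

    def log_cond_lik(tab):
        # conditional likelihood given margins, up to a shared constant
        return -gammaln(tab + 1).sum()

    obs = log_cond_lik(t)
    row_labels = np.repeat(np.arange(t.shape[0]), rows)
    col_labels = np.repeat(np.arange(t.shape[1]), cols)
    rng = np.random.default_rng(seed)
    hits = 0
    tol = 1e-9  # float slack so equally-likely tables count as ties
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        sim = np.zeros_like(t)
        np.add.at(sim, (row_labels, perm), 1)
        if log_cond_lik(sim) <= obs + tol:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return float(p), float(se)


def _mann_whitney_exact_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U as counts, via the standard recursion
    (tie-free case). counts[u] = number of arrangements with U = u."""
    # f[i][j][u]: arrangements of i x-ranks among i+j with U = u
    # classical recurrence f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u)
    f = {}
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if i == 0 or j == 0:
                arr = np.zeros(i * j + 1)
                arr[0] = 1.0
            else:
                arr = np.zeros(i * j + 1)
                a = f[(i - 1, j)]
                arr[j : j + len(a)] += a
                b = f[(i, j - 1)]
                arr[: len(b)] += b
            f[(i, j)] = arr
    return f[(n1, n2)]


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) and two-sided p-value.

    Midrank ties; exact enumeration of the null distribution when the samples
    are tie-free and ``n_x * n_y <= 400``, otherwise a tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty_like(pooled)
    # midranks
    sorted_vals = pooled[order]
    ranks_sorted = np.arange(1, pooled.size + 1, dtype=float)
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks_sorted[i : j + 1] = (i + j + 2) / 2.0
        i = j + 1
    ranks[order] = ranks_sorted
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    m = n1 * n2
    if not has_ties and m <= _MW_EXACT_LIMIT:
        counts = _mann_whitney_exact_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        lo, hi = min(ui, m - ui), max(ui, m - ui)
        if lo == hi:
            p = 1.0
        else:
            p = (counts[: lo + 1].sum() + counts[hi:].sum()) / total
        return float(u), float(min(1.0, p))

    # tie-corrected normal approximation with continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = m / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return float(u), 1.0
    mu = m / 2.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * norm.sf(z)
    return float(u), float(min(1.0, p))


# ---------------------------------------------------------------------------
# Cohort summary (group-comparison table)
# ---------------------------------------------------------------------------

CONTINUOUS_VARIABLES = (
    "age",
    "neck_mm",
    "dome_mm",
    "aspect_ratio",
    "dapt_months",
    "mapt_months",
)

BINARY_VARIABLES = (
    ("sex_male", lambda r: r.sex is Sex.MALE),
    ("anterior_circulation", lambda r: r.anterior_circulation),
    ("coils_used", lambda r: r.coils_used),
    ("mapt_used", lambda r: r.mapt_used),
    ("steroids_postop", lambda r: r.steroids_postop),
    ("reintervention", lambda r: r.reintervention),
    ("partial_thrombosis", lambda r: r.partial_thrombosis),
)


@dataclass
class CohortSummary:
    """Group-comparison table: one row per variable (or variable level)."""

    table: pd.DataFrame
    n_total: int
    n_positive: int
    n_negative: int
    mc_seed: Optional[int] = None


def _cont_row(name, values_neg, values_pos):
    vn = np.array([v for v in values_neg if v is not None], dtype=float)
    vp = np.array([v for v in values_pos if v is not None], dtype=float)
    va = np.concatenate([vn, vp])
    row = {
        "variable": name,
        "level": "",
        "type": "continuous",
        "n_available": int(va.size),
        "mean_overall": va.mean() if va.size else np.nan,
        "sd_overall": va.std(ddof=1) if va.size > 1 else np.nan,
        "median_overall": np.median(va) if va.size else np.nan,
        "iqr_low": np.percentile(va, 25) if va.size else np.nan,
        "iqr_high": np.percentile(va, 75) if va.size else np.nan,
        "n_neg": int(vn.size),
        "mean_neg": vn.mean() if vn.size else np.nan,
        "sd_neg": vn.std(ddof=1) if vn.size > 1 else np.nan,
        "n_pos": int(vp.size),
        "mean_pos": vp.mean() if vp.size else np.nan,
        "sd_pos": vp.std(ddof=1) if vp.size > 1 else np.nan,
        "count_overall": np.nan,
        "pct_overall": np.nan,
        "count_neg": np.nan,
        "pct_neg": np.nan,
        "count_pos": np.nan,
        "pct_pos": np.nan,
    }
    if vn.size and vp.size:
        u, p = mann_whitney_u(vn, vp)
        row["test"] = "mann_whitney_u"
        row["statistic"] = u
        row["p_value"] = p
        try:
            row["shapiro_p_neg"] = shapiro_wilk(vn)[1] if vn.size >= 3 else np.nan
            row["shapiro_p_pos"] = shapiro_wilk(vp)[1] if vp.size >= 3 else np.nan
        except ValueError:
            row["shapiro_p_neg"] = np.nan
            row["shapiro_p_pos"] = np.nan
    else:
        row["test"] = ""
        row["statistic"] = np.nan
        row["p_value"] = np.nan
        row["shapiro_p_neg"] = np.nan
        row["shapiro_p_pos"] = np.nan
    return row


def _binary_row(name, flags_neg, flags_pos):
    fn = [f for f in flags_neg if f is not None]
    fp_ = [f for f in flags_pos if f is not None]
    cn, cp = sum(fn), sum(fp_)
    n_avail = len(fn) + len(fp_)
    row = {
        "variable": name,
        "level": "yes",
        "type": "binary",
        "n_available": n_avail,
        "count_overall": cn + cp,
        "pct_overall": 100.0 * (cn + cp) / n_avail if n_avail else np.nan,
        "n_neg": len(fn),
        "count_neg": cn,
        "pct_neg": 100.0 * cn / len(fn) if fn else np.nan,
        "n_pos": len(fp_),
        "count_pos": cp,
        "pct_pos": 100.0 * cp / len(fp_) if fp_ else np.nan,
        "mean_overall": np.nan,
        "sd_overall": np.nan,
        "median_overall": np.nan,
        "iqr_low": np.nan,
        "iqr_high": np.nan,
        "mean_neg": np.nan,
        "sd_neg": np.nan,
        "mean_pos": np.nan,
        "sd_pos": np.nan,
        "shapiro_p_neg": np.nan,
        "shapiro_p_pos": np.nan,
    }
    if fn and fp_:
        table = [[cn, len(fn) - cn], [cp, len(fp_) - cp]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact_2x2(table)
        row["test"] = "fisher_exact"
        row["statistic"] = np.nan
        row["p_value"] = p
    else:
        row["test"] = ""
        row["statistic"] = np.nan
        row["p_value"] = np.nan
    return row


def summarize_cohort(
    records: Iterable[PatientRecord],
    scores: Mapping[str, ScoreBreakdown],
    mc_seed: int = 0,
    mc_iterations: int = 20000,
) -> CohortSummary:
    """Build the group-comparison table (post-pipeline vs not).

    Continuous variables get Mann-Whitney; binary variables Fisher's exact
    test; the multi-level topography variable a seeded Monte-Carlo
    conditional exact test. Percentages are always recomputed from counts.
    """
    records = list(records)
    pos = [r for r in records if scores[r.patient_id].is_post_pipeline]
    neg = [r for r in records if not scores[r.patient_id].is_post_pipeline]
    rows = []
    for name in CONTINUOUS_VARIABLES:
        rows.append(
            _cont_row(
                name,
                [getattr(r, name) for r in neg],
                [getattr(r, name) for r in pos],
            )
        )
    for name, getter in BINARY_VARIABLES:
        rows.append(_binary_row(name, [getter(r) for r in neg], [getter(r) for r in pos]))

    # multi-level topography
    levels = [loc for loc in ANEURYSM_LOCATIONS]
    counts_neg = {loc: sum(1 for r in neg if r.aneurysm_location == loc) for loc in levels}
    counts_pos = {loc: sum(1 for r in pos if r.aneurysm_location == loc) for loc in levels}
    used = [loc for loc in levels if counts_neg[loc] + counts_pos[loc] > 0]
    topo_p = np.nan
    topo_se = np.nan
    if neg and pos and len(used) > 1:
        table = np.array([[counts_neg[loc] for loc in used], [counts_pos[loc] for loc in used]])
        topo_p, topo_se = fisher_exact_rxc(table, n_mc=mc_iterations, seed=mc_seed)
    for i, loc in enumerate(used):
        cn, cp = counts_neg[loc], counts_pos[loc]
        row = _binary_row(f"topography", [False] * len(neg), [False] * len(pos))
        row.update(
            level=loc,
            type="categorical",
            n_available=len(records),
            count_overall=cn + cp,
            pct_overall=100.0 * (cn + cp) / len(records) if records else np.nan,
            count_neg=cn,
            pct_neg=100.0 * cn / len(neg) if neg else np.nan,
            count_pos=cp,
            pct_pos=100.0 * cp / len(pos) if pos else np.nan,
            test="fisher_exact_mc" if i == 0 and not np.isnan(topo_p) else "",
            statistic=topo_se if i == 0 else np.nan,
            p_value=topo_p if i == 0 else np.nan,
        )
        rows.append(row)

    table = pd.DataFrame(rows)
    return CohortSummary(
        table=table,
        n_total=len(records),
        n_positive=len(pos),
        n_negative=len(neg),
        mc_seed=mc_seed,
    )
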