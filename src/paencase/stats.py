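"""Contingency construction and the cohort's statistical battery.

Lesions whose arteries are all "in the margin" or "disconnected" carry no
mass-effect information and are excluded (but counted).  A lesion with two
analyzable relationships contributes one count to each category, so the
contingency table counts *records*, not lesions; the table keeps the
bookkeeping (``analyzed + excluded = total`` lesions per group,
``records = analyzed + dual_count``) explicit.

Inference follows the standard diagnostic-study toolkit: exact tests on the
category x diagnosis table (full enumeration over tables with fixed margins,
two-sided by the probability-mass rule), Wald odds ratios on the log scale
against the penetration baseline, Wilcoxon rank-sum on encasement degrees,
a pooled two-sample t for ages, and Cohen's kappa with conventional
agreement bands (poor < 0.20, fair 0.21-0.40, moderate 0.41-0.60,
substantial 0.61-0.80, very good > 0.80).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import ANALYZABLE_RELATIONS, Cohort, RelationType

__all__ = [
    "RelationTable",
    "OddsRatioResult",
    "KappaResult",
    "AgreementGrade",
    "GroupSummary",
    "build_relation_table",
    "fisher_exact",
    "odds_ratio_vs_baseline",
    "wilcoxon_rank_sum",
    "two_sample_t",
    "cohens_kappa",
    "group_summary",
]

GROUPS = ("benign", "malignant")


@dataclass(frozen=True)
class RelationTable:
    """Relationship-category x diagnosis counts with exclusion bookkeeping."""

    counts: dict  # (RelationType, group) -> int
    excluded: dict  # group -> lesions with only in_margin/disconnection
    dual_count: dict  # group -> lesions contributing two categories
    total: dict  # group -> total lesions seen

    def count(self, relation: RelationType, group: str) -> int:
        return self.counts.get((relation, group), 0)

    def analyzed(self, group: str) -> int:
        return self.total[group] - self.excluded[group]

    def records(self, group: str) -> int:
        return sum(self.count(r, group) for r in ANALYZABLE_RELATIONS)

    def matrix(self) -> np.ndarray:
        """2x3 array: rows (benign, malignant) x columns (enc, disp, pen)."""
        return np.array(
            [[self.count(r, g) for r in ANALYZABLE_RELATIONS] for g in GROUPS],
            dtype=int,
        )


def build_relation_table(c: Cohort) -> RelationTable:
    """Tally final relationships per diagnosis group with the exclusion rule.

    Every analyzable final relation contributes one count; a dual-relationship
    lesion therefore appears in two cells.
    """
    counts: dict = {}
    excluded = {g: 0 for g in GROUPS}
    dual = {g: 0 for g in GROUPS}
    total = {g: 0 for g in GROUPS}
    for rec in c.records:
        g = rec.truth
        total[g] += 1
        analyzable = [r for r in rec.final_relations if r in ANALYZABLE_RELATIONS]
        if not analyzable:
            excluded[g] += 1
            continue
        if len(analyzable) == 2:
            dual[g] += 1
        for r in analyzable:
            counts[(r, g)] = counts.get((r, g), 0) + 1
    return RelationTable(counts=counts, excluded=excluded, dual_count=dual, total=total)


# ---------------------------------------------------------------------------
# exact tests


def _log_table_prob(table: np.ndarray, lfact_rows: float, lfact_cols: float,
                    lfact_n: float) -> float:
    return (lfact_rows + lfact_cols - lfact_n
            - sum(math.lgamma(v + 1) for v in table.flat))


def fisher_exact(table) -> float:
    """Two-sided exact P for an r x c count table by full enumeration.

    Sums, over all tables with the observed margins, the (multivariate)
    hypergeometric probabilities not exceeding that of the observed table
    (probability-mass rule, with a 1e-7 relative tolerance against rounding).
    """
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        tf = np.asarray(table, dtype=float)
        if np.any(tf < 0) or np.any(tf != np.round(tf)):
            raise ValueError("counts must be nonnegative integers")
        t = tf.astype(int)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return 1.0
    lfact_rows = sum(math.lgamma(r + 1) for r in rows)
    lfact_cols = sum(math.lgamma(c + 1) for c in cols)
    lfact_n = math.lgamma(n + 1)
    logp_obs = _log_table_prob(t, lfact_rows, lfact_cols, lfact_n)
    threshold = logp_obs + 1e-7

    nr, nc = t.shape
    total = 0.0
    work = np.zeros_like(t)

    def recurse(i: int, j: int, row_rem: np.ndarray, col_rem: np.ndarray) -> None:
        nonlocal total
        if i == nr - 1:
            # last row fixed by column margins
            if np.any(col_rem < 0):
                return
            work[i, :] = col_rem
            logp = _log_table_prob(work, lfact_rows, lfact_cols, lfact_n)
            if logp <= threshold:
                total += math.exp(logp)
            return
        if j == nc - 1:
            v = row_rem[i]
            if v < 0 or v > col_rem[j]:
                return
            work[i, j] = v
            new_col = col_rem.copy()
            new_col[j] -= v
            recurse(i + 1, 0, row_rem, new_col)
            return
        hi = min(row_rem[i], col_rem[j])
        for v in range(hi + 1):
            work[i, j] = v
            new_row = row_rem.copy()
            new_row[i] -= v
            new_col = col_rem.copy()
            new_col[j] -= v
            recurse(i, j + 1, new_row, new_col)

    recurse(0, 0, rows.copy(), cols.copy())
    return min(1.0, total)


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with Wald 95% CI and Fisher exact P, vs. a baseline category."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    baseline: str = "penetration"
    exposure: str = ""


def odds_ratio_vs_baseline(a: int, b: int, c: int, d: int, *,
                           baseline: str = "penetration", exposure: str = "",
                           continuity: bool = False) -> OddsRatioResult:
    """Odds ratio for (cases-exposed a, controls-exposed b, cases-baseline c,
    controls-baseline d) with a Wald log-scale 95% CI.

    ``continuity=True`` applies the Haldane-Anscombe +0.5 correction to every
    cell (needed when a zero cell makes the OR or its CI undefined).
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"count {name} must be a nonnegative integer, got {v}")
    p = fisher_exact([[a, b], [c, d]])
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if continuity else (a, b, c, d)
    if bb * cc == 0 or aa * dd == 0:
        raise ValueError(
            "odds ratio undefined for zero cell; enable the continuity correction"
        )
    odds_ratio = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(odds_ratio)
    return OddsRatioResult(
        odds_ratio=odds_ratio,
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        p=p,
        baseline=baseline,
        exposure=exposure,
    )


# ---------------------------------------------------------------------------
# two-sample comparisons


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation P for small untied samples (n_x + n_y <= 20); otherwise
    the normal approximation with tie and continuity corrections.  Returns
    (U statistic of the first sample, P).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(x, y, *, welch: bool = False) -> tuple[float, float]:
    """Two-independent-sample t test (pooled variance by default).

    Returns (t, two-sided P).  Raises on degenerate zero pooled variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x, ddof=1) + np.var(y, ddof=1) == 0.0:
        raise ValueError("zero pooled variance; t statistic undefined")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# inter-observer agreement


class AgreementGrade(enum.Enum):
    POOR = "poor"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    VERY_GOOD = "very_good"


def grade_kappa(kappa: float) -> AgreementGrade:
    if kappa <= 0.20:
        return AgreementGrade.POOR
    if kappa <= 0.40:
        return AgreementGrade.FAIR
    if kappa <= 0.60:
        return AgreementGrade.MODERATE
    if kappa <= 0.80:
        return AgreementGrade.SUBSTANTIAL
    return AgreementGrade.VERY_GOOD


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    grade: str
    p_o: float  # observed agreement
    p_e: float  # chance-expected agreement


def cohens_kappa(confusion) -> KappaResult:
    """Cohen's kappa for a k x k observer-1 x observer-2 count table.

    Chance-corrected agreement kappa = (p_o - p_e)/(1 - p_e) with the
    large-sample (Fleiss-Cohen-Everitt) standard error and a Wald 95% CI,
    graded on the conventional bands.
    """
    t = np.asarray(confusion, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("confusion table must be square")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    n = t.sum()
    if n <= 0:
        raise ValueError("confusion table is empty")
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if p_e >= 1.0:
        raise ValueError("degenerate single-category marginals (p_e = 1)")
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss, Cohen & Everitt large-sample variance
    k = t.shape[0]
    term1 = sum(p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
                for i in range(k))
    term2 = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(k) for j in range(k) if i != j
    )
    term3 = (kappa - p_e * (1.0 - kappa)) ** 2
    var = (term1 + term2 - term3) / (n * (1.0 - p_e) ** 2)
    se = math.sqrt(max(0.0, var))
    lo = max(-1.0, kappa - 1.96 * se)
    hi = min(1.0, kappa + 1.96 * se)
    return KappaResult(kappa=float(kappa), ci_low=lo, ci_high=hi,
                       grade=grade_kappa(kappa).value, p_o=p_o, p_e=p_e)


# ---------------------------------------------------------------------------
# descriptive summaries


@dataclass(frozen=True)
class GroupSummary:
    """Per-diagnosis-group descriptives (sample sd, n-1 denominator)."""

    n: int
    degree_mean: float | None
    degree_sd: float | None
    degree_n: int
    size_mean: float | None
    size_sd: float | None
    age_mean: float | None
    age_sd: float | None
    location_counts: dict
    sex_counts: dict


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd


def group_summary(c: Cohort) -> dict:
    """Mean +/- sd of encasement degrees, sizes and ages, plus location/sex
    tallies, per truth group.  Empty groups yield None with a warning."""
    out: dict = {}
    for g in GROUPS:
        recs = c.subset(g)
        if not recs:
            warnings.warn(f"group {g!r} is empty; no summary", stacklevel=2)
            out[g] = None
            continue
        degrees = [r.degree for r in recs if r.degree is not None]
        dm, ds = _mean_sd(degrees)
        sm, ss = _mean_sd([r.size for r in recs])
        am, asd = _mean_sd([r.age for r in recs if r.age is not None])
        loc: dict = {}
        sex: dict = {}
        for r in recs:
            loc[r.location] = loc.get(r.location, 0) + 1
            if r.sex:
                sex[r.sex] = sex.get(r.sex, 0) + 1
        out[g] = GroupSummary(
            n=len(recs), degree_mean=dm, degree_sd=ds, degree_n=len(degrees),
            size_mean=sm, size_sd=ss, age_mean=am, age_sd=asd,
            location_counts=loc, sex_counts=sex,
        )
    return out
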