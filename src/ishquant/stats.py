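"""Statistical battery for genotype-grouped intensity scores.

Implements the inference chain used for ISH densitometry data: group
summaries with coefficient of variation, pooled and Welch two-sample
t-tests, one-way and Welch ANOVA, Levene's test, Tukey HSD and
Games-Howell post-hoc comparisons, contingency chi-squared with Yates
continuity correction, a square-root transform decision based on a
normality check, Cohen's d, and noncentral-t power / sample-size
computation for the two-sample design.

Every location test accepts either raw data arrays or (n, mean, sd)
summary statistics. Summary mode matters in practice: published work
often prints only group means, CVs and sample sizes, and all of the t,
F, q and power computations here are exact functions of those summaries.

Distribution functions (central/noncentral t, F, chi-squared,
studentized range) come from scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "PowerSpec",
    "summarize",
    "as_summary",
    "pooled_t_from_summaries",
    "welch_t",
    "one_way_anova",
    "welch_anova",
    "levene",
    "tukey_hsd",
    "games_howell",
    "chi_square",
    "sqrt_transform_if_needed",
    "cohen_d",
    "power_two_sample_t",
    "required_n_two_sample_t",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, sample sd of one group; cv = sd/mean (dispersion measure)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")

    @property
    def cv(self) -> float | None:
        """Coefficient of variation s/mean; undefined (None) at mean 0."""
        if self.mean == 0:
            return None
        return self.sd / self.mean

    @property
    def variance(self) -> float:
        return self.sd**2


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    family: str
    groups: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class PowerSpec:
    """A two-sample t-test power configuration."""

    d: float
    alpha: float
    n_per_group: int
    power: float
    tails: int = 2


def summarize(values: Iterable[float], label: str = "") -> GroupSummary:
    """Group summary with sample sd (n-1 denominator)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    return GroupSummary(label, int(x.size), float(x.mean()), float(x.std(ddof=1)))


def as_summary(group: "GroupSummary | Iterable[float]", label: str = "") -> GroupSummary:
    """Coerce raw data to a GroupSummary; pass summaries through."""
    if isinstance(group, GroupSummary):
        return group
    return summarize(group, label)


def _coerce_groups(
    groups: Sequence["GroupSummary | Iterable[float]"],
) -> list[GroupSummary]:
    return [as_summary(g, label=f"group{i}") for i, g in enumerate(groups)]


# ---------------------------------------------------------------------------
# Two-sample t-tests

def pooled_t_from_summaries(
    a: "GroupSummary | Iterable[float]",
    b: "GroupSummary | Iterable[float]",
    alpha: float = 0.05,
) -> TestResult:
    """Classic pooled-variance two-sample t-test from summary statistics."""
    a, b = as_summary(a, "a"), as_summary(b, "b")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.variance + (b.n - 1) * b.variance) / df
    diff = a.mean - b.mean
    if sp2 == 0:
        if diff == 0:
            return TestResult("t", 0.0, df, 1.0, "t-test", (a.label, b.label))
        return TestResult(
            "t", math.inf, df, 0.0, "t-test", (a.label, b.label),
            note="zero pooled variance with unequal means",
        )
    t = diff / math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult("t", t, df, p, "t-test", (a.label, b.label))


def welch_t(
    a: "GroupSummary | Iterable[float]",
    b: "GroupSummary | Iterable[float]",
    alpha: float = 0.05,
) -> TestResult:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    a, b = as_summary(a, "a"), as_summary(b, "b")
    va, vb = a.variance / a.n, b.variance / b.n
    diff = a.mean - b.mean
    if va + vb == 0:
        if diff == 0:
            return TestResult(
                "t", 0.0, a.n + b.n - 2, 1.0, "welch-t", (a.label, b.label)
            )
        return TestResult(
            "t", math.inf, a.n + b.n - 2, 0.0, "welch-t", (a.label, b.label),
            note="zero variances with unequal means",
        )
    # With one zero-variance group the Satterthwaite df collapses to
    # n_other - 1, the correct limiting value.
    df = (va + vb) ** 2 / (
        (va**2 / (a.n - 1) if va else 0.0) + (vb**2 / (b.n - 1) if vb else 0.0)
    )
    t = diff / math.sqrt(va + vb)
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult("t", t, df, p, "welch-t", (a.label, b.label))


# ---------------------------------------------------------------------------
# One-way ANOVA (standard and Welch)

def one_way_anova(
    groups: Sequence["GroupSummary | Iterable[float]"],
) -> TestResult:
    """Standard one-way fixed-effects ANOVA, F with df (k-1, N-k)."""
    gs = _coerce_groups(groups)
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    k = len(gs)
    N = sum(g.n for g in gs)
    grand = sum(g.n * g.mean for g in gs) / N
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in gs)
    ssw = sum((g.n - 1) * g.variance for g in gs)
    df1, df2 = k - 1, N - k
    if ssw == 0:
        if ssb == 0:
            return TestResult("F", 0.0, (df1, df2), 1.0, "anova")
        return TestResult(
            "F", math.inf, (df1, df2), 0.0, "anova",
            note="zero within-group variance",
        )
    F = (ssb / df1) / (ssw / df2)
    return TestResult("F", F, (df1, df2), float(sps.f.sf(F, df1, df2)), "anova")


def welch_anova(
    groups: Sequence["GroupSummary | Iterable[float]"],
) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    Variance-weighted group means, numerator df k-1 and the fractional
    Satterthwaite-type denominator df; reduces to the square of Welch's t
    for two groups.
    """
    gs = _coerce_groups(groups)
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.variance == 0 for g in gs):
        raise ValueError(
            "Welch ANOVA undefined for a zero-variance group (infinite weight)"
        )
    k = len(gs)
    w = np.array([g.n / g.variance for g in gs])
    m = np.array([g.mean for g in gs])
    n = np.array([g.n for g in gs])
    W = w.sum()
    mw = (w * m).sum() / W
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = (((1 - w / W) ** 2) / (n - 1)).sum()
    F = num / (1 + 2 * (k - 2) / (k**2 - 1) * lam)
    df2 = (k**2 - 1) / (3 * lam)
    return TestResult(
        "F", float(F), (k - 1, float(df2)),
        float(sps.f.sf(F, k - 1, df2)), "welch-anova",
    )


def levene(
    groups: Sequence[Iterable[float]], center: str = "mean"
) -> TestResult:
    """Levene's test for equality of variances (raw data required).

    ``center='mean'`` is the classic Levene statistic (the SPSS default);
    ``center='median'`` gives the Brown-Forsythe variant. All-constant
    groups return W = 0, p = 1 by convention.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    k, N = len(arrays), sum(a.size for a in arrays)
    centre = np.mean if center == "mean" else np.median
    if all(np.abs(a - centre(a)).max() == 0 for a in arrays):
        return TestResult("W", 0.0, (k - 1, N - k), 1.0, "levene")
    W, p = sps.levene(*arrays, center=center)
    return TestResult("W", float(W), (k - 1, N - k), float(p), "levene")


# ---------------------------------------------------------------------------
# Post-hoc pairwise comparisons

def tukey_hsd(
    groups: Sequence["GroupSummary | Iterable[float]"], alpha: float = 0.05
) -> list[TestResult]:
    """Tukey's HSD: studentized-range test with pooled variance, df N-k."""
    gs = _coerce_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("need >= 2 groups")
    N = sum(g.n for g in gs)
    df = N - k
    sp2 = sum((g.n - 1) * g.variance for g in gs) / df
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[i], gs[j]
            se = math.sqrt(sp2 / 2 * (1 / a.n + 1 / b.n))
            q = abs(a.mean - b.mean) / se if se > 0 else (
                0.0 if a.mean == b.mean else math.inf
            )
            p = float(sps.studentized_range.sf(q, k, df)) if math.isfinite(q) else 0.0
            out.append(
                TestResult("q", q, df, p, "tukey", (a.label, b.label))
            )
    return out


def games_howell(
    groups: Sequence["GroupSummary | Iterable[float]"], alpha: float = 0.05
) -> list[TestResult]:
    """Games-Howell post-hoc test for unequal variances.

    Each pair uses its own unpooled standard error and Welch df; the
    p-value comes from the studentized range distribution with the full
    number of groups k.
    """
    gs = _coerce_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("need >= 2 groups")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[i], gs[j]
            va, vb = a.variance / a.n, b.variance / b.n
            se2 = va + vb
            if se2 == 0:
                q, df = (0.0 if a.mean == b.mean else math.inf), a.n + b.n - 2
                p = 1.0 if q == 0 else 0.0
            else:
                df = se2**2 / (
                    (va**2 / (a.n - 1) if va else 0.0)
                    + (vb**2 / (b.n - 1) if vb else 0.0)
                )
                q = abs(a.mean - b.mean) / math.sqrt(se2 / 2)
                p = float(sps.studentized_range.sf(q, k, df))
            out.append(
                TestResult("q", q, df, p, "games-howell", (a.label, b.label))
            )
    return out


# ---------------------------------------------------------------------------
# Contingency tables

def chi_square(
    table: Sequence[Sequence[int]], continuity_correction: bool = True
) -> TestResult:
    """Pearson chi-squared test of independence on a contingency table.

    Yates continuity correction is applied iff the table is 2x2 and the
    flag is set (the default), matching common statistical-package
    behaviour for small tables.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total: expected counts undefined")
    correct = continuity_correction and obs.shape == (2, 2)
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=correct)
    return TestResult(
        "chi2", float(chi2), int(df), float(p), "chi-squared",
        note="Yates continuity correction" if correct else "",
    )


# ---------------------------------------------------------------------------
# Transform decision, effect size, power

def sqrt_transform_if_needed(
    values: Iterable[float], alpha: float = 0.05
) -> tuple[np.ndarray, bool, str]:
    """Square-root transform scores when they look non-normal.

    Normality is assessed with Shapiro-Wilk at ``alpha`` (an automatable
    stand-in for visual Q-Q inspection). The transform is applied only if
    the sample is non-normal AND contains no negative value; negative
    scores are legitimate and block the transform with a logged rationale.
    Returns (values, transformed?, rationale).
    """
    x = np.asarray(list(values), dtype=float)
    _, p = sps.shapiro(x)
    if p >= alpha:
        return x, False, f"Shapiro-Wilk p={p:.3g} >= {alpha}: no transform"
    if x.min() < 0:
        return (
            x,
            False,
            f"Shapiro-Wilk p={p:.3g} < {alpha} but negative scores present: "
            "sqrt transform not applicable",
        )
    return (
        np.sqrt(x),
        True,
        f"Shapiro-Wilk p={p:.3g} < {alpha}: sqrt transform applied",
    )


def cohen_d(
    a: "GroupSummary | Iterable[float]", b: "GroupSummary | Iterable[float]"
) -> float:
    """Cohen's d: |mean difference| / pooled sd ((n-1)-weighted)."""
    a, b = as_summary(a, "a"), as_summary(b, "b")
    sp2 = ((a.n - 1) * a.variance + (b.n - 1) * b.variance) / (a.n + b.n - 2)
    if sp2 == 0:
        if a.mean == b.mean:
            return 0.0
        raise ValueError("effect size undefined: zero pooled sd, unequal means")
    return abs(a.mean - b.mean) / math.sqrt(sp2)


def power_two_sample_t(
    d: float, n_per_group: int, alpha: float = 0.05, tails: int = 2
) -> float:
    """Post-hoc power of the two-sample t-test via the noncentral t.

    Noncentrality delta = d*sqrt(n/2), df = 2n-2; the rejection region is
    the usual two-sided (or one-sided) t critical region. This is the
    standard post-hoc power computation for two equal groups.
    """
    if d < 0:
        raise ValueError("effect size d must be >= 0")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2)
    if tails == 2:
        tc = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))
    tc = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tc, df, nc))


def required_n_two_sample_t(
    d: float,
    target_power: float,
    alpha: float = 0.05,
    tails: int = 2,
    n_max: int = 1_000_000,
) -> int:
    """Smallest per-group n reaching the target power.

    Incremental search from n=2 guarantees exact minimality (power is
    monotone in n); cheap at the sample sizes relevant here.
    """
    if not 0 < target_power < 1:
        raise ValueError("target power must be in (0, 1)")
    if d <= 0:
        raise ValueError("no finite sample size for d = 0")
    n = 2
    while power_two_sample_t(d, n, alpha, tails) < target_power:
        n += 1
        if n > n_max:
            raise RuntimeError("sample-size search exceeded n_max")
    return n
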