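"""Statistical layer: t tests, KS tests, mixed models and correlations.

The default two-sample t test uses pooled variance (Student's t); Welch
is available via the ``variant`` flag.  Group differences in delta-SUV
tables are tested with a linear mixed model with a per-subject random
intercept, which absorbs the repeated slice/hemisphere measurements of
each subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from deltapet.errors import FitError, InputError

__all__ = [
    "GroupSummary",
    "TestResult",
    "CorrelationFit",
    "summarize",
    "pooled_t_from_summary",
    "t_from_raw",
    "ks_two_sample",
    "lmm_region_group_test",
    "correlate_region_behavior",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and standard error of the mean."""

    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError(f"need n >= 2, got {self.n}")
        if self.sem < 0:
            raise InputError("sem must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with its p-value."""

    name: str  # "t" | "D" | "F" | "r"
    value: float
    p_value: float
    df: float | tuple[float, float] | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        return {"statistic": self.name, "value": self.value,
                "p_value": self.p_value, "df": self.df, "note": self.note}


@dataclass(frozen=True)
class CorrelationFit:
    """Pearson correlation with the least-squares line for one region/group."""

    region: str
    group: str
    r: float
    slope: float
    intercept: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"region": self.region, "group": self.group, "r": self.r,
                "slope": self.slope, "intercept": self.intercept,
                "p_value": self.p_value, "n": self.n}


def summarize(x) -> GroupSummary:
    """(n, mean, SEM) of a sample, with SEM using the n-1 denominator SD."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InputError("need at least 2 observations")
    return GroupSummary(n=int(x.size), mean=float(x.mean()),
                        sem=float(x.std(ddof=1) / np.sqrt(x.size)))


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Pooled-variance two-sample Student t from printed summaries.

    SDs are recovered as SEM * sqrt(n); the pooled variance is
    ((n_a-1) SD_a^2 + (n_b-1) SD_b^2) / (n_a + n_b - 2) and
    df = n_a + n_b - 2, with a two-sided p-value.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    if se == 0:
        t = 0.0 if a.mean == b.mean else np.inf * np.sign(a.mean - b.mean)
    else:
        t = (a.mean - b.mean) / se
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return TestResult(name="t", value=float(t), p_value=float(p), df=float(df))


def t_from_raw(x, y, variant: str = "pooled") -> TestResult:
    """Two-sample t test on raw samples (``pooled`` or ``welch``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("need at least 2 observations per group")
    if variant not in ("pooled", "welch"):
        raise InputError(f"unknown variant {variant!r}")
    res = scipy.stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TestResult(name="t", value=float(res.statistic),
                      p_value=float(res.pvalue), df=float(res.df))


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test with the asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("empty sample")
    res = scipy.stats.ks_2samp(x, y, method="asymp")
    return TestResult(name="D", value=float(res.statistic), p_value=float(res.pvalue))


def _oneway_fallback(per_subject: pd.DataFrame, note: str) -> TestResult:
    groups = [g["delta_suv"].to_numpy() for _, g in per_subject.groupby("group")]
    df = len(per_subject) - 2
    if all(np.ptp(g) == 0 for g in groups):  # degenerate: no variance anywhere
        equal = groups[0][0] == groups[1][0]
        return TestResult(name="F", value=0.0 if equal else float("inf"),
                          p_value=1.0 if equal else 0.0, df=(1.0, float(df)),
                          note=note)
    res = scipy.stats.ttest_ind(*groups, equal_var=True)
    return TestResult(name="F", value=float(res.statistic**2),
                      p_value=float(res.pvalue), df=(1.0, float(df)), note=note)


def lmm_region_group_test(table: pd.DataFrame, region: str) -> TestResult:
    """Group effect on delta-SUV with a per-subject random intercept.

    Fits ``delta_suv ~ group`` with a random intercept per subject on the
    region's rows (REML) and returns the Wald F statistic for the group
    contrast with denominator df = n_subjects - 2, the residual df at the
    between-subject level where the effect varies.  Degenerate designs
    (one row per subject, or a singular fit) fall back to an ordinary
    one-way test on subject means, with a logged warning.
    """
    sub = table[table["region"] == region]
    if sub.empty:
        raise InputError(f"no rows for region {region!r}")
    groups = sub.groupby("group")["subject_id"].nunique()
    if len(groups) != 2:
        raise InputError(f"need exactly 2 groups, got {list(groups.index)}")
    if (groups < 2).any():
        raise InputError("need >= 2 subjects per group")
    n_subjects = sub["subject_id"].nunique()
    per_subject = (sub.groupby(["subject_id", "group"], as_index=False)["delta_suv"]
                   .mean())
    if (sub.groupby("subject_id").size() == 1).all():
        log.warning("region %s: one row per subject; using ordinary one-way test", region)
        return _oneway_fallback(per_subject, note="one-way fallback (no replication)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("delta_suv ~ C(group)", sub, groups=sub["subject_id"])
            fit = model.fit(reml=True)
        coef_name = [n for n in fit.params.index
                     if n.startswith("C(group)")][0]
        se = fit.bse[coef_name]
        if not np.isfinite(se) or se == 0:
            raise FitError("singular mixed-model fit")
        f_stat = float((fit.params[coef_name] / se) ** 2)
    except (Exception,) as exc:  # statsmodels raises LinAlgError/ValueError on singular fits
        log.warning("region %s: mixed model failed (%s); one-way fallback", region, exc)
        return _oneway_fallback(per_subject, note=f"one-way fallback ({exc})")
    df_den = float(n_subjects - 2)
    p = float(scipy.stats.f.sf(f_stat, 1, df_den))
    return TestResult(name="F", value=f_stat, p_value=p, df=(1.0, df_den))


def correlate_region_behavior(features: pd.Series, behavior: pd.Series,
                              region: str = "", group: str = "") -> CorrelationFit:
    """Pearson r and least-squares line of behavior against region delta-SUV.

    ``features`` and ``behavior`` are per-subject series aligned on
    subject id; features are the independent variable.
    """
    joined = pd.concat({"x": features, "y": behavior}, axis=1).dropna()
    if len(joined) < 3:
        raise InputError("need at least 3 subjects with both measurements")
    x = joined["x"].to_numpy(dtype=float)
    y = joined["y"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return CorrelationFit(region=region, group=group, r=float("nan"),
                              slope=float("nan"), intercept=float("nan"),
                              p_value=float("nan"), n=len(joined))
    res = scipy.stats.linregress(x, y)
    return CorrelationFit(region=region, group=group, r=float(res.rvalue),
                          slope=float(res.slope), intercept=float(res.intercept),
                          p_value=float(res.pvalue), n=len(joined))
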