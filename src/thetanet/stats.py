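"""Behavioral summaries, z-score phenotyping, and the group-statistics battery.

Phenotyping follows a normative-cutoff rule: each patient's mean correct-
trial reaction time and response accuracy are z-scored against the control
group's mean and sample standard deviation, and a patient is classified as
performance-impaired when either score falls beyond 1.5 control SDs in the
impaired direction (slower RT, z_rt > 1.5, or lower ACC, z_acc < -1.5).
The rule is directional by default — unusually fast or accurate
performance is not an impairment — with a two-sided variant behind a flag.

The test battery mirrors a conventional SPSS workflow: Student t-tests,
one-way ANOVA with Fisher's LSD post-hoc (pairwise t on the pooled
within-group mean square, no multiplicity correction — that is what LSD
means), Pearson chi-square for dichotomous variables, Pearson correlation,
and Shapiro-Wilk / Levene assumption checks reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BehaviorSummary",
    "PhenotypeResult",
    "StatTestResult",
    "summarize_behavior",
    "phenotype",
    "t_test",
    "one_way_anova_lsd",
    "chi_square_2xk",
    "pearson_corr",
    "assumption_checks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BehaviorSummary:
    subject: str
    mean_rt_correct: float        # ms; NaN when no correct trials
    acc: float
    n_trials: int
    n_correct: int

    @property
    def rt_defined(self) -> bool:
        return not math.isnan(self.mean_rt_correct)


@dataclass(frozen=True)
class PhenotypeResult:
    subject: str
    z_rt: float
    z_acc: float
    phenotype: str                # "normal" | "impaired"
    is_control: bool
    reference: dict[str, float]   # control mean/sd for rt and acc


@dataclass(frozen=True)
class StatTestResult:
    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    groups: tuple[str, ...] = ()
    direction: str = ""
    extra: dict = field(default_factory=dict)


def summarize_behavior(subject: str, trials: pd.DataFrame) -> BehaviorSummary:
    """Mean correct-trial RT and accuracy for one subject's trial table."""
    if trials.empty:
        raise ValueError("trial table is empty")
    if not {"correct", "rt_ms"} <= set(trials.columns):
        raise ValueError("trial table needs 'correct' and 'rt_ms' columns")
    correct = trials["correct"].astype(bool)
    n_correct = int(correct.sum())
    if n_correct:
        mean_rt = float(trials.loc[correct, "rt_ms"].mean())
    else:
        mean_rt = float("nan")
        logger.warning("subject %s has no correct trials; RT undefined", subject)
    return BehaviorSummary(
        subject=subject,
        mean_rt_correct=mean_rt,
        acc=n_correct / len(trials),
        n_trials=len(trials),
        n_correct=n_correct,
    )


def phenotype(
    summaries: list[BehaviorSummary],
    control_ids: set[str] | list[str],
    threshold: float = 1.5,
    two_sided: bool = False,
) -> list[PhenotypeResult]:
    """Classify every subject against the control group's norms.

    z-scores use the control sample mean and sample SD (n-1 denominator).
    Controls are scored too but retain their control status (they are
    never re-labelled impaired). Requires >= 3 controls with non-zero
    spread on both measures.
    """
    control_ids = set(control_ids)
    controls = [s for s in summaries if s.subject in control_ids]
    if len(controls) < 3:
        raise ValueError("phenotyping needs at least 3 control subjects")
    rt_ref = np.array([s.mean_rt_correct for s in controls], dtype=float)
    acc_ref = np.array([s.acc for s in controls], dtype=float)
    if np.isnan(rt_ref).any():
        raise ValueError("control subjects with undefined RT cannot anchor norms")
    ref = {
        "rt_mean": float(rt_ref.mean()),
        "rt_sd": float(rt_ref.std(ddof=1)),
        "acc_mean": float(acc_ref.mean()),
        "acc_sd": float(acc_ref.std(ddof=1)),
    }
    if ref["rt_sd"] == 0 or ref["acc_sd"] == 0:
        raise ValueError("control group has zero variance; z-scores undefined")

    results = []
    for s in summaries:
        z_rt = (s.mean_rt_correct - ref["rt_mean"]) / ref["rt_sd"]
        z_acc = (s.acc - ref["acc_mean"]) / ref["acc_sd"]
        if two_sided:
            flagged = abs(z_rt) > threshold or abs(z_acc) > threshold
        else:
            flagged = z_rt > threshold or z_acc < -threshold
        results.append(
            PhenotypeResult(
                subject=s.subject,
                z_rt=float(z_rt),
                z_acc=float(z_acc),
                phenotype="impaired" if flagged else "normal",
                is_control=s.subject in control_ids,
                reference=ref,
            )
        )
    return results


# --------------------------------------------------------------------------
# Test battery
# --------------------------------------------------------------------------

def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[np.isfinite(arr)]


def t_test(x, y, variant: str = "student", labels=("x", "y")) -> StatTestResult:
    """Two-sided two-sample t-test (Student pooled-variance by default)."""
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if np.var(np.concatenate([x - x.mean(), y - y.mean()])) == 0:
        raise ValueError("zero pooled variance; t-test undefined")
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return StatTestResult(
        test=f"t ({variant})",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        groups=tuple(labels),
        direction=f"{labels[0]} {'>' if x.mean() > y.mean() else '<'} {labels[1]}",
    )


def one_way_anova_lsd(
    groups: dict[str, np.ndarray] | list,
    labels: list[str] | None = None,
) -> tuple[StatTestResult, list[StatTestResult]]:
    """One-way ANOVA with Fisher's LSD pairwise post-hoc tests.

    Returns the omnibus F test and all pairwise LSD results. LSD t uses
    the pooled within-group mean square MS_w with its N - k degrees of
    freedom; no multiplicity correction is applied.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        samples = [_clean(groups[g]) for g in labels]
    else:
        samples = [_clean(g) for g in groups]
        labels = labels or [f"g{i + 1}" for i in range(len(samples))]
    if len(samples) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")

    all_values = np.concatenate(samples)
    grand = all_values.mean()
    n_total = len(all_values)
    k = len(samples)
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_between, df_within = k - 1, n_total - k
    if ss_within == 0:
        raise ValueError("all groups internally constant; F undefined")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f_stat = ms_between / ms_within
    p = float(sps.f.sf(f_stat, df_between, df_within))
    omnibus = StatTestResult(
        test="one-way ANOVA",
        statistic=float(f_stat),
        df=(float(df_between), float(df_within)),
        p_value=p,
        groups=tuple(labels),
        extra={
            "ss_between": float(ss_between),
            "ss_within": float(ss_within),
            "ss_total": float(((all_values - grand) ** 2).sum()),
            "ms_within": float(ms_within),
        },
    )
    pairwise = []
    for a in range(k):
        for b in range(a + 1, k):
            xa, xb = samples[a], samples[b]
            se = math.sqrt(ms_within * (1 / len(xa) + 1 / len(xb)))
            t = (xa.mean() - xb.mean()) / se
            p_pair = float(2 * sps.t.sf(abs(t), df_within))
            pairwise.append(
                StatTestResult(
                    test="LSD t",
                    statistic=float(t),
                    df=float(df_within),
                    p_value=p_pair,
                    groups=(labels[a], labels[b]),
                    direction=(
                        f"{labels[a]} {'>' if xa.mean() > xb.mean() else '<'} "
                        f"{labels[b]}"
                    ),
                )
            )
    return omnibus, pairwise


def chi_square_2xk(table) -> StatTestResult:
    """Pearson chi-square on a 2 x k contingency table, no continuity
    correction; df = k - 1."""
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero-sum row or column; chi-square undefined")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return StatTestResult(
        test="chi-square", statistic=float(chi2), df=float(dof), p_value=float(p)
    )


def pearson_corr(x, y) -> StatTestResult:
    """Pearson r with two-sided p from the t transform (n - 2 df)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    res = sps.pearsonr(x, y)
    return StatTestResult(
        test="pearson r",
        statistic=float(res.statistic),
        df=float(len(x) - 2),
        p_value=float(res.pvalue),
        direction="negative" if res.statistic < 0 else "positive",
    )


def assumption_checks(samples: dict[str, np.ndarray] | list) -> dict:
    """Shapiro-Wilk normality per sample plus Levene homogeneity across.

    Advisory only: results are reported (and sub-0.05 p-values logged as
    warnings) but tests are never switched automatically.
    """
    if isinstance(samples, dict):
        named = {k: _clean(v) for k, v in samples.items()}
    else:
        named = {f"g{i + 1}": _clean(s) for i, s in enumerate(samples)}
    if any(len(s) < 3 for s in named.values()):
        raise ValueError("assumption checks need n >= 3 per sample")
    report: dict = {"shapiro": {}, "levene": None}
    for name, s in named.items():
        w, p = sps.shapiro(s)
        report["shapiro"][name] = {"statistic": float(w), "p_value": float(p)}
        if p < 0.05:
            logger.warning("Shapiro-Wilk flags non-normality for %s (p=%.3g)", name, p)
    if len(named) >= 2:
        w, p = sps.levene(*named.values(), center="mean")
        report["levene"] = {"statistic": float(w), "p_value": float(p)}
        if p < 0.05:
            logger.warning("Levene flags heteroscedasticity (p=%.3g)", p)
    return report
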