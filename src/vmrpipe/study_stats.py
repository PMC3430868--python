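"""Stage and treatment statistics on VMR threshold tables.

Mirrors the study's workflow: per-rat averaging of the 2–4 baseline sessions
in each estrous stage, one-way (or repeated-measures) ANOVA across stages
with Tukey HSD pairwise comparisons, Dunnett many-to-one comparisons (or a
paired t-test) for treatment arms, and paired percent-change effect
estimates reported as mean ± SEM.

The unit of analysis is always the rat: sessions are averaged within rat
first, and percent changes are computed per rat before aggregation.
Censored thresholds (criterion never met before the 1 ml cap) are excluded
from means by default; ``censored_policy='cap'`` substitutes the cap volume
as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: columns of a study table (one row per session)
TABLE_COLUMNS = [
    "rat_id",
    "group",
    "stage",
    "arm",
    "session_index",
    "volume_ml",
    "censored",
]


@dataclass
class ComparisonResult:
    """Omnibus test with optional post hoc pairwise table."""

    test: str
    statistic: float
    df: tuple
    p_value: float
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05


@dataclass
class EffectEstimate:
    """Paired percent-change effect, aggregated across rats."""

    mean_percent: float
    sem_percent: float
    n: int
    label: str = ""
    per_rat: pd.Series = field(default_factory=lambda: pd.Series(dtype=float), repr=False)


def make_study_table(metas, thresholds) -> pd.DataFrame:
    """Assemble a study table from session metadata and detected thresholds."""
    rows = [
        {
            "rat_id": m.rat_id,
            "group": m.group,
            "stage": m.stage,
            "arm": m.arm,
            "session_index": m.session_date_index,
            "volume_ml": thr.volume,
            "censored": thr.censored,
        }
        for m, thr in zip(metas, thresholds, strict=True)
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _apply_censoring(table: pd.DataFrame, policy: str) -> pd.DataFrame:
    if policy == "exclude":
        return table[~table["censored"].astype(bool)]
    if policy == "cap":
        return table  # censored rows already carry the cap volume
    raise ValueError(f"unknown censored_policy {policy!r}")


def summarize_by_stage(
    table: pd.DataFrame, censored_policy: str = "exclude"
) -> pd.DataFrame:
    """Per-(rat, stage) mean of untreated baseline thresholds.

    Returns one row per rat and stage with ``mean_ml``, ``n_sessions`` and
    ``n_censored``.  Only untreated (baseline) sessions enter the means.
    """
    base = table[table["arm"] == "baseline"]
    kept = _apply_censoring(base, censored_policy)
    grouped = kept.groupby(["rat_id", "group", "stage"], sort=False)
    out = grouped["volume_ml"].agg(mean_ml="mean", n_sessions="size").reset_index()
    cens = (
        base.groupby(["rat_id", "group", "stage"], sort=False)["censored"]
        .sum()
        .rename("n_censored")
        .reset_index()
    )
    return out.merge(cens, on=["rat_id", "group", "stage"], how="left")


def stage_anova(
    summary: pd.DataFrame,
    group: str,
    design: str = "oneway",
    alpha: float = 0.05,
    posthoc: bool = True,
) -> ComparisonResult:
    """ANOVA across estrous stages within one lesion group, with Tukey HSD.

    ``design='oneway'`` treats per-rat stage means as independent samples
    (the study's averaging unit); ``design='rm'`` fits a repeated-measures
    ANOVA with rat as subject, which accounts for the shared rat effect.
    ``posthoc=False`` skips the Tukey table (e.g. in calibration loops that
    only consume the omnibus p-value).
    """
    sub = summary[summary["group"] == group]
    stages = sub["stage"].unique()
    if len(stages) < 2 or sub.groupby("stage")["rat_id"].nunique().min() < 2:
        raise ValueError("need >= 2 stages with >= 2 rats each")
    if design == "oneway":
        samples = [sub.loc[sub["stage"] == s, "mean_ml"].to_numpy() for s in stages]
        f, p = scipy.stats.f_oneway(*samples)
        df = (len(stages) - 1, sum(len(s) for s in samples) - len(stages))
        test = "one-way ANOVA"
    elif design == "rm":
        # one-way repeated measures: stage within rat, closed form
        wide = sub.pivot_table(index="rat_id", columns="stage", values="mean_ml")
        if wide.isna().any().any():
            raise ValueError("repeated-measures design requires complete stages")
        y = wide.to_numpy(dtype=float)
        n, k = y.shape
        grand = y.mean()
        ss_stage = n * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_subject = k * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_error = ((y - grand) ** 2).sum() - ss_stage - ss_subject
        df = (k - 1, (k - 1) * (n - 1))
        f = (ss_stage / df[0]) / (ss_error / df[1])
        p = scipy.stats.f.sf(f, *df)
        test = "repeated-measures ANOVA"
    else:
        raise ValueError(f"unknown design {design!r}")
    table = None
    if posthoc:
        tuk = pairwise_tukeyhsd(sub["mean_ml"].to_numpy(), sub["stage"].to_numpy(), alpha)
        table = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    return ComparisonResult(
        test=test, statistic=float(f), df=df, p_value=float(p), posthoc=table, alpha=alpha
    )


def treatment_comparison(
    arms: pd.DataFrame,
    control: str = "baseline",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare treatment arms against a control arm, per rat.

    ``arms`` is a wide table: one row per rat, one column per arm (per-rat
    threshold means).  With exactly one non-control arm a paired t-test is
    used; with two or more, a one-way ANOVA across arms followed by Dunnett
    many-to-one comparisons against the control.
    """
    if control not in arms.columns:
        raise ValueError(f"control arm {control!r} missing from table")
    others = [c for c in arms.columns if c != control]
    if not others:
        raise ValueError("need at least one non-control arm")
    arms = arms.dropna()
    ctrl = arms[control].to_numpy(dtype=float)
    if len(others) == 1:
        diffs = arms[others[0]].to_numpy(dtype=float) - ctrl
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0  # identical arms: no evidence of a difference
        else:
            t, p = scipy.stats.ttest_rel(arms[others[0]].to_numpy(dtype=float), ctrl)
        return ComparisonResult(
            test="paired t-test",
            statistic=float(t),
            df=(len(arms) - 1,),
            p_value=float(p),
            alpha=alpha,
        )
    samples = [arms[c].to_numpy(dtype=float) for c in others]
    f, p = scipy.stats.f_oneway(ctrl, *samples)
    dun = scipy.stats.dunnett(*samples, control=ctrl)
    posthoc = pd.DataFrame(
        {
            "comparison": [f"{c} vs {control}" for c in others],
            "estimate": [float(np.mean(s) - np.mean(ctrl)) for s in samples],
            "statistic": np.atleast_1d(dun.statistic).astype(float),
            "p": np.atleast_1d(dun.pvalue).astype(float),
        }
    )
    df = (len(others), (len(others) + 1) * (len(arms) - 1))
    return ComparisonResult(
        test="ANOVA + Dunnett",
        statistic=float(f),
        df=df,
        p_value=float(p),
        posthoc=posthoc,
        alpha=alpha,
    )


def percent_change(pre: pd.Series, post: pd.Series, label: str = "") -> EffectEstimate:
    """Paired per-rat percent change ``100 * (post - pre) / pre``.

    ``pre`` and ``post`` are indexed by rat id.  The estimate is the mean of
    the per-rat changes; dispersion is the SEM (SD/sqrt(n)) across rats.
    """
    pre, post = pre.align(post, join="inner")
    if pre.empty:
        raise ValueError("no rats are present in both pre and post")
    if (pre <= 0).any():
        raise ValueError("pre-treatment thresholds must be positive")
    change = 100.0 * (post - pre) / pre
    n = int(change.size)
    sem = float(change.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return EffectEstimate(
        mean_percent=float(change.mean()),
        sem_percent=sem,
        n=n,
        label=label,
        per_rat=change,
    )


def arm_means(
    table: pd.DataFrame, stage: str = "P", censored_policy: str = "exclude"
) -> pd.DataFrame:
    """Wide per-rat table of mean thresholds per arm within one stage."""
    sub = table[table["stage"] == stage]
    kept = _apply_censoring(sub, censored_policy)
    return kept.pivot_table(index="rat_id", columns="arm", values="volume_ml", aggfunc="mean")
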