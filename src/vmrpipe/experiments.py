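"""End-to-end parameter-recovery experiments.

Each function simulates a cohort under an effects configuration, runs the
full detection pipeline (trace -> rectified bin integrals -> baseline ->
200% criterion -> volume mapping), and reports a percent effect on the scale
the study reports it.  They are used both by the test suite and by
``scripts/acceptance.py`` to check that the pipeline recovers the configured
effect structure from raw synthetic telemetry.

Recovery cohorts are simulated at a reduced sampling rate (200 Hz) and a
shortened rest epoch (90 s, of which the final 60 s form the baseline
window): detected thresholds depend only on ramp timing and the activity
ratio, not on the acquisition rate, so these sizes trade nothing but disk
and CPU.
"""

from __future__ import annotations

import pandas as pd

from .detection import DetectionCriterion, compute_threshold
from .session_io import DistentionProtocol
from .study_stats import arm_means, make_study_table, percent_change, summarize_by_stage
from .synthetic import Cohort, CohortDesign, EffectsConfig, simulate_cohort

RECOVERY_SAMPLING_RATE = 200.0  # Hz
RECOVERY_PROTOCOL = DistentionProtocol(inflation_onset=90.0, pre_period=90.0)
BASELINE_WINDOW_S = 60.0


def detect_cohort(
    cohort: Cohort,
    criterion: DetectionCriterion | None = None,
    baseline_window_s: float = BASELINE_WINDOW_S,
) -> pd.DataFrame:
    """Run threshold detection on every session; returns a study table."""
    thresholds = [
        compute_threshold(s, criterion=criterion, baseline_window_s=baseline_window_s)
        for s in cohort.sessions
    ]
    return make_study_table([s.meta for s in cohort.sessions], thresholds)


def _recovery_cohort(design: CohortDesign, cfg: EffectsConfig) -> pd.DataFrame:
    cohort = simulate_cohort(
        design, cfg, protocol=RECOVERY_PROTOCOL, sampling_rate=RECOVERY_SAMPLING_RATE
    )
    return detect_cohort(cohort)


def endo_sham_proestrus_gap(
    cfg: EffectsConfig, n_per_group: int, seed: int, sessions_per_stage: int = 4
) -> float:
    """Percent by which mean detected ENDO proestrus threshold undercuts shamENDO.

    Simulates proestrus baseline sessions for both groups, averages detected
    thresholds per rat and then per group, and returns
    ``100 * (mean_sham - mean_endo) / mean_sham``.
    """
    design = CohortDesign(
        n_endo=n_per_group,
        n_sham=n_per_group,
        sessions_per_stage=sessions_per_stage,
        stages=("P",),
        seed=seed,
    )
    table = _recovery_cohort(design, cfg)
    summary = summarize_by_stage(table)
    means = summary.groupby("group")["mean_ml"].mean()
    return float(100.0 * (means["shamENDO"] - means["ENDO"]) / means["shamENDO"])


def stage_gaps(
    cfg: EffectsConfig, n_rats: int, seed: int, sessions_per_stage: int = 4
) -> dict[str, float]:
    """Percent reduction of the ENDO proestrus mean relative to each other stage.

    Returns ``{stage: 100 * (mean_stage - mean_P) / mean_stage}`` for
    DI, DII and E, computed from detected thresholds of a full-cycle ENDO
    cohort.
    """
    design = CohortDesign(
        n_endo=n_rats, sessions_per_stage=sessions_per_stage, seed=seed
    )
    table = _recovery_cohort(design, cfg)
    summary = summarize_by_stage(table)
    means = summary.groupby("stage")["mean_ml"].mean()
    return {
        s: float(100.0 * (means[s] - means["P"]) / means[s]) for s in ("DI", "DII", "E")
    }


def treatment_percent_change(
    cfg: EffectsConfig,
    n_rats: int,
    seed: int,
    treatment: str,
    dose: float,
    route: str,
    sessions_per_stage: int = 4,
):
    """Mean percent change of detected proestrus thresholds after treatment.

    Each simulated ENDO rat contributes paired untreated proestrus baselines
    and one treated proestrus session; the per-rat percent change is
    ``100 * (treated - baseline mean) / baseline mean``, aggregated as
    mean ± SEM across rats.
    """
    design = CohortDesign(
        n_endo=n_rats,
        sessions_per_stage=sessions_per_stage,
        stages=("P",),
        treatment_arms=((treatment, dose, route),),
        seed=seed,
    )
    table = _recovery_cohort(design, cfg)
    wide = arm_means(table, stage="P")
    arm = [c for c in wide.columns if c != "baseline"][0]
    return percent_change(wide["baseline"], wide[arm], label=f"{arm} vs baseline")
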