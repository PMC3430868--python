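"""Synthetic telemetry cohorts with the study's effect structure.

Each simulated rat carries a latent VMR volume threshold whose mean is set
by lesion group (ENDO vs shamENDO), estrous stage, and treatment arm, with
multiplicative lognormal between-rat and between-session noise.  A session's
EMG is burst-like baseline noise (Gaussian carrier modulated by a smoothed
Poisson shot envelope) whose power jumps by ``vmr_gain`` the instant the
commanded pump ramp crosses the session's latent threshold, reproducing the
characteristic trace morphology: quiet rest epoch, ramp, abrupt sustained
visceromotor response.

Effect sizes default to the published percentages of the vaginal-distention
telemetry study this package models: ENDO proestrus 42.4% below shamENDO,
proestrus 15–19% below the other ENDO stages, indomethacin 10 mg/kg raising
ENDO thresholds by 81% (i.p.) / 93.5% (s.c.), and a ~28% i.p.-injection
(vehicle) effect.  Absolute threshold scale and noise magnitudes are free
parameters; see ``data/default_effects.yaml``.

Random streams are split hierarchically (cohort -> rat -> session) from a
single seed, so enlarging a cohort never perturbs existing rats' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal
import yaml

from .session_io import (
    STAGES,
    DistentionProtocol,
    EMGTrace,
    RecordingSession,
    SessionMeta,
)

DEFAULT_SAMPLING_RATE = 500.0  # Hz; acquisition rate of the simulated channel
POST_RAMP_TAIL_S = 10.0


@dataclass
class NoiseParams:
    """Baseline abdominal-EMG noise model.

    The signal is ``amplitude_uv * envelope * N(0, 1)`` where the envelope
    is ``floor`` plus a shot-noise process: Poisson impulses at
    ``burst_rate_hz``, each of height ``burst_height``, decaying with time
    constant ``burst_tau_s``.  The envelope gives the non-Gaussian,
    burst-like texture of resting muscle activity while keeping the mean
    rectified bin integral in closed form (see ``expected_bin_integral``).
    """

    amplitude_uv: float = 25.0
    burst_rate_hz: float = 60.0
    burst_height: float = 0.4
    burst_tau_s: float = 0.03
    floor: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be non-negative")
        if self.burst_rate_hz < 0 or self.burst_height < 0:
            raise ValueError("burst parameters must be non-negative")
        if self.burst_tau_s <= 0:
            raise ValueError("burst time constant must be positive")

    def envelope_mean(self, sampling_rate: float) -> float:
        """Stationary mean of the envelope at the given sampling rate."""
        dt = 1.0 / sampling_rate
        a = math.exp(-dt / self.burst_tau_s)
        return self.floor + self.burst_height * self.burst_rate_hz * dt / (1.0 - a)

    def expected_bin_integral(self, sampling_rate: float, bin_width: float) -> float:
        """Closed-form mean of a rectified bin integral (µV·s) at rest."""
        return (
            self.amplitude_uv
            * self.envelope_mean(sampling_rate)
            * math.sqrt(2.0 / math.pi)
            * bin_width
        )


@dataclass
class EffectsConfig:
    """Latent-threshold effect structure and noise magnitudes.

    Percentages are on the scale the study reports them: a
    ``endo_proestrus_reduction`` of 42.4 means the ENDO proestrus mean is
    42.4% below the shamENDO mean; ``stage_reductions[s]`` is the percent by
    which ENDO proestrus lies below ENDO stage ``s``; ``drug_effects`` maps
    ``(group, treatment, dose, route)`` to a percent threshold increase over
    the untreated mean for that group/stage.
    """

    reference_threshold: float = 0.5  # ml, shamENDO mean (free parameter)
    max_volume: float = 1.0  # ml, ramp cap — latent thresholds clip here
    endo_proestrus_reduction: float = 42.4
    stage_reductions: dict = field(
        default_factory=lambda: {"DI": 15.0, "DII": 17.0, "E": 19.0}
    )
    sham_stage_effect: float = 0.0
    drug_effects: dict = field(
        default_factory=lambda: {
            ("ENDO", "indomethacin", 10.0, "ip"): 81.0,
            ("ENDO", "indomethacin", 10.0, "sc"): 93.5,
            ("ENDO", "indomethacin", 5.0, "ip"): 40.0,  # direction-only in study
            ("ENDO", "vehicle", 0.0, "ip"): 28.0,
            ("ENDO", "vehicle", 0.0, "sc"): 0.0,
        }
    )
    rat_cv: float = 0.15
    session_cv: float = 0.08
    vmr_gain: float = 6.0
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if not (0 < self.reference_threshold < self.max_volume):
            raise ValueError("reference_threshold must lie inside (0, max_volume)")
        if self.rat_cv < 0 or self.session_cv < 0:
            raise ValueError("CVs must be non-negative")
        if self.vmr_gain <= 1:
            raise ValueError("vmr_gain must exceed 1 (and the detection ratio)")
        for pct in [self.endo_proestrus_reduction, *self.stage_reductions.values()]:
            if not (pct < 100):
                raise ValueError("percent reductions must be < 100")

    def stage_mean(self, group: str, stage: str) -> float:
        """Untreated latent-threshold mean (ml) for a group/stage cell."""
        if group == "shamENDO":
            return self.reference_threshold * (1.0 - self.sham_stage_effect / 100.0)
        p_mean = self.reference_threshold * (1.0 - self.endo_proestrus_reduction / 100.0)
        if stage == "P":
            return p_mean
        return p_mean / (1.0 - self.stage_reductions[stage] / 100.0)

    def drug_multiplier(self, meta: SessionMeta) -> float:
        if meta.treatment == "none":
            return 1.0
        key = (meta.group, meta.treatment, float(meta.dose_mg_kg), meta.route)
        return 1.0 + self.drug_effects.get(key, 0.0) / 100.0


@dataclass
class CohortDesign:
    """Study design: cohort sizes, baselines per stage, treatment arms.

    ``treatment_arms`` lists ``(treatment, dose, route)`` triples; each arm
    adds one treated proestrus session per rat, mirroring the study's single
    post-injection assessment 40–60 min after dosing.
    """

    n_endo: int = 0
    n_sham: int = 0
    sessions_per_stage: int = 2
    stages: tuple = STAGES
    treatment_arms: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_endo < 0 or self.n_sham < 0 or self.n_endo + self.n_sham < 1:
            raise ValueError("cohort needs at least one rat")
        if not (2 <= self.sessions_per_stage <= 4):
            raise ValueError("baselines per stage must be 2–4")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")


def _lognormal_multiplier(cv: float, rng: np.random.Generator) -> float:
    """Mean-one lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def latent_threshold(
    meta: SessionMeta,
    cfg: EffectsConfig,
    rat_effect: float = 1.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw the session's latent VMR threshold (ml).

    The cell mean (group x stage x treatment) is multiplied by the rat's
    persistent random effect and an independent session-level lognormal
    multiplier, then clipped to ``(0, max_volume]``.
    """
    mean = cfg.stage_mean(meta.group, meta.stage) * cfg.drug_multiplier(meta)
    if mean <= 0:
        raise ValueError("configuration implies a non-positive mean threshold")
    session_noise = 1.0
    if rng is not None:
        session_noise = _lognormal_multiplier(cfg.session_cv, rng)
    return min(mean * rat_effect * session_noise, cfg.max_volume)


def simulate_baseline_emg(
    duration: float,
    noise: NoiseParams,
    rng: np.random.Generator,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> EMGTrace:
    """Resting abdominal-EMG noise: Gaussian carrier x burst envelope.

    The envelope's shot process is initialised at its stationary mean so the
    rectified bin integrals are stationary in distribution from the first
    bin.  Amplitude 0 yields an all-zero trace.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * sampling_rate))
    if noise.amplitude_uv == 0:
        return EMGTrace(np.zeros(n), sampling_rate=sampling_rate)
    dt = 1.0 / sampling_rate
    a = math.exp(-dt / noise.burst_tau_s)
    impulses = rng.poisson(noise.burst_rate_hz * dt, size=n).astype(float)
    shot_mean = noise.burst_height * noise.burst_rate_hz * dt / (1.0 - a)
    shot, _ = scipy.signal.lfilter(
        [noise.burst_height], [1.0, -a], impulses, zi=[a * shot_mean]
    )
    envelope = noise.floor + shot
    carrier = rng.standard_normal(n)
    return EMGTrace(noise.amplitude_uv * envelope * carrier, sampling_rate=sampling_rate)


def simulate_session(
    meta: SessionMeta,
    protocol: DistentionProtocol,
    cfg: EffectsConfig,
    rng: np.random.Generator,
    rat_effect: float = 1.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    bin_width: float = 0.1,
) -> tuple[RecordingSession, float]:
    """Simulate one session; returns ``(session, latent_threshold_ml)``.

    Baseline EMG is multiplied by ``cfg.vmr_gain`` from the instant the
    commanded pump volume crosses the session's latent threshold, ramping up
    linearly over one bin width.  A latent threshold at the cap leaves the
    trace unchanged for the whole ramp (a censored session).
    """
    latent = latent_threshold(meta, cfg, rat_effect=rat_effect, rng=rng)
    duration = protocol.inflation_onset + protocol.ramp_duration + POST_RAMP_TAIL_S
    trace = simulate_baseline_emg(duration, cfg.noise, rng, sampling_rate=sampling_rate)
    if latent < cfg.max_volume:
        crossing = protocol.inflation_onset + latent / (protocol.infusion_rate / 60.0)
        t = trace.times
        # full gain reached within half a bin so the first whole bin after the
        # crossing already carries the response; keeps pipeline recovery
        # within one bin-volume of the latent threshold
        gain = np.interp(
            t, [crossing, crossing + 0.5 * bin_width], [1.0, cfg.vmr_gain]
        )
        trace = replace(trace, samples=trace.samples * gain)
    session = RecordingSession(meta=meta, emg=trace, protocol=protocol)
    return session, latent


@dataclass
class Cohort:
    """Simulated cohort: sessions plus the generator's ground truth."""

    sessions: list
    truth: pd.DataFrame  # rat_id, group, stage, arm, session_index, latent_ml


def _rat_rng(seed: int, rat_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rat_index,)))


def _session_rng(seed: int, rat_index: int, session_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(rat_index, session_index))
    )


def _iter_rats(design: CohortDesign):
    for i in range(design.n_endo):
        yield i, f"ENDO{i + 1:03d}", "ENDO"
    for j in range(design.n_sham):
        yield design.n_endo + j, f"SHAM{j + 1:03d}", "shamENDO"


def simulate_cohort(
    design: CohortDesign,
    cfg: EffectsConfig,
    protocol: DistentionProtocol | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    trace: bool = True,
) -> Cohort:
    """Simulate a cohort of recording sessions.

    Each rat receives ``sessions_per_stage`` untreated sessions per stage,
    visited in cycling estrous order (DI, DII, P, E, DI, ...), plus one
    treated proestrus session per treatment arm.  The per-rat random effect
    is drawn once from the rat's stream; per-session noise and EMG come from
    per-session streams, so cohorts are reproducible and extensible without
    perturbing existing rats.

    With ``trace=False`` only latent thresholds are generated (no EMG); the
    ``sessions`` list is then empty.  This is the fast path for
    statistical-calibration studies that operate on thresholds directly.
    """
    protocol = protocol or DistentionProtocol()
    sessions: list[RecordingSession] = []
    rows = []
    cycle = [s for s in ("DI", "DII", "P", "E") if s in design.stages]
    for rat_index, rat_id, group in _iter_rats(design):
        rat_effect = _lognormal_multiplier(cfg.rat_cv, _rat_rng(design.seed, rat_index))
        metas = []
        for rep in range(design.sessions_per_stage):
            for stage in cycle:
                metas.append(SessionMeta(rat_id=rat_id, group=group, stage=stage))
        for treatment, dose, route in design.treatment_arms:
            metas.append(
                SessionMeta(
                    rat_id=rat_id,
                    group=group,
                    stage="P",
                    treatment=treatment,
                    dose_mg_kg=dose,
                    route=route,
                    minutes_post_injection=50.0,
                )
            )
        for s_index, meta in enumerate(metas):
            meta.session_date_index = s_index
            rng = _session_rng(design.seed, rat_index, s_index)
            if trace:
                session, latent = simulate_session(
                    meta,
                    protocol,
                    cfg,
                    rng,
                    rat_effect=rat_effect,
                    sampling_rate=sampling_rate,
                )
                sessions.append(session)
            else:
                latent = latent_threshold(meta, cfg, rat_effect=rat_effect, rng=rng)
            rows.append(
                {
                    "rat_id": rat_id,
                    "group": group,
                    "stage": meta.stage,
                    "arm": meta.arm,
                    "session_index": s_index,
                    "latent_ml": latent,
                }
            )
    return Cohort(sessions=sessions, truth=pd.DataFrame(rows))


def load_effects(path) -> EffectsConfig:
    """Build an :class:`EffectsConfig` from a YAML file (see packaged default)."""
    text = path.read_text() if hasattr(path, "read_text") else open(path).read()
    doc = yaml.safe_load(text)
    noise = NoiseParams(**doc.pop("noise", {}))
    drug = {}
    for rec in doc.pop("drug_effects", []):
        key = (rec["group"], rec["treatment"], float(rec.get("dose", 0.0)), rec["route"])
        drug[key] = float(rec["percent"])
    kwargs = dict(doc)
    if drug:
        kwargs["drug_effects"] = drug
    return EffectsConfig(noise=noise, **kwargs)


def default_effects() -> EffectsConfig:
    """The packaged configuration: published percentages, default free parameters."""
    from importlib.resources import files

    return load_effects(files("vmrpipe.data") / "default_effects.yaml")
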