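"""Rectified-EMG bin integration, baseline estimation and volume alignment.

The activity measure throughout the package is the integral of the rectified
EMG in fixed-width bins (100 ms by default): each bin's value is the sum of
absolute sample amplitudes times the sample period, in µV·s.  The
pre-distention baseline level is a robust location estimate (median by
default) of those integrals over a window that ends at inflation onset, and
each bin is tagged with the commanded pump volume at its start time so that
threshold detection can be read out directly in ml.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .session_io import DistentionProtocol, EMGTrace, SessionValidationError

DEFAULT_BIN_WIDTH = 0.1  # s


class BaselineError(ValueError):
    """Baseline window invalid or baseline degenerate (e.g. silent trace)."""


@dataclass
class BinnedActivity:
    """Per-bin rectified-EMG integrals, optionally aligned with pump volume."""

    bin_width: float
    start_times: np.ndarray  # s, bin start on the session clock
    integrals: np.ndarray  # µV·s
    volumes: np.ndarray | None = None  # ml at bin start, set by align_volume

    def __post_init__(self) -> None:
        self.start_times = np.asarray(self.start_times, dtype=float)
        self.integrals = np.asarray(self.integrals, dtype=float)
        if self.start_times.shape != self.integrals.shape:
            raise ValueError("start_times and integrals must align")
        if np.any(self.integrals < 0):
            raise ValueError("bin integrals must be non-negative")
        if self.volumes is not None:
            self.volumes = np.asarray(self.volumes, dtype=float)
            if self.volumes.shape != self.integrals.shape:
                raise ValueError("volumes must align with bins")
            if np.any(np.diff(self.volumes) < -1e-12):
                raise ValueError("volumes must be non-decreasing")

    @property
    def n_bins(self) -> int:
        return self.integrals.size


@dataclass
class BaselineActivity:
    """Pre-distention activity level (per-bin scale, µV·s)."""

    level: float
    window: tuple[float, float]
    estimator: str = "median"


def rectify(trace: EMGTrace) -> EMGTrace:
    """Sample-wise absolute value; idempotent."""
    return dataclasses.replace(trace, samples=np.abs(trace.samples))


def bin_integral(trace: EMGTrace, bin_width: float = DEFAULT_BIN_WIDTH) -> BinnedActivity:
    """Integrate the rectified trace in fixed bins (rectangular rule).

    Each bin covers ``bin_width`` seconds; its integral is the sum of
    rectified samples in the bin times the sample period.  A trailing
    partial bin is discarded, never extrapolated.
    """
    spb = int(round(bin_width * trace.sampling_rate))
    if spb < 1 or bin_width <= 0:
        raise ValueError("bin_width must cover at least one sample period")
    n_bins = trace.samples.size // spb
    if n_bins < 1:
        raise ValueError("trace shorter than one bin")
    x = np.abs(trace.samples[: n_bins * spb]).reshape(n_bins, spb)
    integrals = x.sum(axis=1) / trace.sampling_rate
    starts = trace.t0 + np.arange(n_bins) * spb / trace.sampling_rate
    return BinnedActivity(bin_width=bin_width, start_times=starts, integrals=integrals)


def estimate_baseline(
    binned: BinnedActivity,
    protocol: DistentionProtocol,
    window_s: float = 60.0,
    estimator: str = "median",
) -> BaselineActivity:
    """Baseline activity level over the final ``window_s`` of the rest epoch.

    The window is ``[inflation_onset - window_s, inflation_onset)``.  The
    median is the default estimator because single movement-artifact bins
    otherwise drag the referent of the 200% criterion upward.
    """
    if window_s <= 0:
        raise BaselineError("baseline window must have positive length")
    w0 = protocol.inflation_onset - window_s
    if w0 < binned.start_times[0] - 1e-9:
        raise BaselineError("baseline window extends before the trace start")
    mask = (binned.start_times >= w0) & (binned.start_times < protocol.inflation_onset)
    if not mask.any():
        raise BaselineError("no bins fall inside the baseline window")
    vals = binned.integrals[mask]
    if estimator == "median":
        level = float(np.median(vals))
    elif estimator == "mean":
        level = float(np.mean(vals))
    else:
        raise BaselineError(f"unknown estimator {estimator!r}")
    return BaselineActivity(
        level=level, window=(w0, protocol.inflation_onset), estimator=estimator
    )


def align_volume(binned: BinnedActivity, protocol: DistentionProtocol) -> BinnedActivity:
    """Tag each bin with the commanded pump volume (ml) at its start time."""
    t = binned.start_times
    if not (t[0] - 1e-9 <= protocol.inflation_onset <= t[-1] + binned.bin_width):
        raise ValueError("inflation onset lies outside the binned trace")
    volumes = np.where(
        t < protocol.inflation_onset,
        0.0,
        np.minimum(
            protocol.infusion_rate * (t - protocol.inflation_onset) / 60.0,
            protocol.max_volume,
        ),
    )
    return dataclasses.replace(binned, volumes=volumes)
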