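"""VMR volume-threshold detection.

The visceromotor response (VMR) threshold of a session is the distention
volume at which the binned rectified-EMG activity first reaches the
criterion multiple of the pre-distention baseline — 200% of baseline by
default — and stays there for a short sustained run.  Sessions in which the
criterion is never met before the ramp reaches the volume cap are
right-censored at the cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .emg import (
    BaselineActivity,
    BinnedActivity,
    BaselineError,
    align_volume,
    bin_integral,
    estimate_baseline,
    rectify,
)
from .session_io import DistentionProtocol, RecordingSession


@dataclass
class DetectionCriterion:
    """Activity criterion defining the VMR onset.

    ``ratio`` is the multiple of baseline the activity must reach (2.0 =
    200% of baseline).  ``sustain_bins`` consecutive qualifying bins are
    required, which rejects single-bin movement artifacts; 1 reproduces the
    literal first-crossing rule.
    """

    ratio: float = 2.0
    sustain_bins: int = 3

    def __post_init__(self) -> None:
        if not self.ratio > 1.0:
            raise ValueError("criterion ratio must exceed 1")
        if self.sustain_bins < 1:
            raise ValueError("sustain_bins must be >= 1")


@dataclass
class VMRThreshold:
    """Detected distention volume threshold for one session."""

    volume: float  # ml, in (0, max_volume]
    censored: bool
    onset_time: float | None  # s, start of the qualifying run; None if censored
    baseline_used: float  # µV·s, the baseline level the criterion referenced


def detect_vmr_onset(
    binned: BinnedActivity,
    baseline: BaselineActivity,
    criterion: DetectionCriterion,
    protocol: DistentionProtocol,
) -> int | None:
    """Index of the first post-onset bin opening a sustained criterion run.

    Scans bins whose start time is at or after inflation onset and returns
    the first index ``i`` such that ``sustain_bins`` consecutive integrals
    from ``i`` on are all >= ``ratio * baseline.level`` while the volume at
    ``i`` is still below the cap.  Returns ``None`` (censored) when no such
    run exists.
    """
    if baseline.level <= 0:
        raise BaselineError(
            "baseline level is zero — silent trace, criterion undefined"
        )
    if binned.volumes is None:
        binned = align_volume(binned, protocol)
    thr = criterion.ratio * baseline.level
    k = criterion.sustain_bins
    hit = (binned.integrals >= thr).astype(int)
    n = binned.n_bins
    if n < k:
        return None
    run = np.convolve(hit, np.ones(k, dtype=int), mode="valid") == k
    t = binned.start_times[: n - k + 1]
    vol = binned.volumes[: n - k + 1]
    ok = run & (t >= protocol.inflation_onset) & (vol < protocol.max_volume)
    idx = np.flatnonzero(ok)
    return int(idx[0]) if idx.size else None


def threshold_from_onset(
    onset: int | None,
    binned: BinnedActivity,
    protocol: DistentionProtocol,
) -> VMRThreshold:
    """Map an onset bin index (or censoring) to a volume threshold.

    The reported volume is the commanded ramp volume at the start of the
    onset bin.  An onset exactly at inflation start maps to the smallest
    positive bin volume with a warning; censored sessions report the cap
    volume with the censored flag set.
    """
    if binned.volumes is None:
        binned = align_volume(binned, protocol)
    if onset is None:
        return VMRThreshold(
            volume=protocol.max_volume, censored=True, onset_time=None, baseline_used=0.0
        )
    t = float(binned.start_times[onset])
    if t < protocol.inflation_onset - 1e-9:
        raise ValueError(
            "onset precedes inflation — baseline contamination, not a VMR"
        )
    volume = float(binned.volumes[onset])
    if volume <= 0.0:
        bin_volume = protocol.infusion_rate * binned.bin_width / 60.0
        warnings.warn(
            "VMR onset at inflation start; reporting one bin-volume",
            stacklevel=2,
        )
        volume = bin_volume
    return VMRThreshold(volume=volume, censored=False, onset_time=t, baseline_used=0.0)


def compute_threshold(
    session: RecordingSession,
    criterion: DetectionCriterion | None = None,
    bin_width: float = 0.1,
    baseline_window_s: float = 60.0,
    baseline_estimator: str = "median",
) -> VMRThreshold:
    """Full per-session pipeline: rectify, bin, baseline, align, detect.

    Deterministic given the session and options.  Raises
    :class:`~vmrpipe.emg.BaselineError` for silent (all-zero) traces.
    """
    criterion = criterion or DetectionCriterion()
    binned = bin_integral(rectify(session.emg), bin_width=bin_width)
    baseline = estimate_baseline(
        binned,
        session.protocol,
        window_s=baseline_window_s,
        estimator=baseline_estimator,
    )
    binned = align_volume(binned, session.protocol)
    onset = detect_vmr_onset(binned, baseline, criterion, session.protocol)
    result = threshold_from_onset(onset, binned, session.protocol)
    result.baseline_used = baseline.level
    return result
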