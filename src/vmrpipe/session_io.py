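"""Telemetry session data model and plain-text round-trip I/O.

A recording session is one rat-day of telemetry: an abdominal-EMG trace, the
commanded distention-pump ramp, and the metadata the downstream statistics
stratify on (lesion group, estrous stage, treatment arm).  Sessions are
persisted as a CSV trace table (``time_s, emg_uV, volume_ml``, one row per
EMG sample, 6 significant digits) plus a YAML sidecar with the same basename
holding metadata and protocol fields.  Commanded pump volume is stored at the
EMG sampling grid so the pair is self-contained and inspectable with any
text tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

GROUPS = ("ENDO", "shamENDO")
STAGES = ("DI", "DII", "P", "E")
TREATMENTS = ("none", "vehicle", "indomethacin")
ROUTES = ("ip", "sc", "none")
DOSES = (0.0, 5.0, 10.0)

#: significant digits used when writing trace tables
WRITE_PRECISION = 6


class SessionValidationError(ValueError):
    """A session, trace or sidecar violates a structural invariant."""


@dataclass
class EMGTrace:
    """Raw (or rectified) EMG samples in microvolts on a uniform grid."""

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise SessionValidationError("EMG trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise SessionValidationError("EMG samples must be finite")
        if not (self.sampling_rate > 0):
            raise SessionValidationError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class DistentionProtocol:
    """Commanded linear balloon-inflation ramp.

    The pump inflates at ``infusion_rate`` ml/min from ``inflation_onset``
    (session clock, seconds) until ``max_volume`` ml, after a resting
    recording of ``pre_period`` seconds.
    """

    infusion_rate: float = 0.3
    max_volume: float = 1.0
    inflation_onset: float = 300.0
    pre_period: float = 300.0

    def __post_init__(self) -> None:
        if not (self.infusion_rate > 0):
            raise SessionValidationError("infusion_rate must be > 0")
        if not (self.max_volume > 0):
            raise SessionValidationError("max_volume must be > 0")
        if self.inflation_onset < self.pre_period:
            raise SessionValidationError(
                "inflation_onset must not precede the end of the pre-period"
            )

    @property
    def ramp_duration(self) -> float:
        """Seconds from inflation onset until the volume cap is reached."""
        return self.max_volume / (self.infusion_rate / 60.0)

    def volume_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Commanded balloon volume (ml) at session time ``t`` (s)."""
        elapsed = np.maximum(np.asarray(t, dtype=float) - self.inflation_onset, 0.0)
        return np.minimum(self.infusion_rate * elapsed / 60.0, self.max_volume)


@dataclass
class SessionMeta:
    """Stratification metadata for one session."""

    rat_id: str
    group: str
    stage: str
    treatment: str = "none"
    dose_mg_kg: float = 0.0
    route: str = "none"
    minutes_post_injection: float | None = None
    session_date_index: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SessionValidationError(
                f"group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.stage not in STAGES:
            raise SessionValidationError(
                f"stage must be one of {STAGES}, got {self.stage!r}"
            )
        if self.treatment not in TREATMENTS:
            raise SessionValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.route not in ROUTES:
            raise SessionValidationError(
                f"route must be one of {ROUTES}, got {self.route!r}"
            )
        if float(self.dose_mg_kg) not in DOSES:
            raise SessionValidationError(
                f"dose_mg_kg must be one of {DOSES}, got {self.dose_mg_kg!r}"
            )
        if self.treatment == "none":
            if self.dose_mg_kg != 0 or self.route != "none":
                raise SessionValidationError(
                    "untreated sessions must have dose 0 and route 'none'"
                )
        else:
            if self.route == "none":
                raise SessionValidationError("treated sessions need a route (ip/sc)")
            if self.treatment == "indomethacin" and self.dose_mg_kg == 0:
                raise SessionValidationError("indomethacin sessions need a dose")
        # the 5 mg/kg dose was only ever given intraperitoneally
        if self.dose_mg_kg == 5.0 and self.route != "ip":
            raise SessionValidationError("dose 5 mg/kg is i.p. only")
        if self.minutes_post_injection is not None and self.treatment == "none":
            raise SessionValidationError(
                "minutes_post_injection set on an untreated session"
            )

    @property
    def arm(self) -> str:
        """Compact treatment-arm label, e.g. ``baseline``, ``indo10_ip``."""
        if self.treatment == "none":
            return "baseline"
        if self.treatment == "vehicle":
            return f"vehicle_{self.route}"
        return f"indo{self.dose_mg_kg:g}_{self.route}"


@dataclass
class RecordingSession:
    """One rat-day: EMG trace + distention protocol + metadata."""

    meta: SessionMeta
    emg: EMGTrace
    protocol: DistentionProtocol
    pump: np.ndarray | None = None  # recorded volume (ml) at the EMG grid

    def __post_init__(self) -> None:
        if self.pump is not None:
            self.pump = np.asarray(self.pump, dtype=float)
            if self.pump.shape != self.emg.samples.shape:
                raise SessionValidationError("pump trace must match the EMG grid")
            if np.any(np.diff(self.pump) < 0):
                raise SessionValidationError("volume not non-decreasing")
            if np.any(self.pump > self.protocol.max_volume + 1e-9):
                raise SessionValidationError("pump volume exceeds max_volume")


def _trace_path(path: Path) -> Path:
    return path if path.suffix == ".csv" else path.with_suffix(".csv")


def _sidecar_path(path: Path) -> Path:
    return _trace_path(path).with_suffix(".yaml")


def write_session(session: RecordingSession, path: str | Path) -> tuple[Path, Path]:
    """Write ``session`` as a CSV trace table plus a YAML metadata sidecar.

    Returns the (trace, sidecar) paths.  Numeric columns are written with 6
    significant digits, which is the package's declared round-trip precision.
    """
    trace_path = _trace_path(Path(path))
    sidecar = _sidecar_path(trace_path)
    t = session.emg.times
    vol = session.pump
    if vol is None:
        vol = session.protocol.volume_at(t)
    table = np.column_stack([t, session.emg.samples, vol])
    fmt = f"%.{WRITE_PRECISION}g"
    np.savetxt(
        trace_path,
        table,
        fmt=fmt,
        delimiter=",",
        header="time_s,emg_uV,volume_ml",
        comments="",
    )
    meta, proto = session.meta, session.protocol
    doc = {
        "meta": {
            "rat_id": meta.rat_id,
            "group": meta.group,
            "stage": meta.stage,
            "treatment": meta.treatment,
            "dose_mg_kg": float(meta.dose_mg_kg),
            "route": meta.route,
            "minutes_post_injection": meta.minutes_post_injection,
            "session_date_index": int(meta.session_date_index),
            **meta.extras,
        },
        "protocol": {
            "infusion_rate": proto.infusion_rate,
            "max_volume": proto.max_volume,
            "inflation_onset": proto.inflation_onset,
            "pre_period": proto.pre_period,
        },
        "sampling_rate": session.emg.sampling_rate,
    }
    sidecar.write_text(yaml.safe_dump(doc, sort_keys=False))
    return trace_path, sidecar


_META_KEYS = {
    "rat_id",
    "group",
    "stage",
    "treatment",
    "dose_mg_kg",
    "route",
    "minutes_post_injection",
    "session_date_index",
}


def read_session(path: str | Path) -> RecordingSession:
    """Read a trace/sidecar pair back into a validated :class:`RecordingSession`.

    Unknown sidecar keys are preserved in ``meta.extras`` but otherwise
    ignored.  Raises :class:`SessionValidationError` on missing columns,
    a non-monotone time column, or a decreasing volume column.
    """
    trace_path = _trace_path(Path(path))
    sidecar = _sidecar_path(trace_path)
    df = pd.read_csv(trace_path)
    required = {"time_s", "emg_uV", "volume_ml"}
    missing = required - set(df.columns)
    if missing:
        raise SessionValidationError(f"trace table missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy()
    if t.size < 1:
        raise SessionValidationError("empty trace table")
    if np.any(np.diff(t) <= 0):
        raise SessionValidationError("time column not strictly increasing")
    vol = df["volume_ml"].to_numpy()
    if np.any(np.diff(vol) < 0):
        raise SessionValidationError("volume not non-decreasing")

    doc = yaml.safe_load(sidecar.read_text())
    meta_doc = dict(doc.get("meta", {}))
    extras = {k: meta_doc.pop(k) for k in list(meta_doc) if k not in _META_KEYS}
    meta = SessionMeta(**meta_doc, extras=extras)
    protocol = DistentionProtocol(**doc["protocol"])
    rate = float(doc["sampling_rate"])
    emg = EMGTrace(df["emg_uV"].to_numpy(), sampling_rate=rate, t0=float(t[0]))
    return RecordingSession(meta=meta, emg=emg, protocol=protocol, pump=vol)
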