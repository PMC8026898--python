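"""Raw force-plate recordings: container, CSV reader and writer.

A recording is one treadmill trial of one runner at one belt speed,
sampled uniformly (typically 1000 Hz) with three force channels:
vertical, anterior-posterior and medial-lateral.  Files are plain CSV
with header ``time,fz,fy,fx`` where ``fz`` is vertical, ``fy`` is
anterior-posterior and ``fx`` is medial-lateral, all in Newtons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

CHANNELS = ("vertical", "ant_post", "med_lat")

#: CSV column name for each channel.
_COLUMN_OF = {"vertical": "fz", "ant_post": "fy", "med_lat": "fx"}

#: Relative tolerance on sample spacing uniformity.
_UNIFORMITY_RTOL = 1e-6

#: Most negative plausible vertical force (sensor noise allowance), N.
VERTICAL_FLOOR = -50.0


@dataclass
class SubjectMeta:
    """Identity and condition labels attached to a recording."""

    subject_id: str
    sex: str  # "female" | "male"
    body_mass: float  # kg
    speed: float  # m/s

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise DataError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not self.body_mass > 0:
            raise DataError(f"body_mass must be positive, got {self.body_mass}")


@dataclass
class ForceRecording:
    """Uniformly sampled multi-channel force time series with metadata.

    ``forces`` has shape (n_samples, 3) with columns ordered as
    :data:`CHANNELS` (vertical, ant_post, med_lat), in Newtons.
    """

    meta: SubjectMeta
    sampling_rate: float  # Hz
    time: np.ndarray  # s, shape (n,)
    forces: np.ndarray  # N, shape (n, 3)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != 3:
            raise DataError("forces must have shape (n, 3)")
        if self.time.shape[0] != self.forces.shape[0]:
            raise DataError("time and forces lengths differ")
        if not self.sampling_rate > 0:
            raise DataError("sampling_rate must be positive")
        validate_time_grid(self.time, self.sampling_rate)
        if not np.all(np.isfinite(self.forces)):
            raise DataError("non-finite force values")
        if np.min(self.forces[:, 0]) < VERTICAL_FLOOR:
            raise DataError(
                f"vertical force below the {VERTICAL_FLOOR} N sensor floor"
            )

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.forces[:, CHANNELS.index(name)]

    @property
    def vertical(self) -> np.ndarray:
        return self.forces[:, 0]

    def with_forces(self, forces: np.ndarray, **provenance) -> "ForceRecording":
        out = replace(self, forces=np.asarray(forces, dtype=float))
        out.provenance = {**self.provenance, **provenance}
        return out


def validate_time_grid(time: np.ndarray, sampling_rate: float) -> None:
    """Check strictly increasing, uniform spacing of 1/sampling_rate."""
    if time.size < 2:
        return
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise DataError("time stamps must be strictly increasing")
    step = 1.0 / sampling_rate
    if np.max(np.abs(dt - step)) > _UNIFORMITY_RTOL * step:
        raise DataError("non-uniform sampling (spacing deviates from 1/rate)")


def infer_sampling_rate(time: np.ndarray) -> float:
    dt = np.diff(time)
    if dt.size == 0:
        raise DataError("recording needs at least 2 samples")
    if np.any(dt <= 0):
        raise DataError("time stamps must be strictly increasing")
    rate = 1.0 / float(np.median(dt))
    # acquisition rates are integer Hz; snap away float noise in the grid
    if abs(rate - round(rate)) < 1e-6 * rate:
        rate = float(round(rate))
    return rate


def read_recording(path: str | Path, meta: SubjectMeta) -> ForceRecording:
    """Read a ``time,fz,fy,fx`` CSV trial file into a :class:`ForceRecording`.

    The sampling rate is inferred from the median time step and the grid is
    then validated for uniformity; a duplicated or decreasing timestamp is a
    :class:`DataError`, a missing column a :class:`FormatError`.
    """
    path = Path(path)
    # round_trip parsing: written %.17g values must re-read bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["time", "fz", "fy", "fx"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    time = df["time"].to_numpy(dtype=float)
    forces = np.column_stack(
        [df[_COLUMN_OF[ch]].to_numpy(dtype=float) for ch in CHANNELS]
    )
    rate = infer_sampling_rate(time)
    return ForceRecording(meta=meta, sampling_rate=rate, time=time, forces=forces)


def write_recording(path: str | Path, recording: ForceRecording) -> None:
    """Write a recording as CSV, round-trippable bit-exactly.

    Floats are printed with %.17g so re-reading reproduces the binary
    values exactly.
    """
    df = pd.DataFrame(
        {
            "time": recording.time,
            "fz": recording.vertical,
            "fy": recording.channel("ant_post"),
            "fx": recording.channel("med_lat"),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
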