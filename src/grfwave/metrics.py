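"""Discrete loading variables of the stance-phase GRF.

The central statistic is the vertical average loading rate (VALR): the
mean slope of the vertical GRF between 20% and 80% of the time from foot
strike to the first (impact) peak,

    VALR = (F_80% - F_20%) / (t_80% - t_20%),   t_x = x * t_peak,

in body weights per second.  The 20/80 bounds are fractions of the
*time to the peak*, not of its force magnitude.  Also provided are the
classic peak variables: first (impact) and second (active) vertical
peaks, and the braking (posterior) and propulsion (anterior) extrema of
the anterior-posterior channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import NoImpactPeakError, ParameterError
from .preprocess import StanceCurve

#: Fraction of stance searched for the impact peak.
DEFAULT_SEARCH_WINDOW = 0.40

#: Minimum peak prominence, BW, to count a bump as an impact peak.
DEFAULT_PROMINENCE = 0.02


@dataclass(frozen=True)
class ValrResult:
    """VALR and its ingredients; forces in BW, times in s from strike."""

    first_peak_value: float
    first_peak_time: float
    f20: float
    f80: float
    t20: float
    t80: float
    valr: float


@dataclass(frozen=True)
class PeakPoint:
    value: float  # BW
    percent: float  # % of stance


@dataclass(frozen=True)
class PeakSet:
    """The four classic GRF peaks of one subject x condition."""

    first_peak: PeakPoint  # vertical, impact (A)
    second_peak: PeakPoint  # vertical, active (B)
    braking_peak: PeakPoint  # ant-post minimum (C)
    propulsion_peak: PeakPoint  # ant-post maximum (D)
    ap_degenerate: bool = False  # flat ant-post channel


def find_first_peak(
    force: np.ndarray,
    time: np.ndarray,
    search_window: float = DEFAULT_SEARCH_WINDOW,
    prominence: float = DEFAULT_PROMINENCE,
) -> tuple[float, float]:
    """Locate the impact peak: first prominent local maximum early in stance.

    Parameters
    ----------
    force, time : arrays
        Vertical stance force in BW on a time grid starting at strike
        (time[0] == 0).
    search_window : float
        Fraction of the stance duration searched from strike.
    prominence : float
        Minimum topographic prominence, BW.

    Returns
    -------
    (value, time) of the first qualifying local maximum.

    Raises
    ------
    NoImpactPeakError
        If no local maximum of sufficient prominence lies in the window
        (e.g. a monotone rise into a mid-stance global maximum).
    """
    force = np.asarray(force, dtype=float)
    time = np.asarray(time, dtype=float)
    if force.shape != time.shape or force.ndim != 1:
        raise ParameterError("force and time must be matching 1-d arrays")
    span = time[-1] - time[0]
    limit = time[0] + search_window * span
    peaks, _ = signal.find_peaks(force, prominence=prominence)
    peaks = peaks[time[peaks] <= limit]
    if peaks.size == 0:
        raise NoImpactPeakError(
            "no prominent local maximum within the impact-peak search window"
        )
    i = int(peaks[0])
    return float(force[i]), float(time[i] - time[0])


def compute_valr(
    force: np.ndarray, time: np.ndarray, first_peak_time: float
) -> ValrResult:
    """VALR between 20% and 80% of the time to the first peak.

    Force values at t20 and t80 are linearly interpolated on the sample
    grid, so query times that fall on samples are exact.
    """
    force = np.asarray(force, dtype=float)
    time = np.asarray(time, dtype=float) - np.asarray(time, dtype=float)[0]
    if not first_peak_time > 0:
        raise ParameterError("first_peak_time must be positive")
    t20 = 0.2 * first_peak_time
    t80 = 0.8 * first_peak_time
    if t80 > time[-1]:
        raise ParameterError("t80 lies beyond the end of the signal")
    f20, f80 = np.interp([t20, t80], time, force)
    peak_val = float(np.interp(first_peak_time, time, force))
    return ValrResult(
        first_peak_value=peak_val,
        first_peak_time=float(first_peak_time),
        f20=float(f20),
        f80=float(f80),
        t20=float(t20),
        t80=float(t80),
        valr=float((f80 - f20) / (t80 - t20)),
    )


def valr_for_stance(
    force: np.ndarray,
    time: np.ndarray,
    search_window: float = DEFAULT_SEARCH_WINDOW,
    prominence: float = DEFAULT_PROMINENCE,
) -> ValrResult:
    """Find the impact peak, then compute VALR, on one stance segment."""
    _, t_peak = find_first_peak(force, time, search_window, prominence)
    return compute_valr(force, time, t_peak)


def valr_from_curve(
    values: np.ndarray, contact_time: float, **kwargs
) -> ValrResult:
    """VALR of a 100-point stance-percent curve mapped to the time domain."""
    n = len(values)
    time = np.arange(n) * (contact_time / n)
    return valr_for_stance(np.asarray(values, float), time, **kwargs)


def find_peaks(
    vertical: StanceCurve,
    ant_post: StanceCurve,
    search_window: float = DEFAULT_SEARCH_WINDOW,
    prominence: float = DEFAULT_PROMINENCE,
) -> PeakSet:
    """The four peaks (A-D) from the averaged stance curves of one condition.

    Second vertical peak: global maximum over 30-80% stance.  Braking:
    minimum of ant-post over 0-50%; propulsion: maximum over 50-100%.
    The impact peak reuses :func:`find_first_peak` on the percent grid.
    A flat ant-post channel yields zero peaks flagged ``ap_degenerate``.
    """
    v = vertical.values
    ap = ant_post.values
    t = vertical.stance_percent * vertical.contact_time / len(v)

    val, t_pk = find_first_peak(v, t, search_window, prominence)
    first = PeakPoint(val, float(t_pk / vertical.contact_time * len(v)))

    i2 = 30 + int(np.argmax(v[30:81]))
    second = PeakPoint(float(v[i2]), float(i2))

    ib = int(np.argmin(ap[:50]))
    ip = 50 + int(np.argmax(ap[50:]))
    degenerate = bool(np.allclose(ap, 0.0))
    return PeakSet(
        first_peak=first,
        second_peak=second,
        braking_peak=PeakPoint(float(ap[ib]), float(ib)),
        propulsion_peak=PeakPoint(float(ap[ip]), float(ip)),
        ap_degenerate=degenerate,
    )
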