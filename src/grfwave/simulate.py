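"""Synthetic rearfoot-strike running GRF cohorts with known ground truth.

The generator emulates the morphology of treadmill running ground
reaction forces: a vertical curve with an early impact peak (~13% of
stance) and a larger mid-stance active peak (~45%), built from two
Gaussian bumps tapered to zero at both ends of stance, and an
anterior-posterior curve that is a braking (negative) half-sine followed
by a propulsion (positive) half-sine.  The medial-lateral channel is
low-amplitude noise about zero.

Between-subject variation is planted through three interpretable modes,
each a per-subject Gaussian score shared across that subject's speeds
(the repeated-measures structure the downstream statistics assume):

* ``magnitude`` - scales all force amplitudes by (1 + score);
* ``timing`` - shifts the bump centers and the braking/propulsion
  crossover by ``score`` percent of stance;
* ``loading_rate`` - compresses the impact bump self-similarly toward
  strike (center and width both divided by 1 + score), which steepens
  the rising edge and raises the vertical average loading rate
  monotonically with the score.

Speed acts through an amplitude multiplier and a linearly shrinking
contact time; sex acts through offsets of the mode-score means and
through body mass, drawn per subject from sex-specific normal
distributions.  Every random draw hangs off a single seed, so a cohort
is bit-reproducible, and every planted quantity (scores, masses, stance
boundaries, peak values and locations) is recorded as ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import GRAVITY, N_STANCE_POINTS
from .recording import ForceRecording, SubjectMeta, write_recording

MODES = ("magnitude", "timing", "loading_rate")

#: Half-width of the cosine taper at each end of stance, % of stance.
TAPER_WIDTH_PCT = 2.0


@dataclass(frozen=True)
class WaveformTemplate:
    """Parameters of the noiseless per-stance force shapes (amplitudes in BW,
    centers/widths in % of stance)."""

    impact_amp: float = 1.6
    impact_center: float = 13.0
    impact_width: float = 4.0
    active_amp: float = 2.4
    active_center: float = 45.0
    active_width: float = 15.0
    ap_amp: float = 0.25
    ap_crossover: float = 50.0

    def validate(self) -> None:
        for name in ("impact_center", "active_center", "ap_crossover"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ParameterError(f"{name}={v} outside (0, 100)")
        for name in ("impact_width", "active_width"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")

    def vertical(self, p: np.ndarray) -> np.ndarray:
        """Vertical force in BW at stance percentages ``p``."""
        p = np.asarray(p, dtype=float)
        v = self.impact_amp * np.exp(
            -((p - self.impact_center) ** 2) / (2 * self.impact_width**2)
        ) + self.active_amp * np.exp(
            -((p - self.active_center) ** 2) / (2 * self.active_width**2)
        )
        return v * _taper(p)

    def ant_post(self, p: np.ndarray) -> np.ndarray:
        """Anterior-posterior force in BW: braking then propulsion."""
        p = np.asarray(p, dtype=float)
        c = self.ap_crossover
        braking = -self.ap_amp * np.sin(np.pi * p / c)
        propulsion = self.ap_amp * np.sin(np.pi * (p - c) / (100.0 - c))
        return np.where(p < c, braking, propulsion)


def _taper(p: np.ndarray) -> np.ndarray:
    """Cosine ramp 0 -> 1 over the first and last TAPER_WIDTH_PCT of stance."""
    w = TAPER_WIDTH_PCT
    up = 0.5 * (1 - np.cos(np.pi * np.clip(p / w, 0, 1)))
    down = 0.5 * (1 - np.cos(np.pi * np.clip((100.0 - p) / w, 0, 1)))
    return up * down


def apply_modes(
    template: WaveformTemplate, mode_scores: dict[str, float]
) -> WaveformTemplate:
    """Realize a subject's template from the base template and mode scores."""
    unknown = set(mode_scores) - set(MODES)
    if unknown:
        raise ParameterError(f"unknown variation mode(s): {sorted(unknown)}")
    t = template
    s = mode_scores.get("magnitude", 0.0)
    if s:
        if s <= -1.0:
            raise ParameterError("magnitude score must exceed -1")
        t = replace(
            t,
            impact_amp=t.impact_amp * (1 + s),
            active_amp=t.active_amp * (1 + s),
            ap_amp=t.ap_amp * (1 + s),
        )
    s = mode_scores.get("timing", 0.0)
    if s:
        t = replace(
            t,
            impact_center=t.impact_center + s,
            active_center=t.active_center + s,
            ap_crossover=t.ap_crossover + s,
        )
    s = mode_scores.get("loading_rate", 0.0)
    if s:
        if s <= -1.0:
            raise ParameterError("loading_rate score must exceed -1")
        t = replace(
            t,
            impact_center=t.impact_center / (1 + s),
            impact_width=t.impact_width / (1 + s),
        )
    t.validate()
    return t


def make_stance_curve(
    template: WaveformTemplate,
    mode_scores: dict[str, float] | None = None,
    channel: str = "vertical",
) -> tuple[np.ndarray, WaveformTemplate]:
    """Noiseless 100-point stance curve plus the realized template (truth)."""
    realized = apply_modes(template, mode_scores or {})
    p = np.arange(N_STANCE_POINTS, dtype=float)
    if channel == "vertical":
        return realized.vertical(p), realized
    if channel == "ant_post":
        return realized.ant_post(p), realized
    raise ParameterError(f"no template for channel {channel!r}")


# ---------------------------------------------------------------------------
# cohort configuration


def _default_mode_sds() -> dict[str, float]:
    return {"magnitude": 0.08, "timing": 1.5, "loading_rate": 0.10}


def _default_speed_effect() -> dict[float, float]:
    # amplitude multiplier per belt speed; loading grows with speed
    return {2.7: 1.00, 3.0: 1.05, 3.3: 1.10, 3.7: 1.18}


def _default_sex_effect() -> dict[str, dict[str, float]]:
    # mode-score mean offsets; females run with a steeper impact rise
    return {"female": {"loading_rate": 0.15}, "male": {}}


@dataclass
class CohortConfig:
    """Design of a synthetic cohort (defaults mirror the study layout:
    15 runners per sex, 4 speeds, 5 recorded steps each, 1000 Hz)."""

    n_per_sex: int = 15
    speeds: tuple = (2.7, 3.0, 3.3, 3.7)
    steps_per_condition: int = 5
    sampling_rate: float = 1000.0
    contact_time_base: float = 0.26  # s at the slowest speed
    contact_time_slope: float = 0.04  # s lost per m/s of extra speed
    flight_time: float = 0.12  # s between consecutive stances
    lead_time: float = 0.08  # s of baseline before/after the steps
    mode_sds: dict = field(default_factory=_default_mode_sds)
    speed_effect: dict = field(default_factory=_default_speed_effect)
    sex_effect: dict = field(default_factory=_default_sex_effect)
    noise_sd: float = 3.0  # N, white measurement noise
    medlat_sd: float = 5.0  # N, medial-lateral channel noise
    threshold: float = 20.0  # N, the detection convention emulated
    body_mass_mean: dict = field(
        default_factory=lambda: {"male": 71.4, "female": 60.6}
    )
    body_mass_sd: dict = field(
        default_factory=lambda: {"male": 3.5, "female": 2.5}
    )
    template: WaveformTemplate = field(default_factory=WaveformTemplate)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_sex < 1 or self.steps_per_condition < 1:
            raise ParameterError("counts must be >= 1")
        if any(sd < 0 for sd in self.mode_sds.values()):
            raise ParameterError("mode SDs must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.noise_sd >= self.threshold / 3.0:
            warnings.warn(
                "noise_sd >= threshold/3: stance detection is no longer "
                "guaranteed to recover planted boundaries",
                stacklevel=2,
            )
        self.template.validate()

    def contact_time(self, speed: float) -> float:
        return self.contact_time_base - self.contact_time_slope * (
            speed - self.speeds[0]
        )

    def speed_multiplier(self, speed: float) -> float:
        return float(self.speed_effect.get(speed, 1.0))


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class StepTruth:
    """Planted truth of one rendered stance."""

    span: tuple[int, int]  # rendered sample interval [start, end)
    event: tuple[int, int]  # threshold-crossing interval on noiseless signal
    contact_time: float  # s, of the rendered span
    event_contact_time: float  # s, of the threshold-crossed interval
    peaks: dict  # realized peak values/locations (threshold frame)


@dataclass
class RecordingTruth:
    """Truth of one subject x speed recording."""

    subject_id: str
    sex: str
    speed: float
    body_mass: float
    mode_scores: dict[str, float]
    template: WaveformTemplate
    curve_vertical: np.ndarray  # noiseless 100-point curves, BW
    curve_ant_post: np.ndarray
    steps: list[StepTruth]


@dataclass
class Cohort:
    config: CohortConfig
    recordings: list[ForceRecording]
    truths: list[RecordingTruth]

    def truth_of(self, subject_id: str, speed: float) -> RecordingTruth:
        for t in self.truths:
            if t.subject_id == subject_id and t.speed == speed:
                return t
        raise KeyError((subject_id, speed))


# ---------------------------------------------------------------------------
# rendering


def _truth_peaks(
    template: WaveformTemplate, threshold_bw: float
) -> dict | None:
    """Realized peak truth on a fine grid, in the threshold-crossed frame.

    Independent of the analysis modules: the continuous template is
    scanned on a 0.01%-step grid; the stance frame is the interval where
    the vertical force reaches ``threshold_bw``, matching how stance is
    detected downstream.
    """
    p = np.arange(0.0, 100.0, 0.01)
    v = template.vertical(p)
    above = np.flatnonzero(v >= threshold_bw)
    if above.size == 0:
        return None
    p0, p1 = p[above[0]], p[above[-1]]
    span = p1 - p0

    def frame(pct: float) -> float:
        return float((pct - p0) / span * 100.0)

    # impact peak: maximum near the realized impact center
    w_lo = max(template.impact_center - 3 * template.impact_width, 0.0)
    w_hi = template.impact_center + 3 * template.impact_width
    win = (p >= w_lo) & (p <= w_hi)
    i1 = np.flatnonzero(win)[np.argmax(v[win])]
    # active peak: maximum near the active center
    win2 = (p >= template.active_center - 2 * template.active_width) & (
        p <= min(template.active_center + 2 * template.active_width, 100.0)
    )
    i2 = np.flatnonzero(win2)[np.argmax(v[win2])]

    ap = template.ant_post(p)
    ib = np.argmin(ap)
    ip = np.argmax(ap)
    return {
        "first_peak": {"value": float(v[i1]), "percent": frame(p[i1])},
        "second_peak": {"value": float(v[i2]), "percent": frame(p[i2])},
        "braking_peak": {"value": float(ap[ib]), "percent": frame(p[ib])},
        "propulsion_peak": {"value": float(ap[ip]), "percent": frame(p[ip])},
        "stance_window_pct": [float(p0), float(p1)],
    }


def render_recording(
    template: WaveformTemplate,
    meta: SubjectMeta,
    config: CohortConfig,
    rng: np.random.Generator,
    mode_scores: dict[str, float] | None = None,
) -> tuple[ForceRecording, RecordingTruth]:
    """Render one subject x speed trial: repeated stances + flight + noise.

    The realized continuous template is sampled in the time domain over
    each step's contact time, scaled to Newtons by body mass x 9.8, and
    white measurement noise is added; baseline (flight) noise is clipped
    to stay safely below the stance-detection threshold.
    """
    mode_scores = dict(mode_scores or {})
    realized = apply_modes(template, mode_scores)
    fs = config.sampling_rate
    bw = meta.body_mass * GRAVITY
    contact = config.contact_time(meta.speed)
    n_c = int(round(contact * fs))
    n_flight = int(round(config.flight_time * fs))
    n_lead = int(round(config.lead_time * fs))
    steps = config.steps_per_condition

    n_total = n_lead + steps * n_c + (steps - 1) * n_flight + n_lead
    vertical = np.zeros(n_total)
    ant_post = np.zeros(n_total)
    clean_mask = np.ones(n_total, dtype=bool)  # True where baseline
    step_truths = []

    p_grid = np.arange(n_c) * (100.0 / n_c)
    v_step = realized.vertical(p_grid) * bw
    ap_step = realized.ant_post(p_grid) * bw
    peaks = _truth_peaks(realized, config.threshold / bw)

    pos = n_lead
    for _ in range(steps):
        vertical[pos : pos + n_c] = v_step
        ant_post[pos : pos + n_c] = ap_step
        clean_mask[pos : pos + n_c] = False
        above = np.flatnonzero(v_step >= config.threshold)
        ev = (
            (pos + int(above[0]), pos + int(above[-1]) + 1)
            if above.size
            else (pos, pos)
        )
        step_truths.append(
            StepTruth(
                span=(pos, pos + n_c),
                event=ev,
                contact_time=n_c / fs,
                event_contact_time=(ev[1] - ev[0]) / fs,
                peaks=peaks,
            )
        )
        pos += n_c + n_flight

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=(n_total, 2))
        # keep flight-phase force safely below the detection threshold
        limit = max(config.threshold - 5.0, 0.0)
        noise[clean_mask] = np.clip(noise[clean_mask], -limit, limit)
        vertical = vertical + noise[:, 0]
        ant_post = ant_post + noise[:, 1]
    med_lat = (
        rng.normal(0.0, config.medlat_sd, size=n_total)
        if config.medlat_sd > 0
        else np.zeros(n_total)
    )

    time = np.arange(n_total) / fs
    recording = ForceRecording(
        meta=meta,
        sampling_rate=fs,
        time=time,
        forces=np.column_stack([vertical, ant_post, med_lat]),
    )
    p100 = np.arange(N_STANCE_POINTS, dtype=float)
    truth = RecordingTruth(
        subject_id=meta.subject_id,
        sex=meta.sex,
        speed=meta.speed,
        body_mass=meta.body_mass,
        mode_scores=mode_scores,
        template=realized,
        curve_vertical=realized.vertical(p100),
        curve_ant_post=realized.ant_post(p100),
        steps=step_truths,
    )
    return recording, truth


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort: subjects x speeds recordings with truth.

    Per-subject draws (body mass, mode scores) happen once and are shared
    across that subject's speeds; the speed effect multiplies amplitudes
    via the magnitude mode and shortens contact time.  Deterministic
    under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    recordings, truths = [], []
    for sex in ("female", "male"):
        offsets = config.sex_effect.get(sex, {})
        for i in range(config.n_per_sex):
            subject_id = f"{sex[0].upper()}{i + 1:02d}"
            mass = rng.normal(
                config.body_mass_mean[sex], config.body_mass_sd[sex]
            )
            scores = {
                mode: rng.normal(offsets.get(mode, 0.0), sd)
                for mode, sd in config.mode_sds.items()
            }
            for speed in config.speeds:
                mult = config.speed_multiplier(speed)
                speed_scores = dict(scores)
                # amplitude multiplier composes with the magnitude mode
                speed_scores["magnitude"] = (
                    (1 + speed_scores.get("magnitude", 0.0)) * mult - 1
                )
                meta = SubjectMeta(
                    subject_id=subject_id,
                    sex=sex,
                    body_mass=float(mass),
                    speed=speed,
                )
                rec, truth = render_recording(
                    config.template, meta, config, rng, speed_scores
                )
                recordings.append(rec)
                truths.append(truth)
    return Cohort(config=config, recordings=recordings, truths=truths)


def make_waveform_matrix(
    n_subjects: int = 15,
    n_speeds: int = 4,
    mode: str = "magnitude",
    mode_sd: float = 0.10,
    noise_sd: float = 0.02,
    template: WaveformTemplate | None = None,
    channel: str = "vertical",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Curve-level cohort matrix with a single planted variation mode.

    Rows (one per subject x speed, subjects' scores shared across speeds)
    are the realized noiseless curves plus white per-point noise of SD
    ``noise_sd`` BW.  Truth reports the planted unit direction (for the
    magnitude mode, the normalized base curve) and the realized scores,
    enabling exact planted-mode recovery checks against PCA.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    template = template or WaveformTemplate()
    base, _ = make_stance_curve(template, {}, channel)
    scores = np.repeat(rng.normal(0.0, mode_sd, size=n_subjects), n_speeds)
    rows = np.empty((n_subjects * n_speeds, N_STANCE_POINTS))
    for r, s in enumerate(scores):
        rows[r], _ = make_stance_curve(template, {mode: float(s)}, channel)
    rows += rng.normal(0.0, noise_sd, size=rows.shape)
    truth = {
        "mode": mode,
        "scores": scores,
        "base_curve": base,
        "direction": base / np.linalg.norm(base),
        "noise_sd": noise_sd,
    }
    return rows, truth


# ---------------------------------------------------------------------------
# on-disk cohort layout consumed by the preprocess stage


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write one CSV per recording plus a metadata table and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for rec in cohort.recordings:
        name = f"{rec.meta.subject_id}_v{rec.meta.speed:.1f}.csv"
        write_recording(outdir / name, rec)
        meta_rows.append(
            {
                "file": name,
                "subject_id": rec.meta.subject_id,
                "sex": rec.meta.sex,
                "body_mass_kg": rec.meta.body_mass,
                "speed_mps": rec.meta.speed,
            }
        )
    pd.DataFrame(meta_rows).to_csv(
        outdir / "metadata.csv", index=False, float_format="%.17g"
    )
    truth_obj = [
        {
            "subject_id": t.subject_id,
            "sex": t.sex,
            "speed": t.speed,
            "body_mass": t.body_mass,
            "mode_scores": t.mode_scores,
            "template": vars(t.template),
            "steps": [
                {
                    "span": list(s.span),
                    "event": list(s.event),
                    "contact_time": s.contact_time,
                    "event_contact_time": s.event_contact_time,
                    "peaks": s.peaks,
                }
                for s in t.steps
            ],
        }
        for t in cohort.truths
    ]
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_obj, fh, indent=1, sort_keys=True, default=float)
    return outdir
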