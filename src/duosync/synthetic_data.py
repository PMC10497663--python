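"""Synthetic duo sessions with known ground truth.

The generator emulates the signal structure the pipeline assumes: the two
performers' front-head markers share sinusoidal speed components at
periods tied to the phrase hierarchy, with a controllable time lag between
performers; beat onsets carry smooth tempo drift and optional missing
beats; and a cohort-level linear association can be planted between the
singer's empathic perspective-taking (EPT) score and the lead/lag
magnitude.

Sign convention: a positive component ``lag_s`` puts the pianist's
oscillation earlier in the cycle (pianist leads), which yields a positive
cross-wavelet phase difference in the in-phase regime.  A planted
singer-lead therefore corresponds to a negative ``lag_s``.

Components are planted in *speed* (a constant baseline plus zero-mean
sinusoids, integrated to positions along a fixed axis) rather than as
zero-mean sinusoidal velocities, because the pipeline analyses the
Euclidean norm of velocity: the norm of a zero-mean oscillation would be
rectified to half the period, moving the spectral ground truth away from
where the planted level says it is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .io_config import SectionAnnotation, SessionManifest
from .kinematics import MARKER_INVENTORY, MarkerTrajectory
from .tempo import BARS_PER_LEVEL, LEVELS, BeatTrack, PhraseLevelSet

__all__ = [
    "PlantedComponent",
    "CohortSpec",
    "PieceTemplate",
    "DuoSession",
    "gen_beat_track",
    "gen_duo_motion",
    "gen_cohort",
    "faure_template",
    "schumann_template",
    "default_sections",
]

#: Amplitude (mm/s) of the slow drift shared by all non-head markers.
COMMON_DRIFT_AMPLITUDE = 0.5


@dataclass(frozen=True)
class PlantedComponent:
    """One shared oscillation planted in both performers' head speed."""

    level: str
    amplitude: float  # mm/s
    lag_s: float  # positive = pianist earlier in the cycle
    time_support: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level design: size, EPT range, planted EPT-lead slope.

    ``lead_slope`` is seconds of singer-lead per EPT unit: each duo's
    planted singer-lead lag is lead_slope * (singer_EPT - midrange).
    """

    n_duos: int = 24
    ept_range: tuple[int, int] = (13, 28)
    lead_slope: float = 0.01
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_duos < 2:
            raise ValueError("n_duos must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.ept_range
        if not (0 <= lo < hi <= 28):
            raise ValueError("ept_range must satisfy 0 <= low < high <= 28")


@dataclass(frozen=True)
class PieceTemplate:
    """Manifest prototype plus score structure for one piece."""

    manifest: SessionManifest
    sections: list[SectionAnnotation]
    n_bars: int
    base_ibi_s: float
    fs: float = 240.0


@dataclass(frozen=True)
class DuoSession:
    """One complete synthetic session with its ground truth."""

    manifest: SessionManifest
    beat_track: BeatTrack
    sections: list[SectionAnnotation]
    pianist_trajs: list[MarkerTrajectory]
    singer_trajs: list[MarkerTrajectory]
    truth: dict


def gen_beat_track(
    n_bars: int,
    beats_per_bar: int,
    base_ibi_s: float,
    drift_fraction: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[BeatTrack, float]:
    """Beat onsets with smooth tempo drift and seeded missing beats.

    The i-th inter-beat interval is base * (1 + drift * sin(2*pi*i/n)).
    A seeded random subset of interior onsets is blanked (the first and
    last beats always remain, since a performance starts and ends with
    played notes).  Returns the track and the ground-truth mean IBI.
    """
    if base_ibi_s <= 0:
        raise ValueError("base_ibi_s must be positive")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    n_beats = n_bars * beats_per_bar + 1
    i = np.arange(n_beats - 1)
    ibis = base_ibi_s * (1.0 + drift_fraction * np.sin(2.0 * np.pi * i / (n_beats - 1)))
    onsets = np.concatenate([[0.0], np.cumsum(ibis)])
    true_mean_ibi = float(np.mean(ibis))
    rng = np.random.default_rng(seed)
    blank = rng.random(n_beats) < missing_rate
    blank[0] = blank[-1] = False
    onsets_out = onsets.copy()
    onsets_out[blank] = np.nan
    track = BeatTrack(beat_index=np.arange(n_beats), onset_s=onsets_out)
    return track, true_mean_ibi


def _component_speed(
    t: np.ndarray, period: float, amplitude: float, delay: float,
    support: tuple[float, float] | None,
) -> np.ndarray:
    s = amplitude * np.sin(2.0 * np.pi * (t - delay) / period)
    if support is not None:
        t0, t1 = support
        s = np.where((t >= t0) & (t < t1), s, 0.0)
    return s


def gen_duo_motion(
    duration_s: float,
    fs: float,
    phrase_levels: PhraseLevelSet,
    components: list[PlantedComponent],
    n_markers_per_performer: int = 14,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[MarkerTrajectory], list[MarkerTrajectory], dict]:
    """Generate both performers' marker trajectories for one session.

    The front-head speed of the pianist is a constant baseline plus the
    planted sinusoids at phase 0; the singer's copy is delayed by each
    component's ``lag_s``.  White Gaussian noise (sd in mm/s) is added to
    velocity on every axis before integration to positions.  Remaining
    markers carry noise plus a low-amplitude drift common to all markers.
    """
    if not (1 <= n_markers_per_performer <= len(MARKER_INVENTORY)):
        raise ValueError("n_markers_per_performer out of range")
    periods = {}
    for comp in components:
        p = phrase_levels[comp.level]
        if fs < 8.0 / p:
            raise ValueError(
                f"component at level {comp.level!r}: fs {fs:g} Hz below the "
                f"safe oversampling bound {8.0 / p:g} Hz"
            )
        if duration_s < 3.0 * p:
            raise ValueError(
                f"component at level {comp.level!r}: duration {duration_s:g} s "
                f"shorter than 3 periods ({3.0 * p:g} s)"
            )
        if abs(comp.lag_s) >= p:
            raise ValueError(
                f"component at level {comp.level!r}: |lag| {abs(comp.lag_s):g} s "
                f"not below the period {p:g} s"
            )
        periods[comp] = p
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs
    baseline = max(1.0, 1.5 * sum(c.amplitude for c in components)) + 3.0 * noise_sd
    speed_pianist = np.full(n, baseline)
    speed_singer = np.full(n, baseline)
    for comp in components:
        speed_pianist += _component_speed(
            t, periods[comp], comp.amplitude, 0.0, comp.time_support
        )
        speed_singer += _component_speed(
            t, periods[comp], comp.amplitude, comp.lag_s, comp.time_support
        )
    drift = COMMON_DRIFT_AMPLITUDE * np.sin(2.0 * np.pi * t / duration_s)
    markers = MARKER_INVENTORY[:n_markers_per_performer]

    def build(performer: str, head_speed: np.ndarray) -> list[MarkerTrajectory]:
        trajs = []
        for m in markers:
            vel = rng.normal(0.0, noise_sd, size=(n, 3)) if noise_sd > 0 else np.zeros((n, 3))
            if m == "front_head":
                vel[:, 0] += head_speed
            else:
                vel[:, 0] += drift
            pos = cumulative_trapezoid(vel, dx=dt, initial=0.0, axis=0)
            trajs.append(
                MarkerTrajectory(performer=performer, marker=m, fs=fs, positions=pos)
            )
        return trajs

    pianist = build("pianist", speed_pianist)
    singer = build("singer", speed_singer)
    truth = {
        "baseline_speed": baseline,
        "components": [
            {
                "level": c.level,
                "period_s": periods[c],
                "amplitude": c.amplitude,
                "lag_s": c.lag_s,
            }
            for c in components
        ],
    }
    return pianist, singer, truth


def default_sections(n_bars: int, beats_per_bar: int) -> list[SectionAnnotation]:
    """Simple synthetic form: a short piano-solo intro, then A, B, A'."""
    if n_bars < 4:
        raise ValueError("need at least 4 bars")
    intro_bars = max(1, n_bars // 8)
    rest = n_bars - intro_bars
    a = intro_bars + rest // 3
    b = a + rest // 3
    bounds = [0, intro_bars, a, b, n_bars]
    labels = ["intro", "A", "B", "A'"]
    solos = [True, False, False, False]
    return [
        SectionAnnotation(
            label=lb,
            start_beat=lo * beats_per_bar,
            end_beat=hi * beats_per_bar,
            solo=so,
        )
        for lb, lo, hi, so in zip(labels, bounds[:-1], bounds[1:], solos)
    ]


def _template_manifest(
    piece: str, beats_per_bar: int, broadband: tuple[float, float]
) -> SessionManifest:
    return SessionManifest(
        duo_id="template",
        piece=piece,
        take=0,
        pianist_ept=20,
        singer_ept=20,
        ept_group="LL",
        meter_beats_per_bar=beats_per_bar,
        broadband_low_s=broadband[0],
        broadband_high_s=broadband[1],
    )


def faure_template(n_bars: int = 39, fs: float = 240.0) -> PieceTemplate:
    """Slow 12/8 piece: 1/8-note IBI 0.38 s, broadband 1-26 s."""
    return PieceTemplate(
        manifest=_template_manifest("faure", 12, (1.0, 26.0)),
        sections=default_sections(n_bars, 12),
        n_bars=n_bars,
        base_ibi_s=0.38,
        fs=fs,
    )


def schumann_template(n_bars: int = 156, fs: float = 240.0) -> PieceTemplate:
    """Fast 2/8 piece: 1/8-note IBI 0.49 s, broadband 0.2-6.2 s."""
    return PieceTemplate(
        manifest=_template_manifest("schumann", 2, (0.2, 6.2)),
        sections=default_sections(n_bars, 2),
        n_bars=n_bars,
        base_ibi_s=0.49,
        fs=fs,
    )


def gen_cohort(
    spec: CohortSpec,
    template: PieceTemplate,
    *,
    dominant_level: str = "two",
    amplitude: float = 10.0,
    drift_fraction: float = 0.02,
    missing_rate: float = 0.0,
    n_markers_per_performer: int = 1,
) -> tuple[list[DuoSession], pd.DataFrame]:
    """Generate a cohort of duo sessions with a planted EPT-lead relation.

    Each duo draws pianist and singer EPT scores uniformly on the spec's
    range; the singer-lead lag planted at the dominant component is
    lead_slope * (singer_EPT - midrange), so the ground-truth table has an
    exactly linear lag-vs-EPT relation.  All randomness flows from the
    spec seed; identical spec + template reproduce identical output.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_duos)
    lo, hi = spec.ept_range
    midrange = (lo + hi) / 2.0
    bpb = template.manifest.meter_beats_per_bar
    sessions = []
    rows = []
    for d, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        pianist_ept = int(rng.integers(lo, hi + 1))
        singer_ept = int(rng.integers(lo, hi + 1))
        singer_lead_s = spec.lead_slope * (singer_ept - midrange)
        lag_s = -singer_lead_s
        group = ("H" if pianist_ept > midrange else "L") + (
            "H" if singer_ept > midrange else "L"
        )
        track, true_ibi = gen_beat_track(
            template.n_bars,
            bpb,
            template.base_ibi_s,
            drift_fraction=drift_fraction,
            missing_rate=missing_rate,
            seed=child_seed,
        )
        levels = PhraseLevelSet(
            {lv: true_ibi * bpb * BARS_PER_LEVEL[lv] for lv in LEVELS}
        )
        present = track.onset_s[~np.isnan(track.onset_s)]
        duration = float(present[-1])
        components = [
            PlantedComponent(level=dominant_level, amplitude=amplitude, lag_s=lag_s)
        ]
        pianist, singer, truth = gen_duo_motion(
            duration_s=duration,
            fs=template.fs,
            phrase_levels=levels,
            components=components,
            n_markers_per_performer=n_markers_per_performer,
            noise_sd=spec.noise_sd,
            seed=child_seed,
        )
        manifest = replace(
            template.manifest,
            duo_id=f"duo{d:02d}",
            pianist_ept=pianist_ept,
            singer_ept=singer_ept,
            ept_group=group,
        )
        truth.update(
            {
                "true_mean_ibi_s": true_ibi,
                "planted_lag_s": lag_s,
                "planted_singer_lead_s": singer_lead_s,
                "dominant_level": dominant_level,
            }
        )
        sessions.append(
            DuoSession(
                manifest=manifest,
                beat_track=track,
                sections=template.sections,
                pianist_trajs=pianist,
                singer_trajs=singer,
                truth=truth,
            )
        )
        rows.append(
            {
                "duo_id": manifest.duo_id,
                "pianist_ept": pianist_ept,
                "singer_ept": singer_ept,
                "ept_group": group,
                "planted_lag_s": lag_s,
                "planted_singer_lead_s": singer_lead_s,
                "dominant_level": dominant_level,
                "period_s": levels[dominant_level],
                "true_mean_ibi_s": true_ibi,
            }
        )
    return sessions, pd.DataFrame(rows)
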