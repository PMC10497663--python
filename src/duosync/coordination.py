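"""Phrase-level aggregation of the cross-wavelet field and leadership calls.

Phase-difference semantics (pianist first channel): values in [0, pi/2]
and [-pi, -pi/2] mean the pianist leads; values in [pi/2, pi] and
[-pi/2, 0] mean the singer leads; 0 is perfectly in sync and the motion is
called in-phase while the angle stays within a quadrant of 0 (out-of-phase
within a quadrant of +/-pi).  A band-aggregated phase is a circular
(phasor) mean; its resultant length is reported as a reliability
diagnostic, since an arithmetic mean of angles is meaningless near the
+/-pi wrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tempo import BARS_PER_LEVEL, LEVELS, BandSpec, BeatTrack
from .xwt import XwtField

__all__ = [
    "BandAggregate",
    "find_top_peaks",
    "tabulate_peak_occurrence",
    "band_aggregate",
    "dominant_level",
    "phase_to_leadership",
    "phase_to_ms",
    "segment_aggregate",
]

log = logging.getLogger("duosync.coordination")

OUTSIDE = "outside"


@dataclass(frozen=True)
class BandAggregate:
    """Grand means of power and phase over one phrase-level band."""

    level: str
    mean_power: float
    mean_phase_rad: float
    resultant_length: float
    phase_ms: float
    leadership: str  # pianist_leads | singer_leads | in_sync
    phase_regime: str  # in_phase | out_of_phase

    def __post_init__(self) -> None:
        if not (-np.pi < self.mean_phase_rad <= np.pi):
            raise ValueError("mean phase must lie in (-pi, pi]")
        if not (0.0 <= self.resultant_length <= 1.0 + 1e-12):
            raise ValueError("resultant length must lie in [0, 1]")


def phase_to_leadership(phase_rad: float) -> tuple[str, str]:
    """Map a phase difference to (leadership, phase_regime).

    Pianist leads on (0, pi/2) and (-pi, -pi/2); singer leads on
    [pi/2, pi] and [-pi/2, 0); zero is in sync.  The boundary angles
    +/-pi/2 and pi belong to the upper (singer) intervals.  The regime is
    in-phase for |phase| < pi/2 and out-of-phase for |phase| >= pi/2.
    """
    phi = float(phase_rad)
    if not (-np.pi < phi <= np.pi):
        raise ValueError("phase must lie in (-pi, pi]")
    half_pi = np.pi / 2.0
    if phi == 0.0:
        leadership = "in_sync"
    elif (0.0 < phi < half_pi) or (-np.pi < phi < -half_pi):
        leadership = "pianist_leads"
    else:
        leadership = "singer_leads"
    if abs(phi) == half_pi:
        log.warning("phase exactly at quadrant boundary +/-pi/2; labeled out_of_phase")
    regime = "in_phase" if abs(phi) < half_pi else "out_of_phase"
    return leadership, regime


def phase_to_ms(phase_rad: float, period_s: float) -> float:
    """Convert a phase angle at a given period into signed milliseconds.

    Negative values mean the singer leads in the in-phase regime.
    """
    if period_s <= 0:
        raise ValueError("period must be positive")
    return phase_rad / (2.0 * np.pi) * period_s * 1000.0


def find_top_peaks(
    periods_s: np.ndarray, power: np.ndarray, k: int = 3
) -> list[tuple[float, float]]:
    """Top-k local maxima of a power-by-period curve, ranked by power.

    A peak is strictly greater than its distinct neighbours on both sides;
    a flat plateau is represented by its left-most sample.  Endpoints are
    never peaks.  Ties in power rank the longer period first.  A curve
    without interior maxima yields an empty list.
    """
    periods_s = np.asarray(periods_s, dtype=float)
    power = np.asarray(power, dtype=float)
    n = len(power)
    if n < 3:
        raise ValueError("curve must have at least 3 samples")
    peaks: list[tuple[float, float]] = []
    for i in range(1, n - 1):
        v = power[i]
        if power[i - 1] == v:  # not the left edge of its plateau
            continue
        if power[i - 1] > v:
            continue
        j = i + 1
        while j < n and power[j] == v:
            j += 1
        if j < n and power[j] < v:
            peaks.append((float(periods_s[i]), float(v)))
    peaks.sort(key=lambda pv: (-pv[1], -pv[0]))
    return peaks[:k]


def tabulate_peak_occurrence(
    peaks_per_session: list[list[tuple[float, float]]],
    bands_per_session: list[list[BandSpec]],
) -> pd.DataFrame:
    """Count peaks falling inside each phrase-level band across sessions.

    Each peak is assigned to the unique band containing its period (bands
    are session-specific), or to the 'outside' category.  Percentages are
    of the total number of classified peaks and sum to 100 up to rounding.
    """
    if len(peaks_per_session) != len(bands_per_session):
        raise ValueError("need one band set per session")
    counts = {lv: 0 for lv in LEVELS}
    counts[OUTSIDE] = 0
    for peaks, bands in zip(peaks_per_session, bands_per_session):
        for period, _ in peaks:
            for band in bands:
                if band.contains(period):
                    counts[band.level] += 1
                    break
            else:
                counts[OUTSIDE] += 1
    total = sum(counts.values())
    rows = [
        {
            "level": lv,
            "count": counts[lv],
            "percentage": 100.0 * counts[lv] / total if total else 0.0,
        }
        for lv in (*LEVELS, OUTSIDE)
    ]
    return pd.DataFrame(rows)


def band_aggregate(
    field: XwtField,
    band: BandSpec,
    mask: np.ndarray | None = None,
) -> BandAggregate:
    """Grand mean power and circular mean phase over one band x time mask.

    The phase is aggregated as the argument of the mean unit phasor; the
    modulus of that mean (resultant length in [0, 1]) flags how reliable
    the mean angle is.  The phase in ms uses the band's level duration as
    the period.
    """
    rows = (field.periods_s >= band.period_low_s) & (
        field.periods_s <= band.period_high_s
    )
    if not rows.any():
        raise ValueError(
            f"band for level {band.level!r} does not overlap the period grid"
        )
    if mask is None:
        mask = np.ones(len(field.times_s), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty time mask")
    power_cells = field.power[np.ix_(rows, mask)]
    phase_cells = field.phase_rad[np.ix_(rows, mask)]
    phasor = np.exp(1j * phase_cells).mean()
    mean_phase = float(np.angle(phasor))
    if mean_phase == -np.pi:
        mean_phase = np.pi
    resultant = float(np.abs(phasor))
    if resultant < 0.1:
        log.debug(
            "band %s: resultant length %.3f; mean phase unreliable",
            band.level,
            resultant,
        )
    ms = phase_to_ms(mean_phase, band.center_s)
    leadership, regime = phase_to_leadership(mean_phase)
    return BandAggregate(
        level=band.level,
        mean_power=float(power_cells.mean()),
        mean_phase_rad=mean_phase,
        resultant_length=min(resultant, 1.0),
        phase_ms=ms,
        leadership=leadership,
        phase_regime=regime,
    )


def dominant_level(aggregates: list[BandAggregate]) -> str:
    """Phrase level with maximal mean power; ties go to the shorter period."""
    if not aggregates:
        raise ValueError("need at least one aggregate")
    best = max(
        aggregates,
        key=lambda a: (a.mean_power, -BARS_PER_LEVEL[a.level]),
    )
    ties = [a.level for a in aggregates if a.mean_power == best.mean_power]
    if len(ties) > 1:
        log.warning("dominant level tie among %s; reporting shortest", ties)
    return best.level


def _section_time_mask(
    times_s: np.ndarray, track: BeatTrack, start_beat: int, end_beat: int
) -> np.ndarray:
    """Half-open time mask for score beats [start_beat, end_beat)."""
    onsets = track.onset_s
    idx0 = start_beat - int(track.beat_index[0])
    idx1 = end_beat - int(track.beat_index[0])
    t0 = onsets[idx0]
    t1 = onsets[idx1] if idx1 < len(onsets) else np.inf
    return (times_s >= t0) & (times_s < t1)


def segment_aggregate(
    field: XwtField,
    bands: list[BandSpec],
    sections,
    track: BeatTrack,
) -> pd.DataFrame:
    """Band aggregates per musical section and for solo vs together unions.

    ``sections`` is an iterable of objects with ``label``, ``start_beat``,
    ``end_beat`` (half-open, in score beats) and ``solo`` attributes; beats
    are mapped to time through the (complete) beat track.
    """
    if not track.is_complete:
        raise ValueError("beat track must be complete (interpolate first)")
    rows = []
    solo_mask = np.zeros(len(field.times_s), dtype=bool)
    together_mask = np.zeros(len(field.times_s), dtype=bool)
    for sec in sections:
        mask = _section_time_mask(field.times_s, track, sec.start_beat, sec.end_beat)
        if not mask.any():
            raise ValueError(f"section {sec.label!r} covers no timestamps")
        if sec.solo:
            solo_mask |= mask
        else:
            together_mask |= mask
        for band in bands:
            agg = band_aggregate(field, band, mask)
            rows.append({"segment": sec.label, "solo": bool(sec.solo), **vars(agg)})
    for name, mask, solo in (
        ("solo", solo_mask, True),
        ("together", together_mask, False),
    ):
        if mask.any():
            for band in bands:
                agg = band_aggregate(field, band, mask)
                rows.append({"segment": name, "solo": solo, **vars(agg)})
    return pd.DataFrame(rows)
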