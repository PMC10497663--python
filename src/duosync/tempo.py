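"""Tempo extraction and tempo-scaled period bands.

A performance's tempo is summarised by its mean inter-beat interval (IBI),
the average time between successive score beats counted at the 1/8-note
level.  Phrase levels (half bar up to four bars) are converted into
durations in seconds from the mean IBI, and each level gets a narrow period
band used to aggregate cross-wavelet output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LEVELS",
    "BARS_PER_LEVEL",
    "BeatTrack",
    "TempoSummary",
    "PhraseLevelSet",
    "BandSpec",
    "interpolate_missing_beats",
    "compute_tempo",
    "phrase_levels",
    "make_bands",
]

#: Phrase levels in increasing order of duration.
LEVELS: tuple[str, ...] = ("half", "one", "two", "three", "four")

#: Number of bars spanned by each phrase level.
BARS_PER_LEVEL: dict[str, float] = {
    "half": 0.5,
    "one": 1.0,
    "two": 2.0,
    "three": 3.0,
    "four": 4.0,
}


@dataclass(frozen=True)
class BeatTrack:
    """Score beat -> onset time mapping; missing onsets are NaN.

    ``interpolated`` flags beats whose onset was estimated rather than
    performed, so downstream consumers can audit gap filling.
    """

    beat_index: np.ndarray
    onset_s: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bi = np.asarray(self.beat_index, dtype=int)
        on = np.asarray(self.onset_s, dtype=float)
        if bi.ndim != 1 or on.shape != bi.shape:
            raise ValueError("beat_index and onset_s must be 1-D and equally long")
        if len(bi) and not np.array_equal(bi, np.arange(bi[0], bi[0] + len(bi))):
            raise ValueError("beat_index must be consecutive integers")
        interp = self.interpolated
        if interp is None:
            interp = np.zeros(len(bi), dtype=bool)
        interp = np.asarray(interp, dtype=bool)
        if interp.shape != bi.shape:
            raise ValueError("interpolated flags must match beat_index length")
        present = on[~np.isnan(on)]
        if np.any(np.diff(present) <= 0):
            raise ValueError("present onsets must be strictly increasing")
        object.__setattr__(self, "beat_index", bi)
        object.__setattr__(self, "onset_s", on)
        object.__setattr__(self, "interpolated", interp)

    @property
    def missing(self) -> np.ndarray:
        """Beat indices with no onset."""
        return self.beat_index[np.isnan(self.onset_s)]

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.onset_s))

    def __len__(self) -> int:
        return len(self.beat_index)


@dataclass(frozen=True)
class TempoSummary:
    """Mean/SD/range of the inter-beat interval, in seconds."""

    mean_ibi_s: float
    sd_ibi_s: float
    min_ibi_s: float
    max_ibi_s: float

    def __post_init__(self) -> None:
        if not (0 < self.min_ibi_s <= self.mean_ibi_s <= self.max_ibi_s):
            raise ValueError("require 0 < min <= mean <= max IBI")


@dataclass(frozen=True)
class PhraseLevelSet:
    """Duration in seconds of each phrase level for one performance."""

    durations_s: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.durations_s) != set(LEVELS):
            raise ValueError(f"need durations for exactly the levels {LEVELS}")
        vals = [self.durations_s[lv] for lv in LEVELS]
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("durations must be strictly increasing in level")

    def __getitem__(self, level: str) -> float:
        return self.durations_s[level]


@dataclass(frozen=True)
class BandSpec:
    """Period band [low, high] seconds attached to one phrase level.

    ``center_s`` is the level's duration; it is the period used when a
    band-aggregated phase angle is converted to milliseconds.
    """

    level: str
    period_low_s: float
    period_high_s: float
    center_s: float

    def __post_init__(self) -> None:
        if not (self.period_low_s <= self.center_s <= self.period_high_s):
            raise ValueError(
                f"band for level {self.level!r} does not contain its duration"
            )
        if self.period_low_s >= self.period_high_s:
            raise ValueError("band must have positive width")

    def contains(self, period_s: float) -> bool:
        return self.period_low_s <= period_s <= self.period_high_s


def interpolate_missing_beats(track: BeatTrack) -> BeatTrack:
    """Fill missing beat onsets by linear interpolation.

    Interior gaps are filled between the nearest performed neighbours;
    leading/trailing gaps are linearly extrapolated from the two nearest
    performed onsets.  Filled beats are flagged.  Idempotent, and exact on
    affine onset sequences.
    """
    on = track.onset_s.copy()
    present = ~np.isnan(on)
    if present.sum() < 2:
        raise ValueError("need at least two performed onsets to interpolate")
    if track.is_complete:
        return track
    bi = track.beat_index.astype(float)
    filled = np.interp(bi, bi[present], on[present])
    # np.interp clamps outside the data; extrapolate edges from the two
    # nearest performed onsets instead.
    pidx = np.flatnonzero(present)
    first, second = pidx[0], pidx[1]
    lead_slope = (on[second] - on[first]) / (bi[second] - bi[first])
    before = np.arange(len(on)) < first
    filled[before] = on[first] + lead_slope * (bi[before] - bi[first])
    last, penult = pidx[-1], pidx[-2]
    trail_slope = (on[last] - on[penult]) / (bi[last] - bi[penult])
    after = np.arange(len(on)) > last
    filled[after] = on[last] + trail_slope * (bi[after] - bi[last])
    flags = track.interpolated | ~present
    return replace(track, onset_s=filled, interpolated=flags)


def compute_tempo(track: BeatTrack) -> TempoSummary:
    """Summarise the inter-beat intervals of a complete beat track.

    SD uses the sample (n-1) denominator.
    """
    if not track.is_complete:
        raise ValueError("beat track has missing onsets; interpolate first")
    if len(track) < 2:
        raise ValueError("need at least two onsets to form an interval")
    ibis = np.diff(track.onset_s)
    sd = float(np.std(ibis, ddof=1)) if len(ibis) > 1 else 0.0
    return TempoSummary(
        mean_ibi_s=float(np.mean(ibis)),
        sd_ibi_s=sd,
        min_ibi_s=float(np.min(ibis)),
        max_ibi_s=float(np.max(ibis)),
    )


def phrase_levels(tempo: TempoSummary, beats_per_bar: int) -> PhraseLevelSet:
    """Duration of each phrase level: mean IBI x beats-per-bar x bars."""
    if beats_per_bar < 1:
        raise ValueError("beats_per_bar must be >= 1")
    return PhraseLevelSet(
        {
            lv: tempo.mean_ibi_s * beats_per_bar * BARS_PER_LEVEL[lv]
            for lv in LEVELS
        }
    )


def make_bands(
    levels: PhraseLevelSet,
    broadband: tuple[float, float],
    half_width_log2: float = 0.25,
) -> list[BandSpec]:
    """Build non-overlapping period bands around the phrase-level durations.

    Each band starts as duration x 2**(+/- half_width_log2), is clipped so
    neighbouring bands meet at most at the geometric midpoint of their
    durations, and is clipped to the broadband.  Adjacent bands therefore
    intersect in at most a boundary point and each contains its duration.
    """
    low_bb, high_bb = broadband
    if not (0 < low_bb < high_bb):
        raise ValueError("broadband must satisfy 0 < low < high")
    if half_width_log2 <= 0:
        raise ValueError("half_width_log2 must be > 0")
    durations = [levels[lv] for lv in LEVELS]
    for lv, d in zip(LEVELS, durations):
        if not (low_bb <= d <= high_bb):
            raise ValueError(
                f"phrase level {lv!r} duration {d:.3g} s outside broadband "
                f"[{low_bb:g}, {high_bb:g}] s"
            )
    bands = []
    for i, (lv, d) in enumerate(zip(LEVELS, durations)):
        lo = d * 2.0 ** (-half_width_log2)
        hi = d * 2.0 ** (half_width_log2)
        if i > 0:
            lo = max(lo, float(np.sqrt(d * durations[i - 1])))
        if i < len(durations) - 1:
            hi = min(hi, float(np.sqrt(d * durations[i + 1])))
        lo = max(lo, low_bb)
        hi = min(hi, high_bb)
        bands.append(BandSpec(level=lv, period_low_s=lo, period_high_s=hi, center_s=d))
    return bands
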