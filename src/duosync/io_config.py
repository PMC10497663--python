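"""Tabular input/output, session metadata, and run bookkeeping.

All on-disk formats are plain text: long-format CSV for marker
trajectories (time_s, performer, marker, x_mm, y_mm, z_mm), CSV for beat
onsets and section annotations, YAML for session manifests, JSON for run
metadata.  Readers validate and reject malformed input rather than
silently repairing it; read(write(x)) == x at value level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinematics import MarkerTrajectory
from .tempo import BeatTrack

__all__ = [
    "SessionManifest",
    "SectionAnnotation",
    "read_marker_table",
    "write_marker_table",
    "read_beat_table",
    "write_beat_table",
    "read_section_table",
    "write_section_table",
    "read_manifest",
    "write_manifest",
    "write_results",
]

log = logging.getLogger("duosync.io")

EPT_GROUPS = ("LL", "HH", "LH", "HL")

#: Relative sampling jitter tolerated before a trajectory is rejected.
JITTER_TOL = 1e-6

MARKER_COLUMNS = ["time_s", "performer", "marker", "x_mm", "y_mm", "z_mm"]


@dataclass(frozen=True)
class SessionManifest:
    """Metadata of one recorded take of one duo.

    ``meter_beats_per_bar`` counts beats at the 1/8-note level (12 for a
    12/8 piece, 2 for a 2/8 piece).  EPT is the empathic perspective
    taking score of each musician (0-28); ``ept_group`` encodes the
    low/high pairing of the pianist and singer.  The broadband is the
    period range (seconds) analysed by the wavelet stage.
    """

    duo_id: str
    piece: str
    take: int
    pianist_ept: int
    singer_ept: int
    ept_group: str
    meter_beats_per_bar: int
    broadband_low_s: float
    broadband_high_s: float

    def __post_init__(self) -> None:
        if self.take < 0:
            raise ValueError("take must be >= 0")
        for name in ("pianist_ept", "singer_ept"):
            v = getattr(self, name)
            if not (0 <= v <= 28):
                raise ValueError(f"{name} must lie in 0..28, got {v}")
        if self.ept_group not in EPT_GROUPS:
            raise ValueError(f"ept_group must be one of {EPT_GROUPS}")
        if self.meter_beats_per_bar < 1:
            raise ValueError("meter_beats_per_bar must be positive")
        if not (0 < self.broadband_low_s < self.broadband_high_s):
            raise ValueError("require 0 < broadband_low_s < broadband_high_s")

    @property
    def broadband(self) -> tuple[float, float]:
        return (self.broadband_low_s, self.broadband_high_s)


@dataclass(frozen=True)
class SectionAnnotation:
    """One formal section of a piece, in score beats, half-open."""

    label: str
    start_beat: int
    end_beat: int
    solo: bool

    def __post_init__(self) -> None:
        if self.start_beat >= self.end_beat:
            raise ValueError(f"section {self.label!r} has non-positive extent")


def validate_sections(sections: list[SectionAnnotation]) -> None:
    """Check sections are ordered, non-overlapping, and contiguous."""
    for a, b in zip(sections, sections[1:]):
        if a.end_beat != b.start_beat:
            raise ValueError(
                f"sections {a.label!r} and {b.label!r} are not contiguous"
            )


def read_marker_table(path, manifest: SessionManifest | None = None) -> list[MarkerTrajectory]:
    """Read a long-format trajectory CSV into one trajectory per marker.

    The sampling rate is inferred from the time column of each
    (performer, marker) group and must be uniform to within ``JITTER_TOL``
    relative jitter.  Non-monotonic time stamps are rejected with the
    offending row index.
    """
    df = pd.read_csv(path)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table missing columns {missing}")
    trajs = []
    for (performer, marker), grp in df.groupby(["performer", "marker"], sort=True):
        t = grp["time_s"].to_numpy(dtype=float)
        dts = np.diff(t)
        bad = np.flatnonzero(dts <= 0)
        if bad.size:
            row = grp.index[bad[0] + 1]
            raise ValueError(
                f"non-monotonic time for ({performer}, {marker}) at input row {row}"
            )
        dt = float(np.median(dts))
        jitter = np.abs(dts - dt)
        worst = int(np.argmax(jitter))
        if jitter[worst] > JITTER_TOL * dt:
            raise ValueError(
                f"irregular sampling for ({performer}, {marker}): gap of "
                f"{dts[worst]:g} s at input row {grp.index[worst + 1]} "
                f"(nominal step {dt:g} s)"
            )
        trajs.append(
            MarkerTrajectory(
                performer=str(performer),
                marker=str(marker),
                fs=1.0 / dt,
                positions=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            )
        )
    return trajs


def write_marker_table(trajs: list[MarkerTrajectory], path) -> None:
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.times_s,
                    "performer": tr.performer,
                    "marker": tr.marker,
                    "x_mm": tr.positions[:, 0],
                    "y_mm": tr.positions[:, 1],
                    "z_mm": tr.positions[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_beat_table(path) -> BeatTrack:
    """Read a beat-onset CSV, preserving missing onsets as NaN."""
    df = pd.read_csv(path)
    for col in ("beat_index", "onset_s"):
        if col not in df.columns:
            raise ValueError(f"beat table missing column {col!r}")
    bi = df["beat_index"].to_numpy(dtype=int)
    on = df["onset_s"].to_numpy(dtype=float)
    if len(bi) and not np.array_equal(bi, np.arange(bi[0], bi[0] + len(bi))):
        raise ValueError("beat_index must be consecutive integers without gaps")
    present = on[~np.isnan(on)]
    dec = np.flatnonzero(np.diff(present) < 0)
    if dec.size:
        raise ValueError("present onsets must be non-decreasing")
    return BeatTrack(beat_index=bi, onset_s=on)


def write_beat_table(track: BeatTrack, path) -> None:
    pd.DataFrame({"beat_index": track.beat_index, "onset_s": track.onset_s}).to_csv(
        path, index=False
    )


def read_section_table(path) -> list[SectionAnnotation]:
    df = pd.read_csv(path)
    for col in ("label", "start_beat", "end_beat", "solo"):
        if col not in df.columns:
            raise ValueError(f"section table missing column {col!r}")
    sections = [
        SectionAnnotation(
            label=str(r.label),
            start_beat=int(r.start_beat),
            end_beat=int(r.end_beat),
            solo=bool(r.solo),
        )
        for r in df.itertuples()
    ]
    validate_sections(sections)
    return sections


def write_section_table(sections: list[SectionAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "label": s.label,
                "start_beat": s.start_beat,
                "end_beat": s.end_beat,
                "solo": int(s.solo),
            }
            for s in sections
        ]
    ).to_csv(path, index=False)


def read_manifest(path) -> SessionManifest:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SessionManifest(**data)


def write_manifest(manifest: SessionManifest, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(manifest), fh, sort_keys=False)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir,
    *,
    config: dict | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write result tables as CSV plus a JSON run-metadata sidecar.

    The sidecar records the configuration, the seed, and the software
    version; output is deterministic for a fixed config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
        log.info("wrote %s (%d rows)", p, len(table))
    meta = {
        "software": "duosync",
        "version": __version__,
        "seed": seed,
        "config": config,
        "tables": sorted(t.name for t in written),
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    written.append(meta_path)
    return written
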