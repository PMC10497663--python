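"""Pipeline orchestration: tempo -> kinematics -> xwt -> coordination -> stats.

A run is driven by a :class:`RunConfig` whose tunables default to the
package's documented choices (Morlet omega0 = 6, dj = 1/20, band
half-width 0.25 octaves, no COI masking, no standardization, modulus
power, path-length QoM).  Each stage error aborts with the stage name and
session id attached.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coordination, io_config, kinematics, stats_models, tempo, xwt
from .synthetic_data import (
    CohortSpec,
    DuoSession,
    faure_template,
    gen_cohort,
    schumann_template,
)

__all__ = ["RunConfig", "PipelineError", "analyze_session", "analyze_cohort",
           "run_pipeline", "simulate_cohort"]

log = logging.getLogger("duosync.pipeline")

TEMPLATES = {"faure": faure_template, "schumann": schumann_template}


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage and session."""

    def __init__(self, stage: str, session_id: str, original: Exception):
        super().__init__(f"stage {stage!r} failed for session {session_id!r}: {original}")
        self.stage = stage
        self.session_id = session_id
        self.original = original


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run."""

    seed: int = 0
    out_dir: str = "results"
    omega0: float = 6.0
    dj: float = 1.0 / 20.0
    band_half_width_log2: float = 0.25
    coi_mask: bool = False
    standardize: bool = False
    power_squared: bool = False
    qom_mode: str = "path_length"
    sg_window: int = 25
    sg_polyorder: int = 3
    # cohort simulation settings (used by `simulate` / synthetic runs)
    piece: str = "schumann"
    n_duos: int = 24
    n_bars: int | None = None
    fs: float | None = None
    ept_range: tuple[int, int] = (13, 28)
    lead_slope: float = 0.01
    noise_sd: float = 2.0
    dominant_level: str = "two"
    amplitude: float = 10.0
    drift_fraction: float = 0.02
    missing_rate: float = 0.0
    n_markers_per_performer: int = 1

    def __post_init__(self) -> None:
        if self.piece not in TEMPLATES:
            raise ValueError(f"piece must be one of {sorted(TEMPLATES)}")
        if self.qom_mode not in ("path_length", "mean_speed"):
            raise ValueError("qom_mode must be 'path_length' or 'mean_speed'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ept_range" in data:
            data["ept_range"] = tuple(data["ept_range"])
        return cls(**data)


@dataclass
class SessionResult:
    """Everything the pipeline derives from one session."""

    manifest: io_config.SessionManifest
    tempo: tempo.TempoSummary
    levels: tempo.PhraseLevelSet
    bands: list[tempo.BandSpec]
    curve: np.ndarray  # time-averaged power by period
    periods_s: np.ndarray
    peaks: list[tuple[float, float]]
    aggregates: list[coordination.BandAggregate]
    dominant: str
    section_table: pd.DataFrame
    qom_mean: float
    field: xwt.XwtField | None = None


def _stage(stage: str, session_id: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, session_id, exc) from exc
            log.info("%s [%s]: %.2f s", stage, session_id, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def analyze_session(session: DuoSession, config: RunConfig, *, keep_field: bool = False) -> SessionResult:
    """Run the full per-session analysis chain."""
    man = session.manifest
    sid = f"{man.duo_id}/{man.piece}/take{man.take}"
    with _stage("tempo", sid):
        track = tempo.interpolate_missing_beats(session.beat_track)
        summary = tempo.compute_tempo(track)
        levels = tempo.phrase_levels(summary, man.meter_beats_per_bar)
        bands = tempo.make_bands(levels, man.broadband, config.band_half_width_log2)
    with _stage("kinematics", sid):
        def front_head_speed(trajs):
            tr = next(t for t in trajs if t.marker == kinematics.FRONT_HEAD)
            return kinematics.traj_speed(tr, config.sg_window, config.sg_polyorder)

        sp_p = front_head_speed(session.pianist_trajs)
        sp_s = front_head_speed(session.singer_trajs)
        all_speeds = [
            kinematics.traj_speed(t, config.sg_window, config.sg_polyorder)
            for t in (*session.pianist_trajs, *session.singer_trajs)
            if "hip" not in t.marker
        ]
        qom = kinematics.quantity_of_motion(all_speeds, man.duo_id, mode=config.qom_mode)
    with _stage("xwt", sid):
        grid = xwt.ScaleGrid.from_range(
            man.broadband_low_s, man.broadband_high_s, dj=config.dj, omega0=config.omega0
        )
        field_ = xwt.cross_wavelet(
            sp_p, sp_s, grid,
            power_squared=config.power_squared,
            standardize=config.standardize,
        )
    with _stage("coordination", sid):
        curve = xwt.time_average_power(field_, exclude_coi=config.coi_mask)
        finite = np.isfinite(curve)
        peaks = coordination.find_top_peaks(grid.periods_s[finite], curve[finite])
        aggregates = [coordination.band_aggregate(field_, b) for b in bands]
        dominant = coordination.dominant_level(aggregates)
        section_table = coordination.segment_aggregate(
            field_, bands, session.sections, track
        )
    return SessionResult(
        manifest=man,
        tempo=summary,
        levels=levels,
        bands=bands,
        curve=curve,
        periods_s=grid.periods_s,
        peaks=peaks,
        aggregates=aggregates,
        dominant=dominant,
        section_table=section_table,
        qom_mean=float(np.mean(qom.values)),
        field=field_ if keep_field else None,
    )


def _band_for(result: SessionResult, level: str) -> tempo.BandSpec:
    return next(b for b in result.bands if b.level == level)


def analyze_cohort(
    sessions: list[DuoSession], config: RunConfig
) -> dict[str, pd.DataFrame]:
    """Per-session analyses plus cohort-level tables.

    Returns tables: ``aggregates`` (one row per session x band),
    ``dominant`` (one row per session, at its dominant level, with EPT
    covariates and QoM), ``peak_occurrence``, ``sections``.
    """
    agg_rows, dom_rows, sec_frames = [], [], []
    peaks_all, bands_all = [], []
    for session in sessions:
        res = analyze_session(session, config)
        man = res.manifest
        meta = {
            "duo_id": man.duo_id,
            "piece": man.piece,
            "take": man.take,
            "pianist_ept": man.pianist_ept,
            "singer_ept": man.singer_ept,
            "ept_group": man.ept_group,
        }
        for agg in res.aggregates:
            agg_rows.append({**meta, **vars(agg)})
        dom = next(a for a in res.aggregates if a.level == res.dominant)
        dom_rows.append(
            {
                **meta,
                "dominant_level": res.dominant,
                "mean_power": dom.mean_power,
                "phase_ms": dom.phase_ms,
                "mean_phase_rad": dom.mean_phase_rad,
                "leadership": dom.leadership,
                "qom": res.qom_mean,
            }
        )
        peaks_all.append(res.peaks)
        bands_all.append(res.bands)
        sec = res.section_table.copy()
        for k, v in meta.items():
            sec[k] = v
        sec_frames.append(sec)
    return {
        "aggregates": pd.DataFrame(agg_rows),
        "dominant": pd.DataFrame(dom_rows),
        "peak_occurrence": coordination.tabulate_peak_occurrence(peaks_all, bands_all),
        "sections": pd.concat(sec_frames, ignore_index=True),
    }


def fit_cohort_models(tables: dict[str, pd.DataFrame]) -> dict[str, stats_models.ModelFit]:
    """Fit the model battery supported by the cohort tables.

    Nested take terms are included only when the table actually has more
    than one take (a single-take cohort would make them aliased).
    """
    fits: dict[str, stats_models.ModelFit] = {}
    agg = tables["aggregates"].rename(columns={"level": "phrase_level"})
    multi_take = agg["take"].nunique() > 1
    lvl_term = "phrase_level/take" if multi_take else "phrase_level"
    fits["power_by_level"] = stats_models.fit_model(
        stats_models.ModelSpec(
            response="mean_power",
            fixed=(lvl_term,),
            random_intercept="duo_id",
            categorical=("phrase_level", "take"),
            baselines={"phrase_level": "four", "take": 0},
        ),
        agg,
    )
    fits["phase_by_level"] = stats_models.fit_model(
        stats_models.ModelSpec(
            response="phase_ms",
            fixed=(lvl_term,),
            random_intercept="duo_id",
            categorical=("phrase_level", "take"),
            baselines={"phrase_level": "four", "take": 0},
        ),
        agg,
    )
    dom = tables["dominant"]
    # EPT models need residual degrees of freedom beyond their 3 parameters
    if len(dom) >= 5:
        fits["phase_by_ept"] = stats_models.fit_model(
            stats_models.ModelSpec(
                response="phase_ms", fixed=("pianist_ept", "singer_ept")
            ),
            dom,
        )
    if dom["ept_group"].nunique() >= 2 and len(dom) > dom["ept_group"].nunique() + 1:
        fits["power_by_ept_group"] = stats_models.fit_model(
            stats_models.ModelSpec(
                response="mean_power", fixed=("ept_group",), categorical=("ept_group",)
            ),
            dom,
        )
    if len(dom) >= 5:
        qom_fixed = ["pianist_ept", "singer_ept"]
        if dom["piece"].nunique() > 1:
            qom_fixed.append("piece/take" if multi_take else "piece")
        elif multi_take:
            qom_fixed.append("take")
        fits["qom_by_ept"] = stats_models.fit_model(
            stats_models.ModelSpec(
                response="qom",
                fixed=tuple(qom_fixed),
                categorical=("piece", "take"),
                baselines={"piece": "faure", "take": 0},
            ),
            dom,
        )
    return fits


def simulate_cohort(config: RunConfig) -> tuple[list[DuoSession], pd.DataFrame]:
    """Build the synthetic cohort described by a run configuration."""
    template = TEMPLATES[config.piece]()
    overrides = {}
    if config.n_bars is not None:
        overrides["n_bars"] = config.n_bars
    if config.fs is not None:
        overrides["fs"] = config.fs
    if overrides:
        template = TEMPLATES[config.piece](**overrides)
    spec = CohortSpec(
        n_duos=config.n_duos,
        ept_range=config.ept_range,
        lead_slope=config.lead_slope,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    return gen_cohort(
        spec,
        template,
        dominant_level=config.dominant_level,
        amplitude=config.amplitude,
        drift_fraction=config.drift_fraction,
        missing_rate=config.missing_rate,
        n_markers_per_performer=config.n_markers_per_performer,
    )


def run_pipeline(config: RunConfig) -> dict:
    """One-command synthetic end-to-end run: simulate, analyze, fit, write."""
    sessions, truth = simulate_cohort(config)
    tables = analyze_cohort(sessions, config)
    fits = fit_cohort_models(tables)
    model_rows = []
    for name, fit in fits.items():
        frame = fit.summary_frame().reset_index(names="term")
        frame.insert(0, "model", name)
        frame["marginal_r2"] = fit.marginal_r2
        frame["conditional_r2"] = fit.conditional_r2
        frame["ols_fallback"] = fit.used_ols_fallback
        model_rows.append(frame)
    tables_out = {
        **tables,
        "ground_truth": truth,
        "model_summaries": pd.concat(model_rows, ignore_index=True),
    }
    io_config.write_results(
        tables_out, Path(config.out_dir), config=asdict(config), seed=config.seed
    )
    return {"tables": tables_out, "fits": fits, "sessions": sessions}
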