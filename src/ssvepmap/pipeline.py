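"""End-to-end orchestration: simulate -> gate -> filter -> score -> tables.

A :class:`PipelineConfig` holds every module's parameters with defaults that
reproduce the reference paradigm (15 Hz flicker, M = 3 harmonics, 500 Hz EEG,
4 s epochs, 50 Hz notch, 4-35 Hz band, 1.5 deg fixation ring, 12 runs, 46
stimuli, 31 channels, 11-channel occipito-parietal scoring subset, alpha
0.05).  :func:`run_pipeline` produces the response table, competitive-effect
error-rate table, layer means, retinotopic surfaces, channel-contribution
maps, contralateral scores, and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cca import build_reference
from .layout import StimulusLayout, build_layout
from .montage import ANALYSIS_SUBSET, SYMMETRIC_PAIRS, Montage, standard_montage
from .preprocess import FilterSpec, apply_filters
from .retinotopy import (
    ANGLES,
    ResponseTable,
    error_rate_table,
    layer_average,
    response_map,
    surface_grid,
)
from .simulate import (
    EEG_FS,
    TRIAL_DURATION_S,
    Session,
    SimParams,
    participant_params,
    simulate_session,
)
from .topography import contribution_map, contralateral_table, single_channel_table

__all__ = ["PipelineConfig", "PipelineResult", "validate_config", "run_pipeline",
           "score_session"]

log = logging.getLogger("ssvepmap")


@dataclass
class PipelineConfig:
    # stimulus geometry
    layer_spacing: float = 2.0
    flicker_diameter: float = 3.0
    ring_counts: tuple[int, ...] = (3, 6, 9, 12, 15)
    angular_offsets: tuple[float, ...] | None = None
    # acquisition / protocol
    fs_eeg: float = EEG_FS
    duration_s: float = TRIAL_DURATION_S
    n_runs: int = 12
    n_participants: int = 8
    ring_radius: float = 1.5
    # scoring
    f0: float = 15.0
    n_harmonics: int = 3
    analysis_channels: tuple[str, ...] = ANALYSIS_SUBSET
    pairs: tuple[tuple[str, str], ...] = SYMMETRIC_PAIRS
    error_rate_variant: str = "runwise"
    alpha: float = 0.05
    compute_contributions: bool = True
    compute_surfaces: bool = True
    surface_resolution: float = 0.5
    # sub-configs
    sim: SimParams = field(default_factory=SimParams)
    filter: FilterSpec = field(default_factory=FilterSpec)

    @property
    def seed(self) -> int:
        return self.sim.seed

    def layout(self) -> StimulusLayout:
        return build_layout(self.layer_spacing, self.flicker_diameter,
                            self.ring_counts, self.angular_offsets)

    def montage(self) -> Montage:
        return standard_montage()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            for key in ("harmonic_decay", "phases"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimParams(**sim)
        if "filter" in d and isinstance(d["filter"], dict):
            f = dict(d["filter"])
            if "band" in f:
                f["band"] = tuple(f["band"])
            d["filter"] = FilterSpec(**f)
        for key in ("ring_counts", "analysis_channels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("angular_offsets") is not None:
            d["angular_offsets"] = tuple(d["angular_offsets"])
        if "pairs" in d and d["pairs"] is not None:
            d["pairs"] = tuple(tuple(p) for p in d["pairs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def validate_config(config: PipelineConfig) -> list[str]:
    """Return human-readable invariant violations (empty list means OK)."""
    v: list[str] = []
    montage = config.montage()
    if config.n_harmonics * config.f0 >= config.fs_eeg / 2:
        v.append(
            f"n_harmonics * f0 = {config.n_harmonics * config.f0:g} Hz reaches "
            f"Nyquist ({config.fs_eeg / 2:g} Hz)"
        )
    unknown = [ch for ch in config.analysis_channels if ch not in montage.labels]
    if unknown:
        v.append(f"analysis_channels not in montage: {unknown}")
    for pair in config.pairs:
        for ch in pair:
            if ch not in montage.labels:
                v.append(f"pair channel {ch!r} not in montage")
    lo, hi = config.filter.band
    if config.fs_eeg <= 2 * hi:
        v.append(f"fs_eeg {config.fs_eeg} Hz too low for bandpass {config.filter.band}")
    if not (config.f0 >= lo and config.f0 <= hi):
        v.append(f"f0 {config.f0} Hz outside the analysis band {config.filter.band}")
    if config.ring_radius <= 0:
        v.append("ring_radius must be positive")
    if config.n_runs < 1 or config.n_participants < 1:
        v.append("n_runs and n_participants must be >= 1")
    if config.error_rate_variant not in ("runwise", "pooled"):
        v.append(f"unknown error_rate_variant {config.error_rate_variant!r}")
    try:
        config.layout()
    except Exception as exc:  # geometry errors surface as violations
        v.append(f"layout: {exc}")
    return v


@dataclass
class PipelineResult:
    response_table: ResponseTable
    error_table: pd.DataFrame
    layer_means: pd.Series
    position_maps: dict
    surfaces: dict
    contributions: dict
    single_channel: dict
    contralateral: pd.DataFrame
    manifest: dict


def _pair_channels(pairs) -> list[str]:
    out: list[str] = []
    for pair in pairs:
        for ch in pair:
            if ch not in out:
                out.append(ch)
    return out


def score_session(
    session: Session,
    config: PipelineConfig,
    layout: StimulusLayout,
    montage: Montage,
):
    """Filter and CCA-score one session.

    Returns (response_records, single_channel_responses, contributions):
    response records on the analysis subset per valid trial, run-averaged
    single-channel responses for the pair channels (stimuli x channels), and
    the channel-contribution map (or None if disabled).
    """
    n = int(round(config.duration_s * config.fs_eeg))
    Y = build_reference(config.f0, config.n_harmonics, config.fs_eeg, n)
    subset = montage.indices(config.analysis_channels)

    def pre(epoch):
        return apply_filters(epoch, config.fs_eeg, config.filter)

    records = []
    filtered = Session(participant=session.participant, trials=[],
                       fs_eeg=session.fs_eeg, fs_gaze=session.fs_gaze)
    from .cca import cca_coefficient  # local import avoids cycle at module load

    for trial in session.valid_trials():
        epoch = pre(np.asarray(trial.eeg, dtype=float))
        ftrial = dataclasses.replace(trial, eeg=epoch)
        filtered.trials.append(ftrial)
        R = cca_coefficient(epoch[subset], Y).R
        records.append((session.participant, trial.run, trial.stimulus, R))

    single = single_channel_table(filtered, Y, montage, _pair_channels(config.pairs))
    contrib = None
    if config.compute_contributions:
        contrib = contribution_map(filtered, Y, montage)
    return records, single, contrib


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Simulate and analyze ``n_participants`` sessions under one config.

    Deterministic under a fixed ``config.sim.seed``; per-participant seeds
    are derived from it.  If ``outdir`` is given, all tables, the resolved
    config, and the run manifest are written there as delimited text/JSON.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    layout = config.layout()
    montage = config.montage()

    all_records: list[tuple] = []
    single_by_p: dict = {}
    contrib_by_p: dict = {}
    counts: dict = {}
    for p_idx in range(config.n_participants):
        pid = f"S{p_idx + 1}"
        params = participant_params(config.sim, p_idx)
        log.info("simulating %s (seed %d)", pid, params.seed)
        session = simulate_session(params, layout, montage,
                                   n_runs=config.n_runs, participant=pid,
                                   ring_radius=config.ring_radius)
        counts[pid] = dict(valid=session.n_valid, rejected=session.n_rejected)
        log.info("%s: %d valid / %d rejected trials; scoring",
                 pid, session.n_valid, session.n_rejected)
        records, single, contrib = score_session(session, config, layout, montage)
        all_records.extend(records)
        single_by_p[pid] = single
        if contrib is not None:
            contrib_by_p[pid] = contrib
        del session

    table = ResponseTable.from_records(all_records)
    maps = {p: response_map(table, p, layout) for p in table.participants}
    layer_means = layer_average(maps, layout)
    err = error_rate_table(table, layout, angles=[
        d for d in ANGLES if d <= layout.layer_radii[-1] + 1e-9
    ], variant=config.error_rate_variant)

    surfaces = {}
    if config.compute_surfaces:
        for p, m in maps.items():
            surfaces[p] = surface_grid(m, layout, config.surface_resolution)

    # per-hemisphere normalization by the central stimulus, then pooled
    normalized = {}
    for pid, single in single_by_p.items():
        normalized[pid] = single / single.loc[1]
    pooled = pd.concat(normalized.values()).groupby(level=0).mean()
    angles = [d for d in ANGLES if d <= layout.layer_radii[-1] + 1e-9]
    contra = contralateral_table(pooled, layout, pairs=config.pairs,
                                 angles=angles, alpha=config.alpha)

    manifest = dict(
        package_version=__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        config=config.to_dict(),
        trial_counts=counts,
        n_valid_total=sum(c["valid"] for c in counts.values()),
        n_rejected_total=sum(c["rejected"] for c in counts.values()),
    )

    result = PipelineResult(
        response_table=table, error_table=err, layer_means=layer_means,
        position_maps=maps, surfaces=surfaces, contributions=contrib_by_p,
        single_channel=single_by_p, contralateral=contra, manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, config, outdir)
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    result.response_table.data.to_csv(
        os.path.join(outdir, "response_table.csv"), index=False)
    result.error_table.to_csv(os.path.join(outdir, "error_rate_table.csv"))
    result.layer_means.rename("mean_response").rename_axis("layer").to_csv(
        os.path.join(outdir, "layer_means.csv"))
    for pid, (xs, ys, grid) in result.surfaces.items():
        path = os.path.join(outdir, f"surface_{pid}.csv")
        with open(path, "w") as fh:
            fh.write("# x_deg=" + ",".join(f"{v:g}" for v in xs) + "\n")
            fh.write("# y_deg=" + ",".join(f"{v:g}" for v in ys) + "\n")
            np.savetxt(fh, grid, delimiter=",")
    for pid, contrib in result.contributions.items():
        contrib.to_csv(os.path.join(outdir, f"contributions_{pid}.csv"))
    result.contralateral.to_csv(os.path.join(outdir, "contralateral.csv"), index=False)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
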