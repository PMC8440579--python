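"""End-to-end orchestration: configuration, stage bookkeeping, pipelines.

``run_lifetime`` chains spot detection → track linking → consensus merge →
mask filter → trace extraction → HMM dwell segmentation → event filtering
→ truncated-exponential lifetime fit.  ``run_rings`` chains cell-length
measurement → midline profiles → ring detection → frequency and
averaged-width summaries.  Every stage's kept/dropped counts land in a
:class:`RunReport` (kept + dropped = input, asserted), and a single global
seed fans out deterministically to per-trace HMM restarts and to the
bootstrap, so identical (inputs, config, seed) give identical outputs.

The default configuration is the analysis recipe used throughout:
1.5-px detection radius, 3-px linking distance, 10-frame gap, 5x5 window
with a 2-px background frame, 500-count trace filter, 60-count state
separation, 2-s minimum dwell, 2-event trace limit, 2-s truncation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import dwell as dwell_mod
from . import rings as rings_mod
from . import spots as spots_mod
from . import traces as traces_mod
from .lifetime import LifetimeResults, TruncatedExponentialModel


class NoEventsError(RuntimeError):
    """Raised when a lifetime run ends with zero accepted dwell events."""

    def __init__(self, report: "RunReport"):
        super().__init__(
            "no accepted dwell events; stage counts: "
            + json.dumps(report.stages, default=str)
        )
        self.report = report


@dataclass
class DetectionConfig:
    radius_px: float = 1.5
    threshold: float = 50.0  # detector response; dataset-dependent, set in config


@dataclass
class LinkingConfig:
    max_link_px: float = 3.0
    max_gap_frames: int = 10


@dataclass
class TraceConfig:
    window_px: int = 5
    bg_frame_px: int = 2
    min_peak_counts: float = 500.0


@dataclass
class DwellConfig:
    orders: tuple[int, ...] = (1, 2, 3, 4)
    n_restarts: int = 5
    min_state_sep_counts: float = 60.0
    min_dwell_s: float = 2.0
    max_events_per_trace: int = 2


@dataclass
class LifetimeConfig:
    truncation_s: float = 2.0
    n_boot: int = 10_000


@dataclass
class RingsConfig:
    smooth_window_um: float = 0.3
    min_prominence: float = 50.0
    region_halfwidth_um: float = 0.5
    transverse_halfwidth_px: float = 4.0


@dataclass
class PipelineConfig:
    """All tunables of the analysis, serializable round-trip stable."""

    frame_interval_s: float = 0.5
    pixel_size_um: float = 0.1
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    trace: TraceConfig = field(default_factory=TraceConfig)
    dwell: DwellConfig = field(default_factory=DwellConfig)
    lifetime: LifetimeConfig = field(default_factory=LifetimeConfig)
    rings: RingsConfig = field(default_factory=RingsConfig)

    @classmethod
    def paper_defaults(cls, **overrides) -> "PipelineConfig":
        """The canonical single-molecule analysis recipe; every default
        above IS that recipe, so this is an alias that accepts top-level
        overrides."""
        return dataclasses.replace(cls(), **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs: dict = {}
        blocks = {
            "detection": DetectionConfig,
            "linking": LinkingConfig,
            "trace": TraceConfig,
            "dwell": DwellConfig,
            "lifetime": LifetimeConfig,
            "rings": RingsConfig,
        }
        for key, value in data.items():
            if key in blocks:
                if key == "dwell" and "orders" in value:
                    value = {**value, "orders": tuple(value["orders"])}
                kwargs[key] = blocks[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Stage-by-stage record counts, rejection reasons, seed and config."""

    seed: int
    config_hash: str
    stages: dict = field(default_factory=dict)

    def add(self, stage: str, **counts) -> None:
        self.stages[stage] = counts
        kept, dropped, n_in = (counts.get(k) for k in ("kept", "dropped", "input"))
        if kept is not None and dropped is not None and n_in is not None:
            assert kept + dropped == n_in, f"count leak at stage {stage}"

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_image(source) -> np.ndarray:
    if isinstance(source, (str, Path)):
        return tifffile.imread(str(source))
    return np.asarray(source)


def _trace_seed(seed: int, spot_id: int) -> int:
    return int(np.random.SeedSequence([seed, spot_id]).generate_state(1)[0] % 2**31)


def run_lifetime(
    movie,
    mask,
    config: PipelineConfig | None = None,
    seed: int = 0,
    log=None,
) -> tuple[LifetimeResults, RunReport, dict]:
    """Full single-molecule lifetime pipeline on one movie.

    ``movie`` and ``mask`` may be arrays or TIFF paths.  Returns the
    lifetime fit, the run report, and a dict of intermediate tables
    (tracks, spots, traces, events, accepted dwell durations).  Raises
    :class:`NoEventsError` when nothing survives the filters.
    """
    cfg = config or PipelineConfig()
    movie = _load_image(movie).astype(float)
    mask = _load_image(mask)
    if movie.ndim == 2:
        movie = movie[None]
    if mask.shape != movie.shape[1:]:
        raise ValueError("mask shape does not match movie frames")
    report = RunReport(seed=int(seed), config_hash=cfg.hash())

    def _log(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    dets = spots_mod.detect_spots_movie(movie, cfg.detection.radius_px, cfg.detection.threshold)
    n_dets = sum(len(d) for d in dets)
    report.add("detect", detections=n_dets, frames=len(dets))
    _log(f"detect: {n_dets} detections in {len(dets)} frames")

    tracks = spots_mod.link_spots(dets, cfg.linking.max_link_px, cfg.linking.max_gap_frames)
    report.add("link", input=n_dets, kept=sum(t.length for t in tracks), dropped=0, tracks=len(tracks))

    consensus = spots_mod.merge_tracks(tracks, cfg.linking.max_link_px)
    in_cells = spots_mod.filter_by_mask(consensus, mask)
    report.add(
        "merge_and_mask",
        input=len(consensus),
        kept=len(in_cells),
        dropped=len(consensus) - len(in_cells),
    )
    _log(f"spots: {len(consensus)} consensus, {len(in_cells)} inside cells")

    all_traces = traces_mod.extract_traces(
        movie,
        in_cells,
        cfg.frame_interval_s,
        cfg.trace.window_px,
        cfg.trace.bg_frame_px,
        drop_clipped=True,
    )
    bright = traces_mod.filter_traces(all_traces, cfg.trace.min_peak_counts)
    report.add(
        "traces",
        input=len(in_cells),
        kept=len(bright),
        dropped=len(in_cells) - len(bright),
        dropped_clipped=len(in_cells) - len(all_traces),
        dropped_dim=len(all_traces) - len(bright),
    )
    _log(f"traces: {len(bright)} pass the {cfg.trace.min_peak_counts}-count filter")

    order_counts: dict[int, int] = {k: 0 for k in cfg.dwell.orders}
    events_per_trace: dict[int, list[dwell_mod.DwellEvent]] = {}
    low_sep = 0
    for t in bright:
        fit, _ = dwell_mod.select_model(
            t, cfg.dwell.orders, cfg.dwell.n_restarts, seed=_trace_seed(seed, t.spot_id)
        )
        order_counts[fit.n_states] += 1
        if fit.n_states != 2:
            continue
        evs = dwell_mod.extract_events(
            fit, cfg.frame_interval_s, cfg.dwell.min_state_sep_counts, trace_id=t.spot_id
        )
        if not evs:
            low_sep += 1
            continue
        events_per_trace[t.spot_id] = evs
    report.add(
        "model_selection",
        input=len(bright),
        kept=len(events_per_trace),
        dropped=len(bright) - len(events_per_trace),
        order_counts={str(k): v for k, v in order_counts.items()},
        dropped_low_separation=low_sep,
    )

    accepted, tally = dwell_mod.filter_events(
        events_per_trace, cfg.dwell.min_dwell_s, cfg.dwell.max_events_per_trace
    )
    report.add("events", **tally)
    _log(f"events: {tally['accepted']} accepted of {tally['events_total']}")

    tables = {
        "tracks": spots_mod.tracks_to_frame(tracks),
        "spots": spots_mod.spots_to_frame(in_cells),
        "traces": traces_mod.traces_to_frame(bright),
        "events": dwell_mod.events_to_frame(events_per_trace, accepted),
        "dwells_s": np.array([e.duration_s for e in accepted]),
    }
    if not accepted:
        raise NoEventsError(report)

    boot_seed = _trace_seed(seed, 2**30)
    results = TruncatedExponentialModel.from_events(accepted, cfg.lifetime.truncation_s).fit(
        n_boot=cfg.lifetime.n_boot, seed=boot_seed
    )
    report.add("lifetime", n_events=results.n_events, tau_s=results.tau_s)
    _log(f"lifetime: tau = {results.tau_s:.3f} s from {results.n_events} events")
    return results, report, tables


def run_rings(
    image,
    mask,
    config: PipelineConfig | None = None,
    midlines: dict[int, np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[dict, RunReport]:
    """Z-ring morphometry pipeline on one snapshot.

    Measures cell lengths (excluding edge-touching cells), builds midline
    profiles (supplied midlines or per-label principal axes), detects
    rings, and summarizes ring frequency per µm and the averaged-peak
    FWHM.  Returns ``(summary, report)`` where summary carries frequency,
    width, per-cell and per-ring tables.
    """
    cfg = config or PipelineConfig()
    image = _load_image(image).astype(float)
    mask = _load_image(mask)
    if mask.size == 0 or mask.max() == 0:
        raise ValueError("empty mask: no cells to analyze")
    report = RunReport(seed=int(seed), config_hash=cfg.hash())

    lengths = rings_mod.measure_cell_lengths(mask, cfg.pixel_size_um)
    included = lengths[~lengths["excluded_edge"]].reset_index(drop=True)
    report.add(
        "cells",
        input=len(lengths),
        kept=len(included),
        dropped=int(lengths["excluded_edge"].sum()),
    )

    profiles: dict[int, rings_mod.MidlineProfile] = {}
    calls: list[rings_mod.RingCall] = []
    for cell_id in included["cell_id"]:
        polyline = (
            midlines[cell_id]
            if midlines is not None and cell_id in midlines
            else rings_mod.principal_axis_midline(mask, cell_id)
        )
        profile = rings_mod.midline_profile(
            image,
            mask,
            polyline,
            cell_id,
            cfg.rings.transverse_halfwidth_px,
            cfg.pixel_size_um,
        )
        smoothed = rings_mod.smooth_profile(profile, cfg.rings.smooth_window_um)
        profiles[cell_id] = smoothed
        calls.extend(rings_mod.detect_rings(smoothed, min_prominence=cfg.rings.min_prominence))
    report.add("rings", profiles=len(profiles), ring_calls=len(calls))

    freq = rings_mod.ring_frequency(calls, included)
    width = (
        rings_mod.ring_width_average(
            profiles, calls, cfg.rings.region_halfwidth_um, cfg.rings.smooth_window_um
        )
        if calls
        else None
    )
    summary = {
        "frequency_per_um": freq["frequency_per_um"],
        "n_rings": freq["n_rings"],
        "n_cells": len(included),
        "total_length_um": freq["total_length_um"],
        "mean_length_um": float(included["length_um"].mean()) if len(included) else float("nan"),
        "averaged_fwhm_um": width["averaged_fwhm_um"] if width else float("nan"),
        "per_ring_fwhm_um": width["per_ring_fwhm_um"] if width else np.array([]),
        "cells": lengths,
        "ring_calls": rings_mod.rings_to_frame(calls),
        "position_histogram": rings_mod.ring_position_histogram(calls, included)
        if calls
        else None,
    }
    report.add(
        "summary",
        frequency_per_um=summary["frequency_per_um"],
        averaged_fwhm_um=summary["averaged_fwhm_um"],
    )
    return summary, report


def write_lifetime_outputs(out_dir: str | Path, results, report: RunReport, tables: dict) -> None:
    """Write the standard lifetime-run artifact set into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .lifetime import lifetime_distribution

    (out / "lifetime.json").write_text(json.dumps(results.to_dict(), indent=1))
    report.to_json(out / "run_report.json")
    for name in ("tracks", "spots", "traces", "events"):
        tables[name].to_csv(out / f"{name}.csv", index=False)
    lifetime_distribution(
        results.model.dwells_s, 0.5, results.truncation_s
    ).to_csv(out / "lifetime_hist.csv", index=False)


def write_ring_outputs(out_dir: str | Path, summary: dict, report: RunReport) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary["cells"].to_csv(out / "cells.csv", index=False)
    summary["ring_calls"].to_csv(out / "rings.csv", index=False)
    (out / "ring_summary.json").write_text(
        json.dumps(
            {
                "frequency_per_um": summary["frequency_per_um"],
                "averaged_fwhm_um": summary["averaged_fwhm_um"],
                "n_rings": summary["n_rings"],
                "n_cells": summary["n_cells"],
            },
            indent=1,
        )
    )
    report.to_json(out / "run_report.json")
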