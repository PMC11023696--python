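"""Session orchestration, configuration and file I/O.

Traces travel as two-column CSV (``time_s,<channel>``), stacks as
single-channel TIFF, reports as JSON plus CSV tables.  A session is
described by a TOML config naming the inputs and the analysis parameters;
``run_session`` executes the stage chain appropriate to the inputs present
(stack -> vessel imaging -> events/spectral; trace pair -> spectral ->
phase; eye trace -> HOKR) and writes every artifact with a provenance
record (config hash, package version, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .core import ImageStack, ROI, TraceSeries
from . import events as _events
from . import hokr as _hokr
from . import phase as _phase
from . import spectral as _spectral
from . import vessel as _vessel

__all__ = ["SessionConfig", "SessionReport", "read_trace", "write_trace",
           "read_stack", "write_stack", "run_session", "write_report"]


def read_trace(path, rate_tolerance: float = 0.01) -> TraceSeries:
    """Read a ``time_s,<channel>`` CSV into a TraceSeries.

    The sampling rate is inferred from the median time step; time stamps
    must be monotone and uniform within ``rate_tolerance`` (relative).
    """
    df = pd.read_csv(path)
    if df.shape[1] != 2 or df.columns[0] != "time_s":
        raise ValueError(f"{path}: expected columns 'time_s,<channel>'")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0)) + 2
        raise ValueError(f"{path}: non-monotone time at line {i}")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > rate_tolerance * med):
        i = int(np.argmax(np.abs(dt - med) > rate_tolerance * med)) + 2
        raise ValueError(f"{path}: non-uniform sampling at line {i}")
    return TraceSeries(df.iloc[:, 1].to_numpy(dtype=float), 1.0 / med,
                       channel=str(df.columns[1]), t0=float(t[0]))


def write_trace(trace: TraceSeries, path) -> None:
    pd.DataFrame({"time_s": trace.time,
                  trace.channel or "value": trace.values}).to_csv(path, index=False)


def read_stack(path, pixel_size: float, frame_rate: float,
               channel: str = "") -> ImageStack:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(np.asarray(data, dtype=float), pixel_size, frame_rate, channel)


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(path, stack.data.astype(np.float32))


@dataclass
class SessionConfig:
    """Inputs and parameters of one analysis session."""

    stack_path: str | None = None
    trace_path: str | None = None  # primary fluorescence channel
    trace2_path: str | None = None  # companion (shadow) channel
    eye_path: str | None = None
    out_dir: str = "."
    # stimulus / spectral parameters
    stimulus_frequency: float = 0.25  # Hz
    f0: float = 0.25
    band: tuple = (0.1, 1.0)
    pr_threshold: float = 3.0
    # stack geometry
    pixel_size: float = 1.0
    frame_rate: float = 5.0
    line_rows: tuple = (0, 1)
    left_roi: tuple | None = None  # (y0, y1, x0, x1)
    right_roi: tuple | None = None
    vessel_roi: tuple | None = None
    # detection / filtering
    event_threshold: str = "auto:3"
    eye_band: tuple = (0.1, 0.5)
    saccade_threshold: float = 1.0
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "SessionConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        return cfg

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SessionReport:
    config_hash: str
    version: str
    seed: int
    sections: dict = field(default_factory=dict)  # name -> dict of results
    skipped: list = field(default_factory=list)


def _roi(t) -> ROI:
    return ROI(*t)


def run_session(config: SessionConfig) -> SessionReport:
    """Run every analysis stage the config provides inputs for."""
    report = SessionReport(config.digest(), __version__, config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cycle = 1.0 / config.stimulus_frequency

    diam = None
    if config.stack_path:
        if not (config.left_roi and config.right_roi and config.vessel_roi):
            raise ValueError("stack analysis requires left/right/vessel ROIs")
        try:
            stack = read_stack(config.stack_path, config.pixel_size,
                               config.frame_rate)
            diam, peak = _vessel.diameter_and_peak_series(
                stack, tuple(config.line_rows), _roi(config.left_roi),
                _roi(config.right_roi), _roi(config.vessel_roi))
        except Exception as exc:
            raise RuntimeError(
                f"stage 'vessel' failed for {config.stack_path}: {exc}") from exc
        write_trace(diam, out / "diameter.csv")
        write_trace(peak, out / "peak_intensity.csv")
        evs = _events.detect_events(diam.with_values(diam.values - 100.0),
                                    config.event_threshold)
        summary = _events.summarize_events([evs])
        pd.DataFrame([dataclasses.asdict(e) for e in evs]).to_csv(
            out / "events.csv", index=False)
        report.sections["vessel"] = {
            "n_frames": stack.n_frames,
            "basal_diameter_um_pct": 100.0,
            "n_events": len(evs),
            "mean_interval_s": (float(np.mean(summary.all_intervals))
                                if summary.all_intervals.size else None),
        }
    else:
        report.skipped.append("vessel: not run (no stack input)")

    if config.trace_path:
        try:
            raw = read_trace(config.trace_path)
            pct = _spectral.normalize_percent(raw)
            spec = _spectral.amplitude_spectrum(pct)
            pr = _spectral.peak_ratio(spec, config.f0, tuple(config.band))
        except Exception as exc:
            raise RuntimeError(
                f"stage 'spectral' failed for {config.trace_path}: {exc}") from exc
        pd.DataFrame({"frequency_hz": spec.frequencies,
                      "amplitude_pct": spec.amplitudes}).to_csv(
            out / "spectrum.csv", index=False)
        report.sections["spectral"] = {
            "pr": pr.pr, "peak_amplitude_pct": pr.peak_amplitude,
            "band_mean_pct": pr.band_mean,
            "argmax_hz": float(spec.frequencies[1:][np.argmax(spec.amplitudes[1:])]),
        }
        if config.trace2_path:
            try:
                raw2 = read_trace(config.trace2_path)
                pct2 = _spectral.normalize_percent(raw2)
                dt = _phase.crosscorr_lag(pct, pct2, max_lag=cycle)
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'phase' failed for {config.trace2_path}: {exc}") from exc
            section = {"excluded": dt is None}
            if dt is not None:
                section.update(delta_t_s=dt,
                               phase_deg=_phase.phase_from_lag(dt, cycle))
            report.sections["phase"] = section
        else:
            report.skipped.append("phase: not run (no companion trace)")
    else:
        report.skipped.append("spectral: not run (no trace input)")

    if config.eye_path:
        try:
            eye = read_trace(config.eye_path)
            clean = _hokr.bandpass_eye(
                _hokr.remove_saccades(eye, config.saccade_threshold),
                tuple(config.eye_band))
            amp = _hokr.eye_amplitude(clean, cycle)
            segs = _phase.segment_average(clean, cycle)
            _, phi, _ = _phase.sine_fit_phase(segs.mean_segment, cycle, clean.rate)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'hokr' failed for {config.eye_path}: {exc}") from exc
        report.sections["hokr"] = {"amplitude_deg": amp,
                                   "phase_lag_deg": -phi,
                                   "n_segments": segs.count}
    else:
        report.skipped.append("hokr: not run (no eye input)")

    write_report(report, out)
    return report


def write_report(report: SessionReport, out_dir) -> Path:
    path = Path(out_dir) / "report.json"
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=1, default=float)
    return path
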