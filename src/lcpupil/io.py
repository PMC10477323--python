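"""Plain-text sample/event tables.

Sample TSV columns: ``time_s, pupil_L, pupil_R, gaze_x_deg, gaze_y_deg,
valid_L, valid_R`` (validity as 0/1; invalid pupil samples hold NaN).
Event TSV columns: ``time_s, event_type, param`` where ``param`` is the
illuminance level in lx or the tone label.  A ground-truth JSON sidecar
carries every generating parameter of a synthetic recording.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SampledSeries
from .synthetic import SimulatedRecording

__all__ = [
    "write_recording",
    "read_samples",
    "read_events",
    "read_ground_truth",
    "write_cleaned",
]

SAMPLE_COLUMNS = [
    "time_s", "pupil_L", "pupil_R", "gaze_x_deg", "gaze_y_deg", "valid_L", "valid_R",
]


def write_recording(rec: SimulatedRecording, out_dir: str | Path, stem: str = "recording") -> dict:
    """Write samples, events and ground truth to ``out_dir``; returns the
    paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = rec.pupil_left or rec.gaze_x
    n = len(ref)
    t = ref.times

    def col(series, fill=np.nan):
        return series.values if series is not None else np.full(n, fill)

    def vcol(series):
        return series.valid.astype(int) if series is not None else np.zeros(n, int)

    df = pd.DataFrame(
        {
            "time_s": t,
            "pupil_L": col(rec.pupil_left),
            "pupil_R": col(rec.pupil_right),
            "gaze_x_deg": col(rec.gaze_x),
            "gaze_y_deg": col(rec.gaze_y),
            "valid_L": vcol(rec.pupil_left),
            "valid_R": vcol(rec.pupil_right),
        }
    )
    samples_path = out_dir / f"{stem}_samples.tsv"
    df.to_csv(samples_path, sep="\t", index=False, float_format="%.6f")

    ev = pd.DataFrame(rec.events, columns=["time_s", "event_type", "param"])
    events_path = out_dir / f"{stem}_events.tsv"
    ev.to_csv(events_path, sep="\t", index=False)

    gt_path = out_dir / f"{stem}_truth.json"
    gt_path.write_text(json.dumps(rec.ground_truth, indent=1, default=_jsonable))
    return {"samples": samples_path, "events": events_path, "truth": gt_path}


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_samples(path: str | Path) -> dict[str, SampledSeries]:
    """Load a sample table; returns named :class:`SampledSeries` channels.
    The sampling rate is inferred from the time column."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("sample table too short")
    rate = 1.0 / float(np.median(np.diff(t)))
    start = float(t[0])
    out = {}
    for name, col, vcol in (
        ("pupil_left", "pupil_L", "valid_L"),
        ("pupil_right", "pupil_R", "valid_R"),
    ):
        out[name] = SampledSeries(
            df[col].to_numpy(), rate, start, df[vcol].to_numpy().astype(bool)
        )
    for name, col in (("gaze_x", "gaze_x_deg"), ("gaze_y", "gaze_y_deg")):
        vals = df[col].to_numpy()
        out[name] = SampledSeries(vals, rate, start, np.isfinite(vals))
    return out


def read_events(path: str | Path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(row) for row in df.itertuples(index=False)]


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_cleaned(series: SampledSeries, path: str | Path) -> None:
    """Write a cleaned single-channel series as TSV (time_s, pupil, valid)."""
    pd.DataFrame(
        {"time_s": series.times, "pupil": series.values, "valid": series.valid.astype(int)}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_cleaned(path: str | Path) -> SampledSeries:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    return SampledSeries(
        df["pupil"].to_numpy(), rate, float(t[0]), df["valid"].to_numpy().astype(bool)
    )
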