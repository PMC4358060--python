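"""Plain-text readers/writers for head logs, rating tables and spot traces.

Head-trace logs follow the headset logger's ASCII convention: one sample
per line with columns ``t_s yaw_deg pitch_deg roll_deg``, either whitespace-
or comma-delimited, with ``#`` comment lines.  The writer emits the
comma-delimited dialect with a commented header; the reader accepts both.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .head_motion import HeadTrace
from .latency import SpotTraces
from .observers import RatingTable
from .scene import FlowField

__all__ = ["write_head_log", "read_head_log",
           "write_ratings_csv", "read_ratings_csv",
           "write_spot_csv", "read_spot_csv",
           "write_flow_table"]


def write_head_log(trace: HeadTrace, path: str | Path) -> None:
    """Write a head trace as a commented, comma-delimited ASCII log."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# head orientation log (Euler angles, degrees)\n")
        fh.write(f"# sample_rate_hz = {trace.sample_rate!r}\n")
        fh.write("# t_s, yaw_deg, pitch_deg, roll_deg\n")
        for t, y, p, r in zip(trace.t, trace.yaw, trace.pitch, trace.roll):
            fh.write(f"{t:.6f},{y:.6f},{p:.6f},{r:.6f}\n")


def read_head_log(path: str | Path) -> HeadTrace:
    """Parse a head-trace log (comma- or whitespace-delimited, # comments).

    Raises :class:`ParseError` with the offending line number on malformed
    rows or non-monotone timestamps.  The sample rate is inferred from the
    median timestamp spacing.
    """
    path = Path(path)
    rows: list[tuple[float, float, float, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 4:
                raise ParseError(
                    f"expected 4 columns (t yaw pitch roll), got {len(parts)}",
                    line=lineno)
            try:
                rows.append(tuple(float(p) for p in parts))
            except ValueError:
                raise ParseError(f"non-numeric field in {line!r}", line=lineno)
    if len(rows) < 2:
        raise ParseError("head log needs at least 2 samples")
    arr = np.asarray(rows, dtype=float)
    dt = np.diff(arr[:, 0])
    bad = np.nonzero(dt <= 0)[0]
    if len(bad):
        raise ParseError("non-monotone timestamp", line=int(bad[0]) + 2)
    rate = 1.0 / float(np.median(dt))
    return HeadTrace(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], rate)


def write_ratings_csv(table: RatingTable, path: str | Path) -> None:
    """Write a rating table as CSV (empty onset field = vection never arose)."""
    cols = [c for c in ("subject", "viewing", "coupling", "strength",
                        "onset_latency_s", "trial_id", "source_trial_id",
                        "playback_equivalent") if c in table.data.columns]
    table.data[cols].to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> RatingTable:
    return RatingTable(pd.read_csv(path))


def write_spot_csv(traces: SpotTraces, path: str | Path) -> None:
    """Write camera spot traces as ``frame,x_deg,y_deg`` CSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# frame_rate_hz = {traces.frame_rate!r}\n")
        fh.write("frame,x_deg,y_deg\n")
        for i, (x, y) in enumerate(zip(traces.stationary_spot_x,
                                       traces.driven_spot_y)):
            fh.write(f"{i},{x:.6f},{y:.6f}\n")


def read_spot_csv(path: str | Path, frame_rate: float | None = None) -> SpotTraces:
    """Read a spot-trace CSV; the frame rate comes from the header comment
    unless overridden."""
    path = Path(path)
    rate = frame_rate
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#") and "frame_rate_hz" in line and rate is None:
                rate = float(line.split("=", 1)[1])
            if line and not line.startswith("#"):
                break
    if rate is None:
        raise ParseError("frame rate not found in header and not supplied")
    df = pd.read_csv(path, comment="#")
    return SpotTraces(rate, df["x_deg"].to_numpy(), df["y_deg"].to_numpy())


def write_flow_table(flow: FlowField, path: str | Path) -> None:
    """Columnar text export of a flow field (one row per dot)."""
    df = pd.DataFrame({
        "dot": np.arange(len(flow.azimuth)),
        "azimuth_deg": flow.azimuth,
        "elevation_deg": flow.elevation,
        "size_deg": flow.optical_size,
        "angular_velocity_deg_s": flow.angular_velocity,
        "visible": flow.visible.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
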