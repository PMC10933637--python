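"""Multichannel trace container and its on-disk format.

A recording travels as a pair of files: a raw little-endian float32 binary
payload (channel-major, microvolts) and a JSON sidecar carrying the sampling
rate, channel count, grid geometry, units, seed provenance and processing
history.  In memory, :class:`TraceSet` holds the data in volts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "TraceSet", "write_traces", "read_traces"]

_PAYLOAD_SUFFIX = ".f32"
_SIDECAR_SUFFIX = ".json"


@dataclass(frozen=True)
class GridGeometry:
    """Electrode grid: rows x cols at a given pitch, row-major channel order.

    Channel index = row * cols + col (0-based).
    """

    rows: int
    cols: int
    pitch_um: float = 500.0
    electrode_diameter_um: float = 300.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.pitch_um > self.electrode_diameter_um > 0:
            raise ValueError("require pitch > electrode diameter > 0")

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def channel_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"({row}, {col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col

    def positions_um(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y) electrode centers in um."""
        rr, cc = np.divmod(np.arange(self.n_channels), self.cols)
        return np.column_stack([cc * self.pitch_um, rr * self.pitch_um]).astype(float)

    def distances_um(self, row: int, col: int) -> np.ndarray:
        """Euclidean distance of every electrode to the given grid site (um)."""
        pos = self.positions_um()
        ref = np.array([col * self.pitch_um, row * self.pitch_um])
        return np.linalg.norm(pos - ref, axis=1)


@dataclass
class TraceSet:
    """Multichannel voltage traces with grid geometry and sampling metadata.

    ``data`` is (n_channels, n_samples) in volts; annotations carry named
    event/trigger tables (anything JSON- or DataFrame-like).
    """

    data: np.ndarray  # V, shape (n_channels, n_samples)
    fs: float  # Hz
    geometry: GridGeometry
    t0: float = 0.0
    annotations: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if np.isnan(self.data).any():
            raise ValueError("trace data must not contain NaN")
        if self.data.shape[0] != self.geometry.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} channels != geometry "
                f"{self.geometry.rows}x{self.geometry.cols}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, row: int, col: int) -> np.ndarray:
        return self.data[self.geometry.channel_index(row, col)]

    def as_grid(self) -> np.ndarray:
        """Reshape to (rows, cols, n_samples)."""
        g = self.geometry
        return self.data.reshape(g.rows, g.cols, self.n_samples)

    def log(self, entry: str) -> None:
        self.history.append(entry)


def write_traces(traces: TraceSet, path: str | Path) -> Path:
    """Write payload + JSON sidecar; returns the payload path.

    The payload stores float32 microvolts, channel-major; the sidecar is
    written next to it with the same stem.  Any JSON-serializable annotations
    travel in the sidecar.
    """
    path = Path(path)
    if path.suffix != _PAYLOAD_SUFFIX:
        path = path.with_suffix(_PAYLOAD_SUFFIX)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = np.ascontiguousarray(traces.data * 1e6, dtype="<f4")
    payload.tofile(path)
    annotations = {}
    for key, val in traces.annotations.items():
        if hasattr(val, "to_dict"):  # DataFrame
            annotations[key] = val.to_dict(orient="list")
        else:
            annotations[key] = val
    g = traces.geometry
    sidecar = {
        "fs_hz": traces.fs,
        "n_channels": traces.n_channels,
        "n_samples": traces.n_samples,
        "units": "uV",
        "dtype": "<f4",
        "t0_s": traces.t0,
        "geometry": {
            "rows": g.rows,
            "cols": g.cols,
            "pitch_um": g.pitch_um,
            "electrode_diameter_um": g.electrode_diameter_um,
        },
        "channel_map": list(range(traces.n_channels)),
        "annotations": annotations,
        "history": traces.history + [f"write_traces -> {path.name}"],
    }
    path.with_suffix(_SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=1))
    return path


def read_traces(path: str | Path) -> TraceSet:
    """Read a payload/sidecar pair back into a :class:`TraceSet`.

    Errors on a missing sidecar, inconsistent payload size, invalid sampling
    rate, or units other than microvolts.
    """
    path = Path(path)
    if path.suffix != _PAYLOAD_SUFFIX:
        path = path.with_suffix(_PAYLOAD_SUFFIX)
    sidecar_path = path.with_suffix(_SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("units") != "uV":
        raise ValueError(f"unsupported units {meta.get('units')!r}; expected 'uV'")
    fs = float(meta["fs_hz"])
    if fs <= 0:
        raise ValueError(f"sidecar fs_hz must be > 0, got {fs}")
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    expected = 4 * n_ch * n_s
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"payload size mismatch for {path.name}: expected {expected} bytes "
            f"({n_ch} ch x {n_s} samples x 4), found {actual}"
        )
    raw = np.fromfile(path, dtype="<f4").reshape(n_ch, n_s)
    g = meta["geometry"]
    geometry = GridGeometry(
        rows=int(g["rows"]),
        cols=int(g["cols"]),
        pitch_um=float(g["pitch_um"]),
        electrode_diameter_um=float(g["electrode_diameter_um"]),
    )
    return TraceSet(
        data=raw.astype(np.float64) * 1e-6,
        fs=fs,
        geometry=geometry,
        t0=float(meta.get("t0_s", 0.0)),
        annotations=dict(meta.get("annotations", {})),
        history=list(meta.get("history", [])),
    )
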