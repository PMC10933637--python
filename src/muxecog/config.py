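"""TOML run configuration: [grid], [field], [stim], [mux], [readout], [analysis].

Unknown keys are rejected so that typos fail loudly; every random process is
keyed by a named seed in its own table.  ``render_config`` writes the
canonical TOML form back out, so parse -> render -> parse is stable.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

from .io import GridGeometry
from .muxsim import MuxConfig, ReadoutConfig
from .neurogen import BandEventSpec, NeuralFieldConfig, StimProtocol

__all__ = ["RunConfig", "load_config", "render_config"]

_TABLES = ("grid", "field", "stim", "mux", "readout", "analysis")


@dataclass
class RunConfig:
    grid: GridGeometry
    field_cfg: NeuralFieldConfig
    mux: MuxConfig
    readout: ReadoutConfig
    stim: StimProtocol | None = None
    analysis: dict = field(default_factory=dict)


def _build(cls, table: dict[str, Any], name: str, **extra):
    known = {f.name for f in fields(cls)}
    unknown = set(table) - known
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    kwargs = dict(table)
    for key, val in kwargs.items():
        if isinstance(val, list):  # TOML arrays -> tuples (centers, bands, ...)
            kwargs[key] = tuple(val)
    kwargs.update(extra)
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    raw = tomllib.loads(Path(path).read_text())
    unknown = set(raw) - set(_TABLES)
    if unknown:
        raise ValueError(f"unknown top-level tables: {sorted(unknown)}")
    for required in ("grid", "mux"):
        if required not in raw:
            raise ValueError(f"missing required table [{required}]")

    grid = _build(GridGeometry, raw["grid"], "grid")

    field_tab = dict(raw.get("field", {}))
    # an absent [field.bands] means the default event population; a present
    # but empty one means "no events" (e.g. grounded-input noise runs)
    band_tabs = field_tab.pop("bands", None)
    if band_tabs is None:
        fkw = {}
    else:
        fkw = {
            "bands": {
                kind: _build(BandEventSpec, tab, f"field.bands.{kind}")
                for kind, tab in band_tabs.items()
            }
        }
    if "duration_s" not in field_tab:
        field_tab["duration_s"] = 10.0
    field_cfg = _build(NeuralFieldConfig, field_tab, "field", **fkw)

    mux = _build(MuxConfig, raw["mux"], "mux")
    readout = _build(ReadoutConfig, raw.get("readout", {}), "readout")
    stim = _build(StimProtocol, raw["stim"], "stim") if "stim" in raw else None
    return RunConfig(
        grid=grid,
        field_cfg=field_cfg,
        mux=mux,
        readout=readout,
        stim=stim,
        analysis=dict(raw.get("analysis", {})),
    )


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot render {type(v)} to TOML")


def _render_table(name: str, obj: Any, skip=()) -> list[str]:
    lines = [f"[{name}]"]
    for f in fields(obj):
        if f.name in skip:
            continue
        v = getattr(obj, f.name)
        if v is None or isinstance(v, dict):
            continue
        lines.append(f"{f.name} = {_toml_value(v)}")
    lines.append("")
    return lines


def render_config(cfg: RunConfig) -> str:
    """Canonical TOML serialization of a run configuration."""
    lines: list[str] = []
    lines += _render_table("grid", cfg.grid)
    lines += _render_table("field", cfg.field_cfg, skip=("bands",))
    if not cfg.field_cfg.bands:
        lines += ["[field.bands]", ""]  # explicitly event-free
    for kind, spec in cfg.field_cfg.bands.items():
        lines += _render_table(f"field.bands.{kind}", spec)
    if cfg.stim is not None:
        lines += _render_table("stim", cfg.stim)
    lines += _render_table("mux", cfg.mux)
    lines += _render_table("readout", cfg.readout)
    if cfg.analysis:
        lines.append("[analysis]")
        for k, v in cfg.analysis.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    return "\n".join(lines)
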