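"""Readers/writers for the table dialects and run-configuration files.

Two CSV dialects are shared package-wide (header row, UTF-8, '.'
decimal):

* track tables: ``frame, time_min, track_id, x_um, y_um``
* nuclei tables: ``day, nucleus_id, x_um, y_um, state, tube_id``

Configuration is TOML with sections mirroring the parameter dataclasses
([simulation], [behaviour], [fusion], [mechanics], [media], [abc],
[synth]); unknown keys are rejected so typos cannot silently fall back
to defaults.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import ABCConfig
from .params import (BehaviourMetrics, FusionParams, MechanicsParams,
                     MediaComposition, ParameterError, SimParams)
from .synthetic import SynthSpec

__all__ = ["read_track_table", "write_track_table", "read_nuclei_table",
           "write_nuclei_table", "RunConfig", "load_config", "save_config"]

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["frame", "time_min", "track_id", "x_um", "y_um"]
NUCLEI_COLUMNS = ["day", "nucleus_id", "x_um", "y_um", "state", "tube_id"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def _coerce_numeric(df: pd.DataFrame, cols: list[str],
                    path: Path) -> pd.DataFrame:
    """Drop rows with non-numeric values in ``cols``, logging line numbers."""
    bad = pd.Series(False, index=df.index)
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(out[c], errors="coerce")
        bad |= vals.isna() & out[c].notna()
        bad |= out[c].isna()
        out[c] = vals
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s",
                       path, len(lines), lines)
        out = out[~bad]
    return out


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trajectory table.

    Rows are returned sorted by (track_id, frame); rows with
    non-numeric coordinates are rejected with their line numbers
    logged; duplicate frames within a track are an error.
    """
    path = Path(path)
    df = _read_csv(path, TRACK_COLUMNS)[TRACK_COLUMNS]
    df = _coerce_numeric(df, ["frame", "time_min", "track_id",
                              "x_um", "y_um"], path)
    if df.empty:
        raise ValueError(f"{path}: no valid rows")
    df = df.astype({"frame": np.int64, "track_id": np.int64})
    df = df.sort_values(["track_id", "frame"], kind="stable",
                        ignore_index=True)
    dup = df.duplicated(["track_id", "frame"])
    if dup.any():
        tid = df.loc[dup.idxmax(), "track_id"]
        raise ValueError(f"{path}: duplicate frame in track {tid}")
    return df


def write_track_table(df: pd.DataFrame, path: str | Path) -> None:
    df[TRACK_COLUMNS].to_csv(path, index=False)


def canonical_nuclei(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise a nuclei table to the canonical dtypes and row order."""
    out = df[NUCLEI_COLUMNS].copy()
    out["day"] = out["day"].astype(np.int64)
    out["nucleus_id"] = out["nucleus_id"].astype(np.int64)
    out["x_um"] = out["x_um"].astype(float)
    out["y_um"] = out["y_um"].astype(float)
    out["state"] = out["state"].astype(str)
    out["tube_id"] = pd.array(
        [pd.NA if pd.isna(v) else int(v) for v in out["tube_id"]],
        dtype="Int64")
    return out.sort_values(["day", "nucleus_id"], kind="stable",
                           ignore_index=True)


def read_nuclei_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a nuclei table.

    Enforces the state/tube consistency invariant: a myonucleus row
    without a tube_id (or a row with an unknown state) is rejected and
    logged; myoblast rows always carry a null tube_id.
    """
    path = Path(path)
    df = _read_csv(path, NUCLEI_COLUMNS)[NUCLEI_COLUMNS]
    df = _coerce_numeric(df, ["day", "nucleus_id", "x_um", "y_um"], path)
    tube = pd.to_numeric(df["tube_id"], errors="coerce")
    state = df["state"].astype(str)
    bad = ~state.isin(["myoblast", "myonucleus"])
    bad |= (state == "myonucleus") & tube.isna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]
        logger.warning("%s: rejected %d inconsistent row(s) at line(s) %s",
                       path, len(lines), lines)
        df, tube, state = df[~bad], tube[~bad], state[~bad]
    if df.empty:
        raise ValueError(f"{path}: no valid rows")
    df = df.copy()
    df["state"] = state
    df["tube_id"] = tube.where(state == "myonucleus")
    return canonical_nuclei(df)


def write_nuclei_table(df: pd.DataFrame, path: str | Path) -> None:
    canonical_nuclei(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: simulation, ABC and synthesis settings."""

    sim: SimParams = field(default_factory=SimParams)
    abc: ABCConfig = field(default_factory=ABCConfig)
    synth: SynthSpec = field(default_factory=SynthSpec)
    log_level: str = "info"


_SECTION_TYPES = {
    "simulation": SimParams,
    "behaviour": BehaviourMetrics,
    "fusion": FusionParams,
    "mechanics": MechanicsParams,
    "media": MediaComposition,
    "abc": ABCConfig,
    "synth": SynthSpec,
}
_SIM_NESTED = {"behaviour": BehaviourMetrics, "fusion": FusionParams,
               "mechanics": MechanicsParams, "media": MediaComposition}
_SIM_SCALAR = {f.name for f in dataclasses.fields(SimParams)
               if f.name not in _SIM_NESTED}


def _build(cls, section: str, values: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - allowed
    if unknown:
        raise ParameterError(
            f"[{section}] unknown key(s): {sorted(unknown)}")
    return cls(**values)


def load_config(path: str | Path) -> RunConfig:
    """Load, validate and default-fill a TOML run configuration.

    Out-of-range values raise :class:`ParameterError` naming the field
    and bound (via the dataclass validators); unknown sections or keys
    are rejected outright.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = set(_SECTION_TYPES) | {"log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config section(s): {sorted(unknown)}")

    sim_kwargs = dict(raw.get("simulation", {}))
    bad = set(sim_kwargs) - _SIM_SCALAR
    if bad:
        raise ParameterError(f"[simulation] unknown key(s): {sorted(bad)}")
    for section, cls in _SIM_NESTED.items():
        if section in raw:
            sim_kwargs[section] = _build(cls, section, raw[section])
    sim = SimParams(**sim_kwargs)
    abc = _build(ABCConfig, "abc", raw.get("abc", {}))
    synth = _build(SynthSpec, "synth", raw.get("synth", {}))
    return RunConfig(sim=sim, abc=abc, synth=synth,
                     log_level=str(raw.get("log_level", "info")))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace('"', '\\"') + '"'


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective (post-default) configuration as TOML.

    ``save_config`` then :func:`load_config` round-trips to an equal
    :class:`RunConfig`.
    """
    lines = [f"log_level = {_toml_value(cfg.log_level)}", ""]

    def _section(name: str, obj, skip: set[str] = frozenset()) -> None:
        lines.append(f"[{name}]")
        for f in dataclasses.fields(obj):
            if f.name in skip:
                continue
            v = getattr(obj, f.name)
            if v is None:
                continue
            lines.append(f"{f.name} = {_toml_value(v)}")
        lines.append("")

    _section("simulation", cfg.sim, skip=set(_SIM_NESTED))
    _section("behaviour", cfg.sim.behaviour)
    _section("fusion", cfg.sim.fusion)
    _section("mechanics", cfg.sim.mechanics)
    _section("media", cfg.sim.media)
    _section("abc", cfg.abc)
    _section("synth", cfg.synth)
    Path(path).write_text("\n".join(lines), encoding="utf-8")
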