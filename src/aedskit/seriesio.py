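"""Tabular energy-series files and run configuration parsing.

The energy-series format is a tab-separated text table with '#'
metadata lines, one row per frame.  Required columns: ``time_ps``,
``lambda``, one ``H_<label>`` per end state, ``E_R`` and ``E_R_star``.
Optional columns: ``dHdl``, per-state ``dHdl_<label>``, ``V_restraint``
and coordinates ``x_<i>``.  Unknown columns are accepted with a warning
(forward compatibility).  Values are written with 17 significant
digits, so a write-read round trip reproduces every float bit-exactly.
"""

from __future__ import annotations

import hashlib
import io
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .dynamics import EnergyTimeSeries
from .reference import reference_energy

log = logging.getLogger("aedskit")

_FMT = "%.17g"
_REQUIRED = ("time_ps", "lambda", "E_R", "E_R_star")


def write_energy_series(
    ts: EnergyTimeSeries, path, force: bool = False, extra_meta: dict | None = None
) -> Path:
    """Serialize a series to a tab-separated text file.

    Refuses to overwrite an existing file unless ``force`` is set.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    cols = {"time_ps": ts.time, "lambda": np.full(ts.n_frames, ts.lam)}
    for i, label in enumerate(ts.labels):
        cols[f"H_{label}"] = ts.H[:, i]
    cols["E_R"] = ts.e_r
    cols["E_R_star"] = ts.e_star
    if ts.dhdl is not None:
        cols["dHdl"] = ts.dhdl
    if ts.dhdl_states is not None:
        for i, label in enumerate(ts.labels):
            cols[f"dHdl_{label}"] = ts.dhdl_states[:, i]
    if ts.v_restraint is not None:
        cols["V_restraint"] = ts.v_restraint
    if ts.x is not None:
        for d in range(ts.x.shape[1]):
            cols[f"x_{d}"] = ts.x[:, d]
    df = pd.DataFrame(cols)
    meta = {
        "labels": " ".join(ts.labels),
        "RT": _FMT % ts.RT,
        "offsets": " ".join(_FMT % v for v in ts.offsets),
        "lambda": _FMT % ts.lam,
        "seed": ts.meta.get("seed", ""),
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(path, "w") as fh:
        fh.write("# aedskit energy series v1\n")
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FMT)
    return path


def read_energy_series(path) -> EnergyTimeSeries:
    """Parse an energy-series file back into an :class:`EnergyTimeSeries`.

    Validates the header, warns on unknown columns, and runs (and logs)
    the E_R self-consistency check against the stored offsets.
    """
    path = Path(path)
    meta: dict = {}
    body_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    k, v = stripped.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            body_lines.append((lineno, line))
    if not body_lines:
        raise ValueError(f"{path}: no table found")
    if "labels" not in meta:
        raise ValueError(f"{path}: metadata line '# labels: ...' missing")
    labels = meta["labels"].split()
    try:
        df = pd.read_csv(
            io.StringIO("".join(l for _, l in body_lines)),
            sep="\t",
            float_precision="round_trip",  # bit-exact re-parsing of %.17g
        )
    except Exception as exc:  # pandas reports its own line numbers
        raise ValueError(f"{path}: malformed table near line "
                         f"{body_lines[0][0]}: {exc}") from exc
    required = list(_REQUIRED) + [f"H_{l}" for l in labels]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    known = set(required)
    known.update({"dHdl", "V_restraint"})
    known.update(f"dHdl_{l}" for l in labels)
    known.update(c for c in df.columns if c.startswith("x_"))
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(
            f"{path}: ignoring unknown columns {unknown}", stacklevel=2
        )
    lam_col = df["lambda"].to_numpy(dtype=float)
    RT = float(meta.get("RT", 2.49435))
    offsets = np.array([float(v) for v in meta.get("offsets", "").split()]) if meta.get(
        "offsets"
    ) else np.zeros(len(labels))
    H = np.column_stack([df[f"H_{l}"].to_numpy(dtype=float) for l in labels])
    dhdl_states = None
    if all(f"dHdl_{l}" in df.columns for l in labels):
        dhdl_states = np.column_stack(
            [df[f"dHdl_{l}"].to_numpy(dtype=float) for l in labels]
        )
    x_cols = sorted((c for c in df.columns if c.startswith("x_")),
                    key=lambda c: int(c[2:]))
    ts = EnergyTimeSeries(
        time=df["time_ps"].to_numpy(dtype=float),
        lam=float(lam_col[0]),
        labels=labels,
        H=H,
        e_r=df["E_R"].to_numpy(dtype=float),
        e_star=df["E_R_star"].to_numpy(dtype=float),
        offsets=offsets,
        RT=RT,
        dhdl=df["dHdl"].to_numpy(dtype=float) if "dHdl" in df.columns else None,
        dhdl_states=dhdl_states,
        x=np.column_stack([df[c].to_numpy(dtype=float) for c in x_cols])
        if x_cols
        else None,
        v_restraint=df["V_restraint"].to_numpy(dtype=float)
        if "V_restraint" in df.columns
        else None,
        meta={k: v for k, v in meta.items() if k not in ("labels",)},
    )
    err = max(
        abs(ts.e_r[k] - reference_energy(ts.H[k], ts.offsets, ts.RT))
        for k in range(ts.n_frames)
    )
    log.info("read %s: %d frames, E_R self-consistency %.2e", path, ts.n_frames, err)
    if err > 1e-6:
        warnings.warn(
            f"{path}: stored E_R deviates from recomputed value by {err:.2e}",
            stacklevel=2,
        )
    return ts


# -- run configuration --------------------------------------------------------


class SystemSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = "pocket"
    g_a: float = -10.0
    g_b: float = 0.0
    k_conf: float = 100.0
    site_width: float = 0.12
    delta_e_s: float = 20.0
    curv_s: float = 10.0


class AccelSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    e_min: float
    e_max: float


class ProtocolSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_windows: int = 41
    lambdas: list[float] | None = None
    steps_per_window: int = 20_000
    equil_per_window: int = 2_000
    direction: str = "forward"

    @field_validator("lambdas")
    @classmethod
    def _unique_sorted(cls, v):
        if v is None:
            return v
        if len(set(v)) != len(v):
            raise ValueError("lambda grid contains duplicate values")
        return v


class RunConfig(BaseModel):
    """Validated run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    system: SystemSpec = SystemSpec()
    temperature: float = 300.0
    accel: AccelSpec | str = "search"
    offsets: list[float] | None = None
    offsets_lam1: list[float] | None = None
    n_steps: int = 200_000
    seed: int | None = None
    occupancy_method: str = "weights"
    protocol: ProtocolSpec = ProtocolSpec()

    @field_validator("accel")
    @classmethod
    def _accel_kind(cls, v):
        if isinstance(v, str) and v != "search":
            raise ValueError("accel must be {e_min, e_max} or the string 'search'")
        return v

    @field_validator("occupancy_method")
    @classmethod
    def _method(cls, v):
        if v not in ("weights", "argmin"):
            raise ValueError("occupancy_method must be 'weights' or 'argmin'")
        return v


def parse_config(path) -> RunConfig:
    """Read and validate a YAML run configuration; defaults are echoed
    to the log."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig.model_validate(raw)
    log.info("config %s: %s", path, cfg.model_dump())
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a validated configuration."""
    canon = yaml.safe_dump(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
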