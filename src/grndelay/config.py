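"""Run configuration, validation, and CSV/JSON output.

A :class:`RunConfig` gathers everything a run needs — model choice, kinetic
parameters, delays, history, integrator settings, boundary-grid axes and
output paths — and is validated strictly (unknown keys rejected, every type
invariant enforced) before any computation starts.  Configs load from JSON
or TOML; every CLI run can be reproduced from the JSON sidecar it writes.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import __version__ as _version
from .boundary import BoundaryGrid
from .models import DelaySpec, GRNParams
from .simulate import HistorySpec, Trajectory

__all__ = ["RunConfig", "load_config", "write_outputs"]

_FLOAT_FMT = "%.12g"


class ParamsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    m_a: float = Field(ge=0)
    m_b: float = Field(ge=0)
    k_a: float = Field(gt=0, default=1.0)
    k_b: float = Field(gt=0, default=1.0)
    gamma_a: float = Field(gt=0, default=1.0)
    gamma_b: float = Field(gt=0, default=1.0)
    delta_a: float = Field(gt=0, default=1.0)
    delta_b: float = Field(gt=0, default=1.0)
    theta_a: float = Field(gt=0)
    theta_b: float = Field(gt=0)
    n_a: int = Field(ge=1, default=1)
    n_b: int = Field(ge=1, default=1)

    def to_params(self) -> GRNParams:
        return GRNParams(**self.model_dump())


class DelayBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tau_ra: float = Field(ge=0, default=0.0)
    tau_rb: float = Field(ge=0, default=0.0)
    tau_pa: float = Field(ge=0, default=0.0)
    tau_pb: float = Field(ge=0, default=0.0)

    def to_delays(self) -> DelaySpec:
        return DelaySpec(**self.model_dump())


class HistoryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["constant"] = "constant"
    values: Optional[list[float]] = None

    @field_validator("values")
    @classmethod
    def _nonneg(cls, v):
        if v is not None and any(x < 0 for x in v):
            raise ValueError("history values must be nonnegative")
        return v

    def to_history(self) -> Optional[HistorySpec]:
        return HistorySpec.constant(self.values) if self.values else None


class IntegratorBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t_end: float = Field(gt=0, default=100.0)
    step: float = Field(gt=0, default=0.01)
    eps_pos: float = Field(gt=0, default=1e-9)


class BoundaryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    axis1_name: str = "delta_a"
    axis1_min: float = Field(gt=0, default=0.1)
    axis1_max: float = Field(gt=0, default=5.0)
    axis2_name: str = "delta_b"
    axis2_min: float = Field(gt=0, default=0.1)
    axis2_max: float = Field(gt=0, default=5.0)
    resolution: int = Field(ge=2, default=11)


class RunConfig(BaseModel):
    """Fully validated description of one run."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["dcnm", "dsnm"] = "dsnm"
    params: ParamsBlock
    delays: DelayBlock = DelayBlock()
    history: HistoryBlock = HistoryBlock()
    integrator: IntegratorBlock = IntegratorBlock()
    boundary: BoundaryBlock = BoundaryBlock()
    seed: int = 0
    output_dir: str = "."

    @model_validator(mode="after")
    def _delays_fit_step(self):
        spec = self.delays.to_delays()
        for lag in (spec.tau_ra, spec.tau_rb, spec.tau_pa, spec.tau_pb):
            if 0.0 < lag < self.integrator.step:
                raise ValueError(
                    f"positive delay {lag} smaller than integrator step "
                    f"{self.integrator.step}"
                )
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or TOML config file."""
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(text.decode())
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data)


def _sidecar(result_kind: str, meta: dict, path: Path) -> None:
    payload = {"kind": result_kind, "grndelay_version": _version, **meta}
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_outputs(result, out_prefix: str | Path, meta: dict | None = None) -> list[Path]:
    """Write a result (Trajectory, stability report, classification, or
    BoundaryGrid) as CSV plus a JSON metadata sidecar.

    Returns the list of files written.  Numbers use 12 significant digits.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(meta or {})
    written: list[Path] = []

    if isinstance(result, Trajectory):
        df = pd.DataFrame(result.states, columns=list(result.components))
        df.insert(0, "t", result.times)
        csv = out_prefix.with_suffix(".csv")
        df.to_csv(csv, index=False, float_format=_FLOAT_FMT)
        meta.update(
            model=result.model,
            step=result.step,
            delays=dataclasses.asdict(result.delays),
            min_value=result.min_value,
        )
        side = out_prefix.with_suffix(".json")
        _sidecar("trajectory", meta, side)
        written += [csv, side]
    elif isinstance(result, BoundaryGrid):
        rows = []
        for i, v1 in enumerate(result.axis1_values):
            for j, v2 in enumerate(result.axis2_values):
                rows.append((v1, v2, result.tau_critical[i, j]))
        df = pd.DataFrame(rows, columns=[result.axis1_name, result.axis2_name, "tau0"])
        csv = out_prefix.with_suffix(".csv")
        df.to_csv(csv, index=False, float_format=_FLOAT_FMT)
        meta.update(model=result.model, base_params=result.base_params.to_dict())
        side = out_prefix.with_suffix(".json")
        _sidecar("boundary-grid", meta, side)
        written += [csv, side]
    elif dataclasses.is_dataclass(result) and not isinstance(result, type):
        # stability reports, steady states, classifications
        side = out_prefix.with_suffix(".json")
        payload = dataclasses.asdict(result)
        _sidecar(type(result).__name__, {**meta, "result": payload}, side)
        written.append(side)
    else:
        raise TypeError(f"unsupported result type {type(result)!r}")
    return written
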