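"""Configuration loading, solution serialization and run logging.

Solutions are exported as tidy tables — one row per (trial, state,
action) with the IEV/FEV decomposition — in CSV or JSON; configs are
YAML mappings validated against per-task schemas with unknown keys
rejected and defaults recorded.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import sys
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .beads import BeadsParams
from .core import SpecError, ValueSolution
from .nonstationary import GenerativeParams
from .patch import PatchParams
from .sampling import SamplingParams

__all__ = ["RunConfig", "load_config", "solution_frame", "write_solution", "run_log_line"]

#: per-task parameter dataclasses; solver/basis blocks are free-form but keyed
_TASK_PARAMS = {
    "bandit": None,
    "gittins": None,
    "nonstationary": GenerativeParams,
    "novelty": None,
    "beads": BeadsParams,
    "patch": PatchParams,
    "sampling": SamplingParams,
}

_SOLVER_KEYS = {"tol", "criterion", "max_iterations", "gamma", "horizon", "p_switch", "seed"}
_BASIS_KEYS = {"mean_knots", "sd_knots", "mean_grid", "sd_grid", "n_knots", "p_knots", "n_grid", "p_grid", "interaction_order"}


@dataclasses.dataclass
class RunConfig:
    """Validated task configuration with defaults filled in."""

    task: str
    params: Any
    solver: dict
    basis: dict
    seed: int | None
    output_dir: Path
    defaulted: list[str]  # provenance: which fields came from defaults

    def resolved(self) -> dict:
        p = self.params
        return {
            "task": self.task,
            "params": dataclasses.asdict(p) if dataclasses.is_dataclass(p) else (p or {}),
            "solver": self.solver,
            "basis": self.basis,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
        }


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config.

    Unknown keys anywhere are rejected by name; omitted task parameters
    are filled from the task's defaults and listed in ``defaulted``.
    A load -> dump -> load round trip is the identity on the resolved
    config.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SpecError(f"config {path} is not a mapping")
    known_top = {"task", "params", "solver", "basis", "seed", "output_dir"}
    for key in raw:
        if key not in known_top:
            raise SpecError(f"unknown config key {key!r} (expected one of {sorted(known_top)})")
    task = raw.get("task")
    if task not in _TASK_PARAMS:
        raise SpecError(f"missing or unknown task {task!r} (expected one of {sorted(_TASK_PARAMS)})")
    cls = _TASK_PARAMS[task]
    block = raw.get("params") or {}
    defaulted: list[str] = []
    if cls is not None:
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key in block:
            if key not in fields:
                raise SpecError(f"unknown parameter {key!r} for task {task!r} (expected one of {sorted(fields)})")
        coerced = {}
        for key, val in block.items():
            if isinstance(val, list):
                val = tuple(val)
            coerced[key] = val
        params = cls(**coerced)
        defaulted = [name for name in fields if name not in block]
    else:
        params = dict(block)
    solver = raw.get("solver") or {}
    for key in solver:
        if key not in _SOLVER_KEYS:
            raise SpecError(f"unknown solver key {key!r} (expected one of {sorted(_SOLVER_KEYS)})")
    basis = raw.get("basis") or {}
    for key in basis:
        if key not in _BASIS_KEYS:
            raise SpecError(f"unknown basis key {key!r} (expected one of {sorted(_BASIS_KEYS)})")
    return RunConfig(
        task=task,
        params=params,
        solver=dict(solver),
        basis=dict(basis),
        seed=raw.get("seed"),
        output_dir=Path(raw.get("output_dir") or "."),
        defaulted=defaulted,
    )


def _encode_state(s: Any) -> str:
    if hasattr(s, "encode"):
        return s.encode()
    if isinstance(s, tuple):
        return ":".join(str(x) for x in s)
    return str(s)


def solution_frame(sol: ValueSolution) -> pd.DataFrame:
    """Tidy table: t, state, action, IEV, FEV, Q, chosen (stable order)."""
    rows = []
    for (t, s, a), q in sol.Q.items():
        rows.append(
            {
                "t": t,
                "state": _encode_state(s),
                "action": str(a),
                "IEV": sol.iev[(t, s, a)],
                "FEV": sol.fev[(t, s, a)],
                "Q": q,
                "chosen": int(sol.policy[(t, s)] == a),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["t", "state", "action"], kind="stable").reset_index(drop=True)


def write_solution(sol: ValueSolution, path: str | Path, fmt: str = "csv") -> Path:
    """Write a solved model as CSV or JSON (floats at 12 significant digits)."""
    path = Path(path)
    df = solution_frame(sol)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "json":
        payload = {
            "meta": {k: v for k, v in sol.meta.items() if isinstance(v, (int, float, str, bool))},
            "rows": json.loads(df.to_json(orient="records", double_precision=12)),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise SpecError(f"unknown format {fmt!r} (expected csv or json)")
    return path


def run_log_line(seed: int | None, meta: dict) -> str:
    """One ISO-timestamped log line recording seed, versions and iterations."""
    import numpy
    import scipy

    stamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    bits = {
        "seed": seed,
        "python": sys.version.split()[0],
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "iterations": meta.get("iterations"),
    }
    return f"{stamp} " + " ".join(f"{k}={v}" for k, v in bits.items())
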