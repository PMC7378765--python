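"""Flat key–value configuration files and structured result serialization.

A config file holds one ``KEY = VALUE`` pair per line; ``#`` starts a
comment.  Recognized keys are the 13 model parameters (with the reporting
probability spelled ``lambda``) plus a few run options (``horizon``,
``seed``, ``init_x``, ``init_y``, ``vertex_tol``).  Unknown keys are
rejected by name.  Results are serialized as JSON/CSV with floats at 10
significant digits so that repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .model import (
    GameParameters,
    PARAM_FIELDS,
    ParameterError,
    StateVector,
)

__all__ = [
    "RunConfig",
    "parse_config",
    "parse_overrides",
    "write_config",
    "round_sig",
    "jsonify",
    "dumps_json",
]

#: Config spelling -> dataclass field name.
CONFIG_ALIASES = {"lambda": "lam"}
_FIELD_TO_CONFIG = {v: k for k, v in CONFIG_ALIASES.items()}

#: Non-parameter option keys and their types.
OPTION_KEYS = {
    "horizon": float,
    "seed": int,
    "init_x": float,
    "init_y": float,
    "vertex_tol": float,
}


@dataclass
class RunConfig:
    """A parameter set plus the run options shared by all subcommands."""

    params: GameParameters
    horizon: float = 500.0
    seed: int = 0
    init: StateVector = StateVector(0.5, 0.5)
    vertex_tol: float = 1e-3


def _parse_number(key: str, text: str, typ=float):
    try:
        return typ(text)
    except ValueError:
        raise ParameterError(f"unparseable value for {key}: {text!r}") from None


def _apply_items(items: Mapping[str, str]) -> RunConfig:
    param_values = GameParameters.baseline().as_dict()
    options: dict = {}
    for key, raw in items.items():
        field = CONFIG_ALIASES.get(key, key)
        if field in PARAM_FIELDS:
            param_values[field] = _parse_number(key, raw)
        elif key in OPTION_KEYS:
            options[key] = _parse_number(key, raw, OPTION_KEYS[key])
        else:
            raise ParameterError(f"unknown parameter {key}")
    init = StateVector(
        options.pop("init_x", 0.5), options.pop("init_y", 0.5)
    )
    return RunConfig(params=GameParameters(**param_values), init=init, **options)


def parse_overrides(pairs) -> dict[str, str]:
    """Split ``KEY=VALUE`` strings (e.g. from repeated CLI flags)."""
    items: dict[str, str] = {}
    for pair in pairs:
        if "=" not in pair:
            raise ParameterError(f"expected KEY=VALUE, got {pair!r}")
        key, _, value = pair.partition("=")
        items[key.strip()] = value.strip()
    return items


def parse_config(
    path: Optional[Union[str, Path]] = None,
    overrides: Optional[Mapping[str, str]] = None,
) -> RunConfig:
    """Build a RunConfig from an optional file plus optional overrides.

    Defaults are the baseline calibration; an empty (or absent) config
    reproduces it exactly.  Overrides are applied after the file.
    """
    items: dict[str, str] = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(
                    f"line {lineno}: expected KEY = VALUE, got {line!r}"
                )
            key, _, value = line.partition("=")
            items[key.strip()] = value.strip()
    if overrides:
        items.update(overrides)
    return _apply_items(items)


def write_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Write a RunConfig as a flat key–value file (full float precision,
    so parse_config round-trips it exactly)."""
    lines = []
    for field in PARAM_FIELDS:
        key = _FIELD_TO_CONFIG.get(field, field)
        lines.append(f"{key} = {getattr(config.params, field)!r}")
    lines.append(f"horizon = {config.horizon!r}")
    lines.append(f"seed = {config.seed}")
    lines.append(f"init_x = {config.init.x!r}")
    lines.append(f"init_y = {config.init.y!r}")
    lines.append(f"vertex_tol = {config.vertex_tol!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# serialization

def round_sig(value: float, digits: int = 10) -> float:
    """Round a float to ``digits`` significant digits."""
    if not math.isfinite(value):
        return value
    return float(f"{value:.{digits}g}")


def jsonify(obj):
    """Recursively convert dataclasses/arrays to JSON-ready structures,
    rounding floats to 10 significant digits."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {
            f.name: jsonify(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
        # include useful computed properties
        for name in ("trace", "det"):
            if hasattr(type(obj), name) and isinstance(
                getattr(type(obj), name), property
            ):
                out[name] = jsonify(getattr(obj, name))
        return out
    if isinstance(obj, Counter):
        return dict(sorted(obj.items()))
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return round_sig(float(obj))
    if isinstance(obj, (np.integer, int, bool, str)) or obj is None:
        return obj
    return str(obj)


def dumps_json(obj) -> str:
    return json.dumps(jsonify(obj), indent=2, sort_keys=False)
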