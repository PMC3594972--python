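"""File formats: breakthrough-curve CSV, topology/binding configs, fit reports.

Curves are plain UTF-8 CSV with header ``time_s,c_norm``, one sample per
row, '.' decimal separator, written at 9 significant digits so a
write/read round trip is the identity at that precision.  Configuration
files (JSON or YAML by extension) use unit-suffixed keys throughout
(``V_pfr_mL``, ``Q_mL_per_s``, ...); unknown or unit-less numeric keys
are rejected before execution.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import yaml

from .kinetics import LangmuirParams, SpreadingParams
from .network import CapsuleTopology
from .simulate import BreakthroughCurve

__all__ = [
    "CurveFormatError",
    "ConfigError",
    "read_curve",
    "write_curve",
    "read_topology",
    "write_topology",
    "binding_to_dict",
    "binding_from_dict",
    "read_binding",
    "write_binding",
    "write_fit_report",
]

CURVE_HEADER = "time_s,c_norm"


class CurveFormatError(ValueError):
    """Malformed breakthrough-curve file; the message names the offending line."""


class ConfigError(ValueError):
    """Malformed or schema-violating configuration file."""


def read_curve(path) -> BreakthroughCurve:
    """Read a breakthrough curve CSV (header ``time_s,c_norm``).

    Validates a strictly increasing time axis and non-negative
    concentrations; violations raise :class:`CurveFormatError` with the
    one-based line number of the offending row.
    """
    path = pathlib.Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != CURVE_HEADER:
            raise CurveFormatError(
                f"{path}: line 1: expected header {CURVE_HEADER!r}, got {header!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise CurveFormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                t, c = float(parts[0]), float(parts[1])
            except ValueError:
                raise CurveFormatError(
                    f"{path}: line {lineno}: non-numeric value in {line!r}"
                ) from None
            if times and t <= times[-1]:
                raise CurveFormatError(
                    f"{path}: line {lineno}: time {t} not strictly increasing"
                )
            if c < 0:
                raise CurveFormatError(
                    f"{path}: line {lineno}: negative concentration {c}"
                )
            times.append(t)
            values.append(c)
    if len(times) < 2:
        raise CurveFormatError(f"{path}: need at least 2 samples")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    return BreakthroughCurve(t=np.array(times), c_norm=np.array(values), meta=meta)


def write_curve(curve: BreakthroughCurve, path, sidecar: bool = True) -> None:
    """Write a curve as CSV at 9 significant digits, with a metadata sidecar."""
    path = pathlib.Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(CURVE_HEADER + "\n")
        for t, c in zip(curve.t, curve.c_norm):
            fh.write(f"{t:.9g},{c:.9g}\n")
    if sidecar and curve.meta:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(_jsonable(curve.meta), indent=2), encoding="utf-8"
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# -- configuration files -----------------------------------------------

def _load_structured(path) -> dict:
    path = pathlib.Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return data


def _dump_structured(data: dict, path) -> None:
    path = pathlib.Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(_jsonable(data), sort_keys=False),
                        encoding="utf-8")
    else:
        path.write_text(json.dumps(_jsonable(data), indent=2), encoding="utf-8")


_TOPOLOGY_KEYS = {
    "mode", "Q_mL_per_s", "V_pfr_mL", "outlet", "tanks", "zones",
    "sectors", "build_info",
}


def _check_unit_keys(data: dict, allowed: set, where: str) -> None:
    for key, value in data.items():
        if key not in allowed:
            raise ConfigError(f"{where}: unknown key {key!r}")
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            # numeric scalars must carry an explicit unit suffix (or be
            # declared dimensionless in the schema)
            dimensionless = {"eps", "N", "outlet", "mode", "u", "f", "phi",
                            "mu", "sigma", "slope", "n_sectors", "beta"}
            if "_" not in key and key not in dimensionless:
                raise ConfigError(
                    f"{where}: numeric key {key!r} lacks a unit suffix"
                )


def read_topology(path) -> CapsuleTopology:
    data = _load_structured(path)
    _check_unit_keys(data, _TOPOLOGY_KEYS, str(path))
    try:
        return CapsuleTopology.from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid topology: {exc}") from exc


def write_topology(topology: CapsuleTopology, path) -> None:
    _dump_structured(topology.to_dict(), path)


def binding_to_dict(params) -> dict:
    if isinstance(params, LangmuirParams):
        model = "langmuir"
    elif isinstance(params, SpreadingParams):
        model = "spreading"
    else:
        raise TypeError(f"unsupported binding parameter type {type(params)!r}")
    return {
        "model": model,
        "params": {k: getattr(params, k) for k in params.__dataclass_fields__},
    }


def binding_from_dict(data: dict):
    try:
        model = data["model"]
        params = data["params"]
    except (KeyError, TypeError):
        raise ConfigError("binding config needs 'model' and 'params'") from None
    try:
        if model == "langmuir":
            return LangmuirParams(**params)
        if model == "spreading":
            return SpreadingParams(**params)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid binding parameters: {exc}") from exc
    raise ConfigError(f"unknown binding model {model!r}")


def read_binding(path):
    return binding_from_dict(_load_structured(path))


def write_binding(params, path) -> None:
    _dump_structured(binding_to_dict(params), path)


def write_fit_report(result, path) -> None:
    """Write a fit result as JSON (params, units, sse, multi-start records)."""
    _dump_structured(result.to_dict(), path)
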