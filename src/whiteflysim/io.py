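"""File I/O for the colony-log, trajectory, parameter and QC schemas.

All tabular files are UTF-8, comma-separated, header-required delimited
text (spreadsheet-friendly, matching the lab-log provenance of the data).
Writers prepend ``#``-prefixed metadata lines carrying the seed, a config
hash and the package version, so every output is traceable to the run that
produced it; readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .calibration import FitResult, ObservationRecord
from .model import ColonyState, ModelParameters, Trajectory, default_parameters

__all__ = [
    "config_hash",
    "read_records",
    "write_records",
    "write_trajectory",
    "read_trajectory",
    "read_parameters",
    "write_parameters",
    "write_deviation_table",
    "read_deviation_table",
    "append_qc_rows",
    "SchemaError",
    "RECORD_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "QC_COLUMNS",
]

RECORD_COLUMNS = [
    "iteration",
    "inoculum",
    "n_plants",
    "initial_area",
    "final_area",
    "harvest_total",
]
TRAJECTORY_COLUMNS = ["week", "P", "A", "N", "E", "T"]
DEVIATION_COLUMNS = ["variable", "fraction", "ratio"]
QC_COLUMNS = ["date", "cage", "metric", "value", "units"]


class SchemaError(ValueError):
    """A delimited-text file does not match its documented schema."""


def config_hash(config: Mapping) -> str:
    """Short stable hash of a flat configuration mapping."""
    blob = json.dumps(
        {str(k): config[k] for k in sorted(config, key=str)}, sort_keys=True, default=str
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _meta_lines(seed: Optional[int], config: Optional[Mapping]) -> List[str]:
    lines = [f"# whiteflysim_version={__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    return lines


def _write_csv(
    df: pd.DataFrame,
    path: Union[str, Path],
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in _meta_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_records(path: Union[str, Path]) -> List[ObservationRecord]:
    """Read a colony-iteration log into observation records."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"records file {path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ObservationRecord(
                    iteration=str(row["iteration"]),
                    inoculum=float(row["inoculum"]),
                    n_plants=int(row["n_plants"]),
                    initial_area=float(row["initial_area"]),
                    final_area=float(row["final_area"]),
                    harvest_total=float(row["harvest_total"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"records file {path}, row {i + 2}: {exc}") from exc
    return records


def write_records(
    records: Sequence[ObservationRecord],
    path: Union[str, Path],
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    df = pd.DataFrame(
        [
            {
                "iteration": r.iteration,
                "inoculum": r.inoculum,
                "n_plants": r.n_plants,
                "initial_area": r.initial_area,
                "final_area": r.final_area,
                "harvest_total": r.harvest_total,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )
    _write_csv(df, path, seed=seed, config=config)


def write_trajectory(
    traj: Trajectory,
    path: Union[str, Path],
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    df = pd.DataFrame(
        [
            {"week": s.week, "P": s.P, "A": s.A, "N": s.N, "E": s.E, "T": s.T}
            for s in traj
        ],
        columns=TRAJECTORY_COLUMNS,
    )
    _write_csv(df, path, seed=seed, config=config)


def read_trajectory(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory file {path}: missing column(s) {missing}")
    return df


def read_parameters(path: Union[str, Path]) -> ModelParameters:
    """Read a flat name -> value parameter mapping (YAML-compatible)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"parameter file {path}: expected a flat mapping")
    scope = data.pop("denominator_scope", "full")
    params = default_parameters()
    return params.replace(denominator_scope=scope, **{k: float(v) for k, v in data.items()})


def write_parameters(
    params: ModelParameters,
    path: Union[str, Path],
    seed: Optional[int] = None,
    extra: Optional[Mapping] = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: Dict[str, object] = {k: float(v) for k, v in params.to_dict().items()}
    payload["denominator_scope"] = params.denominator_scope
    doc = {"parameters": payload, "meta": {"whiteflysim_version": __version__}}
    if seed is not None:
        doc["meta"]["seed"] = int(seed)
    if extra:
        doc["meta"].update(
            {k: (float(v) if isinstance(v, (int, float)) else v) for k, v in dict(extra).items()}
        )
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_parameters_report(path: Union[str, Path]) -> ModelParameters:
    """Read back a parameter file written by :func:`write_parameters`."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    payload = dict(doc["parameters"])
    scope = payload.pop("denominator_scope", "full")
    params = default_parameters()
    return params.replace(
        denominator_scope=scope, **{k: float(v) for k, v in payload.items()}
    )


def write_deviation_table(
    results,
    path: Union[str, Path],
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    df = pd.DataFrame(
        [{"variable": r.variable, "fraction": r.fraction, "ratio": r.ratio} for r in results],
        columns=DEVIATION_COLUMNS,
    )
    _write_csv(df, path, seed=seed, config=config)


def read_deviation_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DEVIATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"deviation file {path}: missing column(s) {missing}")
    return df


def append_qc_rows(rows: Sequence[Mapping], path: Union[str, Path]) -> None:
    """Append QC metric rows to the colony log; never mutates prior rows."""
    path = Path(path)
    df = pd.DataFrame(list(rows), columns=QC_COLUMNS)
    if path.exists():
        df.to_csv(path, mode="a", header=False, index=False)
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
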