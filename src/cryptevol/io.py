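"""Readers, writers and run configuration.

Every CSV the package writes carries its provenance (parameters, seed,
package version) as ``#``-prefixed JSON comment lines before the header, and
every reader skips such lines, so any artifact on disk is re-readable by the
package (round-trip property).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import DomainError, ModelParams

__all__ = [
    "read_incidence_csv",
    "write_csv_with_metadata",
    "read_csv_metadata",
    "RunConfig",
]


def _version() -> str:
    from . import __version__

    return __version__


def write_csv_with_metadata(frame: pd.DataFrame, path, **meta) -> None:
    """Write a CSV with a '#'-prefixed JSON metadata header."""
    meta = dict(meta)
    meta.setdefault("package", "cryptevol")
    meta.setdefault("version", _version())
    payload = json.dumps(meta, default=_jsonable, sort_keys=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {payload}\n")
        frame.to_csv(fh, index=False)


def _jsonable(obj):
    if isinstance(obj, ModelParams):
        return obj.to_dict()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    return str(obj)


def read_csv_metadata(path) -> dict:
    """Return the JSON metadata header of a package-written CSV (or {})."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        try:
            return json.loads(first.lstrip("# ").strip())
        except json.JSONDecodeError:
            return {}
    return {}


def read_incidence_csv(path):
    """Read and validate an age-binned incidence table.

    Expects the header age_lo,age_hi,cohort_size,cases,cumulative_incidence
    (comment lines starting with '#' are ignored). Raises a validation error
    naming the offending rows otherwise.
    """
    from .synthetic import IncidenceTable

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, comment="#")
    required = ["age_lo", "age_hi", "cohort_size", "cases", "cumulative_incidence"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DomainError(f"{path}: missing columns {missing}")
    return IncidenceTable(frame)


@dataclass
class RunConfig:
    """Pipeline configuration: paths, parameter overrides, simulation settings.

    Loaded from a flat JSON file; CLI flags override file values.
    """

    incidence_csv: str | None = None
    outdir: str = "."
    params: ModelParams = field(default_factory=ModelParams)
    n_runs: int = 1000
    t_max: float = 80.0
    seed: int = 0
    cohort_sizes: int = 10_000
    verbosity: int = 1

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        params = ModelParams.from_dict(raw.pop("params", {}))
        known = {"incidence_csv", "outdir", "n_runs", "t_max", "seed",
                 "cohort_sizes", "verbosity"}
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(params=params, **raw)
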