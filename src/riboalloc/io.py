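"""Result serialization and readers.

Outputs are plain CSV (with optional ``#``-prefixed provenance header
lines) or JSON records; floats are written at 10 significant digits so
that write/read round trips preserve values well below solver tolerance.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dynamics import SIMPLE_TRAJECTORY_COLUMNS, Trajectory
from .errors import DomainError
from .flux_parity import FP_TRAJECTORY_COLUMNS

__all__ = [
    "write_results",
    "write_trajectory",
    "read_trajectory",
    "read_observations",
]

FLOAT_FORMAT = "%.10g"


def write_results(
    records,
    path: str | Path,
    format: str = "csv",
    columns: list[str] | None = None,
    header_lines: list[str] | None = None,
) -> None:
    """Write a list of record dicts (or a DataFrame) to CSV or JSON.

    ``columns`` fixes the column order; ``header_lines`` are written as
    ``#``-prefixed comments before the CSV header (provenance).
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records), columns=columns)
    if columns is not None:
        missing = [c for c in columns if c not in frame.columns]
        if missing and len(frame):
            raise DomainError(f"records lack required columns: {missing}")
        frame = frame.reindex(columns=columns)
    if format == "csv":
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            frame.to_csv(fh, index=False, float_format=FLOAT_FORMAT)
    elif format == "json":
        payload = {
            "header": header_lines or [],
            "records": json.loads(frame.to_json(orient="records")),
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise DomainError(f"unknown output format {format!r}")


def write_trajectory(
    traj: Trajectory, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write a trajectory CSV with the canonical column order."""
    columns = (
        SIMPLE_TRAJECTORY_COLUMNS
        if traj.model == "simple"
        else FP_TRAJECTORY_COLUMNS
    )
    write_results(
        traj.frame, path, format="csv", columns=columns,
        header_lines=header_lines,
    )


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    frame = pd.read_csv(path, comment="#")
    model = "flux_parity" if "tRNA_c" in frame.columns else "simple"
    return Trajectory(frame=frame, model=model)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a collated steady-state observation CSV.

    Expected schema: a ``growth_rate_hr`` column, one of ``mass_fraction``
    or ``elongation_rate_aa_s``, and a ``source`` column. No fetching is
    performed; comparing against literature data is a user action.
    """
    frame = pd.read_csv(path, comment="#")
    if "growth_rate_hr" not in frame.columns:
        raise DomainError("observation file lacks a growth_rate_hr column")
    if not (
        "mass_fraction" in frame.columns
        or "elongation_rate_aa_s" in frame.columns
    ):
        raise DomainError(
            "observation file needs mass_fraction or elongation_rate_aa_s"
        )
    return frame
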