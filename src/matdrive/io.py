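"""Table readers/writers and config handling.

All writers emit TSV with a '#'-prefixed provenance header (package
version, command parameters, seed) so that any output can be regenerated
byte-identically from its own header.  Timestamps are deliberately
excluded for that reason.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import IO

import pandas as pd

__all__ = [
    "read_count_table",
    "read_config",
    "write_table",
    "provenance_lines",
]

REQUIRED_COUNT_COLUMNS = ("cross_id", "GAL4plus", "dGAL4", "QF2plus")


def _package_version() -> str:
    try:
        return version("matdrive")
    except PackageNotFoundError:  # pragma: no cover - only during odd installs
        return "unknown"


def provenance_lines(command: str, **params) -> list[str]:
    """Provenance header lines for an output table."""
    lines = [f"# matdrive {_package_version()}", f"# command: {command}"]
    for key, value in params.items():
        if value is not None:
            lines.append(f"# {key}: {value}")
    return lines


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a progeny-class count table.

    CSV or TSV (delimiter sniffed from the extension: ``.tsv``/``.tab`` is
    tab-separated, anything else comma).  Required columns: cross_id,
    GAL4plus, dGAL4, QF2plus.  Counts must be nonnegative integers;
    errors name the offending row and column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in REQUIRED_COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {', '.join(missing)}")
    if table.empty:
        raise ValueError(f"{path.name}: table has a header but no rows")
    for col in REQUIRED_COUNT_COLUMNS[1:]:
        for idx, value in table[col].items():
            try:
                iv = int(value)
                bad = iv != float(value) or iv < 0
            except (TypeError, ValueError):
                bad = True
            if bad:
                raise ValueError(
                    f"{path.name}: row {idx}, column {col}: "
                    f"expected a nonnegative integer, got {value!r}"
                )
        table[col] = table[col].astype(int)
    return table


def read_config(path: str | Path) -> dict:
    """Load a JSON run-configuration file."""
    with open(path) as fh:
        config = json.load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    return config


def write_table(
    frame: pd.DataFrame,
    out: str | Path | IO[str],
    header_lines: list[str] | None = None,
    float_format: str = "%.10g",
) -> None:
    """Write a DataFrame as TSV, preceded by provenance header lines."""
    def _emit(fh: IO[str]) -> None:
        for line in header_lines or []:
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=float_format)

    if hasattr(out, "write"):
        _emit(out)  # type: ignore[arg-type]
    else:
        with open(out, "w") as fh:
            _emit(fh)
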