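"""Tidy long-format measurement tables and their CSV serialisation.

Every stage of the pipeline exchanges data through one table shape: one row
per observation, keyed by system (strain), condition (medium), replicate,
optional time, optional cell, and a function name (the phenotype measured,
e.g. ``mu_max`` or ``biosensor:OxSR``). This mirrors how plate-reader and
microscopy exports are usually reshaped before analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "COLUMNS",
    "MeasurementTable",
    "ValidationReport",
    "FormatError",
    "read_measurements",
    "write_measurements",
    "validate_table",
]

#: Canonical column order of the long format.
COLUMNS = ["system", "condition", "replicate", "time_h", "cell_id", "function_name", "value"]

#: Columns whose cells may be empty (encoded as empty CSV cells / NaN / None).
OPTIONAL_COLUMNS = ["time_h", "cell_id"]

KEY_COLUMNS = ["system", "condition", "replicate", "time_h", "cell_id", "function_name"]


class FormatError(ValueError):
    """Raised when a CSV file does not conform to the measurement layout."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`.

    ``violations`` is a list of ``(row_locator, rule_id, message)`` tuples,
    ordered by record position; ``is_valid`` is true iff it is empty.
    """

    violations: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations


@dataclass
class MeasurementTable:
    """A long-format table of measurements plus free-form metadata.

    ``data`` holds one row per :class:`MeasurementRecord`-shaped observation
    with the columns in :data:`COLUMNS`. Optional fields (``time_h``,
    ``cell_id``) are NaN/None when absent. ``metadata`` carries advisory
    key/value strings (units, screening duration, notes); units are global
    per function name because the robustness statistic is scale-invariant.
    """

    data: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        self.data = self.data.loc[:, COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.data, other.data, check_dtype=False)
        except AssertionError:
            return False
        return self.metadata == other.metadata

    def subset(self, function_name: str) -> pd.DataFrame:
        """Rows for one function, as a plain DataFrame view."""
        return self.data[self.data["function_name"] == function_name]

    def function_names(self) -> list[str]:
        return sorted(self.data["function_name"].unique())


def _normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["system"] = df["system"].astype(str)
    df["condition"] = df["condition"].astype(str)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype("int64")
    df["time_h"] = pd.to_numeric(df["time_h"], errors="coerce")
    # cell_id: keep as nullable string, empty -> None
    cid = df["cell_id"]
    df["cell_id"] = cid.where(cid.notna() & (cid.astype(str) != ""), None)
    df["cell_id"] = df["cell_id"].map(lambda v: None if v is None else str(v))
    return df


def read_measurements(path) -> MeasurementTable:
    """Read a long-format measurement CSV.

    The file must carry a header row naming the :data:`COLUMNS` fields
    (extra columns are ignored). Empty ``time_h``/``cell_id`` cells become
    absent values. Metadata may be embedded as a leading
    ``# metadata {json}`` comment line.
    """
    metadata: dict[str, str] = {}
    header_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                body = line[1:].strip()
                if body.startswith("metadata "):
                    metadata.update(json.loads(body[len("metadata "):]))
            else:
                break
    df = pd.read_csv(path, skiprows=header_lines, dtype={"cell_id": str},
                     float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        # +2: one for the header row, one for 1-based line numbering
        row = int(bad.idxmax()) + header_lines + 2
        raise FormatError(f"{path}: non-numeric value {df['value'][bad.idxmax()]!r} at row {row}")
    df["value"] = values
    return MeasurementTable(_normalise_frame(df), metadata)


def write_measurements(table: MeasurementTable, path) -> None:
    """Write a table as CSV, embedding metadata as a ``# metadata {json}`` line.

    Values are written with enough digits (repr round-trip) that
    ``read_measurements`` reproduces them exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if table.metadata:
            fh.write(f"# metadata {json.dumps(table.metadata)}\n")
        table.data.to_csv(fh, index=False, float_format=None)


def validate_table(table: MeasurementTable) -> ValidationReport:
    """Check every record against the data-model invariants.

    Rules: ``finite-value`` (value must be a finite number),
    ``nonnegative-time`` (time_h >= 0 when present), and ``unique-key``
    (the (system, condition, replicate, time_h, cell_id, function_name)
    tuple must be unique). Violations are reported in record order; they
    are data, not exceptions.
    """
    report = ValidationReport()
    df = table.data
    for idx, value in df["value"].items():
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            report.violations.append((int(idx), "finite-value", f"value {value!r} is not finite"))
    for idx, t in df["time_h"].items():
        if pd.notna(t) and t < 0:
            report.violations.append((int(idx), "nonnegative-time", f"time_h {t} < 0"))
    key = df[KEY_COLUMNS].astype(str)
    dup = key.duplicated(keep="first")
    for idx in df.index[dup]:
        report.violations.append(
            (int(idx), "unique-key", "duplicate (system, condition, replicate, time_h, cell_id, function_name)")
        )
    report.violations.sort(key=lambda v: v[0])
    return report
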