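from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from robustscreen import MeasurementTable


def make_table(rows: list[dict], metadata: dict | None = None) -> MeasurementTable:
    """Build a MeasurementTable from partial row dicts (missing keys -> absent)."""
    full = [
        {"system": r.get("system", "S1"), "condition": r.get("condition", "C1"),
         "replicate": r.get("replicate", 1), "time_h": r.get("time_h"),
         "cell_id": r.get("cell_id"), "function_name": r.get("function_name", "f"),
         "value": r["value"]}
        for r in rows
    ]
    df = pd.DataFrame(full)
    df["replicate"] = df["replicate"].astype("int64")
    return MeasurementTable(df, metadata or {})


def grid_table(values: dict[tuple, float], function_name: str = "f") -> MeasurementTable:
    """Table from {(system, condition, replicate): value} mappings."""
    rows = [
        {"system": s, "condition": c, "replicate": r, "function_name": function_name,
         "value": v}
        for (s, c, r), v in values.items()
    ]
    return make_table(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
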