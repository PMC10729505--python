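"""Fluorescent-biosensor signal correction, normalisation and summaries.

Raw biosensor fluorescence carries background from the medium (blank) and
from cellular autofluorescence (the parental, sensor-free strain). Both
are subtracted, and the corrected signal is divided by a normalisation
reference — either a constitutive normalisation construct or a second
wavelength — which itself receives the same background treatment. The
result is a unitless fluorescence ratio per timepoint, the "function"
that the time-resolved and population robustness modes consume.

Points where the corrected signal or corrected reference drops to zero
or below are flagged ``below_background`` and excluded rather than
clamped: clamping would deflate the variance and bias the Fano factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import PhaseAnnotation
from .io import COLUMNS, MeasurementTable

__all__ = [
    "CHANNELS",
    "BiosensorSeries",
    "NormalizedSeries",
    "NoSignalError",
    "correct_and_normalize",
    "summarize_series_mean",
    "phase_means",
    "aggregate_replicates",
    "series_from_table",
    "normalize_table",
]

#: The eight intracellular parameters the sensor panel reports.
CHANNELS = (
    "pHi", "ATP", "glycolytic_flux", "OxSR",
    "UPR", "ribosome", "pyruvate", "ethanol_consumption",
)

OK = "ok"
BELOW_BACKGROUND = "below_background"


class NoSignalError(ValueError):
    """A summary was requested over zero usable points."""


def _broadcast(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.size != n:
        raise ValueError(f"{name} has length {arr.size}, expected {n} (or a scalar)")
    return arr


@dataclass
class BiosensorSeries:
    """One channel's raw fluorescence time series with its backgrounds.

    ``blank`` and ``parental`` may be scalars (a per-screening constant)
    or per-timepoint arrays; both conventions occur in practice and which
    one an instrument run used is metadata, not a model choice.
    ``ref_blank``/``ref_parental`` are the reference channel's own
    backgrounds (default 0, i.e. the reference is supplied pre-corrected).
    """

    system: str
    condition: str
    replicate: int
    channel: str
    times_h: np.ndarray
    raw: np.ndarray
    blank: np.ndarray | float = 0.0
    parental: np.ndarray | float = 0.0
    reference: np.ndarray | float = 1.0
    ref_blank: np.ndarray | float = 0.0
    ref_parental: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        n = self.times_h.size
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times_h must be strictly increasing")
        self.raw = _broadcast(self.raw, n, "raw")
        self.blank = _broadcast(self.blank, n, "blank")
        self.parental = _broadcast(self.parental, n, "parental")
        self.reference = _broadcast(self.reference, n, "reference")
        self.ref_blank = _broadcast(self.ref_blank, n, "ref_blank")
        self.ref_parental = _broadcast(self.ref_parental, n, "ref_parental")


@dataclass
class NormalizedSeries:
    """Background-corrected, reference-normalised fluorescence ratios.

    ``ratio`` is NaN wherever ``flags`` is not ``"ok"``.
    """

    times_h: np.ndarray
    ratio: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.flags is None:
            self.flags = np.where(np.isfinite(self.ratio), OK, BELOW_BACKGROUND)
        self.flags = np.asarray(self.flags, dtype=object)

    @property
    def ok(self) -> np.ndarray:
        return self.flags == OK


def correct_and_normalize(series: BiosensorSeries) -> NormalizedSeries:
    """Subtract backgrounds and ratio against the corrected reference.

    corrected = raw - blank - parental;
    corrected_ref = reference - ref_blank - ref_parental;
    ratio = corrected / corrected_ref, flagged ``below_background``
    (ratio NaN) wherever either corrected quantity is <= 0.
    """
    corrected = series.raw - series.blank - series.parental
    corrected_ref = series.reference - series.ref_blank - series.ref_parental
    ok = (corrected > 0) & (corrected_ref > 0)
    ratio = np.full(series.times_h.size, np.nan)
    ratio[ok] = corrected[ok] / corrected_ref[ok]
    flags = np.where(ok, OK, BELOW_BACKGROUND).astype(object)
    return NormalizedSeries(times_h=series.times_h, ratio=ratio, flags=flags)


def summarize_series_mean(series: NormalizedSeries) -> tuple[float, int]:
    """Mean ratio over the whole screening, with the point count used.

    This is the per-replicate summary behind strain-level comparisons of
    intracellular parameters: flagged points are excluded; having no ok
    point at all is an error.
    """
    ok = series.ok
    n = int(ok.sum())
    if n == 0:
        raise NoSignalError("no usable (ok) points in series")
    return float(series.ratio[ok].mean()), n


def phase_means(series: NormalizedSeries, phases: PhaseAnnotation) -> tuple[float, float]:
    """Mean ratio within the lag and exponential windows.

    Intervals are closed on the left and open on the right; the final
    (exponential) interval is closed on both ends. A window with no ok
    point yields NaN for that phase — a missing value, not an error.
    """
    t = series.times_h
    lag_lo, lag_hi = phases.lag_interval
    exp_lo, exp_hi = phases.exp_interval
    in_lag = (t >= lag_lo) & (t < lag_hi) & series.ok
    in_exp = (t >= exp_lo) & (t <= exp_hi) & series.ok

    lag_mean = float(series.ratio[in_lag].mean()) if in_lag.any() else float("nan")
    exp_mean = float(series.ratio[in_exp].mean()) if in_exp.any() else float("nan")
    return lag_mean, exp_mean


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation across replicates.

    Replicates are carried through the whole pipeline individually and
    aggregated only here, at the end.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 replicate values, got {x.size}")
    return float(x.mean()), float(x.std(ddof=1))


# ---------------------------------------------------------------------------
# Table-level wiring
# ---------------------------------------------------------------------------

_ROLE_PREFIXES = {
    "raw": "biosensor_raw:",
    "blank": "biosensor_blank:",
    "parental": "biosensor_parental:",
    "reference": "biosensor_ref:",
}


def series_from_table(table: MeasurementTable, system: str, condition: str,
                      replicate: int, channel: str) -> BiosensorSeries:
    """Assemble one channel's :class:`BiosensorSeries` from table rows.

    Expects ``biosensor_raw:<ch>`` rows and, optionally, blank / parental /
    reference rows (per-timepoint or a single scalar row each); missing
    roles default to 0 background and reference 1.
    """
    df = table.data
    at = df[(df["system"] == system) & (df["condition"] == condition)
            & (df["replicate"] == replicate)]
    parts: dict[str, object] = {}
    times = None
    for role, prefix in _ROLE_PREFIXES.items():
        rows = at[at["function_name"] == prefix + channel].sort_values("time_h")
        if rows.empty:
            continue
        if len(rows) == 1:
            parts[role] = float(rows["value"].iloc[0])
        else:
            parts[role] = rows["value"].to_numpy()
            if role == "raw":
                times = rows["time_h"].to_numpy()
    if "raw" not in parts:
        raise KeyError(f"no biosensor_raw:{channel} rows for "
                       f"({system}, {condition}, replicate {replicate})")
    if times is None:
        raise ValueError(f"biosensor_raw:{channel} needs per-timepoint rows")
    return BiosensorSeries(system=system, condition=condition, replicate=replicate,
                           channel=channel, times_h=times, **parts)


def normalize_table(table: MeasurementTable) -> MeasurementTable:
    """Correct and normalise every biosensor channel found in a table.

    Emits ``biosensor:<channel>`` ratio rows (only ok points) for each
    (system, condition, replicate, channel) with raw rows present.
    """
    df = table.data
    raw = df[df["function_name"].str.startswith(_ROLE_PREFIXES["raw"])]
    rows = []
    keys = raw[["system", "condition", "replicate", "function_name"]].drop_duplicates()
    for _, key in keys.iterrows():
        channel = key["function_name"].removeprefix(_ROLE_PREFIXES["raw"])
        series = series_from_table(table, key["system"], key["condition"],
                                   int(key["replicate"]), channel)
        norm = correct_and_normalize(series)
        ok = norm.ok
        rows.extend(
            {"system": key["system"], "condition": key["condition"],
             "replicate": int(key["replicate"]), "time_h": ti, "cell_id": None,
             "function_name": f"biosensor:{channel}", "value": ri}
            for ti, ri in zip(norm.times_h[ok], norm.ratio[ok])
        )
    out = pd.DataFrame(rows, columns=COLUMNS)
    if not out.empty:
        out["replicate"] = out["replicate"].astype("int64")
    return MeasurementTable(out, dict(table.metadata))
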