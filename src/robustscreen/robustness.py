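"""Fano-factor-based robustness quantification.

The central statistic is

    R = -(sigma^2 / xbar) * (1 / m)

where ``sigma^2`` and ``xbar`` are the variance and mean of a measured
function (growth rate, lag, a yield, a biosensor ratio, ...) within a
group of observations, and ``m`` is a grand mean across all groups that
removes the function's scale. ``sigma^2 / xbar`` is the Fano factor, so R
is a negated, mean-normalised dispersion index: 0 for a perfectly stable
function, increasingly negative the noisier the function is relative to
its overall level. R is relative to the systems and conditions analysed,
never absolute.

Four aggregation modes cover the common experimental questions:

====  ==============================  =========================================
mode  one group per                   variance runs over
====  ==============================  =========================================
c     system (strain)                 conditions (replicate-averaged)
s     condition (medium)              systems (replicate-averaged)
t     system, condition, replicate    timepoints of a time series
p     system, condition, timepoint    single cells of a population snapshot
====  ==============================  =========================================

All four are presets of one generic grouping engine
(:func:`robustness_generic`); ``m`` is always the grand mean over every
group of the same function unless the pooling axes are overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MeasurementTable

__all__ = [
    "AXES",
    "InsufficientDataError",
    "UndefinedRobustnessError",
    "RobustnessResult",
    "GroupingScheme",
    "PRESET_SCHEMES",
    "fano_factor",
    "robustness_score",
    "robustness_generic",
    "robustness_across_conditions",
    "robustness_across_systems",
    "robustness_over_time",
    "robustness_across_population",
    "summarize_replicate_results",
    "to_efficiency",
    "results_to_frame",
]

#: Observation axes of the long-format table, in canonical order.
AXES = ["system", "condition", "replicate", "time_h", "cell_id"]


class InsufficientDataError(ValueError):
    """A group holds fewer observations than the statistic requires."""


class UndefinedRobustnessError(ValueError):
    """Fano factor or R is mathematically undefined (zero mean, nonzero variance)."""


@dataclass
class RobustnessResult:
    """R for one group under one mode, with its ingredients.

    ``sigma2``/``xbar`` are the within-group variance and mean, ``m`` the
    normalising grand mean, ``n`` the group size. ``status`` is ``"ok"`` or
    ``"missing"``; missing groups (too small, or undefined 0-mean Fano)
    keep their key and carry a machine-readable ``reason`` instead of
    being silently dropped.
    """

    mode: str
    group_key: dict = field(default_factory=dict)
    n: int = 0
    sigma2: float | None = None
    xbar: float | None = None
    m: float | None = None
    R: float | None = None
    status: str = "ok"
    reason: str | None = None


@dataclass
class GroupingScheme:
    """Axes defining a robustness computation.

    ``within_axes``: axes pooled inside each group (sigma and xbar run over
    them). ``across_key``: axes fixing each group. Axes in neither set are
    nuisance axes and are averaged out first (e.g. replicates for modes c/s).
    ``m_axes``: axes pooled when computing m; must contain ``within_axes``.
    With ``m_axes`` equal to all grouped axes (the default in every preset),
    m is the single grand mean over all groups.
    """

    within_axes: tuple[str, ...]
    across_key: tuple[str, ...]
    m_axes: tuple[str, ...]

    def validate(self) -> None:
        for ax in (*self.within_axes, *self.across_key, *self.m_axes):
            if ax not in AXES:
                raise ValueError(f"unknown axis {ax!r}; expected one of {AXES}")
        if not self.within_axes:
            raise ValueError("within_axes must not be empty")
        if set(self.within_axes) & set(self.across_key):
            raise ValueError("within_axes and across_key must be disjoint")
        if not set(self.m_axes) >= set(self.within_axes):
            raise ValueError("m_axes must contain within_axes")


PRESET_SCHEMES: dict[str, GroupingScheme] = {
    "c": GroupingScheme(("condition",), ("system",), ("condition", "system")),
    "s": GroupingScheme(("system",), ("condition",), ("system", "condition")),
    "t": GroupingScheme(
        ("time_h",), ("system", "condition", "replicate"),
        ("time_h", "system", "condition", "replicate"),
    ),
    "p": GroupingScheme(
        ("cell_id",), ("system", "condition", "time_h"),
        ("cell_id", "system", "condition", "time_h"),
    ),
}

#: Default minimum group size per preset mode. Mode p follows the
#: microscopy convention of at least 25 cells per sample.
DEFAULT_MIN_N = {"c": 2, "s": 2, "t": 3, "p": 25, "generic": 2}


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

def fano_factor(values, ddof: int = 1) -> float:
    """Variance-to-mean ratio of a sample.

    Uses the sample (n-1) variance by default; ``ddof=0`` switches to the
    population convention. A zero-variance sample returns 0 regardless of
    its mean (this resolves the 0/0 of an all-zero group to 0, the
    convention that makes "no strain grew anywhere" read as maximally
    stable rather than undefined). A zero mean with positive variance has
    no meaningful Fano factor and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    var = float(np.var(x, ddof=ddof))
    if var == 0.0:
        return 0.0
    mean = float(np.mean(x))
    if mean == 0.0:
        raise UndefinedRobustnessError("Fano factor undefined: zero mean with nonzero variance")
    return var / mean


def robustness_score(values, m: float, ddof: int = 1, mode: str = "generic",
                     group_key: dict | None = None) -> RobustnessResult:
    """R = -fano_factor(values) / m for one group.

    ``m`` is the grand mean used for normalisation. Zero-variance groups
    score exactly 0 whatever ``m`` is; otherwise ``m`` must be nonzero.
    """
    x = np.asarray(values, dtype=float)
    fano = fano_factor(x, ddof=ddof)
    var = float(np.var(x, ddof=ddof))
    xbar = float(np.mean(x))
    if fano == 0.0:
        r = 0.0
    elif m == 0.0:
        raise UndefinedRobustnessError("R undefined: m = 0 with nonzero variance")
    else:
        r = -fano / m
    return RobustnessResult(
        mode=mode, group_key=dict(group_key or {}), n=int(x.size),
        sigma2=var, xbar=xbar, m=float(m), R=r,
    )


def to_efficiency(values, theoretical_max: float) -> np.ndarray:
    """Divide experimental yields or rates by a theoretical maximum.

    Efficiencies (unitless, ideally in [0, 1]) make across-system
    comparisons meaningful when the systems do not share a theoretical
    maximum (e.g. different species). When every system shares one
    ``theoretical_max`` the downstream R values are unchanged, since R is
    invariant to rescaling the function.
    """
    if not (theoretical_max > 0):
        raise ValueError(f"theoretical_max must be > 0, got {theoretical_max}")
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("values must be non-negative")
    return x / theoretical_max


# ---------------------------------------------------------------------------
# Table-level grouping engine
# ---------------------------------------------------------------------------

def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, MeasurementTable):
        return table.data
    return table


def _key_dict(axes: tuple[str, ...], key) -> dict:
    if not isinstance(key, tuple):
        key = (key,)
    return {ax: (k.item() if hasattr(k, "item") else k) for ax, k in zip(axes, key)}


def robustness_generic(table, function_name: str, scheme: GroupingScheme,
                       ddof: int = 1, min_n: int = 2, mode_label: str = "generic",
                       ) -> list[RobustnessResult]:
    """Compute R for every group a grouping scheme defines.

    Pipeline: select the function's rows; average the value over nuisance
    axes (axes in neither ``within_axes`` nor ``across_key``); compute m by
    pooling over ``m_axes``; then score each ``across_key`` group from its
    values across ``within_axes``. Groups smaller than ``min_n``, or with
    an undefined Fano factor, are reported with status ``"missing"``.
    """
    scheme.validate()
    df = _as_frame(table)
    sub = df[df["function_name"] == function_name]
    if sub.empty:
        raise KeyError(
            f"function {function_name!r} not in table; available: "
            f"{sorted(df['function_name'].unique())}"
        )
    grouped_axes = list(scheme.across_key) + list(scheme.within_axes)
    collapsed = (
        sub.groupby(grouped_axes, dropna=False, sort=True)["value"]
        .mean()
        .reset_index()
    )

    # m: grand mean pooled over m_axes; axes of across_key outside m_axes
    # partition the table into m-groups with their own grand mean.
    fixed_for_m = [ax for ax in scheme.across_key if ax not in scheme.m_axes]
    if fixed_for_m:
        m_lookup = collapsed.groupby(fixed_for_m, dropna=False)["value"].mean()
    else:
        m_global = float(collapsed["value"].mean())

    results: list[RobustnessResult] = []
    for key, grp in collapsed.groupby(list(scheme.across_key), dropna=False, sort=True):
        gkey = _key_dict(tuple(scheme.across_key), key)
        if fixed_for_m:
            mk = tuple(gkey[ax] for ax in fixed_for_m)
            m = float(m_lookup[mk if len(mk) > 1 else mk[0]])
        else:
            m = m_global
        values = grp["value"].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if values.size < min_n:
            results.append(RobustnessResult(
                mode=mode_label, group_key=gkey, n=int(values.size),
                status="missing", reason=f"group size {values.size} < minimum {min_n}",
            ))
            continue
        try:
            res = robustness_score(values, m, ddof=ddof, mode=mode_label, group_key=gkey)
        except UndefinedRobustnessError as exc:
            results.append(RobustnessResult(
                mode=mode_label, group_key=gkey, n=int(values.size),
                sigma2=float(np.var(values, ddof=ddof)), xbar=float(np.mean(values)),
                m=m, status="missing", reason=str(exc),
            ))
            continue
        results.append(res)
    return results


def _preset(table, function_name, mode, ddof, min_n, average_replicates=True):
    scheme = PRESET_SCHEMES[mode]
    if mode in ("c", "s") and not average_replicates:
        # pooled-replicate sensitivity variant: replicate variance enters sigma^2
        scheme = replace(
            scheme,
            within_axes=(*scheme.within_axes, "replicate"),
            m_axes=(*scheme.m_axes, "replicate"),
        )
    if min_n is None:
        min_n = DEFAULT_MIN_N[mode]
    return robustness_generic(table, function_name, scheme, ddof=ddof,
                              min_n=min_n, mode_label=mode)


def robustness_across_conditions(table, function_name: str, ddof: int = 1,
                                 min_n: int | None = None,
                                 average_replicates: bool = True) -> list[RobustnessResult]:
    """R(c): how stable a function is across conditions, one R per system.

    Replicates are averaged per (system, condition) first; m is the mean of
    those replicate-averaged values over all systems and conditions.
    """
    return _preset(table, function_name, "c", ddof, min_n, average_replicates)


def robustness_across_systems(table, function_name: str, ddof: int = 1,
                              min_n: int | None = None,
                              average_replicates: bool = True) -> list[RobustnessResult]:
    """R(s): how similar a function is across systems, one R per condition."""
    return _preset(table, function_name, "s", ddof, min_n, average_replicates)


def robustness_over_time(table, function_name: str, ddof: int = 1,
                         min_n: int | None = None,
                         m_axes: tuple[str, ...] | None = None) -> list[RobustnessResult]:
    """R(t): stability of a time series, one R per (system, condition, replicate).

    By default m pools the function over all systems, conditions,
    replicates and timepoints; pass ``m_axes`` to restrict the pooling
    (e.g. per-condition normalisation).
    """
    scheme = PRESET_SCHEMES["t"]
    if m_axes is not None:
        scheme = replace(scheme, m_axes=tuple(m_axes))
    return robustness_generic(table, function_name, scheme, ddof=ddof,
                              min_n=DEFAULT_MIN_N["t"] if min_n is None else min_n,
                              mode_label="t")


def robustness_across_population(table, function_name: str, ddof: int = 1,
                                 min_cells: int | None = None) -> list[RobustnessResult]:
    """R(p): population homogeneity, one R per (system, condition, timepoint).

    Values are per-cell measurements; groups need at least ``min_cells``
    cells (default 25, the microscopy sample-size convention). Lower R(p)
    means higher population heterogeneity. ``cell_id`` must be unique
    within each (system, condition, time) sample.
    """
    return _preset(table, function_name, "p", ddof, min_cells)


def summarize_replicate_results(results: list[RobustnessResult]) -> pd.DataFrame:
    """Mean and sample SD of replicate-level R per (system, condition).

    The companion summary for :func:`robustness_over_time`: replicate R(t)
    values are aggregated the way triplicate measurements are, mean and
    (n-1) SD at the end. Missing replicates are excluded.
    """
    rows = [
        {**r.group_key, "R": r.R}
        for r in results
        if r.status == "ok"
    ]
    if not rows:
        return pd.DataFrame(columns=["system", "condition", "n_replicates", "R_mean", "R_sd"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["system", "condition"], sort=True)["R"]
        .agg(n_replicates="count", R_mean="mean", R_sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


def results_to_frame(results: list[RobustnessResult]) -> pd.DataFrame:
    """Flatten results into the CSV layout: mode, key columns, n, sigma2, xbar, m, R, status."""
    rows = []
    for r in results:
        rows.append({
            "mode": r.mode, **r.group_key, "n": r.n, "sigma2": r.sigma2,
            "xbar": r.xbar, "m": r.m, "R": r.R, "status": r.status, "reason": r.reason,
        })
    return pd.DataFrame(rows)
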