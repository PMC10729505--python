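"""Independent brute-force implementations used as test oracles.

Everything here is written with explicit Python loops and textbook
formulas, deliberately avoiding the package's grouping engine and numpy
reductions, so that agreement with the package is a genuine two-route
check.
"""

from __future__ import annotations

import math


def brute_mean(values):
    return sum(values) / len(values)


def brute_var(values, ddof=1):
    mu = brute_mean(values)
    return sum((v - mu) ** 2 for v in values) / (len(values) - ddof)


def brute_sd(values, ddof=1):
    return math.sqrt(brute_var(values, ddof))


def brute_R(values, m, ddof=1):
    """Textbook negated mean-normalised Fano factor."""
    var = brute_var(values, ddof)
    if var == 0.0:
        return 0.0
    return -(var / brute_mean(values)) / m


def _collapse(records, group_axes):
    """Average `value` over records sharing the same group_axes key."""
    sums: dict[tuple, list[float]] = {}
    for rec in records:
        key = tuple(rec[a] for a in group_axes)
        sums.setdefault(key, []).append(rec["value"])
    return {key: brute_mean(vals) for key, vals in sums.items()}


def brute_mode(records, within_axes, across_axes, min_n=2, ddof=1):
    """Brute-force any robustness mode on a list of record dicts.

    Nuisance axes are whatever keys exist beyond within+across; values are
    first averaged per (across + within) key, m is the grand mean of those
    collapsed values, and each across-key group is scored.
    """
    collapsed = _collapse(records, list(across_axes) + list(within_axes))
    m = brute_mean(list(collapsed.values()))
    groups: dict[tuple, list[float]] = {}
    for key, value in collapsed.items():
        groups.setdefault(key[: len(across_axes)], []).append(value)
    out = {}
    for gkey, values in groups.items():
        if len(values) < min_n:
            out[gkey] = None
        else:
            out[gkey] = brute_R(values, m, ddof)
    return out
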