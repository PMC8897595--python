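"""AGO1-loading classification from RIP vs input small-RNA counts.

Loading is read out by comparing a miRNA's abundance in an Argonaute
immunoprecipitate (RIP) with its abundance in the total input library.
Counts are normalised to CPM (counts per million) and compared on the
log2(cpm + 1) scale; miRNAs passing an expression floor are ranked by
delta = log2(cpm_rip + 1) - log2(cpm_input + 1), and the top/bottom 20%
are called loaded/unloaded.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "cpm",
    "log2_cpm1",
    "classify_loading",
    "loading_scatter_data",
    "CLASSES",
]

CLASSES = ("loaded_top", "unloaded_bottom", "neutral", "below_floor")


def cpm(table: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation: cpm_ij = count_ij / libsize_j * 1e6.

    ``table`` is miRNAs x samples (raw counts).  Each column of the result
    sums to 1e6.  A zero library size raises ``ValueError``.
    """
    lib = table.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    return table.div(lib, axis=1) * 1e6


def log2_cpm1(cpm_table: pd.DataFrame) -> pd.DataFrame:
    """log2(cpm + 1); the +1 pseudocount maps zero counts to exactly 0."""
    return np.log2(cpm_table + 1.0)


def classify_loading(
    table: pd.DataFrame,
    input_col: str = "input",
    rip_col: str = "rip",
    top_fraction: float = 0.2,
    bottom_fraction: float = 0.2,
    floor: float = 5.0,
    floor_scope: str = "either",
    statistic: str = "log_delta",
) -> pd.DataFrame:
    """Classify each miRNA's Argonaute loading from a raw count table.

    Parameters
    ----------
    table:
        Raw counts, miRNA ids in the index, with at least the input and RIP
        sample columns.
    top_fraction, bottom_fraction:
        Fractions of the *eligible* (floor-passing) set called
        ``loaded_top`` / ``unloaded_bottom``.  Must sum to <= 1.
    floor:
        Minimum expression on the log2(cpm+1) scale (default 5.0).
    floor_scope:
        Which sample(s) must meet the floor: ``input``, ``rip``, ``either``
        or ``both``.
    statistic:
        ``log_delta`` ranks by log2(cpm_rip+1) - log2(cpm_input+1) (the
        scatterplot axes); ``cpm_ratio`` ranks by raw cpm_rip / cpm_input.

    Returns a DataFrame indexed like ``table`` with columns
    ``x_input, x_rip, delta, class``.  ``loaded_top`` holds the first
    floor(top_fraction * n_eligible) miRNAs by descending delta (at least 1
    when any miRNA is eligible); ``unloaded_bottom`` the last
    floor(bottom_fraction * n_eligible); the remainder of the eligible set is
    ``neutral`` and floor-failing miRNAs are ``below_floor``.  Ties in delta
    break lexicographically by id for determinism.
    """
    if top_fraction + bottom_fraction > 1:
        raise ValueError("top_fraction + bottom_fraction must be <= 1")
    if floor_scope not in ("input", "rip", "either", "both"):
        raise ValueError(f"invalid floor_scope {floor_scope!r}")
    if statistic not in ("log_delta", "cpm_ratio"):
        raise ValueError(f"invalid statistic {statistic!r}")

    norm = cpm(table[[input_col, rip_col]])
    x = log2_cpm1(norm)
    x_input = x[input_col]
    x_rip = x[rip_col]
    if statistic == "log_delta":
        delta = x_rip - x_input
    else:
        # raw cpm ratio on the log2 scale; pseudo-cpm of 1 guards zeros
        delta = np.log2((norm[rip_col] + 1.0) / (norm[input_col] + 1.0))

    if floor_scope == "input":
        eligible = x_input >= floor
    elif floor_scope == "rip":
        eligible = x_rip >= floor
    elif floor_scope == "either":
        eligible = (x_input >= floor) | (x_rip >= floor)
    else:
        eligible = (x_input >= floor) & (x_rip >= floor)

    calls = pd.DataFrame(
        {"x_input": x_input, "x_rip": x_rip, "delta": delta, "class": "below_floor"},
        index=table.index,
    )
    elig_ids = calls.index[eligible]
    n_elig = len(elig_ids)
    if n_elig:
        order = sorted(elig_ids, key=lambda i: (-calls.at[i, "delta"], str(i)))
        n_top = max(1, math.floor(top_fraction * n_elig))
        n_bottom = math.floor(bottom_fraction * n_elig)
        n_bottom = min(n_bottom, n_elig - n_top)  # never overlap the top set
        calls.loc[order, "class"] = "neutral"
        calls.loc[order[:n_top], "class"] = "loaded_top"
        if n_bottom:
            calls.loc[order[-n_bottom:], "class"] = "unloaded_bottom"
    return calls


def loading_scatter_data(
    calls: pd.DataFrame, highlight_ids: list[str] | None = None
) -> pd.DataFrame:
    """Plot-ready table for the input-vs-RIP scatter.

    One row per miRNA in ``calls`` with columns
    ``x_input, x_rip, class, highlight`` (``highlight`` flags user-specified
    ids, e.g. the miR-30a/d/e-3p family).
    """
    highlight = set(highlight_ids or [])
    out = calls[["x_input", "x_rip", "class"]].copy()
    out["highlight"] = [i in highlight for i in calls.index]
    return out
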