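"""qPCR enrichment and relative-expression math (2^-ddCt family).

All computations assume an amplification efficiency of exactly 2 (perfect
doubling per cycle), the assumption behind the 2^-ddCt estimator.  ChIP
enrichment is expressed as percent of (dilution-adjusted) input; relative
expression uses a reference gene and a control condition.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_input",
    "relative_to_reference",
    "ddct_expression",
    "summarize_replicates",
    "percent_input_table",
    "expression_fold_table",
]


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP signal as percent of input, adjusting for the input dilution.

    The input Ct is first shifted by log2(1/input_fraction) cycles to
    represent 100% of input; the IP signal is then
    ``100 * 2^(adjusted_input_ct - ct_ip)``.

    >>> percent_input(25.0, 28.0, 0.10)
    80.0
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def relative_to_reference(fold_target: float, fold_reference: float) -> float:
    """Express a fold value relative to a reference fold (ratio of folds)."""
    if fold_reference <= 0:
        raise ValueError("reference fold must be positive")
    return fold_target / fold_reference


def ddct_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by 2^-ddCt.

    dCt = Ct(target) - Ct(reference gene), per condition;
    ddCt = dCt(sample) - dCt(control); fold = 2^-ddCt.
    """
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def summarize_replicates(
    results: Mapping[str, Sequence[float]], test: str = "student"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition mean +/- SD with pairwise two-sided unpaired t tests.

    Parameters
    ----------
    results:
        Mapping condition -> replicate fold (or expression) values.
    test:
        ``"student"`` (equal-variance unpaired t, the default) or
        ``"welch"``.

    Returns ``(summary, pvalues)``: a per-condition table with columns
    ``mean, sd, n`` and a symmetric condition-by-condition matrix of
    two-sided p values (identical groups give p = 1).
    """
    if test not in ("student", "welch"):
        raise ValueError(f"test must be 'student' or 'welch', got {test!r}")
    conditions = list(results)
    summary = pd.DataFrame(
        {
            "mean": [float(np.mean(results[c])) for c in conditions],
            "sd": [float(np.std(results[c], ddof=1)) if len(results[c]) > 1 else 0.0
                   for c in conditions],
            "n": [len(results[c]) for c in conditions],
        },
        index=pd.Index(conditions, name="condition"),
    )
    pvals = pd.DataFrame(1.0, index=conditions, columns=conditions)
    for a, b in itertools.combinations(conditions, 2):
        xa, xb = np.asarray(results[a], float), np.asarray(results[b], float)
        if np.array_equal(xa, xb) or (np.std(xa) == 0 and np.std(xb) == 0
                                      and np.mean(xa) == np.mean(xb)):
            p = 1.0
        else:
            p = float(
                stats.ttest_ind(xa, xb, equal_var=(test == "student")).pvalue
            )
            if math.isnan(p):
                p = 1.0
        pvals.loc[a, b] = pvals.loc[b, a] = p
    return summary, pvals


def _mean_ct(df: pd.DataFrame) -> pd.DataFrame:
    """Average Ct over technical replicates (rows sharing sample/target/assay)."""
    keys = [c for c in ("sample", "target", "assay") if c in df.columns]
    return df.groupby(keys, as_index=False)["ct"].mean()


def percent_input_table(
    ct_table: pd.DataFrame,
    ip_assay: str,
    input_assay: str = "input",
    input_fraction: float = 0.1,
) -> pd.DataFrame:
    """Percent-input enrichment for every (sample, target) in a Ct table.

    ``ct_table`` has columns ``sample, target, assay, ct`` (and optionally
    ``replicate``); technical replicates are averaged before the ddCt step.
    """
    mean = _mean_ct(ct_table)
    rows = []
    for (sample, target), grp in mean.groupby(["sample", "target"]):
        by_assay = grp.set_index("assay")["ct"]
        if ip_assay not in by_assay or input_assay not in by_assay:
            continue
        rows.append(
            {
                "sample": sample,
                "target": target,
                "assay": ip_assay,
                "percent_input": percent_input(
                    by_assay[ip_assay], by_assay[input_assay], input_fraction
                ),
            }
        )
    return pd.DataFrame(rows)


def expression_fold_table(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
) -> pd.DataFrame:
    """2^-ddCt relative expression for every target and condition.

    ``ct_table`` has columns ``sample`` (the condition), ``target`` and
    ``ct``; technical replicates are averaged first.  Every target is
    normalised to ``reference_gene`` within its condition and expressed
    relative to ``control_condition`` (where the fold is 1 by construction).
    """
    mean = _mean_ct(ct_table)
    ct = mean.pivot_table(index="target", columns="sample", values="ct")
    if reference_gene not in ct.index:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    if control_condition not in ct.columns:
        raise ValueError(f"control condition {control_condition!r} not in table")
    rows = []
    for target in ct.index:
        if target == reference_gene:
            continue
        for condition in ct.columns:
            fold = ddct_expression(
                ct.loc[target, condition],
                ct.loc[reference_gene, condition],
                ct.loc[target, control_condition],
                ct.loc[reference_gene, control_condition],
            )
            rows.append({"target": target, "condition": condition, "fold": fold})
    return pd.DataFrame(rows)
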