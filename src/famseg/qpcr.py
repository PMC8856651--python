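"""Relative qPCR quantification (ddCt) and two-group comparison.

Relative expression of a target gene is computed against an internal
reference gene (e.g. 18S rRNA) and a designated control group (e.g. the
scrambled-shRNA group): per sample, replicate Ct values are averaged on the
Ct scale, dCt = Ct_target - Ct_reference, ddCt subtracts the control-group
mean dCt, and relative expression is 2^(-ddCt) (amplification efficiency
fixed at 2, no standard-curve correction). Group differences use Student's
two-sample t-test (pooled variance by default, Welch via flag) with the usual
significance stars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError

CT_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample_id, group, gene, replicate, ct."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"Ct table missing column(s): {missing}")
    if (df["ct"] <= 0).any():
        raise DataError("Ct values must be positive")
    return df


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str,
) -> pd.DataFrame:
    """Per-sample relative expression 2^(-ddCt) of ``target``.

    Samples lacking a reference-gene measurement are dropped with a warning.
    The control group's relative expressions have geometric mean exactly 1 by
    construction.
    """
    mean_ct = (table.groupby(["sample_id", "group", "gene"])["ct"]
               .mean().reset_index())
    tgt = mean_ct[mean_ct["gene"] == target].set_index("sample_id")
    ref = mean_ct[mean_ct["gene"] == reference].set_index("sample_id")
    if tgt.empty:
        raise DataError(f"no measurements for target gene {target!r}")
    no_ref = tgt.index.difference(ref.index)
    if len(no_ref):
        warnings.warn(
            f"dropping sample(s) without reference measurement: {list(no_ref)}",
            stacklevel=2,
        )
        tgt = tgt.drop(no_ref)
    out = pd.DataFrame({
        "group": tgt["group"],
        "delta_ct": tgt["ct"] - ref.loc[tgt.index, "ct"],
    })
    control = out[out["group"] == control_group]
    if control.empty:
        raise DataError(f"control group {control_group!r} is empty")
    out["ddct"] = out["delta_ct"] - control["delta_ct"].mean()
    out["rel_expr"] = 2.0 ** (-out["ddct"])
    return out.reset_index()


@dataclass
class GroupComparison:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t: float
    p: float
    label: str  # "**", "*" or "N.S."


def group_compare(
    rel: pd.DataFrame,
    group_a: str,
    group_b: str,
    value_col: str = "rel_expr",
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided t-test between two groups of per-sample relative expressions.

    ``equal_var=True`` is the classic Student's test; set False for Welch.
    Stars: ``**`` p < 0.01, ``*`` p < 0.05, otherwise ``N.S.``.
    """
    a = rel.loc[rel["group"] == group_a, value_col].to_numpy(dtype=float)
    b = rel.loc[rel["group"] == group_b, value_col].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >=2 values for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):  # zero variance in both groups with identical means
        p = 1.0
    label = "**" if p < 0.01 else ("*" if p < 0.05 else "N.S.")
    return GroupComparison(
        mean_a=float(a.mean()), sem_a=float(stats.sem(a)),
        mean_b=float(b.mean()), sem_b=float(stats.sem(b)),
        t=float(t), p=float(p), label=label,
    )
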