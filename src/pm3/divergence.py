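"""Per-gene two-group divergence metrics.

Three complementary metrics summarise how a panel gene's expression differs
between case and control samples:

* percent expression difference, ``%d = 100 * (mean_case - mean_control) /
  mean_control`` — the signed, scale-free effect size;
* log2 fold change, ``log2(1 + %d/100) == log2(mean_case / mean_control)``
  — the same quantity on the conventional transcriptomics scale;
* mean Euclidean distance — the average absolute deviation of case samples
  from the control centroid (or over all case x control pairs), carrying
  dispersion information the mean-based metrics ignore.

All three are computed on the linear expression scale; no fold-change
threshold is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionStudy
from .gene_model import GeneModel

__all__ = [
    "DivergenceError",
    "DivergenceRecord",
    "percent_diff",
    "log2fc_from_pct",
    "mean_euclidean_distance",
    "divergence_table",
    "FLAG_CONTROL_MEAN_ZERO",
]

FLAG_CONTROL_MEAN_ZERO = "control_mean_zero"


class DivergenceError(ValueError):
    """Raised for undefined divergence (e.g. zero control mean)."""


@dataclass(frozen=True)
class DivergenceRecord:
    symbol: str
    pct_diff: float
    log2fc: float
    mean_ed: float
    case_mean: float
    control_mean: float
    flags: str = ""


def percent_diff(case_values, control_values) -> float:
    """Percent expression difference between group means.

    ``100 * (mean(case) - mean(control)) / mean(control)``; positive values
    mean upregulation in cases.  Undefined when the control mean is zero.
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise DivergenceError("both groups must be nonempty")
    cm = control_values.mean()
    if cm == 0.0:
        raise DivergenceError("control mean is zero; percent difference undefined")
    return 100.0 * (case_values.mean() - cm) / cm


def log2fc_from_pct(pct_diff: float) -> float:
    """log2 fold change implied by a percent difference.

    ``log2(1 + pct/100)``; equals ``log2(case_mean / control_mean)`` exactly
    when both are derived from the same group means.
    """
    if pct_diff <= -100.0:
        raise DivergenceError(
            f"percent difference {pct_diff} <= -100 has no finite log2FC"
        )
    return math.log2(1.0 + pct_diff / 100.0)


def mean_euclidean_distance(case_values, control_values, mode: str = "centroid") -> float:
    """Mean Euclidean distance of case samples from controls (per gene, 1-D).

    mode='centroid' (default): mean over case samples of
    ``|x_i - mean(control)|``.  mode='pairwise': mean of ``|x_i - y_j|``
    over all case x control pairs.
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise DivergenceError("both groups must be nonempty")
    if mode == "centroid":
        return float(np.abs(case_values - control_values.mean()).mean())
    if mode == "pairwise":
        return float(
            np.abs(case_values[:, None] - control_values[None, :]).mean()
        )
    raise DivergenceError(f"unknown Euclidean-distance mode: {mode!r}")


def divergence_table(
    study: ExpressionStudy,
    model: GeneModel | None = None,
    ed_mode: str = "centroid",
    ed_study: ExpressionStudy | None = None,
) -> pd.DataFrame:
    """Compute all divergence metrics for every gene in the (aligned) study.

    Returns a DataFrame indexed by symbol with columns ``pct_diff, log2fc,
    mean_ed, case_mean, control_mean, flags``.  Genes with a zero control
    mean get NaN metrics and the ``control_mean_zero`` flag instead of an
    error.  ``ed_study`` optionally supplies transformed values for the
    distance metric only (the ratio metrics always use the linear scale).
    """
    genes = model.symbols if model is not None else study.genes
    present = set(study.genes)
    genes = [g for g in genes if g in present]
    ed_source = ed_study if ed_study is not None else study
    case = study.case_values
    control = study.control_values
    ed_case = ed_source.case_values
    ed_control = ed_source.control_values

    rows = []
    for g in genes:
        cvals = case.loc[g].to_numpy(dtype=float)
        kvals = control.loc[g].to_numpy(dtype=float)
        med = mean_euclidean_distance(
            ed_case.loc[g].to_numpy(dtype=float),
            ed_control.loc[g].to_numpy(dtype=float),
            mode=ed_mode,
        )
        km = kvals.mean()
        if km == 0.0:
            rows.append(
                DivergenceRecord(g, np.nan, np.nan, med, cvals.mean(), 0.0,
                                 FLAG_CONTROL_MEAN_ZERO)
            )
            continue
        pct = percent_diff(cvals, kvals)
        rows.append(
            DivergenceRecord(g, pct, log2fc_from_pct(pct), med, cvals.mean(), km)
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("symbol")
    return df
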