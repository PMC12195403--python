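"""Per-gene anomaly scoring and rank-based discrimination AUC.

For every panel gene a one-dimensional isolation forest is fitted across
samples and every sample is scored, yielding a genes x samples anomaly-score
matrix.  By default the forest is trained on the control samples only
(``reference_controls``): anomaly then means "deviates from the control
expression distribution", which preserves the monotone link between a
group-level shift and the AUC.  ``pooled`` mode trains on all samples
instead (both tails of the pooled distribution then look anomalous).

The discrimination AUC is the Mann-Whitney statistic
``P(score_case > score_control)`` with ties at half weight.  For unsigned
ranking it is folded to [0.5, 1]; direction is carried by the percent
difference, not the AUC.
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression_io import CASE, CONTROL, ExpressionStudy
from .gene_model import GeneModel
from .isolation_forest import ForestParams, fit_forest

__all__ = [
    "TRAINING_MODES",
    "gene_seed",
    "gene_anomaly_scores",
    "auc_rank",
    "folded_auc",
    "anomaly_table",
]

TRAINING_MODES = ("reference_controls", "pooled")


def gene_seed(base_seed: int, symbol: str) -> int:
    """Deterministic per-gene seed: base seed plus a stable symbol hash.

    Uses CRC-32 of the UTF-8 symbol so results never depend on gene order
    or on Python's randomized ``hash``; reduced mod 2**31.
    """
    return int((int(base_seed) + zlib.crc32(symbol.encode("utf-8"))) % (2**31))


def gene_anomaly_scores(
    study: ExpressionStudy,
    symbol: str,
    params: ForestParams | None = None,
    training_mode: str = "reference_controls",
) -> pd.Series:
    """Anomaly score per sample for one gene.

    The forest is trained on the sorted training values (controls only or
    all samples), so scores depend on the multiset of training values —
    never on sample order.  The per-gene seed is derived from
    ``params.seed`` and the symbol.
    """
    if training_mode not in TRAINING_MODES:
        raise ValueError(f"unknown training_mode: {training_mode!r}")
    if symbol not in study.values.index:
        raise KeyError(f"gene {symbol!r} not present in study")
    params = params or ForestParams()
    row = study.values.loc[symbol]
    if training_mode == "reference_controls":
        train = row[study.group_samples(CONTROL)].to_numpy(dtype=float)
    else:
        train = row.to_numpy(dtype=float)
    if train.size < 2:
        raise ValueError(f"gene {symbol!r}: need >= 2 training samples")
    train = np.sort(train)  # order-invariance w.r.t. sample ordering
    gparams = replace(params, seed=gene_seed(params.seed, symbol))
    forest = fit_forest(train[:, None], gparams)
    scores = forest.score(row.to_numpy(dtype=float)[:, None])
    return pd.Series(scores, index=study.samples, name=symbol)


def auc_rank(scores_case, scores_control) -> float:
    """Directional Mann-Whitney AUC: P(case > control) + 0.5 P(tie).

    Computed from midranks, exactly equal to pair counting:
    ``(#{case > control} + 0.5 #{ties}) / (n_case * n_control)``.
    """
    a = np.asarray(scores_case, dtype=float)
    b = np.asarray(scores_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score vectors must be nonempty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def folded_auc(auc_directional: float) -> float:
    """Fold a directional AUC to the unsigned [0.5, 1] ranking scale."""
    return max(auc_directional, 1.0 - auc_directional)


def anomaly_table(
    study: ExpressionStudy,
    model: GeneModel | None = None,
    params: ForestParams | None = None,
    training_mode: str = "reference_controls",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every panel gene and derive its discrimination AUC.

    Returns ``(auc_table, score_matrix)``: the per-gene table has columns
    ``auc_directional, auc, training_mode`` (indexed by symbol); the score
    matrix is genes x samples and feeds the clustering stage.
    """
    params = params or ForestParams()
    genes = model.symbols if model is not None else study.genes
    present = set(study.genes)
    genes = [g for g in genes if g in present]
    case_ids = study.group_samples(CASE)
    control_ids = study.group_samples(CONTROL)

    score_rows = []
    records = []
    for g in genes:
        s = gene_anomaly_scores(study, g, params, training_mode)
        score_rows.append(s)
        directional = auc_rank(
            s[case_ids].to_numpy(), s[control_ids].to_numpy()
        )
        records.append(
            {
                "symbol": g,
                "auc_directional": directional,
                "auc": folded_auc(directional),
                "training_mode": training_mode,
            }
        )
    score_matrix = pd.DataFrame(score_rows)
    score_matrix.index.name = "symbol"
    auc_table = pd.DataFrame(records).set_index("symbol")
    return auc_table, score_matrix
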