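"""Merged, ranked and stratified screening reports.

Joins the divergence table, the anomaly/AUC table, the cluster assignments
and the panel annotations into one table ranked by folded AUC (ties broken
by |percent difference|, then symbol).  Stratified views — by metabolic
domain, and a long-format cofactor x compartment view — are derived from
the same rows, so every figure-ready table traces back to one report.

Hypothesis testing is deliberately opt-in annotation only: the screening
rank is the anomaly AUC, never a p-value.  When enabled, a two-sided
Mann-Whitney rank-sum test per gene with Benjamini-Hochberg adjustment is
attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu

from .clustering import ClusteringResult
from .expression_io import CASE, CONTROL, ExpressionStudy
from .gene_model import GeneModel

__all__ = [
    "ReportError",
    "Pm3Report",
    "build_report",
    "top_genes",
    "stratify_domains",
    "cofactor_view",
    "optional_tests",
]

_REPORT_COLUMNS = [
    "enzyme_name",
    "pct_diff",
    "log2fc",
    "mean_ed",
    "auc",
    "auc_directional",
    "cofactors",
    "pathway",
    "domain",
    "compartment",
    "functional_role",
    "cluster",
    "flags",
]


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class Pm3Report:
    """Ranked per-gene screening table plus run metadata."""

    rows: pd.DataFrame  # indexed by symbol, ranked
    metadata: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def rounded(self) -> pd.DataFrame:
        """Presentation copy: %d to 2 d.p., log2FC to 3 d.p., AUC to 2 d.p."""
        out = self.rows.copy()
        out["pct_diff"] = out["pct_diff"].round(2)
        out["log2fc"] = out["log2fc"].round(3)
        out["mean_ed"] = out["mean_ed"].round(3)
        out["auc"] = out["auc"].round(2)
        out["auc_directional"] = out["auc_directional"].round(3)
        return out


def _rank_order(df: pd.DataFrame) -> pd.DataFrame:
    """AUC-descending order; ties by |pct_diff| desc, then symbol; flagged last."""
    work = df.copy()
    work["_flagged"] = (work["flags"] != "").astype(int)
    work["_abs_pct"] = work["pct_diff"].abs().fillna(-np.inf)
    work["_symbol"] = work.index
    work = work.sort_values(
        by=["_flagged", "auc", "_abs_pct", "_symbol"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    return work.drop(columns=["_flagged", "_abs_pct", "_symbol"])


def build_report(
    divergence_table: pd.DataFrame,
    anomaly_table: pd.DataFrame,
    clustering_result: ClusteringResult | None,
    model: GeneModel,
    metadata: dict[str, Any] | None = None,
) -> Pm3Report:
    """Merge metrics, anomaly AUCs, clusters and annotations into one report.

    All inputs must cover exactly the same gene set; a mismatch is an error
    listing the offending symbols.
    """
    div_genes = set(divergence_table.index)
    auc_genes = set(anomaly_table.index)
    if div_genes != auc_genes:
        raise ReportError(
            "gene-set mismatch between divergence and anomaly tables: "
            f"{sorted(div_genes ^ auc_genes)}"
        )
    not_in_model = sorted(g for g in div_genes if g not in model)
    if not_in_model:
        raise ReportError(f"genes absent from the gene model: {not_in_model}")

    rows = divergence_table.copy()
    rows["auc"] = anomaly_table["auc"]
    rows["auc_directional"] = anomaly_table["auc_directional"]
    if clustering_result is not None:
        rows["cluster"] = pd.Series(clustering_result.assignments)
    else:
        rows["cluster"] = 1
    ann = {a.symbol: a for a in model}
    rows["enzyme_name"] = [ann[g].enzyme_name for g in rows.index]
    rows["cofactors"] = [";".join(sorted(ann[g].cofactors)) for g in rows.index]
    rows["pathway"] = [ann[g].pathway for g in rows.index]
    rows["domain"] = [ann[g].domain for g in rows.index]
    rows["compartment"] = [ann[g].compartment for g in rows.index]
    rows["functional_role"] = [ann[g].functional_role for g in rows.index]
    rows = _rank_order(rows)
    cols = _REPORT_COLUMNS + [
        c for c in rows.columns if c not in _REPORT_COLUMNS
    ]
    rows = rows[[c for c in cols if c in rows.columns]]
    rows.index.name = "symbol"
    return Pm3Report(rows=rows, metadata=dict(metadata or {}))


def top_genes(report: Pm3Report, auc_threshold: float = 0.70) -> pd.DataFrame:
    """Rows with folded AUC strictly above the threshold (flagged excluded)."""
    if not 0.5 <= auc_threshold <= 1.0:
        raise ReportError("auc_threshold must lie in [0.5, 1]")
    rows = report.rows
    keep = (rows["auc"] > auc_threshold) & (rows["flags"] == "")
    return rows[keep]


def stratify_domains(report: Pm3Report) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Partition the report by metabolic domain.

    Returns ``(sub_reports, summary)``: one sub-table per domain tag (always
    including the three major domains, empty or not) and a per-domain
    summary with n, mean %d and mean Euclidean distance.
    """
    rows = report.rows
    domains = ["glycolysis_ppp", "redox_sulfur_one_carbon", "mitochondrial", "other"]
    subs = {d: rows[rows["domain"] == d] for d in domains}
    summary = pd.DataFrame(
        {
            "domain": domains,
            "n": [len(subs[d]) for d in domains],
            "mean_pct_diff": [
                float(subs[d]["pct_diff"].mean()) if len(subs[d]) else np.nan
                for d in domains
            ],
            "mean_ed": [
                float(subs[d]["mean_ed"].mean()) if len(subs[d]) else np.nan
                for d in domains
            ],
        }
    ).set_index("domain")
    return subs, summary


def cofactor_view(report: Pm3Report, model: GeneModel) -> pd.DataFrame:
    """Long-format cofactor table: one row per (gene, cofactor tag) pair.

    Genes with several cofactor dependencies appear once per tag, carrying
    their compartment, %d and mean Euclidean distance — the tidy input for
    compartment-stratified, cofactor-coloured figures.
    """
    records = []
    for symbol, row in report.rows.iterrows():
        for tag in sorted(model[symbol].cofactors):
            records.append(
                {
                    "symbol": symbol,
                    "cofactor": tag,
                    "compartment": row["compartment"],
                    "domain": row["domain"],
                    "pct_diff": row["pct_diff"],
                    "mean_ed": row["mean_ed"],
                    "auc": row["auc"],
                }
            )
    return pd.DataFrame.from_records(records)


def optional_tests(
    report: Pm3Report,
    study: ExpressionStudy,
    method: str = "mann_whitney",
    correction: str = "benjamini_hochberg",
) -> pd.DataFrame:
    """Opt-in per-gene rank-sum tests with BH adjustment (annotation only).

    Two-sided Mann-Whitney on the expression values (exact where SciPy uses
    the exact null, normal approximation otherwise), adjusted by
    Benjamini-Hochberg.  Returned as ``p`` and ``q`` per symbol; never used
    for ranking.
    """
    if method != "mann_whitney":
        raise ReportError(f"unsupported test method: {method!r}")
    if correction != "benjamini_hochberg":
        raise ReportError(f"unsupported correction: {correction!r}")
    case_ids = study.group_samples(CASE)
    control_ids = study.group_samples(CONTROL)
    symbols = [g for g in report.rows.index if g in set(study.genes)]
    pvals = []
    for g in symbols:
        a = study.values.loc[g, case_ids].to_numpy(dtype=float)
        b = study.values.loc[g, control_ids].to_numpy(dtype=float)
        pvals.append(float(mannwhitneyu(a, b, alternative="two-sided").pvalue))
    qvals = false_discovery_control(pvals, method="bh")
    return pd.DataFrame({"p": pvals, "q": qvals}, index=pd.Index(symbols, name="symbol"))
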