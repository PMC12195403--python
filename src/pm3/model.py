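"""Model/Results front end for the metabolic-margin screening pipeline.

:class:`PM3Model` binds a two-group expression study to a curated gene
panel; :meth:`PM3Model.fit` runs the full pipeline — divergence metrics,
per-gene isolation-forest anomaly scoring, discrimination AUCs, K-means
clustering of the anomaly-score matrix — and returns a
:class:`PM3Results` carrying the ranked report, the intermediate tables
and a text ``summary()``.

Example
-------
>>> from pm3 import PM3Model
>>> from pm3.synthetic_data import reference_spec, simulate, sim_gene_model
>>> spec = reference_spec(seed=7)
>>> study, truth = simulate(spec)
>>> res = PM3Model(study, sim_gene_model(spec)).fit(seed=7)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .anomaly_auc import TRAINING_MODES, anomaly_table
from .clustering import ClusteringResult, choose_k, kmeans
from .divergence import divergence_table
from .domain_report import (
    Pm3Report,
    build_report,
    cofactor_view,
    optional_tests,
    stratify_domains,
    top_genes,
)
from .expression_io import AlignmentReport, ExpressionStudy, align, read_study
from .gene_model import GeneModel, load_gene_model
from .isolation_forest import ForestParams

__all__ = ["PM3Model", "PM3Results"]


class PM3Model:
    """Metabolic-panel screening model for a two-group expression study.

    Parameters
    ----------
    study
        Validated :class:`~pm3.expression_io.ExpressionStudy`.
    gene_model
        Curated panel; the study is aligned (restricted and ordered) to it.
    transform
        ``None`` (default) or ``"log2p1"``: apply ``log2(x + 1)`` before
        the anomaly and distance stages.  Ratio metrics (%d, log2FC) always
        use the linear scale, where group-mean ratios are meaningful.
    ed_mode
        ``"centroid"`` (default) or ``"pairwise"`` Euclidean distance.
    """

    def __init__(
        self,
        study: ExpressionStudy,
        gene_model: GeneModel,
        transform: str | None = None,
        ed_mode: str = "centroid",
    ) -> None:
        self.gene_model = gene_model
        self.transform = transform
        self.ed_mode = ed_mode
        self.study, self.align_report = align(study, gene_model)

    @classmethod
    def from_files(
        cls,
        expression_path,
        labels_path,
        gene_model_path,
        **kwargs,
    ) -> "PM3Model":
        """Build a model straight from the three input TSVs."""
        study = read_study(expression_path, labels_path)
        panel = load_gene_model(gene_model_path)
        return cls(study, panel, **kwargs)

    def fit(
        self,
        n_trees: int = 100,
        subsample: int | None = None,
        max_depth: int | None = None,
        seed: int = 0,
        training_mode: str = "reference_controls",
        k: int | None = None,
        k_range: tuple[int, int] = (2, 8),
        auc_threshold: float = 0.70,
    ) -> "PM3Results":
        """Run divergence, anomaly scoring, clustering and report assembly."""
        if training_mode not in TRAINING_MODES:
            raise ValueError(f"unknown training_mode: {training_mode!r}")
        params = ForestParams(
            n_trees=n_trees, subsample=subsample, max_depth=max_depth, seed=seed
        )
        work = self.study.transformed(self.transform)

        div = divergence_table(
            self.study, self.gene_model, ed_mode=self.ed_mode, ed_study=work
        )
        auc, scores = anomaly_table(
            work, self.gene_model, params=params, training_mode=training_mode
        )

        clustering: ClusteringResult | None = None
        chosen_k = k
        if len(scores) >= 2:
            if chosen_k is None and len(scores) >= 3:
                lo, hi = k_range
                chosen_k = choose_k(
                    scores, range(lo, min(hi, len(scores) - 1) + 1), seed=seed
                )
            elif chosen_k is None:
                chosen_k = 2
            clustering = kmeans(scores, chosen_k, seed=seed)

        metadata: dict[str, Any] = {
            "pm3_version": __version__,
            "gene_model": {"name": self.gene_model.name,
                           "version": self.gene_model.version,
                           "n_genes": len(self.gene_model)},
            "n_case": len(self.study.group_samples("case")),
            "n_control": len(self.study.group_samples("control")),
            "transform": self.transform,
            "ed_mode": self.ed_mode,
            "forest": {"n_trees": n_trees, "subsample": subsample,
                       "max_depth": max_depth, "seed": seed},
            "training_mode": training_mode,
            "k": chosen_k,
            "k_range": list(k_range),
            "auc_threshold": auc_threshold,
            "align": {"missing": list(self.align_report.missing),
                      "n_extra": self.align_report.n_extra},
        }
        report = build_report(div, auc, clustering, self.gene_model, metadata)
        return PM3Results(
            model=self,
            report=report,
            divergence=div,
            anomaly=auc,
            score_matrix=scores,
            clustering=clustering,
            auc_threshold=auc_threshold,
        )


@dataclass
class PM3Results:
    """Fitted screening results: ranked report plus all intermediates."""

    model: PM3Model
    report: Pm3Report
    divergence: pd.DataFrame
    anomaly: pd.DataFrame
    score_matrix: pd.DataFrame
    clustering: ClusteringResult | None
    auc_threshold: float = 0.70

    # -- views -------------------------------------------------------------

    def top_genes(self, auc_threshold: float | None = None) -> pd.DataFrame:
        return top_genes(
            self.report,
            self.auc_threshold if auc_threshold is None else auc_threshold,
        )

    def stratify_domains(self):
        return stratify_domains(self.report)

    def cofactor_view(self) -> pd.DataFrame:
        return cofactor_view(self.report, self.model.gene_model)

    def hypothesis_tests(self) -> pd.DataFrame:
        """Opt-in Mann-Whitney + BH annotation (never used for ranking)."""
        return optional_tests(self.report, self.model.study)

    def summary(self, max_rows: int = 20) -> str:
        """Human-readable ranked summary in the style of a results table."""
        meta = self.report.metadata
        rows = self.report.rounded()
        top = top_genes(self.report, self.auc_threshold)
        lines = [
            "Personalized Metabolic Margin Mapping",
            "=" * 70,
            f"genes: {len(rows)} panel genes   samples: "
            f"{meta.get('n_case', '?')} case / {meta.get('n_control', '?')} control",
            f"forest: {meta['forest']['n_trees']} trees, seed "
            f"{meta['forest']['seed']}, training={meta.get('training_mode')}",
            f"clusters: k={meta.get('k')}   "
            f"AUC > {self.auc_threshold:.2f}: {len(top)} gene(s)",
            "-" * 70,
        ]
        shown = rows.head(max_rows)[
            ["pct_diff", "log2fc", "mean_ed", "auc", "cluster", "domain"]
        ]
        lines.append(shown.to_string())
        if len(rows) > max_rows:
            lines.append(f"... ({len(rows) - max_rows} more rows)")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, outdir) -> Path:
        """Write all result tables as TSV plus a JSON metadata-bearing report.

        Outputs are byte-stable for a fixed configuration: no timestamps,
        fixed float formatting.
        """
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.divergence.to_csv(out / "divergence.tsv", sep="\t", float_format=fmt)
        self.anomaly.to_csv(out / "auc.tsv", sep="\t", float_format=fmt)
        self.score_matrix.to_csv(
            out / "anomaly_scores.tsv", sep="\t", float_format=fmt
        )
        if self.clustering is not None:
            pd.Series(self.clustering.assignments, name="cluster").rename_axis(
                "symbol"
            ).to_csv(out / "clusters.tsv", sep="\t")
            pd.DataFrame(
                self.clustering.centroids,
                index=pd.Index(
                    range(1, self.clustering.k + 1), name="cluster"
                ),
                columns=self.score_matrix.columns,
            ).to_csv(out / "centroids.tsv", sep="\t", float_format=fmt)
        self.report.rows.to_csv(out / "report.tsv", sep="\t", float_format=fmt)
        payload = {
            "metadata": self.report.metadata,
            "rows": json.loads(
                self.report.rows.reset_index().to_json(orient="records")
            ),
        }
        (out / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        )
        return out
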