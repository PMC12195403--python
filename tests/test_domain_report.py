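import json

import numpy as np
import pandas as pd
import pytest

from pm3.domain_report import (
    Pm3Report,
    ReportError,
    build_report,
    cofactor_view,
    optional_tests,
    stratify_domains,
    top_genes,
)
from pm3.model import PM3Model

from conftest import make_study


@pytest.fixture(scope="module")
def results(panel_study, panel):
    return PM3Model(panel_study, panel).fit(seed=11)


@pytest.fixture(scope="module")
def report(results):
    return results.report


class TestBuildReport:
    def test_one_fully_populated_row_per_panel_gene(self, report, panel):
        assert len(report) == 26
        assert set(report.rows.index) == set(panel.symbols)
        for col in ("pct_diff", "log2fc", "mean_ed", "auc", "cofactors",
                    "pathway", "domain", "compartment", "cluster"):
            assert report.rows[col].notna().all(), col

    def test_rows_sorted_by_auc_with_documented_tiebreak(self, report):
        rows = report.rows[report.rows["flags"] == ""]
        keys = list(
            zip(-rows["auc"], -rows["pct_diff"].abs(), rows.index)
        )
        assert keys == sorted(keys)

    def test_gene_set_mismatch_lists_symbols(self, results, panel):
        div = results.divergence.drop(index="GOT1")
        with pytest.raises(ReportError, match="GOT1"):
            build_report(div, results.anomaly, results.clustering, panel)

    def test_equal_auc_ties_broken_by_abs_pct_then_symbol(self, panel):
        div = pd.DataFrame(
            {
                "pct_diff": [5.0, -8.0, 8.0],
                "log2fc": [0.07, -0.12, 0.11],
                "mean_ed": [1.0, 1.0, 1.0],
                "case_mean": [1, 1, 1],
                "control_mean": [1, 1, 1],
                "flags": ["", "", ""],
            },
            index=pd.Index(["GOT1", "GOT2", "GLS"], name="symbol"),
        )
        auc = pd.DataFrame(
            {"auc_directional": [0.2, 0.8, 0.8], "auc": [0.8, 0.8, 0.8],
             "training_mode": ["reference_controls"] * 3},
            index=div.index,
        )
        rep = build_report(div, auc, None, panel)
        assert list(rep.rows.index) == ["GLS", "GOT2", "GOT1"]

    def test_flagged_gene_present_but_ranked_last(self, panel):
        div = pd.DataFrame(
            {
                "pct_diff": [np.nan, 3.0],
                "log2fc": [np.nan, 0.04],
                "mean_ed": [1.0, 1.0],
                "case_mean": [1.0, 1.0],
                "control_mean": [0.0, 1.0],
                "flags": ["control_mean_zero", ""],
            },
            index=pd.Index(["GOT1", "GOT2"], name="symbol"),
        )
        auc = pd.DataFrame(
            {"auc_directional": [0.9, 0.6], "auc": [0.9, 0.6],
             "training_mode": ["reference_controls"] * 2},
            index=div.index,
        )
        rep = build_report(div, auc, None, panel)
        assert list(rep.rows.index) == ["GOT2", "GOT1"]  # flagged last despite AUC
        assert top_genes(rep, 0.5).index.tolist() == ["GOT2"]


class TestTopGenes:
    def test_strict_threshold(self, panel):
        div = pd.DataFrame(
            {
                "pct_diff": [1.0, 2.0, 3.0],
                "log2fc": [0.01, 0.03, 0.04],
                "mean_ed": [1, 1, 1],
                "case_mean": [1, 1, 1],
                "control_mean": [1, 1, 1],
                "flags": ["", "", ""],
            },
            index=pd.Index(["GOT1", "GOT2", "GLS"], name="symbol"),
        )
        auc = pd.DataFrame(
            {"auc_directional": [0.88, 0.70, 0.69], "auc": [0.88, 0.70, 0.69],
             "training_mode": ["reference_controls"] * 3},
            index=div.index,
        )
        rep = build_report(div, auc, None, panel)
        assert len(top_genes(rep, 0.70)) == 1  # 0.70 itself excluded
        assert len(top_genes(rep, 0.5)) == 3

    def test_threshold_domain_checked(self, report):
        with pytest.raises(ReportError):
            top_genes(report, 0.3)


class TestStratification:
    def test_partition_covers_every_row_once(self, report):
        subs, summary = stratify_domains(report)
        total = sum(len(df) for df in subs.values())
        assert total == len(report)
        assert summary["n"].sum() == len(report)
        assert report.rows.loc["GOT1", "domain"] == "other"
        assert "GOT1" in subs["other"].index

    def test_empty_domain_has_zero_summary(self, report):
        subs, summary = stratify_domains(report)
        assert len(subs["glycolysis_ppp"]) == 0
        assert summary.loc["glycolysis_ppp", "n"] == 0

    def test_domain_means_match_hand_computation(self, report):
        subs, summary = stratify_domains(report)
        mito = subs["mitochondrial"]
        assert summary.loc["mitochondrial", "mean_pct_diff"] == pytest.approx(
            float(np.mean([report.rows.loc[g, "pct_diff"] for g in mito.index]))
        )


class TestCofactorView:
    def test_ogdh_appears_once_per_cofactor(self, report, panel):
        view = cofactor_view(report, panel)
        assert len(view[view["symbol"] == "OGDH"]) == 4

    def test_none_gene_has_single_row(self, report, panel):
        view = cofactor_view(report, panel)
        tst = view[view["symbol"] == "TST"]
        assert len(tst) == 1
        assert tst["cofactor"].iloc[0] == "none"

    def test_total_rows_equal_sum_of_cofactor_counts(self, report, panel):
        view = cofactor_view(report, panel)
        assert len(view) == sum(len(a.cofactors) for a in panel)


class TestOptionalTests:
    def test_perfect_separation_4v4_has_exact_p_2_over_70(self, panel):
        vals = np.array([[10.0, 11, 12, 13, 1.0, 2, 3, 4]])
        study = make_study(vals, [f"c{i}" for i in range(4)],
                           [f"k{i}" for i in range(4)], genes=["GOT1"])
        rep = _single_gene_report(panel)
        out = optional_tests(rep, study)
        assert out.loc["GOT1", "p"] == pytest.approx(2 / 70, abs=1e-12)

    def test_identical_groups_p_one(self, panel):
        vals = np.array([[5.0, 6, 7, 8, 5.0, 6, 7, 8]])
        study = make_study(vals, [f"c{i}" for i in range(4)],
                           [f"k{i}" for i in range(4)], genes=["GOT1"])
        out = optional_tests(_single_gene_report(panel), study)
        assert out.loc["GOT1", "p"] == pytest.approx(1.0)

    def test_bh_adjustment_matches_hand_computation(self, results):
        out = results.hypothesis_tests()
        p = out["p"].to_numpy()
        # hand BH: sort, p*m/i, reverse cumulative minimum, cap at 1
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        q_hand = np.empty(m)
        q_hand[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(out["q"].to_numpy(), q_hand, atol=1e-12)

    def test_unsupported_method_rejected(self, results, panel_study):
        with pytest.raises(ReportError):
            optional_tests(results.report, panel_study, method="t_test")


def _single_gene_report(panel):
    div = pd.DataFrame(
        {
            "pct_diff": [10.0],
            "log2fc": [0.14],
            "mean_ed": [1.0],
            "case_mean": [1.0],
            "control_mean": [1.0],
            "flags": [""],
        },
        index=pd.Index(["GOT1"], name="symbol"),
    )
    auc = pd.DataFrame(
        {"auc_directional": [0.9], "auc": [0.9],
         "training_mode": ["reference_controls"]},
        index=div.index,
    )
    return build_report(div, auc, None, panel)


class TestPersistence:
    def test_saved_report_reloads_identically(self, results, tmp_path):
        out = results.save(tmp_path / "run")
        reloaded = pd.read_csv(out / "report.tsv", sep="\t", index_col="symbol")
        assert list(reloaded.index) == list(results.report.rows.index)
        for col in ("pct_diff", "log2fc", "mean_ed", "auc"):
            assert np.allclose(
                reloaded[col].to_numpy(),
                results.report.rows[col].to_numpy(),
                rtol=1e-9, equal_nan=True,
            )
        meta = json.loads((out / "report.json").read_text())["metadata"]
        assert meta["forest"]["seed"] == 11
        assert meta["training_mode"] == "reference_controls"
        assert meta["k"] is not None

    def test_metadata_records_every_result_affecting_parameter(self, report):
        meta = report.metadata
        for key in ("forest", "training_mode", "k", "ed_mode", "transform",
                    "auc_threshold", "gene_model"):
            assert key in meta
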