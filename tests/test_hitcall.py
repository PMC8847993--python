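"""Hit calling: cross-replicate ratios, five-fold rule, gene calls, z-scores."""

import math

import numpy as np
import pandas as pd
import pytest

from slscreen import (
    NONTARGETING,
    ScreenDesign,
    call_genes,
    compute_ratios,
    compute_zscores,
    flag_fivefold,
    report,
)
from slscreen.hitcall import RATIO_COLUMNS

from .conftest import counts_from_rows, make_library, random_count_matrix


def one_gene_counts(lib, per_clone):
    return counts_from_rows(lib, dict(zip(lib.clone_ids, per_clone)))


def stats_from_ratios(ratio_rows, genes=None):
    """Build a stats frame directly from ratio 4-tuples (unit-test shortcut)."""
    idx = [f"sh{i}" for i in range(len(ratio_rows))]
    df = pd.DataFrame(ratio_rows, index=idx, columns=RATIO_COLUMNS)
    df.insert(0, "gene", genes or ["G1"] * len(ratio_rows))
    df["mean_log2_ratio"] = np.log2(df[RATIO_COLUMNS]).mean(axis=1)
    df["low_abundance"] = False
    return df


class TestComputeRatios:
    def test_flat_counts_give_unit_ratios(self, design):
        lib = make_library({"G1": 1})
        cm = one_gene_counts(lib, [(50, 50, 50, 50)])
        stats = compute_ratios(cm, lib, design, pseudocount=0, normalization="raw")
        row = stats.iloc[0]
        assert all(row[c] == 1.0 for c in RATIO_COLUMNS)
        assert row["mean_log2_ratio"] == 0.0

    def test_direct_arithmetic_example(self, design):
        # (KO1,KO2,C1,C2) = (10,8,100,80): r13=10/100, r14=10/80, r23=8/100,
        # r24=8/80; mean log2 = mean(log2(0.1), log2(0.125), log2(0.08),
        # log2(0.1)) = -3.3219 (independent arithmetic oracle)
        lib = make_library({"G1": 1})
        cm = one_gene_counts(lib, [(10, 8, 100, 80)])
        row = compute_ratios(cm, lib, design, pseudocount=0,
                             normalization="raw").iloc[0]
        assert row["r13"] == pytest.approx(0.100)
        assert row["r14"] == pytest.approx(0.125)
        assert row["r23"] == pytest.approx(0.080)
        assert row["r24"] == pytest.approx(0.100)
        want = (math.log2(0.1) + math.log2(0.125) + math.log2(0.08)
                + math.log2(0.1)) / 4
        assert row["mean_log2_ratio"] == pytest.approx(want)
        assert row["mean_log2_ratio"] == pytest.approx(-3.3219, abs=1e-4)

    def test_pseudocount_on_zero_ko_counts(self, design):
        lib = make_library({"G1": 2})
        cm = one_gene_counts(lib, [(0, 0, 40, 60), (10, 10, 20, 20)])
        row = compute_ratios(cm, lib, design, pseudocount=1,
                             normalization="raw").iloc[0]
        assert row["r13"] == pytest.approx(1 / 41)
        assert row["r14"] == pytest.approx(1 / 61)
        assert row["r23"] == pytest.approx(row["r13"])
        assert row["r24"] == pytest.approx(row["r14"])

    def test_pseudocount_zero_drops_zero_count_clones(self, design):
        lib = make_library({"G1": 2})
        cm = one_gene_counts(lib, [(0, 5, 40, 60), (10, 10, 20, 20)])
        stats = compute_ratios(cm, lib, design, pseudocount=0,
                               normalization="raw")
        assert list(stats.index) == ["G1_sh2"]

    def test_all_zero_sample_column_rejected(self, design):
        lib = make_library({"G1": 2})
        cm = one_gene_counts(lib, [(0, 5, 40, 60), (0, 10, 20, 20)])
        with pytest.raises(ValueError, match="all zero"):
            compute_ratios(cm, lib, design)

    def test_cpm_mode_is_column_scale_invariant(self, design):
        lib = make_library({"G1": 4, "G2": 4})
        cm = random_count_matrix(lib, seed=2, low=1, high=500)
        a = compute_ratios(cm, lib, design, normalization="cpm")
        cm.counts["KO1"] *= 7  # depth change only
        b = compute_ratios(cm, lib, design, normalization="cpm")
        assert np.allclose(a[RATIO_COLUMNS], b[RATIO_COLUMNS])

    def test_raw_mode_scales_with_column(self, design):
        lib = make_library({"G1": 2})
        cm = one_gene_counts(lib, [(10, 10, 10, 10), (20, 20, 20, 20)])
        a = compute_ratios(cm, lib, design, pseudocount=0, normalization="raw")
        cm.counts["KO1"] *= 3
        b = compute_ratios(cm, lib, design, pseudocount=0, normalization="raw")
        assert np.allclose(b["r13"], 3 * a["r13"])
        assert np.allclose(b["r23"], a["r23"])

    def test_low_abundance_flagged_on_raw_counts(self, design):
        lib = make_library({"G1": 2})
        cm = one_gene_counts(lib, [(3, 2, 9, 4), (3, 2, 10, 4)])
        stats = compute_ratios(cm, lib, design, min_count=10)
        assert stats["low_abundance"].tolist() == [True, False]


class TestFlagFivefold:
    @pytest.mark.parametrize(
        "ratios, want_flag, want_depleted",
        [
            ((0.19, 0.18, 0.15, 0.20), "depleted", True),
            ((0.19, 0.18, 0.15, 0.21), "none", True),  # boundary: one > 1/5
            ((1.0, 1.0, 1.0, 1.0), "none", False),
            ((6.0, 5.0, 7.0, 5.5), "enriched", False),
            ((6.0, 4.9, 7.0, 5.5), "none", False),
        ],
    )
    def test_rule_on_hand_checked_ratios(self, ratios, want_flag, want_depleted):
        stats = flag_fivefold(stats_from_ratios([ratios]), fold_threshold=5)
        assert stats["fivefold_all4"].iloc[0] == want_flag
        assert bool(stats["depleted_all4"].iloc[0]) is want_depleted

    def test_raising_threshold_never_adds_flags(self):
        rng = np.random.default_rng(0)
        rows = np.exp(rng.normal(0, 2, size=(200, 4)))
        stats = stats_from_ratios(list(map(tuple, rows)))
        n_prev = None
        for fold in (2, 5, 10, 50):
            flagged = flag_fivefold(stats, fold_threshold=fold)
            n = int((flagged["fivefold_all4"] != "none").sum())
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestCallGenes:
    def _calls(self, depleted, fivefold, gene="G1"):
        rows = []
        for d, f in zip(depleted, fivefold):
            if f:  # fivefold depleted implies depleted
                rows.append((0.1, 0.1, 0.1, 0.1))
            elif d:
                rows.append((0.9, 0.8, 0.9, 0.7))
            else:
                rows.append((1.5, 0.9, 1.1, 1.2))
        stats = flag_fivefold(stats_from_ratios(rows, genes=[gene] * len(rows)))
        return call_genes(stats)

    def test_two_depleted_one_fivefold_is_candidate(self):
        calls = self._calls([True, True, False, False, False],
                            [True, False, False, False, False])
        assert bool(calls["candidate"].iloc[0]) is True
        assert calls["n_depleted"].iloc[0] == 2
        assert calls["n_fivefold_depleted"].iloc[0] == 1

    def test_single_depleted_clone_not_candidate(self):
        calls = self._calls([True, False, False, False], [True, False, False, False])
        assert bool(calls["candidate"].iloc[0]) is False

    def test_no_fivefold_clone_not_candidate(self):
        calls = self._calls([True, True, True], [False, False, False])
        assert bool(calls["candidate"].iloc[0]) is False

    def test_controls_excluded_from_gene_calls(self):
        stats = flag_fivefold(stats_from_ratios(
            [(0.1, 0.1, 0.1, 0.1)] * 2 + [(0.1, 0.1, 0.1, 0.1)],
            genes=["G1", "G1", NONTARGETING],
        ))
        calls = call_genes(stats)
        assert calls["gene"].tolist() == ["G1"]

    def test_unknown_gene_rejected_against_library(self):
        lib = make_library({"G1": 2})
        stats = flag_fivefold(stats_from_ratios([(1, 1, 1, 1)], genes=["GX"]))
        with pytest.raises(ValueError, match="GX"):
            call_genes(stats, lib)

    def test_counts_nested_invariant(self):
        rng = np.random.default_rng(3)
        rows = list(map(tuple, np.exp(rng.normal(0, 1.5, size=(120, 4)))))
        genes = [f"G{i % 20}" for i in range(120)]
        stats = flag_fivefold(stats_from_ratios(rows, genes=genes))
        calls = call_genes(stats)
        assert (calls["n_fivefold_depleted"] <= calls["n_depleted"]).all()
        assert (calls["n_depleted"] <= calls["n_clones"]).all()


class TestZScores:
    def test_worked_case_sample_sd(self):
        # x = {-2, 0, 0, 2}: sample sd = sqrt(8/3) = 1.633, z(-2) = -1.2247
        stats = stats_from_ratios([(1, 1, 1, 1)] * 4)
        stats["mean_log2_ratio"] = [-2.0, 0.0, 0.0, 2.0]
        z = compute_zscores(stats)["z"]
        assert z.iloc[0] == pytest.approx(-2 / math.sqrt(8 / 3))
        assert z.iloc[0] == pytest.approx(-1.2247, abs=1e-4)
        assert z.iloc[3] == pytest.approx(1.2247, abs=1e-4)

    def test_mean_zero_sd_one_exactly(self, design):
        lib = make_library({f"G{i}": 4 for i in range(10)}, n_controls=5)
        cm = random_count_matrix(lib, seed=8, low=20, high=800)
        stats = compute_zscores(compute_ratios(cm, lib, design))
        z = stats.loc[stats["in_z_set"], "z"]
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_clone_at_set_mean_scores_zero(self):
        stats = stats_from_ratios([(1, 1, 1, 1)] * 3)
        stats["mean_log2_ratio"] = [-1.0, 0.0, 1.0]
        z = compute_zscores(stats)["z"]
        assert z.iloc[1] == 0.0

    def test_low_abundance_excluded_but_scored(self):
        stats = stats_from_ratios([(1, 1, 1, 1)] * 4)
        stats["mean_log2_ratio"] = [-2.0, 0.0, 2.0, -50.0]
        stats.loc[stats.index[3], "low_abundance"] = True
        out = compute_zscores(stats)
        assert not out["in_z_set"].iloc[3]
        assert np.isfinite(out["z"].iloc[3])
        in_z = out.loc[out["in_z_set"], "z"]
        assert in_z.mean() == pytest.approx(0, abs=1e-12)

    def test_degenerate_zero_variance_rejected(self):
        stats = stats_from_ratios([(1, 1, 1, 1)] * 3)
        with pytest.raises(ValueError, match="variance"):
            compute_zscores(stats)

    def test_exclude_controls_changes_standardization_set(self):
        stats = stats_from_ratios([(1, 1, 1, 1)] * 4,
                                  genes=["G1", "G1", NONTARGETING, NONTARGETING])
        stats["mean_log2_ratio"] = [-1.0, 1.0, 5.0, -5.0]
        out = compute_zscores(stats, include_controls=False)
        assert out["in_z_set"].tolist() == [True, True, False, False]


class TestReport:
    def _full(self, design, tmp_path, lib, cm):
        stats = compute_zscores(flag_fivefold(compute_ratios(cm, lib, design)))
        calls = call_genes(stats, lib)
        summary = report(stats, calls, tmp_path)
        return stats, calls, summary

    def test_artifacts_and_summary_fields(self, design, tmp_path):
        lib = make_library({f"G{i}": 4 for i in range(5)}, n_controls=3)
        cm = random_count_matrix(lib, seed=4, low=20, high=500)
        _, calls, summary = self._full(design, tmp_path, lib, cm)
        for name in ("shrna_stats.tsv", "gene_calls.tsv", "gene_enriched.tsv",
                     "summary.json"):
            assert (tmp_path / name).exists()
        assert summary["n_genes"] == 5
        assert summary["n_candidates"] == int(calls["candidate"].sum())

    def test_empty_candidates_valid_tables(self, design, tmp_path):
        lib = make_library({"G1": 4, "G2": 4})
        cm = counts_from_rows(
            lib, {c: (100, 100, 100, 100) for c in lib.clone_ids[:-1]}
            | {lib.clone_ids[-1]: (120, 90, 100, 100)}
        )
        stats, calls, summary = self._full(design, tmp_path, lib, cm)
        assert summary["n_candidates"] == 0
        header = (tmp_path / "gene_calls.tsv").read_text().splitlines()[0]
        assert header.startswith("gene\t")

    def test_tie_break_is_alphabetical_and_stable(self, tmp_path):
        stats = flag_fivefold(stats_from_ratios(
            [(0.1, 0.1, 0.1, 0.1)] * 4, genes=["GB", "GB", "GA", "GA"]))
        stats["mean_log2_ratio"] = [-2.0, -1.0, -2.0, -1.0]
        stats["z"] = [-1.5, -0.5, -1.5, -0.5]
        calls = call_genes(stats)
        report(stats, calls, tmp_path)
        lines = (tmp_path / "gene_calls.tsv").read_text().splitlines()
        order = [ln.split("\t")[0] for ln in lines[1:]]
        assert order == ["GA", "GB"]


class TestScreenDesign:
    def test_four_distinct_samples_required(self):
        with pytest.raises(ValueError, match="distinct"):
            ScreenDesign(("KO1", "KO1"), ("C1", "C2"))

    def test_missing_sample_detected(self, design):
        lib = make_library({"G1": 1})
        cm = counts_from_rows(lib, {lib.clone_ids[0]: (1, 2, 3, 4)})
        cm.counts.columns = ["KO1", "KO2", "C1", "X"]
        with pytest.raises(ValueError, match="C2"):
            design.validate_against(cm)
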