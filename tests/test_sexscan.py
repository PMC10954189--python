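"""Sex-difference statistics and MHM/FHM block calling."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from zmeth import methwin, sexscan, simdata


def stats_frame(rows):
    """Build a minimal per-window stats frame for find_blocks."""
    return pd.DataFrame(
        [
            {
                "methbin": f"chrZ_{pos}",
                "chrom": "chrZ",
                "pos": pos,
                "avg": 50.0,
                "median": med,
                "avg_male": 50.0 * r,
                "avg_female": 50.0,
                "pvalue": p,
                "mf_ratio": r,
            }
            for pos, med, p, r in rows
        ]
    )


class TestRankSum:
    def test_matches_exhaustive_permutation_enumeration(self):
        """For 6 vs 5 untied values the p equals the exact null enumeration
        over all C(11,6) group labelings of the rank-sum statistic."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            pooled = rng.permutation(np.arange(11, dtype=float) + rng.uniform(0, 0.3))
            x, y = pooled[:6], pooled[6:]
            ranks = pd.Series(np.concatenate([x, y])).rank().to_numpy()
            obs = ranks[:6].sum()
            null = np.array(
                [ranks[list(idx)].sum() for idx in combinations(range(11), 6)]
            )
            mu = null.mean()
            p_exact = np.mean(np.abs(null - mu) >= abs(obs - mu) - 1e-9)
            assert sexscan.rank_sum_pvalue(x, y) == pytest.approx(p_exact, abs=1e-12)

    def test_identical_groups_give_p_one_ratio_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        assert sexscan.rank_sum_pvalue(vals, vals.copy()) == pytest.approx(1.0)


class TestWindowSexStats:
    def test_printed_fhm_row_ratio(self, fhm_table):
        """The chrZ_30195000 row's M:F ratio from printed sex means is 0.78."""
        row = fhm_table.set_index("methbin").loc["chrZ_30195000"]
        assert round(row["avg_male"] / row["avg_female"], 2) == 0.78

    def test_stats_computed_from_matrix(self):
        rng = np.random.default_rng(2)
        n_m, n_f = 10, 9
        counts = pd.DataFrame(
            rng.poisson(20, size=(6, n_m + n_f)),
            index=[f"chr1_{i * 1000}" for i in range(6)],
            columns=[f"i{k}" for k in range(n_m + n_f)],
        )
        samples = pd.DataFrame(
            {"sex": ["male"] * n_m + ["female"] * n_f, "batch": "b1"},
            index=counts.columns,
        )
        mm = methwin.normalize(counts, samples)
        st = sexscan.window_sex_stats(mm)
        male_cols = counts.columns[:n_m]
        expected = mm.values[male_cols].mean(axis=1)
        np.testing.assert_allclose(st.set_index("methbin")["avg_male"], expected)
        assert ((st["pvalue"] >= 0) & (st["pvalue"] <= 1)).all()

    def test_single_sex_input_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]}, index=["chr1_0"])
        samples = pd.DataFrame({"sex": ["male"] * 3, "batch": "b1"}, index=counts.columns)
        with pytest.raises(ValueError):
            sexscan.window_sex_stats(methwin.normalize(counts, samples))


class TestFindBlocks:
    def test_fhm_fixture_reproduces_three_blocks(self, fhm_table):
        """The printed female-hypermethylated windows merge into exactly the
        three printed 6-window blocks."""
        st = fhm_table.rename(columns={"chr": "chrom", "MF_avg": "mf_ratio"})
        st["chrom"] = "chrZ"
        blocks = sexscan.find_blocks(st, sexscan.FHM_CRITERIA)
        assert len(blocks) == 3
        spans = [(b.start, b.end, b.n_windows) for b in blocks]
        assert spans == [
            (30195000, 30201000, 6),
            (42633000, 42639000, 6),
            (49068000, 49074000, 6),
        ]
        for b in blocks:
            assert b.size_bp == 1000 * b.n_windows
            assert (b.windows["pvalue"] < sexscan.FHM_P_MAX).all()
            assert (b.windows["mf_ratio"] < 1).all()

    def test_short_runs_discarded(self):
        rows = [(i * 1000, 20.0, 1e-3, 0.7) for i in range(4)]
        rows.append((6000, 20.0, 1e-3, 0.7))  # gap then one more
        blocks = sexscan.find_blocks(stats_frame(rows), sexscan.FHM_CRITERIA)
        assert blocks == []

    def test_flanking_nonqualifying_windows_do_not_matter(self):
        core = [(1000 * (5 + i), 20.0, 1e-4, 0.6) for i in range(6)]
        flank_lo = [(0, 20.0, 0.9, 1.0)]
        flank_hi = [(12000, 20.0, 0.9, 1.0)]
        b1 = sexscan.find_blocks(stats_frame(core), sexscan.FHM_CRITERIA)
        b2 = sexscan.find_blocks(
            stats_frame(flank_lo + core + flank_hi), sexscan.FHM_CRITERIA
        )
        assert [(b.start, b.end) for b in b1] == [(b.start, b.end) for b in b2]

    def test_median_floor_applies_to_male_direction(self):
        rows = [(i * 1000, 5.0, 1e-12, 3.0) for i in range(6)]
        assert sexscan.find_blocks(stats_frame(rows), sexscan.MHM_CRITERIA) == []
        rows = [(i * 1000, 9.0, 1e-12, 3.0) for i in range(6)]
        found = sexscan.find_blocks(stats_frame(rows), sexscan.MHM_CRITERIA)
        assert len(found) == 1 and found[0].kind == "MHM"

    def test_planted_block_recovered_from_simulation(self):
        """An 8-window 3.3x male block at n=124 is called exactly."""
        windows = tuple(f"chrZ_{s}" for s in range(50_000, 58_000, 1000))
        eff = simdata.PlantedEffect(
            kind="MHM_block", target="mhm", male_multiplier=3.3,
            block_windows=windows,
        )
        cfg = simdata.SimConfig(seed=77, planted_effects=(eff,))
        gt = simdata.simulate_pedigree(cfg)
        mm = simdata.generate_methylation(gt, cfg.planted_effects, cfg)
        st = sexscan.window_sex_stats(mm)
        criteria = sexscan.BlockCriteria(
            "male", p_max=1e-8, median_min=None, min_run=5
        )
        blocks = sexscan.find_blocks(st, criteria)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (50_000, 58_000)


class TestNullCalibration:
    def test_window_false_positive_rate_matches_alpha(self):
        """No sex effect: the fraction of windows with p < alpha stays at
        alpha within 3 SE, and no blocks are called."""
        rng = np.random.default_rng(123)
        n_windows, n = 1200, 124
        counts = pd.DataFrame(
            rng.negative_binomial(5, 5 / 30, size=(n_windows, n)),
            index=[f"chr1_{i * 1000}" for i in range(n_windows)],
            columns=[f"i{k}" for k in range(n)],
        )
        samples = pd.DataFrame(
            {"sex": ["male"] * 69 + ["female"] * 55, "batch": "b1"},
            index=counts.columns,
        )
        st = sexscan.window_sex_stats(methwin.normalize(counts, samples))
        alpha = 0.05
        fpr = sexscan.null_window_fpr(st, alpha)
        se = np.sqrt(alpha * (1 - alpha) / n_windows)
        assert abs(fpr - alpha) < 3 * se + 0.005
        assert sexscan.find_blocks(st, sexscan.MHM_CRITERIA) == []


class TestBlockGeneReport:
    @staticmethod
    def _expression(feature_rows):
        rng = np.random.default_rng(4)
        feats = pd.DataFrame(feature_rows).set_index("probeset")
        ids = [f"i{k}" for k in range(12)]
        samples = pd.DataFrame(
            {"sex": ["male"] * 6 + ["female"] * 6, "batch": "b1"}, index=ids
        )
        values = pd.DataFrame(
            rng.uniform(10, 100, size=(len(feats), 12)), index=feats.index, columns=ids
        )
        return methwin.ExpressionMatrix(values=values, samples=samples, features=feats)

    def test_flank_boundary_closed(self):
        block = sexscan.Block(
            "MHM", "chrZ", 1_000_000, 1_006_000,
            windows=pd.DataFrame({"methbin": []}),
        )
        expr = self._expression(
            [
                {"probeset": "in", "gene_name": "A", "chrom": "chrZ",
                 "start": 1_106_000, "end": 1_107_000},
                {"probeset": "out", "gene_name": "B", "chrom": "chrZ",
                 "start": 1_106_001, "end": 1_107_001},
            ]
        )
        report = sexscan.block_gene_report([block], expr, flank=100_000)
        assert list(report["probeset"]) == ["in"]

    def test_block_with_no_genes_gives_empty_report(self):
        block = sexscan.Block(
            "MHM", "chrZ", 0, 6000, windows=pd.DataFrame({"methbin": []})
        )
        expr = self._expression(
            [{"probeset": "far", "gene_name": "C", "chrom": "chr1",
              "start": 0, "end": 1000}]
        )
        assert sexscan.block_gene_report([block], expr).empty

    def test_planted_suppression_reflected_in_ratios(self):
        """Genes near a planted male block show the generative male:female
        expression fold within sampling error."""
        windows = tuple(f"chrZ_{s}" for s in range(50_000, 58_000, 1000))
        eff = simdata.PlantedEffect(
            kind="MHM_block", target="mhm", male_multiplier=3.3,
            block_windows=windows,
        )
        cfg = simdata.SimConfig(seed=88, planted_effects=(eff,), n_males=300, n_females=300)
        study = simdata.simulate_study(cfg)
        block = sexscan.Block(
            "MHM", "chrZ", 50_000, 58_000, windows=pd.DataFrame({"methbin": list(windows)})
        )
        report = sexscan.block_gene_report([block], study.expression, flank=100_000)
        assert not report.empty
        # generative male log shift is half the block's log fold
        expected = float(np.exp(-np.log(3.3) / 2))
        near = report["mf_ratio"].mean()
        assert abs(near - expected) / expected < 0.15
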