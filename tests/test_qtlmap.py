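"""Haley-Knott interval mapping, thresholds, classification and QC."""

import numpy as np
import pandas as pd
import pytest

from zmeth import qtlmap, simdata


def make_map(markers, z_chrom=None):
    return qtlmap.MarkerMap(pd.DataFrame(markers), z_chrom=z_chrom)


class TestMarkerMap:
    def test_order_validation(self):
        with pytest.raises(ValueError, match="bp"):
            make_map({"marker": ["a", "b"], "chrom": ["c1", "c1"],
                      "cM": [0.0, 5.0], "bp": [200, 100]})
        with pytest.raises(ValueError, match="cM"):
            make_map({"marker": ["a", "b"], "chrom": ["c1", "c1"],
                      "cM": [5.0, 0.0], "bp": [100, 200]})

    def test_bp_cm_interpolation(self):
        mmap = make_map({"marker": ["a", "b"], "chrom": ["c1", "c1"],
                         "cM": [0.0, 10.0], "bp": [0, 100_000]})
        assert mmap.bp_to_cm("c1", 50_000) == pytest.approx(5.0)
        assert mmap.cm_to_bp("c1", 2.5) == pytest.approx(25_000)


class TestGenotypeProbs:
    def test_degenerate_at_typed_markers(self, single_marker_setup):
        mmap, gt, samples, g = single_marker_setup
        probs = qtlmap.genotype_probs(gt, mmap)
        np.testing.assert_allclose(probs.chroms["c1"].dosage[:, 0], g)

    def test_midpoint_matches_transition_matrix_product(self):
        """P(state at the midpoint of a 20-cM interval | identical flanking
        homozygotes) equals the explicit 3-state transition product."""
        mmap = make_map({"marker": ["m0", "m1"], "chrom": ["c1", "c1"],
                         "cM": [0.0, 20.0], "bp": [0, 20_000]})
        ids = ["i0", "i2"]
        samples = pd.DataFrame({"sex": ["male", "male"], "batch": "b1"}, index=ids)
        gt = qtlmap.GenotypeTable(
            dosages=pd.DataFrame({"m0": [0, 2], "m1": [0, 2]}, index=ids),
            samples=samples,
        )
        probs = qtlmap.genotype_probs(gt, mmap, step=10.0)
        T = qtlmap.genotype_transition(10.0, p=0.5, n_states=3)
        for row, geno in ((0, 0), (1, 2)):
            w = T[geno, :] * T[:, geno]
            oracle = (w / w.sum()) @ np.array([0.0, 1.0, 2.0])
            assert probs.chroms["c1"].dosage[row, 1] == pytest.approx(oracle)

    def test_female_z_two_states(self):
        mmap = make_map({"marker": ["z0", "z1"], "chrom": ["chrZ", "chrZ"],
                         "cM": [0.0, 20.0], "bp": [0, 20_000]}, z_chrom="chrZ")
        ids = ["f0", "f1", "m0"]
        samples = pd.DataFrame(
            {"sex": ["female", "female", "male"], "batch": "b1"}, index=ids
        )
        gt = qtlmap.GenotypeTable(
            dosages=pd.DataFrame({"z0": [0, 1, 2], "z1": [1, 0, 2]}, index=ids),
            samples=samples,
        )
        probs = qtlmap.genotype_probs(gt, mmap, step=10.0)
        dosage = probs.chroms["chrZ"].dosage
        # female expected dosage stays within [0, 1]; male can reach 2
        assert (dosage[:2] >= 0).all() and (dosage[:2] <= 1).all()
        assert dosage[2].max() == pytest.approx(2.0)


class TestScan:
    def test_single_marker_lod_matches_least_squares(self, single_marker_setup):
        """HK LOD at a typed marker equals the closed-form regression LOD."""
        mmap, gt, samples, g = single_marker_setup
        rng = np.random.default_rng(11)
        probs = qtlmap.genotype_probs(gt, mmap)
        for _ in range(20):
            y = 0.4 * g + rng.normal(size=len(g))
            lod = qtlmap.scan(probs, pd.Series(y, index=gt.individuals)).table["lod"].iat[0]
            Z = qtlmap.design_covariates(samples, gt.individuals)
            X = np.column_stack([Z, g])
            r0 = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            r1 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            oracle = len(y) / 2 * np.log10((r0 @ r0) / (r1 @ r1))
            assert lod == pytest.approx(oracle, abs=1e-8)

    def test_perfect_fit_peaks_at_marker(self, single_marker_setup):
        mmap, gt, samples, g = single_marker_setup
        probs = qtlmap.genotype_probs(gt, mmap)
        curve = qtlmap.scan(probs, pd.Series(g.astype(float), index=gt.individuals))
        assert curve.table["lod"].iat[0] > 50  # RSS_full -> 0

    def test_lod_invariant_to_affine_phenotype_transform(self, small_study):
        probs = qtlmap.genotype_probs(small_study.genotypes, small_study.marker_map, step=4.0)
        y = small_study.methylation.values.iloc[10]
        c1 = qtlmap.scan(probs, y)
        c2 = qtlmap.scan(probs, y * 3.7 + 11.0)
        np.testing.assert_allclose(c1.table["lod"], c2.table["lod"], atol=1e-8)

    def test_constant_phenotype_gives_zero_lod(self, single_marker_setup):
        mmap, gt, *_ = single_marker_setup
        probs = qtlmap.genotype_probs(gt, mmap)
        curve = qtlmap.scan(probs, pd.Series(5.0, index=gt.individuals))
        assert (curve.table["lod"] == 0).all()

    def test_female_z_design_has_no_dominance_column(self, small_study):
        """Cross-sex Z scans use the additive dosage only: female expected
        dosages never exceed 1 and the scan runs without a het split."""
        probs = qtlmap.genotype_probs(small_study.genotypes, small_study.marker_map, step=4.0)
        female = (small_study.genotypes.samples["sex"] == "female").to_numpy()
        assert probs.chroms["chrZ"].dosage[female].max() <= 1.0 + 1e-9


class TestSexInteractionFlag:
    def _curves(self, lod_add, lod_int):
        t = pd.DataFrame({"chrom": ["c1"], "cM": [0.0], "nearest_marker": ["m"],
                          "lod": [lod_add]})
        ti = t.copy(); ti["lod"] = lod_int
        return qtlmap.LodCurve(t, "additive"), qtlmap.LodCurve(ti, "sex-interactive")

    def test_strictly_greater_than_one(self):
        ca, ci = self._curves(7.0, 8.1)
        assert qtlmap.sex_interaction_flag(ca, ci, "c1", 0.0) is True
        ca, ci = self._curves(7.0, 8.0)
        assert qtlmap.sex_interaction_flag(ca, ci, "c1", 0.0) is False

    def test_planted_interaction_detected(self):
        """A strong male-only allelic effect trips the flag; takes several
        seeds to measure the rate."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            eff = simdata.PlantedEffect(
                kind="cis_methQTL", target="chr1_96000", source_marker="chr1_m06",
                additive_effect=0.6, sex_interaction_effect=1.2,
            )
            cfg = simdata.SimConfig(seed=600 + seed, planted_effects=(eff,))
            gt = simdata.simulate_pedigree(cfg)
            mm = simdata.generate_methylation(gt, cfg.planted_effects, cfg)
            mk = simdata.build_marker_map(cfg)
            probs = qtlmap.genotype_probs(gt, mk, step=2.0)
            y = mm.values.loc["chr1_96000"]
            ca = qtlmap.scan(probs, y)
            ci = qtlmap.scan(probs, y, interactive=True)
            pk = ca.peak()
            hits += qtlmap.sex_interaction_flag(ca, ci, pk["chrom"], pk["cM"])
        assert hits >= 9


class TestPermutationThresholds:
    def test_ordering_and_convergence(self, small_study):
        probs = qtlmap.genotype_probs(
            small_study.genotypes, small_study.marker_map, step=8.0
        )
        n = len(probs.individuals)
        sampler = lambda rng: rng.normal(size=n)
        ts1 = qtlmap.permutation_thresholds(
            sampler, probs, n_phenotypes=4, n_perm=40,
            rng=np.random.default_rng(1), chroms=["chr1"],
        )
        assert ts1.significant >= ts1.suggestive > 0
        ts2 = qtlmap.permutation_thresholds(
            sampler, probs, n_phenotypes=4, n_perm=80,
            rng=np.random.default_rng(2), chroms=["chr1"],
        )
        assert abs(ts1.significant - ts2.significant) < 1.0

    def test_stratified_leq_free_under_sex_main_effect(self, small_study):
        """With a pure sex main effect, free permutation breaks the sex
        structure and inflates max LODs relative to within-sex permutation."""
        probs = qtlmap.genotype_probs(
            small_study.genotypes, small_study.marker_map, step=8.0
        )
        male = (small_study.genotypes.samples["sex"] == "male").to_numpy(float)

        def sampler(rng):
            return 2.0 * male + rng.normal(size=len(male))

        free = qtlmap.permutation_thresholds(
            sampler, probs, 3, 40, np.random.default_rng(3), chroms=["chr1"]
        )
        strat = qtlmap.permutation_thresholds(
            sampler, probs, 3, 40, np.random.default_rng(3), chroms=["chr1"],
            stratify_by_sex=True,
        )
        assert strat.significant <= free.significant + 0.3

    def test_too_few_permutations_rejected(self, small_study):
        probs = qtlmap.genotype_probs(
            small_study.genotypes, small_study.marker_map, step=8.0
        )
        with pytest.raises(ValueError):
            qtlmap.permutation_thresholds(
                lambda rng: rng.normal(size=124), probs, 1, 10,
                np.random.default_rng(0),
            )


class TestClassification:
    @pytest.fixture()
    def mmap(self):
        return make_map(
            {
                "marker": ["a", "b", "c", "d"],
                "chrom": ["c1", "c1", "c1", "c2"],
                "cM": [0.0, 50.0, 100.0, 0.0],
                "bp": [0, 500_000, 1_000_000, 0],
            }
        )

    def test_same_chrom_within_margin_is_cis(self, mmap):
        assert qtlmap.classify_cis_trans("c1", 49.0, "c1", 0, mmap) == "cis"
        assert qtlmap.classify_cis_trans("c1", 50.0, "c1", 0, mmap) == "cis"
        assert qtlmap.classify_cis_trans("c1", 51.0, "c1", 0, mmap) == "trans"

    def test_other_chrom_is_trans(self, mmap):
        assert qtlmap.classify_cis_trans("c2", 0.0, "c1", 0, mmap) == "trans"

    def test_unknown_location_unplaced(self, mmap):
        assert qtlmap.classify_cis_trans("c1", 0.0, None, None, mmap) == "unplaced"


class TestSupportInterval:
    def test_unimodal_drop_crossing(self):
        cms = np.arange(0.0, 101.0, 1.0)
        lods = 8.0 - np.abs(cms - 50.0) * 0.2  # drops 1.5 at +-7.5 cM
        curve = qtlmap.LodCurve(
            pd.DataFrame({"chrom": "c1", "cM": cms, "nearest_marker": "m",
                          "lod": lods}),
            "additive",
        )
        mmap = make_map({"marker": ["a", "b", "c"], "chrom": ["c1"] * 3,
                         "cM": [0.0, 50.0, 100.0], "bp": [0, 500_000, 1_000_000]})
        lo, hi, bp_lo, bp_hi, mk_lo, mk_hi = qtlmap.support_interval(
            curve, "c1", 50.0, mmap
        )
        assert lo == pytest.approx(43.0) and hi == pytest.approx(57.0)
        # expanded outward to flanking typed markers
        assert (mk_lo, mk_hi) == ("a", "c")

    def test_flat_curve_covers_chromosome(self):
        cms = np.arange(0.0, 101.0, 1.0)
        curve = qtlmap.LodCurve(
            pd.DataFrame({"chrom": "c1", "cM": cms, "nearest_marker": "m",
                          "lod": 3.0}),
            "additive",
        )
        mmap = make_map({"marker": ["a", "b"], "chrom": ["c1"] * 2,
                         "cM": [0.0, 100.0], "bp": [0, 1_000_000]})
        lo, hi, *_ = qtlmap.support_interval(curve, "c1", 50.0, mmap)
        assert (lo, hi) == (0.0, 100.0)

    def test_interval_covers_truth_in_simulation(self):
        """1.5-LOD intervals cover the planted position in most seeds."""
        cover = 0
        n_seeds = 10
        for seed in range(n_seeds):
            eff = simdata.PlantedEffect(
                kind="cis_methQTL", target="chr2_96000", source_marker="chr2_m06",
                additive_effect=0.8,
            )
            cfg = simdata.SimConfig(seed=700 + seed, planted_effects=(eff,))
            gt = simdata.simulate_pedigree(cfg)
            mm = simdata.generate_methylation(gt, cfg.planted_effects, cfg)
            mk = simdata.build_marker_map(cfg)
            probs = qtlmap.genotype_probs(gt, mk, step=2.0)
            curve = qtlmap.scan(probs, mm.values.loc["chr2_96000"])
            pk = curve.peak()
            if pk["chrom"] != "chr2":
                continue
            lo, hi, *_ = qtlmap.support_interval(curve, pk["chrom"], pk["cM"], mk)
            cover += lo - 1e-9 <= 96.0 <= hi + 1e-9
        assert cover >= 9


class TestQCFilter:
    def _record(self, counts, study, window):
        return qtlmap.QTLRecord(
            phenotype=window, phenotype_chrom="chr1", phenotype_bp=0,
            peak_chrom="chr1", peak_cm=96.0, peak_marker="chr1_m06",
            lod=5.0, ci_lo_cm=80, ci_hi_cm=110, ci_lo_bp=0, ci_hi_bp=1,
            ci_lo_marker="a", ci_hi_marker="b", sex_interaction=False,
            classification="cis", genotype_class_counts=counts,
        )

    def test_genotype_class_boundary(self, small_study):
        probs = qtlmap.genotype_probs(
            small_study.genotypes, small_study.marker_map, step=8.0
        )
        phen = small_study.methylation.values
        window = phen.index[0]
        rec_drop = self._record((9, 60, 55), small_study, window)
        rec_keep = self._record((10, 60, 54), small_study, window)
        kept = qtlmap.qc_filter(
            [rec_drop, rec_keep], small_study.genotypes, phen, probs, threshold=3.0
        )
        assert [r.genotype_class_counts for r in kept] == [(10, 60, 54)]

    def test_outlier_driven_peak_flagged(self, single_marker_setup):
        """A 10-SD single outlier that manufactures the peak is flagged by
        leave-one-out rescanning."""
        mmap, gt, samples, g = single_marker_setup
        rng = np.random.default_rng(13)
        probs = qtlmap.genotype_probs(gt, mmap)
        y = rng.normal(size=len(g))
        y[np.argmax(g)] += 10.0  # one extreme value aligned with genotype
        phen = pd.DataFrame([y], index=["w"], columns=gt.individuals)
        curve = qtlmap.scan(probs, phen.loc["w"])
        rec = qtlmap.QTLRecord(
            phenotype="w", phenotype_chrom=None, phenotype_bp=None,
            peak_chrom="c1", peak_cm=0.0, peak_marker="mA",
            lod=float(curve.table["lod"].iat[0]),
            ci_lo_cm=0, ci_hi_cm=0, ci_lo_bp=0, ci_hi_bp=0,
            ci_lo_marker="mA", ci_hi_marker="mA", sex_interaction=False,
            classification="unplaced",
            genotype_class_counts=qtlmap.genotype_class_counts(gt, "mA"),
        )
        kept = qtlmap.qc_filter([rec], gt, phen, probs, threshold=rec.lod * 0.75)
        assert kept and kept[0].outlier_flag


class TestRecovery:
    def test_planted_cis_qtl_recovered_within_20cm(self):
        """Planted strong cis effect at n = 124: peak lands within 20 cM of
        the source marker across seeds."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            eff = simdata.PlantedEffect(
                kind="cis_methQTL", target="chrZ_96000", source_marker="chrZ_m06",
                additive_effect=0.8,
            )
            cfg = simdata.SimConfig(seed=800 + seed, planted_effects=(eff,))
            gt = simdata.simulate_pedigree(cfg)
            mm = simdata.generate_methylation(gt, cfg.planted_effects, cfg)
            mk = simdata.build_marker_map(cfg)
            probs = qtlmap.genotype_probs(gt, mk, step=2.0)
            curve = qtlmap.scan(probs, mm.values.loc["chrZ_96000"])
            pk = curve.peak()
            hits += pk["chrom"] == "chrZ" and abs(pk["cM"] - 96.0) <= 20.0
        assert hits >= 9
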