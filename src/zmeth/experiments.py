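"""Reference experiments: fixture statistics and calibration/recovery studies.

These functions recompute the pipeline's headline quantities from scratch —
the printed-table statistics from the shipped fixtures, and the
property-based calibration and recovery rates from fresh synthetic studies.
They are shared by the acceptance checks and the analysis drivers.

Problem sizes are desk-scale by design: the calibration experiments use the
study's n = 124 (69 males, 55 females) on the default 4-chromosome synthetic
genome, with seed counts given per experiment.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from . import integrate, mhmgenes, qtlmap, sexscan, simdata
from .methwin import normalize


# ---------------------------------------------------------------------------
# fixture statistics
# ---------------------------------------------------------------------------

def mhm_gene_statistics() -> dict:
    """Class sizes, group means, Welch t and correlation rates from the
    shipped block-gene table."""
    table = mhmgenes.load_mhm_gene_table()
    labelled = mhmgenes.classify(mhmgenes.dedupe_genes(table))
    sizes = mhmgenes.class_sizes(labelled)
    summary = mhmgenes.group_summary(labelled).set_index(["gene_class", "sex"])
    t_m, p_m = mhmgenes.balanced_vs_unbalanced_test(labelled, "male")
    t_f, p_f = mhmgenes.balanced_vs_unbalanced_test(labelled, "female")
    corr = mhmgenes.correlation_summary(labelled, table).set_index("gene_class")
    bal = corr.loc[mhmgenes.CLASS_BALANCED]
    return {
        "n_unique_genes": int(len(labelled)),
        "n_male_biased": sizes[mhmgenes.CLASS_MALE],
        "n_balanced": sizes[mhmgenes.CLASS_BALANCED],
        "n_female_biased": sizes[mhmgenes.CLASS_FEMALE],
        "unbalanced_male_mean": int(summary.loc[(mhmgenes.CLASS_MALE, "male"), "mean"]),
        "unbalanced_female_mean": int(summary.loc[(mhmgenes.CLASS_MALE, "female"), "mean"]),
        "balanced_male_mean": int(summary.loc[(mhmgenes.CLASS_BALANCED, "male"), "mean"]),
        "balanced_female_mean": int(summary.loc[(mhmgenes.CLASS_BALANCED, "female"), "mean"]),
        "female_biased_male_mean": int(summary.loc[(mhmgenes.CLASS_FEMALE, "male"), "mean"]),
        "welch_t_male": round(t_m, 1),
        "welch_p_male": round(p_m, 3),
        "welch_t_female": round(t_f, 1),
        "balanced_corr_per_gene": float(bal["corr_per_gene"]),
        "balanced_pos_per_gene": float(bal["pos_per_gene"]),
        "balanced_neg_per_gene": float(bal["neg_per_gene"]),
    }


def fhm_window_statistics() -> dict:
    """M:F ratio of the first printed window and the FHM block calls from
    the shipped female-hypermethylated window table."""
    table = mhmgenes.load_fhm_window_table()
    row = table.set_index("methbin").loc["chrZ_30195000"]
    stats_df = table.rename(columns={"chr": "chrom", "MF_avg": "mf_ratio"})
    stats_df["chrom"] = "chrZ"
    blocks = sexscan.find_blocks(stats_df, sexscan.FHM_CRITERIA)
    return {
        "chrZ_30195000_mf_ratio": round(float(row["avg_male"] / row["avg_female"]), 2),
        "n_fhm_blocks": len(blocks),
        "fhm_block_windows": [b.n_windows for b in blocks],
        "fhm_block_spans": [(b.chrom, b.start, b.end) for b in blocks],
    }


def hotspot_statistics() -> dict:
    """Span consistency and mean physical span from the shipped hotspot table."""
    table = mhmgenes.load_hotspot_table()
    sizes_consistent = bool(
        ((table["CI_high_pos"] - table["CI_low_pos"]) == table["CI_size"]).all()
    )
    from .hotspot import hotspot_summary

    summary = hotspot_summary(table, z_chrom="Z")
    h6 = table.set_index("id").loc["hotspot_6"]
    return {
        "ci_sizes_consistent": sizes_consistent,
        "hotspot_6_ci_size": int(h6["CI_size"]),
        "n_hotspots": summary["count"],
        "mean_span_mb": summary["mean_span_mb"],
        "on_z": summary["on_z"],
        "on_autosomes": summary["on_autosomes"],
    }


# ---------------------------------------------------------------------------
# calibration / recovery experiments
# ---------------------------------------------------------------------------

def hk_lod_max_error(n_fixtures: int = 100, seed: int = 0) -> float:
    """Max |HK LOD - closed-form least-squares LOD| over random single-marker
    fixtures (varying n, genotype draws, covariates)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(30, 150))
        ids = [f"i{k}" for k in range(n)]
        samples = pd.DataFrame(
            {
                "sex": np.where(rng.integers(0, 2, n) == 1, "male", "female"),
                "batch": rng.choice(["b1", "b2"], n),
            },
            index=ids,
        )
        g = rng.integers(0, 3, n)
        if len(np.unique(g)) < 2 or samples["sex"].nunique() < 2:
            continue
        mmap = qtlmap.MarkerMap(
            pd.DataFrame({"marker": ["mA"], "chrom": ["c1"], "cM": [0.0], "bp": [1]}),
            z_chrom=None,
        )
        gt = qtlmap.GenotypeTable(
            dosages=pd.DataFrame({"mA": g}, index=ids), samples=samples
        )
        probs = qtlmap.genotype_probs(gt, mmap)
        y = rng.uniform(0.1, 0.9) * g + rng.normal(size=n)
        lod = qtlmap.scan(probs, pd.Series(y, index=ids)).table["lod"].iat[0]
        Z = qtlmap.design_covariates(samples, ids)
        X = np.column_stack([Z, g])
        r0 = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        r1 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        oracle = n / 2 * np.log10((r0 @ r0) / (r1 @ r1))
        worst = max(worst, abs(lod - oracle))
    return worst


def wilcoxon_enumeration_max_error(n_fixtures: int = 30, seed: int = 0) -> float:
    """Max |rank-sum p - exhaustive enumeration p| for group sizes <= 6."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        n1 = int(rng.integers(3, 7))
        n2 = int(rng.integers(3, 7))
        pooled = rng.normal(size=n1 + n2)
        while len(np.unique(pooled)) < n1 + n2:
            pooled = rng.normal(size=n1 + n2)
        x, y = pooled[:n1], pooled[n1:]
        p = sexscan.rank_sum_pvalue(x, y)
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[:n1].sum()
        null = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(n1 + n2), n1)]
        )
        mu = null.mean()
        p_exact = float(np.mean(np.abs(null - mu) >= abs(obs - mu) - 1e-9))
        worst = max(worst, abs(p - p_exact))
    return worst


def mhm_null_calibration(
    seed: int = 0, n_windows: int = 2000, alpha: float = 0.05
) -> dict:
    """Scan a no-sex-effect methylome (124 individuals) at the MHM criteria.

    The null condition uses a sex-balanced genome (Z dose ratio 1) so that
    per-individual totals carry no sex structure; counts are negative
    binomial at the default coverage/dispersion.
    """
    rng = np.random.default_rng(seed)
    n = 124
    alpha_disp = 0.2
    mu = 25.0
    size = 1.0 / alpha_disp
    counts = pd.DataFrame(
        rng.negative_binomial(size, size / (size + mu), size=(n_windows, n)),
        index=[f"chr1_{i * 1000}" for i in range(n_windows)],
        columns=[f"i{k}" for k in range(n)],
    )
    samples = pd.DataFrame(
        {"sex": ["male"] * 69 + ["female"] * 55, "batch": "b1"},
        index=counts.columns,
    )
    stats_df = sexscan.window_sex_stats(normalize(counts, samples))
    blocks = sexscan.find_blocks(stats_df, sexscan.MHM_CRITERIA)
    return {
        "n_blocks": len(blocks),
        "window_fpr": sexscan.null_window_fpr(stats_df, alpha),
        "alpha": alpha,
        "n_windows": n_windows,
        "fpr_se": float(np.sqrt(alpha * (1 - alpha) / n_windows)),
    }


def cis_recovery_rate(
    n_seeds: int = 50, seed0: int = 0, additive_effect: float = 0.8
) -> float:
    """Fraction of seeds in which a planted strong cis methylation QTL
    (allelic effect >= 1 phenotype SD, n = 124) peaks within 20 cM of its
    source marker."""
    hits = 0
    for k in range(n_seeds):
        eff = simdata.PlantedEffect(
            kind="cis_methQTL", target="chrZ_96000", source_marker="chrZ_m06",
            additive_effect=additive_effect,
        )
        cfg = simdata.SimConfig(seed=seed0 + k, planted_effects=(eff,))
        gt = simdata.simulate_pedigree(cfg)
        mm = simdata.generate_methylation(gt, cfg.planted_effects, cfg)
        mk = simdata.build_marker_map(cfg)
        probs = qtlmap.genotype_probs(gt, mk, step=2.0)
        pk = qtlmap.scan(probs, mm.values.loc["chrZ_96000"]).peak()
        hits += pk["chrom"] == "chrZ" and abs(pk["cM"] - 96.0) <= 20.0
    return hits / n_seeds


def interaction_flag_rates(n_seeds: int = 50, seed0: int = 0) -> dict:
    """Sex-interaction flag rate with and without a planted interaction.

    The planted case uses a male-only allelic effect (additive 0.6 with a
    +1.2 male-female slope difference).  The null case plants the same
    additive effect with no interaction on a sex-balanced genome (Z dose
    ratio 1): with sex-imbalanced totals, per-individual normalization itself
    induces a real small sex difference in allelic slopes, so the balanced
    genome is the condition under which the null actually holds.
    """
    def rate(sexint: float, z_ratio: float, base: int) -> float:
        hits = 0
        for k in range(n_seeds):
            eff = simdata.PlantedEffect(
                kind="cis_methQTL", target="chr1_96000", source_marker="chr1_m06",
                additive_effect=0.6, sex_interaction_effect=sexint,
            )
            cfg = simdata.SimConfig(
                seed=base + k, planted_effects=(eff,), z_dose_ratio=z_ratio
            )
            gt = simdata.simulate_pedigree(cfg)
            mm = simdata.generate_methylation(gt, cfg.planted_effects, cfg)
            mk = simdata.build_marker_map(cfg)
            probs = qtlmap.genotype_probs(gt, mk, step=2.0)
            y = mm.values.loc["chr1_96000"]
            ca = qtlmap.scan(probs, y)
            ci = qtlmap.scan(probs, y, interactive=True)
            pk = ca.peak()
            hits += qtlmap.sex_interaction_flag(ca, ci, pk["chrom"], pk["cM"])
        return hits / n_seeds

    return {
        "tpr": rate(1.2, 1.7, seed0),
        "fpr": rate(0.0, 1.0, seed0 + 10_000),
        "n_seeds": n_seeds,
    }


def leo_recovery(n_seeds: int = 50, seed0: int = 0, n: int = 124) -> dict:
    """Orientation recovery for strong planted causal chains, plus the
    worst-case E/M-swap antisymmetry error of the model p-values."""
    hits_gem = hits_gme = 0
    asym = 0.0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed0 + k)
        g = rng.integers(0, 3, size=n).astype(float)
        e = 0.9 * g + rng.normal(size=n)
        m = 0.9 * e + rng.normal(size=n)
        fit = integrate.leo_nb_orient(g, e, m)
        hits_gem += fit.orientation == "genexp->meth" and fit.leo_nb_oca > 1
        swapped = integrate.leo_nb_orient(g, m, e)
        asym = max(
            asym,
            abs(fit.model_pvalues["M1"] - swapped.model_pvalues["M2"]),
            abs(fit.model_pvalues["M2"] - swapped.model_pvalues["M1"]),
        )

        rng2 = np.random.default_rng(seed0 + 5000 + k)
        g2 = rng2.integers(0, 3, size=n).astype(float)
        m2 = 0.9 * g2 + rng2.normal(size=n)
        e2 = 0.9 * m2 + rng2.normal(size=n)
        fit2 = integrate.leo_nb_orient(g2, e2, m2)
        hits_gme += fit2.orientation == "meth->genexp" and fit2.leo_nb_oca > 1
    return {
        "rate_genexp_to_meth": hits_gem / n_seeds,
        "rate_meth_to_genexp": hits_gme / n_seeds,
        "antisymmetry_max_error": asym,
        "n_seeds": n_seeds,
    }
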