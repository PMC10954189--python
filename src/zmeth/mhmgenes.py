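"""Expression statistics of genes adjacent to male-hypermethylated blocks.

Block-adjacent genes are classified by their sex difference in expression:
``male_biased_unbalanced`` (significant, higher in males), ``female_biased``
(significant, higher in females) and ``balanced`` (no significant
difference).  Group summaries, the balanced-vs-unbalanced Welch t-test, and
per-gene counts of significant methylation-expression correlations within
the home block are computed from a deduplicated gene list (genes printed in
several adjacent blocks count once).

The package ships the printed block-gene table and the female-hypermethylated
window table as TSV fixtures; rows without a printed probe id carry
synthesized stable EST ids so that deduplication by probeset is well defined.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .methwin import ExpressionMatrix, MethylationMatrix
from .sexscan import Block

ALPHA = 0.05

CLASS_BALANCED = "balanced"
CLASS_MALE = "male_biased_unbalanced"
CLASS_FEMALE = "female_biased"


def _data_path(name: str):
    return resources.files("zmeth.data").joinpath(name)


def load_mhm_gene_table() -> pd.DataFrame:
    """Block-gene fixture: one row per (block, gene), repeated across blocks."""
    with resources.as_file(_data_path("mhm_gene_table.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_fhm_window_table() -> pd.DataFrame:
    """Female-hypermethylated window fixture (per-window sex statistics)."""
    with resources.as_file(_data_path("fhm_window_table.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_hotspot_table() -> pd.DataFrame:
    """Trans-hotspot fixture (peak marker, member count, CI span)."""
    with resources.as_file(_data_path("hotspot_table.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def dedupe_genes(records: pd.DataFrame) -> pd.DataFrame:
    """One row per probeset; expression fields must agree across duplicates.

    Rows without a probeset (genes absent from the expression data) are
    dropped.  Correlation counts may legitimately differ across a gene's
    blocks; the per-gene count is resolved to the maximum (see
    ``gene_correlation_counts``), so they are excluded from the consistency
    check here.
    """
    present = records.dropna(subset=["probeset"])
    expr_cols = ["avg_exp", "avg_exp_male", "avg_exp_female", "wilcox_pval", "mf_ratio"]
    nun = present.groupby("probeset")[expr_cols].nunique()
    if (nun > 1).any().any():
        bad = nun[(nun > 1).any(axis=1)].index.tolist()
        raise ValueError(f"conflicting expression values for: {bad}")
    return present.drop_duplicates(subset="probeset").reset_index(drop=True)


def classify(records: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Label each deduplicated gene by its sex-difference significance.

    Strict inequality: p exactly at alpha is balanced.
    """
    out = records.copy()
    sig = out["wilcox_pval"] < alpha
    out["gene_class"] = np.select(
        [sig & (out["mf_ratio"] < 1), sig & (out["mf_ratio"] > 1)],
        [CLASS_FEMALE, CLASS_MALE],
        default=CLASS_BALANCED,
    )
    return out


def class_sizes(labelled: pd.DataFrame) -> dict[str, int]:
    counts = labelled["gene_class"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in (CLASS_MALE, CLASS_BALANCED, CLASS_FEMALE)}


def group_summary(labelled: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1) of male/female average expression per class.

    Values are rounded to integers for report parity with array units; a
    single-gene class has SD reported as 0 with ``sd_defined=False``.
    """
    rows = []
    for cls, sub in labelled.groupby("gene_class"):
        for sex_col, sex in (("avg_exp_male", "male"), ("avg_exp_female", "female")):
            vals = sub[sex_col].to_numpy(dtype=float)
            sd_ok = len(vals) > 1
            rows.append(
                {
                    "gene_class": cls,
                    "sex": sex,
                    "n_genes": len(vals),
                    "mean": int(round(vals.mean())),
                    "sd": int(round(vals.std(ddof=1))) if sd_ok else 0,
                    "sd_defined": sd_ok,
                }
            )
    return pd.DataFrame(rows)


def balanced_vs_unbalanced_test(labelled: pd.DataFrame, sex: str) -> tuple[float, float]:
    """Welch two-sample t-test, balanced minus male-biased-unbalanced."""
    col = f"avg_exp_{sex}"
    bal = labelled.loc[labelled["gene_class"] == CLASS_BALANCED, col]
    unb = labelled.loc[labelled["gene_class"] == CLASS_MALE, col]
    if len(bal) < 2 or len(unb) < 2:
        raise ValueError("both classes need >= 2 genes")
    res = stats.ttest_ind(bal, unb, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def gene_correlation_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene correlation counts, each gene's counts taken once.

    Counts repeated identically across a gene's blocks collapse trivially;
    where they differ between blocks the per-gene maximum is used.
    """
    present = records.dropna(subset=["probeset"])
    return present.groupby("probeset")[["n_corr", "n_neg", "n_pos"]].max()


def correlation_summary(labelled: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Mean correlations per gene (total / positive / negative) per class."""
    counts = gene_correlation_counts(records)
    rows = []
    for cls, sub in labelled.groupby("gene_class"):
        c = counts.loc[sub["probeset"]]
        rows.append(
            {
                "gene_class": cls,
                "n_genes": len(sub),
                "corr_per_gene": round(float(c["n_corr"].mean()), 2),
                "pos_per_gene": round(float(c["n_pos"].mean()), 2),
                "neg_per_gene": round(float(c["n_neg"].mean()), 2),
            }
        )
    return pd.DataFrame(rows)


def count_block_correlations(
    block: Block,
    expression: ExpressionMatrix,
    methylation: MethylationMatrix,
    genes: list[str] | None = None,
    flank: int = 100_000,
    alpha: float = ALPHA,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Significant window-expression correlations per gene within one block.

    For every gene x window pair, expression is regressed on the window's
    methylation with sex as a covariate; p-values are adjusted within the
    block's gene x window family and counted by slope sign at ``alpha``.
    """
    inds = [i for i in expression.individuals if i in methylation.individuals]
    male = (expression.samples.loc[inds, "sex"] == "male").to_numpy(float)
    feats = expression.features
    if genes is None:
        genes = [
            ps
            for ps, f in feats.iterrows()
            if f.get("chrom") == block.chrom
            and not pd.isna(f.get("start"))
            and max(block.start - f["end"], f["start"] - block.end, 0) <= flank
        ]
    window_ids = block.windows["methbin"].tolist()
    tvals, pvals, keys = [], [], []
    for ps in genes:
        y = expression.values.loc[ps, inds].to_numpy(dtype=float)
        for w in window_ids:
            x = methylation.values.loc[w, inds].to_numpy(dtype=float)
            X = sm.add_constant(np.column_stack([x, male]))
            fit = sm.OLS(y, X).fit()
            tvals.append(fit.tvalues[1])
            pvals.append(fit.pvalues[1])
            keys.append(ps)
    if not keys:
        return pd.DataFrame(columns=["probeset", "n_corr", "n_neg", "n_pos"])
    adj = multipletests(pvals, method=adjust)[1]
    df = pd.DataFrame({"probeset": keys, "t": tvals, "p_adj": adj})
    df["sig"] = df["p_adj"] < alpha
    out = (
        df.groupby("probeset")
        .apply(
            lambda g: pd.Series(
                {
                    "n_corr": int(g["sig"].sum()),
                    "n_neg": int((g["sig"] & (g["t"] < 0)).sum()),
                    "n_pos": int((g["sig"] & (g["t"] > 0)).sum()),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return out
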