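"""Per-window sex-difference statistics and hyper-methylated block discovery.

Male hyper-methylated (MHM) regions on the avian Z chromosome are runs of
adjacent 1-kb windows whose methylation is strongly elevated in ZZ males
relative to ZW females; female hyper-methylated (FHM) regions are the mirror
case.  A window qualifies for a block when it passes a median-level floor
(male direction only), a Wilcoxon rank-sum significance cut on the
male-vs-female values, and the correct direction of the male:female mean
ratio; blocks are maximal runs of at least ``min_run`` adjacent qualifying
windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methwin import ExpressionMatrix, MethylationMatrix, parse_window_id

#: Criteria calibrated on the originally known MHM region: window median
#: above 8.52 (in the configured normalization units), rank-sum p below
#: 1.75e-10, and five or more adjacent windows.
MHM_P_MAX = 1.75e-10
MHM_MEDIAN_MIN = 8.52
DEFAULT_MIN_RUN = 5
FHM_P_MAX = 0.05


@dataclass(frozen=True)
class BlockCriteria:
    """Window-level criteria for block membership."""

    direction: str  # "male" or "female"
    p_max: float
    median_min: float | None = None
    min_run: int = DEFAULT_MIN_RUN

    def __post_init__(self) -> None:
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.direction not in ("male", "female"):
            raise ValueError("direction must be 'male' or 'female'")


MHM_CRITERIA = BlockCriteria("male", MHM_P_MAX, MHM_MEDIAN_MIN, DEFAULT_MIN_RUN)
FHM_CRITERIA = BlockCriteria("female", FHM_P_MAX, None, DEFAULT_MIN_RUN)


@dataclass
class Block:
    """A maximal run of adjacent qualifying windows."""

    kind: str  # "MHM" or "FHM"
    chrom: str
    start: int  # bp, half-open [start, end)
    end: int
    windows: pd.DataFrame  # constituent per-window stats rows

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def rank_sum_pvalue(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when both groups have fewer than ``exact_max_n``
    observations and the data carry no ties; the normal approximation with
    tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) < exact_max_n and len(y) < exact_max_n and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def window_sex_stats(methylation: MethylationMatrix) -> pd.DataFrame:
    """Per-window sex statistics: means, median, rank-sum p and M:F ratio.

    Returns one row per window with columns
    ``methbin, chrom, pos, avg, median, avg_male, avg_female, pvalue, mf_ratio``.
    """
    male = methylation.sex_mask("male")
    female = methylation.sex_mask("female")
    if male.sum() < 2 or female.sum() < 2:
        raise ValueError("both sexes must be present with >= 2 individuals")

    vals = methylation.values.to_numpy(dtype=float)
    m_vals = vals[:, male]
    f_vals = vals[:, female]
    small = male.sum() < 8 and female.sum() < 8
    if small:
        pvals = np.array(
            [rank_sum_pvalue(m_vals[i], f_vals[i]) for i in range(vals.shape[0])]
        )
    else:
        pvals = stats.mannwhitneyu(
            m_vals, f_vals, alternative="two-sided", method="asymptotic", axis=1
        ).pvalue

    avg_male = m_vals.mean(axis=1)
    avg_female = f_vals.mean(axis=1)
    chrom_pos = [parse_window_id(w) for w in methylation.values.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(avg_female > 0, avg_male / avg_female, np.inf)
    return pd.DataFrame(
        {
            "methbin": methylation.values.index,
            "chrom": [c for c, _ in chrom_pos],
            "pos": [p for _, p in chrom_pos],
            "avg": vals.mean(axis=1),
            "median": np.median(vals, axis=1),
            "avg_male": avg_male,
            "avg_female": avg_female,
            "pvalue": pvals,
            "mf_ratio": ratio,
        }
    ).reset_index(drop=True)


def _qualifies(stats_df: pd.DataFrame, criteria: BlockCriteria) -> np.ndarray:
    ok = stats_df["pvalue"].to_numpy() < criteria.p_max
    if criteria.direction == "male":
        ok &= stats_df["mf_ratio"].to_numpy() > 1
        if criteria.median_min is not None:
            ok &= stats_df["median"].to_numpy() > criteria.median_min
    else:
        ok &= stats_df["mf_ratio"].to_numpy() < 1
        if criteria.median_min is not None:
            ok &= stats_df["median"].to_numpy() > criteria.median_min
    return ok


def find_blocks(
    stats_df: pd.DataFrame,
    criteria: BlockCriteria,
    window_size: int = 1000,
) -> list[Block]:
    """Merge adjacent qualifying windows into maximal blocks.

    Adjacency means a start-to-start distance of exactly one window size on
    the same chromosome; a single failing window breaks a run.  Runs shorter
    than ``criteria.min_run`` are discarded.
    """
    df = stats_df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    qual = _qualifies(df, criteria)
    kind = "MHM" if criteria.direction == "male" else "FHM"
    blocks: list[Block] = []
    run_start = None
    for i in range(len(df) + 1):
        adjacent = (
            i < len(df)
            and qual[i]
            and run_start is not None
            and df.at[i, "chrom"] == df.at[i - 1, "chrom"]
            and df.at[i, "pos"] == df.at[i - 1, "pos"] + window_size
        )
        if i < len(df) and qual[i] and run_start is None:
            run_start = i
        elif not adjacent:
            if run_start is not None:
                run = df.iloc[run_start:i]
                if len(run) >= criteria.min_run:
                    blocks.append(
                        Block(
                            kind=kind,
                            chrom=run["chrom"].iat[0],
                            start=int(run["pos"].iat[0]),
                            end=int(run["pos"].iat[-1]) + window_size,
                            windows=run.reset_index(drop=True),
                        )
                    )
            run_start = i if (i < len(df) and qual[i]) else None
    return blocks


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def block_gene_report(
    blocks: list[Block],
    expression: ExpressionMatrix,
    flank: int = 100_000,
) -> pd.DataFrame:
    """Genes within ``flank`` bp of each block, with sex-difference stats.

    The distance between a gene interval and the block interval must be at
    most ``flank`` (closed boundary).  The per-gene sex-difference p-value is
    a Wilcoxon rank-sum, Holm-adjusted across all genes in the report.
    """
    feats = expression.features
    needed = {"chrom", "start", "end"}
    if not needed.issubset(feats.columns):
        raise ValueError("expression features need chrom/start/end intervals")
    male = (expression.samples.loc[expression.individuals, "sex"] == "male").to_numpy()

    rows = []
    for bi, block in enumerate(blocks):
        for probeset, feat in feats.iterrows():
            if feat["chrom"] != block.chrom or pd.isna(feat["start"]):
                continue
            gap = max(block.start - feat["end"], feat["start"] - block.end, 0)
            if gap > flank:
                continue
            y = expression.values.loc[probeset].to_numpy(dtype=float)
            m, f = y[male], y[~male]
            rows.append(
                {
                    "block_index": bi,
                    "block_kind": block.kind,
                    "block_pos": f"{block.chrom}:{block.start}-{block.end}",
                    "probeset": probeset,
                    "gene_name": feat.get("gene_name", ""),
                    "avg_exp": y.mean(),
                    "avg_exp_male": m.mean(),
                    "avg_exp_female": f.mean(),
                    "pvalue_raw": rank_sum_pvalue(m, f),
                    "mf_ratio": m.mean() / f.mean() if f.mean() > 0 else np.inf,
                }
            )
    report = pd.DataFrame(rows)
    if not report.empty:
        # one adjustment per unique gene, propagated to repeated block rows
        unique = report.drop_duplicates("probeset").set_index("probeset")
        adj = pd.Series(
            holm_adjust(unique["pvalue_raw"].to_numpy()), index=unique.index
        )
        report["wilcox_pval"] = report["probeset"].map(adj)
    return report


def null_window_fpr(stats_df: pd.DataFrame, alpha: float = 0.05) -> float:
    """Fraction of windows with p below alpha (type-I calibration check)."""
    return float((stats_df["pvalue"] < alpha).mean())
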