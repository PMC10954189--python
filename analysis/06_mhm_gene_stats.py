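"""Block-adjacent gene statistics from the printed block-gene table.

Deduplicates the table, classifies genes by their sex difference in
expression, and reports the group summaries, the balanced-vs-unbalanced
Welch test and the per-class correlation rates.  Writes results/mhm_genes/.
"""

import json
from pathlib import Path

from zmeth import experiments, mhmgenes

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "mhm_genes"


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    table = mhmgenes.load_mhm_gene_table()
    labelled = mhmgenes.classify(mhmgenes.dedupe_genes(table))
    labelled.to_csv(OUTDIR / "gene_classes.tsv", sep="\t", index=False)
    mhmgenes.group_summary(labelled).to_csv(
        OUTDIR / "group_summary.tsv", sep="\t", index=False
    )
    mhmgenes.correlation_summary(labelled, table).to_csv(
        OUTDIR / "correlation_summary.tsv", sep="\t", index=False
    )
    stats = experiments.mhm_gene_statistics()
    (OUTDIR / "headline_stats.json").write_text(json.dumps(stats, indent=1))
    print(f"{stats['n_unique_genes']} unique expression-bearing genes: "
          f"{stats['n_male_biased']} male-biased unbalanced, "
          f"{stats['n_balanced']} balanced, "
          f"{stats['n_female_biased']} female-biased")
    print(f"male expression means: unbalanced {stats['unbalanced_male_mean']}, "
          f"balanced {stats['balanced_male_mean']} "
          f"(Welch t {stats['welch_t_male']}, p {stats['welch_p_male']})")
    print(f"balanced-class correlations per gene: "
          f"{stats['balanced_corr_per_gene']} total, "
          f"{stats['balanced_pos_per_gene']} positive, "
          f"{stats['balanced_neg_per_gene']} negative")
    print(f"wrote {OUTDIR}")


if __name__ == "__main__":
    main()
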