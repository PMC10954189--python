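"""Methylation-expression integration and causal edge orientation.

Maps eQTL for the planted genes, overlaps their support intervals with the
methylation QTL, tests the expression-methylation association under the
three models (all/male/female), and orients the significant pairs with the
single-anchor SEM comparison.  The two planted chains should orient in
opposite directions.  Writes results/integrate/.
"""

import json
from pathlib import Path

import pandas as pd

from zmeth import integrate, methwin, qtlmap

ROOT = Path(__file__).resolve().parents[1]
SIMDIR = ROOT / "results" / "simdata"
OUTDIR = ROOT / "results" / "integrate"


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    mmap = qtlmap.MarkerMap.read_tsv(SIMDIR / "marker_map.tsv")
    samples = methwin.read_sample_sheet(SIMDIR / "samples.tsv")
    samples = samples.drop(columns=["total_reads"], errors="ignore")
    geno = pd.read_csv(SIMDIR / "genotypes.tsv", sep="\t").set_index("individual")
    gt = qtlmap.GenotypeTable(dosages=geno, samples=samples)
    mm = methwin.read_methylation_tsv(SIMDIR / "methylation.tsv", SIMDIR / "samples.tsv")
    evals = pd.read_csv(SIMDIR / "expression.tsv", sep="\t").set_index("probeset")
    evals.index.name = None
    feats = pd.read_csv(SIMDIR / "expression_features.tsv", sep="\t").set_index("probeset")
    em = methwin.ExpressionMatrix(values=evals, samples=samples, features=feats)
    truth = json.loads((SIMDIR / "truth.json").read_text())

    probs = qtlmap.genotype_probs(gt, mmap, step=2.0)
    # eQTL scans for the planted genes; mQTL scans for their coupled windows
    e_records, m_records = [], []
    for eff in truth:
        if eff["kind"] != "eQTL" or not eff["coupled_window"]:
            continue
        ps, w = eff["target"], eff["coupled_window"]
        feat = feats.loc[ps]
        e_records.append(
            qtlmap.map_phenotype(
                probs, evals.loc[ps], ps, mmap,
                phenotype_chrom=feat["chrom"], phenotype_bp=feat["start"],
                genotypes=gt,
            )
        )
        chrom, bp = methwin.parse_window_id(w)
        m_records.append(
            qtlmap.map_phenotype(
                probs, mm.values.loc[w], w, mmap,
                phenotype_chrom=chrom, phenotype_bp=bp, genotypes=gt,
            )
        )

    pairs = integrate.overlap_qtl(e_records, m_records, z_filter=False)
    assoc = integrate.associate(pairs, em, mm)
    oriented = integrate.orient_pairs(assoc, geno, em, mm)
    assoc.to_csv(OUTDIR / "associations.tsv", sep="\t", index=False)
    oriented.to_csv(OUTDIR / "causal_orientations.tsv", sep="\t", index=False)
    print(f"{len(pairs)} CI overlap(s), {len(assoc)} association test(s)")
    if not oriented.empty:
        print(oriented[["probeset", "methbin", "neo_edge", "LEO.NB.OCA",
                        "model_pvalue"]].to_string(index=False))
    print(f"wrote {OUTDIR}/causal_orientations.tsv")


if __name__ == "__main__":
    main()
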