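"""Simulate the synthetic advanced-intercross study used by the analyses.

Plants the effects the downstream stages look for: a male hyper-methylated
block (3.3x), a female-biased block, a cis methylation QTL on the Z, a
trans hotspot (12 Z windows driven by one autosomal marker), and two
expression-methylation causal chains (one in each direction).  Writes the
study tables under results/simdata/.
"""

from pathlib import Path

from zmeth import simdata

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "simdata"

MHM_WINDOWS = tuple(f"chrZ_{s}" for s in range(60_000, 68_000, 1000))
FHM_WINDOWS = tuple(f"chrZ_{s}" for s in range(120_000, 126_000, 1000))
HOTSPOT_TARGETS = tuple(f"chrZ_{s}" for s in range(10_000, 22_000, 1000))

EFFECTS = (
    simdata.PlantedEffect(
        kind="MHM_block", target="mhm_block", male_multiplier=3.3,
        block_windows=MHM_WINDOWS,
    ),
    simdata.PlantedEffect(
        kind="FHM_block", target="fhm_block", male_multiplier=0.6,
        block_windows=FHM_WINDOWS,
    ),
    simdata.PlantedEffect(
        kind="cis_methQTL", target="chrZ_96000", source_marker="chrZ_m06",
        additive_effect=0.8,
    ),
    *(
        simdata.PlantedEffect(
            kind="trans_methQTL", target=w, source_marker="chr2_m05",
            additive_effect=0.8, sex_interaction_effect=0.6,
        )
        for w in HOTSPOT_TARGETS
    ),
    simdata.PlantedEffect(  # G -> E -> M chain
        kind="eQTL", target="PS_chr1_004", source_marker="chr1_m04",
        additive_effect=0.4, coupled_window="chr1_90000",
        coupling=0.8, direction="expr_to_meth",
    ),
    simdata.PlantedEffect(  # G -> M -> E chain (methylation drives expression)
        kind="eQTL", target="PS_chr3_006", source_marker="chr3_m07",
        additive_effect=0.0, coupled_window="chr3_130000",
        coupling=0.7, direction="meth_to_expr",
    ),
    simdata.PlantedEffect(  # the coupled window's own QTL for the G->M->E chain
        kind="cis_methQTL", target="chr3_130000", source_marker="chr3_m07",
        additive_effect=0.8,
    ),
)


def main(seed: int = 7) -> simdata.SimulatedStudy:
    cfg = simdata.SimConfig(seed=seed, planted_effects=EFFECTS)
    study = simdata.simulate_study(cfg)
    study.write(OUTDIR)
    n_m = (study.genotypes.samples["sex"] == "male").sum()
    n_f = (study.genotypes.samples["sex"] == "female").sum()
    print(f"simulated {n_m} males + {n_f} females, seed {seed}")
    print(f"  {study.methylation.values.shape[0]} windows, "
          f"{study.expression.values.shape[0]} probesets, "
          f"{len(study.truth)} planted effects")
    print(f"  wrote tables to {OUTDIR}")
    return study


if __name__ == "__main__":
    main()
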