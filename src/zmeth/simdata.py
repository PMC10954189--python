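"""Synthetic advanced-intercross studies with ZW sex chromosomes.

The generator emulates the design the pipeline targets: an F8 advanced
intercross founded by one wild (Red-Junglefowl-like) male and three domestic
females, phenotyped for 1-kb-window MeDIP-style methylation counts and
array-like gene expression.  Defaults follow the study design: 124
individuals (69 ZZ males, 55 ZW females), markers ~16 cM apart, negative-
binomial read counts around a mean per-window coverage of ~25 reads (the
expected read count of a 1-kb window at ~3.4x depth with ~136-bp reads), and
a baseline Z-window male:female dose ratio of ~1.7.

Inheritance bookkeeping: autosomes recombine in both sexes (Haldane map
function, no interference); fathers pass one recombined Z, mothers pass
their single Z intact to sons and their W to daughters, so every female is
hemizygous at every Z marker.

Planted effects (methylation QTL, expression QTL, MHM/FHM blocks, sex
shifts, methylation-expression couplings) are recorded in a ground-truth
ledger so downstream detections can be scored against what was planted.
Fold changes for planted blocks are specified on the normalized scale the
analysis sees; raw count multipliers are calibrated by a fixed point on the
expected per-individual totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import methwin
from .methwin import ExpressionMatrix, MethylationMatrix
from .qtlmap import GenotypeTable, MarkerMap, haldane_r

WILD, DOM = 1, 0
W_CODE = -1  # W chromosome placeholder in the female Z-haplotype slot


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_cm: float
    length_bp: int
    is_z: bool = False


#: Desk-scale default genome: 3 autosomes + Z, 12 markers and 200 windows each.
DEFAULT_CHROMOSOMES = (
    Chromosome("chr1", 176.0, 200_000, False),
    Chromosome("chr2", 176.0, 200_000, False),
    Chromosome("chr3", 176.0, 200_000, False),
    Chromosome("chrZ", 176.0, 200_000, True),
)


@dataclass
class PlantedEffect:
    """One ground-truth effect wired into the generative model.

    ``additive_effect`` is the fractional change in mean per wild allele for
    methylation targets, and the log-scale slope per allele for expression
    targets.  ``sex_interaction_effect`` is the male-minus-female difference
    in that allelic effect (each sex gets additive +/- half the difference).
    ``male_multiplier`` is the male:female fold change planted for
    MHM/FHM blocks and sex shifts, on the normalized scale.  ``coupling``
    links a gene to a methylation window for causality tests; ``direction``
    is "meth_to_expr" (methylation drives expression) or "expr_to_meth".
    """

    kind: str  # cis_methQTL | trans_methQTL | eQTL | MHM_block | FHM_block | sex_shift
    target: str
    source_marker: str | None = None
    additive_effect: float = 0.0
    sex_interaction_effect: float = 0.0
    male_multiplier: float = 1.0
    block_windows: tuple[str, ...] = ()
    coupled_window: str | None = None
    coupling: float = 0.0
    direction: str = "meth_to_expr"

    def __post_init__(self) -> None:
        kinds = {"cis_methQTL", "trans_methQTL", "eQTL", "MHM_block", "FHM_block", "sex_shift"}
        if self.kind not in kinds:
            raise ValueError(f"unknown effect kind: {self.kind}")
        if self.male_multiplier <= 0:
            raise ValueError("male_multiplier must be positive")
        if self.kind in ("MHM_block", "FHM_block"):
            starts = [methwin.parse_window_id(w)[1] for w in self.block_windows]
            if len(starts) > 1:
                gaps = np.diff(sorted(starts))
                if np.any(gaps != gaps[0]):
                    raise ValueError("block windows must be contiguous")


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic intercross."""

    n_males: int = 69
    n_females: int = 55
    n_generations: int = 8
    chromosomes: tuple[Chromosome, ...] = DEFAULT_CHROMOSOMES
    n_markers_per_chrom: int = 12
    n_windows_per_chrom: int = 200
    window_size_bp: int = 1000
    mean_coverage: float = 25.0
    dispersion: float = 0.2  # NB overdispersion alpha: var = mu + alpha*mu^2
    z_dose_ratio: float = 1.7  # baseline Z-window male:female ratio
    n_batches: int = 2
    batch_effect: float = 1.1  # mean multiplier for the second batch
    n_genes_per_chrom: int = 10
    expression_baseline: float = 500.0
    expression_noise_sd: float = 0.3  # log-scale residual SD
    scale: float = methwin.DEFAULT_SCALE
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males + self.n_females <= 0:
            raise ValueError("need at least one individual")
        if self.window_size_bp <= 0:
            raise ValueError("window_size_bp must be positive")
        if sum(c.is_z for c in self.chromosomes) > 1:
            raise ValueError("at most one Z chromosome")
        if any(c.length_cm <= 0 or c.length_bp <= 0 for c in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.n_markers_per_chrom < 1:
            raise ValueError("each chromosome needs at least one marker")


@dataclass
class SimulatedStudy:
    marker_map: MarkerMap
    genotypes: GenotypeTable
    methylation: MethylationMatrix
    expression: ExpressionMatrix
    truth: tuple[PlantedEffect, ...]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.marker_map.write_tsv(outdir / "marker_map.tsv")
        self.genotypes.write_tsv(outdir / "genotypes.tsv")
        self.methylation.write_tsv(outdir / "methylation.tsv")
        self.methylation.write_sample_sheet(outdir / "samples.tsv")
        self.expression.write_tsv(outdir / "expression.tsv")
        feats = self.expression.features.copy()
        feats.insert(0, "probeset", feats.index)
        feats.to_csv(outdir / "expression_features.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump([asdict(e) for e in self.truth], fh, indent=1)


def build_marker_map(config: SimConfig) -> MarkerMap:
    rows = []
    for chrom in config.chromosomes:
        cms = np.linspace(0.0, chrom.length_cm, config.n_markers_per_chrom)
        bps = np.linspace(0, chrom.length_bp - 1, config.n_markers_per_chrom).astype(int)
        for i, (cm, bp) in enumerate(zip(cms, bps)):
            rows.append(
                {
                    "marker": f"{chrom.name}_m{i:02d}",
                    "chrom": chrom.name,
                    "cM": float(cm),
                    "bp": int(bp),
                }
            )
    z_name = next((c.name for c in config.chromosomes if c.is_z), None)
    return MarkerMap(pd.DataFrame(rows), z_chrom=z_name)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def _recomb_gamete(
    haps: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Recombined gametes from diploid haplotypes (vectorized over parents).

    ``haps``: (n, 2, m) parental haplotypes; ``rates``: recombination
    fraction per marker interval (length m-1).  Crossovers occur
    independently per interval (Haldane, no interference).
    """
    n, _, m = haps.shape
    start = rng.integers(0, 2, size=n)
    if m > 1:
        switch = rng.random((n, m - 1)) < rates
        track = np.concatenate([start[:, None], switch], axis=1)
        which = np.cumsum(track, axis=1) % 2
    else:
        which = start[:, None]
    return np.take_along_axis(haps, which[:, None, :], axis=1)[:, 0, :]


class _Population:
    """Haplotype state for one generation."""

    def __init__(self, sexes: np.ndarray, chrom_haps: dict[str, np.ndarray]):
        self.sexes = sexes  # bool array: True = female
        self.chrom_haps = chrom_haps  # name -> (n, 2, m) int8; female Z hap2 = W_CODE


def _founders(config: SimConfig, markers: dict[str, pd.DataFrame]) -> _Population:
    """1 wild male + 3 domestic females, fixed for alternative alleles."""
    n = 4
    sexes = np.array([False, True, True, True])
    haps = {}
    for chrom in config.chromosomes:
        m = len(markers[chrom.name])
        h = np.full((n, 2, m), DOM, dtype=np.int8)
        h[0, :, :] = WILD
        if chrom.is_z:
            h[1:, 1, :] = W_CODE  # females: single Z + W
        haps[chrom.name] = h
    return _Population(sexes, haps)


def _next_generation(
    pop: _Population,
    config: SimConfig,
    markers: dict[str, pd.DataFrame],
    n_males: int,
    n_females: int,
    rng: np.random.Generator,
) -> _Population:
    n = n_males + n_females
    sexes = np.zeros(n, dtype=bool)
    sexes[n_males:] = True  # daughters receive the maternal W
    male_idx = np.flatnonzero(~pop.sexes)
    female_idx = np.flatnonzero(pop.sexes)
    if len(male_idx) == 0 or len(female_idx) == 0:
        raise ValueError("a generation lost one sex entirely")
    sires = rng.choice(male_idx, size=n)
    dams = rng.choice(female_idx, size=n)

    haps = {}
    for chrom in config.chromosomes:
        sub = markers[chrom.name]
        d = np.diff(sub["cM"].to_numpy())
        rates = haldane_r(d)
        parent = pop.chrom_haps[chrom.name]
        m = parent.shape[2]
        child = np.empty((n, 2, m), dtype=np.int8)
        if not chrom.is_z:
            child[:, 0, :] = _recomb_gamete(parent[sires], rates, rng)
            child[:, 1, :] = _recomb_gamete(parent[dams], rates, rng)
        else:
            # paternal gamete: recombined Z (all offspring)
            child[:, 0, :] = _recomb_gamete(parent[sires], rates, rng)
            # maternal: sons get the dam's single Z intact, daughters get W
            child[:, 1, :] = parent[dams][:, 0, :]
            child[sexes, 1, :] = W_CODE
        haps[chrom.name] = child
    return _Population(sexes, haps)


def simulate_pedigree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeTable:
    """Final-generation founder-allele dosages after random intercrossing.

    Returns dosages of the wild allele: autosomes and male Z in {0, 1, 2},
    female Z hemizygous in {0, 1}.  Batch labels (``n_batches`` groups) are
    assigned at random for covariate plumbing.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mmap = build_marker_map(config)
    markers = {c.name: mmap.markers_on(c.name) for c in config.chromosomes}
    pop = _founders(config, markers)
    for _ in range(config.n_generations):
        pop = _next_generation(
            pop, config, markers, config.n_males, config.n_females, rng
        )

    ids = [f"F{config.n_generations}_{i:04d}" for i in range(len(pop.sexes))]
    cols = {}
    for chrom in config.chromosomes:
        h = pop.chrom_haps[chrom.name]
        sub = markers[chrom.name]
        if chrom.is_z:
            dosage = np.where(
                h[:, 1, :] == W_CODE, h[:, 0, :], h[:, 0, :] + h[:, 1, :]
            )
        else:
            dosage = h.sum(axis=1)
        for j, marker in enumerate(sub["marker"]):
            cols[marker] = dosage[:, j].astype(int)
    dosages = pd.DataFrame(cols, index=ids)
    samples = pd.DataFrame(
        {
            "sex": np.where(pop.sexes, "female", "male"),
            "batch": [f"b{rng.integers(1, config.n_batches + 1)}" for _ in ids],
        },
        index=ids,
    )
    return GenotypeTable(dosages=dosages, samples=samples)


# ---------------------------------------------------------------------------
# methylation phenotypes
# ---------------------------------------------------------------------------

def _window_universe(config: SimConfig) -> list[str]:
    ids = []
    for chrom in config.chromosomes:
        ids.extend(
            f"{chrom.name}_{i * config.window_size_bp}"
            for i in range(config.n_windows_per_chrom)
        )
    return ids


def _allelic_multiplier(effect: PlantedEffect, dosage: np.ndarray, male: np.ndarray) -> np.ndarray:
    a_male = effect.additive_effect + effect.sex_interaction_effect / 2.0
    a_female = effect.additive_effect - effect.sex_interaction_effect / 2.0
    per_allele = np.where(male, a_male, a_female)
    mult = 1.0 + per_allele * dosage
    if (mult <= 0).any():
        raise ValueError(
            f"planted effect on {effect.target} drives a negative mean"
        )
    return mult


def _expected_means(
    config: SimConfig,
    genotypes: GenotypeTable,
    truth: Sequence[PlantedEffect],
    block_multipliers: dict[str, float],
    z_raw_ratio: float | None = None,
) -> pd.DataFrame:
    """Expected raw count per (window, individual) before count noise."""
    ids = _window_universe(config)
    inds = genotypes.individuals
    male = (genotypes.samples.loc[inds, "sex"] == "male").to_numpy()
    batch2 = (genotypes.samples.loc[inds, "batch"] != "b1").to_numpy()
    mu = np.full((len(ids), len(inds)), config.mean_coverage)
    idx = {w: i for i, w in enumerate(ids)}

    # per-window male multiplier: Z dose ratio by default; a planted block or
    # sex shift REPLACES it (its fold is the total normalized M:F ratio)
    male_mult = np.ones(len(ids))
    z_name = next((c.name for c in config.chromosomes if c.is_z), None)
    z_eff = config.z_dose_ratio if z_raw_ratio is None else z_raw_ratio
    if z_name is not None:
        on_z = np.array([w.startswith(z_name + "_") for w in ids])
        male_mult[on_z] = z_eff
    for eff in truth:
        if eff.kind in ("MHM_block", "FHM_block", "sex_shift"):
            windows = eff.block_windows or (eff.target,)
            raw_mult = block_multipliers.get(eff.target, eff.male_multiplier)
            for w in windows:
                if w not in idx:
                    raise ValueError(f"planted window {w} not in universe")
                male_mult[idx[w]] = raw_mult
    mu[:, male] *= male_mult[:, None]
    mu[:, batch2] *= config.batch_effect

    for eff in truth:
        if eff.kind in ("cis_methQTL", "trans_methQTL"):
            if eff.target not in idx:
                raise ValueError(f"planted window {eff.target} not in universe")
            dosage = genotypes.dosages[eff.source_marker].to_numpy(dtype=float)
            mu[idx[eff.target]] *= _allelic_multiplier(eff, dosage, male)
    return pd.DataFrame(mu, index=ids, columns=inds)


def _calibrate_multipliers(
    config: SimConfig,
    genotypes: GenotypeTable,
    truth: Sequence[PlantedEffect],
) -> tuple[dict[str, float], float]:
    """Fixed point so planted folds hold on the normalized scale.

    Per-individual total normalization deflates a planted male fold by the
    male:female ratio of expected totals; a few fixed-point sweeps converge
    the raw multipliers so that the realized normalized M:F ratios equal the
    requested ``male_multiplier`` (and the baseline Z dose ratio equals
    ``z_dose_ratio``).  Returns (per-target block multipliers, raw Z ratio).
    """
    male = (genotypes.samples.loc[genotypes.individuals, "sex"] == "male").to_numpy()
    blocks = [e for e in truth if e.kind in ("MHM_block", "FHM_block", "sex_shift")]
    mult = {e.target: e.male_multiplier for e in blocks}
    z_raw = config.z_dose_ratio
    for _ in range(8):
        mu = _expected_means(config, genotypes, truth, mult, z_raw)
        totals = mu.sum(axis=0).to_numpy()
        total_ratio = totals[male].mean() / totals[~male].mean()
        z_raw = config.z_dose_ratio * total_ratio
        for e in blocks:
            mult[e.target] = e.male_multiplier * total_ratio
    return mult, z_raw


def generate_methylation(
    genotypes: GenotypeTable,
    truth: Sequence[PlantedEffect],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    noise: str = "nb",
) -> MethylationMatrix:
    """Per-window negative-binomial counts, normalized per individual.

    ``noise``: "nb" draws gamma-Poisson counts with
    ``var = mu + dispersion * mu^2`` ("poisson" when dispersion is 0);
    "exact" returns the expected counts unchanged (the zero-noise limit used
    by identity tests).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    block_mult, z_raw = _calibrate_multipliers(config, genotypes, truth)
    mu = _expected_means(config, genotypes, truth, block_mult, z_raw)
    if noise == "exact":
        counts = mu
    elif noise == "nb" and config.dispersion > 0:
        lam = rng.gamma(
            shape=1.0 / config.dispersion,
            scale=config.dispersion * mu.to_numpy(),
        )
        counts = pd.DataFrame(
            rng.poisson(lam), index=mu.index, columns=mu.columns
        )
    else:  # Poisson: the dispersion -> 0 count-noise floor
        counts = pd.DataFrame(
            rng.poisson(mu.to_numpy()), index=mu.index, columns=mu.columns
        )
    return methwin.normalize(
        counts, genotypes.samples, scale=config.scale,
        window_size=config.window_size_bp,
    )


# ---------------------------------------------------------------------------
# expression phenotypes
# ---------------------------------------------------------------------------

def _gene_panel(config: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom in config.chromosomes:
        span = config.n_windows_per_chrom * config.window_size_bp
        starts = np.linspace(0, span - 2000, config.n_genes_per_chrom).astype(int)
        for i, s in enumerate(starts):
            rows.append(
                {
                    "probeset": f"PS_{chrom.name}_{i:03d}",
                    "gene_id": f"G{chrom.name}{i:03d}",
                    "gene_name": f"{chrom.name.upper()}G{i}",
                    "chrom": chrom.name,
                    "start": int(s),
                    "end": int(s) + 1500,
                }
            )
    return pd.DataFrame(rows).set_index("probeset")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_expression(
    genotypes: GenotypeTable,
    methylation: MethylationMatrix,
    truth: Sequence[PlantedEffect],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Log-normal expression with planted eQTL, couplings and suppression.

    For a ``meth_to_expr`` coupling the gene's log expression gains
    ``coupling`` x the standardized methylation of the coupled window; for
    ``expr_to_meth`` the expression is generated first and the coupled
    window of ``methylation`` is overwritten in place as a linear response
    to expression plus noise, so the causal chain runs the planted way.
    Planted MHM blocks suppress male expression of genes within 100 kb of
    the block (half the block's log fold, mirroring the partial block-local
    down-regulation of male-biased genes).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    feats = _gene_panel(config)
    inds = genotypes.individuals
    male = (genotypes.samples.loc[inds, "sex"] == "male").to_numpy()
    n = len(inds)
    log_e = pd.DataFrame(
        np.log(config.expression_baseline)
        + rng.normal(0.0, config.expression_noise_sd, size=(len(feats), n)),
        index=feats.index,
        columns=inds,
    )

    gene_effects = [e for e in truth if e.kind == "eQTL"]
    for eff in gene_effects:
        if eff.target not in log_e.index:
            raise ValueError(f"planted gene {eff.target} not in panel")
        if eff.source_marker is not None:
            dosage = genotypes.dosages[eff.source_marker].to_numpy(dtype=float)
            a = eff.additive_effect + np.where(
                male, eff.sex_interaction_effect / 2, -eff.sex_interaction_effect / 2
            )
            log_e.loc[eff.target] += a * dosage
        if eff.coupled_window is not None and eff.direction == "meth_to_expr":
            if eff.coupled_window not in methylation.values.index:
                raise ValueError(f"coupled window {eff.coupled_window} missing")
            m = methylation.values.loc[eff.coupled_window].to_numpy(dtype=float)
            log_e.loc[eff.target] += eff.coupling * _standardize(m)

    # MHM-style suppression of block-adjacent genes in males
    for eff in truth:
        if eff.kind != "MHM_block" or not eff.block_windows:
            continue
        chrom, s0 = methwin.parse_window_id(eff.block_windows[0])
        _, s1 = methwin.parse_window_id(eff.block_windows[-1])
        lo, hi = s0 - 100_000, s1 + config.window_size_bp + 100_000
        near = feats[(feats["chrom"] == chrom) & (feats["end"] >= lo) & (feats["start"] <= hi)]
        supp = np.log(max(1.0 / eff.male_multiplier, 0.05))
        for ps in near.index:
            log_e.loc[ps, np.array(male)] += supp / 2.0

    values = pd.DataFrame(np.exp(log_e), index=log_e.index, columns=inds)

    # expression-drives-methylation couplings overwrite the coupled window
    for eff in gene_effects:
        if eff.coupled_window is None or eff.direction != "expr_to_meth":
            continue
        if eff.coupled_window not in methylation.values.index:
            raise ValueError(f"coupled window {eff.coupled_window} missing")
        w = methylation.values.loc[eff.coupled_window].to_numpy(dtype=float)
        mu_w, sd_w = w.mean(), w.std()
        e_std = _standardize(np.log(values.loc[eff.target].to_numpy()))
        resp = mu_w + sd_w * (
            eff.coupling * e_std
            + np.sqrt(max(1 - eff.coupling**2, 0.05)) * rng.normal(size=n)
        )
        methylation.values.loc[eff.coupled_window] = np.clip(resp, 0.0, None)

    return ExpressionMatrix(values=values, samples=genotypes.samples, features=feats)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run the full generative pipeline under one seed."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_pedigree(config, rng)
    methylation = generate_methylation(genotypes, config.planted_effects, config, rng)
    expression = generate_expression(
        genotypes, methylation, config.planted_effects, config, rng
    )
    return SimulatedStudy(
        marker_map=build_marker_map(config),
        genotypes=genotypes,
        methylation=methylation,
        expression=expression,
        truth=tuple(config.planted_effects),
    )
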