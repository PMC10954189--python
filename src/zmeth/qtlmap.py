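"""Interval mapping of methylation and expression phenotypes in an intercross.

Haley-Knott regression on conditional genotype-probability dosages: at each
position on a pseudomarker grid the phenotype is regressed on the expected
founder-allele dosage plus covariates (sex, batch), and
``LOD = (n/2) * log10(RSS_null / RSS_full)`` where the null model retains the
covariates.  Sex may additionally enter as an interactive covariate
(genotype x sex term); a QTL is flagged sex-interactive when the interactive
model beats the additive model by more than 1 LOD at the peak.

The Z chromosome is handled hemizygously: males (ZZ) carry additive dosages
in {0, 1, 2} modelled with a 3-state Markov chain, females (ZW) carry a
single Z whose dosage is in {0, 1} and follows a 2-state chain; sex is always
in the model, and cross-sex pooling uses the additive dosage column only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

LOD_EPS = 1e-12


def haldane_r(d_cm: float) -> float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def haldane_d(r: float) -> float:
    """Inverse Haldane map function (cM)."""
    return -50.0 * np.log(1.0 - 2.0 * r)


class MarkerMap:
    """Ordered genetic/physical marker positions per chromosome.

    ``table`` columns: marker, chrom, cM, bp.  Within a chromosome cM must be
    non-decreasing and bp strictly increasing.  ``z_chrom`` names the single
    Z chromosome (or None for an all-autosome map).
    """

    def __init__(self, table: pd.DataFrame, z_chrom: str | None = "chrZ"):
        table = table.reset_index(drop=True)
        required = {"marker", "chrom", "cM", "bp"}
        if not required.issubset(table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        for chrom, sub in table.groupby("chrom", sort=False):
            if (np.diff(sub["cM"].to_numpy()) < 0).any():
                raise ValueError(f"cM positions decrease on {chrom}")
            if (np.diff(sub["bp"].to_numpy()) <= 0).any():
                raise ValueError(f"bp positions not strictly increasing on {chrom}")
        self.table = table
        self.z_chrom = z_chrom

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def is_z(self, chrom: str) -> bool:
        return chrom == self.z_chrom

    def markers_on(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)

    def bp_to_cm(self, chrom: str, bp: float) -> float:
        """Nearest-marker linear interpolation of genetic position."""
        sub = self.markers_on(chrom)
        if sub.empty:
            raise ValueError(f"no markers on {chrom}")
        return float(np.interp(bp, sub["bp"].to_numpy(), sub["cM"].to_numpy()))

    def cm_to_bp(self, chrom: str, cm: float) -> float:
        sub = self.markers_on(chrom)
        return float(np.interp(cm, sub["cM"].to_numpy(), sub["bp"].to_numpy()))

    def nearest_marker(self, chrom: str, cm: float) -> str:
        sub = self.markers_on(chrom)
        idx = int(np.argmin(np.abs(sub["cM"].to_numpy() - cm)))
        return str(sub["marker"].iat[idx])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, z_chrom: str | None = "chrZ") -> "MarkerMap":
        return cls(pd.read_csv(path, sep="\t"), z_chrom=z_chrom)


@dataclass
class GenotypeTable:
    """Founder-allele dosages (individuals x markers) with sex/batch labels.

    Autosomal and male-Z dosages are in {0, 1, 2}; female-Z dosages are
    hemizygous in {0, 1}.
    """

    dosages: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if "sex" not in self.samples.columns:
            raise ValueError("sample sheet needs a sex column")
        if self.samples["sex"].isna().any():
            raise ValueError("missing sex labels")

    @property
    def individuals(self) -> list[str]:
        return list(self.dosages.index)

    def validate_z(self, marker_map: MarkerMap) -> None:
        z = marker_map.z_chrom
        if z is None:
            return
        z_markers = marker_map.markers_on(z)["marker"]
        female = self.samples.loc[self.individuals, "sex"] == "female"
        sub = self.dosages.loc[female.to_numpy(), self.dosages.columns.intersection(z_markers)]
        if (sub.to_numpy() > 1).any():
            raise ValueError("female Z dosage of 2 found")

    def write_tsv(self, path: str | Path) -> None:
        out = self.dosages.copy()
        out.insert(0, "individual", out.index)
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------

def _hap_transition(r: float, p: float) -> np.ndarray:
    """2-state founder-allele chain along a mosaic haplotype.

    With probability 1-r the founder origin (and hence the fully informative
    allele) is carried over; with probability r the allele is redrawn from
    the population frequency ``p`` of the wild allele.
    """
    return np.array(
        [[1 - r + r * (1 - p), r * p], [r * (1 - p), 1 - r + r * p]]
    )


_PAIR_TO_DOSE = np.array([0, 1, 1, 2])  # ordered haplotype pairs -> dosage
_DOSE_TO_PAIR = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 0.5, 0.5, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
_PAIR_SUM = np.array(
    [[1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1]], dtype=float
)


def genotype_transition(d_cm: float, p: float = 0.5, n_states: int = 3) -> np.ndarray:
    """Dosage-state transition matrix over a map distance.

    3 states (two independent haplotype chains, heterozygote phase averaged)
    on autosomes and the male Z; 2 states (single haplotype) on the female Z.
    """
    r = haldane_r(d_cm)
    th = _hap_transition(r, p)
    if n_states == 2:
        return th
    t4 = np.kron(th, th)
    return _DOSE_TO_PAIR @ t4 @ _PAIR_SUM


@dataclass
class ChromProbs:
    """Conditional dosage probabilities on one chromosome's position grid."""

    chrom: str
    positions: np.ndarray  # cM grid
    nearest_marker: list[str]
    dosage: np.ndarray  # (n_ind, n_pos) expected dosage


@dataclass
class GenotypeProbs:
    """Expected dosages on a pseudomarker grid for every chromosome."""

    marker_map: MarkerMap
    samples: pd.DataFrame
    individuals: list[str]
    chroms: dict = field(default_factory=dict)  # chrom -> ChromProbs

    def grid(self, chroms: Iterable[str] | None = None) -> list[tuple[str, float]]:
        out = []
        for chrom in (chroms or self.chroms):
            cp = self.chroms[chrom]
            out.extend((chrom, float(c)) for c in cp.positions)
        return out


def _position_grid(marker_cm: np.ndarray, step: float) -> np.ndarray:
    grid = np.arange(marker_cm[0], marker_cm[-1] + step / 2, step)
    grid = np.union1d(np.round(grid, 6), np.round(marker_cm, 6))
    return grid


def _conditional_probs(
    geno: np.ndarray,
    marker_cm: np.ndarray,
    grid: np.ndarray,
    p: float,
    n_states: int,
) -> np.ndarray:
    """P(state at each grid position | flanking observed marker genotypes).

    Returns array (n_ind, n_grid, n_states).  At typed positions the
    distribution is degenerate on the observed state.  The genotype process
    is Markov along the chromosome, so conditioning on the two flanking
    markers is exact.
    """
    n_ind, n_mark = geno.shape
    out = np.zeros((n_ind, len(grid), n_states))
    marker_idx = {round(c, 6): j for j, c in enumerate(np.round(marker_cm, 6))}
    for gi, pos in enumerate(grid):
        key = round(float(pos), 6)
        if key in marker_idx:
            out[np.arange(n_ind), gi, geno[:, marker_idx[key]]] = 1.0
            continue
        right = int(np.searchsorted(marker_cm, pos))
        left = right - 1
        if left < 0:  # before first marker: condition on the first marker
            t = genotype_transition(marker_cm[0] - pos, p, n_states)
            out[:, gi, :] = t[geno[:, 0], :]  # chain run backwards (time-symmetric form)
            continue
        if right >= n_mark:  # past the last marker
            t = genotype_transition(pos - marker_cm[-1], p, n_states)
            out[:, gi, :] = t[geno[:, -1], :]
            continue
        tl = genotype_transition(pos - marker_cm[left], p, n_states)
        tr = genotype_transition(marker_cm[right] - pos, p, n_states)
        w = tl[geno[:, left], :] * tr[:, geno[:, right]].T  # (n_ind, n_states)
        w_sum = w.sum(axis=1, keepdims=True)
        w_sum[w_sum == 0] = 1.0
        out[:, gi, :] = w / w_sum
    return out


def genotype_probs(
    genotypes: GenotypeTable,
    marker_map: MarkerMap,
    step: float = 1.0,
    allele_freq: dict | None = None,
) -> GenotypeProbs:
    """Conditional genotype probabilities and expected dosages on a grid.

    ``allele_freq`` optionally gives the wild-allele frequency per chromosome
    used in the transition model (default 0.5 on autosomes, 2/3 on Z -- the
    conserved Z-pool frequency for a cross founded by one wild male and
    domestic females).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    gp = GenotypeProbs(
        marker_map=marker_map,
        samples=genotypes.samples,
        individuals=genotypes.individuals,
    )
    sex = genotypes.samples.loc[genotypes.individuals, "sex"].to_numpy()
    female = sex == "female"
    for chrom in marker_map.chromosomes:
        sub = marker_map.markers_on(chrom)
        if sub.empty:
            continue
        marker_cm = sub["cM"].to_numpy(dtype=float)
        geno = genotypes.dosages[sub["marker"]].to_numpy()
        grid = _position_grid(marker_cm, step)
        is_z = marker_map.is_z(chrom)
        p = (allele_freq or {}).get(chrom, 2 / 3 if is_z else 0.5)
        dosage = np.zeros((len(geno), len(grid)))
        if is_z and female.any():
            pm = _conditional_probs(
                geno[~female].astype(int), marker_cm, grid, p, 3
            )
            pf = _conditional_probs(
                geno[female].astype(int), marker_cm, grid, p, 2
            )
            dosage[~female] = pm @ np.array([0.0, 1.0, 2.0])
            dosage[female] = pf @ np.array([0.0, 1.0])
        else:
            pr = _conditional_probs(geno.astype(int), marker_cm, grid, p, 3)
            dosage = pr @ np.array([0.0, 1.0, 2.0])
        nearest = [marker_map.nearest_marker(chrom, c) for c in grid]
        gp.chroms[chrom] = ChromProbs(
            chrom=chrom,
            positions=grid,
            nearest_marker=nearest,
            dosage=dosage,
        )
    return gp


# ---------------------------------------------------------------------------
# Haley-Knott scan
# ---------------------------------------------------------------------------

@dataclass
class LodCurve:
    """LOD scores on the pseudomarker grid."""

    table: pd.DataFrame  # columns: chrom, cM, nearest_marker, lod
    model: str  # "additive" or "sex-interactive"

    def peak(self) -> pd.Series:
        return self.table.loc[self.table["lod"].idxmax()]

    def lod_at(self, chrom: str, cm: float) -> float:
        sub = self.table[self.table["chrom"] == chrom]
        idx = (sub["cM"] - cm).abs().idxmin()
        return float(sub.loc[idx, "lod"])

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)


def design_covariates(samples: pd.DataFrame, individuals: Sequence[str]) -> np.ndarray:
    """Intercept + sex + batch indicator columns."""
    sub = samples.loc[list(individuals)]
    cols = [np.ones(len(sub)), (sub["sex"] == "male").to_numpy(float)]
    if "batch" in sub.columns:
        levels = sorted(sub["batch"].unique())
        cols.extend((sub["batch"] == lev).to_numpy(float) for lev in levels[1:])
    return np.column_stack(cols)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ beta


def scan(
    probs: GenotypeProbs,
    phenotype: np.ndarray | pd.Series,
    interactive: bool = False,
    chroms: Iterable[str] | None = None,
) -> LodCurve:
    """Haley-Knott LOD scan of one phenotype over the pseudomarker grid.

    The null model contains intercept, sex and batch; the full model adds the
    expected dosage (and a dosage x sex product when ``interactive``).
    """
    if isinstance(phenotype, pd.Series):
        phenotype = phenotype.loc[probs.individuals].to_numpy()
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    Z = design_covariates(probs.samples, probs.individuals)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear covariates")
    male = (probs.samples.loc[probs.individuals, "sex"] == "male").to_numpy(float)

    y_res = _residualize(y[:, None], Z)[:, 0]
    rss0 = float(y_res @ y_res)
    rows = []
    for chrom in (chroms or probs.chroms):
        cp = probs.chroms[chrom]
        X = _residualize(cp.dosage, Z)
        if interactive:
            XI = _residualize(cp.dosage * male[:, None], Z)
        for j, pos in enumerate(cp.positions):
            if rss0 < LOD_EPS:  # constant phenotype
                lod = 0.0
            else:
                x = X[:, j]
                if interactive:
                    D = np.column_stack([x, XI[:, j]])
                    beta, res, *_ = np.linalg.lstsq(D, y_res, rcond=None)
                    fit = D @ beta
                    rss1 = float(((y_res - fit) ** 2).sum())
                else:
                    xx = float(x @ x)
                    rss1 = rss0 - (float(x @ y_res) ** 2) / xx if xx > LOD_EPS else rss0
                rss1 = max(rss1, LOD_EPS)
                lod = max(0.0, (n / 2.0) * np.log10(rss0 / rss1))
            rows.append(
                {
                    "chrom": chrom,
                    "cM": float(pos),
                    "nearest_marker": cp.nearest_marker[j],
                    "lod": lod,
                }
            )
    return LodCurve(
        table=pd.DataFrame(rows), model="sex-interactive" if interactive else "additive"
    )


def sex_interaction_flag(
    curve_add: LodCurve, curve_int: LodCurve, peak_chrom: str, peak_cm: float
) -> bool:
    """True iff the interactive model beats the additive by > 1 LOD at the peak."""
    return curve_int.lod_at(peak_chrom, peak_cm) - curve_add.lod_at(peak_chrom, peak_cm) > 1.0


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    significant: float
    suggestive: float

    def __post_init__(self) -> None:
        if not self.significant >= self.suggestive > 0:
            raise ValueError("need significant >= suggestive > 0")


def permutation_thresholds(
    phenotype_sampler: Callable[[np.random.Generator], np.ndarray],
    probs: GenotypeProbs,
    n_phenotypes: int,
    n_perm: int,
    rng: np.random.Generator,
    interactive: bool = False,
    chroms: Iterable[str] | None = None,
    stratify_by_sex: bool = False,
    pooling: str = "maxima",
    tail_frac: float = 0.05,
) -> ThresholdSet:
    """Pooled-tail permutation thresholds for genome-wide LOD significance.

    For each sampled phenotype, individual labels are permuted ``n_perm``
    times (optionally within sex strata) and the genome-wide maximum LOD per
    permutation recorded; that phenotype's top ``tail_frac`` of maxima are
    kept, the kept values pooled across phenotypes, and the pool's 95th /
    80th percentiles give the significant / suggestive thresholds.  With
    ``pooling='positions'`` all per-position LODs of every permutation enter
    the per-phenotype tail instead of per-permutation maxima.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 to define a 5% tail")
    if pooling not in ("maxima", "positions"):
        raise ValueError("pooling must be 'maxima' or 'positions'")
    sex = probs.samples.loc[probs.individuals, "sex"].to_numpy()
    idx_all = np.arange(len(probs.individuals))
    kept = []
    for _ in range(n_phenotypes):
        y = phenotype_sampler(rng)
        stats_ = []
        for _ in range(n_perm):
            if stratify_by_sex:
                perm = idx_all.copy()
                for s in np.unique(sex):
                    grp = idx_all[sex == s]
                    perm[sex == s] = rng.permutation(grp)
            else:
                perm = rng.permutation(idx_all)
            curve = scan(probs, y[perm], interactive=interactive, chroms=chroms)
            if pooling == "maxima":
                stats_.append(curve.table["lod"].max())
            else:
                stats_.extend(curve.table["lod"].tolist())
        stats_ = np.sort(stats_)
        k = max(1, int(np.ceil(tail_frac * len(stats_))))
        kept.extend(stats_[-k:])
    kept = np.asarray(kept)
    return ThresholdSet(
        significant=float(np.quantile(kept, 0.95)),
        suggestive=float(np.quantile(kept, 0.80)),
    )


# ---------------------------------------------------------------------------
# QTL records, support intervals, classification, QC
# ---------------------------------------------------------------------------

@dataclass
class QTLRecord:
    phenotype: str
    phenotype_chrom: str | None
    phenotype_bp: float | None
    peak_chrom: str
    peak_cm: float
    peak_marker: str
    lod: float
    ci_lo_cm: float
    ci_hi_cm: float
    ci_lo_bp: float
    ci_hi_bp: float
    ci_lo_marker: str
    ci_hi_marker: str
    sex_interaction: bool
    classification: str
    genotype_class_counts: tuple[int, ...] = ()
    outlier_flag: bool = False


def support_interval(
    curve: LodCurve,
    peak_chrom: str,
    peak_cm: float,
    marker_map: MarkerMap,
    drop: float = 1.5,
) -> tuple[float, float, float, float, str, str]:
    """LOD-drop support interval, expanded outward to flanking typed markers.

    Returns (cM_lo, cM_hi, bp_lo, bp_hi, marker_lo, marker_hi): the widest
    interval around the peak where LOD >= peak - drop, then widened to the
    nearest typed markers at or beyond the endpoints for bp reporting.
    """
    sub = curve.on_chrom(peak_chrom)
    lods = sub["lod"].to_numpy()
    cms = sub["cM"].to_numpy()
    pk = int(np.argmin(np.abs(cms - peak_cm)))
    thresh = lods[pk] - drop
    lo = pk
    while lo > 0 and lods[lo - 1] >= thresh:
        lo -= 1
    hi = pk
    while hi < len(lods) - 1 and lods[hi + 1] >= thresh:
        hi += 1
    cm_lo, cm_hi = float(cms[lo]), float(cms[hi])
    mk = marker_map.markers_on(peak_chrom)
    mcm = mk["cM"].to_numpy()
    below = np.where(mcm <= cm_lo + 1e-9)[0]
    above = np.where(mcm >= cm_hi - 1e-9)[0]
    i_lo = int(below[-1]) if len(below) else 0
    i_hi = int(above[0]) if len(above) else len(mk) - 1
    return (
        cm_lo,
        cm_hi,
        float(mk["bp"].iat[i_lo]),
        float(mk["bp"].iat[i_hi]),
        str(mk["marker"].iat[i_lo]),
        str(mk["marker"].iat[i_hi]),
    )


def classify_cis_trans(
    peak_chrom: str,
    peak_cm: float,
    phenotype_chrom: str | None,
    phenotype_bp: float | None,
    marker_map: MarkerMap,
    margin: float = 50.0,
) -> str:
    """cis iff same chromosome and within ``margin`` cM (closed boundary)."""
    if phenotype_chrom is None or phenotype_bp is None:
        return "unplaced"
    if phenotype_chrom != peak_chrom:
        return "trans"
    pheno_cm = marker_map.bp_to_cm(phenotype_chrom, phenotype_bp)
    return "cis" if abs(peak_cm - pheno_cm) <= margin else "trans"


def genotype_class_counts(
    genotypes: GenotypeTable, marker: str
) -> tuple[int, ...]:
    g = genotypes.dosages[marker].to_numpy()
    return tuple(int((g == k).sum()) for k in sorted(set(g.tolist())))


def qc_filter(
    records: list[QTLRecord],
    genotypes: GenotypeTable,
    phenotypes: pd.DataFrame,
    probs: GenotypeProbs,
    threshold: float,
    min_class: int = 10,
    drop_outlier_driven: bool = False,
) -> list[QTLRecord]:
    """Drop QTL with any genotype class below ``min_class``; flag records
    whose peak LOD falls below ``threshold`` once the single most extreme
    phenotype value is removed (automated leave-one-out surrogate for outlier
    inspection)."""
    kept: list[QTLRecord] = []
    for rec in records:
        counts = rec.genotype_class_counts or genotype_class_counts(
            genotypes, rec.peak_marker
        )
        if min(counts) < min_class:
            continue
        y = phenotypes.loc[rec.phenotype, probs.individuals].to_numpy(dtype=float)
        worst = int(np.argmax(np.abs(y - np.median(y))))
        sub_inds = [ind for i, ind in enumerate(probs.individuals) if i != worst]
        sub_probs = _subset_probs(probs, sub_inds)
        curve = scan(
            sub_probs,
            np.delete(y, worst),
            interactive=False,
            chroms=[rec.peak_chrom],
        )
        loo_lod = curve.lod_at(rec.peak_chrom, rec.peak_cm)
        rec = replace(rec, outlier_flag=bool(loo_lod < threshold),
                      genotype_class_counts=counts)
        if rec.outlier_flag and drop_outlier_driven:
            continue
        kept.append(rec)
    return kept


def _subset_probs(probs: GenotypeProbs, individuals: list[str]) -> GenotypeProbs:
    take = [probs.individuals.index(i) for i in individuals]
    out = GenotypeProbs(
        marker_map=probs.marker_map,
        samples=probs.samples,
        individuals=individuals,
    )
    for chrom, cp in probs.chroms.items():
        out.chroms[chrom] = ChromProbs(
            chrom=cp.chrom,
            positions=cp.positions,
            nearest_marker=cp.nearest_marker,
            dosage=cp.dosage[take],
        )
    return out


def map_phenotype(
    probs: GenotypeProbs,
    phenotype: pd.Series | np.ndarray,
    phenotype_id: str,
    marker_map: MarkerMap,
    phenotype_chrom: str | None = None,
    phenotype_bp: float | None = None,
    genotypes: GenotypeTable | None = None,
    chroms: Iterable[str] | None = None,
    drop: float = 1.5,
    cis_margin: float = 50.0,
) -> QTLRecord:
    """Scan one phenotype (additive + interactive models) and build a record."""
    curve_add = scan(probs, phenotype, interactive=False, chroms=chroms)
    curve_int = scan(probs, phenotype, interactive=True, chroms=chroms)
    pk = curve_add.peak()
    flag = sex_interaction_flag(curve_add, curve_int, pk["chrom"], pk["cM"])
    curve = curve_int if flag else curve_add
    pk = curve.peak()
    cm_lo, cm_hi, bp_lo, bp_hi, mk_lo, mk_hi = support_interval(
        curve, pk["chrom"], pk["cM"], marker_map, drop=drop
    )
    counts: tuple[int, ...] = ()
    if genotypes is not None:
        counts = genotype_class_counts(genotypes, pk["nearest_marker"])
    return QTLRecord(
        phenotype=phenotype_id,
        phenotype_chrom=phenotype_chrom,
        phenotype_bp=phenotype_bp,
        peak_chrom=str(pk["chrom"]),
        peak_cm=float(pk["cM"]),
        peak_marker=str(pk["nearest_marker"]),
        lod=float(pk["lod"]),
        ci_lo_cm=cm_lo,
        ci_hi_cm=cm_hi,
        ci_lo_bp=bp_lo,
        ci_hi_bp=bp_hi,
        ci_lo_marker=mk_lo,
        ci_hi_marker=mk_hi,
        sex_interaction=flag,
        classification=classify_cis_trans(
            str(pk["chrom"]), float(pk["cM"]), phenotype_chrom, phenotype_bp,
            marker_map, margin=cis_margin,
        ),
        genotype_class_counts=counts,
    )


def records_to_frame(records: list[QTLRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phenotype": r.phenotype,
                "phenotype_chrom": r.phenotype_chrom,
                "phenotype_bp": r.phenotype_bp,
                "peak_chrom": r.peak_chrom,
                "peak_cm": r.peak_cm,
                "peak_marker": r.peak_marker,
                "lod": r.lod,
                "ci_lo_cm": r.ci_lo_cm,
                "ci_hi_cm": r.ci_hi_cm,
                "ci_lo_bp": r.ci_lo_bp,
                "ci_hi_bp": r.ci_hi_bp,
                "ci_lo_marker": r.ci_lo_marker,
                "ci_hi_marker": r.ci_hi_marker,
                "sex_interaction": r.sex_interaction,
                "classification": r.classification,
                "outlier_flag": r.outlier_flag,
            }
            for r in records
        ]
    )


#: Fixed genome-wide eQTL thresholds (cis, trans) used for expression scans.
EQTL_THRESHOLDS = {"cis": 4.0, "trans": 6.0}
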