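"""Window-based methylation phenotypes and matrix I/O.

MeDIP-seq coverage is quantified in fixed-size genomic windows (1 kb by
default).  Windows are 0-based, half-open ``[start, start + size)`` and
labelled ``"{chrom}_{start}"``.  Per-window read counts are normalized by
dividing by each individual's total read count and multiplying by a scale
constant (counts-per-million-like, configurable), which removes library-size
differences between individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOW_SIZE = 1000
DEFAULT_SCALE = 1e6

SEXES = ("male", "female")


class DegenerateLibraryError(ValueError):
    """An individual with zero total reads cannot be normalized."""


@dataclass(frozen=True, order=True)
class Window:
    """A fixed-size genomic window, 0-based half-open."""

    chrom: str
    start: int
    size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative window start: {self.start}")
        if self.size <= 0:
            raise ValueError(f"non-positive window size: {self.size}")
        if self.start % self.size != 0:
            raise ValueError(
                f"window start {self.start} not aligned to size {self.size}"
            )

    @property
    def end(self) -> int:
        return self.start + self.size

    @property
    def id(self) -> str:
        return f"{self.chrom}_{self.start}"

    @classmethod
    def from_id(cls, window_id: str, size: int = DEFAULT_WINDOW_SIZE) -> "Window":
        chrom, start = window_id.rsplit("_", 1)
        return cls(chrom=chrom, start=int(start), size=size)


def parse_window_id(window_id: str) -> tuple[str, int]:
    chrom, start = window_id.rsplit("_", 1)
    return chrom, int(start)


def _check_samples(samples: pd.DataFrame, individuals: Iterable[str]) -> pd.DataFrame:
    samples = samples.copy()
    missing = set(individuals) - set(samples.index)
    if missing:
        raise ValueError(f"individuals missing from sample sheet: {sorted(missing)}")
    bad = set(samples["sex"].unique()) - set(SEXES)
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")
    return samples


@dataclass
class MethylationMatrix:
    """Normalized window methylation levels (windows x individuals).

    ``values`` is indexed by window id, columns are individual ids.  The
    per-individual raw totals are retained so normalization round-trips to
    raw counts exactly.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    totals: pd.Series
    scale: float = DEFAULT_SCALE
    window_size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self) -> None:
        self.samples = _check_samples(self.samples, self.values.columns)
        if (self.values.values < 0).any():
            raise ValueError("negative methylation values")
        # sort windows by (chrom, start), drop duplicate window ids
        order = sorted(
            dict.fromkeys(self.values.index), key=parse_window_id
        )
        self.values = self.values.loc[~self.values.index.duplicated()].reindex(order)

    @property
    def individuals(self) -> list[str]:
        return list(self.values.columns)

    @property
    def windows(self) -> list[Window]:
        return [Window.from_id(w, self.window_size) for w in self.values.index]

    def sex_mask(self, sex: str) -> np.ndarray:
        return (self.samples.loc[self.individuals, "sex"] == sex).to_numpy()

    def denormalize(self) -> pd.DataFrame:
        """Recover the raw count matrix (exact by construction)."""
        return self.values * self.totals[self.individuals] / self.scale

    # ---- I/O ----
    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "methbin", out.index)
        out.to_csv(path, sep="\t", index=False)

    def write_sample_sheet(self, path: str | Path) -> None:
        sheet = self.samples.copy()
        sheet.insert(0, "individual", sheet.index)
        sheet["total_reads"] = self.totals[sheet.index].values
        sheet.to_csv(path, sep="\t", index=False)

    def to_bed(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
            }
        )


@dataclass
class ExpressionMatrix:
    """Preprocessed expression levels (probesets x individuals).

    ``features`` carries optional gene annotation per probeset: gene_id,
    gene_name and a genomic interval (chrom, start, end) where known.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.samples = _check_samples(self.samples, self.values.columns)
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        if self.features.empty:
            self.features = pd.DataFrame(index=self.values.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "probeset", out.index)
        out.to_csv(path, sep="\t", index=False)


def bin_reads(
    read_positions: Mapping[str, Sequence[tuple[str, int]]],
    window_size: int = DEFAULT_WINDOW_SIZE,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Count reads per window per individual.

    A read at base-pair ``bp`` falls in the window starting at
    ``(bp // window_size) * window_size`` (half-open binning).  Windows with
    zero reads everywhere are retained when ``chrom_sizes`` defines the
    window universe; otherwise the universe spans every chromosome seen, up
    to its largest read coordinate.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    max_seen: dict[str, int] = {}
    for ind, reads in read_positions.items():
        for chrom, bp in reads:
            if bp < 0:
                raise ValueError(f"negative read coordinate for {ind}: {bp}")
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise ValueError(f"unknown chromosome: {chrom}")
                if bp >= chrom_sizes[chrom]:
                    raise ValueError(f"read beyond chromosome end: {chrom}:{bp}")
            max_seen[chrom] = max(max_seen.get(chrom, 0), bp)

    sizes = dict(chrom_sizes) if chrom_sizes is not None else {
        c: m + 1 for c, m in max_seen.items()
    }
    index: list[str] = []
    offsets: dict[str, int] = {}
    for chrom in sorted(sizes):
        n_win = int(np.ceil(sizes[chrom] / window_size))
        offsets[chrom] = len(index)
        index.extend(f"{chrom}_{i * window_size}" for i in range(n_win))

    counts = pd.DataFrame(0, index=index, columns=list(read_positions), dtype=int)
    for ind, reads in read_positions.items():
        if not reads:
            continue
        rows = np.array(
            [offsets[chrom] + bp // window_size for chrom, bp in reads], dtype=int
        )
        np.add.at(counts[ind].values, rows, 1)
    return counts


def normalize(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    scale: float = DEFAULT_SCALE,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> MethylationMatrix:
    """Library-size normalization: ``value = scale * count / total``."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateLibraryError(
            f"individuals with zero total reads: {list(zero.index)}"
        )
    values = counts.div(totals, axis=1) * scale
    return MethylationMatrix(
        values=values,
        samples=samples,
        totals=totals.astype(float),
        scale=scale,
        window_size=window_size,
    )


def read_methylation_tsv(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    scale: float = DEFAULT_SCALE,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> MethylationMatrix:
    values = pd.read_csv(matrix_path, sep="\t").set_index("methbin")
    values.index.name = None
    sheet = pd.read_csv(sample_sheet_path, sep="\t").set_index("individual")
    sheet.index.name = None
    totals = sheet.pop("total_reads") if "total_reads" in sheet else pd.Series(
        1.0, index=values.columns
    )
    return MethylationMatrix(
        values=values, samples=sheet, totals=totals.astype(float),
        scale=scale, window_size=window_size,
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("individual")
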