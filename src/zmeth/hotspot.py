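"""Trans-QTL hotspot aggregation.

A hotspot is a marker whose genotype associates with many distinct
methylation windows (10 or more by default) whose support intervals mutually
overlap.  The hotspot's span is the minimal shared overlap of its members'
confidence intervals: [max of member CI lows, min of member CI highs].
Groups at adjacent markers whose members' intervals all mutually overlap may
be merged into a single hotspot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qtlmap import MarkerMap, QTLRecord

DEFAULT_MIN_COUNT = 10


@dataclass
class Hotspot:
    id: str
    markers: tuple[str, ...]
    chrom: str
    pos: float  # bp of the (modal) nearest marker
    members: list[QTLRecord]
    ci_low_pos: float
    ci_high_pos: float
    union_fallback: bool = False

    @property
    def ci_size(self) -> float:
        return self.ci_high_pos - self.ci_low_pos

    @property
    def num_qtl(self) -> int:
        return len(self.members)


def _shared_span(members: list[QTLRecord]) -> tuple[float, float, bool]:
    lo = max(m.ci_lo_bp for m in members)
    hi = min(m.ci_hi_bp for m in members)
    if lo < hi:
        return lo, hi, False
    # empty intersection: fall back to the union span
    warnings.warn("hotspot member intervals do not all intersect; using union span")
    return min(m.ci_lo_bp for m in members), max(m.ci_hi_bp for m in members), True


def _all_pairs_overlap(a: list[QTLRecord], b: list[QTLRecord]) -> bool:
    return all(
        x.ci_lo_bp <= y.ci_hi_bp and y.ci_lo_bp <= x.ci_hi_bp
        for x in a
        for y in b
    )


def find_hotspots(
    records: list[QTLRecord],
    marker_map: MarkerMap,
    min_count: int = DEFAULT_MIN_COUNT,
    merge_adjacent: bool = True,
) -> list[Hotspot]:
    """Group trans QTL by peak marker and merge into hotspots.

    Records are grouped by peak marker (input order does not matter); groups
    at consecutive markers on the same chromosome are merged when every
    pairwise member-interval overlap is non-empty; groups with fewer than
    ``min_count`` members after merging are discarded.
    """
    by_marker: dict[str, list[QTLRecord]] = {}
    for rec in sorted(records, key=lambda r: (r.peak_chrom, r.peak_cm, r.phenotype)):
        by_marker.setdefault(rec.peak_marker, []).append(rec)

    # order groups along the genome
    marker_order = {
        (row["chrom"], i): row["marker"]
        for chrom in marker_map.chromosomes
        for i, row in marker_map.markers_on(chrom).iterrows()
    }
    ordered: list[tuple[str, str, int]] = []  # (marker, chrom, index_on_chrom)
    for (chrom, i), marker in marker_order.items():
        if marker in by_marker:
            ordered.append((marker, chrom, i))

    groups: list[dict] = []
    for marker, chrom, idx in ordered:
        members = by_marker[marker]
        if (
            merge_adjacent
            and groups
            and groups[-1]["chrom"] == chrom
            and idx == groups[-1]["last_idx"] + 1
            and _all_pairs_overlap(groups[-1]["members"], members)
        ):
            groups[-1]["members"].extend(members)
            groups[-1]["markers"].append(marker)
            groups[-1]["last_idx"] = idx
        else:
            groups.append(
                {"markers": [marker], "chrom": chrom, "members": list(members), "last_idx": idx}
            )

    hotspots = []
    for g in groups:
        if len(g["members"]) < min_count:
            continue
        lo, hi, fallback = _shared_span(g["members"])
        # nearest-marker bp of the modal peak marker
        counts = pd.Series([m.peak_marker for m in g["members"]]).value_counts()
        modal = counts.index[0]
        pos = float(
            marker_map.table.set_index("marker").loc[modal, "bp"]
        )
        hotspots.append(
            Hotspot(
                id=f"hotspot_{len(hotspots) + 1}",
                markers=tuple(g["markers"]),
                chrom=g["chrom"],
                pos=pos,
                members=g["members"],
                ci_low_pos=lo,
                ci_high_pos=hi,
                union_fallback=fallback,
            )
        )
    return hotspots


def hotspots_to_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": h.id,
                "num_qtl": h.num_qtl,
                "marker": h.markers[0] if len(h.markers) == 1 else ";".join(h.markers),
                "chr": h.chrom,
                "pos": h.pos,
                "CI_low_pos": h.ci_low_pos,
                "CI_high_pos": h.ci_high_pos,
                "CI_size": h.ci_size,
            }
            for h in hotspots
        ]
    )


def hotspot_summary(
    hotspots: list[Hotspot] | pd.DataFrame, z_chrom: str | None = "chrZ"
) -> dict:
    """Count, mean span (Mb, 2 dp) and per-chromosome tally of hotspots."""
    if isinstance(hotspots, pd.DataFrame):
        frame = hotspots
    else:
        frame = hotspots_to_frame(hotspots)
    if frame.empty:
        return {"count": 0, "mean_span_mb": None, "per_chrom": {}, "on_z": 0, "on_autosomes": 0}
    per_chrom = frame.groupby("chr")["id"].count().to_dict()
    z_labels = {str(z_chrom), str(z_chrom).removeprefix("chr")}
    on_z = int(frame["chr"].astype(str).isin(z_labels).sum())
    return {
        "count": int(len(frame)),
        "mean_span_mb": round(float(frame["CI_size"].mean()) / 1e6, 2),
        "per_chrom": per_chrom,
        "on_z": on_z,
        "on_autosomes": int(len(frame)) - on_z,
    }


def count_genes_in_spans(
    hotspots: list[Hotspot], annotation: pd.DataFrame
) -> pd.Series:
    """Optional gene counts per hotspot span from a BED-like annotation
    (columns chrom, start, end)."""
    out = {}
    for h in hotspots:
        sub = annotation[
            (annotation["chrom"] == h.chrom)
            & (annotation["end"] >= h.ci_low_pos)
            & (annotation["start"] <= h.ci_high_pos)
        ]
        out[h.id] = len(sub)
    return pd.Series(out, name="num_genes")
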