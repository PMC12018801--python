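"""Genetic/physical marker maps.

A :class:`GeneticMap` ties each marker to a chromosome, a 1-based physical
position (bp) and a genetic position (cM).  Within a chromosome bp must be
strictly increasing and cM non-decreasing.  Maps with missing genetic
positions can be completed with :func:`interpolate_map`, which places
unanchored markers proportionally to physical distance between the flanking
anchors (terminal markers are extrapolated at the terminal cM/bp rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "interpolate_map"]

MAP_COLUMNS = ["chrom", "marker", "bp", "cM"]


@dataclass
class GeneticMap:
    """Marker map with physical (bp, 1-based) and genetic (cM) coordinates."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"map table missing columns: {missing}")
        t = self.table.loc[:, MAP_COLUMNS].reset_index(drop=True)
        t["chrom"] = t["chrom"].astype(str)
        t["bp"] = t["bp"].astype(np.int64)
        t["cM"] = t["cM"].astype(float)
        for chrom, sub in t.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            cm = sub["cM"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp not strictly increasing on chromosome {chrom}")
            if np.any(np.diff(cm) < -1e-12):
                raise ValueError(f"cM not non-decreasing on chromosome {chrom}")
            if np.any(bp < 1):
                raise ValueError("physical positions are 1-based; found bp < 1")
        self.table = t

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    def chrom_view(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == str(chrom)]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return sub

    def chrom_length_morgans(self, chrom: str) -> float:
        cm = self.chrom_view(chrom)["cM"].to_numpy()
        return float(cm[-1] - cm[0]) / 100.0

    def cm_to_bp(self, chrom: str, cm_positions: np.ndarray) -> np.ndarray:
        """Convert genetic to physical positions by piecewise-linear interpolation."""
        sub = self.chrom_view(chrom)
        cm = sub["cM"].to_numpy()
        bp = sub["bp"].to_numpy().astype(float)
        # np.interp requires increasing x; collapse cM plateaus with tiny jitter-free mapping
        return np.interp(np.asarray(cm_positions, dtype=float), cm, bp)

    def bp_to_cm(self, chrom: str, bp_positions: np.ndarray) -> np.ndarray:
        sub = self.chrom_view(chrom)
        cm = sub["cM"].to_numpy()
        bp = sub["bp"].to_numpy().astype(float)
        return np.interp(np.asarray(bp_positions, dtype=float), bp, cm)

    def marker_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.table["chrom"] == str(chrom)).to_numpy())


def interpolate_map(anchored: pd.DataFrame) -> GeneticMap:
    """Complete a partially anchored map by physical-distance proportionality.

    Parameters
    ----------
    anchored
        DataFrame with columns ``chrom, marker, bp, cM`` where ``cM`` may be
        NaN for unanchored markers.  Each chromosome needs at least two
        anchors with known cM, non-decreasing in bp order.

    Returns
    -------
    GeneticMap
        Fully positioned map.  Markers between anchors receive cM linearly
        proportional to bp between the flanking anchors; markers outside the
        anchored span are extrapolated at the terminal cM/bp rate.
    """
    out = []
    for chrom, sub in anchored.groupby("chrom", sort=False):
        sub = sub.sort_values("bp").reset_index(drop=True)
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cM"].to_numpy(dtype=float)
        known = ~np.isnan(cm)
        if known.sum() < 2:
            raise ValueError(f"chromosome {chrom}: need >=2 anchors with known cM")
        abp, acm = bp[known], cm[known]
        if np.any(np.diff(abp) <= 0):
            raise ValueError(f"chromosome {chrom}: anchor bp not strictly increasing")
        if np.any(np.diff(acm) < 0):
            raise ValueError(f"chromosome {chrom}: anchor cM decreasing")
        filled = np.interp(bp, abp, acm)
        # terminal extrapolation at the boundary rate
        left_rate = (acm[1] - acm[0]) / (abp[1] - abp[0])
        right_rate = (acm[-1] - acm[-2]) / (abp[-1] - abp[-2])
        lo = bp < abp[0]
        hi = bp > abp[-1]
        filled[lo] = acm[0] - (abp[0] - bp[lo]) * left_rate
        filled[hi] = acm[-1] + (bp[hi] - abp[-1]) * right_rate
        res = sub.copy()
        res["cM"] = filled
        out.append(res)
    return GeneticMap(pd.concat(out, ignore_index=True))
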