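"""Virtual 4C: one-dimensional interaction profiles around a viewpoint.

From filtered Hi-C read pairs, pairs with exactly one mate inside the
viewpoint interval (position +/- flank, default 10 kb) are extracted; the
other mate's position adds a count to every overlapping sliding window.
Windows are 20 kb wide, stepped every 1 kb along the viewpoint chromosome
(adjacent windows overlap by 95% of their length), anchored at coordinate 0
with the final partial window clipped.  Counts are normalized to CPM with
the sample's total sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Viewpoint", "Virtual4CTrack", "virtual_4c", "v4c_log2fc",
           "write_bedgraph"]


@dataclass(frozen=True)
class Viewpoint:
    """A 0-based viewpoint position with symmetric flank.

    Use :meth:`from_1based` for coordinates quoted in 1-based convention
    (e.g. the Tet2 promoter chr3:133,544,706).
    """
    chrom: str
    position: int
    flank: int = 10_000

    @classmethod
    def from_1based(cls, chrom: str, position_1based: int,
                    flank: int = 10_000) -> "Viewpoint":
        return cls(chrom, position_1based - 1, flank)

    @property
    def interval(self) -> tuple[int, int]:
        """Inclusive [position - flank, position + flank]."""
        return self.position - self.flank, self.position + self.flank


@dataclass
class Virtual4CTrack:
    """Overlapping-window counts and CPM along the viewpoint chromosome."""
    viewpoint: Viewpoint
    window_size: int
    step: int
    starts: np.ndarray   # window start coordinates (bp)
    ends: np.ndarray     # clipped window ends (bp)
    counts: np.ndarray
    total_depth: int
    n_qualifying: int

    @property
    def cpm(self) -> np.ndarray:
        return self.counts * 1e6 / self.total_depth

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.viewpoint.chrom,
                             "start": self.starts, "end": self.ends,
                             "count": self.counts, "cpm": self.cpm})


def virtual_4c(pairs: pd.DataFrame, viewpoint: Viewpoint, chrom_size: int,
               total_depth: Optional[int] = None, window_size: int = 20_000,
               step: int = 1_000) -> Virtual4CTrack:
    """Build the viewpoint interaction track from read pairs.

    A pair qualifies iff exactly one mate lies within the viewpoint interval
    (pairs with both mates inside carry no distal information and are
    excluded).  For each qualifying pair, +1 is added to every window whose
    interval contains the distal mate; only the viewpoint chromosome is
    profiled.  ``total_depth`` defaults to the number of input pairs.
    """
    if total_depth is None:
        total_depth = len(pairs)
    if total_depth <= 0:
        raise ValueError("total_depth must be positive")
    lo, hi = viewpoint.interval
    if not (0 <= viewpoint.position < chrom_size):
        raise ValueError("viewpoint outside chromosome")

    in1 = (pairs["chrom1"] == viewpoint.chrom) \
        & (pairs["pos1"] >= lo) & (pairs["pos1"] <= hi)
    in2 = (pairs["chrom2"] == viewpoint.chrom) \
        & (pairs["pos2"] >= lo) & (pairs["pos2"] <= hi)
    qual = in1 ^ in2
    # the distal mate must land on the viewpoint chromosome (cis profile)
    distal_chrom = np.where(in1, pairs["chrom2"], pairs["chrom1"])
    distal_pos = np.where(in1, pairs["pos2"], pairs["pos1"])
    keep = qual & (distal_chrom == viewpoint.chrom)
    distal = distal_pos[keep.to_numpy()].astype(np.int64)

    n_windows = -(-chrom_size // step)
    starts = np.arange(n_windows, dtype=np.int64) * step
    ends = np.minimum(starts + window_size, chrom_size)
    counts = np.zeros(n_windows, dtype=np.int64)
    if len(distal):
        # a position p lies in window k iff k*step <= p < k*step + window
        k_max = distal // step
        k_min = np.maximum(0, -(-(distal - window_size + 1) // step))
        diff = np.zeros(n_windows + 1, dtype=np.int64)
        np.add.at(diff, k_min, 1)
        np.add.at(diff, k_max + 1, -1)
        counts = np.cumsum(diff)[:-1]
    else:
        import warnings
        warnings.warn("no qualifying read pairs for this viewpoint")
    return Virtual4CTrack(viewpoint=viewpoint, window_size=window_size,
                          step=step, starts=starts, ends=ends, counts=counts,
                          total_depth=int(total_depth),
                          n_qualifying=int(len(distal)))


def v4c_log2fc(track_a: Virtual4CTrack, track_b: Virtual4CTrack,
               pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-window log2((cpm_a + c) / (cpm_b + c)) between two tracks."""
    if (track_a.window_size, track_a.step) != (track_b.window_size, track_b.step) \
            or len(track_a.starts) != len(track_b.starts) \
            or track_a.viewpoint.chrom != track_b.viewpoint.chrom:
        raise ValueError("window grids do not match")
    # difference of logs so that swapping tracks negates values exactly
    fc = np.log2(track_a.cpm + pseudocount) - np.log2(track_b.cpm + pseudocount)
    return pd.DataFrame({"chrom": track_a.viewpoint.chrom,
                         "start": track_a.starts, "end": track_a.ends,
                         "log2fc": fc})


def write_bedgraph(df: pd.DataFrame, value_col: str, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", value_col])
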