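"""Signal metrics around reference positions: pausing index, metaplots,
and windowed log2 ratios.

Window offsets are inclusive on both ends in strand-relative coordinates,
so -100..+300 spans 401 bases and +301..+3,000 spans 2,700.  A pseudocount
of 1 read is applied to ratio numerators and denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PositionTrack
from .stability import oriented_window

PAUSING_PROXIMAL = (-100, 300)
PAUSING_DISTAL = (301, 3000)


@dataclass
class PausingIndex:
    tss_id: str
    proximal: float
    distal: float

    @property
    def index(self) -> float:
        return (self.proximal + 1.0) / (self.distal + 1.0)


def pausing_index(
    tss_id: str,
    chrom: str,
    strand: str,
    position: int,
    track: PositionTrack,
    proximal_window=PAUSING_PROXIMAL,
    distal_window=PAUSING_DISTAL,
) -> PausingIndex:
    """Sense-strand signal near the TSS over the downstream gene body."""
    ps, pe = oriented_window(position, strand, *proximal_window)
    ds, de = oriented_window(position, strand, *distal_window)
    prox = track.window_sum(chrom, strand, max(0, ps), pe)
    dist = track.window_sum(chrom, strand, max(0, ds), de)
    return PausingIndex(tss_id=tss_id, proximal=prox, distal=dist)


@dataclass
class Metaplot:
    offsets: np.ndarray   # bin-start offsets, strand-relative
    signal: np.ndarray
    mode: str             # "percent_total" | "raw"


def signal_metaplot(
    references: list[tuple[str, str, int]],
    track: PositionTrack,
    half_width: int = 1000,
    bin_size: int = 1,
    mode: str = "percent_total",
) -> Metaplot:
    """Aggregate sense-strand signal by strand-relative offset bin.

    References are (chrom, strand, position) anchors; offsets run
    -half_width..+half_width-1 so that bin_size divides the span evenly.
    In ``percent_total`` mode the bins sum to 100 (when any signal exists).
    """
    if (2 * half_width) % bin_size:
        raise ValueError("bin_size must divide 2*half_width")
    n_bins = (2 * half_width) // bin_size
    agg = np.zeros(n_bins, dtype=float)
    for chrom, strand, pos in references:
        start, end = oriented_window(pos, strand, -half_width, half_width - 1)
        p_arr, v_arr = track.arrays(chrom, strand)
        lo = np.searchsorted(p_arr, max(0, start), side="left")
        hi = np.searchsorted(p_arr, end, side="left")
        for p, v in zip(p_arr[lo:hi].tolist(), v_arr[lo:hi].tolist()):
            offset = p - pos if strand == "+" else pos - p
            if -half_width <= offset < half_width:
                agg[(offset + half_width) // bin_size] += v
    if mode == "percent_total":
        total = agg.sum()
        if total > 0:
            agg = 100.0 * agg / total
    elif mode != "raw":
        raise ValueError(f"unknown mode {mode!r}")
    offsets = np.arange(-half_width, half_width, bin_size)
    return Metaplot(offsets=offsets, signal=agg, mode=mode)


def window_log_ratio(
    chrom: str,
    strand: str,
    position: int,
    track_a: PositionTrack,
    track_b: PositionTrack,
    window: tuple[int, int] = (1, 600),
) -> float:
    """log2((A+1)/(B+1)) over an inclusive strand-relative window,
    the convention used for ChIP-style signal comparisons downstream of
    a TSS (+1..+600 by default)."""
    start, end = oriented_window(position, strand, *window)
    start = max(0, start)
    a = track_a.window_sum(chrom, strand, start, end)
    b = track_b.window_sum(chrom, strand, start, end)
    return float(np.log2((a + 1.0) / (b + 1.0)))
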