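"""Sequence features around TSSs: hexamer stability ranking, IUPAC
consensus scanning, and nucleotide-frequency metaplots.

The hexamer analysis counts all overlapping 6-mers in the +1 kb..+3 kb
window downstream of each major TSS (reverse-complemented for '-' strand
TSRs), normalizes per class by the number of TSRs, and ranks all 4,096
hexamers by the stable/unstable ratio: rank 1 = most enriched downstream
of unstable TSRs, rank 4,096 = most stable-enriched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .io import GenomeSequence
from .stability import oriented_window

BASES = "ACGT"

HEXAMER_WINDOW = (1000, 3000)  # strand-relative offsets downstream of the major TSS

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# sense-strand consensus defaults for RNA-processing motifs; the published
# motif files are not redistributable, so these canonical strings stand in
PROCESSING_MOTIFS = {
    "polyA": "AATAAA",
    "splice5": "GTAAGT",
    "splice3": "TTTCAG",
}


def enumerate_hexamers() -> list[str]:
    """All 4,096 hexamers over {A,C,G,T}, lexicographic."""
    return ["".join(p) for p in product(BASES, repeat=6)]


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _count_kmers(seqs, k: int = 6) -> np.ndarray:
    """Overlapping k-mer counts over a list of sequences (N-containing
    windows skipped), indexed by base-4 code in lexicographic order."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1)
    for seq in seqs:
        if len(seq) < k:
            continue
        codes = np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)
        valid = codes >= 0
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
        idx = (windows[ok] * weights).sum(axis=1)
        np.add.at(counts, idx, 1)
    return counts


def extract_windows(tsrs, genome: GenomeSequence, window=HEXAMER_WINDOW) -> list[str]:
    """Strand-aware downstream sequence windows for a list of TSRs."""
    out = []
    for t in tsrs:
        start, end = oriented_window(t.major_pos, t.strand, window[0], window[1])
        out.append(genome.fetch(t.chrom, start, end, t.strand))
    return out


def hexamer_stability_ranks(stable_windows: list[str], unstable_windows: list[str]) -> pd.DataFrame:
    """Rank all 4,096 hexamers by stable/unstable enrichment.

    Counts are normalized by the number of TSRs in each class; the
    stability ratio adds a pseudocount of 1 to both normalized counts.
    Rank 1 is the most unstable-enriched hexamer; ties break
    lexicographically by hexamer for determinism.
    """
    if not stable_windows or not unstable_windows:
        raise ValueError("both stability classes need at least one sequence window")
    hexamers = enumerate_hexamers()
    c_stable = _count_kmers(stable_windows)
    c_unstable = _count_kmers(unstable_windows)
    n_stable = c_stable / len(stable_windows)
    n_unstable = c_unstable / len(unstable_windows)
    ratio = (n_stable + 1.0) / (n_unstable + 1.0)
    df = pd.DataFrame(
        {
            "hexamer": hexamers,
            "count_stable": c_stable,
            "count_unstable": c_unstable,
            "norm_stable": n_stable,
            "norm_unstable": n_unstable,
            "stability_ratio": ratio,
        }
    )
    df = df.sort_values(["stability_ratio", "hexamer"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.sort_values("hexamer", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# IUPAC consensus scanning
# ---------------------------------------------------------------------------


@dataclass
class ConsensusPattern:
    pattern: str
    sense_only: bool = True

    def __post_init__(self) -> None:
        self.pattern = self.pattern.upper()
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC letters in pattern: {sorted(bad)}")

    def to_regex(self) -> re.Pattern:
        body = "".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]" for c in self.pattern
        )
        return re.compile(f"(?=({body}))")  # lookahead => overlapping matches


def scan_consensus(sequences: list[str], pattern: ConsensusPattern) -> dict:
    """Overlapping IUPAC matches per sequence; summary = matches per TSS."""
    rx = pattern.to_regex()
    positions = [[m.start() for m in rx.finditer(seq.upper())] for seq in sequences]
    counts = [len(p) for p in positions]
    total = sum(counts)
    return {
        "counts": counts,
        "positions": positions,
        "total": total,
        "per_tss": total / len(sequences) if sequences else 0.0,
    }


# ---------------------------------------------------------------------------
# nucleotide-frequency metaplot
# ---------------------------------------------------------------------------


def nucleotide_metaplot(tss_list, genome: GenomeSequence, flank: int = 50) -> pd.DataFrame:
    """Per-offset A/C/G/T frequencies around TSSs, strand-aware.

    ``tss_list`` holds (chrom, strand, position) triples; offset 0 is the
    +1 TSS base in the transcript's orientation.  N bases are ignored;
    frequencies at each offset sum to 1 where any non-N base was seen.
    """
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=np.int64)
    for chrom, strand, pos in tss_list:
        start, end = oriented_window(pos, strand, -flank, flank)
        seq = genome.fetch(chrom, start, end, strand)
        if len(seq) != width:  # clipped at a chromosome edge; skip
            continue
        for i, b in enumerate(seq):
            j = _BASE_CODE.get(b)
            if j is not None:
                counts[i, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    df = pd.DataFrame(freqs, columns=list(BASES))
    df.insert(0, "offset", np.arange(-flank, flank + 1))
    return df
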