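"""Genomic-context classification of TSRs relative to annotated gene 5' ends.

Signed distances are measured in the annotated transcript's orientation:
positive = downstream of the annotated TSS, negative = upstream.  Classes
are assigned with a fixed priority so that every TSR gets exactly one
label:

1. ``tss_sense``       same strand, |d| <= 275 bp of an annotated 5' end
2. ``tss_divergent``   opposite strand, d in [-275, -1] (upstream)
3. ``tss_antisense``   opposite strand, d in [0, +300] (downstream)
4. ``single_exon_gene`` / ``exonic``  sense overlap with a gene body
5. ``mirna_proximal``  within 1,000 bp of an annotated miRNA gene (heuristic)
6. ``distal``          none of the above
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import TSRRecord
from .io import GeneAnnotation

CONTEXT_CLASSES = (
    "tss_sense",
    "tss_divergent",
    "tss_antisense",
    "single_exon_gene",
    "exonic",
    "mirna_proximal",
    "distal",
)

DISTANCE_BIN_EDGES = (100, 1000, 2000)  # |d| <= 100, 101-1000, 1001-2000, > 2000
DISTANCE_BIN_LABELS = ("<=100", "101-1000", "1001-2000", ">2000")


@dataclass
class ContextWindows:
    sense: int = 275           # +/- window for tss_sense
    divergent: tuple[int, int] = (-275, -1)
    antisense: tuple[int, int] = (0, 300)
    mirna: int = 1000          # proximity window for miRNA genes (heuristic)


@dataclass
class ContextCall:
    tsr_id: str
    context: str
    distance: int | None       # signed, in the nearest annotation's orientation
    nearest_id: str | None


def _signed_distance(tsr_pos: int, ann_pos: int, ann_strand_code: int) -> int:
    """Distance of tsr_pos from the annotated 5' end, + = downstream."""
    return (tsr_pos - ann_pos) * ann_strand_code


@dataclass
class _AnnIndex:
    """Per-chromosome sorted 5'-end arrays plus gene-body interval lists."""

    tss: dict = field(default_factory=dict)
    bodies: dict = field(default_factory=dict)
    mirna_tss: dict = field(default_factory=dict)

    @classmethod
    def build(cls, annotation: GeneAnnotation) -> "_AnnIndex":
        idx = cls()
        idx.tss = annotation.tss_by_chrom()
        for t in annotation:
            idx.bodies.setdefault(t.chrom, []).append(t)
        for chrom, ts in idx.bodies.items():
            ts.sort(key=lambda t: (t.start, t.transcript_id))
        for t in annotation:
            if t.feature_type == "miRNA":
                idx.mirna_tss.setdefault(t.chrom, []).append(t.five_prime_end)
        for chrom in idx.mirna_tss:
            idx.mirna_tss[chrom] = np.array(sorted(idx.mirna_tss[chrom]), dtype=np.int64)
        return idx


def _candidates_near(index: _AnnIndex, chrom: str, pos: int, radius: int):
    """(distance-sorted) annotated 5' ends within radius of pos."""
    if chrom not in index.tss:
        return []
    positions, strands, ids = index.tss[chrom]
    lo = int(np.searchsorted(positions, pos - radius, side="left"))
    hi = int(np.searchsorted(positions, pos + radius, side="right"))
    cands = [
        (abs(int(positions[i]) - pos), int(positions[i]), int(strands[i]), ids[i])
        for i in range(lo, hi)
    ]
    cands.sort(key=lambda c: (c[0], c[3]))
    return cands


def _nearest_tss(index: _AnnIndex, chrom: str, pos: int):
    if chrom not in index.tss or len(index.tss[chrom][0]) == 0:
        return None
    positions, strands, ids = index.tss[chrom]
    i = int(np.searchsorted(positions, pos))
    best = None
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(positions):
            cand = (abs(int(positions[j]) - pos), int(positions[j]), int(strands[j]), ids[j])
            if best is None or cand[:1] + (cand[3],) < best[:1] + (best[3],):
                best = cand
    return best


def classify_context(
    tsr: TSRRecord,
    annotation: GeneAnnotation | None,
    windows: ContextWindows | None = None,
    _index: _AnnIndex | None = None,
) -> ContextCall:
    windows = windows or ContextWindows()
    if annotation is None or len(annotation) == 0:
        return ContextCall(tsr.tsr_id, "distal", None, None)
    index = _index if _index is not None else _AnnIndex.build(annotation)
    pos = tsr.major_pos
    s_code = 1 if tsr.strand == "+" else -1
    radius = max(windows.sense, -windows.divergent[0], windows.antisense[1]) + 1
    cands = _candidates_near(index, tsr.chrom, pos, radius)

    # priority 1: sense promoter
    for _, apos, ascode, aid in cands:
        d = _signed_distance(pos, apos, ascode)
        if ascode == s_code and abs(d) <= windows.sense:
            return ContextCall(tsr.tsr_id, "tss_sense", d, aid)
    # priority 2: divergent (opposite strand, upstream of the annotated TSS)
    for _, apos, ascode, aid in cands:
        d = _signed_distance(pos, apos, ascode)
        if ascode != s_code and windows.divergent[0] <= d <= windows.divergent[1]:
            return ContextCall(tsr.tsr_id, "tss_divergent", d, aid)
    # priority 3: antisense (opposite strand, within the gene's TSS region)
    for _, apos, ascode, aid in cands:
        d = _signed_distance(pos, apos, ascode)
        if ascode != s_code and windows.antisense[0] <= d <= windows.antisense[1]:
            return ContextCall(tsr.tsr_id, "tss_antisense", d, aid)
    # priority 4: sense overlap with a gene body
    for t in index.bodies.get(tsr.chrom, []):
        if t.start <= pos < t.end and t.strand == tsr.strand:
            d = _signed_distance(pos, t.five_prime_end, 1 if t.strand == "+" else -1)
            label = "single_exon_gene" if t.n_exons <= 1 else "exonic"
            return ContextCall(tsr.tsr_id, label, d, t.transcript_id)
    # priority 5: miRNA proximity (window not printed anywhere; heuristic)
    mpos = index.mirna_tss.get(tsr.chrom)
    if mpos is not None and len(mpos):
        i = int(np.searchsorted(mpos, pos))
        for j in (i - 1, i):
            if 0 <= j < len(mpos) and abs(int(mpos[j]) - pos) <= windows.mirna:
                return ContextCall(tsr.tsr_id, "mirna_proximal", int(pos - mpos[j]), None)
    # distal: report distance to the nearest annotated 5' end
    near = _nearest_tss(index, tsr.chrom, pos)
    if near is None:
        return ContextCall(tsr.tsr_id, "distal", None, None)
    _, apos, ascode, aid = near
    return ContextCall(tsr.tsr_id, "distal", _signed_distance(pos, apos, ascode), aid)


def classify_all_contexts(tsrs, annotation, windows: ContextWindows | None = None):
    windows = windows or ContextWindows()
    index = _AnnIndex.build(annotation) if annotation is not None and len(annotation) else None
    if index is None:
        return [ContextCall(t.tsr_id, "distal", None, None) for t in tsrs]
    return [classify_context(t, annotation, windows, _index=index) for t in tsrs]


# ---------------------------------------------------------------------------
# distance bins and antisense ratio
# ---------------------------------------------------------------------------


@dataclass
class DistanceBins:
    labels: tuple = DISTANCE_BIN_LABELS
    stable: list[int] = field(default_factory=lambda: [0, 0, 0, 0])
    unstable: list[int] = field(default_factory=lambda: [0, 0, 0, 0])

    def ratios(self) -> list[float]:
        """Unstable/stable per bin; pseudocount 1 on both when either is 0."""
        out = []
        for s, u in zip(self.stable, self.unstable):
            if s == 0 or u == 0:
                out.append((u + 1) / (s + 1))
            else:
                out.append(u / s)
        return out


def _bin_index(abs_d: int) -> int:
    for i, edge in enumerate(DISTANCE_BIN_EDGES):
        if abs_d <= edge:
            return i
    return len(DISTANCE_BIN_EDGES)


def distance_to_nearest_tss(tsr: TSRRecord, index: _AnnIndex) -> int | None:
    near = _nearest_tss(index, tsr.chrom, tsr.major_pos)
    if near is None:
        return None
    _, apos, ascode, _ = near
    return _signed_distance(tsr.major_pos, apos, ascode)


def distance_bin_ratios(tsrs, calls, annotation: GeneAnnotation) -> DistanceBins:
    """Stable/unstable TSR counts binned by |distance| to annotated 5' ends."""
    index = _AnnIndex.build(annotation)
    call_by_id = {c.tsr_id: c for c in calls}
    bins = DistanceBins()
    for tsr in tsrs:
        d = distance_to_nearest_tss(tsr, index)
        if d is None:
            continue
        b = _bin_index(abs(d))
        call = call_by_id[tsr.tsr_id]
        (bins.stable if call.is_stable else bins.unstable)[b] += 1
    return bins


def antisense_ratio(tsrs, annotation: GeneAnnotation, window: int = 275):
    """Opposite-strand over same-strand TSR counts within +/-window of
    annotated 5' ends.  Returns (ratio or None, n_antisense, n_sense)."""
    index = _AnnIndex.build(annotation)
    n_sense = n_anti = 0
    for tsr in tsrs:
        pos = tsr.major_pos
        s_code = 1 if tsr.strand == "+" else -1
        hit_sense = hit_anti = False
        for _, apos, ascode, _ in _candidates_near(index, tsr.chrom, pos, window + 1):
            if abs(pos - apos) <= window:
                if ascode == s_code:
                    hit_sense = True
                else:
                    hit_anti = True
        if hit_sense:
            n_sense += 1
        elif hit_anti:
            n_anti += 1
    ratio = (n_anti / n_sense) if n_sense else None
    return ratio, n_anti, n_sense
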