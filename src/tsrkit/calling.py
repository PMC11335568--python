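"""TSS and TSR calling from normalized csRNA 5'-end profiles.

Candidate TSSs are single positions with at least ``tss_min_norm`` (default
7) normalized csRNA reads whose short-RNA input signal does not exceed the
csRNA signal (high-abundance non-initiating RNAs such as miRNAs pile up in
the input and are discarded as false positives).  TSSs are clustered into
transcription start regions (TSRs) no wider than 200 bp by a greedy
strongest-first sweep, and TSRs below ``tsr_min_norm`` (default 10)
normalized reads total, or with more input than csRNA signal over their
span, are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import NormalizedProfile


@dataclass
class CallerParams:
    tss_min_norm: float = 7.0     # per 10^7 aligned reads, single position
    tsr_min_norm: float = 10.0    # per 10^7, summed over the TSR
    cluster_dist: int = 200       # max TSR width in bp; claim window is +/- cluster_dist/2
    input_fold: float = 1.0       # drop when input > input_fold * csRNA

    def __post_init__(self) -> None:
        if min(self.tss_min_norm, self.tsr_min_norm, self.cluster_dist, self.input_fold) <= 0:
            raise ValueError("all caller parameters must be positive")


@dataclass
class TSSRecord:
    chrom: str
    strand: str
    position: int
    norm_count: float
    raw_count: float = 0.0
    tsr_id: str | None = None


@dataclass
class TSRRecord:
    tsr_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open tight hull of member TSSs
    end: int
    major_pos: int
    total_norm: float
    members: list[TSSRecord] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end - self.start


def call_candidate_tss(
    cs: NormalizedProfile,
    input_profile: NormalizedProfile | None,
    params: CallerParams | None = None,
) -> list[TSSRecord]:
    """Positions with csRNA >= threshold and input <= input_fold x csRNA."""
    params = params or CallerParams()
    out: list[TSSRecord] = []
    for chrom, strand in cs.keys():
        pos, vals = cs.arrays(chrom, strand)
        keep = vals >= params.tss_min_norm
        for p, v in zip(pos[keep].tolist(), vals[keep].tolist()):
            if input_profile is not None:
                inp = input_profile.get(chrom, strand, p)
                if inp > params.input_fold * v:
                    continue
            out.append(TSSRecord(chrom=chrom, strand=strand, position=p, norm_count=v))
    return out


def _five_prime_key(tss: TSSRecord) -> int:
    # smaller key = more 5' relative to the strand
    return tss.position if tss.strand == "+" else -tss.position


def cluster_tsrs(tss_list: list[TSSRecord], params: CallerParams | None = None) -> list[TSRRecord]:
    """Greedy strongest-first clustering of TSSs into TSRs.

    The strongest unclaimed TSS seeds a TSR and claims all unclaimed
    same-strand TSSs at strand-relative offsets in [-cluster_dist/2,
    cluster_dist/2 - 1] around it, which bounds the TSR hull width by
    cluster_dist exactly.  Ties on strength break toward the 5'-most
    position, then lexicographic chromosome.  The TSR span is the tight
    hull of its members; the seed is the major TSS.  TSRs whose summed
    normalized signal falls below ``tsr_min_norm`` are discarded.
    """
    params = params or CallerParams()
    half = params.cluster_dist // 2

    order = sorted(
        range(len(tss_list)),
        key=lambda i: (
            -tss_list[i].norm_count,
            _five_prime_key(tss_list[i]),
            tss_list[i].chrom,
            tss_list[i].strand,
        ),
    )

    # per-(chrom,strand) position-sorted index for window claiming
    groups: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(tss_list):
        groups.setdefault((t.chrom, t.strand), []).append(i)
    sorted_pos: dict[tuple[str, str], tuple[np.ndarray, list[int]]] = {}
    for key, idxs in groups.items():
        idxs.sort(key=lambda i: tss_list[i].position)
        sorted_pos[key] = (np.array([tss_list[i].position for i in idxs], dtype=np.int64), idxs)

    claimed = [False] * len(tss_list)
    tsrs: list[TSRRecord] = []
    for i in order:
        if claimed[i]:
            continue
        seed = tss_list[i]
        positions, idxs = sorted_pos[(seed.chrom, seed.strand)]
        if seed.strand == "+":
            lo_pos, hi_pos = seed.position - half, seed.position + half - 1
        else:
            lo_pos, hi_pos = seed.position - half + 1, seed.position + half
        lo = int(np.searchsorted(positions, lo_pos, side="left"))
        hi = int(np.searchsorted(positions, hi_pos, side="right"))
        members = [tss_list[j] for j in idxs[lo:hi] if not claimed[j]]
        for j in idxs[lo:hi]:
            if not claimed[j]:
                claimed[j] = True
        total = sum(m.norm_count for m in members)
        if total < params.tsr_min_norm:
            continue
        start = min(m.position for m in members)
        end = max(m.position for m in members) + 1
        tsrs.append(
            TSRRecord(
                tsr_id="",
                chrom=seed.chrom,
                strand=seed.strand,
                start=start,
                end=end,
                major_pos=seed.position,
                total_norm=total,
                members=sorted(members, key=lambda m: m.position),
            )
        )

    tsrs.sort(key=lambda r: (r.chrom, r.start, r.strand))
    for k, tsr in enumerate(tsrs):
        tsr.tsr_id = f"TSR{k + 1:05d}"
        for m in tsr.members:
            m.tsr_id = tsr.tsr_id
    return tsrs


def major_tss(tsr: TSRRecord) -> TSSRecord:
    """Member with maximal normalized count; ties break to the 5'-most."""
    if not tsr.members:
        raise ValueError(f"TSR {tsr.tsr_id} has no member TSSs")
    return min(tsr.members, key=lambda m: (-m.norm_count, _five_prime_key(m)))


def filter_tsr_by_input(
    tsrs: list[TSRRecord],
    cs: NormalizedProfile,
    input_profile: NormalizedProfile,
    params: CallerParams | None = None,
) -> list[TSRRecord]:
    """Drop TSRs whose summed input density exceeds their csRNA density."""
    params = params or CallerParams()
    kept = []
    for tsr in tsrs:
        cs_sum = cs.window_sum(tsr.chrom, tsr.strand, tsr.start, tsr.end)
        in_sum = input_profile.window_sum(tsr.chrom, tsr.strand, tsr.start, tsr.end)
        if in_sum > params.input_fold * cs_sum:
            continue
        kept.append(tsr)
    return kept


def call_tsrs(
    cs: NormalizedProfile,
    input_profile: NormalizedProfile | None,
    params: CallerParams | None = None,
) -> list[TSRRecord]:
    """Full caller: candidate TSSs -> clustering -> input-based TSR filter."""
    params = params or CallerParams()
    tss = call_candidate_tss(cs, input_profile, params)
    tsrs = cluster_tsrs(tss, params)
    if input_profile is not None:
        tsrs = filter_tsr_by_input(tsrs, cs, input_profile, params)
    return tsrs
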