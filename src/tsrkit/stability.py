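"""Transcript stability classification from total RNA-seq signal.

A TSR initiates an unstable transcript when fewer than ``threshold``
(default 2) RNA-seq reads per 10^7 fall within -100..+500 bp of its major
TSS on the sense strand; steady-state RNA-seq readily detects stable
transcripts downstream of their TSS, while rapidly degraded ones leave
few-to-no reads.  Windows are oriented by strand: on '-' TSRs the +500
side extends toward decreasing coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import TSRRecord
from .io import CoverageTrack

STABILITY_THRESHOLD = 2.0  # per 10^7 RNA-seq reads
STABILITY_WINDOW = (-100, 500)  # inclusive offsets relative to the major TSS


def oriented_window(position: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Half-open genomic interval for inclusive offsets [upstream, downstream].

    Offsets are strand-relative: negative = upstream of the TSS.
    """
    if strand == "+":
        return position + upstream, position + downstream + 1
    return position - downstream, position + 1 - upstream


@dataclass
class StabilityCall:
    tsr_id: str
    score: float  # normalized sense-strand RNA-seq reads in the window
    stability: str  # "stable" | "unstable"

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


def classify_stability(
    tsr: TSRRecord,
    rnaseq: CoverageTrack,
    threshold: float = STABILITY_THRESHOLD,
    window: tuple[int, int] = STABILITY_WINDOW,
) -> StabilityCall:
    """Score = normalized sense-strand reads in window; unstable iff < threshold."""
    if tsr.major_pos is None:
        raise ValueError(f"TSR {tsr.tsr_id} has no major TSS")
    start, end = oriented_window(tsr.major_pos, tsr.strand, window[0], window[1])
    start = max(0, start)
    score = rnaseq.window_sum(tsr.chrom, tsr.strand, start, end)
    label = "unstable" if score < threshold else "stable"
    return StabilityCall(tsr_id=tsr.tsr_id, score=score, stability=label)


def classify_all(tsrs, rnaseq, threshold: float = STABILITY_THRESHOLD):
    return [classify_stability(t, rnaseq, threshold) for t in tsrs]


def stability_distribution(calls, bin_width: float = 0.1):
    """Histogram of log10(score + 1), the scale on which the stable/unstable
    bimodality is visible.  Returns (bin_edges, counts)."""
    if not calls:
        raise ValueError("no stability calls to histogram")
    x = np.log10(np.array([c.score for c in calls]) + 1.0)
    top = max(x.max(), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    return edges, counts


# ---------------------------------------------------------------------------
# cross-sample switch analysis
# ---------------------------------------------------------------------------


@dataclass
class SwitchSummary:
    n_union: int           # merged TSRs across samples
    n_multi: int           # classified in >= 2 samples
    n_switching: int       # stable in >= 1 sample and unstable in >= 1
    per_tsr: list[dict]    # merged-TSR records with per-sample classes

    @property
    def pct_switching(self) -> float:
        return 100.0 * self.n_switching / self.n_multi if self.n_multi else 0.0


def _merge_same_strand(tsr_lists) -> list[dict]:
    """Union of TSRs across samples: same-strand overlapping spans unify."""
    tagged = []
    for sample, tsrs in tsr_lists.items():
        for t in tsrs:
            tagged.append((t.chrom, t.strand, t.start, t.end, sample, t.tsr_id))
    tagged.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    merged: list[dict] = []
    for chrom, strand, start, end, sample, tid in tagged:
        if (
            merged
            and merged[-1]["chrom"] == chrom
            and merged[-1]["strand"] == strand
            and start < merged[-1]["end"]
        ):
            m = merged[-1]
            m["end"] = max(m["end"], end)
            m["members"].append((sample, tid))
        else:
            merged.append(
                {"chrom": chrom, "strand": strand, "start": start, "end": end, "members": [(sample, tid)]}
            )
    return merged


def switch_analysis(per_sample_tsrs: dict, per_sample_calls: dict) -> SwitchSummary:
    """Identify TSRs whose transcript stability differs between samples.

    TSRs from all samples are unified by same-strand overlap; a merged TSR
    switches when it is called stable in at least one sample and unstable
    in at least one other.  The percentage is reported over merged TSRs
    with stability calls in >= 2 samples; absence of a call in a sample is
    not evidence of instability and contributes nothing.
    """
    if len(per_sample_tsrs) < 2:
        raise ValueError("switch analysis requires >= 2 samples")
    call_lookup = {
        sample: {c.tsr_id: c.stability for c in calls}
        for sample, calls in per_sample_calls.items()
    }
    merged = _merge_same_strand(per_sample_tsrs)
    n_multi = n_switching = 0
    for m in merged:
        classes = {}
        for sample, tid in m["members"]:
            cls = call_lookup.get(sample, {}).get(tid)
            if cls is not None:
                classes[sample] = cls
        m["classes"] = classes
        distinct_samples = len(classes)
        m["switch"] = "stable" in classes.values() and "unstable" in classes.values()
        if distinct_samples >= 2:
            n_multi += 1
            if m["switch"]:
                n_switching += 1
    return SwitchSummary(
        n_union=len(merged), n_multi=n_multi, n_switching=n_switching, per_tsr=merged
    )
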