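"""STARR-seq enhancer-activity integration with TSR classes.

STARR-seq measures the ability of a DNA region, cloned downstream of a
minimal promoter, to enhance its transcription; the activity ratio is
reporter output over input.  Fragments of 1-50 bp are removed (they
disproportionately show no activity), fragment/peak activities are summed
within merged regions and normalized by region length (scaled by 100) to a
per-bp activity, and regions are grouped by the transcription class of any
overlapping TSR (no transcription / stable / unstable, with unstable
subgrouped by initiation style U / UU / US) for one-way ANOVA with Tukey
HSD pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

MIN_FRAGMENT_KEEP = 51  # fragments of 1-50 bp are dropped


def filter_fragments(peaks: pd.DataFrame, min_keep_len: int = MIN_FRAGMENT_KEEP) -> pd.DataFrame:
    """Remove STARR fragments/peaks shorter than ``min_keep_len`` bp."""
    lengths = peaks["end"] - peaks["start"]
    return peaks.loc[lengths >= min_keep_len].reset_index(drop=True)


@dataclass
class MergedRegionActivity:
    region_id: str
    chrom: str
    start: int
    end: int
    peak_names: list[str]
    activity_sum: float
    tsr_class: str      # no_transcription | stable | unstable
    substyle: str       # U | UU | US | none
    covered: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def per_bp_activity(self) -> float:
        # per-bp activity scaled by 100, as plotted for group comparisons
        return 100.0 * self.activity_sum / self.length


def _merge_intervals(frames: list[pd.DataFrame]) -> list[list]:
    """Strand-agnostic union of overlapping intervals across tables."""
    rows = []
    for df in frames:
        for r in df.itertuples(index=False):
            rows.append([r.chrom, int(r.start), int(r.end)])
    rows.sort()
    merged: list[list] = []
    for chrom, start, end in rows:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return merged


def merge_and_score(
    tsrs,
    stability_calls,
    style_calls,
    open_chromatin: pd.DataFrame,
    peaks: pd.DataFrame,
) -> list[MergedRegionActivity]:
    """Merge TSR spans, open-chromatin regions and STARR peaks; score each
    merged region.

    Each STARR peak is assigned once, to the merged region containing its
    midpoint (prevents double counting of straddling peaks).  Per-bp
    activity = 100 x (sum of assigned activities) / merged length.  The
    region's class comes from the strongest overlapping TSR (strand
    ignored: activity has no strand); regions without a TSR are
    no_transcription.
    """
    tsr_df = pd.DataFrame(
        {
            "chrom": [t.chrom for t in tsrs],
            "start": [t.start for t in tsrs],
            "end": [t.end for t in tsrs],
        }
    )
    merged = _merge_intervals([tsr_df, open_chromatin[["chrom", "start", "end"]], peaks[["chrom", "start", "end"]]])

    stab_by_id = {c.tsr_id: c.stability for c in stability_calls}
    style_by_id = {s.tsr_id: s.style for s in style_calls}

    import bisect

    keys = [(m[0], m[1]) for m in merged]

    def _find_region(chrom: str, point: int):
        i = bisect.bisect_right(keys, (chrom, point)) - 1
        if i >= 0 and merged[i][0] == chrom and merged[i][1] <= point < merged[i][2]:
            return i
        return None

    assigned: dict[int, list] = {}
    for r in peaks.itertuples(index=False):
        mid = (int(r.start) + int(r.end)) // 2
        i = _find_region(r.chrom, mid)
        if i is not None:
            assigned.setdefault(i, []).append(r)

    # per-chromosome TSR index sorted by start for fast overlap queries
    tsr_by_chrom: dict[str, list] = {}
    for t in tsrs:
        tsr_by_chrom.setdefault(t.chrom, []).append(t)
    for ts in tsr_by_chrom.values():
        ts.sort(key=lambda t: t.start)
    starts_by_chrom = {c: [t.start for t in ts] for c, ts in tsr_by_chrom.items()}
    max_width = max((t.end - t.start for t in tsrs), default=0)

    def _overlapping_tsrs(chrom: str, start: int, end: int):
        ts = tsr_by_chrom.get(chrom, [])
        if not ts:
            return []
        starts = starts_by_chrom[chrom]
        lo = bisect.bisect_left(starts, start - max_width)
        hi = bisect.bisect_left(starts, end)
        return [t for t in ts[lo:hi] if t.end > start]

    out = []
    for i, (chrom, start, end) in enumerate(merged):
        contained = assigned.get(i, [])
        act = float(sum(getattr(r, "activity") for r in contained))
        overlapping = _overlapping_tsrs(chrom, start, end)
        if overlapping:
            strongest = max(overlapping, key=lambda t: (t.total_norm, t.tsr_id))
            cls = stab_by_id.get(strongest.tsr_id, "stable")
            sub = style_by_id.get(strongest.tsr_id, "none")
            if sub == "S":
                sub = "none"
        else:
            cls, sub = "no_transcription", "none"
        out.append(
            MergedRegionActivity(
                region_id=f"MR{i + 1:05d}",
                chrom=chrom,
                start=start,
                end=end,
                peak_names=[str(getattr(r, "name", "")) for r in contained],
                activity_sum=act,
                tsr_class=cls,
                substyle=sub,
                covered=bool(contained),
            )
        )
    return out


def starr_coverage_fraction(tsrs, regions: list[MergedRegionActivity]) -> float:
    """Fraction of TSRs overlapping a merged region with STARR coverage."""
    import bisect

    if not tsrs:
        return 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in regions:
        if m.covered:
            by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
    for iv in by_chrom.values():
        iv.sort()
    n_cov = 0
    for t in tsrs:
        iv = by_chrom.get(t.chrom, [])
        i = bisect.bisect_right(iv, (t.end, float("inf")))
        if any(s < t.end and e > t.start for s, e in iv[max(0, i - 2): i]):
            n_cov += 1
    return n_cov / len(tsrs)


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    f_stat: float
    p_value: float
    tukey: pd.DataFrame  # columns group1, group2, meandiff, p_adj

    def pair_p(self, a: str, b: str) -> float:
        for r in self.tukey.itertuples(index=False):
            if {r.group1, r.group2} == {a, b}:
                return float(r.p_adj)
        raise KeyError(f"no Tukey pair {a!r} vs {b!r}")


def group_compare(groups: dict[str, "np.ndarray | list[float]"]) -> GroupComparison:
    """One-way ANOVA plus all-pairs Tukey HSD on per-bp activities."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    if len(arrays) < 2:
        raise ValueError("group comparison needs >= 2 groups with n >= 2")
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    if np.allclose(values, values[0]):
        pairs = [(a, b) for i, a in enumerate(arrays) for b in list(arrays)[i + 1:]]
        tukey = pd.DataFrame(
            {"group1": [a for a, _ in pairs], "group2": [b for _, b in pairs],
             "meandiff": 0.0, "p_adj": 1.0}
        )
        return GroupComparison(groups=arrays, f_stat=0.0, p_value=1.0, tukey=tukey)
    f_stat, p_value = stats.f_oneway(*arrays.values())
    res = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    tukey = pd.DataFrame(
        {
            "group1": frame["group1"].astype(str),
            "group2": frame["group2"].astype(str),
            "meandiff": frame["meandiff"].astype(float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
        }
    )
    return GroupComparison(groups=arrays, f_stat=float(f_stat), p_value=float(p_value), tukey=tukey)


def activity_correlation(
    tsr_signals: "np.ndarray | list[float]",
    activities: "np.ndarray | list[float]",
    transform: str = "log10p1",
) -> dict:
    """Pearson correlation between transcription level and STARR activity.

    Both vectors are log10(x+1)-transformed by default; returns the
    coefficient and an ``undefined`` flag when either side has zero
    variance.
    """
    x = np.asarray(tsr_signals, dtype=float)
    y = np.asarray(activities, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if transform == "log10p1":
        x, y = np.log10(x + 1.0), np.log10(y + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        return {"r": float("nan"), "undefined": True, "n": len(x)}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "undefined": False, "n": len(x)}
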