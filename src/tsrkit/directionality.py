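"""Bidirectional TSR pairing and initiation-style assignment.

Divergent geometry: a '-' strand TSR whose major TSS lies within
``pair_window`` bp upstream of a '+' strand TSR's major TSS forms a
bidirectional unit with it (transcription heads outward in both
directions).  Styles combine directionality with transcript stability:

- S   stable (unidirectional, or the stable side of a pair)
- U   unstable and unidirectional
- US  unstable sense transcript with a stable antisense partner
- UU  unstable in both directions
"""

from __future__ import annotations

from dataclasses import dataclass

from .calling import TSRRecord

STYLES = ("S", "U", "US", "UU")
DEFAULT_PAIR_WINDOW = 275  # bp between divergent major TSSs; the divergent
                           # context window is the closest printed anchor


def pair_bidirectional(tsrs: list[TSRRecord], pair_window: int = DEFAULT_PAIR_WINDOW) -> dict[str, str]:
    """Nearest-partner matching of divergent TSR pairs.

    Eligible pairs are (+, -) TSRs on one chromosome with the '-' major
    TSS at 0..pair_window bp upstream of the '+' major TSS.  Each TSR
    takes at most one partner; pairs are accepted nearest-first, ties
    broken by combined signal (strongest first), then by position for
    determinism.  Returns a symmetric tsr_id -> partner_id map.
    """
    plus = [t for t in tsrs if t.strand == "+"]
    minus = [t for t in tsrs if t.strand == "-"]
    by_chrom: dict[str, list[TSRRecord]] = {}
    for t in minus:
        by_chrom.setdefault(t.chrom, []).append(t)

    candidates = []
    for p in plus:
        for m in by_chrom.get(p.chrom, []):
            gap = p.major_pos - m.major_pos
            if 0 <= gap <= pair_window:
                candidates.append(
                    (gap, -(p.total_norm + m.total_norm), p.major_pos, p.tsr_id, m.tsr_id)
                )
    candidates.sort()
    partners: dict[str, str] = {}
    for _, _, _, pid, mid in candidates:
        if pid in partners or mid in partners:
            continue
        partners[pid] = mid
        partners[mid] = pid
    return partners


@dataclass
class StyleCall:
    tsr_id: str
    style: str
    partner_id: str | None
    bidirectional: bool


def assign_styles(tsrs, partners: dict[str, str], calls) -> list[StyleCall]:
    """Combine pairing with stability calls into S/U/US/UU labels.

    The stable side of any pair is reported S (with the bidirectional flag
    preserving the pairing); an unstable TSR is UU when its partner is
    also unstable, US when the partner is stable, U when unpaired.
    """
    stable_by_id = {c.tsr_id: c.is_stable for c in calls}
    out = []
    for t in tsrs:
        partner = partners.get(t.tsr_id)
        self_stable = stable_by_id[t.tsr_id]
        if self_stable:
            style = "S"
        elif partner is None:
            style = "U"
        else:
            style = "US" if stable_by_id[partner] else "UU"
        out.append(
            StyleCall(tsr_id=t.tsr_id, style=style, partner_id=partner, bidirectional=partner is not None)
        )
    return out


def bidirectional_unstable_fraction(
    styles: list[StyleCall],
    distances: dict[str, int | None],
    distal_cutoff: int = 2000,
) -> dict:
    """Fraction of TSRs initiating bidirectional unstable transcripts (UU),
    overall and restricted to TSRs > distal_cutoff from annotated 5' ends.

    ``distances`` maps tsr_id -> signed distance to the nearest annotated
    5' end (None when no annotation exists; such TSRs count as distal).
    """
    n = len(styles)
    uu = [s for s in styles if s.style == "UU"]
    uu_distal = [
        s for s in uu
        if distances.get(s.tsr_id) is None or abs(distances[s.tsr_id]) > distal_cutoff
    ]
    uu_dist_hist = sorted(
        abs(distances[s.tsr_id]) for s in uu if distances.get(s.tsr_id) is not None
    )
    return {
        "n_tsrs": n,
        "n_uu": len(uu),
        "pct_uu": 100.0 * len(uu) / n if n else 0.0,
        "n_uu_distal": len(uu_distal),
        "pct_uu_distal": 100.0 * len(uu_distal) / n if n else 0.0,
        "uu_distances": uu_dist_hist,
    }
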