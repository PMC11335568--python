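"""Relate TSR classes to STARR-seq enhancer activity.

Fragments of 1-50 bp are removed, peaks are merged with TSR spans and
open-chromatin regions, activity is normalized per bp (x100), and per-bp
activities are compared across no-transcription / stable / unstable
regions with one-way ANOVA + Tukey HSD.
"""

import numpy as np

from tsrkit import SimulationConfig, analyze_sample, simulate_all
from tsrkit.starr import activity_correlation, filter_fragments, group_compare, merge_and_score, starr_coverage_fraction

config = SimulationConfig(seed=7)
genome, annotation, truth, cs, inp, rna, gro, starr_peaks = simulate_all(config)
res = analyze_sample("demo", cs.normalize(), inp.normalize(), rna.normalize(), annotation)

peaks = filter_fragments(starr_peaks)
print(f"STARR peaks: {len(starr_peaks)} -> {len(peaks)} after removing 1-50 bp fragments")

merged = merge_and_score(res.tsrs, res.stability_calls, res.style_calls,
                         truth.open_regions.assign(score=0, strand="."), peaks)
print(f"TSR coverage by the STARR library: {starr_coverage_fraction(res.tsrs, merged):.0%}")

groups = {}
for m in merged:
    groups.setdefault(m.tsr_class, []).append(m.per_bp_activity)
for cls, vals in sorted(groups.items()):
    print(f"  {cls:>17}: n={len(vals):3d}  median per-bp activity {np.median(vals):.2f}")

cmp_res = group_compare(groups)
print(f"ANOVA F={cmp_res.f_stat:.1f}, p={cmp_res.p_value:.2e}")
print(f"Tukey stable vs unstable adjusted p = {cmp_res.pair_p('stable', 'unstable'):.2e}")

signals, acts = [], []
for m in merged:
    if m.covered and m.tsr_class != "no_transcription":
        over = [t for t in res.tsrs if t.chrom == m.chrom and t.start < m.end and t.end > m.start]
        signals.append(max(t.total_norm for t in over))
        acts.append(m.per_bp_activity)
corr = activity_correlation(signals, acts)
print(f"transcription vs activity: Pearson r = {corr['r']:.2f} on log10(x+1) scale (n={corr['n']})")
# Stable-transcription regions show the strongest enhancer activity;
# the simulator plants that ordering with 3-SD gaps.
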