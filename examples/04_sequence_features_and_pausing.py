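"""Sequence features around TSSs and the GRO-seq pausing index.

Hexamers are counted in +1..+3 kb downstream of major TSSs and ranked by
stable/unstable enrichment (rank 1 = most unstable-enriched of 4,096).
The nucleotide metaplot recovers the planted TATA box at -30, and the
pausing index compares polymerase signal near the TSS with the gene body.
"""

import numpy as np

from tsrkit import SimulationConfig, analyze_sample, simulate_genome, simulate_signals
from tsrkit.metrics import pausing_index
from tsrkit.seqfeat import ConsensusPattern, extract_windows, hexamer_stability_ranks, nucleotide_metaplot, scan_consensus

config = SimulationConfig(seed=7)
genome, annotation, truth = simulate_genome(config)
cs, inp, rna, gro = simulate_signals(truth, config)
res = analyze_sample("demo", cs.normalize(), inp.normalize(), rna.normalize(), annotation)

stable = {c.tsr_id for c in res.stability_calls if c.is_stable}
table = hexamer_stability_ranks(
    extract_windows([t for t in res.tsrs if t.tsr_id in stable], genome),
    extract_windows([t for t in res.tsrs if t.tsr_id not in stable], genome),
)
print(f"hexamers ranked: {len(table)} (rank 1 = unstable-enriched)")
print("most stable-enriched :", table.nlargest(3, "rank")[["hexamer", "stability_ratio"]].to_dict("records"))

refs = [(t.chrom, t.strand, t.major_pos) for t in res.tsrs]
meta = nucleotide_metaplot(refs, genome, flank=50)
print(f"A frequency at +1 TSS: {meta.loc[meta['offset'] == 0, 'A'].iloc[0]:.2f} (planted initiator)")
upstream = meta[meta["offset"] <= -10].reset_index(drop=True)
ta = upstream["T"] + upstream["A"]
print(f"upstream T+A peaks at offset {upstream.loc[ta.idxmax(), 'offset']:+d} (planted TATA at -31..-26)")

upstream = extract_windows(res.tsrs, genome, window=(-50, -10))
hits = scan_consensus(upstream, ConsensusPattern("TATAWAAR"))
print(f"TATAWAAR matches per TSR in -50..-10: {hits['per_tss']:.2f}")

indices = [pausing_index(t.tsr_id, t.chrom, t.strand, t.major_pos, gro).index for t in res.tsrs]
print(f"median pausing index: {np.median(indices):.3f} "
      "(proximal -100..+300 over distal +301..+3000, pseudocount 1)")
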