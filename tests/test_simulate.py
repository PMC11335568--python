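"""Synthetic-data generator: determinism, planted-class guarantees."""

import numpy as np
import pytest
from scipy import stats

from tsrkit.io import NORM_FACTOR
from tsrkit.simulate import (
    ConfigError,
    SimulationConfig,
    simulate_genome,
    simulate_signals,
    simulate_starr,
)
from tsrkit.stability import oriented_window
from tsrkit.starr import filter_fragments, group_compare


class TestGenome:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=42, n_genes=20, genome_length=400_000, n_no_transcription=10)
        g1, a1, t1 = simulate_genome(cfg)
        g2, a2, t2 = simulate_genome(cfg)
        assert g1.sequences == g2.sequences
        assert t1.elements.equals(t2.elements)
        assert [(x.transcript_id, x.start, x.end) for x in a1] == [
            (x.transcript_id, x.start, x.end) for x in a2
        ]
        s1, i1, r1, gr1 = simulate_signals(t1, cfg)
        s2, i2, r2, gr2 = simulate_signals(t2, cfg)
        assert list(s1.items()) == list(s2.items())
        assert list(r1.items()) == list(r2.items())

    def test_changing_seed_changes_output(self):
        cfg = SimulationConfig(seed=1, n_genes=20, genome_length=400_000, n_no_transcription=10)
        other = SimulationConfig(seed=2, n_genes=20, genome_length=400_000, n_no_transcription=10)
        g1, _, t1 = simulate_genome(cfg)
        g2, _, t2 = simulate_genome(other)
        assert g1.sequences != g2.sequences or not t1.elements.equals(t2.elements)

    def test_no_genes_means_distal_only(self):
        cfg = SimulationConfig(seed=3, n_genes=0, genome_length=400_000, n_no_transcription=5)
        _, annotation, truth = simulate_genome(cfg)
        assert len(annotation) == 0
        assert set(truth.elements["context"]) == {"distal"}

    def test_too_short_genome_rejected(self):
        with pytest.raises(ConfigError, match="too short"):
            simulate_genome(SimulationConfig(seed=0, n_genes=100, genome_length=50_000))

    def test_planted_unstable_count_within_binomial_interval(self):
        cfg = SimulationConfig(
            seed=5, n_genes=400, fraction_distal=0.2, genome_length=4_500_000,
            fraction_bidirectional=0.0, fraction_antisense=0.0, n_no_transcription=10,
        )
        _, _, truth = simulate_genome(cfg)
        n = len(truth.elements)
        k = (truth.elements["stability"] == "unstable").sum()
        lo, hi = stats.binom.interval(0.99, n, 0.3)
        assert lo <= k <= hi

    def test_gene_anchors_spaced_at_least_4kb(self):
        cfg = SimulationConfig(seed=6, n_genes=50, genome_length=900_000, n_no_transcription=10)
        _, _, truth = simulate_genome(cfg)
        primaries = truth.elements[truth.elements["partner_id"] == ""]
        anchors = sorted(
            primaries[primaries["context"].isin(["promoter_sense", "distal"])]["tss"]
        )
        assert min(b - a for a, b in zip(anchors, anchors[1:])) >= 4000


@pytest.fixture(scope="module")
def bundle():
    cfg = SimulationConfig(seed=8, n_genes=60, genome_length=1_500_000, n_no_transcription=10)
    _, _, truth = simulate_genome(cfg)
    cs, inp, rna, gro = simulate_signals(truth, cfg)
    return cfg, truth, cs.normalize(), inp.normalize(), rna.normalize(), gro


class TestSignals:

    def test_stability_window_separates_planted_classes(self, bundle):
        _, truth, _, _, rna, _ = bundle
        for e in truth.elements.itertuples(index=False):
            start, end = oriented_window(e.tss, e.strand, -100, 500)
            score = rna.window_sum(e.chrom, e.strand, start, end)
            if e.stability == "stable":
                assert score >= 2.0
            else:
                assert score < 2.0

    def test_contaminants_have_more_input_than_csrna(self, bundle):
        _, truth, cs, inp, _, _ = bundle
        for c in truth.contaminants.itertuples(index=False):
            cs_sum = cs.window_sum(c.chrom, c.strand, c.pos - 10, c.pos + 11)
            in_sum = inp.window_sum(c.chrom, c.strand, c.pos - 10, c.pos + 11)
            assert in_sum > cs_sum

    def test_no_antisense_rnaseq_at_unidirectional_elements(self, bundle):
        _, truth, _, _, rna, _ = bundle
        elems = truth.elements
        # isolated unpaired elements: no other planted element within 3.5 kb
        for e in elems[elems["partner_id"] == ""].itertuples(index=False):
            near = elems[(elems["element_id"] != e.element_id) & ((elems["tss"] - e.tss).abs() < 3500)]
            if len(near):
                continue
            anti = "-" if e.strand == "+" else "+"
            lo = min(oriented_window(e.tss, e.strand, -100, 2000))
            hi = max(oriented_window(e.tss, e.strand, -100, 2000))
            assert rna.window_sum(e.chrom, anti, max(0, lo), hi) == 0.0

    def test_sharp_shape_concentrates_reads_at_mode(self, bundle):
        cfg, truth, cs, _, _, _ = bundle
        e = truth.elements.iloc[0]
        at_mode = cs.get(e["chrom"], e["strand"], int(e["tss"]))
        total = cs.window_sum(e["chrom"], e["strand"], int(e["tss"]) - 60, int(e["tss"]) + 61)
        assert at_mode / total >= 0.75


class TestStarr:
    def test_short_fragments_are_exactly_the_filtered_rows(self):
        cfg = SimulationConfig(seed=9, n_genes=40, genome_length=1_200_000,
                               starr_short_fragment_rate=0.2, n_no_transcription=10)
        _, _, truth = simulate_genome(cfg)
        peaks = simulate_starr(truth, cfg)
        lengths = peaks["end"] - peaks["start"]
        short = set(peaks.loc[lengths <= 50, "name"])
        assert short == set(peaks.loc[peaks["planted_class"] == "short_fragment", "name"])
        kept = filter_fragments(peaks)
        assert set(kept["name"]) == set(peaks["name"]) - short

    def test_equal_class_means_behave_as_null(self):
        """With no planted effect, ANOVA rejects at ~nominal rate."""
        n_sig = 0
        for seed in range(10):
            cfg = SimulationConfig(
                seed=100 + seed, n_genes=40, genome_length=1_200_000, n_no_transcription=20,
                starr_effects={k: 5.0 for k in ("no_transcription", "stable", "U", "UU", "US")},
            )
            _, _, truth = simulate_genome(cfg)
            peaks = simulate_starr(truth, cfg)
            groups = {
                k: g["activity"].to_numpy()
                for k, g in peaks.groupby("planted_class")
                if k != "short_fragment" and len(g) >= 2
            }
            res = group_compare(groups)
            n_sig += res.p_value < 0.05
        assert n_sig <= 3

    def test_planted_ordering_recovered(self):
        cfg = SimulationConfig(seed=12, n_genes=150, fraction_unstable=0.4,
                               genome_length=2_500_000, n_no_transcription=60)
        _, _, truth = simulate_genome(cfg)
        peaks = simulate_starr(truth, cfg)
        med = peaks.groupby("planted_class")["activity"].median()
        assert med["no_transcription"] < med["U"] < med["stable"]
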