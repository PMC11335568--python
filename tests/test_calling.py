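"""TSS/TSR calling: thresholds, greedy clustering, input filtering."""

import numpy as np
import pytest

from tsrkit.calling import (
    CallerParams,
    TSSRecord,
    call_candidate_tss,
    call_tsrs,
    cluster_tsrs,
    filter_tsr_by_input,
    major_tss,
)

from conftest import make_normalized


def tss(pos, count, strand="+", chrom="chr1"):
    return TSSRecord(chrom=chrom, strand=strand, position=pos, norm_count=count)


class TestCandidateTss:
    @pytest.mark.parametrize(
        "cs,inp,kept",
        [
            (7.0, 0.0, True),    # at the detection threshold
            (6.99, 0.0, False),  # just below
            (20.0, 25.0, False), # input exceeds csRNA -> likely false positive
            (20.0, 20.0, True),  # input equal, not higher: kept
        ],
    )
    def test_threshold_and_input_rule(self, cs, inp, kept):
        cs_prof = make_normalized([("chr1", "+", 50, cs)])
        in_prof = make_normalized([("chr1", "+", 50, inp)]) if inp else make_normalized([])
        out = call_candidate_tss(cs_prof, in_prof, CallerParams())
        assert (len(out) == 1) == kept

    def test_strand_specific(self):
        cs_prof = make_normalized([("chr1", "+", 50, 10.0)])
        in_prof = make_normalized([("chr1", "-", 50, 100.0)])  # other strand: ignored
        assert len(call_candidate_tss(cs_prof, in_prof, CallerParams())) == 1


class TestClustering:
    def test_nearby_tss_join_one_tsr(self):
        out = cluster_tsrs([tss(100, 20.0), tss(180, 20.0)])
        assert len(out) == 1
        assert out[0].start == 100 and out[0].end == 181

    @pytest.mark.parametrize("gap", [150, 250])
    def test_distant_tss_stay_separate(self, gap):
        out = cluster_tsrs([tss(100, 20.0), tss(100 + gap, 20.0)])
        assert len(out) == 2

    def test_weak_tsr_dropped(self):
        assert cluster_tsrs([tss(100, 9.9)]) == []
        assert len(cluster_tsrs([tss(100, 10.0)])) == 1

    def test_tsr_width_never_exceeds_limit(self):
        positions = list(range(0, 1000, 25))
        out = cluster_tsrs([tss(p, 10.0 + 0.01 * p) for p in positions])
        assert all(t.width <= 200 for t in out)

    def test_same_strand_tsrs_never_overlap(self):
        rng = np.random.default_rng(5)
        records = [tss(int(p), float(c)) for p, c in
                   zip(rng.choice(3000, 120, replace=False), rng.uniform(7, 50, 120))]
        out = cluster_tsrs(records)
        out.sort(key=lambda t: t.start)
        for a, b in zip(out, out[1:]):
            assert a.end <= b.start


class TestMajorTss:
    def test_max_count_wins(self):
        tsr = cluster_tsrs([tss(100, 50.0), tss(120, 10.0)])[0]
        assert major_tss(tsr).position == 100

    def test_tie_breaks_to_five_prime_most(self):
        plus = cluster_tsrs([tss(100, 20.0), tss(110, 20.0)])[0]
        assert major_tss(plus).position == 100
        minus = cluster_tsrs([tss(100, 20.0, strand="-"), tss(110, 20.0, strand="-")])[0]
        assert major_tss(minus).position == 110

    def test_major_equals_cluster_seed(self):
        rng = np.random.default_rng(9)
        records = [tss(int(p), float(c)) for p, c in
                   zip(rng.choice(2000, 60, replace=False), rng.uniform(7, 40, 60))]
        for t in cluster_tsrs(records):
            assert major_tss(t).position == t.major_pos


class TestInputFilter:
    def test_contaminant_locus_removed_clean_kept(self):
        cs = make_normalized([("chr1", "+", 100, 20.0), ("chr1", "+", 500, 20.0)])
        inp = make_normalized([("chr1", "+", 100, 60.0)])  # 3x csRNA at first locus
        tsrs = cluster_tsrs(call_candidate_tss(cs, None, CallerParams()))
        kept = filter_tsr_by_input(tsrs, cs, inp, CallerParams())
        assert [t.major_pos for t in kept] == [500]


def reference_greedy(records, cluster_dist=200, tsr_min=10.0):
    """Independent straight-line re-statement of the clustering recurrence."""
    half = cluster_dist // 2
    pool = list(records)
    clusters = []
    while pool:
        # strongest; ties 5'-most, then chromosome
        def key(t):
            five = t.position if t.strand == "+" else -t.position
            return (-t.norm_count, five, t.chrom, t.strand)
        seed = sorted(pool, key=key)[0]
        members = []
        for t in pool:
            if t.chrom != seed.chrom or t.strand != seed.strand:
                continue
            off = t.position - seed.position if seed.strand == "+" else seed.position - t.position
            if -half <= off <= half - 1:
                members.append(t)
        for m in members:
            pool.remove(m)
        total = sum(m.norm_count for m in members)
        if total >= tsr_min:
            clusters.append(
                (
                    seed.chrom,
                    seed.strand,
                    min(m.position for m in members),
                    max(m.position for m in members) + 1,
                    seed.position,
                    round(total, 9),
                )
            )
    return sorted(clusters)


class TestGreedyOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_straight_line_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        records = [
            TSSRecord(
                chrom="chr1",
                strand=rng.choice(["+", "-"]),
                position=int(rng.integers(0, 600)),
                norm_count=float(rng.choice([7, 8, 12, 12, 20])),
            )
            for _ in range(n)
        ]
        # dedupe positions per strand (profile positions are unique)
        seen = set()
        records = [r for r in records if not ((r.strand, r.position) in seen or seen.add((r.strand, r.position)))]
        got = sorted(
            (t.chrom, t.strand, t.start, t.end, t.major_pos, round(t.total_norm, 9))
            for t in cluster_tsrs(records)
        )
        assert got == reference_greedy(records)


class TestOnSimulation:
    def test_invariants_on_called_tsrs(self, sim_result):
        tsrs = sim_result.tsrs
        assert tsrs, "simulation should yield TSRs"
        assert all(t.width <= 200 for t in tsrs)
        assert all(t.total_norm >= 10.0 for t in tsrs)
        by_cs = {}
        for t in tsrs:
            by_cs.setdefault((t.chrom, t.strand), []).append(t)
        for group in by_cs.values():
            group.sort(key=lambda t: t.start)
            for a, b in zip(group, group[1:]):
                assert a.end <= b.start

    def test_planted_elements_recovered_within_10bp(self, sim_bundle, sim_result):
        truth = sim_bundle["truth"].elements
        by_strand = {}
        for t in sim_result.tsrs:
            by_strand.setdefault(t.strand, []).append(t)
        hits = sum(
            1
            for e in truth.itertuples(index=False)
            if min(abs(t.major_pos - e.tss) for t in by_strand[e.strand]) <= 10
        )
        assert hits / len(truth) >= 0.95

    def test_contaminant_loci_filtered(self, sim_bundle, sim_result):
        cont = sim_bundle["truth"].contaminants
        for c in cont.itertuples(index=False):
            near = [
                t for t in sim_result.tsrs
                if t.strand == c.strand and abs(t.major_pos - c.pos) < 100
            ]
            assert not near

    def test_cluster_width_robustness_on_dispersed_shape(self):
        """TSR counts shift by <15% when the clustering window sweeps 150-300."""
        from tsrkit.simulate import SimulationConfig, simulate_genome, simulate_signals

        config = SimulationConfig(seed=23, tss_shape="dispersed")
        _, _, truth = simulate_genome(config)
        cs, inp, _, _ = simulate_signals(truth, config)
        counts = []
        for dist in (150, 200, 250, 300):
            params = CallerParams(cluster_dist=dist)
            counts.append(len(call_tsrs(cs.normalize(), inp.normalize(), params)))
        assert max(counts) - min(counts) < 0.15 * counts[1]
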