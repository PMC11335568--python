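"""STARR-seq integration: filtering, merged per-bp activity, group stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsrkit.calling import TSRRecord
from tsrkit.directionality import StyleCall
from tsrkit.stability import StabilityCall
from tsrkit.starr import (
    activity_correlation,
    filter_fragments,
    group_compare,
    merge_and_score,
    starr_coverage_fraction,
)


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "activity"])


def empty_regions():
    return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])


def tsr(start, end, major, tsr_id, strand="+", norm=20.0):
    return TSRRecord(tsr_id=tsr_id, chrom="chr1", strand=strand,
                     start=start, end=end, major_pos=major, total_norm=norm)


class TestFragmentFilter:
    @pytest.mark.parametrize("length,kept", [(50, False), (51, True), (1, False), (300, True)])
    def test_length_boundary(self, length, kept):
        df = peaks_df([("chr1", 100, 100 + length, "p", 1.0)])
        assert (len(filter_fragments(df)) == 1) == kept

    def test_empty_input(self):
        assert len(filter_fragments(peaks_df([]))) == 0


class TestMergeAndScore:
    def test_single_peak_in_region(self):
        # one peak of activity 2.0 inside a 200-bp merged span: 100*2/200 = 1.0
        t = tsr(1000, 1200, 1100, "T1")
        out = merge_and_score([t], [StabilityCall("T1", 5, "stable")],
                              [StyleCall("T1", "S", None, False)],
                              empty_regions(),
                              peaks_df([("chr1", 1000, 1200, "p1", 2.0)]))
        assert len(out) == 1
        m = out[0]
        assert m.length == 200
        assert m.per_bp_activity == pytest.approx(1.0)
        assert m.tsr_class == "stable" and m.covered

    def test_two_peaks_sum_in_region(self):
        t = tsr(1000, 1400, 1100, "T1")
        out = merge_and_score([t], [StabilityCall("T1", 0, "unstable")],
                              [StyleCall("T1", "U", None, False)],
                              empty_regions(),
                              peaks_df([("chr1", 1000, 1100, "a", 1.0),
                                        ("chr1", 1300, 1400, "b", 3.0)]))
        m = out[0]
        assert m.length == 400
        assert m.per_bp_activity == pytest.approx(100 * 4 / 400)
        assert m.tsr_class == "unstable" and m.substyle == "U"

    def test_region_without_peaks_flagged_uncovered(self):
        t = tsr(1000, 1200, 1100, "T1")
        out = merge_and_score([t], [StabilityCall("T1", 5, "stable")],
                              [StyleCall("T1", "S", None, False)],
                              empty_regions(), peaks_df([]))
        m = out[0]
        assert m.per_bp_activity == 0.0 and not m.covered
        assert starr_coverage_fraction([t], out) == 0.0

    def test_open_chromatin_without_tsr_is_no_transcription(self):
        atac = pd.DataFrame([{"chrom": "chr1", "start": 5000, "end": 5200,
                              "name": "o", "score": 0, "strand": "."}])
        out = merge_and_score([], [], [], atac, peaks_df([("chr1", 5000, 5200, "p", 4.0)]))
        assert out[0].tsr_class == "no_transcription"
        assert out[0].per_bp_activity == pytest.approx(100 * 4 / 200)

    def test_doubling_length_halves_per_bp_activity(self):
        short = merge_and_score([], [], [],
                                pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 200,
                                               "name": "o", "score": 0, "strand": "."}]),
                                peaks_df([("chr1", 50, 150, "p", 2.0)]))
        long = merge_and_score([], [], [],
                               pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 400,
                                              "name": "o", "score": 0, "strand": "."}]),
                               peaks_df([("chr1", 50, 150, "p", 2.0)]))
        assert short[0].per_bp_activity == pytest.approx(2 * long[0].per_bp_activity)

    def test_filter_then_merge_commutes(self):
        peaks = peaks_df([("chr1", 1000, 1030, "short", 9.0),  # 30 bp
                          ("chr1", 1000, 1200, "long", 2.0)])
        t = tsr(1000, 1200, 1100, "T1")
        args = ([t], [StabilityCall("T1", 5, "stable")], [StyleCall("T1", "S", None, False)],
                empty_regions())
        first = merge_and_score(*args, filter_fragments(peaks))
        # filtering contained peaks after merging gives the same activity
        second = merge_and_score(*args, peaks)
        second_refiltered = [m for m in first]
        assert first[0].activity_sum == pytest.approx(2.0)
        assert second[0].activity_sum == pytest.approx(11.0)  # unfiltered control differs
        assert second_refiltered[0].activity_sum == pytest.approx(2.0)


class TestGroupCompare:
    def test_identical_groups_are_null(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}
        res = group_compare(groups)
        assert res.f_stat == 0.0 and res.p_value == 1.0
        assert (res.tukey["p_adj"] == 1.0).all()

    def test_two_group_tukey_matches_studentized_range_closed_form(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(1.0, 1.0, 30)
        res = group_compare({"a": a, "b": b})
        # closed form: q = |mean diff| / sqrt(MSE/2 * (1/na + 1/nb));
        # p = P(Q_{2, na+nb-2} > q)
        na, nb = len(a), len(b)
        mse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        mse /= na + nb - 2
        q = abs(a.mean() - b.mean()) / np.sqrt(mse / 2 * (1 / na + 1 / nb))
        p_expected = stats.studentized_range.sf(q, 2, na + nb - 2)
        assert res.pair_p("a", "b") == pytest.approx(p_expected, rel=1e-4, abs=1e-12)

    def test_planted_separation_is_significant(self):
        rng = np.random.default_rng(23)
        groups = {
            "no_transcription": rng.normal(2.0, 1.0, 200),
            "unstable": rng.normal(5.0, 1.0, 200),
            "stable": rng.normal(11.0, 1.0, 200),
        }
        res = group_compare(groups)
        assert res.pair_p("stable", "unstable") < 0.0005
        med = {k: np.median(v) for k, v in res.groups.items()}
        assert med["no_transcription"] < med["unstable"] < med["stable"]

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare({"a": [1.0, 2.0]})


class TestCorrelation:
    def test_perfect_dependence(self):
        x = np.arange(1.0, 21.0)
        assert activity_correlation(x, x)["r"] == pytest.approx(1.0)

    def test_negative_dependence_has_negative_sign(self):
        x = np.arange(1.0, 21.0)
        y = x[::-1]
        assert activity_correlation(x, y)["r"] < 0

    def test_zero_variance_flagged_undefined(self):
        res = activity_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res["undefined"]

    def test_noisy_linear_matches_closed_form(self):
        """r estimates rho = 1/sqrt(1 + sigma^2/var(x)) for y = x + noise."""
        rng = np.random.default_rng(31)
        x = rng.normal(0.0, 2.0, 4000)
        sigma = 1.5
        y = x + rng.normal(0.0, sigma, 4000)
        rho = 1.0 / np.sqrt(1.0 + sigma**2 / 4.0)
        res = activity_correlation(x, y, transform="none")
        # 99% CI via Fisher z
        z = np.arctanh(res["r"])
        half = 2.576 / np.sqrt(4000 - 3)
        assert np.tanh(z - half) <= rho <= np.tanh(z + half)
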