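import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spidroin.io import MetadataTable
from spidroin.motifs import scan_motifs
from spidroin.quantify import (
    box_summary,
    group_by_architecture,
    motif_abundance,
    residue_percent,
    summarize_sequence,
)
from spidroin.repeats import RepeatUnit, find_polyala_runs, segment_repeats
from spidroin.motifs import profile_repeat
from tests.conftest import make_repeat_profile


def brute_force_box(values):
    """Reference quantiles and Tukey fences via direct order statistics."""
    xs = sorted(values)
    n = len(xs)

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        frac = pos - lo
        return xs[lo] * (1 - frac) + xs[hi] * frac

    q1, med, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    iqr = q3 - q1
    inside = [x for x in xs if q1 - 1.5 * iqr <= x <= q3 + 1.5 * iqr]
    outliers = [x for x in xs if x < q1 - 1.5 * iqr or x > q3 + 1.5 * iqr]
    return med, q1, q3, min(inside), max(inside), sorted(outliers)


class TestMotifAbundance:
    def test_consensus_repeat_gp_percent(self):
        rp = make_repeat_profile({"GP": 4}, 31)
        assert motif_abundance(rp, "GP").percent_of_length == pytest.approx(25.81, abs=0.01)

    def test_zero_count_zero_percent(self):
        rp = make_repeat_profile({}, 31)
        assert motif_abundance(rp, "GP").percent_of_length == 0.0

    def test_two_gp_in_47_residues_is_about_8_5_percent(self):
        rp = make_repeat_profile({"GP": 2}, 47)
        assert motif_abundance(rp, "GP").percent_of_length == pytest.approx(8.51, abs=0.01)

    def test_ggx_uses_length_three(self):
        rp = make_repeat_profile({"GGY": 2}, 30)
        assert motif_abundance(rp, "GGY").percent_of_length == pytest.approx(20.0)

    def test_zero_length_errors(self):
        from spidroin.motifs import RepeatProfile

        with pytest.raises(ValueError):
            motif_abundance(RepeatProfile(repeat_index=0, repeat_length=0), "GP")


class TestBoxSummary:
    def test_simple_five(self):
        box = box_summary([1, 2, 3, 4, 5])
        assert (box.median, box.q1, box.q3) == (3, 2, 4)
        assert box.outliers == []
        assert (box.whisker_low, box.whisker_high) == (1, 5)

    def test_singleton(self):
        box = box_summary([7])
        assert box.median == box.q1 == box.q3 == 7
        assert box.whisker_low == box.whisker_high == 7

    def test_far_value_is_outlier(self):
        box = box_summary([1, 1, 1, 10])
        assert 10 in box.outliers

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            box_summary([])

    @given(st.lists(st.integers(0, 10), min_size=1, max_size=8))
    @settings(max_examples=400, derandomize=True, deadline=None)
    def test_matches_brute_force(self, values):
        box = box_summary(values)
        med, q1, q3, wlo, whi, out = brute_force_box(values)
        assert box.median == pytest.approx(med)
        assert box.q1 == pytest.approx(q1)
        assert box.q3 == pytest.approx(q3)
        assert box.whisker_low == pytest.approx(wlo)
        assert box.whisker_high == pytest.approx(whi)
        assert box.outliers == pytest.approx(out)


def _units_and_profiles(repeat_seqs):
    units, profiles, pos = [], [], 0
    for i, seq in enumerate(repeat_seqs):
        units.append(RepeatUnit(index=i, start=pos, end=pos + len(seq), sequence=seq, complete=True))
        profiles.append(profile_repeat(scan_motifs(seq), len(seq), i))
        pos += len(seq)
    return units, profiles


class TestSummarizeSequence:
    def test_identical_consensus_repeats(self):
        seq = "AAAAAAAGGYGPGAGQQGQQGPGGQGPYGPG"  # 31 residues, 4 GP
        units, profiles = _units_and_profiles([seq] * 3)
        summary = summarize_sequence(units, profiles, ["GP"], "s")
        assert summary.repeat_length.median == 31
        assert summary.motif_percent["GP"].median == pytest.approx(25.81, abs=0.01)

    def test_median_repeat_length(self):
        units, profiles = _units_and_profiles(["A" * 25, "A" * 26, "A" * 27])
        assert summarize_sequence(units, profiles, [], "s").repeat_length.median == 26

    def test_mean_count_per_repeat(self):
        units, profiles = _units_and_profiles(["Y" * 30, "Y" * 30, "GP" + "Y" * 28])
        summary = summarize_sequence(units, profiles, ["GP"], "s")
        assert summary.mean_count_per_repeat["GP"] == pytest.approx(1 / 3)

    def test_duplication_invariance(self):
        base = ["GPGGYQQ" + "Y" * 10, "GPGP" + "Y" * 20]
        u1, p1 = _units_and_profiles(base)
        u3, p3 = _units_and_profiles(base * 3)
        s1 = summarize_sequence(u1, p1, ["GP", "QQ"], "s")
        s3 = summarize_sequence(u3, p3, ["GP", "QQ"], "s")
        assert s1.motif_percent["GP"].median == s3.motif_percent["GP"].median
        assert s1.repeat_length.median == s3.repeat_length.median

    def test_permutation_invariance(self):
        base = ["GP" + "Y" * 10, "QQ" + "Y" * 20, "GGY" + "Y" * 5]
        u1, p1 = _units_and_profiles(base)
        u2, p2 = _units_and_profiles(base[::-1])
        s1 = summarize_sequence(u1, p1, ["GP"], "s")
        s2 = summarize_sequence(u2, p2, ["GP"], "s")
        assert s1.motif_percent["GP"].median == s2.motif_percent["GP"].median

    def test_no_complete_repeats_errors(self):
        unit = RepeatUnit(index=0, start=0, end=5, sequence="GPGPY", complete=False)
        with pytest.raises(ValueError):
            summarize_sequence([unit], [], ["GP"], "s")


class TestResiduePercent:
    def test_glutamine_fraction(self):
        units, _ = _units_and_profiles(["QQGQY" + "G" * 5])
        assert residue_percent(units, "Q") == pytest.approx(30.0)


class TestGroupByArchitecture:
    def _summaries(self, medians_by_id):
        out = []
        for seq_id, gp_percent in medians_by_id.items():
            n_gp = int(gp_percent)  # on a 200-residue repeat, percent == GP count
            seq = "GP" * n_gp + "Y" * (200 - 2 * n_gp)
            units, profiles = _units_and_profiles([seq, seq])
            out.append(summarize_sequence(units, profiles, ["GP"], seq_id))
        return out

    def test_group_range_and_order(self):
        summaries = self._summaries({"o1": 12.0, "o2": 16.0, "s1": 0.0})
        metadata = MetadataTable(
            rows={
                "o1": {"web_architecture": "orb"},
                "o2": {"web_architecture": "orb"},
                "s1": {"web_architecture": "sheet"},
            }
        )
        reports = group_by_architecture(summaries, metadata, ["GP"])
        assert [r.architecture for r in reports] == ["orb", "sheet"]
        orb = reports[0]
        assert orb.median_range == (12.0, 16.0)

    def test_missing_metadata_grouped_unknown(self):
        summaries = self._summaries({"x": 10.0})
        reports = group_by_architecture(summaries, MetadataTable(), ["GP"])
        assert [r.architecture for r in reports] == ["unknown"]

    def test_single_group(self):
        summaries = self._summaries({"a": 10.0})
        metadata = MetadataTable(rows={"a": {"web_architecture": "cobweb"}})
        reports = group_by_architecture(summaries, metadata, ["GP"])
        assert len(reports) == 1 and reports[0].architecture == "cobweb"
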