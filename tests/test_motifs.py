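from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spidroin.motifs import (
    DEFAULT_CATALOG,
    InsufficientRepeatsError,
    MotifCatalog,
    profile_repeat,
    profile_sequence,
    scan_motifs,
)
from tests.conftest import make_repeat_profile


def oracle_scan(seq, x_alphabet=frozenset("ASYQDRPNLF"), doublets=("QQ", "SS")):
    """Independent reference scanner: repeated leftmost-eligible assignment.

    Each precedence stage repeatedly assigns the leftmost still-eligible
    occurrence until none remains, which is equivalent to (but mechanically
    different from) a single left-to-right sweep per stage.
    """
    taken = [False] * len(seq)
    counts = Counter()

    def free(i, k):
        return all(not taken[j] for j in range(i, i + k))

    def claim(i, k, label):
        for j in range(i, i + k):
            taken[j] = True
        counts[label] += 1

    changed = True
    while changed:  # doublet stage
        changed = False
        for i in range(len(seq) - 1):
            if seq[i] == seq[i + 1] and seq[i] * 2 in doublets and free(i, 2):
                claim(i, 2, seq[i] * 2)
                changed = True
                break
    changed = True
    while changed:  # GGX stage
        changed = False
        for i in range(len(seq) - 2):
            if seq[i] == "G" and seq[i + 1] == "G" and seq[i + 2] in x_alphabet and free(i, 3):
                claim(i, 3, seq[i : i + 3])
                changed = True
                break
    changed = True
    while changed:  # GX stage
        changed = False
        for i in range(len(seq) - 1):
            if seq[i] == "G" and seq[i + 1] in x_alphabet and free(i, 2):
                claim(i, 2, seq[i : i + 2])
                changed = True
                break
    return counts


class TestScanMotifs:
    def test_instantiated_araneidae_consensus(self):
        seq = "GQQGPGGQGPYGPGAAAAAAAGGYGPGAGQQ"
        counts = Counter(h.motif for h in scan_motifs(seq))
        assert counts == {"QQ": 2, "GGQ": 1, "GGY": 1, "GP": 4, "GA": 2}

    def test_poly_g_yields_nothing(self):
        assert scan_motifs("GGGG") == []

    def test_qq_blocks_both_ggq_and_gq(self):
        counts = Counter(h.motif for h in scan_motifs("AGGQQA"))
        assert counts == {"QQ": 1}

    def test_qqq_greedy_left(self):
        assert Counter(h.motif for h in scan_motifs("QQQ")) == {"QQ": 1}
        assert Counter(h.motif for h in scan_motifs("QQQQ")) == {"QQ": 2}

    def test_hits_sorted_and_non_overlapping(self):
        hits = scan_motifs("GQQGPGGQGPYGPGAAAAAAAGGYGPGAGQQ")
        occupied = set()
        last = -1
        for h in hits:
            assert h.start > last
            span = set(range(h.start, h.end))
            assert not span & occupied
            occupied |= span
            last = h.start

    def test_rescan_is_deterministic(self):
        seq = "GQQGPGGQGPYGPGAGQQSSGS"
        assert scan_motifs(seq) == scan_motifs(seq)

    def test_removing_qq_frees_gq_or_ggq(self):
        """Dropping the QQ doublet converts each G·QQ context to one GQ/GGQ."""
        no_qq = MotifCatalog(doublets=("SS",))
        assert Counter(h.motif for h in scan_motifs("AGQQA", no_qq)) == {"GQ": 1}
        assert Counter(h.motif for h in scan_motifs("AGGQQA", no_qq)) == {"GGQ": 1}

    @given(st.text(alphabet="GQSAPY", min_size=0, max_size=15))
    @settings(max_examples=500, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, seq):
        got = Counter(h.motif for h in scan_motifs(seq))
        assert got == oracle_scan(seq)

    @given(st.text(alphabet="GQSYAPNDRLF", min_size=0, max_size=40))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_assigned_residues_bounded(self, seq):
        hits = scan_motifs(seq)
        assert sum(h.length for h in hits) <= len(seq)

    def test_ambiguity_codes_never_match(self):
        # X/B/Z are outside the motif alphabet and cannot create hits
        assert scan_motifs("GXGBGZ") == []


class TestCatalog:
    def test_g_in_x_alphabet_rejected(self):
        with pytest.raises(ValueError):
            MotifCatalog(x_alphabet=frozenset("GAY"))

    def test_motif_lengths(self):
        assert DEFAULT_CATALOG.motif_length("GP") == 2
        assert DEFAULT_CATALOG.motif_length("QQ") == 2
        assert DEFAULT_CATALOG.motif_length("GGY") == 3

    def test_all_labels_cover_catalog(self):
        labels = DEFAULT_CATALOG.all_labels()
        assert "QQ" in labels and "SS" in labels
        assert "GGY" in labels and "GP" in labels
        assert len(labels) == 2 + 10 + 10


class TestProfiles:
    def test_profile_repeat_counts(self):
        hits = scan_motifs("GPGGYGP")
        rp = profile_repeat(hits, repeat_length=7, repeat_index=2)
        assert rp.counts == {"GP": 2, "GGY": 1}
        assert rp.counts["GA"] == 0  # absent motifs read as zero

    def test_profile_repeat_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            profile_repeat([], repeat_length=0, repeat_index=0)

    def test_occurrence_fraction_and_threshold(self):
        # GP present in 2 of 6 repeats: 2/6 >= 1/3, so conserved at default theta
        profiles = [make_repeat_profile({"GP": 1}, 30, i) for i in range(2)] + [
            make_repeat_profile({"GGY": 1}, 30, i) for i in range(2, 6)
        ]
        sp = profile_sequence(profiles, sequence_id="s")
        assert sp.occurrence_fraction["GP"] == pytest.approx(2 / 6)
        assert "GP" in sp.conserved_set
        assert sp.occurrence_fraction["GGY"] == pytest.approx(4 / 6)

    def test_ubiquitous_motif_fraction_one(self):
        profiles = [make_repeat_profile({"GGY": 2}, 30, i) for i in range(6)]
        sp = profile_sequence(profiles, sequence_id="s")
        assert sp.occurrence_fraction["GGY"] == 1.0
        assert sp.mean_count_per_repeat["GGY"] == 2.0

    def test_absent_motif_not_present(self):
        profiles = [make_repeat_profile({"GGY": 1}, 30, 0)]
        sp = profile_sequence(profiles, sequence_id="s")
        assert "QQ" not in sp.present_set
        assert sp.conserved_set <= sp.present_set

    def test_zero_repeats_errors(self):
        with pytest.raises(InsufficientRepeatsError):
            profile_sequence([], sequence_id="s")

    def test_below_threshold_not_conserved(self):
        profiles = [make_repeat_profile({"GP": 1}, 30, 0)] + [
            make_repeat_profile({}, 30, i) for i in range(1, 6)
        ]
        sp = profile_sequence(profiles, sequence_id="s")
        assert "GP" in sp.present_set and "GP" not in sp.conserved_set
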