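from collections import Counter

import pytest

from spidroin.motifs import RepeatProfile, SequenceProfile


def make_profile(sequence_id, conserved, present=None, n=6, theta=1 / 3):
    """Build a SequenceProfile directly from a conserved-motif set."""
    conserved = frozenset(conserved)
    present = frozenset(present) if present is not None else conserved
    occurrence = {m: (1.0 if m in conserved else 0.1) for m in present}
    return SequenceProfile(
        sequence_id=sequence_id,
        n_complete_repeats=n,
        occurrence_fraction=occurrence,
        mean_count_per_repeat={m: 1.0 for m in present},
        present_set=present,
        conserved_set=conserved,
        theta=theta,
    )


def make_repeat_profile(counts, length, index=0):
    return RepeatProfile(repeat_index=index, repeat_length=length, counts=Counter(counts))


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
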