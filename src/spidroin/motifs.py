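"""Short amino-acid motif scanning under mutual-exclusion precedence rules.

The catalog covers the glycine-led dipeptide and tripeptide motifs GX and
GGX — with X drawn from {A, S, Y, Q, D, R, P, N, L, F} — plus the doublets
QQ and SS.  Assignments within a repeat are mutually exclusive: no residue
may belong to two motifs.  Precedence resolves the overlaps, doublets
first (so QQ beats GQ and GGQ in a ...GQQ... context), then GGX over GX.

Each pass runs left to right; the doublet pass tiles maximal homopolymer
runs greedily from their left end, so QQQ yields one QQ and QQQQ yields two.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

DEFAULT_X_ALPHABET = frozenset("ASYQDRPNLF")


class InsufficientRepeatsError(ValueError):
    """Raised when a sequence has no complete repeats to profile."""


@dataclass(frozen=True)
class MotifCatalog:
    """The motif inventory and the order its passes are applied in.

    ``precedence`` names the three scanning passes; removing an entry
    removes those motifs from the scan entirely.
    """

    x_alphabet: frozenset = DEFAULT_X_ALPHABET
    doublets: tuple[str, ...] = ("QQ", "SS")
    precedence: tuple[str, ...] = ("doublet", "GGX", "GX")

    def __post_init__(self):
        if "G" in self.x_alphabet:
            raise ValueError("x_alphabet must exclude G (GG/GGG would be ambiguous)")
        for d in self.doublets:
            if len(d) != 2 or d[0] != d[1]:
                raise ValueError(f"doublet {d!r} is not a homodimer label")
        unknown = set(self.precedence) - {"doublet", "GGX", "GX"}
        if unknown:
            raise ValueError(f"unknown precedence pass(es): {sorted(unknown)}")

    def motif_length(self, label: str) -> int:
        """Residue footprint of a motif label (2 for GX/QQ/SS, 3 for GGX)."""
        return len(label)

    def all_labels(self) -> list[str]:
        """Every concrete label the catalog can emit, in a stable order."""
        labels: list[str] = []
        if "doublet" in self.precedence:
            labels.extend(self.doublets)
        if "GGX" in self.precedence:
            labels.extend("GG" + x for x in sorted(self.x_alphabet))
        if "GX" in self.precedence:
            labels.extend("G" + x for x in sorted(self.x_alphabet))
        return labels


DEFAULT_CATALOG = MotifCatalog()


@dataclass(frozen=True)
class MotifHit:
    """One non-overlapping motif assignment within a repeat."""

    motif: str
    start: int

    @property
    def length(self) -> int:
        return len(self.motif)

    @property
    def end(self) -> int:
        return self.start + len(self.motif)


def _scan_doublets(seq: str, taken: list[bool], doublets, hits: list[MotifHit]) -> None:
    residues = {d[0] for d in doublets}
    i, n = 0, len(seq)
    while i < n:
        if seq[i] in residues:
            j = i
            while j < n and seq[j] == seq[i]:
                j += 1
            # tile the homopolymer run [i, j) greedily from the left
            k = i
            while k + 1 < j:
                if not taken[k] and not taken[k + 1]:
                    hits.append(MotifHit(motif=seq[k] * 2, start=k))
                    taken[k] = taken[k + 1] = True
                    k += 2
                else:
                    k += 1
            i = j
        else:
            i += 1


def _scan_ggx(seq: str, taken: list[bool], x_alphabet, hits: list[MotifHit]) -> None:
    i, n = 0, len(seq)
    while i + 2 < n:
        if (
            seq[i] == "G"
            and seq[i + 1] == "G"
            and seq[i + 2] in x_alphabet
            and not (taken[i] or taken[i + 1] or taken[i + 2])
        ):
            hits.append(MotifHit(motif=seq[i : i + 3], start=i))
            taken[i] = taken[i + 1] = taken[i + 2] = True
            i += 3
        else:
            i += 1


def _scan_gx(seq: str, taken: list[bool], x_alphabet, hits: list[MotifHit]) -> None:
    i, n = 0, len(seq)
    while i + 1 < n:
        if (
            seq[i] == "G"
            and seq[i + 1] in x_alphabet
            and not (taken[i] or taken[i + 1])
        ):
            hits.append(MotifHit(motif=seq[i : i + 2], start=i))
            taken[i] = taken[i + 1] = True
            i += 2
        else:
            i += 1


def scan_motifs(repeat_seq: str, catalog: MotifCatalog = DEFAULT_CATALOG) -> list[MotifHit]:
    """Assign non-overlapping motif hits to a repeat sequence.

    Three left-to-right passes run in ``catalog.precedence`` order: the
    doublet pass (QQ/SS inside maximal homopolymer runs), the GGX pass and
    the GX pass.  Later passes only see residues no earlier pass claimed.
    Hits are returned sorted by start coordinate.
    """
    taken = [False] * len(repeat_seq)
    hits: list[MotifHit] = []
    for stage in catalog.precedence:
        if stage == "doublet":
            _scan_doublets(repeat_seq, taken, catalog.doublets, hits)
        elif stage == "GGX":
            _scan_ggx(repeat_seq, taken, catalog.x_alphabet, hits)
        elif stage == "GX":
            _scan_gx(repeat_seq, taken, catalog.x_alphabet, hits)
    return sorted(hits, key=lambda h: h.start)


@dataclass
class RepeatProfile:
    """Motif tallies for one tandem repeat."""

    repeat_index: int
    repeat_length: int
    counts: Counter = field(default_factory=Counter)


def profile_repeat(
    hits: list[MotifHit], repeat_length: int, repeat_index: int
) -> RepeatProfile:
    """Tally scan hits into a per-repeat count table."""
    if repeat_length <= 0:
        raise ValueError("repeat_length must be positive")
    counts = Counter(h.motif for h in hits)
    return RepeatProfile(repeat_index=repeat_index, repeat_length=repeat_length, counts=counts)


@dataclass
class SequenceProfile:
    """Conserved-motif summary of one sequence's complete tandem repeats.

    ``occurrence_fraction[m]`` is the fraction of complete repeats carrying
    at least one hit of motif *m*; motifs at or above the conservation
    threshold θ form ``conserved_set`` (the "regularly appearing" motifs).
    """

    sequence_id: str
    n_complete_repeats: int
    occurrence_fraction: dict[str, float]
    mean_count_per_repeat: dict[str, float]
    present_set: frozenset
    conserved_set: frozenset
    theta: float


def profile_sequence(
    repeat_profiles: list[RepeatProfile],
    theta: float = 1 / 3,
    sequence_id: str = "",
) -> SequenceProfile:
    """Aggregate complete-repeat profiles into a sequence-level motif profile.

    θ defaults to 1/3: a motif recurring at one hit per three repeats still
    counts as conserved (the weakest conservation level treated as a real
    profile feature), while one-off hits in long sequences do not.
    """
    if not repeat_profiles:
        raise InsufficientRepeatsError(f"{sequence_id or '<sequence>'}: no complete repeats")
    n = len(repeat_profiles)
    motifs = sorted({m for rp in repeat_profiles for m in rp.counts})
    occurrence = {
        m: sum(1 for rp in repeat_profiles if rp.counts.get(m, 0) > 0) / n for m in motifs
    }
    mean_count = {
        m: sum(rp.counts.get(m, 0) for rp in repeat_profiles) / n for m in motifs
    }
    present = frozenset(motifs)
    conserved = frozenset(m for m in motifs if occurrence[m] >= theta)
    return SequenceProfile(
        sequence_id=sequence_id,
        n_complete_repeats=n,
        occurrence_fraction=occurrence,
        mean_count_per_repeat=mean_count,
        present_set=present,
        conserved_set=conserved,
        theta=theta,
    )
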