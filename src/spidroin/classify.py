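"""MaSp1/MaSp2 classification and the Araneidae MaSp2 consensus matcher.

Two diagnostic rules separate the dragline spidroins across Entelegynae:
MaSp2 tandem repeats conserve both GP and the di-glutamine QQ motif, while
MaSp1 repeats conserve a GGY-equivalent motif and never QQ.  Sequences
conserving QQ without GP (the *Tetragnatha* pattern) are intermediate.

Within family Araneidae, MaSp2 repeats additionally share an extended
~32-residue consensus around each poly-Ala run:

    GQQGPGGQGPYGP(G/S) A(6-9) GGYGPG(A/S)GQQ

matched here as a 14-residue upstream and a 10-residue downstream flank
with a positionwise mismatch budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import SequenceProfile
from .repeats import PolyAlaRun

#: GGY may be replaced by GGF (as in Euprosthenops australis MaSp2)
GGY_EQUIVALENTS = ("GGY", "GGF")

#: upstream flank template, one allowed-residue set per position (14 residues)
UPSTREAM_TEMPLATE: tuple[frozenset, ...] = tuple(
    frozenset(ch) for ch in "GQQGPGGQGPYGP"
) + (frozenset("GS"),)

#: downstream flank template (10 residues)
DOWNSTREAM_TEMPLATE: tuple[frozenset, ...] = (
    tuple(frozenset(ch) for ch in "GGYGPG")
    + (frozenset("AS"),)
    + tuple(frozenset(ch) for ch in "GQQ")
)

ARANEIDAE_AN_RANGE = (6, 9)


@dataclass
class ConsensusProfile:
    """Motifs conserved across a set of sequence profiles.

    ``consensus_set`` is the strict intersection of member conserved sets;
    ``partial_map`` keeps the per-motif member fractions so majority
    structure is not lost.
    """

    member_ids: list[str]
    consensus_set: frozenset
    partial_map: dict[str, float]


def derive_consensus(profiles: list[SequenceProfile]) -> ConsensusProfile:
    """Superimpose sequence profiles into a cross-sequence consensus."""
    if not profiles:
        raise ValueError("cannot derive a consensus from zero profiles")
    motifs = sorted({m for p in profiles for m in p.conserved_set})
    n = len(profiles)
    partial = {
        m: sum(1 for p in profiles if m in p.conserved_set) / n for m in motifs
    }
    consensus = frozenset(m for m in motifs if partial[m] == 1.0)
    return ConsensusProfile(
        member_ids=[p.sequence_id for p in profiles],
        consensus_set=consensus,
        partial_map=partial,
    )


@dataclass
class SpidroinClass:
    """A classification outcome with the rule firings that produced it."""

    label: str  # MaSp1 | MaSp2 | intermediate | nonconforming
    evidence: list[str] = field(default_factory=list)


def classify(
    profile: SequenceProfile,
    architecture_ok: bool,
    strict_ggy: bool = False,
) -> SpidroinClass:
    """Label a sequence MaSp1, MaSp2, intermediate or nonconforming.

    ``architecture_ok`` asserts the canonical alternating poly-Ala/Gly-rich
    layout (operationally: at least two poly-Ala runs and one complete
    repeat); without it no classification is attempted.  With
    ``strict_ggy`` the MaSp1 criterion accepts only GGY itself, otherwise
    GGF counts as a GGY-equivalent.
    """
    if not architecture_ok:
        return SpidroinClass(label="nonconforming", evidence=[])
    conserved = profile.conserved_set
    has_qq = "QQ" in conserved
    has_gp = "GP" in conserved
    ggy_labels = GGY_EQUIVALENTS[:1] if strict_ggy else GGY_EQUIVALENTS
    ggy_hits = [m for m in ggy_labels if m in conserved]
    if has_qq and has_gp:
        return SpidroinClass(
            label="MaSp2", evidence=["conserved QQ", "conserved GP"]
        )
    if not has_qq and ggy_hits:
        return SpidroinClass(
            label="MaSp1",
            evidence=[f"conserved {m}" for m in ggy_hits] + ["no conserved QQ"],
        )
    if has_qq and not has_gp:
        return SpidroinClass(
            label="intermediate", evidence=["conserved QQ without GP"]
        )
    return SpidroinClass(label="intermediate", evidence=["no diagnostic motifs"])


@dataclass
class ConsensusMatch:
    """Outcome of matching one poly-Ala run against the Araneidae consensus."""

    run_start: int
    run_end: int
    polyala_length: int
    eligible: bool
    upstream_flank: str = ""
    downstream_flank: str = ""
    upstream_mismatches: int | None = None
    downstream_mismatches: int | None = None
    matched: bool = False

    @property
    def total_mismatches(self) -> int | None:
        if self.upstream_mismatches is None or self.downstream_mismatches is None:
            return None
        return self.upstream_mismatches + self.downstream_mismatches


def _template_mismatches(segment: str, template: tuple[frozenset, ...]) -> int:
    return sum(1 for res, allowed in zip(segment, template) if res not in allowed)


def match_araneidae_consensus(
    domain_seq: str,
    runs: list[PolyAlaRun],
    max_mismatch: int = 3,
    an_range: tuple[int, int] = ARANEIDAE_AN_RANGE,
) -> list[ConsensusMatch]:
    """Match each poly-Ala run's flanks against the Araneidae MaSp2 consensus.

    A run is eligible when its length lies in ``an_range`` and the domain
    provides the full 14 upstream and 10 downstream flank residues.  The
    flanks are compared positionwise against the templates (bracketed
    positions accept either residue); the run matches when total mismatches
    stay within ``max_mismatch``.  Ineligible runs are reported unmatched
    with mismatch counts unset.
    """
    lo, hi = an_range
    up_len, down_len = len(UPSTREAM_TEMPLATE), len(DOWNSTREAM_TEMPLATE)
    matches: list[ConsensusMatch] = []
    for run in runs:
        eligible = (
            lo <= run.length <= hi
            and run.start >= up_len
            and run.end + down_len <= len(domain_seq)
        )
        match = ConsensusMatch(
            run_start=run.start,
            run_end=run.end,
            polyala_length=run.length,
            eligible=eligible,
        )
        if eligible:
            upstream = domain_seq[run.start - up_len : run.start]
            downstream = domain_seq[run.end : run.end + down_len]
            match.upstream_flank = upstream
            match.downstream_flank = downstream
            match.upstream_mismatches = _template_mismatches(upstream, UPSTREAM_TEMPLATE)
            match.downstream_mismatches = _template_mismatches(
                downstream, DOWNSTREAM_TEMPLATE
            )
            match.matched = match.total_mismatches <= max_mismatch
        matches.append(match)
    return matches


def instantiate_consensus(
    an_length: int = 7, upstream_choice: str = "G", downstream_choice: str = "A"
) -> str:
    """Spell out the Araneidae MaSp2 consensus core for a given poly-Ala length.

    With the template flanks of 14 and 10 residues, the core length is
    ``24 + an_length`` (about 32 residues across the observed A6–A9 range).
    """
    upstream = "GQQGPGGQGPYGP" + upstream_choice
    downstream = "GGYGPG" + downstream_choice + "GQQ"
    return upstream + "A" * an_length + downstream
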