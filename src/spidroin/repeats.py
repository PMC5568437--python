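"""Poly-alanine run detection and tandem-repeat segmentation.

Major ampullate spidroin (MaSp) repetitive domains alternate short
poly-alanine stretches with glycine-rich regions.  The poly-Ala run is the
only anchor conserved across all taxa, so repeat boundaries are placed at
the START of each run: one tandem repeat is a poly-Ala run plus the
Gly-rich sequence that follows it, up to the start of the next run.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io import SequenceRecord

#: residues tolerated as single interruptions inside a poly-Ala run
INTERRUPTION_RESIDUES = frozenset("GSV")

#: minimum fraction of Ala a merged run must retain
MIN_ALA_FRACTION = 0.75


class NonRepetitiveError(ValueError):
    """Raised when a sequence shows no poly-Ala anchor and no user bounds."""


@dataclass
class PolyAlaRun:
    """A poly-alanine stretch, possibly carrying single G/S/V interruptions."""

    start: int
    end: int
    interruptions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def ala_count(self) -> int:
        return self.length - len(self.interruptions)

    def shifted(self, offset: int) -> "PolyAlaRun":
        """Return a copy with coordinates translated by ``offset``."""
        return PolyAlaRun(
            start=self.start + offset,
            end=self.end + offset,
            interruptions=[(p + offset, r) for p, r in self.interruptions],
        )


@dataclass
class DomainAnnotation:
    """Bounds of the repetitive domain within a record (``source``: auto|user)."""

    repetitive_start: int
    repetitive_end: int
    source: str = "auto"


@dataclass
class RepeatUnit:
    """One tandem-repeat interval of the repetitive domain.

    A leading partial segment (residues before the first poly-Ala run) is
    reported with ``index == -1`` and ``complete=False``; the final unit is
    incomplete because the domain ends inside its Gly-rich region.
    """

    index: int
    start: int
    end: int
    sequence: str
    complete: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def find_polyala_runs(
    residues: str, min_seed: int = 3, min_total: int = 4
) -> list[PolyAlaRun]:
    """Detect poly-Ala runs, merging across single G/S/V interruptions.

    Seeds are maximal runs of at least ``min_seed`` contiguous alanines.
    Two seeds separated by exactly one residue from {G, S, V} are merged,
    recording the interruption; merging chains across multiple seeds.
    Merged runs shorter than ``min_total`` residues, or with less than 75%
    alanine content, are discarded.  Returned runs are disjoint and sorted;
    each starts and ends on an 'A'.
    """
    seeds = [(m.start(), m.end()) for m in re.finditer("A{%d,}" % min_seed, residues)]
    runs: list[PolyAlaRun] = []
    for start, end in seeds:
        if (
            runs
            and start - runs[-1].end == 1
            and residues[runs[-1].end] in INTERRUPTION_RESIDUES
        ):
            prev = runs[-1]
            prev.interruptions.append((prev.end, residues[prev.end]))
            prev.end = end
        else:
            runs.append(PolyAlaRun(start=start, end=end))
    return [
        r
        for r in runs
        if r.length >= min_total and r.ala_count / r.length >= MIN_ALA_FRACTION
    ]


def delimit_repetitive_domain(
    record: SequenceRecord,
    runs: list[PolyAlaRun],
    user_bounds: tuple[int, int] | None = None,
    flank_max: int = 60,
) -> DomainAnnotation:
    """Choose the repetitive-domain interval of a record.

    Explicit ``user_bounds`` win (deposited entries often state the
    repetitive region); otherwise the domain spans the first to the last
    poly-Ala run plus at most ``flank_max`` residues on either side, clamped
    to the sequence.
    """
    n = len(record.residues)
    if user_bounds is not None:
        start, end = user_bounds
        if not (0 <= start < end <= n):
            raise ValueError(
                f"{record.id}: user bounds ({start}, {end}) outside sequence of length {n}"
            )
        return DomainAnnotation(start, end, source="user")
    if not runs:
        raise NonRepetitiveError(
            f"{record.id}: no poly-Ala runs found and no user bounds supplied"
        )
    start = max(0, runs[0].start - flank_max)
    end = min(n, runs[-1].end + flank_max)
    return DomainAnnotation(start, end, source="auto")


def segment_repeats(domain_seq: str, runs: list[PolyAlaRun]) -> list[RepeatUnit]:
    """Cut a repetitive domain into tandem repeats anchored on poly-Ala runs.

    A boundary sits at the start of each run; unit *i* spans run *i*'s start
    to run *i+1*'s start.  Residues before the first run become a leading
    partial segment (index -1, incomplete).  The final unit is incomplete.
    The concatenation of all returned unit sequences reproduces
    ``domain_seq`` exactly.
    """
    n = len(domain_seq)
    for run in runs:
        if not (0 <= run.start < run.end <= n):
            raise ValueError(f"run [{run.start},{run.end}) outside domain of length {n}")
    if not runs:
        return [RepeatUnit(index=0, start=0, end=n, sequence=domain_seq, complete=False)]

    units: list[RepeatUnit] = []
    if runs[0].start > 0:
        units.append(
            RepeatUnit(
                index=-1,
                start=0,
                end=runs[0].start,
                sequence=domain_seq[: runs[0].start],
                complete=False,
            )
        )
    boundaries = [run.start for run in runs] + [n]
    for i in range(len(runs)):
        start, end = boundaries[i], boundaries[i + 1]
        units.append(
            RepeatUnit(
                index=i,
                start=start,
                end=end,
                sequence=domain_seq[start:end],
                complete=i < len(runs) - 1,
            )
        )
    return units


def complete_units(units: list[RepeatUnit]) -> list[RepeatUnit]:
    """The repeats used in statistics: partial leading/trailing segments drop out."""
    return [u for u in units if u.complete]
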