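"""Repeat-length and motif-abundance statistics, grouped by web architecture.

Motif abundance is reported as the percentage of repeat length occupied by
the motif's residues: ``100 × count × motif_length / repeat_length``.  A
repeat of ~47 residues with 2 GP hits is therefore ~8.5% GP.  Distributions
are summarized Tukey-style: median, quartile box, whiskers at the most
extreme data values within 1.5 interquartile ranges of the box, the rest
outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MetadataTable, WEB_ARCHITECTURES
from .motifs import DEFAULT_CATALOG, MotifCatalog, RepeatProfile
from .repeats import RepeatUnit


@dataclass
class AbundanceRecord:
    sequence_id: str
    repeat_index: int
    motif: str
    count: int
    percent_of_length: float


def motif_abundance(
    profile: RepeatProfile,
    motif: str,
    sequence_id: str = "",
    catalog: MotifCatalog = DEFAULT_CATALOG,
) -> AbundanceRecord:
    """Percent of one repeat's length occupied by a motif's residues."""
    if profile.repeat_length <= 0:
        raise ValueError("repeat length must be positive")
    count = profile.counts.get(motif, 0)
    percent = 100.0 * count * catalog.motif_length(motif) / profile.repeat_length
    return AbundanceRecord(
        sequence_id=sequence_id,
        repeat_index=profile.repeat_index,
        motif=motif,
        count=count,
        percent_of_length=percent,
    )


@dataclass
class BoxSummary:
    """Five-number box-plot summary with Tukey 1.5×IQR whiskers."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)
    mean: float = 0.0


def box_summary(values: list[float]) -> BoxSummary:
    """Median, quartiles (linear interpolation), whiskers and outliers.

    Whiskers are attained data values: the most extreme observations lying
    within 1.5×IQR of the quartile box.  Values beyond are outliers.
    """
    if len(values) == 0:
        raise ValueError("cannot summarize an empty list")
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return BoxSummary(
        n=len(arr),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(v) for v in outliers),
        mean=float(arr.mean()),
    )


@dataclass
class SequenceSummary:
    """Per-sequence distribution summaries over complete tandem repeats."""

    sequence_id: str
    n_repeats: int
    repeat_length: BoxSummary
    motif_percent: dict[str, BoxSummary]
    mean_count_per_repeat: dict[str, float]


def summarize_sequence(
    units: list[RepeatUnit],
    profiles: list[RepeatProfile],
    motifs: list[str],
    sequence_id: str = "",
    catalog: MotifCatalog = DEFAULT_CATALOG,
) -> SequenceSummary:
    """Box summaries of repeat length and motif abundance for one sequence.

    Only complete repeats enter the statistics; ``units`` and ``profiles``
    must correspond one-to-one (same repeats, same order).
    """
    complete = [u for u in units if u.complete]
    if not complete or not profiles:
        raise ValueError(f"{sequence_id or '<sequence>'}: no complete repeats to summarize")
    if len(complete) != len(profiles):
        raise ValueError("units and profiles must describe the same complete repeats")
    lengths = [u.length for u in complete]
    motif_percent = {}
    mean_count = {}
    for motif in motifs:
        percents = [
            motif_abundance(rp, motif, sequence_id, catalog).percent_of_length
            for rp in profiles
        ]
        motif_percent[motif] = box_summary(percents)
        mean_count[motif] = sum(rp.counts.get(motif, 0) for rp in profiles) / len(profiles)
    return SequenceSummary(
        sequence_id=sequence_id,
        n_repeats=len(complete),
        repeat_length=box_summary(lengths),
        motif_percent=motif_percent,
        mean_count_per_repeat=mean_count,
    )


def residue_percent(units: list[RepeatUnit], residue: str) -> float:
    """Percent of complete-repeat residues equal to ``residue`` (e.g. Gln)."""
    complete = [u for u in units if u.complete]
    total = sum(u.length for u in complete)
    if total == 0:
        raise ValueError("no complete repeats")
    return 100.0 * sum(u.sequence.count(residue) for u in complete) / total


@dataclass
class GroupReport:
    """Per-architecture collection of per-sequence medians for one motif."""

    architecture: str
    motif: str
    sequence_ids: list[str]
    medians: list[float]

    @property
    def median_range(self) -> tuple[float, float]:
        return (min(self.medians), max(self.medians))


def group_by_architecture(
    summaries: list[SequenceSummary],
    metadata: MetadataTable,
    motifs: list[str],
) -> list[GroupReport]:
    """Group per-sequence motif medians by web architecture.

    Groups are ordered orb, cobweb, sheet, none, unknown; sequences absent
    from the metadata fall into ``unknown``.  Empty groups are omitted.
    """
    by_arch: dict[str, list[SequenceSummary]] = {a: [] for a in WEB_ARCHITECTURES}
    for summary in summaries:
        by_arch[metadata.architecture(summary.sequence_id)].append(summary)
    reports: list[GroupReport] = []
    for arch in WEB_ARCHITECTURES:
        members = by_arch[arch]
        if not members:
            continue
        for motif in motifs:
            reports.append(
                GroupReport(
                    architecture=arch,
                    motif=motif,
                    sequence_ids=[s.sequence_id for s in members],
                    medians=[s.motif_percent[motif].median for s in members],
                )
            )
    return reports
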