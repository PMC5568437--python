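"""End-to-end analysis of single records: segmentation → scan → profile → label.

This is the glue the command-line interface, the examples and the tests
all share.  One :class:`RecordAnalysis` carries every intermediate product
for a record, so downstream consumers (classification, quantification,
consensus matching) never recompute the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import ConsensusMatch, SpidroinClass, classify, match_araneidae_consensus
from .io import SequenceRecord
from .motifs import (
    DEFAULT_CATALOG,
    MotifCatalog,
    RepeatProfile,
    SequenceProfile,
    profile_repeat,
    profile_sequence,
    scan_motifs,
)
from .repeats import (
    DomainAnnotation,
    NonRepetitiveError,
    PolyAlaRun,
    RepeatUnit,
    delimit_repetitive_domain,
    find_polyala_runs,
    segment_repeats,
)


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the pipeline, with their defaults."""

    theta: float = 1 / 3
    min_seed: int = 3
    min_total: int = 4
    flank_max: int = 60
    max_mismatch: int = 3
    strict_ggy: bool = False
    catalog: MotifCatalog = field(default_factory=MotifCatalog)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "min_seed": self.min_seed,
            "min_total": self.min_total,
            "flank_max": self.flank_max,
            "max_mismatch": self.max_mismatch,
            "strict_ggy": self.strict_ggy,
            "x_alphabet": "".join(sorted(self.catalog.x_alphabet)),
            "doublets": list(self.catalog.doublets),
            "precedence": list(self.catalog.precedence),
        }


@dataclass
class RecordAnalysis:
    """Every pipeline product for one sequence record."""

    record: SequenceRecord
    domain: DomainAnnotation | None = None
    runs: list[PolyAlaRun] = field(default_factory=list)
    units: list[RepeatUnit] = field(default_factory=list)
    complete_profiles: list[RepeatProfile] = field(default_factory=list)
    sequence_profile: SequenceProfile | None = None
    classification: SpidroinClass | None = None
    consensus_matches: list[ConsensusMatch] = field(default_factory=list)
    skipped_reason: str | None = None

    @property
    def architecture_ok(self) -> bool:
        """Canonical MaSp layout: ≥2 poly-Ala runs and ≥1 complete repeat."""
        return len(self.runs) >= 2 and any(u.complete for u in self.units)

    @property
    def complete_units(self) -> list[RepeatUnit]:
        return [u for u in self.units if u.complete]

    @property
    def domain_sequence(self) -> str:
        assert self.domain is not None
        return self.record.residues[self.domain.repetitive_start : self.domain.repetitive_end]


def analyze_record(
    record: SequenceRecord,
    config: AnalysisConfig | None = None,
    user_bounds: tuple[int, int] | None = None,
) -> RecordAnalysis:
    """Run the full per-record pipeline; never raises on nonrepetitive input.

    A record without poly-Ala anchors (and without user domain bounds) is
    returned with ``skipped_reason`` set and ``classification`` equal to
    nonconforming, so survey-style batch runs keep going.
    """
    config = config or AnalysisConfig()
    analysis = RecordAnalysis(record=record)
    whole_runs = find_polyala_runs(record.residues, config.min_seed, config.min_total)
    try:
        analysis.domain = delimit_repetitive_domain(
            record, whole_runs, user_bounds=user_bounds, flank_max=config.flank_max
        )
    except NonRepetitiveError as exc:
        analysis.skipped_reason = str(exc)
        analysis.classification = classify(
            _EMPTY_PROFILE, architecture_ok=False, strict_ggy=config.strict_ggy
        )
        return analysis
    start = analysis.domain.repetitive_start
    domain_seq = analysis.domain_sequence
    if analysis.domain.source == "auto":
        # the auto domain contains every detected run by construction
        analysis.runs = [r.shifted(-start) for r in whole_runs]
    else:
        # user bounds may truncate runs: re-detect inside the chosen window
        analysis.runs = find_polyala_runs(domain_seq, config.min_seed, config.min_total)
    analysis.units = segment_repeats(domain_seq, analysis.runs)
    analysis.complete_profiles = [
        profile_repeat(scan_motifs(u.sequence, config.catalog), u.length, u.index)
        for u in analysis.complete_units
    ]
    if analysis.complete_profiles:
        analysis.sequence_profile = profile_sequence(
            analysis.complete_profiles, theta=config.theta, sequence_id=record.id
        )
        analysis.classification = classify(
            analysis.sequence_profile,
            architecture_ok=analysis.architecture_ok,
            strict_ggy=config.strict_ggy,
        )
    else:
        analysis.skipped_reason = "no complete repeats"
        analysis.classification = SpidroinClass(label="nonconforming", evidence=[])
    analysis.consensus_matches = match_araneidae_consensus(
        domain_seq, analysis.runs, max_mismatch=config.max_mismatch
    )
    return analysis


# sentinel used only for the nonrepetitive short-circuit above
from .motifs import SequenceProfile as _SP  # noqa: E402

_EMPTY_PROFILE = _SP(
    sequence_id="",
    n_complete_repeats=0,
    occurrence_fraction={},
    mean_count_per_repeat={},
    present_set=frozenset(),
    conserved_set=frozenset(),
    theta=1 / 3,
)


def analyze_records(
    records: list[SequenceRecord],
    config: AnalysisConfig | None = None,
    bounds_lookup=None,
) -> list[RecordAnalysis]:
    """Analyze a batch; ``bounds_lookup(id)`` may supply per-record domain bounds."""
    config = config or AnalysisConfig()
    out = []
    for record in records:
        user_bounds = bounds_lookup(record.id) if bounds_lookup else None
        out.append(analyze_record(record, config, user_bounds=user_bounds))
    return out
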