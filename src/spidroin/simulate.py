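"""Synthetic spidroin generator with planted, recoverable ground truth.

Sequences follow the canonical major-ampullate architecture: tandem
repeats of a poly-alanine run (6–9 Ala by default, occasionally carrying a
single G/S/V interruption) followed by a Gly-rich region assembled by
sampling catalog motifs (GX, GGX, QQ, SS) by weight until a target length
is reached.  A closing poly-Ala anchor terminates the last Gly-rich region
so that every planted repeat is recovered as a *complete* unit by
anchor-based segmentation.

Juxtaposition guards keep the planted composition exact: whenever two
sampled pieces would fuse into a longer homopolymer run (e.g. GQ followed
by QQ), or a Gly-rich region would end in Ala right before the next
poly-Ala run, a neutral linker residue is inserted.  Linkers are drawn
from non-Gly, non-Ala residues so they can never seed a motif themselves.
At zero substitution noise the motif scanner therefore recovers the
planted counts exactly, and segmentation recovers the planted boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import MetadataTable, SequenceRecord, write_fasta, write_table
from .motifs import DEFAULT_CATALOG, scan_motifs

#: amino acids used for substitution noise; Ala excluded by default so the
#: poly-Ala anchors (and hence segmentation ground truth) stay well defined
NOISE_ALPHABET = tuple(sorted(set("CDEFGHIKLMNPQRSTVWY")))
NOISE_ALPHABET_FREE = tuple(sorted(set("ACDEFGHIKLMNPQRSTVWY")))

INTERRUPTION_CHOICES = ("G", "S", "V")

#: canonical motif repertoires used for panels (weights are relative rates)
MASP1_WEIGHTS = {"GGY": 3.0, "GA": 2.0, "GQ": 2.0, "GS": 1.0}
MASP2_WEIGHTS = {"GP": 4.0, "QQ": 2.0, "GGY": 2.0, "GS": 1.0}
#: Tetragnatha-like pattern: di-glutamine without proline
INTERMEDIATE_WEIGHTS = {"QQ": 2.0, "GGY": 2.0, "GS": 2.0, "GGL": 1.0, "GQ": 1.0}


@dataclass
class SimulationSpec:
    """Generating parameters for one synthetic spidroin."""

    n_repeats: int = 10
    polyala_lengths: dict[int, float] | None = None  # default: uniform over 6..9
    interruption_prob: float = 0.1
    motif_weights: dict[str, float] = field(default_factory=lambda: dict(MASP2_WEIGHTS))
    glyrich_length: int = 25
    linker_residues: tuple[str, ...] = ("Y", "S")
    linker_count_weights: dict[int, float] = field(
        default_factory=lambda: {0: 0.6, 1: 0.3, 2: 0.1}
    )
    substitution_rate: float = 0.0
    free_noise: bool = False
    seed: int = 0
    class_label: str = "custom"
    id: str | None = None
    web_architecture: str = "unknown"

    def validate(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if not self.motif_weights:
            raise ValueError("motif_weights must be non-empty")
        weights = np.array(list(self.motif_weights.values()), dtype=float)
        if not np.all(np.isfinite(weights)) or np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("motif weights must be finite, non-negative, positive-sum")


@dataclass
class GroundTruth:
    """What was planted: boundaries, per-repeat counts, the intended label."""

    class_label: str
    repeat_boundaries: list[tuple[int, int]]
    motif_counts: list[Counter]
    polyala_lengths: list[int]
    interruptions: list[str | None]

    def mean_count(self, motif: str) -> float:
        return sum(c.get(motif, 0) for c in self.motif_counts) / len(self.motif_counts)


def masp1_spec(**overrides) -> SimulationSpec:
    return replace(
        SimulationSpec(motif_weights=dict(MASP1_WEIGHTS), class_label="MaSp1"),
        **overrides,
    )


def masp2_spec(**overrides) -> SimulationSpec:
    return replace(
        SimulationSpec(motif_weights=dict(MASP2_WEIGHTS), class_label="MaSp2"),
        **overrides,
    )


def intermediate_spec(**overrides) -> SimulationSpec:
    return replace(
        SimulationSpec(
            motif_weights=dict(INTERMEDIATE_WEIGHTS), class_label="intermediate"
        ),
        **overrides,
    )


def _sample_polyala_length(spec: SimulationSpec, rng: np.random.Generator) -> int:
    if spec.polyala_lengths is None:
        return int(rng.integers(6, 10))
    lengths = sorted(spec.polyala_lengths)
    probs = np.array([spec.polyala_lengths[k] for k in lengths], dtype=float)
    probs = probs / probs.sum()
    return int(lengths[rng.choice(len(lengths), p=probs)])


def _build_polyala(spec: SimulationSpec, rng: np.random.Generator) -> tuple[str, str | None]:
    """A poly-Ala run string plus its interruption residue (or None).

    Interruptions are only placed when at least three Ala remain on each
    side, so run detection merges across them and the run boundary (hence
    the planted repeat boundary) is unchanged.
    """
    n_ala = _sample_polyala_length(spec, rng)
    interrupted = rng.random() < spec.interruption_prob and n_ala >= 6
    if not interrupted:
        return "A" * n_ala, None
    residue = INTERRUPTION_CHOICES[rng.integers(0, len(INTERRUPTION_CHOICES))]
    pos = int(rng.integers(3, n_ala - 2))  # >=3 Ala on each side
    return "A" * pos + residue + "A" * (n_ala - pos), residue


def _unsafe_junction(tail: str, head: str) -> bool:
    """Would concatenating ``tail + head`` change motif parsing at the seam?"""
    if not tail or not head:
        return False
    t, h = tail[-1], head[0]
    if t == h and t in "QS":
        return True  # homopolymer run would fuse (e.g. GQ + QQ -> GQQQ)
    if t == "G":
        return True  # G + anything glycine-led or in X spawns a new motif
    return False


def _pick_linker(spec: SimulationSpec, tail: str, rng: np.random.Generator) -> str | None:
    """A single linker residue that cannot seed or extend any motif."""
    candidates = [
        c
        for c in spec.linker_residues
        if c not in "GA" and not (tail and c == tail[-1] and c in "QS")
    ]
    if not candidates:
        return None
    return candidates[int(rng.integers(0, len(candidates)))]


def _build_glyrich(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[str, Counter]:
    """Sample one Gly-rich region; returns (text, planted motif counts)."""
    labels = sorted(spec.motif_weights)
    probs = np.array([spec.motif_weights[m] for m in labels], dtype=float)
    probs = probs / probs.sum()
    n_linker_choices = sorted(spec.linker_count_weights)
    linker_probs = np.array(
        [spec.linker_count_weights[k] for k in n_linker_choices], dtype=float
    )
    linker_probs = linker_probs / linker_probs.sum()

    parts: list[str] = []
    counts: Counter = Counter()
    length = 0
    while length < spec.glyrich_length:
        motif = labels[rng.choice(len(labels), p=probs)]
        tail = parts[-1] if parts else ""
        if _unsafe_junction(tail, motif):
            guard = _pick_linker(spec, tail, rng)
            if guard is not None:
                parts.append(guard)
                length += 1
        parts.append(motif)
        counts[motif] += 1
        length += len(motif)
        n_linkers = n_linker_choices[rng.choice(len(n_linker_choices), p=linker_probs)]
        for _ in range(n_linkers):
            linker = _pick_linker(spec, parts[-1], rng)
            if linker is not None:
                parts.append(linker)
                length += 1
    # never end in Ala: a trailing GA would fuse with the next poly-Ala run
    if parts[-1][-1] == "A":
        guard = _pick_linker(spec, parts[-1], rng)
        if guard is not None:
            parts.append(guard)
    return "".join(parts), counts


def _apply_noise(residues: str, spec: SimulationSpec, rng: np.random.Generator) -> str:
    if spec.substitution_rate <= 0:
        return residues
    alphabet = NOISE_ALPHABET_FREE if spec.free_noise else NOISE_ALPHABET
    out = list(residues)
    for i, res in enumerate(out):
        if rng.random() < spec.substitution_rate:
            choices = [c for c in alphabet if c != res]
            out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def simulate_spidroin(spec: SimulationSpec) -> tuple[SequenceRecord, GroundTruth]:
    """Generate one spidroin-like sequence with known composition.

    The emitted sequence is ``n_repeats`` units of poly-Ala + Gly-rich
    region, closed by a terminal poly-Ala anchor; ground truth records the
    pre-noise per-repeat motif counts (including the GA hit contributed by
    a Gly interruption inside a run) and the planted unit boundaries.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pieces: list[str] = []
    boundaries: list[tuple[int, int]] = []
    counts_per_repeat: list[Counter] = []
    ala_lengths: list[int] = []
    interruptions: list[str | None] = []
    pos = 0
    for _ in range(spec.n_repeats):
        run, interruption = _build_polyala(spec, rng)
        glyrich, counts = _build_glyrich(spec, rng)
        if interruption == "G":
            counts = counts + Counter({"GA": 1})  # G inside A-run scans as GA
        unit = run + glyrich
        boundaries.append((pos, pos + len(unit)))
        counts_per_repeat.append(counts)
        ala_lengths.append(len(run))
        interruptions.append(interruption)
        pieces.append(unit)
        pos += len(unit)
    closing, _ = _build_polyala(spec, rng)
    pieces.append(closing)
    residues = _apply_noise("".join(pieces), spec, rng)
    record = SequenceRecord(
        id=spec.id or f"sim_{spec.class_label}_{spec.seed}",
        description=f"synthetic {spec.class_label} spidroin",
        residues=residues,
        metadata={
            "species": "synthetic",
            "family": "synthetic",
            "spidroin_label": spec.class_label,
            "web_architecture": spec.web_architecture,
        },
    )
    truth = GroundTruth(
        class_label=spec.class_label,
        repeat_boundaries=boundaries,
        motif_counts=counts_per_repeat,
        polyala_lengths=ala_lengths,
        interruptions=interruptions,
    )
    return record, truth


def embed_consensus(
    spec: SimulationSpec, an_length: int = 7
) -> tuple[SequenceRecord, GroundTruth]:
    """Generate a sequence whose every repeat carries the Araneidae consensus.

    Each poly-Ala run (length ``an_length``, 6–9) is wrapped with the exact
    14-residue upstream template GQQGPGGQGPYGP(G/S) and 10-residue
    downstream template GGYGPG(A/S)GQQ; variable GP/QQ stretches separate
    the cores.  At zero noise every interior run matches the consensus at
    zero mismatches.  Ground-truth counts are tallied per segmented unit
    (run start to run start) from the constructed unit text.
    """
    spec.validate()
    if not 6 <= an_length <= 9:
        raise ValueError("an_length must be between 6 and 9")
    rng = np.random.default_rng(spec.seed)

    def upstream() -> str:
        return "GQQGPGGQGPYGP" + ("G" if rng.random() < 0.5 else "S")

    def downstream() -> str:
        return "GGYGPG" + ("A" if rng.random() < 0.5 else "S") + "GQQ"

    def spacer() -> str:
        parts: list[str] = []
        for _ in range(int(rng.integers(1, 5))):
            motif = "GP" if rng.random() < 0.6 else "QQ"
            if parts and _unsafe_junction(parts[-1], motif):
                parts.append("Y")
            parts.append(motif)
        return "".join(parts)

    pieces: list[str] = [upstream()]
    run_starts: list[int] = []
    pos = len(pieces[0])
    for i in range(spec.n_repeats):
        run_starts.append(pos)
        core = "A" * an_length + downstream()
        tail = spacer()
        nxt = upstream()
        if _unsafe_junction(tail, nxt):
            tail += "Y"
        if i < spec.n_repeats - 1:
            piece = core + tail + nxt
        else:
            piece = core + tail + "GQQGPGGQGPYGPG"  # closing anchor flank
        pieces.append(piece)
        pos += len(piece)
    pieces.append("A" * an_length)  # closing poly-Ala anchor
    residues = _apply_noise("".join(pieces), spec, rng)

    full = "".join(pieces)
    boundaries = [
        (run_starts[i], run_starts[i + 1] if i + 1 < len(run_starts) else pos)
        for i in range(len(run_starts))
    ]
    counts = [
        Counter(h.motif for h in scan_motifs(full[s:e], DEFAULT_CATALOG))
        for s, e in boundaries
    ]
    record = SequenceRecord(
        id=spec.id or f"sim_consensus_{spec.seed}",
        description="synthetic Araneidae-consensus MaSp2 spidroin",
        residues=residues,
        metadata={
            "species": "synthetic",
            "family": "synthetic",
            "spidroin_label": "MaSp2",
            "web_architecture": spec.web_architecture,
        },
    )
    truth = GroundTruth(
        class_label="MaSp2",
        repeat_boundaries=boundaries,
        motif_counts=counts,
        polyala_lengths=[an_length] * spec.n_repeats,
        interruptions=[None] * spec.n_repeats,
    )
    return record, truth


def derive_seed(panel_seed: int, index: int) -> int:
    """Deterministic per-record seed below 2**31."""
    return int(np.random.SeedSequence([panel_seed, index]).generate_state(1)[0] % (2**31))


def simulate_panel(
    specs: list[SimulationSpec],
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[SequenceRecord], list[GroundTruth]]:
    """Generate a panel of synthetic spidroins with metadata and truth tables.

    Per-record seeds derive deterministically from the panel seed, so a
    rerun with the same seed reproduces the files byte for byte.  When
    ``out_dir`` is given, writes ``panel.fasta``, ``metadata.tsv`` and
    ``truth.tsv`` there.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    records: list[SequenceRecord] = []
    truths: list[GroundTruth] = []
    seen: set[str] = set()
    for i, spec in enumerate(specs):
        child = replace(spec, seed=derive_seed(seed, i))
        if child.id is None:
            child = replace(child, id=f"sim{i:03d}_{child.class_label}")
        if child.id in seen:
            raise ValueError(f"duplicate synthetic sequence id {child.id!r}")
        seen.add(child.id)
        record, truth = simulate_spidroin(child)
        records.append(record)
        truths.append(truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "panel.fasta")
        meta_rows = [
            {
                "id": r.id,
                "species": r.metadata["species"],
                "family": r.metadata["family"],
                "spidroin_label": r.metadata["spidroin_label"],
                "web_architecture": r.metadata["web_architecture"],
            }
            for r in records
        ]
        write_table(meta_rows, out_dir / "metadata.tsv")
        truth_rows = []
        for record, truth in zip(records, truths):
            for j, (bounds, counts) in enumerate(
                zip(truth.repeat_boundaries, truth.motif_counts)
            ):
                truth_rows.append(
                    {
                        "id": record.id,
                        "class_label": truth.class_label,
                        "repeat_index": j,
                        "start": bounds[0],
                        "end": bounds[1],
                        "counts": ";".join(
                            f"{m}={c}" for m, c in sorted(counts.items())
                        ),
                    }
                )
        write_table(truth_rows, out_dir / "truth.tsv")
    return records, truths


def panel_metadata(records: list[SequenceRecord]) -> MetadataTable:
    """An in-memory MetadataTable for a simulated panel."""
    return MetadataTable(
        rows={
            r.id: {
                "species": r.metadata.get("species", "synthetic"),
                "family": r.metadata.get("family", "synthetic"),
                "spidroin_label": r.metadata.get("spidroin_label", ""),
                "web_architecture": r.metadata.get("web_architecture", "unknown"),
            }
            for r in records
            if r.metadata
        }
    )
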