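# Methods

## The model

Major ampullate spidroins carry a long central repetitive domain organized
as tandem repeats of a poly-alanine run followed by a glycine-rich region.
This package treats the short amino-acid motifs of the Gly-rich regions as
discrete, countable units and derives everything else — conserved-motif
profiles, MaSp1/MaSp2 classification, the Araneidae consensus match, and
abundance statistics — from explicit, deterministic rules over those
units.  No alignment is performed anywhere: segmentation is anchor-based
and motif assignment is rule-based, which makes every result reproducible
to the byte.

## Poly-Ala detection and repeat segmentation

A poly-Ala *seed* is a maximal run of ≥ `min_seed` (default 3) contiguous
alanines.  Two seeds separated by exactly one residue from {G, S, V} are
merged, recording the interruption; merging chains.  Merged runs shorter
than `min_total` (default 4) residues, or with < 75% alanine, are
discarded.  These tolerances accept the canonical 6–9-Ala anchors with
occasional single interruptions while rejecting (GA)ₙ stretches, which are
a distinct flanking element, not an anchor.

The repetitive domain is either supplied by the user (metadata columns
`rep_start`/`rep_end`, 1-based inclusive — deposited database entries
usually state their repetitive region) or delimited automatically as the
span from the first to the last run extended by at most `flank_max`
(default 60) residues each way.

Repeat boundaries sit at the **start** of each poly-Ala run: the run is
the only anchor conserved across all taxa, so unit *i* spans run *i*'s
start to run *i+1*'s start.  Residues before the first run form a leading
partial segment; the final unit is likewise partial.  Both are flagged
incomplete and excluded from every statistic, so counts refer to *complete
tandem repeats* only.  Published repeat-length figures that used a
different (unstated) boundary convention can differ from ours by a small
constant offset; comparisons against such numbers should allow ±2
residues.  Coordinates are 0-based half-open throughout.

## Motif scanning

The catalog comprises GX and GGX (X ∈ {A, S, Y, Q, D, R, P, N, L, F};
G is excluded from X so GG/GGG can never self-match) plus the doublets QQ
and SS.  Assignments are mutually exclusive; precedence resolves overlaps
in three left-to-right passes:

1. **Doublets.**  QQ and SS are tiled greedily from the left end of each
   maximal homopolymer run, so QQQ yields one QQ and QQQQ yields two.
   This pass runs first, extending the doublet-over-GQ/GS rule to GGQ as
   well: a GGQQ context yields QQ and leaves the orphaned GG unassigned.
2. **GGX** at any position whose three residues are all unassigned.
3. **GX** on remaining unassigned pairs.

Ambiguity codes (X/B/Z) never match.  Motifs are scanned across the full
repeat unit, poly-Ala run included: run interiors contain no glycine and
cannot spawn motifs, while genuine GA hits at run boundaries are real
(GA)ₙ-type elements and are counted.  The pass order is configurable via
`MotifCatalog.precedence`.

A motif is **conserved** in a sequence when its occurrence fraction over
complete repeats is ≥ θ.  The default θ = 1/3 is the weakest recurrence
level treated as a profile feature — one hit per three repeats — chosen so
that a genuinely regular but sparse motif (the sheet-web-spider GP case)
still registers, while a single hit in a long array does not.  θ is
exposed everywhere (`--theta`).

## Classification and consensus

Cross-sequence consensus profiles are the strict intersection of member
conserved sets (the per-motif member fractions are kept alongside, so
majority structure is not lost).  Classification is a pure function of
the conserved set plus an architecture gate:

- no canonical architecture (< 2 poly-Ala runs or no complete repeat) →
  **nonconforming**;
- QQ and GP conserved → **MaSp2**;
- no QQ, GGY-equivalent conserved → **MaSp1** (GGF is accepted as a
  GGY-equivalent by default; `--strict-ggy` disables this);
- QQ without GP → **intermediate** (the *Tetragnatha*-type pattern);
- anything else → intermediate with evidence "no diagnostic motifs".

Note that proline alone is deliberately not diagnostic: a GP-rich sequence
without conserved QQ classifies as MaSp1 (the ADF4 situation).

The Araneidae MaSp2 consensus matcher compares, for every run of 6–9
residues with sufficient flanks, the 14-mer immediately upstream against
`GQQGPGGQGPYGP[G/S]` and the 10-mer immediately downstream against
`GGYGPG[A/S]GQQ`, counting positionwise mismatches (bracket positions
accept either residue).  A run matches when total mismatches ≤
`max_mismatch` (default 3 of the 24 templated positions).  The budget is a
free parameter, not an empirical claim: real cross-species flanks are
well conserved but not identical, and 3 admits a few substitutions while
keeping random Gly-rich sequence far from matching.

## Quantification

Motif abundance per repeat is `100 × count × motif_length /
repeat_length` — the percentage of the repeat literally occupied by the
motif's residues (2 GP hits on a 47-residue repeat ≈ 8.5%).  Distributions
are summarized with median, quartiles by linear interpolation between
order statistics (the common box-plot default; tie-breaking differs
between quartile conventions only at small n), whiskers at the most
extreme data values within 1.5×IQR of the box, and outliers beyond.
Statistics pool complete repeats within a sequence; grouping by web
architecture collects per-sequence medians and reports their range per
group, ordered orb, cobweb, sheet, none, unknown.

## The synthetic generator

`simulate_spidroin` emulates the canonical architecture: each repeat is a
poly-Ala run (length uniform on 6–9 by default; with probability 0.1 a
single G/S/V interruption is inserted, placed ≥ 3 Ala from either end so
run detection still merges across it) followed by a Gly-rich region built
by sampling catalog motifs i.i.d. by weight until a 25-residue target is
reached.  A closing poly-Ala anchor terminates the sequence so all
`n_repeats` planted units are recovered as complete repeats.  Default
repertoires: MaSp1 = GGY:3, GA:2, GQ:2, GS:1; MaSp2 = GP:4, QQ:2, GGY:2,
GS:1; intermediate = QQ:2, GGY:2, GS:2, GGL:1, GQ:1.

Ground truth must remain exact under the scanner's precedence rules, so
emission is guarded: when two sampled pieces would fuse into a longer
homopolymer run (GQ followed by QQ), a neutral linker is inserted, and a
Gly-rich region never ends in Ala (a trailing GA would fuse with the next
anchor and shift the planted boundary).  Linkers are drawn from {Y, S}
with occasional 0–2-residue spacers (probabilities 0.6/0.3/0.1 for
0/1/2): glycine is excluded from the linker pool because a lone G
preceding any sampled motif or linker would itself seed a GX/GGX hit and
corrupt the planted counts.  A G-type run interruption scans as one GA
hit; the ground truth accounts for it.  Substitution noise is applied
last, per residue, from an alphabet that excludes alanine by default (so
segmentation truth stays well defined; `free_noise` lifts this); planted
counts always refer to the pre-noise sequence.

`embed_consensus` is the structured alternative: every run is wrapped with
the exact consensus flank templates (bracket positions sampled), separated
by variable GP/QQ stretches, so at zero noise every interior run matches
at 0 mismatches.  Its per-repeat truth counts are tallied from the
constructed unit text.

Per-record panel seeds derive from the panel seed via
`numpy.random.SeedSequence`, making panels byte-reproducible.

**What the synthetic benchmarks do and do not show.**  They demonstrate
that segmentation, scanning, profiling, classification and quantification
are internally correct and exactly invert the generator at zero noise, and
that they degrade gracefully under point substitutions.  They do not
emulate concerted-evolution homogenization, positional motif grammar
within Gly-rich regions (motifs are i.i.d. in the null generator),
repeat-length autocorrelation, or sequencing/assembly artifacts of real
database entries — conclusions about real spidroins still require real
sequences (e.g. via `scripts/extended_accessions.py`).

## Numerical and interface choices

- Residues are uppercased on input; whitespace/digits stripped; one
  trailing `*` stop permitted; characters outside the amino-acid alphabet
  rejected.  Metadata is a sidecar TSV, never parsed from FASTA headers.
- Tabular output has deterministic column order and 4-decimal floats.
- Degenerate inputs: a sequence with no poly-Ala anchor and no user bounds
  is reported nonconforming and skipped with a warning rather than
  aborting a batch; zero complete repeats is an error for profiling and
  quantification primitives but a logged skip in the batch pipeline.
- CLI exit codes: 0 success, 1 usage error, 2 empty/invalid input.  Every
  run echoes its configuration (`config.json`) and a log into the output
  directory.
- Problem sizes in the test-suite and acceptance benchmarks (panels of
  5–20 sequences, 10–40 repeats each) were chosen as the smallest sizes at
  which occurrence fractions and medians are stable; all complete in
  seconds.

## Known limitations

- The conservation threshold θ and the consensus mismatch budget are
  tunables; published by-eye profiles may correspond to slightly different
  implicit values.
- GP counting at GPGXX boundaries follows the scanner's precedence passes;
  a manual tally could differ at such junctions.
- Basal-clade (Hypochilidae/Haplogynae) repeat architectures fall outside
  the MaSp1/MaSp2 criteria and will generally classify as intermediate or
  nonconforming by design.
- Multi-variant species are pooled by default when grouping; pass separate
  metadata labels to keep variants apart.
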