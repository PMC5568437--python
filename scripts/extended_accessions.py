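#!/usr/bin/env python
"""Extended analysis of published MaSp repetitive-domain sequences.

This script reproduces the accession-based summaries (repeat counts,
repeat-length medians, GP percent-of-repeat distributions, Gln abundance)
on real spidroin sequences.  It takes a local FASTA of repetitive-domain
protein sequences — for example the GenBank entries U47855 (A. diadematus
ADF4), AM490169 (E. australis MaSp2), EF595245 (L. hesperus MaSp2),
M37137/M92913 (N. clavipes MaSp1/MaSp2) and JX202781 (A. bruennichi
MaSp2), which the user downloads separately — plus an optional metadata
TSV with rep_start/rep_end columns (1-based inclusive) delimiting the
reported repetitive region.

Usage:
    python scripts/extended_accessions.py sequences.fasta \
        [--metadata meta.tsv] [--out results/extended.json]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from spidroin.io import read_fasta, read_metadata
from spidroin.pipeline import AnalysisConfig, analyze_record
from spidroin.quantify import residue_percent, summarize_sequence


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("fasta", type=Path)
    parser.add_argument("--metadata", type=Path, default=None)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    metadata = read_metadata(args.metadata) if args.metadata else None
    config = AnalysisConfig()
    results: dict = {}
    for record in read_fasta(args.fasta):
        bounds = metadata.domain_bounds(record.id) if metadata else None
        analysis = analyze_record(record, config, user_bounds=bounds)
        if not analysis.complete_profiles:
            results[record.id] = {"skipped": analysis.skipped_reason}
            continue
        summary = summarize_sequence(
            analysis.units, analysis.complete_profiles, ["GP", "QQ", "GGY"], record.id
        )
        domain = analysis.domain
        results[record.id] = {
            "repetitive_length": domain.repetitive_end - domain.repetitive_start,
            "n_complete_repeats": summary.n_repeats,
            "median_repeat_length": summary.repeat_length.median,
            "median_gp_percent": round(summary.motif_percent["GP"].median, 2),
            "mean_gp_per_repeat": round(summary.mean_count_per_repeat["GP"], 2),
            "median_qq_percent": round(summary.motif_percent["QQ"].median, 2),
            "median_ggy_percent": round(summary.motif_percent["GGY"].median, 2),
            "gln_percent_of_repeat_residues": round(
                residue_percent(analysis.units, "Q"), 2
            ),
            "classification": analysis.classification.label,
        }
    text = json.dumps(results, indent=2)
    if args.out:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        args.out.write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
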