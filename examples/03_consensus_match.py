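"""Match poly-Ala flanks against the Araneidae MaSp2 consensus under noise.

Embeds the exact consensus around every poly-Ala run, then adds increasing
substitution noise and reports how many runs still match within the
3-mismatch budget across their 24 templated flank positions.
"""

from spidroin import analyze_record, embed_consensus, masp2_spec

for rate in (0.0, 0.05, 0.15, 0.30):
    spec = masp2_spec(n_repeats=20, seed=11, substitution_rate=rate)
    record, _ = embed_consensus(spec, an_length=7)
    analysis = analyze_record(record)
    eligible = [m for m in analysis.consensus_matches if m.eligible]
    matched = sum(m.matched for m in eligible)
    print(f"noise {rate:.2f}: {matched}/{len(eligible)} runs match the consensus")

print(
    "\nA perfectly embedded consensus matches every run at 0 mismatches;\n"
    "the matched fraction decays as point substitutions accumulate in the\n"
    "14-residue upstream and 10-residue downstream flanks."
)
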