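"""Scan the Araneidae MaSp2 consensus core for short motifs.

Instantiates the ~32-residue consensus GQQGPGGQGPYGP(G/S)A_n GGYGPG(A/S)GQQ
with a 7-alanine run and tallies the motif hits the precedence scanner
assigns.  The GP percent-of-length is the abundance statistic used
throughout the package.
"""

from collections import Counter

from spidroin import instantiate_consensus, scan_motifs

core = instantiate_consensus(an_length=7)
counts = Counter(h.motif for h in scan_motifs(core))

print(f"consensus core ({len(core)} residues): {core}")
print(f"motif counts: {dict(sorted(counts.items()))}")
gp_percent = 100 * counts["GP"] * 2 / len(core)
print(f"GP occupies {gp_percent:.1f}% of the core length")
print(
    "Four GP and two QQ hits on a 31-residue repeat are the archetypal\n"
    "proline/di-glutamine signature of an orb-weaver MaSp2 tandem repeat."
)
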