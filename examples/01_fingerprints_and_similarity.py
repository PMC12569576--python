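"""Circular fingerprints, bit tracing and Tanimoto similarity.

Fingerprints hash every atom-centered environment up to a radius into a bit
vector; keeping the bit -> (atom, radius) map is what later lets us point a
model coefficient at a concrete substructure.
"""

from precursorpred import FingerprintConfig, circular_fingerprint, tanimoto

cfg = FingerprintConfig(radius=2, n_bits=2048)
quinine_core = "c1ccc2ncccc2c1"      # quinoline ring system
indole = "c1ccc2[nH]ccc2c1"

fp_q = circular_fingerprint(quinine_core, cfg)
fp_i = circular_fingerprint(indole, cfg)

print(f"quinoline: {len(fp_q.bits)} on-bits; indole: {len(fp_i.bits)} on-bits")
print(f"Tanimoto(quinoline, indole) = {tanimoto(fp_q, fp_i):.3f}")

bit = sorted(fp_q.bits)[0]
print(f"bit {bit} traces to environments {fp_q.bit_info[bit]} (atom index, radius)")
# A similarity well below 1 shows the two alkaloid ring systems share some
# aromatic environments but are clearly distinguishable to the model.
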