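"""Charge composition, unique acidic residues and disorder overlap.

Simulates an 818-residue halophilic polymerase-like sequence (17% D+E vs
11% R+K, ~30% disordered, acidic residues enriched in the disordered
segments), profiles its charge, and maps a toy alignment example.
"""

from halopol.seqprofile import (
    AlignedPair,
    SequenceRecord,
    charge_composition,
    disorder_overlap,
    hydrophobic_classes,
    unique_acidic_positions,
)
from halopol.synthetic_data import SequenceSimParams, simulate_sequence

sim = simulate_sequence(SequenceSimParams(acidic_enrichment_in_disorder=0.6, seed=3))
cc = charge_composition(sim.record)
hc = hydrophobic_classes(sim.record)
print(f"sequence {sim.record.id}: {len(sim.record)} aa")
print(f"acidic (D+E) {cc.pct_acidic:.1f}%   basic (R+K) {cc.pct_basic:.1f}%   "
      f"neg/pos ratio {cc.ratio_neg_pos:.2f}")
print(f"bulky hydrophobics (F,I,L) {hc.pct_bulky:.1f}%   small (G,A,S,T) {hc.pct_small:.1f}%")
print("(a neg/pos ratio well above 1 is the classic halophilic surface signature)")

positions = [(p["position"], p["tag"]) for p in sim.truth["acidic_positions"]]
ov = disorder_overlap(positions, sim.disorder)
print(f"\nacidic residues in predicted-disordered regions: {ov.pct_overall:.0f}% "
      f"(Asp {ov.pct_by_tag['D']:.0f}%, Glu {ov.pct_by_tag['E']:.0f}%)")

pair = AlignedPair.from_gapped("DAKEE-D", "DAKQENN")
unique = unique_acidic_positions(pair, SequenceRecord("halophile", "DAKEED"),
                                 SequenceRecord("mesophile", "DAKQENN"))
print(f"\nacidic positions unique to the halophile vs the homolog: {unique}")
print("(positions whose D/E has no acidic counterpart in the aligned homolog)")
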