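"""Derive the 4-thiouridine adduct and retained-stub mass tables.

Prints the eight stub masses that can remain on peptide fragment ions after
gas-phase cleavage of a crosslinked nucleotide, and the precursor mass deltas
of the six single-nucleotide 4tU adduct states.  All values are computed from
molecular formulas and a central atomic-mass table.
"""

from trappkit import enumerate_targeted_adducts, retention_fragment_set

print("Retained fragment (stub) masses, Da:")
for stub in retention_fragment_set():
    print(f"  {stub.label:18s} {stub.mass:12.6f}")

print("\nSingle-nucleotide 4tU adduct precursor deltas, Da:")
for adduct in enumerate_targeted_adducts(max_len=1, alphabet=("4tU",)):
    print(f"  {adduct.label:18s} {adduct.precursor_mass:12.6f}")

print(
    "\nA peptide crosslinked to one of these adducts gains the precursor delta"
    "\nat MS1; its fragment ions carry either nothing, the full adduct, or one"
    "\nof the stub masses."
)
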