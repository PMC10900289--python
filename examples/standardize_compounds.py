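"""Standardize a handful of drug-like SMILES to their pH-7.4 form.

Each input is cleaned up (salt stripping, neutralization, tautomer
canonicalization) until the canonical SMILES stops changing, then
protonated to its dominant ionization state at physiological pH.
The standard InChI printed last is the key used to match compounds
across datasets.
"""

from dictox import standardize_compound, match_key

INPUTS = [
    "CC(=O)Oc1ccccc1C(=O)O",   # aspirin: carboxylic acid
    "CN1CCC[C@H]1c1cccnc1",    # nicotine: aliphatic amine + pyridine
    "CC(=O)[O-].[Na+]",        # sodium acetate: salt form
    "C(C)O",                   # ethanol, non-canonical spelling
]

for smiles in INPUTS:
    std = standardize_compound(smiles)
    print(f"{smiles:28s} -> {std.std_smiles:32s} "
          f"(iterations={std.n_iterations}, converged={std.converged})")

key = match_key(standardize_compound("CC(=O)O"))
print(f"\nmatch key for acetic acid: {key}")
print("Acidic groups appear deprotonated and basic amines protonated —")
print("the ionization state the compounds would carry in plasma at pH 7.4.")
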