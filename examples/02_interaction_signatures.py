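"""Score compounds against a protein's predicted binding sites.

The interaction score is max over sites of BScore x Dice(ECFP4 compound,
ECFP4 site ligand): site confidence weighted by chemical similarity to
the site's co-crystallized ligand.  Requires RDKit.
"""

from toxsig.chem import standardize_compound
from toxsig.signatures import (
    BindingSite,
    ProteinEntry,
    dice_similarity,
    ecfp4_fingerprint,
    interaction_score,
)

aspirin = standardize_compound("CC(=O)Oc1ccccc1C(=O)O")
salicylic = standardize_compound("O=C(O)c1ccccc1O")
caffeine = standardize_compound("Cn1cnc2c1c(=O)n(C)c(=O)n2C")
print("canonical aspirin:", aspirin.canonical_smiles)
print("salt is rejected:", standardize_compound("CCO.Cl").reason)

fp_a = ecfp4_fingerprint(aspirin.canonical_smiles)
fp_s = ecfp4_fingerprint(salicylic.canonical_smiles)
fp_c = ecfp4_fingerprint(caffeine.canonical_smiles)
print(f"Dice(aspirin, salicylic acid) = {dice_similarity(fp_a, fp_s):.3f}")
print(f"Dice(aspirin, caffeine)      = {dice_similarity(fp_a, fp_c):.3f}")

# a protein with two predicted sites: a confident site whose ligand is
# salicylic acid, and a weak site whose ligand is caffeine
protein = ProteinEntry(
    "P_DEMO",
    sites=[BindingSite(bscore=0.9, ligand_fp=fp_s),
           BindingSite(bscore=0.4, ligand_fp=fp_c)],
)
print(f"interaction score(aspirin, P_DEMO) = {interaction_score(fp_a, protein):.3f}")
# The score follows the confident salicylate site: structurally related
# compounds with a trusted site prediction score high; unrelated ones near 0.
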