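"""Exact-mass arithmetic for the B. brevis nonribosomal peptides.

Computes the neutral monoisotopic masses of britacidin A (a 17-residue,
formyl/ethanolamide-capped gramicidin analog) and tyrocidine A (a cyclic
decapeptide), the five positive-mode adduct m/z values of britacidin A,
and the heme B marker ion used to locate the nitrogen-fixation zone.
"""

import nodmet as nm
from nodmet.peptide import BRITACIDIN_A, TYROCIDINE_A

M = nm.peptide_neutral_mass(BRITACIDIN_A)
print(f"britacidin A  neutral monoisotopic mass: {M:.4f} Da")
for name in ["M+H", "M+2H", "M+H+Na", "M+2Na", "M+Na"]:
    a = nm.NAMED_ADDUCTS[name]
    print(f"  {a.name:<12} m/z {nm.adduct_mz(M, a):.4f}")

Mt = nm.peptide_neutral_mass(TYROCIDINE_A)
print(f"tyrocidine A  neutral mass {Mt:.4f} Da, "
      f"[M+H]+ {nm.adduct_mz(Mt, nm.NAMED_ADDUCTS['M+H']):.2f}, "
      f"[M+2H]2+ {nm.adduct_mz(Mt, nm.NAMED_ADDUCTS['M+2H']):.2f}")

heme = nm.parse_formula("C34H32FeN4O4")
print(f"heme B [M]+.  m/z {nm.formula_mz(heme, z=1, n_electrons_removed=1):.1f}")

# The adduct m/z values are what an Orbitrap in positive mode reports for
# one molecule ionised five different ways; matching them against measured
# features identifies all five as the same compound.
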