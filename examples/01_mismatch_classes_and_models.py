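"""Classify mother-offspring genotype pairs and enumerate the 11 models.

A bi-allelic locus with minor allele A gives seven Mendelian-consistent
mother-offspring genotype combinations; the four mismatched ones (M1-M4) are
the candidate carriers of an incompatibility effect.  Each incompatibility
model declares a subset of them "high risk".
"""

import numpy as np

from mfgi import classify_pair, classify_pairs, code_incompatibility, get_model, standard_models

print("Classification of every genotype combination (mother, offspring):")
for g_m in (2, 1, 0):
    row = [classify_pair(g_m, g_o).name for g_o in (2, 1, 0)]
    print(f"  mother {g_m}: {row}")

print("\nThe 11 incompatibility models:")
for m in standard_models():
    classes = "+".join(sorted(c.name for c in m.risk_classes))
    print(f"  Model {m.model_id:>2}  {{{classes:<11}}}  {m.description}")

# Coding the incompatibility indicator for a handful of families
g_m = np.array([2, 1, 1, 0, 0])
g_o = np.array([1, 2, 1, 1, 0])
cls = classify_pairs(g_m, g_o)
from mfgi import PairClass
print("\nFamilies (Gm, Go):", [(int(m), int(o)) for m, o in zip(g_m, g_o)])
print("Classes:          ", [PairClass(c).name for c in cls])
for mid in (1, 5, 11):
    print(f"G_ic under Model {mid:>2}:", code_incompatibility(get_model(mid), cls).tolist())
# Model 1 marks only the (AA, Aa) family; Model 11 marks every mismatch.
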