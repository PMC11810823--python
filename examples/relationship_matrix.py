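"""Numerator relationship matrix A and its sparse inverse from a pedigree.

A small worked pedigree: a sire mated to two dams, a half-sib pair, and an
inbred full-sib mating, showing the classic coefficients (0.5
parent-offspring, 0.25 half sibs, diagonal 1 + F).
"""

import pandas as pd

from featherblup import build_A, build_A_inverse, inbreeding

ped = pd.DataFrame(
    [
        ("sire", None, None),
        ("damA", None, None),
        ("damB", None, None),
        ("kid1", "sire", "damA"),
        ("kid2", "sire", "damB"),
        ("grand", "kid1", "kid2"),  # half-sib mating -> inbred
    ],
    columns=["animal", "sire", "dam"],
)

rel = build_A(ped)
print("A (additive relationships):")
print(pd.DataFrame(rel.values, index=rel.ids, columns=rel.ids).round(3).to_string())

F = inbreeding(ped)
print(f"\ninbreeding of 'grand': F = {F[-1]:.3f} (half-sib mating -> 0.125)")
print("kid1-kid2 relationship:", rel.values[3, 4], "(paternal half sibs -> 0.25)")

inv = build_A_inverse(ped)
print(f"\nA-inverse is assembled sparsely ({inv.values.nnz} non-zeros), "
      f"log|A| = {inv.log_det_A:.4f}")
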