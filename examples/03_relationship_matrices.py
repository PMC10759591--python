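"""Relationship matrices: pedigree A, partial-selfing A2, VanRaden G, blended Gw, single-step H.

A tiny worked example: one dam with two open-pollinated offspring.  With
selfing probability s = 0.3 the offspring diagonal rises to 1.15, the
mother-offspring relationship to 0.65 and the half-sib relationship to
0.25 * (1 + s)^2 = 0.4225.  The single-step H matrix then merges a marker
matrix for the two genotyped offspring with the pedigree expectations.
"""

import numpy as np
import pandas as pd

from orchardblup import (Pedigree, RelationshipMatrix, build_A,
                         build_A_selfing, build_H)

ped = Pedigree(pd.DataFrame({
    "id": ["dam", "o1", "o2"],
    "mother": [None, "dam", "dam"],
    "father": [None, None, None],
    "provenance": ["P30"] * 3,
    "family": ["F1"] * 3,
    "bulk_lot": [None] * 3,
}))

A = build_A(ped)
A2 = build_A_selfing(ped, s=0.30)
print("A (no selfing):")
print(A.to_square_frame().round(4))
print("\nA2 (selfing rate 0.30):")
print(A2.to_square_frame().round(4))

# genotyped offspring with a marker-based (blended) relationship of 0.5
gw = RelationshipMatrix(["o1", "o2"], np.array([[1.0, 0.5], [0.5, 1.0]]),
                        "Gw")
H = build_H(A, gw, ["o1", "o2"])
print("\nH (single step, offspring genotyped):")
print(H.to_square_frame().round(4))
print("\nThe non-genotyped dam's diagonal moved from 1.0 to "
      f"{H.values[0, 0]:.2f}: the markers say her offspring are more alike "
      "than half-sibs, so she is inferred slightly inbred/related.")
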