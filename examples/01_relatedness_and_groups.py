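"""Relatedness and genetic-group matrices for a small pedigree.

Builds an eight-individual pedigree in which two individuals (an original
founder pair) and two later arrivals have unknown parents, assigns the
phantom parents of founders and immigrants to two genetic groups, and
prints A, A⁻¹, Q and A*. The Q rows show each individual's expected genome
fraction from each group; deleting the two group rows/columns of A*
recovers A⁻¹ exactly.
"""

import numpy as np

from gengroups import (
    Pedigree,
    PedigreeRecord,
    a_inverse,
    a_star,
    additive_relationship,
    assign_groups,
    q_matrix,
    validate_and_order,
)

np.set_printoptions(precision=3, suppress=True)

ped = validate_and_order(
    Pedigree(
        [
            PedigreeRecord("A"),
            PedigreeRecord("B"),
            PedigreeRecord("C", "A", "B"),
            PedigreeRecord("D", "A", "B"),
            PedigreeRecord("M", is_immigrant=True),
            PedigreeRecord("N", is_immigrant=True),
            PedigreeRecord("E", "C", "M"),
            PedigreeRecord("F", "E", "N"),
        ]
    )
)

print("pedigree order:", ped.ids)

A = additive_relationship(ped)
print("\nA (numerator relationship matrix):")
print(A)

Ainv = a_inverse(ped).toarray()
print("\nA-inverse (assembled directly from the pedigree):")
print(Ainv)
print("max |A·A⁻¹ − I| =", np.abs(A @ Ainv - np.eye(len(ped))).max())

gped = assign_groups(ped, "by_flag")  # founder vs immigrant phantom parents
Q = q_matrix(gped)
print("\nQ (genome fraction from each group; rows sum to 1):")
for iid, row in zip(ped.ids, Q):
    print(f"  {iid}: founder={row[0]:.3f} immigrant={row[1]:.3f}")

Astar = a_star(gped).toarray()
print("\nA* (augmented inverse; first two rows/cols are the groups):")
print(Astar)
print(
    "individual block of A* equals A-inverse exactly:",
    bool(np.all(Astar[2:, 2:] == Ainv)),
)
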