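"""Fuzzy classification: phantom parents spread over groups with membership
probabilities.

When a phantom parent cannot be confidently placed in one genetic group,
fuzzy classification assigns it a probability vector over groups; Q and A*
then weight its contributions accordingly. A hard assignment is the unit-
vector special case. Here an individual with an unidentified sire gets a
60/40 split between the local and immigrant groups, and its Q row shifts
accordingly.
"""

import pandas as pd

from gengroups import (
    Pedigree,
    PedigreeRecord,
    assign_groups,
    fuzzy_memberships_from_table,
    q_matrix,
    validate_and_order,
)

ped = validate_and_order(
    Pedigree(
        [
            PedigreeRecord("A"),
            PedigreeRecord("M", is_immigrant=True),
            PedigreeRecord("X", "A", None),  # sire unknown: local or immigrant?
            PedigreeRecord("Y", "X", "M"),
        ]
    )
)

hard = assign_groups(ped, "by_flag", labels=["local", "immigrant"])
print("hard assignment (unknown sire of X placed in 'local'):")
for iid, row in zip(ped.ids, q_matrix(hard)):
    print(f"  {iid}: local={row[0]:.3f} immigrant={row[1]:.3f}")

table = pd.DataFrame(
    {"id": ["X"], "slot": ["sire"], "local": [0.6], "immigrant": [0.4]}
)
fuzzy = fuzzy_memberships_from_table(hard, table)
print("\nfuzzy assignment (X's phantom sire: 60% local, 40% immigrant):")
for iid, row in zip(ped.ids, q_matrix(fuzzy)):
    print(f"  {iid}: local={row[0]:.3f} immigrant={row[1]:.3f}")

print("\nQ rows still sum to one:", q_matrix(fuzzy).sum(axis=1).tolist())
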