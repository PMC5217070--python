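"""Genetic-group matrices: the contribution matrix Q and the augmented
inverse A*.

Q (n × r) holds the expected fraction of each individual's genome derived
from each genetic group of phantom parents; each row sums to one. It obeys
the same parent-average recursion as gene flow: q_i = ½q_dam + ½q_sire,
where an unknown-parent slot contributes ½ × its group-membership vector.
Equivalently, Q is the first r columns of Henderson's T factor when the r
groups are prepended to the pedigree as founders standing in for the
unknown parents.

A* ((r+n) × (r+n), groups first) extends the A⁻¹ assembly rules with each
unknown-parent slot replaced by its group code(s), so that a single random
term models total additive genetic effects u with mean Qg. Deleting the
group rows/columns of A* recovers A⁻¹ exactly; A* itself is singular by
construction (group rows carry only accumulated δ/4 terms).

Fuzzy classification spreads a phantom parent over several groups with
membership probabilities; a hard assignment is the unit-vector special case
and both flow through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import GroupedPedigree, PedigreeError
from .relatedness import mendelian_variances


def q_matrix(gped: GroupedPedigree) -> np.ndarray:
    """Genomic contribution matrix Q (pedigree order × group order).

    q_i = ½·contrib(dam) + ½·contrib(sire), where contrib is the parent's Q
    row if known and the slot's membership vector if unknown.
    """
    ped = gped.base
    if not ped.is_ordered():
        raise ValueError("pedigree must be ordered (run validate_and_order first)")
    n, r = len(ped), gped.r
    dam, sire = ped.parent_codes()
    Q = np.zeros((n, r))
    for i, rec in enumerate(ped.records):
        for par, which in ((int(dam[i]), "dam"), (int(sire[i]), "sire")):
            if par >= 0:
                Q[i] += 0.5 * Q[par]
            else:
                Q[i] += 0.5 * gped.slot_vector(rec.id, which)
    return Q


def a_star(gped: GroupedPedigree) -> sp.csr_matrix:
    """Sparse augmented inverse A*, with the r group rows/columns first.

    Applies the A⁻¹ update (δ_i at (i,i), −δ_i/2 to parents, δ_i/4 among
    parents) with each unknown-parent slot replaced by its group code(s);
    a fuzzy slot distributes each parent-level contribution across groups
    in proportion to membership. δ_i keeps its A⁻¹ value: group pseudo-
    parents do not change the Mendelian sampling variance. The group block
    receives only accumulated δ/4 terms (no own-record contribution), so A*
    is singular by construction — every row sums to zero.
    """
    ped = gped.base
    if not ped.is_ordered():
        raise ValueError("pedigree must be ordered (run validate_and_order first)")
    n, r = len(ped), gped.r
    d = mendelian_variances(ped)
    delta = 1.0 / d
    dam, sire = ped.parent_codes()

    acc: dict[tuple[int, int], float] = {}

    def add(i: int, j: int, v: float) -> None:
        acc[(i, j)] = acc.get((i, j), 0.0) + v

    for i, rec in enumerate(ped.records):
        ci = r + i
        dl = delta[i]
        # combined parent weight vector over codes: v = w_dam + w_sire
        codes: list[int] = []
        weights: list[float] = []
        for par, which in ((int(dam[i]), "dam"), (int(sire[i]), "sire")):
            if par >= 0:
                codes.append(r + par)
                weights.append(1.0)
            else:
                m = gped.slot_vector(rec.id, which)
                for j in np.nonzero(m)[0]:
                    codes.append(int(j))
                    weights.append(float(m[j]))
        add(ci, ci, dl)
        for c, w in zip(codes, weights):
            add(ci, c, -0.5 * dl * w)
            add(c, ci, -0.5 * dl * w)
        for c1, w1 in zip(codes, weights):
            for c2, w2 in zip(codes, weights):
                add(c1, c2, 0.25 * dl * w1 * w2)

    from .relatedness import accumulated_to_csr

    return accumulated_to_csr(acc, (r + n, r + n))


def fuzzy_memberships_from_table(
    gped: GroupedPedigree, table: pd.DataFrame
) -> GroupedPedigree:
    """Replace phantom-slot assignments with fuzzy membership vectors.

    ``table`` needs columns ``id`` and optionally ``slot`` (``dam``/``sire``/
    ``both``, default both) plus one probability column per group label.
    Probabilities must be non-negative; a row summing to 0 is an error, and a
    row whose sum deviates from 1 by more than 1e-6 is an error (within that
    tolerance the vector is rescaled to sum exactly to one, which is
    documented here rather than silent). Hard assignments are the special
    case of a unit vector.
    """
    labels = list(gped.labels)
    for lab in labels:
        if lab not in table.columns and not all(
            l in table.columns for l in labels
        ):
            raise PedigreeError(f"membership table missing column {lab!r}")
    assignment = dict(gped.assignment)
    covered: set[tuple[str, str]] = set()
    for row in table.itertuples(index=False):
        d = row._asdict()
        iid = str(d["id"])
        slot = str(d.get("slot", "both") or "both")
        v = np.array([float(d[lab]) for lab in labels])
        if np.any(v < 0):
            raise PedigreeError(f"negative membership probability for {iid!r}")
        s = v.sum()
        if s == 0:
            raise PedigreeError(f"membership row for {iid!r} sums to 0")
        if abs(s - 1.0) > 1e-6:
            raise PedigreeError(
                f"membership row for {iid!r} sums to {s:.8g}, not 1 "
                "(no silent renormalization)"
            )
        v = v / s  # exact unit sum after the tolerance gate
        for which in ("dam", "sire") if slot == "both" else (slot,):
            if (iid, which) not in assignment:
                raise PedigreeError(
                    f"{iid!r} has no unknown {which} slot to fuzzify"
                )
            assignment[(iid, which)] = v
            covered.add((iid, which))
    return GroupedPedigree(
        base=gped.base,
        labels=labels,
        assignment=assignment,
        reference_group=gped.reference_group,
    )


@dataclass
class GroupMatrices:
    """Q, A* and the group label order for one grouped pedigree."""

    Q: np.ndarray
    Astar: sp.csr_matrix
    labels: list[str]
    reference: str

    @property
    def reference_index(self) -> int:
        return self.labels.index(self.reference)


def group_matrices(gped: GroupedPedigree) -> GroupMatrices:
    """Convenience bundle of :func:`q_matrix` and :func:`a_star`."""
    return GroupMatrices(
        Q=q_matrix(gped),
        Astar=a_star(gped),
        labels=list(gped.labels),
        reference=gped.reference_group,
    )
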