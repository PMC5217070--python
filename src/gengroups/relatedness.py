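"""Pedigree relatedness: inbreeding F, the numerator relationship matrix A,
its generalized Cholesky factors T and D, and the sparse inverse A⁻¹.

The additive (numerator) relationship matrix A holds twice the kinship
between every pair of pedigree members: the expected covariance among
breeding values is σ²_A·A. Phantom parents (unknown-parent slots) are
assumed outbred and unrelated, so an unknown parent contributes zero
kinship. A factors as A = T·D·T′ where T is unit lower triangular (gene
flow: each row is the parent-average of the parents' rows) and D is the
diagonal of Mendelian sampling variances. A⁻¹ is assembled directly from
the pedigree with the classic per-individual update rules, never by
inverting A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .pedigree import Pedigree

#: refuse dense n×n allocations above this size unless explicitly overridden
DENSE_LIMIT = 5000


@dataclass
class RelatednessFactors:
    """Bundle of F, A, T, D and A⁻¹ for one pedigree (dense parts small-n only)."""

    F: np.ndarray
    A: np.ndarray | None
    T: np.ndarray | None
    D: np.ndarray
    Ainv: sp.csr_matrix


def _check_ordered(ped: Pedigree) -> None:
    if not ped.is_ordered():
        raise ValueError("pedigree must be ordered (run validate_and_order first)")


def _check_dense(n: int, max_n: int | None) -> None:
    limit = DENSE_LIMIT if max_n is None else max_n
    if n > limit:
        raise ValueError(
            f"dense computation refused for n={n} > {limit}; "
            "pass max_n to override"
        )


@njit(cache=False)
def _ml_inbreeding(dam: np.ndarray, sire: np.ndarray) -> np.ndarray:  # pragma: no cover
    """Meuwissen & Luo-style inbreeding: per individual, accumulate
    A_ii = Σ_j T_ij² d_j over its ancestor set by back-propagating the
    gene-flow coefficients T_ij; F_i = A_ii − 1. Unknown parents are handled
    by the F = −1 convention inside d_j so that d = 1 (no parents) and
    d = ¾ − ¼F_p (one parent) fall out of the same formula."""
    n = dam.shape[0]
    F = np.zeros(n)
    Fq = np.full(n, -1.0)  # F with the unknown-parent slot convention
    L = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            F[i] = 0.0
            Fq[i] = 0.0
            continue
        # A_ii of individual i via ancestor traversal
        L[i] = 1.0
        top = i
        aii = 0.0
        for j in range(top, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            fs = Fq[sire[j]] if sire[j] >= 0 else -1.0
            fd = Fq[dam[j]] if dam[j] >= 0 else -1.0
            dj = 0.5 - 0.25 * (fs + fd)
            aii += lj * lj * dj
            if sire[j] >= 0:
                L[sire[j]] += 0.5 * lj
            if dam[j] >= 0:
                L[dam[j]] += 0.5 * lj
            L[j] = 0.0
        F[i] = aii - 1.0
        Fq[i] = F[i]
    return F


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F_i = kinship(dam_i, sire_i); 0 if a parent is unknown.

    Uses the Meuwissen & Luo ancestor-traversal algorithm (quadratic worst
    case, near-linear on shallow pedigrees); agrees with the recursive
    kinship definition to 1e-12 (tested).
    """
    _check_ordered(ped)
    dam, sire = ped.parent_codes()
    return _ml_inbreeding(dam, sire)


def kinship_pair(ped: Pedigree, a: str, b: str, _memo=None) -> float:
    """Recursive coefficient-of-kinship oracle (memoized); small pedigrees only."""
    _check_ordered(ped)
    dam, sire = ped.parent_codes()
    memo: dict[tuple[int, int], float] = {} if _memo is None else _memo

    def phi(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5 * (1.0 + phi(int(dam[i]), int(sire[i])))
        else:
            # i is the later individual: condition on i's parents
            val = 0.5 * (phi(int(dam[i]), j) + phi(int(sire[i]), j))
        memo[key] = val
        return val

    return phi(ped.index[a], ped.index[b])


def inbreeding_recursive(ped: Pedigree) -> np.ndarray:
    """Pure-Python oracle for F via recursive kinship (cross-check path)."""
    _check_ordered(ped)
    memo: dict[tuple[int, int], float] = {}
    F = np.zeros(len(ped))
    for i, rec in enumerate(ped.records):
        if rec.dam is None or rec.sire is None:
            continue
        F[i] = kinship_pair(ped, rec.dam, rec.sire, _memo=memo)
    return F


def additive_relationship(ped: Pedigree, max_n: int | None = None) -> np.ndarray:
    """Dense A by the tabular method (brute-force oracle; n ≤ 5000 by default).

    A_ii = 1 + ½·A(dam_i, sire_i); A_ij = ½(A(j, dam_i) + A(j, sire_i)) for
    j < i; unknown parents contribute 0.
    """
    _check_ordered(ped)
    n = len(ped)
    _check_dense(n, max_n)
    dam, sire = ped.parent_codes()
    A = np.zeros((n, n))
    for i in range(n):
        d, s = int(dam[i]), int(sire[i])
        row = np.zeros(i)
        if d >= 0:
            row += 0.5 * A[d, :i]
        if s >= 0:
            row += 0.5 * A[s, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[d, s] if d >= 0 and s >= 0 else 0.0)
    return A


def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Diagonal of D: Mendelian sampling variance per individual (units of σ²_A).

    d_ii = ½ − ¼(F_s + F_d) with both parents known, ¾ − ¼F_p with one,
    1 with neither.
    """
    _check_ordered(ped)
    if F is None:
        F = inbreeding_coefficients(ped)
    dam, sire = ped.parent_codes()
    Fd = np.where(dam >= 0, F[dam], 0.0)
    Fs = np.where(sire >= 0, F[sire], 0.0)
    nknown = (dam >= 0).astype(int) + (sire >= 0).astype(int)
    d = np.where(
        nknown == 2,
        0.5 - 0.25 * (Fd + Fs),
        np.where(nknown == 1, 0.75 - 0.25 * (Fd + Fs), 1.0),
    )
    return d


def tdt_decompose(
    ped: Pedigree, max_n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Henderson's generalized Cholesky A = T·D·T′.

    T is unit lower triangular: row i is ½(row of dam) + ½(row of sire) with
    a 1 at (i, i). Returns (T dense, d diagonal vector).
    """
    _check_ordered(ped)
    n = len(ped)
    _check_dense(n, max_n)
    dam, sire = ped.parent_codes()
    T = np.zeros((n, n))
    for i in range(n):
        d, s = int(dam[i]), int(sire[i])
        if d >= 0:
            T[i, : i + 1] += 0.5 * T[d, : i + 1]
        if s >= 0:
            T[i, : i + 1] += 0.5 * T[s, : i + 1]
        T[i, i] = 1.0
    d = mendelian_variances(ped)
    return T, d


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A⁻¹ assembled directly from the pedigree.

    For each individual i with δ_i = 1/d_ii: add δ_i at (i,i), −δ_i/2 between
    i and each known parent, and δ_i/4 between every pair of known parents
    (including each parent with itself). At most 9 stored entries arise per
    individual.
    """
    _check_ordered(ped)
    n = len(ped)
    d = mendelian_variances(ped, F)
    delta = 1.0 / d
    dam, sire = ped.parent_codes()

    # entry order mirrors the A* assembly exactly (per individual: diagonal,
    # then individual-parent terms, then parent-pair products) with
    # deterministic duplicate accumulation, so that the individual block of
    # A* reproduces A⁻¹ bitwise
    acc: dict[tuple[int, int], float] = {}

    def add(i: int, j: int, v: float) -> None:
        acc[(i, j)] = acc.get((i, j), 0.0) + v

    for i in range(n):
        dl = delta[i]
        codes = [int(p) for p in (dam[i], sire[i]) if p >= 0]
        add(i, i, dl)
        for c in codes:
            add(i, c, -0.5 * dl)
            add(c, i, -0.5 * dl)
        for c1 in codes:
            for c2 in codes:
                add(c1, c2, 0.25 * dl)

    return accumulated_to_csr(acc, (n, n))


def accumulated_to_csr(
    acc: dict[tuple[int, int], float], shape: tuple[int, int]
) -> sp.csr_matrix:
    """Duplicate-free (row, col) -> value mapping to CSR."""
    if not acc:
        return sp.csr_matrix(shape)
    rows, cols = zip(*acc.keys())
    return sp.csr_matrix(
        sp.coo_matrix((list(acc.values()), (rows, cols)), shape=shape)
    )


def relatedness_factors(
    ped: Pedigree, dense: bool | None = None, max_n: int | None = None
) -> RelatednessFactors:
    """Compute the full bundle; dense A/T only when n permits (or dense=True)."""
    _check_ordered(ped)
    n = len(ped)
    F = inbreeding_coefficients(ped)
    D = mendelian_variances(ped, F)
    Ainv = a_inverse(ped, F)
    want_dense = dense if dense is not None else n <= (max_n or DENSE_LIMIT)
    A = T = None
    if want_dense:
        A = additive_relationship(ped, max_n=max_n)
        T, _ = tdt_decompose(ped, max_n=max_n)
    return RelatednessFactors(F=F, A=A, T=T, D=D, Ainv=Ainv)
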