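"""Simulate a pedigreed population receiving immigrants with a shifted mean
additive genetic value.

The generator reproduces a standard demonstration of how unknown parents
bias animal-model estimates: a closed, unselected population of discrete
generations receives a fixed number of immigrants per generation whose
total additive genetic effects are drawn with a mean several units above
the local founders (equal within-group variance). Offspring total effects
are the mid-parent average plus a Mendelian sampling deviation with
variance ½σ²_A(1 − (F_s + F_d)/2); phenotypes add an i.i.d. residual.
Because mating is random, the population mean phenotype rises across
generations purely through gene flow. Immigrants arrive without recorded
parents, so in the observed pedigree they are indistinguishable from
founders unless genetic groups are modelled.

Defaults — 15 generations of 400 (6000 individuals), 40 immigrants per
generation from the second onward, immigrant mean +3, σ²_A = σ²_E = 1 —
give 560 immigrants and a 16% unknown-parent fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeRecord

logger = logging.getLogger(__name__)

GROUP_LABELS = ("founder", "immigrant")


@dataclass
class SimParams:
    """Study conditions for :func:`simulate_population`."""

    n_generations: int = 15
    cohort_size: int = 400
    immigrants_per_generation: int = 40
    immigrant_mean: float = 3.0
    sigma2_A: float = 1.0
    sigma2_E: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.cohort_size > self.immigrants_per_generation >= 0):
            raise ValueError("need cohort_size > immigrants_per_generation >= 0")
        if self.sigma2_A < 0 or self.sigma2_E < 0:
            raise ValueError("variances must be non-negative")
        if self.n_generations < 1:
            raise ValueError("need at least one generation")

    @property
    def n_total(self) -> int:
        return self.n_generations * self.cohort_size


@dataclass
class SimResult:
    """Simulated population: pedigree, truth, and phenotypes.

    ``a_true`` are breeding values as deviations from group means
    (a = u − Q·g with g = (0, immigrant_mean)); ``q_true`` are the genome
    fractions from (founder, immigrant) sources tracked through the
    pedigree. ``masked_pedigree`` is the observed pedigree in which every
    immigrant has unknown parents.
    """

    params: SimParams
    true_pedigree: Pedigree
    masked_pedigree: Pedigree
    g_true: np.ndarray
    q_true: np.ndarray
    u_true: np.ndarray
    a_true: np.ndarray
    e_true: np.ndarray
    y: np.ndarray
    cohort: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_immigrant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def phenotype_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.true_pedigree.ids,
                "y": self.y,
                "cohort": self.cohort,
                "immigrant": self.is_immigrant.astype(int),
            }
        )

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.true_pedigree.ids,
                "u_true": self.u_true,
                "a_true": self.a_true,
                "e_true": self.e_true,
                "q_founder": self.q_true[:, 0],
                "q_immigrant": self.q_true[:, 1],
                "cohort": self.cohort,
                "immigrant": self.is_immigrant.astype(int),
            }
        )


def _pair(females: np.ndarray, males: np.ndarray, rng: np.random.Generator):
    """Random monogamous pairs; with unequal sex counts the extras are each
    mated to a random member of the other sex (triads), logged."""
    females = rng.permutation(females)
    males = rng.permutation(males)
    k = min(len(females), len(males))
    pairs = list(zip(females[:k], males[:k]))
    extra = females[k:] if len(females) > k else males[k:]
    if len(extra):
        logger.info("%d unpaired individual(s) joined existing pairs as triads",
                    len(extra))
        mates = rng.choice(males if len(females) > k else females, size=len(extra))
        for e, m in zip(extra, mates):
            pairs.append((e, m) if len(females) > k else (m, e))
    return pairs


def simulate_population(params: SimParams) -> SimResult:
    """Run the forward simulation under ``params`` (reproducible by seed).

    Generation 1 is all founders (u ~ N(0, σ²_A)); each later generation
    holds ``cohort_size − immigrants_per_generation`` locally bred offspring
    of random monogamous pairs from the previous generation plus the
    immigrants (u ~ N(immigrant_mean, σ²_A)). Offspring get Mendelian
    sampling deviations whose variance accounts for parental inbreeding,
    tracked exactly through a within-cohort relationship recursion (all
    parents of a cohort belong to the previous one).
    """
    rng = np.random.default_rng(params.seed)
    sA = np.sqrt(params.sigma2_A)
    sE = np.sqrt(params.sigma2_E)
    g_true = np.array([0.0, params.immigrant_mean])

    records: list[PedigreeRecord] = []
    u_all: list[float] = []
    q_all: list[np.ndarray] = []
    cohorts: list[int] = []
    imm_all: list[bool] = []

    def new_id(t: int, k: int) -> str:
        return f"G{t:02d}I{k + 1:04d}"

    # previous-cohort state
    prev_ids: list[str] = []
    prev_u = np.zeros(0)
    prev_F = np.zeros(0)
    prev_A = np.zeros((0, 0))  # within-cohort relationship (diag 1+F)
    prev_sex: np.ndarray = np.zeros(0, dtype="U1")

    width = len(GROUP_LABELS)
    for t in range(1, params.n_generations + 1):
        n_imm = 0 if t == 1 else params.immigrants_per_generation
        n_nat = params.cohort_size - n_imm
        ids = [new_id(t, k) for k in range(params.cohort_size)]
        sex = np.array(["F" if k % 2 == 0 else "M" for k in range(params.cohort_size)])

        u = np.empty(params.cohort_size)
        F = np.zeros(params.cohort_size)
        q = np.zeros((params.cohort_size, width))
        dams: list[str | None] = [None] * params.cohort_size
        sires: list[str | None] = [None] * params.cohort_size
        imm = np.zeros(params.cohort_size, dtype=bool)

        if t == 1:
            u[:] = rng.normal(0.0, sA, params.cohort_size)
            q[:, 0] = 1.0
            A = np.eye(params.cohort_size)
        else:
            fem = np.flatnonzero(prev_sex == "F")
            mal = np.flatnonzero(prev_sex == "M")
            pairs = _pair(fem, mal, rng)
            # distribute native offspring near-equally among pairs
            npairs = len(pairs)
            counts = np.full(npairs, n_nat // npairs)
            rem = n_nat - counts.sum()
            if rem:
                counts[rng.choice(npairs, size=rem, replace=False)] += 1
            dam_idx = np.empty(n_nat, dtype=int)
            sire_idx = np.empty(n_nat, dtype=int)
            pos = 0
            for (f, m_), c in zip(pairs, counts):
                dam_idx[pos : pos + c] = f
                sire_idx[pos : pos + c] = m_
                pos += c

            F[:n_nat] = 0.5 * prev_A[dam_idx, sire_idx]
            msd_var = 0.5 * params.sigma2_A * (
                1.0 - 0.5 * (prev_F[dam_idx] + prev_F[sire_idx])
            )
            u[:n_nat] = (
                0.5 * (prev_u[dam_idx] + prev_u[sire_idx])
                + rng.normal(0.0, 1.0, n_nat) * np.sqrt(msd_var)
            )
            q[:n_nat] = 0.5 * (q_prev[dam_idx] + q_prev[sire_idx])
            for k in range(n_nat):
                dams[k] = prev_ids[dam_idx[k]]
                sires[k] = prev_ids[sire_idx[k]]

            u[n_nat:] = rng.normal(params.immigrant_mean, sA, n_imm)
            q[n_nat:, 1] = 1.0
            imm[n_nat:] = True

            # within-cohort relationship among the new natives:
            # A(i,j) = ¼ Σ over parent combinations of A_prev, exact because
            # all native parents sit in the previous cohort and immigrants
            # are unrelated to everyone.
            M = np.zeros((n_nat, prev_A.shape[0]))
            M[np.arange(n_nat), dam_idx] += 0.5
            M[np.arange(n_nat), sire_idx] += 0.5
            A = np.eye(params.cohort_size)
            block = M @ prev_A @ M.T
            np.fill_diagonal(block, 1.0 + F[:n_nat])
            A[:n_nat, :n_nat] = block

        e = rng.normal(0.0, sE, params.cohort_size)
        for k in range(params.cohort_size):
            records.append(
                PedigreeRecord(
                    ids[k], dams[k], sires[k], cohort=t, sex=sex[k],
                    is_immigrant=bool(imm[k]),
                )
            )
        u_all.extend(u)
        q_all.extend(q)
        cohorts.extend([t] * params.cohort_size)
        imm_all.extend(imm)
        if t == 1:
            e_all = [e]
        else:
            e_all.append(e)

        prev_ids, prev_u, prev_F, prev_A, prev_sex = ids, u, F, A, sex
        q_prev = q

    true_ped = Pedigree(records)
    u_arr = np.array(u_all)
    q_arr = np.array(q_all)
    e_arr = np.concatenate(e_all)
    a_arr = u_arr - q_arr @ g_true
    y = u_arr + e_arr
    cohort_arr = np.array(cohorts)
    imm_arr = np.array(imm_all)

    sim = SimResult(
        params=params,
        true_pedigree=true_ped,
        masked_pedigree=true_ped,  # replaced below
        g_true=g_true,
        q_true=q_arr,
        u_true=u_arr,
        a_true=a_arr,
        e_true=e_arr,
        y=y,
        cohort=cohort_arr,
        is_immigrant=imm_arr,
    )
    sim.masked_pedigree = mask_immigrant_parents(sim)
    return sim


def mask_immigrant_parents(sim: "SimResult | Pedigree") -> Pedigree:
    """Observed pedigree: every immigrant-flagged record loses its parents.

    Founders already have unknown parents; native parent links are kept
    intact. Accepts a :class:`SimResult` or any pedigree with immigrant
    flags.
    """
    ped = sim.true_pedigree if isinstance(sim, SimResult) else sim
    out = []
    for rec in ped.records:
        if rec.is_immigrant and (rec.dam is not None or rec.sire is not None):
            out.append(
                PedigreeRecord(
                    rec.id, None, None, cohort=rec.cohort, sex=rec.sex,
                    is_immigrant=True,
                )
            )
        else:
            out.append(rec)
    return Pedigree(out)


def simulation_summary(sim: SimResult) -> pd.DataFrame:
    """Per-cohort, per-origin means and variances of y, u_true and a_true."""
    df = pd.DataFrame(
        {
            "cohort": sim.cohort,
            "immigrant": sim.is_immigrant,
            "y": sim.y,
            "u_true": sim.u_true,
            "a_true": sim.a_true,
        }
    )
    out = (
        df.groupby(["cohort", "immigrant"], sort=True)
        .agg(
            n=("y", "size"),
            mean_y=("y", "mean"),
            var_y=("y", "var"),
            mean_u=("u_true", "mean"),
            var_u=("u_true", "var"),
            mean_a=("a_true", "mean"),
            var_a=("a_true", "var"),
        )
        .reset_index()
    )
    return out
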