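"""Henderson mixed-model equations, BLUP, and profile REML for animal models
with and without genetic groups.

Three model modes are supported, all with a single additive genetic random
term and i.i.d. residuals:

``basic``
    y = Xβ + Za + e, a ~ N(0, σ²_A A), using A⁻¹ — the standard animal model
    with one implicit base population of mean zero.
``explicit``
    y = Xβ + (ZQ)g + Za + e — genetic-group means fitted as fixed covariate
    regressions on the columns of Q (reference column dropped, so estimated
    group effects are contrasts against the reference group).
``implicit``
    y = Xβ + Zu + e with u ~ N(Qg, σ²_A A), fitted in one random term via the
    augmented inverse A*; group solutions appear at the group positions and
    the reference group's equation is removed (its effect constrained to 0).

The explicit and implicit parameterizations are the same statistical model
and return identical group-effect estimates; breeding values and total
additive effects interconvert as u = Qg + a.

Variance components are estimated by REML, profiling the likelihood over
the ratio λ = σ²_E/σ²_A with sparse factorizations of the mixed-model
coefficient matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize_scalar

from .pedigree import GroupedPedigree, Pedigree

__all__ = [
    "ModelData",
    "ModelError",
    "ModelFit",
    "VarianceComponents",
    "build_model",
    "prediction_error_variance",
    "solve_blup",
    "reml_estimate",
    "total_additive_effects",
    "breeding_values_from_total",
    "fit_animal_model",
]


class ModelError(ValueError):
    """Raised for unfittable models (confounding, rank deficiency, bad input)."""


@dataclass
class ModelData:
    """Design matrices for one trait: y, fixed-effect X (intercept first),
    record-to-individual incidence Z, and the pedigree the columns refer to."""

    y: np.ndarray
    X: np.ndarray
    Z: sp.csr_matrix
    ped: Pedigree
    record_ids: list[str]
    fixed_names: list[str]

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_individuals(self) -> int:
        return len(self.ped)


@dataclass
class VarianceComponents:
    """Additive and residual variances with their ratio λ = σ²_E/σ²_A."""

    sigma2_A: float
    sigma2_E: float
    lam: float
    loglik: float = math.nan
    converged: bool = True
    boundary: bool = False

    @classmethod
    def from_values(cls, sigma2_A: float, sigma2_E: float) -> "VarianceComponents":
        if sigma2_E <= 0 or sigma2_A < 0:
            raise ModelError("need sigma2_E > 0 and sigma2_A >= 0")
        lam = math.inf if sigma2_A == 0 else sigma2_E / sigma2_A
        return cls(sigma2_A=sigma2_A, sigma2_E=sigma2_E, lam=lam)


@dataclass
class ModelFit:
    """Solutions of one mixed-model fit.

    ``g_hat`` holds the r group effects with the reference entry exactly 0
    (None for the basic model). ``a_hat``/``u_hat`` are breeding values and
    total additive genetic effects in pedigree order; whichever was not
    solved directly is derived via u = Qg + a when Q is available.
    """

    mode: str
    beta_hat: np.ndarray
    g_hat: np.ndarray | None
    a_hat: np.ndarray | None
    u_hat: np.ndarray | None
    varcomp: VarianceComponents
    fixed_names: list[str]
    group_labels: list[str] | None = None
    g_se: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def build_model(
    ped: Pedigree | GroupedPedigree,
    phenotypes: pd.DataFrame | str | Path,
    fixed: Sequence[str] = (),
    trait: str | None = None,
    id_col: str = "id",
) -> ModelData:
    """Assemble y, X, Z from a phenotype table keyed on pedigree ids.

    The trait column defaults to the first non-id column. Fixed covariates
    listed in ``fixed`` enter X after the intercept; string/categorical
    columns become treatment contrasts (first level dropped). Records with a
    missing trait value are excluded from y/X/Z; pedigree members without
    phenotypes simply contribute relatedness.
    """
    base = ped.base if isinstance(ped, GroupedPedigree) else ped
    if isinstance(phenotypes, (str, Path)):
        phenotypes = pd.read_csv(phenotypes, comment="#")
    df = phenotypes.copy()
    if id_col not in df.columns:
        raise ModelError(f"phenotype table lacks id column {id_col!r}")
    if trait is None:
        candidates = [c for c in df.columns if c != id_col and c not in fixed]
        if not candidates:
            raise ModelError("no trait column found in phenotype table")
        trait = candidates[0]

    df[id_col] = df[id_col].astype(str)
    missing_ids = [i for i in df[id_col] if i not in base.index]
    if missing_ids:
        raise ModelError(
            f"phenotyped id {missing_ids[0]!r} is absent from the pedigree"
        )
    df = df[pd.to_numeric(df[trait], errors="coerce").notna()]
    y = df[trait].astype(float).to_numpy()
    m = len(df)

    cols = [np.ones(m)]
    names = ["(intercept)"]
    for cov in fixed:
        if cov not in df.columns:
            raise ModelError(f"fixed covariate {cov!r} not in phenotype table")
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float).to_numpy())
            names.append(cov)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed-effect design X is rank deficient")

    rows = np.arange(m)
    ind = np.array([base.index[i] for i in df[id_col]], dtype=np.int64)
    Z = sp.csr_matrix(
        (np.ones(m), (rows, ind)), shape=(m, len(base))
    )
    return ModelData(
        y=y, X=X, Z=Z, ped=base, record_ids=list(df[id_col]), fixed_names=names
    )


def _assemble(
    data: ModelData,
    Kinv: sp.spmatrix,
    lam: float,
    mode: str,
    Q: np.ndarray | None,
    reference: int,
):
    """Build the MME coefficient matrix C and right-hand side r.

    Returns (C csc, rhs, layout) where layout describes how solution entries
    map back to (β, g, a/u).
    """
    X = data.X
    Z = data.Z
    y = data.y
    n = data.n_individuals

    if mode == "basic":
        Xa = X
        W: sp.spmatrix = Z
        drop: int | None = None
        q = n
    elif mode == "explicit":
        if Q is None:
            raise ModelError("explicit mode requires Q")
        keep = [j for j in range(Q.shape[1]) if j != reference]
        Xa = np.column_stack([X, (Z @ Q)[:, keep]])
        W = Z
        drop = None
        q = n
    elif mode == "implicit":
        r = Kinv.shape[0] - n
        if r < 1:
            raise ModelError("implicit mode requires the augmented inverse A*")
        W = sp.hstack([sp.csr_matrix((data.n_records, r)), Z]).tocsr()
        Xa = X
        drop = X.shape[1] + reference  # reference-group equation removed
        q = n + r
    else:
        raise ModelError(f"unknown mode {mode!r}")

    if Kinv.shape[0] != q:
        raise ModelError(
            f"Kinv has dimension {Kinv.shape[0]}, expected {q} for mode {mode!r}"
        )

    p = Xa.shape[1]
    XtX = Xa.T @ Xa
    XtW = sp.csr_matrix(Xa.T @ W)
    WtW = (W.T @ W).tocsr()
    C = sp.bmat(
        [
            [sp.csr_matrix(XtX), XtW],
            [XtW.T, WtW + lam * Kinv.tocsr()],
        ],
        format="csc",
    )
    rhs = np.concatenate([Xa.T @ y, W.T @ y])
    if drop is not None:
        keep_idx = np.array([k for k in range(C.shape[0]) if k != drop])
        C = C[keep_idx][:, keep_idx].tocsc()
        rhs = rhs[keep_idx]
    return C, rhs, {"p": p, "p0": X.shape[1], "drop": drop, "q": q}


def _factorize(C: sp.csc_matrix):
    try:
        lu = spla.splu(C)
    except RuntimeError as exc:  # singular factorization
        raise ModelError(
            "mixed-model equations are singular after constraints; check for "
            "confounding (e.g. genetic groups collinear with the intercept or "
            "other fixed effects)"
        ) from exc
    if not np.all(np.isfinite(lu.U.diagonal())) or np.any(lu.U.diagonal() == 0):
        raise ModelError(
            "mixed-model equations are singular after constraints; check for "
            "confounding between genetic groups and fixed effects"
        )
    return lu


def solve_blup(
    data: ModelData,
    Kinv: sp.spmatrix,
    vc: VarianceComponents,
    mode: str = "basic",
    Q: np.ndarray | None = None,
    reference: int = 0,
    group_labels: Sequence[str] | None = None,
    compute_se: bool = False,
) -> ModelFit:
    """Solve the mixed-model equations at fixed variance components.

    ``Kinv`` is A⁻¹ for basic/explicit and A* (groups first) for implicit
    mode; ``reference`` is the index of the reference group whose effect is
    constrained to 0. ``Q`` is required in explicit mode and, when supplied
    in implicit mode, enables the û → â conversion.
    """
    lam = vc.lam
    if not np.isfinite(lam):
        # σ²_A = 0 limit: all random effects shrink to zero, β̂ is OLS
        beta, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
        n = data.n_individuals
        zeros = np.zeros(n)
        r = (Kinv.shape[0] - n) if mode == "implicit" else (
            Q.shape[1] if Q is not None else 0
        )
        g = np.zeros(r) if mode != "basic" else None
        return ModelFit(
            mode=mode, beta_hat=beta, g_hat=g, a_hat=zeros, u_hat=zeros.copy(),
            varcomp=vc, fixed_names=list(data.fixed_names),
            group_labels=list(group_labels) if group_labels else None,
        )

    C, rhs, lay = _assemble(data, Kinv, lam, mode, Q, reference)
    lu = _factorize(C)
    sol = lu.solve(rhs)

    p0 = lay["p0"]
    beta = sol[:p0]
    n = data.n_individuals
    g_se = None
    if mode == "basic":
        a = sol[p0:]
        fit = ModelFit(
            mode=mode, beta_hat=beta, g_hat=None, a_hat=a, u_hat=a.copy(),
            varcomp=vc, fixed_names=list(data.fixed_names),
        )
    elif mode == "explicit":
        r = Q.shape[1]
        gfree = sol[p0 : p0 + r - 1]
        g = np.zeros(r)
        g[[j for j in range(r) if j != reference]] = gfree
        a = sol[lay["p"] :]
        u = total_additive_effects(a, Q, g)
        if compute_se:
            g_se = _solution_se(lu, C.shape[0], range(p0, p0 + r - 1), vc.sigma2_E)
            full = np.zeros(r)
            full[[j for j in range(r) if j != reference]] = g_se
            g_se = full
        fit = ModelFit(
            mode=mode, beta_hat=beta, g_hat=g, a_hat=a, u_hat=u, varcomp=vc,
            fixed_names=list(data.fixed_names),
            group_labels=list(group_labels) if group_labels else None,
            g_se=g_se,
        )
    else:  # implicit
        r = Kinv.shape[0] - n
        eff = sol[p0:]
        g = np.zeros(r)
        free_positions = [j for j in range(r) if j != reference]
        g[free_positions] = eff[: r - 1]
        u = eff[r - 1 :]
        a = breeding_values_from_total(u, Q, g) if Q is not None else None
        if compute_se:
            g_se_free = _solution_se(
                lu, C.shape[0], range(p0, p0 + r - 1), vc.sigma2_E
            )
            g_se = np.zeros(r)
            g_se[free_positions] = g_se_free
        fit = ModelFit(
            mode=mode, beta_hat=beta, g_hat=g, a_hat=a, u_hat=u, varcomp=vc,
            fixed_names=list(data.fixed_names),
            group_labels=list(group_labels) if group_labels else None,
            g_se=g_se,
        )
    return fit


def _solution_se(lu, dim: int, positions, sigma2_E: float) -> np.ndarray:
    """Standard errors from the diagonal of C⁻¹ (sampling variance σ²_E·C⁻¹_jj)."""
    out = []
    for j in positions:
        e = np.zeros(dim)
        e[j] = 1.0
        out.append(math.sqrt(max(lu.solve(e)[j], 0.0) * sigma2_E))
    return np.array(out)


def prediction_error_variance(
    data: ModelData,
    Kinv: sp.spmatrix,
    vc: VarianceComponents,
    mode: str = "basic",
    Q: np.ndarray | None = None,
    reference: int = 0,
    max_n: int = 5000,
) -> np.ndarray:
    """Prediction-error variances of the random-effect solutions.

    Diagonal of the random-effect block of C⁻¹ times σ²_E, computed by dense
    inversion — on request only, and refused above ``max_n`` equations.
    Returns one PEV per random-effect level (â in basic/explicit mode, (ĝ, û)
    order with the reference group's 0 inserted in implicit mode).
    """
    C, rhs, lay = _assemble(data, Kinv, vc.lam, mode, Q, reference)
    if C.shape[0] > max_n:
        raise ModelError(
            f"prediction-error variances refused for {C.shape[0]} equations "
            f"(> {max_n}); raise max_n to override"
        )
    Cinv = np.linalg.inv(C.toarray())
    pev = np.diag(Cinv)[lay["p"]:] * vc.sigma2_E
    if mode == "implicit":
        r = Kinv.shape[0] - data.n_individuals
        full = np.zeros(r + data.n_individuals)
        free = [j for j in range(r) if j != reference]
        full[free] = pev[: r - 1]
        full[r:] = pev[r - 1:]
        pev = full
    return pev


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _logdet_sparse(M: sp.spmatrix) -> float:
    lu = spla.splu(M.tocsc())
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def reml_estimate(
    data: ModelData,
    Kinv: sp.spmatrix,
    mode: str = "basic",
    Q: np.ndarray | None = None,
    reference: int = 0,
    bounds: tuple[float, float] = (1e-3, 1e3),
    rel_tol: float = 1e-6,
    grid_points: int = 15,
) -> VarianceComponents:
    """REML variance components by profiling the likelihood over λ = σ²_E/σ²_A.

    For each λ the residual variance has a closed-form profile and the REML
    log-likelihood is evaluated from one sparse factorization of the MME
    coefficient matrix. A log-spaced grid brackets the optimum, which is
    then refined by bounded scalar minimization to relative tolerance
    ``rel_tol``. A grid-boundary optimum is returned flagged
    (``converged=False``, ``boundary=True``); λ at the upper bound with an
    effectively zero σ²_A is the boundary estimate.

    The implicit (A*) parameterization is estimated through its equivalent
    explicit representation — the individual block of A* plus fixed
    regressions on Q — which has the identical likelihood and avoids the
    singular A* determinant.
    """
    n = data.n_individuals
    if mode == "implicit":
        if Q is None:
            raise ModelError("implicit-mode REML requires Q for the equivalent "
                             "explicit representation")
        r = Kinv.shape[0] - n
        Kinv = Kinv[r:, :][:, r:].tocsr()
        mode = "explicit"
    if mode == "explicit" and Q is None:
        raise ModelError("explicit mode requires Q")

    # effective fixed design size for degrees of freedom
    p = data.X.shape[1] + (Q.shape[1] - 1 if mode == "explicit" else 0)
    N = data.n_records
    if N < p + 2:
        raise ModelError("too few records for REML")

    logdet_Kinv = _logdet_sparse(Kinv)
    yty = float(data.y @ data.y)
    const = (N - p) * math.log(2.0 * math.pi)

    def neg2_reml(log_lam: float) -> float:
        lam = math.exp(log_lam)
        C, rhs, _ = _assemble(data, Kinv, lam, mode, Q, reference)
        lu = _factorize(C)
        sol = lu.solve(rhs)
        ypy = max(yty - float(rhs @ sol), 1e-300)
        sig2e = ypy / (N - p)
        logdetC = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        return (
            const
            + (N - p) * (math.log(sig2e) + 1.0)
            + logdetC
            - n * log_lam
            - logdet_Kinv
        )

    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    grid = np.linspace(lo, hi, grid_points)
    vals = np.array([neg2_reml(x) for x in grid])
    k = int(np.argmin(vals))

    boundary = k in (0, grid_points - 1)
    if boundary:
        best_log_lam = grid[k]
        best_val = vals[k]
        converged = False
    else:
        res = minimize_scalar(
            neg2_reml,
            bounds=(grid[k - 1], grid[k + 1]),
            method="bounded",
            options={"xatol": rel_tol},
        )
        best_log_lam = float(res.x)
        best_val = float(res.fun)
        converged = bool(res.success)

    lam = math.exp(best_log_lam)
    C, rhs, _ = _assemble(data, Kinv, lam, mode, Q, reference)
    lu = _factorize(C)
    sol = lu.solve(rhs)
    sig2e = max(yty - float(rhs @ sol), 1e-300) / (N - p)
    sig2a = sig2e / lam
    return VarianceComponents(
        sigma2_A=sig2a,
        sigma2_E=sig2e,
        lam=lam,
        loglik=-0.5 * best_val,
        converged=converged,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# u <-> a conversions
# ---------------------------------------------------------------------------

def total_additive_effects(
    a: np.ndarray, Q: np.ndarray, g: np.ndarray
) -> np.ndarray:
    """u = Q·g + a: group means weighted by genome fractions plus breeding value."""
    a = np.asarray(a, dtype=float)
    Q = np.asarray(Q, dtype=float)
    g = np.asarray(g, dtype=float)
    if Q.shape != (a.shape[0], g.shape[0]):
        raise ModelError("dimension mismatch between a, Q and g")
    return Q @ g + a


def breeding_values_from_total(
    u: np.ndarray, Q: np.ndarray, g: np.ndarray
) -> np.ndarray:
    """a = u − Q·g: exact inverse of :func:`total_additive_effects`."""
    u = np.asarray(u, dtype=float)
    Q = np.asarray(Q, dtype=float)
    g = np.asarray(g, dtype=float)
    if Q.shape != (u.shape[0], g.shape[0]):
        raise ModelError("dimension mismatch between u, Q and g")
    return u - Q @ g


# ---------------------------------------------------------------------------
# High-level pipeline
# ---------------------------------------------------------------------------

def fit_animal_model(
    ped: Pedigree | GroupedPedigree,
    phenotypes: pd.DataFrame | str | Path,
    mode: str = "basic",
    vc: VarianceComponents | None = None,
    fixed: Sequence[str] = (),
    trait: str | None = None,
    reml_kwargs: dict | None = None,
    compute_se: bool = False,
) -> ModelFit:
    """Build, (optionally) REML-estimate, and solve one animal model.

    With ``mode='basic'`` a plain :class:`~gengroups.pedigree.Pedigree`
    suffices; the group modes need a :class:`GroupedPedigree`. When ``vc``
    is None the variance components are first estimated by REML.
    """
    from .groups import a_star, q_matrix
    from .relatedness import a_inverse

    data = build_model(ped, phenotypes, fixed=fixed, trait=trait)
    if mode == "basic":
        base = ped.base if isinstance(ped, GroupedPedigree) else ped
        Kinv: sp.spmatrix = a_inverse(base)
        Q = None
        reference = 0
        labels = None
    else:
        if not isinstance(ped, GroupedPedigree):
            raise ModelError(f"mode {mode!r} requires a GroupedPedigree")
        Q = q_matrix(ped)
        reference = ped.reference_index
        labels = list(ped.labels)
        Kinv = a_star(ped) if mode == "implicit" else a_inverse(ped.base)
    if vc is None:
        vc = reml_estimate(
            data, Kinv, mode=mode, Q=Q, reference=reference, **(reml_kwargs or {})
        )
    return solve_blup(
        data, Kinv, vc, mode=mode, Q=Q, reference=reference,
        group_labels=labels, compute_se=compute_se,
    )
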