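"""Linear baseline: regularized generalized CCA (one weight per variable).

Each group gets a linear composite y_j = X_j b_j maximizing the same
scheme-transformed sum of pairwise covariances, under the regularized
constraint

    tau_j ||b_j||^2 + (1 - tau_j) Var(b_j' X_j) = 1.

This is the classical multi-block linear method the kernel model reduces
to when relationships are linear; odd nonlinear links are invisible to it,
which is exactly the comparison the simulation study draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .core import FitConfig, full_design, get_scheme, validate_design
from .data import GroupData


@dataclass
class LinearFitResult:
    """Weights and scores; mirrors the kernel FitResult score interface.

    As for the kernel model, ``objective`` is the ordered-pair sum and
    ``rho`` the per-connected-pair scale (half of it). ``column_sd`` holds
    the per-variable standard deviations divided out before fitting (None
    when ``scale=False``); weights apply to data preprocessed that way.
    """

    weights: list[np.ndarray]
    variable_scores: list[list[np.ndarray]]  # b_jl * centered (scaled) x_jl
    group_scores: list[np.ndarray]
    objective_trace: np.ndarray
    objective: float
    rho: float
    converged: bool
    n_iter: int
    tau: np.ndarray
    scheme: str
    design: np.ndarray
    column_sd: list[np.ndarray] | None = None

    @property
    def dims(self) -> list[int]:
        return [len(b) for b in self.weights]


def fit_rgcca(
    data: GroupData,
    design: np.ndarray | None = None,
    scheme="horst",
    config: FitConfig | None = None,
    scale: bool = True,
) -> LinearFitResult:
    """Block-coordinate ascent for the linear multi-block model.

    Same update structure, sign convention and stopping rule as the kernel
    solver; variances use the 1/n convention so the two models share a
    covariance scale. With ``scale=True`` (default, matching the reference
    R implementation of this method) every variable is standardized to
    unit variance before fitting; score correlations are unaffected but
    weights and the objective are on the standardized scale. tau defaults
    to 1 via FitConfig override by caller.
    """
    config = config or FitConfig(tau=1.0)
    n = data.n
    if n < 3:
        raise ValueError("fitting requires at least 3 samples")
    J = data.n_groups
    C = full_design(J) if design is None else validate_design(design, J)
    sch = get_scheme(scheme)
    tau = config.tau_vector(J)

    Xc = [b - b.mean(axis=0) for b in data.blocks]
    column_sd = None
    if scale:
        column_sd = []
        for j, X in enumerate(Xc):
            sd = X.std(axis=0, ddof=1)
            if np.any(sd == 0):
                l = int(np.argmax(sd == 0))
                raise ValueError(
                    f"cannot standardize constant variable {data.var_names[j][l]}"
                )
            Xc[j] = X / sd
            column_sd.append(sd)
    systems = []
    for j in range(J):
        M = tau[j] * np.eye(Xc[j].shape[1]) + (1 - tau[j]) * (Xc[j].T @ Xc[j]) / n
        systems.append(cho_factor(M, lower=True))

    def quadform(j, b):
        y = Xc[j] @ b
        return tau[j] * float(b @ b) + (1 - tau[j]) * float(y @ y) / n

    b = []
    if config.init == "data":
        for j in range(J):
            b.append(np.ones(Xc[j].shape[1]))
    elif config.init == "random":
        rng = np.random.default_rng(config.seed)
        for j in range(J):
            b.append(rng.standard_normal(Xc[j].shape[1]))
    else:
        raise ValueError(f"unknown init mode {config.init!r}")
    for j in range(J):
        q = quadform(j, b[j])
        if q <= 0:
            raise ValueError(f"degenerate initialization for group {j}")
        b[j] = b[j] / np.sqrt(q)
    y = [Xc[j] @ b[j] for j in range(J)]

    def covs():
        c = np.empty((J, J))
        for j in range(J):
            for k in range(J):
                c[j, k] = y[j] @ y[k] / n
        return c

    def obj_from(cov):
        return sum(
            C[j, k] * float(sch.g(cov[j, k]))
            for j in range(J)
            for k in range(J)
            if j != k and C[j, k]
        )

    cov = covs()
    trace = [obj_from(cov)]
    converged = False
    for _ in range(config.max_iter):
        for j in range(J):
            z = np.zeros(n)
            for k in range(J):
                if k != j and C[j, k]:
                    z += C[j, k] * float(sch.gprime(cov[j, k])) * y[k]
            if not np.any(z):
                continue
            cand = cho_solve(systems[j], Xc[j].T @ z / n)
            q = quadform(j, cand)
            if q <= 0:
                continue
            b[j] = cand / np.sqrt(q)
            y[j] = Xc[j] @ b[j]
            for k in range(J):
                cov[j, k] = y[j] @ y[k] / n
                cov[k, j] = cov[j, k]
        trace.append(obj_from(cov))
        if trace[-1] - trace[-2] < config.tol:
            converged = True
            break

    for j in range(J):
        s = sum(C[j, k] * cov[j, k] for k in range(J) if k != j)
        if s < 0:
            b[j] = -b[j]
            y[j] = -y[j]
            for k in range(J):
                if k != j:
                    cov[j, k] = -cov[j, k]
                    cov[k, j] = cov[j, k]

    variable_scores = [
        [b[j][l] * Xc[j][:, l] for l in range(Xc[j].shape[1])] for j in range(J)
    ]
    final_obj = obj_from(cov)
    return LinearFitResult(
        weights=[bj.copy() for bj in b],
        variable_scores=variable_scores,
        group_scores=[yj.copy() for yj in y],
        objective_trace=np.asarray(trace),
        objective=final_obj,
        rho=final_obj / 2.0,
        converged=converged,
        n_iter=len(trace) - 1,
        tau=tau,
        scheme=sch.name,
        design=C,
        column_sd=column_sd,
    )


def rgcca_constraint_value(fit: LinearFitResult, data: GroupData, j: int) -> float:
    """tau ||b_j||^2 + (1 - tau) Var(b_j' X_j) at the fitted weights.

    The variance is taken on the same (centered, optionally standardized)
    scale the weights were fitted on.
    """
    Xc = data.blocks[j] - data.blocks[j].mean(axis=0)
    if fit.column_sd is not None:
        Xc = Xc / fit.column_sd[j]
    y = Xc @ fit.weights[j]
    return float(
        fit.tau[j] * fit.weights[j] @ fit.weights[j]
        + (1 - fit.tau[j]) * (y @ y) / data.n
    )


def rgcca_measures(fit: LinearFitResult, absolute: bool = True, **kwargs):
    """Association report for the linear baseline.

    Relation = correlation of group scores; contribution of variable l =
    correlation of b_jl x_jl with the other group's score. Reported in
    absolute value by default, the convention used when comparing against
    the kernel model (signs flip freely across resamples).
    """
    from .measures import association_report

    return association_report(fit, absolute=absolute, **kwargs)
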