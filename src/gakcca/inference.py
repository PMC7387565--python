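"""Resampling test of no multi-group relationship.

The null distribution is built by resampling each group's rows with
replacement, independently across groups, which breaks any alignment
between groups while preserving every within-group joint distribution.
The whole estimation pipeline (bandwidths included) is re-run on every
resample. The p-value is the fraction of null statistics at or above the
observed one (the 1 - F_hat convention), so it can be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FitConfig, fit_gakcca
from .data import GroupData
from .kernels import DegenerateVariableError
from .measures import contribution_coefficient, relation_measure


@dataclass
class PermutationResult:
    statistic: tuple
    observed: float
    null_statistics: np.ndarray
    p_value: float
    m: int
    seed: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        assert len(self.null_statistics) == self.m


def resample_groups(data: GroupData, seed) -> GroupData:
    """Row-resample each group with replacement, independently per group.

    A row travels intact within its group (all p_j values together), but
    the alignment across groups is destroyed — the null configuration.
    ``seed`` may be an int or an existing Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = [b[rng.integers(0, data.n, size=data.n)] for b in data.blocks]
    return GroupData(blocks, list(data.group_names), [list(v) for v in data.var_names])


def _normalize_statistic(statistic) -> tuple:
    if statistic == "rho":
        return ("rho",)
    if isinstance(statistic, (tuple, list)):
        kind = statistic[0]
        if kind == "relation" and len(statistic) == 3:
            return ("relation", int(statistic[1]), int(statistic[2]))
        if kind == "contribution" and len(statistic) == 4:
            return ("contribution", int(statistic[1]), int(statistic[2]), int(statistic[3]))
    raise ValueError(f"unknown statistic {statistic!r}")


def _evaluate(fit, stat: tuple) -> float:
    if stat[0] == "rho":
        return fit.rho
    if stat[0] == "relation":
        return relation_measure(fit, stat[1], stat[2], strict=False)
    return contribution_coefficient(fit, stat[1], stat[2], stat[3], strict=False)


def permutation_test(
    data: GroupData,
    statistic="rho",
    m: int = 300,
    seed: int = 0,
    design=None,
    scheme="horst",
    kernel: str = "gaussian",
    config: FitConfig | None = None,
    method: str = "gakcca",
) -> PermutationResult:
    """Resampling p-value for one statistic.

    ``statistic`` is ``"rho"`` (the maximized objective), ``("relation",
    j, k)`` or ``("contribution", j, l, k)``. Signed statistics are
    compared on absolute values, since the sign of a canonical solution is
    not identified. A resample producing a degenerate (constant) variable
    is redrawn, up to ``10*m`` total attempts. ``method`` selects the
    kernel model (``"gakcca"``) or the linear baseline (``"rgcca"``).
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    stat = _normalize_statistic(statistic)

    def one_fit(d: GroupData):
        if method == "gakcca":
            return fit_gakcca(d, design=design, scheme=scheme, kernel=kernel, config=config)
        if method == "rgcca":
            from .rgcca import fit_rgcca

            return fit_rgcca(d, design=design, scheme=scheme, config=config)
        raise ValueError(f"unknown method {method!r}")

    observed = _evaluate(one_fit(data), stat)
    rng = np.random.default_rng(seed)
    null = np.empty(m)
    n_redrawn = 0
    attempts = 0
    i = 0
    while i < m:
        if attempts >= 10 * m:
            raise RuntimeError(
                f"resampling produced degenerate variables in {n_redrawn} of "
                f"{attempts} attempts; giving up"
            )
        attempts += 1
        resample = resample_groups(data, rng)
        try:
            null[i] = _evaluate(one_fit(resample), stat)
        except DegenerateVariableError:
            n_redrawn += 1
            continue
        i += 1

    if stat[0] == "rho":
        obs_cmp, null_cmp = observed, null
    else:
        obs_cmp, null_cmp = abs(observed), np.abs(null)
    valid = ~np.isnan(null_cmp)
    p_value = float(np.sum(null_cmp[valid] >= obs_cmp) / m)
    return PermutationResult(
        statistic=stat,
        observed=observed,
        null_statistics=null,
        p_value=p_value,
        m=m,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def permutation_test_all(
    data: GroupData,
    m: int = 300,
    seed: int = 0,
    design=None,
    scheme="horst",
    kernel: str = "gaussian",
    config: FitConfig | None = None,
    method: str = "gakcca",
) -> dict:
    """One resampling pass serving every statistic at once.

    Refitting is by far the dominant cost, so the pipeline computes the
    null draws of rho, all design-connected relation measures and all
    contribution coefficients from the same m refits. Returns a dict with
    ``rho`` (PermutationResult-like summary), ``relations`` (J x J array of
    p-values) and ``contributions`` (list of (j, l, k, p) records).
    """

    def one_fit(d):
        if method == "gakcca":
            return fit_gakcca(d, design=design, scheme=scheme, kernel=kernel, config=config)
        from .rgcca import fit_rgcca

        return fit_rgcca(d, design=design, scheme=scheme, config=config)

    fit = one_fit(data)
    C = fit.design
    J = len(fit.group_scores)
    dims = fit.dims
    pairs = [(j, k) for j in range(J) for k in range(J) if j != k and C[j, k]]
    triples = [(j, l, k) for (j, k) in pairs for l in range(dims[j])]

    obs_rho = fit.rho
    obs_rel = {p: relation_measure(fit, *p, strict=False) for p in pairs}
    obs_con = {t: contribution_coefficient(fit, *t, strict=False) for t in triples}

    rng = np.random.default_rng(seed)
    null_rho = np.empty(m)
    ge_rel = {p: 0 for p in pairs}
    ge_con = {t: 0 for t in triples}
    attempts = 0
    i = 0
    while i < m:
        if attempts >= 10 * m:
            raise RuntimeError("too many degenerate resamples")
        attempts += 1
        try:
            f = one_fit(resample_groups(data, rng))
        except DegenerateVariableError:
            continue
        null_rho[i] = f.rho
        for p in pairs:
            v = relation_measure(f, *p, strict=False)
            if not np.isnan(v) and abs(v) >= abs(obs_rel[p]):
                ge_rel[p] += 1
        for t in triples:
            v = contribution_coefficient(f, *t, strict=False)
            if not np.isnan(v) and abs(v) >= abs(obs_con[t]):
                ge_con[t] += 1
        i += 1

    rel_p = np.full((J, J), np.nan)
    for p in pairs:
        rel_p[p] = ge_rel[p] / m
    return {
        "fit": fit,
        "rho": PermutationResult(
            statistic=("rho",),
            observed=obs_rho,
            null_statistics=null_rho,
            p_value=float(np.sum(null_rho >= obs_rho) / m),
            m=m,
            seed=seed,
        ),
        "relations": {"observed": obs_rel, "p_values": rel_p},
        "contributions": [
            {"j": j, "l": l, "k": k, "estimate": obs_con[j, l, k], "p_value": ge_con[j, l, k] / m}
            for (j, l, k) in triples
        ],
    }
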