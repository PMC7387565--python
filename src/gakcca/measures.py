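"""Relation measures, per-variable contribution coefficients, prediction.

Because every fitted component is mean-zero (centered Grams), both measures
are plain Pearson correlations of score vectors:

* relation measure r_jk — correlation of the two groups' additive scores,
* contribution coefficient r_{jl,k} — correlation of one variable's fitted
  component with the *other* group's additive score; large magnitude means
  that variable carries the between-group relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GroupData
from .kernels import cross_gram_centered


class UndefinedMeasureError(ValueError):
    """Correlation undefined because a score vector has zero norm."""


def _corr(u: np.ndarray, v: np.ndarray, strict: bool, label: str) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        if strict:
            raise UndefinedMeasureError(f"zero-norm score vector in {label}")
        return math.nan
    return float(u @ v / (nu * nv))


def relation_measure(fit, j: int, k: int, strict: bool = True) -> float:
    """Correlation of group j's and group k's fitted score vectors.

    Algebraically identical to the ratio of the summed between-group
    Gram quadratic form to the two groups' own norms. With ``strict=False``
    a degenerate (zero-variance) score yields NaN instead of raising.
    """
    if j == k:
        raise ValueError("relation measure requires two distinct groups")
    return _corr(
        fit.group_scores[j], fit.group_scores[k], strict, f"relation({j},{k})"
    )


def contribution_coefficient(fit, j: int, l: int, k: int, strict: bool = True) -> float:
    """Correlation of variable (j, l)'s fitted component with group k's score."""
    if j == k:
        raise ValueError("contribution is defined against a different group")
    return _corr(
        fit.variable_scores[j][l],
        fit.group_scores[k],
        strict,
        f"contribution({j},{l},{k})",
    )


def evaluate_additive_function(
    fit, train_data: GroupData, j: int, new_block: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate group j's fitted additive function at new sample points.

    Each component f_jl is evaluated through the centered cross-kernel of
    the new values against the training values (centering statistics from
    training only), then summed. Feeding the training block back reproduces
    the stored in-sample scores exactly.

    Returns ``(per_variable, total)`` with shapes ``(q, p_j)`` and ``(q,)``.
    """
    new_block = np.atleast_2d(np.asarray(new_block, dtype=float))
    p_j = len(fit.coefficients[j])
    if new_block.shape[1] != p_j:
        raise ValueError(
            f"new block has {new_block.shape[1]} columns, expected {p_j}"
        )
    per_var = np.empty((new_block.shape[0], p_j))
    for l in range(p_j):
        Kc = cross_gram_centered(
            train_data.column(j, l), new_block[:, l], fit.kernel_specs[j][l]
        )
        per_var[:, l] = Kc @ fit.coefficients[j][l]
    return per_var, per_var.sum(axis=1)


@dataclass
class AssociationReport:
    """Tidy summary of group-level and variable-level association."""

    group_names: list[str]
    var_names: list[list[str]]
    relations: pd.DataFrame            # J x J, NaN where not design-connected
    contributions: pd.DataFrame        # group, variable, target_group, estimate
    rho: float
    relation_pvalues: pd.DataFrame | None = None
    rho_pvalue: float | None = None

    def contribution(self, j: int, l: int, k: int) -> pd.Series:
        mask = (
            (self.contributions["group"] == self.group_names[j])
            & (self.contributions["variable"] == self.var_names[j][l])
            & (self.contributions["target_group"] == self.group_names[k])
        )
        return self.contributions[mask].iloc[0]

    def to_tsv(self, path) -> None:
        rows = []
        J = len(self.group_names)
        for j in range(J):
            for k in range(J):
                if j == k or math.isnan(self.relations.iloc[j, k]):
                    continue
                rows.append(
                    {
                        "group_j": self.group_names[j],
                        "var_l": "*",
                        "group_k": self.group_names[k],
                        "estimate": self.relations.iloc[j, k],
                        "p_value": (
                            self.relation_pvalues.iloc[j, k]
                            if self.relation_pvalues is not None
                            else math.nan
                        ),
                    }
                )
        for _, r in self.contributions.iterrows():
            rows.append(
                {
                    "group_j": r["group"],
                    "var_l": r["variable"],
                    "group_k": r["target_group"],
                    "estimate": r["estimate"],
                    "p_value": r.get("p_value", math.nan),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def association_report(
    fit,
    group_names: list[str] | None = None,
    var_names: list[list[str]] | None = None,
    absolute: bool = False,
) -> AssociationReport:
    """All design-connected relation measures and contribution coefficients.

    Degenerate (zero-variance) entries become NaN so resampling loops
    survive pathological refits. ``absolute=True`` reports magnitudes, the
    convention used when signs are not identified.
    """
    J = len(fit.group_scores)
    dims = fit.dims
    if group_names is None:
        group_names = [f"g{j + 1}" for j in range(J)]
    if var_names is None:
        var_names = [[f"g{j + 1}_v{l + 1}" for l in range(dims[j])] for j in range(J)]
    rel = np.full((J, J), math.nan)
    for j in range(J):
        for k in range(J):
            if j != k and fit.design[j, k]:
                rel[j, k] = relation_measure(fit, j, k, strict=False)
    rows = []
    for j in range(J):
        for k in range(J):
            if j == k or not fit.design[j, k]:
                continue
            for l in range(dims[j]):
                est = contribution_coefficient(fit, j, l, k, strict=False)
                rows.append(
                    {
                        "group": group_names[j],
                        "variable": var_names[j][l],
                        "target_group": group_names[k],
                        "estimate": abs(est) if absolute else est,
                    }
                )
    if absolute:
        rel = np.abs(rel)
    return AssociationReport(
        group_names=list(group_names),
        var_names=[list(v) for v in var_names],
        relations=pd.DataFrame(rel, index=group_names, columns=group_names),
        contributions=pd.DataFrame(rows),
        rho=fit.rho,
    )
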