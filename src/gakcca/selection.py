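"""Cross-validated choice of the regularization parameter tau.

The criterion L(tau) compares, for every sample, the full-data fitted
additive score f_j(x) with the score predicted by a fit that never saw
that sample (G-fold), through the squared relative discrepancy

    L(tau) = (1/G) sum_g sum_j sum_{x in fold g} ((f_j(x) - f_j^{-g}(x)) / f_j(x))^2.

A small L means the fitted functions are stable under data splitting.
The denominator can be arbitrarily close to zero, so terms with
|f_j(x)| below a guard (1e-8 times the score's standard deviation) are
dropped and counted. Ties in the grid search are broken toward the larger
(more regularized) tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import FitConfig, fit_gakcca
from .data import GroupData
from .measures import evaluate_additive_function


@dataclass(frozen=True)
class CvConfig:
    grid: tuple = (0.01, 0.05, 0.1, 0.25, 0.5, 1.0)
    n_folds: int = 5
    seed: int = 0
    eps_denom_scale: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not self.grid:
            raise ValueError("tau grid must be nonempty")
        if any(not (0 < t <= 1) for t in self.grid):
            raise ValueError("grid values must lie in (0, 1]")


@dataclass
class CvScore:
    tau: float
    L: float
    n_terms: int
    n_guarded: int


@dataclass
class SelectionResult:
    tau: float
    table: pd.DataFrame = field(repr=False)


def make_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of range(n) into near-equal folds."""
    if n_folds < 2 or n_folds > n:
        raise ValueError("need 2 <= n_folds <= n")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def cv_score(
    data: GroupData,
    tau: float,
    folds,
    design=None,
    scheme="horst",
    kernel: str = "gaussian",
    config: FitConfig | None = None,
    eps_denom_scale: float = 1e-8,
) -> CvScore:
    """Compute L(tau) for one candidate on a given fold structure.

    ``folds`` is a list of held-out index arrays (their complements are
    the training sets), or a list of ``(train_idx, test_idx)`` pairs for
    explicit control. Fold fits recompute bandwidths on their own training
    rows; each fold fit's group score is sign-aligned to the full fit on
    the training samples before the discrepancy is formed, because the
    canonical solution's sign is arbitrary.
    """
    base = config or FitConfig()
    cfg = replace(base, tau=tau)
    n = data.n

    pairs = []
    for f in folds:
        if isinstance(f, tuple):
            train_idx, test_idx = np.asarray(f[0]), np.asarray(f[1])
        else:
            test_idx = np.asarray(f)
            train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(test_idx) < 2:
            raise ValueError("every fold must hold out at least 2 samples")
        pairs.append((train_idx, test_idx))

    full_fit = fit_gakcca(data, design=design, scheme=scheme, kernel=kernel, config=cfg)
    f_full = full_fit.group_scores
    J = len(f_full)
    eps = [eps_denom_scale * float(np.std(f_full[j])) for j in range(J)]

    total = 0.0
    n_terms = 0
    n_guarded = 0
    for train_idx, test_idx in pairs:
        sub = data.subset_rows(train_idx)
        fold_fit = fit_gakcca(sub, design=design, scheme=scheme, kernel=kernel, config=cfg)
        for j in range(J):
            _, pred = evaluate_additive_function(
                fold_fit, sub, j, data.blocks[j][test_idx]
            )
            if fold_fit.group_scores[j] @ f_full[j][train_idx] < 0:
                pred = -pred
            denom = f_full[j][test_idx]
            guard = np.abs(denom) < eps[j]
            n_guarded += int(guard.sum())
            ok = ~guard
            total += float(np.sum(((denom[ok] - pred[ok]) / denom[ok]) ** 2))
            n_terms += int(ok.sum())
    return CvScore(tau=float(tau), L=total / len(pairs), n_terms=n_terms, n_guarded=n_guarded)


def select_tau(
    data: GroupData,
    cv: CvConfig | None = None,
    design=None,
    scheme="horst",
    kernel: str = "gaussian",
    config: FitConfig | None = None,
) -> SelectionResult:
    """Grid-search tau (shared across groups) by minimizing L(tau).

    Folds depend only on (n, G, seed), so the selection is deterministic.
    Duplicated grid entries are collapsed; exact ties go to the larger tau.
    Raises if the guard removed every term for every candidate.
    """
    cv = cv or CvConfig()
    folds = make_folds(data.n, cv.n_folds, cv.seed)
    rows = []
    best = None
    for tau in sorted(set(float(t) for t in cv.grid)):
        score = cv_score(
            data, tau, folds, design=design, scheme=scheme, kernel=kernel,
            config=config, eps_denom_scale=cv.eps_denom_scale,
        )
        rows.append(score)
        if score.n_terms == 0:
            continue
        if best is None or score.L <= best.L:
            best = score
    if best is None:
        raise RuntimeError("tau selection failed: every candidate fully guarded")
    table = pd.DataFrame(
        {
            "tau": [r.tau for r in rows],
            "L": [r.L for r in rows],
            "n_terms": [r.n_terms for r in rows],
            "n_guarded": [r.n_guarded for r in rows],
        }
    )
    return SelectionResult(tau=best.tau, table=table)
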