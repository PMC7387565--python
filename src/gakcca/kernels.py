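"""Per-variable kernels, Gram matrices, centering, and cross-kernel columns.

Every variable gets its own scalar kernel. For the Gaussian family the
bandwidth is the median of the pairwise absolute differences among that
variable's samples (the median heuristic); the linear kernel ``phi(x,y)=xy``
is provided so the method collapses to its linear counterpart in tests.
All empirical quantities downstream are quadratic forms in the
double-centered Gram matrices built here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .data import GroupData


class DegenerateVariableError(ValueError):
    """A variable whose median pairwise distance is zero (near-constant)."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and (for the Gaussian family) its fitted bandwidth."""

    family: str  # "gaussian" or "linear"
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "linear"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian":
            if self.bandwidth is None or not self.bandwidth > 0:
                raise ValueError("gaussian kernel requires bandwidth > 0")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Evaluate the kernel on broadcastable scalar arrays."""
        if self.family == "gaussian":
            return np.exp(-((x - y) ** 2) / (2.0 * self.bandwidth**2))
        return np.asarray(x * y, dtype=float)


def median_bandwidth(x: np.ndarray, name: str | None = None) -> float:
    """Median of the n(n-1)/2 pairwise absolute differences |x_i - x_i'|.

    Ties contribute zero distances; only a zero *median* is an error,
    raised as :class:`DegenerateVariableError` naming the column.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("median_bandwidth needs at least 2 samples")
    med = float(np.median(pdist(x[:, None], metric="cityblock")))
    if med == 0.0:
        label = name if name is not None else "<unnamed>"
        raise DegenerateVariableError(
            f"variable {label}: median pairwise distance is zero"
        )
    return med


def gaussian_gram(x: np.ndarray, sigma: float) -> np.ndarray:
    """Gram matrix of exp(-(x_i - x_i')^2 / (2 sigma^2)); unit diagonal."""
    if not sigma > 0:
        raise ValueError("bandwidth sigma must be positive")
    x = np.asarray(x, dtype=float).ravel()
    d2 = (x[:, None] - x[None, :]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def linear_gram(x: np.ndarray) -> np.ndarray:
    """Gram matrix of the linear kernel phi(x,y) = xy (outer product)."""
    x = np.asarray(x, dtype=float).ravel()
    return np.outer(x, x)


def center_gram(K: np.ndarray) -> np.ndarray:
    """Double-center a Gram matrix: K - rowmean - colmean + grandmean.

    Equivalent to H K H with H = I - J/n; idempotent, and leaves all row
    and column sums at zero.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("center_gram requires a square matrix")
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    return K - row - col + K.mean()


def cross_gram_centered(
    x_train: np.ndarray, x_new: np.ndarray, spec: KernelSpec
) -> np.ndarray:
    """Centered kernel evaluations of new points against the training set.

    Row r, column i holds ``phi(x_new[r], x_train[i])`` centered with
    statistics of the *training* Gram only, so evaluating the fitted
    additive component at held-out points is ``Kc @ a``. When
    ``x_new == x_train`` the result equals ``center_gram`` of the training
    Gram row-for-row.
    """
    x_train = np.asarray(x_train, dtype=float).ravel()
    x_new = np.asarray(x_new, dtype=float).ravel()
    if x_train.size == 0:
        raise ValueError("cross_gram_centered requires a nonempty training set")
    K_train = spec(x_train[:, None], x_train[None, :])
    Kc = spec(x_new[:, None], x_train[None, :])
    return (
        Kc
        - Kc.mean(axis=1, keepdims=True)
        - K_train.mean(axis=0, keepdims=True)
        + K_train.mean()
    )


@dataclass
class GramSet:
    """Per-variable raw and centered Gram matrices for a whole dataset."""

    raw: list[list[np.ndarray]]
    centered: list[list[np.ndarray]]
    specs: list[list[KernelSpec]]
    n: int

    @property
    def dims(self) -> list[int]:
        return [len(g) for g in self.centered]


def build_gram_set(data: GroupData, family: str = "gaussian") -> GramSet:
    """Fit per-variable kernels on a dataset and assemble all Gram matrices.

    Gaussian bandwidths come from the median heuristic on each column of
    the data given here, so refits on resampled or training subsets get
    their own bandwidths.
    """
    raw, centered, specs = [], [], []
    for j, block in enumerate(data.blocks):
        raw_j, cent_j, spec_j = [], [], []
        for l in range(block.shape[1]):
            x = block[:, l]
            if family == "gaussian":
                sigma = median_bandwidth(x, name=data.var_names[j][l])
                spec = KernelSpec("gaussian", sigma)
                K = gaussian_gram(x, sigma)
            elif family == "linear":
                spec = KernelSpec("linear")
                K = linear_gram(x)
            else:
                raise ValueError(f"unknown kernel family {family!r}")
            raw_j.append(K)
            cent_j.append(center_gram(K))
            spec_j.append(spec)
        raw.append(raw_j)
        centered.append(cent_j)
        specs.append(spec_j)
    return GramSet(raw=raw, centered=centered, specs=specs, n=data.n)
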