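"""Multi-block sample container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GroupData:
    """J groups of variables measured on the same n samples.

    Parameters
    ----------
    blocks
        List of J arrays, block ``j`` of shape ``(n, p_j)``. All blocks must
        share the same number of rows and contain no missing values.
    group_names
        Optional group labels; defaults to ``g1, ..., gJ``.
    var_names
        Optional per-group variable labels; defaults to ``g{j}_v{l}``.
    """

    blocks: list[np.ndarray]
    group_names: list[str] = field(default=None)
    var_names: list[list[str]] = field(default=None)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("GroupData requires at least one block")
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        n = self.blocks[0].shape[0]
        for j, b in enumerate(self.blocks):
            if b.ndim != 2:
                raise ValueError(f"block {j} is not 2-dimensional")
            if b.shape[0] != n:
                raise ValueError(
                    f"block {j} has {b.shape[0]} rows, expected {n}"
                )
            if b.shape[1] < 1:
                raise ValueError(f"block {j} has no variables")
            if not np.all(np.isfinite(b)):
                raise ValueError(f"block {j} contains non-finite values")
        if self.group_names is None:
            self.group_names = [f"g{j + 1}" for j in range(len(self.blocks))]
        if len(self.group_names) != len(self.blocks):
            raise ValueError("group_names length does not match blocks")
        if self.var_names is None:
            self.var_names = [
                [f"g{j + 1}_v{l + 1}" for l in range(b.shape[1])]
                for j, b in enumerate(self.blocks)
            ]
        for j, (names, b) in enumerate(zip(self.var_names, self.blocks)):
            if len(names) != b.shape[1]:
                raise ValueError(f"var_names for block {j} mismatch its width")

    @property
    def n(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.blocks)

    @property
    def dims(self) -> list[int]:
        return [b.shape[1] for b in self.blocks]

    def column(self, j: int, l: int) -> np.ndarray:
        """Return variable ``l`` of group ``j`` as a 1-d array."""
        return self.blocks[j][:, l]

    def subset_rows(self, idx) -> "GroupData":
        """New GroupData with the given rows (kept aligned across groups)."""
        idx = np.asarray(idx)
        return GroupData(
            [b[idx] for b in self.blocks],
            group_names=list(self.group_names),
            var_names=[list(v) for v in self.var_names],
        )

    def zscored(self) -> "GroupData":
        """Return a copy with every column standardized to mean 0, sd 1."""
        out = []
        for j, b in enumerate(self.blocks):
            sd = b.std(axis=0, ddof=1)
            if np.any(sd == 0):
                l = int(np.argmax(sd == 0))
                raise ValueError(
                    f"cannot z-score constant variable {self.var_names[j][l]}"
                )
            out.append((b - b.mean(axis=0)) / sd)
        return GroupData(out, list(self.group_names), [list(v) for v in self.var_names])

    def to_frame(self) -> pd.DataFrame:
        """Flatten into a samples x variables DataFrame (group-map order)."""
        cols = {}
        for j, b in enumerate(self.blocks):
            for l in range(b.shape[1]):
                cols[self.var_names[j][l]] = b[:, l]
        return pd.DataFrame(cols)

    def group_map(self) -> dict[str, list[str]]:
        """JSON-serializable mapping group name -> list of its column names."""
        return {
            self.group_names[j]: list(self.var_names[j])
            for j in range(self.n_groups)
        }
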