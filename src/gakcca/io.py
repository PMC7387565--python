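"""CSV / JSON input and output for grouped tabular data and fit results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GroupData


class ParseError(ValueError):
    pass


def read_group_map(path) -> dict[str, list[str]]:
    with open(path) as fh:
        mapping = json.load(fh)
    if not isinstance(mapping, dict) or not mapping:
        raise ParseError(f"{path}: group map must be a nonempty JSON object")
    for g, cols in mapping.items():
        if not isinstance(cols, list) or not cols:
            raise ParseError(f"{path}: group {g!r} must list at least one column")
    return mapping


def read_grouped_csv(data_path, groups_path) -> GroupData:
    """Read a flat samples x variables CSV plus a JSON group map.

    Blocks come back in group-map order. Columns absent from the map are
    ignored; a column mapped twice, an unknown column, a non-numeric cell
    or a missing value is an error naming the offending location.
    """
    mapping = read_group_map(groups_path)
    sep = "\t" if str(data_path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(data_path, sep=sep)

    seen: dict[str, str] = {}
    for g, cols in mapping.items():
        for c in cols:
            if c in seen:
                raise ParseError(f"column {c!r} mapped to both {seen[c]!r} and {g!r}")
            if c not in df.columns:
                raise ParseError(f"column {c!r} (group {g!r}) not in {data_path}")
            seen[c] = g

    used = [c for cols in mapping.values() for c in cols]
    sub = df[used].apply(lambda s: pd.to_numeric(s, errors="coerce"))
    bad = sub.isna()
    if bad.to_numpy().any():
        locs = [
            (int(i), c) for c in used for i in sub.index[bad[c]][:5]
        ]
        raise ParseError(f"missing or non-numeric cells at (row, column): {locs}")

    blocks = [sub[cols].to_numpy(dtype=float) for cols in mapping.values()]
    return GroupData(
        blocks,
        group_names=list(mapping.keys()),
        var_names=[list(cols) for cols in mapping.values()],
    )


def write_grouped_csv(data: GroupData, data_path, groups_path=None) -> None:
    data.to_frame().to_csv(data_path, index=False)
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            json.dump(data.group_map(), fh, indent=1)


def read_design(path, J: int) -> np.ndarray:
    with open(path) as fh:
        C = np.asarray(json.load(fh), dtype=float)
    if C.shape != (J, J):
        raise ParseError(f"{path}: design must be a {J}x{J} list of lists")
    return C


def _round_floats(obj, digits: int = 12):
    """Recursively round floats to a fixed significant-digit budget."""
    if isinstance(obj, float):
        return float(f"{obj:.{digits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, np.floating):
        return float(f"{float(obj):.{digits}g}")
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), digits)
    return obj


def write_json(obj, path) -> None:
    """Serialize with all floats at 12 significant digits (stable output)."""
    Path(path).write_text(json.dumps(_round_floats(obj), indent=1, allow_nan=True) + "\n")


def fit_to_dict(fit) -> dict:
    """JSON-serializable view of a (kernel or linear) fit result."""
    out = {
        "rho": fit.rho,
        "objective": fit.objective,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "tau": fit.tau.tolist(),
        "scheme": fit.scheme,
        "design": fit.design.tolist(),
        "objective_trace": np.asarray(fit.objective_trace).tolist(),
        "group_scores": [s.tolist() for s in fit.group_scores],
        "variable_scores": [[s.tolist() for s in g] for g in fit.variable_scores],
    }
    if hasattr(fit, "coefficients"):
        out["coefficients"] = [[a.tolist() for a in g] for g in fit.coefficients]
        out["bandwidths"] = [
            [spec.bandwidth for spec in g] for g in fit.kernel_specs
        ]
    if hasattr(fit, "weights"):
        out["weights"] = [b.tolist() for b in fit.weights]
    return out
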