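"""Compositional preprocessing: closure, zero replacement, CLR/ILR.

Flow-injection MRM intensities carry only relative information, so every
analysis operates on compositions (rows normalized to total ion count) and
log-ratio coordinates.  The centered log-ratio (CLR) keeps one coordinate
per ion and is used for feature-level analyses; the isometric log-ratio
(ILR) maps to an orthonormal basis of D-1 balances and is offered for
distance-based work.  Both are invariant to per-sample rescaling, which is
the property that makes uncalibrated flow-injection signal usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mrm_io import IntensityMatrix


class DegenerateSampleError(ValueError):
    """A sample has no positive signal and cannot be closed."""


class BasisError(ValueError):
    """An ILR basis is not orthonormal on the CLR plane."""


@dataclass
class LogRatioMatrix:
    """Samples x features matrix on a log-ratio scale.

    ``transform`` is "clr" or "ilr"; for ILR, ``basis`` holds the
    (D-1) x D orthonormal contrast matrix used.
    """

    values: pd.DataFrame
    transform: str
    basis: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.transform not in ("clr", "ilr"):
            raise ValueError(f"transform must be 'clr' or 'ilr', got {self.transform!r}")
        if self.transform == "ilr" and self.basis is None:
            raise BasisError("ilr output must record its basis")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


def _as_frame(matrix: IntensityMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, IntensityMatrix) else matrix


def close(matrix: IntensityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its total so rows sum to 1; zeros are preserved."""
    frame = _as_frame(matrix)
    arr = frame.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("intensities must be nonnegative")
    totals = arr.sum(axis=1)
    dead = np.flatnonzero(totals <= 0)
    if dead.size:
        raise DegenerateSampleError(
            f"sample(s) with no positive signal: {list(frame.index[dead])}"
        )
    return pd.DataFrame(arr / totals[:, None], index=frame.index, columns=frame.columns)


def replace_zeros(
    composition: pd.DataFrame,
    strategy: str = "multiplicative",
    delta_fraction: float = 0.65,
) -> pd.DataFrame:
    """Replace zeros so log-ratios are defined, keeping rows summing to 1.

    The multiplicative strategy imputes each zero with
    ``delta_fraction * (smallest positive value in that column)`` and
    rescales the positive parts of the row so it still sums to 1 — the
    standard below-detection-limit treatment for compositions.  The
    pseudocount strategy adds ``delta_fraction`` times the smallest overall
    positive value to every cell and re-closes.  Columns that are entirely
    zero carry no relative information and are dropped with a warning.
    """
    arr = composition.to_numpy(float).copy()
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("input rows must sum to 1 (apply close() first)")
    all_zero = (arr <= 0).all(axis=0)
    if all_zero.any():
        dropped = list(composition.columns[all_zero])
        warnings.warn(f"dropping all-zero feature column(s): {dropped}", stacklevel=2)
        composition = composition.loc[:, ~all_zero]
        arr = arr[:, ~all_zero]
        arr = arr / arr.sum(axis=1, keepdims=True)
    if (arr > 0).all():
        return pd.DataFrame(arr, index=composition.index, columns=composition.columns)
    if strategy == "multiplicative":
        col_min = np.where(arr > 0, arr, np.inf).min(axis=0)
        delta = delta_fraction * col_min
        zero = arr <= 0
        replaced = np.where(zero, delta[None, :], arr)
        delta_sum = (zero * delta[None, :]).sum(axis=1)
        if (delta_sum >= 1).any():
            raise ValueError("imputed zeros exceed the unit total; lower delta_fraction")
        scale = (1.0 - delta_sum) / (arr * ~zero).sum(axis=1)
        out = np.where(zero, replaced, arr * scale[:, None])
    elif strategy == "pseudocount":
        eps = delta_fraction * arr[arr > 0].min()
        out = arr + eps
        out = out / out.sum(axis=1, keepdims=True)
    else:
        raise ValueError("strategy must be 'multiplicative' or 'pseudocount'")
    return pd.DataFrame(out, index=composition.index, columns=composition.columns)


def clr(composition: pd.DataFrame) -> LogRatioMatrix:
    """Centered log-ratio transform: log(x_i / geometric mean of the row)."""
    arr = composition.to_numpy(float)
    if (arr <= 0).any():
        raise ValueError("clr requires strictly positive compositions")
    logs = np.log(arr)
    values = logs - logs.mean(axis=1, keepdims=True)
    return LogRatioMatrix(
        values=pd.DataFrame(values, index=composition.index, columns=composition.columns),
        transform="clr",
    )


def pivot_basis(n_parts: int) -> np.ndarray:
    """Orthonormal pivot (sequential binary partition) ILR basis.

    Row i contrasts part i against the geometric mean of parts i+1..D; the
    rows are orthonormal vectors in the CLR plane (each sums to zero).
    """
    if n_parts < 2:
        raise ValueError("need at least 2 parts")
    D = n_parts
    basis = np.zeros((D - 1, D))
    for i in range(D - 1):
        r = D - i - 1  # number of parts to the right
        basis[i, i] = np.sqrt(r / (r + 1))
        basis[i, i + 1 :] = -1.0 / np.sqrt(r * (r + 1))
    return basis


def ilr(composition: pd.DataFrame, basis: np.ndarray | None = None) -> LogRatioMatrix:
    """Isometric log-ratio transform onto an orthonormal balance basis.

    Coordinates are ``clr(row) @ basis.T``; the map is an isometry, so ILR
    rows have the same Euclidean norm as the CLR rows.
    """
    D = composition.shape[1]
    if basis is None:
        basis = pivot_basis(D)
    basis = np.asarray(basis, float)
    if basis.shape != (D - 1, D):
        raise BasisError(f"basis must be (D-1, D) = {(D - 1, D)}, got {basis.shape}")
    if not np.allclose(basis @ basis.T, np.eye(D - 1), atol=1e-8) or not np.allclose(
        basis.sum(axis=1), 0.0, atol=1e-8
    ):
        raise BasisError("basis rows must be orthonormal and sum to zero")
    clr_values = clr(composition).values.to_numpy()
    coords = clr_values @ basis.T
    columns = [f"ilr_{i + 1}" for i in range(D - 1)]
    return LogRatioMatrix(
        values=pd.DataFrame(coords, index=composition.index, columns=columns),
        transform="ilr",
        basis=basis,
    )


def standardize_to_reference(
    lrm: LogRatioMatrix | pd.DataFrame, reference: list[str]
) -> pd.DataFrame:
    """Scale features to SD units of a reference subgroup (e.g. WT females).

    Per feature, subtract the reference-group mean and divide by the
    reference-group SD (ddof=1), so values read as "SDs away from the
    reference group".  Features constant within the reference are flagged
    and set to NaN with a warning.
    """
    frame = lrm.values if isinstance(lrm, LogRatioMatrix) else lrm
    reference = list(reference)
    if not reference:
        raise ValueError("reference subset must be nonempty")
    missing = [s for s in reference if s not in frame.index]
    if missing:
        raise KeyError(f"reference sample(s) not found: {missing}")
    ref = frame.loc[reference]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    degenerate = ~(sd > 0)
    if degenerate.any():
        warnings.warn(
            f"feature(s) constant in reference set to NaN: "
            f"{list(frame.columns[degenerate])}",
            stacklevel=2,
        )
    out = (frame - mean) / sd.where(~degenerate)
    return out
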