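"""Compositional principal components (CPCs) and per-category compression.

PCA on CLR-transformed compositions ("compositional PCA") is used two
ways: globally, to visualize how samples separate by sex, genotype and
disease stage; and per lipid category, to compress each category's ions
into the smallest number of components retaining 95% of that category's
variance.  The per-category score columns — named like
"sphingolipid CPC 4" — form the compressed feature set fed to the
downstream univariate and elastic-net selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coda
from .mrm_io import IntensityMatrix, TransitionTable


class DegenerateInputError(ValueError):
    """The input matrix is constant and has no principal directions."""


@dataclass
class CompressedFeatureSet:
    """Retained CPC scores and loadings for one category (or "global").

    ``scores`` is samples x k; ``loadings`` is k x features with orthonormal
    rows; ``variance_fraction`` holds the k retained fractions and
    ``all_variance_fraction`` the full spectrum (summing to 1).
    """

    category: str
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    all_variance_fraction: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.all_variance_fraction) > 1e-12):
            raise ValueError("variance fractions must be nonincreasing")
        if abs(self.all_variance_fraction.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")

    @property
    def feature_names(self) -> list[str]:
        return list(self.scores.columns)


def fit_cpc(
    lrm: "coda.LogRatioMatrix | pd.DataFrame",
    n_components: int | float | None = None,
    category: str = "global",
) -> CompressedFeatureSet:
    """PCA via SVD of the column-centered log-ratio matrix.

    ``n_components`` is either an integer count, a variance target in
    (0, 1] (smallest k whose cumulative variance fraction reaches it), or
    None for the full rank.  Scores are the centered data projected on the
    right singular vectors; variance_fraction_i = sigma_i^2 / sum sigma^2.
    Sign convention: the largest-magnitude loading of each component is
    positive, so CPC features are reproducible across runs and platforms.
    """
    frame = lrm.values if isinstance(lrm, coda.LogRatioMatrix) else lrm
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    X = frame.to_numpy(float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    if total <= 1e-24:
        raise DegenerateInputError("constant input matrix has no principal components")
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    fractions = s**2 / total

    if n_components is None:
        k = len(s)
    elif isinstance(n_components, (int, np.integer)) and not isinstance(
        n_components, bool
    ):
        if not 1 <= n_components <= len(s):
            raise ValueError(f"n_components must be in [1, {len(s)}]")
        k = int(n_components)
    else:
        target = float(n_components)
        if not 0 < target <= 1:
            raise ValueError("variance target must lie in (0, 1]")
        cumulative = np.cumsum(fractions)
        k = int(np.searchsorted(cumulative, target - 1e-12) + 1)
        k = min(k, len(s))

    names = [f"{category} CPC {j + 1}" for j in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=frame.index, columns=names)
    loadings = pd.DataFrame(Vt[:k], index=names, columns=frame.columns)
    return CompressedFeatureSet(
        category=category,
        scores=scores,
        loadings=loadings,
        variance_fraction=fractions[:k],
        all_variance_fraction=fractions,
        k=k,
    )


def compress_categories(
    matrix: IntensityMatrix,
    transitions: TransitionTable,
    variance_target: float = 0.95,
    delta_fraction: float = 0.65,
    zero_strategy: str = "multiplicative",
    mode: str = "subcomposition",
) -> tuple[list[CompressedFeatureSet], pd.DataFrame]:
    """Compress each lipid category into CPCs retaining ``variance_target``.

    In the default "subcomposition" mode each category's ions are treated
    as a composition of their own: re-closed, zero-replaced and
    CLR-transformed before the SVD.  Mode "global-clr" instead slices the
    category's columns out of a single whole-matrix CLR (no re-closure),
    for comparison.  Categories with fewer than two ions are skipped with a
    warning.  Returns the per-category feature sets and the column-bound
    combined score matrix with names "<category> CPC <j>".
    """
    if mode not in ("subcomposition", "global-clr"):
        raise ValueError("mode must be 'subcomposition' or 'global-clr'")
    categories = transitions.categories()
    ids_present = [t for t in matrix.transitions if t in categories.index]
    if len(ids_present) != len(matrix.transitions):
        missing = sorted(set(matrix.transitions) - set(categories.index))
        raise KeyError(f"transitions without category annotation: {missing[:5]}")
    global_lrm = None
    if mode == "global-clr":
        comp = coda.close(matrix)
        comp = coda.replace_zeros(comp, zero_strategy, delta_fraction)
        global_lrm = coda.clr(comp).values
    feature_sets: list[CompressedFeatureSet] = []
    blocks: list[pd.DataFrame] = []
    for label in sorted(set(categories.loc[ids_present])):
        ions = [t for t in matrix.transitions if categories[t] == label]
        if len(ions) < 2:
            warnings.warn(
                f"category {label!r} has fewer than 2 ions; skipped", stacklevel=2
            )
            continue
        if mode == "subcomposition":
            sub = coda.close(matrix.values[ions])
            sub = coda.replace_zeros(sub, zero_strategy, delta_fraction)
            lrm = coda.clr(sub)
        else:
            lrm = global_lrm[[i for i in ions if i in global_lrm.columns]]
        cfs = fit_cpc(lrm, n_components=variance_target, category=label)
        feature_sets.append(cfs)
        blocks.append(cfs.scores)
    combined = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=matrix.values.index)
    return feature_sets, combined


def variable_contributions(cfs: CompressedFeatureSet, component: int) -> pd.Series:
    """Percent contribution of each feature to one component.

    ``contribution_i = 100 * loading_i^2 / sum(loadings^2)``; sums to 100.
    ``component`` is 1-based, matching the CPC naming.
    """
    if not 1 <= component <= cfs.k:
        raise ValueError(f"component must be in [1, {cfs.k}]")
    loadings = cfs.loadings.iloc[component - 1].to_numpy()
    weights = loadings**2
    return pd.Series(
        100.0 * weights / weights.sum(),
        index=cfs.loadings.columns,
        name=f"{cfs.category} CPC {component} contribution (%)",
    )
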