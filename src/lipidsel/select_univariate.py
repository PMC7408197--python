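"""Tier-1 univariate filter: per-feature linear models and effect sizes.

Each feature (a log-ratio-transformed ion or a compressed per-category CPC
score) is regressed on one experimental factor — sex, genotype, or ordinal
disease progression — optionally adjusting for covariates.  Effect sizes
are reported as eta-squared (SS_factor / SS_total) and partial eta-squared
(SS_factor / (SS_factor + SS_error)) from a sequential decomposition with
the factor entered last, p-values are Benjamini–Hochberg adjusted within
each factor's family, and the published inclusion/exclusion rules rank and
truncate the surviving features.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The closed set of lipid-category annotations.  Composite labels reflect
#: attribution uncertainty when a single MRM is compatible with two classes.
CATEGORY_LABELS = (
    "acylcarnitine",
    "acylcarnitine-or-glycerolipid",
    "cholesteryl-ester",
    "DAG",
    "glycerolipid",
    "phospholipid",
    "phospholipid-or-cholesteryl-ester",
    "phospholipid-or-glycerolipid",
    "sphingolipid",
    "sphingolipid-or-glycerolipid",
)

#: Ordinal coding of disease stage used by the progression models.
STAGE_SCORES = {"control": 0, "non-lesional": 1, "established": 2, "advanced": 3}

FACTORS = ("sex", "genotype", "progression")


def _factor_columns(
    metadata: pd.DataFrame, factor: str, progression_coding: str = "numeric"
) -> np.ndarray:
    """Design columns for one factor, shape (n, k)."""
    if factor == "sex":
        levels = metadata["sex"].astype(str)
        if set(levels) - {"F", "M"}:
            raise ValueError(f"unexpected sex levels {sorted(set(levels))}")
        return (levels == "M").to_numpy(float)[:, None]
    if factor == "genotype":
        levels = metadata["genotype"].astype(str)
        if set(levels) - {"WT", "cpdm"}:
            raise ValueError(f"unexpected genotype levels {sorted(set(levels))}")
        return (levels == "cpdm").to_numpy(float)[:, None]
    if factor == "progression":
        scores = metadata["stage"].map(STAGE_SCORES)
        if scores.isna().any():
            raise ValueError("unknown stage label in metadata")
        if progression_coding == "numeric":
            return scores.to_numpy(float)[:, None]
        if progression_coding == "categorical":
            # treatment contrasts against the lowest observed stage
            present = sorted(set(scores))
            return np.column_stack(
                [(scores == lvl).to_numpy(float) for lvl in present[1:]]
            )
        raise ValueError("progression_coding must be 'numeric' or 'categorical'")
    raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")


def fit_feature_models(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    factor: str,
    covariates: Sequence[str] = (),
    progression_coding: str = "numeric",
    adjust: bool = True,
) -> pd.DataFrame:
    """Fit one OLS model per feature and return effect sizes and p-values.

    The model is ``feature ~ intercept + covariates + factor`` with the
    factor entered last, so SS_factor is the sequential (type-I) increment
    over the covariate-only model.  With no covariates, partial eta-squared
    equals eta-squared.  Constant features get eta2 = 0, p = 1 and are
    flagged.  Returns a DataFrame indexed by feature_id with columns
    factor, coefficient, p_value, p_adjusted, eta2, partial_eta2, n, constant.
    """
    if not features.index.equals(metadata.index):
        metadata = metadata.loc[features.index]
    n = len(features)
    Y = features.to_numpy(float)
    if not np.isfinite(Y).all():
        raise ValueError("features contain non-finite values")
    factor_cols = _factor_columns(metadata, factor, progression_coding)
    base = [np.ones((n, 1))]
    for cov in covariates:
        base.append(_factor_columns(metadata, cov))
    X_red = np.column_stack(base)
    X_full = np.column_stack([X_red, factor_cols])
    rank_red = np.linalg.matrix_rank(X_red)
    rank_full = np.linalg.matrix_rank(X_full)
    df_factor = rank_full - rank_red
    df_error = n - rank_full
    if df_factor < 1:
        raise ValueError(f"factor {factor!r} has fewer than 2 distinct levels")
    if df_error < 1:
        raise ValueError("more model terms than samples")

    beta_full, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    beta_red, *_ = np.linalg.lstsq(X_red, Y, rcond=None)
    sse_full = ((Y - X_full @ beta_full) ** 2).sum(axis=0)
    sse_red = ((Y - X_red @ beta_red) ** 2).sum(axis=0)
    ss_factor = np.maximum(sse_red - sse_full, 0.0)
    ss_total = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)

    constant = ss_total <= 1e-12 * np.maximum(1.0, np.abs(Y).max(axis=0)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        eta2 = np.where(constant, 0.0, ss_factor / np.where(constant, 1.0, ss_total))
        partial = np.where(
            ss_factor + sse_full > 0, ss_factor / (ss_factor + sse_full), 0.0
        )
        f_stat = (ss_factor / df_factor) / np.where(
            sse_full > 0, sse_full / df_error, np.nan
        )
    p = stats.f.sf(f_stat, df_factor, df_error)
    # perfect fits: SSE == 0 with a real factor effect
    p = np.where(np.isnan(p) & (ss_factor > 0) & ~constant, 0.0, p)
    p = np.where(constant, 1.0, p)
    eta2 = np.clip(eta2, 0.0, 1.0)
    partial = np.where(constant, 0.0, np.clip(partial, 0.0, 1.0))
    # single-column factors: report the (last) slope; multi-column: NaN
    coef = beta_full[-1] if factor_cols.shape[1] == 1 else np.full(Y.shape[1], np.nan)

    result = pd.DataFrame(
        {
            "factor": factor,
            "coefficient": coef,
            "p_value": p,
            "eta2": eta2,
            "partial_eta2": partial,
            "n": n,
            "constant": constant,
        },
        index=pd.Index(features.columns, name="feature_id"),
    )
    result["p_adjusted"] = bh_adjust(result["p_value"].to_numpy()) if adjust else p
    return result


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending, set adjusted_(i) = min_{j >= i} (m * p_(j) / j) capped
    at 1, and map back to the original order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _ranked(results: pd.DataFrame) -> pd.DataFrame:
    """Sort by partial eta2 descending, ties broken by feature_id."""
    return results.sort_values(
        ["partial_eta2", "feature_id"],
        ascending=[False, True],
        key=lambda s: s if s.name == "partial_eta2" else s.astype(str),
    )


def select_genotype_ions(
    results_genotype: pd.DataFrame,
    results_sex: pd.DataFrame,
    include_threshold: float = 0.01,
    exclude_threshold: float = 0.05,
    top_k: int = 100,
) -> pd.DataFrame:
    """Sex-independent genotype ion filter.

    Keeps features with genotype p_adjusted < ``include_threshold`` and sex
    p_adjusted > ``exclude_threshold`` (i.e. not confounded with sex), ranks
    them by partial eta-squared descending (ties lexicographic by
    feature_id) and truncates to ``top_k``.
    """
    if not results_genotype.index.equals(results_sex.index):
        results_sex = results_sex.loc[results_genotype.index]
    keep = (results_genotype["p_adjusted"] < include_threshold) & (
        results_sex["p_adjusted"] > exclude_threshold
    )
    survivors = results_genotype.loc[keep].reset_index()
    if survivors.empty:
        warnings.warn("no features survive the genotype/sex filter", stacklevel=2)
        return survivors.set_index("feature_id")
    ranked = _ranked(survivors).head(top_k).set_index("feature_id")
    ranked["sex_p_adjusted"] = results_sex.loc[ranked.index, "p_adjusted"]
    ranked["sex_eta2"] = results_sex.loc[ranked.index, "eta2"]
    return ranked


def select_category_features(
    results: pd.DataFrame, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Select compressed features with adjusted p below ``p_threshold``.

    No sex exclusion and no top-k truncation; output ranked by partial
    eta-squared descending with deterministic lexicographic tie-breaks.
    """
    survivors = results.loc[results["p_adjusted"] < p_threshold].reset_index()
    if survivors.empty:
        warnings.warn("no features pass the univariate threshold", stacklevel=2)
        return survivors.set_index("feature_id")
    return _ranked(survivors).set_index("feature_id")


def eta2_to_f(eta2: float) -> float:
    """Cohen's f from eta-squared: f = sqrt(eta2 / (1 - eta2))."""
    eta2 = float(eta2)
    if not 0 <= eta2 < 1:
        raise ValueError(f"eta2 must lie in [0, 1), got {eta2}")
    return float(np.sqrt(eta2 / (1.0 - eta2)))


def f_to_d(f: float) -> float:
    """Cohen's d from Cohen's f for two equal-size groups: d = 2 f."""
    f = float(f)
    if f < 0:
        raise ValueError(f"f must be nonnegative, got {f}")
    return 2.0 * f
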