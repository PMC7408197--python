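"""Config-driven orchestration of the published analyses.

``run_analysis`` executes the full chain for one analysis — closure, zero
replacement, log-ratio transform, optional per-category CPC compression,
the tier-1 univariate filter, elastic-net training with LOO tuning, and
metric/table generation — and writes every intermediate and final table
plus a run manifest (config hash, seed, library versions, collected
warnings) under the configured output directory.  ``make_tables`` formats
the published table layouts (univariate effect sizes; binary and
multiclass importance rankings).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coda, cpc, enet, select_univariate
from .mrm_io import IntensityMatrix, TransitionTable

ANALYSES = ("sex_binary", "genotype_binary", "progression_multiclass")
FEATURE_MODES = ("compressed_categories", "individual_ions")

_FACTOR_OF = {
    "sex_binary": "sex",
    "genotype_binary": "genotype",
    "progression_multiclass": "progression",
}
_LABEL_COLUMN = {
    "sex_binary": "sex",
    "genotype_binary": "genotype",
    "progression_multiclass": "stage",
}


@dataclass
class AnalysisConfig:
    """One end-to-end analysis run."""

    analysis: str = "genotype_binary"
    feature_mode: str = "compressed_categories"
    output_dir: str | Path | None = None
    seed: int = 0
    # preprocessing
    zero_strategy: str = "multiplicative"
    delta_fraction: float = 0.65
    transform: str = "clr"
    # compression
    variance_target: float = 0.95
    compression_mode: str = "subcomposition"
    # univariate selection
    include_threshold: float = 0.01
    exclude_threshold: float = 0.05
    category_p_threshold: float = 0.05
    top_k: int = 100
    progression_coding: str = "numeric"
    sex_as_covariate: bool = False
    # elastic net
    enet_alpha: float | tuple = 0.5
    lambda_grid: tuple = enet.DEFAULT_LAMBDA_GRID
    imbalance: str = "none"
    smote_k: int = 5

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}")
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")

    def config_hash(self) -> str:
        raw = {k: str(v) for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(raw, sort_keys=True).encode()).hexdigest()[:16]


def _enet_config(config: AnalysisConfig, family: str) -> enet.EnetConfig:
    return enet.EnetConfig(
        alpha=config.enet_alpha,
        lambda_grid=config.lambda_grid,
        family=family,
        imbalance=config.imbalance,
        smote_k=config.smote_k,
        seed=config.seed,
    )


def run_analysis(
    config: AnalysisConfig,
    data: IntensityMatrix,
    transitions: TransitionTable,
) -> dict:
    """Run one analysis; returns the report bundle (and writes it if
    ``config.output_dir`` is set).

    Bundle keys: ``features`` (the post-preprocessing feature matrix),
    ``univariate`` (per-feature effect sizes), ``selected`` (tier-1
    survivors), ``enet`` (:class:`~lipidsel.enet.EnetResult`), ``tables``
    (published-layout frames), ``warnings`` and ``manifest``.
    """
    factor = _FACTOR_OF[config.analysis]
    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # ---- preprocessing / feature construction ----
        if config.feature_mode == "compressed_categories":
            feature_sets, features = cpc.compress_categories(
                data,
                transitions,
                variance_target=config.variance_target,
                delta_fraction=config.delta_fraction,
                zero_strategy=config.zero_strategy,
                mode=config.compression_mode,
            )
        else:
            composition = coda.close(data)
            composition = coda.replace_zeros(
                composition, config.zero_strategy, config.delta_fraction
            )
            if config.transform == "clr":
                features = coda.clr(composition).values
            else:
                features = coda.ilr(composition).values
            feature_sets = []

        # ---- tier 1: univariate filter ----
        covariates = ("sex",) if (config.sex_as_covariate and factor != "sex") else ()
        results_factor = select_univariate.fit_feature_models(
            features,
            data.metadata,
            factor,
            covariates=covariates,
            progression_coding=config.progression_coding,
        )
        results_sex = (
            results_factor
            if factor == "sex"
            else select_univariate.fit_feature_models(features, data.metadata, "sex")
        )
        if config.feature_mode == "compressed_categories":
            selected = select_univariate.select_category_features(
                results_factor, p_threshold=config.category_p_threshold
            )
        elif factor == "sex":
            selected = select_univariate.select_category_features(
                results_factor, p_threshold=config.category_p_threshold
            ).head(config.top_k)
        else:
            selected = select_univariate.select_genotype_ions(
                results_factor,
                results_sex,
                include_threshold=config.include_threshold,
                exclude_threshold=config.exclude_threshold,
                top_k=config.top_k,
            )

        # ---- tier 2: elastic net ----
        enet_result = None
        if selected.empty:
            warnings.warn("empty tier-1 selection; elastic net skipped", stacklevel=2)
        else:
            y = data.metadata[_LABEL_COLUMN[config.analysis]]
            family = (
                "multinomial" if config.analysis == "progression_multiclass" else "binomial"
            )
            class_order = (
                [s for s in ("control", "non-lesional", "established", "advanced")
                 if s in set(y)]
                if family == "multinomial"
                else None
            )
            enet_result = enet.train_enet(
                features[list(selected.index)],
                y.to_numpy(),
                _enet_config(config, family),
                class_order=class_order,
            )
        collected = [str(w.message) for w in caught]

    bundle = {
        "config": config,
        "factor": factor,
        "features": features,
        "feature_sets": feature_sets,
        "univariate": results_factor,
        "univariate_sex": results_sex,
        "selected": selected,
        "enet": enet_result,
        "warnings": collected,
    }
    bundle["tables"] = make_tables(bundle, transitions)
    bundle["manifest"] = _manifest(config, bundle)
    if config.output_dir is not None:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _annotation(transitions: TransitionTable, feature_ids) -> pd.DataFrame:
    """Category / attribution / MRM columns for ion features; CPC features
    get their category parsed from the feature name."""
    by_id = {t.transition_id: t for t in transitions}
    rows = []
    for fid in feature_ids:
        if fid in by_id:
            t = by_id[fid]
            rows.append((t.category, t.attribution, t.mrm))
        elif " CPC " in str(fid):
            rows.append((str(fid).rsplit(" CPC ", 1)[0], str(fid), ""))
        else:
            rows.append(("", str(fid), ""))
    return pd.DataFrame(
        rows,
        columns=["Category", "Tentative Attributions", "MRM"],
        index=pd.Index(feature_ids, name="feature_id"),
    )


def make_tables(bundle: dict, transitions: TransitionTable) -> dict[str, pd.DataFrame]:
    """Published table layouts from a completed run.

    ``univariate``: top tier-1 features with the factor's eta2 (2 dp) and,
    for ion analyses, the sex eta2 (3 dp, showing the confound screen).
    ``importance``: features ranked by elastic-net importance — a single
    score column for binary runs, per-class columns plus their row-sum
    Overall for multiclass runs (both 2 dp).
    """
    factor = bundle["factor"]
    selected: pd.DataFrame = bundle["selected"]
    tables: dict[str, pd.DataFrame] = {}

    annot = _annotation(transitions, list(selected.index))
    uni = annot.copy()
    uni[f"{factor.capitalize()} (eta2)"] = selected["eta2"].round(2)
    if "sex_eta2" in selected.columns:
        uni["Sex (eta2)"] = selected["sex_eta2"].round(3)
    tables["univariate"] = uni.reset_index(drop=True)

    result = bundle["enet"]
    if result is not None and result.importance is not None:
        imp = result.importance
        nonzero = imp.loc[imp["Overall"] > 0]
        annot = _annotation(transitions, list(nonzero.index))
        table = pd.concat([annot, nonzero.round(2)], axis=1)
        if len(result.classes) == 2:
            table = table.rename(columns={"Overall": "Importance Score"})
            table = table.drop(columns=[str(c) for c in result.classes if str(c) in table])
        tables["importance"] = table.reset_index(drop=True)
        if result.loo_predictions is not None:
            tables["parallel_plot"] = result.loo_predictions.reset_index()
    else:
        tables["importance"] = pd.DataFrame(
            columns=["Category", "Tentative Attributions", "MRM", "Importance Score"]
        )
    return tables


def _manifest(config: AnalysisConfig, bundle: dict) -> dict:
    import sklearn

    from . import __version__

    result = bundle["enet"]
    manifest = {
        "config": {k: str(v) for k, v in asdict(config).items()},
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "lipidsel": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "n_features": int(bundle["features"].shape[1]),
        "n_selected": int(len(bundle["selected"])),
        "warnings": bundle["warnings"],
    }
    if result is not None:
        manifest["metrics"] = {
            "accuracy": result.accuracy,
            "accuracy_ci": list(result.accuracy_ci),
            "kappa_unweighted": result.kappa_unweighted,
            "kappa_weighted": result.kappa_weighted,
            "selected_lambda": result.selected_lambda,
            "selected_alpha": result.selected_alpha,
            "n_nonzero": result.n_nonzero(),
        }
    return manifest


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["univariate"].to_csv(out_dir / "univariate_results.csv")
    bundle["selected"].to_csv(out_dir / "selected_features.csv")
    for name, table in bundle["tables"].items():
        table.to_csv(out_dir / f"table_{name}.csv", index=False)
    result = bundle["enet"]
    if result is not None:
        result.coefficients.to_csv(out_dir / "enet_coefficients.csv")
        if result.importance is not None:
            result.importance.to_csv(out_dir / "enet_importance.csv")
        if result.confusion is not None:
            result.confusion.to_csv(out_dir / "confusion_matrix.csv")
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2)
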