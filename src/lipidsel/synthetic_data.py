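"""Synthetic MRM lipidomics cohorts with planted, calibrated effects.

The generator emulates the statistical structure of a dermatitis-model
epidermis screen: 72 samples (6 males + 6 females per genotype at each of
three ages; wild-type samples are "control", mutant samples progress
non-lesional -> established -> advanced with age), 1030 monitored lipid
ions spread over 10 annotation categories, log-normal intensities that are
only meaningful as relative amounts, a *diffuse* sex effect touching many
ions, a *concentrated* genotype effect in the phospholipid/glycerolipid
categories, and a monotone ordinal disease-stage effect.

Effects are planted as multiplicative (log-scale) group shifts calibrated
from the ANOVA identity eta2 = f^2 / (1 + f^2): for a contrast coding c
with standard deviation sd(c) across samples, the per-ion shift
delta = sigma * f / sd(c), corrected for the CLR back-reaction when a
fraction of ions carry the effect, yields the requested large-n eta2 on
the CLR scale.  The planted-truth ledger (which ions carry which factor)
supports recovery tests in the downstream selection stages.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .mrm_io import IntensityMatrix, Transition, TransitionTable
from .select_univariate import CATEGORY_LABELS, STAGE_SCORES


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation settings."""


#: Default ion counts per category: a plausible skew with phospholipids
#: dominating.  These are assumptions (configuration), not measured counts.
DEFAULT_CATEGORY_SIZES = {
    "phospholipid": 320,
    "glycerolipid": 180,
    "sphingolipid": 150,
    "acylcarnitine": 90,
    "cholesteryl-ester": 70,
    "DAG": 60,
    "phospholipid-or-glycerolipid": 50,
    "sphingolipid-or-glycerolipid": 40,
    "acylcarnitine-or-glycerolipid": 40,
    "phospholipid-or-cholesteryl-ester": 30,
}

_PRODUCT_IONS = (85.1, 155.1, 184.1, 264.3, 266.2, 280.0, 282.2, 369.1, 598.0)


@dataclass
class EffectSpec:
    """One planted factor effect.

    ``factor`` is sex, genotype or stage; ``target_ions`` names explicit
    transition ids, or ``categories`` + ``n_target`` lets the generator
    draw targets from those categories ("concentrated") or from all ions
    ("diffuse" with ``categories=None``).  ``target_eta2`` is the per-ion
    eta-squared aimed for on the CLR scale; ``stage_profile`` gives the
    monotone multipliers over the four stages for ordinal effects.
    """

    factor: str
    target_eta2: float
    effect_style: str = "concentrated"
    target_ions: Sequence[str] | None = None
    categories: Sequence[str] | None = None
    n_target: int | None = None
    stage_profile: Sequence[float] = (0.0, 1.0, 2.0, 3.0)
    #: draw targets only among ions NOT already targeted by these factors
    #: (e.g. genotype markers that are free of the sex effect)
    avoid_factors: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.factor not in ("sex", "genotype", "stage"):
            raise ConfigError(f"unknown factor {self.factor!r}")
        if not 0 <= self.target_eta2 <= 0.95:
            raise ConfigError(
                f"target_eta2 must lie in [0, 0.95], got {self.target_eta2}"
            )
        if self.effect_style not in ("diffuse", "concentrated"):
            raise ConfigError(f"unknown effect_style {self.effect_style!r}")
        if self.target_ions is None and not self.n_target:
            raise ConfigError("specify target_ions or n_target")
        if self.factor == "stage" and np.any(np.diff(self.stage_profile) < 0):
            raise ConfigError("stage_profile must be monotone nondecreasing")


def default_effects() -> list[EffectSpec]:
    """The default study conditions: diffuse sex, concentrated genotype,
    ordinal stage effects mirroring the cohort the generator emulates."""
    return [
        EffectSpec(
            factor="sex", target_eta2=0.20, effect_style="diffuse", n_target=600
        ),
        EffectSpec(
            factor="genotype",
            target_eta2=0.50,
            effect_style="concentrated",
            categories=["phospholipid", "glycerolipid", "phospholipid-or-glycerolipid"],
            n_target=150,
            avoid_factors=("sex",),
        ),
        EffectSpec(
            factor="stage",
            target_eta2=0.45,
            effect_style="concentrated",
            categories=[
                "phospholipid",
                "acylcarnitine",
                "cholesteryl-ester",
                "sphingolipid",
                "glycerolipid",
            ],
            n_target=80,
            avoid_factors=("sex",),
        ),
    ]


@dataclass
class SimConfig:
    """Cohort design and noise model for :func:`generate`."""

    n_per_cell: int = 6
    ages: Sequence[int] = (5, 7, 10)
    n_ions: int = 1030
    category_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SIZES)
    )
    base_log_mean: float = 11.0
    base_log_mean_sd: float = 1.5
    base_log_sd: float = 0.15
    # within-category correlation: latent factors with geometrically
    # decaying strengths, giving each category a low effective rank as
    # co-regulated lipid classes show in practice
    n_latent: int = 12
    latent_sd: float = 0.6
    latent_decay: float = 0.5
    effects: list[EffectSpec] = field(default_factory=default_effects)
    zero_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ConfigError("n_per_cell must be >= 2")
        if not 0 <= self.zero_rate <= 0.2:
            raise ConfigError("zero_rate must lie in [0, 0.2]")
        if sum(self.category_sizes.values()) != self.n_ions:
            raise ConfigError(
                f"category_sizes sum to {sum(self.category_sizes.values())}, "
                f"expected n_ions = {self.n_ions}"
            )
        unknown = set(self.category_sizes) - set(CATEGORY_LABELS)
        if unknown:
            raise ConfigError(f"unknown categories {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "effects" in raw:
            raw["effects"] = [EffectSpec(**e) for e in raw.pop("effects")]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def make_transition_table(config: SimConfig, rng: np.random.Generator) -> TransitionTable:
    """Synthetic but realistic transition list matching the category sizes."""
    transitions = []
    # unique Q1 grid with one decimal, jittered start per category block
    q1_grid = np.round(np.linspace(250.0, 950.0, config.n_ions), 1)
    idx = 0
    for category in sorted(config.category_sizes):
        for _ in range(config.category_sizes[category]):
            q1 = float(q1_grid[idx])
            q3_choices = [p for p in _PRODUCT_IONS if p <= q1 + 2.0]
            q3 = float(rng.choice(q3_choices))
            transitions.append(
                Transition(
                    transition_id=f"T{idx + 1:04d}",
                    precursor_mz=q1,
                    product_mz=q3,
                    polarity="positive",
                    collision_energy=20.0,
                    attribution=f"synthetic {category} ion {idx + 1}",
                    category=category,
                )
            )
            idx += 1
    return TransitionTable(transitions)


def make_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: sex x genotype x age cells of ``n_per_cell`` each.

    WT samples are stage "control" at every age; mutant samples map ages
    (youngest to oldest) onto non-lesional, established and advanced.
    """
    stage_by_age = {
        age: stage
        for age, stage in zip(
            sorted(config.ages), ["non-lesional", "established", "advanced"]
        )
    }
    rows = []
    for genotype in ("WT", "cpdm"):
        for sex in ("F", "M"):
            for age in sorted(config.ages):
                for _ in range(config.n_per_cell):
                    stage = "control" if genotype == "WT" else stage_by_age[age]
                    rows.append((sex, genotype, age, stage))
    metadata = pd.DataFrame(
        rows, columns=["sex", "genotype", "age_weeks", "stage"]
    )
    metadata.index = pd.Index(
        [f"S{i + 1:03d}" for i in range(len(metadata))], name="sample_id"
    )
    return metadata


def _contrast(metadata: pd.DataFrame, spec: EffectSpec) -> np.ndarray:
    """Centered per-sample contrast codes for one planted factor."""
    if spec.factor == "sex":
        c = (metadata["sex"] == "M").to_numpy(float)
    elif spec.factor == "genotype":
        c = (metadata["genotype"] == "cpdm").to_numpy(float)
    else:
        profile = np.asarray(spec.stage_profile, float)
        c = metadata["stage"].map(STAGE_SCORES).to_numpy()
        c = profile[c]
    return c - c.mean()


def generate(config: SimConfig) -> tuple[IntensityMatrix, TransitionTable, dict]:
    """Draw a synthetic cohort; returns (matrix, transitions, truth ledger).

    The truth ledger records, per effect, the targeted transition ids, the
    requested eta2 and the calibrated log-scale shift delta, so recovery
    tests can score selections against the plant.
    """
    rng = np.random.default_rng(config.seed)
    transitions = make_transition_table(config, rng)
    metadata = make_metadata(config)
    n, D = len(metadata), config.n_ions

    ion_baseline = rng.normal(config.base_log_mean, config.base_log_mean_sd, size=D)
    log_x = ion_baseline[None, :] + rng.normal(0.0, config.base_log_sd, size=(n, D))

    categories = transitions.categories()
    ids = np.asarray(transitions.ids)

    # correlated within-category structure from decaying latent factors
    strengths = config.latent_sd * config.latent_decay ** np.arange(config.n_latent)
    cat_arr = categories.loc[ids].to_numpy()
    sigma2_ion = np.full(D, config.base_log_sd**2)
    for label in sorted(set(cat_arr)):
        cols = cat_arr == label
        m = int(cols.sum())
        r = min(config.n_latent, max(m - 1, 0))
        if r == 0:
            continue
        sigma2_ion[cols] += (strengths[:r] ** 2).sum()
        z = rng.normal(size=(n, r))
        w = rng.normal(size=(m, r)) * strengths[:r]
        # equalize each ion's total latent variance so planted effect
        # sizes calibrate exactly against a known per-ion SD
        norms = np.sqrt((w**2).sum(axis=1, keepdims=True))
        target_norm = np.sqrt((strengths[:r] ** 2).sum())
        w = w / np.where(norms > 0, norms, 1.0) * target_norm
        log_x[:, cols] += z @ w.T
    truth: dict = {"seed": config.seed, "effects": []}
    taken: dict[str, set[str]] = {}
    for spec in config.effects:
        if spec.target_ions is not None:
            targets = np.asarray(list(spec.target_ions))
            missing = set(targets) - set(ids)
            if missing:
                raise ConfigError(f"unknown target ions {sorted(missing)[:5]}")
        else:
            if spec.categories is None:
                pool = ids
            else:
                pool = ids[np.isin(categories.loc[ids].to_numpy(), list(spec.categories))]
            excluded: set[str] = set()
            for other in spec.avoid_factors:
                excluded |= taken.get(other, set())
            pool = pool[~np.isin(pool, list(excluded))] if excluded else pool
            if spec.n_target > len(pool):
                raise ConfigError(
                    f"{spec.factor}: requested {spec.n_target} target ions, "
                    f"only {len(pool)} available"
                )
            targets = rng.choice(pool, size=spec.n_target, replace=False)
        cols = np.isin(ids, targets)
        m = int(cols.sum())
        c = _contrast(metadata, spec)
        sd_c = c.std(ddof=0)
        if sd_c == 0:
            raise ConfigError(f"factor {spec.factor} is constant in this design")
        f = np.sqrt(spec.target_eta2 / (1.0 - spec.target_eta2))
        sigma = float(np.sqrt(sigma2_ion[cols].mean()))
        delta = sigma * f / sd_c
        # balanced up/down signs keep the row geometric mean (and hence the
        # CLR back-reaction) essentially unchanged, so delta lands on the
        # target ions at full strength
        signs = rng.permutation(
            np.concatenate([np.ones(m // 2), -np.ones(m - m // 2)])
        )
        log_x[:, cols] += np.outer(c, delta * signs)
        taken.setdefault(spec.factor, set()).update(str(t) for t in targets)
        truth["effects"].append(
            {
                "factor": spec.factor,
                "style": spec.effect_style,
                "target_eta2": spec.target_eta2,
                "delta": float(delta),
                "ions": [str(t) for t in targets],
            }
        )

    values = np.exp(log_x)
    if config.zero_rate > 0:
        zeros = rng.random(values.shape) < config.zero_rate
        values[zeros] = 0.0
    frame = pd.DataFrame(values, index=metadata.index, columns=list(ids))
    matrix = IntensityMatrix(values=frame, metadata=metadata)
    return matrix, transitions, truth


def save_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


# ---------------------------------------------------------------------------
# mzML fixture emission
# ---------------------------------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <chromatogramList count="{count}" defaultDataProcessingRef="dp">
"""

_MZML_FOOTER = """    </chromatogramList>
  </run>
</mzML>
"""

_CHROM_TEMPLATE = """      <chromatogram index="{index}" id="{cid}" defaultArrayLength="{npoints}">
        <cvParam cvRef="MS" accession="MS:1001473" name="selected reaction monitoring chromatogram" value=""/>
        <precursor>
          <isolationWindow>
            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{q1}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
          </isolationWindow>
        </precursor>
        <product>
          <isolationWindow>
            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{q3}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
          </isolationWindow>
        </product>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{tlen}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000595" name="time array" value="" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
            <binary>{tdata}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{ilen}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{idata}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </chromatogram>
"""


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


def emit_mzml_fixtures(
    matrix: IntensityMatrix,
    transitions: TransitionTable,
    out_dir: str | Path,
    points_per_chromatogram: int = 3,
    n_methods: int = 6,
) -> list[Path]:
    """Write one mzML file per (sample, method) with SRM chromatograms.

    Transitions are partitioned round-robin into ``n_methods`` method files
    per sample, mirroring a multi-injection acquisition.  Each cell value is
    spread over ``points_per_chromatogram`` intensity points summing to the
    cell value; zero cells are omitted entirely (the extractor reports 0).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = set(matrix.transitions) - set(transitions.ids)
    if missing:
        raise KeyError(f"matrix transitions missing from table: {sorted(missing)[:5]}")
    if points_per_chromatogram < 1:
        raise ValueError("points_per_chromatogram must be >= 1")
    by_id = {t.transition_id: t for t in transitions}
    method_of = {
        tid: i % n_methods for i, tid in enumerate(matrix.transitions)
    }
    times = np.linspace(0.1, 2.0, points_per_chromatogram)
    paths = []
    for sample_id in matrix.samples:
        row = matrix.values.loc[sample_id]
        for method in range(n_methods):
            tids = [t for t in matrix.transitions if method_of[t] == method]
            chroms = []
            for idx, tid in enumerate(tids):
                value = float(row[tid])
                if value == 0.0:
                    continue
                t = by_id[tid]
                points = np.full(points_per_chromatogram, value / points_per_chromatogram)
                tdata, idata = _b64(times), _b64(points)
                chroms.append(
                    _CHROM_TEMPLATE.format(
                        index=len(chroms),
                        cid=f"SRM SIC Q1={t.precursor_mz:g},Q3={t.product_mz:g}",
                        npoints=points_per_chromatogram,
                        q1=f"{t.precursor_mz:g}",
                        q3=f"{t.product_mz:g}",
                        tlen=len(tdata),
                        tdata=tdata,
                        ilen=len(idata),
                        idata=idata,
                    )
                )
            run_id = f"{sample_id}_method{method + 1}"
            path = out_dir / f"{run_id}.mzML"
            with open(path, "w") as fh:
                fh.write(_MZML_HEADER.format(run_id=run_id, count=len(chroms)))
                fh.writelines(chroms)
                fh.write(_MZML_FOOTER)
            paths.append(path)
    return paths


def write_sample_manifest(
    matrix: IntensityMatrix, mzml_paths: Sequence[Path], path: str | Path
) -> None:
    """Manifest CSV (sample_id, mzml_path, metadata) for re-extraction."""
    by_sample: dict[str, list[Path]] = {s: [] for s in matrix.samples}
    for p in mzml_paths:
        sample = p.stem.rsplit("_method", 1)[0]
        if sample in by_sample:
            by_sample[sample].append(p)
    rows = []
    for sample, files in by_sample.items():
        md = matrix.metadata.loc[sample]
        for f in files:
            rows.append(
                {
                    "sample_id": sample,
                    "mzml_path": str(f),
                    "sex": md.get("sex", ""),
                    "genotype": md.get("genotype", ""),
                    "age_weeks": md.get("age_weeks", ""),
                    "stage": md.get("stage", ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
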