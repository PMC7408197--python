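"""Transition tables, mzML chromatogram extraction and intensity matrices.

Flow-injection MRM screening monitors a fixed list of precursor/product
transitions split over several instrument methods; each sample is injected
once per method, producing one mzML file per (sample, method).  This module
reads the transition method table, locates the SRM chromatogram matching
each transition in a sample's mzML files, and integrates it into a single
samples x transitions intensity matrix carrying the sample metadata
(sex, genotype, age, disease stage) needed downstream.

The mzML support is deliberately narrow: only ``<chromatogram>`` elements
with selected-reaction-monitoring precursor/product isolation targets and
uncompressed or zlib-compressed 32/64-bit float binary arrays are handled,
which is exactly what converted flow-injection SRM runs contain.
"""

from __future__ import annotations

import base64
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .select_univariate import CATEGORY_LABELS

STAGE_ORDER = ("control", "non-lesional", "established", "advanced")
POLARITIES = ("positive", "negative")

# Accessions used when reading and writing SRM chromatograms.
_ACC_SRM_CHROMATOGRAM = "MS:1001473"
_ACC_ISOLATION_TARGET = "MS:1000827"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ZLIB = "MS:1000574"
_ACC_TIME_ARRAY = "MS:1000595"
_ACC_INTENSITY_ARRAY = "MS:1000515"


class SchemaError(ValueError):
    """A required column is missing from a delimited input table."""


class TableParseError(ValueError):
    """A table cell could not be parsed (the row is named in the message)."""


class DuplicateTransitionError(ValueError):
    """The same (precursor, product, polarity) triple occurs twice."""


class MzmlError(IOError):
    """An mzML file could not be read or is structurally unusable."""


class AmbiguityError(ValueError):
    """More than one chromatogram in one file matches a single transition."""


class AlignmentError(ValueError):
    """Partial matrices do not share an identical sample set."""


class DisjointnessError(ValueError):
    """Partial matrices overlap in their transition sets."""


@dataclass(frozen=True)
class Transition:
    """One monitored MRM transition (precursor -> product ion pair)."""

    transition_id: str
    precursor_mz: float
    product_mz: float
    polarity: str
    collision_energy: float = float("nan")
    attribution: str = ""
    category: str = "phospholipid"

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor_mz must be > 0, got {self.precursor_mz}")
        if not self.product_mz > 0:
            raise ValueError(f"product_mz must be > 0, got {self.product_mz}")
        # allow near-equal precursor scans but not products far above Q1
        if self.product_mz > self.precursor_mz + 2.0:
            raise ValueError(
                f"product_mz {self.product_mz} exceeds precursor_mz "
                f"{self.precursor_mz} by more than 2 Th"
            )
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        if self.category not in CATEGORY_LABELS:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def mrm(self) -> str:
        """The conventional 'Q1→Q3' display string."""
        return f"{self.precursor_mz:g}→{self.product_mz:g}"


@dataclass
class TransitionTable:
    """Ordered collection of monitored transitions."""

    transitions: list[Transition]

    def __post_init__(self) -> None:
        seen: set[tuple[float, float, str]] = set()
        ids: set[str] = set()
        for t in self.transitions:
            key = (t.precursor_mz, t.product_mz, t.polarity)
            if key in seen:
                raise DuplicateTransitionError(
                    f"duplicate transition {t.mrm} ({t.polarity})"
                )
            if t.transition_id in ids:
                raise DuplicateTransitionError(
                    f"duplicate transition_id {t.transition_id!r}"
                )
            seen.add(key)
            ids.add(t.transition_id)

    def __len__(self) -> int:
        return len(self.transitions)

    def __iter__(self):
        return iter(self.transitions)

    @property
    def ids(self) -> list[str]:
        return [t.transition_id for t in self.transitions]

    def by_id(self, transition_id: str) -> Transition:
        for t in self.transitions:
            if t.transition_id == transition_id:
                return t
        raise KeyError(transition_id)

    def categories(self) -> pd.Series:
        """Category label per transition, indexed by transition_id."""
        return pd.Series(
            {t.transition_id: t.category for t in self.transitions}, name="category"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transition_id": [t.transition_id for t in self.transitions],
                "precursor_mz": [t.precursor_mz for t in self.transitions],
                "product_mz": [t.product_mz for t in self.transitions],
                "polarity": [t.polarity for t in self.transitions],
                "collision_energy": [t.collision_energy for t in self.transitions],
                "attribution": [t.attribution for t in self.transitions],
                "category": [t.category for t in self.transitions],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class IntensityMatrix:
    """Samples x transitions signal matrix plus per-sample metadata.

    ``values`` is indexed by sample_id with one column per transition_id;
    ``metadata`` is indexed identically with columns ``sex`` ({F, M}),
    ``genotype`` ({WT, cpdm}), ``age_weeks`` and ``stage`` (one of
    :data:`STAGE_ORDER`; "control" exactly for WT samples).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.metadata.index):
            raise AlignmentError("values and metadata sample sets differ")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicated sample or transition identifiers")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")
        md = self.metadata
        if "stage" in md and "genotype" in md:
            is_control = md["stage"] == "control"
            is_wt = md["genotype"] == "WT"
            if not (is_control == is_wt).all():
                bad = md.index[is_control != is_wt].tolist()
                raise ValueError(f"stage 'control' must coincide with WT: {bad}")
            unknown = set(md["stage"]) - set(STAGE_ORDER)
            if unknown:
                raise ValueError(f"unknown stages {sorted(unknown)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def transitions(self) -> list[str]:
        return list(self.values.columns)

    def stage_codes(self) -> pd.Series:
        """Ordinal stage scores: control=0 < non-lesional=1 < ... < advanced=3."""
        mapping = {s: i for i, s in enumerate(STAGE_ORDER)}
        return self.metadata["stage"].map(mapping)

    def to_csv(self, values_path: str | Path, metadata_path: str | Path) -> None:
        self.values.to_csv(values_path, index_label="sample_id")
        self.metadata.to_csv(metadata_path, index_label="sample_id")

    @classmethod
    def from_csv(cls, values_path: str | Path, metadata_path: str | Path) -> "IntensityMatrix":
        values = pd.read_csv(values_path, index_col="sample_id")
        metadata = pd.read_csv(metadata_path, index_col="sample_id")
        return cls(values=values, metadata=metadata.loc[values.index])


# ---------------------------------------------------------------------------
# Transition method tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("precursor_mz", "product_mz", "polarity", "category")


def read_method_table(path: str | Path, sep: str = ",") -> TransitionTable:
    """Read a transition method table from a delimited text file.

    Required columns: ``precursor_mz``, ``product_mz``, ``polarity``,
    ``category``.  Optional: ``transition_id`` (defaults to the Q1→Q3
    string), ``collision_energy``, ``attribution``.  Row order is preserved;
    duplicated (Q1, Q3, polarity) triples are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    transitions = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            q1 = float(row.precursor_mz)
            q3 = float(row.product_mz)
        except ValueError as exc:
            raise TableParseError(
                f"non-numeric m/z in {path} row {row_number}: {exc}"
            ) from None
        ce = float("nan")
        if getattr(row, "collision_energy", "") != "":
            try:
                ce = float(row.collision_energy)
            except ValueError:
                raise TableParseError(
                    f"non-numeric collision_energy in {path} row {row_number}"
                ) from None
        tid = getattr(row, "transition_id", "") or f"{q1:g}->{q3:g}"
        transitions.append(
            Transition(
                transition_id=tid,
                precursor_mz=q1,
                product_mz=q3,
                polarity=row.polarity,
                collision_energy=ce,
                attribution=getattr(row, "attribution", ""),
                category=row.category,
            )
        )
    return TransitionTable(transitions)


def read_sample_manifest(path: str | Path, sep: str = ",") -> tuple[dict[str, list[Path]], pd.DataFrame]:
    """Read a sample manifest mapping sample_id -> mzML paths + metadata.

    The manifest has one row per (sample, file) with columns ``sample_id``,
    ``mzml_path`` and the metadata columns ``sex``, ``genotype``,
    ``age_weeks``, ``stage`` (constant within a sample).  Relative mzML
    paths are resolved against the manifest's directory.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=sep)
    required = {"sample_id", "mzml_path", "sex", "genotype", "age_weeks", "stage"}
    missing = sorted(required - set(frame.columns))
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    files: dict[str, list[Path]] = {}
    for sample_id, group in frame.groupby("sample_id", sort=False):
        files[str(sample_id)] = [
            p if p.is_absolute() else path.parent / p
            for p in (Path(s) for s in group["mzml_path"])
        ]
    metadata = (
        frame.drop_duplicates("sample_id")
        .set_index("sample_id")[["sex", "genotype", "age_weeks", "stage"]]
    )
    metadata.index = metadata.index.astype(str)
    return files, metadata


# ---------------------------------------------------------------------------
# mzML chromatogram reading
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SrmChromatogram:
    """One SRM chromatogram: its isolation targets and intensity trace."""

    chromatogram_id: str
    q1: float
    q3: float
    intensities: np.ndarray
    times: np.ndarray | None = None


def _decode_binary(binary_element) -> np.ndarray:
    accessions = {
        cv.get("accession")
        for cv in binary_element.iter()
        if cv.tag.endswith("cvParam")
    }
    blob_el = next(
        (el for el in binary_element.iter() if el.tag.endswith("}binary")), None
    )
    raw = base64.b64decode((blob_el.text or "").encode()) if blob_el is not None else b""
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_srm_chromatograms(path: str | Path) -> list[SrmChromatogram]:
    """Read all SRM chromatograms from an mzML file.

    Non-SRM chromatograms (e.g. TIC) are ignored.  Raises
    :class:`MzmlError` for unreadable or structurally broken files.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise MzmlError(f"cannot read mzML file {path}: {exc}") from None
    out: list[SrmChromatogram] = []
    for chrom in tree.iter("{*}chromatogram"):
        accessions = {
            cv.get("accession")
            for cv in chrom.iterchildren("{*}cvParam")
        }
        if _ACC_SRM_CHROMATOGRAM not in accessions:
            continue
        q1 = q3 = None
        for scope, tag in (("q1", "{*}precursor"), ("q3", "{*}product")):
            el = next(chrom.iterchildren(tag), None)
            if el is None:
                continue
            for cv in el.iter("{*}cvParam"):
                if cv.get("accession") == _ACC_ISOLATION_TARGET:
                    value = float(cv.get("value"))
                    if scope == "q1":
                        q1 = value
                    else:
                        q3 = value
        if q1 is None or q3 is None:
            raise MzmlError(
                f"SRM chromatogram {chrom.get('id')!r} in {path} lacks "
                "precursor/product isolation targets"
            )
        times = intensities = None
        for bda in chrom.iter("{*}binaryDataArray"):
            accs = {
                cv.get("accession")
                for cv in bda.iterchildren("{*}cvParam")
            }
            if _ACC_INTENSITY_ARRAY in accs:
                intensities = _decode_binary(bda)
            elif _ACC_TIME_ARRAY in accs:
                times = _decode_binary(bda)
        if intensities is None:
            raise MzmlError(
                f"SRM chromatogram {chrom.get('id')!r} in {path} has no intensity array"
            )
        out.append(
            SrmChromatogram(
                chromatogram_id=chrom.get("id", ""),
                q1=q1,
                q3=q3,
                intensities=intensities,
                times=times,
            )
        )
    return out


def extract_intensities(
    sample_files: Mapping[str, Sequence[str | Path]],
    transitions: TransitionTable,
    q1_tol: float = 0.5,
    q3_tol: float = 0.5,
    metadata: pd.DataFrame | None = None,
    statistic: str = "sum",
) -> IntensityMatrix:
    """Integrate each transition's SRM chromatogram into one number per sample.

    For every transition, the chromatogram whose Q1 and Q3 targets match
    within ``q1_tol`` / ``q3_tol`` is located across the sample's files and
    its intensity points are integrated over the whole injection window
    (``statistic``: "sum", the default, or "mean").  A transition matched by
    two chromatograms *within one file* means the tolerance is too wide and
    raises :class:`AmbiguityError`; matches in different files (methods are
    disjoint by design, so this indicates reinjection) are summed.
    Unmatched transitions yield 0 with a warning.
    """
    if q1_tol <= 0 or q3_tol <= 0:
        raise ValueError("q1_tol and q3_tol must be > 0")
    if statistic not in ("sum", "mean"):
        raise ValueError("statistic must be 'sum' or 'mean'")
    q1s = np.array([t.precursor_mz for t in transitions])
    q3s = np.array([t.product_mz for t in transitions])
    ids = transitions.ids
    rows = {}
    for sample_id, paths in sample_files.items():
        acc = np.zeros(len(ids))
        matched = np.zeros(len(ids), dtype=bool)
        for p in paths:
            chroms = read_srm_chromatograms(p)
            hit_in_file = np.zeros(len(ids), dtype=int)
            for ch in chroms:
                hits = np.flatnonzero(
                    (np.abs(q1s - ch.q1) <= q1_tol) & (np.abs(q3s - ch.q3) <= q3_tol)
                )
                value = (
                    float(ch.intensities.sum())
                    if statistic == "sum"
                    else float(ch.intensities.mean()) if ch.intensities.size else 0.0
                )
                for j in hits:
                    hit_in_file[j] += 1
                    if hit_in_file[j] > 1:
                        raise AmbiguityError(
                            f"transition {ids[j]} matches more than one chromatogram "
                            f"in {p}; narrow q1_tol/q3_tol"
                        )
                    acc[j] += value
                    matched[j] = True
        for j in np.flatnonzero(~matched):
            warnings.warn(
                f"transition {ids[j]} unmatched in sample {sample_id}; set to 0",
                stacklevel=2,
            )
        rows[sample_id] = acc
    values = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    values.index.name = "sample_id"
    if metadata is None:
        metadata = pd.DataFrame(index=values.index)
    return IntensityMatrix(values=values, metadata=metadata.loc[values.index])


def merge_injections(partial_matrices: Sequence[IntensityMatrix]) -> IntensityMatrix:
    """Column-concatenate partial matrices over disjoint transition subsets."""
    if not partial_matrices:
        raise ValueError("no matrices to merge")
    first = partial_matrices[0]
    if len(partial_matrices) == 1:
        return first
    seen: set[str] = set(first.transitions)
    for other in partial_matrices[1:]:
        if set(other.samples) != set(first.samples):
            raise AlignmentError(
                "partial matrices cover different sample sets: "
                f"{sorted(set(first.samples) ^ set(other.samples))}"
            )
        overlap = seen & set(other.transitions)
        if overlap:
            raise DisjointnessError(f"overlapping transitions: {sorted(overlap)[:5]}")
        seen |= set(other.transitions)
    values = pd.concat(
        [m.values.loc[first.samples] for m in partial_matrices], axis=1
    )
    return IntensityMatrix(values=values, metadata=first.metadata)
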