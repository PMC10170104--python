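"""Reading, writing, and validation of feature tables, compound registries, and pathway sets.

The central object is :class:`FeatureTable`: a non-negative peak-area matrix
(features x samples) with feature metadata (m/z, retention time, optional
upstream annotation) and sample metadata (extraction group, sample type,
injection order, analytical run).  Missing areas are encoded as NaN in memory
and as *empty* CSV fields on disk -- a measured zero is a legitimate area and
is kept distinct from "not detected".

All retention times are in seconds.
"""
from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "Column",
    "Polarity",
    "AnalyticalRun",
    "STUDY_GROUPS",
    "GROUPS",
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "CompoundRecord",
    "CompoundRegistry",
    "read_registry",
    "PathwayDef",
    "load_pathways",
]


class ValidationError(ValueError):
    """Structural problem in an input file or table, naming the offending row/column."""


class Column(str, enum.Enum):
    """Chromatographic column of an analytical run."""

    RP_PHENYL_HEXYL = "RP_PHENYL_HEXYL"
    HILIC = "HILIC"


class Polarity(str, enum.Enum):
    """Electrospray ionization polarity."""

    POS = "POS"
    NEG = "NEG"


@dataclass(frozen=True)
class AnalyticalRun:
    """One of the four column x polarity combinations a sample was acquired in."""

    column: Column
    polarity: Polarity


#: Extraction groups; the ``_B`` suffix denotes added bead homogenization.
STUDY_GROUPS: tuple[str, ...] = ("I", "II", "III", "IV", "III_B", "IV_B")
GROUPS: tuple[str, ...] = STUDY_GROUPS + ("QC",)
SAMPLE_TYPES: tuple[str, ...] = ("STUDY", "QC")

_SAMPLE_COLUMNS = ["group", "sample_type", "injection_order", "column", "polarity"]
_FEATURE_COLUMNS = ["mz", "rt", "annotation"]


class FeatureTable:
    """A validated peak-area matrix with feature and sample metadata.

    Parameters
    ----------
    areas
        DataFrame of non-negative areas, indexed by ``feature_id`` with one
        column per ``sample_id``.  NaN marks a missing (undetected) area.
    features
        DataFrame indexed by ``feature_id`` with columns ``mz`` (Th),
        ``rt`` (seconds) and ``annotation`` (free-text isotope/adduct flag,
        empty string when absent).
    samples
        DataFrame indexed by ``sample_id`` with columns ``group``,
        ``sample_type``, ``injection_order``, ``column``, ``polarity``.
    """

    def __init__(self, areas: pd.DataFrame, features: pd.DataFrame, samples: pd.DataFrame):
        self.areas = areas.astype(float)
        self.features = features
        self.samples = samples
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        feats, samps, areas = self.features, self.samples, self.areas
        dup = feats.index[feats.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicated feature_id(s): {sorted(map(str, dup))}")
        dup = samps.index[samps.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicated sample_id(s): {sorted(map(str, dup))}")
        if list(areas.index) != list(feats.index):
            raise ValidationError(
                f"area matrix has {len(areas.index)} feature rows but metadata lists "
                f"{len(feats.index)} features (or ids/order disagree)"
            )
        if list(areas.columns) != list(samps.index):
            raise ValidationError(
                f"area matrix has {len(areas.columns)} sample columns but metadata lists "
                f"{len(samps.index)} samples (or ids/order disagree)"
            )
        missing_cols = [c for c in _FEATURE_COLUMNS if c not in feats.columns]
        if missing_cols:
            raise ValidationError(f"feature metadata lacks column(s) {missing_cols}")
        missing_cols = [c for c in _SAMPLE_COLUMNS if c not in samps.columns]
        if missing_cols:
            raise ValidationError(f"sample metadata lacks column(s) {missing_cols}")

        bad = feats.index[~(feats["mz"].astype(float) > 0)]
        if len(bad):
            raise ValidationError(f"non-positive m/z for feature(s) {list(map(str, bad))}")
        bad = feats.index[feats["rt"].astype(float) < 0]
        if len(bad):
            raise ValidationError(f"negative rt for feature(s) {list(map(str, bad))}")

        vals = areas.to_numpy(dtype=float)
        neg = np.argwhere(vals < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative area at feature {areas.index[i]!r}, sample {areas.columns[j]!r}"
            )

        bad = samps.index[~samps["group"].isin(GROUPS)]
        if len(bad):
            labels = sorted(set(samps.loc[bad, "group"].astype(str)))
            raise ValidationError(f"unknown group label(s) {labels} for sample(s) {list(map(str, bad))}")
        bad = samps.index[~samps["sample_type"].isin(SAMPLE_TYPES)]
        if len(bad):
            raise ValidationError(f"unknown sample_type for sample(s) {list(map(str, bad))}")
        mismatch = samps.index[(samps["group"] == "QC") != (samps["sample_type"] == "QC")]
        if len(mismatch):
            raise ValidationError(
                f"group==QC must coincide with sample_type==QC; offending sample(s) "
                f"{list(map(str, mismatch))}"
            )
        orders = samps["injection_order"].astype(int)
        if (orders <= 0).any():
            bad = samps.index[orders <= 0]
            raise ValidationError(f"non-positive injection_order for sample(s) {list(map(str, bad))}")
        for col in ("column", "polarity"):
            allowed = {e.value for e in (Column if col == "column" else Polarity)}
            bad = samps.index[~samps[col].isin(allowed)]
            if len(bad):
                raise ValidationError(f"unknown {col} value for sample(s) {list(map(str, bad))}")
        for (colval, polval), grp in samps.groupby(["column", "polarity"], sort=False):
            o = grp["injection_order"].astype(int)
            if o.duplicated().any():
                dups = sorted(o[o.duplicated()].unique())
                raise ValidationError(
                    f"duplicated injection_order {dups} within run {colval}/{polval}"
                )

    # -- convenience --------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def qc_sample_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["sample_type"] == "QC"])

    @property
    def study_sample_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["sample_type"] == "STUDY"])

    @property
    def study_groups_present(self) -> list[str]:
        present = set(self.samples.loc[self.study_sample_ids, "group"])
        return [g for g in STUDY_GROUPS if g in present]

    @property
    def run(self) -> AnalyticalRun:
        """The single analytical run of this table; raises if samples mix runs."""
        combos = set(zip(self.samples["column"], self.samples["polarity"]))
        if len(combos) != 1:
            raise ValidationError(f"table mixes analytical runs: {sorted(combos)}")
        colval, polval = next(iter(combos))
        return AnalyticalRun(Column(colval), Polarity(polval))

    def group_areas(self, feature_id: str, group: str) -> np.ndarray:
        """Non-missing areas of one feature in one group (study samples only)."""
        ids = self.samples.index[
            (self.samples["group"] == group) & (self.samples["sample_type"] == "STUDY")
        ]
        if group == "QC":
            ids = self.qc_sample_ids
        vals = self.areas.loc[feature_id, ids].to_numpy(dtype=float)
        return vals[~np.isnan(vals)]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.areas.copy(), self.features.copy(), self.samples.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FeatureTable({self.n_features} features x {self.n_samples} samples)"


# -- feature-table CSV I/O --------------------------------------------------


def read_feature_table(areas_path: str | Path, samples_path: str | Path) -> FeatureTable:
    """Read a feature table from the two-file CSV layout.

    The areas CSV starts with ``feature_id, mz, rt, annotation`` followed by
    one column per sample; the samples CSV has
    ``sample_id, group, sample_type, injection_order, column, polarity``.
    Empty area fields parse as missing (NaN), never as zero.
    """
    areas_path, samples_path = Path(areas_path), Path(samples_path)
    for p in (areas_path, samples_path):
        if not p.exists():
            raise ValidationError(f"input file does not exist: {p}")
    raw = pd.read_csv(areas_path, dtype={"feature_id": str}, keep_default_na=False,
                      na_values=[""], float_precision="round_trip")
    required = ["feature_id"] + _FEATURE_COLUMNS
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValidationError(f"{areas_path}: missing required column(s) {missing}")
    raw = raw.set_index("feature_id")
    features = raw[_FEATURE_COLUMNS].copy()
    features["annotation"] = features["annotation"].fillna("").astype(str)
    for col in ("mz", "rt"):
        try:
            features[col] = features[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{areas_path}: non-numeric {col}: {exc}") from exc
    area_cols = [c for c in raw.columns if c not in _FEATURE_COLUMNS]
    try:
        areas = raw[area_cols].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{areas_path}: non-numeric area value: {exc}") from exc

    samples = pd.read_csv(samples_path, dtype={"sample_id": str, "group": str},
                          keep_default_na=False, na_values=[""])
    required = ["sample_id"] + _SAMPLE_COLUMNS
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise ValidationError(f"{samples_path}: missing required column(s) {missing}")
    samples = samples.set_index("sample_id")[_SAMPLE_COLUMNS]
    try:
        samples["injection_order"] = samples["injection_order"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{samples_path}: non-integer injection_order: {exc}") from exc

    if set(area_cols) != set(samples.index):
        only_areas = sorted(set(area_cols) - set(samples.index))
        only_meta = sorted(set(samples.index) - set(area_cols))
        raise ValidationError(
            f"sample ids disagree between {areas_path} and {samples_path}: "
            f"only in areas {only_areas}, only in metadata {only_meta}"
        )
    samples = samples.loc[area_cols]
    return FeatureTable(areas, features, samples)


def write_feature_table(table: FeatureTable, areas_path: str | Path,
                        samples_path: str | Path) -> None:
    """Write ``table`` so that :func:`read_feature_table` round-trips it exactly.

    Missing areas are serialized as empty fields.
    """
    out = table.features.copy()
    out = out.join(table.areas)
    out.index.name = "feature_id"
    # shortest round-trip representation; pandas' default str() truncates
    out.to_csv(areas_path, na_rep="",
               float_format=lambda v: repr(float(v)))
    samples = table.samples.copy()
    samples.index.name = "sample_id"
    samples.to_csv(samples_path)


# -- compound registry ------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """One registry entry: a compound as observable in one ionization polarity."""

    name: str
    polarity: Polarity
    mz: float
    rt_rp: float | None
    rt_hilic: float | None
    detected_rp: bool
    detected_hilic: bool
    compound_subclass: str
    role: str  # "MOINT" | "IS"
    spike_group: int | None
    hmdb_id: str | None
    kegg_id: str | None

    def rt(self, column: Column) -> float | None:
        return self.rt_rp if column is Column.RP_PHENYL_HEXYL else self.rt_hilic

    def detected(self, column: Column) -> bool:
        return self.detected_rp if column is Column.RP_PHENYL_HEXYL else self.detected_hilic


REGISTRY_COLUMNS = [
    "name", "polarity", "mz", "rt_rp", "rt_hilic", "detected_rp", "detected_hilic",
    "compound_subclass", "role", "spike_group", "hmdb_id", "kegg_id",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(value, *, context: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"{context}: cannot parse boolean {value!r}")


class CompoundRegistry:
    """The catalogue of molecules of interest (MoInt) and internal standards (IS)."""

    def __init__(self, records: Sequence[CompoundRecord]):
        self.records = list(records)
        seen = set()
        for r in self.records:
            key = (r.name, r.polarity)
            if key in seen:
                raise ValidationError(f"duplicate registry record for {key}")
            seen.add(key)
            if r.detected_rp and r.rt_rp is None:
                raise ValidationError(f"{r.name}/{r.polarity.value}: detected_rp without rt_rp")
            if r.detected_hilic and r.rt_hilic is None:
                raise ValidationError(f"{r.name}/{r.polarity.value}: detected_hilic without rt_hilic")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def moint(self, polarity: Polarity | None = None) -> list[CompoundRecord]:
        recs = [r for r in self.records if r.role == "MOINT"]
        if polarity is not None:
            recs = [r for r in recs if r.polarity is polarity]
        return recs

    def internal_standards(self, polarity: Polarity | None = None) -> list[CompoundRecord]:
        recs = [r for r in self.records if r.role == "IS"]
        if polarity is not None:
            recs = [r for r in recs if r.polarity is polarity]
        return recs

    def unique_moint_names(self) -> list[str]:
        return sorted({r.name for r in self.moint()})

    def kegg_annotated_moint_names(self) -> list[str]:
        """Unique MoInt names carrying a KEGG identifier (pathway-analysis input)."""
        return sorted({r.name for r in self.moint() if r.kegg_id})

    def for_run(self, run: AnalyticalRun) -> list[CompoundRecord]:
        """Records observable in ``run``: matching polarity and flagged detected on its column."""
        return [r for r in self.records
                if r.polarity is run.polarity and r.detected(run.column)]


def read_registry(path: str | Path) -> CompoundRegistry:
    """Read the compound-registry CSV (one row per compound x polarity)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"registry file does not exist: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        ctx = f"{path} row {i + 2}"  # 1-based plus header
        try:
            mz = float(row["mz"])
        except ValueError as exc:
            raise ValidationError(f"{ctx}: non-numeric m/z {row['mz']!r}") from exc
        try:
            pol = Polarity(row["polarity"].strip())
        except ValueError as exc:
            raise ValidationError(f"{ctx}: unknown polarity {row['polarity']!r}") from exc
        role = row["role"].strip().upper()
        if role not in ("MOINT", "IS"):
            raise ValidationError(f"{ctx}: unknown role {row['role']!r}")
        rt_rp = float(row["rt_rp"]) if row["rt_rp"].strip() else None
        rt_hilic = float(row["rt_hilic"]) if row["rt_hilic"].strip() else None
        spike = row["spike_group"].strip()
        records.append(CompoundRecord(
            name=row["name"].strip(),
            polarity=pol,
            mz=mz,
            rt_rp=rt_rp,
            rt_hilic=rt_hilic,
            detected_rp=_parse_bool(row["detected_rp"], context=ctx),
            detected_hilic=_parse_bool(row["detected_hilic"], context=ctx),
            compound_subclass=row["compound_subclass"].strip(),
            role=role,
            spike_group=int(spike) if spike else None,
            hmdb_id=row["hmdb_id"].strip() or None,
            kegg_id=row["kegg_id"].strip() or None,
        ))
    return CompoundRegistry(records)


# -- pathway fixtures -------------------------------------------------------


@dataclass(frozen=True)
class PathwayDef:
    """A named pathway: member compound ids plus an undirected graph over them."""

    name: str
    members: tuple[str, ...]
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        member_set = set(self.members)
        if len(member_set) != len(self.members):
            raise ValidationError(f"pathway {self.name!r}: duplicated members")
        for a, b in self.edges:
            if a not in member_set or b not in member_set:
                raise ValidationError(
                    f"pathway {self.name!r}: edge ({a}, {b}) has a non-member endpoint"
                )


def load_pathways(path: str | Path) -> list[PathwayDef]:
    """Load a pathway set from a JSON file mapping name -> {members, edges}."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"pathway file does not exist: {path}")
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a JSON object of pathways")
    pathways = []
    for name, spec in raw.items():
        members = tuple(str(m) for m in spec.get("members", []))
        edges = tuple((str(a), str(b)) for a, b in spec.get("edges", []))
        pathways.append(PathwayDef(name=name, members=members, edges=edges))
    return pathways
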