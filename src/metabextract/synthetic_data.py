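"""Synthetic feature-table generator with recorded ground truth.

Generates tables with the structure the downstream analysis assumes:
log-normal baseline abundances, multiplicative replicate noise at a
configurable CV, smooth multiplicative injection-order drift shared across
features, group-specific fold-change and CV effects, pooled-QC injections,
and left-censoring at a detection limit (missing, never zero).

Every generated quantity is recorded in :class:`GroundTruth` so each
downstream stage has a parameter-recovery oracle.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_io import (STUDY_GROUPS, Column, FeatureTable, Polarity,
                         ValidationError)

__all__ = [
    "EffectSpec",
    "DriftSpec",
    "PlantedCompound",
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "default_paper_scenario",
]

#: Selector keywords accepted by :attr:`EffectSpec.target` besides explicit
#: feature-id lists: "all", "planted", or any feature-class name
#: ("lipophilic" plus the keys of ``extra_class_fractions``).
_BUILTIN_TARGETS = ("all", "planted", "lipophilic")


@dataclass(frozen=True)
class EffectSpec:
    """A group-restricted multiplicative effect on a feature class.

    ``fold_change`` scales the expected abundance; ``cv_multiplier`` scales
    the relative noise of affected features in the named groups.
    """

    target: str | tuple[str, ...]
    groups: tuple[str, ...]
    fold_change: float = 1.0
    cv_multiplier: float = 1.0

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.cv_multiplier <= 0:
            raise ValueError("cv_multiplier must be > 0")
        unknown = set(self.groups) - set(STUDY_GROUPS)
        if unknown:
            raise ValueError(f"unknown group(s) in effect: {sorted(unknown)}")


@dataclass(frozen=True)
class DriftSpec:
    """Injection-order intensity drift, multiplicative and shared across features."""

    model: str = "LINEAR"  # LINEAR | EXPONENTIAL | SMOOTH_RANDOM
    magnitude: float = 0.1
    per_feature_jitter: float = 0.0

    def __post_init__(self):
        if self.model not in ("LINEAR", "EXPONENTIAL", "SMOOTH_RANDOM"):
            raise ValueError(f"unknown drift model {self.model!r}")
        if self.magnitude <= -1.0:
            raise ValueError("drift magnitude must keep the multiplier positive")
        if self.per_feature_jitter < 0:
            raise ValueError("per_feature_jitter must be >= 0")


@dataclass(frozen=True)
class PlantedCompound:
    """A feature pinned to a known compound identity (m/z, rt, feature class)."""

    name: str
    mz: float
    rt: float
    feature_class: str = "planted_other"


@dataclass
class SimulationConfig:
    n_features: int = 300
    replicates: Mapping[str, int] = field(
        default_factory=lambda: {g: 5 for g in STUDY_GROUPS})
    n_qc: int = 6
    qc_spacing: int | None = None       # explicit QC cadence; None = even placement
    baseline_log_mean: float = 9.0      # natural-log scale
    baseline_log_sd: float = 1.1
    base_cv: float = 0.10
    lipophilic_fraction: float = 0.3
    extra_class_fractions: Mapping[str, float] = field(default_factory=dict)
    effects: Sequence[EffectSpec] = field(default_factory=list)
    drift: DriftSpec | None = None
    missing_below: float = 0.0
    seed: int = 0
    column: Column = Column.RP_PHENYL_HEXYL
    polarity: Polarity = Polarity.POS
    planted: Sequence[PlantedCompound] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if not self.replicates:
            raise ValueError("at least one study group required")
        for g, n in self.replicates.items():
            if g not in STUDY_GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError(f"replicate count for {g} must be >= 2")
        if not 0.0 <= self.base_cv < 1.0:
            raise ValueError("base_cv must lie in [0, 1)")
        if not 0.0 <= self.lipophilic_fraction <= 1.0:
            raise ValueError("lipophilic_fraction must lie in [0, 1]")
        total_frac = self.lipophilic_fraction + sum(self.extra_class_fractions.values())
        if total_frac > 1.0 + 1e-12:
            raise ValueError("feature-class fractions sum to more than 1")
        if self.missing_below < 0:
            raise ValueError("missing_below must be >= 0")
        if self.drift is not None and self.n_qc < 1:
            raise ValueError("drift simulation requires at least one QC injection "
                             "(set n_qc >= 1 or drift=None)")
        if len(self.planted) > self.n_features:
            raise ValueError("more planted compounds than features")
        if self.n_qc < 0:
            raise ValueError("n_qc must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knew: the oracle for parameter-recovery tests."""

    feature_info: pd.DataFrame    # index feature_id: baseline, feature_class, lipophilic
    group_means: pd.DataFrame     # features x study groups, expected areas (drift-free)
    group_cvs: pd.DataFrame       # features x study groups, true CV of the noise
    drift_curve: pd.Series        # injection_order -> shared drift multiplier
    feature_drift_exponent: pd.Series  # per-feature jitter exponent on log-drift
    qc_expected: pd.Series        # feature -> drift-free expected QC (pooled) area

    def differential_features(self, group_a: str, group_b: str,
                              rtol: float = 1e-9) -> list[str]:
        """Feature ids whose true means differ between two groups."""
        a = self.group_means[group_a]
        b = self.group_means[group_b]
        diff = ~np.isclose(a, b, rtol=rtol)
        return list(self.group_means.index[diff])


def _resolve_target(target, feature_class: pd.Series, planted_ids: set[str]) -> pd.Index:
    if isinstance(target, str):
        if target == "all":
            return feature_class.index
        if target == "planted":
            return feature_class.index[[fid in planted_ids for fid in feature_class.index]]
        hit = feature_class.index[feature_class == target]
        if len(hit) == 0 and target not in set(feature_class):
            raise ValueError(f"effect target {target!r} matches no feature class")
        return hit
    ids = list(target)
    unknown = set(ids) - set(feature_class.index)
    if unknown:
        raise ValueError(f"effect target ids not in table: {sorted(unknown)[:5]}")
    return pd.Index(ids)


def _drift_curve(spec: DriftSpec, n_inj: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_inj, dtype=float)
    frac = t / max(n_inj - 1, 1)
    if spec.model == "LINEAR":
        curve = 1.0 + spec.magnitude * frac
    elif spec.model == "EXPONENTIAL":
        curve = (1.0 + spec.magnitude) ** frac
    else:  # SMOOTH_RANDOM: smoothed random walk on the log scale
        raw = rng.standard_normal(n_inj)
        window = max(n_inj // 5, 3)
        kernel = np.ones(window) / window
        smooth = np.convolve(raw, kernel, mode="same")
        smooth -= smooth[0]
        peak = np.abs(smooth).max()
        if peak > 0:
            smooth *= math.log1p(abs(spec.magnitude)) / peak
        curve = np.exp(np.sign(spec.magnitude or 1.0) * smooth)
    if (curve <= 0).any():
        raise ValueError("drift multiplier must be strictly positive over the run")
    return curve


def _qc_positions(n_qc: int, n_total: int, spacing: int | None) -> list[int]:
    """0-based injection indices reserved for QC samples."""
    if n_qc == 0:
        return []
    if spacing is not None:
        pos, idx = [], 0
        while len(pos) < n_qc and idx < n_total:
            pos.append(idx)
            idx += spacing + 1
        if len(pos) < n_qc:
            raise ValueError("qc_spacing too wide to place all QC injections")
        return pos
    return sorted(set(np.round(np.linspace(0, n_total - 1, n_qc)).astype(int)))


def simulate(config: SimulationConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table plus its ground truth; deterministic per seed.

    QC samples are the per-injection drift-scaled mean of the pooled
    study-sample expectations (emulating a physical pool), with noise at the
    base CV.  Areas below ``missing_below`` are censored to missing.  When
    drift is simulated, the shared drift curve is anchored so its median over
    the QC injections is 1, which makes the drift-free expectations directly
    comparable to QC-corrected areas.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    fids = [f"F{i + 1:05d}" for i in range(n)]

    # feature classes: planted compounds first, then random class assignment
    feature_class = pd.Series("other", index=fids, dtype=object)
    mz = rng.uniform(80.0, 900.0, n)
    rt = rng.uniform(20.0, 700.0, n)
    planted_ids: set[str] = set()
    for i, comp in enumerate(config.planted):
        feature_class.iloc[i] = comp.feature_class
        mz[i] = comp.mz
        rt[i] = comp.rt
        planted_ids.add(fids[i])
    free = np.arange(len(config.planted), n)
    shuffled = rng.permutation(free)
    cursor = 0
    n_lipo = int(round(config.lipophilic_fraction * len(free)))
    feature_class.iloc[shuffled[cursor:cursor + n_lipo]] = "lipophilic"
    cursor += n_lipo
    for cls, fracv in config.extra_class_fractions.items():
        n_cls = int(round(fracv * len(free)))
        feature_class.iloc[shuffled[cursor:cursor + n_cls]] = cls
        cursor += n_cls

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)

    groups = [g for g in STUDY_GROUPS if g in config.replicates]
    fold = pd.DataFrame(1.0, index=fids, columns=groups)
    cv_mult = pd.DataFrame(1.0, index=fids, columns=groups)
    for eff in config.effects:
        idx = _resolve_target(eff.target, feature_class, planted_ids)
        for g in eff.groups:
            if g in fold.columns:
                fold.loc[idx, g] *= eff.fold_change
                cv_mult.loc[idx, g] *= eff.cv_multiplier
    group_means = fold.mul(baseline, axis=0)
    group_cvs = cv_mult * config.base_cv

    # injection layout
    study_ids, study_groups = [], []
    for g in groups:
        for r in range(1, config.replicates[g] + 1):
            study_ids.append(f"{g}_{r}")
            study_groups.append(g)
    n_study = len(study_ids)
    n_total = n_study + config.n_qc
    qc_pos = _qc_positions(config.n_qc, n_total, config.qc_spacing)
    study_pos = [i for i in range(n_total) if i not in set(qc_pos)]
    if len(study_pos) != n_study:
        raise ValueError("QC placement does not leave room for all study samples")
    study_order = rng.permutation(n_study)

    sample_rows = []  # (sample_id, group, sample_type, injection_order)
    for k, pos in enumerate(qc_pos):
        sample_rows.append((f"QC_{k + 1}", "QC", "QC", pos + 1))
    for slot, s_idx in zip(study_pos, study_order):
        sample_rows.append((study_ids[s_idx], study_groups[s_idx], "STUDY", slot + 1))
    sample_rows.sort(key=lambda rrow: rrow[3])

    # drift
    if config.drift is not None:
        curve = _drift_curve(config.drift, n_total, rng)
        if qc_pos:
            curve = curve / np.median(curve[qc_pos])
        exponent = 1.0 + rng.normal(0.0, config.drift.per_feature_jitter, n) \
            if config.drift.per_feature_jitter > 0 else np.ones(n)
    else:
        curve = np.ones(n_total)
        exponent = np.ones(n)
    log_curve = np.log(curve)

    pooled = group_means[ [g for g in groups] ].to_numpy() @ \
        np.array([config.replicates[g] for g in groups], dtype=float) / n_study

    # draw areas
    areas = np.empty((n, len(sample_rows)))
    sigma = None
    for j, (sid, grp, stype, order) in enumerate(sample_rows):
        if stype == "QC":
            mean_j = pooled
            cv_j = np.full(n, config.base_cv)
        else:
            mean_j = group_means[grp].to_numpy()
            cv_j = group_cvs[grp].to_numpy()
        sigma = np.sqrt(np.log1p(cv_j ** 2))
        noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma)) if config.base_cv > 0 \
            else np.where(sigma > 0, np.exp(rng.normal(-0.5 * sigma ** 2, sigma)), 1.0)
        drift_j = np.exp(exponent * log_curve[order - 1])
        areas[:, j] = mean_j * noise * drift_j
    if config.missing_below > 0:
        areas[areas < config.missing_below] = np.nan

    sample_index = [r[0] for r in sample_rows]
    samples = pd.DataFrame({
        "group": [r[1] for r in sample_rows],
        "sample_type": [r[2] for r in sample_rows],
        "injection_order": [r[3] for r in sample_rows],
        "column": config.column.value,
        "polarity": config.polarity.value,
    }, index=pd.Index(sample_index, name="sample_id"))
    features = pd.DataFrame({
        "mz": mz, "rt": rt,
        "annotation": ["planted:" + config.planted[i].name if i < len(config.planted) else ""
                       for i in range(n)],
    }, index=pd.Index(fids, name="feature_id"))
    table = FeatureTable(pd.DataFrame(areas, index=fids, columns=sample_index),
                         features, samples)

    truth = GroundTruth(
        feature_info=pd.DataFrame({
            "baseline": baseline,
            "feature_class": feature_class.to_numpy(),
            "lipophilic": (feature_class == "lipophilic").to_numpy(),
        }, index=pd.Index(fids, name="feature_id")),
        group_means=group_means,
        group_cvs=group_cvs,
        drift_curve=pd.Series(curve, index=pd.RangeIndex(1, n_total + 1,
                                                         name="injection_order")),
        feature_drift_exponent=pd.Series(exponent, index=fids),
        qc_expected=pd.Series(pooled, index=fids),
    )
    return table, truth


#: Subclass -> simulation feature class for planted registry compounds.
_LIPOPHILIC_SUBCLASSES = {"Cholestane steroids", "Ceramides", "Amines", "Fatty acids"}


def default_paper_scenario(seed: int = 0) -> SimulationConfig:
    """A six-group scenario encoding the study's qualitative findings.

    Two-phase groups (III, IV and their bead variants) lose lipophilic
    features almost entirely (fold 0.02) and double amino-acid-class
    abundances; bead homogenization (_B) raises abundance (fold 1.5), raises
    noise, and releases a "latent" feature class that stays below the
    detection limit without mechanical tissue disruption; extraction II has
    slightly lower recovery of the target panel and clearly worse precision.
    Registry compounds detected in the simulated run (RP column, positive
    mode) are planted as real features so targeted matching works end to end.
    """
    from .data import load_bundled_registry

    registry = load_bundled_registry()
    planted = []
    for rec in registry.moint(Polarity.POS):
        if not rec.detected_rp:
            continue
        if rec.compound_subclass in _LIPOPHILIC_SUBCLASSES:
            cls = "lipophilic"
        elif rec.compound_subclass == "Amino acids":
            cls = "amino"
        else:
            cls = "planted_other"
        planted.append(PlantedCompound(rec.name, rec.mz, rec.rt_rp, cls))

    two_phase = ("III", "IV", "III_B", "IV_B")
    bead = ("III_B", "IV_B")
    effects = [
        EffectSpec(target="lipophilic", groups=two_phase, fold_change=0.02),
        EffectSpec(target="amino", groups=two_phase, fold_change=2.0),
        EffectSpec(target="all", groups=two_phase, cv_multiplier=1.5),
        EffectSpec(target="all", groups=bead, fold_change=1.5, cv_multiplier=1.5),
        # latent features need bead homogenization to be released at all
        EffectSpec(target="latent", groups=("I", "II", "III", "IV"), fold_change=0.05),
        EffectSpec(target="planted", groups=("II",), fold_change=0.8, cv_multiplier=1.8),
    ]
    return SimulationConfig(
        n_features=600,
        replicates={g: 5 for g in STUDY_GROUPS},
        n_qc=8,
        baseline_log_mean=9.0,
        baseline_log_sd=1.1,
        base_cv=0.10,
        lipophilic_fraction=0.10,
        extra_class_fractions={"amino": 0.15, "latent": 0.20},
        effects=effects,
        drift=DriftSpec(model="LINEAR", magnitude=0.10, per_feature_jitter=0.02),
        missing_below=2500.0,
        seed=seed,
        planted=planted,
    )
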