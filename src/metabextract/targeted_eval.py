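"""Internal-standard / MoInt evaluation: feature matching, reference
normalization, and mean/SD/CV summaries with Welch contrasts.

Compounds are matched to features by m/z (ppm tolerance, default 5) and
retention time (absolute seconds, default 10); peak areas are normalized on
the mean area of the reference extraction, and per-compound plus aggregate
per-group summaries are produced.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_io import (CompoundRecord, CompoundRegistry, FeatureTable,
                         ValidationError)
from .univariate_stats import TestResult, welch_t

__all__ = [
    "CompoundMatch",
    "UnmatchedCompound",
    "CompoundSummary",
    "PanelSummary",
    "match_compounds",
    "normalize_to_reference",
    "cv_percent",
    "summarize_compounds",
]

DEFAULT_MZ_TOL_PPM = 5.0
DEFAULT_RT_TOL_S = 10.0


@dataclass(frozen=True)
class CompoundMatch:
    compound: str
    feature_id: str
    mz_error_ppm: float
    rt_error_s: float


@dataclass(frozen=True)
class UnmatchedCompound:
    compound: str
    reason: str  # "no m/z candidate" | "rt out of window"


def match_compounds(table: FeatureTable, registry: CompoundRegistry,
                    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
                    rt_tol_s: float = DEFAULT_RT_TOL_S,
                    ) -> tuple[list[CompoundMatch], list[UnmatchedCompound]]:
    """Match registry compounds to table features for the table's analytical run.

    Only records of the table's polarity that are flagged detected on its
    column participate.  Each compound takes the candidate with the smallest
    |m/z error in ppm| (ties broken by |rt error|) among features within both
    tolerances.  ``matched + unmatched`` always covers the applicable records.
    """
    run = table.run
    records = registry.for_run(run)
    if not any(r.polarity is run.polarity for r in registry):
        raise ValidationError(
            f"registry contains no records for polarity {run.polarity.value}"
        )
    mz = table.features["mz"].to_numpy(dtype=float)
    rt = table.features["rt"].to_numpy(dtype=float)
    fids = np.asarray(table.feature_ids)
    matches: list[CompoundMatch] = []
    unmatched: list[UnmatchedCompound] = []
    for rec in records:
        ppm = (mz - rec.mz) / rec.mz * 1e6
        in_mz = np.abs(ppm) <= mz_tol_ppm
        if not in_mz.any():
            unmatched.append(UnmatchedCompound(rec.name, "no m/z candidate"))
            continue
        rt_ref = rec.rt(run.column)
        rt_err = rt - (rt_ref if rt_ref is not None else np.nan)
        ok = in_mz & (np.abs(rt_err) <= rt_tol_s)
        if not ok.any():
            unmatched.append(UnmatchedCompound(rec.name, "rt out of window"))
            continue
        cand = np.flatnonzero(ok)
        order = sorted(cand, key=lambda i: (abs(ppm[i]), abs(rt_err[i]), fids[i]))
        best = order[0]
        matches.append(CompoundMatch(rec.name, str(fids[best]),
                                     float(ppm[best]), float(rt_err[best])))
    return matches, unmatched


def normalize_to_reference(areas_by_group: Mapping[str, Sequence[float]],
                           reference: str) -> dict[str, np.ndarray]:
    """Divide every group's areas by the reference group's mean area.

    Raises ``ValueError`` (NOT_NORMALIZABLE) when the reference group has no
    usable areas or mean 0 -- callers flag and exclude such compounds.
    """
    if reference not in areas_by_group:
        raise ValueError(f"reference group {reference!r} absent")
    ref = np.asarray(areas_by_group[reference], dtype=float)
    ref = ref[~np.isnan(ref)]
    if len(ref) == 0 or ref.mean() <= 0:
        raise ValueError("NOT_NORMALIZABLE: reference group mean is zero or all-missing")
    ref_mean = ref.mean()
    return {g: np.asarray(v, dtype=float) / ref_mean for g, v in areas_by_group.items()}


def cv_percent(values: Sequence[float]) -> float:
    """Percent coefficient of variation: sample SD (n-1) / mean * 100."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        raise ValueError("cv_percent requires >= 2 non-missing values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("cv_percent undefined for mean 0")
    return float(arr.std(ddof=1) / mean * 100.0)


@dataclass
class CompoundSummary:
    """Per-compound normalized-area summary across extraction groups."""

    compound: str
    feature_id: str
    mean_norm: dict[str, float]     # group -> mean normalized area (ref == 1)
    sd_norm: dict[str, float]
    cv_pct: dict[str, float]        # CV of the raw (equivalently normalized) areas
    contrasts: list[TestResult] = field(default_factory=list)
    flag: str = ""                  # "" | "NOT_NORMALIZABLE"


@dataclass
class PanelSummary:
    """Aggregate over compounds: mean of per-group normalized means, with SD."""

    mean_of_means: dict[str, float]
    sd_of_means: dict[str, float]
    mean_cv_pct: dict[str, float]
    n_compounds: int


def summarize_compounds(table: FeatureTable, registry: CompoundRegistry,
                        matches: Sequence[CompoundMatch], reference: str = "I",
                        ) -> tuple[list[CompoundSummary], PanelSummary]:
    """Summarize matched compounds: normalized means, SDs, CVs, Welch contrasts.

    The aggregate mirrors the per-extraction bar summaries: for each group,
    the mean (and SD) over compounds of the per-compound mean normalized area,
    plus the mean per-compound CV.  Compounds whose reference group cannot
    anchor the normalization are flagged NOT_NORMALIZABLE and excluded from
    the aggregate.
    """
    groups = table.study_groups_present
    if reference not in groups:
        raise ValidationError(f"reference group {reference!r} not present in table")
    summaries: list[CompoundSummary] = []
    for m in matches:
        by_group = {g: table.group_areas(m.feature_id, g) for g in groups}
        try:
            norm = normalize_to_reference(by_group, reference)
        except ValueError:
            summaries.append(CompoundSummary(m.compound, m.feature_id, {}, {}, {},
                                             flag="NOT_NORMALIZABLE"))
            continue
        mean_norm, sd_norm, cvs = {}, {}, {}
        contrasts = []
        for g in groups:
            vals = norm[g]
            vals = vals[~np.isnan(vals)]
            mean_norm[g] = float(vals.mean()) if len(vals) else float("nan")
            sd_norm[g] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
            try:
                cvs[g] = cv_percent(by_group[g])
            except ValueError:
                cvs[g] = float("nan")
            if g != reference and len(vals) >= 2 and len(by_group[reference]) >= 2:
                contrasts.append(welch_t(by_group[g], by_group[reference],
                                         unit_id=m.compound,
                                         contrast=f"{g} vs {reference}"))
        summaries.append(CompoundSummary(m.compound, m.feature_id, mean_norm,
                                         sd_norm, cvs, contrasts))

    usable = [s for s in summaries if not s.flag]
    mean_of_means, sd_of_means, mean_cv = {}, {}, {}
    for g in groups:
        per_comp = np.array([s.mean_norm.get(g, np.nan) for s in usable])
        per_cv = np.array([s.cv_pct.get(g, np.nan) for s in usable])
        per_comp = per_comp[~np.isnan(per_comp)]
        per_cv = per_cv[~np.isnan(per_cv)]
        mean_of_means[g] = float(per_comp.mean()) if len(per_comp) else float("nan")
        sd_of_means[g] = float(per_comp.std(ddof=1)) if len(per_comp) > 1 else float("nan")
        mean_cv[g] = float(per_cv.mean()) if len(per_cv) else float("nan")
    panel = PanelSummary(mean_of_means, sd_of_means, mean_cv, len(usable))
    return summaries, panel
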