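"""Missing-data handling, 0-10 harmonization and pain outcome statistics.

All measures enter the correlation/factor stages on a common 0-10 scale with
10 = worst: instruments scored "higher is better" (KOOS, SF-36, six-minute
walk) are reversed by the affine rescale.  Missing entries of an instrument
are mean-imputed from the subject's observed entries of the same instrument
at the same visit unless 30% or more of them are missing, in which case the
instrument is excluded for that subject-visit.

The primary outcome statistic is percent residual pain,
``100 * post / pre`` - i.e. 100% means surgery changed nothing, 0% complete
relief, >100% worsening.  It is undefined (NaN, logged) for a pain-free
baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import (
    HIGHER_IS_BETTER,
    VISITS,
    AnalysisConfig,
    CohortTable,
    MeasureEntry,
    MeasureRegistry,
)

logger = logging.getLogger("painnet")


# ---------------------------------------------------------------------------
# Rescaling
# ---------------------------------------------------------------------------

def rescale_measure(value, entry: MeasureEntry):
    """Affine map from native units to the 0-10 worse-is-higher scale."""
    value = np.asarray(value, float)
    if np.any((value < entry.native_min) | (value > entry.native_max)):
        raise ValueError(
            f"{entry.measure_id}: value outside native range "
            f"[{entry.native_min}, {entry.native_max}]"
        )
    span = entry.native_max - entry.native_min
    scaled = 10.0 * (value - entry.native_min) / span
    if entry.orientation == HIGHER_IS_BETTER:
        scaled = 10.0 - scaled
    return scaled if scaled.ndim else float(scaled)


def inverse_rescale_measure(value_0_10, entry: MeasureEntry):
    """Inverse of :func:`rescale_measure` (0-10 back to native units)."""
    v = np.asarray(value_0_10, float)
    if entry.orientation == HIGHER_IS_BETTER:
        v = 10.0 - v
    span = entry.native_max - entry.native_min
    out = entry.native_min + v * span / 10.0
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Missing data
# ---------------------------------------------------------------------------

def handle_missing(items, threshold: float = 0.30):
    """Impute or exclude one instrument's items for one subject-visit.

    Returns ``(imputed_items, excluded)``.  If the missing fraction is >=
    ``threshold`` (inclusive, so 3 of 10 missing already excludes) the items
    are returned untouched with ``excluded=True``; otherwise missing items
    are replaced by the mean of the observed items.
    """
    items = np.asarray(items, float)
    if items.size == 0:
        raise ValueError("empty item vector")
    miss = np.isnan(items)
    frac = miss.mean()
    if frac >= threshold:
        return items.copy(), True
    if miss.any():
        out = items.copy()
        out[miss] = items[~miss].mean()
        return out, False
    return items.copy(), False


# ---------------------------------------------------------------------------
# Harmonized per-visit matrices
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedMatrix:
    """Complete subjects x measures matrices on the 0-10 scale, per visit."""

    matrices: dict            # visit -> DataFrame (subjects x measures)
    imputed: dict             # visit -> boolean DataFrame, True where imputed
    exclusions: pd.DataFrame  # columns: subject_id, visit, instrument, reason

    def matrix(self, visit: str) -> pd.DataFrame:
        return self.matrices[visit]


def harmonize(cohort: CohortTable, config: AnalysisConfig | None = None,
              measure_ids=None, group: str | None = None) -> HarmonizedMatrix:
    """Rescale to 0-10, impute/exclude by instrument, drop incomplete rows.

    Imputation operates within one instrument's subscales for a given
    subject-visit (the subscale-level fallback: inputs carry subscale scores,
    not raw items).  Subjects still holding missing cells after the rule -
    excluded instruments or singleton instruments - are dropped from that
    visit's matrix and recorded in the exclusion report.
    """
    config = config or AnalysisConfig()
    registry = cohort.registry
    ids = list(measure_ids) if measure_ids is not None else registry.network_ids
    instruments: dict[str, list[str]] = {}
    for m in ids:
        instruments.setdefault(registry[m].instrument, []).append(m)

    matrices, imputed_maps, excl = {}, {}, []
    for visit in VISITS:
        wide = cohort.wide(visit, measure_ids=ids, group=group)
        harm = pd.DataFrame(index=wide.index, columns=ids, dtype=float)
        for m in ids:
            col = wide[m]
            ok = col.notna()
            harm.loc[ok, m] = rescale_measure(col[ok].to_numpy(), registry[m])
        imputed = pd.DataFrame(False, index=harm.index, columns=ids)
        for instr, members in instruments.items():
            block = harm[members]
            miss = block.isna()
            frac = miss.mean(axis=1)
            # inclusive threshold: 30% missing already excludes the instrument
            excluded_rows = frac >= config.missing_threshold
            impute_rows = (frac > 0) & ~excluded_rows
            for sid in harm.index[excluded_rows]:
                excl.append({"subject_id": sid, "visit": visit,
                             "instrument": instr,
                             "reason": f">={config.missing_threshold:.0%} missing"})
            if impute_rows.any():
                sub = block.loc[impute_rows]
                filled = sub.T.fillna(sub.mean(axis=1)).T
                harm.loc[impute_rows, members] = filled
                imputed.loc[impute_rows, members] = miss.loc[impute_rows]
        complete = harm.notna().all(axis=1)
        dropped = harm.index[~complete]
        for sid in dropped:
            excl.append({"subject_id": sid, "visit": visit, "instrument": "*",
                         "reason": "incomplete after imputation"})
        matrices[visit] = harm.loc[complete]
        imputed_maps[visit] = imputed.loc[complete]

    exclusions = pd.DataFrame(excl, columns=["subject_id", "visit", "instrument", "reason"])
    if len(exclusions):
        logger.info("harmonize: %d exclusion records", len(exclusions))
    return HarmonizedMatrix(matrices=matrices, imputed=imputed_maps, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Pain outcome statistics
# ---------------------------------------------------------------------------

def residual_pain(pre, post):
    """Percent residual pain: 100 * post / pre on the 0-10 scale.

    100 = no change, 0 = complete relief, >100 = worsening.  Undefined (NaN)
    when the baseline is pain-free; negative inputs are an error.
    """
    pre_a = np.asarray(pre, float)
    post_a = np.asarray(post, float)
    if np.any(pre_a < 0) or np.any(post_a < 0):
        raise ValueError("pain scores must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pre_a > 0, 100.0 * post_a / pre_a, np.nan)
    n_undef = int(np.sum((pre_a == 0) & ~np.isnan(post_a)))
    if n_undef:
        logger.info("residual_pain: %d pain-free baselines left undefined", n_undef)
    return out if out.ndim else float(out)


def aggregate_pain(values):
    """Composite pain: arithmetic mean of the four outcome scales (0-10).

    NaN if any scale is missing after preprocessing.
    """
    vals = np.asarray(values, float)
    if vals.shape[-1] != 4:
        raise ValueError("aggregate_pain expects the four outcome scales")
    return np.where(np.isnan(vals).any(axis=-1), np.nan, vals.mean(axis=-1)) \
        if vals.ndim > 1 else (float("nan") if np.isnan(vals).any() else float(vals.mean()))


@dataclass
class PainTrajectory:
    """Per subject x scale pain course and residual-pain percentages."""

    table: pd.DataFrame  # subject_id, group, scale, pre, post3, post6,
    #                      residual_m3, residual_m6 (plus scale == "aggregate")


def pain_trajectories(cohort: CohortTable,
                      config: AnalysisConfig | None = None) -> PainTrajectory:
    """Harmonized pre/post pain per scale plus residual pain and aggregate."""
    config = config or AnalysisConfig()
    registry = cohort.registry
    scales = registry.pain_outcome_ids
    harm = harmonize(cohort, config, measure_ids=scales)
    group = cohort.group_of()

    frames = {v: harm.matrix(v) for v in VISITS}
    rows = []
    subjects = sorted(set(frames["baseline"].index)
                      & set(frames["m3"].index) & set(frames["m6"].index))
    for sid in subjects:
        per_scale = {}
        for scale in scales:
            pre = frames["baseline"].loc[sid, scale]
            p3 = frames["m3"].loc[sid, scale]
            p6 = frames["m6"].loc[sid, scale]
            per_scale[scale] = (pre, p3, p6)
            rows.append({
                "subject_id": sid, "group": group[sid], "scale": scale,
                "pre": pre, "post3": p3, "post6": p6,
                "residual_m3": residual_pain(pre, p3),
                "residual_m6": residual_pain(pre, p6),
            })
        agg = [aggregate_pain([per_scale[s][i] for s in scales]) for i in range(3)]
        rows.append({
            "subject_id": sid, "group": group[sid], "scale": "aggregate",
            "pre": agg[0], "post3": agg[1], "post6": agg[2],
            "residual_m3": residual_pain(agg[0], agg[1]),
            "residual_m6": residual_pain(agg[0], agg[2]),
        })
    return PainTrajectory(table=pd.DataFrame(rows))
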