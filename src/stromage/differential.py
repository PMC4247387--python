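"""Quantifiability filtering and per-feature age-association screening.

A protein is quantifiable when it has at least ``min_unique_peptides``
unique peptides and was identified in at least 14 of 15 samples (the
fraction is configurable). Age association is then screened on log10
intensities by two tests jointly: classical one-way fixed-effects ANOVA
across the three age groups, and Pearson correlation against calendar age
with no grouping. A feature is called age-associated only when both raw
p-values fall at or below their alpha (no multiple-testing correction in
the primary screen; BH q-values are emitted for transparency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .data import CohortDesign, FeatureTable
from .errors import ValidationError


@dataclass
class AnovaResult:
    p: float
    f: float
    degenerate: bool = False


@dataclass
class PearsonResult:
    r: float
    p: float
    undefined: bool = False


@dataclass
class DifferentialResult:
    feature_id: str
    anova_p: float
    pearson_r: float
    pearson_p: float
    fold_change: float
    direction: str  # "up" | "down"
    age_associated: bool
    degenerate: bool = False


def filter_quantifiable(table: FeatureTable, config: AnalysisConfig) -> FeatureTable:
    """Keep proteins with enough unique peptides and sample presence."""
    required = {"unique_peptide_count", "n_samples_identified"}
    missing = required - set(table.meta.columns)
    if missing:
        raise ValidationError(f"protein metadata missing columns: {sorted(missing)}")
    n_samples = len(table.sample_ids)
    min_present = math.ceil(config.min_samples_identified_fraction * n_samples)
    keep = (
        (table.meta["unique_peptide_count"] >= config.min_unique_peptides)
        & (table.meta["n_samples_identified"] >= min_present)
    )
    return table.subset(table.feature_ids[keep.to_numpy(dtype=bool)])


def anova_age_groups(values: pd.Series, design: CohortDesign) -> AnovaResult:
    """One-way fixed-effects ANOVA of log-scale values across age groups.

    ``values`` must already be on the analysis (log) scale, indexed by donor
    id; missing values are dropped. A feature with zero total variance is
    reported as p = 1 with the degenerate flag set.
    """
    groups = []
    for g in design.groups:
        v = values.reindex(design.donors_in_group(g)).dropna().to_numpy(dtype=float)
        if len(v) >= 2:
            groups.append(v)
    if len(groups) < 2:
        return AnovaResult(p=float("nan"), f=float("nan"), degenerate=True)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return AnovaResult(p=1.0, f=0.0, degenerate=True)
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(p):  # zero within-group variance, separated means
        p = 0.0
    return AnovaResult(p=float(p), f=float(f))


def pearson_age_correlation(values: pd.Series, design: CohortDesign) -> PearsonResult:
    """Pearson r of log-scale value vs calendar age; two-sided t-based p."""
    ages = design.ages()
    df = pd.DataFrame({"age": ages, "y": values.reindex(ages.index)}).dropna()
    if len(df) < 3:
        return PearsonResult(r=float("nan"), p=float("nan"), undefined=True)
    if df["y"].nunique() == 1 or df["age"].nunique() == 1:
        return PearsonResult(r=float("nan"), p=float("nan"), undefined=True)
    r, p = stats.pearsonr(df["age"], df["y"])
    return PearsonResult(r=float(r), p=float(p))


def _fold_change(values: pd.Series, design: CohortDesign) -> tuple[float, str]:
    """Linear-scale ratio of extreme age-group means, reported >= 1."""
    log_vals = values
    young = log_vals.reindex(design.donors_in_group("young")).dropna()
    old = log_vals.reindex(design.donors_in_group("old")).dropna()
    if len(young) == 0 or len(old) == 0:
        return float("nan"), "up"
    gy = 10.0 ** young.mean()
    go = 10.0 ** old.mean()
    if gy == 0 or go == 0:
        return float("nan"), "up"
    fc = max(gy, go) / min(gy, go)
    return float(fc), ("up" if go >= gy else "down")


def call_age_associated(
    table: FeatureTable,
    design: CohortDesign,
    config: AnalysisConfig,
    alpha_override: float | None = None,
) -> list[DifferentialResult]:
    """Screen every feature; direction follows the sign of the age correlation."""
    table.check_design(design)
    a_anova = alpha_override if alpha_override is not None else config.anova_alpha
    a_pears = alpha_override if alpha_override is not None else config.pearson_alpha
    log_vals = table.log10()
    out: list[DifferentialResult] = []
    for fid in table.feature_ids:
        row = log_vals.loc[fid]
        an = anova_age_groups(row, design)
        pe = pearson_age_correlation(row, design)
        fc, fc_dir = _fold_change(row, design)
        called = (
            not an.degenerate
            and not pe.undefined
            and an.p <= a_anova
            and pe.p <= a_pears
        )
        direction = (
            ("up" if pe.r >= 0 else "down") if not pe.undefined else fc_dir
        )
        out.append(
            DifferentialResult(
                feature_id=str(fid),
                anova_p=an.p,
                pearson_r=pe.r,
                pearson_p=pe.p,
                fold_change=fc,
                direction=direction,
                age_associated=bool(called),
                degenerate=an.degenerate or pe.undefined,
            )
        )
    return out


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Tabulate results; adds BH q-values for both tests (reporting only)."""
    frame = pd.DataFrame([vars(r) for r in results]).set_index("feature_id")
    from .enrichment import bh_adjust

    for col, qcol in (("anova_p", "anova_q_bh"), ("pearson_p", "pearson_q_bh")):
        p = frame[col].to_numpy(dtype=float)
        ok = np.isfinite(p)
        q = np.full_like(p, np.nan)
        if ok.any():
            q[ok] = bh_adjust(p[ok])
        frame[qcol] = q
    return frame
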