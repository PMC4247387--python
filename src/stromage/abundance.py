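"""Abundance-class ranking and cross-age class-shift detection.

Quantified features are binned into four classes of log10 intensity
(class I = highest abundance, IV = lowest) against boundaries computed
once on the pooled per-(feature, age-group) means, so a feature's class
can shift between age groups on a common scale. Two binning modes are
exposed: equal-width intervals over [min, max] (default) and equal-count
quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .data import CohortDesign, FeatureTable
from .errors import ConfigurationError

CLASS_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass
class ClassAssignment:
    feature_id: str
    age_group: str
    class_label: str
    group_mean_log10: float


def group_mean_log10(table: FeatureTable, design: CohortDesign) -> pd.DataFrame:
    """Per-feature per-age-group mean of log10 intensity (NaN if group empty)."""
    log_vals = table.log10()
    cols = {}
    for g in design.groups:
        cols[g] = log_vals[design.donors_in_group(g)].mean(axis=1, skipna=True)
    return pd.DataFrame(cols)


def compute_class_boundaries(
    table: FeatureTable, design: CohortDesign, config: AnalysisConfig
) -> np.ndarray:
    """Interior boundaries (descending abundance order I..IV uses ascending cuts)."""
    means = group_mean_log10(table, design)
    pooled = means.to_numpy(dtype=float).ravel()
    pooled = pooled[np.isfinite(pooled)]
    k = config.n_abundance_classes
    if np.unique(pooled).size < k:
        raise ConfigurationError(
            f"need at least {k} distinct pooled group means to form {k} classes"
        )
    if config.abundance_mode == "width":
        lo, hi = pooled.min(), pooled.max()
        return lo + (hi - lo) * np.arange(1, k) / k
    return np.quantile(pooled, np.arange(1, k) / k)


def assign_classes(
    table: FeatureTable,
    design: CohortDesign,
    boundaries: np.ndarray,
    config: AnalysisConfig | None = None,
) -> list[ClassAssignment]:
    """Assign each (feature, group) to a class by its group-mean log10.

    Class I is the most abundant interval. Values exactly on a boundary are
    assigned to the higher-abundance class.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    k = len(boundaries) + 1
    means = group_mean_log10(table, design)
    out: list[ClassAssignment] = []
    for fid, row in means.iterrows():
        for g in means.columns:
            m = row[g]
            if not np.isfinite(m):
                continue  # feature absent in this group; flagged by omission
            # number of boundaries strictly above m -> class index from the top
            idx = int(np.sum(boundaries > m))
            out.append(
                ClassAssignment(
                    feature_id=str(fid),
                    age_group=g,
                    class_label=CLASS_LABELS[idx],
                    group_mean_log10=float(m),
                )
            )
    return out


def assignments_frame(assignments: list[ClassAssignment]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in assignments])


def detect_class_shifts(assignments: list[ClassAssignment]) -> list[dict]:
    """Features whose class differs between any two age groups.

    Returns records ordered by feature id with the young->middle->old class
    path and the first (from, to) transition between consecutive groups
    where the class changes.
    """
    frame = assignments_frame(assignments)
    if frame.empty:
        return []
    order = [g for g in ("young", "middle", "old") if g in set(frame["age_group"])]
    wide = frame.pivot(index="feature_id", columns="age_group", values="class_label")
    shifts: list[dict] = []
    for fid in sorted(wide.index):
        path = [wide.loc[fid].get(g) for g in order]
        present = [(g, c) for g, c in zip(order, path) if isinstance(c, str)]
        labels = [c for _, c in present]
        if len(set(labels)) <= 1:
            continue
        from_class, to_class, at_group = None, None, None
        for (g0, c0), (g1, c1) in zip(present, present[1:]):
            if c0 != c1:
                from_class, to_class, at_group = c0, c1, g1
                break
        shifts.append(
            {
                "feature_id": fid,
                "from_class": from_class,
                "to_class": to_class,
                "at_group": at_group,
                "path": "->".join(labels),
                "groups": ",".join(g for g, _ in present),
            }
        )
    return shifts
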