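"""Equivalence ("unchanged") classification by pairwise TOST.

For each feature, the three pairwise age-group contrasts (young-middle,
young-old, middle-old) are tested for equivalence on the log10 scale with
the two one-sided tests (TOST) procedure against a fixed equivalence range
epsilon = 0.3: the TOST p-value is the maximum of the two one-sided
two-sample t p-values for H01: mu_a - mu_b >= eps and H02:
mu_a - mu_b <= -eps. A feature is "unchanged" when all three pairwise TOST
p-values are at or below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .data import CohortDesign, FeatureTable

PAIRS = (("young", "middle"), ("young", "old"), ("middle", "old"))


@dataclass
class StabilityResult:
    feature_id: str
    mean_diff_ym: float
    mean_diff_yo: float
    mean_diff_mo: float
    tost_p_ym: float
    tost_p_yo: float
    tost_p_mo: float
    unchanged: bool
    not_evaluable: bool = False


def tost_two_groups(
    a: np.ndarray,
    b: np.ndarray,
    epsilon: float,
    config: AnalysisConfig | None = None,
) -> float:
    """TOST p-value for equivalence of two group means within +/- epsilon.

    Pooled-variance two-sample t by default; Welch when
    ``config.tost_welch`` is set. Degenerate zero-variance data: p = 0 when
    |mean difference| < epsilon (equivalence certain in the limit), 0.5 on
    the boundary, 1 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return float("nan")
    welch = bool(config.tost_welch) if config is not None else False
    d = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 > 0:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = na + nb - 2
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = na + nb - 2
    if se2 == 0:
        if np.isclose(abs(d), epsilon, rtol=1e-12, atol=0):
            return 0.5
        return 0.0 if abs(d) < epsilon else 1.0
    se = np.sqrt(se2)
    p_upper = stats.t.cdf((d - epsilon) / se, df)  # H01: diff >= +eps
    p_lower = stats.t.sf((d + epsilon) / se, df)  # H02: diff <= -eps
    return float(max(p_upper, p_lower))


def classify_unchanged(
    table: FeatureTable, design: CohortDesign, config: AnalysisConfig
) -> list[StabilityResult]:
    """Per-feature pairwise TOST over the three age groups on log10 values."""
    table.check_design(design)
    log_vals = table.log10()
    groups = {g: design.donors_in_group(g) for g in ("young", "middle", "old")}
    out: list[StabilityResult] = []
    for fid in table.feature_ids:
        row = log_vals.loc[fid]
        by_group = {
            g: row.reindex(d).dropna().to_numpy(dtype=float) for g, d in groups.items()
        }
        diffs, ps = [], []
        evaluable = True
        for ga, gb in PAIRS:
            va, vb = by_group[ga], by_group[gb]
            if len(va) < 2 or len(vb) < 2:
                evaluable = False
                diffs.append(float("nan"))
                ps.append(float("nan"))
                continue
            diffs.append(abs(float(va.mean() - vb.mean())))
            ps.append(tost_two_groups(va, vb, config.equivalence_epsilon, config))
        unchanged = evaluable and all(p <= config.tost_alpha for p in ps)
        out.append(
            StabilityResult(
                feature_id=str(fid),
                mean_diff_ym=diffs[0],
                mean_diff_yo=diffs[1],
                mean_diff_mo=diffs[2],
                tost_p_ym=ps[0],
                tost_p_yo=ps[1],
                tost_p_mo=ps[2],
                unchanged=bool(unchanged),
                not_evaluable=not evaluable,
            )
        )
    return out


def results_frame(results: list[StabilityResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("feature_id")
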