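"""Two-sided hypergeometric gene-set enrichment with kappa grouping.

The two-sided exact p-value uses the minimum-likelihood convention: it is
the sum of hypergeometric point probabilities not exceeding the observed
one. Benjamini-Hochberg q-values are reported for every tested set, but the
significance filter is applied on the raw p at ``enrich_alpha`` (default
0.01). Sets with <= 5 members after background intersection are discarded
before testing, exact duplicate member sets are collapsed, and significant
terms are grouped by connected components of the Cohen-kappa >= threshold
agreement graph over the background universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .data import GeneSetCollection, normalize_gene
from .errors import ValidationError

#: relative tolerance when comparing point probabilities (minimum-likelihood
#: method); guards against floating-point noise at exact ties
_PMF_RTOL = 1e-9


def hypergeom_two_sided(k: int, K: int, n: int, N: int) -> tuple[float, str]:
    """Two-sided hypergeometric p (minimum-likelihood method) and direction.

    ``k`` of ``n`` drawn list members fall in a set of ``K`` out of ``N``
    background genes. Direction is "enriched" when k >= n*K/N (ties count
    as enriched).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"impossible counts: K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValidationError(f"impossible draw: k={k} for K={K}, n={n}, N={N}")
    rv = stats.hypergeom(N, K, n)
    support = np.arange(max(0, n + K - N), min(n, K) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(k)
    p = float(pmf[pmf <= p_obs * (1.0 + _PMF_RTOL)].sum())
    p = min(1.0, p)
    direction = "enriched" if (N > 0 and k >= n * K / N) else "depleted"
    return p, direction


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-stable."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_two_sided: float
    q_bh: float
    direction: str
    significant: bool
    kappa_group: int = -1


def enrich_collection(
    feature_list,
    background,
    sets: GeneSetCollection,
    config: AnalysisConfig,
) -> list[EnrichmentResult]:
    """Test every eligible set; filter at raw p <= enrich_alpha; kappa-group."""
    lst = {normalize_gene(g) for g in feature_list}
    bg = {normalize_gene(g) for g in background}
    if not lst <= bg:
        raise ValidationError(
            f"feature list is not a subset of the background "
            f"({len(lst - bg)} ids missing from background)"
        )
    N, n = len(bg), len(lst)
    # intersect with background, apply the size filter, collapse duplicates
    eligible: list[tuple[str, frozenset[str]]] = []
    seen_members: dict[frozenset, str] = {}
    for sid in sets.sets:
        members = frozenset(sets.sets[sid]) & frozenset(bg)
        if len(members) < config.min_set_size:
            continue
        if members in seen_members:  # redundant: exact duplicate membership
            continue
        seen_members[members] = sid
        eligible.append((sid, members))
    results: list[EnrichmentResult] = []
    for sid, members in eligible:
        K = len(members)
        k = len(members & lst)
        p, direction = hypergeom_two_sided(k, K, n, N)
        results.append(
            EnrichmentResult(
                set_id=sid,
                name=sets.names.get(sid, sid),
                k=k,
                K=K,
                n=n,
                N=N,
                p_two_sided=p,
                q_bh=float("nan"),
                direction=direction,
                significant=p <= config.enrich_alpha,
            )
        )
    if results:
        q = bh_adjust([r.p_two_sided for r in results])
        for r, qv in zip(results, q):
            r.q_bh = float(qv)
    sig = [r for r in results if r.significant]
    groups = kappa_group_terms(
        [r.set_id for r in sig],
        {sid: members for sid, members in eligible},
        bg,
        config,
    )
    for r in sig:
        r.kappa_group = groups[r.set_id]
    return results


def cohen_kappa(members_a, members_b, universe) -> float:
    """Cohen's kappa between two membership indicator vectors over a universe."""
    universe = set(universe)
    a = set(members_a) & universe
    b = set(members_b) & universe
    N = len(universe)
    if N == 0:
        return float("nan")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = N - both - only_a - only_b
    po = (both + neither) / N
    pe = ((both + only_a) * (both + only_b) + (only_b + neither) * (only_a + neither)) / N**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_group_terms(
    significant_ids,
    memberships: dict,
    background,
    config: AnalysisConfig,
) -> dict[str, int]:
    """Connected components of the kappa >= threshold agreement graph.

    Group ids are integers numbered by the lexicographically smallest
    member; singleton terms get singleton groups.
    """
    ids = sorted(significant_ids)
    parent = {sid: sid for sid in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            kap = cohen_kappa(memberships[a], memberships[b], background)
            if kap >= config.kappa_threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(sid) for sid in ids})
    root_no = {r: i for i, r in enumerate(roots)}
    return {sid: root_no[find(sid)] for sid in ids}


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("set_id")
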