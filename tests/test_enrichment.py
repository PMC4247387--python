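import math

import numpy as np
import pytest

from stromage.config import AnalysisConfig
from stromage.data import GeneSetCollection
from stromage.enrichment import (
    bh_adjust,
    cohen_kappa,
    enrich_collection,
    hypergeom_two_sided,
    kappa_group_terms,
)
from stromage.errors import ValidationError


def enumeration_oracle(k, K, n, N):
    """Two-sided minimum-likelihood p by exhaustive support enumeration."""
    def pmf(i):
        return (math.comb(K, i) * math.comb(N - K, n - i)) / math.comb(N, n)

    support = range(max(0, n + K - N), min(n, K) + 1)
    p_obs = pmf(k)
    return sum(pmf(i) for i in support if pmf(i) <= p_obs * (1 + 1e-9))


class TestHypergeom:
    def test_full_overlap_small_universe(self):
        p, direction = hypergeom_two_sided(5, 5, 5, 20)
        assert p == pytest.approx(enumeration_oracle(5, 5, 5, 20), abs=1e-12)
        assert direction == "enriched"

    def test_set_equals_universe(self):
        p, direction = hypergeom_two_sided(7, 20, 7, 20)
        assert p == pytest.approx(1.0)
        assert direction == "enriched"

    def test_central_value_p_one(self):
        # k exactly at expectation with a symmetric distribution
        p, _ = hypergeom_two_sided(5, 10, 10, 20)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_small_universes(self):
        for N in (5, 9, 12):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        p, _ = hypergeom_two_sided(k, K, n, N)
                        assert p == pytest.approx(
                            enumeration_oracle(k, K, n, N), abs=1e-10
                        ), (k, K, n, N)

    def test_role_exchange_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            N = int(rng.integers(5, 25))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k_lo, k_hi = max(0, n + K - N), min(n, K)
            k = int(rng.integers(k_lo, k_hi + 1))
            assert hypergeom_two_sided(k, K, n, N)[0] == pytest.approx(
                hypergeom_two_sided(k, n, K, N)[0], abs=1e-10
            )

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_two_sided(3, 2, 2, 10)


class TestBH:
    def test_equal_ps_unchanged(self):
        q = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_hand_stepped_fixture(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_permutation_invariance_and_statsmodels_agreement(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 40)
        q = bh_adjust(p)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p[perm]), q[perm])
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


def toy_collection():
    return GeneSetCollection.from_lists([
        ("PLANTED", "fully in list", [f"g{i}" for i in range(10)]),
        ("TINY", "five members", [f"g{i}" for i in range(5)]),
        ("RANDOM", "spread", [f"g{i}" for i in range(5, 25)]),
        ("DUP", "duplicate of planted", [f"g{i}" for i in range(10)]),
    ])


class TestEnrichCollection:
    BG = [f"g{i}" for i in range(200)]

    def test_list_equals_background_never_significant(self):
        res = enrich_collection(self.BG, self.BG, toy_collection(), AnalysisConfig())
        assert all(r.p_two_sided == pytest.approx(1.0) for r in res)
        assert not any(r.significant for r in res)

    def test_planted_set_detected(self):
        lst = [f"g{i}" for i in range(10)]
        res = enrich_collection(lst, self.BG, toy_collection(), AnalysisConfig())
        planted = next(r for r in res if r.set_id == "PLANTED")
        assert planted.significant and planted.direction == "enriched"
        assert planted.p_two_sided <= 0.01
        assert planted.k == 10 and planted.K == 10

    def test_small_set_discarded(self):
        res = enrich_collection(["g0"], self.BG, toy_collection(), AnalysisConfig())
        assert "TINY" not in {r.set_id for r in res}

    def test_duplicate_membership_collapsed(self):
        res = enrich_collection(["g0"], self.BG, toy_collection(), AnalysisConfig())
        ids = {r.set_id for r in res}
        assert not {"PLANTED", "DUP"} <= ids  # one representative only

    def test_list_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            enrich_collection(["NOT_THERE"], self.BG, toy_collection(),
                              AnalysisConfig())


class TestKappa:
    UNIVERSE = [f"g{i}" for i in range(1000)]

    def test_identical_sets_kappa_one_same_group(self):
        a = set(self.UNIVERSE[:30])
        assert cohen_kappa(a, set(a), self.UNIVERSE) == pytest.approx(1.0)
        groups = kappa_group_terms(
            ["A", "B"], {"A": a, "B": set(a)}, self.UNIVERSE, AnalysisConfig()
        )
        assert groups["A"] == groups["B"]

    def test_disjoint_sets_separate_groups(self):
        a = set(self.UNIVERSE[:30])
        b = set(self.UNIVERSE[30:60])
        assert cohen_kappa(a, b, self.UNIVERSE) <= 0
        groups = kappa_group_terms(
            ["A", "B"], {"A": a, "B": b}, self.UNIVERSE, AnalysisConfig()
        )
        assert groups["A"] != groups["B"]

    def test_crafted_contingency_matches_closed_form(self):
        # a=30 in both, b=10 only-A, c=10 only-B, d=950 neither
        a_set = set(f"x{i}" for i in range(40))          # 30 shared + 10 own
        b_set = set(f"x{i}" for i in range(30)) | set(f"y{i}" for i in range(10))
        universe = a_set | b_set | {f"z{i}" for i in range(950)}
        N = 1000
        po = (30 + 950) / N
        pe = (40 * 40 + 960 * 960) / N**2
        expect = (po - pe) / (1 - pe)
        kap = cohen_kappa(a_set, b_set, universe)
        assert kap == pytest.approx(expect, abs=1e-12)
        groups = kappa_group_terms(["A", "B"], {"A": a_set, "B": b_set},
                                   universe, AnalysisConfig())
        same = groups["A"] == groups["B"]
        assert same == (kap >= 0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = set(rng.choice(self.UNIVERSE, 50, replace=False))
        b = set(rng.choice(self.UNIVERSE, 80, replace=False))
        assert cohen_kappa(a, b, self.UNIVERSE) == pytest.approx(
            cohen_kappa(b, a, self.UNIVERSE), abs=1e-12
        )


class TestBHProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_step_up_invariants(self, p):
        """q-values stay in [0,1], dominate p/m scaling, and are monotone
        along the sorted p-values."""
        q = bh_adjust(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(np.asarray(p), kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
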