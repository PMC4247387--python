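import numpy as np
import pandas as pd
import pytest

from stromage.data import FeatureTable, Layer, TargetPrior
from stromage.network import (
    NetworkEdge,
    NetworkParams,
    annotate_anticorrelated,
    build_design,
    cv_select_lambda,
    edges_frame,
    fit_constrained_enet,
    infer_network,
    kkt_violation,
    lambda_max,
    make_lambda_grid,
    penalized_objective,
)


def qp_oracle(y, X, lam, alpha):
    """Independent solver: with b <= 0 the penalty is smooth, so the
    constrained elastic net is a box-constrained smooth problem."""
    from scipy.optimize import minimize

    X = np.atleast_2d(X)
    p = X.shape[1]

    def f(b):
        return penalized_objective(y, X, b, lam, alpha)

    res = minimize(f, np.zeros(p), method="L-BFGS-B",
                   bounds=[(None, 0.0)] * p,
                   options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 5000})
    return res.x


def random_problem(rng, p=None, n=15):
    p = p or rng.integers(1, 4)
    X = rng.normal(0, 1, (n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = -rng.uniform(0, 1, p) * rng.integers(0, 2, p)
    y = X @ beta + rng.normal(0, 0.5, n)
    return y - y.mean(), X


class TestConstrainedFit:
    def test_lambda_above_null_threshold_gives_zero(self):
        rng = np.random.default_rng(0)
        y, X = random_problem(rng, p=3)
        params = NetworkParams(mixing_alpha=1.0)
        lmax = lambda_max(y, X, 1.0)
        beta, conv = fit_constrained_enet(y, X, lmax * 1.01, params)
        assert conv and np.all(beta == 0)

    def test_positive_association_is_clamped_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (15, 1))
        X = (X - X.mean()) / X.std()
        y = 0.8 * X[:, 0] + rng.normal(0, 0.1, 15)  # positive effect
        beta, _ = fit_constrained_enet(y - y.mean(), X, 0.01, NetworkParams())
        assert beta[0] == 0.0

    def test_two_predictor_toy_matches_qp_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (15, 2))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ np.array([-0.7, -0.2]) + rng.normal(0, 0.3, 15)
        y = y - y.mean()
        params = NetworkParams(mixing_alpha=0.5)
        beta, conv = fit_constrained_enet(y, X, 0.1, params)
        assert conv
        assert np.allclose(beta, qp_oracle(y, X, 0.1, 0.5), atol=1e-6)
        assert kkt_violation(y, X, beta, 0.1, 0.5) < 1e-7

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            y, X = random_problem(rng)
            lam = rng.uniform(0.01, 0.5)
            alpha = rng.uniform(0.2, 1.0)
            beta, _ = fit_constrained_enet(y, X, lam, NetworkParams(mixing_alpha=alpha))
            assert np.all(beta <= 0)
            assert np.allclose(beta, qp_oracle(y, X, lam, alpha), atol=1e-6)
            assert kkt_violation(y, X, beta, lam, alpha) < 1e-7

    def test_objective_nonincreasing_over_sweeps(self):
        from stromage.network import _cd_gram

        rng = np.random.default_rng(4)
        y, X = random_problem(rng, p=3)
        n = len(y)
        G, q = X.T @ X / n, X.T @ y / n
        beta = np.zeros(3)
        prev = penalized_objective(y, X, beta, 0.05, 0.5)
        for _ in range(10):
            beta, _ = _cd_gram(G, q, 0.05, 0.5, beta, tol=0.0, max_sweeps=1)
            cur = penalized_objective(y, X, beta, 0.05, 0.5)
            assert cur <= prev + 1e-12
            prev = cur

    def test_unconstrained_objective_not_worse(self):
        # dropping the sign constraint can only lower the optimum
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (15, 2))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ np.array([0.5, -0.5]) + rng.normal(0, 0.2, 15)
        y -= y.mean()
        beta_c, _ = fit_constrained_enet(y, X, 0.05, NetworkParams())
        from sklearn.linear_model import ElasticNet

        en = ElasticNet(alpha=0.05, l1_ratio=0.5, fit_intercept=False,
                        max_iter=50000, tol=1e-10).fit(X, y)
        f_unc = penalized_objective(y, X, en.coef_, 0.05, 0.5)
        f_con = penalized_objective(y, X, beta_c, 0.05, 0.5)
        assert f_unc <= f_con + 1e-10

    def test_warm_vs_cold_start_along_grid(self):
        rng = np.random.default_rng(6)
        y, X = random_problem(rng, p=3)
        params = NetworkParams()
        grid = make_lambda_grid(y, X, params)
        assert grid is not None
        from stromage.network import _cd_gram

        n = len(y)
        G, q = X.T @ X / n, X.T @ y / n
        warm = np.zeros(3)
        for lam in grid[::10]:
            warm, _ = _cd_gram(G, q, lam, 0.5, warm, 1e-12, 5000)
            cold, _ = fit_constrained_enet(y, X, lam, params)
            assert np.allclose(warm, cold, atol=1e-8)


class TestCvSelection:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        y, X = random_problem(rng, p=2)
        params = NetworkParams(seed=13)
        l1, _ = cv_select_lambda(y, X, params)
        l2, _ = cv_select_lambda(y, X, params)
        assert l1 == l2

    def test_pure_noise_mostly_selects_null_model(self):
        rng = np.random.default_rng(8)
        at_null = total = 0
        for _ in range(60):
            X = rng.normal(0, 1, (15, int(rng.integers(1, 4))))
            X = (X - X.mean(0)) / X.std(0)
            y = rng.normal(0, 0.33, 15)
            y -= y.mean()
            params = NetworkParams(seed=int(rng.integers(1 << 30)))
            grid = make_lambda_grid(y, X, params)
            if grid is None:
                at_null += 1  # constraint already forces the zero model
                total += 1
                continue
            lam, _ = cv_select_lambda(y, X, params)
            beta, _ = fit_constrained_enet(y, X, lam, params)
            total += 1
            at_null += bool(np.all(beta == 0))
        assert at_null / total >= 0.9

    def test_strong_negative_signal_recovered(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            X = rng.normal(0, 1, (15, 2))
            X = (X - X.mean(0)) / X.std(0)
            y = -0.9 * X[:, 0] + rng.normal(0, 0.1, 15)
            y -= y.mean()
            params = NetworkParams(seed=int(rng.integers(1 << 30)))
            lam, _ = cv_select_lambda(y, X, params)
            beta, _ = fit_constrained_enet(y, X, lam, params)
            hits += beta[0] < 0 and beta[1] == 0
        assert hits >= 16

    def test_fold_floor_when_n_below_k(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (6, 1))
        X = (X - X.mean(0)) / X.std(0)
        y = -0.5 * X[:, 0] + rng.normal(0, 0.1, 6)
        lam, curve = cv_select_lambda(y - y.mean(), X, NetworkParams(cv_folds=10))
        assert lam is None or lam > 0  # leave-one-out floor, no crash


class TestBuildAndInfer:
    def _mirna_table(self, design_cols, rng):
        ids = ["miR-a", "miR-b", "miR-c"]
        vals = 2.0 ** rng.normal(8, 1, (3, len(design_cols)))
        return FeatureTable(
            Layer.mirna,
            pd.DataFrame(vals, index=ids, columns=design_cols),
            pd.DataFrame(index=pd.Index(ids)),
        )

    def test_empty_prior_empty_design(self, design15):
        rng = np.random.default_rng(11)
        mir = self._mirna_table(list(design15.donor_id), rng)
        X, kept, dropped = build_design(
            "GZ", TargetPrior.from_pairs([]), mir.log2(), ["miR-a"],
            list(design15.donor_id),
        )
        assert X.shape[1] == 0 and kept == []

    def test_single_prior_edge_single_column(self, design15):
        rng = np.random.default_rng(12)
        mir = self._mirna_table(list(design15.donor_id), rng)
        prior = TargetPrior.from_pairs([("miR-a", "DNAJC3")])
        X, kept, _ = build_design("DNAJC3", prior, mir.log2(),
                                  ["miR-a", "miR-b"], list(design15.donor_id))
        assert kept == ["miR-a"]
        assert X.shape == (15, 1)
        assert abs(X.mean()) < 1e-12 and X.std() == pytest.approx(1.0)

    def test_constant_mirna_column_dropped(self, design15):
        ids = ["miR-flat"]
        vals = np.full((1, 15), 256.0)
        mir = FeatureTable(Layer.mirna,
                           pd.DataFrame(vals, index=ids, columns=list(design15.donor_id)),
                           pd.DataFrame(index=pd.Index(ids)))
        prior = TargetPrior.from_pairs([("miR-flat", "GZ")])
        X, kept, dropped = build_design("GZ", prior, mir.log2(), ids,
                                        list(design15.donor_id))
        assert kept == [] and dropped == ["miR-flat"]

    def test_network_recovery_on_planted_dataset(self, default_dataset):
        from stromage.config import AnalysisConfig
        from stromage.correlation import preprocess_mrna

        params, (design, protein, probes, mirna, prior, _, truth) = default_dataset
        mrna_gene = preprocess_mrna(probes, AnalysisConfig())
        cands = sorted(truth.age_mirnas)
        edges = infer_network(mrna_gene, mirna, prior, cands, NetworkParams(seed=42))
        assert edges, "no edges inferred"
        for e in edges:
            assert e.coefficient < 0
            assert (e.mirna_id, e.gene_id) in prior.edges
        emitted = {(e.mirna_id, e.gene_id) for e in edges}
        planted = truth.planted_repressive_edges
        precision = len(emitted & planted) / len(emitted)
        recall = len(emitted & planted) / len(planted)
        assert precision >= 0.7
        assert recall >= 0.5


class TestAnnotate:
    def _edge(self):
        return NetworkEdge("miR-x", "P1", "G1", -0.5, 0.1, "protein")

    class _Res:
        def __init__(self, fid, direction, called):
            self.feature_id = fid
            self.direction = direction
            self.age_associated = called

    def test_opposite_directions_flagged(self):
        e = self._edge()
        annotate_anticorrelated([e], {"miR-x": "up"}, [self._Res("P1", "down", True)])
        assert e.anticorrelated

    def test_same_direction_not_flagged(self):
        e = self._edge()
        annotate_anticorrelated([e], {"miR-x": "up"}, [self._Res("P1", "up", True)])
        assert not e.anticorrelated

    def test_non_age_associated_target_not_flagged(self):
        e = self._edge()
        annotate_anticorrelated([e], {"miR-x": "up"}, [self._Res("P1", "down", False)])
        assert not e.anticorrelated

    def test_graphml_export(self, tmp_path):
        import networkx as nx

        e = self._edge()
        from stromage.network import to_graphml

        to_graphml([e], tmp_path / "g.graphml")
        g = nx.read_graphml(tmp_path / "g.graphml")
        assert g.has_edge("miR-x", "P1")
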