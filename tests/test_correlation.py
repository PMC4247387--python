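import numpy as np
import pandas as pd
import pytest

from stromage.config import AnalysisConfig
from stromage.correlation import (
    correlate_per_sample,
    coverage_overlap,
    match_pairs,
    percent_of_max,
    preprocess_mrna,
    preprocess_protein,
)
from stromage.data import FeatureTable, Layer
from stromage.errors import ValidationError

from conftest import make_protein_table


def make_probe_table(values, design, gene_ids):
    values = np.asarray(values, dtype=float)
    ids = [f"PR{i:03d}" for i in range(1, values.shape[0] + 1)]
    return FeatureTable(
        layer=Layer.mrna_probe,
        values=pd.DataFrame(values, index=ids, columns=list(design.donor_id)),
        meta=pd.DataFrame({"gene_id": gene_ids}, index=ids),
    )


class TestPreprocessMrna:
    def test_multi_probe_gene_averaged(self, design15):
        # two probes of one gene at log2 = 2 and 4 -> gene log2 mean = 3;
        # low filter disabled to isolate the averaging step
        cfg = AnalysisConfig(mrna_low_median_quantile=0.0)
        vals = np.vstack([np.full(15, 2.0**2), np.full(15, 2.0**4)])
        probes = make_probe_table(vals, design15, ["GA", "GA"])
        gene = preprocess_mrna(probes, cfg)
        # before rescaling the mean is 3; rescaling maps the max (3) to 100
        assert gene.values.loc["GA"].iloc[0] == pytest.approx(100.0)
        raw_mean = (2.0 + 4.0) / 2
        assert raw_mean == 3.0

    def test_quantile_filter_drops_exactly_two_of_eight(self, design15):
        cfg = AnalysisConfig(mrna_low_median_quantile=0.25)
        vals = np.vstack([np.full(15, 2.0**k) for k in range(1, 9)])
        probes = make_probe_table(vals, design15, [f"G{i}" for i in range(8)])
        gene = preprocess_mrna(probes, cfg)
        assert gene.n_features() == 6
        assert {"G0", "G1"} & set(gene.values.index) == set()

    def test_hand_stepped_oracle(self, design15):
        # 10 probes: 2 below the low-median cut, 1 unmapped, two genes with
        # two probes each; worked through step by step
        cfg = AnalysisConfig(mrna_low_median_quantile=0.25)
        log2_levels = [1.0, 1.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        genes = ["GL1", "GL2", "GA", "GA", "GB", "GB", None, "GC", "GD", "GE"]
        vals = np.vstack([np.full(15, 2.0**v) for v in log2_levels])
        probes = make_probe_table(vals, design15, genes)
        gene = preprocess_mrna(probes, cfg)
        # drop 2 lowest medians (log2 1.0, 1.5) and the unmapped probe (7.0)
        # remaining: GA=(3+4)/2=3.5, GB=(5+6)/2=5.5, GC=8, GD=9, GE=10
        # rescale: max 10 -> 100
        expect = {"GA": 35.0, "GB": 55.0, "GC": 80.0, "GD": 90.0, "GE": 100.0}
        assert set(gene.values.index) == set(expect)
        for g, v in expect.items():
            assert gene.values.loc[g].iloc[0] == pytest.approx(v, abs=1e-9)

    def test_filter_before_average_is_pinned(self, design15):
        # a gene with one high and one very low probe: filter-then-average
        # keeps the high probe's value; average-then-filter would retain a
        # diluted mean instead
        cfg = AnalysisConfig(mrna_low_median_quantile=0.25)
        vals = np.vstack(
            [np.full(15, 2.0**10), np.full(15, 2.0**1)]  # gene GX: probes hi+lo
            + [np.full(15, 2.0**k) for k in (2, 5, 6, 7, 8, 9)]
        )
        genes = ["GX", "GX", "GY", "G5", "G6", "G7", "G8", "G9"]
        probes = make_probe_table(vals, design15, genes)
        gene = preprocess_mrna(probes, cfg)
        # the two lowest probes (log2 1 and 2) are dropped -> GX keeps only
        # its high probe (log2 10 -> 100 after rescale), GY disappears
        assert gene.values.loc["GX"].iloc[0] == pytest.approx(100.0, abs=1e-9)
        assert "GY" not in gene.values.index
        averaged_first = (10 + 1) / 2  # would have produced 5.5, not 10
        assert averaged_first != 10


class TestPreprocessProtein:
    def test_peptide_normalization(self, design15):
        table = make_protein_table(np.full((1, 15), 8.0), design15, peptides=[2])
        out = preprocess_protein(table, AnalysisConfig())
        # 8/2 = 4 -> log2 = 2 -> single protein max -> 100
        assert out.values.iloc[0, 0] == pytest.approx(100.0)

    def test_single_protein_max_is_100(self, design15):
        rng = np.random.default_rng(0)
        table = make_protein_table(rng.uniform(10, 1000, (1, 15)), design15)
        out = preprocess_protein(table, AnalysisConfig())
        assert np.nanmax(out.values.to_numpy()) == pytest.approx(100.0)

    def test_zero_peptide_count_rejected(self, design15):
        table = make_protein_table(np.full((1, 15), 8.0), design15, peptides=[0])
        with pytest.raises(ValidationError):
            preprocess_protein(table, AnalysisConfig())

    def test_hand_stepped_oracle(self, design15):
        sums = np.array([16.0, 64.0, 256.0, 1024.0, 4096.0])
        peps = [2, 4, 2, 8, 4]
        table = make_protein_table(
            np.tile(sums[:, None], (1, 15)), design15, peptides=peps
        )
        out = preprocess_protein(table, AnalysisConfig())
        # per-pep: 8, 16, 128, 128, 1024 -> log2: 3, 4, 7, 7, 10 -> %max
        expect = np.array([30.0, 40.0, 70.0, 70.0, 100.0])
        got = out.values.iloc[:, 0].to_numpy()
        assert np.allclose(np.sort(got), np.sort(expect), atol=1e-9)


class TestCorrelate:
    def _pairs(self, design15, mrna, protein):
        m = FeatureTable(Layer.mrna_gene,
                         pd.DataFrame(mrna, columns=list(design15.donor_id)),
                         pd.DataFrame(index=pd.RangeIndex(len(mrna))))
        p = FeatureTable(Layer.mrna_gene,
                         pd.DataFrame(protein, columns=list(design15.donor_id)),
                         pd.DataFrame(index=pd.RangeIndex(len(protein))))
        return match_pairs(p, m)

    def test_identical_layers_give_unit_correlation(self, design15):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 100, (20, 15))
        per_donor, mean_r = correlate_per_sample(self._pairs(design15, x, x.copy()))
        assert np.allclose(per_donor, 1.0)
        assert mean_r == pytest.approx(1.0)

    def test_sign_flip_gives_anticorrelation(self, design15):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 100, (20, 15))
        per_donor, mean_r = correlate_per_sample(self._pairs(design15, x, 200.0 - x))
        assert np.allclose(per_donor, -1.0)

    def test_affine_invariance_per_layer(self, design15):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 100, (30, 15))
        y = rng.uniform(1, 100, (30, 15))
        r0, _ = correlate_per_sample(self._pairs(design15, x, y))
        r1, _ = correlate_per_sample(self._pairs(design15, 0.5 * x + 7, y))
        assert np.allclose(r0, r1, atol=1e-12)

    def test_zero_variance_donor_excluded(self, design15):
        x = np.tile(np.arange(1.0, 6.0)[:, None], (1, 15))
        y = x.copy()
        x[:, 0] = 42.0  # first donor flat on the mRNA axis
        per_donor, mean_r = correlate_per_sample(self._pairs(design15, x, y))
        assert np.isnan(per_donor.iloc[0])
        assert mean_r == pytest.approx(1.0)


class TestRescaleAndCoverage:
    def test_percent_of_max_idempotent(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(rng.uniform(0, 57, (10, 5)))
        once = percent_of_max(frame)
        twice = percent_of_max(once)
        pd.testing.assert_frame_equal(once, twice)

    @pytest.mark.parametrize(
        "n_protein,n_shared,expect",
        [(50, 50, 1.0), (50, 0, 0.0), (50, 49, 0.98)],
    )
    def test_coverage_fractions(self, design15, n_protein, n_shared, expect):
        prot_genes = [f"G{i}" for i in range(n_protein)]
        mrna_genes = [f"G{i}" for i in range(n_shared)] + [
            f"X{i}" for i in range(n_protein - n_shared)
        ]
        mk = lambda idx: FeatureTable(
            Layer.mrna_gene,
            pd.DataFrame(np.ones((len(idx), 15)), index=idx,
                         columns=list(design15.donor_id)),
            pd.DataFrame(index=pd.Index(idx)),
        )
        cov = coverage_overlap(mk(prot_genes), mk(mrna_genes))
        assert cov["fraction_proteins_with_mrna"] == pytest.approx(expect)
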