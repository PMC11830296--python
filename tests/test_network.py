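"""Co-expression network variants, rank normalization and integration."""

import numpy as np
import pytest

import covote.network as nw
from covote.expression import SC_LOG, ExpressionMatrix, ValidationError


def sc_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = [f"C{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells, SC_LOG)


class TestVariantSpec:
    def test_ten_standard_variants(self):
        names = {s.name for s in nw.STANDARD_VARIANTS}
        assert names == {
            "MI", "MI_dp", "pearson", "pearson_dp", "pearson_abs",
            "pearson_dp_abs", "spearman", "spearman_dp", "spearman_abs",
            "spearman_dp_abs",
        }

    def test_mi_absolute_rejected(self):
        with pytest.raises(ValidationError):
            nw.NetworkVariantSpec(metric="mi", absolute=True)

    def test_integration_groups(self):
        sizes = {k: len(v) for k, v in nw.INTEGRATION_GROUPS.items()}
        assert sizes == {"integrated_MI": 2, "integrated_pearson": 4,
                         "integrated_spearman": 4, "integrated_all": 10}


class TestPairwiseAssociation:
    def test_duplicated_gene_perfect_correlation(self, rng):
        x = rng.uniform(0.1, 5, size=12)
        m = sc_matrix(np.vstack([x, x, rng.uniform(0.1, 5, size=12)]))
        raw = nw.pairwise_association(m, nw.NetworkVariantSpec("pearson"))
        assert raw[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = sc_matrix(np.vstack([x, 5.0 - x]))
        raw = nw.pairwise_association(m, nw.NetworkVariantSpec("pearson"))
        assert raw[0, 1] == pytest.approx(-1.0)

    def test_min_overlap_gives_nan(self):
        # both genes detected together in only 3 of 12 cells
        x = np.zeros((2, 12))
        x[0, :3] = [1.0, 2.0, 3.0]
        x[1, :3] = [2.0, 1.0, 3.0]
        x[0, 3:8] = 1.0
        x[1, 8:] = 1.0
        m = sc_matrix(x)
        raw = nw.pairwise_association(
            m, nw.NetworkVariantSpec("pearson", drop_zeros=True), min_overlap=10
        )
        assert np.isnan(raw[0, 1])

    def test_pearson_matches_two_pass_oracle(self, rng):
        """Vectorized Pearson equals the textbook two-pass formula."""
        spec = nw.NetworkVariantSpec("pearson")
        for _ in range(20):
            m = sc_matrix(rng.uniform(0, 6, size=(8, 30)))
            raw = nw.pairwise_association(m, spec)
            for i in range(8):
                for j in range(i + 1, 8):
                    x, y = m.values[i], m.values[j]
                    xc, yc = x - x.mean(), y - y.mean()
                    r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
                    assert raw[i, j] == pytest.approx(r, abs=1e-12)

    def test_pearson_dp_matches_masked_oracle(self, rng):
        """Closed-form dropout Pearson equals per-pair masked recomputation."""
        spec = nw.NetworkVariantSpec("pearson", drop_zeros=True)
        vals = rng.uniform(0, 6, size=(6, 40)) * (rng.random((6, 40)) > 0.3)
        m = sc_matrix(vals)
        raw = nw.pairwise_association(m, spec, min_overlap=5)
        for i in range(6):
            for j in range(i + 1, 6):
                sel = (vals[i] > 0) & (vals[j] > 0)
                if sel.sum() < 5:
                    assert np.isnan(raw[i, j])
                    continue
                x, y = vals[i, sel], vals[j, sel]
                xc, yc = x - x.mean(), y - y.mean()
                r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
                assert raw[i, j] == pytest.approx(r, abs=1e-10)

    def test_mi_matches_contingency_oracle(self, rng):
        """Vectorized all-pairs MI equals a per-pair contingency computation."""
        from covote.network import _mi_from_bins, _mi_matrix, _quantile_bins
        import math

        vals = rng.uniform(0, 5, size=(5, 36))
        out = _mi_matrix(vals)
        n_bins = max(2, math.ceil(math.sqrt(36)))
        bins = [_quantile_bins(vals[i], n_bins) for i in range(5)]
        for i in range(5):
            for j in range(i + 1, 5):
                expected = _mi_from_bins(bins[i], bins[j], n_bins)
                assert out[i, j] == pytest.approx(expected, abs=1e-12)

    def test_mi_positive_for_dependent_pair(self, rng):
        x = rng.normal(size=100)
        m = sc_matrix(np.vstack([x, x + rng.normal(0, 0.1, 100), rng.normal(size=100)]) + 10)
        raw = nw.pairwise_association(m, nw.NetworkVariantSpec("mi"))
        assert raw[0, 1] > raw[0, 2]
        assert raw[0, 1] > 0

    def test_too_few_genes_errors(self):
        with pytest.raises(ValidationError):
            nw.pairwise_association(sc_matrix([[1.0, 2.0]]),
                                    nw.NetworkVariantSpec("pearson"))


class TestRankNormalize:
    def triangle(self, a, b, c):
        raw = np.full((3, 3), np.nan)
        raw[0, 1] = raw[1, 0] = a
        raw[0, 2] = raw[2, 0] = b
        raw[1, 2] = raw[2, 1] = c
        return raw

    def test_forced_weights(self):
        net = nw.rank_normalize(self.triangle(0.9, 0.5, 0.1))
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.weights[0, 2] == pytest.approx(2 / 3)
        assert net.weights[1, 2] == pytest.approx(1 / 3)

    def test_absolute_ranking(self):
        net = nw.rank_normalize(self.triangle(-0.9, 0.5, 0.1), absolute=True)
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_all_ties_average_rank(self):
        net = nw.rank_normalize(self.triangle(0.4, 0.4, 0.4))
        off = net.weights[np.triu_indices(3, 1)]
        assert np.allclose(off, 2 / 3)

    def test_weight_multiset_without_ties(self, rng):
        g = 7
        raw = np.zeros((g, g))
        iu = np.triu_indices(g, 1)
        vals = rng.permutation(len(iu[0])) + rng.uniform(0, 0.1, len(iu[0]))
        raw[iu] = vals
        raw = raw + raw.T
        net = nw.rank_normalize(raw)
        e = len(iu[0])
        expected = np.arange(1, e + 1) / e
        assert np.allclose(np.sort(net.weights[iu]), expected)

    def test_nan_neutral_weight(self):
        net = nw.rank_normalize(self.triangle(0.9, np.nan, 0.1))
        assert net.weights[0, 2] == pytest.approx(0.5)
        assert net.weights[0, 1] == pytest.approx(1.0)  # max weight still 1

    def test_all_nan_errors(self):
        with pytest.raises(ValidationError):
            nw.rank_normalize(np.full((3, 3), np.nan))


class TestDegreeAndBuild:
    def test_degree_arithmetic(self):
        raw = np.zeros((3, 3))
        net = nw.rank_normalize(self.__class__._triangle())
        deg = nw.node_degree(net)
        assert np.allclose(deg, [5 / 3, 4 / 3, 1.0])

    @staticmethod
    def _triangle():
        raw = np.full((3, 3), np.nan)
        raw[0, 1] = raw[1, 0] = 0.9  # -> weight 1
        raw[0, 2] = raw[2, 0] = 0.5  # -> 2/3
        raw[1, 2] = raw[2, 1] = 0.1  # -> 1/3
        return raw

    def test_degree_sum_equals_twice_weight(self, rng):
        raw = rng.uniform(-1, 1, size=(5, 5))
        raw = (raw + raw.T) / 2
        net = nw.rank_normalize(raw)
        iu = np.triu_indices(5, 1)
        assert nw.node_degree(net).sum() == pytest.approx(2 * net.weights[iu].sum())

    def test_spearman_monotone_invariance(self, rng):
        vals = rng.uniform(0.1, 5, size=(6, 25))
        m1 = sc_matrix(vals)
        m2 = sc_matrix(np.exp(vals) / 50.0)  # strictly monotone per-gene map
        spec = nw.NetworkVariantSpec("spearman")
        n1 = nw.build_network(m1, spec)
        n2 = nw.build_network(m2, spec)
        assert np.allclose(n1.weights, n2.weights)

    def test_pearson_affine_invariance(self, rng):
        vals = rng.uniform(0.1, 5, size=(6, 25))
        spec = nw.NetworkVariantSpec("pearson")
        n1 = nw.build_network(sc_matrix(vals), spec)
        n2 = nw.build_network(sc_matrix(2.5 * vals + 1.0), spec)
        assert np.allclose(n1.weights, n2.weights)

    def test_gene_permutation_equivariance(self, rng):
        vals = rng.uniform(0.1, 5, size=(6, 25))
        m = sc_matrix(vals)
        perm = rng.permutation(6)
        mp = m.subset_genes([m.gene_ids[i] for i in perm])
        spec = nw.NetworkVariantSpec("spearman")
        n1 = nw.build_network(m, spec)
        n2 = nw.build_network(mp, spec)
        assert np.allclose(n1.weights[np.ix_(perm, perm)], n2.weights)

    def test_drop_zeros_noop_without_zeros(self, rng):
        vals = rng.uniform(0.5, 5, size=(5, 30))
        n1 = nw.build_network(sc_matrix(vals), nw.NetworkVariantSpec("pearson"))
        n2 = nw.build_network(sc_matrix(vals),
                              nw.NetworkVariantSpec("pearson", drop_zeros=True))
        assert np.allclose(n1.weights, n2.weights)

    def test_spearman_dp_subset_ranks(self):
        # monotone on the co-detected subset even though not globally
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([9.0, 2.0, 3.0, 4.0, 5.0, 0.0])  # co-detected: cells 1..4
        m = sc_matrix(np.vstack([x, y, x + 0.5]))
        raw = nw.pairwise_association(
            m, nw.NetworkVariantSpec("spearman", drop_zeros=True), min_overlap=4
        )
        assert raw[0, 1] == pytest.approx(1.0)


class TestIntegration:
    def _random_net(self, rng, g=5, variant="pearson"):
        raw = rng.uniform(-1, 1, size=(g, g))
        raw = (raw + raw.T) / 2
        return nw.rank_normalize(raw, variant=variant)

    def test_identity_on_identical_members(self, rng):
        net = self._random_net(rng)
        merged = nw.integrate_networks([net, net])
        assert np.allclose(merged.weights, net.weights)

    def test_reversed_orders_tie(self):
        # two 3-gene nets with equally spaced, opposite edge orders:
        # averaged weights all tie -> every edge gets the average rank weight
        raw_a = np.full((3, 3), np.nan)
        raw_a[0, 1] = raw_a[1, 0] = 3.0
        raw_a[0, 2] = raw_a[2, 0] = 2.0
        raw_a[1, 2] = raw_a[2, 1] = 1.0
        raw_b = np.full((3, 3), np.nan)
        raw_b[0, 1] = raw_b[1, 0] = 1.0
        raw_b[0, 2] = raw_b[2, 0] = 2.0
        raw_b[1, 2] = raw_b[2, 1] = 3.0
        merged = nw.integrate_networks(
            [nw.rank_normalize(raw_a), nw.rank_normalize(raw_b)]
        )
        off = merged.weights[np.triu_indices(3, 1)]
        assert np.allclose(off, 2 / 3)

    def test_integrated_all_requires_ten_variants(self, rng):
        nets = [self._random_net(rng, variant=v) for v in ("pearson", "spearman")]
        with pytest.raises(ValidationError, match="integrated_all"):
            nw.integrate_networks(nets, variant="integrated_all")

    def test_mismatched_genes_error(self, rng):
        a = self._random_net(rng)
        b = self._random_net(rng)
        b.gene_ids = [f"X{i}" for i in range(5)]
        with pytest.raises(ValidationError):
            nw.integrate_networks([a, b])

    def test_full_group_integration(self, rng):
        vals = rng.uniform(0, 4, size=(8, 40)) * (rng.random((8, 40)) > 0.3)
        m = sc_matrix(vals)
        nets = nw.build_all_variants(m, min_overlap=5)
        merged = nw.integrate_networks(list(nets.values()), variant="integrated_all")
        assert merged.variant == "integrated_all"
        iu = np.triu_indices(8, 1)
        assert merged.weights[iu].max() == pytest.approx(1.0)
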