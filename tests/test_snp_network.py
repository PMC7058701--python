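import numpy as np
import pytest

from episnp.epistasis_scan import STATUS_COLLINEAR, STATUS_OK
from episnp.snp_network import (
    GREY,
    MODULE_COLORS,
    AdjacencyMatrix,
    cluster_and_cut,
    compute_eigen_snps,
    dendrogram_newick,
    eigen_snp,
    merge_close_modules,
    pick_power,
    scale_free_fit_r2,
    signed_adjacency,
    soft_connectivity,
    tom_similarity,
)
from conftest import make_gm


def symmetric_noise(rng, n, sd=0.05):
    b = rng.normal(0, sd, (n, n))
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    return b


def planted_two_modules(rng, n, m, within=(0.8, 0.1), bg=(0.0, 0.05)):
    b = rng.normal(*bg, (n, n))
    b[:m, :m] = rng.normal(*within, (m, m))
    b[m : 2 * m, m : 2 * m] = rng.normal(*within, (m, m))
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    return b


class TestSignedAdjacency:
    def test_endpoints(self):
        b = np.array([[0, 1.0, -1.0], [1.0, 0, 0.0], [-1.0, 0.0, 0]])
        adj = signed_adjacency(b, power_beta=1)
        assert adj.values[0, 1] == pytest.approx(1.0)
        assert adj.values[0, 2] == pytest.approx(0.0)
        assert adj.values[1, 2] == pytest.approx(0.5)

    def test_zero_signal_closed_form(self):
        b = np.array([[0, 1.0, 0.0], [1.0, 0, 0.0], [0.0, 0.0, 0]])
        adj = signed_adjacency(b, power_beta=12)
        assert adj.values[1, 2] == pytest.approx(0.5**12, abs=1e-15)
        assert adj.values[1, 2] == pytest.approx(2.44140625e-4)

    def test_monotone_in_similarity(self, rng):
        b = symmetric_noise(rng, 15, sd=0.5)
        adj = signed_adjacency(b, power_beta=6)
        iu = np.triu_indices(15, k=1)
        order_b = np.argsort(b[iu])
        a_sorted = adj.values[iu][order_b]
        assert np.all(np.diff(a_sorted) >= -1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no interaction signal"):
            signed_adjacency(np.zeros((4, 4)), 6)

    def test_failed_cells_neutral(self, rng):
        b = symmetric_noise(rng, 6, sd=0.5)
        status = np.full((6, 6), STATUS_OK, dtype=np.int8)
        status[0, 1] = status[1, 0] = STATUS_COLLINEAR
        adj = signed_adjacency(b, power_beta=3, status_matrix=status)
        assert adj.values[0, 1] == pytest.approx(0.5**3)

    def test_clip_quantile_normalization(self, rng):
        b = symmetric_noise(rng, 30, sd=1.0)
        adj = signed_adjacency(b, 6, clip_quantile=0.9)
        off = ~np.eye(30, dtype=bool)
        assert adj.normalization_constant == pytest.approx(
            np.quantile(np.abs(b[off]), 0.9), rel=1e-6
        )
        assert adj.values.max() <= 1.0


class TestTOM:
    def test_two_node_closed_form(self):
        for x in (0.2, 0.5, 0.9):
            a = np.array([[0, x], [x, 0]])
            tom = tom_similarity(AdjacencyMatrix(a.copy(), 1, 1.0))
            # no shared neighbors: TOM12 = x / (x + 1 - x) = x
            assert tom[0, 1] == pytest.approx(x, abs=1e-12)

    def test_complete_graph_saturation(self):
        a = np.ones((5, 5)) - np.eye(5)
        tom = tom_similarity(AdjacencyMatrix(a, 1, 1.0))
        assert np.allclose(tom, 1.0)

    def test_bounds_on_random_adjacencies(self, rng):
        for _ in range(20):
            n = rng.integers(3, 25)
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            tom = tom_similarity(AdjacencyMatrix(a, 1, 1.0))
            assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12
            assert np.allclose(tom, tom.T)


class TestClusterAndCut:
    def test_two_planted_blocks_perfect(self, rng):
        b = planted_two_modules(rng, 100, 50)
        part = cluster_and_cut(
            1 - tom_similarity(signed_adjacency(b, 6)), min_module_size=30
        )
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 50 + [1] * 50
        assert adjusted_rand_score(truth, part.labels) == 1.0
        assert set(part.modules()) == {"turquoise", "blue"}

    def test_noise_mostly_grey(self, rng):
        b = symmetric_noise(rng, 200)
        part = cluster_and_cut(
            1 - tom_similarity(signed_adjacency(b, 6)), min_module_size=30
        )
        assert np.mean([lab == GREY for lab in part.labels]) >= 0.9

    def test_identical_profiles_single_module(self):
        b = np.full((40, 40), 0.7)
        np.fill_diagonal(b, 0)
        part = cluster_and_cut(
            1 - tom_similarity(signed_adjacency(b, 6)), min_module_size=10
        )
        assert part.labels == [MODULE_COLORS[0]] * 40

    def test_fewer_snps_than_min_size(self, rng):
        b = symmetric_noise(rng, 5)
        with pytest.warns(UserWarning):
            part = cluster_and_cut(np.abs(b), min_module_size=30)
        assert part.labels == [GREY] * 5

    def test_determinism(self, rng):
        b = planted_two_modules(rng, 80, 30)
        d = 1 - tom_similarity(signed_adjacency(b, 6))
        p1 = cluster_and_cut(d, min_module_size=10)
        p2 = cluster_and_cut(d.copy(), min_module_size=10)
        assert p1.labels == p2.labels

    def test_planted_recovery_over_replicates(self):
        # ARI >= 0.8 over 20 replicates (module SNPs only are labeled)
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            b = planted_two_modules(rng, 120, 40)
            part = cluster_and_cut(
                1 - tom_similarity(signed_adjacency(b, 6)), min_module_size=20
            )
            truth = [1] * 40 + [2] * 40 + [0] * 40
            aris.append(adjusted_rand_score(truth, part.labels))
        assert np.mean(aris) >= 0.8


class TestPickPower:
    def test_fallback_on_noise(self, rng):
        b = symmetric_noise(rng, 40, sd=1.0)
        with pytest.warns(UserWarning, match="falling back"):
            assert pick_power(b, candidate_powers=(2,), target_r2=0.999) == 12

    def test_scale_free_network_fits(self, rng):
        # hub-structured interaction matrix approximating a power-law degree
        n = 300
        weights = (np.arange(1, n + 1) ** -0.7)[rng.permutation(n)]
        b = np.outer(weights, weights)
        b = b / b.max()
        np.fill_diagonal(b, 0)
        power = pick_power(b, target_r2=0.8)
        adj = signed_adjacency(b, power)
        assert scale_free_fit_r2(adj.values.sum(axis=1)) >= 0.8

    def test_monotone_in_target(self, rng):
        n = 300
        weights = (np.arange(1, n + 1) ** -0.7)[rng.permutation(n)]
        b = np.outer(weights, weights) / weights.max() ** 2
        np.fill_diagonal(b, 0)
        chosen = []
        import warnings

        for target in (0.5, 0.7, 0.9):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chosen.append(pick_power(b, target_r2=target))
        assert chosen == sorted(chosen)


class TestEigenSNP:
    def test_rank_one_module(self, rng):
        col = rng.integers(0, 3, size=30).astype(np.int8)
        values = np.column_stack([col] * 5)
        vec, ve = eigen_snp(values)
        assert ve == pytest.approx(1.0)
        z = (col - col.mean()) / col.std(ddof=1)
        r = np.corrcoef(vec, z)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # sign anchored to mean genotype

    def test_matches_power_iteration(self, rng):
        values = rng.integers(0, 3, size=(40, 8)).astype(np.int8)
        vec, ve = eigen_snp(values)
        # independent oracle: power iteration on the sample covariance of z
        x = values.astype(float)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        c = z @ z.T
        v = np.ones(40)
        for _ in range(5000):
            v = c @ v
            v /= np.linalg.norm(v)
        v *= np.sign(v @ z.mean(axis=1))
        v = (v - v.mean()) / v.std(ddof=1)
        assert np.allclose(np.abs(vec), np.abs(v), atol=1e-6)
        assert 0 <= ve <= 1

    def test_coding_flip_invariance(self, rng):
        values = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        y = rng.normal(size=30)
        vec_a, _ = eigen_snp(values)
        vec_b, _ = eigen_snp(2 - values)
        assert abs(np.corrcoef(vec_a, y)[0, 1]) == pytest.approx(
            abs(np.corrcoef(vec_b, y)[0, 1]), abs=1e-10
        )

    def test_zero_variance_column_dropped(self, rng):
        values = rng.integers(0, 3, size=(20, 3)).astype(np.int8)
        values[:, 1] = 1
        with pytest.warns(UserWarning, match="zero-variance"):
            vec, _ = eigen_snp(values)
        assert vec.shape == (20,)

    def test_standardized(self, rng):
        values = rng.integers(0, 3, size=(25, 6)).astype(np.int8)
        vec, _ = eigen_snp(values)
        assert vec.mean() == pytest.approx(0.0, abs=1e-10)
        assert vec.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestMergeCloseModules:
    def _gm_with_modules(self, rng, duplicate=False):
        base1 = rng.integers(0, 3, size=40).astype(np.int8)
        base2 = (
            base1 if duplicate else rng.integers(0, 3, size=40).astype(np.int8)
        )
        noise = lambda b: np.clip(
            b + rng.integers(-1, 2, size=(40, 10)).astype(np.int8).T * 0, 0, 2
        )
        cols = [base1] * 6 + [base2] * 6
        gm = make_gm(np.column_stack(cols))
        assignment = {}
        for j, s in enumerate(gm.snp_ids):
            assignment[s] = "turquoise" if j < 6 else "blue"
        from episnp.snp_network import ModulePartition

        part = ModulePartition(gm.snp_ids, assignment, None, 3)
        return gm, part

    def test_identical_eigensnps_merged(self, rng):
        gm, part = self._gm_with_modules(rng, duplicate=True)
        merged, eigen = merge_close_modules(part, gm, cut_height=0.25)
        assert len(merged.modules()) == 1

    def test_unrelated_not_merged(self, rng):
        gm, part = self._gm_with_modules(rng, duplicate=False)
        merged, _ = merge_close_modules(part, gm, cut_height=0.25)
        assert len(merged.modules()) == 2

    def test_merge_monotone_in_height(self, rng):
        counts = []
        for height in (0.05, 0.25, 0.9):
            gm, part = self._gm_with_modules(rng, duplicate=False)
            merged, _ = merge_close_modules(part, gm, cut_height=height)
            counts.append(len(merged.modules()))
        assert counts == sorted(counts, reverse=True)


class TestSoftConnectivity:
    def test_star_graph(self):
        m = 6
        a = np.zeros((m + 1, m + 1))
        a[0, 1:] = a[1:, 0] = 1.0
        tbl = soft_connectivity(AdjacencyMatrix(a, 1, 1.0))
        k = dict(zip(tbl["snp_id"], tbl["connectivity"]))
        assert k["snp0"] == pytest.approx(m)
        assert all(k[f"snp{i}"] == pytest.approx(1.0) for i in range(1, m + 1))

    def test_all_zero(self):
        tbl = soft_connectivity(AdjacencyMatrix(np.zeros((4, 4)), 1, 1.0))
        assert (tbl["connectivity"] == 0).all()

    def test_handshake_identity(self, rng):
        for _ in range(10):
            n = rng.integers(3, 20)
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            tbl = soft_connectivity(AdjacencyMatrix(a.copy(), 1, 1.0))
            iu = np.triu_indices(n, k=1)
            assert tbl["connectivity"].sum() == pytest.approx(2 * a[iu].sum())


def test_dendrogram_newick(rng):
    b = planted_two_modules(rng, 30, 10)
    part = cluster_and_cut(
        1 - tom_similarity(signed_adjacency(b, 6)), min_module_size=5
    )
    nwk = dendrogram_newick(part)
    assert nwk.endswith(";")
    assert nwk.count("snp") == 30
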