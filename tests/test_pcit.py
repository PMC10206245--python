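import numpy as np
import pandas as pd
import pytest

from mircornet.containers import NormalizedMatrix
from mircornet.pcit import (
    build_group_network,
    correlation_matrix,
    partial_correlation,
    pcit,
)

from conftest import make_count_matrix


def random_corr(rng, n):
    """A valid correlation matrix from random sample vectors."""
    x = rng.normal(size=(n, n + 5))
    c = np.corrcoef(x)
    np.fill_diagonal(c, 1.0)
    return c


def pcit_bruteforce(corr):
    """Plain-Python trio loop; the contract for the vectorized version."""
    n = corr.shape[0]
    eliminated = np.zeros((n, n), dtype=bool)
    for x in range(n - 2):
        for y in range(x + 1, n - 1):
            for z in range(y + 1, n):
                rxy, rxz, ryz = corr[x, y], corr[x, z], corr[y, z]
                if max(abs(rxy), abs(rxz), abs(ryz)) >= 1.0:
                    continue
                pxy = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
                pxz = (rxz - rxy * ryz) / np.sqrt((1 - rxy**2) * (1 - ryz**2))
                pyz = (ryz - rxy * rxz) / np.sqrt((1 - rxy**2) * (1 - rxz**2))
                eps = 0.0
                if rxy != 0.0:
                    eps += abs(pxy / rxy)
                if rxz != 0.0:
                    eps += abs(pxz / rxz)
                if ryz != 0.0:
                    eps += abs(pyz / ryz)
                eps /= 3.0
                if abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz):
                    eliminated[x, y] = eliminated[y, x] = True
                if abs(rxz) < abs(eps * rxy) and abs(rxz) < abs(eps * ryz):
                    eliminated[x, z] = eliminated[z, x] = True
                if abs(ryz) < abs(eps * rxy) and abs(ryz) < abs(eps * rxz):
                    eliminated[y, z] = eliminated[z, y] = True
    out = ~eliminated
    np.fill_diagonal(out, True)
    return out


class TestPartialCorrelation:
    def test_formula_evaluation(self):
        # 0.34 / sqrt(0.36 * 0.51)
        assert partial_correlation(0.9, 0.8, 0.7) == pytest.approx(
            0.34 / np.sqrt(0.36 * 0.51)
        )

    def test_matches_matrix_inversion(self, rng):
        """r_xy.z equals the value from inverting the 3x3 correlation matrix."""
        for _ in range(200):
            c = random_corr(rng, 3)
            p = np.linalg.inv(c)
            expected = -p[0, 1] / np.sqrt(p[0, 0] * p[1, 1])
            got = partial_correlation(c[0, 1], c[0, 2], c[1, 2])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_degenerate_conditioning_raises(self):
        with pytest.raises(ValueError):
            partial_correlation(0.5, 1.0, 0.5)


class TestPcit:
    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            c = random_corr(rng, 25)
            assert np.array_equal(pcit(c), pcit_bruteforce(c))

    def test_single_association_survives(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.8
        sig = pcit(c)
        assert sig[0, 1] and sig[1, 0]

    def test_significance_matrix_symmetric(self, rng):
        sig = pcit(random_corr(rng, 20))
        assert np.array_equal(sig, sig.T)

    def test_permutation_equivariance(self, rng):
        c = random_corr(rng, 15)
        perm = rng.permutation(15)
        sig = pcit(c)
        sig_p = pcit(c[np.ix_(perm, perm)])
        assert np.array_equal(sig_p, sig[np.ix_(perm, perm)])

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="square"):
            pcit(np.ones((2, 3)))
        c = random_corr(rng, 4)
        c[0, 0] = 0.5
        with pytest.raises(ValueError, match="diagonal"):
            pcit(c)

    def test_perfect_correlation_trios_skipped(self, caplog):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 1.0
        c[0, 2] = c[2, 0] = 0.5
        sig = pcit(c)  # trio undefined: nothing eliminated
        assert sig.all()


class TestCorrelationMatrix:
    def _norm(self, vals, n_fh=3, n_sfh=3):
        cm = make_count_matrix(vals, n_fh=n_fh, n_sfh=n_sfh)
        return NormalizedMatrix(cm.counts.astype(float), cm.groups)

    def test_duplicate_feature_r_one(self, rng):
        v = rng.poisson(50, size=6)
        norm = self._norm(np.vstack([v, v, rng.poisson(50, size=6)]))
        c = correlation_matrix(norm)
        assert c.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_feature_r_minus_one(self, rng):
        v = rng.normal(100, 10, size=6)
        norm = self._norm(np.round(np.vstack([v, 200 - v])))
        assert correlation_matrix(norm).iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self, rng):
        x = rng.poisson(40, size=(20, 6)).astype(float)
        norm = self._norm(x)
        got = correlation_matrix(norm).to_numpy()
        mean = x.mean(axis=1, keepdims=True)
        xc = x - mean
        cov = xc @ xc.T
        sd = np.sqrt(np.diag(cov))
        expected = cov / np.outer(sd, sd)
        assert np.abs(got - expected).max() < 1e-12

    def test_zero_variance_feature_r_zero(self, rng):
        vals = np.vstack([np.full(6, 7), rng.poisson(50, size=6)])
        c = correlation_matrix(self._norm(vals))
        assert c.iloc[0, 1] == 0.0
        assert c.iloc[0, 0] == 1.0

    def test_too_few_samples(self, rng):
        norm = self._norm(rng.poisson(50, size=(4, 6)))
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(norm, samples=["FH1", "FH2"])


class TestBuildGroupNetwork:
    def _norm(self, rng, n_feat=12, n=12):
        cm = make_count_matrix(rng.poisson(100, size=(n_feat, n)),
                               feature_ids=[f"m{i}" if i < 3 else f"g{i}"
                                            for i in range(n_feat)])
        return NormalizedMatrix(cm.counts.astype(float), cm.groups)

    def test_all_weak_correlations_no_edges(self):
        r = np.random.default_rng(0)
        # independent high-count features, many samples: |r| stays < 0.6
        cm = make_count_matrix(r.poisson(10000, size=(8, 40)), n_fh=40, n_sfh=0,
                               feature_ids=[f"m{i}" if i < 2 else f"g{i}"
                                            for i in range(8)])
        norm = NormalizedMatrix(cm.counts.astype(float), cm.groups)
        edges = build_group_network(norm, ["m0", "m1"], [f"g{i}" for i in range(2, 8)],
                                    "FH", 0.6)
        assert edges == []

    def test_gene_gene_excluded_from_network(self, rng):
        vals = rng.poisson(100, size=(4, 12)).astype(float)
        vals[1] = vals[0] * 1.1  # miRNA-gene strong pair
        vals[3] = vals[2] * 0.9  # gene-gene strong pair
        cm = make_count_matrix(np.round(vals), feature_ids=["m0", "g1", "g2", "g3"])
        norm = NormalizedMatrix(cm.counts.astype(float), cm.groups)
        edges, all_edges = build_group_network(
            norm, ["m0"], ["g1", "g2", "g3"], "FH",
            samples=list(cm.sample_ids), full_output=True
        )
        assert all(e.edge_class != "gene-gene" for e in edges)
        assert any(e.edge_class == "gene-gene" for e in all_edges)

    def test_raising_r_min_never_adds_edges(self, rng):
        norm = self._norm(rng)
        demis, targets = ["m0", "m1", "m2"], [f"g{i}" for i in range(3, 12)]
        samples = list(norm.cpm.columns)
        loose = build_group_network(norm, demis, targets, "FH", 0.3, samples=samples)
        tight = build_group_network(norm, demis, targets, "FH", 0.6, samples=samples)
        loose_keys = {(e.node_a, e.node_b) for e in loose}
        assert {(e.node_a, e.node_b) for e in tight} <= loose_keys

    def test_empty_node_set_errors(self, rng):
        norm = self._norm(rng)
        with pytest.raises(ValueError, match="empty node set"):
            build_group_network(norm, ["absent"], ["alsoabsent"], "FH")

    def test_edges_canonically_ordered(self, rng):
        norm = self._norm(rng)
        edges = build_group_network(norm, ["m0", "m1", "m2"],
                                    [f"g{i}" for i in range(3, 12)], "FH", 0.1,
                                    samples=list(norm.cpm.columns))
        assert all(e.node_a < e.node_b for e in edges)
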