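import numpy as np
import pandas as pd
import pytest

from braakmap.coexpression import (
    cluster_modules,
    consensus,
    donor_correlation_matrix,
    module_braak_association,
    module_eigengene,
)
from conftest import make_donor


def block_network(rng, blocks, n_noise=0, within=0.95, between=0.0):
    """Correlation matrix with planted blocks plus small symmetric jitter."""
    n = sum(blocks) + n_noise
    r = np.full((n, n), between)
    start = 0
    for size in blocks:
        r[start:start + size, start:start + size] = within
        start += size
    jitter = rng.normal(0, 0.01, (n, n))
    r += (jitter + jitter.T) / 2
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1, 1, out=r)
    genes = [f"G{i:04d}" for i in range(n)]
    return pd.DataFrame(r, index=genes, columns=genes)


class TestCorrelationMatrix:
    def test_identical_and_negated_genes(self, rng):
        expr, samples = make_donor(rng, n_genes=3)
        frame = expr.data
        frame.iloc[1] = frame.iloc[0]
        frame.iloc[2] = -frame.iloc[0]
        m = donor_correlation_matrix(frame, samples)
        assert m.iloc[0, 1] == pytest.approx(1.0)
        assert m.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_matches_numpy_corrcoef(self, rng):
        expr, samples = make_donor(rng, n_genes=50, samples_per_region=2)
        m = donor_correlation_matrix(expr.data, samples)
        np.testing.assert_allclose(
            m.to_numpy(), np.corrcoef(expr.data.to_numpy()), atol=1e-10
        )

    def test_zero_variance_gene_flagged(self, rng):
        expr, samples = make_donor(rng, n_genes=4)
        frame = expr.data
        frame.iloc[2] = 3.14
        m = donor_correlation_matrix(frame, samples)
        assert m.iloc[2].drop(m.index[2]).isna().all()


class TestConsensus:
    def test_mean_and_mismatch(self, rng):
        a = block_network(rng, [5])
        b = a.copy()
        b.iloc[0, 1] = -a.iloc[0, 1]
        c = consensus([a, b])
        assert c.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(
            c.to_numpy(), (a.to_numpy() + b.to_numpy()) / 2, atol=1e-14
        )
        with pytest.raises(ValueError, match="share gene sets"):
            consensus([a, a.iloc[:3, :3]])

    def test_identity(self, rng):
        a = block_network(rng, [4])
        pd.testing.assert_frame_equal(consensus([a, a, a]), a)


class TestClusterModules:
    def test_two_planted_blocks_recovered(self, rng):
        net = block_network(rng, [60, 60], n_noise=0)
        labels = cluster_modules(net, min_size=50)
        assert labels.max() == 2
        first = labels.iloc[:60]
        second = labels.iloc[60:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_all_correlated_single_module(self, rng):
        net = block_network(rng, [70])
        labels = cluster_modules(net, min_size=50)
        assert (labels == 1).all()

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        net = block_network(rng, [30])
        labels = cluster_modules(net, min_size=50)
        assert (labels == 0).all()

    def test_gene_order_invariance(self, rng):
        net = block_network(rng, [55, 70], n_noise=20)
        labels = cluster_modules(net, min_size=50)
        perm = rng.permutation(len(net))
        permuted = net.iloc[perm, perm]
        labels2 = cluster_modules(permuted, min_size=50)
        # same partition up to label names
        joined = pd.DataFrame({
            "orig": labels, "perm": labels2.reindex(labels.index)
        })
        mapping = joined.drop_duplicates()
        assert mapping.groupby("orig").size().max() == 1
        assert mapping.groupby("perm").size().max() == 1

    def test_labels_ordered_by_size(self, rng):
        net = block_network(rng, [80, 60])
        labels = cluster_modules(net, min_size=50)
        sizes = labels[labels > 0].value_counts()
        assert sizes.loc[1] >= sizes.loc[2]


class TestEigengene:
    def test_matches_independent_svd_on_random_modules(self, rng):
        for _ in range(50):
            n_genes = int(rng.integers(5, 30))
            n_samples = int(rng.integers(6, 20))
            frame = pd.DataFrame(
                rng.normal(size=(n_genes, n_samples)),
                index=[f"G{i}" for i in range(n_genes)],
                columns=[f"s{i}" for i in range(n_samples)],
            )
            eg = module_eigengene(frame, frame.index)
            x = frame.to_numpy()
            xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
            w, v = np.linalg.eigh(xs.T @ xs)  # independent full decomposition
            lead = v[:, -1]
            got = eg.vector.to_numpy()
            assert min(
                np.abs(got - lead).max(), np.abs(got + lead).max()
            ) < 1e-8
            assert np.linalg.norm(got) == pytest.approx(1.0)
            assert eg.explained_variance == pytest.approx(
                w[-1] / w.sum(), abs=1e-10
            )

    def test_sign_correction_aligns_with_module_mean(self, rng):
        frame = pd.DataFrame(
            np.tile(np.arange(8.0), (4, 1)) + rng.normal(0, 0.01, (4, 8)),
            index=list("abcd"), columns=[f"s{i}" for i in range(8)],
        )
        eg = module_eigengene(frame, frame.index)
        mean_expr = frame.mean(axis=0)
        assert np.corrcoef(eg.vector, mean_expr)[0, 1] > 0
        # negating the input flips the raw component but not the convention
        eg2 = module_eigengene(-frame, frame.index)
        assert np.corrcoef(eg2.vector, (-frame).mean(axis=0))[0, 1] > 0

    def test_constant_module_is_error(self):
        frame = pd.DataFrame(np.ones((3, 5)), index=list("abc"),
                             columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="nonzero variance"):
            module_eigengene(frame, frame.index)


class TestModuleAssociation:
    def _eigengenes(self, rng, r_by_module, donors=("d1", "d2")):
        tables, frames = {}, []
        for donor in donors:
            _, samples = make_donor(rng, n_genes=2, donor=donor)
            labels = samples.set_index("sample_id")["braak_region"].astype(float)
            z = (labels - labels.mean()).to_numpy()
            z /= np.sqrt((z**2).mean())
            cols = {}
            for m, rho in r_by_module.items():
                noise = rng.normal(size=len(z))
                noise = noise - noise.mean() - (noise @ z) / (z @ z) * z
                noise /= np.sqrt((noise**2).mean())
                cols[m] = pd.Series(rho * z + np.sqrt(1 - rho**2) * noise,
                                    index=labels.index)
            tables[donor] = pd.DataFrame(cols)
            frames.append(samples)
        return tables, pd.concat(frames, ignore_index=True)

    def test_homogeneous_correlation_recovered(self, rng):
        tables, samples = self._eigengenes(rng, {1: 0.5})
        out = module_braak_association(tables, samples)
        assert out.loc[1, "r"] == pytest.approx(0.5, abs=1e-6)
        assert out.loc[1, "tau2"] == pytest.approx(0.0, abs=1e-10)

    def test_near_perfect_correlation(self, rng):
        tables, samples = self._eigengenes(rng, {1: 0.999})
        out = module_braak_association(tables, samples)
        assert out.loc[1, "r"] == pytest.approx(0.999, abs=1e-4)

    def test_q_values_match_hand_chain(self, rng):
        from braakmap.stats import bh_adjust, meta_random_effects

        tables, samples = self._eigengenes(rng, {1: 0.9, 2: 0.3, 3: 0.05})
        out = module_braak_association(tables, samples)
        ps = []
        for m in (1, 2, 3):
            zs, vzs = [], []
            for donor, table in tables.items():
                sub = samples[samples["donor_id"] == donor]
                labels = sub.set_index("sample_id")["braak_region"].astype(float)
                r = np.corrcoef(table.loc[labels.index, m], labels)[0, 1]
                zs.append(np.arctanh(r))
                vzs.append(1.0 / (len(labels) - 3))
            ps.append(meta_random_effects(zs, vzs).p)
        np.testing.assert_allclose(out["q"], bh_adjust(ps), atol=1e-10)
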