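"""Edge-weight construction, filtering, consensus and group averaging."""

import numpy as np
import pandas as pd
import pytest

from wconn.build import (
    apply_commit_edge_filter,
    build_all_weightings,
    build_commit,
    build_fc,
    build_nos_los,
    build_sift2,
    build_tractometry,
    commit_filter,
    consensus_mask,
    group_average,
    volume_normalize,
)
from wconn.core import (
    FormatError,
    Parcellation,
    StreamlineTable,
    SubjectEnsemble,
    WeightedConnectome,
)


def make_table(rows, subject="s1"):
    cols = ["node_i", "node_j", "length_mm", "w_commit", "w_sift2",
            "med_R1", "med_FA", "med_RD", "med_ICVF"]
    return StreamlineTable(pd.DataFrame(rows, columns=cols), subject_id=subject)


def random_table(rng, n_nodes=6, n_rows=200):
    i = rng.integers(0, n_nodes - 1, n_rows)
    j = rng.integers(0, n_nodes, n_rows)
    j = np.where(j == i, i + 1, j)
    return make_table(
        {
            "node_i": i, "node_j": j,
            "length_mm": rng.uniform(5, 80, n_rows),
            "w_commit": rng.uniform(0, 1, n_rows),
            "w_sift2": rng.uniform(0, 1, n_rows),
            "med_R1": rng.uniform(0.8, 1.2, n_rows),
            "med_FA": rng.uniform(0.2, 0.6, n_rows),
            "med_RD": rng.uniform(0.5, 0.9, n_rows),
            "med_ICVF": rng.uniform(0.3, 0.7, n_rows),
        }
    )


@pytest.fixture
def parc6():
    return Parcellation(
        node_ids=[f"n{i}" for i in range(6)],
        labels=[f"L{i}" for i in range(6)],
        module=np.array(["VIS"] * 3 + ["DMN"] * 3, dtype=object),
        volume=np.ones(6),
        coords=np.arange(18, dtype=float).reshape(6, 3),
    )


class TestCommitFilter:
    def test_threshold_direct(self):
        t = make_table([[0, 1, 10, 0.5, 1, 1, 1, 1, 1],
                        [0, 1, 10, 1e-13, 1, 1, 1, 1, 1],
                        [0, 1, 10, 0.2, 1, 1, 1, 1, 1]])
        out, rep = commit_filter(t)
        assert len(out) == 2 and rep == {"retained": 2, "removed": 1}

    def test_all_pass_unchanged(self):
        t = make_table([[0, 1, 10, 0.5, 1, 1, 1, 1, 1]])
        out, rep = commit_filter(t)
        assert len(out) == 1 and rep["removed"] == 0

    def test_mass_removal_binomial(self):
        # emulates the >90% tractogram shrinkage regime of heavy filtering
        rng = np.random.default_rng(5)
        n = 10_000
        w = np.where(rng.random(n) < 0.9, 1e-14, 0.5)
        t = make_table({
            "node_i": np.zeros(n, int), "node_j": np.ones(n, int),
            "length_mm": np.full(n, 10.0), "w_commit": w, "w_sift2": np.ones(n),
            "med_R1": np.ones(n), "med_FA": np.ones(n), "med_RD": np.ones(n),
            "med_ICVF": np.ones(n)})
        _, rep = commit_filter(t)
        assert rep["removed"] >= 0.85 * n

    def test_empty_result_warns(self):
        t = make_table([[0, 1, 10, 1e-14, 1, 1, 1, 1, 1]])
        with pytest.warns(UserWarning, match="every streamline"):
            out, _ = commit_filter(t)
        assert len(out) == 0


class TestBuilders:
    def test_nos_los_basic(self, parc6):
        t = make_table([[0, 1, 10, 1, 1, 1, 1, 1, 1],
                        [0, 1, 20, 1, 1, 1, 1, 1, 1],
                        [0, 1, 30, 1, 1, 1, 1, 1, 1]])
        nos, los = build_nos_los(t, parc6)
        assert nos.matrix[0, 1] == 3
        assert los.matrix[0, 1] == 20
        assert nos.matrix[2, 3] == 0 and los.matrix[2, 3] == 0

    def test_sift2_sum(self, parc6):
        t = make_table([[0, 1, 10, 1, 0.2, 1, 1, 1, 1],
                        [0, 1, 10, 1, 0.3, 1, 1, 1, 1]])
        assert build_sift2(t, parc6).matrix[0, 1] == pytest.approx(0.5)

    def test_commit_single_streamline_identity(self, parc6):
        t = make_table([[0, 1, 37.5, 1.0, 1, 1, 1, 1, 1]])
        assert build_commit(t, parc6).matrix[0, 1] == pytest.approx(1.0)

    def test_commit_length_weighted_sum(self, parc6):
        # x = [2, 4], l = [10, 20]: alpha = (2*10 + 4*20) / 15 = 100/15
        t = make_table([[0, 1, 10, 2, 1, 1, 1, 1, 1],
                        [0, 1, 20, 4, 1, 1, 1, 1, 1]])
        assert build_commit(t, parc6).matrix[0, 1] == pytest.approx(100 / 15)

    def test_commit_equal_lengths_reduces_to_sum(self, parc6):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 10)
        t = make_table([[0, 1, 25.0, xi, 1, 1, 1, 1, 1] for xi in x])
        assert build_commit(t, parc6).matrix[0, 1] == pytest.approx(x.sum())

    def test_tractometry_mean_of_medians(self, parc6):
        t = make_table([[0, 1, 10, 1, 1, 0.6, 1, 1, 1],
                        [0, 1, 10, 1, 1, 0.8, 1, 1, 1]])
        assert build_tractometry(t, parc6, "R1").matrix[0, 1] == pytest.approx(0.7)

    def test_tractometry_unknown_metric(self, parc6):
        t = make_table([[0, 1, 10, 1, 1, 1, 1, 1, 1]])
        with pytest.raises(FormatError):
            build_tractometry(t, parc6, "T2star")

    @pytest.mark.parametrize("builder,column,agg", [
        (build_sift2, "w_sift2", "sum"),
        (lambda t, p: build_tractometry(t, p, "FA"), "med_FA", "mean"),
    ])
    def test_against_groupby_oracle(self, parc6, builder, column, agg):
        rng = np.random.default_rng(7)
        t = random_table(rng)
        net = builder(t, parc6)
        expected = t.df.groupby(["node_i", "node_j"])[column].agg(agg)
        for (i, j), v in expected.items():
            assert net.matrix[i, j] == pytest.approx(v)

    def test_row_order_invariance(self, parc6):
        rng = np.random.default_rng(8)
        t = random_table(rng)
        shuffled = StreamlineTable(
            t.df.sample(frac=1.0, random_state=3), subject_id=t.subject_id
        )
        for name in ("NoS", "LoS", "SIFT2", "COMMIT", "R1"):
            a = build_all_weightings(t, parc6)[name]
            b = build_all_weightings(shuffled, parc6)[name]
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)


class TestVolumeNormalize:
    def test_unit_volumes_identity(self, parc6):
        net = WeightedConnectome("NoS", "s", np.ones((6, 6)) - np.eye(6))
        np.testing.assert_allclose(volume_normalize(net, parc6).matrix, net.matrix)

    def test_mean_volume_rule(self):
        parc = Parcellation(
            node_ids=["a", "b"], labels=["A", "B"],
            module=np.array(["VIS", "VIS"], dtype=object),
            volume=np.array([2.0, 2.0]), coords=np.zeros((2, 3)),
        )
        net = WeightedConnectome("NoS", "s", np.array([[0, 4.0], [4.0, 0]]))
        assert volume_normalize(net, parc).matrix[0, 1] == pytest.approx(2.0)

    def test_homogeneity(self, parc6):
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 1, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        net = WeightedConnectome("NoS", "s", m)
        doubled = Parcellation(
            parc6.node_ids, parc6.labels, parc6.module, parc6.volume * 2, parc6.coords
        )
        np.testing.assert_allclose(
            volume_normalize(net, doubled).matrix, volume_normalize(net, parc6).matrix / 2
        )


class TestFC:
    def test_fisher_z_closed_form(self):
        # two correlated series engineered to r = 0.5 exactly
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x.copy()
        y = (y - y.mean()) / y.std()
        z = np.array([1.0, -1.0, 0.5, -0.5, 0.25, -0.25])
        z = z - z.mean()
        z = z - (z @ y) / (y @ y) * y  # orthogonalize
        mix = 0.5 * y + np.sqrt(1 - 0.25) * z / z.std()
        net = build_fc(np.vstack([y, mix]))
        assert net.matrix[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-12)

    def test_zero_correlation_zero_z(self):
        ts = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        assert build_fc(ts).matrix[0, 1] == pytest.approx(0.0)

    def test_perfect_copy_clipped_finite(self):
        x = np.array([1.0, 2.0, 4.0, 1.5, 3.0])
        net = build_fc(np.vstack([x, x]))
        assert np.isfinite(net.matrix[0, 1]) and net.matrix[0, 1] > 10

    def test_constant_row_names_node(self):
        ts = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="node 0"):
            build_fc(ts)


class TestConsensusAndGrouping:
    def _ensemble(self, parc, mats, name="COMMIT"):
        nets = [WeightedConnectome(name, f"sub-{k}", m) for k, m in enumerate(mats)]
        return SubjectEnsemble(parc, name, nets)

    def test_consensus_boundary_inclusive(self, parc6):
        m1 = np.zeros((6, 6)); m1[0, 1] = m1[1, 0] = 1
        m0 = np.zeros((6, 6))
        ens = self._ensemble(parc6, [m1, m1, m0, m0])
        assert consensus_mask(ens, 0.5).matrix[0, 1] == 1  # 2 of 4 retained

    def test_consensus_minority_removed(self, parc6):
        m1 = np.zeros((6, 6)); m1[0, 1] = m1[1, 0] = 1
        m0 = np.zeros((6, 6))
        ens = self._ensemble(parc6, [m1, m0, m0, m0])
        assert consensus_mask(ens, 0.5).matrix[0, 1] == 0

    def test_consensus_full_fraction_is_intersection(self, parc6):
        rng = np.random.default_rng(4)
        mats = []
        for _ in range(3):
            m = (rng.random((6, 6)) < 0.5).astype(float)
            m = np.triu(m, 1); m += m.T
            mats.append(m)
        mask = consensus_mask(self._ensemble(parc6, mats), 1.0)
        expected = np.logical_and.reduce([m != 0 for m in mats])
        np.testing.assert_array_equal(mask.matrix != 0, expected)

    def test_single_subject_consensus_is_own_map(self, parc6):
        m = np.zeros((6, 6)); m[0, 1] = m[1, 0] = 2.5
        ens = self._ensemble(parc6, [m])
        np.testing.assert_array_equal(consensus_mask(ens).matrix != 0, m != 0)

    def test_group_average_excludes_zeros(self, parc6):
        mats = []
        for v in (2.0, 0.0, 4.0):
            m = np.zeros((6, 6)); m[0, 1] = m[1, 0] = v
            mats.append(m)
        ens = self._ensemble(parc6, mats)
        mask = np.zeros((6, 6)); mask[0, 1] = mask[1, 0] = 1
        group, rep = group_average(ens, WeightedConnectome("binary", "g", mask))
        assert group.matrix[0, 1] == pytest.approx(3.0)
        assert rep["masked_edges_all_zero"] == 0

    def test_group_average_all_zero_edge_flagged(self, parc6):
        m = np.zeros((6, 6))
        ens = self._ensemble(parc6, [m, m])
        mask = np.zeros((6, 6)); mask[2, 3] = mask[3, 2] = 1
        group, rep = group_average(ens, WeightedConnectome("binary", "g", mask))
        assert group.matrix[2, 3] == 0 and rep["masked_edges_all_zero"] == 1

    def test_commit_edge_filter_uniformizes_binary_maps(self, parc6):
        rng = np.random.default_rng(11)
        tables = [random_table(rng, n_rows=300, n_nodes=6) for _ in range(3)]
        # plant sub-threshold commit weights on some rows
        for t in tables:
            lo = rng.random(len(t.df)) < 0.3
            t.df.loc[lo, "w_commit"] = 1e-14
        per = {name: [] for name in ("NoS", "LoS", "SIFT2", "COMMIT", "R1", "FA", "RD", "ICVF")}
        for k, t in enumerate(tables):
            t = StreamlineTable(t.df, subject_id=f"sub-{k}")
            for name, net in build_all_weightings(t, parc6).items():
                per[name].append(net)
        ens = {n: SubjectEnsemble(parc6, n, nets) for n, nets in per.items()}
        out = apply_commit_edge_filter(ens, ens["COMMIT"])
        for s in range(3):
            ref = out["COMMIT"].subjects[s].binary()
            for name in out:
                np.testing.assert_array_equal(out[name].subjects[s].binary(), ref)

    def test_commit_edge_filter_noop_when_all_pass(self, parc6):
        rng = np.random.default_rng(12)
        t = random_table(rng, n_rows=100, n_nodes=6)
        t.df["w_commit"] += 0.1  # everything above threshold
        nets = build_all_weightings(t, parc6)
        ens = {n: SubjectEnsemble(parc6, n, [net]) for n, net in nets.items()}
        out = apply_commit_edge_filter(ens, ens["COMMIT"])
        for name in ens:
            np.testing.assert_array_equal(
                out[name].subjects[0].matrix, ens[name].subjects[0].matrix
            )
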