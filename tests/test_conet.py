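"""Network construction, tree cutting, eigenproteins and module summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from coabund import conet, ingest


def frame(a, prefix="P"):
    ids = [f"{prefix}{i}" for i in range(len(a))]
    return pd.DataFrame(np.asarray(a, dtype=float), index=ids, columns=ids)


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return frame(a)


def tom_oracle(a):
    """Triple-loop reference implementation of topological overlap."""
    a = np.asarray(a, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = len(a)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def log2_matrix(values, genotypes=None, timepoints=None):
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    genotypes = genotypes or ["control"] * n_samples
    timepoints = timepoints or ["1wk"] * n_samples
    samples = [
        ingest.SampleMeta(f"s{i}", genotypes[i], timepoints[i], "plex1", f"c{i}")
        for i in range(n_samples)
    ]
    design = ingest.StudyDesign(samples, {"plex1": "ref"})
    vals = pd.DataFrame(
        values, index=pd.Index([f"P{i}" for i in range(len(values))], name="protein_id"),
        columns=design.sample_ids,
    )
    return ingest.AbundanceMatrix(vals, design, scale=ingest.LOG2_RATIO)


class TestCorrelation:
    def test_self_and_anticorrelation(self, rng):
        x = rng.normal(0, 1, 10)
        matrix = log2_matrix([x, -x, x * 2])
        cor = conet.correlation_matrix(matrix)
        assert cor.iloc[0, 0] == 1.0
        assert cor.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert cor.iloc[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_pearson_formula(self, rng):
        X = rng.normal(0, 1, (4, 5))
        cor = conet.correlation_matrix(log2_matrix(X))
        for i in range(4):
            for j in range(4):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cor.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_with_missing(self, rng):
        X = rng.normal(0, 1, (3, 12))
        Xm = X.copy()
        Xm[0, :4] = np.nan
        cor = conet.correlation_matrix(log2_matrix(Xm))
        shared = ~np.isnan(Xm[0])
        xi = Xm[0, shared] - Xm[0, shared].mean()
        xj = X[1, shared] - X[1, shared].mean()
        expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
        assert cor.iloc[0, 1] == pytest.approx(expected, abs=1e-10)


class TestSignedAdjacency:
    def test_endpoint_mapping(self):
        cor = frame([[1.0, 1.0, -1.0], [1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
        adj = conet.signed_adjacency(cor, beta=8)
        assert adj.iloc[0, 1] == 1.0
        assert adj.iloc[0, 2] == 0.0
        assert adj.iloc[1, 2] == pytest.approx(0.5**8)

    def test_beta_one_midpoint(self):
        cor = frame([[1.0, 0.5], [0.5, 1.0]])
        assert conet.signed_adjacency(cor, 1).iloc[0, 1] == 0.75

    def test_absolute_variant(self):
        cor = frame([[1.0, -0.5], [-0.5, 1.0]])
        assert conet.signed_adjacency(cor, 2, "absolute").iloc[0, 1] == 0.25

    @given(c=st.floats(-0.999, 1.0), c2=st.floats(-0.999, 1.0),
           b=st.integers(1, 12))
    def test_monotone_in_correlation_and_beta(self, c, c2, b):
        lo, hi = sorted([c, c2])
        cor_lo = frame([[1.0, lo], [lo, 1.0]])
        cor_hi = frame([[1.0, hi], [hi, 1.0]])
        a_lo = conet.signed_adjacency(cor_lo, b).iloc[0, 1]
        a_hi = conet.signed_adjacency(cor_hi, b).iloc[0, 1]
        assert a_lo <= a_hi + 1e-15
        a_next = conet.signed_adjacency(cor_lo, b + 1).iloc[0, 1]
        assert a_next <= a_lo + 1e-15  # base in [0,1): higher power shrinks


class TestConnectivity:
    def test_complete_and_empty_graphs(self):
        n = 5
        full = frame(np.ones((n, n)))
        assert np.allclose(conet.connectivity(full), n - 1)
        empty = frame(np.eye(n))
        assert np.allclose(conet.connectivity(empty), 0.0)

    def test_matches_brute_force_sum(self, rng):
        adj = random_adjacency(rng, 10)
        k = conet.connectivity(adj)
        a = adj.to_numpy()
        for i in range(10):
            assert k.iloc[i] == pytest.approx(
                sum(a[i, j] for j in range(10) if j != i), abs=1e-12
            )


class TestScaleFreeFit:
    def test_perfect_power_law_gives_unit_r2(self):
        # bin means 1..10 with counts 2520/b: log10 freq linear in log10 k
        k = np.concatenate([[b] * (2520 // b) for b in range(1, 11)]).astype(float)
        fit = conet.scale_free_fit(k)
        assert fit.defined
        assert fit.signed_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)

    def test_uniform_connectivity_near_zero(self, rng):
        k = np.repeat(np.linspace(1, 10, 10), 50) + rng.normal(0, 1e-9, 500)
        fit = conet.scale_free_fit(k)
        assert abs(fit.signed_r2) < 0.3

    def test_increasing_distribution_is_negative(self):
        k = np.concatenate([[b] * (b * 10) for b in range(1, 11)]).astype(float)
        fit = conet.scale_free_fit(k)
        assert fit.signed_r2 < 0


class TestTopologicalOverlap:
    def test_complete_graph_is_all_ones(self):
        for n in (3, 5, 8):
            tom = conet.topological_overlap(frame(np.ones((n, n))))
            assert np.allclose(tom, 1.0)

    def test_empty_graph_is_identity(self):
        tom = conet.topological_overlap(frame(np.eye(4)))
        assert np.allclose(tom.to_numpy(), np.eye(4))

    def test_three_node_hand_example(self):
        a = frame([[1.0, 0.8, 0.6], [0.8, 1.0, 0.4], [0.6, 0.4, 1.0]])
        tom = conet.topological_overlap(a)
        # l_12 = 0.6*0.4; min(k)=1.2; (0.24+0.8)/(1.2+1-0.8) = 1.04/1.4
        assert tom.iloc[0, 1] == pytest.approx(1.04 / 1.4, abs=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        adj = random_adjacency(rng, 30)
        tom = conet.topological_overlap(adj).to_numpy()
        expected = tom_oracle(adj.to_numpy())
        assert np.max(np.abs(tom - expected)) < 1e-10
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestClusterTree:
    def test_three_point_upgma_hand_example(self):
        d = frame([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        dendro = conet.cluster_tree(d)
        heights = dendro.linkage[:, 2]
        assert heights[0] == pytest.approx(0.2)
        assert heights[1] == pytest.approx(0.8)

    def test_identical_points_merge_at_zero(self):
        d = frame(np.zeros((4, 4)))
        dendro = conet.cluster_tree(d)
        assert np.allclose(dendro.linkage[:, 2], 0.0)

    def test_nan_distance_rejected(self):
        d = frame([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            conet.cluster_tree(d)

    def test_newick_export_parses(self):
        d = frame([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        nwk = conet.cluster_tree(d).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2
        assert "P0" in nwk and "P2" in nwk


def two_block_distance(rng, sizes=(50, 50), within=0.1, between=0.9, jitter=0.01):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = within
        start += s
    d += rng.uniform(0, jitter, (n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return frame(d)


class TestDynamicTreeCut:
    def test_two_planted_blocks_fully_recovered(self, rng):
        d = two_block_distance(rng)
        dendro = conet.cluster_tree(d)
        out = conet.dynamic_tree_cut(dendro, d, min_cluster_size=20)
        labels = out.labels
        assert (labels == conet.GREY).sum() == 0
        assert len(out.modules()) == 2
        block1 = labels.iloc[:50]
        block2 = labels.iloc[50:]
        assert block1.nunique() == 1 and block2.nunique() == 1
        assert block1.iloc[0] != block2.iloc[0]

    def test_small_block_all_grey(self, rng):
        d = two_block_distance(rng, sizes=(10,), between=0.9)
        dendro = conet.cluster_tree(d)
        out = conet.dynamic_tree_cut(dendro, d, min_cluster_size=20)
        assert (out.labels == conet.GREY).all()

    def test_duplicated_proteins_never_split(self, rng):
        d = two_block_distance(rng, sizes=(30, 30), jitter=0.02)
        dd = d.to_numpy().copy()
        dd[1, 0] = dd[0, 1] = 0.0  # P0 and P1 are exact duplicates
        d2 = frame(dd)
        out = conet.dynamic_tree_cut(conet.cluster_tree(d2), d2, min_cluster_size=20)
        assert out.labels.iloc[0] == out.labels.iloc[1]

    def test_labels_follow_size_ordered_colors(self, rng):
        d = two_block_distance(rng, sizes=(60, 30))
        out = conet.dynamic_tree_cut(conet.cluster_tree(d), d, min_cluster_size=20)
        sizes = out.labels.value_counts()
        assert sizes["turquoise"] == 60
        assert sizes["blue"] == 30

    def test_deterministic_repeat(self, rng):
        d = two_block_distance(rng)
        a1 = conet.dynamic_tree_cut(conet.cluster_tree(d), d, 20)
        a2 = conet.dynamic_tree_cut(conet.cluster_tree(d), d, 20)
        pd.testing.assert_series_equal(a1.labels, a2.labels)


class TestEigenproteins:
    def test_identical_profiles_explain_everything(self, rng):
        v = rng.normal(0, 1, 12)
        matrix = log2_matrix([v, v * 2, v * 0.5 + 1.0])
        assignment = conet.ModuleAssignment(
            pd.Series(["m1"] * 3, index=matrix.values.index)
        )
        eig = conet.module_eigenproteins(matrix, assignment)
        assert eig.explained_variance["m1"] == pytest.approx(1.0, abs=1e-12)
        kme = conet.module_membership_kme(matrix, eig)
        assert np.allclose(kme["m1"], 1.0, atol=1e-12)

    def test_two_orthogonal_groups_split_variance(self):
        n = 8
        v1 = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        v2 = np.concatenate([np.ones(n // 4), -np.ones(n // 2), np.ones(n // 4)])
        assert abs(v1 @ v2) < 1e-12
        matrix = log2_matrix([v1, v1, v2, v2])
        assignment = conet.ModuleAssignment(
            pd.Series(["m1"] * 4, index=matrix.values.index)
        )
        eig = conet.module_eigenproteins(matrix, assignment)
        assert eig.explained_variance["m1"] == pytest.approx(0.5, abs=1e-12)

    def test_collinear_with_covariance_eigenvector(self, rng):
        X = rng.normal(0, 1, (30, 20))
        matrix = log2_matrix(X)
        assignment = conet.ModuleAssignment(
            pd.Series(["m1"] * 30, index=matrix.values.index)
        )
        eig = conet.module_eigenproteins(matrix, assignment)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        top = evecs[:, -1]
        v = eig.vectors["m1"].to_numpy()
        assert abs(abs(v @ top) - 1.0) < 1e-8

    def test_sign_convention_positive_mean_correlation(self, rng):
        X = np.outer(np.ones(10), rng.normal(0, 1, 15)) + rng.normal(0, 0.1, (10, 15))
        matrix = log2_matrix(X)
        assignment = conet.ModuleAssignment(
            pd.Series(["m1"] * 10, index=matrix.values.index)
        )
        eig = conet.module_eigenproteins(matrix, assignment)
        kme = conet.module_membership_kme(matrix, eig)
        assert kme["m1"].mean() > 0


class TestKme:
    def test_orthogonal_protein_has_zero_kme(self):
        n = 8
        v1 = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        v2 = np.concatenate([np.ones(n // 4), -np.ones(n // 2), np.ones(n // 4)])
        matrix = log2_matrix([v1, v1, v1, v2])
        assignment = conet.ModuleAssignment(
            pd.Series(["m1", "m1", "m1", "grey"], index=matrix.values.index)
        )
        eig = conet.module_eigenproteins(matrix, assignment)
        kme = conet.module_membership_kme(matrix, eig)
        assert kme["m1"].iloc[3] == pytest.approx(0.0, abs=1e-12)
        assert kme["m1"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_hub_ranking_descends(self, small_dataset):
        _, log_matrix, truth = small_dataset
        labels = truth.module_label_by_protein.reindex(log_matrix.values.index)
        assignment = conet.ModuleAssignment(
            labels.where(labels != "background", conet.GREY)
        )
        eig = conet.module_eigenproteins(log_matrix, assignment)
        kme = conet.module_membership_kme(log_matrix, eig)
        hubs = conet.hub_proteins(kme, assignment, top_n=6)
        for module, top in hubs.items():
            vals = kme.loc[top, module].to_numpy()
            assert np.all(np.diff(vals) <= 1e-12)
            assert vals[0] == kme.loc[assignment.members(module), module].max()

    def test_members_outrank_background(self, small_dataset):
        _, log_matrix, truth = small_dataset
        labels = truth.module_label_by_protein.reindex(log_matrix.values.index)
        assignment = conet.ModuleAssignment(
            labels.where(labels != "background", conet.GREY)
        )
        eig = conet.module_eigenproteins(log_matrix, assignment)
        kme = conet.module_membership_kme(log_matrix, eig)
        background = labels.index[labels == "background"]
        for module in assignment.modules():
            member_median = kme.loc[assignment.members(module), module].median()
            bg_median = kme.loc[background, module].median()
            assert member_median > bg_median


class TestModuleProfiles:
    def test_constant_shift_module_recovers_shift(self):
        genotypes = ["control"] * 3 + ["rNLS8"] * 3
        timepoints = ["1wk"] * 6
        base = np.zeros(6)
        shifted = np.array([0.0, 0.0, 0.0, 1.5, 1.5, 1.5])
        matrix = log2_matrix([shifted, base], genotypes, timepoints)
        assignment = conet.ModuleAssignment(
            pd.Series(["m1", "grey"], index=matrix.values.index)
        )
        prof = conet.module_profiles(matrix, assignment, ("control", "1wk"))
        by_group = prof.set_index(["genotype", "timepoint"])
        assert by_group.loc[("rNLS8", "1wk"), "median"] == pytest.approx(1.5)
        assert by_group.loc[("control", "1wk"), "median"] == pytest.approx(0.0)

    def test_transient_module_elevated_early_only(self, small_dataset):
        _, log_matrix, truth = small_dataset
        labels = truth.module_label_by_protein.reindex(log_matrix.values.index)
        assignment = conet.ModuleAssignment(
            labels.where(labels != "background", conet.GREY)
        )
        prof = conet.module_profiles(
            log_matrix, assignment,
            [("control", tp) for tp in ("1wk", "2wk", "4wk", "6wk")],
        )
        mb = prof[prof["module"] == "mB"].set_index(["genotype", "timepoint"])
        # shared module factor adds ~0.2 group-level jitter at n=5, so the
        # checks are directional rather than exact
        assert mb.loc[("rNLS8", "1wk"), "median"] > 0.4
        assert abs(mb.loc[("rNLS8", "rec"), "median"]) < 0.35
        assert mb.loc[("rNLS8", "1wk"), "median"] > mb.loc[("rNLS8", "rec"), "median"] + 0.3
        for tp in ("1wk", "2wk", "4wk", "6wk"):
            assert abs(mb.loc[("control", tp), "median"]) < 0.35


class TestPickSoftThreshold:
    def test_rsq_cut_zero_returns_smallest_power(self, rng):
        X = rng.normal(0, 1, (60, 20))
        matrix = log2_matrix(X)
        beta, table, reached = conet.pick_soft_threshold(
            matrix, candidate_powers=(1, 2, 3), rsq_cut=1e-9
        )
        assert reached in (True, False)
        if reached:
            assert beta == int(table.loc[table["signed_r2"] >= 1e-9, "power"].iloc[0])

    def test_fit_table_covers_all_candidates(self, rng):
        X = rng.normal(0, 1, (40, 15))
        _, table, _ = conet.pick_soft_threshold(log2_matrix(X), candidate_powers=(1, 4, 8))
        assert list(table["power"]) == [1, 4, 8]
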