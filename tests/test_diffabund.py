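"""Differential abundance: t tests, calls, ANOVA, overlaps, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from coabund import diffabund, ingest


def two_group_matrix(values_a, values_b, extra_rows=None):
    """Matrix with one (or more) proteins over groups A (control) and B."""
    na, nb = len(values_a[0]), len(values_b[0])
    samples = [
        ingest.SampleMeta(f"a{i}", "control", "1wk", "plex1", f"c{i}") for i in range(na)
    ] + [
        ingest.SampleMeta(f"b{i}", "rNLS8", "1wk", "plex1", f"c{na + i}") for i in range(nb)
    ]
    design = ingest.StudyDesign(samples, {"plex1": "ref"})
    rows = [list(a) + list(b) for a, b in zip(values_a, values_b)]
    vals = pd.DataFrame(
        rows, index=pd.Index([f"P{i}" for i in range(len(rows))], name="protein_id"),
        columns=design.sample_ids,
    )
    matrix = ingest.AbundanceMatrix(vals, design, scale=ingest.LOG2_RATIO)
    spec = diffabund.ComparisonSpec(
        frozenset({("control", "1wk")}), frozenset({("rNLS8", "1wk")}), "b_vs_a"
    )
    return matrix, spec


class TestPairwiseDe:
    def test_pooled_t_worked_example(self):
        """A = {-0.1, 0, 0.1}, B = {0.9, 1.0, 1.1}: t = dmean / (s_p sqrt(2/3))
        with s_p = 0.1, so t = 12.247 on 4 degrees of freedom."""
        matrix, spec = two_group_matrix([[-0.1, 0.0, 0.1]], [[0.9, 1.0, 1.1]])
        out = diffabund.pairwise_de(matrix, spec)
        assert out["t"].iloc[0] == pytest.approx(12.247448, abs=1e-5)
        assert out["df"].iloc[0] == 4

    def test_fold_change_is_geometric_mean_ratio(self):
        matrix, spec = two_group_matrix([[0.0, 0.0, 1e-9]], [[1.0, 1.0, 1.0]])
        out = diffabund.pairwise_de(matrix, spec)
        assert out["fold_change"].iloc[0] == pytest.approx(2.0, rel=1e-6)

    def test_reciprocal_ratios_cancel(self):
        # group B ratios {2, 0.5} vs flat baseline: GM fold change = 1
        matrix, spec = two_group_matrix([[0.0, 1e-10]], [[1.0, -1.0]])
        out = diffabund.pairwise_de(matrix, spec)
        assert out["fold_change"].iloc[0] == pytest.approx(1.0, rel=1e-8)

    def test_zero_variance_contracts(self):
        matrix, spec = two_group_matrix(
            [[0.0, 0.0], [0.0, 0.0]], [[0.0, 0.0], [1.0, 1.0]]
        )
        out = diffabund.pairwise_de(matrix, spec)
        assert out["t"].iloc[0] == 0.0  # equal means, zero variance
        assert out["call"].iloc[1] == diffabund.CALL_UNTESTABLE

    def test_missing_reduces_group_to_one_sample(self):
        matrix, spec = two_group_matrix([[0.0, np.nan, np.nan]], [[1.0, 1.1, 0.9]])
        out = diffabund.pairwise_de(matrix, spec)
        assert out["call"].iloc[0] == diffabund.CALL_UNTESTABLE

    def test_log_base_invariance_of_fold_change(self):
        matrix, spec = two_group_matrix([[0.1, -0.2, 0.05]], [[0.8, 1.1, 0.95]])
        fc2 = diffabund.pairwise_de(matrix, spec)["fold_change"].iloc[0]
        # same data expressed in natural log: FC = e**(mean diff in ln units)
        ln = matrix.values * np.log(2.0)
        dmean = ln.iloc[0, 3:].mean() - ln.iloc[0, :3].mean()
        assert fc2 == pytest.approx(float(np.exp(dmean)), rel=1e-12)


class TestClassifyDe:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [(1.25, 0.01, "up"), (1.19, 0.0001, "ns"), (0.80, 0.04, "down"),
         (1.5, 0.2, "ns"), (0.5, 0.06, "ns")],
    )
    def test_joint_gate(self, fc, p, expected):
        table = pd.DataFrame(
            {"fold_change": [fc], "p": [p], "call": ["ns"]},
            index=pd.Index(["P0"], name="protein_id"),
        )
        out = diffabund.classify_de(table)
        assert out["call"].iloc[0] == expected

    def test_invalid_thresholds(self):
        table = pd.DataFrame({"fold_change": [1.0], "p": [0.5], "call": ["ns"]})
        with pytest.raises(ValueError):
            diffabund.classify_de(table, fc_up=0.9)

    @given(
        p_cut=st.floats(0.01, 0.2), widen=st.floats(0.0, 0.5),
        fc=st.floats(0.4, 2.5), p=st.floats(0.0, 1.0),
    )
    def test_monotone_in_thresholds(self, p_cut, widen, fc, p):
        """Raising p_cut or widening the FC gates never removes a call."""
        table = pd.DataFrame({"fold_change": [fc], "p": [p], "call": ["ns"]})
        tight = diffabund.classify_de(table, 1.2 + widen, 1 / (1.2 + widen), p_cut)
        loose = diffabund.classify_de(table, 1.2, 1 / 1.2, p_cut + 0.1)
        if tight["call"].iloc[0] in ("up", "down"):
            assert loose["call"].iloc[0] == tight["call"].iloc[0]


class TestProteinAnova:
    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, (25, 4)).tolist()
        b = rng.normal(0.5, 1, (25, 5)).tolist()
        matrix, spec = two_group_matrix(a, b)
        t = diffabund.pairwise_de(matrix, spec)["t"]
        F = diffabund.protein_anova(matrix)["F"]
        assert np.allclose(F, t**2, atol=1e-10)

    def test_group_reduced_to_one_sample_untestable(self):
        matrix, _ = two_group_matrix([[0.0, np.nan, np.nan]], [[1.0, 1.1, 0.9]])
        out = diffabund.protein_anova(matrix)
        assert np.isnan(out["F"].iloc[0])
        assert "fewer than 2 groups" in out["untestable_reason"].iloc[0]

    def test_flat_zero_variance_is_f_zero(self):
        matrix, _ = two_group_matrix([[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]])
        out = diffabund.protein_anova(matrix)
        assert out["F"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0


class TestOverlapSets:
    def test_enumeration_example(self):
        out = diffabund.overlap_sets(
            {"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3}}
        )
        cells = {r["cell"]: r["members"] for _, r in out.iterrows()}
        assert cells == {"A": ["1"], "A&B": ["2"], "A&B&C": ["3"], "B": ["4"]}
        assert out["count"].sum() == 4  # cells partition the union

    def test_identical_and_disjoint(self):
        same = diffabund.overlap_sets({"A": {1, 2}, "B": {1, 2}})
        assert len(same) == 1 and same["count"].iloc[0] == 2
        disj = diffabund.overlap_sets({"A": {1}, "B": {2}})
        assert sorted(disj["cell"]) == ["A", "B"]

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            diffabund.overlap_sets({"A": {1}})


class TestSamplePca:
    def test_duplicated_samples_give_zero_second_component(self):
        matrix, _ = two_group_matrix([[x, x] for x in [0.1, 0.5, -0.3, 0.8]],
                                     [[x, x] for x in [0.2, -0.1, 0.4, 0.0]])
        out = diffabund.sample_pca(matrix, k=2)
        assert out.variance_ratio[0] == pytest.approx(1.0)

    def test_variance_ratios_match_covariance_eigenvalues(self, rng):
        vals = rng.normal(0, 1, (40, 7))
        matrix, _ = two_group_matrix(vals[:, :3].tolist(), vals[:, 3:].tolist())
        out = diffabund.sample_pca(matrix, k=7)
        X = matrix.values.to_numpy().T  # samples x proteins
        C = np.cov(X, rowvar=False, ddof=0)  # protein covariance
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        expected = evals / evals.sum()
        assert np.allclose(out.variance_ratio, expected[: len(out.variance_ratio)],
                           atol=1e-10)
        assert np.all(np.diff(out.variance_ratio) <= 1e-12)

    def test_missing_rows_excluded_and_counted(self):
        matrix, _ = two_group_matrix(
            [[0.1, 0.2, 0.3], [np.nan, 0.0, 0.1], [0.4, 0.1, 0.0]],
            [[1.0, 0.9, 1.1], [1.0, 1.0, 1.0], [0.2, 0.3, 0.1]],
        )
        out = diffabund.sample_pca(matrix, k=2)
        assert out.n_proteins_used == 2
        assert out.n_proteins_dropped == 1
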