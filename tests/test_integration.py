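"""Variable pooling, full-order partial correlations, network thresholding."""

import numpy as np
import pandas as pd
import pytest

from triomics import (
    ContrastResult,
    SubNetwork,
    TriomicsError,
    build_network,
    build_variable_set,
    partial_correlations,
)
from triomics.integration import PartialCorrelationMatrix, VariableSet
from triomics.set_analysis import SubNetworkSummary

from conftest import make_matrix, make_meta


def varset_from(data: pd.DataFrame, contrast="healthy_vs_active"):
    prov = pd.DataFrame(
        {"column": data.columns, "kind": "analyte", "block": "metabolite"}
    ).set_index("column")
    return VariableSet(data=data, contrast=contrast, provenance=prov)


def pcor_bruteforce(data: np.ndarray) -> np.ndarray:
    """Residual-regression oracle: correlate residuals of i and j after
    regressing each on all remaining columns."""
    n, k = data.shape
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            others = [c for c in range(k) if c not in (i, j)]
            Z = np.column_stack([np.ones(n), data[:, others]])
            ri = data[:, i] - Z @ np.linalg.lstsq(Z, data[:, i], rcond=None)[0]
            rj = data[:, j] - Z @ np.linalg.lstsq(Z, data[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


class TestPartialCorrelations:
    def test_collider_induces_negative_partial(self):
        """X3 = X1 + X2 + noise: conditioning on the sum makes X1, X2
        negatively partially correlated even though marginally independent."""
        rng = np.random.default_rng(0)
        x1, x2 = rng.standard_normal((2, 400))
        x3 = x1 + x2 + 0.5 * rng.standard_normal(400)
        data = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        marginal = np.corrcoef(x1, x2)[0, 1]
        pcm = partial_correlations(varset_from(data))
        assert abs(marginal) < 0.15
        assert pcm.matrix.loc["x1", "x2"] < -0.3

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        n = 500
        data = pd.DataFrame(
            rng.standard_normal((n, 6)), columns=[f"x{i}" for i in range(6)]
        )
        pcm = partial_correlations(varset_from(data))
        off = pcm.matrix.to_numpy()[np.triu_indices(6, k=1)]
        assert np.all(np.abs(off) < 3 / np.sqrt(n))

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            raw = rng.standard_normal((40, 8))
            raw[:, 0] += 0.5 * raw[:, 1]  # give it some structure
            data = pd.DataFrame(raw, columns=[f"x{i}" for i in range(8)])
            pcm = partial_correlations(varset_from(data), ridge=0)
            oracle = pcor_bruteforce(raw)
            np.testing.assert_allclose(
                pcm.matrix.to_numpy(), oracle, atol=1e-10
            )

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            rng.standard_normal((60, 5)), columns=list("abcde")
        )
        pcm1 = partial_correlations(varset_from(data))
        perm = ["d", "a", "e", "b", "c"]
        pcm2 = partial_correlations(varset_from(data[perm]))
        np.testing.assert_allclose(
            pcm1.matrix.loc[perm, perm].to_numpy(),
            pcm2.matrix.to_numpy(),
            atol=1e-12,
        )

    def test_ridge_engages_when_underdetermined(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(
            rng.standard_normal((10, 9)), columns=[f"x{i}" for i in range(9)]
        )
        with pytest.warns(UserWarning, match="ridge"):
            pcm = partial_correlations(varset_from(data))
        assert pcm.ridge > 0
        assert np.isfinite(pcm.matrix.to_numpy()).all()

    def test_too_few_columns_rejected(self):
        data = pd.DataFrame(np.random.default_rng(0).standard_normal((20, 2)),
                            columns=["a", "b"])
        with pytest.raises(TriomicsError, match="3 columns"):
            partial_correlations(varset_from(data))


def contrast_result(sig_analytes, all_analytes, contrast="healthy_vs_active"):
    rows = []
    for a in all_analytes:
        rows.append(
            {
                "analyte": a,
                "block": "metabolite",
                "contrast": contrast,
                "estimate": 1.0,
                "t": 3.0,
                "df": 30.0,
                "p": 0.001 if a in sig_analytes else 0.9,
                "p_adj": 0.01 if a in sig_analytes else 0.95,
                "significant": a in sig_analytes,
            }
        )
    return ContrastResult(pd.DataFrame(rows))


class TestBuildVariableSet:
    def _setup(self, n_per_group=4, p=8, seed=0):
        meta = make_meta(n_per_group=n_per_group, seed=seed)
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.standard_normal((3 * n_per_group, p)))
        return meta, m

    def test_empty_significance_gives_covariates_only(self):
        meta, m = self._setup()
        res = contrast_result([], list(m.analyte_ids))
        vs = build_variable_set(res, [], {"metabolite": m}, meta, "healthy_vs_active")
        assert list(vs.data.columns) == ["age", "sex"]

    def test_column_counting(self):
        """3 significant singles + one sub-network with 2 PCs -> 7 columns."""
        meta, m = self._setup()
        res = contrast_result(["a0", "a1", "a2"], list(m.analyte_ids))
        sn = SubNetwork(block_label="metabolite", members=("a5", "a6"), K=1.0)
        scores = pd.DataFrame(
            np.random.default_rng(1).standard_normal((12, 2)),
            index=meta.sample_ids, columns=["PC1", "PC2"],
        )
        summary = SubNetworkSummary(
            subnetwork=sn, scores=scores,
            loadings=pd.DataFrame(np.eye(2), index=["a5", "a6"],
                                  columns=["PC1", "PC2"]),
            pc1_variance_fraction=0.6,
        )
        vs = build_variable_set(
            res, [summary], {"metabolite": m}, meta, "healthy_vs_active"
        )
        assert vs.n_variables == 7

    def test_subnetwork_member_deduplicated(self):
        """A significant analyte inside a summarized sub-network appears only
        through the PC column."""
        meta, m = self._setup()
        res = contrast_result(["a0", "a5"], list(m.analyte_ids))
        sn = SubNetwork(block_label="metabolite", members=("a5", "a6"), K=1.0)
        scores = pd.DataFrame(
            np.random.default_rng(2).standard_normal((12, 1)),
            index=meta.sample_ids, columns=["PC1"],
        )
        summary = SubNetworkSummary(
            subnetwork=sn, scores=scores,
            loadings=pd.DataFrame(np.ones((2, 1)), index=["a5", "a6"],
                                  columns=["PC1"]),
            pc1_variance_fraction=0.9,
        )
        vs = build_variable_set(
            res, [summary], {"metabolite": m}, meta, "healthy_vs_active"
        )
        assert "a5" not in vs.data.columns
        assert "a0" in vs.data.columns
        assert any(c.endswith("PC1") for c in vs.data.columns)


class TestBuildNetwork:
    def _pcm(self, R, ids):
        return PartialCorrelationMatrix(
            matrix=pd.DataFrame(R, index=ids, columns=ids)
        )

    def _attrs(self, ids):
        return pd.DataFrame(
            {"kind": "analyte", "block": "metabolite", "log2fc": 1.0},
            index=ids,
        )

    def test_threshold_is_strict(self):
        ids = ["a", "b", "c"]
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.6
        R[0, 2] = R[2, 0] = 0.600001
        net = build_network(self._pcm(R, ids), self._attrs(ids), "healthy_vs_active")
        assert not net.graph.has_edge("a", "b")  # exactly 0.6: no edge
        assert net.graph.has_edge("a", "c")

    def test_all_below_threshold_keeps_isolated_nodes(self):
        ids = ["a", "b", "c"]
        R = np.eye(3) * 1.0
        net = build_network(self._pcm(R, ids), self._attrs(ids), "healthy_vs_active")
        assert net.n_edges == 0
        assert net.graph.number_of_nodes() == 3

    def test_zero_threshold_complete_graph(self):
        rng = np.random.default_rng(5)
        ids = [f"a{i}" for i in range(5)]
        R = np.eye(5)
        iu = np.triu_indices(5, 1)
        R[iu] = rng.uniform(0.01, 0.5, len(iu[0]))
        R = np.triu(R) + np.triu(R, 1).T
        net = build_network(
            self._pcm(R, ids), self._attrs(ids), "healthy_vs_active", threshold=0.0
        )
        assert net.n_edges == 5 * 4 // 2

    def test_edges_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        ids = [f"a{i}" for i in range(6)]
        R = np.eye(6)
        iu = np.triu_indices(6, 1)
        R[iu] = rng.uniform(-1, 1, len(iu[0]))
        R = np.triu(R) + np.triu(R, 1).T
        counts = [
            build_network(self._pcm(R, ids), self._attrs(ids), "c", threshold=t).n_edges
            for t in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_edge_sign_preserved(self):
        ids = ["a", "b", "c"]
        R = np.eye(3)
        R[0, 1] = R[1, 0] = -0.8
        net = build_network(self._pcm(R, ids), self._attrs(ids), "c")
        assert net.graph.edges["a", "b"]["R"] == pytest.approx(-0.8)

    def test_missing_attributes_rejected(self):
        ids = ["a", "b", "c"]
        with pytest.raises(TriomicsError, match="attributes"):
            build_network(
                self._pcm(np.eye(3), ids), self._attrs(["a", "b"]), "c"
            )
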