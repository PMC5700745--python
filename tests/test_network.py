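import numpy as np
import pandas as pd
import pytest
from scipy import stats

from organtx.errors import ComputationError, ConsistencyError, ParameterError
from organtx.io import PipelineConfig, TFTable
from organtx.network import (
    build_network,
    family_distribution,
    hcluster_order,
    pearson,
    r_tail_probability,
)
from organtx.quantify import rpkm
from organtx.simulate import simulate_counts, simulate_tf_panel
from .conftest import make_expression


class TestPearson:
    def test_self_correlation(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        r, p = pearson(x, x)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        r, _ = pearson(np.array([1, 2, 3]), np.array([1, 2, 4]))
        assert r == pytest.approx(9 / np.sqrt(84), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r, p = pearson(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r0, _ = pearson(x, y)
        r_pos, _ = pearson(2.5 * x + 7, y)
        r_neg, _ = pearson(-1.5 * x + 2, y)
        assert r_pos == pytest.approx(r0, abs=1e-12)
        assert r_neg == pytest.approx(-r0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ComputationError):
            pearson(np.ones(5), np.arange(5.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            pearson(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


@pytest.fixture(scope="module")
def targets():
    cm, _ = simulate_counts(n_genes=60, organs=("F", "L", "S"),
                            reps=(3, 2, 3), unique_per_organ=0, seed=13)
    expr = rpkm(cm)
    return expr.subset_genes(expr.gene_ids[:7])


class TestBuildNetwork:

    def test_identical_profile_gives_unit_edge(self, targets):
        tf_expr, _ = simulate_tf_panel(targets, n_tfs=1, n_linked=1,
                                       link_strength=1.0, noise_sd=1e-12, seed=1)
        net = build_network(tf_expr, targets)
        row = net[(net["regulator"] == "TF0000")].iloc[0]
        assert row["r"] == pytest.approx(1.0) and row["p"] < 1e-10

    def test_threshold_semantics_inclusive_r_strict_p(self):
        # the retention rule is >= on |r| and strict < on p: set the
        # threshold to the pair's own computed |r| (edge kept), then to the
        # next float above it (edge dropped)
        organ = {f"s{i}": "F" for i in range(8)}
        rep = {f"s{i}": i + 1 for i in range(8)}
        rng = np.random.default_rng(7)
        x = rng.normal(size=8) + 10
        y = 0.9 * x + rng.normal(0, 0.2, size=8)
        y -= y.min() - 1
        tf = make_expression({f"s{i}": [y[i]] for i in range(8)}, organ, rep,
                             genes=["tf"])
        tgt = make_expression({f"s{i}": [x[i]] for i in range(8)}, organ, rep,
                              genes=["t"])
        r_exact = abs(build_network(tf, tgt, PipelineConfig(pcc_threshold=0.0,
                                                            pcc_alpha=0.5))
                      .iloc[0]["r"])
        at = build_network(tf, tgt, PipelineConfig(pcc_threshold=r_exact))
        above = build_network(
            tf, tgt,
            PipelineConfig(pcc_threshold=float(np.nextafter(r_exact, 1.0))),
        )
        assert len(at) == 1 and (at["p"] < 0.01).all()
        assert len(above) == 0

    def test_all_planted_edges_recovered(self, targets):
        tf_expr, planted = simulate_tf_panel(targets, n_tfs=100, n_linked=10,
                                             seed=5)
        net = build_network(tf_expr, targets)
        got = set(zip(net["regulator"], net["target"]))
        assert planted <= got

    def test_every_edge_satisfies_both_thresholds(self, targets):
        tf_expr, _ = simulate_tf_panel(targets, n_tfs=200, n_linked=20, seed=6)
        cfg = PipelineConfig()
        net = build_network(tf_expr, targets, cfg)
        assert (net["r"].abs() >= cfg.pcc_threshold).all()
        assert (net["p"] < cfg.pcc_alpha).all()

    def test_no_shared_samples_rejected(self, targets):
        organ = {"zz1": "F", "zz2": "F", "zz3": "F"}
        other = make_expression({"zz1": [1], "zz2": [2], "zz3": [3]}, organ)
        with pytest.raises(ConsistencyError):
            build_network(other, targets)


class TestFamilyDistribution:
    def _tfs(self):
        return TFTable(pd.DataFrame({
            "gene": ["a", "b", "c", "d"],
            "family": ["bHLH", "bHLH", "MYB", "bZIP"],
        }))

    def test_counts_sorted_descending(self):
        edges = pd.DataFrame({"regulator": ["a", "b", "c"], "target": ["x"] * 3,
                              "r": [1.0] * 3, "p": [0.0] * 3})
        df = family_distribution(edges, self._tfs())
        assert list(df["family"]) == ["bHLH", "MYB"]
        assert list(df["count"]) == [2, 1]

    def test_tie_broken_alphabetically(self):
        df = family_distribution({"a", "c", "d"}, self._tfs())
        # bHLH, MYB, bZIP each count 1 -> alphabetical (capitals first is not
        # the rule; plain lexicographic sort of the labels)
        assert list(df["count"]) == [1, 1, 1]
        assert list(df["family"]) == sorted(df["family"])

    def test_empty_edge_set_gives_empty_distribution(self):
        edges = pd.DataFrame(columns=["regulator", "target", "r", "p"])
        assert len(family_distribution(edges, self._tfs())) == 0

    def test_missing_gene_listed(self):
        with pytest.raises(ConsistencyError, match="zzz"):
            family_distribution({"a", "zzz"}, self._tfs())


class TestHclusterOrder:
    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(10, 6))
        vals[7] = vals[2]
        organ = {f"s{i}": "F" for i in range(6)}
        expr = make_expression({f"s{i}": vals[:, i] for i in range(6)}, organ)
        order, Z = hcluster_order(expr)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {2, 7}
        i2, i7 = order.index("g2"), order.index("g7")
        assert abs(i2 - i7) == 1  # identical rows end up adjacent

    def test_two_planted_blocks_stay_contiguous(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 1, 8)
        block1 = np.sin(2 * np.pi * t) + rng.normal(0, 0.05, size=(5, 8)) + 2
        block2 = -np.sin(2 * np.pi * t) + rng.normal(0, 0.05, size=(5, 8)) + 2
        vals = np.vstack([block1, block2])
        organ = {f"s{i}": "F" for i in range(8)}
        expr = make_expression({f"s{i}": vals[:, i] for i in range(8)}, organ)
        order, _ = hcluster_order(expr)
        labels = ["A" if int(g[1:]) < 5 else "B" for g in order]
        # contiguous blocks: exactly one switch point
        switches = sum(a != b for a, b in zip(labels, labels[1:]))
        assert switches == 1

    def test_single_pair_trivially_ordered(self):
        organ = {f"s{i}": "F" for i in range(4)}
        expr = make_expression(
            {f"s{i}": [i, 3 - i] for i in range(4)}, organ
        )
        order, Z = hcluster_order(expr)
        assert sorted(order) == ["g0", "g1"] and Z.shape == (1, 4)

    def test_constant_row_instructs_euclidean_fallback(self):
        organ = {f"s{i}": "F" for i in range(4)}
        expr = make_expression({f"s{i}": [1.0, i] for i in range(4)}, organ)
        with pytest.raises(ComputationError, match="euclidean"):
            hcluster_order(expr)
        order, _ = hcluster_order(expr, metric="euclidean")
        assert sorted(order) == ["g0", "g1"]
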