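import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organtx.deg import (
    NoiseDistribution,
    build_noise,
    call_degs,
    compute_md,
    deg_probabilities,
    deg_probability,
    pairwise_screen,
    signal_md,
)
from organtx.errors import ComputationError, ParameterError
from organtx.io import PipelineConfig
from organtx.quantify import rpkm
from organtx.simulate import simulate_counts
from .conftest import make_expression


def brute_force_p(m: float, d: float, noise: NoiseDistribution) -> float:
    """Independent oracle: literal loop over noise points with strict '<'."""
    hits = 0
    for ms, ds in zip(noise.m, noise.d):
        if abs(ms) < abs(m) and ds < d:
            hits += 1
    return hits / noise.n_points


class TestComputeMd:
    def test_identical_values(self):
        assert compute_md(5, 5) == (0.0, 0.0)

    def test_four_fold(self):
        m, d = compute_md(8, 2)
        assert m == pytest.approx(2.0) and d == pytest.approx(6.0)

    def test_zero_substitution_only_in_ratio(self):
        m, d = compute_md(10, 0)
        assert m == pytest.approx(math.log2(10 / 0.001))
        assert d == 10.0  # pre-substitution difference

    def test_substitute_in_d_variant(self):
        _, d = compute_md(10, 0, substitute_in_d=True)
        assert d == pytest.approx(10 - 0.001)

    def test_negative_input_rejected(self):
        with pytest.raises(ParameterError):
            compute_md(-1, 2)


class TestBuildNoise:
    def test_identical_replicates_give_all_zero_noise(self):
        organ = {"F1": "F", "F2": "F", "L1": "L", "L2": "L"}
        expr = make_expression(
            {"F1": [4, 7], "F2": [4, 7], "L1": [1, 2], "L2": [1, 2]}, organ
        )
        noise = build_noise(expr, ("F", "L"))
        assert (noise.m == 0).all() and (noise.d == 0).all()

    def test_single_gene_enumeration(self):
        # F replicates (2, 4): M = log2(2/4) = -1, D = 2; L replicates (3, 3): (0, 0)
        organ = {"F1": "F", "F2": "F", "L1": "L", "L2": "L"}
        expr = make_expression({"F1": [2], "F2": [4], "L1": [3], "L2": [3]}, organ)
        noise = build_noise(expr, ("F", "L"))
        points = sorted(zip(noise.m, noise.d))
        assert noise.n_points == 2
        assert points == [(-1.0, 2.0), (0.0, 0.0)]

    def test_point_count_formula(self):
        cm, _ = simulate_counts(n_genes=100, reps=3, de_fraction=0,
                                unique_per_organ=0, seed=1)
        noise = build_noise(rpkm(cm), ("F", "L"))
        # 100 genes x (C(3,2) + C(3,2)) = 600
        assert noise.n_points == 600

    def test_single_replicate_organ_rejected(self):
        organ = {"F1": "F", "L1": "L", "L2": "L"}
        expr = make_expression({"F1": [1], "L1": [2], "L2": [3]}, organ)
        with pytest.raises(ComputationError, match="F"):
            build_noise(expr, ("F", "L"))


class TestSignalMd:
    def test_equal_means(self):
        organ = {"F1": "F", "F2": "F", "L1": "L", "L2": "L"}
        expr = make_expression({"F1": [3], "F2": [5], "L1": [4], "L2": [4]}, organ)
        row = signal_md(expr, ("F", "L")).iloc[0]
        assert row["m"] == 0.0 and row["d"] == 0.0

    def test_mean_fold_change(self):
        organ = {"F1": "F", "F2": "F", "L1": "L", "L2": "L"}
        expr = make_expression({"F1": [6], "F2": [10], "L1": [1], "L2": [3]}, organ)
        row = signal_md(expr, ("F", "L")).iloc[0]
        assert row["m"] == pytest.approx(2.0) and row["d"] == pytest.approx(6.0)

    def test_zero_mean_substitution(self):
        organ = {"F1": "F", "F2": "F", "L1": "L", "L2": "L"}
        expr = make_expression({"F1": [0], "F2": [0], "L1": [4], "L2": [4]}, organ)
        row = signal_md(expr, ("F", "L")).iloc[0]
        assert row["m"] == pytest.approx(math.log2(0.001 / 4))
        assert row["d"] == 4.0


class TestDegProbability:
    def test_worked_example(self):
        noise = NoiseDistribution(np.array([0.5, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        assert deg_probability(1.5, 2.5, noise) == pytest.approx(2 / 3)

    def test_zero_signal_gives_zero(self):
        noise = NoiseDistribution(np.zeros(5), np.zeros(5))
        assert deg_probability(0.0, 1.0, noise) == 0.0
        assert deg_probability(1.0, 0.0, noise) == 0.0

    def test_dominating_query_gives_one(self):
        noise = NoiseDistribution(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
        assert deg_probability(5.0, 10.0, noise) == 1.0

    def test_empty_noise_rejected(self):
        noise = NoiseDistribution(np.array([]), np.array([]))
        with pytest.raises(ComputationError):
            deg_probability(1.0, 1.0, noise)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 500))
        noise = NoiseDistribution(rng.normal(0, 2, n), np.abs(rng.normal(0, 5, n)))
        m, d = rng.normal(0, 2), abs(rng.normal(0, 5))
        expected = brute_force_p(m, d, noise)
        assert deg_probability(m, d, noise) == expected
        assert deg_probabilities(np.array([m]), np.array([d]), noise)[0] == expected

    def test_p_lies_on_grid_of_n_points(self):
        rng = np.random.default_rng(0)
        noise = NoiseDistribution(rng.normal(size=7), np.abs(rng.normal(size=7)))
        for _ in range(50):
            p = deg_probability(rng.normal(), abs(rng.normal()), noise)
            assert (p * 7) == int(round(p * 7))

    def test_monotone_in_m_and_d(self):
        rng = np.random.default_rng(1)
        noise = NoiseDistribution(rng.normal(size=200), np.abs(rng.normal(size=200)))
        ms = np.linspace(0, 4, 30)
        ps = [deg_probability(m, 1.0, noise) for m in ms]
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        ds = np.linspace(0, 4, 30)
        ps = [deg_probability(1.0, d, noise) for d in ds]
        assert all(a <= b for a, b in zip(ps, ps[1:]))


class TestCallDegs:
    @pytest.mark.parametrize(
        "m, p, expected",
        [
            (2.5, 0.85, "up"),
            (2.5, 0.8, "not_de"),   # strict on p
            (2.0, 0.85, "not_de"),  # strict on m
            (-3.0, 0.95, "down"),
            (-2.0, 0.95, "not_de"),
            (1.0, 0.99, "not_de"),
            (2.01, 0.81, "up"),
        ],
    )
    def test_threshold_rule(self, m, p, expected):
        df = pd.DataFrame({"gene": ["g"], "m": [m], "d": [1.0], "p": [p]})
        assert call_degs(df)["call"].iloc[0] == expected

    def test_signed_rule_never_calls_down(self):
        cfg = PipelineConfig(signed_m=True)
        df = pd.DataFrame({"gene": ["a", "b"], "m": [-5.0, 5.0], "d": [1, 1],
                           "p": [0.99, 0.99]})
        assert list(call_degs(df, cfg)["call"]) == ["not_de", "up"]

    def test_invalid_p_rejected(self):
        df = pd.DataFrame({"gene": ["g"], "m": [1.0], "d": [1.0], "p": [1.5]})
        with pytest.raises(ParameterError):
            call_degs(df)


class TestPairwiseScreen:
    def test_three_organs_give_three_pairs(self):
        cm, _ = simulate_counts(n_genes=200, seed=2)
        screens = pairwise_screen(rpkm(cm))
        assert set(screens) == {("F", "L"), ("F", "S"), ("L", "S")}

    def test_output_row_count_equals_gene_count(self):
        cm, _ = simulate_counts(n_genes=80, unique_per_organ=5, seed=2)
        for df in pairwise_screen(rpkm(cm)).values():
            assert len(df) == 80

    def test_silent_genes_reported_not_de_with_zero_p(self):
        organ = {"F1": "F", "F2": "F", "L1": "L", "L2": "L"}
        expr = make_expression(
            {"F1": [0, 5], "F2": [0, 6], "L1": [0, 5], "L2": [0, 7]}, organ
        )
        df = pairwise_screen(expr)[("F", "L")]
        silent = df.set_index("gene").loc["g0"]
        assert silent["call"] == "not_de" and silent["p"] == 0.0

    def test_antisymmetry_of_pair_order(self):
        cm, _ = simulate_counts(n_genes=500, de_fraction=0.05, fold_change=8,
                                seed=4)
        expr = rpkm(cm)
        fwd = pairwise_screen(expr, [("F", "L")])[("F", "L")].set_index("gene")
        rev = pairwise_screen(expr, [("L", "F")])[("L", "F")].set_index("gene")
        np.testing.assert_allclose(fwd["m"], -rev["m"])
        np.testing.assert_allclose(fwd["d"], rev["d"])
        np.testing.assert_allclose(fwd["p"], rev["p"])
        swap = {"up": "down", "down": "up", "not_de": "not_de"}
        assert list(fwd["call"].map(swap)) == list(rev["call"])
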