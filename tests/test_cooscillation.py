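"""The paired-sine statistic, its null, FDR, network and communities."""
import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinecell import (
    OscillatorGroupSpec,
    PipelineConfig,
    SyntheticMatrixSpec,
    all_pair_statistics,
    bh_adjust,
    build_network,
    extract_communities,
    generate_cosc_matrix,
    infer_oscillators,
    pair_pvalue,
    pair_sine_distance,
    permutation_null,
    rescale_matrix,
    rescale_to_unit,
)
from sinecell.cooscillation import PAIR_TABLE_COLUMNS

from conftest import brute_force_pair_distance


class TestRescale:
    def test_endpoint_mapping(self):
        np.testing.assert_allclose(rescale_to_unit([0.0, 5.0, 10.0]), [-1.0, 0.0, 1.0])

    def test_idempotent_on_canonical_range(self):
        x = np.array([-1.0, -0.2, 0.4, 1.0])
        np.testing.assert_allclose(rescale_to_unit(x), x)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rescale_to_unit([2.0, 2.0, 2.0])


class TestPairSineDistance:
    @pytest.mark.parametrize("psi", [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4, np.pi])
    def test_phase_shifted_sinusoids_have_zero_distance(self, psi, rng):
        theta = rng.uniform(0, 2 * np.pi, 250)
        eps, psi_hat = pair_sine_distance(np.sin(theta), np.sin(theta + psi))
        assert eps <= 1e-10
        assert psi_hat == pytest.approx(psi, abs=1e-3)

    def test_matches_frozen_brute_force_value(self):
        # value computed by the independent 1e6-point grid oracle
        rng = np.random.default_rng(42)
        x = rng.uniform(-1, 1, 50)
        y = rng.uniform(-1, 1, 50)
        eps, psi_hat = pair_sine_distance(x, y)
        assert eps == pytest.approx(0.24248154536739233, rel=1e-6)
        assert psi_hat == pytest.approx(2.0651625535189932, abs=1e-4)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(5):
            x = rng.uniform(-1, 1, 40)
            y = rng.uniform(-1, 1, 40)
            expected_eps, expected_psi = brute_force_pair_distance(x, y, n_grid=200_000)
            eps, psi_hat = pair_sine_distance(x, y)
            assert eps == pytest.approx(expected_eps, rel=1e-6)
            assert psi_hat == pytest.approx(expected_psi, abs=1e-4)

    def test_symmetry_exact(self, rng):
        x = rng.uniform(-1, 1, 60)
        y = rng.uniform(-1, 1, 60)
        assert pair_sine_distance(x, y) == pair_sine_distance(y, x)

    def test_half_period_psi_range_suffices(self, rng):
        # the objective depends on psi only through cos(psi): scanning
        # [0, 2*pi) directly never beats the [0, pi] minimum
        x = rng.uniform(-1, 1, 30)
        y = rng.uniform(-1, 1, 30)
        eps, _ = pair_sine_distance(x, y)
        psi = np.linspace(0, 2 * np.pi, 20001)
        c = np.cos(psi)
        r = (
            x[:, None] ** 2 + y[:, None] ** 2
            - 2 * x[:, None] * y[:, None] * c[None, :]
            - np.sin(psi)[None, :] ** 2
        )
        full_scan = (r**2).sum(axis=0).min() / x.size
        assert eps <= full_scan + 1e-12

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pair_sine_distance(np.zeros(5), np.zeros(6))

    def test_all_pairs_agrees_with_single_pair(self, rng):
        R = rescale_matrix(rng.random((6, 40)), [f"g{i}" for i in range(6)])
        table = all_pair_statistics(R)
        assert len(table) == 15
        for row in table.itertuples(index=False):
            i = R.gene_ids.index(row.gene_i)
            j = R.gene_ids.index(row.gene_j)
            eps, psi_hat = pair_sine_distance(R.values[i], R.values[j])
            assert row.epsilon == pytest.approx(eps, rel=1e-9, abs=1e-12)
            assert row.psi_hat == pytest.approx(psi_hat, abs=1e-6)


class TestPermutationNull:
    def test_zero_permutations_rejected(self, rng):
        R = rescale_matrix(rng.random((4, 30)), list("abcd"))
        with pytest.raises(ValueError):
            permutation_null(R, n_perm=0)

    def test_single_gene_rejected(self, rng):
        values = np.vstack([rng.random(30), rng.random(30)])
        R = rescale_matrix(values[:1], ["a"])
        with pytest.raises(ValueError):
            permutation_null(R, n_perm=10)

    def test_seeded_determinism(self, rng):
        R = rescale_matrix(rng.random((6, 40)), [f"g{i}" for i in range(6)])
        n1 = permutation_null(R, n_perm=50, seed=7)
        n2 = permutation_null(R, n_perm=50, seed=7)
        assert np.array_equal(n1, n2)
        assert not np.array_equal(n1, permutation_null(R, n_perm=50, seed=8))

    def test_null_pvalues_roughly_uniform_on_pure_noise(self):
        # on i.i.d. noise the observed epsilons are themselves null draws,
        # so their empirical p-values should look Uniform(0,1)
        from scipy.stats import kstwobign

        reps, passed = 10, 0
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            R = rescale_matrix(rng.normal(size=(20, 120)), [f"g{i:02d}" for i in range(20)])
            table = all_pair_statistics(R)
            null = permutation_null(R, n_perm=400, seed=seed)
            p = pair_pvalue(table["epsilon"].to_numpy(), null)
            n = p.size
            u = np.sort(p)
            d = np.max(np.abs(u - np.arange(1, n + 1) / n))
            passed += d < kstwobign.ppf(0.99) / np.sqrt(n)
        assert passed >= 9


class TestPairPvalue:
    def test_best_possible_p_with_99_nulls(self):
        null = np.linspace(0.1, 1.0, 99)
        assert pair_pvalue(0.0, null) == pytest.approx(1 / 100)

    def test_worst_case_p_is_one(self):
        null = np.linspace(0.1, 1.0, 99)
        assert pair_pvalue(2.0, null) == pytest.approx(1.0)

    def test_median_epsilon_gives_half(self, rng):
        null = rng.random(999)
        p = pair_pvalue(np.median(null), null)
        assert abs(p - 0.5) <= 1 / 1000 + 1e-12

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            pair_pvalue(0.5, np.array([]))


class TestBHAdjust:
    def test_step_up_formula(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=60))
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, rtol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=40))
    def test_rank_monotone(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestNetworkAndCommunities:
    def _table(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)

    def test_no_significant_pairs_edgeless(self):
        t = self._table([["a", "b", 0.5, 0.1, 0.9, 0.9], ["a", "c", 0.4, 0.2, 0.8, 0.9]])
        g = build_network(t, alpha=0.05)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"a", "b", "c"}

    def test_alpha_one_gives_complete_graph(self):
        rows = [
            ["a", "b", 0.5, 0.1, 0.9, 0.9],
            ["a", "c", 0.4, 0.2, 0.8, 0.9],
            ["b", "c", 0.3, 0.3, 0.7, 0.9],
        ]
        g = build_network(self._table(rows), alpha=1.0)
        assert g.number_of_edges() == 3

    def test_triangle_plus_isolate(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_node("d")
        comms = extract_communities(g)
        assert [set(c.genes) for c in comms] == [{"a", "b", "c"}]

    def test_edgeless_network_yields_nothing(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert extract_communities(g) == []

    def test_two_disjoint_cliques_are_two_communities(self):
        g = nx.compose(
            nx.complete_graph([f"x{i}" for i in range(5)]),
            nx.complete_graph([f"y{i}" for i in range(5)]),
        )
        comms = extract_communities(g)
        assert len(comms) == 2
        assert {frozenset(c.genes) for c in comms} == {
            frozenset(f"x{i}" for i in range(5)),
            frozenset(f"y{i}" for i in range(5)),
        }

    def test_planted_two_group_network_separates_groups(self):
        # two noise-free planted groups at different frequencies: every
        # within-group pair is a significant edge, cross-group edges stay
        # within the FDR budget, and the communities recover the groups
        spec = SyntheticMatrixSpec(
            n_cells=400,
            groups=[
                OscillatorGroupSpec(n_genes=6, relative_frequency=1.0),
                OscillatorGroupSpec(n_genes=6, relative_frequency=2.0),
            ],
            n_noise_genes=0,
            noise_sd=0.0,
            dropout_rate=0.0,
            seed=17,
        )
        matrix, truth = generate_cosc_matrix(spec)
        genes = sorted(matrix.gene_ids)
        R = rescale_matrix(matrix.submatrix(genes, "c0"), genes)
        table = all_pair_statistics(R)
        null = permutation_null(R, n_perm=500, seed=17)
        table["p_value"] = pair_pvalue(table["epsilon"].to_numpy(), null)
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        g = build_network(table, alpha=0.05)
        group_of = truth.genes["group"]
        within = [e for e in g.edges if group_of[e[0]] == group_of[e[1]]]
        across = [e for e in g.edges if group_of[e[0]] != group_of[e[1]]]
        assert len(within) == 2 * (6 * 5 // 2)  # every within-group pair
        assert len(across) <= 0.05 * g.number_of_edges() + 1
        comms = extract_communities(g)
        expected = {
            frozenset(truth.genes.index[truth.genes["group"] == k]) for k in (0, 1)
        }
        assert {c.genes for c in comms} == expected


class TestInferOscillators:
    def test_pipeline_monotonicity(self):
        matrix, _ = generate_cosc_matrix(SyntheticMatrixSpec(seed=2))
        call = infer_oscillators(matrix, "c0", PipelineConfig(seed=2))
        from sinecell import filter_cascade

        expressed, variable, _ = filter_cascade(matrix, "c0")
        assert call.oscillators <= set(variable) <= set(expressed)
        assert call.report.n_oscillators == len(call.oscillators)
        assert call.oscillators == (
            set().union(*(c.genes for c in call.communities)) if call.communities else set()
        )

    def test_too_few_cells_rejected(self):
        matrix, _ = generate_cosc_matrix(SyntheticMatrixSpec(n_cells=10, seed=2))
        with pytest.raises(ValueError):
            infer_oscillators(matrix, "c0", PipelineConfig(min_cells=20))

    def test_empty_call_when_filters_remove_everything(self):
        matrix, _ = generate_cosc_matrix(
            SyntheticMatrixSpec(dropout_rate=0.6, seed=2)
        )
        with pytest.warns(UserWarning, match="fewer than 2 genes"):
            call = infer_oscillators(matrix, "c0", PipelineConfig(seed=2))
        assert call.oscillators == set()
        assert call.report.n_oscillators == 0

    def test_deterministic_given_seed(self):
        matrix, _ = generate_cosc_matrix(SyntheticMatrixSpec(seed=4))
        c1 = infer_oscillators(matrix, "c0", PipelineConfig(seed=9))
        c2 = infer_oscillators(matrix, "c0", PipelineConfig(seed=9))
        assert c1.oscillators == c2.oscillators
        assert c1.pair_table.equals(c2.pair_table)
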