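import json

import numpy as np
import pytest
from scipy.stats import binom, chi2

from transmitbias import (
    BiasParameters,
    Content,
    CountTable,
    ExperimentDesign,
    Order,
    Source,
    TableLayout,
    TransmissionContext,
    simulate_counts_batch,
    simulate_experiment,
    simulate_participant,
)
from transmitbias.simulator import cell_rng, counterbalanced_assignments

E2N = TransmissionContext.EXPERT_TO_NOVICE
P2P = TransmissionContext.PEER_TO_PEER


class TestCountTable:
    def test_four_cell_accessors(self):
        t = CountTable.from_four_counts(27, 3, 14, 18)
        assert t.expert_count(E2N) == 27
        assert t.context_total(E2N) == 30
        assert t.context_total(P2P) == 32
        assert t.source_totals() == (41, 21)

    def test_rejects_negative_and_misshaped_cells(self):
        with pytest.raises(ValueError):
            CountTable(TableLayout.FOUR_CELL, np.array([[1, -1], [0, 0]]))
        with pytest.raises(ValueError):
            CountTable(TableLayout.EIGHT_CELL, np.zeros((2, 2)))

    def test_json_round_trip_uses_named_schema(self, tmp_path):
        t = CountTable.from_four_counts(27, 3, 14, 18)
        path = tmp_path / "counts.json"
        t.to_json(path)
        data = json.loads(path.read_text())
        assert data == {
            "e2n": {"expert": 27, "peer": 3},
            "p2p": {"expert": 14, "peer": 18},
        }
        assert CountTable.from_json(path) == t

    def test_csv_round_trip_both_layouts(self, tmp_path):
        four = CountTable.from_four_counts(5, 1, 2, 4)
        eight = CountTable(
            TableLayout.EIGHT_CELL, np.arange(8).reshape(2, 2, 2)
        )
        for i, table in enumerate((four, eight)):
            path = tmp_path / f"t{i}.csv"
            table.to_csv(path)
            assert CountTable.from_csv(path) == table

    def test_eight_cell_marginalizes_to_four(self):
        eight = CountTable(TableLayout.EIGHT_CELL, np.arange(8).reshape(2, 2, 2))
        four = eight.as_four_cell()
        assert four.layout is TableLayout.FOUR_CELL
        assert four.cells.tolist() == [[1, 5], [9, 13]]


class TestExperimentDesign:
    def test_defaults_are_post_exclusion_cohort(self):
        design = ExperimentDesign()
        assert (design.n_e2n, design.n_p2p) == (30, 32)

    @pytest.mark.parametrize("n, expected", [(30, (15, 15)), (31, (16, 15)), (0, (0, 0))])
    def test_order_split_puts_extra_participant_first(self, n, expected):
        assert ExperimentDesign(n, n).order_split(E2N) == expected

    def test_rejects_negative_sizes(self):
        with pytest.raises(ValueError):
            ExperimentDesign(-1, 32)


class TestSimulateParticipant:
    def test_deterministic_limits(self):
        rng = np.random.default_rng(0)
        pair = counterbalanced_assignments(1, E2N, ExperimentDesign(1, 1))[0]
        for _ in range(20):
            assert (
                simulate_participant(BiasParameters(1, 0, 0), E2N, pair, rng).source
                is Source.EXPERT
            )
            assert (
                simulate_participant(BiasParameters(-1, 0, 0), P2P, pair, rng).source
                is Source.PEER
            )

    def test_unbiased_draws_concentrate_at_half(self):
        rng = np.random.default_rng(7)
        pair = counterbalanced_assignments(1, E2N, ExperimentDesign(1, 1))[0]
        n = 10_000
        frac = (
            sum(
                simulate_participant(BiasParameters(0, 0, 0), E2N, pair, rng).source
                is Source.EXPERT
                for _ in range(n)
            )
            / n
        )
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)


class TestSimulateExperiment:
    def test_deterministic_limit_table(self):
        table = simulate_experiment(
            BiasParameters(1, 0, 0), ExperimentDesign(30, 32), rng=0
        )
        assert table.cells.tolist() == [[30, 0], [32, 0]]

    def test_per_context_counts_conserved(self):
        for seed, params in enumerate(
            [BiasParameters(0.3, -0.5, 0.2), BiasParameters(-0.8, 0.9, 0)]
        ):
            for layout in TableLayout:
                table = simulate_experiment(params, ExperimentDesign(9, 12), layout, seed)
                assert table.context_total(E2N) == 9
                assert table.context_total(P2P) == 12

    def test_seed_contract(self):
        a = simulate_experiment(BiasParameters(0.2, 0.4, -0.1), ExperimentDesign(), rng=42)
        b = simulate_experiment(BiasParameters(0.2, 0.4, -0.1), ExperimentDesign(), rng=42)
        assert a == b

    def test_unbiased_mean_table_near_half_per_condition(self):
        # binomial-law batch: 5000 replicates of the unbiased experiment
        sims = simulate_counts_batch(
            [BiasParameters(0, 0, 0)], ExperimentDesign(30, 32), 5000, seed=11
        )[0]
        mean = sims.mean(axis=0)
        se = 3 * np.sqrt(np.array([[30, 30], [32, 32]]) * 0.25 / 5000)
        assert np.all(np.abs(mean - [[15, 15], [16, 16]]) <= se)


class TestSimulateCountsBatch:
    def test_single_sim_replays_participant_simulation(self):
        params = BiasParameters(0.4, -0.2, 0.3)
        design = ExperimentDesign(7, 8)
        batch = simulate_counts_batch(
            [params], design, 1, TableLayout.EIGHT_CELL, seed=5, method="participant"
        )
        direct = simulate_experiment(params, design, TableLayout.EIGHT_CELL, cell_rng(5, 0))
        assert np.array_equal(batch[0, 0], direct.cells)

    def test_degenerate_parameters_give_constant_tables(self):
        sims = simulate_counts_batch(
            [BiasParameters(1, 0, 0)], ExperimentDesign(30, 32), 50, seed=0
        )[0]
        assert np.all(sims == np.array([[30, 0], [32, 0]]))

    def test_chunk_offset_reproduces_whole_batch(self):
        cells = [BiasParameters(e, c) for e in (-0.5, 0, 0.5) for c in (-0.4, 0.6)]
        design = ExperimentDesign(10, 12)
        whole = simulate_counts_batch(cells, design, 100, seed=3)
        parts = np.concatenate(
            [
                simulate_counts_batch(cells[i : i + 2], design, 100, seed=3, cell_offset=i)
                for i in range(0, 6, 2)
            ]
        )
        assert np.array_equal(whole, parts)

    def test_exact_count_frequency_matches_binomial_pmf(self):
        sims = simulate_counts_batch(
            [BiasParameters(0, 0, 0)], ExperimentDesign(30, 32), 5000, seed=2
        )[0]
        freq = float(np.mean(sims[:, 0, 0] == 27))
        p = binom.pmf(27, 30, 0.5)
        assert abs(freq - p) <= 3 * np.sqrt(p * (1 - p) / 5000)

    def test_participant_and_binomial_methods_agree_in_distribution(self):
        """Chi-squared homogeneity of E2N expert-count histograms, both methods."""
        params = BiasParameters(0.4, 0.5, 0)
        design = ExperimentDesign(30, 32)
        S = 5000
        by_participant = simulate_counts_batch(
            [params], design, S, seed=21, method="participant"
        )[0, :, 0, 0]
        by_binomial = simulate_counts_batch(
            [params], design, S, seed=22, method="binomial"
        )[0, :, 0, 0]
        edges = [0, 24, 26, 27, 28, 29, 31]  # pools sparse tails
        h1, _ = np.histogram(by_participant, bins=edges)
        h2, _ = np.histogram(by_binomial, bins=edges)
        keep = (h1 + h2) > 0
        h1, h2 = h1[keep], h2[keep]
        expected = (h1 + h2) / 2
        stat = float((((h1 - expected) ** 2) / expected + ((h2 - expected) ** 2) / expected).sum())
        assert chi2.sf(stat, keep.sum() - 1) > 1e-3

    def test_eight_cell_strata_are_consistent(self):
        design = ExperimentDesign(9, 12)  # odd E2N: strata 5 + 4
        sims = simulate_counts_batch(
            [BiasParameters(0.3, 0.2, 0.6)], design, 200, TableLayout.EIGHT_CELL, seed=9
        )[0]
        # (expert, first) + (peer, last) = expert-first stratum size
        assert np.all(sims[:, 0, 0, 0] + sims[:, 0, 1, 1] == 5)
        assert np.all(sims[:, 0, 0, 1] + sims[:, 0, 1, 0] == 4)
        assert np.all(sims[:, 1].sum(axis=(1, 2)) == 12)


def test_counterbalanced_assignments_are_opposite_pairs():
    design = ExperimentDesign(9, 12)
    pairs = counterbalanced_assignments(9, E2N, design)
    assert len(pairs) == 9
    assert all(expert.is_opposite_of(peer) for expert, peer in pairs)
    n_first = sum(expert.order is Order.FIRST for expert, _ in pairs)
    assert n_first == 5
    contents = {expert.content for expert, _ in pairs}
    assert contents == {Content.PARITY, Content.SKIPPING}
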