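import numpy as np
import pytest

from cycletx import (
    Cell,
    CycleRule,
    TranscriptionParams,
    divide,
    make_founders,
    make_uniform_genome,
    partition_transcripts,
    proportions_over_time,
    run_asynchronous,
    run_mixed_lineage_scenario,
    run_synchronous,
    sample_one_division,
    transcribe,
)
from cycletx.lineage import SCENARIOS


@pytest.fixture
def small_genome():
    return make_uniform_genome(5, 1, 2)


@pytest.fixture
def params():
    return TranscriptionParams()


class TestPartitioning:
    def test_empty_parent_gives_empty_children(self, rng):
        c1, c2 = partition_transcripts(np.zeros(3, dtype=int), rng)
        assert not c1.any() and not c2.any()

    def test_per_gene_conservation(self, rng):
        parent = rng.integers(0, 50, size=8)
        c1, c2 = partition_transcripts(parent, rng)
        np.testing.assert_array_equal(c1 + c2, parent)
        assert (c1 >= 0).all() and (c2 >= 0).all()

    def test_all_in_one_child_probability(self):
        """With N=5 transcripts, P(one child gets all) = 2 * (1/2)^5 = 0.0625;
        a 1e5-trial Monte Carlo estimate must fall within 3 standard errors."""
        n_trials = 100_000
        rng = np.random.default_rng(7)
        parent = np.array([3, 1, 1])
        pool = np.broadcast_to(parent, (n_trials, 3))
        c1 = rng.binomial(pool, 0.5)
        totals = c1.sum(axis=1)
        frac = np.mean((totals == 0) | (totals == parent.sum()))
        p = 2 * 0.5 ** parent.sum()
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(frac - p) < 3 * se


class TestDivide:
    def make_cell(self, genome, gamma=1.0, tx=None):
        tx = np.zeros(genome.n_genes, dtype=int) if tx is None else np.asarray(tx)
        return Cell(0, None, 0, gamma, 0.0, tx, "founder", phase_time=gamma)

    def test_constant_rule_preserves_gamma(self, small_genome, params, rng):
        cell = self.make_cell(small_genome, gamma=1.0)
        c1, c2 = divide(cell, small_genome, params, CycleRule("constant"), rng)
        assert c1.gamma == c2.gamma == 1.0
        assert c1.generation == c2.generation == 1
        assert c1.birth_time == c2.birth_time == 1.0

    def test_children_share_parent_pool_exactly(self, small_genome, params, rng):
        """Base model: divisible pool is exactly the parent's new transcription."""
        cell = self.make_cell(small_genome, gamma=2.0, tx=[9, 9, 9, 9, 9])
        c1, c2 = divide(cell, small_genome, params, CycleRule("inherit"), rng)
        np.testing.assert_array_equal(
            c1.transcriptome + c2.transcriptome, transcribe(small_genome, 2.0, params)
        )

    def test_retention_adds_surviving_inherited_share(self, small_genome, rng):
        full = TranscriptionParams(parental_retention=1.0)
        cell = self.make_cell(small_genome, gamma=2.0, tx=[4, 0, 0, 0, 0])
        c1, c2 = divide(cell, small_genome, full, CycleRule("inherit"), rng)
        expected = transcribe(small_genome, 2.0, full) + [4, 0, 0, 0, 0]
        np.testing.assert_array_equal(c1.transcriptome + c2.transcriptome, expected)

    def test_asymmetric_fast_cell_splits_fast_slow(self, small_genome, params, rng):
        rule = CycleRule("asymmetric", fast_gamma=1.0, slow_gamma=2.0)
        fast = self.make_cell(small_genome, gamma=1.0)
        gammas = sorted([c.gamma for c in divide(fast, small_genome, params, rule, rng)])
        assert gammas == [1.0, 2.0]
        slow = self.make_cell(small_genome, gamma=2.0)
        gammas = [c.gamma for c in divide(slow, small_genome, params, rule, rng)]
        assert gammas == [2.0, 2.0]

    def test_gaussian_rule_with_zero_sigma_is_exact_increment(
        self, small_genome, params, rng
    ):
        rule = CycleRule("gaussian_increment", delta_mean=0.5, sigma=0.0)
        cell = self.make_cell(small_genome, gamma=1.0)
        c1, c2 = divide(cell, small_genome, params, rule, rng)
        assert c1.gamma == c2.gamma == 1.5

    def test_gaussian_draws_truncated_at_floor(self, small_genome, params):
        rule = CycleRule("gaussian_increment", delta_mean=-5.0, sigma=0.01,
                         gamma_min=0.25)
        cell = self.make_cell(small_genome, gamma=1.0)
        c1, c2 = divide(cell, small_genome, params, rule, np.random.default_rng(0))
        assert c1.gamma >= 0.25 and c2.gamma >= 0.25

    def test_division_before_cycle_completion_is_an_error(
        self, small_genome, params, rng
    ):
        cell = Cell(0, None, 0, 2.0, 0.0, np.zeros(5, dtype=int), phase_time=1.0)
        with pytest.raises(RuntimeError, match="cannot divide"):
            divide(cell, small_genome, params, CycleRule("inherit"), rng)


class TestSynchronousRuns:
    def test_zero_divisions_returns_founders(self, small_genome, params, rng):
        pop = run_synchronous(
            small_genome, params, make_founders(small_genome, [1.0]),
            CycleRule("inherit"), 0, rng,
        )
        assert pop.n_live == pop.n_total == 1

    def test_binary_tree_growth(self, small_genome, params, rng):
        pop = run_synchronous(
            small_genome, params, make_founders(small_genome, [1.0]),
            CycleRule("inherit"), 3, rng,
        )
        assert pop.n_live == 8
        assert pop.n_total == 15
        assert len(pop.division_log()) == 7

    def test_mixed_founder_gammas_rejected(self, small_genome, params, rng):
        founders = make_founders(small_genome, [1.0, 2.0])
        with pytest.raises(ValueError, match="common cycle duration"):
            run_synchronous(small_genome, params, founders, CycleRule("inherit"), 1, rng)

    def test_negative_divisions_rejected(self, small_genome, params, rng):
        with pytest.raises(ValueError):
            run_synchronous(small_genome, params, make_founders(small_genome, [1.0]),
                            CycleRule("inherit"), -1, rng)

    def test_transcript_conservation_one_round(self, small_genome, params, rng):
        """After one round the two daughters' shares sum to the parent pool."""
        pop = run_synchronous(
            small_genome, params, make_founders(small_genome, [2.0]),
            CycleRule("inherit"), 1, rng,
        )
        np.testing.assert_array_equal(
            pop.counts.sum(axis=0), transcribe(small_genome, 2.0, params)
        )

    def test_empty_transcriptomes_are_preserved(self, small_genome, params, rng):
        """Cells that received no transcripts remain in the population."""
        pop = run_synchronous(
            small_genome, params, make_founders(small_genome, [1.0]),
            CycleRule("inherit"), 4, rng,
        )
        assert pop.n_live == 16
        assert (pop.counts.sum(axis=1) == 0).any()

    def test_identical_seeds_give_identical_populations(self, small_genome, params):
        pops = [
            run_synchronous(
                small_genome, params, make_founders(small_genome, [1.5]),
                CycleRule("gaussian_increment"), 5, np.random.default_rng(99),
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(pops[0].counts, pops[1].counts)
        np.testing.assert_array_equal(pops[0].gamma, pops[1].gamma)
        np.testing.assert_array_equal(pops[0].birth_time, pops[1].birth_time)


class TestAsynchronousRuns:
    @pytest.mark.parametrize("gamma, t, expected_cells", [
        (1.0, 10.0, 1024),   # 10 division rounds
        (10.0, 10.0, 2),     # a single division
        (2.0, 5.0, 4),       # floor(5/2) = 2 rounds
    ])
    def test_constant_gamma_floor_contract(self, small_genome, params, gamma, t,
                                           expected_cells):
        pop = run_asynchronous(
            small_genome, params, make_founders(small_genome, [gamma]),
            CycleRule("inherit"), t, np.random.default_rng(3),
        )
        assert pop.n_live == expected_cells

    def test_zero_time_leaves_founders_untouched(self, small_genome, params, rng):
        founders = make_founders(small_genome, [1.0, 2.0])
        pop = run_asynchronous(small_genome, params, founders, CycleRule("inherit"),
                               0.0, rng)
        assert pop.n_live == 2 and pop.n_total == 2

    def test_min_gamma_stepping_matches_event_driven(self, small_genome, params):
        """The literal minimum-duration time-stepping mode produces the same
        population as the event-driven engine under the same seed."""
        pops = [
            run_asynchronous(
                small_genome, params, make_founders(small_genome, [1.0, 1.7]),
                CycleRule("inherit"), 6.0, np.random.default_rng(11), stepping=mode,
            )
            for mode in ("event", "min_gamma")
        ]
        np.testing.assert_array_equal(pops[0].cell_id, pops[1].cell_id)
        np.testing.assert_array_equal(pops[0].birth_time, pops[1].birth_time)
        np.testing.assert_array_equal(pops[0].counts, pops[1].counts)


class TestScenarios:
    def test_unknown_scenario_rejected(self, small_genome, params, rng):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_mixed_lineage_scenario("bogus", 1, 1, small_genome, params, 3, rng)

    def test_fast_fast_even_split(self, small_genome, params, rng):
        pop, summary = run_mixed_lineage_scenario(
            "fast_fast", 1.0, 1.0, small_genome, params, 6, rng
        )
        assert pop.n_live == 2 * 2**6
        assert summary["proportion"].tolist() == [0.5, 0.5]

    def test_heritable_slow_lineage_falls_behind(self, small_genome, params, rng):
        pop, summary = run_mixed_lineage_scenario(
            "slow_fast_heritable", 1.0, 1.5, small_genome, params, 6, rng
        )
        by_label = summary.set_index("lineage_label")["n_cells"]
        assert by_label["fast"] == 2**6
        assert by_label["slow"] == 2 ** (6 * 1.0 // 1.5)
        assert by_label["slow"] < by_label["fast"]

    def test_asymmetric_single_fast_cell_every_generation(self, small_genome, params,
                                                          rng):
        pop, summary = run_mixed_lineage_scenario(
            "slow_fast_asymmetric", 1.0, 2.0, small_genome, params, 10, rng
        )
        fast = pop.gamma == 1.0
        # one founding fast cell -> exactly one fast cell in every generation
        for gen in np.unique(pop.generation[fast]):
            assert (fast & (pop.generation == gen)).sum() == 1
        live_idx = np.searchsorted(pop.cell_id, pop.live_ids)
        assert (pop.gamma[live_idx] == 1.0).sum() == 1

    def test_slower_lineage_contributes_more_diversity(self, small_genome, params):
        """The slow lineage holds fewer cells but more distinct transcriptomes."""
        pop, summary = run_mixed_lineage_scenario(
            "slow_fast_heritable", 1.0, 2.0, small_genome, params, 8,
            np.random.default_rng(5),
        )
        s = summary.set_index("lineage_label")
        assert s.loc["slow", "n_cells"] < s.loc["fast", "n_cells"]
        assert s.loc["slow", "transcriptome_diversity"] > s.loc[
            "fast", "transcriptome_diversity"]


class TestProportionsOverTime:
    def test_single_founder_is_always_proportion_one(self, small_genome, params, rng):
        pop = run_synchronous(
            small_genome, params, make_founders(small_genome, [1.0]),
            CycleRule("inherit"), 3, rng,
        )
        table = proportions_over_time(pop)
        assert (table["proportion"] == 1.0).all()

    def test_proportions_sum_to_one_per_timepoint(self, small_genome, params, rng):
        pop, _ = run_mixed_lineage_scenario(
            "slow_fast_heritable", 1.0, 1.5, small_genome, params, 5, rng
        )
        table = proportions_over_time(pop, by="time", class_by="label", n_points=10)
        sums = table.groupby("time_hr")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_gaussian_drift_fastest_class_shrinks(self, params):
        """With upward cycle-duration drift, the fastest duration class loses
        population share generation over generation (averaged replicates)."""
        genome = make_uniform_genome(10, 1, 10)
        rule = CycleRule("gaussian_increment", delta_mean=0.1, sigma=0.06)
        n_reps, divisions = 10, 6
        acc = np.zeros(divisions + 1)
        for rep in range(n_reps):
            pop = run_synchronous(
                genome, params, make_founders(genome, [1.0]), rule, divisions,
                np.random.default_rng(rep), compute_transcriptomes=False,
            )
            table = proportions_over_time(pop, class_by="gamma",
                                          bin_edges=[1.2, 1.45, 1.7])
            fastest = table[table["class"].str.startswith("gamma[-inf")]
            for _, row in fastest.iterrows():
                acc[int(row["generation"])] += row["proportion"] / n_reps
        # averaged replicates: share never rises appreciably, and collapses
        assert np.all(np.diff(acc[1:]) <= 0.02)
        assert acc[-1] < 0.2 * acc[1]


def test_one_division_sampler_interleaves_sibling_pairs():
    genome = make_uniform_genome(3, 1, 3)
    params = TranscriptionParams(serial_mode=True)
    X = sample_one_division(genome, 3.0, params, 50, np.random.default_rng(0))
    assert X.shape == (100, 3)
    parent = transcribe(genome, 3.0, params)
    np.testing.assert_array_equal(X[0::2] + X[1::2], np.broadcast_to(parent, (50, 3)))
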