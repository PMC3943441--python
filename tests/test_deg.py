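"""Pooling and the no-replicate M-D differential-expression caller."""

import numpy as np
import pandas as pd
import pytest

from chordaseq import deg, simdata
from chordaseq.errors import ConfigError, InputFormatError


@pytest.fixture()
def small_counts(nine_library_design):
    counts, _ = simdata.simulate_count_matrix(
        100, 150.0, [simdata.DEGene("gene0001", "T1-vs-T3", 8.0)], seed=42)
    return counts


class TestPool:
    def test_stage_pool_sums_the_three_segments(self, nine_library_design):
        m = pd.DataFrame({f"{t}{s}": [1.0 * i] for i, (t, s) in enumerate(
            [(t, s) for t in ("T1", "T2", "T3") for s in "AMP"])}, index=["g"])
        pools = deg.pool(m, nine_library_design, "stage")
        assert pools.loc["g", "sumT1"] == pytest.approx(0 + 1 + 2)
        assert pools.loc["g", "sumT3"] == pytest.approx(6 + 7 + 8)

    def test_both_axes_conserve_the_grand_total(self, small_counts,
                                                nine_library_design):
        by_stage = deg.pool(small_counts, nine_library_design, "stage")
        by_segment = deg.pool(small_counts, nine_library_design, "segment")
        assert by_stage.to_numpy().sum() == pytest.approx(
            by_segment.to_numpy().sum())
        assert by_stage.to_numpy().sum() == pytest.approx(
            small_counts.to_numpy().sum())

    def test_empty_gene_row_pools_to_zero(self, nine_library_design):
        m = pd.DataFrame(0.0, index=["g"],
                         columns=nine_library_design["library"])
        assert (deg.pool(m, nine_library_design, "stage") == 0).all().all()

    def test_missing_library_is_an_error(self, nine_library_design):
        m = pd.DataFrame({lib: [1.0] for lib in ["T1A", "T1M"]}, index=["g"])
        with pytest.raises(InputFormatError):
            deg.pool(m, nine_library_design, "stage")

    def test_unknown_axis_is_a_config_error(self, small_counts, nine_library_design):
        with pytest.raises(ConfigError):
            deg.pool(small_counts, nine_library_design, "time")


class TestTechnicalReplicates:
    def test_degenerate_multinomial_puts_all_mass_on_one_gene(self):
        counts = pd.Series({"g1": 1000.0, "g2": 0.0})
        reps = deg.simulate_technical_replicates(
            counts, nss=4, pnr=1.0, v=0.0, rng=np.random.default_rng(0))
        assert (reps[0, :] == 1000).all()
        assert (reps[1, :] == 0).all()

    def test_seeded_runs_identical(self):
        counts = pd.Series(np.arange(1.0, 21.0))
        a = deg.simulate_technical_replicates(counts, 5, 0.2, 0.02,
                                              np.random.default_rng(3))
        b = deg.simulate_technical_replicates(counts, 5, 0.2, 0.02,
                                              np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_replicate_sizes_near_pnr_total(self):
        counts = pd.Series(np.full(50, 100.0))
        total = counts.sum()
        reps = deg.simulate_technical_replicates(counts, 10, 0.2, 0.02,
                                                 np.random.default_rng(1))
        sizes = reps.sum(axis=0)
        assert np.all(np.abs(sizes - 0.2 * total) <= 0.02 * 0.2 * total + 1)

    def test_invalid_pnr_rejected(self):
        with pytest.raises(ConfigError):
            deg.simulate_technical_replicates(pd.Series([1.0]), 5, 0.0, 0.02,
                                              np.random.default_rng(0))

    def test_empty_pool_rejected(self):
        with pytest.raises(ConfigError):
            deg.simulate_technical_replicates(pd.Series([0.0]), 5, 0.2, 0.02,
                                              np.random.default_rng(0))


class TestDeProbability:
    def test_identical_conditions_give_zero_probability_for_flat_gene(self):
        # one perfectly flat gene among noisy ones: M = D = 0 => p = 0
        rng = np.random.default_rng(5)
        base = rng.poisson(300.0, size=50).astype(float)
        pools = pd.DataFrame({"sumT1": base, "sumT2": base},
                             index=[f"g{i}" for i in range(50)])
        table = deg.de_probability(pools, "sumT1", "sumT2", seed=1)
        flat = table[(table["M"] == 0) & (table["D"] == 0)]
        assert (flat["prob"] == 0).all()

    def test_probability_invariant_under_label_exchange(self, small_counts,
                                                        nine_library_design):
        pools = deg.pool(small_counts, nine_library_design, "stage")
        fwd = deg.de_probability(pools, "sumT1", "sumT3", seed=7)
        rev = deg.de_probability(pools, "sumT3", "sumT1", seed=7)
        assert np.allclose(fwd["prob"], rev["prob"], equal_nan=True)
        assert np.allclose(fwd["M"], -rev["M"])
        strong = fwd[fwd["de"]]
        flipped = rev.loc[strong.index]
        assert ((strong["direction"] == "up") == (flipped["direction"] == "down")).all()

    def test_planted_eightfold_gene_called(self, small_counts, nine_library_design):
        pools = deg.pool(small_counts, nine_library_design, "stage")
        table = deg.de_probability(pools, "sumT1", "sumT3", seed=3)
        rec = table.loc["gene0001"]
        assert rec["de"]
        assert rec["direction"] == "up"
        assert rec["fold_change"] == pytest.approx(8.0, rel=0.35)

    def test_zero_in_both_conditions_is_skipped(self, nine_library_design):
        pools = pd.DataFrame({"sumT1": [0.0, 100.0, 120.0],
                              "sumT3": [0.0, 110.0, 100.0]},
                             index=["dead", "g1", "g2"])
        table = deg.de_probability(pools, "sumT1", "sumT3", seed=1)
        assert np.isnan(table.loc["dead", "prob"])
        assert not table.loc["dead", "de"]

    def test_direction_consistent_with_sign_of_m(self, small_counts,
                                                 nine_library_design):
        pools = deg.pool(small_counts, nine_library_design, "stage")
        table = deg.de_probability(pools, "sumT1", "sumT3", seed=3)
        assert ((table["M"] >= 0) == (table["direction"] == "up")).all()
        assert np.allclose(table["fold_change"], np.exp2(table["M"].abs()))


class TestPairwiseDeg:
    def test_all_null_input_gives_empty_venn(self, nine_library_design):
        counts, _ = simdata.simulate_count_matrix(60, 200.0, [], seed=9)
        pools = deg.pool(counts, nine_library_design, "stage")
        table, summary = deg.pairwise_deg(pools, q=0.99, seed=2)
        assert sum(summary["venn"].values()) == len(
            set(table["gene_id"])) if len(table) else True
        # up + down = total for every comparison
        for comp, d in summary["per_comparison"].items():
            assert d["up"] + d["down"] == d["total"]

    def test_disjoint_planted_sets_have_empty_intersections(self,
                                                            nine_library_design):
        de = ([simdata.DEGene(f"gene{i + 1:04d}", "T1-vs-T2", 10.0)
               for i in range(5)] +
              [simdata.DEGene(f"gene{i + 11:04d}", "T2-vs-T3", 0.1)
               for i in range(5)])
        counts, _ = simdata.simulate_count_matrix(120, 300.0, de, seed=21)
        pools = deg.pool(counts, nine_library_design, "stage")
        table, summary = deg.pairwise_deg(pools, q=0.8, seed=4)
        t12 = set(table.loc[table["comparison"] == "sumT1-vs-sumT2", "gene_id"])
        planted_12 = {f"gene{i + 1:04d}" for i in range(5)}
        assert planted_12 <= t12

    def test_deg_count_non_increasing_in_q(self, small_counts, nine_library_design):
        pools = deg.pool(small_counts, nine_library_design, "stage")
        table = deg.de_probability(pools, "sumT1", "sumT3", seed=5)
        counts = [int((table["prob"] > q).sum())
                  for q in (0.5, 0.6, 0.7, 0.8, 0.9, 0.95)]
        assert counts == sorted(counts, reverse=True)
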