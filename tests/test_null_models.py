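from fractions import Fraction

import numpy as np
import pytest

from menzerath import (
    generate_pseudo_sequence,
    production_constraint_null,
    shuffle_null,
    simulate_call_table,
    trained_crow_preset,
)
from menzerath.null_models import empirical_p

from conftest import make_table


@pytest.fixture(scope="module")
def medium_table():
    cfg = trained_crow_preset(beta1=-0.3, beta2=0.02, sequences_per_individual=60, seed=31)
    return simulate_call_table(cfg)


class TestEmpiricalP:
    def test_correction_and_bounds(self):
        nulls = np.array([-0.1, 0.05, 0.2, -0.3])
        assert empirical_p(nulls, 0.25) == pytest.approx(2 / 5)
        assert empirical_p(nulls, 10.0) == pytest.approx(1 / 5)  # never exactly 0
        assert empirical_p(nulls, 0.0) == 1.0

    def test_monotone_in_observed_magnitude(self, rng):
        nulls = rng.normal(size=200)
        ps = [empirical_p(nulls, obs) for obs in np.linspace(0, 3, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestShuffleNull:
    def test_constant_durations_give_zero_null_slopes(self):
        table = make_table({f"s{i}": [0.4] * (1 + i % 3) for i in range(9)})
        nd = shuffle_null(table, n_iter=5, seed=1)
        assert np.all(np.abs(nd.slopes_size) < 1e-10)
        assert np.all(np.abs(nd.slopes_position) < 1e-10)

    def test_destroys_strong_association(self, medium_table):
        """With generating slope -0.3 the shuffled slopes center on zero and
        the observed slope is extreme among them."""
        nd = shuffle_null(medium_table, n_iter=60, seed=4)
        assert abs(nd.slopes_size.mean()) < 4 * nd.slopes_size.std(ddof=1) / np.sqrt(nd.n_iter)
        assert nd.empirical_p_size <= 2 / (nd.n_iter + 1)
        assert nd.observed_size < -0.2

    def test_deterministic_given_seed(self, medium_table):
        a = shuffle_null(medium_table, n_iter=4, seed=9)
        b = shuffle_null(medium_table, n_iter=4, seed=9)
        np.testing.assert_array_equal(a.slopes_size, b.slopes_size)
        np.testing.assert_array_equal(a.slopes_position, b.slopes_position)

    def test_preserves_per_individual_duration_multiset(self, medium_table, rng):
        """Conservation: one manual shuffle iteration keeps, per individual,
        the multiset of durations and the sequence/position scaffold."""
        df = medium_table.df
        for _, grp in df.groupby("individual_id"):
            durs = grp["duration_s"].to_numpy()
            shuffled = durs[rng.permutation(len(durs))]
            assert sorted(shuffled) == pytest.approx(sorted(durs))


class TestPseudoSequence:
    def test_forced_removal_by_fifty_percent_rule(self, rng):
        # pool {3}, total 10: 3,3,3,3 overshoots by 2 > 1.5 -> last removed
        assert generate_pseudo_sequence(10.0, np.array([3.0]), rng) == [3.0, 3.0, 3.0]

    def test_forced_keep_at_or_below_fifty_percent(self, rng):
        # pool {3}, total 11: overshoot 1 <= 1.5 -> kept
        assert generate_pseudo_sequence(11.0, np.array([3.0]), rng) == [3.0] * 4
        # exact 50% overshoot is kept ("more than 50%" removes)
        assert generate_pseudo_sequence(10.5, np.array([3.0]), rng) == [3.0] * 4

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            generate_pseudo_sequence(1.0, np.array([]), rng)

    def test_length_distribution_matches_exhaustive_enumeration(self):
        """Pool {1, 3}, target 4: enumerate all equally likely sampling paths,
        apply the 50% rule, and compare exact length probabilities with
        simulated frequencies."""

        def enumerate_paths(total, path, prob, out):
            if total > 4:
                overshoot = total - 4
                length = len(path) - 1 if overshoot > 0.5 * path[-1] else len(path)
                out[length] = out.get(length, Fraction(0)) + prob
                return
            for d in (1, 3):
                enumerate_paths(total + d, path + [d], prob / 2, out)

        exact: dict[int, Fraction] = {}
        enumerate_paths(0, [], Fraction(1), exact)
        assert sum(exact.values()) == 1

        rng = np.random.default_rng(2024)
        n = 40000
        lengths = np.array([
            len(generate_pseudo_sequence(4.0, np.array([1.0, 3.0]), rng)) for _ in range(n)
        ])
        for length, p in exact.items():
            freq = (lengths == length).mean()
            assert freq == pytest.approx(float(p), abs=4 * np.sqrt(float(p) * (1 - float(p)) / n) + 1e-9)
        assert set(np.unique(lengths)) <= set(exact)


class TestProductionConstraintNull:
    def test_constant_durations_reproduce_real_sizes(self):
        """With all durations d, a real sequence of n calls totals n*d, so the
        pseudo-sequence is forced to exactly n calls and slopes are zero."""
        table = make_table({f"s{i}": [0.4] * (1 + i % 3) for i in range(9)})
        nd = production_constraint_null(table, n_iter=4, seed=6)
        assert np.all(np.abs(nd.slopes_size) < 1e-10)
        assert np.all(np.abs(nd.slopes_position) < 1e-10)

    def test_pseudo_totals_satisfy_overshoot_band(self, medium_table):
        """Every pseudo-sequence either overshoots by at most half its last
        call or (after removal) totals at most the real total."""
        df = medium_table.df
        pools = {k: g["duration_s"].to_numpy() for k, g in df.groupby("individual_id")}
        totals = df.groupby("sequence_id")["duration_s"].sum()
        inds = df.groupby("sequence_id")["individual_id"].first()
        rng = np.random.default_rng(77)
        for _ in range(25):
            for seq_id, total in totals.items():
                durs = generate_pseudo_sequence(total, pools[inds[seq_id]], rng)
                if not durs:
                    continue
                s = sum(durs)
                if s > total:
                    assert s - total <= 0.5 * durs[-1] + 1e-12
                else:
                    assert s <= total + 1e-12

    def test_null_slopes_predominantly_negative_on_compression_free_data(self):
        """Duration matching alone induces negative size slopes: sequences
        that sample shorter calls need more of them to fill the same time."""
        cfg = trained_crow_preset(beta1=0.0, beta2=0.0, sequences_per_individual=80, seed=13)
        table = simulate_call_table(cfg)
        nd = production_constraint_null(table, n_iter=12, seed=3)
        assert (nd.slopes_size < 0).mean() > 0.9

    def test_deterministic_given_seed(self, medium_table):
        a = production_constraint_null(medium_table, n_iter=3, seed=5)
        b = production_constraint_null(medium_table, n_iter=3, seed=5)
        np.testing.assert_array_equal(a.slopes_size, b.slopes_size)
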