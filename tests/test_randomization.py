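import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphdispersal import (
    CandidateDistanceSet,
    candidate_distances,
    morph_stratified_test,
    random_median_draws,
    randomization_test,
)
from morphdispersal.geometry import BoxRegistry, NestBox, ValidationError


def _sets(*dists):
    return [CandidateDistanceSet(f"r{i}", np.array(d, float)) for i, d in enumerate(dists)]


class TestCandidateDistances:
    def test_self_excluded_counting(self, tiny_registry, tiny_recruits):
        sets = candidate_distances(tiny_recruits, tiny_registry)
        for s in sets:
            # all hatch years are post-cutoff: 5 boxes minus self
            assert s.distances.size == 4
            assert (s.distances > 0).all()

    def test_pythagorean_candidates(self):
        reg = BoxRegistry(
            [NestBox("a", 0, 0, 1980), NestBox("b", 3, 4, 1980), NestBox("c", 6, 8, 1980)]
        )
        rec = pd.DataFrame(
            {"recruit_id": ["r"], "natal_box_id": ["a"], "hatch_year": [1990]}
        )
        (s,) = candidate_distances(rec, reg)
        assert sorted(s.distances) == pytest.approx([5.0, 10.0])

    def test_pre_cutoff_recruit_restricted_to_early_boxes(self, tiny_registry):
        rec = pd.DataFrame(
            {"recruit_id": ["r"], "natal_box_id": ["A"], "hatch_year": [1985]}
        )
        (s,) = candidate_distances(rec, tiny_registry)
        assert s.distances.size == 1  # only box B is pre-1987 besides natal A
        assert s.distances[0] == pytest.approx(5.0)

    def test_unknown_natal_box_names_recruit(self, tiny_registry):
        rec = pd.DataFrame(
            {"recruit_id": ["lost"], "natal_box_id": ["Z"], "hatch_year": [1990]}
        )
        with pytest.raises(ValidationError, match="lost"):
            candidate_distances(rec, tiny_registry)


class TestRandomMedianDraws:
    def test_degenerate_singleton_sets(self):
        null = random_median_draws(_sets([7.0], [7.0], [7.0]), m=25, seed=0)
        assert null.shape == (25,)
        assert (null == 7.0).all()

    def test_single_recruit_two_candidates_is_a_fair_coin(self):
        m = 20000
        null = random_median_draws(_sets([1.0, 3.0]), m=m, seed=1)
        frac = (null == 1.0).mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(m)

    def test_matches_exhaustive_enumeration(self):
        """Three recruits with two candidates each: the 2^3 equally likely
        outcomes fully determine the null-median distribution."""
        sets = _sets([1.0, 9.0], [2.0, 8.0], [3.0, 7.0])
        support = {}
        for combo in itertools.product(*[s.distances for s in sets]):
            med = float(np.median(combo))
            support[med] = support.get(med, 0) + 1
        m = 100_000
        null = random_median_draws(sets, m=m, seed=2)
        values = sorted(support)
        observed = [int((null == v).sum()) for v in values]
        expected = [m * support[v] / 8 for v in values]
        assert sum(observed) == m  # no medians outside the enumerated support
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.01

    def test_deterministic_under_seed(self):
        sets = _sets([1, 2, 3], [4, 5], [6.0])
        a = random_median_draws(sets, m=99, seed=42)
        b = random_median_draws(sets, m=99, seed=42)
        c = random_median_draws(sets, m=99, seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            random_median_draws(_sets([1.0]), m=0)


class TestRandomizationTest:
    def test_observed_equal_to_all_null_medians_gives_p_one(self):
        res = randomization_test([5.0, 5.0], _sets([5.0], [5.0]), m=99, seed=0)
        assert res.p_value == 1.0

    def test_observed_below_all_null_gives_minimum_p(self):
        res = randomization_test(
            [0.5, 0.5], _sets([10.0, 20.0], [10.0, 20.0]), m=999, tail="lower", seed=0
        )
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_value_lies_on_the_attainable_grid(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            obs = rng.uniform(0, 10, size=4)
            sets = _sets(*[rng.uniform(0, 10, size=5) for _ in range(4)])
            m = 49
            res = randomization_test(obs, sets, m=m, seed=int(rng.integers(1e6)))
            k = round(res.p_value * (m + 1))
            assert res.p_value == pytest.approx(k / (m + 1))
            assert 1 <= k <= m + 1

    def test_tie_counts_toward_rejection(self):
        # every null median is exactly the observed median: inclusive count
        res = randomization_test([2.0], _sets([2.0]), m=9, tail="lower", seed=0)
        assert res.p_value == 1.0

    def test_upper_tail_is_the_literal_reading(self):
        res_low = randomization_test(
            [0.5], _sets([10.0, 20.0]), m=99, tail="lower", seed=0
        )
        res_up = randomization_test(
            [0.5], _sets([10.0, 20.0]), m=99, tail="upper", seed=0
        )
        assert res_low.p_value == pytest.approx(1 / 100)
        assert res_up.p_value == 1.0

    def test_expected_median_is_median_of_null(self):
        sets = _sets([1, 2, 3, 4], [2, 3, 4, 5])
        res = randomization_test([1.0, 2.0], sets, m=199, seed=5)
        assert res.expected_median_km == pytest.approx(np.median(res.random_medians))

    def test_mismatched_recruits_rejected(self):
        with pytest.raises(ValueError, match="candidate sets"):
            randomization_test([1.0, 2.0], _sets([1.0]), m=9)

    def test_pooled_urn_variant_runs_and_differs(self):
        sets = _sets([1.0, 1.0, 1.0], [9.0])
        per_recruit = random_median_draws(sets, m=500, seed=0)
        pooled = random_median_draws(sets, m=500, seed=0, pooled=True)
        # per-recruit: median of {1, 9} -> always 5; pooled urn can give 1
        assert (per_recruit == 5.0).all()
        assert (pooled == 1.0).any()


class TestMorphStratification:
    def _recruits(self, tiny_registry):
        return pd.DataFrame(
            {
                "recruit_id": [f"r{i}" for i in range(6)],
                "natal_box_id": ["A", "B", "C", "D", "E", "A"],
                "hatch_year": [1990] * 6,
                "morph": ["gray", "gray", "gray", "brown", "brown", "gray"],
                "dispersal_km": [5.0, 5.0, 10.0, 8.0, 10.0, 5.0],
            }
        )

    def test_full_sample_stratum_equals_unstratified(self, tiny_registry):
        rec = self._recruits(tiny_registry)
        gray = rec[rec["morph"] == "gray"]
        sets = candidate_distances(gray, tiny_registry)
        direct = randomization_test(
            gray["dispersal_km"].to_numpy(), sets, m=199, seed=11
        )
        strat = morph_stratified_test(rec, tiny_registry, "gray", m=199, seed=11)
        assert strat.p_value == direct.p_value
        assert np.array_equal(strat.random_medians, direct.random_medians)

    def test_strata_partition_the_sample(self, tiny_registry):
        rec = self._recruits(tiny_registry)
        g = morph_stratified_test(rec, tiny_registry, "gray", m=99, seed=0)
        b = morph_stratified_test(rec, tiny_registry, "brown", m=99, seed=0)
        assert g.n_recruits + b.n_recruits == len(rec)

    def test_smaller_stratum_has_wider_null(self, tiny_registry):
        rec = self._recruits(tiny_registry)
        g = morph_stratified_test(rec, tiny_registry, "gray", m=2999, seed=1)
        b = morph_stratified_test(rec, tiny_registry, "brown", m=2999, seed=1)
        assert b.n_recruits < g.n_recruits
        assert b.random_medians.std() > g.random_medians.std()

    def test_empty_stratum_is_an_error(self, tiny_registry):
        rec = self._recruits(tiny_registry)
        with pytest.raises(ValidationError, match="albino"):
            morph_stratified_test(rec, tiny_registry, "albino", m=9, seed=0)
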