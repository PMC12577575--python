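import numpy as np
import pytest

from sirepower import (
    Clutch,
    ClutchDemography,
    DECREASING_MATING,
    SamplingDesign,
    SeasonConfig,
    SeasonOutcome,
    build_male_pool,
    mate_females,
    mating_numbers,
    minimal_clutch_fraction,
    sample_season,
    season_confidence,
    season_confidence_curve,
    simulate_season,
    split_population,
)
from sirepower.season import _ceil_count


def one_male_config():
    # 2 adults at OSR 0.5: one male, one female, strict monogamy
    return SeasonConfig(
        osr=0.5, pop_size=2, polyandry="none", polygyny="none", mode="random"
    )


class TestSplitPopulation:
    @pytest.mark.parametrize(
        "pop, osr, expected",
        [(100, 0.05, (5, 95)), (100, 0.95, (95, 5)), (1000, 0.5, (500, 500))],
    )
    def test_rounded_split(self, pop, osr, expected):
        assert split_population(pop, osr) == expected

    def test_degenerate_splits_rejected(self):
        with pytest.raises(ValueError, match="degenerate split"):
            split_population(100, 0.001)
        with pytest.raises(ValueError):
            split_population(1, 0.5)
        with pytest.raises(ValueError):
            split_population(100, 1.0)


class TestMatingNumbers:
    def test_named_distributions(self):
        assert mating_numbers("decreasing") is DECREASING_MATING
        np.testing.assert_allclose(mating_numbers("uniform"), 0.2)
        np.testing.assert_allclose(mating_numbers("none"), [1, 0, 0, 0, 0])

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValueError):
            mating_numbers("bimodal")
        with pytest.raises(ValueError):
            mating_numbers([0.5, 0.5])
        with pytest.raises(ValueError):
            mating_numbers([0.5, 0.2, 0.2, 0.2, -0.1])


class TestMalePool:
    def test_no_polygyny_gives_one_slot_per_male(self, rng):
        pool = build_male_pool(5, "none", rng)
        assert sorted(pool.tolist()) == [0, 1, 2, 3, 4]

    def test_mean_slots_per_male(self, rng):
        uniform = build_male_pool(5_000, "uniform", rng)
        assert abs(len(uniform) / 5_000 - 3.0) < 0.1
        decreasing = build_male_pool(5_000, "decreasing", rng)
        expected = float(np.arange(1, 6) @ DECREASING_MATING)  # 1.846
        assert abs(len(decreasing) / 5_000 - expected) < 0.05


class TestMateFemales:
    def test_monandrous_pool_exhaustion(self, rng):
        pool = build_male_pool(5, "none", rng)
        lists, remaining = mate_females(95, pool, "none", rng)
        assert sum(len(m) > 0 for m in lists) == 5
        assert len(remaining) == 0
        # females processed after exhaustion stay unmated
        assert all(len(m) == 0 for m in lists[5:])

    def test_slot_conservation_and_distinct_mates(self, rng):
        pool = build_male_pool(200, "decreasing", rng)
        lists, remaining = mate_females(150, pool, "uniform", rng)
        consumed = sum(len(m) for m in lists)
        assert consumed + len(remaining) == len(pool)
        for mates in lists:
            assert len(set(mates.tolist())) == len(mates)
            assert len(mates) <= 5

    def test_mean_mates_with_unconstrained_pool(self, rng):
        # pool far larger than demand: realized mates ~ the target draw,
        # mean 3 with SD sqrt(2); bound is 4 standard errors over 400 mothers
        pool = build_male_pool(5_000, "uniform", rng)
        lists, _ = mate_females(400, pool, "uniform", rng)
        assert abs(np.mean([len(m) for m in lists]) - 3.0) < 4 * np.sqrt(2 / 400)


class TestSimulateSeason:
    def test_single_male_sires_everything(self, rng):
        outcome = simulate_season(one_male_config(), rng)
        assert outcome.breeding_fathers == {0}
        assert len(outcome.clutches) >= 1
        for _, clutch in outcome.clutches:
            assert (clutch.father_of_egg == 0).all()

    def test_clutch_fathers_drawn_from_mother_mates(self, rng):
        config = SeasonConfig(
            osr=0.4, pop_size=40, polyandry="uniform", polygyny="decreasing",
            mode="mixed_dominant",
        )
        outcome = simulate_season(config, rng)
        union = set()
        for mother, clutch in outcome.clutches:
            mates = set(outcome.mate_lists[mother].tolist())
            assert clutch.fathers_present() <= mates
            union |= mates
        assert union == outcome.breeding_fathers
        # mothers without mates laid nothing
        unmated = {i for i, m in enumerate(outcome.mate_lists) if len(m) == 0}
        assert unmated.isdisjoint({mother for mother, _ in outcome.clutches})

    def test_mated_mother_count_tracks_slot_accounting(self, rng):
        # 50 single-slot males split among mothers wanting 1.846 mates each
        config = SeasonConfig(
            osr=0.5, pop_size=100, polyandry="decreasing", polygyny="none",
            mode="random",
        )
        counts = [
            sum(len(m) > 0 for m in simulate_season(config, rng).mate_lists)
            for _ in range(300)
        ]
        assert abs(np.mean(counts) - 50 / 1.846) < 3


class TestSampleSeason:
    def test_census_identifies_every_father_with_eggs(self, rng):
        config = SeasonConfig(
            osr=0.3, pop_size=30, polyandry="uniform", polygyny="uniform",
            mode="dominant90",
        )
        outcome = simulate_season(config, rng)
        design = SamplingDesign(clutch_fraction=1.0, n_per_clutch=10_000)
        identified, breeding = sample_season(outcome, design, rng)
        with_eggs = set()
        for _, clutch in outcome.clutches:
            with_eggs |= clutch.fathers_present()
        assert identified == with_eggs
        assert with_eggs <= breeding

    def test_identified_nested_in_fathers_with_eggs_and_breeders(self, rng):
        config = SeasonConfig(
            osr=0.5, pop_size=20, polyandry="decreasing", polygyny="decreasing",
            mode="mixed_dominant",
        )
        for _ in range(20):
            outcome = simulate_season(config, rng)
            identified, breeding = sample_season(
                outcome, SamplingDesign(0.4, 8), rng
            )
            with_eggs = set()
            for _, clutch in outcome.clutches:
                with_eggs |= clutch.fathers_present()
            assert identified <= with_eggs <= breeding

    def test_clutch_count_rounds_up(self):
        assert _ceil_count(0.2 * 25) == 5
        assert _ceil_count(0.05 * 25) == 2
        assert _ceil_count(0.9 * 10) == 9
        assert _ceil_count(1.0 * 7) == 7

    def test_unsampled_clutch_cannot_reveal_its_father(self, rng):
        # two clutches by two mothers with disjoint single fathers; sampling
        # half the clutches always leaves one father unseen
        outcome = SeasonOutcome(
            n_males=2,
            breeding_fathers={0, 1},
            mate_lists=[np.array([0]), np.array([1])],
            clutches=[
                (0, Clutch(10, np.zeros(10, dtype=int))),
                (1, Clutch(10, np.ones(10, dtype=int))),
            ],
        )
        for _ in range(20):
            identified, _ = sample_season(outcome, SamplingDesign(0.5, 96), rng)
            assert len(identified) == 1


class TestSeasonConfidence:
    def test_single_male_design_always_succeeds(self, rng):
        result = season_confidence(
            one_male_config(), SamplingDesign(0.05, 32), reps=50, rng=rng
        )
        assert result.confidence == 1.0

    def test_relaxed_threshold_nests_success_events(self):
        config = SeasonConfig(
            osr=0.6, pop_size=60, polyandry="uniform", polygyny="none",
            mode="dominant90",
        )
        strict = season_confidence(config, SamplingDesign(0.6, 32, 1.0), reps=400, rng=7)
        relaxed = season_confidence(config, SamplingDesign(0.6, 32, 0.9), reps=400, rng=7)
        assert relaxed.confidence >= strict.confidence

    def test_curve_monotone_in_clutch_fraction_by_construction(self, rng):
        config = SeasonConfig(
            osr=0.5, pop_size=60, polyandry="decreasing", polygyny="decreasing",
            mode="mixed_dominant",
        )
        curve = season_confidence_curve(config, reps=300, rng=rng)
        assert (np.diff(curve.confidence) >= 0).all()

    def test_confidence_increases_with_offspring_per_clutch(self):
        config = SeasonConfig(
            osr=0.5, pop_size=60, polyandry="uniform", polygyny="none",
            mode="dominant90",
        )
        small = season_confidence(config, SamplingDesign(0.8, 4), reps=500, rng=3)
        large = season_confidence(config, SamplingDesign(0.8, 96), reps=500, rng=3)
        assert large.confidence > small.confidence

    def test_fast_and_egg_level_paths_estimate_same_confidence(self, rng):
        config = SeasonConfig(
            osr=0.5, pop_size=20, polyandry="decreasing", polygyny="decreasing",
            mode="mixed_dominant",
        )
        design = SamplingDesign(0.5, 16)
        reps_slow = 600
        hits = 0
        for _ in range(reps_slow):
            outcome = simulate_season(config, rng)
            identified, breeding = sample_season(outcome, design, rng)
            hits += len(identified) >= len(breeding)
        slow = hits / reps_slow
        fast = season_confidence(config, design, reps=3_000, rng=rng)
        se = np.sqrt(
            slow * (1 - slow) / reps_slow
            + fast.confidence * (1 - fast.confidence) / 3_000
        )
        assert abs(slow - fast.confidence) < 4 * se

    def test_confidence_peaks_at_extreme_sex_ratios(self):
        # the U-shape over OSR: moderate ratios spread paternity across the
        # most single-clutch-vulnerable father pools
        confs = {}
        for osr in (0.05, 0.5, 0.95):
            config = SeasonConfig(
                osr=osr, pop_size=100, polyandry="decreasing",
                polygyny="decreasing", mode="random",
            )
            confs[osr] = season_confidence(
                config, SamplingDesign(0.5, 32), reps=600, rng=13
            ).confidence
        assert confs[0.05] > confs[0.5]
        assert confs[0.95] > confs[0.5]


class TestMinimalClutchFraction:
    def test_single_male_needs_smallest_fraction(self, rng):
        assert minimal_clutch_fraction(one_male_config(), reps=50, rng=rng) == 0.05

    def test_relaxed_threshold_never_needs_more_sampling(self):
        config = SeasonConfig(
            osr=0.3, pop_size=100, polyandry="uniform", polygyny="uniform",
            mode="random",
        )
        strict = minimal_clutch_fraction(
            config, success_threshold=1.0, reps=400, rng=17
        )
        relaxed = minimal_clutch_fraction(
            config, success_threshold=0.9, reps=400, rng=17
        )
        assert strict is not None and relaxed is not None
        assert relaxed <= strict

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            SamplingDesign(0.0, 32)
        with pytest.raises(ValueError):
            SamplingDesign(0.5, 0)
        with pytest.raises(ValueError):
            SamplingDesign(0.5, 32, 1.5)
        with pytest.raises(ValueError):
            minimal_clutch_fraction(one_male_config(), target_confidence=1.0, reps=10)
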