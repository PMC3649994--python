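"""Zone assignment, pairing, karyotype accounting, exact tests, respiration."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from netrack import ConfigurationError, CytoSimConfig
from netrack.cytosim import simulate_oocyte_counts
from netrack.cytostats import (
    assign_zones,
    bivalents_from_bodies,
    bodies_from_bivalents,
    classify_synapsis_association,
    compare_body_counts,
    count_category_histogram,
    estimate_chiasma_prob,
    normalize_respiration,
    pairing_contingency_test,
    pairing_table_tests,
    score_pairing,
    summarize_associations,
)


class TestAssignZones:
    def test_uniform_positions_split_evenly(self):
        pos = (np.arange(100) + 0.5) / 100
        zones = assign_zones(pos, 5)
        assert all((zones == z).sum() == 20 for z in range(1, 6))

    def test_boundaries(self):
        assert assign_zones(np.array([0.0]), 5)[0] == 1
        assert assign_zones(np.array([1.0]), 5)[0] == 5

    def test_named_scheme_sets_zone_count(self):
        zones = assign_zones(np.array([0.95]), scheme="rad51-5")
        assert zones[0] == 5
        with pytest.raises(ConfigurationError):
            assign_zones(np.array([0.5]), scheme="nope")

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_zones(np.array([-0.01]), 5)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50), st.integers(1, 9))
    def test_matches_floor_division_oracle(self, positions, n_zones):
        got = assign_zones(np.array(positions), n_zones)
        want = [min(int(p * n_zones), n_zones - 1) + 1 for p in positions]
        assert list(got) == want


class TestScorePairing:
    def test_single_signal_is_paired(self):
        assert score_pairing(np.array([[1.0, 2.0, 3.0]])) == "paired"

    def test_two_distant_signals_unpaired(self):
        coords = np.array([[0, 0, 0], [0, 0, 2.0]])
        assert score_pairing(coords, merge_dist_um=0.75) == "unpaired"

    def test_boundary_distance_is_inclusive(self):
        coords = np.array([[0, 0, 0], [0, 0, 0.75]])
        assert score_pairing(coords, merge_dist_um=0.75) == "paired"

    def test_excess_signals_flagged(self):
        coords = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="flagged"):
            assert score_pairing(coords) == "excluded"


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric outcomes no more likely
    than the observed table (fixed margins)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {x: comb(r1, x) * comb(n - r1, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert pairing_contingency_test(5, 10, 5, 10) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        assert pairing_contingency_test(10, 10, 0, 10) == pytest.approx(
            fisher_oracle(10, 0, 0, 10), rel=1e-9
        )

    def test_swapping_groups_leaves_p_unchanged(self):
        p1 = pairing_contingency_test(7, 12, 3, 9)
        p2 = pairing_contingency_test(3, 9, 7, 12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            pairing_contingency_test(5, 0, 1, 10)
        with pytest.raises(ConfigurationError):
            pairing_contingency_test(11, 10, 1, 10)

    def test_per_zone_table_comparison(self, rng):
        rows_a = [{"zone": z, "paired": bool(rng.random() < 0.9)} for z in (1, 2, 3) for _ in range(30)]
        rows_b = [{"zone": z, "paired": bool(rng.random() < 0.5)} for z in (1, 2, 3) for _ in range(30)]
        res = pairing_table_tests(pd.DataFrame(rows_a), pd.DataFrame(rows_b))
        assert set(res["zone"]) == {1, 2, 3}
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()


class TestBivalentAccounting:
    @pytest.mark.parametrize(
        "bodies,bivalents",
        [(7.2, 4.8), (11.9, 0.1), (8.2, 3.8), (10.2, 1.8), (6.0, 6.0), (12.0, 0.0)],
    )
    def test_printed_conversions(self, bodies, bivalents):
        assert bivalents_from_bodies(bodies) == pytest.approx(bivalents)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bivalents_from_bodies(5.0)
        with pytest.raises(ConfigurationError):
            bivalents_from_bodies(12.5)

    @given(st.floats(6.0, 12.0))
    def test_round_trip_is_identity(self, bodies):
        assert bodies_from_bivalents(bivalents_from_bodies(bodies)) == pytest.approx(bodies)

    def test_chiasma_probability_recovered_within_three_se(self):
        p, n = 0.85, 2000
        df = simulate_oocyte_counts(CytoSimConfig(chiasma_prob=p, n_oocytes=n, seed=11))
        est = estimate_chiasma_prob(df["bodies"])
        se = np.sqrt(p * (1 - p) / (6 * n))
        assert abs(est - p) < 3 * se


def mw_exact_oracle(x, y):
    """scipy permutation test with full enumeration as an independent check."""
    def statistic(a, b):
        return stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic

    res = stats.permutation_test(
        (x, y), statistic, permutation_type="independent",
        alternative="two-sided", n_resamples=np.inf,
    )
    return float(res.pvalue)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        assert compare_body_counts([6, 6, 6], [6, 6, 6]) == pytest.approx(1.0)

    def test_fully_separated_triples_by_enumeration(self):
        # U = 0; of the C(6,3) = 20 rank arrangements, 2 are at least as
        # extreme (both fully separated orders) -> p = 0.1
        assert compare_body_counts([6, 6, 6], [12, 12, 12]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_permutation_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(6, 13, rng.integers(2, 7))
        y = rng.integers(6, 13, rng.integers(2, 7))
        assert compare_body_counts(x, y) == pytest.approx(mw_exact_oracle(x, y), abs=1e-9)

    def test_swapping_samples_leaves_p_unchanged(self):
        x, y = [6, 7, 7, 8], [9, 9, 10]
        assert compare_body_counts(x, y) == pytest.approx(compare_body_counts(y, x))

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(3)
        x = rng.integers(6, 9, 52)
        y = rng.integers(10, 13, 30)
        p = compare_body_counts(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=False).pvalue
        assert p == pytest.approx(float(ref))
        assert p < 1e-10

    def test_too_small_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_body_counts([6], [7, 8])


class TestCountHistograms:
    def test_all_zero_counts_land_in_first_bin(self):
        df = pd.DataFrame({"zone": [1] * 10, "focus_count": [0] * 10})
        hist = count_category_histogram(df, "focus")
        assert hist.loc[0, "0"] == 100.0

    def test_six_to_ten_bin_captures_mutant_like_counts(self):
        df = pd.DataFrame({"zone": [3] * 3, "focus_count": [6, 7, 10]})
        hist = count_category_histogram(df, "focus")
        assert hist.loc[0, "6-10"] == 100.0

    def test_fractions_sum_to_one_per_zone(self, rng):
        df = pd.DataFrame(
            {"zone": rng.integers(1, 6, 200), "focus_count": rng.integers(0, 14, 200)}
        )
        hist = count_category_histogram(df, "focus")
        bins = [c for c in hist.columns if c not in ("zone", "n")]
        assert np.allclose(hist[bins].sum(axis=1), 100.0)

    def test_rad51_stretches_tallied_separately(self):
        df = pd.DataFrame(
            {
                "zone": [1, 1, 1, 1],
                "rad51_count": [2, 5, 0, 0],
                "rad51_stretch": [False, False, True, True],
            }
        )
        hist = count_category_histogram(df, "rad51")
        assert hist.loc[0, "stretch"] == 50.0
        bins = [c for c in hist.columns if c not in ("zone", "n")]
        assert hist.loc[0, bins].sum() == 100.0

    def test_empty_zone_reported_with_zero_n(self):
        df = pd.DataFrame({"zone": [2], "focus_count": [1]})
        df = pd.concat([df, pd.DataFrame({"zone": [4], "focus_count": [np.nan]}).dropna()])
        hist = count_category_histogram(df, "focus")
        assert set(hist["zone"]) == {2}

    def test_missing_column_rejected(self):
        with pytest.raises(ConfigurationError):
            count_category_histogram(pd.DataFrame({"zone": [1]}), "focus")


class TestSynapsisAssociation:
    SC_A = [(0.0, 0.0), (0.0, 5.0)]
    SC_B = [(3.0, 0.0), (3.0, 5.0)]

    def test_two_signals_on_different_stretches(self):
        res = classify_synapsis_association(
            [[0.1, 2.0], [2.9, 2.0]], [self.SC_A, self.SC_B], assoc_dist_um=0.3
        )
        assert res.association_class == "both-on-different-SC"

    def test_single_signal_on_stretch_is_paired(self):
        res = classify_synapsis_association([[0.05, 1.0]], [self.SC_A], assoc_dist_um=0.3)
        assert res.association_class == "single-SC-paired"

    def test_one_of_two_signals_on_stretch(self):
        res = classify_synapsis_association(
            [[0.1, 1.0], [1.5, 1.0]], [self.SC_A], assoc_dist_um=0.3
        )
        assert res.association_class == "one-on-SC"

    def test_no_stretch_nearby(self):
        res = classify_synapsis_association([[1.5, 1.0]], [self.SC_A], assoc_dist_um=0.3)
        assert res.association_class == "none-on-SC"

    def test_population_summary_reproduces_37_of_40_split(self, rng):
        # 40 nuclei with two separated signals: 37 land on different
        # stretches, 3 with only one signal associated
        nuclei = []
        for i in range(40):
            if i < 37:
                coords = [[0.1, 2.0 + 0.01 * i], [2.9, 2.0]]
            else:
                coords = [[0.1, 2.0], [1.5, 2.0]]
            nuclei.append(
                classify_synapsis_association(coords, [self.SC_A, self.SC_B], 0.3)
            )
        tally = summarize_associations(nuclei)
        assert tally["both-on-different-SC"] == 37
        assert tally["one-on-SC"] == 3


class TestRespiration:
    def _records(self, means, worms, genotypes, rng):
        rows = []
        for i, (m, w, g) in enumerate(zip(means, worms, genotypes)):
            row = {"well_id": i, "worms_in_well": w, "genotype": g}
            row.update({f"ocr_{k}": m + rng.normal(0, 0.5) for k in range(1, 8)})
            rows.append(row)
        return pd.DataFrame(rows)

    def test_per_worm_rate_arithmetic(self):
        df = pd.DataFrame(
            [{"well_id": 0, "worms_in_well": 55, "genotype": "wt",
              **{f"ocr_{k}": 550.0 for k in range(1, 8)}}]
        )
        res = normalize_respiration(df)
        assert res["rates"]["per_worm_rate"].iloc[0] == pytest.approx(10.0)

    def test_identical_groups_give_high_p(self, rng):
        df = self._records([100] * 20, [50] * 20, ["a"] * 10 + ["b"] * 10, rng)
        res = normalize_respiration(df)
        assert res["p"] > 0.05

    def test_five_sd_separation_is_highly_significant(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rates_a = rng.normal(10.0, 0.2, 10)
            rates_b = rng.normal(11.0, 0.2, 10)  # 5 SD apart
            df = self._records(
                np.concatenate([rates_a, rates_b]) * 50,
                [50] * 20,
                ["a"] * 10 + ["b"] * 10,
                rng,
            )
            if normalize_respiration(df)["p"] < 1e-4:
                hits += 1
        assert hits >= 95

    def test_zero_worms_rejected(self, rng):
        df = self._records([100], [0], ["a"], rng)
        with pytest.raises(ConfigurationError):
            normalize_respiration(df)

    def test_sem_reported_per_genotype(self, rng):
        df = self._records([100] * 20, [50] * 20, ["a"] * 10 + ["b"] * 10, rng)
        res = normalize_respiration(df)
        assert set(res["summary"].index) == {"a", "b"}
        assert (res["summary"]["count"] == 10).all()
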