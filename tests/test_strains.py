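"""Strain dissimilarity, replacement calling and dynamics summaries."""

import numpy as np
import pandas as pd
import pytest

import microdyn as md
from microdyn.containers import AllelePileup
from microdyn.strains import (
    allele_set,
    call_replacements,
    comparable_positions,
    compare_environments,
    dissimilarity_sets,
    dynamics_correlation,
    intra_dissimilarity_matrix,
    pairwise_dissimilarity,
    participant_replacement_rate,
    replacement_threshold,
    species_replacement_rate,
    species_thresholds,
)


def uniform_pileup(species, sample, n_positions, allele=0, depth=10):
    counts = np.zeros((n_positions, 4), dtype=np.int32)
    counts[:, allele] = depth
    return AllelePileup(species, sample, np.arange(n_positions), counts)


class TestAlleleSet:
    def test_single_allele(self):
        assert allele_set([10, 0, 0, 0]) == {"A"}

    def test_presence_fraction_rule(self):
        assert allele_set([9, 1, 0, 0], presence_fraction=0.10) == {"A", "C"}
        assert allele_set([9, 1, 0, 0], presence_fraction=0.20) == {"A"}

    def test_zero_depth_empty(self):
        assert allele_set([0, 0, 0, 0]) == frozenset()

    def test_minimum_one_read(self):
        # at depth 5 the 10% rule floors at one read
        assert allele_set([4, 1, 0, 0]) == {"A", "C"}


class TestComparable:
    def test_depth_boundary(self):
        a = uniform_pileup("s", "x", 5, depth=3)
        b = uniform_pileup("s", "y", 5, depth=3)
        assert len(comparable_positions(a, b)) == 5
        b.counts[:, 0] = 2
        assert len(comparable_positions(a, b)) == 0

    def test_disjoint_positions(self):
        a = AllelePileup("s", "x", [0, 1], [[3, 0, 0, 0]] * 2)
        b = AllelePileup("s", "y", [5, 6], [[3, 0, 0, 0]] * 2)
        assert len(comparable_positions(a, b)) == 0


class TestPairwiseDissimilarity:
    def test_ratio(self):
        a = uniform_pileup("s", "x", 20_000, allele=0)
        b = uniform_pileup("s", "y", 20_000, allele=0)
        b.counts[:100] = 0
        b.counts[:100, 2] = 10  # 100 positions with no shared allele
        rec = pairwise_dissimilarity(a, b)
        assert rec["n_comparable"] == 20_000
        assert rec["dissimilarity"] == pytest.approx(0.005)

    def test_identical_samples_clipped_to_floor(self):
        a = uniform_pileup("s", "x", 20_000)
        b = uniform_pileup("s", "y", 20_000)
        rec = pairwise_dissimilarity(a, b)
        assert rec["dissimilarity"] == 1.0 / 20_000 == 5e-5

    def test_below_gate_not_comparable(self):
        a = uniform_pileup("s", "x", 19_999)
        b = uniform_pileup("s", "y", 19_999)
        rec = pairwise_dissimilarity(a, b)
        assert np.isnan(rec["dissimilarity"])

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        counts_a = rng.integers(0, 12, (25_000, 4)).astype(np.int32)
        counts_b = rng.integers(0, 12, (25_000, 4)).astype(np.int32)
        pos = np.arange(25_000)
        a = AllelePileup("s", "x", pos, counts_a)
        b = AllelePileup("s", "y", pos, counts_b)
        r1 = pairwise_dissimilarity(a, b)
        r2 = pairwise_dissimilarity(b, a)
        assert r1["dissimilarity"] == r2["dissimilarity"]
        assert r1["n_comparable"] == r2["n_comparable"]


class TestDissimilaritySets:
    def test_pair_enumeration(self):
        cohort = md.generate_cohort(1, seed=0)  # 2 participants
        spec = md.PileupSpec(n_species=1, n_positions=50)
        pileups, _ = md.generate_pileups(cohort, spec, seed=1)
        records = dissimilarity_sets(pileups, md.sample_pairing(cohort),
                                     min_positions=10)
        assert len(records) == 6  # C(4,2)
        assert (records["pair_type"] == "intra_person").sum() == 2
        assert (records["pair_type"] == "inter_person").sum() == 4

    def test_single_participant_no_inter(self):
        cohort = md.generate_cohort(1, seed=0).iloc[:1]
        spec = md.PileupSpec(n_species=1, n_positions=50)
        pileups, _ = md.generate_pileups(cohort, spec, seed=2)
        records = dissimilarity_sets(pileups, md.sample_pairing(cohort),
                                     min_positions=10)
        assert (records["pair_type"] == "intra_person").all()

    def test_comparable_records_meet_gate_and_floor(self):
        cohort = md.generate_cohort(4, seed=3)
        spec = md.PileupSpec(n_species=2, n_positions=22_000, depth_mean=15)
        pileups, _ = md.generate_pileups(cohort, spec, seed=4)
        records = dissimilarity_sets(pileups, md.sample_pairing(cohort))
        comparable = records[records["dissimilarity"].notna()]
        assert (comparable["n_comparable"] >= 20_000).all()
        assert (comparable["dissimilarity"] >= 1.0 / 20_000).all()
        assert (comparable["dissimilarity"] <= 1.0).all()


class TestThresholdAndCalls:
    def test_quantile_linear_interpolation(self):
        inter = np.arange(1, 101) / 100.0  # 0.01 .. 1.00
        assert replacement_threshold(inter, q=0.05) == pytest.approx(0.0595)

    def test_constant_and_single_value(self):
        assert replacement_threshold([0.3, 0.3, 0.3]) == 0.3
        assert replacement_threshold([0.7]) == 0.7

    def test_empty_gives_none(self):
        assert replacement_threshold([]) is None

    def test_min_inter_pairs_gate(self):
        records = pd.DataFrame(
            {
                "species_id": ["s"] * 5,
                "pair_type": ["inter_person"] * 5,
                "dissimilarity": [0.01, 0.02, 0.03, 0.04, 0.05],
            }
        )
        assert species_thresholds(records, min_inter_pairs=10) == {}
        out = species_thresholds(records, min_inter_pairs=5)
        assert "s" in out

    def test_strict_exceedance(self):
        records = pd.DataFrame(
            {
                "species_id": ["s", "s"],
                "sample_a": ["a", "c"],
                "sample_b": ["b", "d"],
                "participant_a": ["P1", "P2"],
                "participant_b": ["P1", "P2"],
                "n_comparable": [25_000, 25_000],
                "dissimilarity": [0.0595, 0.07],
                "pair_type": ["intra_person", "intra_person"],
            }
        )
        calls = call_replacements(records, {"s": 0.0595})
        by_p = calls.set_index("participant_id")["replaced"]
        assert not by_p["P1"]  # equal to threshold: not replaced
        assert by_p["P2"]

    def test_miss_rate_matches_quantile_by_construction(self):
        """Intra values drawn from the inter distribution are missed ~q of
        the time."""
        rng = np.random.default_rng(5)
        misses, total = 0, 0
        for _ in range(50):
            inter = rng.lognormal(np.log(0.02), 0.5, 500)
            intra = rng.lognormal(np.log(0.02), 0.5, 100)
            thr = replacement_threshold(inter, q=0.05)
            misses += int((intra <= thr).sum())
            total += len(intra)
        assert misses / total == pytest.approx(0.05, abs=0.01)


class TestAggregation:
    def _calls(self):
        return pd.DataFrame(
            {
                "participant_id": ["P1"] * 12 + ["P2"] * 4,
                "species_id": [f"s{i}" for i in range(12)] + ["s0", "s1", "s2", "s3"],
                "intra_dissimilarity": 0.01,
                "threshold": 0.005,
                "replaced": [True] * 3 + [False] * 9 + [True] * 4,
            }
        )

    def test_participant_rates(self):
        rates = participant_replacement_rate(self._calls())
        assert rates["P1"] == 25.0  # 3 of 12
        assert rates["P2"] == 100.0

    def test_species_rates_and_top_k(self):
        rates = species_replacement_rate(self._calls())
        assert rates["s0"] == 100.0  # replaced in both carriers
        assert rates["s4"] == 0.0
        top = rates.sort_values(ascending=False)
        assert set(top.index[:4]) == {"s0", "s1", "s2", "s3"}


class TestEnvironmentComparison:
    def test_identical_distributions(self):
        rng = np.random.default_rng(6)
        rates = pd.DataFrame({"rate": rng.uniform(0, 50, 80),
                              "n_compared": rng.integers(5, 50, 80)})
        out = compare_environments(rates, rates.copy(), bin_width=10)
        assert out["pooled"]["p"] > 0.9

    def test_planted_gap_detected_in_all_bins(self):
        rng = np.random.default_rng(7)
        n = 150
        counts = rng.integers(5, 45, n)
        oral = pd.DataFrame({"rate": rng.normal(55, 8, n), "n_compared": counts})
        gut = pd.DataFrame({"rate": rng.normal(20, 8, n),
                            "n_compared": rng.integers(5, 45, n)})
        for width in (10, 20):
            out = compare_environments(oral, gut, bin_width=width)
            assert out["pooled"]["p"] < 0.05
            assert all(b["p"] < 0.05 for b in out["bins"].values())

    def test_one_sided_bins_skipped(self):
        oral = pd.DataFrame({"rate": [50.0, 55.0], "n_compared": [5, 6]})
        gut = pd.DataFrame({"rate": [20.0, 22.0], "n_compared": [35, 36]})
        out = compare_environments(oral, gut, bin_width=10)
        assert out["bins"] == {}
        assert set(out["skipped_bins"]) == {0, 3}


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(20.0)
        r, p = dynamics_correlation(100 - 2 * x, x)
        assert r == pytest.approx(-1.0)
        r2, _ = dynamics_correlation(2 * x + 1, x)
        assert r2 == pytest.approx(1.0)

    def test_planted_negative_richness_coupling(self):
        rng = np.random.default_rng(8)
        richness = rng.uniform(100, 300, 120)
        rates = 80 - 0.2 * richness + rng.normal(0, 8, 120)
        r, p = dynamics_correlation(pd.Series(rates), pd.Series(richness))
        assert r < -0.5 and p < 1e-6

    def test_independent_inputs_small_r(self):
        rng = np.random.default_rng(9)
        r, p = dynamics_correlation(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        assert abs(r) < 0.2


class TestEndToEndRecovery:
    def test_planted_replacements_recovered(self):
        """Sensitivity >= 0.9 and specificity >= 0.95 on generator defaults
        (depth 20, inter divergence 0.02, 30K positions)."""
        cohort = md.generate_cohort(8, seed=21)
        spec = md.PileupSpec(n_species=4)  # default depth/divergence/positions
        pileups, truth = md.generate_pileups(cohort, spec, seed=22)
        records = dissimilarity_sets(pileups, md.sample_pairing(cohort))
        thresholds = species_thresholds(records, min_inter_pairs=10)
        calls = call_replacements(records, thresholds)
        called = set(
            zip(calls.loc[calls["replaced"], "participant_id"],
                calls.loc[calls["replaced"], "species_id"])
        )
        evaluated = set(zip(calls["participant_id"], calls["species_id"]))
        planted = truth.replaced & evaluated
        negatives = evaluated - truth.replaced
        sensitivity = len(called & planted) / len(planted)
        specificity = 1 - len(called - planted) / len(negatives)
        assert sensitivity >= 0.9
        assert specificity >= 0.95

    def test_intra_matrix_shape(self):
        cohort = md.generate_cohort(3, seed=23)
        spec = md.PileupSpec(n_species=2, n_positions=21_000, depth_mean=12)
        pileups, _ = md.generate_pileups(cohort, spec, seed=24)
        records = dissimilarity_sets(pileups, md.sample_pairing(cohort))
        mat = intra_dissimilarity_matrix(records)
        assert mat.shape == (6, 2)
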