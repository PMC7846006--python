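"""Simulator contracts: determinism, count conservation, binomial moments,
germline propagation and the single-strand artifact asymmetry."""

import numpy as np
import pytest

from mtduplex.errors import ConfigurationError, ValidationError
from mtduplex.reference_panel import BASE_INDEX
from mtduplex.synthetic_data import (
    GERMLINE_MAF,
    PlantedEvent,
    SimulationConfig,
    plant_events,
    read_pileup_tsv,
    simulate_cohort_presence,
    simulate_strand_pileups,
    simulate_subject,
    write_pileup_tsv,
)


def _other_base(ref):
    return "T" if ref != "T" else "C"


class TestSimulateSubject:
    def test_i1a1b_profile_carries_its_thirty_path_snps(self, tree):
        prof = simulate_subject(tree, "I1a1b", seed=5)
        assert len(prof.germline_variants) == 30
        assert (199, "T", "C") in prof.germline_variants
        assert (16223, "C", "T") in prof.germline_variants

    def test_u2e2a1_profile_has_thirty_two(self, tree):
        assert len(simulate_subject(tree, "U2e2a1").germline_variants) == 32

    def test_root_profile_is_empty(self, tree):
        assert simulate_subject(tree, tree.root).germline_variants == ()

    def test_unknown_haplogroup_rejected(self, tree):
        from mtduplex.errors import HaplogroupLookupError

        with pytest.raises(HaplogroupLookupError):
            simulate_subject(tree, "Z9z9")


class TestPlantEvents:
    def test_truth_retains_events(self, tree, reference):
        prof = simulate_subject(tree, tree.root)
        ref = reference.base(1120)
        ev = PlantedEvent(1120, ref, _other_base(ref), 0.089)
        truth = plant_events(prof, "blood", [ev])
        assert truth.events == (ev,) and truth.tissue == "blood"

    def test_duplicate_event_rejected(self, tree, reference):
        prof = simulate_subject(tree, tree.root)
        ref = reference.base(100)
        ev = PlantedEvent(100, ref, _other_base(ref), 0.05)
        with pytest.raises(ValidationError):
            plant_events(prof, "blood", [ev, ev])

    def test_artifact_schema(self):
        ev = PlantedEvent(10, "C", "T", 0.05, "single_strand_artifact", "A")
        assert ev.artifact_pool == "A"
        with pytest.raises(ValidationError):
            PlantedEvent(10, "C", "T", 0.05, "single_strand_artifact", "none")
        with pytest.raises(ValidationError):
            PlantedEvent(10, "C", "C", 0.05)

    def test_out_of_range_position_rejected(self, tree):
        prof = simulate_subject(tree, tree.root)
        with pytest.raises(ValidationError):
            plant_events(prof, "blood", [PlantedEvent(99999, "A", "G", 0.1)], 16569)


class TestConfig:
    def test_depth_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(depth_mean=500, depth_min=1000, depth_max=2000)

    def test_error_rate_bounded(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(base_error_rate=0.5)


@pytest.fixture(scope="module")
def clean_pileups(tree, panel):
    prof = simulate_subject(tree, tree.root)
    truth = plant_events(prof, "blood", [])
    cfg = SimulationConfig(base_error_rate=0.0, seed=11)
    return simulate_strand_pileups(truth, panel, cfg)


class TestPileups:
    def test_reference_only_when_no_events_no_error(self, clean_pileups, reference):
        ref_idx = reference.base_indices
        for pu in clean_pileups:
            alt_mask = np.ones_like(pu.counts, dtype=bool)
            alt_mask[np.arange(len(reference)), ref_idx] = False
            assert pu.counts[alt_mask].sum() == 0

    def test_counts_conserve_depth_within_range(self, clean_pileups):
        for pu in clean_pileups:
            d = pu.depth()
            assert d.min() >= 1000 and d.max() <= 100000

    def test_same_seed_identical(self, tree, panel):
        prof = simulate_subject(tree, "H7b")
        truth = plant_events(prof, "blood", [])
        cfg = SimulationConfig(seed=123)
        a1, b1 = simulate_strand_pileups(truth, panel, cfg)
        a2, b2 = simulate_strand_pileups(truth, panel, cfg)
        assert np.array_equal(a1.counts, a2.counts)
        assert np.array_equal(b1.counts, b2.counts)

    def test_mean_depth_near_configured(self, clean_pileups):
        for pu in clean_pileups:
            assert 25000 < pu.depth().mean() < 33000

    def test_alt_count_matches_binomial_moments(self, tree, panel, reference):
        """A 1% event at fixed 30,000x: mean alt count over seeds within 4
        standard errors of 300 in each pool."""
        prof = simulate_subject(tree, tree.root)
        pos, maf, n_seeds, depth = 4000, 0.01, 100, 30000
        ref = reference.base(pos)
        ev = PlantedEvent(pos, ref, _other_base(ref), maf)
        truth = plant_events(prof, "blood", [ev])
        alt_i = BASE_INDEX[ev.alt]
        totals = np.zeros(2)
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                depth_mean=depth, depth_min=depth, depth_max=depth,
                base_error_rate=0.001, seed=seed,
            )
            for k, pu in enumerate(simulate_strand_pileups(truth, panel, cfg)):
                totals[k] += pu.counts[pos - 1, alt_i]
        expected = depth * maf
        se_mean = np.sqrt(depth * maf * (1 - maf) / n_seeds)
        for mean_alt in totals / n_seeds:
            # small positive bias from base errors hitting the alt base
            assert abs(mean_alt - expected) < 4 * se_mean + depth * 0.001 / 3

    def test_germline_propagates_to_both_pools(self, tree, panel):
        prof = simulate_subject(tree, "U2e2a1")
        truth = plant_events(prof, "blood", [])
        cfg = SimulationConfig(seed=7)
        for pu in simulate_strand_pileups(truth, panel, cfg):
            for pos, ref, alt in prof.germline_variants:
                counts = pu.counts[pos - 1]
                freq = counts[BASE_INDEX[alt]] / counts.sum()
                sigma = np.sqrt(GERMLINE_MAF * (1 - GERMLINE_MAF) / counts.sum())
                assert freq >= 0.99 - 3 * sigma

    def test_artifact_is_asymmetric_across_pools(self, tree, panel, reference):
        pos = 8000
        ref = reference.base(pos)
        ev = PlantedEvent(pos, ref, _other_base(ref), 0.05, "single_strand_artifact", "A")
        prof = simulate_subject(tree, tree.root)
        truth = plant_events(prof, "blood", [ev])
        cfg = SimulationConfig(seed=19)
        pu_a, pu_b = simulate_strand_pileups(truth, panel, cfg)
        alt_i = BASE_INDEX[ev.alt]
        freq_a = pu_a.counts[pos - 1, alt_i] / pu_a.counts[pos - 1].sum()
        freq_b = pu_b.counts[pos - 1, alt_i] / pu_b.counts[pos - 1].sum()
        assert freq_a > 0.04
        assert freq_b < 0.005  # ~ error/3 only


class TestCohortPresence:
    def test_extreme_probabilities(self):
        snp = (4104, "A", "G")
        zero = simulate_cohort_presence({"g": 50}, {("g", snp): 0.0}, seed=1)
        ones = simulate_cohort_presence({"g": 50}, {("g", snp): 1.0}, seed=1)
        assert zero["carriers"][("g", snp)] == 0
        assert ones["carriers"][("g", snp)] == 50

    def test_strong_carrier_prob_lands_near_expectation(self):
        snp = (4104, "A", "G")
        n, p = 83, 0.988
        draws = [
            simulate_cohort_presence({"young": n}, {("young", snp): p}, seed=s)["carriers"][("young", snp)]
            for s in range(50)
        ]
        # binomial 99% interval around np = 82
        sd = np.sqrt(n * p * (1 - p))
        assert all(n * p - 3 * sd <= d <= n for d in draws)

    def test_deterministic_per_seed(self):
        snp = (13105, "A", "G")
        args = ({"g": 70}, {("g", snp): 0.5})
        assert simulate_cohort_presence(*args, seed=9) == simulate_cohort_presence(*args, seed=9)


def test_pileup_tsv_round_trip(tmp_path, tree, panel, reference):
    prof = simulate_subject(tree, "H7b")
    truth = plant_events(prof, "blood", [])
    cfg = SimulationConfig(depth_mean=1000, depth_min=1000, depth_max=1000, seed=3)
    pus = simulate_strand_pileups(truth, panel, cfg)
    path = tmp_path / "pileup.tsv"
    write_pileup_tsv(pus, path)
    back = read_pileup_tsv(path, len(reference))
    assert np.array_equal(back[0].counts, pus[0].counts)
    assert np.array_equal(back[1].counts, pus[1].counts)
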