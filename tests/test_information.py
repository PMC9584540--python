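"""Coordinate mappings, rate binning, and mutual-information readout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ringbump import (
    ModelConfig,
    coordinate_map,
    cue_states,
    compute_mi,
    mi_experiment,
    mutual_information,
    rescale_gamma,
)
from ringbump.information import (
    InformationError,
    bin_rates,
    cue_only_information,
)
from ringbump.tracking import bump_positions


def brute_force_mi(counts):
    counts = np.asarray(counts, dtype=float)
    p_u = np.full(counts.shape[1], 1.0 / counts.shape[1])
    p_su = counts / counts.sum(axis=0)
    p_s = (p_su * p_u).sum(axis=1)
    total = 0.0
    for s in range(counts.shape[0]):
        for u in range(counts.shape[1]):
            if p_su[s, u] > 0:
                total += p_su[s, u] * p_u[u] * np.log2(p_su[s, u] / p_s[s])
    return total


class TestCoordinateMap:
    def test_circular_conversion_factor(self):
        cmap = coordinate_map(ModelConfig(N=600, M=3), "circular", 360.0)
        assert cmap.units_per_neuron == pytest.approx(1.8)
        # one bump distance (200 neurons) spans 360 degrees
        assert cmap.units_per_neuron * 200 == pytest.approx(360.0)

    def test_linear_is_one_cm_per_neuron(self):
        cmap = coordinate_map(ModelConfig(N=400, M=2), "linear", 200.0)
        assert cmap.units_per_neuron == 1.0
        assert float(cmap.to_network(200.0)) == pytest.approx(200.0)

    def test_round_trip(self):
        cmap = coordinate_map(ModelConfig(N=600, M=3), "circular", 360.0)
        u = np.arange(1, 21) * 18.0
        np.testing.assert_allclose(cmap.to_physical(cmap.to_network(u)) % 360, u % 360, atol=1e-9)

    def test_circular_range_cap(self):
        with pytest.raises(InformationError):
            coordinate_map(ModelConfig(N=600, M=3), "circular", 720.0)


class TestGammaRescale:
    def test_reference_config_is_identity(self):
        assert rescale_gamma(ModelConfig(N=600, M=3, mapping="circular")) == pytest.approx(0.1)

    def test_doubling_bumps_halves_gamma(self):
        assert rescale_gamma(ModelConfig(N=600, M=6, mapping="circular")) == pytest.approx(0.05)

    def test_linear_mapping_unchanged(self):
        assert rescale_gamma(ModelConfig(N=300, M=3, mapping="linear")) == 0.1


class TestBinRates:
    def test_all_equal_rates_fall_in_lowest_bin(self):
        # degenerate edges: every sample in bin 0 (zero rates)
        assert not bin_rates(np.zeros((4, 5))).any()

    def test_above_percentile_lands_in_top_bin(self, rng):
        x = rng.uniform(0, 1, 10000)
        x[:50] = 100.0
        assert np.all(bin_rates(x)[:50] == 5)

    def test_uniform_rates_occupy_bins_uniformly(self, rng):
        x = rng.uniform(0, 1, 10000)
        b = bin_rates(x)
        counts = np.bincount(b, minlength=6)
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestMutualInformation:
    def test_independent_variables_carry_no_information(self):
        counts = np.full((6, 20), 7.0)
        assert mutual_information(counts) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_code_gives_coordinate_entropy(self):
        counts = np.eye(4) * 13.0
        assert mutual_information(counts) == pytest.approx(2.0)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 60, size=(6, 12)).astype(float)
        assert mutual_information(counts) == pytest.approx(brute_force_mi(counts), abs=1e-12)

    def test_bounds(self, rng):
        counts = rng.integers(0, 40, size=(6, 20)).astype(float) + 1e-9
        mi = mutual_information(counts)
        assert 0.0 <= mi <= np.log2(6)


class TestCues:
    def test_quadrant_labels(self):
        coords = np.arange(1, 21) * 10.0  # u_max = 200
        labels = cue_states(coords, 200.0)
        np.testing.assert_array_equal(labels, np.repeat([0, 1, 2, 3], 5))

    def test_cue_only_information_is_two_bits(self):
        assert cue_only_information() == pytest.approx(2.0, abs=1e-12)

    def test_out_of_range_coordinate_rejected(self):
        with pytest.raises(InformationError):
            cue_states(np.array([250.0]), 200.0)


@pytest.fixture(scope="module")
def noiseless_samples():
    cfg = ModelConfig(N=150, M=1)
    cmap = coordinate_map(cfg, "linear", 20.0)
    return cfg, cmap, mi_experiment(
        cfg, cmap, sigma=0.0, n_coords=5, n_rep=3, duration_ms=400.0, seed=1
    )


class TestMIExperiment:
    def test_noiseless_runs_keep_their_coordinate(self, noiseless_samples):
        cfg, cmap, samples = noiseless_samples
        for ci, u in enumerate(samples.coordinates):
            S = samples.rates[ci, 0, : cfg.N] + samples.rates[ci, 0, cfg.N :]
            pos = bump_positions(S, 1)[0]
            assert pos == pytest.approx(float(cmap.to_network(u)), abs=1.0)

    def test_seeded_experiment_reproducible(self, noiseless_samples):
        cfg, cmap, samples = noiseless_samples
        again = mi_experiment(
            cfg, cmap, sigma=0.0, n_coords=5, n_rep=3, duration_ms=400.0, seed=1
        )
        np.testing.assert_array_equal(samples.rates, again.rates)

    def test_joint_cue_information_refines_cue_alone(self):
        # neuron+cue MI can never fall below what the cues alone convey
        cfg = ModelConfig(N=150, M=1)
        cmap = coordinate_map(cfg, "linear", 150.0)
        samples = mi_experiment(
            cfg, cmap, sigma=0.5, n_coords=8, n_rep=6, duration_ms=400.0, seed=2
        )
        joint = compute_mi(samples, with_cues=True)
        labels = cue_states(samples.coordinates, 150.0)
        counts = np.zeros((4, labels.size))
        counts[labels, np.arange(labels.size)] = 1.0
        cue_alone = mutual_information(counts)
        assert joint.per_neuron_mi.min() >= cue_alone - 1e-9


class TestInformationTrends:
    """Scaled-down versions of the bump-number / network-size orderings.

    Narrow linear coordinate ranges favour more bumps (steeper tuning);
    once the coordinate range exceeds the physical bump distance the
    advantage is lost to bump ambiguity, and quadrant cues restore it.
    """

    N = 300
    SIGMA = 0.5

    def _mi(self, M, u_max, with_cues=False):
        cfg = ModelConfig(N=self.N, M=M)
        cmap = coordinate_map(cfg, "linear", u_max)
        samples = mi_experiment(
            cfg, cmap, sigma=self.SIGMA, n_coords=10, n_rep=16,
            duration_ms=2500.0, seed=42,
        )
        return compute_mi(samples, with_cues=with_cues, seed=0)

    def test_narrow_linear_range_favours_more_bumps(self):
        lo = self._mi(M=1, u_max=20.0)
        hi = self._mi(M=3, u_max=20.0)
        assert hi.mean_mi > lo.mean_mi + 2 * np.hypot(hi.se, lo.se)

    def test_wide_linear_range_loses_the_advantage_without_cues(self):
        # u_max = 200 cm exceeds the 100-neuron bump distance of the 3-bump
        # network: ambiguity cancels the diffusion advantage
        lo = self._mi(M=1, u_max=200.0)
        hi = self._mi(M=3, u_max=200.0)
        assert hi.mean_mi < lo.mean_mi + 2 * np.hypot(hi.se, lo.se)

    def test_cues_restore_the_multi_bump_advantage(self):
        lo = self._mi(M=1, u_max=200.0, with_cues=True)
        hi = self._mi(M=3, u_max=200.0, with_cues=True)
        assert hi.mean_mi > lo.mean_mi + 2 * np.hypot(hi.se, lo.se)
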