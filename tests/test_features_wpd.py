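"""Wavelet-packet decomposition, sub-band statistics and fusion.

Transform correctness is checked against pywt's inverse transform (perfect
reconstruction) and Parseval (energy conservation) rather than against the
forward path itself.
"""

import numpy as np
import pytest
import pywt

from mibci import (
    WaveletPacketFeatureExtractor,
    extract_time_features,
    extract_wpd_features,
    fuse_features,
    subband_stats,
    wpd_decompose,
)
from mibci.exceptions import (
    AlignmentError,
    DecompositionDepthError,
    DegenerateDataError,
)


class TestDecompose:
    def test_sixteen_nodes_at_level_4(self, rng):
        nodes = wpd_decompose(rng.standard_normal(256), level=4)
        assert len(nodes) == 16

    def test_zero_signal_gives_zero_nodes(self):
        nodes = wpd_decompose(np.zeros(256), level=4)
        assert all(np.allclose(n, 0) for n in nodes)

    def test_counts_and_energy_conserved(self, rng):
        y = rng.standard_normal(256)
        nodes = wpd_decompose(y, level=4, mode="periodization")
        assert sum(n.size for n in nodes) == y.size
        energy = sum(float(np.sum(n * n)) for n in nodes)
        assert energy == pytest.approx(float(np.sum(y * y)), rel=1e-8)

    def test_perfect_reconstruction_oracle(self, rng):
        """Assigning the terminal nodes back into a pywt packet tree and
        inverting must reproduce the signal."""
        y = rng.standard_normal(256)
        nodes = wpd_decompose(y, level=4, wavelet="db4", mode="periodization")
        wp_ref = pywt.WaveletPacket(data=y, wavelet="db4",
                                    mode="periodization", maxlevel=4)
        paths = [n.path for n in wp_ref.get_level(4, order="freq")]
        wp2 = pywt.WaveletPacket(data=None, wavelet="db4",
                                 mode="periodization", maxlevel=4)
        for path, data in zip(paths, nodes):
            wp2[path] = data
        rec = wp2.reconstruct(update=False)[:y.size]
        assert np.abs(rec - y).max() < 1e-8

    def test_short_signal_depth_error(self):
        with pytest.raises(DecompositionDepthError):
            wpd_decompose(np.ones(16), level=4, wavelet="db4")

    def test_frequency_ordering_sinusoid_concentration(self):
        """A tone at a terminal node's center frequency concentrates its
        energy in that node (frequency-ascending order sanity check)."""
        fs = 256.0
        n_nodes, width = 16, fs / 2 / 16  # 8 Hz per node
        t = np.arange(1024) / fs
        for node_idx in (2, 9):
            f0 = (node_idx + 0.5) * width
            y = np.sin(2 * np.pi * f0 * t)
            nodes = wpd_decompose(y, level=4, wavelet="db8",
                                  mode="periodization")
            energies = np.array([np.sum(n * n) for n in nodes])
            assert energies[node_idx] / energies.sum() >= 0.8


class TestSubbandStats:
    def test_hand_arithmetic(self):
        stats = subband_stats([[1.0, 2.0, 2.0], [1.0, -1.0, 1.0, -1.0]])
        s0 = stats[0]
        assert s0.mu == pytest.approx(5.0 / 3.0)
        assert s0.pav == pytest.approx(3.0)
        assert s0.sigma == pytest.approx(np.sqrt(2.0 / 9.0))

    def test_symmetric_node_moments(self):
        stats = subband_stats([[1.0, -1.0, 1.0, -1.0], [1.0, 2.0, 2.0]])
        assert stats[0].skew == pytest.approx(0.0)
        assert stats[0].kurt == pytest.approx(1.0)  # z = +/-1, non-excess

    def test_cyclic_gamma_closure(self):
        # two nodes with absolute means 1 and 2
        stats = subband_stats([[1.0, -1.0, 1.5, -0.5], [2.0, -2.0, 2.5, -1.5]])
        mu0, mu1 = stats[0].mu, stats[1].mu
        assert stats[0].gamma == pytest.approx(mu0 / mu1)
        assert stats[1].gamma == pytest.approx(mu1 / mu0)

    def test_adjacent_gamma_drops_last(self):
        stats = subband_stats([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]],
                              gamma_mode="adjacent")
        assert stats[0].gamma == pytest.approx(0.5)
        assert stats[1].gamma == pytest.approx(2.0 / 3.0)
        assert stats[2].gamma is None

    def test_zero_variance_node_rejected(self):
        with pytest.raises(DegenerateDataError):
            subband_stats([[1.0, 1.0, 1.0], [1.0, -1.0]])

    def test_zero_neighbor_mu_rejected_unless_floored(self):
        with pytest.raises(DegenerateDataError):
            subband_stats([[1.0, -1.0], [0.0, 0.0]])

    def test_population_moments_against_numpy(self, rng):
        x = rng.standard_normal(128)
        (s,) = subband_stats([x], gamma_mode="cyclic")
        z = (x - x.mean()) / x.std()
        assert s.skew == pytest.approx(np.mean(z**3))
        assert s.kurt == pytest.approx(np.mean(z**4))
        assert s.sigma == pytest.approx(x.std())


class TestExtractor:
    def test_width_law(self, rng):
        X = rng.standard_normal((4, 3, 256))
        ext = WaveletPacketFeatureExtractor(level=4).fit(X)
        out = ext.transform(X)
        assert out.shape == (4, 3 * 96)

    def test_cells_match_composition_oracle(self, rng):
        X = rng.standard_normal((3, 2, 128))
        ext = WaveletPacketFeatureExtractor(level=3).fit(X)
        out = ext.transform(X)
        names = list(ext.get_feature_names_out())
        t, c = 1, 1
        stats = subband_stats(wpd_decompose(X[t, c], level=3))
        j = names.index("CH:ch01|wpd|b05|skew")
        assert out[t, j] == pytest.approx(stats[5].skew, abs=1e-12)
        j = names.index("CH:ch01|wpd|b00|mu")
        assert out[t, j] == pytest.approx(stats[0].mu, abs=1e-12)

    def test_adjacent_layout_width(self, rng):
        X = rng.standard_normal((2, 2, 256))
        ext = WaveletPacketFeatureExtractor(level=4, gamma_mode="adjacent").fit(X)
        assert ext.transform(X).shape == (2, 2 * 95)


class TestFusion:
    def test_full_set_width_18_channels(self, features_small):
        assert features_small.features.shape[1] == 1836

    def test_full_set_width_13_channels(self, epochs_small):
        ep = epochs_small.pick(
            ["C5", "C3", "C1", "C2", "C4", "C6", "CP5", "CP3", "CP1", "CP2",
             "CP4", "CP6", "P5"])  # any 13 channels
        fm = fuse_features(extract_time_features(ep), extract_wpd_features(ep),
                           ep.labels)
        assert fm.features.shape[1] == 1326

    def test_time_block_comes_first(self, features_small):
        assert features_small.features.columns[0].endswith("|time|NA|rms")
        assert "|wpd|" in features_small.features.columns[-1]

    def test_alternative_layout_also_102_per_channel(self, epochs_small):
        ep = epochs_small.pick(["C3", "C4"])
        tb = extract_time_features(ep, include_activity=True)
        wb = extract_wpd_features(ep, gamma_mode="adjacent")
        fm = fuse_features(tb, wb, ep.labels)
        assert fm.features.shape[1] == 2 * 102  # 7 + 95 per channel

    def test_empty_block_identity(self, epochs_small):
        import pandas as pd

        tb = extract_time_features(ep := epochs_small.pick(["C3"]))
        empty = pd.DataFrame(index=range(ep.n_trials))
        fm = fuse_features(tb, empty, ep.labels)
        assert fm.features.shape == tb.shape
        np.testing.assert_array_equal(fm.X, tb.to_numpy())

    def test_trial_count_mismatch(self, epochs_small):
        tb = extract_time_features(epochs_small.pick(["C3"]))
        wb = extract_wpd_features(epochs_small.pick(["C3"])).iloc[:10]
        with pytest.raises(AlignmentError):
            fuse_features(tb, wb, epochs_small.labels)
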