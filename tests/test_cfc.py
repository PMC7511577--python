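"""Phase-amplitude metric pipeline against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate as sci_integrate
from scipy import stats

from dendrocfc import cfc
from conftest import synthetic_decomposition


def profile_from_p(p):
    """Wrap a probability vector as a profile object."""
    p = np.asarray(p, dtype=float)
    n = p.size
    edges = np.linspace(0.0, 360.0, n + 1)
    return cfc.PhaseAmplitudeProfile(n, edges, p.copy(), p / p.sum())


def mi_oracle(p):
    """MI via scipy's entropy (independent of the implementation route)."""
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    return float((np.log(p.size) - stats.entropy(p)) / np.log(p.size))


class TestModulationIndex:
    def test_uniform_is_zero(self):
        prof = profile_from_p(np.full(72, 1.0))
        assert cfc.modulation_index(prof) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_is_one(self):
        p = np.zeros(72)
        p[5] = 1.0
        assert cfc.modulation_index(profile_from_p(p)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_known_profile(self):
        # hand evaluation of the entropy-deficit formula, natural logs
        p = np.array([0.4, 0.3, 0.2, 0.1])
        expected = (np.log(4) + np.sum(p * np.log(p))) / np.log(4)
        prof = profile_from_p(p)
        assert cfc.modulation_index(prof) == pytest.approx(expected, abs=1e-14)
        assert cfc.modulation_index(prof) == pytest.approx(
            mi_oracle(p), abs=1e-12
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                 max_size=8)
    )
    def test_matches_entropy_oracle(self, weights):
        """For any small profile MI equals the entropy-deficit oracle."""
        prof = profile_from_p(np.array(weights))
        assert cfc.modulation_index(prof) == pytest.approx(
            mi_oracle(weights), abs=1e-12
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                 max_size=8),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, weights, scale):
        """MI and height ratio ignore uniform envelope rescaling."""
        w = np.array(weights)
        a, b = profile_from_p(w), profile_from_p(w * scale)
        assert cfc.modulation_index(a) == pytest.approx(
            cfc.modulation_index(b), abs=1e-12
        )
        assert cfc.height_ratio(a) == pytest.approx(
            cfc.height_ratio(b), abs=1e-12
        )


class TestHeightRatio:
    def test_uniform_is_zero(self):
        assert cfc.height_ratio(profile_from_p(np.ones(8))) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_one_hot_is_one(self):
        p = np.zeros(8)
        p[3] = 2.0
        assert cfc.height_ratio(profile_from_p(p)) == pytest.approx(1.0)

    def test_known_profile(self):
        prof = profile_from_p([0.4, 0.3, 0.2, 0.1])
        assert cfc.height_ratio(prof) == pytest.approx(0.75, abs=1e-12)


class TestDecompose:
    fs = 1000.0
    t = np.arange(int(6000 * fs / 1000)) / fs * 1000.0  # 6 s, ms

    def test_pure_fast_sinusoid(self):
        ts = self.t * 1e-3
        x = 2.5 * np.sin(2 * np.pi * 40.0 * ts)
        dec = cfc.decompose(self.t, x)
        v = dec.valid
        assert np.allclose(dec.envelope[v], 2.5, rtol=0.01)
        assert np.sqrt(np.mean(dec.theta[v] ** 2)) < 0.01 * 2.5
        # phase on a pure fast signal is undefined for binning
        with pytest.raises(ValueError):
            cfc.phase_amplitude_profile(dec, 8)

    def test_pure_slow_sinusoid(self):
        ts = self.t * 1e-3
        x = 3.0 * np.sin(2 * np.pi * 4.0 * ts)
        dec = cfc.decompose(self.t, x)
        v = dec.valid
        # phase advances 360 deg per 250 ms
        ph = np.unwrap(np.deg2rad(dec.phase_deg[v]))
        slope = np.polyfit(dec.t[v], ph, 1)[0]  # rad/ms
        assert slope == pytest.approx(2 * np.pi / 250.0, rel=0.01)
        assert np.all(dec.envelope[v] < 0.02 * 3.0)

    def test_am_signal_envelope_recovery(self):
        ts = self.t * 1e-3
        truth = 1.0 + 0.5 * np.sin(2 * np.pi * 4.0 * ts)
        x = truth * np.sin(2 * np.pi * 40.0 * ts)
        dec = cfc.decompose(self.t, x)
        v = dec.valid
        err = np.sqrt(np.mean((dec.envelope[v] - truth[v]) ** 2))
        assert err < 0.02 * np.sqrt(np.mean(truth[v] ** 2))

    def test_band_edges_beyond_nyquist_rejected(self):
        t = np.arange(500) * 12.5  # 80 Hz sampling
        with pytest.raises(ValueError):
            cfc.decompose(t, np.sin(t))

    def test_window_too_short_rejected(self):
        t = np.arange(1000)  # 1 s at 1 kHz
        with pytest.raises(ValueError):
            cfc.decompose(t, np.random.default_rng(0).normal(size=1000))


class TestProfile:
    def test_constant_envelope_uniform_profile(self):
        dec = synthetic_decomposition(lambda ph: np.ones_like(ph))
        prof = cfc.phase_amplitude_profile(dec, 72)
        assert prof.p == pytest.approx(np.full(72, 1 / 72), abs=1e-12)
        assert prof.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_one_hot_envelope(self):
        dec = synthetic_decomposition(
            lambda ph: ((ph >= 10.0) & (ph < 15.0)).astype(float)
        )
        prof = cfc.phase_amplitude_profile(dec, 72)
        assert prof.p[2] == pytest.approx(1.0)
        assert np.all(prof.p[np.arange(72) != 2] == 0.0)

    def test_cosine_envelope_matches_quadrature(self):
        # <A>(j) over 90-degree bins of 1 + 0.5 cos(phase)
        dec = synthetic_decomposition(
            lambda ph: 1.0 + 0.5 * np.cos(np.deg2rad(ph)), n_samples=400_000
        )
        prof = cfc.phase_amplitude_profile(dec, 4)
        means = []
        for j in range(4):
            lo, hi = np.deg2rad([90.0 * j, 90.0 * (j + 1)])
            val, _ = sci_integrate.quad(
                lambda ph: 1.0 + 0.5 * np.cos(ph), lo, hi
            )
            means.append(val / (hi - lo))
        expected = np.array(means) / np.sum(means)
        assert prof.p == pytest.approx(expected, abs=1e-4)

    def test_empty_bin_raises(self):
        dec = synthetic_decomposition(lambda ph: np.ones_like(ph),
                                      n_samples=50)
        with pytest.raises(cfc.EmptyBinError):
            cfc.phase_amplitude_profile(dec, 72)


class TestAmplitudeRatio:
    fs = 1000.0
    t = np.arange(6000) / fs * 1000.0

    def _ratio(self, a_slow, a_fast):
        ts = self.t * 1e-3
        x = a_slow * np.sin(2 * np.pi * 4 * ts) + a_fast * np.sin(
            2 * np.pi * 40 * ts
        )
        return cfc.amplitude_ratio(cfc.decompose(self.t, x))

    def test_equal_amplitudes(self):
        assert self._ratio(2.0, 2.0) == pytest.approx(1.0, rel=0.02)

    def test_five_to_one(self):
        assert self._ratio(10.0, 2.0) == pytest.approx(5.0, rel=0.02)

    def test_low_pass_filtered_ratio(self):
        # single-pole RC low-pass, 10 Hz cutoff, on an equal-amplitude sum
        g4 = 1.0 / np.sqrt(1.0 + (4.0 / 10.0) ** 2)
        g40 = 1.0 / np.sqrt(1.0 + (40.0 / 10.0) ** 2)
        expected = g4 / g40  # = sqrt(1+16)/sqrt(1+0.16)
        assert self._ratio(2.0 * g4, 2.0 * g40) == pytest.approx(
            expected, rel=0.02
        )


class TestPhaseOfExtrema:
    def test_shifted_cosine(self):
        dec = synthetic_decomposition(
            lambda ph: 1.0 + 0.5 * np.cos(np.deg2rad(ph - 270.0))
        )
        prof = cfc.phase_amplitude_profile(dec, 72)
        ext = cfc.phase_of_extrema(prof)
        assert abs(ext["phase_max"] - 270.0) <= 2.5
        assert abs((ext["phase_min"] - 90.0 + 180) % 360 - 180) <= 2.5

    def test_one_hot_ties_break_early(self):
        p = np.zeros(8)
        p[3] = 1.0
        pass

        ext = cfc.phase_of_extrema(profile_from_p(p))
        assert ext["phase_max"] == pytest.approx(3 * 45.0 + 22.5)
        assert ext["phase_min"] == pytest.approx(22.5)  # earliest zero bin
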