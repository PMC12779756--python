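"""Spike-metric tests: rates, sparse filter, phase extraction, PLV and the
pairwise phase consistency estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.special import i0, i1

from sacskit.core import SpikeTrain, StimProtocol
from sacskit.spikemetrics import (
    PhaseSet,
    firing_rate,
    instantaneous_phase,
    plv,
    ppc,
    spike_phases,
    sparse_filter,
    sqrt_abs_ppc,
)


def ppc_bruteforce(phases: np.ndarray) -> float:
    """O(N²) pairwise oracle: mean of cos(θj − θk) over all pairs j < k."""
    n = phases.size
    acc = 0.0
    for j in range(n - 1):
        acc += np.sum(
            np.cos(phases[j]) * np.cos(phases[j + 1:])
            + np.sin(phases[j]) * np.sin(phases[j + 1:])
        )
    return 2.0 * acc / (n * (n - 1))


class TestFiringRate:
    def test_uniform_60_spikes_over_60s_is_1hz(self):
        tr = SpikeTrain("n", 0, np.arange(60) + 0.5)
        assert firing_rate(tr, 0.0, 60.0).mean_rate == pytest.approx(1.0)

    def test_empty_train_is_0hz(self):
        tr = SpikeTrain("n", 0, np.empty(0))
        assert firing_rate(tr, 0.0, 60.0).mean_rate == 0.0

    def test_matches_direct_count_oracle(self, rng):
        times = np.sort(rng.uniform(0.0, 60.0, size=120))
        tr = SpikeTrain("n", 0, np.unique(times))
        rs = firing_rate(tr, 0.0, 60.0, window=1.0)
        assert rs.mean_rate == pytest.approx(tr.n_spikes / 60.0)
        assert rs.mean_rate == pytest.approx(2.0, abs=0.2)

    def test_partial_trailing_window_discarded(self):
        tr = SpikeTrain("n", 0, np.array([0.5, 1.5, 2.5, 3.1]))
        rs = firing_rate(tr, 0.0, 3.5, window=1.0)
        assert rs.counts.size == 3
        assert rs.mean_rate == pytest.approx(3 / 3.0)

    def test_no_whole_window_rejected(self):
        tr = SpikeTrain("n", 0, np.array([0.1]))
        with pytest.raises(ValueError):
            firing_rate(tr, 0.0, 0.5, window=1.0)


class TestSparseFilter:
    segments = [(0.0, 60.0), (60.0, 120.0)]

    def _constant_rate_train(self, rate: float) -> SpikeTrain:
        return SpikeTrain("n", 0, np.arange(0, 120, 1.0 / rate) + 1e-4)

    def test_constant_0p3hz_neuron_retained(self):
        retained, mask = sparse_filter([self._constant_rate_train(0.3)], self.segments)
        assert mask[0]

    def test_silent_neuron_discarded(self):
        retained, mask = sparse_filter([SpikeTrain("n", 0, np.empty(0))], self.segments)
        assert not mask[0]

    def test_exactly_threshold_rate_retained(self):
        # strict "<" reading: 0.25 Hz in every window is not sparse
        retained, mask = sparse_filter([self._constant_rate_train(0.25)], self.segments)
        assert mask[0]

    def test_just_below_threshold_discarded(self):
        retained, mask = sparse_filter([self._constant_rate_train(0.2)], self.segments)
        assert not mask[0]


class TestInstantaneousPhase:
    def test_cosine_analytic_identity(self):
        rate, f = 1000.0, 8.0
        t = np.arange(int(4 * rate)) / rate
        ph = instantaneous_phase(np.cos(2 * np.pi * f * t))
        inner = slice(int(rate), int(3 * rate))
        expected = np.mod(2 * np.pi * f * t[inner], 2 * np.pi)
        d = np.angle(np.exp(1j * (ph[inner] - expected)))
        assert np.max(np.abs(d)) < 0.02

    def test_sine_lags_cosine_by_half_pi(self):
        rate, f = 1000.0, 8.0
        t = np.arange(int(4 * rate)) / rate
        pc = instantaneous_phase(np.cos(2 * np.pi * f * t))
        ps = instantaneous_phase(np.sin(2 * np.pi * f * t))
        inner = slice(int(rate), int(3 * rate))
        d = np.angle(np.exp(1j * (pc[inner] - ps[inner])))
        assert np.median(d) == pytest.approx(np.pi / 2, abs=0.02)

    def test_phase_advances_two_pi_between_positive_peaks(self):
        rate, f = 2000.0, 10.0
        t = np.arange(int(3 * rate)) / rate
        x = np.cos(2 * np.pi * f * t)
        ph = np.unwrap(np.angle(np.exp(1j * instantaneous_phase(x))))
        peaks = np.where((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]))[0] + 1
        peaks = peaks[(peaks > rate // 2) & (peaks < 2.5 * rate)]
        dph = np.diff(ph[peaks])
        assert np.allclose(dph, 2 * np.pi, atol=0.05)

    def test_all_zero_waveform_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(1000))


class TestSpikePhases:
    def test_spikes_at_waveform_positive_peaks(self):
        # analytic-signal convention: the phase at a positive peak of the
        # waveform is 0, whatever the waveform's sine/cosine form
        rate, f = 2000.0, 10.0
        t = np.arange(int(2 * rate)) / rate
        ph = instantaneous_phase(np.sin(2 * np.pi * f * t))
        peak_times = (np.arange(5, 15) + 0.25) / f  # sin peaks at (k + 1/4)/f
        tr = SpikeTrain("n", 0, peak_times)
        ps = spike_phases(tr, ph, rate)
        d = np.angle(np.exp(1j * ps.phases))
        assert np.max(np.abs(d)) < 0.1

    def test_empty_train_gives_empty_set(self):
        ps = spike_phases(SpikeTrain("n", 0, np.empty(0)), np.zeros(100) + 1.0, 100.0)
        assert ps.n == 0

    def test_out_of_support_spikes_dropped_with_warning(self):
        tr = SpikeTrain("n", 0, np.array([0.5, 99.0]))
        with pytest.warns(UserWarning):
            ps = spike_phases(tr, np.ones(100), 100.0)
        assert ps.n == 1

    def test_jittered_spikes_circular_mean_near_target(self, rng):
        p = StimProtocol(40.0, 100.0, 0.0, 60.0, 24000.0)
        t = np.arange(int(10 * 24000)) / 24000.0
        ph_series = p.phase(t)
        base = (np.arange(40, 360) + 0.25) / 40.0  # positive sine peaks
        spikes = np.sort(base + rng.normal(0, 0.5e-3, base.size))
        ps = spike_phases(SpikeTrain("n", 0, spikes), ph_series, 24000.0)
        circ_mean = np.angle(np.mean(np.exp(1j * ps.phases)))
        assert abs(np.angle(np.exp(1j * circ_mean))) < 0.15


class TestPlvPpc:
    def test_identical_phases(self):
        ps = PhaseSet(np.full(7, 1.3))
        assert plv(ps) == pytest.approx(1.0)
        assert ppc(ps) == pytest.approx(1.0)
        assert sqrt_abs_ppc(ps) == pytest.approx(1.0)

    def test_antipodal_pair_plv_zero(self):
        ps = PhaseSet(np.array([0.0, np.pi]))
        assert plv(ps) == pytest.approx(0.0, abs=1e-12)
        # single pair contributes cos(π) = −1, so √|PPC| = 1: documented edge
        assert sqrt_abs_ppc(ps) == pytest.approx(1.0)

    def test_known_small_sets(self):
        assert plv(PhaseSet(np.array([0.0, np.pi / 2]))) == pytest.approx(np.sqrt(2) / 2)
        quad = PhaseSet(np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert ppc(quad) == pytest.approx(-1.0 / 3.0)

    def test_fast_path_equals_bruteforce(self, rng):
        for n in (2, 3, 5, 20, 100, 500):
            phases = rng.uniform(0, 2 * np.pi, size=n)
            assert ppc(PhaseSet(phases)) == pytest.approx(
                ppc_bruteforce(phases), abs=1e-12
            )

    def test_rotation_invariance(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=50)
        for shift in (0.3, 2.0, 5.5):
            assert plv(PhaseSet(phases + shift)) == pytest.approx(plv(PhaseSet(phases)))
            assert ppc(PhaseSet(phases + shift)) == pytest.approx(ppc(PhaseSet(phases)))

    def test_undefined_cases_signalled(self):
        with pytest.raises(ValueError):
            plv(PhaseSet(np.empty(0)))
        with pytest.raises(ValueError):
            ppc(PhaseSet(np.array([0.5])))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        phases=arrays(
            float,
            st.integers(min_value=2, max_value=200),
            elements=st.floats(0.0, 2 * np.pi, exclude_max=True),
        )
    )
    def test_ppc_bounds_and_fastpath_property(self, phases):
        val = ppc(PhaseSet(phases))
        n = phases.size
        assert -1.0 / (n - 1) - 1e-9 <= val <= 1.0 + 1e-9
        assert val == pytest.approx(ppc_bruteforce(phases), abs=1e-10)
        # rotating all phases leaves the statistic unchanged
        assert ppc(PhaseSet(phases + 1.234)) == pytest.approx(val, abs=1e-9)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_ppc_unbiased_for_plv_squared(self, kappa, rng):
        # mean PPC over replicates approaches (I1(κ)/I0(κ))², while mean PLV²
        # carries the ≈ (1 − PLV²)/N positive bias
        target = (i1(kappa) / i0(kappa)) ** 2
        n, reps = 30, 2000
        ppcs = np.empty(reps)
        plv2 = np.empty(reps)
        for r in range(reps):
            phases = rng.vonmises(0.0, kappa, size=n)
            ps = PhaseSet(phases)
            ppcs[r] = ppc(ps)
            plv2[r] = plv(ps) ** 2
        se = ppcs.std(ddof=1) / np.sqrt(reps)
        assert abs(ppcs.mean() - target) < 4 * se
        expected_bias = (1 - target) / n
        assert plv2.mean() - target == pytest.approx(expected_bias, rel=0.5)
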