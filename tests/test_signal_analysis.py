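"""Zero-phase filtering, epoching, rejection, ERP averaging and PLV."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.special import i0, i1

from cortimap import (BANDS, DomainError, Recording, average_erp,
                      bandpass_zero_phase, plv_from_phases, plv_matrix,
                      reject, segment)
from cortimap.fixtures import make_coupled_pair


def tone(freq, fs=2500.0, dur=10.0, amp=1.0, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestBandpassZeroPhase:
    def test_passband_amplitude_and_phase_preserved(self):
        fs = 2500.0
        rec = Recording(tone(10.0, fs), fs, [])
        out = bandpass_zero_phase(rec, 0.5, 250.0).data[0]
        mid = slice(int(2 * fs), int(8 * fs))  # away from edges
        ref = rec.data[0]
        amp_ratio = out[mid].std() / ref[mid].std()
        assert 0.99 <= amp_ratio <= 1.01
        # zero-phase: projection onto the quadrature carrier stays ~0
        quad = tone(10.0, fs, 10.0, phase=np.pi / 2)
        shift = np.arctan2((out[mid] * quad[mid]).mean(),
                           (out[mid] * ref[mid]).mean())
        assert abs(shift) < 0.01

    def test_dc_offset_removed(self):
        fs = 2500.0
        rec = Recording(np.full(int(5 * fs), 3.0), fs, [])
        out = bandpass_zero_phase(rec, 0.5, 250.0).data[0]
        mid = slice(int(2 * fs), int(3 * fs))
        assert np.abs(out[mid]).max() < 0.03  # < 1% of the input offset

    def test_impulse_response_symmetric(self):
        # long buffer: the 0.5 Hz high-pass tail must die before the edges
        fs = 2500.0
        x = np.zeros(int(20 * fs))
        x[len(x) // 2] = 1.0
        out = bandpass_zero_phase(Recording(x, fs, []), 0.5, 250.0).data[0]
        center = len(x) // 2  # where the extremum of a zero-phase IR sits
        assert int(np.argmax(np.abs(out))) == center
        k = 200
        assert np.abs(out[center - k:center] -
                      out[center + 1:center + 1 + k][::-1]).max() <= 1e-6

    def test_nyquist_violation_rejected(self):
        rec = Recording(np.zeros(1000), 100.0, [])
        with pytest.raises(DomainError, match="Nyquist"):
            bandpass_zero_phase(rec, 0.5, 50.0)


class TestSegment:
    def test_default_window_duration_4300ms(self):
        fs = 1000.0
        rec = Recording(np.zeros((2, 20000)), fs, [5000, 12000])
        ep = segment(rec, -800.0, 3500.0)
        assert ep.duration_ms == pytest.approx(4300.0)
        assert ep.data.shape == (2, 2, 4300)

    def test_window_is_half_open_and_aligned(self):
        fs = 1000.0
        data = np.arange(20000.0)[None]
        ep = segment(Recording(data, fs, [5000]), -800.0, 3500.0)
        assert ep.data[0, 0, 0] == 4200.0     # onset - 800 samples
        assert ep.data[0, 0, -1] == 8499.0    # onset + 3500 - 1 (half-open)

    def test_zero_events_zero_trials(self):
        ep = segment(Recording(np.zeros((3, 9000)), 1000.0, []))
        assert ep.n_trials == 0

    def test_edge_event_skipped(self):
        rec = Recording(np.zeros((1, 9000)), 1000.0, [100, 5000])
        ep = segment(rec)
        assert ep.n_trials == 1

    def test_inverted_window_rejected(self):
        rec = Recording(np.zeros((1, 9000)), 1000.0, [5000])
        with pytest.raises(DomainError):
            segment(rec, 100.0, -100.0)


class TestReject:
    def _epochs(self, rng, n=24, amp=1.0):
        t = np.linspace(0, 1, 500)
        base = np.sin(2 * np.pi * 5 * t)
        data = base[None, None] * np.ones((n, 2, 1)) \
            + 0.1 * rng.normal(size=(n, 2, 500))
        rec_like = data * amp
        from cortimap import EpochSet
        return EpochSet(data=rec_like, fs=500.0, window=(0.0, 1000.0))

    def test_clean_epochs_all_kept(self, rng):
        ep = self._epochs(rng)
        assert reject(ep).n_trials == ep.n_trials

    def test_injected_artifact_epoch_dropped(self, rng):
        ep = self._epochs(rng)
        d = ep.data.copy()
        d[7, 1, 250] += 100.0 * np.abs(d).max()  # a huge transient spike
        ep2 = replace(ep, data=d)
        out = reject(ep2)
        assert out.n_trials == ep.n_trials - 1
        assert np.abs(out.data).max() < 10.0  # the artifact epoch is gone

    def test_infinite_threshold_keeps_all(self, rng):
        ep = self._epochs(rng)
        d = ep.data.copy()
        d[0] *= 1000.0
        assert reject(replace(ep, data=d), np.inf).n_trials == ep.n_trials


class TestAverageErp:
    def test_mean_of_identical_epochs_is_the_epoch(self, rng):
        one = rng.normal(size=(1, 3, 400))
        from cortimap import EpochSet
        ep = EpochSet(data=np.repeat(one, 11, axis=0), fs=400.0,
                      window=(0.0, 1000.0))
        assert np.abs(average_erp(ep) - one[0]).max() <= 1e-12

    def test_noise_shrinks_as_inverse_sqrt_n(self, rng):
        n, sd = 100, 2.0
        sig = np.sin(np.linspace(0, 8 * np.pi, 600))
        data = sig[None, None] + rng.normal(0, sd, size=(n, 1, 600))
        from cortimap import EpochSet
        ep = EpochSet(data=data, fs=600.0, window=(0.0, 1000.0))
        resid = average_erp(ep)[0] - sig
        assert resid.std() == pytest.approx(sd / np.sqrt(n), rel=0.3)

    def test_pure_noise_erp_shrinks_with_n(self, rng):
        from cortimap import EpochSet
        def max_erp(n):
            data = rng.normal(size=(n, 1, 300))
            ep = EpochSet(data=data, fs=300.0, window=(0.0, 1000.0))
            return np.abs(average_erp(ep)).max()
        assert max_erp(400) < max_erp(4)

    def test_empty_rejected(self):
        from cortimap import EpochSet
        ep = EpochSet(data=np.zeros((0, 2, 100)), fs=100.0,
                      window=(0.0, 1000.0))
        with pytest.raises(DomainError):
            average_erp(ep)


class TestPlv:
    def test_exact_copy_gives_unity(self, rng):
        x = rng.normal(size=30000)
        rec = Recording(np.vstack([x, x]), 1000.0, [])
        assert plv_matrix(rec, "theta").values[0, 1] == pytest.approx(
            1.0, abs=1e-9)

    def test_constant_phase_lag_gives_unity(self):
        fs = 1000.0
        a = tone(6.0, fs, 30.0)
        b = tone(6.0, fs, 30.0, phase=1.1)
        rec = Recording(np.vstack([a, b]), fs, [])
        assert plv_matrix(rec, "theta").values[0, 1] >= 1.0 - 1e-3

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_von_mises_phase_pairs_match_bessel_ratio(self, kappa):
        _, phases = make_coupled_pair(kappa, fs=1000.0, duration_s=100.0,
                                      seed=7, return_phases=True)
        plv = plv_from_phases(phases)[0, 1]
        assert plv == pytest.approx(i1(kappa) / i0(kappa), abs=0.02)

    def test_independent_noise_near_zero(self, rng):
        rec = Recording(rng.normal(size=(2, 100000)), 1000.0, [])
        # wide band -> ~1e4 effective samples; Rayleigh null well below 0.05
        assert plv_matrix(rec, "high_gamma").values[0, 1] < 0.05

    def test_matrix_properties(self, rng):
        rec = Recording(rng.normal(size=(4, 20000)), 1000.0, [])
        m = plv_matrix(rec, "alpha").values
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert (m >= 0).all() and (m <= 1).all()

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.normal(size=(2, 20000))
        a = plv_matrix(Recording(x, 1000.0, []), "beta").values[0, 1]
        x2 = x * np.array([[3.7], [0.2]])
        b = plv_matrix(Recording(x2, 1000.0, []), "beta").values[0, 1]
        assert a == pytest.approx(b, abs=1e-12)

    def test_common_phase_offset_invariance(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(2, 50000))
        assert plv_from_phases(ph + 0.9)[0, 1] == pytest.approx(
            plv_from_phases(ph)[0, 1], abs=1e-12)

    def test_band_above_nyquist_rejected(self, rng):
        rec = Recording(rng.normal(size=(2, 5000)), 400.0, [])
        with pytest.raises(DomainError):
            plv_matrix(rec, "high_gamma")  # 250 Hz >= 200 Hz Nyquist

    def test_epoched_plv_concatenates_trials(self, rng):
        fs = 500.0
        a = tone(6.0, fs, 40.0)
        b = tone(6.0, fs, 40.0, phase=0.8)
        rec = Recording(np.vstack([a, b]), fs,
                        np.arange(2000, 18000, 3000))
        ep = segment(rec, -800.0, 3500.0)
        assert plv_matrix(ep, "theta").values[0, 1] >= 1.0 - 1e-3


def test_pipeline_defaults_match_clinical_parameterization():
    """Default filter band, epoch window and display threshold agree with
    standard iEEG language-mapping practice and with each other."""
    from cortimap.signal_analysis import (DEFAULT_BANDPASS,
                                          DEFAULT_WINDOW_MS,
                                          DISPLAY_PLV_THRESHOLD)
    assert DEFAULT_BANDPASS == (0.5, 250.0)
    assert DEFAULT_WINDOW_MS == (-800.0, 3500.0)
    assert DEFAULT_WINDOW_MS[1] - DEFAULT_WINDOW_MS[0] == 4300.0
    assert DISPLAY_PLV_THRESHOLD == 0.6
    assert [(b.lo, b.hi) for b in BANDS.values()] == [
        (1, 4), (4, 8), (8, 16), (16, 30), (30, 80), (80, 250)]
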