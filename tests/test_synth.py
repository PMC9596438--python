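"""Synthetic EEG generator: harmonic purity, mixing identity, determinism."""

import numpy as np
import pytest

from dispvep import synth
from dispvep.harmonics import FilterSpec, apply_spectral_filter, cycle_average

CFG_TINY = synth.SimConfig(
    n_subjects=1, n_trials_per_condition=1, n_channels=8,
    noise_amplitude=0.0, sensor_noise_amplitude=0.0, subject_gain_sd=0.0,
    active_duration=10.0 / 14.0, seed=0,
)


def _harmonic_energy(waveform, fs, f1, parity):
    """FFT oracle: fraction of total energy at odd/even multiples of f1."""
    n = len(waveform)
    power = np.abs(np.fft.rfft(waveform)) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    df = fs / n
    total = power[1:].sum()
    sel = 0.0
    k = 1
    while k * f1 <= freqs[-1]:
        if (k % 2 == 1) == (parity == "odd"):
            sel += power[int(round(k * f1 / df))]
        k += 1
    return sel / total


class TestTopographies:
    def test_columns_unit_norm_and_peak_at_center(self):
        layout = synth.channel_layout(64)
        centers = [layout[10], layout[40]]
        topo = synth.make_topographies(64, layout, centers)
        assert np.allclose(np.linalg.norm(topo, axis=0), 1.0, atol=1e-12)
        assert np.argmax(topo[:, 0]) == 10
        assert np.argmax(topo[:, 1]) == 40
        assert abs(np.corrcoef(topo[:, 0], topo[:, 1])[0, 1]) < 1.0

    def test_more_sources_than_channels_raises(self):
        layout = synth.channel_layout(3)
        with pytest.raises(ValueError):
            synth.make_topographies(3, layout, np.zeros((4, 2)))


class TestSourceWaveforms:
    def test_transient_is_exactly_halfperiod_symmetric(self):
        cfg = CFG_TINY
        w = synth.source_cycle_waveform(synth.SourceSpec("transient"), cfg)
        assert np.abs(w - np.roll(w, cfg.cycle_samples // 2)).max() == 0.0

    def test_sustained_is_exactly_halfperiod_antisymmetric(self):
        cfg = CFG_TINY
        w = synth.source_cycle_waveform(synth.SourceSpec("sustained"), cfg)
        assert np.abs(w + np.roll(w, cfg.cycle_samples // 2)).max() == 0.0

    def test_sustained_energy_purely_odd_harmonic(self):
        cfg = CFG_TINY
        w = np.tile(synth.source_cycle_waveform(synth.SourceSpec("sustained"), cfg), 14)
        assert _harmonic_energy(w, cfg.sampling_rate, cfg.f1, "even") < 1e-10
        assert _harmonic_energy(w, cfg.sampling_rate, cfg.f1, "odd") > 1.0 - 1e-10

    def test_transient_zero_before_onset_peak_near_100ms(self):
        cfg = CFG_TINY
        w = synth.source_cycle_waveform(synth.SourceSpec("transient"), cfg)
        t_ms = np.arange(len(w)) * 1000.0 / cfg.sampling_rate
        assert np.abs(w[t_ms < 75.0]).max() == 0.0
        peak_ms = t_ms[np.argmax(w)]
        assert 90.0 <= peak_ms <= 110.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            synth.SourceSpec("oscillatory")

    def test_dot_update_epoch_is_pure_f2(self):
        # 5 s spans whole F2 cycles so the 20 Hz line is bin-aligned
        cfg = synth.SimConfig(n_subjects=1, n_trials_per_condition=1, n_channels=8,
                              active_duration=5.0, seed=0)
        w = synth.source_epoch_waveform(synth.SourceSpec("dot_update"), cfg)
        power = np.abs(np.fft.rfft(w)) ** 2
        freqs = np.fft.rfftfreq(len(w), 1.0 / cfg.sampling_rate)
        peak = freqs[np.argmax(power)]
        assert peak == pytest.approx(cfg.f2)
        assert power.max() / power.sum() > 1.0 - 1e-10


class TestSimulateDataset:
    def test_noiseless_limit_equals_mixing_model(self, small_sim):
        cfg, ts = small_sim
        sources = synth.default_sources()
        layout = synth.channel_layout(cfg.n_channels)
        topo = synth.make_topographies(
            cfg.n_channels, layout, [s.topography_center for s in sources]
        )
        # plane:attend_fixation -> sustained scaled by 1/8, no task extra
        expected = np.zeros((cfg.n_channels, cfg.n_samples))
        for i, s in enumerate(sources):
            w = synth.source_epoch_waveform(s, cfg)
            if s.kind == "sustained":
                w = w / 8.0
            expected += np.outer(topo[:, i], w)
        c = ts.condition_index("plane:attend_fixation")
        for trial in range(cfg.n_trials_per_condition):
            assert np.allclose(ts.data[0, c, trial], expected, atol=1e-12)

    def test_seed_determinism_bit_identical(self):
        cfg = synth.SimConfig(n_subjects=2, n_trials_per_condition=2, n_channels=8,
                              active_duration=10.0 / 14.0, seed=9)
        a = synth.simulate_dataset(cfg)
        b = synth.simulate_dataset(cfg)
        assert np.array_equal(a.data, b.data)

    def test_plane_odd_harmonic_amplitude_is_one_eighth_of_grating(self, small_sim):
        cfg, ts = small_sim
        fs = ts.sampling_rate
        spec = FilterSpec("odd", f1=cfg.f1, f2=cfg.f2)
        amps = {}
        for cond in ("plane:attend_fixation", "grating:attend_fixation"):
            c = ts.condition_index(cond)
            trace = ts.data[0, c, 0]
            filt = apply_spectral_filter(trace, spec, fs)
            amps[cond] = np.abs(filt).max()
        ratio = amps["grating:attend_fixation"] / amps["plane:attend_fixation"]
        assert ratio == pytest.approx(8.0, rel=1e-6)

    def test_task_extra_onset_sharp_at_184ms(self, small_sim):
        cfg, ts = small_sim
        c_att = ts.condition_index("grating:attend_stimulus")
        c_fix = ts.condition_index("grating:attend_fixation")
        diff = ts.data[0, c_att, 0] - ts.data[0, c_fix, 0]
        cyc, _ = cycle_average(diff, cfg.f1, cfg.sampling_rate)
        t_ms = np.arange(cyc.shape[-1]) * 1000.0 / cfg.sampling_rate
        pre = np.abs(cyc[..., t_ms < 183.0]).max()
        post = np.abs(cyc[..., (t_ms > 200.0) & (t_ms < 350.0)]).max()
        assert pre < 1e-12
        assert post > 0.1

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_dataset(CFG_TINY, sources=[])


class TestEOG:
    def test_silent_configuration_gives_flat_traces(self):
        out = synth.simulate_eog(CFG_TINY, saccade_rate=0.0, noise_amplitude=0.0)
        assert np.abs(out["heog"]).max() == 0.0
        assert np.abs(out["veog"]).max() == 0.0

    def test_condition_variance_ratio_recovered(self):
        cfg = synth.SimConfig(n_subjects=10, n_trials_per_condition=60, n_channels=8,
                              active_duration=10.0, seed=2)
        out = synth.simulate_eog(cfg, saccade_rate=1.0, amplitude=20.0,
                                 condition_variance_ratio=1.1, noise_amplitude=5.0)
        v = out["heog"].var(axis=-1, ddof=1)
        ratio = v[:, 1].mean() / v[:, 0].mean()
        assert ratio == pytest.approx(1.1, rel=0.03)

    def test_eog_independent_of_vep_stream(self):
        # same master seed drives both generators through separate branches
        cfg = synth.SimConfig(n_subjects=2, n_trials_per_condition=1, n_channels=8,
                              active_duration=10.0 / 14.0, seed=4)
        a = synth.simulate_eog(cfg)
        b = synth.simulate_eog(cfg)
        assert np.array_equal(a["heog"], b["heog"])
        ts = synth.simulate_dataset(cfg)
        r = np.corrcoef(a["heog"][0, 0, 0, : ts.data.shape[-1]], ts.data[0, 0, 0, 0])[0, 1]
        assert abs(r) < 0.25


class TestObserver:
    def test_probability_at_threshold_is_82_percent(self):
        assert synth.observer_probability(0.1, threshold=0.1, lapse=0.0) == pytest.approx(0.82)

    def test_probability_approaches_one_minus_lapse(self):
        p = synth.observer_probability(0.5, threshold=0.05, slope=6.0, lapse=0.02)
        assert p == pytest.approx(0.98, abs=0.01)

    def test_seeded_sequence_reproducible(self):
        a = [synth.simulate_observer(0.1, rng=np.random.default_rng(7)) for _ in range(5)]
        b = [synth.simulate_observer(0.1, rng=np.random.default_rng(7)) for _ in range(5)]
        assert a == b
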