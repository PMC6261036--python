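"""Wavelet NZT coefficient selection, denoising and P1 alignment."""

import numpy as np
import pytest

from eegduo import EpochSet
from eegduo.correction import (
    CoefficientMask,
    align_trials_by_p1,
    denoise_trials,
    select_coefficients_nzt,
    time_corrected_erp,
)
from eegduo.erp import average_erp
from eegduo.simulate import gonogo_template

FS = 128.0
WINDOW = (-200.0, 800.0)


def make_epochs(data, conditions=None):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    return EpochSet(data, FS, tuple(f"C{i}" for i in range(data.shape[1])),
                    WINDOW, np.array(conditions or ["a"] * n, dtype=object),
                    np.ones(n, dtype=bool))


def template_trials(n, noise_sd=0.0, seed=0, shifts=None):
    t = (np.arange(128) - 26) * 1000.0 / FS
    base = gonogo_template().waveform("Go", t)
    rng = np.random.default_rng(seed)
    data = np.empty((n, 1, 128))
    for i in range(n):
        x = base if shifts is None else np.roll(base, shifts[i])
        data[i, 0] = x + rng.standard_normal(128) * noise_sd
    return make_epochs(data), base


def full_mask(ep, keep=True):
    ref = select_coefficients_nzt(ep, ("C0",))
    return CoefficientMask(ref.wavelet, ref.n_scales, ref.n_samples,
                           [np.full(k.shape, keep) for k in ref.keep],
                           [np.zeros(k.shape) for k in ref.keep],
                           ref.threshold)


class TestNztSelection:
    def test_noiseless_template_reconstructed_below_one_percent(self):
        ep, base = template_trials(10)
        mask = select_coefficients_nzt(ep, ("C0",))
        den = denoise_trials(ep, mask)
        err = np.linalg.norm(den.data[0, 0] - base) / np.linalg.norm(base)
        assert err < 0.01

    def test_false_selection_rate_on_pure_noise(self):
        fractions = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ep = make_epochs(rng.standard_normal((30, 1, 128)))
            mask = select_coefficients_nzt(ep, ("C0",))
            fractions.append(mask.n_kept / mask.n_cells)
        assert np.mean(fractions) <= 0.05

    def test_denoised_average_tracks_template_at_0db(self):
        """At single-trial SNR 0 dB the denoised trials correlate with the
        template better than the raw trials do, on average."""
        gains = []
        for seed in range(10):
            ep, base = template_trials(60, noise_sd=base_rms(), seed=seed)
            mask = select_coefficients_nzt(ep, ("C0",))
            den = denoise_trials(ep, mask)
            raw_r = np.mean([np.corrcoef(tr[0], base)[0, 1]
                             for tr in ep.data])
            den_r = np.mean([np.corrcoef(tr[0], base)[0, 1]
                             for tr in den.data])
            gains.append(den_r - raw_r)
        assert np.mean(gains) > 0.1

    def test_epoch_length_constraint(self):
        ep = make_epochs(np.zeros((5, 1, 128)))
        bad = EpochSet(np.zeros((5, 1, 120)), FS, ("C0",), (-200.0, 737.5),
                       np.array(["a"] * 5, dtype=object), np.ones(5, bool))
        with pytest.raises(ValueError):
            select_coefficients_nzt(bad, ("C0",))
        select_coefficients_nzt(
            make_epochs(np.random.default_rng(0).standard_normal((5, 1, 128))),
            ("C0",))  # valid length passes


def base_rms():
    t = (np.arange(128) - 26) * 1000.0 / FS
    return float(np.sqrt(np.mean(gonogo_template().waveform("Go", t) ** 2)))


class TestDenoiseTrials:
    def test_all_pass_mask_is_identity(self, rng):
        ep = make_epochs(rng.standard_normal((6, 2, 128)))
        den = denoise_trials(ep, full_mask(ep, keep=True))
        assert np.allclose(den.data, ep.data, atol=1e-9)

    def test_all_reject_mask_zeroes_trials(self, rng):
        ep = make_epochs(rng.standard_normal((6, 2, 128)))
        den = denoise_trials(ep, full_mask(ep, keep=False))
        assert np.allclose(den.data, 0.0)

    def test_linearity_mean_of_denoised_equals_denoised_mean(self, rng):
        ep = make_epochs(rng.standard_normal((12, 1, 128)))
        mask = select_coefficients_nzt(ep, ("C0",))
        den = denoise_trials(ep, mask)
        mean_ep = make_epochs(ep.data.mean(axis=0, keepdims=True))
        den_mean = denoise_trials(mean_ep, mask)
        assert np.allclose(den.data.mean(axis=0), den_mean.data[0], atol=1e-9)

    def test_incompatible_mask_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((6, 1, 128)))
        mask = select_coefficients_nzt(ep, ("C0",))
        mask.n_samples = 256
        with pytest.raises(ValueError):
            denoise_trials(ep, mask)

    def test_mask_serialization_round_trip(self, rng):
        ep = make_epochs(rng.standard_normal((6, 1, 128)))
        mask = select_coefficients_nzt(ep, ("C0",))
        d = mask.to_dict()
        assert d["n_scales"] == 4
        assert sum(sum(b["keep"]) for b in d["bands"].values()) == mask.n_kept


class TestAlignment:
    def test_known_jitter_inverted_exactly(self):
        shifts = [0, 3, -4, 2, -1, 0, 4, -3]
        ep, _ = template_trials(len(shifts), shifts=shifts)
        al = align_trials_by_p1(ep, ("C0",), (100.0, 250.0),
                                target_latency_ms=164.0625)
        assert np.array_equal(al.shifts_samples, -np.array(shifts))

    def test_identical_trials_get_zero_shifts(self):
        ep, _ = template_trials(6)
        al = align_trials_by_p1(ep, ("C0",), (130.0, 200.0))
        assert np.all(al.shifts_samples == 0)
        assert al.aligned.all()

    def test_unalignable_trials_flagged_and_unshifted(self):
        data = np.zeros((3, 1, 128))
        data[0, 0] = np.linspace(0, 1, 128)  # no interior maximum
        t = (np.arange(128) - 26) * 1000.0 / FS
        data[1, 0] = np.exp(-((t - 160.0) ** 2) / 200.0)
        data[2, 0] = np.exp(-((t - 180.0) ** 2) / 200.0)
        al = align_trials_by_p1(make_epochs(data), ("C0",), (130.0, 200.0))
        assert not al.aligned[0]
        assert al.shifts_samples[0] == 0
        assert al.aligned[1] and al.aligned[2]

    def test_lc_latencies_cluster_at_delay_plus_template_p1(self, small_epochs):
        ep = small_epochs["LC"]
        mask = select_coefficients_nzt(ep, ("F3", "F4"))
        den = denoise_trials(ep, mask)
        al = align_trials_by_p1(den, ("F3", "F4"), (240.0, 310.0))
        med = np.nanmedian(al.trial_latencies_ms)
        assert abs(med - (164.0 + 93.75)) <= 2 * 1000.0 / FS

    def test_edge_fill_uses_edge_value(self):
        data = np.zeros((1, 1, 128))
        t = (np.arange(128) - 26) * 1000.0 / FS
        data[0, 0] = np.exp(-((t - 140.0) ** 2) / 200.0) + 5.0
        al = align_trials_by_p1(make_epochs(data), ("C0",), (100.0, 200.0),
                                target_latency_ms=180.0)
        assert al.shifts_samples[0] > 0
        assert np.allclose(al.epochs.data[0, 0, :al.shifts_samples[0]],
                           data[0, 0, 0])


class TestTimeCorrectedErp:
    def test_zero_jitter_tcerp_equals_plain_erp(self):
        ep, _ = template_trials(8)
        al = align_trials_by_p1(ep, ("C0",), (130.0, 200.0))
        tc = time_corrected_erp(al, "a", ("C0",))
        plain = average_erp(ep, "a", ("C0",))
        assert np.allclose(tc.values, plain.values)

    def test_alignment_improves_template_correlation_under_jitter(self):
        rng = np.random.default_rng(3)
        gains = []
        for seed in range(8):
            shifts = rng.integers(-4, 5, size=40)
            ep, base = template_trials(40, noise_sd=3.0, seed=seed,
                                       shifts=shifts)
            raw = average_erp(ep, "a", ("C0",))
            al = align_trials_by_p1(ep, ("C0",), (100.0, 240.0))
            tc = time_corrected_erp(al, "a", ("C0",))
            gains.append(np.corrcoef(tc.values, base)[0, 1]
                         - np.corrcoef(raw.values, base)[0, 1])
        assert np.mean(gains) > 0.0

    def test_correction_removes_constant_intersystem_delay(self, small_epochs):
        """After P1 alignment to a shared target, the paired sessions'
        averaged waveforms peak within one sample of each other."""
        from eegduo.erp import COMPONENT_POLARITY, detect_peak, smooth_waveform

        als = {}
        target = None
        for name, win in (("HQ", (130.0, 200.0)), ("LC", (240.0, 310.0))):
            ep = small_epochs[name]
            mask = select_coefficients_nzt(ep, ("F3", "F4"))
            den = denoise_trials(ep, mask)
            als[name] = align_trials_by_p1(den, ("F3", "F4"), win,
                                           target_latency_ms=target)
            target = als[name].target_latency_ms if target is None else target
        peaks = {}
        for name, al in als.items():
            w = smooth_waveform(time_corrected_erp(al, None, ("F3", "F4")),
                                20.0)
            peaks[name] = detect_peak(w, "P1", COMPONENT_POLARITY["P1"],
                                      (100.0, 220.0))
        assert abs(peaks["LC"].latency_ms - peaks["HQ"].latency_ms) \
            <= 1000.0 / FS
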