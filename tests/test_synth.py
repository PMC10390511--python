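import numpy as np
import pytest

from eegdyn.aperiodic import SEGMENT_HIGH, fit_segment
from eegdyn.pac import (
    DEFAULT_AMP_BAND,
    _phase_and_amplitude,
    modulation_index_from_signal,
    phase_band_for,
)
from eegdyn.preprocessing import epoch
from eegdyn.spectral import bartlett_spectrum
from eegdyn.stats import PairedSample, paired_t
from eegdyn.synth import (
    CohortSpec,
    ConditionParams,
    EffectSpec,
    Oscillation,
    PACParams,
    apply_shifts,
    generate_cohort,
    generate_recording,
    template_gains,
    write_cohort,
)


class TestSpecValidation:
    def test_invariants(self):
        with pytest.raises(ValueError):
            CohortSpec(n_participants=1)
        with pytest.raises(ValueError):
            CohortSpec(n_participants=4, fs=100.0)
        with pytest.raises(ValueError):
            CohortSpec(n_participants=4, duration=1.0)
        with pytest.raises(ValueError):
            ConditionParams(aperiodic_low=(0.0, -0.5))
        with pytest.raises(ValueError):
            PACParams(phase_freq=9.0, depth=1.5, gain=(1.0,))
        with pytest.raises(ValueError):
            EffectSpec({"high_exponent": (0.1, -0.2)})


class TestGenerateRecording:
    def test_deterministic(self, single_channel_spec):
        p = ConditionParams()
        a = generate_recording(single_channel_spec, p, 5)
        b = generate_recording(single_channel_spec, p, 5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seed_differs(self, single_channel_spec):
        p = ConditionParams()
        a = generate_recording(single_channel_spec, p, 5)
        b = generate_recording(single_channel_spec, p, 6)
        assert not np.array_equal(a.data, b.data)

    def test_degenerate_zero_case(self, single_channel_spec):
        p = ConditionParams(
            aperiodic_low=(-np.inf, 0.0), aperiodic_high=(-np.inf, 0.0), noise_sd=0.0
        )
        rec = generate_recording(single_channel_spec, p, 0)
        assert np.allclose(rec.data, 0.0, atol=1e-12)

    def test_high_band_exponent_recovered(self, single_channel_spec):
        # oracle: the generative parameter, recovered via the aperiodic module
        p = ConditionParams(aperiodic_low=(0.1, 1.0), aperiodic_high=(0.1, 1.0))
        est = []
        for s in range(5):
            rec = generate_recording(single_channel_spec, p, s)
            spec = bartlett_spectrum(epoch(rec, 1.0))
            est.append(fit_segment(spec, SEGMENT_HIGH, 0)[0].exponent)
        assert np.mean(est) == pytest.approx(1.0, abs=0.1)

    def test_spectral_fidelity_loglog_slope(self, single_channel_spec):
        p = ConditionParams(aperiodic_low=(0.1, 0.8), aperiodic_high=(0.1, 0.8))
        rec = generate_recording(single_channel_spec, p, 3)
        spec = bartlett_spectrum(epoch(rec, 1.0))
        sl = slice(spec.bin_index(26.0), spec.bin_index(90.0) + 1)
        slope = np.polyfit(np.log10(spec.freqs[sl]), np.log10(spec.amplitude[0, sl]), 1)[0]
        assert slope == pytest.approx(-0.8, abs=0.1)

    def test_pac_mi_exceeds_null_tenfold(self, single_channel_spec):
        def rec_for(m):
            p = ConditionParams(
                aperiodic_low=(0.0, 1.0), aperiodic_high=(0.0, 1.0),
                pac=PACParams(9.0, m, (1.0,), phase_amp=0.5, carrier_amp=0.3),
            )
            return generate_recording(single_channel_spec, p, 123)

        mi_on = modulation_index_from_signal(rec_for(0.8).data[0], 250.0, phase_band_for(9.0)).mi
        mi_off = modulation_index_from_signal(rec_for(0.0).data[0], 250.0, phase_band_for(9.0)).mi
        assert mi_on > 10 * mi_off

    def test_pac_preferred_phase(self, single_channel_spec):
        # circular mean of envelope-weighted phase ~ injected preferred phase
        target = 1.2
        p = ConditionParams(
            aperiodic_low=(-np.inf, 0.0), aperiodic_high=(-np.inf, 0.0),
            pac=PACParams(9.0, 0.9, (1.0,), preferred_phase=target,
                          phase_amp=0.5, carrier_amp=0.3),
        )
        rec = generate_recording(single_channel_spec, p, 9)
        phase, amp = _phase_and_amplitude(
            rec.data[0], 250.0, phase_band_for(9.0), DEFAULT_AMP_BAND
        )
        mean_phase = np.angle(np.sum(amp * np.exp(1j * phase)))
        err = np.angle(np.exp(1j * (mean_phase - target)))
        assert abs(err) < 0.2

    def test_mi_monotone_in_depth(self, single_channel_spec):
        mis = []
        for m in (0.0, 0.3, 0.6, 0.9):
            p = ConditionParams(
                aperiodic_low=(0.0, 1.0), aperiodic_high=(0.0, 1.0),
                pac=PACParams(9.0, m, (1.0,), phase_amp=0.5, carrier_amp=0.3),
            )
            rec = generate_recording(single_channel_spec, p, 77)
            mis.append(
                modulation_index_from_signal(rec.data[0], 250.0, phase_band_for(9.0)).mi
            )
        assert all(a < b for a, b in zip(mis, mis[1:]))

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_participants=2, duration=1.5)

    def test_oscillation_gain_shapes_channels(self):
        spec = CohortSpec(n_participants=2, n_channels=4, fs=250.0, duration=10.0, seed=0)
        osc = Oscillation(10.0, 2.0, 1.0, gain=(1.0, 0.0, 0.5, 0.0))
        p = ConditionParams(
            aperiodic_low=(-1.0, 0.5), aperiodic_high=(-1.0, 0.5), oscillations=(osc,)
        )
        rec = generate_recording(spec, p, 4)
        sp = bartlett_spectrum(epoch(rec, 1.0))
        alpha = sp.amplitude[:, sp.bin_index(10.0)]
        assert alpha[0] > alpha[2] > alpha[1]


class TestTemplates:
    def test_gain_lengths_and_range(self):
        for kind in ("frontal", "posterior", "occipital", "uniform"):
            g = template_gains(kind)
            assert len(g) == 32
            assert all(0 <= x <= 1 for x in g)

    def test_frontal_peaks_front(self, labels32):
        g = dict(zip(labels32, template_gains("frontal")))
        assert g["Fz"] > g["Oz"]

    def test_occipital_peaks_back(self, labels32):
        g = dict(zip(labels32, template_gains("occipital")))
        assert g["Oz"] > g["Fz"]


class TestApplyShifts:
    def test_exponent_shift(self):
        p = ConditionParams(aperiodic_high=(0.1, 1.0))
        q = apply_shifts(p, {"high_exponent": -0.3})
        assert q.aperiodic_high == (0.1, 0.7)

    def test_pac_depth_clipped(self):
        p = ConditionParams(pac=PACParams(9.0, 0.8, (1.0,)))
        q = apply_shifts(p, {"pac_depth": 0.5})
        assert q.pac.depth == 1.0

    def test_named_oscillation(self):
        osc = Oscillation(10.0, 1.0, 1.0, (1.0,), name="alpha")
        p = ConditionParams(oscillations=(osc,))
        q = apply_shifts(p, {"osc_alpha_amplitude": -0.4})
        assert q.oscillations[0].amplitude == pytest.approx(0.6)

    def test_unknown_key(self):
        with pytest.raises(ValueError, match="unknown effect key"):
            apply_shifts(ConditionParams(), {"bogus": 1.0})


class TestGenerateCohort:
    SMALL = CohortSpec(n_participants=2, n_channels=2, fs=250.0, duration=2.0, seed=11)

    def test_pair_count(self):
        pairs = generate_cohort(self.SMALL, ConditionParams(), EffectSpec())
        assert len(pairs) == 2
        for a, b in pairs:
            assert a.participant_id == b.participant_id

    def test_reproducible_from_seed(self):
        p1 = generate_cohort(self.SMALL, ConditionParams(), EffectSpec())
        p2 = generate_cohort(self.SMALL, ConditionParams(), EffectSpec())
        for (a1, b1), (a2, b2) in zip(p1, p2):
            np.testing.assert_array_equal(a1.data, a2.data)
            np.testing.assert_array_equal(b1.data, b2.data)

    def test_null_effect_false_positive_rate(self):
        # oracle: simulation under the null at alpha = 0.05
        spec = CohortSpec(n_participants=10, n_channels=1, fs=250.0, duration=2.0, seed=0)
        base = ConditionParams(aperiodic_low=(0.0, 1.0), aperiodic_high=(0.0, 1.0))
        hits = 0
        n_sim = 150
        for s in range(n_sim):
            pairs = generate_cohort(
                CohortSpec(n_participants=10, n_channels=1, fs=250.0, duration=2.0, seed=s),
                base, EffectSpec(),
            )
            a = np.array([np.log(r.data.var()) for r, _ in pairs])
            b = np.array([np.log(r2.data.var()) for _, r2 in pairs])
            hits += paired_t(PairedSample(a, b), exclude=False).p < 0.05
        assert 0.01 <= hits / n_sim <= 0.11

    def test_planted_exponent_effect_power(self):
        # oracle: power simulation; d = 0.3/0.1 = 3 so nearly every cohort hits
        detections = 0
        n_rep = 10
        for s in range(n_rep):
            spec = CohortSpec(n_participants=40, n_channels=1, fs=250.0,
                              duration=20.0, seed=1000 + s)
            base = ConditionParams(aperiodic_low=(0.1, 1.0), aperiodic_high=(0.1, 1.0))
            effect = EffectSpec({"high_exponent": (-0.3, 0.1)})
            pairs = generate_cohort(spec, base, effect)
            est = {"a": [], "b": []}
            for ra, rb in pairs:
                for key, r in (("a", ra), ("b", rb)):
                    sp = bartlett_spectrum(epoch(r, 1.0))
                    est[key].append(fit_segment(sp, SEGMENT_HIGH, 0)[0].exponent)
            p = paired_t(PairedSample(np.array(est["a"]), np.array(est["b"]))).p
            detections += p < 0.01
        assert detections >= 9

    def test_write_cohort_manifest(self, tmp_path):
        pairs = generate_cohort(self.SMALL, ConditionParams(), EffectSpec())
        manifest = write_cohort(pairs, tmp_path)
        lines = open(manifest).read().strip().splitlines()
        assert len(lines) == 1 + 4  # header + 2 participants x 2 conditions
        from eegdyn.io import read_hdf5

        first = lines[1].split("\t")
        back = read_hdf5(tmp_path / first[4])
        np.testing.assert_array_equal(back.data, pairs[0][0].data)
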