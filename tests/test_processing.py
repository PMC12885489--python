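"""Impedance estimation, breath segmentation, artifact rejection, sampling."""

import numpy as np
import pandas as pd
import pytest

from oscivar import (
    BreathSegment,
    ProcessingConfig,
    Recording,
    SubjectSpec,
    breath_resistance,
    estimate_impedance_series,
    inject_artifacts,
    process_recording,
    segment_breaths,
    separate_components,
    synthesize_recording,
)
from oscivar.processing import ProcessingError, RejectReason

FS = 200.0
F0 = 5.0


def _constant_impedance_signals(R, X, n=24000, fs=FS, amp=1.5):
    """Direct construction of oscillatory P/Q for a constant impedance."""
    t = np.arange(n) / fs
    w0 = 2 * np.pi * F0
    p = amp * np.sin(w0 * t)
    zmag = np.hypot(R, X)
    theta = np.arctan2(X, R)
    q = (amp / zmag) * np.sin(w0 * t - theta)
    return p, q, t


class TestSeparateComponents:
    def test_pure_forcing_leaves_no_breathing(self):
        t = np.arange(24000) / FS
        x = np.sin(2 * np.pi * F0 * t)
        rec = Recording("s", 1, t, x, x, FS)
        q_breath, _, q_osc = separate_components(rec)
        assert np.max(np.abs(q_breath)) < 0.01
        # and the oscillatory channel keeps the sinusoid
        assert np.max(np.abs(q_osc[1000:-1000])) > 0.95

    def test_pure_tidal_leaves_no_oscillation(self):
        t = np.arange(24000) / FS
        x = np.sin(2 * np.pi * 0.25 * t)
        rec = Recording("s", 1, t, x, x, FS)
        _, _, q_osc = separate_components(rec)
        assert np.max(np.abs(q_osc)) < 0.01

    def test_extracted_matches_generator_oscillation(self, clean_recording):
        """Band-passed flow tracks the generator's oscillatory flow."""
        rec, _ = clean_recording
        spec_T, vt = 4.0, 0.5
        q_br_true = (np.pi * vt / spec_T) * np.sin(2 * np.pi * rec.time / spec_T)
        q_osc_true = rec.flow - q_br_true
        _, _, q_osc = separate_components(rec)
        i = slice(2000, -2000)  # away from filter edges
        r = np.corrcoef(q_osc[i], q_osc_true[i])[0, 1]
        assert r > 0.999

    def test_short_recording_raises(self):
        t = np.arange(100) / FS
        rec = Recording("s", 1, t, np.sin(t), np.sin(t), FS)
        with pytest.raises(ProcessingError):
            separate_components(rec)


class TestEstimateImpedance:
    def test_exact_on_constant_resistance(self):
        p, q, _ = _constant_impedance_signals(R=3.0, X=0.0)
        s = estimate_impedance_series(p, q, FS)
        np.testing.assert_allclose(s["R"], 3.0, rtol=1e-6)
        np.testing.assert_allclose(s["X"], 0.0, atol=1e-6)
        assert s["quality"].all()

    def test_reactance_closed_form(self):
        """R=4, E=10, I=0.01 at 5 Hz: X = 2*pi*5*0.01 - 10/(2*pi*5)."""
        w0 = 2 * np.pi * F0
        X_true = w0 * 0.01 - 10.0 / w0  # about -0.0042
        p, q, _ = _constant_impedance_signals(R=4.0, X=X_true)
        s = estimate_impedance_series(p, q, FS)
        np.testing.assert_allclose(s["X"], X_true, atol=1e-3)
        np.testing.assert_allclose(s["R"], 4.0, rtol=1e-6)

    def test_least_squares_equals_dft_oracle(self):
        """On integer-cycle windows, LS projection == single-bin DFT."""
        rng = np.random.default_rng(0)
        p, q, t = _constant_impedance_signals(R=3.5, X=-0.2, n=4000)
        p = p + 0.05 * rng.standard_normal(len(p))
        q = q + 0.05 * rng.standard_normal(len(q))
        s = estimate_impedance_series(p, q, FS)
        w = int(FS / F0)
        w0 = 2 * np.pi * F0
        for i in range(len(s)):
            sl = slice(i * w, i * w + w)
            P = 2 * np.mean(p[sl] * np.exp(-1j * w0 * t[sl]))
            Q = 2 * np.mean(q[sl] * np.exp(-1j * w0 * t[sl]))
            z = P / Q
            assert abs(z.real - s["R"].iloc[i]) < 1e-9
            assert abs(z.imag - s["X"].iloc[i]) < 1e-9

    def test_tracks_slow_ramp(self):
        """Windowed estimates follow a slowly varying resistance."""
        n = 24000
        t = np.arange(n) / FS
        r_t = 3.0 + 2.0 * t / t[-1]  # 3 -> 5 over 2 min
        w0 = 2 * np.pi * F0
        p = 1.5 * np.sin(w0 * t)
        q = (1.5 / r_t) * np.sin(w0 * t)
        s = estimate_impedance_series(p, q, FS)
        truth = np.interp(s["t_center"], t, r_t)
        per_window_change = 2.0 / (120 * F0)  # ramp change per forcing cycle
        assert np.max(np.abs(s["R"] - truth)) < 5 * per_window_change

    def test_low_flow_windows_withheld(self):
        p, q, _ = _constant_impedance_signals(R=3.0, X=0.0, n=4000)
        q = q * 1e-4  # below the amplitude floor
        s = estimate_impedance_series(p, q, FS)
        assert not s["quality"].any()
        assert s["R"].isna().all()


class TestSegmentBreaths:
    def test_sinusoidal_flow_breath_count_and_fraction(self):
        t = np.arange(24000) / FS
        q = 0.4 * np.sin(2 * np.pi * t / 4.0)
        segs = segment_breaths(q, FS)
        accepted = [s for s in segs if s.accepted]
        assert len(accepted) in (29, 30)
        for s in accepted:
            assert s.insp_fraction() == pytest.approx(0.5, abs=0.02)

    def test_apnea_rejected_by_duration(self):
        t = np.arange(24000) / FS
        q = 0.4 * np.sin(2 * np.pi * t / 4.0)
        q[(t >= 40) & (t < 60)] = 0.0  # 20 s apnea
        segs = segment_breaths(q, FS)
        # the pseudo-breath spanning the apnea violates the duration rule
        long_segs = [s for s in segs if s.duration(FS) > 15]
        assert long_segs and all(
            s.reason == RejectReason.DURATION for s in long_segs
        )

    def test_all_zero_flow_raises(self):
        with pytest.raises(ProcessingError):
            segment_breaths(np.zeros(24000), FS)

    def test_invalid_bounds_raise(self):
        with pytest.raises(ProcessingError):
            BreathSegment(start=10, insp_end=5, end=20)


class TestBreathResistance:
    def _samples(self, t_vals, r_vals):
        return pd.DataFrame(
            {
                "t_center": t_vals,
                "R": r_vals,
                "X": 0.0,
                "p_amp": 1.0,
                "q_amp": 1.0,
                "quality": True,
            }
        )

    def test_constant_breath_all_schemes_equal(self):
        fs = 100.0
        seg = BreathSegment(start=0, insp_end=200, end=400)
        t = np.arange(0.0, 4.0, 0.2) + 0.1
        s = self._samples(t, np.full(len(t), 4.0))
        br = breath_resistance(seg, s, fs)
        assert br.R_full_breath == br.R_full_insp == br.R_mid_insp == 4.0

    def test_mid_window_arithmetic(self):
        """Inspiration of 2.0 s starting at t=10 s: mid window [10.4, 11.6)."""
        fs = 100.0
        seg = BreathSegment(start=1000, insp_end=1200, end=1400)
        t = np.arange(10.0, 14.0, 0.1) + 0.05
        r = np.where(t < 10.4, 1.0, np.where(t < 11.6, 2.0, 3.0))
        br = breath_resistance(seg, self._samples(t, r), fs)
        assert br.R_mid_insp == 2.0

    def test_too_few_samples_gives_nan(self):
        fs = 100.0
        seg = BreathSegment(start=0, insp_end=200, end=400)
        s = self._samples(np.array([0.5]), np.array([4.0]))
        br = breath_resistance(seg, s, fs)
        assert np.isnan(br.R_mid_insp)


class TestEndToEnd:
    def test_surcharge_ordering(self, clean_recording):
        """Early-insp + expiratory surcharges: mid < full-insp < full-breath."""
        rec, _ = clean_recording
        br = process_recording(rec)
        acc = br[br["accepted"]]
        assert acc["R_mid_insp"].mean() < acc["R_full_insp"].mean()
        assert acc["R_full_insp"].mean() < acc["R_full_breath"].mean()

    def test_clean_recording_no_rejections(self, clean_recording):
        rec, _ = clean_recording
        br = process_recording(rec)
        assert br["accepted"].all()

    def test_mid_insp_matches_ground_truth(self, clean_recording):
        """Per-breath mid-inspiratory estimate within 2% of generator truth."""
        rec, gt = clean_recording
        br = process_recording(rec)
        acc = br[br["accepted"]]
        gt_starts = np.array([b[0] for b in gt.breath_bounds])
        for _, row in acc.iterrows():
            k = int(np.argmin(np.abs(gt_starts - row["t_start"])))
            truth = gt.true_mid_insp[k]
            assert abs(row["R_mid_insp"] - truth) / truth < 0.02

    def test_negative_r_sample_rejected(self, clean_recording):
        """A breath containing a non-physical R sample is flagged."""
        rec, _ = clean_recording
        from oscivar.processing import (
            estimate_impedance_series,
            reject_artifacts,
            segment_breaths,
            separate_components,
        )
        q_breath, p_osc, q_osc = separate_components(rec)
        samples = estimate_impedance_series(p_osc, q_osc, rec.sampling_rate)
        segs = segment_breaths(q_breath, rec.sampling_rate)
        target = next(s for s in segs if s.accepted)
        t0, t1 = target.start / rec.sampling_rate, target.end / rec.sampling_rate
        in_breath = (samples["t_center"] >= t0) & (samples["t_center"] < t1)
        samples.loc[in_breath.idxmax(), "R"] = -0.5
        out = reject_artifacts(segs, samples, rec)
        flagged = next(
            s for s in out if s.start == target.start
        )
        assert not flagged.accepted
        assert flagged.reason == RejectReason.NON_PHYSICAL_R


def _overlap_detect(br, gt, gt2, min_overlap=0.3):
    """Score rejection against ground-truth corruption labels by time overlap."""
    segs = br[["t_start", "t_end", "accepted"]].to_numpy()
    detected, n_corr, clean_lost, n_clean = 0, 0, 0, 0
    for k, (t0, _, t1) in enumerate(gt.breath_bounds):
        overlaps = [
            not acc for s, e, acc in segs if min(e, t1) - max(s, t0) > min_overlap
        ]
        if k in gt2.corrupted_breaths:
            n_corr += 1
            detected += any(overlaps) if overlaps else 1
        else:
            n_clean += 1
            clean_lost += all(overlaps) if overlaps else 0
    return detected, n_corr, clean_lost, n_clean


class TestArtifactRejection:
    def test_corrupted_breaths_rejected_clean_kept(self, asthma_spec):
        det, n_corr, lost, n_clean = 0, 0, 0, 0
        for seed in range(6):
            rec, gt = synthesize_recording(
                asthma_spec, 3.9, np.random.default_rng(seed + 50)
            )
            rec2, gt2 = inject_artifacts(rec, gt, 0.1, np.random.default_rng(seed))
            br = process_recording(rec2)
            d, nc, cl, ncl = _overlap_detect(br, gt, gt2)
            det += d
            n_corr += nc
            lost += cl
            n_clean += ncl
        assert n_corr >= 10
        assert det / n_corr >= 0.90
        assert lost / n_clean <= 0.05

    def test_rejection_monotone_in_rate(self, asthma_spec):
        """On a fixed seed, more artifacts never means fewer rejections."""
        rec, gt = synthesize_recording(asthma_spec, 3.9, np.random.default_rng(7))
        n_rejected = []
        for rate in (0.0, 0.1, 0.3, 0.6):
            rec2, _ = inject_artifacts(rec, gt, rate, np.random.default_rng(123))
            br = process_recording(rec2)
            n_rejected.append(int((~br["accepted"]).sum()))
        assert n_rejected == sorted(n_rejected)
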