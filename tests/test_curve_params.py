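"""Phase segmentation and curve-parameter extraction.

Closed-form oracles: for a logistic EI(pO2) = L + (U-L)/(1+exp(-(p-p50)/s)),
the point of sickling solves EI = 0.95 * EI(150), i.e.
pos = p50 + s * logit((0.95*EI(150) - L) / (U - L)).
"""

import numpy as np
import pytest
from scipy.special import expit, logit

from oxyscan.curve_params import (
    NO_HYPOXIC_SAMPLES,
    POS_UNDEFINED,
    ExtractionConfig,
    ExtractionError,
    SegmentationError,
    compute_ei_max,
    compute_ei_min,
    compute_pos,
    compute_recovery,
    extract_parameters,
    rolling_median,
    segment_phases,
)
from oxyscan.trace_io import OxygenscanTrace

from conftest import logistic_trace, nominal_po2_profile


def logistic_pos_closed_form(upper, lower, p50, slope, p_plateau=150.0):
    ei_max = lower + (upper - lower) * expit((p_plateau - p50) / slope)
    frac = (0.95 * ei_max - lower) / (upper - lower)
    return p50 + slope * logit(frac)


class TestSegmentation:
    def test_noiseless_boundaries_exact(self):
        """Plateau to 100 s, decline to 1,400 s: onsets at those samples."""
        tr = logistic_trace(0.55, 0.2, 40, 6)
        seg = segment_phases(tr)
        assert seg.deox_start_idx == 100
        assert seg.reox_start_idx == 1400

    def test_noisy_boundaries_near_noiseless_oracle(self):
        """With 1 mmHg pO2 noise, detected onsets track the noiseless answer
        (within 10 samples for most realizations, never far off)."""
        t, po2 = nominal_po2_profile()
        base = logistic_trace(0.55, 0.2, 40, 6)
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(30):
            noisy = OxygenscanTrace(
                t, np.clip(po2 + rng.normal(0, 1, len(t)), 0, 200), base.ei
            )
            seg = segment_phases(noisy)
            errs.append((seg.deox_start_idx - 100, seg.reox_start_idx - 1400))
        errs = np.abs(np.array(errs))
        assert (errs <= 10).mean() >= 0.8
        assert errs.max() <= 25

    def test_constant_po2_has_no_cycle(self):
        t = np.arange(200.0)
        tr = OxygenscanTrace(t, np.full(200, 150.0), np.full(200, 0.5))
        with pytest.raises(SegmentationError, match="no_deoxygenation_phase"):
            segment_phases(tr)

    def test_monotone_decline_has_no_reox(self):
        t = np.arange(400.0)
        tr = OxygenscanTrace(t, np.linspace(150, 10, 400), np.full(400, 0.5))
        with pytest.raises(SegmentationError, match="no_reoxygenation_phase"):
            segment_phases(tr)


class TestEiMax:
    def test_constant_plateau(self):
        tr = logistic_trace(0.55, 0.2, 40, 6)
        seg = segment_phases(tr)
        val, idx = compute_ei_max(tr, seg)
        assert val == pytest.approx(0.55, abs=1e-6)
        assert idx <= seg.deox_start_idx

    def test_noisy_plateau_within_tolerance(self):
        """EI noise sd 0.005 on a 0.55 plateau: the reading equals the max of
        the independently smoothed series and stays close to the plateau."""
        tr = logistic_trace(0.55, 0.2, 40, 6)
        rng = np.random.default_rng(3)
        devs = []
        for _ in range(10):
            noisy = OxygenscanTrace(
                tr.time_s, tr.pO2_mmHg,
                np.clip(tr.ei + rng.normal(0, 0.005, len(tr)), 0, 0.999),
            )
            seg = segment_phases(noisy)
            val, _ = compute_ei_max(noisy, seg)
            # oracle: max of the independently smoothed series over the window
            sm = rolling_median(noisy.ei, 11)
            mask = (noisy.pO2_mmHg[: seg.deox_start_idx + 1] >= 100) & (
                noisy.pO2_mmHg[: seg.deox_start_idx + 1] <= 150
            )
            assert val == pytest.approx(sm[: seg.deox_start_idx + 1][mask].max())
            devs.append(abs(val - 0.55))
        assert np.mean(devs) < 0.01
        assert max(devs) < 0.015

    def test_no_normoxic_samples_is_error(self):
        t = np.arange(500.0)
        po2 = np.concatenate([np.full(100, 80.0), np.linspace(80, 5, 300),
                              np.linspace(5, 80, 100)])
        tr = OxygenscanTrace(t, po2, np.full(500, 0.5))
        seg = segment_phases(tr)
        with pytest.raises(ExtractionError, match="no_normoxic_samples"):
            compute_ei_max(tr, seg)


class TestEiMin:
    def test_matches_closed_form_minimum(self):
        """On a noiseless logistic whose transition completes above the
        hypoxic window the reading matches the closed-form minimum over the
        window to 1e-6 (the curve is flat there, so median smoothing is
        exact)."""
        upper, lower, p50, slope = 0.55, 0.2, 70.0, 5.0
        tr = logistic_trace(upper, lower, p50, slope)
        seg = segment_phases(tr)
        val, idx, flags = compute_ei_min(tr, seg)
        p_min = tr.pO2_mmHg[seg.deox_start_idx:seg.reox_start_idx + 1].min()
        expected = lower + (upper - lower) * expit((p_min - p50) / slope)
        assert val == pytest.approx(expected, abs=1e-6)
        assert not flags

    def test_floor_reached_above_20(self):
        """A transition completed well above 20 mmHg still reads the floor."""
        tr = logistic_trace(0.55, 0.2, 80, 4)
        seg = segment_phases(tr)
        val, _, _ = compute_ei_min(tr, seg)
        assert val == pytest.approx(0.2, abs=1e-4)

    def test_no_hypoxic_samples_flagged(self):
        t = np.arange(600.0)
        po2 = np.concatenate([np.full(100, 150.0), np.linspace(150, 40, 400),
                              np.linspace(40, 150, 100)])
        tr = OxygenscanTrace(t, po2, np.full(600, 0.5))
        seg = segment_phases(tr)
        val, idx, flags = compute_ei_min(tr, seg)
        assert np.isnan(val) and idx is None
        assert NO_HYPOXIC_SAMPLES in flags


class TestPos:
    @pytest.mark.parametrize(
        "upper,lower,p50,slope",
        [(0.55, 0.20, 40.0, 6.0), (0.60, 0.15, 25.0, 4.0),
         (0.50, 0.30, 55.0, 9.0)],
    )
    def test_matches_analytic_crossing(self, upper, lower, p50, slope):
        tr = logistic_trace(upper, lower, p50, slope)
        seg = segment_phases(tr)
        ei_max, _ = compute_ei_max(tr, seg)
        pos, flags = compute_pos(tr, seg, ei_max)
        oracle = logistic_pos_closed_form(upper, lower, p50, slope)
        # confirm the closed form itself against dense-grid brute force
        grid = np.linspace(150, 5, 2_000_001)
        ei = lower + (upper - lower) * expit((grid - p50) / slope)
        brute = grid[np.argmax(ei <= 0.95 * ei[0])]
        assert oracle == pytest.approx(brute, abs=1e-3)
        assert pos == pytest.approx(oracle, abs=1e-3)
        assert not flags

    def test_flat_curve_undefined(self):
        tr = logistic_trace(0.55, 0.54, 40, 6)  # < 5% total drop
        seg = segment_phases(tr)
        ei_max, _ = compute_ei_max(tr, seg)
        pos, flags = compute_pos(tr, seg, ei_max)
        assert np.isnan(pos)
        assert POS_UNDEFINED in flags

    def test_step_curve_crossing_at_step(self):
        t, po2 = nominal_po2_profile()
        ei = np.where(po2 > 40.0, 0.55, 0.30)
        tr = OxygenscanTrace(t, po2, ei)
        seg = segment_phases(tr)
        ei_max, _ = compute_ei_max(tr, seg)
        pos, _ = compute_pos(tr, seg, ei_max)
        grid_step = 145.0 / 1300.0
        # median smoothing spreads the step over half a window of samples
        assert pos == pytest.approx(40.0, abs=grid_step * 7)

    def test_pos_within_observed_deox_range(self):
        tr = logistic_trace(0.55, 0.2, 40, 6)
        seg = segment_phases(tr)
        ei_max, _ = compute_ei_max(tr, seg)
        pos, _ = compute_pos(tr, seg, ei_max)
        deox_po2 = tr.pO2_mmHg[seg.deox_start_idx:seg.reox_start_idx]
        assert deox_po2.min() <= pos <= deox_po2.max()

    def test_time_axis_rescaling_invariance(self):
        """PoS is a function of the EI-vs-pO2 relation, not the sampling
        clock: an affine time rescale leaves it within one grid step."""
        tr = logistic_trace(0.55, 0.2, 40, 6)
        fast = OxygenscanTrace(tr.time_s * 0.25 + 7.0, tr.pO2_mmHg, tr.ei)
        p1 = extract_parameters(tr).pos_mmHg
        p2 = extract_parameters(fast).pos_mmHg
        assert p1 == pytest.approx(p2, abs=145.0 / 1300.0)

    def test_lower_p50_never_increases_pos(self):
        positions = []
        for p50 in (55.0, 45.0, 35.0, 25.0):
            tr = logistic_trace(0.55, 0.2, p50, 6)
            positions.append(extract_parameters(tr).pos_mmHg)
        assert all(a >= b for a, b in zip(positions, positions[1:]))

    def test_undefined_ei_max_is_error(self):
        tr = logistic_trace(0.55, 0.2, 40, 6)
        seg = segment_phases(tr)
        with pytest.raises(ExtractionError):
            compute_pos(tr, seg, float("nan"))


class TestRecovery:
    def _two_path_trace(self, post_scale: float) -> OxygenscanTrace:
        """EI follows one logistic down and returns scaled by post_scale."""
        t, po2 = nominal_po2_profile()
        ei = 0.2 + 0.35 * expit((po2 - 40.0) / 6.0)
        reox = t > 1400
        ei = np.where(reox, np.clip(ei * post_scale, 0, 0.999), ei)
        return OxygenscanTrace(t, po2, ei)

    def test_full_return_is_100(self):
        tr = self._two_path_trace(1.0)
        p = extract_parameters(tr)
        assert p.recovery_pct == pytest.approx(100.0, abs=0.1)

    @pytest.mark.parametrize("scale,expected", [(1.1, 110.0), (0.9, 90.0)])
    def test_over_and_under_recovery(self, scale, expected):
        """Recovery above 100% is legitimate (lysis of rigid cells raises
        the population EI) and must not be clipped."""
        p = extract_parameters(self._two_path_trace(scale))
        assert p.recovery_pct == pytest.approx(expected, abs=0.2)

    def test_zero_ei_max_is_domain_error(self):
        tr = self._two_path_trace(1.0)
        seg = segment_phases(tr)
        with pytest.raises(ExtractionError):
            compute_recovery(tr, seg, 0.0)


class TestExtractParameters:
    def test_composition_flags_and_ordering(self):
        tr = logistic_trace(0.55, 0.2, 40, 6)
        p = extract_parameters(tr)
        assert p.ei_min <= p.ei_max < 1
        assert p.flags == frozenset()

    def test_normal_rbc_trace(self, normal_control_config):
        """Non-sickling cells: no PoS, recovery ~ 100, flat EI."""
        from oxyscan.synthetic_cohort import (
            PatientRecord, patient_rng, simulate_curve,
        )
        rec = PatientRecord("n", 30.0, 90.0, 0.0, 12.0, 4.5)
        tr = simulate_curve(rec, normal_control_config, patient_rng(0, 0))
        p = extract_parameters(tr)
        assert np.isnan(p.pos_mmHg) and POS_UNDEFINED in p.flags
        assert p.recovery_pct == pytest.approx(100.0, abs=0.5)
        assert p.ei_max - p.ei_min < 0.02
        assert p.ei_max == pytest.approx(0.60, abs=0.02)

    def test_trace_without_hypoxia_keeps_flag(self):
        t = np.arange(600.0)
        po2 = np.concatenate([np.full(100, 150.0), np.linspace(150, 40, 400),
                              np.linspace(40, 150, 100)])
        ei = 0.2 + 0.35 * expit((po2 - 60.0) / 6.0)
        tr = OxygenscanTrace(t, po2, ei)
        p = extract_parameters(tr)
        assert NO_HYPOXIC_SAMPLES in p.flags
        assert np.isnan(p.ei_min)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExtractionConfig(smooth_window=10)
        with pytest.raises(ValueError):
            ExtractionConfig(sustain_k=0)
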