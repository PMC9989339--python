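import numpy as np
import pytest

from caiso import constants
from caiso.config import ReductionConfig
from caiso.errors import CalibrationError, ReductionError, StructureError
from caiso.reduction import (
    BlockType,
    ConcentrationCalibration,
    check_interference,
    delta_bracketed,
    mass_bias_factor,
    mass_bias_factors,
    qc_intensity_match,
    qc_mass_bias_spread,
    qc_mass_dependence,
    quantify_concentration,
    reduce_session,
    subtract_blank,
    summarize_ratios,
)
from caiso.synth import SessionSpec, generate_session
from tests.conftest import make_block


# ---------------------------------------------------------------------------
# blank subtraction
# ---------------------------------------------------------------------------

class TestSubtractBlank:
    def test_zero_blank_is_identity(self):
        blk = make_block("s", BlockType.SAMPLE, 2, 1.0, 0.2, 0.0, 3.0)
        blank = make_block("b", BlockType.BLANK, 1, 0.0, 0.0, 0.0, 0.0)
        out = subtract_blank(blk, blank)
        np.testing.assert_array_equal(out.intensity_44, blk.intensity_44)
        np.testing.assert_array_equal(out.intensity_42, blk.intensity_42)

    def test_mean_blank_is_subtracted(self):
        blk = make_block("s", BlockType.SAMPLE, 2, 1.0, 0.2, 0.0, 1.000)
        blank = make_block("b", BlockType.BLANK, 1, 0.001, 0.001, 0.001, 0.001)
        out = subtract_blank(blk, blank)
        assert out.intensity_44[0] == pytest.approx(0.999, abs=1e-15)

    def test_negative_results_retained_and_flagged(self):
        blk = make_block("s", BlockType.SAMPLE, 2, 1.0, 0.2, 0.0005, 3.0)
        blank = make_block("b", BlockType.BLANK, 1, 0.001, 0.001, 0.001, 0.001)
        out = subtract_blank(blk, blank)
        assert np.all(out.intensity_43p5 < 0)
        assert out.meta["negative_intensities"] is True

    def test_blank_must_precede(self):
        blk = make_block("s", BlockType.SAMPLE, 1, 1.0, 0.2, 0.0, 3.0)
        blank = make_block("b", BlockType.BLANK, 5, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(StructureError):
            subtract_blank(blk, blank)

    def test_blank_subtraction_matches_blank_free_twin(self):
        """A session with blank level b reduces to the same delta as its blank-free twin."""
        kw = dict(true_delta44_42=0.35, beta=1.2, seed=7)
        m_blank = reduce_session(generate_session(SessionSpec(blank_level=0.02, **kw)))[0]
        m_clean = reduce_session(generate_session(SessionSpec(blank_level=0.0, **kw)))[0]
        assert m_blank.delta44_42 == pytest.approx(m_clean.delta44_42, abs=1e-6)


# ---------------------------------------------------------------------------
# ratio summaries
# ---------------------------------------------------------------------------

class TestSummarizeRatios:
    def test_constant_cycles(self):
        blk = make_block("s", BlockType.SAMPLE, 1, 1.0, 0.2, 0.0, 3.0)
        s = summarize_ratios(blk)
        assert s.r44_42 == pytest.approx(3.0)
        assert s.r43_42 == pytest.approx(0.2)
        assert s.r43p5_44 == pytest.approx(0.0)
        assert s.two_sd_44_42 == 0.0
        assert s.two_sd_43_42 == 0.0
        assert s.mean_intensity_44 == pytest.approx(3.0)

    def test_two_cycle_spread_hand_computed(self):
        """r = {3.000, 3.003} → mean 3.0015, deviations ±0.49975‰, 2·sd ≈ 1.0‰."""
        blk = make_block(
            "s", BlockType.SAMPLE, 1,
            np.array([1.0, 1.0]), np.array([0.2, 0.2]),
            np.array([0.0, 0.0]), np.array([3.000, 3.003]),
        )
        s = summarize_ratios(blk)
        assert s.r44_42 == pytest.approx(3.0015)
        dev = (3.003 / 3.0015 - 1.0) * 1000.0  # +0.49975‰; sd(ddof=0) of ±d is d
        assert s.two_sd_44_42 == pytest.approx(2 * dev, rel=1e-9)
        assert s.two_sd_44_42 == pytest.approx(0.9995, abs=1e-3)

    def test_injected_noise_recovered_in_spread(self, rng):
        """Per-cycle relative ratio noise σ shows up as two_sd ≈ 2σ (within 30%)."""
        sigma = 0.5  # per mille
        spreads = []
        for seed in range(100):
            s = generate_session(
                SessionSpec(true_delta44_42=0.0, cycle_noise_permil=sigma, seed=seed)
            )
            sample = next(b for b in s.blocks if b.block_type is BlockType.SAMPLE)
            spreads.append(summarize_ratios(sample).two_sd_44_42)
        assert np.mean(spreads) == pytest.approx(2 * sigma, rel=0.30)

    def test_nonpositive_denominator_rejected(self):
        blk = make_block("s", BlockType.SAMPLE, 1, -1.0, 0.2, 0.0, 3.0)
        with pytest.raises(ReductionError):
            summarize_ratios(blk)


# ---------------------------------------------------------------------------
# bracketed delta
# ---------------------------------------------------------------------------

class TestDeltaBracketed:
    def _summary(self, r44):
        blk = make_block("x", BlockType.SAMPLE, 1, 1.0, 0.2, 0.0, r44)
        return summarize_ratios(blk)

    def test_self_bracketing_is_zero(self):
        s = self._summary(3.0)
        assert delta_bracketed(s, s, s) == 0.0

    def test_forced_arithmetic(self):
        assert delta_bracketed(
            self._summary(3.003), self._summary(3.000), self._summary(3.000)
        ) == pytest.approx(1.000, abs=1e-9)

    def test_symmetric_drift_cancels(self):
        assert delta_bracketed(
            self._summary(3.000), self._summary(2.998), self._summary(3.002)
        ) == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# QC checks
# ---------------------------------------------------------------------------

class TestQCChecks:
    def _sum_with_interference(self, ratio):
        blk = make_block("s", BlockType.SAMPLE, 1, 1.0, 0.2, ratio * 3.0, 3.0)
        return summarize_ratios(blk)

    @pytest.mark.parametrize(
        "ratio, expect_pass",
        [(5e-6, True), (2e-5, False), (1e-5, True)],  # boundary: strictly greater
    )
    def test_interference(self, ratio, expect_pass):
        chk = check_interference(self._sum_with_interference(ratio))
        assert chk.passed is expect_pass
        assert chk.value == pytest.approx(ratio, rel=1e-9)

    def test_mass_bias_factor_identity_and_inversion(self):
        assert mass_bias_factor(3.224, 3.224, (constants.MASS_44, constants.MASS_42)) == 0.0
        measured = 3.224 * (constants.MASS_44 / constants.MASS_42) ** (-0.5)
        beta = mass_bias_factor(measured, 3.224, (constants.MASS_44, constants.MASS_42))
        assert beta == pytest.approx(0.5, abs=1e-12)

    def test_three_factors_agree_on_exponentially_biased_block(self):
        """One β applied to all masses → the three pairwise factors agree."""
        session = generate_session(SessionSpec(true_delta44_42=0.0, beta=1.3, blank_level=0.0))
        std = next(b for b in session.blocks if b.block_type is BlockType.STANDARD)
        betas = mass_bias_factors(summarize_ratios(std))
        assert np.ptp(betas) < 1e-3
        assert betas[0] == pytest.approx(1.3, abs=1e-6)

    @pytest.mark.parametrize(
        "betas, stat, expect_pass",
        [
            ((0.5, 0.5, 0.5), 0.0, True),
            ((0.40, 0.50, 0.60), 0.2, False),
            ((0.48, 0.50, 0.52), 0.04, True),
        ],
    )
    def test_mass_bias_spread(self, betas, stat, expect_pass):
        chk = qc_mass_bias_spread(betas)
        assert chk.value == pytest.approx(stat, abs=1e-12)
        assert chk.passed is expect_pass

    def test_mass_bias_spread_needs_three(self):
        with pytest.raises(ReductionError):
            qc_mass_bias_spread((0.5, 0.5))

    @pytest.mark.parametrize(
        "d44, d43, stat, expect_pass",
        [
            (1.000, 0.50667, 0.0, True),
            (1.000, 0.30, 0.20667, False),
        ],
    )
    def test_mass_dependence(self, d44, d43, stat, expect_pass):
        chk = qc_mass_dependence(d44, d43)
        assert chk.value == pytest.approx(stat, abs=1e-9)
        assert chk.passed is expect_pass

    def test_mass_dependence_spike_vs_twin(self):
        kw = dict(true_delta44_42=0.2, seed=3)
        spiked = reduce_session(generate_session(SessionSpec(spike43_permil=0.3, **kw)))[0]
        clean = reduce_session(generate_session(SessionSpec(**kw)))[0]
        assert not spiked.qc.massdependence.passed
        assert clean.qc.massdependence.passed

    @pytest.mark.parametrize(
        "sample, std, expect_pass, dev",
        [(3.0, 3.0, True, 0.0), (3.4, 3.0, False, 0.4 / 3.0), (2.75, 3.0, True, 0.25 / 3.0)],
    )
    def test_intensity_match(self, sample, std, expect_pass, dev):
        chk = qc_intensity_match(sample, std)
        assert chk.passed is expect_pass
        assert chk.value == pytest.approx(dev, abs=1e-12)


# ---------------------------------------------------------------------------
# full-session reduction
# ---------------------------------------------------------------------------

class TestReduceSession:
    def test_noise_free_round_trip(self):
        session = generate_session(
            SessionSpec(true_delta44_42=0.527, beta=0.0, blank_level=0.0)
        )
        m = reduce_session(session)[0]
        assert m.delta44_42 == pytest.approx(0.527, abs=1e-9)
        assert m.qc.overall_accept

    @pytest.mark.parametrize("beta", [-2.0, -0.5, 0.3, 2.0])
    def test_bracketing_cancels_constant_bias(self, beta):
        session = generate_session(
            SessionSpec(true_delta44_42=-0.70, beta=beta, blank_level=0.01)
        )
        m = reduce_session(session)[0]
        assert m.delta44_42 == pytest.approx(-0.70, abs=1e-6)
        # exponential-law fractionation stays mass-dependent for any β
        assert m.qc.massdependence.passed

    def test_recovered_delta_monotone_in_truth(self):
        recovered = []
        for d in (-0.5, 0.0, 0.3, 0.8):
            s = generate_session(SessionSpec(true_delta44_42=d, beta=1.1))
            recovered.append(reduce_session(s)[0].delta44_42)
        assert np.all(np.diff(recovered) > 0)

    def test_rejections_are_flagged_not_dropped(self):
        session = generate_session(
            SessionSpec(true_delta44_42=(0.2, 0.2), sr_ratio_43p5_44=2e-5)
        )
        out = reduce_session(session)
        assert len(out) == 2  # nothing silently dropped
        assert all(not m.qc.interference.passed for m in out)
        assert all(not m.usable for m in out)

    def test_overall_accept_is_conjunction(self):
        session = generate_session(SessionSpec(true_delta44_42=0.2, intensity_mismatch=1.13))
        m = reduce_session(session)[0]
        assert m.qc.failed_checks() == ["intensity"]
        assert m.qc.overall_accept is False

    def test_multi_sample_session_with_drift(self):
        truths = (-0.7, 0.14, 0.92)
        session = generate_session(
            SessionSpec(true_delta44_42=truths, beta_drift=(1.5, 1.7), blank_level=0.005)
        )
        out = reduce_session(session)
        for m, t in zip(out, truths):
            # linear drift is slightly curved in ratio space; mean bracketing
            # cancels it to first order
            assert m.delta44_42 == pytest.approx(t, abs=5e-3)

    def test_linear_bracketing_mode(self):
        session = generate_session(SessionSpec(true_delta44_42=0.3, beta=1.0))
        cfg = ReductionConfig(bracketing="linear")
        m = reduce_session(session, cfg)[0]
        assert m.delta44_42 == pytest.approx(0.3, abs=1e-6)

    def test_missing_bracket_is_structural_error(self):
        session = generate_session(SessionSpec(true_delta44_42=0.3))
        session.blocks = session.blocks[:-1]  # drop the closing standard
        with pytest.raises(StructureError):
            reduce_session(session)


# ---------------------------------------------------------------------------
# concentration quantification
# ---------------------------------------------------------------------------

class TestQuantifyConcentration:
    def _calib(self):
        return ConcentrationCalibration(
            concentrations=np.array([0.0, 100.0]),
            analyte_counts=np.array([0.0, 1000.0]),
            istd_counts=np.array([500.0, 500.0]),
        )

    def test_linear_interpolation(self):
        res = quantify_concentration(500.0, 500.0, self._calib())
        assert res.value_ng_g == pytest.approx(50.0, abs=1e-9)
        assert res.in_range

    def test_drift_normalization_doubles_halved_istd(self):
        res = quantify_concentration(500.0, 250.0, self._calib())
        assert res.value_ng_g == pytest.approx(100.0, abs=1e-9)

    def test_out_of_range_flagged(self):
        res = quantify_concentration(3000.0, 500.0, self._calib())
        assert res.value_ng_g == pytest.approx(300.0, abs=1e-9)
        assert not res.in_range

    def test_singular_calibration_rejected(self):
        with pytest.raises(CalibrationError):
            ConcentrationCalibration(
                concentrations=np.array([10.0, 10.0]),
                analyte_counts=np.array([100.0, 100.0]),
                istd_counts=np.array([500.0, 500.0]),
            )
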