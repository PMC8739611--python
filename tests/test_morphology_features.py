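import numpy as np
import pytest

from cardiotrait import (
    ALL_FEATURES,
    CLINICAL_FEATURES,
    EcgSimConfig,
    amplitude_features,
    assemble_feature_vector,
    bazett_qtc,
    extract_features,
    generate_ecg,
    relative_amplitude,
    temporal_features,
)
from cardiotrait.delineation import FiducialSet
from cardiotrait.exceptions import (
    ConfigurationError,
    InsufficientDataError,
    ParameterError,
    StructuralError,
)
from cardiotrait.config import ExtractionConfig
from cardiotrait.features import (
    AMPLITUDE_FEATURES,
    FEATURE_GROUPS,
    HRV_FEATURES,
    TEMPORAL_FEATURES,
)


def _short_config():
    """Extraction config with a spectral floor suited to short test records."""
    return ExtractionConfig(spectral_min_span_s=20.0)


class TestBazett:
    @pytest.mark.parametrize("qt,rr,expected", [
        (0.40, 1.00, 0.40),
        (0.40, 0.64, 0.50),
        (0.36, 0.81, 0.40),
    ])
    def test_examples(self, qt, rr, expected):
        assert bazett_qtc(qt, rr) == pytest.approx(expected, rel=1e-12)

    def test_literal_variant_divides_by_rr(self):
        assert bazett_qtc(0.40, 0.64, literal=True) == pytest.approx(0.625)

    @pytest.mark.parametrize("qt,rr", [(0.0, 1.0), (0.4, 0.0), (-0.4, 1.0)])
    def test_nonpositive_rejected(self, qt, rr):
        with pytest.raises(ParameterError):
            bazett_qtc(qt, rr)


class TestRelativeAmplitude:
    def test_equal_amplitudes_give_zero(self):
        assert relative_amplitude(0.5, 0.5, 1.0) == 0.0

    def test_p_to_r_example(self):
        assert relative_amplitude(0.2, 1.0, 1.0) == pytest.approx(0.8)

    def test_scale_invariance(self):
        a = relative_amplitude(0.2, 1.0, 1.0)
        b = relative_amplitude(0.4, 2.0, 2.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_r_amplitude_rejected(self):
        with pytest.raises(ParameterError):
            relative_amplitude(0.2, 1.0, 0.0)

    def test_alternative_modes(self):
        assert relative_amplitude(0.2, 1.0, 2.0, mode="difference") == pytest.approx(0.8)
        assert relative_amplitude(0.5, 1.0, 2.0, mode="abs_ratio") == pytest.approx(2.0)
        with pytest.raises(ParameterError):
            relative_amplitude(0.2, 1.0, 1.0, mode="bogus")


def _identical_beats(n_beats=5, fs=500.0):
    """Hand-built fiducial set: identical beats, known intervals."""
    period = 400  # 0.8 s at 500 Hz
    base = {"p_on": 0, "p": 25, "p_off": 50, "qrs_on": 80, "q": 90,
            "r": 100, "s": 110, "qrs_off": 120, "t_on": 160, "t": 205,
            "t_off": 250}
    indices = {k: np.array([v + period * b for b in range(n_beats)])
               for k, v in base.items()}
    amplitudes = {"p": np.full(n_beats, 0.15), "q": np.full(n_beats, -0.1),
                  "r": np.full(n_beats, 1.0), "s": np.full(n_beats, -0.2),
                  "t": np.full(n_beats, 0.3)}
    return FiducialSet(fs=fs, indices=indices, amplitudes=amplitudes)


class TestTemporalFeatures:
    def test_identical_beats_have_zero_spread(self):
        out = temporal_features(_identical_beats())
        assert len(out) == 31
        for name, value in out.items():
            if name.endswith("_sd"):
                assert value == pytest.approx(0.0, abs=1e-6), name
        assert out["PR_min"] == out["PR_max"] == out["PR_mean"] == out["PR_median"]

    def test_hand_computed_intervals(self):
        out = temporal_features(_identical_beats())
        fs = 500.0
        assert out["PRinterval_mean"] == pytest.approx(80 / fs)
        assert out["PRsegment_mean"] == pytest.approx(30 / fs)
        assert out["QRScomplex_mean"] == pytest.approx(40 / fs)
        assert out["Pwave_mean"] == pytest.approx(50 / fs)
        assert out["Twave_mean"] == pytest.approx(90 / fs)
        assert out["STinterval_mean"] == pytest.approx(130 / fs)
        assert out["STsegment_mean"] == pytest.approx(40 / fs)
        assert out["PR_mean"] == pytest.approx(75 / fs)     # P peak to R peak
        assert out["ST_mean"] == pytest.approx(95 / fs)     # S peak to T peak
        assert out["QRS_mean"] == pytest.approx(20 / fs)    # Q peak to S peak
        # QT = 170 samples = 0.34 s; RR = 0.8 s -> QTc = 0.34/sqrt(0.8)
        assert out["QTnorm_mean"] == pytest.approx(0.34 / np.sqrt(0.8), rel=1e-9)

    def test_bazett_identity_at_unit_rr(self):
        """Planted QT at constant RR=1 s: QTnorm equals raw QT."""
        cfg = EcgSimConfig(hr_mean=60, lf_amp=0, hf_amp=0, qt_duration=0.40,
                           fs=500, duration_s=40, seed=0)
        record, _ = generate_ecg(cfg)
        feats = extract_features(record, _short_config())
        assert feats["QTnorm_mean"] == pytest.approx(0.40, abs=0.005)

    def test_planted_pr_interval_recovered(self):
        cfg = EcgSimConfig(hr_mean=65, lf_amp=0, hf_amp=0, pr_interval=0.16,
                           fs=500, duration_s=40, seed=0)
        record, _ = generate_ecg(cfg)
        feats = extract_features(record, _short_config())
        assert feats["PRinterval_mean"] == pytest.approx(0.16, abs=0.005)
        assert feats["PRinterval_sd"] < 0.005

    def test_needs_two_beats(self):
        fids = _identical_beats(n_beats=1)
        with pytest.raises(InsufficientDataError):
            temporal_features(fids)


class TestAmplitudeFeatures:
    def test_identical_beats_zero_spread_and_expected_means(self):
        out = amplitude_features(_identical_beats())
        assert len(out) == 14
        for name, value in out.items():
            if name.endswith("_sd"):
                assert value == pytest.approx(0.0, abs=1e-6), name
        assert out["PRa_mean"] == pytest.approx((1.0 - 0.15) / 1.0)
        assert out["RQa_mean"] == pytest.approx((-0.1 - 1.0) / 1.0)
        assert out["RTa_mean"] == pytest.approx((0.3 - 1.0) / 1.0)
        assert out["STa_mean"] == pytest.approx((0.3 - (-0.2)) / 1.0)
        assert out["QSa_mean"] == pytest.approx((-0.2 - (-0.1)) / 1.0)

    def test_degenerate_ek_weights(self):
        weights = {"w_0": 0.0, "w_P": 0.0, "w_Q": 0.0, "w_R": 1.0,
                   "w_S": 0.0, "w_T": 0.0}
        out = amplitude_features(_identical_beats(), ek_weights=weights)
        assert out["Ek_mean"] == pytest.approx(1.0)
        assert out["Ek_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_ek_weights_config_error(self):
        with pytest.raises(ConfigurationError, match="ek_weights"):
            amplitude_features(_identical_beats(), ek_weights=None)
        with pytest.raises(ConfigurationError, match="w_T"):
            amplitude_features(_identical_beats(), ek_weights={"w_0": 0.0})

    def test_scaling_signal_leaves_relative_amplitudes_unchanged(self):
        fids = _identical_beats()
        scaled = FiducialSet(fs=fids.fs, indices=fids.indices,
                             amplitudes={k: 2.0 * v for k, v in fids.amplitudes.items()})
        a = amplitude_features(fids)
        b = amplitude_features(scaled)
        for name in a:
            if not name.startswith("Ek"):
                assert a[name] == pytest.approx(b[name], rel=1e-12), name

    def test_rta_increases_with_planted_t_amplitude(self):
        values = []
        for t_amp in (0.25, 0.50):
            cfg = EcgSimConfig(t_amplitude=t_amp, fs=500, duration_s=30, seed=3)
            record, _ = generate_ecg(cfg)
            values.append(extract_features(record, _short_config())["RTa_mean"])
        assert values[1] > values[0]


class TestAssembleFeatureVector:
    def test_structural_identities(self, clean_record):
        _, record, _ = clean_record
        feats = extract_features(record)
        assert len(feats) == 62
        assert list(feats) == list(ALL_FEATURES)
        assert len([f for f in feats if f != "HRV_index"]) == 61
        assert len(CLINICAL_FEATURES) == 34
        # clinical decomposition: 16 HRV + 16 temporal + 2 Ek
        groups = [FEATURE_GROUPS[f] for f in CLINICAL_FEATURES]
        assert groups.count("hrv") == 16
        assert groups.count("temporal") == 16
        assert groups.count("amplitude") == 2
        assert len(HRV_FEATURES) == 17
        assert len(TEMPORAL_FEATURES) == 31
        assert len(AMPLITUDE_FEATURES) == 14

    def test_missing_feature_named(self):
        hrv = {f: 0.0 for f in HRV_FEATURES}
        temporal = {f: 0.0 for f in TEMPORAL_FEATURES}
        amplitude = {f: 0.0 for f in AMPLITUDE_FEATURES}
        del temporal["QTnorm_sd"]
        with pytest.raises(StructuralError, match="QTnorm_sd"):
            assemble_feature_vector(hrv, temporal, amplitude)

    def test_amplitude_scaling_leaves_temporal_features_unchanged(self, clean_record):
        _, record, _ = clean_record
        from cardiotrait.signal_io import EcgRecord
        feats1 = extract_features(record)
        feats2 = extract_features(
            EcgRecord(record.samples * 2.0, record.fs, record.subject_id))
        for name in TEMPORAL_FEATURES:
            assert feats1[name] == pytest.approx(feats2[name], abs=0.004), name
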