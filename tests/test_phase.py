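import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eplsa import (
    BinaryPatternSeries,
    ScanRecord,
    all_patterns,
    binarize,
    decode_codes,
    dpl_matrix,
    dpl_tensor,
    encode_patterns,
    hilbert_phase,
    leading_eig,
    phase_pipeline,
    sign_fix,
)
from eplsa.phase import DegenerateSignalError, PhaseSeries, ValidationError


def _wrap(x):
    return np.angle(np.exp(1j * x))


def _scan(columns, tr=1.0):
    data = np.column_stack(columns)
    return ScanRecord(
        data=data,
        region_labels=[f"c{i}" for i in range(data.shape[1])],
        tr_seconds=tr,
    )


class TestHilbertPhase:
    def test_cosine_phase_ramp(self):
        t = np.arange(600)
        omega = 2 * np.pi * 0.02
        scan = _scan([np.cos(omega * t), np.cos(omega * t + 1.0)])
        ps = hilbert_phase(scan, trim=30)
        frames = np.array(ps.valid_frames)
        err = np.abs(_wrap(ps.phases[frames, 0] - omega * frames))
        assert err.max() < 0.05

    def test_sine_lags_cosine_by_quarter_cycle(self):
        t = np.arange(600)
        omega = 2 * np.pi * 0.02
        scan = _scan([np.cos(omega * t), np.sin(omega * t)])
        ps = hilbert_phase(scan, trim=30)
        frames = np.array(ps.valid_frames)
        diff = _wrap(ps.phases[frames, 1] - ps.phases[frames, 0] + np.pi / 2)
        assert np.abs(diff).max() < 0.05

    def test_constant_column_rejected(self):
        scan = _scan([np.ones(50), np.sin(np.arange(50))])
        with pytest.raises(DegenerateSignalError, match="c0"):
            hilbert_phase(scan)

    def test_trim_range(self):
        scan = _scan([np.sin(np.arange(10.0)), np.cos(np.arange(10.0))])
        ps = hilbert_phase(scan, trim=2)
        assert (ps.valid_start, ps.valid_stop) == (2, 8)

    def test_phases_wrapped(self, rng):
        scan = _scan([rng.normal(size=200), rng.normal(size=200)])
        ps = hilbert_phase(scan)
        assert np.all(ps.phases > -np.pi) and np.all(ps.phases <= np.pi)


class TestDPL:
    def test_hand_values(self):
        phases = PhaseSeries(
            phases=np.array([[0.0, np.pi, np.pi / 2]]), valid_start=0, valid_stop=1
        )
        m = dpl_matrix(phases, 0)
        assert m[0, 0] == pytest.approx(1.0)
        assert m[0, 1] == pytest.approx(-1.0)
        assert m[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_frame(self):
        phases = PhaseSeries(
            phases=np.zeros((4, 2)), valid_start=1, valid_stop=3
        )
        with pytest.raises(ValidationError):
            dpl_matrix(phases, 0)

    def test_tensor_invariants_random(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=(20, 5))
        phases = PhaseSeries(phases=phi, valid_start=0, valid_stop=20)
        tensor = dpl_tensor(phases)
        assert tensor.shape == (5, 5, 20)
        np.testing.assert_allclose(tensor, tensor.transpose(1, 0, 2), atol=1e-12)
        np.testing.assert_allclose(tensor[np.arange(5), np.arange(5)], 1.0)
        assert np.all(tensor >= -1 - 1e-12) and np.all(tensor <= 1 + 1e-12)


class TestLeadingEig:
    def test_full_synchrony(self):
        v, lam = leading_eig(np.ones((4, 4)))
        assert lam == pytest.approx(4.0)
        np.testing.assert_allclose(np.abs(v), 0.5)
        assert len(set(np.sign(v))) == 1

    def test_two_by_two_closed_form(self):
        c = 0.6
        v, lam = leading_eig(np.array([[1.0, c], [c, 1.0]]))
        assert lam == pytest.approx(1 + c)
        np.testing.assert_allclose(np.abs(v), 1 / np.sqrt(2))

    def test_identity_deterministic(self):
        v1, lam1 = leading_eig(np.eye(3))
        v2, lam2 = leading_eig(np.eye(3))
        assert lam1 == pytest.approx(1.0)
        np.testing.assert_array_equal(v1, v2)

    def test_nonsymmetric_rejected(self):
        m = np.eye(3)
        m[0, 1] = 1e-6
        with pytest.raises(ValidationError):
            leading_eig(m)

    def test_eigen_residual_random(self, rng):
        for _ in range(25):
            a = rng.normal(size=(6, 6))
            a = (a + a.T) / 2
            v, lam = leading_eig(a)
            assert np.linalg.norm(a @ v - lam * v) < 1e-8
            assert lam == pytest.approx(np.linalg.eigvalsh(a)[-1])
            assert np.linalg.norm(v) == pytest.approx(1.0)


class TestSignFixAndBinarize:
    def test_zero_counts_inactive(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.3, -0.2, 0.0])), [1, -1, -1]
        )

    def test_all_negative(self):
        np.testing.assert_array_equal(binarize(-np.ones(3)), [-1, -1, -1])

    def test_majority_negative_convention(self, rng):
        for _ in range(50):
            v = rng.normal(size=7)
            fixed = sign_fix(v)
            assert (fixed <= 0).sum() > (fixed > 0).sum()

    def test_global_sign_invariance(self, rng):
        for _ in range(50):
            v = rng.normal(size=6)
            np.testing.assert_array_equal(
                binarize(sign_fix(v)), binarize(sign_fix(-v))
            )

    def test_exact_tie_largest_component_negative(self):
        fixed = sign_fix(np.array([2.0, -1.0]))
        assert fixed[0] < 0


class TestPatternCodes:
    @pytest.mark.parametrize("n", range(1, 11))
    def test_round_trip_all_patterns(self, n):
        codes = np.arange(1 << n)
        pats = decode_codes(codes, n)
        np.testing.assert_array_equal(encode_patterns(pats), codes)
        assert len(np.unique(encode_patterns(pats))) == 1 << n

    def test_msb_is_first_unit(self):
        # +1 in unit 0 only: 100 -> code 4 for N=3
        assert encode_patterns(np.array([[1, -1, -1]]))[0] == 4

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=12))
    def test_round_trip_property(self, bits):
        pat = np.array([bits])
        code = encode_patterns(pat)
        np.testing.assert_array_equal(decode_codes(code, len(bits)), pat)

    def test_series_consistency_enforced(self):
        with pytest.raises(ValidationError):
            BinaryPatternSeries(patterns=np.array([[1, -1]]), codes=np.array([0]))


class TestPhasePipeline:
    def test_antiphase_pair_opposite_states(self):
        t = np.arange(200)
        omega = 2 * np.pi * 0.05
        scan = _scan([np.cos(omega * t), np.cos(omega * t + np.pi)])
        series = phase_pipeline(scan, trim=5)
        assert np.all(series.patterns[:, 0] != series.patterns[:, 1])

    def test_full_synchrony_single_pattern(self):
        t = np.arange(200)
        omega = 2 * np.pi * 0.05
        base = np.cos(omega * t)
        scan = _scan([base, 2.0 * base, 0.5 * base])
        series = phase_pipeline(scan, trim=5)
        assert len(np.unique(series.codes)) == 1

    def test_output_length(self):
        t = np.arange(10.0)
        scan = _scan([np.sin(t), np.cos(t)])
        series = phase_pipeline(scan, trim=1)
        assert series.n_frames == 8

    def test_all_patterns_enumeration(self):
        assert all_patterns(7).shape == (128, 7)
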