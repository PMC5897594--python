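"""Rotor decomposition, mode reassignment, and the L spectrum."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locoefa import (
    Contour,
    EFACoefficients,
    RotorPair,
    assign_modes,
    canonical_phase,
    canonicalise,
    compute_L,
    cosine_lobed_circle,
    decompose_rotors,
    efa_decompose,
    efa_reconstruct,
    loco_reconstruct,
    loco_spectrum,
    resample_contour,
    rotors_to_harmonics,
    superformula_shape,
    STAR_PARAMS,
)

from conftest import chord_spectrum, circle_contour, polar_spectrum


def _coef(harmonics):
    return EFACoefficients(np.zeros(2), np.asarray(harmonics, float), 2 * np.pi)


def radial_maxima_count(rotors_spec, n_samples=4096):
    """Numeric oracle: lobes drawn by a base circle plus one extra rotor.

    Counts strict local maxima of |z(t)| for
    z = e^{it} + sum of eps rotors given as (radius, harmonic, sense).
    """
    t = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    z = np.exp(1j * t)
    for radius, harmonic, sense in rotors_spec:
        z = z + radius * np.exp(1j * sense * harmonic * t)
    r = np.abs(z)
    return int(np.sum((r > np.roll(r, 1)) & (r > np.roll(r, -1))))


class TestRotors:
    def test_ellipse_split(self):
        (r,) = decompose_rotors(_coef([[2, 0, 0, 1]]))
        assert r.lambda_plus == pytest.approx(1.5)
        assert r.lambda_minus == pytest.approx(0.5)

    def test_pure_ccw_circle(self):
        (r,) = decompose_rotors(_coef([[1, 0, 0, 1]]))
        assert r.lambda_plus == pytest.approx(1.0)
        assert r.lambda_minus == pytest.approx(0.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=4))
    def test_roundtrip_exact(self, quad):
        coef = _coef([quad])
        back = rotors_to_harmonics(decompose_rotors(coef))
        assert np.allclose(back[0], quad, atol=1e-12)


class TestCanonicalPhase:
    def test_starting_vertex_invariance(self, star6):
        base = None
        pts = resample_contour(star6, 800).points
        for shift in range(0, 800, 100):
            c = Contour(np.roll(pts, shift, axis=0))
            rotors, zeta = canonical_phase(decompose_rotors(efa_decompose(c, 12)))
            vec = np.array(
                [(r.lambda_plus, r.lambda_minus, r.phi_plus, r.phi_minus) for r in rotors]
            )
            # compare radii everywhere; phases only where a rotor exists
            if base is None:
                base = vec
            else:
                assert np.allclose(vec[:, :2], base[:, :2], atol=1e-9)
                live = base[:, :2] > 1e-9
                dphi = (vec[:, 2:] - base[:, 2:])[live]
                assert np.allclose(np.arctan2(np.sin(dphi), np.cos(dphi)), 0, atol=1e-6)

    def test_circle_phase_zeroed(self):
        rotors, zeta = canonical_phase(
            decompose_rotors(efa_decompose(circle_contour(512), 3))
        )
        assert rotors[0].phi_plus == pytest.approx(0.0, abs=1e-12)
        assert zeta == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_first_harmonic(self):
        with pytest.raises(ValueError, match="degenerate"):
            canonical_phase([RotorPair(1, 0.0, 0.0, 0.0, 0.0)])


class TestModeAssignment:
    @pytest.mark.parametrize(
        "harmonic,sense", [(5, -1), (7, +1)],
        ids=["cw-rotor-h5", "ccw-rotor-h7"],
    )
    def test_epicycle_rule_matches_radial_oracle(self, harmonic, sense):
        """A CW rotor of harmonic 5 and a CCW rotor of harmonic 7 both
        draw six radial bumps, and both land in lobe mode 6."""
        eps = 0.05
        assert radial_maxima_count([(eps, harmonic, sense)]) == 6
        harmonics = np.zeros((8, 4))
        harmonics[0] = [1, 0, 0, 1]  # CCW unit circle
        h = np.zeros(4)
        if sense > 0:  # pure CCW rotor: a=d=eps
            h[[0, 3]] = eps
        else:  # pure CW rotor: a=eps, d=-eps
            h[0], h[3] = eps, -eps
        harmonics[harmonic - 1] = h
        spec = loco_spectrum(_coef(harmonics))
        nz = np.nonzero(spec.L[1:] > 1e-12)[0] + 2
        assert list(nz) == [6]
        assert spec.L[5] == pytest.approx(eps, abs=1e-12)

    def test_circle_has_no_lobe_modes(self):
        spec = loco_spectrum(efa_decompose(circle_contour(1024), 20))
        assert np.all(spec.L[1:] < 1e-6)

    def test_rotor_conservation(self, star6):
        """Every rotor of every harmonic is owned by exactly one mode."""
        coef = efa_decompose(resample_contour(star6, 800), 20)
        rotors, _ = canonical_phase(decompose_rotors(coef))
        modes = assign_modes(rotors)
        owned = sorted(
            (t.harmonic, t.sense, round(t.radius, 12))
            for m in modes
            for t in (m.ccw, m.cw)
            if t is not None
        )
        expected = sorted(
            [(r.n, +1, round(r.lambda_plus, 12)) for r in rotors]
            + [(r.n, -1, round(r.lambda_minus, 12)) for r in rotors]
        )
        assert owned == expected


class TestComputeL:
    def test_single_rotor_limit(self):
        harmonics = np.zeros((8, 4))
        harmonics[0] = [1, 0, 0, 1]
        harmonics[6] = [0.15, 0, 0, 0.15]
        spec = loco_spectrum(_coef(harmonics))
        assert spec.L[5] == pytest.approx(0.15, abs=1e-12)

    @pytest.mark.parametrize("delta,expected", [(0.0, 0.2), (np.pi, 0.0)])
    def test_constructive_destructive(self, delta, expected):
        rotors = [
            RotorPair(1, 1.0, 0.0, 0.0, 0.0),
            RotorPair(5, 0.0, 0.1, 0.0, delta),
            RotorPair(7, 0.1, 0.0, 0.0, 0.0),
        ]
        spec = compute_L(assign_modes(rotors), zeta=0.0)
        assert spec.L[5] == pytest.approx(expected, abs=1e-12)

    def test_amplitude_calibration(self, lobed15):
        """Area-normalised r = 1 + 0.15 cos(6 theta) has L6 = 0.15."""
        spec = polar_spectrum(lobed15)
        assert spec.L[5] == pytest.approx(0.15, abs=0.003)

    @pytest.mark.parametrize("l", range(3, 10))
    @pytest.mark.parametrize("eps", [0.05, 0.1, 0.15, 0.2])
    def test_epsilon_recovery(self, eps, l):
        spec = polar_spectrum(cosine_lobed_circle(eps, l))
        assert abs(spec.L[l - 1] - eps) <= 0.02 * eps + 0.003


class TestReconstruct:
    def test_circle_mode_one(self):
        spec = loco_spectrum(efa_decompose(circle_contour(512), 10))
        rec = loco_reconstruct(spec, 1, 256)
        assert np.allclose(np.hypot(*rec.points.T), 1.0, atol=1e-4)

    def test_all_modes_equal_full_efa(self, star6):
        """Mode bookkeeping conserves rotor content exactly."""
        c = resample_contour(star6, 800)
        coef = efa_decompose(c, 20)
        spec = loco_spectrum(coef)
        rec = loco_reconstruct(spec, spec.n_modes, 512)
        # canonical phase shifted the parameter start by tau
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False) + spec.tau
        n = np.arange(1, 21)[:, None]
        x = coef.offset[0] + coef.harmonics[:, 0] @ np.cos(n * t) + coef.harmonics[:, 1] @ np.sin(n * t)
        y = coef.offset[1] + coef.harmonics[:, 2] @ np.cos(n * t) + coef.harmonics[:, 3] @ np.sin(n * t)
        assert np.hypot(rec.points[:, 0] - x, rec.points[:, 1] - y).max() < 1e-9

    def test_out_of_range(self):
        spec = loco_spectrum(efa_decompose(circle_contour(256), 5))
        with pytest.raises(ValueError):
            loco_reconstruct(spec, spec.n_modes + 1, 64)


class TestSpectrumInvariances:
    def test_rotation_invariance(self, star6):
        base = chord_spectrum(star6).L
        for rho in (0.31, 1.57, 2.9):
            R = np.array([[np.cos(rho), -np.sin(rho)], [np.sin(rho), np.cos(rho)]])
            rot = Contour(star6.points @ R.T)
            assert np.allclose(chord_spectrum(rot).L, base, atol=1e-9)

    def test_starting_point_invariance(self, star6):
        # cyclic permutation of the vertex list: same polygon, new start
        pts = resample_contour(star6, 1000).points
        base = None
        for shift in (0, 137, 411, 800):
            canon, scale = canonicalise(Contour(np.roll(pts, shift, axis=0)))
            L = loco_spectrum(efa_decompose(canon, 51, scale=scale)).L
            if base is None:
                base = L
            else:
                assert np.allclose(L, base, atol=1e-6)

    @pytest.mark.parametrize("k", range(3, 10))
    def test_superformula_argmax_matches_lobes(self, k):
        for amplitude in ("low", "mid", "high"):
            spec = chord_spectrum(superformula_shape(STAR_PARAMS[(k, amplitude)]))
            assert spec.argmax_lobe() == k
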