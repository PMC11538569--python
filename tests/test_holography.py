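"""Virtual sources, skull-slab transmission, recording, and conjugation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonolens import (
    FocusTarget,
    Medium,
    PlanarGrid,
    SkullLayer,
    conjugate,
    make_virtual_sources,
    record_hologram,
    skull_layer_transmission,
    wavenumber,
    wrap_phase,
)
from sonolens.holography import slab_transmission
from sonolens.errors import GeometryError, InvalidArgumentError, InvalidStateError

FREQ = 3e6


def _k0(water):
    return wavenumber(water, FREQ)


class TestVirtualSources:
    def test_two_foci_of_100_sources_each(self, water):
        targets = [
            FocusTarget(center=(-1.5e-3, 0, 3.5e-3), amplitude=1.0, n_sources=100),
            FocusTarget(center=(+1.5e-3, 0, 3.5e-3), amplitude=2.0, n_sources=100),
        ]
        s = make_virtual_sources(targets, 0.25e-3, seed=0, carrier_wavenumber=_k0(water))
        assert s.positions.shape == (200, 3)
        # per-focus strengths sum to the focus amplitude (times the unit-
        # magnitude carrier phase)
        assert abs(s.strengths[:100].sum()) == pytest.approx(1.0)
        assert abs(s.strengths[100:].sum()) == pytest.approx(2.0)

    def test_zero_jitter_collocates_sources(self, water):
        t = FocusTarget(center=(0, 0, 3e-3), n_sources=25)
        s = make_virtual_sources([t], 0.0, seed=1, carrier_wavenumber=_k0(water))
        assert np.all(s.positions == np.array(t.center))

    def test_jitter_stays_inside_ball(self, water):
        t = FocusTarget(center=(1e-3, -1e-3, 3e-3), n_sources=500)
        s = make_virtual_sources([t], 0.3e-3, seed=5, carrier_wavenumber=_k0(water))
        r = np.linalg.norm(s.positions - np.array(t.center), axis=1)
        assert r.max() <= 0.3e-3

    def test_same_seed_is_bitwise_identical(self, water):
        targets = [FocusTarget(center=(0, 0, 3e-3), n_sources=50)]
        a = make_virtual_sources(targets, 0.2e-3, seed=9, carrier_wavenumber=_k0(water))
        b = make_virtual_sources(targets, 0.2e-3, seed=9, carrier_wavenumber=_k0(water))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.strengths, b.strengths)

    def test_mirror_x_reflects_partner_cloud(self, water):
        targets = [
            FocusTarget(center=(-1.5e-3, 0, 3.5e-3), n_sources=40),
            FocusTarget(center=(+1.5e-3, 0, 3.5e-3), n_sources=40),
        ]
        s = make_virtual_sources(
            targets, 0.25e-3, seed=2, carrier_wavenumber=_k0(water), mirror_x=True
        )
        left, right = s.positions[:40], s.positions[40:]
        np.testing.assert_array_equal(left * [-1, 1, 1], right)

    def test_negative_jitter_rejected(self, water):
        with pytest.raises(InvalidArgumentError):
            make_virtual_sources(
                [FocusTarget(center=(0, 0, 1e-3))], -1e-4, 0, _k0(water)
            )

    def test_empty_targets_rejected(self, water):
        with pytest.raises(InvalidArgumentError):
            make_virtual_sources([], 0.0, 0, _k0(water))


class TestSkullTransmission:
    def test_vanishing_layer_is_transparent(self, water, skull_medium):
        layer = SkullLayer(medium=skull_medium, thickness=1e-12)
        t = skull_layer_transmission(layer, FREQ, water)
        assert t == pytest.approx(1.0 + 0j, abs=1e-6)

    def test_matched_slab_is_pure_delay(self, water):
        d = 250e-6
        layer = SkullLayer(medium=water, thickness=d)
        t = skull_layer_transmission(layer, FREQ, water)
        assert t == pytest.approx(np.exp(-1j * _k0(water) * d), rel=1e-12)

    def test_skull_250um_matches_boundary_value_oracle(self, water, skull_medium):
        """Independent oracle: solve the four-interface-unknown linear system
        (reflection, two slab waves, transmission) from pressure/velocity
        continuity, and compare the transmitted amplitude."""
        d = 250e-6
        k1 = wavenumber(water, FREQ)
        k2 = wavenumber(skull_medium, FREQ)
        z1, z2 = water.impedance, skull_medium.impedance
        # unknowns [r, A, B, t]; incident wave exp(-i k1 z), slab A e^{-ik2 z} + B e^{ik2 z},
        # transmitted t e^{-i k1 (z-d)}
        e_m, e_p = np.exp(-1j * k2 * d), np.exp(1j * k2 * d)
        m = np.array(
            [
                [1, -1, -1, 0],
                [-1 / z1, -1 / z2, 1 / z2, 0],
                [0, e_m, e_p, -1],
                [0, e_m / z2, -e_p / z2, -1 / z1],
            ],
            dtype=complex,
        )
        rhs = np.array([-1, -1 / z1, 0, 0], dtype=complex)
        r, a, b, t_oracle = np.linalg.solve(m, rhs)
        layer = SkullLayer(medium=skull_medium, thickness=d)
        assert skull_layer_transmission(layer, FREQ, water) == pytest.approx(
            t_oracle, rel=1e-12
        )
        # energy conservation of the lossless stack
        assert abs(r) ** 2 + abs(t_oracle) ** 2 == pytest.approx(1.0, rel=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=500, max_value=5000),
        st.floats(min_value=800, max_value=6000),
        st.floats(min_value=10e-6, max_value=2e-3),
    )
    def test_magnitude_never_exceeds_unity(self, rho, c, thickness):
        inner = Medium("m", rho, c)
        outer = Medium("w", 1000.0, 1500.0)
        t = slab_transmission(inner, outer, thickness, FREQ)
        assert abs(t) <= 1.0 + 1e-12


class TestRecording:
    def _plane(self, spacing=0.25e-3, n=16):
        return PlanarGrid.centered((0, 0, 0), (n * spacing, n * spacing), spacing)

    def test_single_focus_phase_is_spherical(self, water):
        """Without a skull, the recorded phase at each plane sample equals
        the analytic spherical-wave phase pi/2 + k z_c - k r (wrapped)."""
        center = (0.0, 0.0, 3.5e-3)
        k = _k0(water)
        s = make_virtual_sources(
            [FocusTarget(center=center, n_sources=1)], 0.0, 0, carrier_wavenumber=k
        )
        plane = self._plane()
        holo = record_hologram(s, None, plane, water, FREQ)
        r = np.linalg.norm(plane.points() - np.array(center), axis=1).reshape(
            plane.shape
        )
        expected = wrap_phase(np.pi / 2 + k * center[2] - k * r)
        np.testing.assert_allclose(
            np.cos(holo.phase.values - expected), 1.0, atol=1e-9
        )

    def test_bilateral_foci_give_mirror_symmetric_magnitude(self, water):
        k = _k0(water)
        targets = [
            FocusTarget(center=(-1.5e-3, 0, 3.5e-3), n_sources=1),
            FocusTarget(center=(+1.5e-3, 0, 3.5e-3), n_sources=1),
        ]
        s = make_virtual_sources(targets, 0.0, 0, carrier_wavenumber=k)
        holo = record_hologram(s, None, self._plane(), water, FREQ)
        mag = np.abs(holo.pressure.values)
        np.testing.assert_allclose(mag, mag[::-1, :], rtol=1e-10)

    def test_flat_slab_adds_uniform_phase(self, water, skull_medium):
        k = _k0(water)
        s = make_virtual_sources(
            [FocusTarget(center=(0.5e-3, 0, 3.5e-3), n_sources=1)],
            0.0, 0, carrier_wavenumber=k,
        )
        plane = self._plane()
        layer = SkullLayer(medium=skull_medium, thickness=250e-6, z_entry=0.5e-3)
        with_skull = record_hologram(s, layer, plane, water, FREQ)
        without = record_hologram(s, None, plane, water, FREQ)
        ratio = with_skull.pressure.values / without.pressure.values
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-12)
        delta = wrap_phase(with_skull.phase.values - without.phase.values)
        np.testing.assert_allclose(delta, delta.flat[0], atol=1e-9)

    def test_plane_inside_slab_rejected(self, water, skull_medium):
        k = _k0(water)
        s = make_virtual_sources(
            [FocusTarget(center=(0, 0, 3.5e-3), n_sources=1)],
            0.0, 0, carrier_wavenumber=k,
        )
        layer = SkullLayer(medium=skull_medium, thickness=250e-6, z_entry=0.5e-3)
        plane = PlanarGrid.centered((0, 0, 0.6e-3), (4e-3, 4e-3), 0.25e-3)
        with pytest.raises(GeometryError):
            record_hologram(s, layer, plane, water, FREQ)


class TestConjugation:
    def _holo(self, water):
        k = _k0(water)
        s = make_virtual_sources(
            [FocusTarget(center=(0, 0, 3e-3), n_sources=1)], 0.0, 0,
            carrier_wavenumber=k,
        )
        plane = PlanarGrid.centered((0, 0, 0), (2e-3, 2e-3), 0.25e-3)
        return record_hologram(s, None, plane, water, FREQ)

    def test_phase_negated_and_magnitude_preserved(self, water):
        holo = self._holo(water)
        conj = conjugate(holo)
        assert conj.conjugated
        np.testing.assert_allclose(
            conj.phase.values, wrap_phase(-holo.phase.values), atol=1e-15
        )
        np.testing.assert_allclose(
            np.abs(conj.pressure.values), np.abs(holo.pressure.values), rtol=1e-15
        )

    def test_wrap_fixed_point_at_pi(self):
        # -pi wraps to pi; negating pi gives -pi which wraps back to pi
        assert float(wrap_phase(-np.pi)) == pytest.approx(np.pi)
        assert float(wrap_phase(-float(wrap_phase(np.pi)))) == pytest.approx(np.pi)

    def test_double_conjugation_rejected_then_forced_is_involution(self, water):
        holo = self._holo(water)
        conj = conjugate(holo)
        with pytest.raises(InvalidStateError):
            conjugate(conj)
        back = conjugate(conj, force=True)
        np.testing.assert_allclose(back.phase.values, holo.phase.values, atol=1e-15)
        assert not back.conjugated
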