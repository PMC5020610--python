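"""Geometric primitives: dihedrals, rotations, atom placement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimerscope.geometry import (dihedral, perpendicular_vector, place_atom,
                                 random_rotation, rotation_about_axis, unit)
from dimerscope.synth import (DihedralSpec, build_backbone, measure_dihedrals)

angles = st.floats(min_value=-179.0, max_value=180.0)


def test_dihedral_sign_convention():
    # canonical +90 degree twist about the z axis
    p0 = np.array([1.0, 0.0, -1.0])
    p1 = np.array([0.0, 0.0, -1.0])
    p2 = np.array([0.0, 0.0, 0.0])
    p3 = np.array([0.0, 1.0, 0.0])
    assert dihedral(p0, p1, p2, p3) == pytest.approx(90.0)
    assert dihedral(p3, p2, p1, p0) == pytest.approx(90.0)  # reversal symmetry
    assert dihedral(p0, p1, p2, -p3) == pytest.approx(-90.0)  # mirror flips sign


def test_rotation_about_axis_is_orthonormal_and_periodic():
    R = rotation_about_axis([1.0, 2.0, 3.0], 73.0)
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
    assert np.linalg.det(R) == pytest.approx(1.0)
    R360 = rotation_about_axis([1.0, 2.0, 3.0], 360.0)
    assert np.allclose(R360, np.eye(3), atol=1e-12)


def test_random_rotation_is_proper_and_seeded():
    rng = np.random.default_rng(3)
    R = random_rotation(rng)
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
    assert np.linalg.det(R) == pytest.approx(1.0)
    R2 = random_rotation(np.random.default_rng(3))
    assert np.allclose(R, R2)


def test_perpendicular_vector_is_unit_and_orthogonal():
    for v in ([1, 0, 0], [0, 0, 1], [1.0, -2.0, 0.5]):
        p = perpendicular_vector(np.asarray(v, dtype=float))
        assert np.linalg.norm(p) == pytest.approx(1.0)
        assert abs(np.dot(p, unit(np.asarray(v, float)))) < 1e-12


def test_place_atom_reproduces_internal_coordinates():
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([1.5, 0.0, 0.0])
    c = np.array([2.0, 1.4, 0.0])
    d = place_atom(a, b, c, 1.5, 109.5, 60.0)
    assert np.linalg.norm(d - c) == pytest.approx(1.5, abs=1e-12)
    v1, v2 = unit(b - c), unit(d - c)
    assert np.degrees(np.arccos(np.dot(v1, v2))) == pytest.approx(109.5, abs=1e-9)
    assert dihedral(a, b, c, d) == pytest.approx(60.0, abs=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(phi=angles, psi=angles)
def test_build_measure_dihedral_round_trip(phi, psi):
    """Building from uniform (phi, psi) and re-measuring is the identity."""
    spec = DihedralSpec.uniform(6, phi, psi)
    conf, top = build_backbone("A" * 6, spec)
    meas = measure_dihedrals(conf, top)
    for i in range(1, 5):
        assert meas[i, 0] == pytest.approx(phi, abs=1e-3)
        assert meas[i, 1] == pytest.approx(psi, abs=1e-3)
        assert abs(abs(meas[i, 2]) - 180.0) < 1e-3
    # chain-boundary dihedrals are geometrically undefined
    assert np.isnan(meas[0, 0]) and np.isnan(meas[5, 1])
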