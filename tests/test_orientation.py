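"""Structure-tensor orientation extraction and helix-angle mapping."""

import numpy as np
import pytest
from scipy import stats

from conductionscan import Volume, generate_fiber_test_volume
from conductionscan.orientation import (CardiacFrame, OrientationField,
                                        TensorScales, extract_orientation,
                                        helical_angle_map, structure_tensor)

PITCH = 28.0


def scales(sg=1.0, st=3.0):
    return TensorScales.from_pitch(PITCH, sg, st)


def angular_error_deg(directions, true_axis):
    d = np.abs(directions @ np.asarray(true_axis))
    return np.degrees(np.arccos(np.clip(d, 0, 1)))


def test_scale_validation():
    with pytest.raises(ValueError):
        TensorScales(-1.0, 3.0)
    with pytest.raises(ValueError, match="sigma_tensor"):
        TensorScales(84.0, 28.0)


def test_constant_volume_zero_tensor_and_invalid():
    vol = Volume(np.full((24, 24, 24), 3.0), PITCH)
    J = structure_tensor(vol, scales())
    assert np.allclose(J, 0.0)
    with pytest.warns(UserWarning, match="no valid"):
        field = extract_orientation(vol, scales())
    assert not field.valid.any()
    assert np.allclose(field.coherence, 0.0)


def test_linear_ramp_tensor_is_diagonal_x():
    x = np.arange(32, dtype=float)[:, None, None] * np.ones((32, 32, 32))
    J = structure_tensor(Volume(x, PITCH), scales())
    core = J[8:-8, 8:-8, 8:-8]
    assert np.all(core[..., 0, 0] > 1e-6)
    assert np.allclose(core[..., 1, 1], 0.0, atol=1e-12)
    assert np.allclose(core[..., 2, 2], 0.0, atol=1e-12)
    assert np.allclose(core[..., 0, 1], 0.0, atol=1e-12)


def test_tensor_positive_semidefinite_on_random_volume(rng):
    vol = Volume(rng.standard_normal((24, 24, 24)), PITCH)
    J = structure_tensor(vol, scales())
    evals = np.linalg.eigvalsh(J)
    assert evals.min() >= -1e-10


def test_cylinders_along_z_recovered():
    vol, true = generate_fiber_test_volume("parallel_cylinders", (0, 0, 1),
                                           period_um=PITCH * 6,
                                           shape=(48, 48, 48))
    field = extract_orientation(vol, scales())
    core = np.zeros(vol.shape, bool)
    core[8:-8, 8:-8, 8:-8] = True
    d = field.direction[core & field.valid]
    assert np.median(np.abs(d @ np.array([0, 0, 1.0]))) > 0.999


def test_oblique_axis_median_error_below_2_degrees():
    a = np.deg2rad(30)
    axis = (np.sin(a), 0.0, np.cos(a))
    vol, true = generate_fiber_test_volume("parallel_cylinders", axis,
                                           period_um=PITCH * 6,
                                           shape=(48, 48, 48), seed=2)
    field = extract_orientation(vol, scales())
    core = np.zeros(vol.shape, bool)
    core[8:-8, 8:-8, 8:-8] = True
    err = angular_error_deg(field.direction[core & field.valid], true)
    assert np.median(err) < 2.0


def test_invariance_to_intensity_scaling_and_inversion():
    vol, _ = generate_fiber_test_volume("parallel_cylinders", (0, 0, 1),
                                        period_um=PITCH * 6, shape=(32, 32, 32))
    f1 = extract_orientation(vol, scales())
    f2 = extract_orientation(Volume(-5.0 * vol.data + 100.0, PITCH), scales())
    m = f1.valid & f2.valid
    dots = np.abs(np.einsum("...k,...k->...", f1.direction, f2.direction))[m]
    assert np.nanmin(dots) > 1 - 1e-9


def test_direction_sign_canonicalized():
    vol, _ = generate_fiber_test_volume("parallel_cylinders", (0.5, 0.2, -0.8),
                                        period_um=PITCH * 6, shape=(32, 32, 32))
    field = extract_orientation(vol, scales())
    assert np.nanmin(field.direction[field.valid][:, 2]) >= 0.0


def test_rotation_equivariance_90_degrees():
    vol, _ = generate_fiber_test_volume("parallel_cylinders", (1, 0, 0),
                                        period_um=PITCH * 6, shape=(32, 32, 32),
                                        seed=3)
    f = extract_orientation(vol, scales())
    # rotate x -> y in the image: recovered axis rotates accordingly
    rot = Volume(np.rot90(vol.data, axes=(0, 1)).copy(), PITCH)
    fr = extract_orientation(rot, scales())
    core = np.zeros(vol.shape, bool)
    core[8:-8, 8:-8, 8:-8] = True
    med = np.median(np.abs(fr.direction[core & fr.valid][:, 1]))
    assert med > 0.999


def test_coherence_decreases_with_noise():
    meds = []
    levels = [0.0, 0.3, 0.6, 1.0, 1.5]
    for ns in levels:
        vol, _ = generate_fiber_test_volume("sinusoidal_grating", (0, 0, 1),
                                            period_um=PITCH * 6, noise_sd=ns,
                                            shape=(32, 32, 32), seed=4)
        f = extract_orientation(vol, scales())
        meds.append(np.median(f.coherence[f.valid]))
    rho, _ = stats.spearmanr(levels, meds)
    assert rho < 0


def _uniform_field(direction, shape=(10, 10, 10)):
    d = np.zeros(shape + (3,))
    d[:] = np.asarray(direction) / np.linalg.norm(direction)
    return OrientationField(d, np.ones(shape), np.ones(shape, bool), 280.0)


def test_helix_angle_trivial_directions():
    # thick cylindrical wall around the z long axis
    shape = (10, 10, 10)
    pitch_mm = 0.28
    c = (np.asarray(shape) - 1) * pitch_mm / 2
    X, Y, _ = np.meshgrid(*[np.arange(n) * pitch_mm for n in shape], indexing="ij")
    R = np.hypot(X - c[0], Y - c[1])
    wall = (R > 0.3) & (R < 1.2)
    frame = CardiacFrame((0, 0, 1), tuple(c))
    n_hat = np.zeros(shape + (3,))
    n_hat[..., 0] = (X - c[0]) / np.maximum(R, 1e-9)
    n_hat[..., 1] = (Y - c[1]) / np.maximum(R, 1e-9)
    # circumferential fiber c = z x n
    circ = np.cross(np.array([0.0, 0.0, 1.0]), n_hat)
    f_circ = OrientationField(circ, np.ones(shape), np.ones(shape, bool), 280.0)
    ang = helical_angle_map(f_circ, frame, wall, radial=n_hat)
    assert np.nanmax(np.abs(ang[wall])) < 1e-6
    # longitudinal fiber -> +90 degrees
    ang_l = helical_angle_map(_uniform_field((0, 0, 1)), frame, wall, radial=n_hat)
    assert np.allclose(ang_l[wall], 90.0)
    # absolute variant folds sign
    ang_abs = helical_angle_map(_uniform_field((0, 0, 1)), frame, wall,
                                radial=n_hat, absolute=True)
    assert np.allclose(ang_abs[wall], 90.0)


def test_helix_angle_invariant_under_fiber_sign_flip():
    shape = (10, 10, 10)
    pitch_mm = 0.28
    c = (np.asarray(shape) - 1) * pitch_mm / 2
    X, Y, _ = np.meshgrid(*[np.arange(n) * pitch_mm for n in shape], indexing="ij")
    R = np.hypot(X - c[0], Y - c[1])
    wall = (R > 0.3) & (R < 1.2)
    n_hat = np.zeros(shape + (3,))
    n_hat[..., 0] = (X - c[0]) / np.maximum(R, 1e-9)
    n_hat[..., 1] = (Y - c[1]) / np.maximum(R, 1e-9)
    frame = CardiacFrame((0, 0, 1), tuple(c))
    v = np.array([0.3, 0.5, 0.6])
    a1 = helical_angle_map(_uniform_field(v), frame, wall, radial=n_hat)
    a2 = helical_angle_map(_uniform_field(-v), frame, wall, radial=n_hat)
    # axial quantity: compare circularly (angles live on a 180-degree circle)
    d = np.abs(a1[wall] - a2[wall])
    assert np.allclose(np.minimum(d, 180.0 - d), 0.0, atol=1e-9)
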