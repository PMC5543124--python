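"""Conductivity assembly, ionic kinetics, and the monodomain solver."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from conductionscan.ep.conductivity import build_conductivity
from conductionscan.ep.ionic import (Courtemanche1998, MitchellSchaeffer,
                                     TenTusscher2004Epi, get_model,
                                     integrate_cell, ionic_step)
from conductionscan.ep.solver import (DiffusionOperator, StimulusProtocol,
                                      activation_times, simulate)
from conductionscan.volumes import LabelVolume


def uniform_labels(shape, pitch_um=250.0, name="myo"):
    return LabelVolume(np.full(shape, 2, dtype=np.int32), {2: name}, pitch_um)


# ---------------------------------------------------------------------------
# conductivity
# ---------------------------------------------------------------------------

def test_isotropic_limit():
    labels = uniform_labels((4, 4, 4))
    fib = np.zeros((4, 4, 4, 3))
    fib[..., 2] = 1.0
    cond = build_conductivity(labels, fib, {"myo": (0.2, 0.2)})
    M = cond.as_matrix()
    assert np.allclose(M, 0.2 * np.eye(3))


def test_axis_aligned_fiber_tensor():
    labels = uniform_labels((3, 3, 3))
    fib = np.zeros((3, 3, 3, 3))
    fib[..., 0] = 1.0
    cond = build_conductivity(labels, fib, {"myo": (0.4, 0.1)})
    assert np.allclose(cond.as_matrix()[1, 1, 1], np.diag([0.4, 0.1, 0.1]))


def test_arbitrary_fiber_eigenvalues(rng):
    labels = uniform_labels((3, 3, 3))
    f = rng.standard_normal(3)
    f /= np.linalg.norm(f)
    fib = np.broadcast_to(f, (3, 3, 3, 3)).copy()
    cond = build_conductivity(labels, fib, {"myo": (0.5, 0.125)})
    ev = np.sort(np.linalg.eigvalsh(cond.as_matrix()[0, 0, 0]))
    assert np.allclose(ev, [0.125, 0.125, 0.5])


def test_nonconducting_labels_zero_and_isotropic_fallback():
    labels = LabelVolume(np.array([[[1, 2]]], dtype=np.int32),
                         {1: "fat", 2: "myo"}, 250.0)
    fib = np.full((1, 1, 2, 3), np.nan)
    cond = build_conductivity(labels, fib, {"myo": (0.4, 0.1)})
    assert np.allclose(cond.tensors[0, 0, 0], 0.0)          # fat: no entry
    assert np.allclose(cond.as_matrix()[0, 0, 1], 0.25 * np.eye(3))
    with pytest.raises(ValueError):
        build_conductivity(labels, fib, {"myo": (0.1, 0.4)})  # d_L < d_T


# ---------------------------------------------------------------------------
# ionic models
# ---------------------------------------------------------------------------

def test_mitchell_schaeffer_rest_is_exact_fixed_point():
    m = MitchellSchaeffer()
    V, S = m.resting_state(4)
    S2, dV = ionic_step(m, S, V, 0.1)
    assert np.array_equal(S2, S)
    assert np.all(dV == 0.0)


@pytest.mark.parametrize("Model", [TenTusscher2004Epi, Courtemanche1998])
def test_resting_potential_matches_adaptive_ode_reference(Model):
    """Fixed-step Rush-Larsen vs adaptive LSODA over a 10 s quiescent run."""
    m = Model()
    V0, S0 = m.resting_state(1)
    y0 = np.concatenate([[V0[0]], S0[:, 0]])
    sol = solve_ivp(lambda t, y: m.packed_rhs(t, y), (0.0, 10_000.0), y0,
                    method="LSODA", rtol=1e-8, atol=1e-8)
    _, _, V, _ = integrate_cell(m, 10_000.0)
    assert abs(V[0] - sol.y[0, -1]) < 1.0
    assert abs(V[0] - V0[0]) < 1.0  # drift from the published rest stays small


@pytest.mark.parametrize("Model,stim_ms", [(TenTusscher2004Epi, 1.0),
                                           (Courtemanche1998, 2.0)])
def test_single_action_potential_fires_and_returns_to_rest(Model, stim_ms):
    m = Model()
    V0, _ = m.resting_state(1)
    ts, vs, V, _ = integrate_cell(m, 2000.0, stim_onset_ms=10.0,
                                  stim_duration_ms=stim_ms, record_every=5)
    assert vs.max() > 0.0              # overshoot: a real action potential
    assert abs(V[0] - V0[0]) < 1.0     # back to within 1 mV of rest by 2 s


def test_compiled_and_plain_kinetics_agree(rng):
    from conductionscan.ep.ionic import _compiled_rates, _PLAIN
    for name in ("ten_tusscher_2004_epi", "courtemanche_1998"):
        m = get_model(name)
        fast = _compiled_rates(m)
        if fast is None:
            pytest.skip("numba unavailable")
        V, S = m.resting_state(3)
        V = V + rng.uniform(-30, 60, 3)
        for a, b in zip(fast(V, S, -2.0), _PLAIN[name](V, S, -2.0)):
            assert np.allclose(a, b, rtol=1e-12, atol=1e-300)


def test_ionic_step_guards():
    m = TenTusscher2004Epi()
    V, S = m.resting_state(1)
    with pytest.raises(ValueError, match="dt"):
        ionic_step(m, S, V, 1.0)
    with pytest.raises(FloatingPointError):
        ionic_step(m, S * np.nan, V, 0.01)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def test_no_stimulus_quiescence_and_all_sentinel():
    labels = uniform_labels((8, 8, 3))
    cond = build_conductivity(labels, None, {"myo": (0.1, 0.1)})
    stim = np.zeros((8, 8, 3), bool)
    stim[0, 0, 0] = True
    act, traces = simulate(labels, cond, {"myo": MitchellSchaeffer()},
                           [StimulusProtocol(1e9, 1.0, site_mask=stim)],
                           20.0, record_voxels=[(4, 4, 1)])
    assert not np.isfinite(act.times_ms).any()
    _, vs = traces[(4, 4, 1)]
    assert np.allclose(vs, -85.0)


def test_diffusion_conserves_total_potential(rng):
    labels = uniform_labels((10, 9, 8))
    fib = rng.standard_normal((10, 9, 8, 3))
    fib /= np.linalg.norm(fib, axis=-1, keepdims=True)
    cond = build_conductivity(labels, fib, {"myo": (0.4, 0.1)})
    op = DiffusionOperator(cond)
    v = rng.standard_normal(op.n)
    assert abs(op.apply_packed(v).sum()) < 1e-10 * np.abs(v).sum()


def test_stability_violation_refused():
    labels = uniform_labels((6, 6, 3))
    cond = build_conductivity(labels, None, {"myo": (0.4, 0.4)})
    with pytest.raises(ValueError, match="stability"):
        simulate(labels, cond, {"myo": MitchellSchaeffer()}, [], 5.0, dt_ms=0.1)


def test_stimulus_on_nonconducting_site_refused():
    lab = np.full((6, 6, 3), 2, dtype=np.int32)
    lab[0, 0, 0] = 1
    labels = LabelVolume(lab, {1: "fat", 2: "myo"}, 250.0)
    cond = build_conductivity(labels, None, {"myo": (0.1, 0.1)})
    bad = np.zeros((6, 6, 3), bool)
    bad[0, 0, 0] = True
    with pytest.raises(ValueError, match="conducting"):
        simulate(labels, cond, {"myo": MitchellSchaeffer()},
                 [StimulusProtocol(0.0, 1.0, site_mask=bad)], 5.0)


def test_missing_model_for_conducting_label():
    labels = uniform_labels((4, 4, 3))
    cond = build_conductivity(labels, None, {"myo": (0.1, 0.1)})
    with pytest.raises(ValueError, match="ionic model"):
        simulate(labels, cond, {}, [], 5.0)


def test_determinism_of_simulation():
    labels = uniform_labels((20, 4, 3))
    cond = build_conductivity(labels, None, {"myo": (0.1, 0.1)})
    stim = np.zeros((20, 4, 3), bool)
    stim[:3] = True
    runs = [simulate(labels, cond, {"myo": MitchellSchaeffer()},
                     [StimulusProtocol(1.0, 1.0, site_mask=stim)], 30.0)[0]
            for _ in range(2)]
    assert np.array_equal(runs[0].times_ms, runs[1].times_ms)


# ---------------------------------------------------------------------------
# activation-time detection
# ---------------------------------------------------------------------------

def test_threshold_crossing_linear_interpolation():
    t = np.array([12.0, 13.0])
    v = np.array([[-50.0], [-30.0]])
    out = activation_times(t, v, -40.0)
    assert out[0] == pytest.approx(12.5)


def test_subthreshold_trace_gets_sentinel():
    t = np.arange(5.0)
    v = np.full((5, 1), -80.0)
    v[2, 0] = -60.0
    with pytest.warns(UserWarning):
        out = activation_times(t, v, -40.0)
    assert not np.isfinite(out[0])


def test_travelling_wave_activation_linear_in_x():
    c = 0.5  # mm/ms
    x = np.arange(40) * 0.1
    t = np.arange(0, 20, 0.5)
    V = -85.0 + 100.0 / (1 + np.exp(-(t[:, None] * c - x[None]) / 0.2))
    act = activation_times(t, V, -40.0)
    inner = slice(5, 35)
    slope = np.polyfit(x[inner], act[inner], 1)[0]
    assert slope == pytest.approx(1.0 / c, rel=0.02)
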