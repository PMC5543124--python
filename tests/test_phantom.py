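"""Ground-truth guarantees of the synthetic phantoms."""

import numpy as np
import pytest
from scipy import ndimage

from conductionscan import (PhantomSpec, ShellSpec, generate_fiber_test_volume,
                            generate_phantom, generate_shell_phantom)
from conductionscan.phantom import TISSUE_CLASS_OF_LABEL

S26 = ndimage.generate_binary_structure(3, 3)


def test_determinism_and_seed_sensitivity():
    spec = PhantomSpec().coarse()
    v1, _ = generate_phantom(spec)
    v2, _ = generate_phantom(spec)
    assert np.array_equal(v1.data, v2.data)
    v3, _ = generate_phantom(PhantomSpec(seed=7).coarse())
    assert not np.array_equal(v1.data, v3.data)


def test_labels_independent_of_noise():
    _, g_noisy = generate_phantom(PhantomSpec(noise_sd=5.0).coarse())
    _, g_clean = generate_phantom(PhantomSpec(noise_sd=0.0).coarse())
    assert np.array_equal(g_noisy.labels.labels, g_clean.labels.labels)


def test_noiseless_intensities_equal_class_means():
    spec = PhantomSpec(noise_sd=0.0).coarse()
    vol, gt = generate_phantom(spec)
    for lab, cls in TISSUE_CLASS_OF_LABEL.items():
        m = gt.labels.labels == lab if lab else gt.labels.labels == 0
        if m.any():
            assert np.allclose(vol.data[m], spec.class_means[cls])


def test_empirical_class_mean_ordering(default_phantom):
    vol, gt = default_phantom
    means = {}
    for cls in ("fat", "working_myocardium", "paranodal", "node", "connective"):
        labs = [l for l, c in TISSUE_CLASS_OF_LABEL.items() if c == cls and l]
        means[cls] = vol.data[np.isin(gt.labels.labels, labs)].mean()
    assert means["fat"] > means["working_myocardium"] > means["paranodal"] \
        > means["node"] > means["connective"]


def test_structural_topology(default_phantom):
    _, gt = default_phantom
    lab = gt.labels.labels
    # node body is a single connected component
    assert ndimage.label(lab == 5, structure=S26)[1] == 1
    # paranodal projections contact both node and working myocardium
    dil = ndimage.binary_dilation(lab == 4, structure=S26)
    assert (dil & (lab == 5)).any() and (dil & (lab == 2)).any()
    # Purkinje contacts the ventricular wall (endocardial coupling)
    dil_p = ndimage.binary_dilation(lab == 8, structure=S26)
    assert (dil_p & (lab == 3)).any()
    # the axis is the only conducting bridge between atria and ventricles
    conducting = np.isin(lab, (2, 3, 4, 5, 8))
    assert ndimage.label(conducting, structure=S26)[1] == 2
    assert ndimage.label(conducting | (lab == 7), structure=S26)[1] == 1


def test_fibers_unit_norm_and_cover_conducting(default_phantom):
    _, gt = default_phantom
    f = gt.fibers[gt.fiber_mask]
    assert np.allclose(np.linalg.norm(f, axis=1), 1.0, atol=1e-12)
    conducting = np.isin(gt.labels.labels, (2, 3, 4, 5, 7, 8))
    assert gt.fiber_mask[conducting].all()


def test_invalid_specs_rejected():
    bad = PhantomSpec()
    bad.class_means = dict(bad.class_means, node=90.0)  # above myocardium
    with pytest.raises(ValueError, match="ordering"):
        generate_phantom(bad)
    with pytest.raises(ValueError, match="noise"):
        generate_phantom(PhantomSpec(noise_sd=-1.0))
    with pytest.raises(ValueError, match="helix"):
        generate_phantom(PhantomSpec(helix_endo_deg=120.0))
    with pytest.raises(ValueError, match="grid"):
        generate_phantom(PhantomSpec(ventricular_outer_semiaxes_mm=(30, 30, 30)))


# ---------------------------------------------------------------------------
# fiber test volumes
# ---------------------------------------------------------------------------

def test_cylinder_texture_elongated_along_axis():
    vol, axis = generate_fiber_test_volume("parallel_cylinders", (0, 0, 1),
                                           period_um=28 * 6, shape=(32, 32, 32))
    d = vol.data - vol.data.mean()
    # autocorrelation at lag 3: largest along the cylinder axis
    def corr(shift):
        a = d[tuple(slice(None, -s if s else None) for s in shift)]
        b = d[tuple(slice(s, None) for s in shift)]
        return (a * b).mean()
    assert corr((0, 0, 3)) > corr((3, 0, 0))
    assert corr((0, 0, 3)) > corr((0, 3, 0))


def test_fiber_volume_axis_and_determinism():
    a = np.deg2rad(30)
    v1, true = generate_fiber_test_volume("sinusoidal_grating",
                                          (np.sin(a), 0, np.cos(a)),
                                          period_um=28 * 6, noise_sd=0.5, seed=5,
                                          shape=(24, 24, 24))
    assert np.allclose(true, (np.sin(a), 0, np.cos(a)))
    v2, _ = generate_fiber_test_volume("sinusoidal_grating",
                                       (np.sin(a), 0, np.cos(a)),
                                       period_um=28 * 6, noise_sd=0.5, seed=5,
                                       shape=(24, 24, 24))
    assert np.array_equal(v1.data, v2.data)


def test_fiber_volume_period_floor():
    with pytest.raises(ValueError, match="period"):
        generate_fiber_test_volume("parallel_cylinders", (0, 0, 1),
                                   period_um=28 * 3)


# ---------------------------------------------------------------------------
# helical shell
# ---------------------------------------------------------------------------

def test_shell_helix_ramp_midwall_and_tangency(shell_phantom):
    _, gt = shell_phantom
    t = gt.helix_deg
    wall = gt.fiber_mask
    shape = gt.labels.shape
    pitch = gt.labels.pitch_mm
    c = (np.asarray(shape) - 1) * pitch / 2
    X, Y, Z = np.meshgrid(*[np.arange(n) * pitch for n in shape], indexing="ij")
    R = np.hypot(X - c[0], Y - c[1])
    # mid-wall angle is the mean of endo and epi (= 0 for +60/-60)
    mid = wall & (np.abs(R - 1.57) < 0.02)
    assert abs(np.nanmean(t[mid])) < 3.0
    # fibers tangent to the shell: orthogonal to the analytic radial
    n_hat = np.stack([(X - c[0]) / np.maximum(R, 1e-9),
                      (Y - c[1]) / np.maximum(R, 1e-9),
                      np.zeros_like(R)], axis=-1)
    dots = np.einsum("...k,...k->...", gt.fibers, n_hat)[wall]
    assert np.nanmax(np.abs(dots)) < 1e-6


def test_shell_all_circumferential_when_flat():
    spec = ShellSpec(shape=(64, 64, 24), inner_radius_mm=0.3,
                     outer_radius_mm=0.55, helix_endo_deg=0.0,
                     helix_epi_deg=0.0)
    _, gt = generate_shell_phantom(spec)
    assert np.nanmax(np.abs(gt.helix_deg[gt.fiber_mask])) < 1e-9
    assert np.nanmax(np.abs(gt.fibers[gt.fiber_mask][:, 2])) < 1e-9


def test_shell_wall_thickness_floor():
    with pytest.raises(ValueError, match="6 voxels"):
        generate_shell_phantom(ShellSpec(inner_radius_mm=1.0,
                                         outer_radius_mm=1.1))
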