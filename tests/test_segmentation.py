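"""Attenuation banding and seeded region growing."""

import numpy as np
import pytest
from scipy import ndimage

from conductionscan import (AttenuationBands, PhantomSpec, SeedSpec, Volume,
                            classify_tissues, estimate_bands, generate_phantom,
                            region_grow, segment_conduction_system)
from conductionscan.phantom import TISSUE_CLASS_OF_LABEL
from conductionscan.segmentation import bands_from_means

NAMES = ("fat", "working_myocardium", "paranodal", "node", "connective",
         "background")


def brute_force_flood(in_band, seed, connectivity=26):
    """Independent breadth-first flood fill."""
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
            and {6: abs(i) + abs(j) + abs(k) == 1,
                 18: abs(i) + abs(j) + abs(k) <= 2,
                 26: True}[connectivity]]
    mask = np.zeros_like(in_band)
    stack = [tuple(seed)]
    mask[tuple(seed)] = True
    while stack:
        p = stack.pop()
        for o in offs:
            q = tuple(np.add(p, o))
            if all(0 <= qi < s for qi, s in zip(q, in_band.shape)) \
                    and in_band[q] and not mask[q]:
                mask[q] = True
                stack.append(q)
    return mask


def test_bands_validation():
    with pytest.raises(ValueError, match="overlap"):
        AttenuationBands({"a": (0, 10), "b": (5, 20)})
    with pytest.raises(ValueError, match="empty"):
        AttenuationBands({"a": (10, 10)})


def test_two_delta_boundary_strictly_between():
    data = np.where(np.arange(512).reshape(8, 8, 8) % 2 == 0, 10.0, 90.0)
    bands = estimate_bands(Volume(data, 73.0), "kmeans_1d", 2,
                           class_names=("hi", "lo"))
    cut = bands.bands["lo"][1]
    assert 10.0 < cut < 90.0
    assert bands.bands["hi"][0] == cut


def test_constant_volume_rejected():
    with pytest.raises(ValueError):
        estimate_bands(Volume(np.full((6, 6, 6), 5.0), 73.0), "kmeans_1d", 2)


def test_noiseless_phantom_bands_exactly_separate_classes():
    vol, gt = generate_phantom(PhantomSpec(noise_sd=0.0).coarse())
    bands = estimate_bands(vol, "kmeans_1d", 6, class_names=NAMES)
    cls = classify_tissues(vol, bands)
    inv = {v: k for k, v in cls.legend.items()}
    for lab, cname in TISSUE_CLASS_OF_LABEL.items():
        if lab == 0:
            continue
        m = gt.labels.labels == lab
        assert (cls.labels[m] == inv[cname]).all(), cname


def test_half_open_band_convention():
    vol = Volume(np.array([[[10.0, 20.0, 29.999, 30.0]]]), 73.0)
    bands = AttenuationBands({"lo": (0.0, 20.0), "hi": (20.0, 40.0)})
    cls = classify_tissues(vol, bands)
    inv = {v: k for k, v in cls.legend.items()}
    assert cls.labels[0, 0, 1] == inv["hi"]  # value at lo edge joins the band
    assert cls.labels[0, 0, 0] == inv["lo"]


def test_classification_is_pure_per_voxel_map(rng):
    data = rng.uniform(0, 100, (8, 8, 8))
    bands = AttenuationBands({"a": (0.0, 50.0), "b": (50.0, 90.0)})
    cls = classify_tissues(Volume(data, 73.0), bands)
    inv = {v: k for k, v in cls.legend.items()}
    expect = np.where(data < 50, inv["a"], np.where(data < 90, inv["b"], 0))
    assert np.array_equal(cls.labels, expect)


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_region_grow_matches_brute_force(rng, connectivity):
    data = (rng.random((12, 12, 12)) < 0.45).astype(float) * 50
    in_band = data > 25
    seeds = np.argwhere(in_band)
    seed = tuple(seeds[len(seeds) // 2])
    got = region_grow(Volume(data, 73.0),
                      SeedSpec(seed, (25.0, 100.0), connectivity))
    want = brute_force_flood(in_band, seed, connectivity)
    assert np.array_equal(got, want)


def test_region_grow_full_flood_and_seed_invariance(rng):
    vol = Volume(np.full((6, 6, 6), 7.0), 73.0)
    m = region_grow(vol, SeedSpec((3, 3, 3), (5.0, 9.0)))
    assert m.all()
    # seed anywhere in the same component gives the same mask
    data = np.zeros((10, 10, 3))
    data[1:4, 1:4] = 50
    data[6:9, 6:9] = 50
    vol = Volume(data, 73.0)
    m1 = region_grow(vol, SeedSpec((1, 1, 0), (40.0, 60.0)))
    m2 = region_grow(vol, SeedSpec((3, 3, 2), (40.0, 60.0)))
    assert np.array_equal(m1, m2)
    assert not m1[6, 6, 0]  # the other blob is untouched


def test_region_grow_seed_outside_band():
    vol = Volume(np.zeros((4, 4, 4)), 73.0)
    with pytest.raises(ValueError, match="band"):
        region_grow(vol, SeedSpec((0, 0, 0), (10.0, 20.0)))


def _node_seed(gt):
    return tuple(np.argwhere(gt.labels.labels == 5).mean(axis=0).round().astype(int))


def test_conduction_segmentation_recovers_node_and_projections(default_phantom):
    vol, gt = default_phantom
    bands = bands_from_means(PhantomSpec().class_means)
    seg = segment_conduction_system(
        vol, bands, {"node": SeedSpec(_node_seed(gt), bands.bands["node"])})
    node_seg, node_gt = seg.mask("node"), gt.mask("node")
    dice = 2 * (node_seg & node_gt).sum() / (node_seg.sum() + node_gt.sum())
    assert dice >= 0.95
    n_comp = ndimage.label(seg.mask("paranodal"),
                           structure=ndimage.generate_binary_structure(3, 3))[1]
    assert n_comp == 3


def test_phantom_without_projections_gives_empty_paranodal():
    spec = PhantomSpec(paranodal_count=0).coarse()
    vol, gt = generate_phantom(spec)
    bands = bands_from_means(spec.class_means)
    seg = segment_conduction_system(
        vol, bands, {"node": SeedSpec(_node_seed(gt), bands.bands["node"])})
    assert not seg.mask("paranodal").any()


def test_corridor_excludes_decoy_blob():
    # two blobs in the axis band; the corridor contains only one
    data = np.full((20, 10, 10), 80.0)
    data[2:5, 2:5, 2:5] = 50.0      # true axis segment
    data[14:17, 2:5, 2:5] = 50.0    # decoy
    data[9, 4, 4] = 52.0            # node voxel to seed from
    vol = Volume(data, 300.0)
    bands = AttenuationBands({"node": (40.0, 60.0),
                              "working_myocardium": (70.0, 90.0)})
    corridor = np.zeros(data.shape, dtype=bool)
    corridor[:8] = True
    seg = segment_conduction_system(
        vol, bands,
        {"node": SeedSpec((9, 4, 4), bands.bands["node"]),
         "axis": SeedSpec((3, 3, 3), bands.bands["node"])},
        corridors={"axis": corridor}, paranodal_class="node",
        min_component_voxels=100_000)
    axis = seg.mask("axis")
    assert axis[3, 3, 3] and not axis[15, 3, 3]


def test_semi_automatic_structure_requires_corridor():
    vol = Volume(np.full((5, 5, 5), 50.0), 73.0)
    bands = AttenuationBands({"node": (40.0, 60.0)})
    with pytest.raises(ValueError, match="corridor"):
        segment_conduction_system(
            vol, bands, {"node": SeedSpec((2, 2, 2), (40.0, 60.0)),
                         "axis": SeedSpec((0, 0, 0), (40.0, 60.0))},
            paranodal_class="node")


def test_structure_labels_are_disjoint(default_phantom):
    vol, gt = default_phantom
    bands = bands_from_means(PhantomSpec().class_means)
    seg = segment_conduction_system(
        vol, bands, {"node": SeedSpec(_node_seed(gt), bands.bands["node"])})
    # one label per voxel by construction; every named structure resolvable
    assert seg.mask("node").sum() > 0
    assert not (seg.mask("node") & seg.mask("paranodal")).any()
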