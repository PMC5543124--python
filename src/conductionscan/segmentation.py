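"""Attenuation-band tissue classification and seeded region growing.

Iodine contrast separates tissue classes by X-ray attenuation, so
classification is a pure per-voxel banding of intensity: each class owns a
half-open interval ``[lo, hi)``.  Conduction structures are then extracted
the way an operator would with a magic-wand tool, made reproducible:

* the sinus-node body by automatic region growing from a seed voxel inside
  the nodal band;
* the paranodal projections and islands as connected components of the
  intermediate band that touch the grown node body;
* the conduction axis and bundles by region growing restricted to landmark
  "corridor" masks (the reproducible surrogate for manual, histology-guided
  segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, Volume

__all__ = [
    "AttenuationBands",
    "SeedSpec",
    "bands_from_means",
    "estimate_bands",
    "classify_tissues",
    "region_grow",
    "segment_conduction_system",
]

#: label precedence when structures compete for a voxel (earlier wins)
PRECEDENCE = ("node", "paranodal", "axis", "purkinje", "working_myocardium")


@dataclass
class AttenuationBands:
    """Ordered, disjoint half-open intensity intervals, one per class.

    ``bands[name] = (lo, hi)`` assigns intensities ``lo <= v < hi`` to
    ``name``.  Intensities in no band are background.  ``classes`` lists the
    names by decreasing mean attenuation.
    """

    bands: dict[str, tuple[float, float]]
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = tuple(sorted(self.bands, key=lambda c: -self.bands[c][0]))
        ivals = sorted(self.bands.values())
        for (lo1, hi1), (lo2, hi2) in zip(ivals, ivals[1:]):
            if hi1 > lo2:
                raise ValueError(f"bands overlap: [{lo1},{hi1}) and [{lo2},{hi2})")
        for lo, hi in ivals:
            if not lo < hi:
                raise ValueError(f"empty band [{lo},{hi})")

    def band_of(self, value: float) -> str | None:
        for name, (lo, hi) in self.bands.items():
            if lo <= value < hi:
                return name
        return None


@dataclass
class SeedSpec:
    """A region-growing seed: voxel index, target band, connectivity."""

    seed: tuple[int, int, int]
    band: tuple[float, float]
    connectivity: int = 26
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


_CONN_RANK = {6: 1, 18: 2, 26: 3}


def bands_from_means(class_means: dict[str, float],
                     background: str = "background") -> AttenuationBands:
    """Bands with boundaries midway between adjacent class mean intensities.

    The reproducible surrogate for operator-set thresholds: when the expected
    per-class attenuation levels are known (from calibration or from the
    phantom configuration), midpoint boundaries are the maximum-likelihood
    decision rule for equal-variance Gaussian noise.  The ``background``
    class, if present, is excluded from the returned bands (it is the
    unclassified remainder) but still bounds its neighbours.
    """
    ordered = sorted(class_means.items(), key=lambda kv: kv[1])
    mids = [(a[1] + b[1]) / 2.0 for a, b in zip(ordered, ordered[1:])]
    edges = [-np.inf] + mids + [np.inf]
    bands = {name: (float(edges[i]), float(edges[i + 1]))
             for i, (name, _) in enumerate(ordered) if name != background}
    classes = tuple(name for name, _ in reversed(ordered) if name != background)
    return AttenuationBands(bands, classes)


def _kmeans_1d_binned(vals: np.ndarray, k: int, bins: int = 512) -> np.ndarray:
    """Exact 1D k-means on histogram bins by dynamic programming.

    Bin weights are log-compressed (``log1p(count)``): a sinus node occupies
    three orders of magnitude fewer voxels than the background, and raw
    count weights would let k-means split bulky classes while merging small,
    well-separated ones.  Compression makes band placement follow the
    intensity structure rather than structure volume.  The dynamic program
    returns the globally optimal sorted cluster centres (no initialization
    sensitivity).  Suited to classes of comparable intensity spread; classes
    that form mere shoulders of a dominant neighbour need operator-style
    thresholds (:func:`bands_from_means`) instead.
    """
    lo, hi = np.percentile(vals, [0.05, 99.95])
    if hi <= lo:
        lo, hi = float(vals.min()), float(vals.max())
    counts, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    x = (edges[:-1] + edges[1:]) / 2.0
    w = np.log1p(counts.astype(float))
    occ = w > 0
    x, w = x[occ], w[occ]
    n = x.size
    if n < k:
        raise ValueError(f"fewer than {k} occupied intensity levels")
    W = np.concatenate([[0.0], np.cumsum(w)])
    WX = np.concatenate([[0.0], np.cumsum(w * x)])
    WX2 = np.concatenate([[0.0], np.cumsum(w * x * x)])

    def seg_cost(i, j):
        """Weighted SSE of bins i..j (inclusive); i may be an array."""
        ww = W[j + 1] - W[i]
        s = WX[j + 1] - WX[i]
        return (WX2[j + 1] - WX2[i]) - s * s / np.maximum(ww, 1e-300)

    D = np.full((k, n), np.inf)
    B = np.zeros((k, n), dtype=int)
    idx = np.arange(n)
    D[0] = seg_cost(np.zeros(n, dtype=int), idx)
    for m in range(1, k):
        for j in range(m, n):
            i = np.arange(m, j + 1)
            c = D[m - 1][i - 1] + seg_cost(i, j)
            a = int(np.argmin(c))
            D[m, j], B[m, j] = c[a], i[a]
    # backtrack segment starts, then centres
    starts = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = B[m, j]
        starts.append(i)
        j = i - 1
    starts = [0] + starts[::-1]
    ends = starts[1:] + [n]
    return np.array([np.average(x[a:b], weights=w[a:b]) for a, b in zip(starts, ends)])


def estimate_bands(
    volume: Volume,
    method: str = "kmeans_1d",
    n_classes: int = 6,
    class_names: tuple[str, ...] | None = None,
    seed: int = 0,
    subsample: int = 400_000,
) -> AttenuationBands:
    """Estimate intensity bands separating ``n_classes`` attenuation classes.

    ``kmeans_1d`` clusters the intensity histogram (see
    :func:`_kmeans_1d_binned`) and places boundaries midway between sorted
    cluster centres; ``percentile`` splits the histogram into equal-mass
    groups (useful only when class volumes are comparable).  Class names are
    assigned brightest-first; defaults to generic names.
    """
    vals = np.asarray(volume.data, dtype=float).ravel()
    if np.unique(vals[: min(vals.size, 100_000)]).size < n_classes and \
            np.unique(vals).size < n_classes:
        raise ValueError(f"volume has fewer than {n_classes} distinct values")
    rng = np.random.default_rng(seed)
    if vals.size > subsample:
        vals_fit = rng.choice(vals, size=subsample, replace=False)
    else:
        vals_fit = vals

    if method == "kmeans_1d":
        centres = _kmeans_1d_binned(vals_fit, n_classes)
        cuts = (centres[:-1] + centres[1:]) / 2.0
    elif method == "percentile":
        qs = np.linspace(0, 100, n_classes + 1)[1:-1]
        cuts = np.percentile(vals_fit, qs)
        if np.unique(cuts).size < cuts.size:
            raise ValueError("percentile method produced degenerate boundaries")
    else:
        raise ValueError(f"unknown method {method!r}")

    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    if class_names is None:
        class_names = tuple(f"class_{i}" for i in range(n_classes, 0, -1))
    if len(class_names) != n_classes:
        raise ValueError("need one class name per class")
    # brightest class first
    bands = {name: (float(edges[n_classes - 1 - i]), float(edges[n_classes - i]))
             for i, name in enumerate(class_names)}
    return AttenuationBands(bands, tuple(class_names))


def classify_tissues(volume: Volume, bands: AttenuationBands,
                     label_ids: dict[str, int] | None = None) -> LabelVolume:
    """Per-voxel banding of intensity into tissue classes.

    A pure map with no spatial regularization; voxels falling in no band are
    background (0).  Band boundaries are half-open: a value equal to ``lo``
    belongs to that band.
    """
    if label_ids is None:
        label_ids = {name: i + 1 for i, name in enumerate(bands.classes)}
    out = np.zeros(volume.shape, dtype=np.int32)
    data = volume.data
    for name, (lo, hi) in bands.bands.items():
        out[(data >= lo) & (data < hi)] = label_ids[name]
    legend = {v: k for k, v in label_ids.items()}
    return LabelVolume(out, legend, volume.voxel_pitch_um, volume.origin_mm)


def region_grow(volume: Volume, seed: SeedSpec) -> np.ndarray:
    """Maximal connected in-band region containing the seed voxel.

    Deterministic: the result is the connected component (at the requested
    connectivity) of ``{v : lo <= I(v) < hi} ∩ mask`` that contains the seed,
    so it is invariant to the choice of seed within that component.
    """
    idx = tuple(int(i) for i in seed.seed)
    for i, n in zip(idx, volume.shape):
        if not 0 <= i < n:
            raise ValueError(f"seed {idx} outside volume of shape {volume.shape}")
    lo, hi = seed.band
    val = float(volume.data[idx])
    if not lo <= val < hi:
        raise ValueError(f"seed intensity {val} outside target band [{lo}, {hi})")
    in_band = (volume.data >= lo) & (volume.data < hi)
    if seed.mask is not None:
        in_band &= seed.mask
        if not in_band[idx]:
            raise ValueError("seed excluded by the spatial mask")
    structure = ndimage.generate_binary_structure(3, _CONN_RANK[seed.connectivity])
    comp, _ = ndimage.label(in_band, structure=structure)
    return comp == comp[idx]


def segment_conduction_system(
    volume: Volume,
    bands: AttenuationBands,
    seeds: dict[str, SeedSpec],
    corridors: dict[str, np.ndarray] | None = None,
    myocardium_class: str = "working_myocardium",
    paranodal_class: str = "paranodal",
    min_component_voxels: int = 10,
    label_ids: dict[str, int] | None = None,
) -> LabelVolume:
    """Extract conduction structures on top of the band classification.

    ``seeds`` maps structure names (``node``, ``axis``, ``purkinje`` ...) to
    their :class:`SeedSpec`.  Structures other than the node require a
    corridor mask in ``corridors`` (semi-automatic mode); the node grows
    automatically.  Paranodal tissue needs no seed: it is every
    sufficiently-large connected component of the paranodal band lying within
    one voxel (26-connectivity) of the grown node body.  Components smaller
    than ``min_component_voxels`` are treated as noise specks and dropped.
    Output labels follow the precedence node > paranodal > axis > purkinje >
    myocardium; the remaining band classes keep their plain classification.
    """
    corridors = corridors or {}
    if "node" not in seeds:
        raise ValueError("a 'node' seed is required")
    for name in seeds:
        if name not in ("node",) and name not in corridors:
            raise ValueError(f"structure {name!r} is semi-automatic and needs a corridor mask")

    base = classify_tissues(volume, bands, label_ids)
    ids = {v: k for k, v in base.legend.items()}
    legend = dict(base.legend)
    next_id = max(legend) + 1
    labels = base.labels.copy()

    # structures get fresh label ids; a band class sharing a structure's name
    # is renamed '<name>_band' (its residual voxels, e.g. unsegmented
    # conduction tissue elsewhere in the nodal band)
    for name in list(seeds) + [paranodal_class, "paranodal"]:
        if name in ids:
            band_id = ids.pop(name)
            legend[band_id] = f"{name}_band"
            ids[f"{name}_band"] = band_id

    def new_id(name):
        nonlocal next_id
        if name in ids:
            return ids[name]
        ids[name] = next_id
        legend[next_id] = name
        next_id += 1
        return ids[name]

    struct26 = ndimage.generate_binary_structure(3, 3)

    node_mask = region_grow(volume, seeds["node"])
    grown: dict[str, np.ndarray] = {"node": node_mask}

    # paranodal projections/islands: intermediate-band components adjacent to
    # the node body
    plo, phi_ = bands.bands[paranodal_class]
    para_band = (volume.data >= plo) & (volume.data < phi_)
    comp, n = ndimage.label(para_band, structure=struct26)
    near_node = ndimage.binary_dilation(node_mask, structure=struct26)
    touching = np.unique(comp[near_node & (comp > 0)])
    para = np.zeros(volume.shape, dtype=bool)
    if touching.size:
        counts = np.bincount(comp.ravel(), minlength=n + 1)
        keep = [c for c in touching if counts[c] >= min_component_voxels]
        if keep:
            para = np.isin(comp, keep)
    grown["paranodal"] = para

    for name, sd in seeds.items():
        if name == "node":
            continue
        sd = SeedSpec(sd.seed, sd.band, sd.connectivity, corridors[name])
        grown[name] = region_grow(volume, sd)

    # apply with precedence: later (higher-priority) paints win
    order = [s for s in reversed(PRECEDENCE) if s in grown]
    for name in order:
        labels[grown[name]] = new_id(name)
    return LabelVolume(labels, legend, volume.voxel_pitch_um, volume.origin_mm)
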