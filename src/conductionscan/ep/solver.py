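"""Explicit operator-split monodomain solver on the voxel grid.

Each time step advances the reaction term (ionic model kinetics, Rush-Larsen
gates) and then the diffusion term div(D grad V) by conservative finite
differences: fluxes live on cell faces, with harmonic-mean face
conductivities for the normal component and arithmetic means for the mixed
(cross-derivative) components.  A face bordering a non-conducting voxel
carries zero flux, so no-flux boundaries hold by construction and the
diffusion operator conserves the total potential exactly (to round-off).

Activation times are detected online as the first upward threshold crossing,
linearly interpolated within the time step; voxels that never cross keep the
sentinel +inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..volumes import LabelVolume
from .conductivity import ConductivityField
from .ionic import IonicModel, get_model, ionic_step

__all__ = [
    "StimulusProtocol",
    "ActivationMap",
    "DiffusionOperator",
    "simulate",
    "activation_times",
]

SENTINEL = np.inf


@dataclass
class StimulusProtocol:
    """A stimulus applied to a voxel set or a sphere around a point (mm)."""

    onset_ms: float
    duration_ms: float
    amplitude: float | None = None   # model units; None -> model default
    site_mask: np.ndarray | None = None
    centre_mm: tuple[float, float, float] | None = None
    radius_mm: float = 1.0

    def resolve_mask(self, shape, pitch_mm) -> np.ndarray:
        if self.site_mask is not None:
            return self.site_mask.astype(bool)
        if self.centre_mm is None:
            raise ValueError("stimulus needs a site mask or a centre point")
        grids = np.meshgrid(*[np.arange(n) * pitch_mm for n in shape],
                            indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.centre_mm))
        return d2 <= self.radius_mm ** 2


@dataclass
class ActivationMap:
    """First time V crosses ``threshold_mv`` upward (ms); +inf if never."""

    times_ms: np.ndarray
    threshold_mv: float
    pitch_mm: float

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.times_ms)


class DiffusionOperator:
    """Conservative finite-difference div(D grad V) with no-flux boundaries.

    The operator is assembled once in a packed (sparse) form: only faces
    joining two conducting voxels carry flux, listed as index pairs with a
    harmonic-mean normal conductivity and arithmetic-mean cross (mixed
    derivative) conductivities.  Applying the operator is a handful of
    gathers and ``bincount`` scatter-adds over those pairs, so the cost
    scales with the conducting tissue volume, not the bounding grid.
    Because each face adds +flux to one cell and -flux to the other, the
    total potential is conserved to round-off and no-flux boundaries hold
    by construction.
    """

    def __init__(self, cond: ConductivityField):
        self.h = cond.pitch_mm
        self.conducting = cond.conducting
        self.shape = cond.conducting.shape
        M = cond.conducting
        self.n = int(M.sum())
        flat_id = np.full(self.shape, -1, dtype=np.int64)
        flat_id[M] = np.arange(self.n)
        self._flat_idx = np.nonzero(M)
        t = cond.tensors

        def sl(ax, a, b):
            s = [slice(None)] * 3
            s[ax] = slice(a, b)
            return tuple(s)

        # cross components entering the flux along each axis; component
        # order is (xx,yy,zz,xy,xz,yz) and e.g. the x-flux picks up
        # D_xy dV/dy and D_xz dV/dz
        cross_of_axis = {0: ((3, 1), (4, 2)), 1: ((3, 0), (5, 2)),
                         2: ((4, 0), (5, 1))}
        self.pairs = []
        for ax in range(3):
            lo, hi = sl(ax, None, -1), sl(ax, 1, None)
            both = M[lo] & M[hi]
            ii = flat_id[lo][both]
            jj = flat_id[hi][both]
            d_lo, d_hi = t[lo][both, ax], t[hi][both, ax]
            den = d_lo + d_hi
            c_nn = np.where(den > 0, 2.0 * d_lo * d_hi / np.maximum(den, 1e-300), 0.0)
            crosses = []
            for comp, other_ax in cross_of_axis[ax]:
                cc = 0.5 * (t[lo][both, comp] + t[hi][both, comp])
                crosses.append((cc, other_ax) if np.any(cc) else None)
            self.pairs.append((ii, jj, c_nn, crosses))

        # neighbour tables for masked central differences per axis
        self.grad_nb = []
        idx3 = np.argwhere(M)
        for ax in range(3):
            nb = []
            for sgn in (1, -1):
                q = idx3.copy()
                q[:, ax] += sgn
                ok = (q[:, ax] >= 0) & (q[:, ax] < self.shape[ax])
                qi = np.zeros(self.n, dtype=np.int64)
                safe = q[ok]
                ids = flat_id[safe[:, 0], safe[:, 1], safe[:, 2]]
                has = np.zeros(self.n, dtype=bool)
                has[ok] = ids >= 0
                qi_ok = np.zeros(self.n, dtype=np.int64)
                qi_ok[ok] = np.where(ids >= 0, ids, 0)
                nb.append((has, qi_ok))
            self.grad_nb.append(nb)
        self._needs_grad = any(c is not None for (_, _, _, cr) in self.pairs
                               for c in cr)

    def _gradients(self, v):
        """Per-cell central differences on the packed vector (one-sided at
        conducting boundaries)."""
        grads = []
        for ax in range(3):
            (has_p, ip), (has_m, im) = self.grad_nb[ax]
            vp = np.where(has_p, v[ip], v)
            vm = np.where(has_m, v[im], v)
            cnt = has_p.astype(np.float64) + has_m
            g = np.where(cnt > 0, (vp - vm) / (np.maximum(cnt, 1.0) * self.h), 0.0)
            grads.append(g)
        return grads

    def apply_packed(self, v: np.ndarray) -> np.ndarray:
        """div(D grad V) over the packed conducting-voxel vector."""
        h = self.h
        out = np.zeros_like(v)
        grads = self._gradients(v) if self._needs_grad else None
        for ii, jj, c_nn, crosses in self.pairs:
            flux = c_nn * (v[jj] - v[ii]) / h
            for cr in crosses:
                if cr is None:
                    continue
                cc, other_ax = cr
                gb = grads[other_ax]
                flux = flux + cc * 0.5 * (gb[ii] + gb[jj])
            out += np.bincount(ii, weights=flux, minlength=self.n)
            out -= np.bincount(jj, weights=flux, minlength=self.n)
        return out / h

    def pack(self, V: np.ndarray) -> np.ndarray:
        return V[self._flat_idx]

    def unpack(self, v: np.ndarray, fill=0.0) -> np.ndarray:
        out = np.full(self.shape, fill)
        out[self._flat_idx] = v
        return out

    def apply(self, V: np.ndarray) -> np.ndarray:
        """div(D grad V) on the full grid; zero on non-conducting voxels."""
        return self.unpack(self.apply_packed(self.pack(V)))


def stability_limit(cond: ConductivityField, safety: float = 0.8) -> float:
    """Largest explicit step (ms): safety * h^2 / (2 max trace D)."""
    tr = cond.max_trace
    if tr <= 0:
        return np.inf
    return safety * cond.pitch_mm ** 2 / (2.0 * tr)


def simulate(
    labels: LabelVolume,
    cond: ConductivityField,
    model_assignment: dict[str | int, IonicModel | str],
    stimuli: list[StimulusProtocol],
    duration_ms: float,
    dt_ms: float | None = None,
    threshold_mv: float = -40.0,
    record_voxels: list[tuple[int, int, int]] | None = None,
    record_every: int = 10,
):
    """Run the monodomain simulation and return the activation map.

    ``model_assignment`` maps label ids or legend names to ionic models (or
    model-id strings); every conducting label needs an entry.  ``dt_ms``
    defaults to the tightest of the diffusion stability limit and the
    models' stable reaction steps; an explicit dt above the limit raises.
    Returns ``(ActivationMap, traces)`` where traces maps recorded voxel
    indices to (time, V) arrays.  Deterministic for identical inputs.
    """
    shape = labels.shape
    name_to_id = {v: k for k, v in labels.legend.items()}
    groups: dict[int, IonicModel] = {}
    for key, model in model_assignment.items():
        lab = name_to_id[key] if isinstance(key, str) else int(key)
        groups[lab] = get_model(model) if isinstance(model, str) else model

    conducting = cond.conducting
    missing = np.unique(labels.labels[conducting & ~np.isin(labels.labels, list(groups))])
    if missing.size:
        names = [labels.legend.get(int(m), str(m)) for m in missing]
        raise ValueError(f"conducting labels without an ionic model: {names}")

    limit = stability_limit(cond)
    model_limit = min(g.max_dt_ms for g in groups.values()) if groups else np.inf
    if dt_ms is None:
        dt_ms = min(limit, model_limit)
    elif dt_ms > limit * (1 + 1e-9):
        raise ValueError(f"dt={dt_ms} ms violates the diffusion stability limit "
                         f"{limit:.4g} ms for h={cond.pitch_mm} mm")
    dt = float(dt_ms)

    op = DiffusionOperator(cond)
    n = op.n
    V = np.zeros(n)
    packed_labels = labels.labels[op._flat_idx]
    group_members: dict[int, np.ndarray] = {}
    group_state: dict[int, np.ndarray] = {}
    for lab, model in groups.items():
        sel = np.nonzero(packed_labels == lab)[0]
        group_members[lab] = sel
        v0, s0 = model.resting_state(sel.size)
        V[sel] = v0
        group_state[lab] = s0

    stim_masks = []
    for st in stimuli:
        m = st.resolve_mask(shape, cond.pitch_mm)[op._flat_idx]
        if not m.any():
            raise ValueError("stimulus site contains no conducting voxels")
        stim_masks.append(m)

    act = np.full(n, SENTINEL)
    rec_ids = []
    for v in (record_voxels or []):
        if not conducting[tuple(v)]:
            raise ValueError(f"recorded voxel {v} is not conducting")
        flat = np.zeros(shape, dtype=bool)
        flat[tuple(v)] = True
        rec_ids.append(int(np.nonzero(flat[op._flat_idx])[0][0]))
    traces = {tuple(v): ([], []) for v in (record_voxels or [])}

    n_steps = int(np.ceil(duration_ms / dt))
    t = 0.0
    for step in range(n_steps):
        V_old = V
        dVr = np.zeros(n)
        for lab, model in groups.items():
            sel = group_members[lab]
            i_stim = np.zeros(sel.size)
            for st, m in zip(stimuli, stim_masks):
                if st.onset_ms <= t < st.onset_ms + st.duration_ms:
                    amp = st.amplitude if st.amplitude is not None \
                        else model.default_stim_amplitude
                    i_stim = i_stim + amp * m[sel]
            s_new, dv = ionic_step(model, group_state[lab], V[sel], dt, i_stim)
            group_state[lab] = s_new
            dVr[sel] = dv
        V = V + dt * (dVr + op.apply_packed(V))
        t += dt
        crossed = (V >= threshold_mv) & (V_old < threshold_mv) & ~np.isfinite(act)
        if crossed.any():
            frac = (threshold_mv - V_old[crossed]) / (V[crossed] - V_old[crossed])
            act[crossed] = (t - dt) + dt * frac
        if record_voxels and step % record_every == 0:
            for v, rid in zip(traces, rec_ids):
                ts, vs = traces[v]
                ts.append(t)
                vs.append(float(V[rid]))

    traces = {v: (np.asarray(ts), np.asarray(vs)) for v, (ts, vs) in traces.items()}
    return ActivationMap(op.unpack(act, fill=SENTINEL), threshold_mv,
                         cond.pitch_mm), traces


def activation_times(times: np.ndarray, voltages: np.ndarray,
                     threshold_mv: float) -> np.ndarray:
    """First upward crossing per trace, linearly interpolated between samples.

    ``voltages`` has shape (n_samples, ...); returns activation times of the
    trailing shape, +inf where the threshold is never crossed upward.  Warns
    (and returns all-sentinel) if the threshold lies outside the simulated
    voltage range.
    """
    import warnings

    v = np.asarray(voltages, dtype=float)
    t = np.asarray(times, dtype=float)
    if threshold_mv < v.min() or threshold_mv > v.max():
        warnings.warn("threshold outside simulated voltage range; no activations",
                      stacklevel=2)
        return np.full(v.shape[1:], SENTINEL)
    below = v[:-1] < threshold_mv
    above = v[1:] >= threshold_mv
    cross = below & above
    out = np.full(v.shape[1:], SENTINEL)
    any_cross = cross.any(axis=0)
    first = np.argmax(cross, axis=0)
    idx = tuple(np.indices(v.shape[1:]))
    f = first[any_cross] if v.ndim > 1 else first
    if v.ndim == 1:
        if any_cross:
            i = int(first)
            frac = (threshold_mv - v[i]) / (v[i + 1] - v[i])
            return np.asarray(t[i] + frac * (t[i + 1] - t[i]))
        return np.asarray(SENTINEL)
    sel = tuple(a[any_cross] for a in idx)
    v0 = v[(f,) + sel]
    v1 = v[(f + 1,) + sel]
    frac = (threshold_mv - v0) / (v1 - v0)
    out[any_cross] = t[f] + frac * (t[f + 1] - t[f])
    return out
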