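"""Distance transforms, marker construction and marker-controlled watershed.

Three watershed methods assemble these pieces:

* ``A``: markers are connected components of binary seeds; one flood of the
  nuclei mask.
* ``B``: markers come from the H-maxima of the mask's own distance transform
  (the H-minima transform of the inverted relief, depth ``h``); one flood.
* ``C``: the H-minima watershed is first run on the *seeds*, and its labelled
  output is used as markers for the flood of the mask -- watershed twice.

All methods finish by removing objects whose volume is 5% or less of the
average object volume.

The flood itself is a priority queue over the negated distance transform,
restricted to the mask, with a fully specified tie policy: voxels are
processed in ascending (relief value, insertion age) order, and markers are
inserted in raster order.  Outputs are therefore bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from numba import njit
from scipy import ndimage
from skimage.morphology import local_maxima, reconstruction

from .volume_core import BinaryMask, LabelVolume, relabel_consecutive

__all__ = [
    "MarkerVolume", "WatershedConfig", "distance_transform", "cc_markers",
    "hminima_markers", "ws_from_markers", "run_method", "remove_small_objects",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return _CONN26
    if connectivity == 6:
        return _CONN6
    raise ValueError("connectivity must be 6 or 26")


@dataclass
class MarkerVolume:
    """Labelled marker components (pairwise disjoint, labels 1..K)."""

    labels: np.ndarray
    n_markers: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("markers must be 3D")


@dataclass
class WatershedConfig:
    method: Literal["A", "B", "C"] = "C"
    h: float = 2.0
    connectivity: int = 26
    min_volume_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.method in ("B", "C") and self.h <= 0:
            raise ValueError("h must be positive")
        if not 0 <= self.min_volume_fraction < 1:
            raise ValueError("min_volume_fraction must lie in [0, 1)")
        _structure(self.connectivity)


def distance_transform(mask: BinaryMask) -> np.ndarray:
    """Euclidean distance transform on the spacing-normalised grid.

    Spacings are normalised to {1, 1, s_z/s_xy}; the value at a foreground
    voxel is the distance from its center to the nearest background voxel
    center.  Background voxels are 0.
    """
    sampling = (mask.z_anisotropy, 1.0, 1.0)  # (z, y, x)
    return ndimage.distance_transform_edt(mask.voxels, sampling=sampling)


def cc_markers(seeds: BinaryMask, connectivity: int = 26) -> MarkerVolume:
    """Label isolated seeds with unique ids (26-connectivity by default)."""
    labels, n = ndimage.label(seeds.voxels, structure=_structure(connectivity))
    return MarkerVolume(labels.astype(np.int32), int(n))


def hminima_markers(mask_or_seeds: BinaryMask, h: float,
                    connectivity: int = 26,
                    dt: Optional[np.ndarray] = None) -> MarkerVolume:
    """Markers from the depth-h maxima of the distance transform.

    The H-maxima transform (morphological reconstruction by dilation of
    ``DT - h`` under ``DT``) merges every dome shallower than ``h`` into its
    surroundings; the markers are the 26-connected components of the
    regional maxima of the transformed relief, restricted to the foreground.
    Equivalent to the H-minima transform of ``-DT``.  Nearby domes whose
    separating saddle is less than ``h`` below their tops collapse into a
    single marker.

    The transform is evaluated geodesically within each foreground
    component (the background is held far below every foreground value), so
    a component whose entire relief is shallower than ``h`` keeps a single
    all-component marker instead of dissolving into the background plateau.
    This keeps every mask component represented and makes the marker count
    non-increasing in ``h``.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    if dt is None:
        dt = distance_transform(mask_or_seeds)
    if not mask_or_seeds.voxels.any():
        return MarkerVolume(np.zeros(dt.shape, dtype=np.int32), 0)
    footprint = _structure(connectivity)
    # reconstruct on the padded foreground bounding box; beyond it the
    # relief is background and cannot host a maximum
    zs, ys, xs = np.nonzero(mask_or_seeds.voxels)
    box = tuple(slice(max(int(i.min()) - 1, 0), min(int(i.max()) + 2, s))
                for i, s in zip((zs, ys, xs), dt.shape))
    fg = mask_or_seeds.voxels[box]
    floor = -(h + float(dt.max()) + 1.0)   # below any foreground rec value
    sub = np.where(fg, dt[box], floor)
    rec = reconstruction(sub - h, sub, method="dilation", footprint=footprint)
    peaks = np.zeros(dt.shape, dtype=bool)
    if rec.max() == rec.min():
        # a constant relief is one all-covering plateau maximum
        peaks[box] = True
    else:
        peaks[box] = local_maxima(rec, footprint=footprint, allow_borders=True)
    peaks &= mask_or_seeds.voxels
    labels, n = ndimage.label(peaks, structure=footprint)
    return MarkerVolume(labels.astype(np.int32), int(n))


# ---------------------------------------------------------------------------
# Priority flood
# ---------------------------------------------------------------------------

def _neighbour_offsets(connectivity: int) -> np.ndarray:
    struct = _structure(connectivity)
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if struct[dz + 1, dy + 1, dx + 1]:
                    offs.append((dz, dy, dx))
    return np.array(offs, dtype=np.int64)


@njit(cache=True)
def _flood3d(relief, mask, out, deltas):  # pragma: no cover - jitted
    """Priority flood: ascending (relief, insertion age); seeds in raster order.

    Each voxel is processed exactly once, at its earliest-queued entry; later
    duplicate entries are ignored, which leaves the result unchanged because
    they can only carry later ages at the same or higher relief.
    """
    Z, Y, X = relief.shape
    cap = 4096
    heap_v = np.empty(cap, np.float64)
    heap_a = np.empty(cap, np.int64)
    heap_z = np.empty(cap, np.int64)
    heap_y = np.empty(cap, np.int64)
    heap_x = np.empty(cap, np.int64)
    heap_l = np.empty(cap, np.int32)
    size = 0
    age = 0
    done = np.zeros((Z, Y, X), np.bool_)

    # inlined push/pop over parallel arrays (numba-friendly)
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if out[z, y, x] > 0:
                    if size == cap:
                        heap_v = np.concatenate((heap_v, np.empty(cap, np.float64)))
                        heap_a = np.concatenate((heap_a, np.empty(cap, np.int64)))
                        heap_z = np.concatenate((heap_z, np.empty(cap, np.int64)))
                        heap_y = np.concatenate((heap_y, np.empty(cap, np.int64)))
                        heap_x = np.concatenate((heap_x, np.empty(cap, np.int64)))
                        heap_l = np.concatenate((heap_l, np.empty(cap, np.int32)))
                        cap *= 2
                    heap_v[size] = relief[z, y, x]
                    heap_a[size] = age
                    heap_z[size] = z
                    heap_y[size] = y
                    heap_x[size] = x
                    heap_l[size] = out[z, y, x]
                    age += 1
                    k = size
                    size += 1
                    while k > 0:
                        p = (k - 1) // 2
                        if (heap_v[k] < heap_v[p]) or (heap_v[k] == heap_v[p] and heap_a[k] < heap_a[p]):
                            heap_v[k], heap_v[p] = heap_v[p], heap_v[k]
                            heap_a[k], heap_a[p] = heap_a[p], heap_a[k]
                            heap_z[k], heap_z[p] = heap_z[p], heap_z[k]
                            heap_y[k], heap_y[p] = heap_y[p], heap_y[k]
                            heap_x[k], heap_x[p] = heap_x[p], heap_x[k]
                            heap_l[k], heap_l[p] = heap_l[p], heap_l[k]
                            k = p
                        else:
                            break

    while size > 0:
        z0 = heap_z[0]
        y0 = heap_y[0]
        x0 = heap_x[0]
        l0 = heap_l[0]
        size -= 1
        heap_v[0] = heap_v[size]
        heap_a[0] = heap_a[size]
        heap_z[0] = heap_z[size]
        heap_y[0] = heap_y[size]
        heap_x[0] = heap_x[size]
        heap_l[0] = heap_l[size]
        k = 0
        while True:
            left = 2 * k + 1
            right = left + 1
            small = k
            if left < size and ((heap_v[left] < heap_v[small]) or
                                (heap_v[left] == heap_v[small] and heap_a[left] < heap_a[small])):
                small = left
            if right < size and ((heap_v[right] < heap_v[small]) or
                                 (heap_v[right] == heap_v[small] and heap_a[right] < heap_a[small])):
                small = right
            if small == k:
                break
            heap_v[k], heap_v[small] = heap_v[small], heap_v[k]
            heap_a[k], heap_a[small] = heap_a[small], heap_a[k]
            heap_z[k], heap_z[small] = heap_z[small], heap_z[k]
            heap_y[k], heap_y[small] = heap_y[small], heap_y[k]
            heap_x[k], heap_x[small] = heap_x[small], heap_x[k]
            heap_l[k], heap_l[small] = heap_l[small], heap_l[k]
            k = small

        if done[z0, y0, x0]:
            continue
        done[z0, y0, x0] = True
        if out[z0, y0, x0] == 0:
            out[z0, y0, x0] = l0
        lab = out[z0, y0, x0]
        for t in range(deltas.shape[0]):
            z = z0 + deltas[t, 0]
            y = y0 + deltas[t, 1]
            x = x0 + deltas[t, 2]
            if z < 0 or z >= Z or y < 0 or y >= Y or x < 0 or x >= X:
                continue
            if not mask[z, y, x] or done[z, y, x] or out[z, y, x] > 0:
                continue
            if size == cap:
                heap_v = np.concatenate((heap_v, np.empty(cap, np.float64)))
                heap_a = np.concatenate((heap_a, np.empty(cap, np.int64)))
                heap_z = np.concatenate((heap_z, np.empty(cap, np.int64)))
                heap_y = np.concatenate((heap_y, np.empty(cap, np.int64)))
                heap_x = np.concatenate((heap_x, np.empty(cap, np.int64)))
                heap_l = np.concatenate((heap_l, np.empty(cap, np.int32)))
                cap *= 2
            heap_v[size] = relief[z, y, x]
            heap_a[size] = age
            heap_z[size] = z
            heap_y[size] = y
            heap_x[size] = x
            heap_l[size] = lab
            age += 1
            k = size
            size += 1
            while k > 0:
                p = (k - 1) // 2
                if (heap_v[k] < heap_v[p]) or (heap_v[k] == heap_v[p] and heap_a[k] < heap_a[p]):
                    heap_v[k], heap_v[p] = heap_v[p], heap_v[k]
                    heap_a[k], heap_a[p] = heap_a[p], heap_a[k]
                    heap_z[k], heap_z[p] = heap_z[p], heap_z[k]
                    heap_y[k], heap_y[p] = heap_y[p], heap_y[k]
                    heap_x[k], heap_x[p] = heap_x[p], heap_x[k]
                    heap_l[k], heap_l[p] = heap_l[p], heap_l[k]
                    k = p
                else:
                    break
    return out


def ws_from_markers(mask: BinaryMask, markers: MarkerVolume,
                    connectivity: int = 26,
                    dt: Optional[np.ndarray] = None) -> LabelVolume:
    """Morphological marker-controlled watershed (WS_m).

    Floods the negated distance transform from the markers, restricted to the
    mask.  There are no watershed lines: every mask voxel reachable from a
    marker receives that marker's label.  Marker voxels outside the mask are
    discarded with a warning.  Output labels are compacted to 1..K.
    """
    if markers.labels.shape != mask.voxels.shape:
        raise ValueError("marker and mask shapes differ")
    seeds = markers.labels.astype(np.int32)
    outside = (seeds > 0) & ~mask.voxels
    if outside.any():
        warnings.warn(f"{int(outside.sum())} marker voxels fall outside the mask "
                      "and are discarded", stacklevel=2)
        seeds = np.where(outside, 0, seeds)
    if not (seeds > 0).any():
        warnings.warn("no markers inside the mask; returning an empty segmentation",
                      stacklevel=2)
        return _as_labels(np.zeros(mask.voxels.shape, np.int32), mask)
    if dt is None:
        dt = distance_transform(mask)
    relief = -dt
    out = seeds.copy()
    deltas = _neighbour_offsets(connectivity)
    _flood3d(np.ascontiguousarray(relief, dtype=np.float64),
             np.ascontiguousarray(mask.voxels), out, deltas)
    return _as_labels(relabel_consecutive(out), mask)


def _as_labels(arr: np.ndarray, mask: BinaryMask) -> LabelVolume:
    return LabelVolume(arr.astype(np.int32), mask.spacing, space=mask.space,
                       expansion_factor=mask.expansion_factor)


def remove_small_objects(lv: LabelVolume, min_volume_fraction: float = 0.05) -> LabelVolume:
    """Drop objects whose volume is <= fraction * mean object volume."""
    ids = lv.label_ids()
    if ids.size == 0:
        return lv.with_labels(lv.labels.copy())
    volumes = np.bincount(lv.labels.ravel())[ids]
    cutoff = min_volume_fraction * volumes.mean()
    keep = ids[volumes > cutoff]
    out = np.where(np.isin(lv.labels, keep), lv.labels, 0)
    return lv.with_labels(relabel_consecutive(out).astype(np.int32))


def run_method(mask: BinaryMask, seeds: Optional[BinaryMask],
               cfg: WatershedConfig,
               mask_dt: Optional[np.ndarray] = None,
               seed_dt: Optional[np.ndarray] = None,
               h_markers: Optional[MarkerVolume] = None) -> LabelVolume:
    """Run watershed method A, B or C and the small-object filter.

    Distance transforms, and for methods B/C the H-minima markers of the
    h-dependent stage, can be passed in when a caller sweeps several h
    values over the same mask/seeds; they are recomputed otherwise.
    """
    method = cfg.method
    if method in ("A", "C") and seeds is None:
        raise ValueError(f"method {method} requires seeds")
    if method == "B" and seeds is not None:
        raise ValueError("method B takes no seeds")
    if mask_dt is None:
        mask_dt = distance_transform(mask)

    if method == "A":
        markers = cc_markers(seeds, cfg.connectivity)
        out = ws_from_markers(mask, markers, cfg.connectivity, dt=mask_dt)
    elif method == "B":
        markers = h_markers if h_markers is not None else \
            hminima_markers(mask, cfg.h, cfg.connectivity, dt=mask_dt)
        out = ws_from_markers(mask, markers, cfg.connectivity, dt=mask_dt)
    else:  # C: watershed twice -- seeds first, then the mask
        if seed_dt is None:
            seed_dt = distance_transform(seeds)
        seed_markers = h_markers if h_markers is not None else \
            hminima_markers(seeds, cfg.h, cfg.connectivity, dt=seed_dt)
        seed_labels = ws_from_markers(seeds, seed_markers, cfg.connectivity, dt=seed_dt)
        out = ws_from_markers(
            mask, MarkerVolume(seed_labels.labels, seed_labels.n_objects),
            cfg.connectivity, dt=mask_dt)
    return remove_small_objects(out, cfg.min_volume_fraction)
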