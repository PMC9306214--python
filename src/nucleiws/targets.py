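"""Training targets from instance ground truths: masks M3D/M3DE/M2DE and seeds.

Ground truths drawn on the anisotropic input grid are first lifted to the
expanded grid by per-label shape-based interpolation (linear blending of
signed distance fields between consecutive slices).  Plain shape
interpolation can open gaps between nuclei that touch across slices; in
*between-nuclei regions* -- where a morphological closing of the foreground
union differs from the union itself -- nearest-neighbour interpolation along
z is used instead, so nuclei touching in z stay touching.

From the expanded ground truth three mask types and the seeds are derived:

* ``M3D``   -- plain binarisation.
* ``M3DE``  -- binarisation with every nucleus's 3D outer boundary (the
  26-adjacent voxels *outside* it) forced to background; where two nuclei
  touch, each erases the other's contact layer, leaving a two-voxel
  separating stripe.
* ``M2DE``  -- the same idea slice-wise with 2D 8-adjacency, computed on the
  input-space ground truth (z contacts are invisible to it by construction).
* ``seeds`` -- per-nucleus morphological erosion with a spherical element,
  with a fallback ladder (smaller radius, then in-plane-only erosion) so
  that every nucleus keeps exactly one seed component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume_core import BinaryMask, LabelVolume, expand_labels_nn, _check_factor

__all__ = ["SeedGenConfig", "interpolate_ground_truth", "make_m3d", "make_m3de",
           "make_m2de", "make_seeds"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class SeedGenConfig:
    primary_radius: float = 3.0
    fallback_radius: float = 1.0
    fallback_2d_radius: float = 1.0

    def __post_init__(self) -> None:
        if min(self.primary_radius, self.fallback_radius, self.fallback_2d_radius) < 1:
            raise ValueError("seed erosion radii must be >= 1")


def _ball(radius: float, z_aniso: float = 1.0) -> np.ndarray:
    """Euclidean ball of ``radius`` voxels on the spacing-normalised grid."""
    rz = max(int(np.floor(radius / z_aniso)), 0)
    r = int(np.floor(radius))
    dz, dy, dx = np.meshgrid(np.arange(-rz, rz + 1), np.arange(-r, r + 1),
                             np.arange(-r, r + 1), indexing="ij")
    return (dz * z_aniso) ** 2 + dy ** 2 + dx ** 2 <= radius ** 2


def _disc(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    dy, dx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    return dy ** 2 + dx ** 2 <= radius ** 2


def _sdf2d(mask: np.ndarray) -> np.ndarray:
    """Signed distance: positive inside, negative outside."""
    if not mask.any():
        return np.full(mask.shape, -np.inf)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def interpolate_ground_truth(gt: LabelVolume, factor: int,
                             closing_radius: Optional[float] = None) -> LabelVolume:
    """Lift an input-space ground truth to the expanded grid.

    Original slices are preserved exactly at ``k % factor == 0``.  In-between
    slices morph each label by linearly interpolating its 2D signed distance
    fields; a label present on only one side tapers out towards the far
    slice.  Inside between-nuclei regions (closing of the foreground union
    minus the union; spherical element of radius ``closing_radius``, default
    the expansion factor) background voxels are filled from the
    nearest-neighbour expansion so that z contacts survive.
    """
    factor = _check_factor(factor)
    if gt.space != "input":
        raise ValueError("interpolate_ground_truth expects an input-space GT")
    if factor == 1:
        return gt.with_labels(gt.labels.copy())
    if closing_radius is None:
        closing_radius = float(factor)

    Z, Y, X = gt.shape
    nn = expand_labels_nn(gt, factor)
    out = np.zeros((Z * factor, Y, X), dtype=gt.labels.dtype)
    out[::factor] = gt.labels

    for k in range(Z * factor):
        if k % factor == 0:
            continue
        p = k / factor
        lo = int(np.floor(p))
        hi = min(lo + 1, Z - 1)
        w = p - lo
        sl_lo, sl_hi = gt.labels[lo], gt.labels[hi]
        labels_here = np.union1d(np.unique(sl_lo), np.unique(sl_hi))
        labels_here = labels_here[labels_here > 0]
        best = np.full((Y, X), -np.inf)
        for lab in labels_here:
            in_lo, in_hi = sl_lo == lab, sl_hi == lab
            if in_lo.any() and in_hi.any():
                sdf = (1.0 - w) * _sdf2d(in_lo) + w * _sdf2d(in_hi)
            elif in_lo.any():
                s = _sdf2d(in_lo)
                sdf = s - w * (s.max() + 1.0)   # taper towards the far slice
            else:
                s = _sdf2d(in_hi)
                sdf = s - (1.0 - w) * (s.max() + 1.0)
            claim = sdf > 0
            take = claim & (sdf > best)
            out[k][take] = lab
            best[take] = sdf[take]

    # between-nuclei regions: closing(union) minus union, gap-filled by NN
    union = nn.labels > 0
    ball = _ball(closing_radius, z_aniso=1.0)  # expanded grid is near isotropic
    closed = ndimage.binary_closing(union, structure=ball)
    between = closed & ~union
    fill = between & (out == 0) & (nn.labels > 0)
    out[fill] = nn.labels[fill]

    s_xy, _, s_z = gt.spacing
    return LabelVolume(out, (s_xy, s_xy, s_z / factor), space="expanded",
                       expansion_factor=factor)


def _bbox(mask: np.ndarray, pad: int):
    idx = np.nonzero(mask)
    lo = [max(int(i.min()) - pad, 0) for i in idx]
    hi = [min(int(i.max()) + 1 + pad, s) for i, s in zip(idx, mask.shape)]
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def make_m3d(gt_expanded: LabelVolume) -> BinaryMask:
    """Plain binarisation of the expanded ground truth."""
    return BinaryMask(gt_expanded.labels > 0, "M3D", gt_expanded.spacing,
                      space=gt_expanded.space,
                      expansion_factor=gt_expanded.expansion_factor)


def make_m3de(gt_expanded: LabelVolume) -> BinaryMask:
    """Edge-emphasised mask: per-nucleus 3D outer boundaries set to background.

    The outer boundary of a nucleus is the set of voxels *not* belonging to
    it that are 26-adjacent to it; erasing those from the union mask turns
    every nucleus-nucleus contact into a two-voxel background stripe while
    leaving isolated nuclei untouched.
    """
    m3d = gt_expanded.labels > 0
    edges = np.zeros_like(m3d)
    for lab in gt_expanded.label_ids():
        mask = gt_expanded.labels == lab
        box = _bbox(mask, pad=1)
        sub = mask[box]
        outer = ndimage.binary_dilation(sub, structure=_CONN26) & ~sub
        edges[box] |= outer
    return BinaryMask(m3d & ~edges, "M3DE", gt_expanded.spacing,
                      space=gt_expanded.space,
                      expansion_factor=gt_expanded.expansion_factor)


def make_m2de(gt_input: LabelVolume) -> BinaryMask:
    """Slice-wise edge emphasis with 2D 8-adjacency, on the input-space GT."""
    if gt_input.space != "input":
        raise ValueError("make_m2de expects an input-space GT")
    m = gt_input.labels > 0
    edges = np.zeros_like(m)
    for z in range(gt_input.shape[0]):
        sl = gt_input.labels[z]
        for lab in np.unique(sl):
            if lab == 0:
                continue
            mask = sl == lab
            outer = ndimage.binary_dilation(mask, structure=_CONN8) & ~mask
            edges[z] |= outer
    return BinaryMask(m & ~edges, "M2DE", gt_input.spacing, space="input",
                      expansion_factor=1)


def _erode_one(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    return ndimage.binary_erosion(mask, structure=structure, border_value=0)


def _n_components(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    return ndimage.label(mask, structure=_CONN26)[1]


def make_seeds(gt_expanded: LabelVolume,
               cfg: SeedGenConfig = SeedGenConfig()) -> BinaryMask:
    """Eroded per-nucleus seeds; every nucleus keeps exactly one component.

    Erosion ladder per nucleus: spherical element of ``primary_radius``; if
    the result is empty or splits (26-connectivity), retry with
    ``fallback_radius``; if it still is not a single component, erode each
    xy-slice with a 2D disc of ``fallback_2d_radius``; if even that fails,
    the nucleus itself is kept as its seed.
    """
    az = gt_expanded.z_anisotropy
    ball_primary = _ball(cfg.primary_radius, az)
    ball_fallback = _ball(cfg.fallback_radius, az)
    disc = _disc(cfg.fallback_2d_radius)
    seeds = np.zeros(gt_expanded.shape, dtype=bool)
    pad = int(np.ceil(cfg.primary_radius)) + 1
    for lab in gt_expanded.label_ids():
        mask = gt_expanded.labels == lab
        box = _bbox(mask, pad=pad)
        sub = mask[box]
        eroded = _erode_one(sub, ball_primary)
        if _n_components(eroded) != 1:
            eroded = _erode_one(sub, ball_fallback)
        if _n_components(eroded) != 1:
            eroded = np.stack([
                ndimage.binary_erosion(sl, structure=disc, border_value=0)
                for sl in sub
            ])
        if _n_components(eroded) != 1:
            eroded = sub  # pathological nucleus: keep it whole
        seeds[box] |= eroded
    return BinaryMask(seeds, "seeds", gt_expanded.spacing,
                      space=gt_expanded.space,
                      expansion_factor=gt_expanded.expansion_factor)
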