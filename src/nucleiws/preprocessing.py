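"""Slice resizing, background-slice zeroing and near-isotropic z expansion.

Confocal z-stacks arrive with in-plane pixels much finer than the slice step
(e.g. 0.1 um vs 1.01 um).  The pipeline first standardises the in-plane size,
zeroes slices that carry no signal, and then interpolates new slices with an
odd integer factor chosen so that ``s_z / factor`` is close to ``s_xy``.
Odd factors keep every original slice in the expanded stack, which makes the
return trip to the input grid a plain slice subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Set, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .volume_core import VolumeStack, _check_factor

__all__ = ["PreprocessConfig", "resize_slices", "zero_background_slices",
           "expand_stack", "preprocess"]


@dataclass
class PreprocessConfig:
    target_xy: int = 256
    antialias_sigma: float = 1.0     # 2D Gaussian before downsampling, pixels
    background_sigma: float = 3.0    # 2D Gaussian used only for detection, pixels
    background_fraction: float = 0.10
    expansion_factor: int = 3        # odd; pick so s_z / factor ~ s_xy

    def __post_init__(self) -> None:
        if not 0 < self.background_fraction < 1:
            raise ValueError("background_fraction must lie in (0, 1)")
        _check_factor(self.expansion_factor)


def resize_slices(vs: VolumeStack, cfg: PreprocessConfig = PreprocessConfig()) -> VolumeStack:
    """Bilinear-resize every slice to ``target_xy`` square.

    When downsampling, each slice is first low-pass filtered with a 2D
    Gaussian (``antialias_sigma``) to prevent aliasing; upsampling applies no
    pre-filter.  The xy spacing metadata is rescaled by the resize ratio.
    """
    if vs.space != "input":
        raise ValueError("resize_slices operates in input space")
    Z, H, W = vs.shape
    if H <= 0 or W <= 0:
        raise ValueError("non-positive slice dimensions")
    t = int(cfg.target_xy)
    if (H, W) == (t, t):
        return vs.with_voxels(vs.voxels.copy())
    vox = vs.voxels.astype(np.float32)
    if H > t or W > t:
        vox = ndimage.gaussian_filter(vox, sigma=(0, cfg.antialias_sigma, cfg.antialias_sigma),
                                      mode="reflect")
    out = np.stack([
        _sk_resize(sl, (t, t), order=1, mode="reflect", anti_aliasing=False,
                   preserve_range=True)
        for sl in vox
    ]).astype(np.float32)
    s_xy, _, s_z = vs.spacing
    new_sxy = s_xy * W / t
    return VolumeStack(out, (new_sxy, new_sxy, s_z), space="input")


def zero_background_slices(vs: VolumeStack, cfg: PreprocessConfig = PreprocessConfig()
                           ) -> Tuple[VolumeStack, Set[int]]:
    """Zero slices that carry no or only minimal signal.

    Detection runs on a per-slice Gaussian-smoothed copy (``background_sigma``)
    to discount isolated intensity peaks.  A slice is background iff its
    smoothed maximum is strictly below ``background_fraction`` times the
    smoothed stack maximum *and* it is the first/last slice or adjacent to an
    already-detected background slice -- i.e. the background grows inward from
    both ends of the stack.  Detected slices are set to 0 in the returned
    (unsmoothed) stack.
    """
    if vs.shape[0] < 1:
        raise ValueError("stack needs at least one slice")
    smoothed = ndimage.gaussian_filter(
        vs.voxels.astype(np.float32),
        sigma=(0, cfg.background_sigma, cfg.background_sigma), mode="reflect")
    slice_max = smoothed.reshape(vs.shape[0], -1).max(axis=1)
    threshold = cfg.background_fraction * slice_max.max()
    if threshold == 0.0:         # an all-zero stack is all background
        dim = np.ones(vs.shape[0], dtype=bool)
    else:
        dim = slice_max < threshold  # strict

    Z = vs.shape[0]
    background: Set[int] = set()
    for z in range(Z):          # grow from the front
        if dim[z]:
            background.add(z)
        else:
            break
    for z in range(Z - 1, -1, -1):  # grow from the back
        if dim[z]:
            background.add(z)
        else:
            break
    out = vs.voxels.copy()
    for z in background:
        out[z] = 0
    return vs.with_voxels(out), background


def expand_stack(vs: VolumeStack, factor: int) -> VolumeStack:
    """Linearly interpolate new slices so the stack becomes near isotropic.

    Output depth is ``factor * Z``; output slice ``k`` is the linear
    interpolation of the input at z-coordinate ``k / factor``, clamped to the
    last slice past the end.  Original slices are reproduced bit-exactly at
    ``k % factor == 0``.
    """
    factor = _check_factor(factor)
    if vs.space != "input":
        raise ValueError("expand_stack expects an input-space stack")
    Z = vs.shape[0]
    if factor == 1:
        out = vs.voxels.copy()
    else:
        pos = np.minimum(np.arange(Z * factor) / factor, Z - 1)
        lo = np.floor(pos).astype(np.int64)
        hi = np.minimum(lo + 1, Z - 1)
        w = (pos - lo).astype(np.float64)
        out = np.empty((Z * factor,) + vs.shape[1:], dtype=np.float32)
        for k in range(Z * factor):
            if w[k] == 0.0:
                out[k] = vs.voxels[lo[k]]
            else:
                out[k] = ((1.0 - w[k]) * vs.voxels[lo[k]].astype(np.float64)
                          + w[k] * vs.voxels[hi[k]].astype(np.float64))
    s_xy, _, s_z = vs.spacing
    return VolumeStack(out, (s_xy, s_xy, s_z / factor), space="expanded",
                       expansion_factor=factor)


def preprocess(vs: VolumeStack, cfg: PreprocessConfig = PreprocessConfig()
               ) -> Tuple[VolumeStack, Set[int]]:
    """resize -> zero background slices -> expand; the standard front end."""
    resized = resize_slices(vs, cfg)
    zeroed, background = zero_background_slices(resized, cfg)
    return expand_stack(zeroed, cfg.expansion_factor), background
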