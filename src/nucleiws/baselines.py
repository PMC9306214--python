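"""Non-deep-learning reference pipeline: denoise -> Otsu mask -> watershed B.

These are the traditional comparators: the nuclei mask comes from global
Otsu thresholding of the (optionally denoised) intensity volume instead of
a CNN, and instances from the H-minima watershed (method B) with roundness
selection of h.  Denoisers are stock filters behind a pluggable registry;
their parameters pass through verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np
import SimpleITK as sitk
from skimage.filters import threshold_otsu
from skimage.restoration import denoise_nl_means
from scipy import ndimage

from .hselect import HGrid, ProposalSet, select_by_roundness
from .volume_core import BinaryMask, VolumeStack

__all__ = ["BaselineConfig", "otsu_threshold", "baseline_segment",
           "DENOISERS"]


def _denoise_none(vol: np.ndarray, **_: float) -> np.ndarray:
    return vol


def _denoise_gaussian(vol: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    if sigma <= 0:
        return vol
    return ndimage.gaussian_filter(vol, sigma, mode="reflect")


def _denoise_anisotropic_diffusion(vol: np.ndarray, time_step: float = 0.02,
                                   conductance: float = 2.0,
                                   iterations: int = 5) -> np.ndarray:
    img = sitk.GetImageFromArray(vol.astype(np.float64))
    out = sitk.GradientAnisotropicDiffusion(
        img, timeStep=time_step, conductanceParameter=conductance,
        numberOfIterations=int(iterations))
    return sitk.GetArrayFromImage(out).astype(np.float32)


def _denoise_bilateral(vol: np.ndarray, domain_sigma: float = 2.0,
                       range_sigma: float = 20.0) -> np.ndarray:
    img = sitk.GetImageFromArray(vol.astype(np.float64))
    out = sitk.Bilateral(img, domainSigma=domain_sigma, rangeSigma=range_sigma)
    return sitk.GetArrayFromImage(out).astype(np.float32)


def _denoise_nonlocal_patch(vol: np.ndarray, patch_size: int = 3,
                            patch_distance: int = 5,
                            h: float = 10.0) -> np.ndarray:
    return denoise_nl_means(vol.astype(np.float32), patch_size=int(patch_size),
                            patch_distance=int(patch_distance), h=h,
                            preserve_range=True).astype(np.float32)


DENOISERS: Dict[str, Callable[..., np.ndarray]] = {
    "none": _denoise_none,
    "gaussian": _denoise_gaussian,
    "anisotropic_diffusion": _denoise_anisotropic_diffusion,
    "bilateral": _denoise_bilateral,
    "nonlocal_patch": _denoise_nonlocal_patch,
}


@dataclass
class BaselineConfig:
    denoiser: str = "none"
    denoiser_params: Dict[str, float] = field(default_factory=dict)
    h_grid: HGrid = field(default_factory=HGrid)

    def __post_init__(self) -> None:
        if self.denoiser not in DENOISERS:
            raise ValueError(f"unknown denoiser {self.denoiser!r}; "
                             f"choose from {sorted(DENOISERS)}")


def otsu_threshold(vs: VolumeStack) -> BinaryMask:
    """Global Otsu mask: threshold maximising between-class variance over a
    256-bin histogram; foreground is strictly above the threshold."""
    vol = vs.voxels
    if float(vol.max()) == float(vol.min()):
        raise ValueError("Otsu threshold is undefined for a constant volume")
    t = threshold_otsu(vol, nbins=256)
    return BinaryMask(vol > t, "M3D", vs.spacing, space=vs.space,
                      expansion_factor=vs.expansion_factor)


def baseline_segment(vs: VolumeStack,
                     cfg: BaselineConfig = BaselineConfig()) -> ProposalSet:
    """Denoise, Otsu-threshold, then watershed method B over the h grid.

    Fully deterministic for a fixed configuration (no RNG anywhere).
    """
    if vs.space != "expanded":
        raise ValueError("baseline_segment expects a preprocessed, expanded stack")
    den = DENOISERS[cfg.denoiser](vs.voxels, **cfg.denoiser_params)
    mask = otsu_threshold(vs.with_voxels(den))
    return select_by_roundness(mask, None, "B", cfg.h_grid)
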