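"""Synthetic confocal spheroid phantoms with known instance ground truth.

The generator emulates the geometry this pipeline targets: a dense clump of
near-ellipsoidal nuclei imaged as an anisotropic z-stack (slice step several
times the in-plane pixel), with optical blur and sensor noise.  Nuclei are
placed on an isotropic generation grid at the in-plane resolution, blurred
there, and only then subsampled along z, so the anisotropy interacts with
the blur the way real sampling does.

It is deliberately simple optics: a Gaussian stand-in for the PSF, no
photobleaching, no intensity texture unless asked for.  What passing tests
show is therefore that the geometry-driven parts of the pipeline (masking,
marker generation, watershed, metrics) behave correctly -- not that any
particular microscope is modelled faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume_core import LabelVolume, VolumeStack

__all__ = ["SimConfig", "generate_spheroid", "benchmark_configs"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic spheroid.

    Defaults describe a clumped spheroid in a 128x128 field of view with a
    0.75/0.25 = 3x z anisotropy and nuclei of 7.5--10.5 px in-plane radius
    with mild elongation -- the nucleus-to-pixel proportions of a confocal
    HepG2 spheroid resampled to a coarse grid, kept large enough that seeds
    eroded by 3 voxels still carry distance-transform domes deeper than the
    upper end of the h grid.
    """

    n_nuclei: int = 25
    radius_range: Tuple[float, float] = (7.5, 10.5)  # voxels on the iso grid
    elongation_max: float = 1.3                      # >= 1; 1 = spheres
    clumping: float = 0.5                            # 0 disjoint .. 1 heavy contact
    volume_shape: Tuple[int, int, int] = (20, 128, 128)  # input-space (Z, Y, X)
    spacing: Tuple[float, float, float] = (0.25, 0.25, 0.75)  # (s_xy, s_xy, s_z) um
    blur_sigma: float = 1.0                          # iso-grid voxels
    gaussian_sd: float = 3.0
    poisson_noise: bool = True
    intensity_range: Tuple[float, float] = (120.0, 255.0)
    speckle_sd: float = 0.0      # multiplicative texture, off for determinism
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (r_min, r_max) with r_min <= r_max")
        if not 0.0 <= self.clumping <= 1.0:
            raise ValueError("clumping must lie in [0, 1]")
        if self.elongation_max < 1.0:
            raise ValueError("elongation_max must be >= 1")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")


def _sample_nucleus(rng: np.random.Generator, cfg: SimConfig):
    r = rng.uniform(*cfg.radius_range)
    elong = rng.uniform(1.0, cfg.elongation_max)
    semi = np.array([r, r, r * elong])
    rot = Rotation.random(random_state=rng).as_matrix()
    return semi, rot


def _min_center_distance(r_a: float, r_b: float, clumping: float) -> float:
    """Closest allowed center distance for effective radii r_a, r_b.

    Disjoint placement keeps one voxel of clearance; clumped placement allows
    interpenetration of at most 20% of the smaller radius, scaled by the
    clumping strength.
    """
    if clumping == 0.0:
        return r_a + r_b + 1.0
    return r_a + r_b - 0.2 * clumping * min(r_a, r_b)


def _place_centers(rng, cfg: SimConfig, eff_radii: np.ndarray,
                   iso_shape: Tuple[int, int, int]) -> np.ndarray:
    lo = eff_radii[:, None] * 0 + eff_radii[:, None]  # margin per nucleus
    dims = np.array(iso_shape, dtype=float)
    centers: List[np.ndarray] = []
    max_tries = 1000 * len(eff_radii)
    tries = 0
    for i, r in enumerate(eff_radii):
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place nucleus {i + 1}/{len(eff_radii)} after "
                    f"{max_tries} attempts (volume {iso_shape}, r_eff {r:.1f}, "
                    f"clumping {cfg.clumping}); enlarge the volume or lower n_nuclei"
                )
            # nuclei at the border may be truncated when the volume is small
            margin = np.minimum(r, dims / 2.0 - 0.5)
            if centers and rng.random() < cfg.clumping:
                # attach next to an existing nucleus: aim at touching distance
                j = rng.integers(len(centers))
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                d = _min_center_distance(r, eff_radii[j], cfg.clumping)
                # stronger clumping aims closer to the touching distance
                slack = 1.0 + 0.1 * (1.0 - cfg.clumping)
                c = centers[j] + u * d * rng.uniform(1.0, slack)
            else:
                c = rng.uniform(margin, dims - margin)
            if np.any(c < margin) or np.any(c > dims - margin):
                continue
            ok = all(
                np.linalg.norm(c - centers[j]) >=
                _min_center_distance(r, eff_radii[j], cfg.clumping)
                for j in range(len(centers))
            )
            if ok:
                centers.append(c)
                break
    return np.array(centers)


def _paint(labels: np.ndarray, center: np.ndarray, semi: np.ndarray,
           rot: np.ndarray, value: int) -> None:
    """Rasterise one ellipsoid; earlier-placed nuclei keep contested voxels."""
    r_max = float(semi.max())
    lo = np.maximum(np.floor(center - r_max - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + r_max + 2).astype(int), labels.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                             indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(float) - center
    local = pts @ rot            # rotate into the ellipsoid frame
    inside = np.sum((local / semi) ** 2, axis=-1) <= 1.0
    region = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    region[inside & (region == 0)] = value


def generate_spheroid(cfg: SimConfig = SimConfig()) -> Tuple[VolumeStack, LabelVolume]:
    """Simulate one spheroid; returns intensity stack and GT, both input space.

    Deterministic for a fixed ``cfg`` (including ``rng_seed``).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    s_xy, _, s_z = cfg.spacing
    aniso = max(1, int(round(s_z / s_xy)))
    Z, Y, X = cfg.volume_shape
    iso_shape = (Z * aniso, Y, X)

    params = [_sample_nucleus(rng, cfg) for _ in range(cfg.n_nuclei)]
    eff_radii = np.array([semi.max() for semi, _ in params])
    centers = _place_centers(rng, cfg, eff_radii, iso_shape)

    labels_iso = np.zeros(iso_shape, dtype=np.int32)
    for i, ((semi, rot), c) in enumerate(zip(params, centers), start=1):
        _paint(labels_iso, c, semi, rot, i)

    lo, hi = cfg.intensity_range
    brightness = rng.uniform(lo, hi, size=cfg.n_nuclei)
    img = np.zeros(iso_shape, dtype=np.float32)
    fg = labels_iso > 0
    img[fg] = brightness[labels_iso[fg] - 1]
    if cfg.speckle_sd > 0:
        img[fg] *= np.clip(1.0 + rng.normal(0, cfg.speckle_sd, size=int(fg.sum())), 0.2, 2.0)
    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma, mode="reflect")

    # anisotropic sampling: keep every aniso-th slice of the iso grid
    img_in = img[::aniso].copy()
    labels_in = labels_iso[::aniso].copy()

    if cfg.poisson_noise:
        img_in = rng.poisson(np.maximum(img_in, 0.0)).astype(np.float32)
    if cfg.gaussian_sd > 0:
        img_in = img_in + rng.normal(0, cfg.gaussian_sd, size=img_in.shape)
    img_in = np.clip(img_in, 0.0, None).astype(np.float32)

    vs = VolumeStack(img_in, cfg.spacing, space="input")
    gt = LabelVolume(labels_in.astype(np.int32), cfg.spacing, space="input")
    if gt.n_objects != cfg.n_nuclei:
        raise RuntimeError(
            f"a nucleus vanished during rasterisation ({gt.n_objects} of "
            f"{cfg.n_nuclei} labels present); radii too small for the grid"
        )
    return vs, gt


def benchmark_configs(n_volumes: int = 20, clumping: float = 0.5,
                      seed0: int = 0) -> List[SimConfig]:
    """The default benchmark: ``n_volumes`` spheroids, 15-40 nuclei each.

    Volume ``i`` uses seed ``seed0 + i``; its nucleus count is drawn
    deterministically from that seed.
    """
    cfgs = []
    for i in range(n_volumes):
        seed = seed0 + i
        n = int(np.random.default_rng(seed).integers(15, 41))
        cfgs.append(SimConfig(n_nuclei=n, clumping=clumping, rng_seed=seed))
    return cfgs
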