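"""System-configuration orchestration {w, M, s} and cross-validation planning.

A configuration names a watershed method ``w`` (A, B or C), a mask type
``M`` (M3D, M3DE or M2DE) and whether CNN seeds ``s`` are used.  Methods A
and C need seeds; method B works from the mask alone.  The configuration
{A, M3D, S} is the classic deep-learning-enhanced seeded watershed used as
the baseline comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .hselect import HGrid, ProposalSet, select_by_roundness
from .preprocessing import PreprocessConfig, preprocess
from .unet.masking import UNetMasker, predict_masks
from .volume_core import LabelVolume, VolumeStack, collapse_to_input_space
from .watershed import WatershedConfig, run_method

__all__ = ["SystemConfig", "plan_cross_validation", "run_configuration"]


@dataclass
class SystemConfig:
    w: str = "C"                      # A | B | C
    M: str = "M3DE"                   # M3D | M3DE | M2DE
    s: str = "seeds"                  # seeds | none
    grid: HGrid = field(default_factory=HGrid)

    def __post_init__(self) -> None:
        if self.w not in ("A", "B", "C"):
            raise ValueError("w must be A, B or C")
        if self.M not in ("M3D", "M3DE", "M2DE"):
            raise ValueError("M must be M3D, M3DE or M2DE")
        if self.s not in ("seeds", "none"):
            raise ValueError("s must be 'seeds' or 'none'")
        if self.w in ("A", "C") and self.s != "seeds":
            raise ValueError(f"method {self.w} requires seeds")
        if self.w == "B" and self.s != "none":
            raise ValueError("method B takes no seeds")


def plan_cross_validation(n_volumes: int) -> List[Tuple[List[int], int, int]]:
    """Leave-one-out folds with a rolling validation volume (ids 1-based).

    Fold m tests on volume m and validates on m-1 (volume n for m=1); the
    remaining n-2 volumes train.
    """
    n = int(n_volumes)
    if n < 3:
        raise ValueError("cross-validation needs at least 3 volumes")
    folds = []
    for m in range(1, n + 1):
        val = n if m == 1 else m - 1
        train = [i for i in range(1, n + 1) if i not in (m, val)]
        folds.append((train, val, m))
    return folds


def run_configuration(volume: VolumeStack, mask_model: UNetMasker,
                      sc: SystemConfig,
                      seed_model: Optional[UNetMasker] = None,
                      pre_cfg: PreprocessConfig = PreprocessConfig(),
                      original_xy: Optional[Tuple[int, int]] = None
                      ) -> Tuple[LabelVolume, Optional[ProposalSet]]:
    """Preprocess, predict masks/seeds, segment and collapse to input space.

    Returns the input-space segmentation and, for methods B/C, the full
    h-sweep report.  Deterministic given the model weights.
    """
    if sc.s == "seeds" and seed_model is None:
        raise ValueError(f"configuration {{{sc.w}, {sc.M}, S}} needs a seed model")
    if sc.s == "none" and seed_model is not None:
        raise ValueError("configuration without seeds got a seed model")
    if mask_model.target_kind != sc.M:
        raise ValueError(f"mask model predicts {mask_model.target_kind}, "
                         f"configuration wants {sc.M}")
    original_xy = original_xy or volume.shape[1:]
    expanded, _ = preprocess(volume, pre_cfg)
    mask, seeds = predict_masks(expanded, mask_model, seed_model)

    sweep: Optional[ProposalSet] = None
    if sc.w == "A":
        seg = run_method(mask, seeds, WatershedConfig(method="A"))
    else:
        sweep = select_by_roundness(mask, seeds if sc.w == "C" else None,
                                    sc.w, sc.grid)
        seg = sweep.selected_labels
    return collapse_to_input_space(seg, original_xy,
                                   pre_cfg.expansion_factor), sweep
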