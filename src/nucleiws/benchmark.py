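"""Desk-scale benchmark: the watershed stages run on ground-truth-derived
masks and seeds over the default synthetic spheroid set.

Bypassing the CNNs isolates the geometric half of the pipeline -- ground
truth interpolation, target generation, H-minima marker construction, the
flood and the roundness-based h selection -- and gives an upper bound that
the trained models can approach.  The Otsu route scores the same volumes
with the traditional intensity-threshold mask instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .baselines import BaselineConfig, baseline_segment
from .hselect import select_by_roundness
from .metrics import EvalReport, evaluate
from .preprocessing import expand_stack
from .synth import SimConfig, benchmark_configs, generate_spheroid
from .targets import interpolate_ground_truth, make_m3d, make_seeds

__all__ = ["gt_pipeline_report", "otsu_baseline_report", "run_benchmark"]

_FACTOR = 3


def gt_pipeline_report(cfg: SimConfig, method: str = "C") -> EvalReport:
    """Method C (or B) + roundness h selection with GT-derived mask/seeds."""
    _, gt = generate_spheroid(cfg)
    gtx = interpolate_ground_truth(gt, _FACTOR)
    mask = make_m3d(gtx)
    seeds = make_seeds(gtx) if method == "C" else None
    ps = select_by_roundness(mask, seeds, method)
    return evaluate(gt, ps.selected_labels, gt.shape[1:], _FACTOR)


def otsu_baseline_report(cfg: SimConfig) -> EvalReport:
    """Otsu mask + watershed method B on the raw intensity volume."""
    vs, gt = generate_spheroid(cfg)
    expanded = expand_stack(vs, _FACTOR)
    ps = baseline_segment(expanded, BaselineConfig())
    return evaluate(gt, ps.selected_labels, gt.shape[1:], _FACTOR)


@dataclass
class BenchmarkResult:
    pipeline: List[EvalReport]
    baseline: Optional[List[EvalReport]]

    def mean(self, attr: str, which: str = "pipeline") -> float:
        reports = self.pipeline if which == "pipeline" else self.baseline
        return sum(getattr(r, attr) for r in reports) / len(reports)


def run_benchmark(n_volumes: int = 20, with_baseline: bool = True,
                  seed0: int = 0) -> BenchmarkResult:
    """Score the default benchmark (seeds ``seed0`` .. ``seed0+n-1``)."""
    cfgs = benchmark_configs(n_volumes, seed0=seed0)
    pipeline = [gt_pipeline_report(c) for c in cfgs]
    baseline = [otsu_baseline_report(c) for c in cfgs] if with_baseline else None
    return BenchmarkResult(pipeline, baseline)
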