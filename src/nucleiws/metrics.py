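"""Instance-segmentation scoring: IoU matching, DQ/SQ/PQ, JI, AJI, NNDP.

All metrics treat label 0 as background and are invariant to permutations
of the positive labels.  Matching for PQ uses the strict ``IoU > 0.5``
criterion, under which each ground-truth and each predicted object can have
at most one partner, so no tie-breaking is needed.

JI here follows the per-ground-truth-nucleus formulation: each GT nucleus
contributes its best IoU over all predictions (0 if nothing overlaps), and
false-positive predictions go unpenalised.  AJI aggregates voxel counts
instead, consuming each predicted object at most once and adding unused
predictions to the denominator, which does penalise false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .volume_core import LabelVolume, collapse_to_input_space

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "EvalReport", "match_objects", "panoptic_quality",
           "jaccard_index", "aggregated_jaccard", "nndp", "evaluate"]


@dataclass
class MatchResult:
    pairs: List[Tuple[int, int, float]]  # (gt_label, seg_label, IoU)
    TP: int
    FP: int
    FN: int


@dataclass
class EvalReport:
    DQ: float
    SQ: float
    PQ: float
    JI: float
    AJI: float
    NNDP: float          # percent, in [0, 200]
    TP: int
    FP: int
    FN: int
    S_num: int
    G_num: int

    def as_dict(self) -> Dict[str, float]:
        return {"dq": self.DQ, "sq": self.SQ, "pq": self.PQ, "ji": self.JI,
                "aji": self.AJI, "nndp_percent": self.NNDP, "tp": self.TP,
                "fp": self.FP, "fn": self.FN, "s_num": self.S_num,
                "g_num": self.G_num}


def _overlap_table(gt: np.ndarray, seg: np.ndarray):
    """Pairwise intersection counts plus per-object sizes.

    Returns (gt_ids, seg_ids, inter) where ``inter[i, j]`` is the voxel
    overlap of gt_ids[i] with seg_ids[j], and the two size vectors.
    """
    gt_ids = np.unique(gt); gt_ids = gt_ids[gt_ids > 0]
    seg_ids = np.unique(seg); seg_ids = seg_ids[seg_ids > 0]
    gt_sizes = {int(g): int(n) for g, n in zip(*np.unique(gt[gt > 0], return_counts=True))}
    seg_sizes = {int(s): int(n) for s, n in zip(*np.unique(seg[seg > 0], return_counts=True))}
    both = (gt > 0) & (seg > 0)
    pair_keys, pair_counts = np.unique(
        np.stack([gt[both], seg[both]]), axis=1, return_counts=True)
    gt_index = {int(g): i for i, g in enumerate(gt_ids)}
    seg_index = {int(s): j for j, s in enumerate(seg_ids)}
    inter = np.zeros((gt_ids.size, seg_ids.size), dtype=np.int64)
    for (g, s), c in zip(pair_keys.T, pair_counts):
        inter[gt_index[int(g)], seg_index[int(s)]] = c
    return gt_ids, seg_ids, inter, gt_sizes, seg_sizes


def _iou_matrix(gt: np.ndarray, seg: np.ndarray):
    gt_ids, seg_ids, inter, gt_sizes, seg_sizes = _overlap_table(gt, seg)
    gt_vol = np.array([gt_sizes[int(g)] for g in gt_ids], dtype=np.int64)
    seg_vol = np.array([seg_sizes[int(s)] for s in seg_ids], dtype=np.int64)
    union = gt_vol[:, None] + seg_vol[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return gt_ids, seg_ids, inter, union, iou, gt_vol, seg_vol


def match_objects(gt: LabelVolume, seg: LabelVolume) -> MatchResult:
    """Pair objects with IoU strictly above 0.5 (provably unique pairs)."""
    if gt.shape != seg.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs seg {seg.shape}")
    gt_ids, seg_ids, _, _, iou, _, _ = _iou_matrix(gt.labels, seg.labels)
    pairs = [(int(gt_ids[i]), int(seg_ids[j]), float(iou[i, j]))
             for i, j in zip(*np.nonzero(iou > 0.5))]
    tp = len(pairs)
    return MatchResult(pairs=pairs, TP=tp, FP=int(seg_ids.size) - tp,
                       FN=int(gt_ids.size) - tp)


def panoptic_quality(m: MatchResult) -> Tuple[float, float, float]:
    """(DQ, SQ, PQ): object-level F1, mean matched IoU, and their product."""
    if m.TP == 0 and m.FP == 0 and m.FN == 0:
        logger.info("panoptic_quality: no objects on either side; scoring (1, 1, 1)")
        return 1.0, 1.0, 1.0
    dq = m.TP / (m.TP + 0.5 * (m.FP + m.FN))
    sq = float(np.mean([iou for _, _, iou in m.pairs])) if m.TP else 0.0
    return dq, sq, dq * sq


def jaccard_index(gt: LabelVolume, seg: LabelVolume) -> float:
    """Mean, over GT nuclei, of the best IoU against any predicted nucleus."""
    if gt.shape != seg.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs seg {seg.shape}")
    gt_ids, seg_ids, _, _, iou, _, _ = _iou_matrix(gt.labels, seg.labels)
    if gt_ids.size == 0:
        raise ValueError("jaccard_index is undefined for an empty ground truth")
    if seg_ids.size == 0:
        return 0.0
    return float(iou.max(axis=1).mean())


def aggregated_jaccard(gt: LabelVolume, seg: LabelVolume) -> float:
    """AJI with the original greedy consumption of predicted objects.

    GT nuclei are visited in ascending label order; each takes the *unused*
    predicted nucleus with the highest IoU (ties to the smaller predicted
    label).  Unmatched GT contribute their full volume to the denominator;
    so do all predictions that end up unused.  The visit-order dependence is
    inherent to the definition and pinned by the fixed ordering.
    """
    if gt.shape != seg.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs seg {seg.shape}")
    gt_ids, seg_ids, inter, union, iou, gt_vol, seg_vol = _iou_matrix(gt.labels, seg.labels)
    if gt_ids.size == 0 and seg_ids.size == 0:
        logger.info("aggregated_jaccard: both volumes empty; scoring 1.0")
        return 1.0
    used = np.zeros(seg_ids.size, dtype=bool)
    num = 0
    den = 0
    for i in range(gt_ids.size):
        cand = np.where(~used & (inter[i] > 0))[0]
        if cand.size == 0:
            den += int(gt_vol[i])
            continue
        j = cand[np.argmax(iou[i, cand])]
        num += int(inter[i, j])
        den += int(union[i, j])
        used[j] = True
    den += int(seg_vol[~used].sum())
    return num / den if den > 0 else 0.0


def nndp(s_num: int, g_num: int) -> float:
    """Nuclei-number difference percentage: 2|S - G| / (S + G) x 100."""
    if s_num + g_num == 0:
        raise ValueError("NNDP undefined when both counts are zero")
    return 200.0 * abs(s_num - g_num) / (s_num + g_num)


def evaluate(gt: LabelVolume, seg_expanded: LabelVolume,
             original_xy: Tuple[int, int], factor: int) -> EvalReport:
    """Collapse an expanded-space segmentation and score it in input space."""
    if gt.space != "input":
        raise ValueError("ground truth must be in input space")
    seg = collapse_to_input_space(seg_expanded, original_xy, factor)
    return evaluate_in_place(gt, seg)


def evaluate_in_place(gt: LabelVolume, seg: LabelVolume) -> EvalReport:
    """Score two label volumes on the same grid."""
    m = match_objects(gt, seg)
    dq, sq, pq = panoptic_quality(m)
    g_num = gt.n_objects
    s_num = seg.n_objects
    ji = jaccard_index(gt, seg) if g_num else float("nan")
    aji = aggregated_jaccard(gt, seg)
    nn = nndp(s_num, g_num) if (s_num + g_num) else 0.0
    return EvalReport(DQ=dq, SQ=sq, PQ=pq, JI=ji, AJI=aji, NNDP=nn,
                      TP=m.TP, FP=m.FP, FN=m.FN, S_num=s_num, G_num=g_num)
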