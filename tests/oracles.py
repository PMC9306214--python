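"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately naive (exhaustive search, elementary iteration,
O(K^2) loops) and shares no code with the package: agreement between the
two routes is the point of the comparison.
"""

from __future__ import annotations

import heapq
from typing import Dict, List, Tuple

import numpy as np


def dt_bruteforce(mask: np.ndarray, z_aniso: float = 1.0) -> np.ndarray:
    """Euclidean DT by exhaustive nearest-background search."""
    out = np.zeros(mask.shape, dtype=np.float64)
    bg = np.argwhere(~mask).astype(np.float64)
    if bg.size == 0:
        return np.full(mask.shape, np.inf)
    scale = np.array([z_aniso, 1.0, 1.0])
    for idx in np.argwhere(mask):
        d = (bg - idx) * scale
        out[tuple(idx)] = np.sqrt((d * d).sum(axis=1).min())
    return out


def _neighbours(shape, idx, connectivity: int = 26):
    z, y, x = idx
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                n = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(n, shape)):
                    yield n


def reconstruct_bruteforce(marker: np.ndarray, mask_img: np.ndarray) -> np.ndarray:
    """Grayscale reconstruction by dilation: iterate elementary geodesic
    dilations (26-connectivity) until stable."""
    rec = np.minimum(marker, mask_img).astype(np.float64)
    coords = list(np.ndindex(rec.shape))
    while True:
        prev = rec.copy()
        for sweep in (coords, coords[::-1]):   # forward then backward raster
            for idx in sweep:
                best = rec[idx]
                for n in _neighbours(rec.shape, idx):
                    if rec[n] > best:
                        best = rec[n]
                if best > rec[idx]:
                    rec[idx] = min(best, mask_img[idx])
        if np.array_equal(prev, rec):
            return rec


def regional_maxima_bruteforce(img: np.ndarray) -> np.ndarray:
    """Plateau-wise regional maxima: a connected component of constant value
    is a maximum iff no voxel in it has a strictly greater neighbour."""
    out = np.zeros(img.shape, dtype=bool)
    seen = np.zeros(img.shape, dtype=bool)
    for start in np.ndindex(img.shape):
        if seen[start]:
            continue
        value = img[start]
        plateau = [start]
        seen[start] = True
        stack = [start]
        is_max = True
        while stack:
            cur = stack.pop()
            for n in _neighbours(img.shape, cur):
                if img[n] == value:
                    if not seen[n]:
                        seen[n] = True
                        plateau.append(n)
                        stack.append(n)
                elif img[n] > value:
                    is_max = False
        if is_max:
            for idx in plateau:
                out[idx] = True
    return out


def hmaxima_markers_bruteforce(mask: np.ndarray, h: float,
                               z_aniso: float = 1.0) -> np.ndarray:
    """Markers = regional maxima of the H-maxima-transformed DT, in the
    foreground, via the iterative reconstruction.  The background is held
    far below every foreground value so the transform acts geodesically
    within each foreground component."""
    dt = dt_bruteforce(mask, z_aniso)
    floor = -(h + float(dt.max()) + 1.0)
    relief = np.where(mask, dt, floor)
    rec = reconstruct_bruteforce(relief - h, relief)
    peaks = regional_maxima_bruteforce(rec) & mask
    return label_components(peaks)


def label_components(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """26-connected component labelling by BFS, labels in raster order."""
    out = np.zeros(mask.shape, dtype=np.int32)
    nxt = 1
    for start in np.ndindex(mask.shape):
        if not mask[start] or out[start]:
            continue
        out[start] = nxt
        stack = [start]
        while stack:
            cur = stack.pop()
            for n in _neighbours(mask.shape, cur, connectivity):
                if mask[n] and not out[n]:
                    out[n] = nxt
                    stack.append(n)
        nxt += 1
    return out


def flood_bruteforce(relief: np.ndarray, mask: np.ndarray,
                     markers: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Priority-flood with (value, insertion age) ordering and raster-order
    seed insertion -- the documented tie policy, via heapq."""
    out = markers.astype(np.int64).copy()
    heap: List[Tuple[float, int, Tuple[int, int, int], int]] = []
    age = 0
    for idx in np.ndindex(relief.shape):
        if out[idx] > 0:
            heapq.heappush(heap, (float(relief[idx]), age, idx, int(out[idx])))
            age += 1
    done = np.zeros(relief.shape, dtype=bool)
    while heap:
        _, _, idx, lab = heapq.heappop(heap)
        if done[idx]:
            continue
        done[idx] = True
        if out[idx] == 0:
            out[idx] = lab
        lab = int(out[idx])
        for n in _neighbours(relief.shape, idx, connectivity):
            if mask[n] and not done[n] and out[n] == 0:
                heapq.heappush(heap, (float(relief[n]), age, n, lab))
                age += 1
    return out


def outer_boundary_bruteforce(labels: np.ndarray, lab: int) -> np.ndarray:
    """Voxels not belonging to ``lab`` that are 26-adjacent to it."""
    own = labels == lab
    out = np.zeros(labels.shape, dtype=bool)
    for idx in np.ndindex(labels.shape):
        if own[idx]:
            continue
        for n in _neighbours(labels.shape, idx):
            if own[n]:
                out[idx] = True
                break
    return out


def metrics_bruteforce(gt: np.ndarray, seg: np.ndarray) -> Dict[str, float]:
    """PQ family, JI, AJI and NNDP via explicit O(K^2) pairwise overlaps."""
    gt_ids = sorted(int(v) for v in np.unique(gt) if v > 0)
    seg_ids = sorted(int(v) for v in np.unique(seg) if v > 0)
    gt_vox = {g: {tuple(i) for i in np.argwhere(gt == g)} for g in gt_ids}
    seg_vox = {s: {tuple(i) for i in np.argwhere(seg == s)} for s in seg_ids}

    def iou(a, b):
        inter = len(a & b)
        union = len(a | b)
        return inter / union if union else 0.0

    pairs = []
    for g in gt_ids:
        for s in seg_ids:
            v = iou(gt_vox[g], seg_vox[s])
            if v > 0.5:
                pairs.append((g, s, v))
    tp = len(pairs)
    fp = len(seg_ids) - tp
    fn = len(gt_ids) - tp
    if tp == fp == fn == 0:
        dq = sq = pq = 1.0
    else:
        dq = tp / (tp + 0.5 * (fp + fn))
        sq = float(np.mean([v for _, _, v in pairs])) if tp else 0.0
        pq = dq * sq

    ji = (float(np.mean([max([iou(gt_vox[g], seg_vox[s]) for s in seg_ids],
                             default=0.0) for g in gt_ids]))
          if gt_ids else float("nan"))

    used = set()
    num = den = 0
    for g in gt_ids:
        cands = [(iou(gt_vox[g], seg_vox[s]), -s) for s in seg_ids
                 if s not in used and len(gt_vox[g] & seg_vox[s]) > 0]
        if not cands:
            den += len(gt_vox[g])
            continue
        best_iou, neg_s = max(cands)
        s = -neg_s
        used.add(s)
        num += len(gt_vox[g] & seg_vox[s])
        den += len(gt_vox[g] | seg_vox[s])
    for s in seg_ids:
        if s not in used:
            den += len(seg_vox[s])
    if not gt_ids and not seg_ids:
        aji = 1.0
    else:
        aji = num / den if den else 0.0

    s_num, g_num = len(seg_ids), len(gt_ids)
    nndp = (200.0 * abs(s_num - g_num) / (s_num + g_num)
            if s_num + g_num else 0.0)
    return {"dq": dq, "sq": sq, "pq": pq, "ji": ji, "aji": aji, "nndp": nndp,
            "tp": tp, "fp": fp, "fn": fn}


def otsu_bruteforce(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search over histogram bin boundaries for the threshold
    maximising between-class variance; returns the bin-center threshold."""
    hist, edges = np.histogram(values.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_t = -1.0, centers[0]
    total = hist.sum()
    for k in range(1, nbins):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_t = (centers[k - 1] + centers[k]) / 2.0
    return float(best_t)
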