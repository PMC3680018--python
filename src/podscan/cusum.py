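"""Bidirectional CUSUM boundary refinement.

Detected regions carry approximate boundaries (window edges retracted to
informative SNPs).  When the region's LRR or mirrored-BAF signal is strong
enough, each boundary is re-estimated with a one-sided CUSUM
S_n = max(0, S_{n-1} + x_n - k) scanned outward from inside the region: the
partial sums climb while the data stay abnormal (x > k) and fall in the
baseline, so the maximum marks the change-point.  The reference value
k = (abnormal median - local baseline median) / 2 balances the slopes on
either side of the peak; for homozygous deletions, whose variance dwarfs
the others, k is capped at 1.5.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .trio_data import AB, NC, Region, TrioDataset, mirrored_baf

logger = logging.getLogger(__name__)

HD_K_CAP = 1.5


def cusum_changepoint(x, k: float):
    """Index of the maximum partial sum of S_n = max(0, S_{n-1} + x_n - k),
    first occurrence on ties; None when every S_n = 0 (no peak)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return None
    # evaluated as the literal recurrence: a cumsum/prefix-min rewrite is
    # algebraically identical but loses small increments to cancellation
    s = 0.0
    best = 0.0
    best_i = None
    for i, v in enumerate(x - k):
        s = s + v
        if s < 0.0:
            s = 0.0
        if s > best:
            best, best_i = s, i
    return best_i


def _moving_median_stop(x: np.ndarray, start: int, step: int, k: float,
                        window: int, min_dist: int, limit: int) -> int:
    """Walk outward from ``start`` (exclusive) in direction ``step`` taking
    moving medians of the trailing ``window`` values; stop once the median
    falls below k, but go at least ``min_dist`` and never past ``limit``.

    Returns the most distant index reached.
    """
    pos = start
    dist = 0
    buf: list[float] = []
    while True:
        nxt = pos + step
        if (step > 0 and nxt > limit) or (step < 0 and nxt < limit):
            return pos if dist > 0 else start
        pos = nxt
        dist += 1
        buf.append(x[pos])
        if len(buf) > window:
            buf.pop(0)
        if dist >= min_dist and len(buf) >= window and np.median(buf) < k:
            return pos
    # unreachable


def _refine_side(x: np.ndarray, inner: int, boundary: int, k: float,
                 side: str, min_dist: int, window: int, limit: int,
                 region_median: float):
    """Refine one boundary.  ``x`` is the centred (and sign-adjusted) value
    sequence; ``inner`` the interior scan origin; ``boundary`` the initial
    boundary; ``limit`` the furthest admissible exterior index.  Returns the
    refined boundary index (in x coordinates)."""
    step = -1 if side == "start" else 1
    stop = _moving_median_stop(x, boundary, step, k, window, min_dist, limit)
    if stop == boundary:
        return boundary  # no baseline available; keep initial value
    # guard: adjacent data as large as the region suggests a distinct
    # abnormality next door; keep the initial boundary
    adj = x[boundary + step: stop + step: step][:window]
    if adj.size and region_median > 0 and np.median(adj) >= 2.0 * region_median:
        return boundary

    seq = x[inner: stop + step: step]  # from inside the region outward
    cp = cusum_changepoint(seq, k)
    if cp is None:
        return boundary
    return inner + step * cp


def region_value_sequence(data: TrioDataset, region: Region, params,
                          base_lrr: float, base_mbaf: float):
    """Pick the CUSUM data channel for a region.

    Returns ``(mode, seq_idx, x, k, region_median)`` where ``mode`` is
    "lrr", "baf" or None (ineligible), ``seq_idx`` are global SNP indices of
    the sequence members, ``x`` the centred, sign-adjusted values and
    ``region_median`` the centred region median.  Eligibility follows the
    threshold rules: LRR when |median - baseline| >= 0.1, else mirrored BAF
    when median - baseline > 0.1.
    """
    s, e = data.arms[region.arm]
    lrr = data.lrr("child")
    reg_lrr = np.median(lrr[region.start_idx:region.end_idx + 1])
    dev_lrr = reg_lrr - base_lrr

    if abs(dev_lrr) >= 0.1:
        sign = 1.0 if dev_lrr >= 0 else -1.0  # reflect negative medians
        x = sign * (lrr[s:e] - base_lrr)
        k = min(abs(dev_lrr) / 2.0, HD_K_CAP)
        if k < HD_K_CAP:
            # stray homozygous-deletion outliers inside a hemizygous
            # deletion must not dominate the partial sums
            x = np.minimum(x, HD_K_CAP)
        return "lrr", np.arange(s, e), x, k, abs(dev_lrr)

    gt = data.gt("child")
    baf = data.baf("child")
    non_hom = (gt == AB) | (gt == NC)
    nh_idx = np.flatnonzero(non_hom[s:e]) + s
    if nh_idx.size == 0:
        return None, None, None, 0.0, 0.0
    mb = mirrored_baf(baf[nh_idx], params.non_hom_center)
    in_reg = (nh_idx >= region.start_idx) & (nh_idx <= region.end_idx)
    if not in_reg.any():
        return None, None, None, 0.0, 0.0
    dev_baf = float(np.median(mb[in_reg])) - base_mbaf
    if dev_baf > 0.1:
        x = mb - base_mbaf
        x = np.minimum(x, dev_baf + 0.1)  # random BAF outliers are ignored
        return "baf", nh_idx, x, dev_baf / 2.0, dev_baf
    return None, None, None, 0.0, 0.0


def refine_region_boundaries(region: Region, data: TrioDataset, params,
                             min_region: int, called_mask: np.ndarray,
                             base_lrr: float, base_mbaf: float,
                             inf: np.ndarray | None = None) -> Region:
    """CUSUM-refine both boundaries of a region when eligible.

    ``params`` is the child's SampleParams; ``called_mask`` marks SNPs
    inside any detected region so the outward scans stop before entering a
    neighbouring abnormality; baselines are the local (arm-level) medians.
    Regions whose LRR and mBAF medians both sit within 0.1 of baseline keep
    their initial boundaries.
    """
    mode, seq_idx, x, k, reg_med = region_value_sequence(
        data, region, params, base_lrr, base_mbaf)
    if mode is None or k <= 0:
        return region

    # region bounds in sequence coordinates
    ra = int(np.searchsorted(seq_idx, region.start_idx, side="left"))
    rb = int(np.searchsorted(seq_idx, region.end_idx, side="right")) - 1
    if rb < ra:
        return region
    i = rb - ra + 1
    if i < 2:
        return region
    if mode == "baf" and i < max(10, 0.05 * region.n_snps):
        # a (nearly) fully homozygous region leaves almost no non-hom
        # sequence members inside it; the channel carries no boundary
        # information and the initial boundaries stand
        return region

    if i == 2:
        s0, e0 = rb, ra
        min_dist = 10
    elif i <= 3 * min_region:
        if mode == "lrr":
            interior = x[ra + 1: rb]
            crit = ra + 1 + int(np.argmax(interior)) if interior.size else (ra + rb) // 2
        else:
            crit = (ra + rb) // 2  # centre sequence member for BAF CUSUM
        s0 = e0 = crit
        min_dist = 5 * i
    else:
        # large regions: start the scans "min inf" informative SNPs inside
        # so an imprecise initial boundary cannot hide the change-point
        s0 = min(ra + min_region, rb)
        e0 = max(rb - min_region, ra)
        if inf is not None:
            code = {"father": 1, "mother": 2}.get(region.parent, 0)
            match = np.flatnonzero(
                inf[region.start_idx:region.end_idx + 1] == code) \
                + region.start_idx
            if match.size >= 2 * min_region:
                g_s0 = match[min_region - 1]
                g_e0 = match[-min_region]
                s0 = min(max(int(np.searchsorted(seq_idx, g_s0)), ra), rb)
                e0 = min(max(int(np.searchsorted(seq_idx, g_e0)), ra), rb)
        min_dist = 25
    window = min(5 * i, 25)

    # exterior scan limits: the arm edge or the nearest neighbouring region
    other = called_mask.copy()
    other[region.start_idx:region.end_idx + 1] = False
    blocked = other[seq_idx]
    left_block = np.flatnonzero(blocked[:ra])
    lo_limit = int(left_block[-1]) + 1 if left_block.size else 0
    right_block = np.flatnonzero(blocked[rb + 1:])
    hi_limit = rb + int(right_block[0]) if right_block.size else seq_idx.size - 1

    new_a = _refine_side(x, s0, ra, k, "start", min_dist, window, lo_limit,
                         reg_med)
    new_b = _refine_side(x, e0, rb, k, "end", min_dist, window, hi_limit,
                         reg_med)
    if new_b < new_a:
        return region
    out = replace(region,
                  start_idx=int(seq_idx[new_a]), end_idx=int(seq_idx[new_b]))
    out.n_snps = out.end_idx - out.start_idx + 1
    return out


def cusum_validation_boundary(baf, het_band=(0.3, 0.7), k: float | None = None):
    """Change-point estimate from the upper half of the heterozygous band.

    ``baf`` is a chromosome-level child BAF track.  The analysed subset
    holds the values at or above the median of the in-band values and below
    the upper band limit; a mosaic split widens that subset's level in the
    abnormal segment.  When ``k`` is not given it is estimated as half the
    90th percentile of the centred subset (an estimate of the abnormal
    deviation).  Returns the index *into the original track* of the
    change-point, or None for a homogeneous (degenerate) chromosome.
    """
    baf = np.asarray(baf, dtype=float)
    band = baf[(baf > het_band[0]) & (baf < het_band[1])]
    if band.size == 0:
        raise ValueError("no heterozygous-band BAF values")
    med = float(np.median(band))
    sel = np.flatnonzero((baf >= med) & (baf < het_band[1]))
    if sel.size == 0:
        raise ValueError("empty BAF subset")
    x = baf[sel] - med
    if k is None:
        k = float(np.percentile(x, 90)) / 2.0
    if k <= 0:
        return None
    # the forward maximum marks an abnormal-to-normal transition; when it
    # sits at the end of the track the abnormality is terminal and the
    # boundary comes from the reversed scan instead
    cp = cusum_changepoint(x, k)
    if cp is None:
        return None
    if cp >= x.size - max(2, int(0.02 * x.size)):
        rcp = cusum_changepoint(x[::-1], k)
        if rcp is None:
            return None
        cp = x.size - 1 - rcp
    return int(sel[cp])
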