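"""Identification of normal chromosome arms.

Sample-specific parameters (BAF band statistics, informative-SNP rates)
must be estimated from chromosome arms free of abnormalities.  Arms are
screened twice: first on the spread of the heterozygous BAF band, then on
the scan statistic of informative SNPs (the largest count found in any
window), each time clustering the per-arm values with k-means (k = 2),
judging the cluster count with the jump method, and discarding the
high-value cluster until a single normal cluster remains.  Outliers beyond
4 SDs of the normal cluster are removed last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trio_data import AB, TrioDataset

logger = logging.getLogger(__name__)


@dataclass
class ArmStats:
    arm: str
    het_baf_sd: float    # NaN when too few heterozygous SNPs
    scan_stat: int = -1
    is_normal: bool = True


def arm_scan_statistic(positions, w: int, arm_length: int) -> int:
    """Largest number of informative SNPs in any window of ``w`` SNPs.

    ``positions`` are informative SNP indices within the arm.  When the
    window exceeds the arm, the total informative count is returned.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    positions = np.sort(np.asarray(positions, dtype=np.int64))
    n = positions.size
    if n == 0:
        return 0
    if w >= arm_length:
        return int(n)
    # window [p_i, p_i + w - 1]: events inside = searchsorted(p_i + w) - i
    hi = np.searchsorted(positions, positions + w, side="left")
    return int((hi - np.arange(n)).max())


def _kmeans_1d(values: np.ndarray):
    """Deterministic 1-D 2-means: centers initialised at min and max."""
    c1, c2 = float(values.min()), float(values.max())
    lab = None
    for _ in range(100):
        new_lab = values > (c1 + c2) / 2
        if lab is not None and np.array_equal(new_lab, lab):
            break
        lab = new_lab
        if lab.any():
            c2 = float(values[lab].mean())
        if (~lab).any():
            c1 = float(values[~lab].mean())
    dist = float(np.mean((values - np.where(lab, c2, c1)) ** 2))
    return lab, dist


def jump_cluster_count(values, y: float) -> int:
    """Optimal cluster count (1 or 2) by the jump method.

    Distortions d_K (mean squared error of K-means fits) are transformed as
    d_K^(-y); the jump J_K is the increase over d_{K-1}^(-y) with the K = 0
    transformed distortion taken as 0, and K* = argmax J_K.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need >= 3 values for jump evaluation")
    d1 = float(np.mean((values - values.mean()) ** 2))
    if d1 == 0.0:
        return 1
    _, d2 = _kmeans_1d(values)
    t1 = d1 ** (-y)
    if d2 == 0.0:
        return 2
    t2 = d2 ** (-y)
    j1 = t1 - 0.0
    j2 = t2 - t1
    return 1 if j1 >= j2 else 2


def _cluster_filter(arm_names: list[str], values: np.ndarray) -> set[str]:
    """Iterative jump-method filtering plus the final 4 SD outlier rule.

    Returns the arm names retained as normal.
    """
    keep = np.ones(values.size, dtype=bool)
    y = 0.5
    while keep.sum() >= 3:
        sub = values[keep]
        if np.ptp(sub) == 0 or jump_cluster_count(sub, y) == 1:
            break
        lab, _ = _kmeans_1d(sub)
        drop_local = lab  # upper-mean cluster; the lower one holds the normals
        if not drop_local.any() or drop_local.all():
            break
        idx = np.flatnonzero(keep)
        keep[idx[drop_local]] = False
        y = 0.475

    # final 4 SD outlier rule; the spread of the normal cluster is taken
    # robustly (scaled MAD) so that any abnormal arms the jump criterion
    # failed to split off cannot widen their own removal bound
    sub = values[keep]
    if sub.size >= 2:
        center = float(np.median(sub))
        sd = 1.4826 * float(np.median(np.abs(sub - center)))
        if sd == 0.0:
            sd = float(sub.std(ddof=1))
        if sd > 0:
            bound = center + 4 * sd
            idx = np.flatnonzero(keep)
            keep[idx[values[idx] > bound]] = False
    return {arm_names[i] for i in np.flatnonzero(keep)}


def detect_normal_arms(data: TrioDataset, member: str, w: int = 100,
                       k_sd: float = 2.0, min_het: int = 20):
    """Two-step normal-arm screen for one trio member.

    Step 1 filters arms on heterozygous BAF SD; provisional BAF thresholds
    are then computed from the survivors, informative SNPs classified, and
    step 2 filters on the per-arm scan statistic.  Returns
    ``(normal_arms, arm_stats)``.  With fewer than 6 informative arms, or
    fewer than 2 survivors, all arms are retained with a logged warning.
    """
    from .pod_core import classify_informative_snps
    from .sample_stats import compute_baf_stats

    gt = data.gt(member)
    baf = data.baf(member)
    stats = []
    for arm, (s, e) in data.arms.items():
        sel = (gt[s:e] == AB) & (baf[s:e] > 0.3) & (baf[s:e] < 0.7)
        het = baf[s:e][sel]
        sd = float(het.std(ddof=1)) if het.size >= min_het else np.nan
        stats.append(ArmStats(arm=arm, het_baf_sd=sd))

    usable = [a for a in stats if np.isfinite(a.het_baf_sd)]
    if len(usable) < 6:
        logger.warning("%s: only %d arms with enough heterozygous SNPs; "
                       "treating all arms as normal", member, len(usable))
        return set(data.arms), stats

    names = [a.arm for a in usable]
    sd_normal = _cluster_filter(names, np.array([a.het_baf_sd for a in usable]))

    # provisional thresholds from SD-surviving arms, then scan statistics
    try:
        params = compute_baf_stats(data, member, sd_normal, k_sd=k_sd)
    except ValueError:
        logger.warning("%s: provisional band estimation failed; all arms kept",
                       member)
        return set(data.arms), stats
    inf = classify_informative_snps(data, params, target=member if member != "child" else "child")
    for a in stats:
        s, e = data.arms[a.arm]
        a.scan_stat = arm_scan_statistic(np.flatnonzero(inf[s:e] != 0), w, e - s)

    sw_normal = _cluster_filter(names, np.array(
        [float(next(x.scan_stat for x in stats if x.arm == n)) for n in names]))

    normal = sd_normal & sw_normal
    for a in stats:
        a.is_normal = a.arm in normal
    if len(normal) < 2:
        logger.warning("%s: fewer than 2 normal arms survived screening; "
                       "falling back to all-arm estimation", member)
        return set(data.arms), stats
    return normal, stats
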