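"""Streak-based detectors: PODhd, PODmi1 and PODcr.

These detectors complement the window-based POD method by looking for runs
(streaks) of adjacent abnormal SNPs: homozygous-deletion SNPs (extreme
negative LRR), single-Mendelian-error (MI1) SNPs, and outlier-BAF SNPs in
regions with too little parental information content ("cryptic" regions).
A streak is significant when it is at least as long as the smallest run
length whose p-value, under the per-SNP background rate of the class, falls
below alpha.  The streak p-value uses the standard run-length approximation
P(m; n, p) = 1 - Q2 * (Q3/Q2)^(n/m - 2).
"""

from __future__ import annotations

import numpy as np

from .pod_core import binom_two_tailed_p
from .sample_stats import mi1_mask, polymorphic_mask
from .trio_data import AA, AB, BB, NC, Region, TrioDataset

NO_STREAK = None


def streak_pvalue(m: int, n: int, p: float) -> float:
    """P-value for observing a streak of >= m successes in n Bernoulli(p)
    trials, by the Q2/Q3 run-length approximation; clipped to [0, 1]."""
    if not 1 <= m <= n:
        raise ValueError("need 1 <= m <= n")
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    q = 1.0 - p
    pm = p ** m
    q2 = 1.0 - pm * (1.0 + m * q)
    q3 = (1.0 - pm * (1.0 + 2.0 * m * q)
          + 0.5 * p ** (2 * m) * (2.0 * m * q + m * (m - 1) * q * q))
    if q2 <= 0.0 or q3 <= 0.0:
        return 1.0  # outside the approximation's domain: streaks near-certain
    # the approximation is built for n >= 3m; shorter sequences clamp the
    # exponent at zero, leaving the (conservative) 2m-trial bound
    expo = max(n / m - 2.0, 0.0)
    pval = 1.0 - q2 * (q3 / q2) ** expo
    return float(min(1.0, max(0.0, pval)))


def min_streak_length(n: int, p: float, alpha: float,
                      m_cap: int = 5000) -> int | None:
    """Smallest streak length m with p-value below alpha, or None when no
    streak up to min(n, m_cap) can reach significance."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if p <= 0.0:
        return 1
    if p >= 1.0:
        return NO_STREAK
    for m in range(1, min(n, m_cap) + 1):
        if streak_pvalue(m, n, p) < alpha:
            return m
    return NO_STREAK


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, end) inclusive index pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    out: list[list[int]] = []
    for a, b in spans:
        if out and a <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(s) for s in out]


def _arm_region(data: TrioDataset, arm: str, start: int, end: int,
                detector: str, parent: str, n_inf: int) -> Region:
    return Region(chrom=arm.rstrip("pq"), arm=arm, start_idx=start,
                  end_idx=end, detector=detector, parent=parent,
                  n_informative=n_inf)


# ---------------------------------------------------------------------------
# PODhd
# ---------------------------------------------------------------------------

def detect_hd_regions(data: TrioDataset, params: dict,
                      hd_lrr_threshold: float = -1.5,
                      alpha: float = 0.1) -> list[Region]:
    """Significant streaks of homozygous-deletion SNPs in any trio member.

    A parental HD streak implies total absence of genetic contribution at
    the locus and is reported as an abnormality of the child carrying that
    parent's identity; overlapping streaks from several members combine.
    """
    n_total = data.n_snps
    member_spans: dict[tuple[int, int], set[str]] = {}
    for member in ("father", "mother", "child"):
        # a zero observed background rate gets one pseudo-count
        p = max(params[member].hd_rate, 1.0 / n_total)
        m_min = min_streak_length(n_total, p, alpha)
        if m_min is NO_STREAK:
            continue
        m_min = max(m_min, 2)
        hd = data.lrr(member) < hd_lrr_threshold
        for arm, (s, e) in data.arms.items():
            for a, b in _runs(hd[s:e]):
                if b - a + 1 >= m_min:
                    member_spans.setdefault((s + a, s + b), set()).add(member)

    if not member_spans:
        return []
    merged = _merge_spans(list(member_spans))
    regions = []
    for a, b in merged:
        members = set()
        for (x, y), who in member_spans.items():
            if x <= b and y >= a:
                members |= who
        parents = members & {"father", "mother"}
        if len(parents) == 1:
            parent = parents.pop()
        elif len(parents) == 2:
            parent = "both"
        else:
            parent = "both"  # HD in the child requires loss from both sides
        arm = data.arm_of(a)
        regions.append(_arm_region(data, arm, a, b, "PODhd", parent, b - a + 1))
    return regions


# ---------------------------------------------------------------------------
# PODmi1
# ---------------------------------------------------------------------------

# excess-parent inference for a homozygous child MI1 call: the parent whose
# allele the child over-represents, when unambiguous
def _mi1_excess_parent(f_gt: np.ndarray, m_gt: np.ndarray,
                       c_gt: np.ndarray) -> np.ndarray:
    """0 = undetermined, 1 = father, 2 = mother."""
    out = np.zeros(c_gt.size, dtype=np.int8)
    for hom, carrier in ((AA, (AA, AB)), (BB, (AB, BB))):
        child_hom = c_gt == hom
        f_has = np.isin(f_gt, carrier)
        m_has = np.isin(m_gt, carrier)
        out[child_hom & f_has & ~m_has] = 1
        out[child_hom & ~f_has & m_has] = 2
    return out


def detect_mi1_regions(data: TrioDataset, params: dict,
                       alpha: float = 0.1) -> list[Region]:
    """Significant streaks of MI1 SNPs along the polymorphic subsequence.

    MI1 SNPs are genotype triples from which a single inheritance error can
    be inferred, augmented by parent-informative combinations whose child
    BAF lies beyond 5 SD of the heterozygous mean.  The run-length model
    uses n = polymorphic SNPs and p = the autosomal MI1 rate.
    """
    cp = params["child"]
    poly = polymorphic_mask(data)
    n_poly = int(poly.sum())
    if n_poly == 0 or cp.mi1_snp_rate >= 1.0:
        return []
    p = max(cp.mi1_snp_rate, 1.0 / n_poly)
    m_min = min_streak_length(n_poly, p, alpha)
    if m_min is NO_STREAK:
        return []
    m_min = max(m_min, 2)

    mi1 = mi1_mask(data, cp.het_mean, cp.het_sd)
    excess = _mi1_excess_parent(data.gt("father"), data.gt("mother"),
                                data.gt("child"))
    regions = []
    for arm, (s, e) in data.arms.items():
        poly_idx = np.flatnonzero(poly[s:e]) + s
        if poly_idx.size == 0:
            continue
        for a, b in _runs(mi1[poly_idx]):
            if b - a + 1 < m_min:
                continue
            g_start, g_end = int(poly_idx[a]), int(poly_idx[b])
            sub = excess[poly_idx[a:b + 1]]
            n_f, n_m = int((sub == 1).sum()), int((sub == 2).sum())
            if n_f > n_m:
                parent = "father"
            elif n_m > n_f:
                parent = "mother"
            else:
                parent = "undetermined"
            regions.append(_arm_region(data, arm, g_start, g_end, "PODmi1",
                                       parent, b - a + 1))
    return regions


# ---------------------------------------------------------------------------
# PODcr
# ---------------------------------------------------------------------------

def detect_cryptic_regions(data: TrioDataset, params: dict,
                           alpha: float = 0.1) -> list[Region]:
    """Streaks of outlier BAF values with a significant up/down asymmetry.

    Candidate streaks of adjacent non-homozygous SNPs whose BAF exceeds the
    heterozygous thresholds are tested for asymmetry between the upper and
    lower band (two-tailed binomial, k = the smaller count); candidates
    rejecting symmetry at the Bonferroni-corrected alpha become PODcr
    regions with parent of origin initially undetermined.
    """
    cp = params["child"]
    poly = polymorphic_mask(data)
    n_poly = int(poly.sum())
    if n_poly == 0 or cp.baf_outlier_rate >= 1.0:
        return []
    p = max(cp.baf_outlier_rate, 1.0 / n_poly)
    m_min = min_streak_length(n_poly, p, alpha)
    if m_min is NO_STREAK:
        return []
    m_min = max(m_min, 2)

    gt = data.gt("child")
    baf = data.baf("child")
    non_hom = (gt == AB) | (gt == NC)
    upper = baf > cp.het_high
    lower = baf < cp.het_low

    candidates = []
    for arm, (s, e) in data.arms.items():
        nh_idx = np.flatnonzero(non_hom[s:e]) + s
        if nh_idx.size == 0:
            continue
        out_sub = (upper | lower)[nh_idx]
        for a, b in _runs(out_sub):
            if b - a + 1 >= m_min:
                candidates.append((arm, nh_idx[a:b + 1]))
    if not candidates:
        return []

    corr = alpha / len(candidates)
    regions = []
    for arm, idx in candidates:
        n_up = int(upper[idx].sum())
        n_lo = int(lower[idx].sum())
        k = min(n_up, n_lo)
        if binom_two_tailed_p(k, n_up + n_lo, 0.5) < corr:
            regions.append(_arm_region(data, arm, int(idx[0]), int(idx[-1]),
                                       "PODcr", "undetermined", idx.size))
    return regions
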