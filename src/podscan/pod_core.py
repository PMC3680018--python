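"""The parent-of-origin detection (POD) method.

At a SNP where the parental genotype combination is informative, an outlying
child BAF reveals excess contribution from one specific parent.  In a region
of normal biparental inheritance the parent indicated by successive
informative SNPs is a fair coin; a run of windows skewed toward one parent
is therefore detectable with a two-tailed binomial test at p = 0.5.

Because tests are applied to heavily overlapping windows, the familywise
error rate (FWER) is controlled with a scan-statistics construction: the
expected number of windows containing k informative SNPs, E(W_k), converts a
candidate per-test threshold beta into a genome-wide type-I error bound
P_FWER(beta), and the largest beta keeping that bound under alpha is used
for the window tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .trio_data import AA, AB, BB, NC, Region

PATERNAL, MATERNAL = 1, 2
_PARENT_NAME = {PATERNAL: "father", MATERNAL: "mother"}


# ---------------------------------------------------------------------------
# informative-SNP classification
# ---------------------------------------------------------------------------

def informative_genotype_mask(f_gt: np.ndarray, m_gt: np.ndarray) -> np.ndarray:
    """Parental genotype combinations that can render a child SNP
    informative (either direction), regardless of the child BAF."""
    r1 = ((f_gt == AA) | (f_gt == AB) | (f_gt == NC)) & (m_gt == BB)
    r2 = ((f_gt == AB) | (f_gt == BB) | (f_gt == NC)) & (m_gt == AA)
    r3 = (f_gt == AA) & ((m_gt == AB) | (m_gt == BB) | (m_gt == NC))
    r4 = (f_gt == BB) & ((m_gt == AA) | (m_gt == AB) | (m_gt == NC))
    return r1 | r2 | r3 | r4


def classify_informative_snps(data, params, target: str = "child") -> np.ndarray:
    """Classify every SNP as uninformative (0), indicating abnormal paternal
    contribution (1), or abnormal maternal contribution (2).

    For ``target="child"`` the parental genotype pair must match an
    informative combination and the child BAF must cross the heterozygous
    outlier threshold in the direction given by the combination.  For a
    parental target the roles are inverted: the child's genotype anchors the
    expectation and the parent's own BAF is tested (codes 1/2 then mean
    upward/downward deviation).

    ``params`` is the SampleParams of the *target* member; per-arm local
    thresholds are used where available.
    """
    n = data.n_snps
    low = np.full(n, params.het_low)
    high = np.full(n, params.het_high)
    for arm, (s, e) in data.arms.items():
        lo, hi = params.thresholds_for(arm)
        low[s:e] = lo
        high[s:e] = hi

    if target == "child":
        f_gt, m_gt = data.gt("father"), data.gt("mother")
        baf = data.baf("child")
        down, up = baf < low, baf > high
        out = np.zeros(n, dtype=np.int8)
        pat = ((((f_gt == AA) | (f_gt == AB) | (f_gt == NC)) & (m_gt == BB) & down)
               | (((f_gt == AB) | (f_gt == BB) | (f_gt == NC)) & (m_gt == AA) & up))
        mat = (((f_gt == AA) & ((m_gt == AB) | (m_gt == BB) | (m_gt == NC)) & up)
               | ((f_gt == BB) & ((m_gt == AA) | (m_gt == AB) | (m_gt == NC)) & down))
        out[pat] = PATERNAL
        out[mat] = MATERNAL
        return out

    if target not in ("father", "mother"):
        raise ValueError(f"unknown target {target!r}")
    other = "mother" if target == "father" else "father"
    c_gt = data.gt("child")
    o_gt = data.gt(other)
    baf = data.baf(target)
    down, up = baf < low, baf > high
    out = np.zeros(n, dtype=np.int8)
    up_mask = (((c_gt == AB) & (o_gt == BB))
               | ((c_gt == AA) & ((o_gt == AA) | (o_gt == AB) | (o_gt == NC))))
    down_mask = (((c_gt == AB) & (o_gt == AA))
                 | ((c_gt == BB) & ((o_gt == AB) | (o_gt == BB) | (o_gt == NC))))
    out[up_mask & up] = 1
    out[down_mask & down] = 2
    return out


# ---------------------------------------------------------------------------
# binomial tests
# ---------------------------------------------------------------------------

def binom_two_tailed_p(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-tailed binomial p-value, evaluated piecewise as symmetric
    tail sums; returns 1 when k = n/2 or n = 0."""
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if n == 0 or 2 * k == n:
        return 1.0
    if 2 * k < n:
        lo, hi = k, n - k
    else:
        lo, hi = n - k, k
    return float(min(1.0, binom.cdf(lo, n, p) + binom.sf(hi - 1, n, p)))


def _two_tailed_half(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorised two-tailed p-values at p = 0.5."""
    k = np.asarray(k)
    n = np.asarray(n)
    lo = np.minimum(k, n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        pv = binom.cdf(lo, n, 0.5) + binom.sf(n - lo - 1, n, 0.5)
    pv = np.where((n == 0) | (2 * lo == n), 1.0, pv)
    return np.minimum(pv, 1.0)


# ---------------------------------------------------------------------------
# FWER threshold
# ---------------------------------------------------------------------------

NO_THRESHOLD = None


@dataclass
class FwerContext:
    """Scan-statistics FWER machinery for one window size."""

    M: int                      # total SNPs
    N: int                      # total informative SNPs
    w: int                      # window size in SNPs
    alpha: float
    beta: float | None = None   # selected per-window significance threshold
    min_region: int = 0         # smallest k with P(k; k, 0.5) <= beta
    p_fwer: float = 1.0         # bound achieved at beta
    ew: np.ndarray = field(default=None, repr=False)  # E(W_k), k = 1..K

    @property
    def usable(self) -> bool:
        return self.beta is not None


def expected_windows(M: int, N: int, w: int) -> np.ndarray:
    """E(W_k) for k = 1..min(w, N): expected number of w-SNP windows
    containing at least k of the N informative SNPs scattered over M."""
    kmax = min(w, N)
    k = np.arange(1, kmax + 1)
    # sum_{i=k-1}^{N} B(i; N, w/M) = sf(k-2)
    tail = binom.sf(k - 2, N, min(1.0, w / M))
    return (N - k + 1) * tail


def fwer_beta_threshold(M: int, N: int, w: int, alpha: float) -> FwerContext:
    """Select the window-test threshold beta controlling the FWER at alpha.

    Candidate thresholds are beta_k = P(k; k, 0.5) for increasing k (the
    smallest achievable p-value of a window with k informative SNPs); the
    first candidate whose P_FWER bound falls below alpha is selected.
    Returns a context with ``beta=None`` when N = 0 (no informative SNPs,
    POD analysis impossible).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if N > M or w > M:
        raise ValueError("need N <= M and w <= M")
    if N <= 0:
        return FwerContext(M=M, N=N, w=w, alpha=alpha)

    kmax = min(w, N)
    ew = expected_windows(M, N, w)
    n_k = np.rint(ew).astype(np.int64)
    # the printed bound uses E(W_k) as a binomial index; fractional
    # expectations below 1 count as a single window unless negligible
    n_k[(ew < 1.0) & (ew > 0.01)] = 1
    n_k[ew <= 0.01] = 0

    # per k, the attainable two-tailed p-values P(j; k, 0.5), sorted
    pvals = [np.unique(_two_tailed_half(np.arange(kk + 1), np.full(kk + 1, kk)))
             for kk in range(1, kmax + 1)]

    def p_fwer(beta: float) -> float:
        total = 0.0
        for kk in range(kmax):
            nk = n_k[kk]
            if nk == 0:
                continue
            pv = pvals[kk]
            j = np.searchsorted(pv, beta, side="right")
            if j == 0:
                continue  # gamma_k = 0: no admissible p-value at this k
            gamma = pv[j - 1]
            # sum_{i=1}^{nk} B(i; nk, gamma) = 1 - (1-gamma)^nk
            if gamma >= 1.0:
                total += 1.0
            else:
                total += -np.expm1(nk * np.log1p(-gamma))
        return total

    for k in range(1, kmax + 1):
        beta_k = binom_two_tailed_p(k, k, 0.5)
        bound = p_fwer(beta_k)
        if bound < alpha:
            return FwerContext(M=M, N=N, w=w, alpha=alpha, beta=beta_k,
                               min_region=k, p_fwer=bound, ew=ew)
    raise ValueError(
        f"no candidate threshold controls the FWER at alpha={alpha} "
        f"(M={M}, N={N}, w={w})")


# ---------------------------------------------------------------------------
# region detection
# ---------------------------------------------------------------------------

def detect_pod_regions(inf: np.ndarray, ctx: FwerContext, e: float,
                       alpha: float = 0.1, offset: int = 0,
                       chrom: str = "?", arm: str = "?") -> list[Region]:
    """Scan one chromosome arm for regions of skewed parental contribution.

    ``inf`` is the per-SNP informative code array of the arm (0 / paternal /
    maternal).  Windows of ``ctx.w`` SNPs slide in single-SNP steps; windows
    whose two-tailed binomial p-value falls at or below ``ctx.beta`` seed
    abnormal regions.  Overlapping significant windows merge; nearby
    clusters also merge when the one-tailed opposite-parent error test (each
    window SNP a Bernoulli(e) trial) never rejects in between, mirroring
    region expansion until evidence of a change-point.  Each merged region
    is retracted to the end of its last significant window and then to the
    first/last informative SNP matching its parent.

    ``offset`` translates arm-local indices to global ones; ``e`` is the
    estimated per-SNP genotyping error rate.
    """
    if not ctx.usable:
        return []
    inf = np.asarray(inf, dtype=np.int8)
    L = inf.size
    if L == 0:
        return []
    w = min(ctx.w, L)

    cp = np.concatenate([[0], np.cumsum(inf == PATERNAL)])
    cm = np.concatenate([[0], np.cumsum(inf == MATERNAL)])
    starts = np.arange(L - w + 1)
    n_pat = cp[starts + w] - cp[starts]
    n_mat = cm[starts + w] - cm[starts]
    n = n_pat + n_mat

    pval = _two_tailed_half(n_pat, n)
    sig = np.flatnonzero(pval <= ctx.beta)
    if sig.size == 0:
        return []
    win_parent = np.where(n_pat >= n_mat, PATERNAL, MATERNAL)

    # one-tailed termination test per window, for each candidate parent:
    # success = SNP informative for the opposite parent, probability e
    term = {
        PATERNAL: binom.sf(n_mat - 1, w, e),
        MATERNAL: binom.sf(n_pat - 1, w, e),
    }

    # cluster overlapping significant windows of the same parent
    clusters: list[list[int]] = []  # [first_start, last_start, parent]
    for s in sig:
        par = int(win_parent[s])
        if clusters and s - clusters[-1][1] <= w and clusters[-1][2] == par:
            clusters[-1][1] = s
        else:
            clusters.append([int(s), int(s), par])

    # merge clusters when extension crosses the gap without the error test
    # rejecting (no barrier window in between)
    merged: list[list[int]] = []
    for cl in clusters:
        if merged and merged[-1][2] == cl[2]:
            gap = term[cl[2]][merged[-1][1] + 1: cl[0]]
            if gap.size == 0 or not np.any(gap <= alpha):
                merged[-1][1] = cl[1]
                continue
        merged.append(cl)

    regions = []
    for first, last, par in merged:
        a, b = first, min(last + w - 1, L - 1)
        match = np.flatnonzero(inf[a:b + 1] == par)
        if match.size == 0:
            continue
        a2, b2 = a + match[0], a + match[-1]
        regions.append(Region(
            chrom=chrom, arm=arm,
            start_idx=offset + a2, end_idx=offset + b2,
            detector="POD", parent=_PARENT_NAME[par],
            n_informative=int(match.size),
        ))
    return regions


def uncalled_segments(arms: dict, regions: list[Region]) -> list[tuple[str, int, int]]:
    """Maximal (arm, start, end) index ranges not covered by any region."""
    out = []
    for arm, (s, e) in arms.items():
        covered = sorted((max(s, r.start_idx), min(e - 1, r.end_idx))
                         for r in regions
                         if r.start_idx < e and r.end_idx >= s)
        cur = s
        for a, b in covered:
            if a > cur:
                out.append((arm, cur, a - 1))
            cur = max(cur, b + 1)
        if cur <= e - 1:
            out.append((arm, cur, e - 1))
    return out


def large_window_rescan(inf: np.ndarray, segments: list[tuple[str, int, int]],
                        ctx: FwerContext, e: float, alpha: float = 0.1,
                        chrom_of=None) -> list[Region]:
    """Rescan still-normal segments with the enlarged window context.

    Segments shorter than the large window are skipped.  ``segments`` are
    (arm, start_idx, end_idx) index ranges from :func:`uncalled_segments`;
    ``chrom_of`` maps an arm label to its chromosome.
    """
    if not ctx.usable:
        return []
    regions = []
    for arm, s, e_idx in segments:
        if e_idx - s + 1 < ctx.w:
            continue
        chrom = chrom_of(arm) if chrom_of else arm.rstrip("pq")
        regions.extend(detect_pod_regions(
            inf[s:e_idx + 1], ctx, e, alpha=alpha, offset=s,
            chrom=chrom, arm=arm))
    return regions
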