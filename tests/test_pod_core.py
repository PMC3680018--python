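import math
from fractions import Fraction

import numpy as np
import pytest

from podscan.pod_core import (FwerContext, binom_two_tailed_p,
                              classify_informative_snps, detect_pod_regions,
                              expected_windows, fwer_beta_threshold,
                              large_window_rescan, uncalled_segments)
from podscan.sample_stats import SampleParams


# ---------------------------------------------------------------------------
# exact-fraction oracle for the two-tailed binomial test
# ---------------------------------------------------------------------------

def _pmf(i, n, p=Fraction(1, 2)):
    return math.comb(n, i) * p ** i * (1 - p) ** (n - i)


def _two_tailed_oracle(k, n):
    if n == 0 or 2 * k == n:
        return Fraction(1)
    lo, hi = min(k, n - k), max(k, n - k)
    return sum(_pmf(i, n) for i in range(lo + 1)) + \
        sum(_pmf(i, n) for i in range(hi, n + 1))


class TestBinomTwoTailed:
    def test_matches_exact_enumeration_up_to_n12(self):
        for n in range(13):
            for k in range(n + 1):
                exact = float(_two_tailed_oracle(k, n))
                assert binom_two_tailed_p(k, n, 0.5) == pytest.approx(
                    min(1.0, exact), abs=1e-12)

    def test_center_is_one(self):
        assert binom_two_tailed_p(2, 4, 0.5) == 1.0

    def test_tails(self):
        assert binom_two_tailed_p(0, 4, 0.5) == pytest.approx(0.125)
        assert binom_two_tailed_p(4, 4, 0.5) == pytest.approx(0.125)

    def test_n_zero(self):
        assert binom_two_tailed_p(0, 0, 0.5) == 1.0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            binom_two_tailed_p(5, 4, 0.5)


# ---------------------------------------------------------------------------
# brute-force FWER oracle (independent nested-loop implementation)
# ---------------------------------------------------------------------------

def _fwer_oracle(M, N, w, alpha):
    from scipy.stats import binom as B
    kmax = min(w, N)
    ew = {}
    for k in range(1, kmax + 1):
        ew[k] = (N - k + 1) * sum(B.pmf(i, N, w / M)
                                  for i in range(k - 1, N + 1))

    def p_fwer(beta):
        total = 0.0
        for k in range(1, kmax + 1):
            e = ew[k]
            n_k = round(e)
            if e < 1.0:
                n_k = 1 if e > 0.01 else 0
            if n_k == 0:
                continue
            admissible = [float(_two_tailed_oracle(j, k))
                          for j in range(k + 1)]
            admissible = [p for p in admissible if p <= beta]
            if not admissible:
                continue
            gamma = max(admissible)
            total += sum(B.pmf(i, n_k, gamma) for i in range(1, n_k + 1))
        return total

    for k in range(1, kmax + 1):
        beta_k = float(_two_tailed_oracle(k, k))
        if p_fwer(beta_k) < alpha:
            return beta_k, k
    raise AssertionError("oracle found no threshold")


class TestFwerThreshold:
    def test_against_brute_force_oracle(self):
        M, N, w, alpha = 10_000, 1_000, 100, 0.05
        beta_o, k_o = _fwer_oracle(M, N, w, alpha)
        ctx = fwer_beta_threshold(M, N, w, alpha)
        assert ctx.beta == pytest.approx(beta_o, rel=1e-9)
        assert ctx.min_region == k_o
        assert ctx.p_fwer < alpha

    def test_small_problem_against_oracle(self):
        beta_o, k_o = _fwer_oracle(2_000, 150, 50, 0.1)
        ctx = fwer_beta_threshold(2_000, 150, 50, 0.1)
        assert ctx.beta == pytest.approx(beta_o, rel=1e-9)
        assert ctx.min_region == k_o

    def test_lenient_alpha_small_problem(self):
        # with a near-unity alpha an early candidate passes; the exact stop
        # is checked against the brute-force oracle
        beta_o, k_o = _fwer_oracle(1_000, 5, 100, 0.9999)
        ctx = fwer_beta_threshold(1_000, 5, 100, 0.9999)
        assert ctx.beta == pytest.approx(beta_o)
        assert ctx.min_region == k_o
        assert ctx.beta >= 0.25

    def test_no_informative_sentinel(self):
        ctx = fwer_beta_threshold(1_000, 0, 100, 0.05)
        assert not ctx.usable

    def test_expected_windows_shape(self):
        ew = expected_windows(10_000, 500, 100)
        assert len(ew) == 100
        assert (ew >= 0).all()


# ---------------------------------------------------------------------------
# informative-SNP classification
# ---------------------------------------------------------------------------

def _one_snp_dataset(f_gt, m_gt, c_baf):
    import pandas as pd
    from podscan.trio_data import TrioDataset
    code = {"AA": 0, "AB": 1, "BB": 2, "NC": 3}
    df = pd.DataFrame({
        "name": ["s0"], "chrom": ["1"], "pos": [100],
        "f_gt": np.int8(code[f_gt]), "f_baf": 0.5, "f_lrr": 0.0,
        "m_gt": np.int8(code[m_gt]), "m_baf": 0.5, "m_lrr": 0.0,
        "c_gt": np.int8(1), "c_baf": float(c_baf), "c_lrr": 0.0,
    })
    return TrioDataset(df, {"1p": (0, 1)})


PARAMS = SampleParams(het_low=0.44, het_high=0.56)


@pytest.mark.parametrize("f,m,baf,expected", [
    ("AA", "BB", 0.40, 1),   # depressed BAF, opposite homozygotes: paternal
    ("AA", "BB", 0.60, 2),   # elevated: maternal
    ("AA", "AB", 0.60, 2),   # hom x het, elevated: maternal
    ("AB", "AA", 0.60, 1),   # elevated with M=AA: paternal
    ("BB", "AB", 0.40, 2),   # depressed with F=BB: maternal
    ("NC", "BB", 0.40, 1),   # NC parent keeps the combination usable
    ("AB", "AB", 0.40, 0),   # double het: never informative
    ("AA", "BB", 0.50, 0),   # in-band BAF: not an outlier
    ("AA", "AA", 0.60, 0),   # same homozygotes: ambiguous, uninformative
])
def test_child_classification_rows(f, m, baf, expected):
    data = _one_snp_dataset(f, m, baf)
    assert classify_informative_snps(data, PARAMS)[0] == expected


@pytest.mark.parametrize("c,other,baf,expected", [
    ("AB", "BB", 0.60, 1),   # child AB, other parent BB, target BAF up
    ("AB", "AA", 0.40, 2),   # down
    ("AA", "AB", 0.60, 1),
    ("BB", "AB", 0.40, 2),
    ("AB", "AB", 0.60, 0),
])
def test_parental_classification_rows(c, other, baf, expected):
    import pandas as pd
    from podscan.trio_data import TrioDataset
    code = {"AA": 0, "AB": 1, "BB": 2, "NC": 3}
    df = pd.DataFrame({
        "name": ["s0"], "chrom": ["1"], "pos": [100],
        "f_gt": np.int8(0), "f_baf": float(baf), "f_lrr": 0.0,
        "m_gt": np.int8(code[other]), "m_baf": 0.5, "m_lrr": 0.0,
        "c_gt": np.int8(code[c]), "c_baf": 0.5, "c_lrr": 0.0,
    })
    data = TrioDataset(df, {"1p": (0, 1)})
    assert classify_informative_snps(data, PARAMS, target="father")[0] == expected


# ---------------------------------------------------------------------------
# region detection
# ---------------------------------------------------------------------------

def _null_inf(rng, n, rate=0.01):
    inf = np.zeros(n, dtype=np.int8)
    hits = rng.random(n) < rate
    inf[hits] = rng.integers(1, 3, int(hits.sum()))
    return inf


class TestDetectPodRegions:
    def test_planted_paternal_run(self):
        rng = np.random.default_rng(0)
        inf = _null_inf(rng, 10_000)
        inf[4000:5000] = 0
        plant = 4000 + np.sort(rng.choice(1000, 200, replace=False))
        inf[plant] = 1
        ctx = fwer_beta_threshold(10_000, int((inf != 0).sum()), 100, 0.05)
        regions = detect_pod_regions(inf, ctx, e=0.004, alpha=0.05)
        assert len(regions) == 1
        r = regions[0]
        assert r.parent == "father"
        assert r.start_idx >= 3900 and r.end_idx <= 5100
        assert r.end_idx - r.start_idx > 800

    def test_balanced_null_mostly_clean(self):
        calls = 0
        n_sims = 40
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            inf = _null_inf(rng, 20_000)
            ctx = fwer_beta_threshold(20_000, int((inf != 0).sum()), 100, 0.05)
            if detect_pod_regions(inf, ctx, e=0.004, alpha=0.05):
                calls += 1
        assert calls / n_sims <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_unusable_context_returns_empty(self):
        ctx = FwerContext(M=100, N=0, w=10, alpha=0.05)
        assert detect_pod_regions(np.zeros(100, np.int8), ctx, 0.01) == []

    def test_boundaries_near_plant(self):
        # pre-refinement boundaries stay within a window of the truth
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            inf = _null_inf(rng, 10_000, rate=0.008)
            idx = 3000 + np.flatnonzero(rng.random(2000) < 0.15)
            inf[idx] = 2
            ctx = fwer_beta_threshold(10_000, int((inf != 0).sum()), 100, 0.05)
            regions = detect_pod_regions(inf, ctx, e=0.004, alpha=0.05)
            assert regions, f"seed {seed}: plant not detected"
            start = min(r.start_idx for r in regions)
            end = max(r.end_idx for r in regions)
            assert abs(start - 3000) <= 100 + 60
            assert abs(end - 4999) <= 100 + 60


class TestLargeWindowRescan:
    def test_low_level_plant_found_only_at_large_window(self):
        rng = np.random.default_rng(3)
        inf = _null_inf(rng, 30_000, rate=0.008)
        idx = 10_000 + np.flatnonzero(rng.random(8000) < 0.030)
        inf[idx] = 1
        N = int((inf != 0).sum())
        ctx_s = fwer_beta_threshold(30_000, N, 100, 0.05)
        ctx_l = fwer_beta_threshold(30_000, N, 500, 0.05)
        arms = {"1q": (0, 30_000)}
        small = detect_pod_regions(inf, ctx_s, e=0.004, alpha=0.05)
        segs = uncalled_segments(arms, small)
        large = large_window_rescan(inf, segs, ctx_l, e=0.004, alpha=0.05)
        covered = np.zeros(30_000, bool)
        for r in small + large:
            covered[r.start_idx:r.end_idx + 1] = True
        assert covered[10_000:18_000].mean() > 0.6
        assert large, "large-window pass contributed nothing"

    def test_short_segments_skipped(self):
        ctx = fwer_beta_threshold(1_000, 100, 500, 0.5)
        out = large_window_rescan(np.ones(300, np.int8),
                                  [("1p", 0, 299)], ctx, 0.01)
        assert out == []

    def test_all_called_returns_empty(self):
        segs = uncalled_segments({"1p": (0, 100)}, [
            __import__("podscan.trio_data", fromlist=["Region"]).Region(
                chrom="1", arm="1p", start_idx=0, end_idx=99)])
        assert segs == []
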