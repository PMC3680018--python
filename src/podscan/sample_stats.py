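"""Per-sample parameter estimation.

Every statistical test downstream depends on sample-specific quantities
estimated from chromosome arms believed to be normal: the centre and spread
of the heterozygous BAF band, outlier thresholds, the no-call and Mendelian
inconsistency (MI1) rates, and the derived per-SNP genotyping error rate
``e``.

The error rate uses the fact that only a fraction of single genotyping
errors in a trio are visible as a Mendelian inconsistency.  Exhaustive
enumeration over the 15 Mendelian-consistent genotype triples shows that the
90 possible single-genotype-error events collapse onto 24 distinct
detectable (observed triple, inferable erring member) combinations, so the
overall error rate is estimated as 90/24 = 3.75 times the observed MI1 rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .trio_data import AA, AB, BB, NC, TrioDataset

GENOTYPES = ("AA", "AB", "BB")


# ---------------------------------------------------------------------------
# error-model enumeration
# ---------------------------------------------------------------------------

def _mendelian_consistent(f: str, m: str, c: str) -> bool:
    """Child can receive one allele from each parent."""
    return any(sorted(a + b) == sorted(c) for a in set(f) for b in set(m))


def mendelian_consistent_triples() -> list[tuple[str, str, str]]:
    """The 15 (father, mother, child) genotype triples over {AA, AB, BB}
    compatible with biparental inheritance."""
    return [t for t in product(GENOTYPES, repeat=3) if _mendelian_consistent(*t)]


def enumerate_single_error_combinations() -> tuple[int, int, float]:
    """Enumerate single-genotype-error trio combinations.

    Returns ``(n_err, n_mi1, ratio)`` where ``n_err`` counts every way of
    replacing one member's genotype in a Mendelian-consistent triple with a
    different genotype, and ``n_mi1`` counts the distinct detectable
    outcomes: pairs of (Mendelian-inconsistent observed triple, member whose
    single error can explain it).
    """
    consistent = mendelian_consistent_triples()
    n_err = 0
    detectable: set[tuple[tuple[str, str, str], int]] = set()
    for triple in consistent:
        for member in range(3):
            for alt in GENOTYPES:
                if alt == triple[member]:
                    continue
                mutated = list(triple)
                mutated[member] = alt
                mutated = tuple(mutated)
                n_err += 1
                if not _mendelian_consistent(*mutated):
                    detectable.add((mutated, member))
    n_mi1 = len(detectable)
    return n_err, n_mi1, n_err / n_mi1


ERROR_RATE_FACTOR = 3.75  # = 90 / 24, cross-checked by the enumeration test


def estimate_error_rate(mi1_rate: float) -> float:
    """Per-SNP genotyping error probability from the observed MI1 rate."""
    if mi1_rate < 0:
        raise ValueError("MI1 rate must be non-negative")
    return min(1.0, ERROR_RATE_FACTOR * mi1_rate)


# ---------------------------------------------------------------------------
# MI1 classification
# ---------------------------------------------------------------------------

# Lookup over genotype-code triples (4**3): 1 if the called triple is a
# Mendelian inconsistency inferable as a single error.  Triples involving NC
# are never MI1 (nothing can be inferred).
_MI1_TABLE = np.zeros((4, 4, 4), dtype=bool)
_HET_MI1_TABLE = np.zeros((4, 4, 4), dtype=bool)
_code = {"AA": AA, "AB": AB, "BB": BB}
for _f, _m, _c in product(GENOTYPES, repeat=3):
    if not _mendelian_consistent(_f, _m, _c):
        _MI1_TABLE[_code[_f], _code[_m], _code[_c]] = True
        if _c == "AB":
            # novel allele in the child (e.g. AA, AA, AB)
            _HET_MI1_TABLE[_code[_f], _code[_m], _code[_c]] = True


def mi1_mask(data: TrioDataset, het_mean: float | None = None,
             het_sd: float | None = None, n_sd: float = 5.0) -> np.ndarray:
    """Per-SNP MI1 indicator from the called genotype triples.

    When ``het_mean``/``het_sd`` are given, parent-informative genotype
    combinations whose child BAF lies more than ``n_sd`` SDs from the
    heterozygous mean are also counted as MI1 (inference from BAF).
    """
    f, m, c = data.gt("father"), data.gt("mother"), data.gt("child")
    out = _MI1_TABLE[f, m, c].copy()
    if het_mean is not None and het_sd is not None and het_sd > 0:
        # BAF-based inference only where the child is an obligate
        # heterozygote (opposite homozygous parents); elsewhere an extreme
        # BAF is compatible with a legitimate homozygous child
        obligate = (((f == AA) & (m == BB)) | ((f == BB) & (m == AA)))
        baf = data.baf("child")
        out |= obligate & (np.abs(baf - het_mean) > n_sd * het_sd)
    return out


def het_mi1_mask(data: TrioDataset) -> np.ndarray:
    """MI1 calls in which the child carries a novel heterozygous allele."""
    return _HET_MI1_TABLE[data.gt("father"), data.gt("mother"), data.gt("child")]


def polymorphic_mask(data: TrioDataset) -> np.ndarray:
    """SNPs showing allelic variation within the trio (not all three members
    the same homozygous call; NC ignored)."""
    gts = np.stack([data.gt(m) for m in ("father", "mother", "child")])
    called = gts != NC
    any_het = ((gts == AB) & called).any(axis=0)
    has_a = ((gts == AA) & called).any(axis=0)
    has_b = ((gts == BB) & called).any(axis=0)
    return any_het | (has_a & has_b)


# ---------------------------------------------------------------------------
# BAF band statistics
# ---------------------------------------------------------------------------

@dataclass
class SampleParams:
    """BAF band statistics, thresholds and informative-SNP rates for one
    trio member."""

    member: str = "child"
    het_mean: float = 0.5
    het_sd: float = 0.03
    het_low: float = 0.44
    het_high: float = 0.56
    hom_low: float = 0.05     # upper threshold of the A-homozygous band
    hom_high: float = 0.95    # lower threshold of the B-homozygous band
    k_sd: float = 2.0
    non_hom_center: float = 0.5
    nc_rate: float = 0.0
    mi1_rate: float = 0.0       # genotype-only, for the quality gate
    mi1_snp_rate: float = 0.0   # BAF-augmented, non-adjacent, normal arms
    het_mi1_rate: float = 0.0
    hd_rate: float = 0.0
    baf_outlier_rate: float = 0.0
    error_rate: float = 0.0
    degenerate: bool = False
    # per-arm local overrides: arm -> (het_mean, het_sd)
    arm_het: dict = field(default_factory=dict)

    def thresholds_for(self, arm: str | None = None) -> tuple[float, float]:
        """(low, high) heterozygous outlier thresholds, arm-local if known."""
        if arm is not None and arm in self.arm_het:
            mean, sd = self.arm_het[arm]
            return mean - self.k_sd * sd, mean + self.k_sd * sd
        return self.het_low, self.het_high


def compute_baf_stats(data: TrioDataset, member: str,
                      normal_arms: set[str] | None = None,
                      k_sd: float = 2.0,
                      min_het: int = 100,
                      mask: np.ndarray | None = None) -> SampleParams:
    """Estimate the BAF band statistics of one member from normal arms.

    ``mask`` optionally excludes SNPs (e.g. inside detected regions) from
    the estimation.  Raises if fewer than ``min_het`` heterozygous SNPs are
    available, which indicates a data-quality failure.
    """
    baf = data.baf(member)
    gt = data.gt(member)
    sel = np.zeros(data.n_snps, dtype=bool)
    if normal_arms is None:
        sel[:] = True
    else:
        for arm in normal_arms:
            sel[data.arm_slice(arm)] = True
    if mask is not None:
        sel &= mask

    # genotyping errors put homozygous BAF values into the AB class; band
    # statistics are therefore taken inside the heterozygous window
    het = sel & (gt == AB) & (baf > 0.3) & (baf < 0.7)
    if het.sum() < min_het:
        raise ValueError(
            f"{member}: only {int(het.sum())} heterozygous SNPs on normal "
            f"arms (< {min_het}); data quality insufficient for band estimation")
    het_mean = float(baf[het].mean())
    het_sd = float(baf[het].std(ddof=1))

    hom_a = sel & (gt == AA)
    hom_b = sel & (gt == BB)
    hom_a_thr = float(baf[hom_a].mean() + k_sd * baf[hom_a].std(ddof=1)) if hom_a.sum() > 1 else 0.05
    hom_b_thr = float(baf[hom_b].mean() - k_sd * baf[hom_b].std(ddof=1)) if hom_b.sum() > 1 else 0.95

    non_hom = sel & ((gt == AB) | (gt == NC))
    non_hom_center = float(baf[non_hom].mean()) if non_hom.any() else 0.5

    degenerate = het_sd == 0.0
    return SampleParams(
        member=member,
        het_mean=het_mean,
        het_sd=het_sd,
        het_low=het_mean - k_sd * het_sd,
        het_high=het_mean + k_sd * het_sd,
        hom_low=hom_a_thr,
        hom_high=hom_b_thr,
        k_sd=k_sd,
        non_hom_center=non_hom_center,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# autosomal rates
# ---------------------------------------------------------------------------

def isolated_positive_count(positive: np.ndarray) -> int:
    """Count positives excluding runs of >= 2 adjacent positives.

    Adjacent abnormal SNPs are more plausibly biological than chance, so
    rate estimates of what is expected by chance use only isolated hits.
    """
    positive = np.asarray(positive, dtype=bool)
    if positive.size == 0:
        return 0
    padded = np.concatenate([[False], positive, [False]])
    isolated = positive & ~padded[:-2] & ~padded[2:]
    return int(isolated.sum())


def non_adjacent_rate(positive: np.ndarray, denominator_mask: np.ndarray) -> float:
    denom = int(np.asarray(denominator_mask, dtype=bool).sum())
    if denom == 0:
        raise ValueError("empty denominator for autosomal rate")
    return isolated_positive_count(positive) / denom


def autosomal_informative_rates(data: TrioDataset, params: dict,
                                normal_arms: set[str],
                                hd_lrr_threshold: float = -1.5) -> dict:
    """Fill the informative-SNP class rates of every member's params.

    Rates are computed on normal arms only, counting isolated (non-adjacent)
    positives.  Denominators: all normal-arm SNPs for HD and BAF-outlier
    rates; polymorphic normal-arm SNPs for MI1 rates.
    """
    if not normal_arms:
        raise ValueError("no normal arms available for rate estimation")
    sel = np.zeros(data.n_snps, dtype=bool)
    for arm in normal_arms:
        sel[data.arm_slice(arm)] = True

    poly = polymorphic_mask(data)
    n_poly = int((poly & sel).sum())
    cp = params["child"]

    mi1_plain = mi1_mask(data)
    mi1_aug = mi1_mask(data, cp.het_mean, cp.het_sd)
    het_mi1 = het_mi1_mask(data)

    for member in ("father", "mother", "child"):
        p = params[member]
        hd = data.lrr(member) < hd_lrr_threshold
        p.hd_rate = non_adjacent_rate(hd & sel, sel)
        gt = data.gt(member)
        p.nc_rate = float((gt[sel] == NC).mean())

    if n_poly == 0:
        raise ValueError("no polymorphic SNPs on normal arms")
    for member in ("father", "mother", "child"):
        p = params[member]
        p.mi1_rate = isolated_positive_count(mi1_plain & sel) / n_poly
        p.mi1_snp_rate = isolated_positive_count(mi1_aug & sel) / n_poly
        p.het_mi1_rate = isolated_positive_count(het_mi1 & sel) / n_poly
        p.error_rate = estimate_error_rate(p.mi1_snp_rate)

    # child BAF outliers among non-homozygous calls (cryptic-region detector)
    cgt = data.gt("child")
    cbaf = data.baf("child")
    non_hom = (cgt == AB) | (cgt == NC)
    outlier = non_hom & ((cbaf < cp.het_low) | (cbaf > cp.het_high))
    cp.baf_outlier_rate = non_adjacent_rate(outlier & sel, sel)
    return params


# ---------------------------------------------------------------------------
# quality gate
# ---------------------------------------------------------------------------

@dataclass
class QualityDecision:
    ok: bool
    reasons: list = field(default_factory=list)


def quality_gate(params: dict, mi1_max: float = 0.02,
                 nc_max: float = 0.03) -> QualityDecision:
    """Halt the analysis when any member's MI1 or NC rate is implausibly
    high: an elevated MI1 rate suggests a relationship annotation error, an
    elevated NC rate suggests poor DNA quality."""
    reasons = []
    for member, p in params.items():
        if p.mi1_rate >= mi1_max:
            reasons.append(
                f"{member}: MI1 rate {p.mi1_rate:.3%} >= {mi1_max:.0%} "
                "(possible relationship annotation error)")
        if p.nc_rate >= nc_max:
            reasons.append(
                f"{member}: NC rate {p.nc_rate:.3%} >= {nc_max:.0%} "
                "(possible DNA quality issue)")
    return QualityDecision(ok=not reasons, reasons=reasons)


def params_table(params: dict):
    """Flat (member, parameter, value) table for the optional parameter dump."""
    import pandas as pd

    rows = []
    for member, p in params.items():
        for key in ("het_mean", "het_sd", "het_low", "het_high", "hom_low",
                    "hom_high", "k_sd", "non_hom_center", "nc_rate",
                    "mi1_rate", "mi1_snp_rate", "het_mi1_rate", "hd_rate",
                    "baf_outlier_rate", "error_rate"):
            rows.append({"member": member, "parameter": key,
                         "value": getattr(p, key)})
    return pd.DataFrame(rows)
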