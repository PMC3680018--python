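"""Overlap resolution, typing, parent-of-origin and inheritance annotation.

Regions from the four detectors are reconciled (priority and splice rules),
typed from the normalized median LRR (amplification / deletion / homozygous
deletion) or, for copy-neutral regions, from genotype structure
(uniparental hetero- or isodisomy), annotated for inheritance against the
parental tracks, and screened for parental somatic artifacts via the
heterozygous-MI1 rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .sample_stats import het_mi1_mask, polymorphic_mask
from .trio_data import AB, NC, Region, TrioDataset, mirrored_baf

AMP_THR = 0.1
DEL_THR = -0.1
HD_THR = -1.5


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineContext:
    """Local baseline medians per member for one arm."""
    arm: str
    source: str = "arm"  # arm | adjacent-arm | autosomal
    lrr_med: dict = field(default_factory=dict)
    mbaf_med: dict = field(default_factory=dict)


def _member_medians(data: TrioDataset, idx: np.ndarray, params: dict):
    lrr_med, mbaf_med = {}, {}
    for member in ("father", "mother", "child"):
        lrr_med[member] = float(np.median(data.lrr(member)[idx]))
        gt = data.gt(member)[idx]
        nh = (gt == AB) | (gt == NC)
        if nh.any():
            mb = mirrored_baf(data.baf(member)[idx][nh],
                              params[member].non_hom_center)
            mbaf_med[member] = float(np.median(mb))
        else:
            mbaf_med[member] = params[member].non_hom_center
    return lrr_med, mbaf_med


def local_baseline(data: TrioDataset, arm: str, called_mask: np.ndarray,
                   params: dict, min_frac: float = 0.25,
                   min_snps: int = 25) -> BaselineContext:
    """Baseline medians from the uncalled SNPs of an arm.

    When more than 75% of the arm is called abnormal the adjacent arm of
    the same chromosome supplies the baseline; when the whole chromosome is
    abnormal (aneuploidy) the autosomal uncalled SNPs do.
    """
    s, e = data.arms[arm]
    free = np.flatnonzero(~called_mask[s:e]) + s
    if free.size >= max(min_snps, min_frac * (e - s)):
        lrr, mb = _member_medians(data, free, params)
        return BaselineContext(arm=arm, source="arm", lrr_med=lrr, mbaf_med=mb)

    chrom = arm.rstrip("pq")
    sib_free = []
    for other in data.arms_of_chrom(chrom):
        if other == arm:
            continue
        os, oe = data.arms[other]
        sib_free.append(np.flatnonzero(~called_mask[os:oe]) + os)
    sib = np.concatenate(sib_free) if sib_free else np.empty(0, dtype=int)
    if sib.size >= min_snps:
        lrr, mb = _member_medians(data, sib, params)
        return BaselineContext(arm=arm, source="adjacent-arm",
                               lrr_med=lrr, mbaf_med=mb)

    free_all = np.flatnonzero(~called_mask)
    if free_all.size == 0:  # pathological: everything called
        free_all = np.arange(data.n_snps)
    lrr, mb = _member_medians(data, free_all, params)
    return BaselineContext(arm=arm, source="autosomal", lrr_med=lrr,
                           mbaf_med=mb)


def build_baselines(data: TrioDataset, regions: list[Region],
                    params: dict) -> dict:
    called = np.zeros(data.n_snps, dtype=bool)
    for r in regions:
        called[r.start_idx:r.end_idx + 1] = True
    return {arm: local_baseline(data, arm, called, params)
            for arm in data.arms}


# ---------------------------------------------------------------------------
# overlap resolution
# ---------------------------------------------------------------------------

def _informative_in(region: Region, inf: np.ndarray, lo: int, hi: int) -> int:
    """Informative SNPs of the region's parent in [lo, hi]."""
    code = {"father": 1, "mother": 2}.get(region.parent, 0)
    seg = inf[max(lo, region.start_idx):min(hi, region.end_idx) + 1]
    if code == 0:
        return int((seg != 0).sum())
    return int((seg == code).sum())


def resolve_overlaps(regions: list[Region], min_region: int,
                     inf: np.ndarray) -> list[Region]:
    """Reconcile overlapping detections.

    PODhd regions pass through without fragmenting larger regions.  A POD
    region overlapping at most two PODmi1 regions is discarded in favour of
    them when its non-overlapping segments hold no more than ``min_region``
    informative SNPs (the PODmi1 detector defines small regions better).
    Remaining overlapping regions combine when parent-compatible, otherwise
    the later is spliced to start past the earlier's refined boundary.
    """
    hd = [r for r in regions if r.detector == "PODhd"]
    rest = [r for r in regions if r.detector != "PODhd"]

    drop: set[int] = set()
    for i, r in enumerate(rest):
        if r.detector != "POD":
            continue
        mi1s = [m for m in rest if m.detector == "PODmi1" and r.overlaps(m)]
        if not mi1s or len(mi1s) > 2:
            continue
        spans = sorted(m.span for m in mi1s)
        outside = 0
        cur = r.start_idx
        for a, b in spans:
            if a > cur:
                outside += _informative_in(r, inf, cur, a - 1)
            cur = max(cur, b + 1)
        if cur <= r.end_idx:
            outside += _informative_in(r, inf, cur, r.end_idx)
        if outside <= min_region:
            drop.add(i)
    rest = [r for i, r in enumerate(rest) if i not in drop]

    rest.sort(key=lambda r: (r.chrom, r.start_idx, r.end_idx))
    out: list[Region] = []
    for r in rest:
        if out and out[-1].chrom == r.chrom and out[-1].overlaps(r):
            prev = out[-1]
            compatible = (prev.parent == r.parent
                          or "undetermined" in (prev.parent, r.parent))
            if compatible:
                prev.end_idx = max(prev.end_idx, r.end_idx)
                prev.start_idx = min(prev.start_idx, r.start_idx)
                prev.n_snps = prev.end_idx - prev.start_idx + 1
                prev.n_informative = max(prev.n_informative, r.n_informative)
                if prev.parent == "undetermined":
                    prev.parent = r.parent
                continue
            # incompatible: splice at the refined boundary
            if r.end_idx > prev.end_idx:
                r.start_idx = prev.end_idx + 1
                r.n_snps = r.end_idx - r.start_idx + 1
            else:
                continue  # nested with conflicting parent: keep the larger
        out.append(r)
    return out + hd


# ---------------------------------------------------------------------------
# typing
# ---------------------------------------------------------------------------

def _region_medians(region: Region, data: TrioDataset, params: dict,
                    baseline: BaselineContext):
    idx = np.arange(region.start_idx, region.end_idx + 1)
    for member in ("father", "mother", "child"):
        lrr = float(np.median(data.lrr(member)[idx]))
        region.med_lrr[member] = lrr - baseline.lrr_med[member]
        gt = data.gt(member)[idx]
        nh = (gt == AB) | (gt == NC)
        if nh.any():
            mb = float(np.median(mirrored_baf(
                data.baf(member)[idx][nh], params[member].non_hom_center)))
        else:
            mb = params[member].non_hom_center
        region.med_mbaf[member] = mb - baseline.mbaf_med[member]
    return region


def assign_abnormality_type(region: Region, data: TrioDataset, params: dict,
                            baseline: BaselineContext) -> Region:
    """Threshold cascade on the normalized median LRR; copy-neutral regions
    are tested for uniparental hetero- then isodisomy."""
    _region_medians(region, data, params, baseline)
    lrr = region.med_lrr["child"]
    # detector parent labels name the parent whose contribution is in
    # excess; for losses the parent of origin is the parent whose material
    # is missing, i.e. the opposite one
    flip = {"father": "mother", "mother": "father"}
    if lrr >= AMP_THR:
        region.abn_type = "AMP"
        return region
    if lrr <= HD_THR:
        region.abn_type = "HD"
        region.parent = flip.get(region.parent, region.parent)
        return region
    if lrr <= DEL_THR:
        region.abn_type = "DEL"
        region.parent = flip.get(region.parent, region.parent)
        return region

    idx = np.arange(region.start_idx, region.end_idx + 1)
    cgt = data.gt("child")[idx]
    called = cgt != NC
    e = params["child"].error_rate
    if region.parent in ("father", "mother") and called.any():
        pgt = data.gt(region.parent)[idx]
        ogt = data.gt({"father": "mother", "mother": "father"}[region.parent])[idx]
        # judge the match where it is discriminating: SNPs at which the two
        # parents' genotypes differ, so "matches the parent of origin" is
        # not satisfied trivially by any normal region
        disc = called & (pgt != NC) & (ogt != NC) & (pgt != ogt)
        if disc.sum() >= 20:
            mismatch = float((cgt[disc] != pgt[disc]).mean())
            if mismatch <= max(e, 1e-12):
                region.abn_type = "UPhD"
                return region
    if called.any():
        hom_frac = float((cgt[called] != AB).mean())
        raw_mbaf = region.med_mbaf["child"] + baseline.mbaf_med["child"]
        if hom_frac >= 0.9 or (raw_mbaf > 0.55 and -0.05 < lrr < 0.05):
            region.abn_type = "UPiD"
            return region
    region.abn_type = "NA"
    return region


# ---------------------------------------------------------------------------
# inheritance
# ---------------------------------------------------------------------------

def _parent_state(region: Region, data: TrioDataset, member: str,
                  baseline: BaselineContext) -> str:
    idx = np.arange(region.start_idx, region.end_idx + 1)
    dev = float(np.median(data.lrr(member)[idx])) - baseline.lrr_med[member]
    if dev >= AMP_THR:
        return "AMP"
    if dev <= HD_THR:
        return "HD"
    if dev <= DEL_THR:
        return "DEL"
    return "normal"


def assign_inheritance(region: Region, data: TrioDataset,
                       baseline: BaselineContext) -> Region:
    """INH / INH-CN annotation from the parental LRR over the same span."""
    f_state = _parent_state(region, data, "father", baseline)
    m_state = _parent_state(region, data, "mother", baseline)
    contrib = {"father": f_state, "mother": m_state}.get(region.parent)
    other = {"father": m_state, "mother": f_state}.get(region.parent)

    t = region.abn_type
    inh = ""
    if t == "AMP" and contrib == "AMP":
        inh = "INH"
    elif t == "DEL":
        if contrib == "DEL":
            inh = "INH"
        elif contrib == "HD" and other == "normal":
            inh = "INH-CN"
    elif t == "HD":
        if f_state == "DEL" and m_state == "DEL":
            inh = "INH-CN"
        elif {f_state, m_state} <= {"DEL", "HD"}:
            inh = "INH"
    region.inheritance = inh
    return region


# ---------------------------------------------------------------------------
# parental artifact filter
# ---------------------------------------------------------------------------

def filter_parental_artifacts(region: Region, data: TrioDataset, params: dict,
                              alpha_corr: float) -> bool:
    """True = keep the region; False = drop it as a parental somatic change.

    Heterozygous MI1 calls (a novel allele in the child) should occur at the
    autosomal background rate inside a genuine child abnormality; an excess
    betrays a somatic alteration in a parent.  One-tailed binomial test with
    n = polymorphic SNPs in the region, p = the autosomal het-MI1 rate.
    """
    idx = slice(region.start_idx, region.end_idx + 1)
    poly = polymorphic_mask(data)[idx]
    n = int(poly.sum())
    if n == 0:
        return True
    k = int((het_mi1_mask(data)[idx] & poly).sum())
    p = max(params["child"].het_mi1_rate, 1e-9)
    pval = float(binom.sf(k - 1, n, p)) if k > 0 else 1.0
    return pval >= alpha_corr
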