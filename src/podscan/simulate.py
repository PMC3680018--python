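"""Synthetic trio generator, tumor-dilution series and benchmark metrics.

The generator emulates a genotyping-array trio experiment: per-SNP
population B-allele frequencies, Hardy-Weinberg parental genotypes,
Mendelian transmission to the child, Gaussian BAF/LRR noise, genotype
re-calling from the noisy BAF, and planted abnormalities (deletion,
amplification, uniparental disomy, homozygous deletion) carried by a chosen
parent-of-origin at an arbitrary mosaic cell fraction.

Because transmission is simulated with phased haplotypes, the BAF deviation
at every informative SNP inside a planted region is automatically
consistent with the assigned parent: duplicating or deleting the
transmitted haplotype shifts the BAF toward or away from that parent's
allele, which is the parent-of-origin reflection the evaluation design
requires.

The dilution series mirrors the classic simulated tumor benchmark: ten
abnormalities of both parental origins in 21 mosaic states from 0 to 100%
normal cells in 5% steps, with shared noise so only the mosaic fraction
varies between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trio_data import AA, AB, BB, NC, Region, TrioDataset

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Default chromosome-arm layout (SNPs per arm), ~150k autosomal SNPs.
DEFAULT_CHROM_ARMS: dict[str, tuple[int, int]] = {
    "1": (2400, 3000), "2": (2300, 2900), "3": (2000, 2700),
    "4": (1900, 2600), "5": (9000, 12000), "6": (1800, 2500),
    "7": (1700, 2400), "8": (8000, 9000), "9": (8000, 5000),
    "10": (4000, 9000), "11": (1600, 2300), "12": (3600, 5400),
    "13": (500, 9000), "14": (300, 2700), "15": (300, 2600),
    "16": (1500, 1900), "17": (7000, 7500), "18": (1100, 2000),
    "19": (1200, 1600), "20": (1100, 1500), "21": (250, 1300),
    "22": (250, 1300),
}

ABN_TYPES = ("DEL", "AMP", "UPD", "HD")


@dataclass(frozen=True)
class AbnormalitySpec:
    """A planted abnormality.

    ``start``/``end`` are chromosome-local SNP indices (inclusive, p arm
    first).  ``fraction`` is the abnormal-cell fraction in the undiluted
    sample; ``parent`` the origin of the extra/lost material; ``carrier``
    the member whose DNA carries the change (a non-child carrier models a
    parental somatic artifact that leaves the child's DNA untouched).
    """
    chrom: str
    start: int
    end: int
    abn_type: str
    parent: str
    fraction: float = 1.0
    carrier: str = "child"

    def __post_init__(self):
        if self.abn_type not in ABN_TYPES:
            raise ValueError(f"unknown abnormality type {self.abn_type}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("mosaic fraction must lie in [0, 1]")
        if self.end < self.start:
            raise ValueError("abnormality end before start")

    def copy_numbers(self) -> tuple[int, int]:
        """(paternal, maternal) transmitted-haplotype copies in abnormal
        cells; normal is (1, 1)."""
        sign = {"DEL": -1, "AMP": 1, "UPD": 0, "HD": 0}[self.abn_type]
        if self.abn_type == "HD":
            return 0, 0
        if self.abn_type == "UPD":
            return (2, 0) if self.parent == "father" else (0, 2)
        if self.parent == "father":
            return 1 + sign, 1
        return 1, 1 + sign


def default_dilution_regions() -> list[AbnormalitySpec]:
    """Ten abnormalities emulating the reference tumor-dilution design:
    four hemizygous deletions, three single-copy gains (one a whole
    chromosome), and three uniparental disomies, with assigned parental
    origins; mean size 7,355 SNPs."""
    mk = AbnormalitySpec
    return [
        mk("5", 250, 8749, "UPD", "mother"),      # 5p, 8500 SNPs
        mk("5", 11000, 18999, "DEL", "father"),   # 5q22-like, 8000
        mk("8", 500, 7499, "AMP", "mother"),      # 8p, 7000
        mk("8", 9800, 16799, "AMP", "father"),    # 8q24-like, 7000
        mk("9", 250, 6749, "DEL", "father"),      # 9p, 6500
        mk("10", 4500, 12499, "DEL", "mother"),   # 10q23-like, 8000
        mk("12", 0, 8999, "AMP", "mother"),       # trisomy 12, 9000
        mk("13", 2000, 8049, "DEL", "father"),    # 13q13-like, 6050
        mk("17", 250, 6749, "UPD", "father"),     # 17p13-like, 6500
        mk("17", 7250, 14249, "UPD", "father"),   # 17q, 7000
    ]


@dataclass
class SimConfig:
    """Generator settings; the defaults are the benchmark study conditions."""
    chrom_arms: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_ARMS))
    maf_range: tuple[float, float] = (0.2, 0.8)  # per-SNP B-allele frequency
    baf_noise_sd: float = 0.03
    lrr_noise_sd: float = 0.15
    lrr_attenuation: float = 0.55
    genotype_error_rate: float = 0.002
    nc_rate: float = 0.005
    spacing: int = 5000          # base pairs between SNPs
    seed: int = 0
    abnormalities: list = field(default_factory=list)

    def __post_init__(self):
        if self.baf_noise_sd <= 0 or self.lrr_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")

    @property
    def n_snps(self) -> int:
        return sum(p + q for p, q in self.chrom_arms.values())


# ---------------------------------------------------------------------------
# base draw (everything random, shared across a dilution series)
# ---------------------------------------------------------------------------

class _BaseDraw:
    """All random material for one trio, independent of mosaic fractions."""

    def __init__(self, config: SimConfig):
        rng = np.random.default_rng(config.seed)
        n = config.n_snps
        self.config = config

        # place p-arm SNPs below the build's centromere and q-arm SNPs
        # above it, so a written table re-indexes to the same arms
        from .trio_data import load_centromeres
        cen = load_centromeres().set_index("chrom")

        chroms, offsets, arms = [], {}, {}
        pos = np.empty(n, dtype=np.int64)
        i = 0
        for chrom, (p, q) in config.chrom_arms.items():
            offsets[chrom] = i
            if p:
                arms[f"{chrom}p"] = (i, i + p)
            if q:
                arms[f"{chrom}q"] = (i + p, i + p + q)
            chroms.extend([chrom] * (p + q))
            if chrom in cen.index:
                p_end = int(cen.loc[chrom, "p_end"])
                q_start = int(cen.loc[chrom, "q_start"])
            else:  # synthetic label: place a nominal centromere
                p_end = (p + 1) * config.spacing
                q_start = p_end + 3_000_000
            sp_p = min(config.spacing, p_end // (p + 1)) if p else 0
            pos[i:i + p] = (np.arange(p, dtype=np.int64) + 1) * sp_p
            pos[i + p:i + p + q] = q_start \
                + (np.arange(q, dtype=np.int64) + 1) * config.spacing
            i += p + q
        self.chrom = np.array(chroms)
        self.pos = pos
        self.offsets = offsets
        self.arms = arms

        lo, hi = config.maf_range
        self.p_b = rng.uniform(lo, hi, n)
        # phased parental haplotypes (B-allele indicators)
        self.f_h = rng.random((2, n)) < self.p_b
        self.m_h = rng.random((2, n)) < self.p_b
        # transmitted haplotype choice
        self.f_pick = rng.integers(0, 2, n)
        self.m_pick = rng.integers(0, 2, n)
        self.eps_baf = rng.normal(0.0, config.baf_noise_sd, (3, n))
        self.eps_lrr = rng.normal(0.0, config.lrr_noise_sd, (3, n))
        self.err_mask = rng.random((3, n)) < config.genotype_error_rate
        self.err_shift = rng.integers(1, 3, (3, n))
        self.nc_mask = rng.random((3, n)) < config.nc_rate

    @property
    def pat_b(self) -> np.ndarray:
        return self.f_h[self.f_pick, np.arange(self.f_pick.size)].astype(float)

    @property
    def mat_b(self) -> np.ndarray:
        return self.m_h[self.m_pick, np.arange(self.m_pick.size)].astype(float)

    def global_span(self, spec: AbnormalitySpec) -> tuple[int, int]:
        off = self.offsets[spec.chrom]
        size = sum(self.config.chrom_arms[spec.chrom])
        if spec.end >= size:
            raise ValueError(
                f"abnormality span {spec.start}-{spec.end} exceeds "
                f"chromosome {spec.chrom} ({size} SNPs)")
        return off + spec.start, off + spec.end


def call_genotypes(baf: np.ndarray) -> np.ndarray:
    """Band-based genotype calling: AA < 0.2, AB in [0.3, 0.7], BB > 0.8,
    NC in the gaps (the call of a mosaic mixture is the genotype of the
    dominant subpopulation, or NC when the BAF falls between clusters)."""
    gt = np.full(baf.shape, NC, dtype=np.int8)
    gt[baf < 0.2] = AA
    gt[(baf >= 0.3) & (baf <= 0.7)] = AB
    gt[baf > 0.8] = BB
    return gt


# ---------------------------------------------------------------------------
# realisation
# ---------------------------------------------------------------------------

_MIN_CN = 0.05  # LRR floor for fully deleted material


def _realize(base: _BaseDraw, specs: list[AbnormalitySpec],
             fraction_scale: float = 1.0):
    cfg = base.config
    n = cfg.n_snps
    pat_b, mat_b = base.pat_b, base.mat_b

    # per-SNP mixture state for each member: B-copies and total copies
    b_mix = {m: None for m in ("father", "mother", "child")}
    cn_mix = {m: np.full(n, 2.0) for m in ("father", "mother", "child")}
    b_mix["father"] = base.f_h.sum(axis=0).astype(float)
    b_mix["mother"] = base.m_h.sum(axis=0).astype(float)
    b_mix["child"] = pat_b + mat_b

    region_id = np.full(n, -1, dtype=np.int32)
    for rid, spec in enumerate(specs):
        a, b = base.global_span(spec)
        f = spec.fraction * fraction_scale
        if f <= 0.0:
            continue
        sl = slice(a, b + 1)
        if spec.carrier == "child":
            cp, cm = spec.copy_numbers()
            b_abn = cp * pat_b[sl] + cm * mat_b[sl]
            cn_abn = float(cp + cm)
            b_mix["child"][sl] = (1 - f) * b_mix["child"][sl] + f * b_abn
            cn_mix["child"][sl] = (1 - f) * 2.0 + f * cn_abn
            region_id[sl] = rid
        else:
            # somatic change in a parent's own DNA; the transmitted
            # haplotype (h[0] by convention: kept/duplicated is h[1])
            h = base.f_h if spec.carrier == "father" else base.m_h
            sign = {"DEL": -1, "AMP": 1, "UPD": 0, "HD": 0}[spec.abn_type]
            if spec.abn_type == "HD":
                b_abn = np.zeros(b + 1 - a)
                cn_abn = 0.0
            elif spec.abn_type == "UPD":
                b_abn = 2.0 * h[1, sl]
                cn_abn = 2.0
            else:
                b_abn = h[0, sl].astype(float) + (1 + sign) * h[1, sl]
                cn_abn = 2.0 + sign
            b_mix[spec.carrier][sl] = ((1 - f) * b_mix[spec.carrier][sl]
                                       + f * b_abn)
            cn_mix[spec.carrier][sl] = (1 - f) * 2.0 + f * cn_abn
            region_id[sl] = rid

    df = pd.DataFrame({
        "name": [f"snp{i:06d}" for i in range(n)],
        "chrom": base.chrom,
        "pos": base.pos,
    })
    for mi, member in enumerate(("father", "mother", "child")):
        col = "fmc"[mi]
        cn = cn_mix[member]
        with np.errstate(divide="ignore", invalid="ignore"):
            exp_baf = np.where(cn > 0.1, b_mix[member] / np.maximum(cn, _MIN_CN), 0.5)
        baf = np.clip(exp_baf + base.eps_baf[mi], 0.0, 1.0)
        lrr = cfg.lrr_attenuation * np.log2(np.maximum(cn, _MIN_CN) / 2.0) \
            + base.eps_lrr[mi]
        gt = call_genotypes(baf)
        err = base.err_mask[mi] & (gt != NC)
        gt[err] = (gt[err] + base.err_shift[mi][err]) % 3
        gt[base.nc_mask[mi]] = NC
        df[f"{col}_gt"] = gt
        df[f"{col}_baf"] = baf
        df[f"{col}_lrr"] = lrr

    child_carried = np.zeros(n, dtype=bool)
    for rid, spec in enumerate(specs):
        if spec.carrier == "child":
            child_carried |= region_id == rid
    truth = pd.DataFrame({
        "region_id": region_id,
        "true_child_het": (pat_b != mat_b),
        "modified_het": child_carried & (pat_b != mat_b),
    })
    return TrioDataset(df, base.arms), truth


def simulate_trio(config: SimConfig):
    """Generate one trio dataset plus per-SNP truth labels.

    Returns ``(TrioDataset, truth)`` where truth holds ``region_id`` (−1
    outside planted regions), ``true_child_het`` and ``modified_het`` (true
    heterozygous child SNPs whose expected BAF a child-carried abnormality
    shifted — the denominators of the benchmark sensitivity metric).
    """
    base = _BaseDraw(config)
    for spec in config.abnormalities:
        base.global_span(spec)  # validates spans
    return _realize(base, config.abnormalities)


def inject_abnormality(config: SimConfig, spec: AbnormalitySpec) -> SimConfig:
    """Return a config with one more planted abnormality."""
    return replace(config, abnormalities=[*config.abnormalities, spec])


def make_dilution_series(config: SimConfig,
                         region_set: list[AbnormalitySpec] | None = None,
                         percents: list[int] | None = None):
    """Yield ``(percent_normal, TrioDataset, truth)`` over the dilution grid.

    All randomness (haplotypes, noise, error masks) is drawn once from the
    config seed, so samples differ only in the abnormal-cell fraction
    f = 1 − percent_normal/100.
    """
    if region_set is None:
        region_set = config.abnormalities or default_dilution_regions()
    if percents is None:
        percents = list(range(0, 101, 5))
    cfg = replace(config, abnormalities=list(region_set))
    base = _BaseDraw(cfg)
    for spec in region_set:
        base.global_span(spec)
    for pct in percents:
        data, truth = _realize(base, region_set, fraction_scale=1.0 - pct / 100.0)
        yield pct, data, truth


# ---------------------------------------------------------------------------
# benchmark metrics
# ---------------------------------------------------------------------------

def _called_mask(n: int, regions: list[Region]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for r in regions:
        mask[r.start_idx:r.end_idx + 1] = True
    return mask


def benchmark_metrics(samples: list[dict]) -> dict:
    """Performance metrics over a dilution series.

    ``samples`` is a list of dicts with keys ``percent_normal``, ``truth``
    (the per-SNP truth frame) and ``regions`` (the calls).  Sensitivity is
    computed per region on modified heterozygous SNPs; specificity pools
    true-negative heterozygous SNPs over all samples; PPV pools over the
    mosaic samples (100% normal excluded).  The detection threshold of a
    region is the first percent-normal level above 50 at which its
    sensitivity reaches zero (100 when it never does).
    """
    samples = sorted(samples, key=lambda s: s["percent_normal"])
    region_ids = sorted(set(
        int(r) for s in samples for r in np.unique(s["truth"]["region_id"])
        if r >= 0))

    sens: dict[int, dict[int, float]] = {rid: {} for rid in region_ids}
    tn = fp = tp = pos_total = 0
    tp_mosaic = fp_mosaic = 0
    sizes = []
    for s in samples:
        truth = s["truth"]
        pct = s["percent_normal"]
        mask = _called_mask(len(truth), s.get("regions", []))
        modified = truth["modified_het"].to_numpy() & (pct < 100)
        het = truth["true_child_het"].to_numpy()
        neg = het & ~modified
        tn += int((neg & ~mask).sum())
        fp += int((neg & mask).sum())
        tp += int((modified & mask).sum())
        pos_total += int(modified.sum())
        if 0 < pct < 100:
            rid_arr = truth["region_id"].to_numpy()
            for rid in region_ids:
                denom = modified & (rid_arr == rid)
                nd = int(denom.sum())
                sens[rid][pct] = float((denom & mask).sum() / nd) if nd else 0.0
        if pct < 100:
            tp_mosaic += int((modified & mask).sum())
            fp_mosaic += int((neg & mask).sum())
        sizes.extend(r.n_snps for r in s.get("regions", []))
        if pct == 0:
            rid_arr = truth["region_id"].to_numpy()
            for rid in region_ids:
                denom = modified & (rid_arr == rid)
                nd = int(denom.sum())
                sens[rid][0] = float((denom & mask).sum() / nd) if nd else 0.0

    pcts = sorted({s["percent_normal"] for s in samples})
    mean_sens_by_pct = {
        pct: float(np.mean([sens[rid].get(pct, 0.0) for rid in region_ids]))
        for pct in pcts if pct < 100 and region_ids}

    thresholds = {}
    for rid in region_ids:
        thr = 100.0
        for pct in [p for p in pcts if 50 < p < 100]:
            if sens[rid].get(pct, 0.0) == 0.0:
                thr = float(pct)
                break
        thresholds[rid] = thr

    mosaic_instances = [(rid, pct) for rid in region_ids
                        for pct in pcts if 0 < pct < 100]
    prop_95 = (float(np.mean([sens[rid][pct] >= 0.95
                              for rid, pct in mosaic_instances]))
               if mosaic_instances else float("nan"))

    specificity = tn / (tn + fp) if tn + fp else float("nan")
    ppv = (tp_mosaic / (tp_mosaic + fp_mosaic)
           if tp_mosaic + fp_mosaic else float("nan"))
    return {
        "sensitivity": sens,
        "mean_sens_by_pct": mean_sens_by_pct,
        "detection_thresholds": thresholds,
        "mean_detection_threshold": (float(np.mean(list(thresholds.values())))
                                     if thresholds else float("nan")),
        "prop_detected_ge95": prop_95,
        "specificity": specificity,
        "ppv": ppv,
        "overall_sensitivity": tp / pos_total if pos_total else float("nan"),
        "mean_region_size": float(np.mean(sizes)) if sizes else 0.0,
    }
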