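"""Two-pass detection pipeline and batch/benchmark drivers.

The workflow: (1) estimate sample parameters on screened normal arms,
(2) classify informative SNPs, (3) POD window detection with the
scan-statistics FWER threshold plus a large-window rescan of still-normal
segments, (4) streak detectors, (5) CUSUM boundary refinement; steps 2-5
repeat once with arm-locally refined BAF parameters (pass-one calls
masked); finally overlaps are resolved and regions annotated for type,
parent-of-origin, inheritance and parental artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import annotate as ann
from . import cusum, pod_core, sample_stats, streaks
from .normal_arms import detect_normal_arms
from .sample_stats import SampleParams, compute_baf_stats, quality_gate
from .trio_data import AB, NC, Region, TrioDataset, write_outputs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    alpha: float = 0.1
    window: int = 100
    large_window_factor: int = 5
    k_sd: float = 2.0
    hd_lrr_threshold: float = -1.5
    enable_hd: bool = True
    enable_mi1: bool = True
    enable_cr: bool = True
    mi1_max: float = 0.02
    nc_max: float = 0.03
    two_pass: bool = True
    skip_quality_gate: bool = False
    min_arm_het: int = 100
    cores: int = 1  # per-arm work is independent; execution is serial

    def __post_init__(self):
        if self.window < 10:
            raise ValueError("window must be >= 10 SNPs")
        if self.large_window_factor < 2:
            raise ValueError("large window factor must be >= 2")


@dataclass
class PipelineResult:
    regions: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    contexts: dict = field(default_factory=dict)
    halted: bool = False
    halt_reasons: list = field(default_factory=list)
    log: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _merge_adjacent(regions: list[Region], max_gap: int) -> list[Region]:
    """Combine same-arm, same-parent regions separated by at most
    ``max_gap`` SNPs (keeps distinct parents and distant regions apart)."""
    regions = sorted(regions, key=lambda r: (r.arm, r.start_idx))
    out: list[Region] = []
    for r in regions:
        if (out and out[-1].arm == r.arm and out[-1].parent == r.parent
                and out[-1].detector == r.detector
                and r.start_idx - out[-1].end_idx - 1 <= max_gap):
            prev = out[-1]
            prev.end_idx = max(prev.end_idx, r.end_idx)
            prev.n_snps = prev.end_idx - prev.start_idx + 1
            prev.n_informative += r.n_informative
        else:
            out.append(r)
    return out


def _called_mask(n: int, regions: list[Region]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for r in regions:
        mask[r.start_idx:r.end_idx + 1] = True
    return mask


def _global_quality(data: TrioDataset) -> dict:
    """NC and genotype-only MI1 rates over all autosomes, for the gate."""
    params = {m: SampleParams(member=m) for m in ("father", "mother", "child")}
    poly = sample_stats.polymorphic_mask(data)
    n_poly = max(int(poly.sum()), 1)
    mi1 = sample_stats.mi1_mask(data)
    for m in params:
        params[m].nc_rate = float((data.gt(m) == NC).mean())
        params[m].mi1_rate = float(mi1.sum()) / n_poly
    return params


def _detect_pass(data: TrioDataset, params: dict, config: RunConfig,
                 log: list) -> tuple[list[Region], dict]:
    """Steps 2-5 for one pass: classify, POD scan, streaks, refine."""
    cp = params["child"]
    e = max(cp.error_rate, 1e-6)
    inf = pod_core.classify_informative_snps(data, cp, target="child")
    M = data.n_snps
    N = int((inf != 0).sum())
    if N and N / M < 0.001:
        log.append("warning: informative-SNP density unusually low; "
                   "check trio relationships (consanguinity reduces "
                   "informative content)")

    ctx_s = pod_core.fwer_beta_threshold(M, N, config.window, config.alpha) \
        if N else pod_core.FwerContext(M=M, N=N, w=config.window,
                                       alpha=config.alpha)
    w_large = config.window * config.large_window_factor
    ctx_l = pod_core.fwer_beta_threshold(M, N, w_large, config.alpha) \
        if N else pod_core.FwerContext(M=M, N=N, w=w_large, alpha=config.alpha)

    regions: list[Region] = []
    for arm, (s, e_idx) in data.arms.items():
        regions.extend(pod_core.detect_pod_regions(
            inf[s:e_idx], ctx_s, e, alpha=config.alpha, offset=s,
            chrom=arm.rstrip("pq"), arm=arm))
    segments = pod_core.uncalled_segments(data.arms, regions)
    regions.extend(pod_core.large_window_rescan(
        inf, segments, ctx_l, e, alpha=config.alpha))
    # the large-window pass scans only the remainder, so its calls abut the
    # small-window calls; reunite same-parent pieces split by the masking
    regions = _merge_adjacent(regions, max_gap=config.window)

    if config.enable_hd:
        regions.extend(streaks.detect_hd_regions(
            data, params, config.hd_lrr_threshold, config.alpha))
    if config.enable_mi1:
        regions.extend(streaks.detect_mi1_regions(data, params, config.alpha))
    if config.enable_cr:
        regions.extend(streaks.detect_cryptic_regions(data, params,
                                                      config.alpha))

    # CUSUM boundary refinement against arm-local baselines
    called = _called_mask(data.n_snps, regions)
    baselines = {arm: ann.local_baseline(data, arm, called, params)
                 for arm in data.arms}
    refined = []
    for r in regions:
        base = baselines[r.arm]
        refined.append(cusum.refine_region_boundaries(
            r, data, cp, max(ctx_s.min_region, 2), called,
            base.lrr_med["child"], base.mbaf_med["child"], inf=inf))
    ctxs = {"small": ctx_s, "large": ctx_l, "informative": inf}
    return refined, ctxs


def _refine_params(data: TrioDataset, params: dict, config: RunConfig,
                   called: np.ndarray, normal_sets: dict) -> dict:
    """Pass-two parameters: global band stats re-estimated outside pass-one
    calls, plus arm-local heterozygous thresholds on screened-normal arms.

    Arms that failed the normal-arm screen keep the global (imputed)
    parameters: their local band statistics are contaminated by whatever
    abnormality got them excluded."""
    out = {}
    for member, p in params.items():
        try:
            p2 = compute_baf_stats(data, member, normal_sets[member] or None,
                                   k_sd=config.k_sd,
                                   min_het=config.min_arm_het, mask=~called)
        except ValueError:
            p2 = p
        # carry the rate estimates over
        for key in ("nc_rate", "mi1_rate", "mi1_snp_rate", "het_mi1_rate",
                    "hd_rate", "baf_outlier_rate", "error_rate"):
            setattr(p2, key, getattr(p, key))
        gt, baf = data.gt(member), data.baf(member)
        for arm in normal_sets[member]:
            s, e = data.arms[arm]
            sel = ((gt[s:e] == AB) & ~called[s:e]
                   & (baf[s:e] > 0.3) & (baf[s:e] < 0.7))
            if sel.sum() >= config.min_arm_het:
                het = baf[s:e][sel]
                p2.arm_het[arm] = (float(het.mean()), float(het.std(ddof=1)))
        out[member] = p2
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(data: TrioDataset, config: RunConfig | None = None) -> PipelineResult:
    """Run the full detection workflow on one trio."""
    config = config or RunConfig()
    log: list[str] = []
    result = PipelineResult(log=log)

    gate_params = _global_quality(data)
    decision = quality_gate(gate_params, config.mi1_max, config.nc_max)
    if not decision.ok and not config.skip_quality_gate:
        result.halted = True
        result.halt_reasons = decision.reasons
        log.extend("halted: " + r for r in decision.reasons)
        return result
    log.extend("quality warning (gate bypassed): " + r
               for r in decision.reasons)

    # step 1: normal arms and sample parameters
    normal_sets = {}
    for member in ("father", "mother", "child"):
        normal_sets[member], _ = detect_normal_arms(
            data, member, w=config.window, k_sd=config.k_sd)
    common = normal_sets["father"] & normal_sets["mother"] & normal_sets["child"]
    if not common:
        common = normal_sets["child"] or set(data.arms)
        log.append("warning: no arm normal in all members; using the "
                   "child's normal set for rate estimation")

    params = {}
    for member in ("father", "mother", "child"):
        arms = normal_sets[member] or set(data.arms)
        params[member] = compute_baf_stats(data, member, arms,
                                           k_sd=config.k_sd,
                                           min_het=config.min_arm_het)
    sample_stats.autosomal_informative_rates(
        data, params, common, config.hd_lrr_threshold)
    for member, gp in gate_params.items():
        params[member].nc_rate = gp.nc_rate

    # passes: the second pass repeats detection with refined parameters and
    # supersedes the first, whose calls serve as the estimation mask
    regions, ctxs = _detect_pass(data, params, config, log)
    if config.two_pass:
        called = _called_mask(data.n_snps, regions)
        params2 = _refine_params(data, params, config, called, normal_sets)
        regions, ctxs = _detect_pass(data, params2, config, log)
        params = params2

    # overlap resolution and annotation
    min_region = max(ctxs["small"].min_region, 2)
    regions = ann.resolve_overlaps(regions, min_region, ctxs["informative"])
    called = _called_mask(data.n_snps, regions)
    baselines = {arm: ann.local_baseline(data, arm, called, params)
                 for arm in data.arms}
    kept = []
    alpha_corr = config.alpha / max(len(regions), 1)
    for r in regions:
        base = baselines[r.arm]
        ann.assign_abnormality_type(r, data, params, base)
        ann.assign_inheritance(r, data, base)
        if not ann.filter_parental_artifacts(r, data, params, alpha_corr):
            log.append(f"dropped {r.chrom}:{r.start_idx}-{r.end_idx} "
                       "(parental somatic artifact signature)")
            continue
        r.start_pos = int(data.pos[r.start_idx])
        r.end_pos = int(data.pos[r.end_idx])
        r.n_snps = r.end_idx - r.start_idx + 1
        kept.append(r)
    kept.sort(key=lambda r: (int(r.chrom), r.start_idx))

    result.regions = kept
    result.params = params
    result.contexts = ctxs
    return result


def run_batch(datasets: dict, config: RunConfig | None = None,
              out_dir=None) -> dict:
    """Analyse several trios; a failing trio is logged and skipped."""
    results = {}
    for name, data in datasets.items():
        try:
            res = run_pipeline(data, config)
        except Exception as exc:  # noqa: BLE001 - batch isolation
            logger.error("trio %s failed: %s", name, exc)
            res = PipelineResult(halted=True, halt_reasons=[str(exc)])
        results[name] = res
        if out_dir is not None and not res.halted:
            write_outputs(res.regions, out_dir, prefix=str(name),
                          params_table=sample_stats.params_table(res.params),
                          log_lines=res.log)
    return results


# ---------------------------------------------------------------------------
# dilution benchmark
# ---------------------------------------------------------------------------

def run_dilution_benchmark(seed: int = 0, alpha: float = 0.1,
                           window: int = 100,
                           percents: list[int] | None = None,
                           pod_only: bool = True,
                           config: "SimConfig | None" = None) -> dict:
    """Simulate the 21-state dilution series and score POD detection.

    Uses the default dilution genome and regions unless ``config`` is
    given.  ``pod_only`` disables the streak detectors, matching the
    benchmark design.  The quality gate is bypassed: on this deliberately
    abnormality-dense genome the region-driven MI1 excess at high mosaic
    fractions trips the relationship-error heuristic by construction.
    """
    from .simulate import (SimConfig, benchmark_metrics,
                           default_dilution_regions, make_dilution_series)

    sim = config or SimConfig(seed=seed,
                              abnormalities=default_dilution_regions())
    run_cfg = RunConfig(alpha=alpha, window=window,
                        enable_hd=not pod_only, enable_mi1=not pod_only,
                        enable_cr=not pod_only, skip_quality_gate=True)
    samples = []
    for pct, data, truth in make_dilution_series(sim, percents=percents):
        res = run_pipeline(data, run_cfg)
        samples.append({"percent_normal": pct, "truth": truth,
                        "regions": res.regions})
        logger.info("dilution %d%% normal: %d regions", pct, len(res.regions))
    metrics = benchmark_metrics(samples)
    metrics["samples"] = samples
    return metrics
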