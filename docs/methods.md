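# Methods

`podscan` detects chromosomal abnormalities — deletions, amplifications,
uniparental disomy (UPD), homozygous deletions (HD) — in the offspring of a
parent–child trio genotyped on a SNP array, with particular emphasis on
low-level mosaicism. This note describes the statistical model, the
parameters that matter, the synthetic data the test suite relies on, and
the numerical choices made where the design was open.

## The parent-of-origin detection (POD) model

At a SNP where the parental genotype combination is *informative* (e.g.
father AA, mother BB), an outlying child B-allele frequency (BAF) reveals
which parent contributed excess (or missing) material: a depressed BAF at
an AA×BB SNP means surplus paternal A, an elevated one surplus maternal B.
Under normal biparental inheritance the excess parent indicated by
successive informative SNPs is a fair coin, so for a window holding `n`
informative SNPs of which `k` point to the father, a two-tailed binomial
test at p = 0.5 measures local skew. Windows of `w` SNPs (default 100)
slide in single-SNP steps along each chromosome arm.

Informative SNPs are BAF outliers beyond the heterozygous-band thresholds
`hetMean ± kSD·hetSD` with `kSD = 2` by default; Chebyshev's inequality
guarantees that at least 1 − 1/kSD² of normal heterozygous BAF values are
excluded from the informative class whatever the BAF distribution.

### Familywise error control

Tests on heavily overlapping windows are strongly dependent, so the
per-test threshold β comes from a scan-statistics argument. With `M` SNPs,
`N` informative SNPs and window `w`, the expected number of windows
containing `k` informative SNPs is

    E(W_k) = (N − k + 1) · Σ_{i=k−1..N} B(i; N, w/M),

and for a candidate β the familywise type-I bound is

    P_FWER(β) = Σ_k Σ_{i=1..round(E(W_k))} B(i; round(E(W_k)), γ_k),
    γ_k = max { P(j; k, 0.5) : P(j; k, 0.5) ≤ β, j ≤ k },

with P the two-tailed binomial p-value. Candidates β_k = P(k; k, 0.5) are
tried for increasing k and the first with P_FWER(β_k) < α is used; that k
is also the minimum acceptable region size ("min"). Fractional E(W_k) < 1
count as one window unless below 0.01, in which case the term vanishes;
γ_k = 0 (no contribution) when no attainable p-value is ≤ β. α defaults to
0.1 and is deliberately exposed: it bounds the probability of *any* false
POD region per genome.

### Regions

Windows with p ≤ β seed regions. Overlapping significant windows merge;
neighbouring clusters also merge when the one-tailed termination test
never rejects in the gap. That test treats every SNP of a window as a
Bernoulli trial whose success — informativeness for the *opposite* parent
— has probability `e`, the estimated genotyping error rate; its rejection
is evidence of a change in parental contribution. Merged regions retract
to the end of their outermost significant windows and then inward to the
first/last informative SNP matching the region's parent. Chromosomal
segments without calls are rescanned with a five-fold window (and its own
β), which trades boundary sharpness for sensitivity to large low-level
mosaics; segments shorter than the large window are skipped.

The detector's parent label names the parent with *excess* contribution.
Because a deletion of one parent's material manifests as excess of the
other, annotation flips the label for regions typed DEL or HD; the parent
of origin reported is the parent whose material changed.

### Error-rate model

Only a fraction of single genotyping errors in a trio are visible as a
Mendelian inconsistency. Enumerating the 15 Mendelian-consistent genotype
triples over {AA, AB, BB}, mutating one member at a time to each
alternative genotype yields 90 single-error events, which collapse onto 24
distinct detectable (observed inconsistent triple, inferable erring
member) combinations — hence `e = 90/24 × MI1 rate = 3.75 × MI1 rate`.
The MI1 rate itself is measured on normal arms, counting only isolated
(non-adjacent) MI1 SNPs among polymorphic SNPs, and includes BAF-based
inference: at obligate-heterozygous SNPs (opposite homozygous parents) a
child BAF beyond 5 SD of the heterozygous mean is counted as MI1. The
5-SD clause is restricted to obligate heterozygotes because elsewhere an
extreme BAF is compatible with a legitimate homozygous child.

## Streak detectors

Three complementary detectors look for runs of adjacent abnormal SNPs,
using the run-length approximation

    P_s(m; n, p) = 1 − Q2 · (Q3/Q2)^(n/m − 2)

(Q2, Q3 the 2m- and 3m-trial no-run probabilities) to find the smallest
run length significant at α given the class's autosomal background rate p:

- **PODhd** — runs of SNPs with LRR below −1.5 (default) in any member;
  a parental HD implies absent contribution and is reported as a child
  region carrying that parent's identity.
- **PODmi1** — runs of MI1 SNPs along the polymorphic subsequence;
  precise for small non-mosaic or high-level mosaic events.
- **PODcr** — runs of outlier-BAF non-homozygous SNPs, kept only when the
  outliers are significantly one-sided (two-tailed binomial on the
  up/down split, Bonferroni-corrected across candidates). Symmetric band
  splits are left to the window detectors.

Zero observed background rates receive one pseudo-count, and run lengths
below 2 are never called. The approximation's exponent is clamped at 0
for sequences shorter than 3m, the edge of its validity domain.

## CUSUM boundary refinement

Eligible regions have each boundary re-estimated by a one-sided CUSUM
S_n = max(0, S_{n−1} + x_n − k) scanned outward from inside the region;
the maximum partial sum marks the change-point. `x` is the arm's LRR
track when |region median − baseline| ≥ 0.1, else the non-homozygous
mirrored-BAF (mBAF) track when its median exceeds baseline by > 0.1;
otherwise boundaries stand. The reference `k` is half the
region-to-baseline median difference (capped at 1.5 for HD, whose
variance dwarfs the rest); negative-median LRR regions are reflected.
Interior scan origins and exterior stops follow the region's size `i`:
whole-region scans for i = 2 (stops ≥ 10 SNPs out), the maximum-LRR /
central-informative position for 3 ≤ i ≤ 3·min (stops ≥ 5i), and the
min-th informative SNP from each end for larger regions (stops ≥ 25).
Exterior stops extend by moving medians (window min(5i, 25)) until the
median drops below k. Guards: boundaries stay put when the adjacent
median is ≥ twice the region median (a likely distinct abnormality),
stray HD outliers inside hemizygous deletions are clipped, BAF outliers
above region median + 0.1 are clipped, and the mBAF channel is ignored
when fewer than max(10, 5%) of the region's SNPs are non-homozygous — a
(near-)non-mosaic UPD is homozygous throughout, so that channel carries
no boundary information there.

A validation-style CUSUM over the upper half of the heterozygous BAF band
(values in [band median, 0.7)) provides an independent boundary estimate
for benchmarking; its `k` defaults to half the 90th percentile of the
centred subset, an estimate of the abnormal deviation, and the reversed
scan is used when the forward peak sits at the end of the track (terminal
events).

## Two-pass workflow

Normal arms — the substrate for every parameter — are screened per member
by k-means (k = 2) with the jump method (distortion transformed as
d^(−Y); Y = 0.5 initially, 0.475 while iterating on the lower cluster)
applied first to per-arm heterozygous BAF SDs, then to per-arm scan
statistics of informative SNPs, each followed by a 4-SD outlier rule. Two
robustness choices: heterozygous band statistics use AB calls with BAF
inside (0.3, 0.7) (miscalled homozygotes otherwise inflate the SD), and
the 4-SD rule estimates the normal cluster's spread by scaled MAD so
abnormal arms cannot widen their own removal bound. Excluded arms inherit
global (imputed) parameters.

Detection runs twice: pass one with globally estimated parameters, pass
two — which supersedes it — with band parameters re-estimated outside
pass-one calls and arm-local thresholds on screened-normal arms. Finally
overlaps are resolved (PODhd passes through unfragmented; a POD region
overlapping ≤ 2 PODmi1 regions yields to them when its non-overlapping
informative content is ≤ min; same-parent overlaps combine, conflicting
ones splice), regions are typed from the baseline-normalized median LRR
(AMP ≥ 0.1; DEL in (−1.5, −0.1]; HD ≤ −1.5; copy-neutral regions tested
for UPhD via genotype identity with the origin parent at
parent-discriminating SNPs, then UPiD via ≥ 90% homozygosity or raw
mBAF > 0.55 with |LRR| < 0.05), inheritance is annotated from parental
LRR over the same span, and regions whose heterozygous-MI1 rate is
binomially elevated are removed as parental somatic artifacts
(one-tailed test at α / number of regions). Baselines come from the
uncalled SNPs of the arm, from the adjacent arm when > 75% of the arm is
called, and from all uncalled autosomal SNPs for whole-chromosome events.

A trio is halted up front when any member's genotype-only MI1 rate is
≥ 2% (likely relationship annotation error) or NC rate ≥ 3% (likely DNA
quality problem). The gate is monotone and can be bypassed explicitly.

## Synthetic data

The generator draws per-SNP B-allele frequencies uniformly on (0.2, 0.8)
— genotyping arrays target common variants; this gives a heterozygosity
near 0.44, in line with the array class the method was designed for —
phased parental haplotypes under Hardy–Weinberg, and Mendelian
transmission. Child BAF is the allele-dosage mixture

    BAF = [(1−f)·b + f·b′] / [(1−f)·2 + f·c′]

for mosaic fraction f, normal/abnormal B-dosages b, b′ and abnormal total
copies c′, plus Gaussian noise (SD 0.03, clipped to [0, 1]); LRR is
0.55·log2(CN/2) + noise (SD 0.15), the 0.55 attenuation approximating
array saturation. Genotypes are re-called from the noisy BAF (AA < 0.2,
AB in [0.3, 0.7], BB > 0.8, NC in the gaps), then perturbed by a 0.2%
genotype error rate and a 0.5% NC rate. Because transmission is phased,
the deviation direction at every informative SNP inside a planted region
is automatically consistent with the assigned parent. UPD is simulated as
isodisomy (the transmitted haplotype duplicated), so non-mosaic UPD
regions annotate as UPiD. Re-calling genotypes as the mosaic fraction
changes is deliberate: the classic frozen-genotype simulation artifact
is not reproduced.

The dilution benchmark plants ten abnormalities (four hemizygous
deletions, three single-copy gains including a whole-chromosome trisomy,
three UPDs; both parental origins; mean 7,355 SNPs) on a 150,000-SNP,
22-autosome genome and realises 21 mosaic states from 0 to 100% normal
cells in 5% steps with shared noise. Sensitivity is scored per region on
modified heterozygous SNPs, specificity on unmodified heterozygous SNPs
pooled over all states, PPV over the mosaic states; a region's detection
threshold is the first percent-normal level above 50 at which its
sensitivity reaches zero.

What this does and does not show: the generator has no wave artifacts, GC
bias, probe-specific effects or LD structure, its noise is homoscedastic
Gaussian, and ~49% of the genome is inside planted regions (the original
region sizes on a ~4× smaller genome). Passing tests therefore
demonstrate the statistical machinery under idealised array behaviour,
not performance on any particular chip. Two scale effects deserve note:
the window-to-genome ratio w/M is ~4× larger than on the array the
benchmark design came from, which raises E(W_k) and hence the minimum
informative count a significant window needs; and at 0–10% normal cells
the region-driven MI1 excess trips the 2% relationship gate, so the
benchmark driver bypasses the gate explicitly. Detection sensitivity at
the weakest mosaic levels is governed almost entirely by the ratio of
the BAF shift (f-dependent, smallest for amplifications) to the
heterozygous noise SD; with the generator's SD of 0.03 the
5–10%-mosaicism states sit at the detection boundary for copy-number
events, while UPDs (shift f/2) remain detectable.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `window` | 100 SNPs | POD window; large pass uses 5× |
| `alpha` | 0.1 | familywise bound per genome; also streak/artifact α |
| `k_sd` | 2 | heterozygous threshold multiplier (SDs) |
| `hd_lrr_threshold` | −1.5 | HD call cutoff (LRR) |
| `mi1_max`, `nc_max` | 2%, 3% | quality-gate bounds |
| `baf_noise_sd`, `lrr_noise_sd` | 0.03, 0.15 | generator noise |
| `lrr_attenuation` | 0.55 | generator log-ratio damping |
| `genotype_error_rate`, `nc_rate` | 0.2%, 0.5% | generator call errors |

## Known limitations

- Autosomes only; sex chromosomes are dropped on input.
- Consanguineous trios reduce informative content genome-wide; the
  pipeline only warns when informative density is anomalously low.
- Mosaic fraction is not estimated or reported per region, and mosaic is
  not distinguished from constitutional.
- The overlap splice rules are deterministic simplifications of a
  many-case procedure; unusual multi-detector stacks may splice
  differently than the original tool would.
- Parallel execution is accepted in the interface but runs serially;
  per-arm independence makes results identical by construction.
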