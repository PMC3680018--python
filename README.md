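# podscan

Parent-of-origin based detection of chromosomal abnormalities in
parent–child trio SNP-array data.

`podscan` is for researchers and clinical scientists who genotype trios on
SNP arrays and want to find deletions, amplifications, uniparental disomy
(UPD) and homozygous deletions in the offspring — including **low-level
mosaic** events that single-sample copy-number callers miss. Its core idea:
at a SNP where the parental genotypes are informative (say father AA,
mother BB), an outlying child B-allele frequency (BAF) reveals *which*
parent contributed excess or missing material. In a normal region the
parent indicated by successive informative SNPs is a fair coin, so for a
sliding window with `n` informative SNPs of which `k` point to the father,

    k ~ Binomial(n, 1/2)

and a two-tailed binomial test flags skewed windows. The per-window
significance threshold β is chosen by a scan-statistics argument that
bounds the familywise error rate across the genome's overlapping windows
at α; a five-fold window rescans still-normal segments for large low-level
mosaics. Three streak detectors (PODhd, PODmi1, PODcr) complement the
window test, detected boundaries are refined by bidirectional CUSUM
change-point analysis on LRR or mirrored BAF, and regions are annotated
for abnormality type, parent of origin, inheritance state and parental
somatic artifacts. See `docs/methods.md` for the full model.

A seeded synthetic-trio generator (Mendelian phased transmission, BAF/LRR
noise, genotype re-calling, planted mosaic abnormalities, and the 21-state
tumor-dilution benchmark design) is part of the package, not a test
fixture: `podscan.simulate`.

## Worked example

Simulate a trio carrying the ten benchmark abnormalities at 20%
mosaicism (80% normal cells), then analyse it:

```sh
$ podscan simulate --out demo_trio.tsv --seed 7 --percent-normal 80
wrote 150000 SNPs (80% normal cells) to demo_trio.tsv
$ podscan detect demo_trio.tsv --out demo_out
11 regions -> demo_out/demo_trio_regions.tsv
```

The region table (first nine columns):

```
chrom  start_pos  end_pos   detector  parent  abn_type  inheritance  n_snps  n_informative
5      1090000    43845000  POD       mother  UPiD      .            8552    1682
5      59570000   99395000  POD       mother  NA        .            7966    815
8      2680000    37240000  POD       mother  NA        .            6913    511
8      55705000   90770000  POD       father  NA        .            7014    538
9      1760000    33735000  POD       mother  NA        .            6396    649
10     45630000   85310000  POD       father  NA        .            7937    788
12     40000      17965000  POD       mother  NA        .            3586    243
12     37940000   64880000  POD       mother  NA        .            5389    405
13     26530000   55475000  POD       mother  NA        .            5790    592
17     764400     21450975  POD       father  UPiD      .            6496    1289
17     26625000   61550000  POD       father  UPiD      .            6986    1366
```

Reading it: every planted region is recovered. The three UPDs (5p, 17p,
17q) are typed `UPiD` with the correct parent of origin — at 20%
mosaicism their mirrored-BAF deviation is strong while LRR stays flat.
The deletions and gains carry `abn_type NA` with a parental *contributor*
label: at this mosaic level their LRR deviation (|ΔLRR| ≈ 0.08) sits
below the ±0.1 typing threshold, so the caller reports the detected
contribution imbalance without committing to a copy-number class (the
BED name field then reads e.g. `NA:M(C)`). Trisomy 12 is reported per
arm. A `--plot` flag adds a per-chromosome LRR/BAF/calls figure;
`demo_out/` also contains a BED file, the estimated per-sample
parameters, and a log.

Remaining columns give each member's region-median mirrored BAF and LRR
as distances from the local (arm) baseline median.

Quality note: trios whose genotype-only Mendelian-inconsistency rate is
≥ 2% or no-call rate ≥ 3% in any member halt with a diagnostic
(relationship annotation error / DNA quality) instead of producing calls.

## Library use

```python
from podscan import RunConfig, run_pipeline, read_trio_table

data = read_trio_table("demo_trio.tsv")
result = run_pipeline(data, RunConfig(alpha=0.1, window=100))
for region in result.regions:
    print(region.chrom, region.start_pos, region.end_pos,
          region.abn_type, region.parent)
```

`podscan batch` analyses many trios; `podscan benchmark` runs the full
dilution benchmark and prints summary metrics.

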