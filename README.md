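# mtduplex

Dual-strand mitochondrial DNA heteroplasmy analysis.

Mitochondrial DNA is a circular, multi-copy genome; a site can be
*homoplasmic* (all copies identical — inherited variants that define the
maternal haplogroup) or *heteroplasmic* (a mutant/wild-type mixture at some
minor allele frequency, MAF). Detecting heteroplasmies at a few percent MAF
is confounded by post-extraction DNA damage (deamination-like C>T/G>A),
which mimics low-frequency variants but lives on a **single strand**. When
two complementary amplicon pools sequence the two strands independently, a
simple rule separates biology from damage:

> a variant present on **both** strands is a *true variant*; a variant on
> one strand only is an *artifact*.

`mtduplex` implements this analysis end to end for researchers working on
mtDNA heteroplasmy in tissues and cohorts:

* `reference_panel` — the circular 16,569-bp reference frame (1-based rCRS
  coordinates, origin wrap) and the two-pool overlapping amplicon panel;
* `synthetic_data` — a strand-resolved pileup simulator (log-uniform depth
  1,000–100,000 around a 30,000× mean, 0.1% base error, planted germline
  haplogroup paths, true heteroplasmies and single-strand artifacts);
* `strand_caller` — a minimal per-pool caller: binomial tail test against
  the error model, Phred quality capped at 100, 1% MAF reporting floor;
* `duplex_concordance` — the both-strand rule, with strict / lenient /
  presence stringencies and depth-weighted combined frequencies;
* `variant_classification` — homoplasmy vs heteroplasmy (≥ 85%), transition
  vs transversion, haplogroup-defining / private / unique, and a
  Kulczynski-scored haplogroup assignment on a packaged mini-tree;
* `hotspot_analysis` — per-tissue burden, recurrence hot-spots, blood-only
  SNPs, MAF-band histograms;
* `cohort_stats` — carrier 2×2 tables, cross-product odds ratios (no
  continuity correction), exact two-sided Fisher tests, paired t-tests;
* packaged, checksummed transcriptions of the published homoplasmy,
  heteroplasmy, annotation and cohort tables, so the reporting pipeline
  runs with no downloads.

## Worked example

Odds ratios on the packaged 222-subject cohort (83 young normal vs 66
older normal), from the command line:

```sh
$ mtduplex cohort --pairs young_nl:old_nl
m.4104A>G    young_nl vs old_nl   OR=26.24   p=7.68e-06
m.5320C>T    young_nl vs old_nl   OR=4.588   p=0.00362
m.13105A>G   young_nl vs old_nl   OR=0.9532  p=1
...
```

m.4104A>G is carried by 82/83 young but only 50/66 older subjects: the
cross-product odds ratio 82·16/(1·50) = 26.24 says the heteroplasmy
declines sharply with age. m.13105A>G shows no young-vs-old difference
(OR ≈ 0.95, p = 1).

The full simulation pipeline, in Python:

```python
import mtduplex as mt
from mtduplex import fixtures

reference = mt.load_packaged_reference()          # 16,569 bp
panel = mt.design_panel(reference)                # 171 amplicons per pool
tree = mt.load_packaged_tree()

subject = mt.simulate_subject(tree, "U2e2a1", seed=1)
truth = mt.plant_events(subject, "blood",
                        [mt.PlantedEvent(1120, reference.base(1120), "T", 0.089)])
pool_a, pool_b = mt.simulate_strand_pileups(truth, panel, mt.SimulationConfig(seed=42))

calls_a = mt.call_pool_variants(pool_a, reference)
calls_b = mt.call_pool_variants(pool_b, reference)
true_vars, artifacts = mt.concord(calls_a, calls_b)
classified, haplogroup, score = mt.classify_variants(
    true_vars, tree, fixtures.annotation_db())
print(haplogroup, score)                          # U2e2a1 1.0
print([(v.position, round(v.combined_freq, 4)) for v in classified
       if v.zygosity == "heteroplasmy"])          # [(1120, 0.0909)]
```

The 32 germline variants come back as homoplasmies (≈ 99.5%) and identify
the haplogroup; the planted 8.9% heteroplasmy is recovered on both strands
at its depth-weighted combined frequency; single-strand artifacts land in
`artifacts` with the reason recorded.

Reproducing the published summary tables from the packaged fixtures:

```sh
$ mtduplex reproduce-paper --out out/
blood heteroplasmy share: 83.8%
S1: haplogroup I1a1b
S2: haplogroup H7b
S3: haplogroup U2e2a1
```

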