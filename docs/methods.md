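# Methods

## The problem and the model

Mitochondrial DNA is a circular, 16,569-bp, multi-copy genome. A variant can
be *homoplasmic* (essentially all mtDNA copies carry it; these are inherited
and jointly define the maternal haplogroup) or *heteroplasmic* (a mixture of
mutant and wild-type copies, quantified by the variant's allele frequency,
MAF). Calling heteroplasmies at a few percent MAF from amplicon sequencing is
confounded by post-extraction DNA modification (classically cytosine
deamination, read out as C>T on one strand / G>A on the other): such damage
lives on a *single* strand, whereas real variants exist on both.

The dual-strand design exploits this. Two complementary primer pools
interrogate the two strands of the circle independently; each pool is called
on its own, and a candidate is accepted as a **true variant** only if it is
observed in both pools — otherwise it is rejected as an artifact. This is
the core rule implemented in `duplex_concordance`.

Downstream, true variants are classified (`variant_classification`):

* zygosity — homoplasmy iff combined frequency ≥ `homoplasmy_min`
  (default 0.85, inclusive). Observed homoplasmies sit at ≥ 89.5% and
  heteroplasmies at ≤ 60.4%, and 85–90% heteroplasmy is the load at which
  point mutations start to impair cellular function, so 0.85 separates the
  regimes with margin. The "<40%" threshold (`low_frequency_max`) is a
  reporting flag, not part of the heteroplasmy definition: the source
  heteroplasmy table itself contains entries at 50.6% and 60.4%.
* substitution class — transition iff {ref,alt} = {A,G} or {C,T}.
* category — haplogroup-defining if on the assigned haplogroup's path,
  else private if present in the packaged annotation set, else unique.
  "Unique" is therefore relative to the shipped fixture, not to any live
  database.
* haplogroup — a Kulczynski-style scorer over a packaged mini-tree:
  for each node, score = ½·(matched/expected-on-path + matched/observed),
  maximised over nodes, ties broken toward the shallowest node then
  lexicographically. An empty homoplasmy set returns the root. This is a
  deliberate simplification of Haplogrep/Phylotree; the packaged tree
  carries only the three study haplogroup paths (I1a1b, H7b, U2e2a1) plus
  their shared trunk, and the fixture tests pin all three labels so the
  simplification is audited.

Cohort statistics (`cohort_stats`) treat carrier status as presence/absence
of the heteroplasmy. For a 2×2 carrier table the odds ratio is the raw
cross-product (a·d)/(b·c) — no Haldane/continuity correction; a zero
cross-cell raises a typed error, because the published ratios are plainly
raw cross-products (e.g. 82·16/(1·50) = 26.24). The two-sided Fisher exact
p-value uses the point-probability rule (sum of hypergeometric
probabilities ≤ the observed one, with the customary 1+1e-7 relative
tolerance), accumulated in log-space; mid-p and doubling variants are *not*
used. No multiple-testing adjustment is applied by default (a
Benjamini–Hochberg option exists behind a flag).

## The simulator

`synthetic_data` generates exactly what the analysis consumes: per-pool,
per-position nucleotide counts. It emulates

* **depth**: log-uniform per position between `depth_min` = 1,000 and
  `depth_max` = 100,000, rescaled toward `depth_mean` = 30,000 and clipped —
  the deep-amplicon regime of this panel type. The rescaling is one-step, so
  the realised mean is ≈ 28,500 rather than exactly 30,000; the range
  constraint wins over the mean.
* **germline**: the subject's haplogroup path SNPs at 99.5% allele
  frequency in both pools of every tissue (printed homoplasmies cluster at
  99.0–99.9%, never 100%).
* **true heteroplasmies**: binomial alt counts at the event MAF in *both*
  pools.
* **single-strand artifacts**: the same, but in one pool only —
  deamination-like C>T/G>A where the reference base allows.
* **errors**: each reference read substitutes to a non-reference base at
  `base_error_rate` = 0.1%, split uniformly across the three targets by
  default (`ts_error_weight` = 1/3; raising it gives a transition-biased
  spectrum for transition/transversion power studies).

All draws flow from a single `numpy` generator per simulation call, so runs
are bit-reproducible from one seed. Tissue differences (more heteroplasmy
in blood) are imposed through the event lists, not modelled mechanistically
— the source study reports the tissue effect, it does not explain it.

What the simulator does **not** model: read-level effects (PCR duplicates,
mapping bias, primer-proximal artifacts), NUMT cross-amplification, mtDNA
copy number, indels, and position-dependent error spectra. Passing the
recovery tests therefore demonstrates the statistical soundness of the
duplex rule under binomial noise, not robustness to every failure mode of
real libraries.

## The caller and its thresholds

`strand_caller` is intentionally minimal: per (position, alt) it computes
the binomial upper tail P[X ≥ alt_count], X ~ Binom(depth, error_rate/3),
Phred-scales it (capped at 100), and applies `min_maf` = 1% (the assay's
reporting floor), `min_depth` = 1,000 and `min_qual` = 30. Candidates down
to `min_maf/2` are emitted with explanatory filter flags instead of being
dropped, so the concordance stage can account for every near-threshold
observation. The published pipeline used a production somatic caller; none
of the downstream results depend on caller subtleties — only on
frequencies well above the noise floor.

**Detection-limit studies use the presence rule.** A hard per-strand PASS
cutoff placed exactly at the planted MAF censors ~half of borderline events
(the observed frequency of a 1% variant is ≥ 1% with probability ≈ 0.5 per
strand), so strict both-PASS concordance cannot characterise the detection
limit of the duplex design itself. The recovery/specificity experiments in
`experiments.py` therefore use `concord(..., require_pass=False)` — the
literal both-strand-presence rule with the `min_maf/2` candidate floor.
This is the *harder* setting for artifact rejection and specificity (more
candidates survive per pool), and both still hold: a single-strand artifact
produces ~error/3 ≈ 0.03% signal on the other strand, far below the 0.5%
candidate floor, and a coincidental same-alt ≥ 0.5% error on both strands
is (depth ≥ ~1,400, error 0.1%) a ≪ 10⁻⁶-per-genome event. The production
pipeline default remains strict both-PASS; a lenient middle mode (PASS on
one strand + presence on the other) is available.

## Packaged fixtures and their known quirks

The five table fixtures are verbatim transcriptions of the published
summary tables, checksummed and verified on load. Known internal
inconsistencies of the printed tables are preserved as printed:

* the full heteroplasmy table has **167** Subject-3 blood entries while the
  printed per-tissue summary and the transition/transversion summary both
  say 165; consequently the aggregate blood share computes as 337/402 =
  83.8% (the printed headline value) but per-subject denominators differ by
  two;
* the heteroplasmy table prints m.6266A>C at 1.47% in Subject-2 blood — an
  A>C transversion — while the transition/transversion summary counts only
  6 transversions among the same 135 blood entries. Recomputing from the
  table necessarily gives 7 (5.19%). No transcription can satisfy both
  printed numbers; the fixture keeps the table, and the recomputed
  partition is reported as computed;
* the hot-spot table's published membership (23 SNPs) is not derivable from
  the heteroplasmy table by the stated at-least-two-subjects rule alone
  (e.g. the poly-C-tract SNPs 309C>T/310T>C recur but are excluded without
  comment), so the hot-spot *count* is not pinned; membership of specific
  SNPs is. An optional exclusion preset for the poly-C tract (302–316) is
  provided;
* the printed per-tissue significance ("blood > retina, p ≤ 0.05") is not
  reproducible by the two-tailed paired t-test on the printed counts
  (35,135,165 vs 9,8,3 → p = 0.1235 with 2 df); the t-test operation is
  provided and its computed value pinned in tests;
* the published group comparisons print odds ratios for three SNPs
  (m.5471/m.5474/m.5498) that do not follow from the published carrier
  counts by the cross-product formula; those rows are excluded from the
  pinned checks.

The packaged reference FASTA is a **synthetic** rCRS-length stand-in: a
seeded pseudo-random 16,569-bp sequence with the printed reference allele
pinned at the 245 positions any fixture or tree SNP refers to. A real rCRS
FASTA can be supplied by path. Coordinates are 1-based inclusive
throughout; amplicons may wrap the origin (end < start), since the control
region spans it.

## Problem sizes used by tests and the acceptance script

Fixture-derived checks are exact and instantaneous. The seeded studies use
200 runs × 5 planted true heteroplasmies (1% MAF) and 5 artifacts (≤ 10%
MAF) for the duplex detection limit, 100 event-free genomes for
specificity, 100 simulated subjects for haplogroup recovery, and 100
simulated cohorts (83 vs 66 subjects, carrier probabilities 0.988 vs 0.758,
mirroring the strongest published age effect) for odds-ratio direction
recovery — sizes at which the binomial standard errors of the pinned rates
are well below the asserted margins, and a full run takes a few seconds.

## Limitations

The haplogroup scorer only distinguishes haplogroups present in the packaged
mini-tree; it is not a general classifier. Fisher p-values are exact but the
published p-values themselves conflict between text and tables, so only the
odds ratios are pinned. Indels, structural variants and copy-number are out
of scope; the pipeline calls SNVs only.
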