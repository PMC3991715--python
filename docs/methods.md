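# Methods

## Scope and data model

The package analyses loss of heterozygosity (LOH) in paired samples of one
patient: a germline reference (blood) and one or two tissue samples
(e.g. distant normal Td and tumor Tt, or tumor and metastasis). Input is a
shared ordered panel of biallelic autosomal loci with a genotype call per
sample — AA, AB, BB, or no-call. Genotypes are abstracted to two allele
codes; multi-allelic and non-diploid records are rejected or skipped at
ingest. Sex chromosomes, phasing, and tumor-purity correction are out of
scope. All internal coordinates are 1-based inclusive; BED import/export
converts to and from 0-based half-open.

## Transition taxonomy

Each germline x tissue call pair maps to exactly one of ten categories
(the 4x4 pair space partitions completely): HET→HOM (the LOH event),
HOM→HOM, HET→HET, HET→UNK, UNK→UNK, UNK→HET, UNK→HOM, HOM→UNK,
monoallelic mutation (AA→AB), and biallelic mutation (AA→BB). The
classification is symmetric under relabeling the two alleles.

## Tract calling

A tract is a maximal run of HET→HOM events within one copy-number-state
block on one arm, terminated by HET→HET, HET→UNK, UNK→UNK, UNK→HET, a
biallelic mutation, or a block/arm boundary. Interior loci may be
HOM→HOM, monoallelic mutations, HOM→UNK or UNK→HOM: these carry no
evidence against LOH continuity. HOM→UNK and UNK→HOM are not part of the
terminator set — they are uninformative about heterozygosity — but they do
count toward the no-call QC fractions. Tract coordinates span the
outermost supporting events; length is inclusive (`end − start + 1`), so
one event gives the minimum length of 1 bp. We chose the inclusive
convention uniformly because the single-event case fixes it: an interval
containing one base has length 1.

Parameters (`CallerParams`):

| parameter | default | meaning |
|---|---|---|
| `min_events` | 2 | support criterion; 2 = stringent, 1 = loose |
| `gap_threshold_bp` | 40,000 | copy-neutral sparsity split distance |
| `apply_sparsity_split` | on (array mode) | split neutral tracts at >threshold event gaps |
| `qc_monoallelic_max` | 0.20 | exclusive bound on monoallelic fraction |
| `qc_nocall_max` | 0.20 | exclusive bound on either no-call fraction |
| `cnv_min_length_bp` | 0 (array) / 100,000 (sequencing) | drop short CNV calls before stratification |

`CallerParams.array_mode()` and `.sequencing_mode()` encode the two
platform presets: sparse array panels need the sparsity split and take CNV
segments as given; dense sequencing panels need no split but benefit from
dropping sub-100 kb CNV calls, which are enriched for false positives.

The 40 kb default derives from the spacing distribution of consecutive
germline heterozygotes on the genotyping platform: the upper outer fence
Q3 + 3·IQR, computed with linear-interpolation quantiles
(`derive_gap_threshold`). Supply platform-specific spacings to
recalibrate.

Numerical choices where the procedure admits variants:

* **Sparsity splitting is single-pass**: every qualifying gap (> threshold,
  strict) is cut at once, then fragments are re-filtered by `min_events`.
  Iterating cannot create new qualifying gaps, so one pass is exact.
* **QC runs last**, on final (post-split) tracts. QC denominators use all
  panel loci within the tract span, not only informative loci; this keeps
  the 20% bounds stable at high marker density.
* QC bounds are **strict**: exactly 20% is retained.
* Loci in centromeric gaps (outside every annotated arm) are ignored by
  the caller; `assign_arm` raises for them when called directly.

### Variant-level ingest QC

`ingest_qc` removes variants with cohort call rate below 95% and variants
exceeding a per-panel no-call budget (default: more than 2 no-calls across
the configured sample vectors, i.e. removal at ≥3), both configurable.

## Concurrence and overlap patterns

Concurrent LOH is ≥1 bp of overlap between tracts of the two samples
(inclusive arithmetic: `min(ends) − max(starts) + 1`). Overlapping pairs
partition into: Equal (identical endpoints); Exa-s / Exa-d (the low-stage
tract longer, sharing one endpoint / strictly containing the high-stage
tract); Exb-s / Exb-d (symmetric); Pa (staggered: both endpoints differ,
neither contains the other). Containment with both endpoints differing is
double-end extension, not partial overlap — Pa is reserved for staggered
pairs. Endpoint equality is exact, which is well-defined because both
samples are called on the same locus panel.

Extension lengths are the bp of each tract outside the shared region; for
Pa pairs the non-overlap length is their sum, so
`overlap + extensions = union footprint` holds for every pair. The change
statistic is (Total − Equal)/Total.

Counting convention: a tract overlapping k partner tracts contributes k
pair records to overlap-pattern tallies (preserving length bookkeeping)
but counts once in concurrence rates, whose denominators are tracts. The
convention is recorded in output provenance.

## Permutation null

Each tract keeps its arm and its length and is re-placed uniformly among
the positions that keep it wholly inside the arm's eligible interval: the
arm minus 3 Mb on the centromeric edge and 10 kb on the telomeric edge.
Tracts longer than the eligible interval stay at their original location
with a logged warning. Overlapping placed tracts are merged into their
union and the merged set is what enters the null rate; the mean fraction
of tracts lost to merging is reported (not asserted — on realistic
densities it is a few percent). Both sets are shuffled by default;
single-set shuffling is available. The empirical p-value uses the
(b + 1)/(n + 1) estimator, one-sided in the ≥ direction, and the result
also reports the null min/max/mean per direction. 5,000 permutations is
the default. Determinism: one seed in `PermutationConfig` drives a single
generator; identical inputs and seed give byte-identical null arrays.

## Arm and gene summaries

Arm profiles divide per-arm total tract length by arm length, making arms
comparable; cohort summaries report median/Q1/Q3 per stratum (e.g. tumor
T stage). Profile correlation between two samples' mean profiles is
Pearson's r with the two-sided t-transform p-value (df = #arms − 2);
cohort-mean profiles are the default (per-patient profiles remain
available), and arms undefined on either side drop pairwise.

Gene-level concurrence counts, per gene: patients whose two samples both
carry a stringent tract overlapping the gene region (≥1 bp of tract inside
the gene — tract events need not lie inside it); patients where
additionally some tract pair overlaps ≥1 bp inside the gene; and
informative patients (≥1 germline HET locus in the gene). The ordering
`overlap ≤ no-overlap-required ≤ informative` is asserted cohort-wide.
Enrichment of a gene category among top-concurrence genes (default cut:
≥6 patients with overlapping concurrent LOH) is a df = 1 chi-square
goodness-of-fit against the category's baseline frequency, computed either
over all genes or over genes with ≥1 concurrent patient; outputs label the
baseline used. No multiple-testing correction is applied across genes.

## Synthetic cohorts

The generator emulates the structure the pipeline consumes, with truth
recorded for every planted feature. Defaults define the package's standard
study conditions; they are desk-scale, chosen once:

* **Genome**: 6 chromosomes, 30 Mb p-arm + 40 Mb q-arm, 4 Mb centromeric
  gap (12-arm, 420 Mb toy genome — large enough for hundreds of planted
  tracts at realistic density, small enough for fast tests).
* **Markers**: Poisson-process positions, mean spacing 2 kb; germline HET
  rate 0.33 (≈ the heterozygous fraction of a deep catalog of segregating
  biallelic variants). Exponential spacing also makes the Q3 + 3·IQR fence
  well-defined on synthetic spacings.
* **Noise**: no-call rates 0.0044 (blood) and 0.0165 (tissue) — platform
  averages for those sample classes; monoallelic 0.002 and biallelic
  0.0005 mutation noise (small, order-of-magnitude realistic).
* **Planted Td tracts**: 40 per patient, lengths log-uniform 20 kb–2 Mb,
  arm weights configurable (uniform default), 99% copy-neutral — matching
  the observation that nearly all normal-tissue LOH is copy-neutral —
  with each non-neutral tract emitting a covering CNV segment so caller
  state labels agree with truth.
* **Inheritance**: each Td tract recurs in Tt with probability 2/3; each
  end of an inherited tract extends with probability 0.3 by a geometric
  draw with mean 100 kb. The extend-or-not mixture is deliberate: it gives
  Equal, single-end and double-end extension patterns computable, non-zero
  probabilities (a pure bp-geometric would make Equal essentially
  impossible). 80 independent Tt tracts model tumor-private LOH, giving
  the characteristic rate asymmetry (high Td→Tt, low Tt→Td).
* **Cohort**: 12 patients split ~27/62/11% across T1/T2/T3&4 with planted
  burden multipliers 1/2/3.

Planted tracts that overlap, or that have no informative marker between
them, are merged in truth — two tracts indistinguishable on the realized
panel are one tract to any marker-based caller.

What the generator does **not** model: linkage disequilibrium, realistic
allele-frequency spectra, subclonal mixtures, GC or mappability structure,
read-level errors. Passing recovery tests therefore demonstrates the
pipeline's correctness on its own model of the data, not calibration on
real cohorts.

## Verification strategy and problem sizes

* The tract scanner is checked against a brute-force enumeration of
  maximal terminator-free runs on 1,000 random paired vectors of ≤50 loci,
  for both support criteria.
* The overlap classifier is checked exhaustively over all interval pairs
  on a 12-position axis (partition and swap symmetry).
* The permutation null is checked analytically: for one tract per set the
  null concurrence probability equals the exact uniform-placement overlap
  probability, verified within three standard errors at 5,000 permutations
  for three length/arm configurations.
* Parameter recovery: with zero noise every callable planted tract is
  recovered exactly (boundary error within the local informative-marker
  spacing, the resolution limit) with zero false positives; with
  inheritance 2/3 over 20 replicate cohorts (200 planted tracts each, on a
  12-chromosome genome so placement collisions stay negligible) the
  pipeline-estimated concurrence rate falls in the pooled binomial 95%
  band; stage multipliers 1<2<3 order the per-stratum median burdens; and
  arms with doubled planting weight top the cohort mean profile.
  Concurrence for the binomial check is counted per planted tract (a
  planted tract is concurrent when any called fragment of it overlaps the
  partner sample), because no-call noise fragments called tracts and
  fragments of one planted tract are not independent Bernoulli draws.

## Known limitations

* Endpoint equality is exact-position; comparing samples called on
  different panels would misclassify near-equal pairs (not a supported
  use).
* The permutation null preserves tract lengths and arm assignment but not
  local marker density; a density-matched null is out of scope.
* Gene-level counting uses interval overlap only; it does not require
  supporting events inside the gene.
* The merged-tract count reduction in the null (typically 1–3%) slightly
  deflates null concurrence when tract density is high.
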