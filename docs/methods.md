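# Methods

This note records the models, procedures, parameter choices and known
limitations of `cpvar`, in the order the pipeline runs them.

## Scope and inputs

The pipeline starts where variant calling and annotation end. Read
alignment, SNV/indel calling, CNV calling and functional annotation
(BWA/GATK-class and ClinSV/CNVnator/Lumpy-class tools, ANNOVAR-class
annotators) are upstream; their outputs — an annotated VCF, a PED file,
a CNV call table with population allele frequencies, phenotype and
gene-resource tables — are this package's inputs. INFO key names are
configurable (`info_key_map`) because annotator dialects vary; the
defaults are GNOMAD_AF, EXAC_AF, CADD_PHRED, SIFT, PP2_HVAR, MT,
METASVM, GERP_RS, CLNSIG, GENE, CSQ_CLASS.

Internal coordinates are 1-based inclusive everywhere (the VCF
convention). BED-like CNV input is 0-based half-open and converted on
read; a CNV touching a gene's single terminal base overlaps it.
Multi-allelic VCF records are split per ALT before annotation lookup.
Readers never default a missing annotation: absent INFO keys become
`None`, and downstream predicates must decide what missingness means.
VCF floats are normalized to six significant digits on read, since the
format carries single-precision values.

## Filter thresholds and their meaning

Defaults (all exposed in `FilterConfig`):

| parameter | default | meaning |
|---|---|---|
| `filter1_af` | 1e-4 | rare-deleterious track frequency cut (fraction) |
| `filter2_af` | 1e-2 | recessive track frequency cut |
| `cadd_min` | 20 | CADD scaled-score cut ("where available") |
| `gerp_min` | 4 | GERP++ RS deleterious-vote cut |
| `votes_min` | 3 | deleterious in-silico votes required (of 5) |
| `batch_ac_max` | 2 | max ALT allele count within a calling batch |
| `min_batch_size` | 40 | joint-calling batch size below which we warn |
| `cnv_af_max` | 0.01 | CNV population-frequency (MGRB) cut |
| `intolerant_missense_z` | 2 | missense-constraint cut for the VUS track |
| `intolerant_lof_oe` | 0.5 | LoF observed/expected cut for the VUS track |
| `ba1_af` / `bs1_af` | 0.05 / 0.01 | ACMG benign frequency thresholds |

Decisions where the source methods were open:

- **Frequency join.** "Frequency in gnomAD and ExAC" is read as the
  *maximum* of the two being below threshold — the conservative join.
  A variant absent from both databases is treated as frequency 0.
- **Evidence routes in the rare-deleterious track.** The in-silico vote
  and panel membership are alternative support routes combined with OR
  by default (`evidence_mode: any`); AND is available (`all`). Missing
  CADD does not veto the track (stopgains and indels often lack scores);
  missing predictors shrink the vote denominator, so a variant with
  fewer than three available predictors can only pass via a panel.
- **ClinVar matching** is against whole significance categories,
  case-insensitively, splitting slash/comma composites; "conflicting
  interpretations" strings never match.
- **Di-genic candidacy** is off by default and requires an explicit
  gene-pair list; no defensible default pair source exists.
- **Parental no-calls** are treated as an absent parent (the label
  degrades from, e.g., de novo to single-parent evidence) and the
  distinction is recorded in the confidence note.

## Inheritance and phasing

Labels are a pure function of the genotypes and pedigree. De novo
requires both parents genotyped reference; "not maternal"/"not paternal"
encode a single reference-genotyped parent; a heterozygous proband with
both parents carrying is labelled unknown (either parent could have
transmitted). Mendelian impossibilities (autosomal homozygote with a
reference-genotyped parent) yield `unknown` with a `mendelian_conflict`
note, never a silent relabel. "Biparental" covers homozygous-by-descent
findings with both parents carrying. Sibling genotypes refine the
confidence note only, never the label. Mitochondrial variants are
labelled maternal when detectable in the mother at any heteroplasmy.

Compound-heterozygote phase is derived from parental origin: opposite
parents ⇒ trans (recessive candidate), same parent ⇒ cis (reported,
rejected from candidacy), unresolved ⇒ unknown (kept as "possible").
An external long-read phasing table overrides genotype-derived phase.

## Classification policy

Only six ACMG tags are auto-derived — PVS1 (loss-of-function class in a
LoF-intolerant gene with an established LoF mechanism), PM2 (below the
rare-variant threshold), PP3 (≥ 3 in-silico votes), PS2 (trio-confirmed
de novo), PP4 (curated phenotype fit), BA1/BS1 (benign frequency) — and
everything else is accepted as a curated assertion with provenance.
Real-world classifications rest on literature evidence a pipeline cannot
recompute; what must be reproducible is the combining step, so the
published combining rules are hard-coded as an explicit rule table and
verified in two ways: unit tests against the published rule statements,
and full-lattice equivalence against a second, independently coded
decision procedure over all 2¹⁶ subsets of a 16-tag universe.

The penetrance policy downgrades a P/LP variant to uncertain when it was
demonstrably inherited (label maternal or paternal) from an unaffected
parent and the gene has no documented incomplete-penetrance/variable-
expressivity caveat. The rule never applies to recessive- or
mitochondrial-mode genes, where unaffected carrier parents are expected,
and never upgrades.

Clinical significance combines the class with two curated inputs: a
phenotype-fit level (full / partial / none / unknown) and a risk-allele
flag. Full fit + P/LP ⇒ causative; partial fit (aetiology-consistent
predisposition) or a flagged risk allele ⇒ risk factor; no fit ⇒
incidental; otherwise uncertain. Aetiology groups
(stroke/cardiovascular, HSP, NDD) come from disjoint gene sets; a gene
in two sets is an error.

## The packaged fixture

`cpvar/data` carries a transcription of the published summary tables of
a 150-proband CP genome-sequencing cohort: 59 variant rows across 51
individuals (28 causative, 9 risk-factor, 10 with uncertain P/LP
findings, 4 incidental; 7 diagnosed individuals carry CNVs), the
aetiology gene sets, and the cohort composition. Counting conventions:
an individual is "uncertain" if they carry ≥ 1 P/LP finding of uncertain
significance and no causative finding (this is what makes the count ten,
including one individual who also carries a risk-factor CNV); the
stroke/cardiovascular set is the thrombophilic + small-vessel +
cardiac/vascular genes (14 diagnosed individuals), with the ion-channel
and other-syndrome genes in the NDD group (18 individuals).

The per-row curated ACMG tag sets are **synthetic stand-ins**: the
study's real evidence items live in an unpublished supplementary table,
so the loader derives a deterministic tag set from each row's printed
class, consequence and frequency (loss-of-function rows get PVS1-based
sets, others PS/PM-based sets; the moderate tag is PM2 only where the
printed frequency supports it). They are constructed so the combining
rules reproduce every printed class — which is exactly what the
classification invariant tests assert — and carry no independent
evidential meaning. A checksum file guards the transcription against
accidental edits.

## Synthetic cohorts

The generator's defaults are the study conditions: 150 probands (18
trios, 63 maternal + 13 paternal duos — the printed 62/13 split does not
sum to the printed 76 duos, so one maternal duo is added — 56
singletons; 93 male / 57 female), 37 planted reportable findings
(28 causative + 9 risk-factor; 7 CNVs, 2 homozygous-recessive, 2
compound-het, 2 known-pathogenic-track, the rest dominant), proband
batches of 50 and separate parental batches, and comorbidity counts
linked to diagnosis through a logistic model with OR 1.68.

Mechanics worth knowing:

- Variants live on two synthetic contigs with a packaged ~60-gene toy
  model; the pipeline never touches sequence, only annotations.
- Inheritance truth is drawn first, genotypes second, so Mendelian
  consistency is guaranteed except for deliberately planted de novo
  (rate 0.02 among background variants) and Mendelian-conflict cases
  (rate 0.01).
- Background annotations are drawn from mixtures placing mass on both
  sides of every threshold, and dedicated shared variants sit at batch
  allele counts of exactly 2 and 3, so the filters are exercised at
  their boundaries; a separate deterministic `boundary_suite` pins one
  case on each side of each threshold.
- Probands and parents are batched separately. This mirrors
  proband-first sequencing and keeps a trio-transmitted homozygote
  (proband 2 alleles + 2 parental) from tripping the within-batch
  allele-count exclusion, which counts alleles wherever the batch map
  puts the carriers.
- Comorbidity counts are drawn retrospectively: with diagnosis status
  fixed, counts come from the Bayes-consistent conditional of the
  logistic model (Binomial(3, 0.35) prior on the count, intercept
  solved so the marginal diagnosis rate matches the planted 37/150).
  Case-control sampling leaves the logistic slope estimable without
  bias, which the parameter-recovery tests verify; 13 individuals get
  missing comorbidity data, matching the 137/150 availability.
- Output is byte-identical for identical (config, seed).

What passing on synthetic data does **not** show: the generator has no
linkage disequilibrium, no annotation errors or caller artefacts beyond
the planted batch-sharing structure, phenotype fit is a clean curated
flag rather than a judgement call, and planted evidence tags are always
sufficient for P/LP. Recovery of the planted truth therefore validates
the plumbing and the predicates, not robustness to messy annotation.

## Statistics

- Percentages are rounded half-up to one decimal, matching
  clinical-yield reporting.
- Subset enrichment is the upper-tail hypergeometric P(X ≥ k), computed
  via scipy's log-space implementation and cross-checked against
  exhaustive subset enumeration for N ≤ 12.
- The χ² test is Pearson without continuity correction by default (the
  correction is a config switch); the published per-comorbidity χ²
  values depend on per-individual tables that are not part of the
  published summary, so they are exercised by formula-level tests, not
  reproduced.
- Logistic regression is a statsmodels ML fit (Newton/IRLS, gradient
  tolerance 1e-8, 50 iterations); odds ratios are exp(coefficients)
  with Wald 95% CIs. Perfect separation and constant covariates raise,
  naming the covariate. The published adjusted ORs likewise need the
  per-individual table; the estimator is validated by closed-form
  identities (a single binary covariate's OR equals the 2×2
  cross-product ratio) and by parameter recovery at OR 1.68, n = 150,
  500 replicates.

## Assay calculators

qPCR copy number is the 2^(−ΔΔCt) method with a diploid calibrator
(CN = 2·RQ); replicate Cts are averaged upstream (the assays run in
quadruplicate). Standard-curve efficiency is 10^(−1/slope) − 1 from the
least-squares slope of Ct on log₁₀ input; a non-negative slope is a
non-amplifying error. MLPA copy calls use thresholds 0.25/0.75/1.25 —
midpoints between the expected normalized ratios 0, 0.5, 1, 1.5 for 0–3
copies; the thresholds are not part of the assay description and are
exposed in config. XCI skewing uses the standard correction at a
polymorphic locus: each allele's digested/undigested peak ratio is its
bias-corrected inactivation share; skew is reported raw as
100·max(fraction) with no categorical call, since no numeric cutoff for
"complete skewing" is defined.

## Problem sizes in tests and the acceptance script

The routine suite runs a 40-proband synthetic cohort (12 planted
findings) for pipeline-level checks and the full 150-proband default
cohort once for the recovery check; the ACMG lattice check covers all
65 536 subsets; the OR-recovery check uses 500 replicates at n = 150.
These sizes keep the whole suite in the tens of seconds while exercising
each component at the study's own scale where it matters.

## Known limitations

- Only the explicit penetrance-downgrade rule is implemented; the wider
  "more evidence required without trio data" tightening is not
  quantifiable and is left to curated tags.
- Transcript selection, canonical-isoform logic and re-computation of
  any in-silico score are out of scope; annotations are consumed as-is.
- CNV/MGRB frequency matching (what overlap counts as "the same
  variant") is the upstream caller's concern; its AF is consumed as-is.
- Parental mosaicism is not modelled; an inherited label means the
  allele was detected in the parent, nothing more.
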