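# Methods

`ithkit` analyses somatic single-base substitutions (SNVs) from tumours
sampled at several spatial regions and, optionally, at two timepoints
around neoadjuvant chemo(radio)therapy. This note describes the models
behind each stage, the defaults and why they were chosen, what the
synthetic cohort generator does and does not emulate, and the numerical
choices that matter for reproducing results.

## Mutation populations

A mutation is identified across samples by its genomic key
(chromosome, 1-based position, ref, alt). Within one tumour:

* **Spatial** (two treatment-naive biopsies): a key called in both
  biopsies is *shared*; called in exactly one, *private*.
* **Temporal** (pre- + post-treatment samples): *shared* means called in
  every available sample; *unique pre* means called in at least one
  treatment-naive sample and no post-treatment sample; *unique post* is
  the converse. Keys present in some-but-not-all samples spanning both
  timepoints fit none of those definitions; rather than silently folding
  them into a class, they are labelled *partial* and excluded from
  unique-pre/post analyses.

"Called" means present in the sample's input call set. No pileup-based
rescue of uncalled sites happens at this stage; rescue counts feed only
the clonal decomposition. Tumours with more than two treatment-naive
biopsies must name the analysis pair explicitly in the pipeline
configuration (`spatial_pairs`).

## Mutational signatures

Catalogues are 96-channel trinucleotide-context counts under the
standard pyrimidine-centric convention (purine-reference mutations are
reverse-complemented; the 192 strand-specific inputs map two-to-one onto
96 channels, COSMIC channel order).

Exposures solve a quadratic programme: minimise `||P w − c||²` over the
probability simplex, where `c` is the frequency-normalised catalogue and
`P` the signature matrix. The catalogue is normalised first so weights
are mutation-fraction exposures. The solver is projected SLSQP with an
analytic gradient; it is deterministic and agrees with a dense simplex
grid search to well under the grid resolution on small problems.

Signature selection follows a two-threshold protocol:

1. **Cohort screen (10%)** — exposures are fitted per sample over all of
   that sample's mutations against the full candidate matrix; signatures
   reaching ≥ 10% weight in at least one sample form the cohort set.
   A fixed set can be pinned in configuration instead; the shipped
   default candidate list is SBS1/2/3/5/8/13/17a/17b/18/20/26/36/39/40/44/93.
2. **Per-population prune (5%)** — each mutation population (shared,
   private, unique-pre/post, per-clone) is refitted against the cohort
   set; signatures below 5% are removed and the fit repeated, iterating
   to a fixed point so every retained signature ends at ≥ 5% (the
   largest-weight signature is never dropped, so one signature always
   survives). A single-pass mode is available for strict replication of
   a one-shot prune; the fixed-point default guarantees the stated
   postcondition.

The platinum-therapy signatures SBS31/SBS35 are added to the candidate
set only for pre-/post-treatment (temporal and per-clone-with-post)
analyses. Populations smaller than 50 mutations are fitted but flagged
low-confidence — small catalogues carry large multinomial noise.

A signature group (APOBEC = SBS2+SBS13, MMR/MSI = SBS20+SBS26+SBS44) is
*present* in a population when any member survives the 5% prune; the
pruning threshold is deliberately the dichotomisation cutoff, since any
surviving weight is by construction ≥ 5%.

## Platinum enrichment odds ratio

Platinum chemotherapy deposits C>A substitutions at CpC dinucleotides.
For a mutation population, eligible mutations are C>A (and G>T, read as
C>A on the opposite strand). In a 41-base window centred on each mutated
cytosine:

* numerator odds — mutated cytosines with a 5′ C neighbour : without;
* background odds — over all windows with multiplicity, reference C
  positions in CpC context : not (G positions counted as reverse-strand
  Cs); window edge positions whose defining neighbour falls outside the
  window are skipped.

The odds ratio is their quotient. "CpC" is read as the CC dinucleotide
5′→3′ ending at the mutated base; the 3′-neighbour variant is available
(`neighbor_side="3p"`) because the convention is genuinely ambiguous in
the source literature. The background is window-restricted rather than
genome-wide, matching the per-mutation-centred definition of the
statistic. Any zero cell triggers a Haldane +0.5 correction on all four
cells, flagged in the result; populations with no eligible mutation
return a flagged undefined result rather than a number.

## Clonal decomposition

Read counts for the union of a tumour's calls are collated across
samples (uncalled cells filled from a pileup table; cells absent from
both flagged missing). The cancer cell fraction (CCF) estimator is
multiplicity-based: with VAF `f`, purity `ρ`, total copy number `n_t`
(tumour) and 2 (normal), mutation copies are
`f·(ρ·n_t + (1−ρ)·2)/ρ`; the integer multiplicity is the nearest
integer clamped to `[1, n_major]`, and CCF is copies/multiplicity
clamped to [0, 1].

Clones are fitted as a finite mixture: clone `k` is a vector of
per-sample CCF centroids `c_ks`; a mutation's alt count in sample `s`
is binomial with success probability `q_is · c_ks`, where `q_is` maps
CCF to expected VAF through purity, copy number and multiplicity. EM
alternates responsibilities with an exact per-centroid M-step (the
weighted binomial log-likelihood is concave in each centroid, solved by
clamped Newton from the ratio estimator). Exploratory restarts use the
cheap ratio-estimator M-step on a seeded subsample of mutations; the
top candidates are polished on the full data. Model size is chosen by
BIC over K = 1..40 with 100 seeded restarts per K (restart r uses seed
+ r), stopping the K sweep after three consecutive non-improvements.
The fit is deterministic given the seed; the EM log-likelihood is
non-decreasing across iterations.

Post-processing: clones holding < 1% of the tumour's mutations are
excluded (their mutations flagged unassigned; pre-prune fractions
retained); per-clone signature profiles use only mutations assigned to
that clone, so clone profiles never share information; prevalences are
averaged within each timepoint for fishplot-style tables.

The clone tree is a greedy containment heuristic replacing manual
review: clones in decreasing mean prevalence, each attached to the
placed candidate parent with the smallest mean prevalence that
satisfies (a) child ≤ parent per sample and (b) siblings sum ≤ parent
per sample, both within tolerance 0.05; ties break on smaller clone id.
Unattachable clones fall back to the founder; cohorts without a clone
spanning all samples at maximal prevalence are flagged as forests.

## Neoantigens and DAI

Predicted epitopes with mutant IC50 ≤ 500 nM (inclusive) are putative
neoantigens. The differential agretopicity index is
`DAI = IC50_WT − IC50_MT` (nM): positive values mean the mutant peptide
binds MHC more strongly than its wild-type counterpart. Group summaries
(per population or clone) report n, median and quartiles per
(peptide, HLA) record by default; a best-binder-per-mutation mode
exists because the aggregation convention varies between studies.

## Survival and hypothesis tests

Disease-specific survival is censored at 60 months at table-read time,
so no downstream code ever sees uncensored times. Kaplan-Meier curves
and the log-rank test come from lifelines; Cox proportional-hazards
fits use partial likelihood with Breslow tie handling (Efron
selectable), with clinical cTNM stage encoded as a single ordinal
covariate (IB=1, IIB=2, III=3, IVA=4). Constant exposure flags and
monotone likelihoods (separation) yield flagged results with no finite
hazard ratio. Paired t, Fisher's exact and Kruskal-Wallis tests are the
scipy implementations; FDR adjustment is Benjamini-Hochberg step-up.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the
analysis assumes, so every stage is testable without access to
restricted patient data. Defaults describe a 29-tumour cohort with two
treatment-naive biopsies each, post-treatment samples for a
configurable fraction of tumours, 1–9 pre-treatment clones plus 1–3
post-only clones, ~63% shared mutations, 60× depth, purity 0.38–0.94,
and exponential survival (median 35 months, censored at 60) whose
hazard is multiplied by 4 for tumours carrying APOBEC in private
clones.

Mechanics and deliberate simplifications:

* **Genome** — a seeded i.i.d. random contig (default 800 kb) with
  controllable CpC density. No repeats, chromatin or replication-timing
  structure, hence no covariation of mutation rate with genomic
  features.
* **Signature matrix** — a deterministic, seeded *synthetic* stand-in
  for a COSMIC-style catalogue: sparse random channel profiles per
  signature with the biologically load-bearing concentrations imposed
  (platinum on C>A at CpC, APOBEC on TpC, SBS17a/b at CTT, SBS1 at
  CpG). Any real COSMIC TSV can be supplied instead. Because columns
  are near-orthogonal, exposure recovery here is somewhat easier than
  with the true, partially collinear COSMIC profiles (notably flat
  SBS5/SBS40); the recovery bound (mean absolute error ≤ 0.03 at 5,000
  mutations) should be read with that caveat.
* **Clones** — a random tree; founder at CCF 1 everywhere; subclones
  present in both biopsies with probability 0.25, otherwise one;
  presence is monotone along the tree, and per-sample prevalences obey
  the sum rule by construction with a detectability floor of 0.15 CCF.
  Clone pairs closer than 0.15 (Chebyshev over samples) are merged in
  the truth, because at desk-scale mutation counts such pairs are not
  distinguishable by any method — the recovery checks therefore measure
  the fitter against an identifiable truth, not against labels no
  estimator could separate. Mutation loads are scaled down from the
  real data (150–500 mutations per subclone; the founder carries the
  clonal mass needed to land the shared-mutation target given that
  subclones are mostly region-specific).
* **Reads** — binomial alt counts at Poisson(60×) depth on diploid copy
  number, multiplicity 1; no overdispersion by default, no copy-number
  variation, no sequencing error. A mutation is "called" where its
  clone is present and ≥ 3 alt reads were drawn, emulating a caller's
  detection floor; this makes called shared fractions drift a few
  points above the planted target, as detection losses hit private
  mutations hardest.
* **Platinum** — post-only clones draw 30% of their mutations from the
  platinum signature; `plant_platinum` can additionally inject explicit
  C>A-at-CpC mutations at a configurable CpC bias.
* **Neoantigens** — log-normal mutant IC50s with a log-normal WT/MT
  ratio for a random 15% of mutations; no planted DAI difference
  between populations, so DAI summaries exercise plumbing, not effect
  recovery.

Everything is driven by one `numpy` Generator seeded from the config,
and two runs with the same config are byte-identical on disk. Passing
tests on these cohorts shows the pipeline recovers structure it is
designed for under idealised noise; it does not certify behaviour under
alignment artefacts, subclonal copy number, contamination or caller
biases absent from the generator.

## Numerical choices

* Exposure solver: SLSQP, `ftol 1e-14`, uniform start; weights clipped
  at 0 and renormalised (unit-sum enforced to 1e-8).
* EM: probabilities clipped to [1e-9, 1−1e-9]; restart bursts 10
  iterations on ≤ 800 subsampled mutations; polish tolerance 1e-4 on
  the log-likelihood; BIC parameter count `K·S + (K−1)`.
* Tree rules: tolerance 0.05 on containment and sum constraints.
* Haldane +0.5 on any zero cell of the platinum table keeps the OR
  finite on small populations and is always flagged.
* Degenerate inputs raise early with the offending name: zero
  catalogues, empty count matrices, constant exposure flags, negative
  survival times, non-unit signature columns.

## Problem sizes used in validation

Validation runs use a 29–30 tumour cohort (≈ 1,000–2,500 mutations per
tumour), 5,000-mutation signature catalogues, 300-mutation three-clone
tumours, n = 500 Cox recovery, 2,000 null simulations for log-rank
calibration and n = 2,000 platinum null populations. These sizes are
the package's choice of a desk-scale replica of the study design.

## Known limitations

* The binomial mixture ignores copy-number changes within clones and
  overdispersion; real WGS shows both.
* Clone-count estimates are conservative when clones differ by less
  than ~0.15 CCF or purity is low — BIC merges what the read counts
  cannot separate.
* The greedy tree is a heuristic; crossing-free configurations with
  ambiguous nesting resolve by prevalence order, not by enumeration.
* The 10% cohort screen is computed from per-sample fits over all of a
  sample's mutations; other screening conventions exist.
* Survival fits on ~29 patients have limited power; flagged
  (inestimable) results are expected when a presence flag is nearly
  constant.
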