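# Methods

This note documents the statistical models, the synthetic-data
assumptions and the numerical choices in `sexomics`, stage by stage.

## Sexing and sex-ratio statistics

An embryo is male when both the Y-linked and the autosomal control
amplicon are present, female when only the autosomal amplicon is
present, and undetermined when the autosomal control is absent — a
failed reaction cannot be read as female no matter what the Y lane
shows. Undetermined embryos are excluded from all ratio statistics.

The stage-wise test is a Pearson chi-square of the observed (male,
female) split against a 1:1 null: chi2 = Σ(obs − exp)²/exp with
exp = n/2, one degree of freedom, upper-tail p. No Yates continuity
correction is applied: with 8 males vs 4 females the uncorrected test
gives p = 0.248 while the corrected one gives 0.386, and only the
uncorrected value matches all five published stage results this package
reproduces, so the correction is deliberately off. The 1:1 null was
confirmed by back-calculation from all five published p-values.

Expression-based verification calls a sample male when its mean TPM over
Y-linked genes exceeds a threshold (default 1 TPM); the report lists
discordances against the amplicon calls.

## Differential expression

The DE stage is a deliberately simple per-gene negative-binomial GLM,
not a reimplementation of the shrinkage machinery of dedicated DE
packages; its published gene counts are therefore not reproduction
targets here, while its thresholding semantics are:

- size factors: median-of-ratios over genes positive in every sample,
  entering the GLM as a log offset;
- dispersion: per-gene method of moments on normalised counts, pooled
  within sex groups (α = max((s² − μ)/μ², 0)); genes with α ≈ 0 fall
  back to Poisson. No shrinkage across genes;
- model: counts ~ sex (+ collection-week batch when given), log link;
  Wald p on the sex coefficient (male relative to female); BH FDR;
- a gene is sex-biased iff |log2FC| > log2(1.5) and FDR < 0.1, both
  strict, on the raw (unshrunken) estimate;
- all-zero genes are excluded from testing and reported.

Gene-group enrichment is a two-sided Fisher exact test on the 2×2 table
(DEG membership × group membership), significant at p < 0.01. The
background defaults to all annotated genes and is configurable to the
expressed set. 2^−ΔΔCt aggregates reference genes by the arithmetic mean
of their Ct values (equivalent to a geometric mean of linear
quantities).

## Dosage compensation

Per-gene expression is the mean TPM over the group's samples; genes are
then filtered to a category (expressed ⇔ mean TPM > 1; DEG / non-DEG
from the DE stage, within the expressed set), optionally excluding
paralogs, and X:A = median over X genes / median over autosomal genes.
Y-linked genes never enter either stratum. The conventional reading of
the scale — ≈1 complete compensation, ≈0.5 none, between the two partial
— is attached to results as annotation, not asserted.

The 95% CI is a percentile bootstrap (not BCa; the simplest interval
consistent with a ratio-of-medians estimator): genes are resampled with
replacement independently within the X stratum and the autosome stratum,
the ratio recomputed per replicate, and the 2.5/97.5 percentiles taken;
1000 replicates by default, deterministic under a seed. An alternate
stratification (`stratify="samples"`: resample the group's samples and
recompute gene means) is provided because the original description of
the stratified resampling is ambiguous; chromosome-class strata are the
default as the reading consistent with gene-level resampling in the X:A
literature. Percentile bootstrap CIs for medians are known to
undercover at small strata; coverage checks here use ≥100 genes per
stratum, far below a real annotation but large enough for nominal-level
behaviour.

DEG density on X uses 0-based half-open windows of 1 Mb; a gene belongs
to the window containing its start coordinate, which makes the counts
conservation-testable; runs of empty windows are flagged.

## Splicing

PSI for a skipped-exon event with inclusion reads I, skipping reads S
and effective lengths l_I, l_S is (I/l_I)/(I/l_I + S/l_S); undefined
(missing) when I = S = 0. Effective lengths default to the
junction-count convention l_I = 2, l_S = 1 (two inclusion junctions vs
one skipping junction); the synthetic generator allocates reads with
exactly this weighting, so estimator consistency is testable.

The group test is a likelihood-ratio test between a binomial-logit GLM
of per-sample (I, S) with a sex term and the intercept-only model
(χ², 1 df). It ignores overdispersion; a beta-binomial variant
(logit-mean, shared overdispersion, Nelder-Mead ML) is available via
`method="betabinomial"`. This is a stand-in for mixed-model splicing
tests, chosen to keep the stage self-contained; its published event
counts are not reproduction targets. Group-mean PSI is the unweighted
mean of per-sample PSI over samples with I + S > 0; ΔPSI is male minus
female.

Significance requires all four of: mean (I+S) ≥ 10 in each group; the
PSI-range filter; FDR ≤ 0.01; |ΔPSI| ≥ 0.05 (the count and FDR/ΔPSI
cutoffs inclusive as written). The PSI-range criterion as commonly
printed — "filter out events with average PSI from 0.05 to 0.95" —
would, read literally, discard every informative event; the default
`standard` mode implements the evident intent and removes
near-constitutive events whose group-mean PSI lies outside (0.05, 0.95)
in both groups, while `literal` mode implements the printed sentence.
Pre-filtered events contribute neither a p-value nor to the BH FDR.
Only skipped-exon events are modelled end to end; other event classes
(A5SS/A3SS/MXE/RI) can be parsed and counted but are not tested.

## Domains

CDS intervals are concatenated in transcription order (reverse
complemented on the minus strand) and translated with the standard
code; a trailing stop codon is dropped from the protein, an internal
stop is an error. Hit filtering keeps a PFAM-style alignment iff
score > 10, domain E-value < 0.01, full-sequence E-value < 1e−5,
accuracy ≥ 0.8 and domain-model coverage ≥ 0.9 — strict and inclusive
exactly as listed; "proportion of the domain aligned" is read as
coverage of the domain model (hmm span / model length), the hmmscan
sense, not coverage of the protein. A hit with a missing metric is
rejected with reason "incomplete".

Lift-over: amino acid k owns spliced-CDS nucleotides 3k−2..3k wherever
they fall, including codons split across exon junctions; those positions
map through the exon structure to sorted, merged genomic intervals whose
lengths always sum to 3× the residue span. Coordinates are 1-based
inclusive at GTF I/O and 0-based half-open internally; overlap is
evaluated in the internal convention. A filtered hit is disrupted iff
any lifted interval overlaps (≥1 bp, same chromosome) a significant
skipped exon — the skipped exon itself, not the whole event region,
per the literal overlap rule; extending to the event region is a caller
choice (pass wider intervals).

## Isoforms

Classification compares the query intron chain to reference transcripts
on the same chromosome and strand. Gene-overlap categories are resolved
first: no overlapping gene → intergenic; opposite-strand overlap only →
antisense (antisense wins over NNC for such chains); spanning ≥2
mutually non-overlapping same-strand genes → fusion. Within one gene:
FSM (chain identical to a reference chain) before ISM (consecutive
reference sub-chain — the 5′-degradation signature; arbitrary subsets do
not qualify); otherwise NIC when every splice site is known but the
combination is novel, NNC when ≥1 site is novel. A splice site is known
on exact coordinate match; a wobble window (default 0) can relax this.
Mono-exonic chains are FSM when contained in a mono-exonic reference
transcript's span, else genic_genomic inside a gene or intergenic
outside.

The sex-biased isoform test is a Welch t-test on log2 size-factor-
normalised counts (+0.5 pseudocount) with BH q-values, biased at
q < 0.05. A rank-based test was rejected by design: with 5v6 samples an
exact rank null has only 462 orderings (minimum two-sided p ≈ 0.0043),
so BH at q < 0.05 could never select any isoform once more than ~11 are
tested. The t-test is a stand-in for inferential-replicate methods;
published isoform counts are not reproduction targets. Gene-set
integration partitions DEG/DSG/DEI identifiers into the 7 disjoint
membership patterns, which sum to the union size by construction.

## Synthetic data

The generators encode the study conditions rather than tunable test
knobs. Defaults: a 444-embryo cohort with sexing failure probability
32/444 (a failure silences both amplicons); sex Bernoulli(0.5); stage
drawn from per-sex categoricals over (non-expanded, expanded, hatched) —
female (0.60, 0.31, 0.09), male (0.20, 0.62, 0.18), i.e. roughly 2:1
male bias at the later stages, the developmental-pace signal; 5 male
and 6 female RNA-seq pools; X-linked expression scaled 1.3× in females
and 1.0× in males; 10% of autosomal coding genes spiked at
|log2FC| = 2 (half up in males, half down — the magnitude of autosomal
sex effects is a free parameter, not an estimate); NB dispersion 0.05
around a 1e6-read depth with lognormal library-size variation (σ = 0.15);
skipped-exon events at Poisson junction depth 200 with a 0.3 PSI shift
in a quarter of events; and domain hits engineered to pass all five
filter criteria, fail exactly one each, straddle exon junctions, and sit
inside to-be-skipped exons.

Counts are gamma-Poisson: mean = depth × relative abundance (normalised
lognormal, σ = 1) × library factor × sex effects; Y-linked genes are
zero in females (configurable leak) and an XIST-like non-coding X gene
is zero in males. Junction reads are Poisson totals with binomial
inclusion allocation at p = ψ·l_I/(ψ·l_I + (1−ψ)·l_S). The toy genome
writes each designed CDS (ATG + non-stop codons + stop) into random
chromosome sequence, complemented on the minus strand, so translation
round-trips exactly. All draws flow from one root seed through named
per-generator substreams, so each stage reproduces independently.

What the generator does **not** emulate: read-level error, positional
coverage bias, correlated gene–gene structure, multi-mapping ambiguity
(paralogy is only a label), realistic gene/intron length distributions,
overdispersed junction counts, and annotation incompleteness. Passing
tests therefore demonstrate correctness of the statistics and coordinate
geometry under the assumed generative model, not performance on real
libraries; in particular the binomial splicing test is exactly
calibrated here because the generator is binomial, and would be
anti-conservative under extra-binomial variation (use the beta-binomial
variant there).

## Problem sizes and numerical notes

Tests and the acceptance script run the simulations at desk scale,
chosen as the smallest sizes at which the measured properties are
stable: 10–1000 genes per stage, 1000 events for null calibration,
20-replicate power/recovery runs, 100-gene-per-stratum (or larger)
bootstrap strata, 1000 bootstrap replicates. GLM fits use IRLS with up
to 200 iterations; non-converged or degenerate fits (zero variance,
perfect separation) degrade to p = 1 or exclusion rather than raising.
BH adjustment is applied only across actually tested features. Ties and
degenerate inputs follow the conventions stated above (missing PSI,
all-zero genes/events excluded and reported, empty strata are errors
naming the stratum).
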