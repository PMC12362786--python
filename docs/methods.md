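# Methods

This note documents the models, parameter choices and numerical decisions
behind each deafscape module, what the synthetic-data generators do and do
not emulate, and the package's known limitations.

## Variant catalog

A variant is classified against one transcript model. Genomic coordinates
are handled 0-based half-open internally and exposed 1-based (VCF
convention); indels are expected left-aligned with an anchor base.
Intronic positions 1–2 nt from an exon edge are canonical splice sites,
3–8 nt splice regions, deeper ones deep-intronic; exonic positions outside
the CDS are 5′/3′ UTR by transcription direction; positions within 1 kb of
the transcript are up/downstream, further ones out of scope. Coding SNVs
are resolved at codon level from the transcript's CDS sequence (synonymous,
missense, stop-gain, start-loss, stop-loss); coding indels by length modulo
3 (frameshift vs in-frame). Codon-level resolution therefore requires a CDS
sequence; transcripts read from GFF3 (which carries no sequence) support
every other class.

Pathogenicity labels are normalized per source: five-tier clinical dialects
map verbatim onto {P, LP, VUS, LB, B}; HGMD's DM → P and DM? → LP, with no
benign vocabulary; unknown strings become "unclassified". Consensus over
sources is order-invariant. Sources spanning P/LP and B/LB constitute the
severe conflict class (the consensus is then reported as VUS); sources
spanning P/LP and VUS the milder one, with the consensus still reported as
the P/LP stratum and the conflict recorded separately — consistency and
conflict are deliberately decoupled so a conflicted variant is never
silently promoted or demoted.

Frequency bins partition (AC, MAF): absent (AC 0), singleton through
quadrupleton (AC 1–4), rare-polymorphic (AC > 4, MAF < 2×10⁻⁴), common
otherwise. Reclassification of P/LP calls to B/LB uses the maximum MAF
across populations (the population-maximum convention of BA1/BS1 practice):
MAF > 0.5% for recessive genes or > 0.1% for dominant ones; genes with both
modes take the stricter recessive threshold, X-linked the dominant one. Two
secondary rules are configurable because their source descriptions are
qualitative: "relatively high MAF plus benign predictions" fires at half
the primary threshold together with a caller-supplied benign-prediction
flag, and the control rule fires for dominant variants seen in ≥ 2
unaffected controls (default). All rules are pure functions of their
inputs, hence idempotent.

## PTV mechanism and NMD escape

PTVs are exactly stop-gain, frameshift, start-loss, stop-loss and canonical
splice changes. The NMD rule is applied in coding coordinates: last coding
exon, final 50 nt of the penultimate coding exon (window configurable to
the 50–55 nt variant used elsewhere in the literature; it never extends
past the penultimate exon's 5′ end), remainder. The boundary position
exactly 50 nt from the penultimate junction is inside the escape window.
Single-coding-exon transcripts escape: there is no downstream exon
junction. The PTC position of a frameshift is approximated by the variant's
own CDS position (first affected codon, aa = ⌈cds/3⌉) rather than the
recomputed downstream stop — the same operational definition used when
plotting variant positions; canonical splice PTVs get a not-applicable
call because they have no defined PTC.

Per-gene mechanism quadrants apply the > 50% rule to both the P/LP ratio of
classified PTVs and the PTV ratio of P/LP variants; a zero denominator
leaves the quadrant unassigned rather than raising. The PTV-count vs
CDS-length relation is an ordinary least-squares fit; genes with
standardized residuals below −2 are flagged as candidate PTV-intolerant.

## Hotspot scan

The unit of testing is the annotated domain: enrichment is evaluated per
domain, with the kernel-density profile serving visualization and ranking
rather than region calling (user-supplied sub-domain intervals are accepted
by the same 2×2 machinery). KDE bandwidth follows Scott's rule on the
amino-acid positions; degenerate strata (a single position, or all
positions identical) fall back to a fixed kernel of max(1 aa, 2% of the
protein length); densities are renormalized to trapezoid mass 1 on the
integer grid 1…L.

LR+ uses a Haldane 0.5-on-all-cells correction when no benign variant falls
inside the domain; the odds ratio applies it on any zero cell. The Fisher
test is one-sided in the enrichment direction (the hypothesis is
enrichment, not two-sided deviation). Multiple testing across a gene's
domains defaults to Bonferroni (Benjamini–Hochberg available). The
bootstrap is a stratified nonparametric percentile bootstrap, B = 2000 by
default, resampling variants with replacement within each stratum; each
resample's LR+ uses the same zero-cell handling, so degenerate resamples
are essentially absent (a > 50% drop rate would raise an unstable-estimate
error). Evidence strengths are a step function of the CI lower bound with
strict inequalities, so a boundary value maps to the lower level.

## Gene prioritizer

SMOTE is implemented directly (it is part of the procedure under test):
each synthetic row is x + u·(x_nn − x) with u ~ U[0, 1] and x_nn one of the
k = 5 nearest minority neighbors by Euclidean distance (k is reduced with a
warning when the minority is smaller); binary features are re-thresholded
at 0.5 after interpolation so the 0/1 contract survives. SMOTE runs on the
training fold only, after the stratified 80/20 split, to avoid evaluation
leakage; the synthetic rows are retained on each trained model so tests can
audit that no test-fold row served as an interpolation endpoint. The
oversampling target is parity of the positive class with the negatives in
the same training set; when positives already outnumber negatives nothing
is generated. Random forests use 500 trees and sqrt-features per split by
default, all configurable. Positive genes sit in all ten training sets and
therefore receive no out-of-training vote; scoring is defined for negatives
only (votes 0–9 from the nine models whose subset excluded the gene).
Feature importances are mean-decrease-impurity values averaged across
models and rolled up by feature block. Whether the ten models share one
SMOTE realization is an open choice; each model draws independently here,
seeded from the ensemble seed.

## Concordance

Expression values are log2(x+1)-transformed or z-scored over genes
(z-scoring a constant profile raises). Cross-species comparison correlates
shared genes through a supplied two-column ortholog map (no homology
inference); the default scale for correlations is log2, switchable, since
Pearson r is invariant to the affine z-transform anyway. The relative
z difference (|z_a| − |z_b|) / max(|z_a|, |z_b|) is set to 0 and flagged
when both z-scores are zero, where the formula is undefined.

## Synthetic data: what it emulates, and what it does not

The generators produce data with the statistical structure the analyses
assume, with ground truth recorded for testing. The observational dataset
they stand in for has no generative description, so all generator
parameters are artifact choices:

- **Transcripts**: 1–8 coding exons of 90–450 nt (multiples of 3 by
  default, so protein length is CDS/3 exactly and no codon-phase
  bookkeeping leaks into tests; configurable off), introns of 0.2–2 kb,
  short UTR stubs, a stop-free random CDS starting with ATG, random strand,
  one contig per gene.
- **Domains**: 1–3 non-overlapping domains of 5–15% of the protein; one per
  gene is flagged DNA-binding and is the designated enrichment target.
- **Planted enrichment**: benign missense positions are uniform over the
  protein, so their in-domain probability is the domain length fraction p0;
  pathogenic positions fall in the designated domain with probability p1
  solved from odds(p1) = θ·odds(p0). The expected 2×2 table then has odds
  ratio exactly θ, making θ the single interpretable knob, and the implied
  true LR+ is p1/p0. Mean recovered OR over 200 replicates at
  n_path = 60, n_benign = 240 sits within 15% of θ for θ ∈ {1, 2, 8}
  (the ratio estimator is slightly biased upward, as expected).
- **Labels**: each variant has one latent stratum (P/LP, B/LB or VUS); each
  reporting source labels it inside that stratum with probability
  1 − conflict_rate, otherwise uniformly from the other strata — the
  simplest mechanism that produces the downstream conflict taxonomy, with
  conflict_rate = 0 provably conflict-free. Pathogenic variants are
  reported by 2–3 sources, benign by at most one, PTVs are latently
  pathogenic with probability 0.7.
- **Allele counts**: a zipf(2.5) power law capped in the rare range
  (AF = AC / 300 000), reproducing a singleton-dominated spectrum whose
  singleton fraction is monotone in the exponent — demography is not
  modeled.
- **Feature matrices**: continuous informative features shift the positive
  mean by δ within-class SDs; correlation-block values are clipped to
  [−1, 1] with a shift of min(0.9, 0.25δ); binary features shift the
  Bernoulli rate by δ on the log-odds scale from a base rate of 0.15.
  Block sizes default to 18 expression + 30 correlation + 12 binary and are
  fully configurable. Hidden positives are negatives drawn from the
  positive distribution, recorded for recovery experiments.
- **Expression pairs** are z-scored bivariate normal draws with population
  correlation ρ.

Not emulated: real genome coordinates, trinucleotide mutation spectra,
linkage, demographic history, correlated features within a block, or
gene-length confounding between blocks. Passing tests therefore certify
the statistical machinery — formula correctness, calibration, error
control, reproducibility — not performance on any real cohort, where
feature correlations and label noise are richer than the planted model.

## Problem sizes and reproducibility

Simulation experiments use 200 replicate genes for planted-enrichment
ranking and bootstrap-coverage measurement (n_path = 60, n_benign = 240,
three domains), 500 replicate genes for null type-I-error measurement,
1000 random transcripts for the NMD partition check, and a single
200-positive / 1800-negative feature matrix (δ = 2.0, 30% informative) for
the prioritizer regime — sizes at which the measured rates have small
enough Monte-Carlo error to be meaningful while a full run stays in the
minutes range on one CPU. Every generator and every stochastic procedure
is a pure function of (config, seed); the pipeline derives per-stage seeds
from the global seed by stable hashing and writes a manifest of config
hash, seeds and output checksums, so a rerun is byte-identical.

## Known limitations

- Frameshift PTC positions are first-affected-codon approximations; exact
  downstream-stop computation (and hence exact NMD calls for frameshifts
  near exon ends) is out of scope.
- The hotspot scanner does not perform de novo changepoint detection of
  enrichment regions; regions are annotated domains or user intervals.
- Codon-level consequence classification needs a CDS sequence; GFF3-only
  transcript input restricts SNV classification.
- The bootstrap resamples variants, not genotype-level observations.
- No full ACMG 28-criterion engine, genotype–phenotype curation, or
  literature mining.
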