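# Methods

## Overview

hapsomatic detects somatic point mutations in tumour samples sequenced with
long reads when no matched normal is available. It has two layers: a
count-level feasibility layer (`simcore`) that simulates pileups and applies
closed-form Bayesian classifiers, and a read-level calling pipeline
(`realign`, `genotyper`, `haplotagger`, `somatic_caller`, `burden`) that
operates on BAM/VCF/FASTA inputs. `synthbam` generates fully synthetic,
truth-annotated inputs with the statistical structure the caller assumes, so
the entire pipeline is testable without external data.

## Classification model

A sample with tumour purity α ∈ [0,1] mixes cancer and normal cells. At a
site with a alternate and r reference reads, three hypotheses are compared
with binomial likelihoods Bin(a; a+r, p):

- somatic: p = (1−ε)α/2 + ε(1−α/2) unphased, or (1−ε)α + ε(1−α) per
  haplotype once reads are phased (the factor 2 disappears because the
  haplotype of each read is known);
- het SNP: p = 1/2 unphased (the error terms cancel), 1−ε per haplotype;
- reference: p = ε.

Priors are (μ, π, 1−μ−π). Posteriors are computed in log space and the
argmax label is reported; on an exact tie somatic wins over het, het over
reference (ties are measure-zero except in degenerate parameter corners,
but the rule makes the decision deterministic). Sites (or haplotypes) with
zero informative reads are uncallable and skipped.

Note that ε enters the reference class as the probability that a read shows
*the* alternate base, not any of the three; this matches the generative
error model only up to the 1/3 base-choice factor and is deliberately kept
as the classifier's observation model.

## Pileup simulation

Per site: a het SNP is placed on a random haplotype with probability π
(default 10⁻³); each haplotype independently acquires a somatic mutation
with probability μ (default 5×10⁻⁶, chosen so a 10 Mbp genome carries ~50
mutations — sparse enough that false positives dominate precision, the
regime the method must survive); total depth is Poisson(λ) split
Binomial(d, 1/2) across haplotypes; reads on a mutated haplotype carry the
mutant base with probability α; every read base is flipped to one of the
three other bases with probability ε. Counts are aggregated per base so
both the per-haplotype and the pooled classifier see the same draws. The
unphased alternate count is the modal non-reference base (ties broken in
A<C<G<T order); reads supporting a non-modal non-reference base are not
counted, matching the observation model above.

The purity sweep exploits the fact that the background (reference and het)
counts do not depend on α: they are simulated once per (depth, error) cell
and shared across the purity grid as common random numbers, compressed to
unique count patterns; somatic sites (and the α-dependent classifier) are
re-drawn per purity from an independent child seed. This reduces a 99-point
grid over 10⁷ sites from hours to seconds, removes background Monte-Carlo
jitter between adjacent purities, and leaves all marginal distributions
exactly as specified. F1 is computed on the somatic class; a phased site is
called somatic when either haplotype's argmax label is somatic. With no
somatic truth sites and no predictions, precision/recall/F1 are reported as
1.0 by convention (documented degenerate case).

## Read-haplotype likelihoods

Real reads are scored against candidate haplotype windows with a banded
pair-HMM forward algorithm over match/insert/delete states. Match emissions
derive from the base quality q (correct base 1−10^(−q/10), each other base
10^(−q/10)/3, q capped at 40 to avoid emission saturation, floored at 10⁻⁸);
insertions emit 1/4; transitions use gap-open 10⁻³ and gap-extend 0.1
(configurable — the parameter roles are standard, the values are this
package's defaults for modern long reads). Every path is closed with its
exit-to-match transition, which makes the total likelihood exactly
invariant under joint reverse-complementation of read and window — a
property the caller relies on since reads come from both strands. The band
(default ±20 diagonals) must connect the corners; length differences beyond
it raise an explicit band-overflow error.

Windows span ±20 bp around a site. Candidate sites closer than one flank
are evaluated jointly: all allele combinations (up to 2⁴) are substituted
into the shared window and the per-allele likelihood is the average over
combination haplotypes carrying that allele; larger clusters fall back to
single-site substitution. Reads must pass QC (mapping quality ≥ 20, not
duplicate/secondary/supplementary) and cover the site itself.

## Genotyping under copy-number imbalance

Known biallelic SNP sites (in practice a population resource such as gnomAD
biallelic SNPs with allele frequency > 0.1%) are genotyped from the
realignment likelihoods. Hom-ref/hom-alt likelihoods are per-read products;
the het likelihood averages two orientations of a mixture in which a read
draws the higher-copy haplotype with probability f (default 0.25), so LOH
regions where the minor haplotype contributes only normal-cell reads are
still recognized as heterozygous. Priors: 1/1000 of sites variant, 2/3 of
variants het. Sites with < 8 informative reads, or with allele-by-strand
association at Fisher p < 10⁻⁴, are left uncalled (the threshold is this
package's choice; the strand-bias principle is standard). Only 0/1 calls
are emitted — false-negative hets shrink the phasable genome, false
positives corrupt haplotagging, so the caller prefers the former. Fitting f
per copy-number segment is out of scope (f is global configuration), as is
phasing itself, which is delegated to an external tool.

## Haplotagging

A phased het VCF defines allele strings B0/B1 per phase set. A read's
log-likelihood for haplotype j sums its realignment likelihoods for the
alleles Bj selects at the het sites it covers; the posterior uses a uniform
prior (configurable). Reads are left unassigned when the PHRED-scaled
probability of mis-assignment (the posterior of the non-assigned haplotype)
is < 20, when more than 10% of the covered sites' better-supported alleles
disagree with the assigned haplotype, or when no phased site is covered.
Reads spanning several phase sets keep only the phase set contributing the
most sites; the rejection rules then handle genuinely ambiguous reads,
including those crossing phase-block boundaries.

## Somatic calling

Calling proceeds in genome windows (default 10 Mbp; any sub-window can be
requested). A position is callable when both haplotypes have ≥ 10 assigned
reads and their sum is ≤ 400; callable intervals are emitted as BED.
Candidate discovery is deliberately permissive: on each haplotype the modal
non-reference base becomes a candidate when seen ≥ 3 times and in > 10% of
that haplotype's reads (raw pileup counts are used for discovery; realigned
likelihoods for classification). Each candidate is classified on its
haplotype: reference expects every read to match the reference allele, het
the alternate, and somatic draws each read from
(1−αφ)·P(R|ref) + αφ·P(R|alt) with φ integrated over a CCF prior with
clonal mass ρ = 0.95 at φ = 1 plus Beta(2, 2), the point mass handled
analytically and the Beta component by 100 equal-width bins weighted by
exact CDF differences (midpoint abscissae). The integral is per read,
following the likelihood factorization used throughout. QUAL is
−10·log₁₀(1−P(somatic)), capped at 60. When both haplotypes nominate the
same position the higher-QUAL call is kept.

Class priors for real-data classification default to μ = 10⁻⁵ per candidate
and π = 10⁻³ (candidates are enriched for real variation relative to the
genome-wide rates; the values are configurable and deliberately
conservative).

Six filters are evaluated independently and all that fire are recorded;
PASS means none fired:

- MaxOtherHaplotypeObservations: alt seen > 2 times or in > 20% of the
  other haplotype's reads (the non-called haplotype is an internal control);
- MinObsPerStrand: alt not observed on both sequencing strands;
- PossibleAlignmentArtifact: > 50% of alt reads have window mismatch rates
  > 15% (operationalizing the structural-variant-breakpoint failure mode;
  thresholds are this package's choice);
- LowQual: QUAL < 20;
- MinHaplotypeDepth: either haplotype < 10x;
- StrandBias: Fisher exact p < 10⁻³ on the allele-by-strand table.

## TMB and mutation spectrum

TMB = (PASS calls with QUAL ≥ 20) / (callable footprint in Mbp), using the
BED from the same run — the genome-wide burden is extrapolated from the
phased, callable subset. The spectrum maps each called SNV to one of 96
pyrimidine-centred trinucleotide contexts (purine-reference mutations are
reverse-complemented; the mapping is involutive) in COSMIC-style order, and
spectra are compared by cosine similarity. Signature decomposition is out
of scope.

## Synthetic data generator

`synthbam` emulates the pipeline's inputs: a uniform-random reference, het
SNPs at rate π phased onto two haplotypes (single phase set), somatic SNVs
on one haplotype with CCFs from the ρ/Beta mixture, and pre-aligned
full-match reads drawn uniformly with a configurable haplotype fraction
(values away from 1/2 emulate LOH), tumour origin with probability α, and
uniform errors at ε with constant base qualities at the matching PHRED
value. Outputs: FASTA(+fai), sorted/indexed BAM, phased germline truth VCF
(GT|GT + PS), somatic truth VCF with CCFs, a population-style sites VCF
(true hets plus hom-ref decoys), and a per-read truth table. The same spec
seed reproduces byte-identical truth files; mixture series share truth
variants across (purity, depth) cells and vary only the reads.

What the generator does not emulate — context-dependent (homopolymer)
errors, indels, mapping ambiguity, chimeric reads, structural variation,
real phasing-tool behaviour, per-read correlated somatic genotypes across
multiple subclonal sites — bounds what passing tests show: they validate
the statistical machinery and rule conformance, not robustness to real
long-read artifact structure.

## Numerical and design choices

- All likelihood work is in log space; posteriors normalized with
  log-sum-exp. Classifier correctness is tested against exact rational
  arithmetic, the pair-HMM against brute-force path enumeration, and the
  CCF integral against a 10⁵-bin fine grid.
- The calls VCF carries a full-precision copy of its float fields in a
  String INFO entry so write→read round-trips are bit-exact (native VCF
  floats are 32-bit).
- Problem sizes in tests and examples (0.05–1 Mbp regions, 20–80x, 10–50
  planted mutations; 10 Mbp simulated genomes) were chosen as the smallest
  scales at which the measured quantities are statistically stable.
- The haplotag assignment quality is the PHRED of the non-assigned
  haplotype's posterior (for two haplotypes this equals the complement of
  the max).

## Known limitations

- Substitutions only; no indels, MNVs or microsatellite instability.
- Purity is a fixed input (default 0.5), not estimated; allele-specific
  copy number is not modelled and f is global rather than per-segment.
- CCF posteriors are integrated out, not reported per variant.
- A purely tumour sample (α = 1) is uncallable by construction — the
  evidence for the inherited allele comes from normal-cell contamination —
  and the caller refuses α ≥ 1.
- The unphased-classifier feasibility band is sensitive to the somatic
  rate μ through the prior; its lower endpoint moves several purity points
  per decade of μ.
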