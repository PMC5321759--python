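# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of each matrikin component, and what the synthetic
generators do and do not emulate.

## Synthetic data: what is emulated

The generators are first-class, tested code: they define the conditions
under which every statistical claim in the test suite is made.

**Pedigrees and genotypes.** A pedigree is a DAG of (child, mother, father)
links; founders are unrelated and non-inbred. Genotypes are dropped down
the pedigree by fair Mendelian transmission: founders are Hardy–Weinberg
draws at each site, each child receives one uniformly chosen allele from
each parent, and an absent parent contributes a fresh population allele.
Sites are unlinked given transmission (no recombination map), spread over
autosomes 1–22 with strictly increasing positions. Ground-truth relatedness
is twice the kinship coefficient from the standard recursive identities,
equivalent to path counting for the non-inbred pedigrees supported.

Allele frequencies default to Uniform(0.05, 0.95). This is a deliberate
stand-in: the real capture panel's spectrum is not published as a
distribution, and the uniform choice keeps unrelated-pair mismatch
(≈ 0.365) well away from zero so the *b*-correction is genuinely exercised.
The consequence is that the synthetic unrelated baseline differs from the
real panel's ≈ 0.21, which is why synthetic runs derive *b* from the run
itself (below) instead of using the published 0.105.

**Read sampling.** Per individual and site, read depth is Poisson(coverage)
and each read reports one uniformly chosen allele, flipped to the other
allele with the sequencing error rate. Deamination damage on SNP
observations is applied only at CpG-flagged sites (C→T / G→A with
probability d₀), emulating the elevated and individually variable
post-mortem damage at CpG dinucleotides that motivates excluding such sites
from kinship estimation. CpG flags mark a configurable random 20 % of
sites rather than being derived from sequence context — the pipeline
consumes only the flag.

**Mitochondrial stacks.** Reads are stored in reference orientation (as in
SAM). Each read draws independent 5′ and 3′ overhang lengths from
Geometric(λ) with support starting at 1 (every fragment end has at least
one single-stranded base, matching the per-base termination
interpretation); within the 5′ overhang each C deaminates to T with
probability d₀ and mirrored G→A within the 3′ overhang. Deamination of the
complementary strand presents identically after complementing into
reference orientation, so both strands show C→T at the stored left end —
this is why profiling and masking can operate on stored sequences without
per-strand branching. Interior (double-strand) damage is omitted: the
single-strand model is sufficient to exercise masking and PMD filtering.
Read starts, ends and orientations are recorded so duplicate removal can be
tested; mapping quality and length distributions include a tail below the
filtering thresholds so the filters have work to do.

**What is not emulated.** No FASTQ/BAM round-trip, no alignment error, no
indels other than the one diagnostic 9-bp deletion, no contamination, no
linkage between SNPs, no UDG treatment. Passing tests therefore demonstrate
correctness of the estimators under their stated sampling models, not
robustness to alignment artefacts or contamination in real libraries.

## Damage profile and masking

Terminal misincorporation rates are counted per position from each read
end (ref-C → T from 5′, ref-G → A from 3′; default K = 25 positions) and
the three-parameter decay `rate(i) = baseline + d₀(1−λ)^(i−1)` is fitted to
the 5′ rates by bounded nonlinear least squares, the 3′ profile serving as
a consistency check. This deliberately replaces the full Bayesian machinery
of damage-pattern tools: only the mean λ is consumed downstream. Profiles
whose fitted amplitude falls below 0.005 are flagged flat — λ is then
unidentifiable and masking defaults to a single base. Positions with zero
opportunities are excluded from the fit.

The mask width is the smallest k with cumulative geometric mass
1 − (1−λ)^k ≥ 0.95 (computed in closed form, with an explicit minimality
guard against floating-point edge cases). Masking replaces 5′ T and 3′ A
residues within k by N rather than deleting them, preserving coordinates
for the pileup; it is idempotent by construction.

The PMD score is a per-read log-likelihood ratio summed over ref-C (scored
from 5′) and ref-G (scored from 3′) positions: under the damage model a
ref-C at position i reads T with probability D(i) + (1−D(i))·ε where
D(i) = d₀(1−λ)^(i−1) and ε is the base-quality error probability; under the
null, ε alone. Matching bases contribute negatively; a read with no
informative positions scores exactly 0 by convention. The default pass
threshold is 3.

Duplicates are clusters sharing (start, end, orientation); the surviving
read has the highest mean base quality, ties broken by input order (the
source procedure specifies only "highest quality"; input order is the
minimal deterministic tie-break).

## Consensus and the haplogroup-B deletion

A site is called as the majority base iff non-redundant (deduplicated)
coverage ≥ 2 and the majority fraction ≥ 0.80, else N. Two conventions are
fixed here: the identity threshold is inclusive (0.80 calls, so 4-of-5
calls), and masked N bases are non-observations — they count toward neither
coverage nor the identity denominator. A 1–1 split at minimum coverage
cannot reach 80 % and yields N. The damage-restricted (PMD ≥ 3) consensus
uses the same identity rule at 4× minimum coverage, absorbing the higher
per-read damage load.

The haplogroup-B 9-bp deletion (one copy of the tandem CCCCCTCTA repeat at
reference positions 8,271–8,279) is handled by a dedicated local check, not
a general indel caller: within a ±30 bp window the no-deletion alignment is
scored against every placement of a single 9-bp gap (N bases ignored), and
the deletion is accepted when the best gapped score beats the ungapped
score by ≥ 5 matches. Because the deletion removes one copy of a tandem
repeat, gap placements within the repeat are equivalent; the output is
canonicalized to '-' over 8,271–8,279 in the reference frame. The synthetic
mitochondrial founder carries the motif as a true tandem repeat
(8,262–8,270 and 8,271–8,279) so the ambiguity is real in the fixtures.

Pairwise distances default to global complete-case site removal (any
position with N or '-' in any sequence is dropped from all comparisons, and
`bp_analysed` reports the retained count); a pairwise complete-case option
exists but is non-default.

## Relatedness estimator

The estimator r̂ = 2 − x/b is the unique affine function of the pairwise
pseudo-haploid mismatch x satisfying the two boundary conditions r̂(2b) = 0
(unrelated) and r̂(b) = 1 (identical genomes). It is not clipped to [0, 1]:
clipping would bias CI coverage. The 95 % CI is propagated as
1.96·SE(x)/b with b treated as fixed, matching how the source analysis
reported block-jackknife CIs without b uncertainty.

The jackknife uses contiguous 5-Mb windows per chromosome (block size is
not specified by the source analysis; 5 Mb is conventional for genome-wide
f-statistics and is configurable), weighted by per-block site counts, with
the weighted delete-one variance of Busing et al. (1999); with equal
weights it reduces exactly to the ordinary delete-one jackknife, which the
tests verify.

Three routes to *b* are supported and should be chosen deliberately:

* `b = 0.105` (default) — the published constant for the real capture
  panel, appropriate for real inputs;
* `b = None` in `kin_table` — derived as (maximum observed pairwise x)/2,
  mirroring how the published constant was anchored; note that at a few
  thousand overlapping sites the maximum over many pairs is upward-biased
  by sampling noise, which propagates into a small upward bias in r̂;
* `expected_b(freqs)` — the exact value Σp(1−p)/n from panel allele
  frequencies, available when the panel spectrum is known (always true for
  synthetic runs). The recovery experiments use this route so that they
  measure the estimator's sampling properties rather than the noise of the
  b-anchoring heuristic.

Detection uses Z = (baseline − x)/SE with baseline 2b by default (the
per-dataset maximum is available as an alternative); Z > 3 flags a pair.
Degree classification compares the 95 % CI against {1, 0.5, 0.25, 0}:
exactly one canonical value inside gives that degree, two adjacent values
give a combined label (e.g. first-or-second), anything else is ambiguous.
Mismatch compares sampled bases directly, so triallelic observations count
as mismatches. X-chromosome kinship is out of scope (too few informative
sites in the motivating data).

Observed behaviour of the recovery experiment (100 replicates, 50k sites,
0.5× coverage, ~6.2k overlapping sites per pair): mean r̂ within ±0.01 of
truth for r ∈ {0, 0.25, 0.5} and CI coverage 90–95 %. The jackknife is
mildly anticonservative at ~40 blocks, which is why coverage sits slightly
below the nominal 95 %.

## Genetic sexing

Ry = nY/nXY with the normal-approximation 95 % CI (Clopper–Pearson exact
intervals are available as an option). Call thresholds 0.016 (female) and
0.075 (male) follow the published defaults of the read-ratio sexing method;
the motivating analysis does not restate them numerically, so they remain
configurable. A point estimate in the male zone whose CI still overlaps the
female zone is reported as consistent-male-unresolved rather than forced to
a call. Concordance against osteological tables is computed over
individuals with confident genetic calls only. The generator models male Ry
as ≈ 0.09 under equal X/Y mappability of capture bleed-through reads, with
a residual 0.001 Y-misalignment rate in females; true mappability is
panel-dependent, so the value is config-exposed.

## Chronology

Calibration evaluates the Gaussian likelihood of the conventional age
against the interpolated curve on a 1-calendar-year grid and normalizes;
HPD regions are the smallest grid sets reaching 68.2 / 95.4 % mass,
accumulated in descending density (the 1σ level is taken as the
conventional 68.2 %). Marine dates receive μ + ΔR with σ added in
quadrature; the default ΔR is 234 ± 23 ¹⁴C yr (southern California coast
shell). Calibration commutes with joint shifts of curve and age, and HPD
levels nest, both verified as properties.

Phase models place events in ordered intervals delimited by boundaries
B₀ ≤ (phase-1 events) ≤ B₁ ≤ … with uniform order-constrained boundary
priors over the curve span — deliberately simpler than the span-scaling
priors and outlier models of full calibration programs. Sampling is exact
Gibbs: each event is drawn from its calibration density truncated to its
phase interval by inverse-CDF on the grid, and each boundary uniformly
between its neighbouring constraints. Because every conditional is exact,
no proposal tuning is needed; defaults are 4 chains × 20,000 iterations
with 50 % burn-in, and on the two-event toy model the sampler agrees with
brute-force grid integration to well under a year (the marginalized
boundary volume factor (e₁−lo)(e₂−e₁)(hi−e₂) is included in the oracle).
Mixed atmospheric/marine curves are handled per event.

The plateau-bias design simulates, by default, 10 dates of ±20 ¹⁴C yr
precision every 25 calendar years across 750–1250 CE (21 grid points, 210
dates, an expected 40 per century), histograms the conventional ages in
20-¹⁴C-yr bins, and reports per-bin z-scores against a uniform deposition
rate computed over interior bins (bins within 3σ of the curve edges are
excluded, since edge run-off is a windowing artefact, not curve structure).
Continuity-versus-episodicity is reported as this histogram plus deviation
summary, not as a formal hypothesis test — the underlying argument is
comparative, not inferential.

Synthetic curves are linear (strictly monotone, constant σ) or
plateau-bearing (a flat segment of configurable width, default 150 yr
centred on 1000 CE, emulating the reversal/plateau structure of the real
curve between 900 and 1150 CE).

## Problem sizes and determinism

Default experiment sizes — 50k SNPs at 0.5× coverage with 100 replicates
for relatedness recovery, 10⁵ reads for damage-parameter recovery, 500
draws for HPD coverage, 200 simulated individuals per sex — were chosen as
the smallest sizes at which the quantities of interest are measured with
comfortable margin over their Monte-Carlo noise. Every generator and
sampler is reproducible under an explicit seed, and the end-to-end pipeline
is byte-identical across reruns with the same configuration.

## Known limitations

* The damage fit uses 5′ C→T rates only; strand-asymmetric damage would go
  undetected (the 3′ profile is exposed for manual inspection).
* The B-deletion check handles exactly one locus; it is not a general
  realigner and assumes the reference carries the motif at the canonical
  coordinates.
* The phase sampler supports sequential phases only (no overlapping or
  cross-cutting constraints) and no outlier down-weighting.
* Degree classification is CI-based and inherits the jackknife's mild
  anticonservativeness; at very low overlap (<2 blocks) no SE is available
  and pairs are reported without Z or CI.
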