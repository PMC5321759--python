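# matrikin

**matrikin** is a toolkit for reconstructing family structure from highly
degraded ancient-DNA sequence data, built around the analysis design used to
identify multigenerational elite matrilines in archaeological burial crypts.
It is aimed at archaeogenomics practitioners who need each link of that
chain as tested, reusable code: damage-aware mitochondrial consensus calling
and haplotype identity testing, genetic sexing from sex-chromosome read
ratios, pairwise nuclear relatedness from pseudo-haploid data with honest
uncertainty, and radiocarbon calibration with stratigraphic phase modelling —
together with synthetic-data generators that produce every input with known
ground truth.

## The statistics at the core

**Pseudo-haploid relatedness.** Low-coverage ancient samples cannot be
genotyped diploid, so each individual is reduced to one randomly sampled
read per SNP. For a pair of individuals the mean mismatch rate *x* over
jointly covered autosomal non-CpG SNPs carries the kinship signal: unrelated
pairs mismatch at a rate 2*b* set by panel heterozygosity, while two
samplings of a single genome still mismatch at *b* (heterozygous sites
disagree half the time). The relatedness coefficient is estimated by the
affine form

```
r̂ = 2 − x/b ,        b = (maximum unrelated mismatch)/2
```

so that r̂ = 0 at the unrelated baseline and r̂ = 1 for identical genomes
(first degree 0.5, second degree 0.25). Standard errors come from a
weighted block jackknife over 5-Mb genomic blocks; related pairs are
detected at Z = (2b − x)/SE > 3, and degrees are classified by which
canonical values {1, 0.5, 0.25, 0} the 95 % CI contains. For real capture
panels *b* = 0.105 (half the ≈ 21 % unrelated maximum) is the default.

**Damage modelling.** Post-mortem cytosine deamination concentrates in
single-stranded overhangs whose lengths are geometric with termination
probability λ, so terminal C→T rates decay as d₀(1−λ)^(i−1). The package
fits (λ, d₀, baseline) from the 5′ mismatch profile, hard-masks 5′ T and
3′ A residues within the overhang length covering 95 % of overhangs
(k = ⌈ln 0.05 / ln(1−λ)⌉; 9 nt at λ = 0.3, 14 nt at λ = 0.2), scores reads
with a PMD likelihood ratio (threshold 3), and calls consensus sequences at
2× non-redundant coverage and 80 % identity (4× for the damage-restricted
consensus). The diagnostic haplogroup-B 9-bp deletion (CCCCCTCTA at
mitochondrial positions 8,271–8,279) is detected by exhaustive gapped
realignment of that window.

**Genetic sex.** Ry = nY/(nX + nY) over sex-chromosome-mapped reads, with a
normal-approximation 95 % CI; calls require the CI to clear the female
(< 0.016) or male (> 0.075) zones.

**Chronology.** Radiocarbon dates are calibrated on a 1-yr grid against an
IntCal-layout curve (marine dates take a ΔR = 234 ± 23 reservoir offset),
HPD regions are extracted at 68.2 / 95.4 %, and stratigraphic
Boundary/Phase models are sampled by an exact Gibbs scheme. A
simulate-and-recalibrate design (10 dates ± 20 ¹⁴C yr every 25 yr across
750–1250 CE; 210 dates, 40 expected per century) quantifies how curve
plateaus stack conventional ages into apparent burial episodes.

## Worked example

Simulate a three-generation pedigree (grandmother GM → mother MO → children
SON/DAU, plus unrelated founders U1/U2), sample damaged low-coverage reads,
and estimate all pairwise relatedness coefficients:

```python
from matrikin import synthetic_data as synth, relatedness as rel
from matrikin.pipeline import default_pedigree

ped = default_pedigree()
gt = synth.simulate_pedigree(ped, n_sites=50_000, seed=0)
reads = synth.sample_snp_reads(
    gt, synth.SimReadParams(coverage=0.5, error=0.001, seed=1))
b = rel.expected_b(gt.sites.loc[~gt.sites.cpg, "freq"].to_numpy())
kin = rel.kin_table(reads, seed=2, b=b)
```

Selected rows of `kin` (related pairs and one unrelated pair):

```
id_a id_b  n_sites      x   se_x       r  ci_low  ci_high       z    degree
  GM   MO     6179 0.2735 0.0058  0.5019  0.4398   0.5641 15.8309     first
  MO  SON     6140 0.2767 0.0051  0.4844  0.4300   0.5388 17.4551     first
  GM  SON     6197 0.3311 0.0054  0.1863  0.1280   0.2447  6.2584 ambiguous
 DAU   GM     6238 0.3201 0.0060  0.2465  0.1821   0.3110  7.4949    second
  U1   U2     6246 0.3727 0.0076 -0.0415 -0.1227   0.0397 -1.0021 unrelated
```

Each pair overlaps at ~6,200 of the 50,000 simulated SNPs at 0.5×
coverage. Mother–daughter and mother–son pairs (true r = 0.5) estimate
r̂ ≈ 0.48–0.53 with Z ≫ 3; the grandmother–grandson pair (true r = 0.25)
is clearly detected as related (Z = 6.3) and estimated at r̂ = 0.19 with a
CI that narrowly misses the canonical 0.25 in this replicate — exactly the
kind of first-versus-second-degree uncertainty real crypt assemblages show.
The unrelated pair sits at the baseline (Z ≈ −1, r̂ ≈ 0).

The whole pipeline (matriline mitogenome consensus → distance matrix,
sexing, kinship, calibration) runs end-to-end on synthetic data with

```sh
matrikin run-all --out results/demo --seed 1
```

which reports, among other things, a 9 × 9 all-zero distance matrix for the
simulated matriline (identical mitogenomes), 100 % sex-call concordance
with the simulated truth, and the 210-date plateau-bias histogram. Every
stage is also exposed as a subcommand (`simulate`, `damage`, `consensus`,
`distances`, `sex`, `kin`, `calibrate`, `phase`, `c14sim`).

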