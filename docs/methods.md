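# Methods

## Observation model

Polyploid microsatellite electropherograms do not yield reliable allele
dosage, so a genotype is modelled as the *set* of distinct fragment lengths
(base pairs) at a locus — the allele phenotype. Every statistic in the
package is defined on these sets; nothing downstream ever assumes copy
number. A missing genotype is a locus absent from an individual's mapping:
it contributes zero counts and is logged, never an error.

## The cross simulator

The simulator produces a two-parent cross with known ground truth under
polysomic inheritance: at each locus, a reduced gamete receives a uniformly
random half of the parent's homologs, independently across loci (one locus
per chromosome; no preferential pairing, no double reduction in normal
gametes). This is the standard null model for tetrasomic/hexasomic
segregation; nothing in the analysed statistics depends on a finer pairing
model.

Unreduced oocytes come in two arms:

- **PB2 retention (second-division restitution).** A normal reduced set is
  formed and duplicated. A retained sister chromatid is identical to its
  partner at centromere-proximal loci and differs distal to a crossover;
  rather than tracking chiasmata, each duplicated copy is independently
  restored, with per-locus probability *r*, to the allele of a uniformly
  chosen non-selected homolog. *r* therefore subsumes centromere–locus map
  distance: *r* = 0 is full SDR homozygosity, *r* = 1 approaches the allele
  diversity of two independent gametes. The default *r* = 0.8 reflects the
  high effective recombination needed to produce a near-1.8-fold
  private-allele increase at microsatellite loci, which are typically far
  from centromeres; `calibrate_r` inverts the simulated fold-change curve
  for any observed fold.
- **Clonal oocyte (apomixis or premeiotic endomitosis).** An exact copy of
  the dam's copy-list. The two biological routes are one simulator arm
  because they are indistinguishable by the data this analysis uses —
  both yield oocytes genetically identical to the dam.

Polyspermy is modelled as dispermy (two independent reduced sperm).
First-division restitution is out of scope.

Parent genomes draw each homolog's allele uniformly from a per-locus pool
of 10 dinucleotide-spaced lengths (non-overlapping ladders across loci).
A pool of 10 gives parents that are polymorphic with several private
alleles per locus, emulating a marker panel pre-selected for informativeness
between the parents. Observation applies per-allele dropout (default 0) to
offspring only; parental genotypes are the reference sets of the analysis
and are taken as known. Each `simulate_cross` call uses a single seeded
`numpy` generator threaded through all sub-operations.

A config can mix arms: `n_normal_offspring` normally reduced monospermic
siblings precede the `n_offspring` focal-arm offspring, so one cross can
contain e.g. 143 pentaploid and 7 heptaploid full sibs
(`baerii_cross_config`).

DNA content per nucleus is Gaussian around ploidy × per-set pg with a
coefficient of variation (default 0.02, typical of DAPI flow cytometry);
a measurement is the mean over 3000 nuclei.

## Ploidy calling

The call is the candidate ploidy minimising |measurement − candidate ×
reference|, with a relative no-call band (default tolerance 0.15 — wide
because the candidate spacing in this cross, 5n/7n/8n, is coarse; cytometry
histograms separate such clusters cleanly). Ties break toward the lower
ploidy with a warning. The measured contents of the two sibling groups
(8.98 pg at 5n, 15.02 pg at 7n) imply *different* per-set constants
(1.796 vs 2.146 pg/set); the package does not resolve this calibration gap
(standards, instrument drift, or biology) — the reference is an explicit
input, scalar or per-candidate mapping. Feulgen densitometry readings are
converted with the linear two-standard rule (implied pg averaged over
standards; tench 2.02/3.10 pg defaults).

Chromosome arithmetic mirrors the ploidy arithmetic on somatic counts with
halves rounded half-up, since parental counts are "~" approximations.

## Private-allele battery

Each offspring's distinct alleles are classified per locus against the
parental sets (dam-private / sire-private / shared / non-parental).
Shared alleles are uninformative; non-parental alleles (mutation or scoring
artefact) are excluded and logged. Counts are summed within ploidy groups;
fold change is the ratio of group totals, interpretable when group sizes
match (enforced with a warning otherwise — the full analysis subsamples the
baseline group to the anomalous group's size, seeded).

The paired t test is computed in closed form over loci (d = baseline −
elevated, two-sided p), with defined degenerate behaviour: all-zero
differences give t = 0, p = 1; zero variance with nonzero mean gives
t = ±inf, p = 0, flagged. An increase is *supported* when p < alpha
(default 0.05) and the mean difference is negative — i.e. the elevated
group carries more. With this sign convention an increase prints a negative
t, matching how such analyses conventionally report the statistic;
magnitude and p are unchanged either way. Shapiro–Wilk on the differences
is advisory: the pipeline warns, never aborts, because with 8 loci the test
has little power and the t test is robust to mild non-normality. Loci where
the parents share every allele are excluded before testing, reducing the
degrees of freedom.

Hypotheses: H1 (dam-private increase → maternal origin), H2 (sire-private →
paternal), H3 ≡ H1 ∧ H2 (both).

## Mechanism classifier

A pure rule chain per anomalous called-ploidy group:

1. excess 0 → normal;
2. excess = sire gamete ploidy (≠ dam's contribution) → polyspermy;
3. excess = dam's full set count → maternal: clone if the mean fraction of
   loci whose observed offspring alleles contain the dam's full set is ≥
   `identity_threshold`, else PB2 retention if H1 is supported, else
   unresolved;
4. equal parental gamete ploidies (not this cross) → the genotype evidence
   (H1 vs H2) decides, never the arithmetic alone;
5. anything else → unresolved.

Every verdict carries an ordered evidence trail. `identity_threshold`
defaults to 1.0 (exact containment at all loci — any single non-identity
excludes a clone when observation is error-free). Under allele dropout the
clone group's expected identity fraction is ≈ (1 − dropout)^k per locus
(k = distinct dam alleles, ≈ 3.5–4 at the defaults), i.e. ≈ 0.92–0.93 at
2% dropout, while PB2 offspring sit near 0.3–0.5; dropout-tolerant runs
therefore use a threshold of 0.85, chosen analytically to sit between those
expectations. The PB2 verdict label names meiosis II because
recombination-bearing maternal duplication is conventionally read as
second-division restitution; allele data alone cannot formally separate
first- from second-polar-body retention, and the evidence trail states the
observable fact (recombined maternal duplication).

The per-offspring verdict inherits the group verdict: the t statistic is
group-level by construction.

## Numerical and design choices

- Alleles are integer base-pair lengths; no binning or stutter correction
  (scored-genotype granularity).
- Canonical I/O is long-format TSV (`sample role locus allele`), one allele
  per row, deterministic order; wide format (semicolon-separated) read-only.
  Reading is row-order independent; read∘write is the identity.
- The per-locus count-matrix reader (`locus group parent count`) runs the
  full battery when only counts, not genotypes, are available.
- Tie-breaks: ploidy calls toward the lower candidate; baseline subsampling
  uses a fixed seed so the whole analysis is deterministic given inputs.

## What the simulator does and does not show

Passing tests demonstrate the chain's behaviour under the stated model:
unlinked loci, uniform polysomic segregation, presence-only observation
with independent dropout, Gaussian DNA-content noise, parents drawn from
uniform allele pools. Real crosses add linkage, preferential pairing and
double reduction, allele-size homoplasy, stutter and binning error, and
population allele-frequency structure — none modelled here. Simulation
results therefore validate the *inference machinery*, not field error rates.

Problem sizes used in the statistical tests — 7 + 7 offspring at 8 loci,
100–1000 replicates, 200 mixed-mechanism crosses, 500–2000 offspring for
calibration — are the sizes at which the corresponding claims are stated.

## Known limitations

- The observed fold change depends on the parental allele configuration;
  for some parents the achievable fold at *r* = 1 is well below 2, and
  `calibrate_r` flags targets outside the achievable curve instead of
  extrapolating.
- The type-I rate of the paired t on small discrete counts is only
  approximately nominal (counts are sums over 7 individuals; the
  differences are near-normal but not exactly so).
- The battery needs a baseline group; a cross in which *all* offspring are
  anomalous resolves polyspermy and clones but leaves maternal
  recombination-bearing duplication unresolved.
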