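# Methods

## Data model

The package works on four tab-separated tables: mutation annotations
(pedigree, gene, chromosome, 1-based position, mutation class, PP2 score),
long-format per-mouse genotype calls (REF/HET/HOM keyed by pedigree, dam
and litter), gene essentiality annotations (essential flag plus a
totally/partially lethal mode), and screen/mutation linkage P values.
Class labels form a closed set: three PP2 missense categories
(`probably_benign`, score ≤ 0.45; `possibly_damaging`, 0.45–0.95;
`probably_damaging`, 0.95–1.0) and two putative-null categories
(`null_class_I` for nonsense/makesense/start-loss SNVs, `null_class_II`
for indels and splice defects). Scores are present exactly for the
missense classes. Readers reject malformed rows with their line numbers;
genes carrying self-contradictory essentiality records are discarded and
counted, mirroring how conflicting database annotations are handled.
TSV was chosen over VCF deliberately: the analysis needs per-mouse calls
at validated sites plus class labels, which VCF would carry awkwardly.

## Filtering cascade

Analyses are restricted to mutations whose phenotypic effect is
attributable to a single gene:

1. **Isolation** — a mutation is dropped if any other mutation of the same
   pedigree on the same chromosome lies strictly closer than 100 Mb
   (1 Mb = 1e6 bp exactly; exactly 100 Mb apart is retained). Chromosomes
   are compared by name only; genetic-map distances and the X chromosome
   are out of scope.
2. **Pedigree size** — mutations from pedigrees with fewer than three
   genotyped G3 mice (any genotype) are dropped.
3. **Essentiality** — for damage estimation, only mutations in annotated
   essential genes are kept. Unannotated genes are treated as
   non-essential and logged, since annotation coverage is partial.

For each surviving mutation, `p_hom` is the proportion of HOM calls among
genotyped G3 offspring of dams heterozygous for that mutation. The
denominator is restricted to HET-dam offspring because a REF dam cannot
produce HOM pups and her litters would dilute the proportion below the
Mendelian 0.25 that the mixture model takes as its no-lethality reference.
Mutations with no HET-dam offspring have undefined `p_hom` and are flagged
and excluded downstream. Only successfully genotyped mice enter either
count. A separate phenotype-analysis filter keeps isolated mutations from
pedigrees with ≥ 4 G3 mice and `p_hom` ≥ 0.25 (both boundaries inclusive).

## Mixture estimator

The per-class truly-damaging fraction is estimated by the method of
moments under a three-subgroup mixture of `p_i` values (totally lethal at
0, partially lethal around θ, non-damaging around 1/4), generalized to

    rho_raw = (1 + r) (1/4 − mean(p)) / (1/4 (1 + r) − θ r)

with defaults θ = 0.125 (the midpoint of (0, 0.25); the true center of the
partial-lethality subgroup is unknowable from these data) and
r = 0.39 (the partial:total essential-gene ratio, 250/635 from viability
annotations). At the defaults the denominator is 0.29875. Choices made
where the procedure was open:

- **Clamping.** The raw estimator leaves [0, 1] under sampling noise (an
  all-lethal sample gives ≈ 1.163); both raw and clamped values are
  reported and the clamped one feeds downstream modules.
- **Bootstrap.** Percentile intervals from 5,000 resamples; the mutation
  (with its `p_i`) is the resampling unit, since the estimator is a
  functional of the `p_i` sample. Class-level seeds are spawned from one
  master seed.
- **Score windows.** Half-open `(low, high]` bins over PP2 scores, with
  the first window additionally admitting its left endpoint so a score of
  exactly 0 is not orphaned. Window lists are user-supplied.
- The weighted overall damage probability is the count-weighted average of
  clamped class estimates.

## Gene damage probability and saturation

For gene *g*, the J×K homozygosity matrix *M* pools all its mutations and
every G3 mouse genotyped for them, across pedigrees (a "superpedigree").
Given per-mutation damage probabilities P(m_j) (class-level values by
default, overridable per mutation),

    P_g(n) = Σ_{d ∈ {0,1}^J} Π_j P(m_j)^{d_j} (1−P(m_j))^{1−d_j} · I(c(d) ≥ n)

where c(d) counts mice HOM for ≥ 1 mutation with d_j = 1. The sum is
evaluated exactly for J ≤ 10 (configurable) and by Monte Carlo (default
1,000 simulations) above that; both paths use the inclusive inequality
c ≥ n. Genome saturation S is the sum of P_g(n) over genes, accumulated
along an explicit mutation chronology (record order as fallback) and
optionally expressed as a percentage of a user-supplied genome gene count.
The cumulative update is incremental: adding a mutation recomputes only
its gene's P_g over the mutations seen so far, which also guarantees the
curve is nondecreasing on the exact path.

## Essential-fraction scan

The fraction of essential genes is estimated by re-breeding each
pedigree's G3 generation in silico at its *neutral* size (its expected
size had no mutation been lethal), culling homozygous-damaged virtual
pups, and matching the simulated count of genes with ≥ 1 surviving
homozygote to the observed count:

1. **Neutral sizes.** An OLS regression of observed G3 counts on breeding
   covariates (pedigree type, litters, per-class HET mutation counts of
   the G2 dams) is fitted and the mutation-count covariates zeroed. When
   litter records are available the model is fitted per litter and the
   neutral pedigree size is the rounded sum of its litters' neutral
   predictions. The litter-level form is the default because at
   whole-pedigree granularity the culling loss scales with the litter
   count and is partly absorbed into the litters coefficient, biasing the
   neutral prediction low; per litter the loss is additive in the dam's
   mutation counts and the zero-count extrapolation is clean.
2. **Breeding.** Each virtual pup draws one allele per parent per locus
   (HET transmits the variant with probability 1/2); loci are unlinked —
   the analyzed mutations are pre-filtered to be ≥ 100 Mb apart, and the
   simulation does not model recombination. Pups are assigned to dams
   multinomially.
3. **Labels and culling.** A fraction *f* of genes is marked essential,
   split partial:total at 39:100; each mutation is damaging with its
   class probability. Pups HOM for a damaging mutation in a totally
   essential gene are culled deterministically; in a partially essential
   gene at rate 0.5 (independently per mutation); the total rule dominates
   when both apply. Culled pups are not replaced and are excluded from all
   counts, mirroring viability at weaning.
4. **Scan.** Five replicate cohorts are simulated at each grid fraction;
   a single linear regression over all replicate points (not per-fraction
   means) of the genes-with-homozygote count on *f* is solved for the
   fraction reproducing the observed count, clipped to [0, 1]. A
   non-negative slope is an error. Randomness is split into independent
   label/breeding/culling streams per cell, so a run at *f* = 0 breeds
   exactly the same pups as a lethality-free simulation with the same seed.

## Phenotype enrichment

The probability that a mutation yields a viable detectable phenotype is
the fraction of screen/mutation combinations with Bonferroni-adjusted
linkage P strictly below 1e-5, compared between essential and
non-essential gene sets with Clopper–Pearson exact 95% intervals (the
interval method is documented so alternatives can be compared). By
default the three transmission models (recessive/additive/dominant)
collapse to one combination per screen/mutation pair carrying the minimum
adjusted P; `collapse_models="none"` counts model records separately,
since the right denominator convention is not fully determined. The
comparison also reports each set's class composition (probably-damaging
and probably-null fractions) as a confounding check.

## Synthetic cohort generator

The generator emulates the statistical structure of a large ENU program:
G1 sires heterozygous at Poisson(55) private loci (so surviving G3 mice
carry ≈ 34 mutations, the carrier probability under the backcross being
5/8), G2 dams HET or REF per locus with probability 1/2, on average four
dams per pedigree producing 1–2 litters each of mean size 7 (≈ 30
surviving G3 mice per pedigree after lethality), mutation classes mixed
at the reference cohort proportions with scores uniform within class
windows, positions uniform on length-weighted mouse autosomes (so the
100-Mb filter has realistic bite), a 34% essential-gene fraction with a
39:100 partial:total split, and per-class true-damage fractions at the
package's published defaults. Partial lethality is implemented as a
per-HOM-pup death probability of 1 − θ/0.25 = 0.5, so the surviving HOM
rate per born pup centers on θ. By default each mutation gets its own
gene; a 5% collision rate draws from a shared gene pool to exercise
superpedigrees. Pedigree/litter count distributions are Poisson-based
artifact choices — the real joint distribution is only known graphically.
All latent labels (per-gene essentiality mode, per-mutation damage, born
and surviving counts per litter) are written to truth tables, and the
same seed yields byte-identical files.

What the generator does *not* emulate: sequencing/genotyping error,
structured genotype missingness, X-linked loci, within-chromosome linkage,
litter-level environmental effects, or the empirical shape of real
pedigree-size distributions. Passing recovery tests therefore show that
the estimators are consistent under the stated model assumptions, not that
those assumptions hold in any particular real cohort.

## Numerical and testing choices

- All randomized operations take explicit integer seeds or numpy
  Generators; nested streams are spawned via `SeedSequence` so replicates
  are independent yet reproducible.
- Exact enumeration is cross-checked in the tests against an independent
  brute-force oracle that materializes every outcome table with plain
  Python loops (J ≤ 6); Monte Carlo is checked against the exact value
  within binomial standard error.
- Estimator recovery is tested on mixtures drawn at the reference
  per-class sample sizes (477/281/690/78/60) with Poisson(15) HET-dam
  denominators, which injects the finite-litter counting noise the
  estimator itself ignores.
- The essential-fraction scan is tested end to end at generating fractions
  0.2/0.34/0.5 with 100-pedigree cohorts, a 0–0.6 grid in steps of 0.02
  and 5 replicates per point, requiring mean recovery within ±0.05 over
  20 seeds. Problem sizes throughout the suite (pedigree counts, bootstrap
  and simulation replicates) are the package's chosen test scale: large
  enough for the stated tolerances, small enough to keep the suite quick.

## Known limitations

- `p_i` from surviving litters over-represents lethality slightly: deaths
  remove HOM pups from the numerator *and* shrink the denominator, so the
  partial-lethality subgroup centers a little above θ in realistic data
  (≈ 0.143 for θ = 0.125); the estimator inherits a correspondingly small
  downward-then-rescaled bias (≈ 2% relative) that the recovery tests
  absorb.
- The scan's neutral-size regression extrapolates to zero mutation counts
  well outside the observed covariate range; with heavy mutational load
  the residual extrapolation error leaves a per-seed scatter of ~0.07 on
  the recovered fraction at 100 pedigrees.
- Class-level damage probabilities treat every mutation of a class as
  exchangeable; per-mutation overrides are available but no covariate
  model (score within class, transcript structure) is fitted.
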