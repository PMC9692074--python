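# Methods

## Model and estimators

For an autosomal-recessive gene *g* in a cohort of *N* diploid
individuals, let the pathogenic allele set be the variants classified
Pathogenic or Likely pathogenic under a chosen source. The plug-in
estimators from aggregate counts are

- pathogenic allele frequency `q_g = (Σ_v AC_v) / 2N`,
- carrier frequency `CF_g = (Σ_v (AC_v − hom_v)) / N`,
- Hardy–Weinberg incidence `I_g = q_g²` (from `1 = p² + 2pq + q²`),
- panel incidence `I = Σ_g q_g²` and panel carrier count `Σ_g Σ_v (AC_v − hom_v)`.

Assumptions, made explicit:

- **Denominator 2N, not per-site AN.** The cohort chromosome count is the
  denominator for q even though each site has its own AN ≤ 2N. At the
  call rates typical of exome aggregates (AN/2N ≈ 0.95–1.00) the
  difference is below the rounding of the reported figures, and a common
  denominator makes per-gene sums and panel sums commensurable. Per-site
  AN is kept on the records for diagnostics. Note the estimator is
  downward-biased by the mean call rate when call rates are materially
  below 1; the synthetic recovery study can quantify this by setting
  `call_rate < 1`.
- **One carrier per observed allele.** Carriers are equated with
  `AC − hom`: each allele not inside a homozygote marks one distinct
  heterozygous individual. Compound heterozygosity within a gene, and
  double carriers across genes, have probability of order q² and are
  ignored — consistent with treating the allele count 12/1,909 as "12
  carriers".
- **Hardy–Weinberg equilibrium, full penetrance, no inbreeding
  adjustment, no founder-effect modelling.** Incidence is the random-mating
  expectation q²; panel incidence sums gene incidences (biallelic
  causation in any one gene).
- **Zero observed alleles ≠ frequency zero.** A gene with no observed
  pathogenic allele in a stratum is reported *not estimable* and excluded
  from the panel incidence sum; an aggregate zero is weak evidence, not
  certainty. Likewise a population with AN = 0 at a site is treated as
  unobserved there, never as q = 0.

## Uncertainty

All intervals are exact binomial (Clopper–Pearson), computed from Beta
quantiles: `lower = B(α/2; x, n−x+1)`, `upper = B(1−α/2; x+1, n−x)`,
with lower = 0 at x = 0 and upper = 1 at x = n. They apply to carrier
counts (out of N), allele counts (out of 2N), and the summed panel
carrier count. The incidence interval squares the allele-frequency bounds
per gene and sums across genes — a conservative transformation (the
bounds of a monotone function of a single binomial parameter per gene;
correlations across genes are ignored, as the panel sum is dominated by
its largest gene at these frequencies). Exact intervals are deliberately
conservative: empirical coverage in the recovery study runs at or above
the nominal 95%.

## Classification engine

The engine implements the 2015 ACMG/AMP combining rules over *assigned*
evidence criteria. Each criterion code (PVS1, PS1–PS4, PM1–PM6, PP1–PP5,
BA1, BS1–BS4, BP1–BP7) carries an applied strength defaulting to its
native level; counting uses applied strengths, so SVI-style strength
modification (e.g. PVS1 applied at Strong) behaves identically to native
evidence at that level. Numerical conventions where the written rules are
silent:

- a second very-strong criterion counts as strong (strengths stack
  downward rather than being discarded);
- benign-side strengths below strong count toward supporting, since the
  benign rules only distinguish stand-alone / strong / supporting;
- BA1 is stand-alone benign only in the absence of any pathogenic-side
  criterion; with pathogenic evidence present the call is VUS
  (conflicting evidence), as it is whenever both sides fire a category;
- the mapping is total: any profile matching no rule is VUS with
  `rule_fired = "default-VUS"`.

The engine does **not** compute criteria from data — population
frequencies and in-silico predictors are upstream concerns. Label-based
sources are provided for parity: ClinVar-style labels (case-insensitive;
slash-combined "Pathogenic/Likely pathogenic" accepted) and HGMD-style
labels where exactly `DM` is pathogenic-equivalent (`DM?` is not).

The bundled panel's evidence profiles are illustrative assignments
(loss-of-function: PVS1+PM2+PP5; functionally characterised missense:
PS3+PM2+PP3; other missense: PM1+PM2+PP3+PP5) chosen so each variant's
engine call reproduces its published five-tier category; the pathogenic
*set* is the authoritative content, not the individual criteria.

## Synthetic cohorts

`synthetic.generate_cohort` emulates the aggregate structure of an exome
cohort: per variant and population, `AN ~ Binomial(2N, call_rate)` (fixed
2N at call rate 1); among the `AN//2` fully genotyped individuals,
homozygotes are `Binomial(AN//2, q²)` and heterozygotes binomial at the
conditional Hardy–Weinberg rate `2pq/(1−q²)`, an odd chromosome is
genotyped haploidly; `AC = 2·hom + het (+ lone)`. Aggregates are
therefore always self-consistent (`2·hom ≤ AC ≤ AN`) with
`E[AC] ≈ AN·q`. Identical seeds reproduce byte-identical tables.

Not modelled: linkage/haplotype structure, admixture, genotyping error,
site-specific call-rate covariates, and individual-level genotypes.
Passing recovery tests therefore demonstrate correctness of the
estimators under the sampling model, not robustness to real-data
artefacts such as joint-calling batch effects.

The default scenarios mirror the two bundled cohorts: Korean-like
(N = 1,909; true per-gene q of 6/3818, 5/3818, 1/3818) and
East-Asian-like (N = 9,197; 14, 9, 2, 5 alleles over 18,394
chromosomes). `recovery_study` reports the bias of q̂ with Monte-Carlo
standard errors, empirical interval coverage, and the relative bias of
the plug-in panel incidence Σq̂² — which is upward-biased by Var(q̂)
(≈ +30% at the Korean-like scale, where q itself is of order 10⁻³); the
study quantifies the bias rather than correcting it, because the plug-in
estimator is what the reported figures use. Test and acceptance runs use
200–1,000 replicates, sizes at which the Monte-Carlo error is already far
below the effects being checked.

## Reporting conventions

- carrier frequency: percent, 2 decimals; allele shares: percent,
  1 decimal; per-population frequencies: 4 significant figures,
  fixed-point.
- incidence: `1/round(1/q²)` with thousands separators; interval
  endpoints likewise; not-estimable renders `NE`.
- published 1/n figures inherit their authors' intermediate rounding, so
  recomputed denominators can drift by up to ~2×10⁻⁴ relative (e.g.
  583,085 recomputed where 583,162 was printed); comparisons in the
  acceptance suite therefore use 1e-3 relative tolerance.
- census projections (expected carrier newborns, affected births) start
  from the *reported* carrier frequency — the rounded 2-decimal percent —
  because that is the figure such projections are quoted from; the
  rounding-free value is always available on the estimate object.

## Known limitations

- Variants invisible to the aggregate (structural variants, deep-intronic
  founder alleles outside exome capture) are necessarily missing, so
  carrier frequencies are lower bounds for populations with such alleles
  (the Korean *UNC13D* deep-intronic founder variant is the canonical
  example for the bundled panel).
- The Korean *STX11* stratum has zero observed alleles; its incidence is
  reported not estimable rather than by any substituted figure.
- The pipeline supports ClinVar- and HGMD-label selection modes, but the
  bundled table carries illustrative labels only; quantitative results
  for those modes require the corresponding variant lists.
- No liftover, transcript-aware HGVS normalisation, or variant effect
  prediction; variant identity is (gene, coding HGVS) with a genomic
  coordinate fallback.
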