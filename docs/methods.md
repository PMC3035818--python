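# Methods

## Scientific setting

Recently diverged species can continue to exchange genes. Two signals are
used here to detect and date such exchange between a recipient and a donor
species:

1. **mtDNA haplotypes that are "too similar" across the species
   boundary.** If a haplotype found in the recipient species sits only a
   few silent substitutions away from a donor-species haplotype, the pair's
   divergence time can be estimated from the substitution count and
   compared with the species' split time. A divergence much younger than
   the split indicates introgression rather than retained ancestral
   polymorphism.
2. **Nuclear loci whose differentiation is too low (or too high) for the
   species' divergence time.** Under a neutral isolation model, the
   distribution of per-locus F<sub>ST</sub> is fully determined by the
   sampling configuration, θ and the split time τ; loci in the tails of a
   simulated null are candidates for introgression (low tail) or barriers
   to gene flow (high tail).

## Poisson dating

Model: after the haplotype lineages separate, silent substitutions
accumulate independently on both at rate μ per site per year, so the count
over L compared silent sites is Poisson with mean λ = 2μLT.

* Point estimate: t = k/(2μL). Defaults used throughout: μ = 1.6e-8
  substitutions/site/year (a standard *Drosophila* silent-site rate),
  L = 737 silent sites, α = 0.05.
* Upper bound: the largest T whose Poisson mean is still compatible with
  observing ≤ k substitutions at level α, i.e. λ\* solving
  PoissonCDF(k; λ\*) = α, found by bracketed root-finding (brentq,
  |Δλ| ≈ 1e-12; closed form −ln α for k = 0). The inversion is exact; note
  that rounding L or the printed bound changes the answer by 1–2%, so
  published values derived from the same inputs may differ at that level.
* The factor 2 in λ counts both lineages; with k = 3, L = 737,
  μ = 1.6e-8 the point estimate is 127 205 years and the 95% bound
  ≈ 328 800 years; for k = 0 the bound is ≈ 127 000 years.
* `closest_pair_differences` selects the pair to date: for each putative
  introgressed haplotype, the minimum substitution count over all
  donor-species sequences on masked (silent) gap-free columns, with ties
  reported in full.
* `prob_unsampled_haplotype(p, n) = (1 − p)ⁿ` quantifies whether the
  haplotype could have been missed in an earlier sample of n individuals.

## Alignment statistics

Columns containing a gap or N in any sequence are excluded from every
statistic (lengths are "after discarding gaps"); haplotype identity is
computed on the analysed columns only, since excluded columns cannot
distinguish haplotypes consistently. Inputs are resolved sequences —
upstream decisions about heteroplasmic or heterozygous reads (majority
peak, random allele drop) are input conventions, not re-implemented here.

* S counts analysed columns with ≥ 2 distinct bases; h counts distinct
  row strings; Hd = n(1 − Σp²)/(n − 1).
* Nucleotide diversity is the mean p-distance over all C(n,2) sequence
  pairs. The Jukes–Cantor correction −(3/4)ln(1 − 4p/3) is applied to the
  *mean* distance, not per pair — this is the convention that reproduces
  the dating point estimate when applied to the between-species mean.
  p ≥ 3/4 is outside the JC domain and raises an error.
* Between species: F counts columns whose species base sets are disjoint;
  S\* counts columns polymorphic in both species sharing ≥ 2 bases; Ks is
  the JC-corrected between-species mean pairwise distance over the silent
  mask when present.
* `silent_site_mask` is a convenience classifier (third codon positions
  whose observed codons are all ≥ 2-fold degenerate, standard code).
  Curated annotations should be passed in directly; published silent-site
  counts are generally not reproducible from a heuristic classifier.

## Coalescent null and microsatellite conversion

Time is in 4N₀ generations (Hudson's ms convention): j lineages coalesce
at rate j(j−1), demes are isolated until the join at τ, equal deme sizes,
no migration or recombination. Mutations are infinite-sites: S ~
Poisson(θ·total branch length), each mutation on a branch with probability
proportional to length. The stepwise conversion assigns each segregating
site an equiprobable ±1 repeat-unit step (seed-controlled; the classical
single-step model — the step-sign convention of the original conversion
scripts is not documented anywhere, so random equiprobable signs are this
package's fixed choice) and sums steps per chromosome; homoplasy is
intended. The per-locus statistic of a null replicate is computed on
allele copies, so simulated haploid chromosomes and observed diploid
tables are directly comparable.

Null configuration defaults: θ = 4, n1 = n2 = 200 chromosomes, τ = 1.25,
10 000 replicates. τ = 1.25 replicates the published simulation command
verbatim; note that converting the stated 250 000-year split with
N₀ = 10⁶ and 10 generations/year gives τ = 0.625 — the two are mutually
inconsistent in the source, so the package treats τ as a free parameter,
defaults to the printed command, and provides `years_to_tau` for the
alternative. Sensitivity grids (e.g. τ for 50 000 and 510 000 years, the
95% CI of the split-time estimate) are supported by `sensitivity_rescan`.

Calibration anchors (tested): E[T₂] = 0.5, E[TMRCA(4)] = 0.75 (4N units),
E[S] = θ·Σ₁ⁿ⁻¹ 1/i (≈ 26.27 for n = 400, θ = 4), and distributional
agreement of S with msprime under the identical two-deme demography
(KS test, n1 = n2 = 10).

## Differentiation statistics

* **F<sub>ST</sub>**: Weir & Cockerham (1984) variance-components θ̂ in
  the haploid (allele-copy) form — per allele, MSP the among-deme and MSG
  the within-deme mean square, θ̂ = Σ(MSP − MSG) / Σ(MSP + (n_c − 1)MSG).
  Negative estimates are retained: truncation would bias the null's lower
  tail, the key region for introgression detection. Monomorphic loci are
  undefined (NaN) and excluded/flagged downstream.
* **G′<sub>ST</sub>**: GST = (H_T − H_S)/H_T with H_S the unweighted mean
  within-deme He and H_T from unweighted mean frequencies (a
  `weight_by_size` toggle gives the sample-size-weighted variant);
  G′ = GST(k−1+H_S)/((k−1)(1−H_S)) with k = 2. G′ = 1 exactly when the
  demes share no alleles; it cannot exceed 1.
* **Rarefaction**: E[A_g] = Σᵢ[1 − C(N−Nᵢ, g)/C(N, g)], exact binomials.
* **Inbred allele-drop**: each replicate keeps one uniform allele of every
  heterozygous genotype of an inbred-flagged individual (homozygotes and
  outbred individuals keep both copies); the statistic is averaged over
  200 replicates by default; > 10% undefined replicates aborts.
* **Dps**: 1 − (1/L)ΣΣ min(p|g1, p|g2) on pooled group frequencies, loci
  missing in either group excluded pairwise. NJ trees come from
  scikit-bio's Saitou–Nei implementation; bootstrap support resamples loci
  with replacement (default 100 replicates) and scores each bipartition of
  the point tree by its replicate frequency.

## Outlier classification

Cutoffs are inverse-ECDF (type-1) order statistics — unambiguous at
10 000 draws, no interpolation. Two tail conventions are provided because
"outside the 95th percentile" admits both readings: `central95`
(2.5%/tail; the default — consistent with expecting ~1 extreme locus in
24 at a *total* 5% rate) and `tail5` (5%/tail). The convention used is
recorded in every report. Monomorphic replicates are excluded from the
cutoffs and their rate reported; > 50% undefined aborts. One statistic is
drawn per simulated locus.

## Synthetic data generator

The generator reproduces the *study conditions*, not arbitrary data:
125 recipient + 15 donor individuals, 25 loci (8 X, 8 second, 8 third
chromosome; 1 fourth-chromosome locus forced monomorphic in both species,
which the scan must flag as undefined), θ = 4, split at τ = 1.25,
inbred_fraction = 0.8 of recipient individuals (most are isofemale lines;
donor individuals and F1s of wild females are not inbred), and 5
introgressed loci — introgression is modelled by deme-swapped lineage
sampling (those loci are simulated at τ = 0), so reduced differentiation
emerges from a genuinely shared genealogy rather than copied alleles.

The mtDNA alignment plants haplotype classes on a star-like scaffold:
each class copies its donor class and mutates the requested number of
*fresh* silent-mask columns, making pairwise class distances exact path
sums. Default plan: donor classes siI/siII/siIII (30/—/35 substitutions
from the siII root), recipient classes maI (identical to siIII — the
long-shared haplogroup), maII (40 from the root, the endemic divergent
class) and maIII (4 copies, exactly 3 substitutions from siII — the
introgressed class the dating stage must recover), over a 737-column
silent mask in a 2088-bp alignment.

What the generator does *not* emulate: within-class sequence
polymorphism, heteroplasmy, linkage between loci, realistic collection
structure (collections are cyclic slices of one simulated population) and
allele-size constraints. Tests passing on this generator therefore
validate the estimators and the pipeline logic, not field realism; on real
data the null's θ and τ must be justified externally, which is why both
are plain parameters.

## Problem sizes and numerics

The full-scale null (10 000 replicates, 400 chromosomes) is the CLI
default. The test suite and the acceptance script use the package's
scaled configurations — 2 000-replicate nulls, 1 000 observed null loci,
5 000 (tests) / 2 000 (acceptance script) replicates for the Watterson
calibration, 3 000 replicates for the msprime cross-check — sizes at
which Monte-Carlo error is well inside the asserted 3-SE / binomial-99%
bands. All stochastic stages take an explicit `numpy.random.Generator`;
pipeline stages derive their seeds from one top-level seed via
`SeedSequence`, and identical seeds give bit-identical outputs, including
written files. Quantile and root-finding conventions are fixed (type-1
ECDF; brentq with closed-form k = 0 shortcut) so reruns are exactly
reproducible.

## Known limitations

* The isolation model has no migration after the split, no population
  growth, and equal deme sizes; the null is only as good as θ and τ.
* The W&C estimator is applied to allele copies; genotype-level (diploid)
  weighting for partially inbred data is not implemented (the published
  tooling's choice is not recoverable), and the allele-drop correction is
  the supported route for inbred lines.
* NJ tie-breaking follows scikit-bio's implementation; on continuous
  distances ties have measure zero.
* The silent-site classifier is a heuristic; curated masks should be
  supplied for real alignments.
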