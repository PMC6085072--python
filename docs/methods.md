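# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `ancinv`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Site data and filtering

Sites are biallelic, 1-based, with per-group (ref, alt, depth, GQ) summaries;
multi-allelic records are rejected and counted, because every downstream
statistic is written in terms of a single alternate-allele frequency
p (q = 1 − p).  Group frequency is alt/(ref+alt), undefined (site skipped for
that comparison) when the group has no reads.  Intervals are 0-based
half-open (BED); point positions are 1-based (VCF).

Filtering keeps sites where every group has GQ ≥ 30 and depth strictly above
a floor (default 1) and strictly below mean + 3 SD, with mean and SD computed
per group from the unfiltered table.  Two deliberate interpretations: the
bounds are applied *per group* (a pooled alternative is possible but couples
groups with very different coverage), and a degenerate SD of 0 keeps sites at
exactly the mean depth, so uniform-coverage synthetic data is not discarded.
Filtering is idempotent only when the second pass recomputes moments from the
filtered table and the data were already inside the bounds; the test suite
checks the subset and idempotence properties.

Scaffold-to-chromosome lifting: forward scaffolds map pos → offset + pos;
reverse scaffolds map pos → offset + (length − pos + 1).  Collisions (two
sites landing on one chromosome coordinate) are errors, as is a scaffold
missing from the map.

## Window statistics

* d_xy = Σ_sites [p₁(1−p₂) + p₂(1−p₁)] / n_callable.  When no callability
  track is supplied, n_callable defaults to the window length; on real data
  this biases d_xy downward wherever invariant sites were uncallable, and the
  scan logs a prominent warning.  RND is unaffected when the bias is shared
  by numerator and denominator windows.
* Nei's D_A = 1 − mean_sites[√(p₁p₂) + √(q₁q₂)] over sites usable for the
  pair.
* F_ST: the estimator is not pinned down by the quantities it feeds, so we
  use a Hudson-type ratio of window sums, 1 − Σ(p₁q₁ + p₂q₂)/Σ(p₁q₂ + p₂q₁),
  the standard recommendation for two-population comparisons; it is a ratio
  of averages (not an average of ratios) for stability in windows with weak
  signal.  No finite-pool-size correction is applied to the frequencies, so
  under panmixia the estimator carries a small positive bias of order 1/pool
  size; the panmixia test uses pools of 50 accordingly.  Values are clamped
  to [0, 1−10⁻¹²) before the log transform; clamping is logged.
* RND = d_xy(pair) / mean of the two ingroup–outgroup d_xy values.  The mean
  (rather than either single comparison) is the standard relative-node-depth
  denominator; either single comparison can be selected instead.  Windows
  with zero outgroup divergence are flagged missing.
* T = −log(1 − F_ST) with the natural log, scaled per window so the
  calibration pair (ingroup versus outgroup) equals 2 Mya.  Scaling is done
  per window and then averaged; scaling after averaging is a defensible
  alternative that weights windows differently.  Absolute years are
  interpretive only — the package's inferences rest on comparisons between
  distributions of RND/T, not on the calibration.
* Windows with fewer than 10 segregating sites are excluded from summaries
  and trees alike, one rule for both pathways.
* Partition summaries: percentile bootstrap over windows (default 1000
  resamples, 95% interval), deterministic given a seed.  Distribution
  contrasts: Mann–Whitney rank-sum (exact when both n ≤ 8 and tie-free,
  tie-corrected normal approximation otherwise; all-tied input returns
  p = 1).  Outlier enrichment: Pearson χ² with 1 df, no continuity
  correction, on the 2×2 table of (top-1% genome-wide) × (inside partition);
  degenerate margins are flagged rather than computed.

## Window phylogenies

Distance matrices are pairwise D_A over the four role-bearing taxa.
Neighbor joining follows Saitou–Nei exactly; ties in the Q criterion are
broken by the lexicographically smallest pair of node keys (a node's key is
its smallest leaf label), so results are independent of input order.
Negative branch lengths are clamped to zero with the deficit moved to the
sibling branch, preserving path lengths.  On additive matrices NJ recovers
the generating topology and branch lengths exactly; this is enforced against
an independent random-tree generator, and the topology is cross-checked
against scikit-bio's NJ in a test.

Classification roots the tree on the outgroup and reads the ingroup cherry:
(DperST, DperSR) sisters → species-concordant; (DpseST, DperSR) sisters →
discordant; the remaining quartet → other.  Classifying by rooted triplet
(rather than raw joining order) is order- and scale-invariant.  Bootstrap
support resamples *sites* within the window (inputs are frequency tables, not
alignments); support is the fraction of replicate topologies equal to the
point estimate, and windows under 0.75 stay in the output as "unclassified"
so that their run-breaking effect on block calling is explicit.  The default
10,000 replicates is configurable; tests and the acceptance script use 200,
which bounds the support standard error at ~0.035.  Blocks are maximal runs
of ≥ 3 same-class windows (30 kb); the run length is a package choice
surfaced in the config, since no canonical value exists.

## Pairwise-difference likelihoods (Iso / IM / IIM)

Units: coalescence time t is mutational (a pair separated for time t
accumulates s ~ Poisson(r·t) differences; r is the locus relative rate).  A
deme with diversity parameter θ coalesces a pair at rate 1/θ, so θ is that
deme's expected pairwise diversity.  Migration rates M₁, M₂ are per
coalescent unit of the reference deme (θ₁), i.e. rate M/θ₁ per mutational
time unit, backwards in time: M₁ is the rate at which a lineage sampled in
population 1 traces into population 2.  This matches the convention in which
the within-population difference count under panmixia is geometric with mean
θ (e.g. P(0) = 1/2 at θ = 1).

Epochs backwards in time: [0, t₁) isolated demes θ₁, θ₂; [t₁, t₀) the same
demes exchanging migrants; [t₀, ∞) one ancestral deme θ_anc.  Iso is t₁ = t₀
with M = 0; IM is t₁ = 0.  The lineage process over {both-in-1, both-in-2,
split} gives the density: closed exponentials during isolation, an
eigendecomposed matrix exponential during migration (with a direct `expm`
fallback if the eigenbasis is ill-conditioned), and an exponential ancestral
tail.

The pmf P(s) = ∫ Poisson(s; r t) f(t) dt is computed piecewise:

* isolation epoch — exact, via the regularized lower incomplete gamma;
* migration epoch — Gauss–Legendre panels (12 points each, 8 panels
  initially), doubled adaptively until the quadrature mass matches the
  exactly known absorbed probability to 10⁻¹⁰; non-convergence raises rather
  than returning silently degraded values;
* ancestral tail — a scaled Gauss–Laguerre rule, exact for the polynomial ×
  exponential integrand when the node count exceeds (s_max+1)/2 (nodes are
  max(40, s_max/2 + 10), capped at 120).

The Iso between-class pmf also has a Poisson ⊕ Geometric closed form
(computed via the upper incomplete gamma); it is kept strictly as a
validation oracle and never used by the fitting path, so the two routes stay
independent.  Total pmf mass equals 1 to the quadrature tolerance by
construction (Poisson kernels sum to one at every node).

Fitting maximizes the summed log-likelihood by L-BFGS-B in transformed
coordinates (log for θ and t₀; t₁ = t₀·logistic(z); softplus for M so the
boundary M = 0 is reachable in the limit), from a method-of-moments center
plus Latin-hypercube jitter (default 3 restarts; the heavy acceptance loops
use 2).  Wald 95% CIs come from a central-finite-difference Hessian on the
natural scale, inverted; parameters pinned at a boundary (M below 10⁻⁵, or
t₁ within 10⁻⁵ of 0 or t₀) are flagged and their CIs suppressed, and a
singular Hessian yields "CI unavailable" rather than a fabricated interval.
The likelihood surface of IIM has a known soft ridge trading t₀ against
migration; split-time recovery is therefore validated by median relative
error over replicates rather than per-fit guarantees.

LRTs: statistic 2ΔlnL/x against χ² with df equal to the free-parameter
difference (Iso→IIM: 3; IM→IIM: 1; free-vs-shared across k partitions:
(k−1)·n_params).  x is the mean number of loci per dependence block — 7.75
when reproducing the published tables, 1 for independent synthetic loci.
Negative 2ΔlnL beyond numerical slack is a nesting violation and raises.
Boundary hypotheses (M = 0) make the χ² reference conservative-to-liberal
depending on the mixture; this is inherent to the published procedure and is
left as-is.

Locus sampling places 500-bp segments uniformly inside intergenic intervals
with ≥ 10 kb between nearest ends, by randomized rejection; accepted loci are
split as evenly as possible into three disjoint sets (the three comparison
classes need disjoint loci).  Relative rates are r_i = d_i/mean(d) from
outgroup divergence, with zero-divergence loci floored at 10⁻³ and flagged
(no renormalization after flooring).

## Simulator

The generic generator is an epoch-wise Gillespie structured coalescent
(within-deme pair rate k(k−1)/(2·size), per-lineage migration, deme merges at
epoch boundaries) with infinite-sites Poisson mutations on branches.
Divergences here are far below saturation, so no finite-sites correction is
applied.  The per-locus pair generator is a separate vectorized
implementation of the same two-lineage chain in mutational units — different
code from the likelihood's matrix exponentials, which is what makes the
simulator-versus-likelihood total-variation check a genuine cross-oracle
(a KS comparison against msprime provides a third, external route in a test).

The inversion scenario has four sampled groups (DpseST, DperST, DperSR,
outgroup) and times t₀ = 1 (species split) < t_inv = 3 (inversion origin,
in the ancestral population) < t_out = 8 (outgroup), deme size 0.25 for the
species-era and arrangement demes.  DperST carries the derived inversion;
DperSR and DpseST carry the ancestral arrangement.  Suppression is modeled
as reduced lineage exchange — a per-window weight multiplying both the
arrangement-exchange rate (12) and the between-species introgression rate
(1), equal to 1 in collinear windows and 0 at breakpoints — rather than
explicit recombination, which the downstream inference never uses.  Small
deme sizes relative to the epoch lengths make coalescence fast wherever
exchange is allowed, so breakpoint windows show deep DperST divergence
(t_inv) and DperSR–DpseST coalescence shortly after t₀, while collinear
windows are homogenized below t₀ — the qualitative structure the scan is
meant to detect.  The default window mutation rate (3 per unit branch
length) yields a median of roughly 60–70 segregating sites per 10-kb window
at 4 sampled chromosomes per group, comfortably above the 10-site rule.

What the generator does *not* emulate: within-window recombination (each
window is one genealogy), sequencing error and coverage heterogeneity,
selection (including the segregation-distortion dynamics of sex-ratio
chromosomes), and gene conversion.  Passing tests therefore demonstrate the
statistical machinery under the stated coalescent models, not robustness to
those real-data complications.

True window classes are recorded from the realized genealogy: the ingroup
pair with the smallest mean between-group TMRCA is the true sister pair.
The lineage-sorting law check uses one lineage per taxon and a high mutation
rate (60 per unit branch length), where the inferred class is the realized
gene-tree class with error well below the test tolerance.

## Problem sizes used by tests and the acceptance script

Chosen as the package's standard verification workload: cross-oracle TV at
10⁶ pairs for each of nine model/class points; IIM recovery at 20 replicates
of 4,000 loci (2 restarts); Iso Wald coverage at 50 replicates of 2,500
loci; NJ exactness on 100 random additive matrices of 4–8 taxa; the ILS law
at 5,000 windows for Δt ∈ {0, 0.5, 1}; the end-to-end signature at 100
replicates of 60 windows (10 breakpoint) with 200 bootstrap replicates per
window.

## Known limitations

* The coverage floor ("> 1 N") is user-specified; ploidy-aware depth
  expectations are not reconstructed.
* d_xy needs a callability track for unbiased absolute values on real data.
* The IIM likelihood treats loci as free of intralocus recombination and
  linkage between loci only through the 1/x LRT scaling; x is supplied, not
  estimated.
* Only two demes plus an ancestral deme are modeled in the likelihood (the
  simulator is general).
* Calibrated years inherit all uncertainty of the 2-Mya outgroup calibration
  and of the F_ST transform; they are reported for interpretability, and
  conclusions should rest on the distributional comparisons.
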