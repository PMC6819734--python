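# Methods

## Scores and the pair table

All statistics are built from log abundance. The fitness index of a microbe
is G = log N, motivated by a metabolic power law F = N₀·N^b whose constants
cancel once logs are taken; they are carried on `FitnessModel` purely as
documentation. Natural log is the default; base 10 is available
(`FitnessModel("10")`). The base only rescales every score by a common
positive constant, so every correlation downstream — network correlations,
trait correlations, the transition plane — is base-invariant (tested
end-to-end).

For each unordered taxon pair, per sample:

* mutualism y⁺ = log Nₐ + log N_b (symmetric),
* parasitism y⁻ = log Nₐ − log N_b (antisymmetric).

The signed y⁻ is stored under a fixed lexicographic taxon order
(taxon_a < taxon_b), so averages across samples, pairs and hosts are
well defined; the larger-over-smaller reporting convention (magnitude plus
direction, with direction "none" at exact ties, no epsilon jitter) is
applied only when results are displayed or serialized. A pair table on I
taxa always has ½·I(I−1) rows and annotates each pair with its clade pair
at every rank the taxonomy declares.

**Zeros.** The framework requires positive abundances. The `pseudocount`
policy is explicit: `"auto"` adds 1.0 when the matrix is declared as
counts, half the smallest nonzero value when declared as relative
abundances, and nothing when the kind is undeclared (zeros then raise with
the offending cells named). Any float overrides the policy.

**Normalization.** Scores are computed on abundances as provided. An
optional per-sample total-sum scaling exists (off by default) because the
fixed-resource argument behind the mutualism score presumes comparable
sample totals. Scaling leaves every y⁻ untouched and shifts each sample's
y⁺ by −2·log(total) — an analytic identity the tests verify.

## Networks: merging and aggregation

Per-host networks at the lowest rank are complete graphs with y⁺ (or
signed y⁻) as edge weights. Merging to a coarser rank averages: a clade's
node weight is the mean edge weight over pairs inside the clade (absent
for singleton clades), and the edge weight between two clades is the mean
over cross pairs. For parasitism, cross-pair values are oriented
consistently before averaging — first-clade side minus second-clade side
under the sorted clade-pair key — and the aggregate direction is the sign
of the mean. Within-clade parasitism pairs have no canonical orientation;
they keep the stored lexicographic taxon order, which makes within-clade
parasitism node weights orientation-dependent bookkeeping quantities
rather than directed claims (the transition plane uses magnitudes, where
this does not matter).

Host aggregation is an element-wise available-case mean, keeping the
unbiased across-host variance and the per-element host count for
inference, plus (parasitism) the fraction of hosts whose per-host edge
direction disagrees with the aggregate direction as a diagnostic. Because
merging and host aggregation are both plain means over the same multiset
of pair values, they commute; the implementation exploits this with a
vectorised groupby path (`merged_element_values`) that the tests verify
against the explicit per-network route and against an independent
brute-force oracle.

Network comparison is a Pearson correlation (Spearman available) over
shared element weights — edges by default, since whether node weights were
included in published season comparisons is not stated — with a 95% CI
from the Fisher z transform.

## Likelihood machinery

Pairs grouped by their clade-pair annotation at a chosen rank contribute
bivariate observations (y⁺, y⁻), modelled as Gaussian with group-specific
means (μₛ⁺, μₛ⁻) and a covariance (σ⁺², σ⁻², ρ) shared across groups
under every hypothesis (the covariance symbols carry no group index;
stated explicitly because it is easy to miss). Within a group, signed
differences are oriented to the sorted clade pair so all members share one
orientation. Same-clade pair groups (annotation like "1 x 1") participate
as ordinary groups: the pair table pairs taxa within clades too, and those
rows carry the same-clade annotation.

Fits: the free fit (per-group means, pooled ML covariance) and the fully
tied fit (grand mean, total ML covariance) are closed form. Tying a single
component's means, with the other component's means free, has no closed
form; it is fitted by alternating an exact GLS mean update (the tied
component's estimate is the grand mean; the free component's group means
are shifted by −(cov_tf/cov_tt)·(group deviation of the tied component))
with the ML covariance of the residuals. Each half-step is an exact
conditional maximisation, so the log likelihood ascends monotonically;
iteration stops at a relative change below 1e-10 (cap 500 iterations).
The resulting maximum was verified to match the general-linear-hypothesis
closed form (below) to machine precision.

Tests: the pair-group test ties both components (df = 2(S−1)); the
component tests tie one (df = S−1). The statistic is 2·Δloglik, always
non-negative by nesting. For p-values, both nulls are general linear
hypotheses on the mean matrix of a Gaussian linear model, so Wilks'
Λ = exp(−statistic/n) has an exact finite-sample null: Rao's F
transformation (exact for two response dimensions) for the pair-group
test, and a plain univariate F for the component tests, which reduce to
ANOVA on the constrained component. `LRTResult.p_value` uses these exact
references; the asymptotic chi-square tail is kept as `p_value_chisq` and
is visibly anticonservative at the simulation sizes the test suite uses
(size ≈ 0.066 instead of 0.05 at S = 4 groups of 25).

**Element significance.** Signed parasitism weights are tested against 0
(their natural null) with a per-element one-sample t on the across-host
mean, variance and n. Mutualism log products have no natural zero — they
shift with overall abundance scale — so each element is tested against the
grand mean of all element weights in the network: "significant" reads as
stronger or weaker than typical for that network, and this choice is
deliberate and prominent rather than hidden. Elements seen in fewer than
two hosts are flagged untestable; zero-variance elements are flagged
degenerate with p reported below the machine floor. Benjamini–Hochberg
q-values are attached per network; raw p-values are always kept.

**Group differences.** Per shared element, an unpaired Welch t test on the
two groups' summary statistics, with the +/0/− change code assigned at the
configured alpha. Unpaired is the default even when host ids overlap
between groups (whether published seasonal comparisons treated resampled
hosts as paired is not stated); a paired analysis can be run by subsetting
to shared hosts upstream.

## Trait association

Abundance–trait: clade abundance at a rank is the **sum** of member
abundances before the log (abundance aggregates additively; a mean of logs
would be a geometric mean), then Pearson-correlated with the trait across
the hosts of one group. Interaction–trait: per network element, the
per-host merged weight against the trait (signed weights for parasitism).
Missing traits are excluded pairwise, never imputed; analyses run within
group by default, matching a season-stratified design. Both result tables
share hosts and n so they can be read side by side — e.g. comparing a
clade's abundance–BMI correlation with its within-clade mutualism–BMI
correlation. p-values are the exact two-sided t test of Pearson's r;
q-values are Benjamini–Hochberg within each call.

The trait correlation of interaction weights is invariant to the log base
and, for parasitism, to per-sample total-sum scaling (both identities
tested).

## Transition plane

Elements of a mutualism/parasitism network pair are embedded by
standardized mutualism weight against standardized parasitism magnitude
(strength, not direction). Standardization is (x − mean)/SD with the
unbiased SD, pooling nodes and edges into one distribution per axis by
default (separate standardization available; the pooled reading matches
standardizing 8 + 28 = 36 values together). The transition line joins the
observed maximum-mutualism and maximum-parasitism points — observed
extremes, not theoretical limits, since only observed values are plotted —
and is user-overridable. Each element gets a signed perpendicular
distance; positive is the half-plane containing the
(max z-mutualism, max z-parasitism) corner, i.e. the side of more intense
interactions; |distance| ≤ 1e-9 classifies as "on". Construction is
invariant to affine rescaling of the raw scores.

## Synthetic communities

The generator emulates the *shape* of a two-season 16S gut survey — a
multi-rank taxonomy (e.g. 101 genera in 8 phyla), per-host log-scale
abundances, two sample groups with partially overlapping hosts (93 + 91
samples, 57 hosts in both for the survey-shaped preset), and a numeric
trait linearly coupled to chosen interaction elements plus Gaussian noise.
Log abundances are multivariate normal; lognormality was chosen because
every framework statistic is linear in log abundance, which makes planted
effects analytic.

Cooperation within a clade (value in [0, 1]) acts twice, consistent with
the fixed-resource argument behind the mutualism score:

* it is the equicorrelation of member log abundances across hosts (a
  shared host-level clade factor) — a correlation-only effect cannot move
  the clade's mean log product, because the mean of pairwise log products
  over a clade depends only on the member means;
* it sets the evenness of the member mean abundances: members split a
  common clade total with mean offsets log(pᵢ·m) that flatten to zero as
  cooperation approaches 1. For a fixed clade total, flatter proportions
  raise the summed log abundance (concavity of the log), hence the clade's
  within-clade mutualism strength — exactly the equal-abundance optimum
  the mutualism score encodes.

A parasitism shift δ planted on a clade pair moves member means by ±δ/2,
so the merged signed clade-level edge has expectation δ (pair-count factor
1 under mean-based merging; exact when the member spread is disabled).
Traits are linear combinations of realized per-host merged interaction
values plus noise, so trait recovery can be checked against the implied
correlation. A single RNG stream per call (from the spec seed) makes
output bit-identical under a fixed seed.

What the generator does **not** emulate: sequencing counts and their
zero-inflation, compositional closure, phylogenetic signal in the
taxonomy, realistic abundance distributions of any particular survey, or
season-by-host interaction structure beyond a per-clade group shift.
Passing tests therefore certify the machinery — scoring, merging,
inference calibration, recovery of planted effects — not the biology of
any real data set.

## Numerical choices and problem sizes

* Exact identities (merging vs brute force, geometric distances, loglik
  vs direct density products) are asserted at 1e-10–1e-12; LRT
  non-negativity at −1e-8.
* Ties in abundance give parasitism direction "none" and magnitude 0.
* Singular fitted covariances (constant or collinear observations) raise
  a dedicated error suggesting a pseudocount or jitter.
* Simulation sizes were chosen to make the checks sharp but quick: null
  calibration uses S = 4 pair-groups × 25 observations × 1000 replicates;
  estimator recovery uses 500 observations per group with a
  {50, 200, 800} consistency ladder; trait FDR control uses 200 replicate
  traits on a 9-genus community; the survey-shaped preset is run at its
  natural size (101 genera, 184 samples).

## Known limitations

* Commensalism and ammensalism cannot be separated from parasitism by
  these scores alone; the log-ratio magnitude covers both.
* Co-occurrence-style confounding is not addressed: the scores are
  functions of observed abundances, not causal interaction estimates.
* Within-clade parasitism node weights depend on the internal taxon
  ordering (see above); prefer magnitudes or the transition plane for
  within-clade strength statements.
* The shared-covariance assumption across pair groups is structural; no
  heterogeneity test is provided.
* Cross-rank hypotheses (a taxon versus a whole higher clade) are not
  first-class; only rank-homogeneous groupings are.
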