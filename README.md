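# microgame

Game-theoretic reconstruction of microbial interaction networks from plain
abundance tables.

Cross-sectional surveys (e.g. 16S gene profiles of a gut-microbiota cohort)
give one abundance vector per host and no time series, which rules out most
dynamical network-inference methods. `microgame` implements a deliberately
simple alternative rooted in metabolic and behavioral ecology: treat each
pairwise microbial encounter as a game whose payoffs can be read off the
abundances themselves, score every taxon pair in every host, and assemble
the scores into weighted interaction networks at any taxonomic rank.

## The model

Fitness is assumed to scale with abundance as a metabolic power law,
F = N₀·N^b, so the fitness index of a microbe is

    G = log(F/N₀)/b = log N

(the constants N₀ and b cancel and never enter any computation). For two
microbes with abundances N₁ and N₂:

* **mutualism** (inclusive fitness): y⁺ = log N₁ + log N₂ = log N₁N₂.
  For a fixed resource pool N₁ + N₂ this is maximal exactly when
  N₁ = N₂, so the log product measures the strength of cooperation —
  the microbial analogue of the behavioral-ecology observation that
  similarly sized animals cooperate (the "oddity effect" penalises the
  one that stands out).
* **parasitism** (exclusive fitness): y⁻ = log N₁ − log N₂ = log(N₁/N₂).
  The magnitude (larger abundance over smaller) measures the strength of
  asymmetric exploitation; the sign gives its direction.

An I-taxon table becomes W = ½·I(I−1) unordered pairs, each carrying y⁺
and y⁻ per host plus its clade-pair annotation at every available rank.
From there:

* **networks** — per-host complete networks at the lowest rank are merged
  upward by averaging (within-clade pairs → node weights, cross-clade
  pairs → signed edge weights) and aggregated across the hosts of a group
  (e.g. season), keeping per-element sampling variances;
* **inference** — pairs grouped by clade pair are modelled with bivariate
  normal densities sharing a covariance (σ⁺², σ⁻², ρ) while means
  (μₛ⁺, μₛ⁻) vary by group; likelihood-ratio tests probe whether clade
  pairs structure the interactions (df = 2(S−1)) or a single component
  does (df = S−1), with exact finite-sample F null distributions;
  element-level t tests and Welch tests give per-edge significance and
  between-group change codes (+/0/−);
* **trait association** — Pearson/Spearman correlation of clade
  abundances and of per-host interaction weights with numeric host traits
  (e.g. BMI), with Benjamini–Hochberg q-values;
* **transition plane** — standardized parasitism against standardized
  mutualism per network element; the line joining the maximum-mutualism
  and maximum-parasitism points separates milder (below) from more
  intense (above) interaction regimes.

A synthetic-community generator with planted cooperation, parasitism and
trait couplings makes every stage testable without external data.

## Worked example

```python
import microgame as mg

abundance, taxonomy, metadata = mg.davenport_shaped_fixture(seed=1)
pairs = mg.build_pair_table(abundance, taxonomy)
print(f"{pairs.n_taxa} genera -> {pairs.n_pairs} pairs across {len(pairs.samples)} samples")

aggregates = {}
for interaction in (mg.MUTUALISM, mg.PARASITISM):
    nodes, edges = mg.merged_element_values(pairs, "phylum", interaction)
    for season in metadata.groups:
        samples = metadata.samples_in_group(season)
        aggregates[(interaction, season)] = mg.network_builder.aggregate_from_values(
            nodes, edges, "phylum", interaction, group=season, samples=samples)

for interaction in (mg.MUTUALISM, mg.PARASITISM):
    r, ci, n = mg.network_correlation(
        aggregates[(interaction, "winter")], aggregates[(interaction, "summer")])
    print(f"winter-summer {interaction} network: r = {r:.2f} "
          f"(95% CI {ci[0]:.2f}-{ci[1]:.2f}, {n} phylum pairs)")

lrt = mg.lrt_pair_group_effect(pairs, "phylum")
print(f"phylum-pair effect: LRT = {lrt.statistic:.0f}, df = {lrt.df}, p = {lrt.p_value:.3g}")

bmi = mg.interaction_trait_correlation(
    mg.merged_element_values(pairs, "phylum", mg.MUTUALISM), metadata, "BMI", group="winter")
top = bmi.sort_values("p").iloc[0]
print(f"strongest BMI link (winter): {top.element_type} {top.clade_1}"
      f"{' x ' + top.clade_2 if top.clade_2 else ''}, r = {top.r:.2f}, q = {top.q:.2g}")
```

prints

```
101 genera -> 5050 pairs across 184 samples
winter-summer mutualism network: r = 0.89 (95% CI 0.78-0.95, 28 phylum pairs)
winter-summer parasitism network: r = 0.88 (95% CI 0.75-0.94, 28 phylum pairs)
phylum-pair effect: LRT = 72785, df = 70, p = 0
strongest BMI link (winter): edge P1 x P2, r = 0.65, q = 6.2e-11
```

Reading the numbers: the synthetic community is shaped like a published
two-season gut survey (101 genera, 8 phyla, 93 winter + 91 summer samples,
57 hosts in both). Its 5050 genus pairs merge into 8 phylum nodes and 28
phylum-pair edges per season; the seasonal aggregates correlate strongly
(r ≈ 0.9) because the planted interaction structure is mostly
season-stable. The likelihood-ratio test rejects overwhelmingly — phylum
pairs really do structure the pairwise scores in this community — and the
strongest BMI association is picked up on an edge whose mutualism weight
was planted into the BMI trait by the generator.

The same workflow is scriptable from a shell:

```sh
microgame simulate --preset davenport --seed 1 --out data/
microgame run --abundance data/abundance.tsv --taxonomy data/taxonomy.tsv \
    --metadata data/metadata.tsv --rank phylum --trait BMI --out results/run1
```

which writes per-season GraphML/TSV networks, significance and
group-difference tables, trait-correlation tables, transition-plane tables
and the resolved configuration into `results/run1/`.

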