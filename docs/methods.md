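# Methods

## Scope and model

The package implements the two-stage null-model framework for partitioning
community assembly processes, the statistics around it, and a synthetic
data generator that produces communities whose assembly process is known.

Stage one is phylogenetic: for every sample pair, the abundance-weighted
between-community mean nearest taxon distance (βMNTD) is compared with a
null distribution generated by shuffling taxon labels across the patristic
distance matrix, holding both community abundance vectors fixed. The
z-score (βNTI) measures whether phylogenetic turnover is smaller
(βNTI < −2, homogeneous selection) or larger (βNTI > +2, variable
selection) than expected when phylogenetic relatedness is random with
respect to community membership. The framework's key assumption is that
ecological niches are phylogenetically conserved, so selection leaves a
phylogenetic signature; the generator enforces exactly this assumption
(Brownian traits, Gaussian environmental filter) and the assumption's
failure modes are discussed under limitations.

Stage two is taxonomic: pairs not assigned to selection are scored with the
Bray–Curtis-based Raup–Crick statistic. Null community pairs preserve each
sample's observed richness and total abundance; membership is drawn without
replacement with probability proportional to occurrence frequency across
the table (weighted sampling implemented via Gumbel top-k keys), each member
receives one individual, and the remaining individuals are distributed
multinomially in proportion to total relative abundance. RC_bray is the
tie-corrected fraction of null Bray–Curtis values below the observed one,
rescaled to [−1, +1]. RC_bray > +0.95 is dispersal limitation,
RC_bray < −0.95 homogenizing dispersal, the remainder drift/undominated.
All classification inequalities are strict; a value exactly at a threshold
falls through to the next rule, and selection takes precedence over the
dispersal terms.

Within-sample clustering (MNTD, NTI = −z) uses the same label-shuffle null.
One seeded shuffle sequence serves all samples (or all pairs), so the (i,j)
and (j,i) entries see identical nulls and runs are bit-reproducible.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_null` (βNTI, NTI) | 999 | label shuffles; z-scores stabilise well before this conventional count |
| `n_null` (RC_bray) | 999 | null community pairs per sample pair, child-seeded per pair from the master seed |
| `n_perm` (Mantel, PERMANOVA) | 999 | permutation p uses the +1 correction, p = (1 + #{perm ≥ obs}) / (1 + n_perm) |
| βNTI weighting | abundance-weighted | the framework's usual choice; `weighted=False` gives incidence weighting. NTI defaults to unweighted |
| network abundance filter | 0.1 % of total reads | drops rare OTUs before correlation |
| edge thresholds | \|r\| > 0.6, BH-adjusted p < 0.05 | BH family = all tested pairs of one network; `use_adjusted=False` reproduces the raw-p variant |
| rarefaction depth | per-habitat minimum library | habitats are sequenced to different depths and are analysed separately |
| Shannon log base | e | switchable via `base=` |
| Chao1 | bias-corrected | S_obs + F1(F1−1)/(2(F2+1)); defined even when F2 = 0 |

## The synthetic generator

`synthetic` produces a Yule tree with exponential waiting times (tips
OTU_1..n), Brownian-motion traits (tip covariance = rate × shared path
length), a lognormal metacommunity (meanlog 0, sdlog 1.5 — the heavy tail
that makes rarefaction behave like real amplicon libraries), and count
tables under four regimes. Defaults were chosen to make each regime mean
what its label claims, derived from the statistics' own semantics:

- **selection** — sampling weight of OTU *k* in sample *j* ∝
  base_k · exp(−(trait_k − optimum_j)²/(2σ²)). Default σ = 0.3 trait SD
  (strong filtering) and three equal optimum groups at mean and ±1.5 SD,
  mirroring a three-level warming design. Two-group designs were found
  inadequate during development for a mechanistic reason worth recording:
  same-optimum samples are compositionally near-identical, and shared taxa
  contribute zero to βMNTD under *every* label shuffle (a shared taxon's
  nearest neighbour in the other community is itself), so convergent pairs
  carry almost no z-score signal. Detectable selection majorities come from
  between-optimum pairs, hence three groups.
- **drift** — `generations` rounds of multinomial resampling per sample at
  the library size, from a common metacommunity. Default g = 5 at library
  2000: the value at which the RC_bray distribution of drift pairs centres
  near zero, i.e. turnover sits inside the null-assembly band, which is the
  framework's definition of drift-dominated turnover. Larger g produces
  genuine divergence that the classifier (correctly) calls dispersal
  limitation.
- **dispersal limitation** — isolated patches seeded from disjoint subsets
  of the metacommunity, then drift. Default n_patches = n_samples // 3:
  RC_bray can only resolve excess turnover when null pairs of the same
  richness would almost surely overlap, which requires patch richness² to
  exceed the pool size.
- **homogenizing dispersal** — each generation every sample pool is mixed
  toward the global mean pool with migration m = 0.8.

`build_mesocosm_fixture` assembles the full design: 18 tanks × 3 treatments
(C ambient; T = C + 4 °C; H oscillating ±4 °C around T with zero annual
mean, so T and H share the annual mean) × 4 seasons × 2 habitats
= 144 samples; temperature follows a seasonal sinusoid (mean 19.5 °C,
amplitude 10 °C) and the other covariates (TN, TP, NH₄⁺-N, NO₃⁻-N, pH, DO,
conductivity, Chl-a for water; TN, TP, NH₄⁺-N, NO₃⁻-N, NO₂⁻-N, IP for
sediment) are monotone functions of season and warming plus noise, with
habitat-specific missingness. By default the water community assembles
under temperature-driven selection (optima = z-scored temperature mapped to
trait space) and the sediment community under drift; ground-truth pair
labels are emitted for recovery tests.

**What the generator does not emulate:** sequencing error, chimeras and
compositional artefacts of amplicon data; taxon-specific interaction
structure (network edges in fixtures come from shared environmental
responses, not direct interactions); realistic nutrient dynamics beyond
monotone effects; phylogenetic niche convergence (traits are strictly
Brownian). Passing recovery tests therefore demonstrates the inference
machinery is correct under the framework's own assumptions — not that those
assumptions hold in any particular real system.

## Null-model calibration

Type-I behaviour of the pairwise statistics is checked on iid multinomial
samples from one pool. For βNTI this is done both at the default fixture
scale (200 OTUs, library 2000) and on a deep pool; for RC_bray the
calibration pool is deliberately occupancy-saturated (100 OTUs, lognormal
sdlog 1.0, library 10⁴). The reason is structural, not cosmetic: when
occupancy is unsaturated, the null's membership randomisation breaks the
shared-membership structure that iid sampling always produces, so null
Bray–Curtis stochastically dominates the observed values and RC_bray sits
near −1 for genuinely neutral pairs. Near saturation, membership is forced
and the null's abundance-fill step is exchangeable with the generative
process, making the score informative. Users should read RC_bray values on
real data with this in mind: "more similar than null" is partly a statement
about shared membership of abundant taxa.

## Numerical choices

- Degenerate nulls (sd ≤ 1e-12, e.g. star phylogenies or a community that
  spans the whole pool) are flagged; z is reported as 0, never ±∞.
- Null spread uses the sample SD (ddof = 1) of the shuffle draws.
- RC_bray tie detection uses an absolute tolerance of 1e-12 on Bray–Curtis
  values; ties receive half weight.
- Per-pair RC seeds are spawned from the master seed via `SeedSequence`, so
  pairs are independent but the whole matrix is reproducible; pipeline
  stages derive seeds from the master seed and the stage name (CRC32).
- Bray–Curtis on relative abundances by default; a zero-sum sample is
  rejected at table construction.
- Path length and diameter are computed on the largest connected component
  and flagged when the graph is disconnected; modularity scores the greedy
  modularity-maximisation partition (deterministic; a seed parameter is
  accepted for interface stability).
- Spearman pairs involving a constant OTU vector are excluded and counted
  rather than propagated as NaN.

## Open design choices made here

- Taxon-label shuffles ("taxa labels" style) as the null for MNTD/βMNTD:
  the standard choice for this framework.
- Mantel defaults to Spearman correlation, one-sided (greater), 999
  permutations; environmental variables are z-standardised and converted to
  Euclidean distance matrices one at a time.
- PERMANOVA R² is the among-group share of the total sum of squared
  distances from the same decomposition that yields pseudo-F.
- Networks are built per habitat × treatment (pooling seasons) by default;
  βNTI/RC pairs are grouped within habitat × treatment × season. Both are
  configuration, not claims about the right grouping.
- "Keystone" nodes (top 1 % by degree) are a labelled convention, off by
  default.
- Node phylum annotations are optional metadata defaulting to "unknown".

## Problem sizes

Regime-recovery and calibration checks run at 12 samples, 200 OTUs, library
2000 (recovery) and 100 OTUs, library 10⁴ (calibration) with 999 nulls —
sizes at which the fixtures' signals are unambiguous while the full test
suite stays in the minutes range. The acceptance script's mesocosm run uses
144 samples, 150 OTUs, library 1500, 299 nulls for the same reason. All are
package choices; the statistics scale to survey-sized tables (10³–10⁴ OTUs)
at the cost of proportionally longer null loops.

## Known limitations

- βNTI inherits the framework's reliance on phylogenetic niche
  conservatism; convergent evolution of niches weakens or inverts the
  signal.
- RC_bray's occurrence/abundance null is not compositional: strong
  abundance gradients can masquerade as membership effects.
- Homogeneous selection among near-identical communities is structurally
  hard to detect (see the selection-design note above); its proportions are
  conservative.
- The permutation tests are one-factor; no partial Mantel, PERMDISP or
  multi-factor PERMANOVA.
- UniFrac-type phylogenetic beta diversity is intentionally out of scope.
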