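# Methods

`chronocomm` re-implements, as a tested library, the statistical workflow used
to study abundant, intermediate and rare soil bacterial subcommunities along a
restoration chronosequence: how each subcommunity's richness and composition
change with restoration duration, which ecological processes assemble them,
how they organize into co-occurrence networks, and how they relate to
ecosystem multifunctionality. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Rarity classification

ASVs are classified by mean relative abundance across samples with strict
thresholds: abundant above 0.028%, rare below 0.002%, intermediate otherwise
(boundaries inclusive to intermediate). Two definitions of "mean relative
abundance" exist — the mean of per-sample proportions (default) and the
pooled total-count ratio — which coincide on tables rarefied to equal depth;
both are exposed because the choice matters on uneven tables.

The thresholds themselves come from multivariate cutoff level analysis
(MultiCoLA): ASVs are ranked ascending by total count (ties broken by id) and
the rare tail holding up to a given percentage of total sequences is split
off. For each cutoff the "removed" (dominant remainder) and "retained" (rare
tail only) datasets are compared to the full dataset by Spearman correlation
of lower-triangle Bray–Curtis distances and by symmetric Procrustes
correlation (sqrt(1 − m²)) of seeded 2-D NMDS configurations. Cutoffs that
empty a sample are flagged rather than silently dropped. Threshold selection
from the profile is deliberately not automated — the profile is emitted and
the thresholds are configuration values.

## Niche breadth

Levins' breadth B = 1/Σp² is computed over resource states; the default
states are the stage means of relative abundance (11 states), which reduces
replicate noise relative to using all 55 samples; a per-sample mode and a
binned-function mode (5 equal-frequency bins per measured function, averaged
across functions) are available because the state definition for continuous
environments is genuinely open. The tolerance index places samples in the
principal-component space of the z-scored function matrix (axes with positive
eigenvalue retained) and reports the abundance-weighted mean squared distance
of an ASV's occupied samples from its abundance-weighted centroid; it is zero
for single-sample ASVs and invariant to rescaling an ASV's counts and to
rotations of the score space. Group contrasts use Kruskal–Wallis with
tie-corrected Dunn z tests, Bonferroni-adjusted, summarized as a compact
letter display.

## Community statistics

Bray–Curtis dissimilarity is decomposed per pair into balanced variation
(species replacement), min(B,C)/(A+min(B,C)), and abundance gradient
(richness difference), d − balanced. Because equal sample depths force B = C,
rarefied tables are purely balanced by construction; the gradient component
only registers depth differences. The dataset summary reports mean similarity
(1 − mean d), mean balanced share, and mean gradient share, which sum to one.
Two similarity normalizations appear in the literature; both are derivable
from the per-pair table we emit.

NMDS uses non-metric MDS (Kruskal stress-1, 20 seeded restarts, tolerance
1e-6). ANOSIM, SIMPER and the Mantel test are implemented directly (rank
formula, per-ASV contribution identity, and joint row/column permutation
respectively) with the +1-corrected one-sided permutation p-value used
uniformly; scikit-bio's implementations serve as independent cross-checks in
the test suite.

Richness-vs-duration model selection compares linear, quadratic, logarithmic
(ln(t+1), so age 0 is admissible) and a monomolecular "restoration" curve
y = a(1 − e^(−kt)) + c with a, k > 0, fitted by bounded nonlinear least
squares initialized from the data range and k = 1/median(t). Gaussian
AIC = n·ln(RSS/n) + 2p decides; RSS is floored at 1e-12 so exactly
interpolating models of different sizes are ranked by parameter count.

## Assembly null models

βMNTD is the abundance-weighted mean nearest-taxon patristic distance between
two communities, averaged over both directions. The βNTI null relocates each
community independently to a random tip set of the same richness, holding the
abundance vector fixed, and standardizes the observed βMNTD against 999 such
draws. The independent (per-community) relocation — rather than one shared
tip permutation applied to both communities — is what makes shared taxa
informative: two communities that retain the same dominant taxa have
zero-distance nearest neighbours that a random relocation would destroy, so
they register as phylogenetically closer than expected (βNTI ≪ 0). It also
makes the null exactly self-consistent: pairs generated by random relocation
reject at the nominal ≈5% rate at |βNTI| > 2, which the acceptance tests
verify. A degenerate null (sd = 0, e.g. both communities spanning the whole
pool) reports βNTI = 0 with a warning.

The Raup–Crick index draws both null communities of a pair independently:
taxa are selected without replacement with probability proportional to
regional-pool occupancy until the observed richness is reached, each selected
taxon receives one individual, and the remaining observed individuals are
allocated multinomially by pool relative abundance. Seeding every selected
taxon with one individual keeps the realized richness equal to the target —
without it the null is slightly over-dispersed and the two-sided rejection
rate at |RC| > 0.95 drifts above its nominal 5%. RC is the tie-splitting
fraction of null Bray–Curtis values below the observed, rescaled to [−1, 1].

Processes per pair: βNTI > 2 variable selection, βNTI < −2 homogeneous
selection; otherwise RC > 0.95 dispersal limitation, RC < −0.95 homogenizing
dispersal, else undominated. Subcommunity analyses re-normalize the class's
own counts and build the pool from that subcommunity across all samples.
Stage-wise analyses use within-stage pairs (10 per stage at n = 5);
consecutive-stage pairing is available as a sensitivity mode. Per-pair RNG
streams derive from the master seed plus the pair index, so results do not
depend on evaluation order.

## Co-occurrence networks

SparCC is implemented from its published procedure: Dirichlet posterior
resampling of fractions (add-one smoothing), log-ratio variation matrix,
basis variances solved from the sparsity-approximated linear system
((D−2)I + 1)ω² = t, and iterative exclusion (20 rounds, threshold 0.1) of the
strongest pair from the system; ρ is averaged over 100 resamples. Edge
p-values come from a permutation bootstrap — each taxon's counts shuffled
independently across samples, one single-resample SparCC pass per replicate,
two-sided with the +1 correction. Network membership is prefiltered to ASVs
whose relative abundance changes significantly (Pearson, p < 0.05) with
restoration duration. Edges require |ρ| > 0.3 (strict) and p < 0.05 (strict);
isolated nodes are dropped.

Topology uses standard unweighted definitions; closeness is computed within
connected components. Modules come from greedy modularity maximization
(deterministic; Louvain available). Zi is the within-module degree z-score
(0, flagged, for singleton or zero-spread modules); Pi = 1 − Σ(k_is/k_i)².
Role thresholds: hubs at Zi > 2.5, connectors at Pi > 0.62. Note a node
bridging exactly two modules tops out at Pi = 0.5 and is therefore
peripheral under these thresholds; a connector needs at least three foreign
modules or an uneven split. Robustness removes ⌊n/2⌋ random nodes 1000 times
and reports the mean share of survivors that keep at least one edge (the
largest-component share is an alternative mode). Per-stage subnetworks are
emitted with an explicit low-replication warning (five samples per stage
gives weak correlation estimates) and summarized as mean degree vs duration.

## Multifunctionality

Each of the 17 functions (AGB, PC, PN, PP / DNA, Suc, β-Glu, Cel, Ure, ALP,
Cat / SOC, NH4, NO3, STN, SAP, STP) is log10-transformed and z-scored across
samples; EMF is the mean of the 17 z-scores, and PPI, DRI, SNPI average the
plant-productivity, decomposition-rate and soil-nutrient-pool subsets. Zeros
are offset by half the function's smallest positive value (logged per
function). Per-ASV function associations use Pearson correlations of relative
abundance at raw alpha by default — mirroring the analysis convention — with a
Benjamini–Hochberg mode available but off; this uncorrected default inflates
per-ASV significant-function counts and is flagged as a deliberate choice.

## Path models

Path models are piecewise: one OLS per endogenous variable on its parents,
all variables z-scored so coefficients are standardized. Predictor blocks
(e.g. per-class richness) can be consolidated into composites weighted by
standardized regression coefficients against the block's response.
Goodness-of-fit is Shipley's d-separation test: for each non-adjacent pair
the topologically later variable is regressed on the earlier, conditioning
on the union of both variables' parents; Fisher's C = −2Σln p is referred to
χ²(2k). Conditioning on both parent sets (rather than the later variable's
parents alone) is what guarantees the basis claims hold in the true DAG, and
is required for the calibration the tests enforce (p > 0.05 in ≥90% of
simulations from the true model). Covariance-based fit statistics (model χ²,
CFI) are out of scope: they require a full SEM engine and add nothing to the
d-separation decision.

## Synthetic chronosequence generator

The generator emulates the study design — 11 stages at 0, 1, 3, 4, 5, 6, 11,
20, 23, 26 and 53 years with 5 replicates — and the statistical features the
analysis assumes:

- **Abundance skew.** Regional pool abundances are lognormal (σ = 2.5), so a
  few taxa hold most reads; at the default settings the top 2.5% of taxa
  carry well over half the sequences.
- **Phylogeny and traits.** A birth–death tree (λ = 1, μ = 0.5) carries an
  environmental-optimum trait evolved by Brownian motion on
  depth-transformed branch lengths (depth^δ with δ = 0.3). The transform
  concentrates trait evolution near the root, giving deep clades distinct
  optima — without it, traits on coalescent-shaped trees are nearly
  unstructured at depth and selection regimes leave no nearest-taxon signal
  for βNTI to detect.
- **Richness ramps.** Per-sample availability of the top-decile "abundant
  pool" rises as a saturating function of duration; availability of the rare
  remainder rises linearly but shallowly (0.15 → 0.3), keeping rare richness
  noisy across replicates.
- **Assembly regimes.** Homogeneous selection weights sampling by
  exp(−(trait−env)²/2w²) with a fixed optimum; variable selection moves the
  optimum across stages; dispersal limitation applies per-sample lognormal
  drift (σ = 3) with weak pool migration (m = 0.05); drift is plain
  multinomial sampling. The scenario presets sharpen these (w = 0.25,
  drift σ = 4, m = 0.01, pool 150, depth 2000) so each regime's signature is
  unambiguous at a size the per-pair null models can process quickly.
- **Functions.** log f = a·g(t) + b·z(abundant richness) + ε with saturating
  g(t), a ≈ 0.5, b ≈ 0.4, ε ~ N(0, 0.6), exponentiated to stay positive. The
  defaults couple the functions to duration and abundant-taxon richness
  while leaving rare richness decoupled — the qualitative community–function
  pattern the analysis is designed to resolve.

All randomness flows from one master seed through named substreams (tree,
pool, assembly, functions); identical configurations are byte-identical on
disk. Path-model data are linear-Gaussian draws from a stated DAG whose noise
variances are solved from the implied covariance so every variable has unit
population variance and OLS recovers the stated standardized effects in
expectation.

What the generator does **not** emulate: sequencing error, PCR or primer
bias, compositional coupling between classes beyond shared sampling depth,
spatial autocorrelation, taxonomy, or realistic per-function measurement
error structure. Passing tests therefore demonstrate the statistical
machinery is correct and well-calibrated on data satisfying its assumptions,
not that those assumptions hold in any particular field dataset. One known
mismatch is intrinsic: under the "drift" regime all samples are drawn from a
single shared pool, so dominant taxa recur in every sample and the βNTI null
reads that recurrence as homogenizing — pure multinomial sampling of one
pool is, in nearest-taxon terms, genuinely homogeneous.

## Problem sizes and determinism

The test suite and acceptance script use a 400-taxon / 5,000-read default
dataset and 150-taxon / 2,000-read scenario presets, 199–999 null draws, and
10–100 SparCC resamples with 49–99 bootstraps; these sizes were chosen so a
full run completes on a single CPU in minutes while every calibration band
(nominal 5% rejection rates, scenario recovery, effect recovery within ±0.1)
remains resolvable. Null-model calibration uses the nominal 200 pairs × 999
draws. All permutation p-values use the +1 correction; all stochastic steps
are seeded and reproducible.
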