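# Methods notes

This note documents the models and conventions behind `nicheweb`: what
each stage assumes, which defaults matter and why, what the synthetic
data generator does and does not emulate, and where the design was
genuinely open.

## Niche quantification

**Standardization.** Environmental dimensions (mean seasonal soil
temperature in °C; aspect folded to a 0–180° southness axis) are min–max
standardized to [0, 1] separately per spatial scale, so that the local
(microclimatic) and regional (elevational) pools each span the full unit
square and Euclidean distances are comparable within a pool but not
between pools. Trait dimensions (mm) are standardized the same way across
the pooled individuals of one trophic level at one scale; without this,
Euclidean trait distance is dominated by body length. A degenerate
dimension (all values equal) maps to 0.5 with a warning and contributes
zero length to volumes.

**Weighted clouds.** A taxon's Grinnellian cloud replicates each occupied
site's (temperature′, aspect′) row a_pj times; integer weights therefore
encode the abundance weighting exactly, and the position J (column mean)
equals the explicit weighted mean to machine precision. Plant a_pj comes
from percent cover × 100 rounded to the nearest integer (halves away from
zero, since the convention only says "nearest"); the symbols "+" and "r"
stand for 0.5 % and 0.1 % cover. Animal a_pj defaults to interactions
observed per site, the only abundance measure a visitation campaign
yields; see the caveat under *Edge-length null model*.

**Marginality.** The pool centroid c is the unweighted mean of the
*taxon positions* of one trophic level (not the centroid of the pooled
individual/occurrence cloud, which would weight abundant taxa more). This
matches reading the pool as a set of taxa; the alternative is a one-line
change and would shift c toward dominant taxa.

**Volumes (dynamic range boxes).** Per dimension k and quantile level α,
the box length is (Q_{1−α} − Q_α)/(hi_k − lo_k) with linear-interpolation
quantiles and pooled per-level global ranges; per-α sizes aggregate over
dimensions by the arithmetic mean (the "mean" aggregation; "product" is
available but vanishes whenever any single dimension is degenerate), and
vol(j) is the mean over the default grid α ∈ {0, 0.05, …, 0.5} (11
levels). Two analytic anchors pin the scale: a point mass has volume
exactly 0, and a uniform full-range sample converges to the grid mean of
(1 − 2α) = 0.5.

## Bipartite role indices

Degree, species strength, Shannon partner diversity (natural log), and
d′ are computed from the count matrix; betweenness (normalized by
(n−1)(n−2)/2, defined as 0 for n < 3) and the node specialization index
(mean shortest-path length to same-level taxa) from the *unweighted*
one-mode projection — the definitions speak of shortest paths only, so no
edge weights enter. On a disconnected projection, unreachable taxa are
excluded from the NSI mean, flagged per taxon (`fully_reachable`), and
warned about; this is a package convention, not a published rule.

**d′ standardization.** d_i = Σ p′_ij ln(p′_ij/q_j) is standardized to
[0, 1] between its feasible extremes over integer allocations of A_i
interactions, each partner capped at its observed marginal total. The
minimum is found by adding the A_i units one at a time to the partner
with the smallest marginal increment — exact, because the objective is
separable and convex. The maximum is found by dynamic programming over
partners with the allocated-units count as state (O(A_i·m)); the folklore
shortcut of filling the rarest partners to capacity is *not* the true
maximum (a capacity-limited rare partner can force a mixed allocation
that a point mass on a common partner beats), and both routes are checked
against exhaustive enumeration for small problems (A_i ≤ 12, ≤ 4
partners), where enumeration also replaces them outright. One consequence
of integer standardization: multiplying all counts by a constant leaves d
exactly unchanged but refines the feasible extremes, so d′ is only
approximately scale-invariant (drift ≲ 0.05 at small counts).

## Preprocessing conventions

Insect taxa qualify as pollinators when the mean pollen-load category
(0–4, four body regions) over *all individuals of all member species
pooled into the analysis taxon* is strictly > 1; the filter runs at the
family level because that is the unit of analysis. A per-species or
species-averaged variant would weight speciose families differently; with
individuals pooled, every sampled insect counts once. Filtering precedes
pooling in the pipeline, but because the criterion is evaluated on pooled
records the order is immaterial (regression-tested). Families removed by
the filter drop out of interaction and trait tables entirely, and the
interaction bookkeeping (totals before/after) is carried into the run
manifest.

## Interconnectedness

Pearson correlations are pairwise-complete (taxa missing a niche type
contribute where they can), two-sided, α = 0.05, with no multiple-testing
correction — "significant" follows the conventional per-pair reading, and
α is configurable. The network weights significant pairs by r² and keeps
the sign as an edge attribute. Modularity uses greedy weighted
agglomeration (Clauset–Newman–Moore, as implemented in networkx), which
matches the exhaustive optimum on the small test graphs; no published
choice of community-detection algorithm exists to follow. The integration
index is the population variance of the correlation-matrix eigenvalues,
identically (N−1) × mean off-diagonal r²; missing pairs are imputed as 0
only here (eigenvalues need a full matrix), never in the network. The
finite-sample correction subtracts (N−1)/(n_eff−1) — the null expectation
under E[r²] ≈ 1/(n−1) — with n_eff the median pairwise n, floored at 0.
The uncorrected excess is mean-zero on i.i.d.-noise index matrices
(property-tested); the floor makes the *reported* corrected value
nonnegative, so its null mean is slightly positive by construction.

## Edge-length null model

⟨E⟩ = Σ a_ij·E(i,j)/Σ a_ij over the aggregated matrix; the null
randomizes the aggregate table with fixed margins (Patefield), holding
taxon positions fixed, since positions derive from site-level
distributions rather than partner identity. The sampler fills rows by
sequential conditional multivariate hypergeometric draws, which is exactly
the fixed-margin distribution; it is verified against exhaustive
enumeration with exact table probabilities (P(T) ∝ product of per-row
multinomial counts) and against an independent library sampler. The
permutation p uses the add-one estimator with the weak inequality
(⟨E_e⟩ ≤ ⟨E_r⟩ counts against significance): published descriptions of
this test vary between "lower than" and "lower than or equal", and the
weak form is the conservative choice (immaterial at n = 10,000).

**Circularity caveat.** When animal abundance is taken as interactions
per site (the field protocol), animal positions are weighted averages of
their partners' site profiles — the tested matrix and the positions are
then not independent, which biases the null test anticonservative. The
pipeline keeps the field convention as the default
(`animal_positions_from="interactions"`) because visitation data offer
nothing better, but all simulation-based calibration and power scenarios
use the generator's independent animal abundance tables
(`edge_length_inputs`), where the test is well calibrated.

## The synthetic community generator

The generator emulates the *shape* of a two-scale field campaign: sites
with evenly spaced temperatures plus noise and uniform folded aspects
(regional: the full 5–15 °C gradient; local: the central fifth,
emulating microclimate within one meadow, with a quarter of the
interaction effort); Poisson plant cover counts and animal observations
around Gaussian responses exp(−Σ((x−μ)/b)²/2); multinomial allocation of
a fixed interaction total over (site, animal, plant) cells with rate
a_pi·a_pj·exp(−θ·D_env)·exp(−γ·|proboscis − nectar depth|), D_env being
the optimum distance with each dimension scaled by its gradient span;
individual traits Gaussian around taxon means (nectar depth exactly 0
for open/bowl flowers); pollen-load categories that pass the filter for
most families and fail it for a configurable fraction; families holding
1–2 species with interactions split uniformly. All randomness flows from
one seed through named child streams (`STREAMS`), so adding draws in one
stage never perturbs another.

Default study conditions: 24 sites, 12 plants, 8 animal families, 800
interactions (regional) — about a tenth of the published campaign's taxon
and interaction counts, sized so that hundreds of replicate datasets fit
in a test run. Plant baseline cover 30 integer units (0.3 %), animal
baseline 20 observations per site.

**Why the default niche breadths are broad.** The default environmental
breadths (15 °C, 270°) are 1.5 × the gradient spans: the default
community consists of environmental generalists. This is a deliberate
consequence of requiring θ = 0 to mean *environment-independent
interactions*: because interaction rates are abundance products summed
over sites, any strong environmental filtering of abundances induces
co-occurrence assortment — interacting pairs sit closer in niche space
than fixed-margin tables expect even with no direct coupling. With broad
breadths this leakage is negligible and the θ = 0 rejection rate at the
5 % level is nominal (measured 0.044–0.050 over 500 replicate datasets);
with narrow breadths it is real and scientifically meaningful
(environmental filtering alone structures networks), but it is then not
a type-I error. Scenarios that need strong environmental structure —
marginality recovery and the power analysis — pass narrow breadths
(4 °C, 72°) explicitly; with θ = 8 on such a community the test rejects
in ~100 % of runs with the realized mean edge length roughly half the
null expectation.

What the generator does **not** emulate: phenology and within-season
turnover, observer and weather-dependent detectability, spatially
explicit foraging, trait plasticity along the gradient, and
phylogenetic structure among taxa. Passing tests therefore demonstrate
correctness of the estimators and the null machinery under a clean
generative model, not robustness to these field realities.

## Problem sizes and runtimes

The test suite runs the null-model calibration at 500 datasets × 500
null tables and the power analysis at 100 runs × 500 tables (together
under a minute on one CPU); the acceptance script uses 300 × 400 and
60 × 400 plus a full two-scale study at 24 plants/14 families/2,000
interactions with 2,000-table edge tests. These sizes were chosen so
binomial confidence bands on the measured rates are a few percentage
points wide while whole-suite runs stay interactive.

## Known limitations

- Pairwise niche overlap (the port(i,j) machinery of dynamic range
  boxes) and kernel-density hypervolumes are out of scope; volumes and
  marginalities only.
- Network-level aggregate indices (H2′, nestedness, connectance) are not
  computed.
- The NSI convention on disconnected projections and the individuals-
  pooled pollen filter are package choices where published descriptions
  are silent; both are flagged in output or documented above.
- Cross-scale correlations assume taxon identity is stable across
  scales (same labels in both pools).
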