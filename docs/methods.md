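# Methods

`mothdrift` reimplements, as a tested pipeline, a long-term analysis of
macro-moth community change in an isolated forest reserve: historic museum
vouchers and recent standardized light-trap surveys are reduced to binary
species × time-layer incidence, and the community's body-size structure,
ecological specialization and composition are tracked across roughly eighty
years. This note documents the models, the choices made where the design was
open, and what the synthetic test-beds do and do not establish.

## Incidence, time layers and species status

Only incidence (presence/absence) is used: museum collections carry no
usable abundances, and pooling everything a year produced into one species
list is the most robust common denominator across trap types and collector
habits. Records are pooled into *time layers*: four multi-year museum
partitions ("1940s" = 1933–1949, "1960s" = 1950–1976, "1970s" = 1977–1984,
"1980s" = 1985–1996) and one layer per standardized survey year from 1997
onward. The layer scheme is data (`TimeLayerScheme`), not code, so
alternative poolings are a configuration change. Duplicate vouchers collapse
at incidence construction.

Species are partitioned around a cut-year (default 1997, the start of the
standardized surveys): **lost** = recorded only in layers entirely before
the cut-year, **previously unrecorded** = only from the cut-year on,
**persistent** = both. Records in the cut-year itself count as post-cut. A
layer straddling the cut-year is rejected as a configuration error, since
the partition would be ambiguous. Species flagged as early/late flyers,
long-distance migrants or strictly diurnal are removed wholesale
(flag-driven, since the original cleaning was expert judgement, not an
algorithm).

The published layer counts are ambiguous between a 15-layer series (trend
models) and 12 layers (4 museum partitions + 8 survey years, ordination).
`scheme_for_layers(n)` exposes both; the simulators default to 12.

## Specialization register

Three niche dimensions are each scored 1 (most specialized) to 4 (least):

| dimension | 1 | 2 | 3 | 4 |
|---|---|---|---|---|
| larval food | monophagous (one genus) | oligophagous (one family) | polyphagous (>1 family) | highly polyphagous (>5 families) |
| northern limit | 43–46°N | 47–50°N | 51–54°N | 55–71°N |
| habitat breadth | 1–2 types | 3–4 types | ≥5 or common/nonspecial types | numerous/anthropogenic |

The total is the sum, 3–12. Interpretations fixed here: fractional
latitudes are rounded to the nearest whole degree (the register is defined
on integer bands; round-half-to-even at the .5 boundary); a host-family
count of exactly 1 maps to score 2, 2–5 to score 3, >5 to score 4; the
"common/nonspecial habitat" qualifier promotes to score 3 and the
anthropogenic qualifier overrides any count to 4. Latitudes outside
43–71°N are errors, not clamped — the register does not define them.

## Functional dispersion

The 12-trait functional matrix mixes types: wingspan (quantitative, the
body-size proxy), proboscis (binary), larval food source (a multi-label
binary block: detritivore, lichen feeder, and 15 host plant families),
salt-tolerant hosts, ruderal hosts (binary), host growth form, habitat
guild, adult phenology, hibernating stage (categorical), food
specialization, voltinism, range extent (ordinal). The food-source block is
down-weighted so it counts as one of the 12 slots in Gower aggregation. The
15-family label set is configurable; the bundled default is a documented
list of host families common among European macro-moths.

Gower dissimilarity: quantitative traits contribute |xᵢ−xⱼ|/range, ordinal
traits likewise after rank conversion (classic Gower, not Podani), binary
and categorical traits contribute simple mismatch; missing values are
deleted pairwise (per-pair denominators count only traits observed in both
species) and never imputed. Zero-range columns are dropped with a warning.

Functional dispersion of a community with weights *aⱼ* (1 for present
species under incidence) is

    c = Σ aⱼ xⱼ / Σ aⱼ,   zⱼ = ‖xⱼ − c‖,   FDis = Σ aⱼ zⱼ / Σ aⱼ,

with xⱼ the species coordinates in a principal-coordinates embedding of the
Gower matrix, computed once for the full pool; each layer's FDis then uses
its present species. Gower matrices over mixed traits are typically
non-Euclidean, so the embedding checks the most negative eigenvalue of the
double-centred −D²/2 and, beyond tolerance (relative 1e-9 of the leading
eigenvalue, scaled by n), applies a correction before re-embedding:
element-wise square root (default, matching the common default of
distance-based FD software), Cailliez or Lingoes additive constants by
configuration. Axes with eigenvalue below 1e-9 × the largest are dropped.
The correction actually applied is recorded in the run manifest, since the
choice is an assumption, not something the reproduced analysis states.

A definitional oracle (`fdis_brute_oracle`) computes the same quantity
without any eigendecomposition, via Gower's centroid identity
zⱼ² = Σₖ wₖ dⱼₖ² − ½ ΣₖΣₗ wₖwₗ dₖₗ² on the corrected distances; production
and oracle agree to 1e-8 on random mixed-trait fixtures (they differ only
through floating-point rank truncation).

## Community metrics and models

Per layer: species richness, arithmetic mean wingspan and its log, mean
total specialization, proportion of open-habitat species with an empirical
logit (ε = 0.5/n), and FDis. "Log mean wingspan" is log(mean of
wingspans) — the phrase orders the operations — while the status model uses
per-species log wingspan; both readings are exposed via configuration.
Pooled layers enter trend models at their midpoint year ("1940s" → 1941).

**Trend GAMs.** Each community metric is smoothed on layer midpoint year
with a cubic B-spline basis (default dimension 4 — a dozen points cannot
support more; reduced automatically for shorter series). The penalty weight
is chosen by a deterministic GCV grid search (n·RSS/(n−EDF)², 23 log-spaced
weights from 1e-3 to 1e8). Reported: smooth EDF, adjusted R², an
approximate F test of the smooth against the intercept-only model (signed
square root of F as the test statistic, carrying the trend's direction),
and a standardized trend coefficient — the slope of the fitted smooth
regressed on year, × sd(year)/sd(response), which equals the Pearson
correlation when the smooth is effectively linear. A published single
"regression coefficient" for a smooth is not uniquely defined; this is the
interpretation adopted, and it is what the scenario suites exercise. An
exactly interpolating fit (zero residual) is handled as a perfect-fit edge
case rather than an optimizer error.

**Status models.** Body size: log(wingspan) ~ status with a
taxonomic-family random intercept (REML, statsmodels MixedLM); the primary
contrast is lost vs previously unrecorded (Wald test). Variance explained
is summarized by Nakagawa–Schielzeth R²: marginal = var(fixed)/(var(fixed)
+ var(random) + var(residual)); conditional adds the random-intercept
variance to the numerator. A singular random-effect fit falls back to OLS
with a warning. Specialization scores: Poisson mixed models (variational
Bayes, statsmodels PoissonBayesMixedGLM; the global-RNG-driven optimizer is
seeded for reproducibility) with the same reporting contract; the residual
variance on the link scale uses the lognormal approximation ln(1 + 1/λ̄).
The responses are bounded scores, not counts — the Poisson family follows
the design being reproduced, and every fit carries a dispersion-check
warning.

## Ordination

Between-layer dissimilarity is Sørensen: 1 − 2a/(2a+b+c) for shared (a)
and unique (b, c) species — computed as the Dice dissimilarity on binary
incidence. Layers ordinate by non-metric MDS (SMACOF with monotone
regression, scikit-learn), best of 50 random restarts, deterministic given
a seed; Kruskal stress-1 is recomputed from the final configuration with
isotonic regression (ties pooled), and coordinates are centred.

Community descriptors — log mean wingspan, mean total specialization,
logit proportion of open-habitat species — are fitted envfit-style: least
squares of the centred descriptor on the centred ordination axes, R² the
squared multiple correlation, and a permutation p-value with the add-one
rule, p = (#{R²_perm ≥ R²_obs} + 1)/(n_perm + 1) over 999 permutations of
descriptor values across layers (so p ≥ 0.001).

## Synthetic scenarios

The generators define the test-bed conditions. A pool of 300 species (the
observed richness scale) carries log-normal wingspans (median 33 mm,
σ_log = 0.35, so group means in the low-to-high 30s mm and a right skew),
Dirichlet-multinomial family sizes, habitat guilds at
forest/open/shrub/reed = 0.45/0.30/0.15/0.10, register components drawn so
totals span 3–12 with the mode near 10 (a generalist-dominated community),
and guild-correlated functional traits. The register's raw inputs are
generated score-consistently: scoring the generated species reproduces the
drawn scores exactly, which is itself tested.

Occupancy follows a per-species two-state Markov chain over 12 layers with
baseline extinction = colonization = 0.06 per layer and the chain started
at its stationary occupancy (0.5) — a neutral scenario must be stationary,
otherwise richness drift masquerades as directional change. Scenario
modifiers: *size_filter* adds 2.0 log-odds of extinction per unit centred
log wingspan; *succession* multiplies open-habitat survival (and,
geometrically, colonization) by 0.7 per layer while forest colonization
rises 15% per layer; *generalization* shrinks late colonists' traits
toward the pool centroid by a factor 0.5. Observed records thin latent
presence with detection probability 0.9 (trait-independent by default; the
museum-bias caveat is deliberately not modeled). No published
colonization/extinction rates exist; these are free parameters chosen for
realism and statistical power at n ≈ 300 and are not estimates.

The replicate suites establish: nominal type-I error of the body-size
status test under drift (binomial 99% envelope around 5% at 1000
replicates); the lost > previously-unrecorded mean-wingspan ordering in
≥90% of size-filter replicates; a negative, significant FDis trend in ≥80%
of succession replicates; and direction-symmetric FDis "trends" under
drift. Note the absolute rate of nominally significant FDis trends under
drift is well above 5% in both directions — temporal autocorrelation of
drifting communities mimics trend — which is exactly the
drift-vs-directional-change caveat this analysis design must live with;
the suites therefore test symmetry, not raw rate.

What the synthetic tests do **not** show: robustness to collector bias
(detection is trait-independent), to mis-specified layer pooling, or to
trait measurement error; and the simulated trait correlations are far
simpler than real phylogenetic structure (family is independent of traits
in the pool, so the mixed models' random intercepts absorb less variance
than in real data).

## Numerical conventions

Problem sizes in the bundled suites (300 species, 12 layers, 200–1000
replicates) match the scale of the reproduced study while keeping the whole
suite runnable on one CPU in minutes. All stochastic components take
explicit seeds; pipeline runs write a manifest with seeds, options,
warnings and output checksums, and re-running a config reproduces
deterministic outputs bit-for-bit. Degenerate inputs are contracts, not
crashes: empty layers are dropped with warnings, constant descriptors and
empty habitat lists raise, all-zero weights raise, single-species
communities have FDis 0 by definition.

## Known limitations

- The Poisson family on bounded 3–12 scores is under-dispersed; it is kept
  for fidelity to the reproduced design, flagged in every fit.
- The GAM p-value is an approximate F test conditioning on the GCV-chosen
  penalty; it is anti-conservative in small samples, which the scenario
  suites quantify empirically rather than hide.
- The variational Bayes Poisson GLMM underestimates posterior spread
  relative to full likelihood methods; contrasts are accurate, p-values
  approximate.
- NMDS with 12 points in 2-D can have multiple near-optimal configurations;
  only the best-of-restarts solution is reported, with its stress.
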