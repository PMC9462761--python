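# Methods

This note documents the statistical procedures implemented in
`streamdisturb`, the choices made where the published conventions leave
room, and what the synthetic-data tests do and do not demonstrate.

## Disturbance indices

**LDI.** The local index accumulates, over 11 disturbance categories, the
transect-mean of proximity weights: absent → 0, in channel or margin (B) →
1.5, within 10 m (C) → 1.0, beyond 10 m (P) → 0.667. The weights follow
the W1_hall convention; field protocols print the proximity codes but not
the numeric weights, so the weights are exposed in `ProximityWeights` and
fully overridable. Missing tally cells are treated as absent with a
warning, since the protocol records presence.

**CDI.** `4·%urban + 2·%(agriculture+pasture+silviculture)`, range 0–400.
Forest cover enters the pipeline only through the correlation screen, not
the index.

**IDI.** The default ("printed") normalisation is
`sqrt((LDI/5)² + (CDI/300)²)`. Because CDI can reach 400, the raw value
can exceed 1 (a catchment at 100% urban with no local disturbance scores
4/3); both the raw and the [0, 1]-clamped value are always reported. An
alternative normalisation, `sqrt((LDI/5)² + (CDI/400)²)/√2`, which is
bounded in [0, 1] by construction, is available as
`variant="cdi400_rescaled"`. The default stays with the printed form; the
bundled 25-stream table carries its IDI values as data, so the choice of
variant does not affect analyses that consume that table.

**Classification.** The published wording ("< 0.09 low, 0.10–0.19 medium,
> 0.2 high") leaves the intervals [0.09, 0.10) and [0.19, 0.20] unassigned
and does not state boundary closure. We close the gaps as
LOW < 0.10 ≤ MEDIUM < 0.20 ≤ HIGH, so every non-negative value classifies;
thresholds are arguments, not constants. Under this rule the bundled
25-stream table partitions 11/7/7.

## RHDA

Each sheet sums 22 parameter scores; a site's habitat-diversity total is
the arithmetic mean over observer sheets, which is how fractional totals
(e.g. 85.6) arise. Per-parameter maxima are configuration — the shipped
default scores every parameter 0–5 (first ten parameters rate human
pressure, the remaining twelve environmental character), and a user config
can encode the exact protocol sheet.

## Diversity and rarity metrics

Shannon diversity uses natural logarithms (base overridable); Simpson is
reported as dominance `Σ pᵢ²` (higher = more dominated); equitability is
Pielou's `J = H/ln S`, undefined at richness 1 and returned as missing
rather than 0. The non-native:native abundance ratio is undefined when a
site has no native individuals (missing, with a warning). Restrictedness
is occupancy-based, `1 − Kᵢ/K`; abundance matrices are binarised at
count > 0, so relative-abundance input gives identical values. A species
with zero total count scores 1 with a warning rather than an error.

## Indicator-species analysis

Specificity uses per-group *mean* abundances (`A_g = x̄_g / Σ_k x̄_k`),
i.e. the group-size-corrected convention; fidelity is the occupancy
fraction within the group. The reported statistic is `sqrt(A·B)` by
default, which puts a perfect indicator at exactly 1; the raw product and
the uncorrected (total-based) specificity are available by flag, since
published tables do not always state which convention they print.
Combination search (unions of groups as candidate targets, scored with the
pooled union mean against the remaining groups' means) is implemented but
off by default. The permutation test permutes site-to-group labels with
the matrix fixed and uses the `(b+1)/(n_perm+1)` estimator with ties
counted as exceedances; the p-value is for each species' *best* target, a
max-statistic null. The smallest attainable p is `1/(n_perm+1)`, reached
only when no relabelling reproduces the observed association — with few
sites the exchangeable null can recreate a perfect split by chance, so the
floor is not always attainable.

## Constrained ordination

Bray–Curtis dissimilarity is computed on square-root-transformed counts by
default. dbRDA Gower-centres `−½D²`, eigendecomposes to principal
coordinates, regresses the coordinates on the centred and standardised
explanatory variables, and eigendecomposes the fitted values into
constrained axes. Negative PCoA eigenvalues (possible under Bray–Curtis)
are excluded from the regression step and their magnitude reported as
discarded negative inertia; `sqrt_correction=True` instead embeds
`sqrt(d)`, which is Euclidean for Bray–Curtis and leaves no negative
eigenvalues. Total inertia is conserved (constrained + residual = PCoA
total) to 1e−8 relative, and under Euclidean input the constrained
solution coincides with classical RDA on the raw coordinates.

Permutation inference permutes site rows of the PCoA coordinates freely
(no blocks). The global pseudo-F is `(SS_fit/q)/(SS_res/(n−q−1))`. Axis
tests are sequential: axis k is tested with the preceding constrained axes
partialled out of both response and constraints, so a dominant first axis
does not inflate later axes. Marginal tests drop one term with all others
retained, and additionally report the term's standalone adjusted r²
(`1−(1−R²)(n−1)/(n−2)`).

**Collinearity screen.** Stage 1 examines Spearman pairs with |ρ| ≥ 0.7
and p < 0.05 and drops, per iteration, the flagged variable with the
largest mean absolute correlation to all others (alphabetical tie-break) —
the published workflow states the thresholds but not the drop rule, so the
rule here is a fixed, deterministic convention. Stage 2 iteratively drops
the highest-VIF variable while any VIF exceeds 10. Every exclusion is
logged with its trigger. Pairwise dropping always leaves at least one
survivor.

## Correlation screen and trend tests

The environmental screen reports pairwise Spearman ρ with tie-corrected
p-values and a significance mask; ranks are invariant to the conventional
log transform (zeros offset by 0.01 before logging, offset configurable),
which therefore only matters for consumers of the transformed values.
`trend_test` relates a per-site assemblage metric to log IDI via Spearman
ρ (least-squares slope reported alongside) with a two-sided permutation p.
This is a deliberate, documented stand-in for mixed-model coefficient
estimation, which is out of scope here: it recovers the *direction* of a
planted effect on synthetic data and makes no claim to reproduce
random-effect model coefficients from field designs with basin structure.

## Synthetic generator

`generate_landscape` draws a stratified-uniform latent gradient g over
sites, so every landscape spans pristine → urban. Forest cover falls as
`97 − 95·g^1.6` (%, Gaussian noise sd 4, clipped to [2, 97]), matching a
3–80% forest range; urban cover replaces agriculture in the upper gradient
(`((g−0.55)/0.45)²` of the non-forest remainder), so heavily urban
catchments occur only at the disturbed end. Tally presence probabilities
rise with urban cover for the seven urban-associated categories and with
agricultural cover for crop/pasture/logging, so expected LDI increases
along the gradient; given presence, codes B/C/P are drawn 0.3/0.4/0.3.
The IDI of each synthetic site is computed by the package's own scoring
functions from the generated tallies and land use — never sampled — so
generator and scorer cannot drift apart. Habitat diversity responds as
`RHDA = 95 − 80·IDI + N(0, 7)` truncated to [0, 100], and chlorophyll-α as
`0.02 + 0.015·%urban + N(0, 0.2)` truncated at 0, mirroring the observed
ranges (RHDA ≈ 34–98, Chl-α ≈ 0–2.4 µg/L). Water physico-chemistry
(temperature, conductivity, oxygen, turbidity, ammonia, phosphorus)
co-varies with the same gradient plus noise.

`generate_assemblage` samples counts as negative binomial (shared size
parameter 2, emulating field overdispersion) around
`exp(2.0 + slope·IDI)`, with slope −3 for the sensitive quarter of the
species pool, +3 for the tolerant quarter, 0 otherwise; over the observed
IDI range these slopes produce roughly an order-of-magnitude decline/rise,
the kind of turnover seen between forested and urban reaches. Six species
are planted at single random sites (restrictedness exactly 1 − 1/n), three
as indicators of the HIGH class (present at every HIGH site, 5%
leak probability elsewhere), and the non-native flag is assigned to 15% of
the pool, tolerant species first. All draws derive from
`GeneratorConfig.seed` through separate named streams, so outputs are
byte-identical across runs.

Under the printed IDI normalisation the class balance of a default
landscape is roughly 8 low / 4 medium / 13 high; in a small fraction of
seeds the MEDIUM class can hold a single site, which degrades permutation
power for that class (a warning is emitted) but does not affect the
HIGH-class plants used by the recovery tests.

**What the synthetic tests show.** Passing recovery tests demonstrate that
the estimators detect effects of the planted size under negative-binomial
noise at n = 25 sites, and that the permutation tests hold their nominal
type-I error under exchangeable nulls. They do not demonstrate robustness
to features of real survey data that the generator omits: spatial
autocorrelation along the river network, basin-level random effects,
seasonal replication, detection bias of electrofishing, or species
interactions.

## Numerical conventions

* Eigenvalues below 1e−9 of the leading magnitude are treated as zero;
  negative PCoA inertia is reported, not silently dropped.
* Permutation p-values use `(b+1)/(n_perm+1)` with a 1e−12 slack on
  tie comparison, so ties count as exceedances.
* Explanatory variables are centred and unit-scaled before projection
  (scale does not change the fitted subspace; it improves conditioning and
  makes biplot scores comparable).
* Validators name the offending cell/parameter; pure validators return
  violation lists instead of raising.
* Problem sizes in the test suite (200 null replicates at 199
  permutations for calibration; 100 seeds at 999 permutations for
  recovery) were chosen to give binomial confidence intervals tight enough
  to detect miscalibration of ±0.03 around α = 0.05 while keeping the full
  suite fast.

## Known limitations

* The printed IDI normalisation is internally inconsistent (CDI/300 with a
  0–400 range); we implement it literally, report clamped values, and
  expose the bounded variant. Published per-site IDI values consumed as
  data are unaffected.
* Marginal dbRDA tests permute the raw response rather than residuals of
  the reduced model; with strong covariates this is slightly conservative.
* The trend test is not a mixed model; it ignores grouping structure among
  sites.
* The RHDA default scale (22 × 0–5) is a stand-in configuration; encode
  the actual protocol sheet via `RHDAConfig` for field use.
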