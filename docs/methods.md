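# Methods

This note documents the models behind `traitgaps`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic experiments do and do not show about real trait databases.

## The synthetic study system

The generator (`simulate`) produces complete, internally consistent clades
so that every downstream stage can be exercised against known ground truth.

**Trees.** A forward Yule process (birth–death optional, with extinct
lineages pruned) yields rooted bifurcating ultrametric trees. Root depth is
normalised to 1 so Brownian-motion and liability variances are directly
comparable across replicates and tree sizes. All operations are
deterministic given their seed, down to byte-identical Newick output.
`perturb_branch_lengths` applies lognormal jitter (default sd 0.2) to edge
lengths, emulating the between-tree variation of a posterior tree set so
multi-tree imputation runs can be built from one true tree.

**Taxonomy.** Genus and family labels come from cutting the ultrametric
tree at two depths chosen so that exactly the requested numbers of
monophyletic groups cross the cuts; the shallower (family) cut guarantees
genera nest within families. Exact counts can be unattainable only when two
internal nodes share a depth; this raises an error naming the achievable
count rather than silently returning something else.

**Traits.** Log10 body length evolves by Brownian motion (default sigma 1,
root state 1.5 ≈ 32 mm); log10 body mass is a + b·log10 length + N(0, s)
with defaults a = −4, b = 3, s = 0.05 — cubic scaling with tight residuals,
giving a plausible small-tetrapod clade (~3 g at the root state). Binary
attributes follow a threshold (liability) model: an independent Brownian
liability per attribute, thresholded at a per-attribute value chosen for
realistic prevalences (terrestrial common, aerial rare, roughly half of
species nocturnal, most species assessed). The threshold model, rather than
a Markov transition model, is used because it gives the binary traits
exactly the kind of continuous phylogenetic signal the eigenvector filters
can carry. All-zero microhabitat or activity rows are repaired by switching
on the category whose liability is least below its threshold, because the
real schema guarantees every species at least one category.

**Ranges.** Each species occupies a contiguous block of grid cells whose
width grows monotonically with the rank of a size covariate (average ranks,
so ties get equal widths) and whose position is uniform. This reproduces
the one property the analyses need — range size correlates with how well a
species is known — without any geographic realism.

**Missingness.** Gaps are imposed per attribute *block* (body length, body
mass, activity time = Diu+Noc, microhabitat = the five categories, assessed
status), because real data sources report or omit whole category sets. For
each block the missingness probability is
`logistic(logit(rate) + coef · z(driver) + shared · u)`, where the driver is
nothing (MCAR), a named always-observed column (MAR), or the block's own
value (MNAR: log10 value for continuous blocks, the nocturnality or
verticality score for the categorical ones); `u` is a standard-normal
per-species latent "poorly known species" factor shared across blocks, and
`shared` its weight. Base rates 0 and 1 short-circuit exactly. A MAR driver
that is itself subject to missingness is rejected as an invalid
configuration. The defaults (coefficient magnitude 1, i.e. small, nocturnal
and fossorial/arboreal species undersampled) are illustrative study
conditions, not estimates of any real database's mechanism mixture.

## Pre-processing

Name harmonisation applies, in order: exact match; match through *unique*
synonyms of the record name; match through unique synonyms of the reference
ids (for references carrying outdated names); everything else is flagged
for manual review. A synonym applied to more than one valid name is never
used automatically. Records resolving to an already-matched reference id
are flagged as duplicates so no data entry is used twice. The procedure is
idempotent on its own matched output.

Stratum binarisation marks a microhabitat as typical when relative usage is
at least 30% — the boundary is inclusive, fixed here because the rule's
verbal form does not specify it.

Outlier screening is two-stage. The IQR screen flags log10 values outside
[q25 − 1.5·IQR, q75 + 1.5·IQR]; quartiles use linear interpolation between
order statistics (numpy's default convention, fixed so results are
reproducible), and fewer than four values yields a warning and no flags.
The allometric screen fits log10 mass on log10 length per taxonomic group
with Theil–Sen (robust to the very outliers being hunted), scales residuals
by 1.4826·MAD, and flags |z| > 3.5. This replaces an interactive
scatterplot inspection with a deterministic rule; flagged values are
reported, never auto-deleted. Groups under five complete pairs, without
length variation, or with zero residual MAD are skipped with a warning.

Taxonomic imputation fills a missing binary attribute with 1 when at least
70% of the genus's species are observed to have it. The denominator is all
species in the genus (an observed-only denominator is available behind a
flag). Fixed-group overrides (e.g. "all bats are aerial") apply first.
Continuous attributes are never taxon-imputed, observed cells are never
overwritten, and the rule only asserts presence (1), never absence.

## Phylogenetic filters

The phylogenetic covariance matrix (entry i,j = shared root-to-MRCA path
length; diagonal = tip depth) is eigendecomposed directly — not via a
distance-matrix ordination. Retention follows the broken-stick rule
sequentially: keep leading components while the relative eigenvalue exceeds
b_k = (1/p) Σ_{i=k..p} 1/i, stop at the first failure ("keep all passing"
is available as an option), with a floor of one filter so the phylogeny
always contributes at least one predictor. Eigenvector sign is fixed so
each column's largest-magnitude loading is positive, making filters
comparable across trees and tip orderings. Retention is computed per tree;
when several trees are supplied to the engine each contributes its own
filter set.

## Multiple imputation

The learner is XGBoost (`reg:squarederror` for continuous targets on the
log10 scale, `binary:logistic` for binary ones), treated as a pluggable
engine; the bespoke machinery is everything around it. For each tree in the
filter set, each target attribute, and each of `n_folds` fold-specific
models (folds split the target's usable rows), the model predicts the
missing cells from the retained filters plus all other trait columns, and
predictive mean matching replaces each prediction with the observed value
of one of the `k_donors` nearest observed entries in prediction space
(ties at the k-th distance broken by the seeded random stream), repeated
`m_imputations` times. Binary targets are matched on predicted probability
and the donor's observed 0/1 is drawn. A fully missing cell therefore
accumulates exactly m × folds × trees draws; point summaries are the median
of draws for continuous attributes and the mean (plus a ≥ 0.5 majority
call) for binary ones. Because PMM returns observed values, continuous
summaries always lie inside the observed range — a feature (no wild
extrapolation) and a limitation (true out-of-range values cannot be
recovered).

Missing *predictor* cells are passed through as NaN and routed by the
learner's learned default directions; additionally, predictor columns with
no observed value among the rows being predicted are dropped for that
target. The alternative — mean/mode-filling — was implemented first and
found to bias co-missing blocks: when activity time is missing, Diu is
missing for exactly the rows whose Noc is being predicted, and mode-filling
Diu with the observed pool's majority value pushes Noc predictions toward
that majority. Native sparsity handling avoids injecting the observed
pool's bias through a constant fill.

Hyperparameters: either fixed defaults (eta 0.1, depth 6, subsample 0.9,
min child weight 1, 150 rounds) or a two-stage uniform random search over
eta ∈ [0.01, 0.3], depth ∈ [3, 12], subsample ∈ [0.7, 1], min child weight
∈ [0.5, 1.5] and rounds ∈ [30, 1000]: stage 2 redraws inside the bounding
box of the top 5% of stage-1 draws by cross-validated NRMSE or
misclassification. Published-scale searches use 1,000 draws per stage;
the desk-scale default is 100. Tuning is done once per attribute, not per
fold. Attributes with fewer than max(20, 2·k_donors) usable rows are
skipped with a warning. Taxon-imputed cells count as observed during
training; whether that is appropriate for a given dataset deserves a
sensitivity check.

Scale defaults: the published-scale configuration is k = 10 donors, m = 10
imputations, 10 folds, 100 trees (10,000 draws per cell); the package's
desk-scale default tree set is 5, and the acceptance experiments use 1–3
trees, 3–5 folds and 3–5 imputations on clades of 100–300 species so the
full suite runs in minutes on one CPU.

## Validation

Four metrics between imputed and observed values on held-out data, on the
log10 scale for continuous attributes: Pearson r; the least-squares slope
of imputed on observed (slope > 1 reads as overestimation); NRMSE = RMSE /
population sd of the observed test values, so mean-imputation scores
exactly 1 (range-normalisation is an option); and, for binary attributes,
the proportion of correct majority calls. The harness partitions complete
cases into folds, masks each test fold's target cells, imputes them with
the engine across the whole tree set, and reports per-fold and pooled
metrics; both are emitted since fold-median versus pooled reporting is a
legitimate choice. The report is a pure function of the stored prediction
table.

## Shared missingness

Missing-data indicators for the five blocks form a per-taxon PAM (taxa with
fewer than two species are skipped). Cells filled by taxonomic or
phylogenetic imputation still count as missing by default — the analysis
concerns gaps in the observed record — with a switch to count them as
present. For each attribute pair, C = (R_i − S)(R_j − S). The null holds
row sums fixed and treats species as equiprobable; such draws are
independent, so the sampler redraws each row uniformly without replacement
rather than running a Markov chain, and the burn-in parameter (default
10,000 iterations, burn-in 500) simply discards initial draws for interface
fidelity with sequential null-model software. SES uses the sample sd of the
null; p-values are two-tailed and rank-based with an add-one correction
(the tail convention is a package choice; one-tailed conventions exist).
Pairs are aggregated (SES < 0, p < 0.05) or segregated (SES > 0, p < 0.05);
taxa are summarised by the median SES across all pairs and across pairs
involving a focal attribute (the threat-status analogue, `assessed`).

## Change analysis

Verticality assigns each microhabitat category a vertical level (fossorial
0; terrestrial and aquatic 0.5; arboreal and aerial 1) and scores a species
by the mean level over its categories; nocturnality does the same with
diurnal 0 / nocturnal 1. The mean-of-levels rule reproduces every
conventional anchor (0, 0.25, 0.5, 0.75, 1 and 0, 0.5, 1) and extends to
combinations the anchors do not cover (e.g. aquatic + arboreal = 0.75).
Species whose activity or microhabitat was imputed are scored from the
majority calls; if every category's call is 0, the category with the
largest mean draw is used (an exact tie in activity gives cathemeral, 0.5).
Scoring from fractional means instead is available as a flag.

Clade and assemblage properties are the geometric mean (10^mean(log10)) for
continuous attributes and the arithmetic mean of scores for binary ones.
RelativeChange = 1 − property_comb / property_obs, which is *negative* when
gap filling raises a property; because that sign convention is easy to
misread, reports also carry the negated column
(`relative_change_increase`), and the two are exact negations. A zero
observed-only property (all observed species strictly diurnal, say) leaves
the ratio undefined and is reported as NaN. Assemblage averages are
unweighted means over member species, with continuous attributes
log10-transformed first; completeness is the fraction of member species
with observed values. Kruskal–Wallis (tie-corrected, chi-square p) and
Spearman correlations serve as the association diagnostics.

## What the synthetic experiments show — and what they do not

The acceptance experiments demonstrate, at desk scale: exact score anchors;
a null model that matches exhaustive enumeration and is calibrated (2–10%
type-I at alpha 0.05, mean SES ≈ 0); detection of engineered shared gaps as
negative median SES; recovery of hidden values well above the no-skill
baseline under MCAR (r ≈ 0.96 for log length at 20% missingness on 300
tips, driven largely by the tight simulated allometry); and recovery of the
*direction* of MNAR-induced bias — geometric-mean body size down, mean
nocturnality up — in ≥ 80% of pipeline replicates.

They do not show that real databases achieve these numbers. The generator's
traits are cleanly Brownian, its allometry is tight, its missingness
mechanisms are exactly the ones modelled, and its clades are hundreds (not
tens of thousands) of species with a single latent gap factor. Published
full-data reliability (r ≈ 0.93–0.95, accuracy ≈ 0.88–0.90 for tetrapod
size and activity data) depends on database scale and richly correlated
predictors that the desk-scale fixtures deliberately lack. MNAR recovery in
particular degrades when missingness is so phylogenetically clustered that
whole clades lack training data; the directional-bias experiment operates
in the regime where relatives remain observed.

## Known limitations

- Polytomies are resolved arbitrarily with zero-length branches at read
  time; no branch-length rescaling (e.g. Pagel's lambda) is applied.
- PMM cannot impute outside the observed range of an attribute.
- The C-score null assumes equiprobable species within a taxon; row-sum
  *and* column-sum constrained nulls are out of scope.
- Fuzzy (spelling-distance) name matching is not implemented; unresolved
  names are flagged for manual review.
- No geographic realism in ranges; assemblage analyses use the synthetic
  membership matrix as given.
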