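# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical conventions implemented in `protometa`, including the
choices made where the design was genuinely open.

## Data model and filtering

A `FeatureMatrix` is a features × samples numeric table with an explicit
missing mask (NaN). Missingness is never encoded as zero and no imputation
is performed anywhere: every model operates on observed entries only. Label-
free intensities enter raw and are log-transformed (base 2 by default, so
fold changes read in log₂ units); metabolite panels enter as concentrations
with a parallel per-cell quality-status matrix (`valid`, `below_limit`,
`above_limit`, `missing`).

Two filtering rules govern feature inclusion:

* **Completeness (proteins/peptides)** — keep a feature iff its observed
  fraction strictly exceeds the threshold (default 0.5). The strict
  inequality is deliberate: with 35 samples the smallest admissible count is
  18, not 17.5 rounded down.
* **Validity (metabolites)** — keep a metabolite iff the fraction of
  `valid` statuses is ≥ 2/3 (non-strict, "at least 2/3").

Sample-level QC flags a sample when its missing-value fraction or its median
intensity deviates from the cohort median by more than k·1.4826·MAD
(default k = 3; 1.4826 makes the MAD consistent for normal data). The
comparison is strict, so a zero-dispersion cohort flags nothing. This robust-z
rule is our operationalisation of the qualitative criterion "more missing
values and elevated median intensity than other samples"; the k = 3 default
is the conventional robust-outlier cut, not a fitted constant. At least 4
samples are required — below that a cohort median/MAD is meaningless.

## Blocked linear models and moderated statistics

Each feature is fit by OLS against a shared design: indicator columns for
each condition×method cell plus 0/1 subject dummies as the blocking term.
For complete paired layouts, subject fixed effects yield the same
within-subject contrast estimates as a correlated-errors (consensus
intra-block correlation) fit while staying deterministic and closed-form;
the GLS route is a possible extension, not implemented. Missing values are
handled by per-feature row deletion; features whose observed rows cannot
support the full design are flagged and excluded downstream; features that
fit exactly (d_g = 0) keep their coefficients and receive moderated
statistics purely through the prior when it is informative.

Variance moderation assumes s²_g | σ²_g ~ σ²_g·χ²_{d_g}/d_g with a scaled
inverse-χ² prior σ²_g ~ d₀s₀²/χ²_{d₀}. The hyperparameters are estimated by
method of moments on e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of
Var(e) over the sampling term mean ψ′(d_g/2) equals ψ′(d₀/2), inverted by
monotone root-finding (trigamma is strictly decreasing); s₀² then follows
from the mean equation. Conventions for the degenerate cases:

* empirical dispersion ≤ sampling dispersion → d₀ = ∞ with
  s₀² = exp(mean(e)), the limit of the general formula;
* all s²_g exactly equal → d₀ = ∞ with s₀² equal to that common value
  (point-mass prior — the natural reading of zero observed dispersion);
* d₀ = 0 is accepted as the classical limit: the moderated t reduces exactly
  to the ordinary t-statistic.

The moderated t for contrast c is c′β̂_g / (s̃_g √(c′(X′X)⁻¹c)) with
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g), two-sided p from Student-t with
d₀+d_g df (standard normal when d₀ = ∞). Multiplicity is controlled by
Benjamini–Hochberg step-up within each contrast; missing p-values pass
through without counting toward the number of tests.

Concordance metrics: CV uses the population (1/N) standard deviation over
the mean, in percent. The rank-sum test on fold-change magnitudes reports
the Mann–Whitney W and a two-sided p — exact by enumeration for small
tie-free samples, tie-corrected normal approximation with 0.5 continuity
correction otherwise (the regime of any realistically sized comparison).
Overlap summaries decompose feature sets into disjoint regions and report
the largest region relative to the union. The random-split heterogeneity
test shuffles each method subset into two groups balanced within tissue
type (one sample per odd stratum left out at random and recorded), adjusts
for tissue type, and tests group1 − group2; under homogeneous tissue it
should find ~nothing. Spearman correlations use average ranks for ties with
the t-approximation p-value.

## Physico-chemical properties

GRAVY is the mean Kyte–Doolittle hydropathy over the sequence. Net charge
at a given pH is the Henderson–Hasselbalch census over nine ionizable
groups — one N-terminus, one C-terminus, and the side chains of D, E, C, Y
(acidic) and H, K, R (basic) — with the IPC_protein pKa constants shipped
as a package data file with provenance header. Cysteine is treated as a
free thiol (no disulfide modelling). The charge curve is strictly
decreasing in pH, positive at 0 and negative at 14, so the isoelectric
point is the unique root on [0, 14]; bisection runs to a bracket width of
10⁻⁴ pH by default, and tests verify agreement with a 0.001-step
grid-search oracle to 0.01 pH. Sequences containing non-standard letters
(B, Z, X, U, …) are rejected outright rather than silently skipped — for a
bias diagnostic, silent coercion is worse than failure.

## Pathway enrichment with a permutation null

Metabolites inherit pathway membership from every enzyme they touch in the
bipartite reaction network (direct adjacency as reactant or product — the
narrowest defensible reading of "associated through the network"); gene
members are never removed. Per-patient log₂ fold changes are z-scored
across patients per feature (sample SD, n−1; constant features become
missing), so enrichment compares each patient against the cohort.

The raw set score is the sum of member z-scores (membership weights 1; a
weight column is accepted but defaults to 1). The null redraws the value
vector by B random permutations over all measured features — identically
across patient columns and after canonical (lexicographic) id sorting, so
results are invariant to input row order — and the normalized score is
(raw − null mean)/null SD. B defaults to 1000 and the seed is mandatory.
Sets with fewer than 2 measured members are skipped and recorded; sets
whose null SD is zero up to float-summation tolerance (e.g. a set equal to
the whole universe) are flagged degenerate. The three data configurations
are: proteins only; integrated (concatenated gene+metabolite values against
the mixed ontology); and the element-wise mean of the separate gene and
metabolite normalized scores, where a set measured in only one modality
keeps that modality's score rather than being dropped. Cross-method
agreement is summarised by Pearson correlation per patient and pooled, and
differences between correlation vectors by a paired Student t-test with
df = n−1 (identically zero differences are reported as t = 0, p = 1).

## Imbalance scoring

For each (enzyme, reaction), upstream metabolites are gathered against edge
direction (reactants, then the reactants of the reactions producing them,
…) and downstream along it, by BFS recording each metabolite's minimal
reaction-step distance d up to `max_depth` (default 5). Weights are
p^−(d−1) with distance penalty p = 8, so direct partners count fully.
Side scores are weighted means (not sums) over measured metabolite
t-values — deliberately, so enzymes with many reachable metabolites are not
inflated. Imbalance = downstream − upstream, negated for reverse-annotated
reactions; enzymes participating in several reactions average their
reaction scores; reactions missing a measured metabolite on either side are
skipped, and enzymes with no scored reaction are reported missing. Upstream
and downstream depths are not linked by any ratio constraint. This scoring
is this package's own defined surrogate for footprint-style enzyme
analysis: it honours the stated parameters (penalty 8, minimum branch 1
each side, reverse inversion, per-enzyme averaging) and the qualitative
contract (planted bottlenecks attain the maximal imbalance), without
claiming numeric equivalence to any external implementation.

## Synthetic cohorts: what they emulate, and what they do not

`simulate_cohort` draws log₂ intensities

x = baseline_f + b_{f,subject} + (effect_f + γ_{f,subject}) · 1[TT]
  + offset_{f,method} + ε

* baselines N(25, 2) for proteins (LFQ-like log₂ scale), N(5, 1.5) for
  metabolite log₂ concentrations;
* subject random effects sized so repeated measures of one subject
  correlate at ρ_block (default 0.3): σ_b = σ_ε·√(ρ/(1−ρ));
* planted condition effects: a fraction `fraction_de` of features receives
  ±|N(effect_mean, effect_sd)| log₂ units, identical under both methods —
  the shared biology;
* patient heterogeneity γ: per feature and subject, N(0, 1.0) log₂ on the
  tumour side, shared across methods (inter-patient variability of tumour
  proteomes is of order two-fold), plus a coherent per-hallmark per-patient
  activity term N(0, 0.5) added to all members of a planted set — this is
  what gives pathway scores their patient-level structure;
* independent per-feature method offsets N(0, 0.1) — the small systematic
  differences between preparation routes;
* noise ε ~ N(0, 0.25) log₂ units;
* missingness Bernoulli with logit(base rate) − slope·(x − median), i.e.
  low-abundance measurements drop out more often (slope 0 recovers MCAR);
  metabolite cells below the 5th-percentile concentration are additionally
  labelled `below_limit`.

Defaults mirror a 10-patient paired tumour/normal design measured under two
extraction methods, with metabolites measured once per subject×condition
through the biphasic route. Every generator is a pure function of its
parameters including the seed.

What the generator does **not** emulate: peptide-to-protein inference,
normalization artefacts, batch/drift effects, non-normal heavy-tailed
noise, correlated missingness between features, or feature-specific
variance heterogeneity (beyond what truncation induces). Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under its stated assumptions — not robustness to every failure
mode of real LC-MS data.

Chain networks from `simulate_network_truth` plant a bottleneck by giving
all metabolites upstream of the chosen enzyme negative t-values and all
downstream positive ones, magnitudes jittered ±20 % multiplicatively so
recovery is non-trivial but sign structure is preserved.

## Problem sizes and numerical conventions

Calibration checks run at 2000 features × 10 paired subjects × 20
replicate cohorts (type-I error, FDR, power) and 500 features × 50
partition sets × B = 1000 permutations × 20 replicates (enrichment null);
the concordance analysis uses 1000 proteins, 200 metabolites and B = 500.
These sizes put Monte-Carlo error well below the tolerances being checked
while keeping a full run in the minutes range on one CPU. For the
enrichment-null check the 50 sets partition the universe; with overlapping
random sets the across-set mean of normalized scores retains sampling noise
from the value vector itself and only the partition construction isolates
the permutation-machinery property being tested. Other conventions:
trigamma inversion by `brentq` on [10⁻⁸, 10⁸]; BH implemented over the
non-missing p-values; OLS solved per missingness pattern (features sharing
a pattern are batch-solved); permutation draws via numpy's PCG64
`default_rng`, one generator per operation seeded explicitly.

## Known limitations

* Blocking is by subject fixed effects; for incomplete pairs the estimates
  remain valid OLS but no consensus-correlation information is pooled
  across features.
* The variance prior has no abundance trend and no robust down-weighting of
  hypervariable features.
* The mixed ontology uses direct metabolite–enzyme adjacency only; a
  proximity-based transfer would enlarge metabolite coverage at the cost of
  specificity.
* The imbalance surrogate ranks bottlenecks; its absolute scale is not
  comparable across networks with different connectivity.
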