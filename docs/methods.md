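# Methods

This note documents the statistical model behind each stage, the
parameters that matter, the numerical choices, and what the synthetic
cohorts do and do not establish about real data.

## Clinical stratification

Subjects are subgrouped independently per variable. CBCL t-scores use the
instrument's published bands: t < 60 non-clinical, 60 ≤ t ≤ 63 at risk,
t ≥ 64 clinical (both boundary values 60 and 63 fall in the at-risk
band). Two thresholds are not fixed by the instruments and are exposed in
`StratConfig` as documented assumptions: the CSS severe cutoff (default
CSS ≥ 8, consistent with published severity banding and with a cohort
whose mean CSS sits near 7 splitting roughly 60/40) and the CI/DD cutoff
(default IQ/DQ < 70, the conventional clinical boundary). Missing scores
are never imputed; a subject simply drops out of that one stratification,
and summary percentages always use the scored count as denominator,
rounded half-away-from-zero to integers for reporting.

## Feature-table preprocessing

Filtering keeps an ASV iff it is nonzero in at least
`ceil(0.25 · n_samples)` samples (boundary inclusive) **and** its
relative abundance exceeds 0.01. The abundance threshold is interpreted
as a fraction, tested per sample (`any_sample`) by default — the least
destructive reading — with a mean-across-samples variant available. The
kept set is the intersection of the two rules, so application order is
irrelevant; the removal log names the rule(s) that removed each feature.

Rarefaction draws without replacement (multivariate hypergeometric) to a
common depth, by default the smallest library; with an explicit depth,
shallower samples are dropped. A 1000-read quality floor is applied
before any analysis in the pipeline. Rarefied counts feed α- and
β-diversity only.

Cumulative sum scaling divides each sample by the sum of its counts at or
below the chosen quantile (default the median) of its nonzero counts,
times a common scale (1000). The percentile is fixed rather than chosen
adaptively per dataset (the adaptive selection of the original method is
deliberately out of scope); the fixed-quantile factor is invariant to
multiplying a sample by a positive constant, which is the property the
models downstream rely on. CSS-normalised abundances feed the dysbiosis
index models and biomarker discovery.

Rank aggregation sums features sharing a rank label; features with no
assignment at the rank pool into an explicit `unassigned` taxon so totals
are conserved. Greengenes-style rank prefixes (`g__`) are stripped on
read; suffix-disambiguated names (`Bacteroides_H`) are kept verbatim.

## Diversity

Shannon entropy uses natural log by default (configurable base); the
Gini–Simpson index is `1 − Σ p²`; Chao1 is the bias-corrected estimator
`S_obs + F1(F1−1)/(2(F2+1))` and requires integer counts. Subgroup
testing uses the tie-corrected Kruskal–Wallis statistic with asymptotic
p-values and two-sided Mann–Whitney post-hocs; no multiple-testing
correction is applied to post-hoc pairs by default (the analysis design
reports raw thresholds), with BH adjustment available. Pairs containing
a group of fewer than two samples are flagged, not tested.

Bray–Curtis distances come from `scipy`'s pairwise implementation.
PERMANOVA is implemented in-package so that permutations are driven by an
explicit seed: the pseudo-F partitions squared distances within/between
groups and `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)`; the
statistic is checked against scikit-bio's implementation in the tests.
PCoA double-centres the squared distance matrix and reports the *full*
eigenvalue spectrum — negative eigenvalues (non-Euclidean input) are
visible rather than corrected away; explained-variance fractions are
taken over the positive part.

## Dysbiosis index

The reference profile is the coordinate-wise median of the control
subjects' relative-abundance vectors at a rank. Medians of compositions
do not generally sum to one, so the reference is renormalised onto the
simplex by default (disableable; without it the 0–100 bound is not
guaranteed). At least three control samples are required. Each case
subject's own relative-abundance vector at the rank plays the role of
`f_case` — a per-subject score is required for cohort means and subgroup
comparisons — and a group-level score can be formed by passing a subgroup
median profile instead. The composite across phylum/family/genus is the
unweighted mean, with per-rank values always retained; no monotonicity
across ranks is assumed or asserted. The index is symmetric and bounded
in [0, 100] for simplex inputs (property-tested); it is not claimed to be
a metric.

## Biomarker consensus

Two arms run on the same normalised table and labels.

*Effect-size arm.* A per-feature tie-corrected Kruskal–Wallis screen at
α = 0.05, then a bootstrapped effect size: in each of 30 rounds, 2/3 of
each class is subsampled without replacement and per-feature class means
are compared. The discriminant is fit one feature at a time; in one
dimension the unit-normalised discriminant weight is ±1, so the published
combination of raw mean difference and discriminant-axis projection
reduces to the absolute class-mean difference. The reported score is
`log10(1 + mean |effect|)`, maximised over class pairs, with the enriched
group from full-data means. Effects are measured on the input
(CSS-normalised) abundance scale by default: this keeps null features at
realistic abundances below the conventional "LDA > 2" threshold, which a
per-million rescaling (available via `rescale_total=1e6` for
compatibility with the original tool) would not. Scores therefore grow
monotonically if all abundances are multiplied by a constant — a
documented scale covariance. The subclass (within-class Wilcoxon) stage
of the original algorithm is omitted: this design has no subclasses.

*Linear-model arm.* Per feature, `log(abundance + pseudocount)` is
regressed on subgroup plus age and gender by OLS (statsmodels); the
subgroup term is tested by a nested-model F comparison, which reduces to
the coefficient t-test for two groups. The pseudocount is half the
smallest nonzero abundance in the table, recorded in the result.
Constant features are rejected with a reason; collinear covariates raise
an error naming the pair.

A feature is a **consensus biomarker** iff KW p < 0.05, LDA score > 2 and
adjusted-model p < 0.05. Single-arm hits remain in the report flagged
`single-method`. BH q-values are emitted alongside the raw thresholds but
do not gate the consensus.

For functional (KO/pathway) tables the same consensus runs on log2
counts-per-million; optionally the linear model uses inverse-variance
precision weights from a lowess mean–variance trend (per-feature weights,
a simplification of per-observation precision weighting). The unweighted
log-linear model is the reference arm and the default.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: ~70 cases,
80/20 male/female (exact counts), ages 3–17 from a truncated normal
(mean 6.91, SD 3.17), CSS from a discretised truncated normal on 1–10
(mean 6.98, SD 1.47), CBCL t-scores from normals whose default means
(65/60/64, SD 9) populate all three bands, IQ/DQ normal (62.9, 19.9), and
small missingness rates in the score columns mirroring a realistic
cohort (5/70 CSS, 9/70 CBCL, 1/70 IQ). Subgroup labels are derived from
the sampled scores through the cohort module, so labels and scores are
consistent by construction.

Count tables are hierarchical: a base composition from a log-normal
ranked-abundance curve (σ = 1.6 over 300 ASVs by default — a few dominant
taxa plus a long tail), per-sample Dirichlet draws around it
(concentration 50, giving the strong between-subject compositional
variability typical of gut communities), and multinomial counts at a
negative-binomial depth (mean 20 000, dispersion 5) floored at 1000
reads. Planted effects multiply a taxon's base abundance by
`exp(log_fold)` for subjects in one subgroup before renormalisation.
Because the simplex renormalises, same-direction planting on abundant
taxa induces a genuine global compression of all other taxa in the
affected subgroup; recovery studies therefore plant mass-balanced
signals (some up, some down) so the perturbation stays local. The
`auto:k` placeholder selects the k-th most abundant base taxon, which
guarantees planted signals survive the prevalence/abundance filters.

`perturb_for_mdi` constructs a composition at an exact target
dissimilarity from a base by moving `target` mass from the largest taxon
to the smallest — the quadratic index of a two-coordinate transfer of δ
is exactly δ — and errors when the base cannot donate that much mass.

What the generator does *not* emulate: phylogenetic correlation between
taxa, sequencing error and chimeras, zero-inflation beyond what the
Dirichlet-multinomial induces, covariation between clinical scores and
composition except through explicitly planted effects, and control
cohorts that differ systematically from cases. Passing recovery tests on
these cohorts demonstrates that the machinery detects what it claims to
detect under its own assumptions, not that effects of that size are
detectable in real stool data.

## Pipeline and problem sizes

The pipeline's stage order is: quality floor → filter → (rarefy →
diversity) and (CSS-normalise → dysbiosis index, biomarkers). Biomarker
discovery runs at the genus rank by default, the rank at which such
cohort analyses typically report discriminatory taxa. The confounder
check bins age at 6 years (configurable) and flags a factor when
PERMANOVA on Bray–Curtis is significant at 0.05; age and gender are
always carried as linear-model covariates regardless, with the check
reported for transparency. Each variable's analysis is isolated: a
failure (e.g., all scores missing) marks that variable failed and the
rest proceed. All stochastic stages draw seeds from a single run seed via
`numpy.random.SeedSequence`, so identical configurations give identical
reports.

The statistical studies in the test suite use deliberately modest problem
sizes chosen as the package's own working scale: null calibrations at 40
samples × 100 features (250 and 200 simulations), and the
planted-recovery study at 150 ASVs (~57 genera after filtering and
aggregation) × 50 cases over 50 seeds. At these sizes the whole suite
runs in well under a minute. One property of the consensus design is
worth stating plainly: its two arms test the same group contrast on the
same samples, so their false positives are strongly correlated, and the
expected number of false consensus discoveries grows roughly as 2 % of
the number of null features tested rather than as the product of the
arms' error rates. With ~57 genera the recovery study measures a mean of
about 1.2 false discoveries per cohort alongside 0.96 sensitivity; the
intersection bounds the false-discovery rate by each arm's rate but does
not multiply the rates.

## Known limitations

* Phylogenetic diversity metrics (UniFrac, Faith's PD) are out of scope;
  β-diversity is Bray–Curtis only.
* The CSS-normalisation percentile is fixed, not data-adaptive.
* The effect-size arm's LDA is univariate per feature; cross-feature
  discriminant weights (as in the original multivariate fit) are not
  modelled.
* The voom-style weighting uses per-feature, not per-observation,
  precision weights.
* The dysbiosis-index reference requires a user-supplied control cohort;
  no reference distribution ships with the package.
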