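# Methods

## Statistical model per layer

Intensities are analysed on the log2 scale throughout. Reading raw-scale
tables maps empty cells and non-positive intensities to missing (never to
−∞) before the log transform; metabolite tables can additionally be
total-ion-count normalised (each column divided by its sum over observed
values, then log2), which makes the result invariant to per-sample
injection amount.

Differential abundance is a classical two-sided pooled-variance Student
*t* test per feature, preceded by (a) averaging technical replicates to
one value per processing replicate (mean over non-missing technical
values) and (b) the valid-value filter, which keeps a feature only when
it is quantified in at least `min_valid` (default 2) processing
replicates of at least one condition. Missing values are never imputed in
testing; they simply reduce the per-group n, and a feature with fewer
than two valid values in either group is reported untested (missing *p*,
direction `ns`). No multiple-testing adjustment is applied to the
differential call — that is the analysis design this pipeline encodes;
a Benjamini–Hochberg column is emitted alongside for reference. Welch's
unequal-variance variant is available behind `equal_var=False`; the
default is pooled because the named test is Student's. Degenerate inputs
follow a documented convention: zero pooled variance with equal means
gives t = 0, p = 1; with unequal means t = ±∞, p = 0.

## Multivariate diagnostics

PCA treats samples as observations. Missing values are resolved only
here, by feature-wise mean imputation (PCA and distance computations need
complete data; the testing path never imputes). Default scaling is
autoscaling (centre, divide by feature SD; constant features are dropped
there), matching common metabolomics practice; plain centring is a
switch. Hierarchical clustering is exact complete-linkage agglomeration
on Euclidean distances; items are pre-sorted lexicographically by id so
equal-height merges resolve deterministically. Both sample-wise and
feature-wise clustering are supported. Dendrograms export as Newick with
branch lengths from merge-height differences.

## Overrepresentation

For a query of n ids from a background of N, a term with K members in
the background and k in the query scores the one-sided hypergeometric
tail p = P[X ≥ k]. The Bonferroni multiplier is the number of terms with
a non-empty background intersection — the tests actually performed — not
the catalogue size. The background defaults to all features surviving
the valid-value filter in the relevant layer; `query_fraction` (k/n) is
reported because result tables in this field conventionally state "x % of
the query set".

## Network integration and hub proteins

The integration step is deliberately conservative: an interaction edge
(miRNA→gene from a validated-target snapshot, gene↔metabolite from
reaction membership, taken as symmetric) enters the graph only when both
endpoints are differential in their own layers at the same α. Snapshot
ids that match no supplied layer are logged and skipped. The lipid layer
never contributes nodes: it enters as a boolean lipid-association
annotation on differential proteins present in the lipid-associated-
protein list, mirroring how lipid involvement is typically catalogued at
the protein level rather than as measured-species edges. Isolated
non-protein molecules are dropped; isolated proteins are retained only
when lipid-associated.

A hub protein is a protein node whose cross-layer degree — edges to
non-protein differential nodes plus one if lipid-associated — reaches
`hub_min_degree` (default 1; "central" has no canonical quantification,
and one cross-layer partner already distinguishes wired from unwired
proteins). Direction concordance between a hub and its partners is not
required: biologically, up-regulated miRNAs plausibly accompany
down-regulated target proteins. Hub sets are monotone non-increasing in
`hub_min_degree`, and removing an edge can never add a hub; both are
property-tested.

Cell–EV concordance: per condition, Pearson r between hub-wise mean log2
intensities in the cell matrix vs the EV matrix. Fewer than three shared
hubs is an error (r on two points is meaningless). Plasma detectability
is a pure lookup with units preserved verbatim.

## Prognostic workflow

Patient stratification fits univariate two-component Gaussian mixtures by
EM (equal-variance and free-variance, winner by BIC) against a
one-component model; if one component wins, or a class would be empty,
the split falls back to the median (ties to the low arm) and records the
method. Group comparisons against clinical categories are gated by
Shapiro–Wilk on each level (all levels p > 0.05 → Student t / one-way
ANOVA; otherwise Wilcoxon rank-sum / Kruskal–Wallis; a level with n < 3
forces the nonparametric branch). Levene's homogeneity test is computed
and recorded but does not gate, since only normality drives the decision
here. ROC discrimination is the single-feature Mann–Whitney AUC,
U/(n₁n₂) with midrank ties — with one gene as the only input a
tree-ensemble scorer reduces to thresholding that gene, so the
deterministic rank statistic reports the same quantity reproducibly. The
AUC is reported as computed (higher expression scores the positive
class), together with max(AUC, 1−AUC) as "discrimination"; the decision
threshold is 0.70. Survival uses the median-expression cut (ties to low),
product-limit curves per arm, and the two-sample log-rank χ² (1 df). All
p-values in this workflow are unadjusted.

## Synthetic data generator

The generator emulates the study design: two conditions, three processing
replicates per group (five for metabolites), technical triplicates for
the protein layer only. Per layer, baseline per-feature log2 means are
Normal(20, 2) (log2-normal intensities, LFQ-like); a planted fraction of
features (defaults ~0.4–0.5 per layer, layer sizes 1722 proteins, 457
miRNAs, 33 metabolites, 153 lipids) is shifted by ±`effect_size`
(default 2.0 log2 units) in the metastatic group; replicate noise is
Normal(0, 0.25), technical re-measurements add Normal(0, 0.1); dropout is
missing-at-random with probability 0.1 (a left-censored mode is not the
default — missing-at-random is the simplest model that exercises the
valid-value filter). At these settings the closed-form noncentral-t power
at n = 3 vs 3 is ≈ 1, so planted-feature recall is a sharp diagnostic.

The interaction snapshot wires exactly `n_planted_hubs` differential
proteins to ≥ 1 differential miRNA and/or metabolite each; decoy edges
join only non-differential molecules on both ends, so the both-ends rule
must recover exactly the planted hub set when differential status is
taken from the truth. Through the *estimated* differential calls recovery
is statistical: dropout can leave a planted partner with fewer than two
valid values (untestable), and a decoy edge attaches only if both of its
null endpoints are false positives simultaneously (~0.05² per edge).
Lipid-association flags go to a stated subset of hubs plus
non-differential proteins only. A paired parental-cell proteome shares
the EV layer's baselines and effects with an extra Normal(0, 0.5)
per-protein offset, so hub-mean cell–EV correlations are high but not 1.

The cohort plants prognostic genes (drawn from the hub set) with bimodal
expression — two Normal(·, 1) modes separated by 5 SDs — and exponential
survival whose hazard is `hazard_ratio` (default 3) times higher in the
low-expression mode (low hub abundance is the adverse state), under
independent exponential censoring. One clinical category links to the
first planted gene's mode with P(adverse level | low) = 0.85, which
implies a single-feature AUC ≈ p² + p(1−p) ≈ 0.80 — a marker that
genuinely clears the 0.70 decision threshold. Null genes are unimodal
and outcome-independent. A single global seed expands into fixed-order
substreams (one per layer, snapshot, cohort, cells), so adding a layer
never perturbs the others and fixed seeds give byte-identical output.

What the generator does **not** emulate: intensity-dependent
(left-censored) missingness, batch effects, correlated features,
heavy-tailed intensity noise, annotation incompleteness, or real
interaction-database topology. Passing tests therefore demonstrate the
correctness and calibration of the machinery under the stated model, not
performance on any particular real dataset.

## Numerical and design choices

- Tie-breaks: clustering pre-sorts items lexicographically; median splits
  assign ties to the low arm; hub reports sort by degree then id.
- The GMM caps at two components; when more structure exists, BIC may
  still prefer two, and the recorded `method` field keeps the path
  auditable.
- On-disk formats are TAB-separated UTF-8 with '.' decimals; floats are
  written as shortest-exact decimals so write→read round trips are
  bit-identical; missing cells are empty or "NA".
- Problem sizes in the test-suite and the acceptance script (e.g. 80–600
  features per layer, 100 fixtures for hub recovery, 1000 null
  features/genes for calibration, 100 cohort simulations at n = 200) were
  chosen so each check has sharp statistical resolution at desk scale.

## Known limitations

- Reproducing the printed numbers of any specific published EV study
  requires that study's processed supplementary tables and the original
  interaction-snapshot versions as inputs; with different snapshot
  releases the hub list can differ. The pipeline accepts such tables as
  ordinary TSV inputs but does not ship them.
- The both-ends rule makes the network sensitive to the differential α on
  both layers simultaneously; borderline molecules flip edges.
- The category-association battery tests one gene × one category at a
  time and reports unadjusted p-values by design; callers screening many
  genes should expect the stated type-I error per test.
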