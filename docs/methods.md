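# Methods

`conncog` analyses FA-weighted structural brain connectomes in a three-group
design — healthy volunteers (HV), cognitively preserved (CP) and cognitively
impaired (CI) MS patients — and evaluates how well nodal network properties
classify disease and cognitive status. Because no individual-level imaging
data can ship with the package, every stage is exercised end-to-end on a
synthetic cohort generator that emulates the statistical structure of such a
study. This note documents the models, the defaults and why, the numerical
choices, and what the synthetic results do and do not show.

## Synthetic cohorts (`synthcohort`)

**Connectivity model.** A cohort shares one edge template: each of the
n(n−1)/2 node pairs is present with probability `edge_presence_prob`
(default 0.5) and carries a mean FA drawn Uniform(`base_weight_low`,
`base_weight_high`) (default 0.30–0.60, a plausible white-matter FA range;
no empirical edge-weight distribution is imposed). A subject's weight on a
template edge is

    w = mean_FA × attenuation(group, edge)
        + age_slope × (age − age_ref) + ε,   ε ~ N(0, subject_noise_sd²)

truncated to [0, 1], with the edge independently dropped (set to exactly 0)
with probability `subject_dropout_prob` (default 0.05) so the prevalence
filter has work to do. Attenuation acts only on edges incident to a
designated set of *vulnerable nodes*: a factor (1 − `delta_cp`) for all
patients (default 0.10) and an additional (1 − `delta_ci`) for CI subjects
(default 0.15). This encodes the working hypothesis that damage concentrates
at nodes that are already affected and deepens as cognition declines.
Truncation (clipping) rather than resampling is used at the FA bounds; with
the default weight range the bounds are essentially never active. The linear
age effect (default −0.001 FA/year, centred at 40 y) gives the confound
regression a known ground truth to remove.

**Demographics.** Group sizes default to 45/104/84 and ages to
37.8 ± 11.0 / 41.9 ± 9.1 / 44.6 ± 11.3 years (truncated-normal within
18–65), female proportions 60/74/62% — the composition of the reference
three-group MS study design. Because CI patients are older, the age slope
creates genuine group confounding, which the pipeline must (and does) remove.

**Cognitive profiles.** Each patient receives `n_cog_tests` (default 9, a
typical BRB-N subtest count) z-scores. A subject's global level G is drawn
once from the group's global-cognition distribution (CP: 0.014 ± 0.436,
CI: −1.099 ± 0.571); per-test scores are G plus mean-centred Gaussian
deviations, so the profile mean equals G *exactly* and the across-subject
mean of global z is unbiased for the configured group mean. The shared G
acts as the single common factor tying the tests together; the deviation
scale is sd·sqrt(1−λ²)/λ with loading λ = 0.7 by default. The impairment
rule — impaired iff two or more tests fall strictly below −1.5 — is enforced
by rejection-resampling the deviations only (G is never redrawn, which would
bias the group mean). For global levels where rejection is hopeless (a CP
subject drawn very low, a CI subject drawn near zero — a few percent of
draws) a deterministic rule-consistent profile with the same mean is
constructed by pinning the required number of tests just below the cut-off
and redistributing the balance. If even that construction would need
deviations beyond 10× the deviation scale, the parameters are declared
incompatible and an error is raised.

**Determinism.** Everything is driven by one `numpy` Generator seeded from
`SimulationConfig.seed`; identical configs give bit-identical cohorts.

## Preparation (`connprep`)

Edges are retained when present (weight strictly > 0; the presence epsilon
is configurable) in *strictly more than* 60% of the HV group — the strict
inequality follows the "more than 60%" consensus convention. Age and sex are
then removed from each retained edge by OLS (`weight ~ 1 + age + sex`)
pooled over all subjects; each weight is replaced by its residual plus the
fitted value at the covariate means, which preserves the edge-wise mean and
the FA scale, then clipped to [0, 1]. Pooling (rather than HV-only fitting)
is the standard confound-removal reading when group labels are the object of
study. Values of subjects whose edge happened to drop out are adjusted like
any other observation; edges absent in every subject stay exactly zero.
Exact mean preservation holds wherever the [0, 1] clip is inactive.

## Nodal metrics (`graphmetrics`)

Five node-based measures on the weighted undirected graph:

* **strength** s_i = Σ_j w_ij and **degree** d_i = #{j : w_ij > 0};
* **shortest paths** under the reciprocal-weight convention length = 1/w
  (the dominant choice for FA-weighted connectomes: strong = short;
  −log w is available as an alternative convention);
* **local efficiency**: for the subgraph induced by node i's neighbours
  (original weights), the mean over ordered neighbour pairs of 1/d_jk,
  with 1/∞ = 0; nodes with < 2 neighbours score 0;
* **clustering** in the Barrat weighted form
  C_i = [s_i(d_i−1)]⁻¹ Σ_{j,k} ((w_ij+w_ik)/2) a_ij a_ik a_jk
  (the Onnela form is deliberately not used; Barrat matches the igraph
  default, which the tests cross-check);
* **betweenness** by Brandes' algorithm with exact tied-path multiplicity,
  halved for undirectedness and normalised by (n−1)(n−2)/2.

Defining local efficiency and clustering as 0 (not NaN) for under-connected
nodes keeps the downstream statistics free of missing values. All-pairs
distances inside the neighbour subgraphs use a vectorised Floyd–Warshall;
the public `shortest_path_lengths` uses scipy's Dijkstra. Every metric is
equivalence-tested against brute-force path/triangle enumeration on ≥500
random graphs of ≤8 nodes (1e-9) and cross-checked against networkx and
python-igraph on larger random graphs (1e-8).

## Group statistics (`groupstats`)

Per node and metric, the three groups are compared with a test chosen by two
gates at a fixed 0.05 gate level: Shapiro–Wilk per group (any rejection →
Kruskal–Wallis omnibus with Dunn's rank post-hoc), then Levene (rejection →
Welch's ANOVA with pairwise Welch t post-hoc, since Tukey assumes equal
variances); otherwise one-way ANOVA with Tukey HSD. Only the two contrasts
of interest are reported: CP−HV and CI−CP, with direction the sign of the
mean (parametric) or median (rank) difference. P-values are corrected across
nodes within each metric × contrast family, Benjamini–Hochberg by default
(Bonferroni available); the correction scope is a package choice — the
wider "across all metrics" scope would be more conservative.

Numerical choice: Tukey p-values are evaluated from a cached monotone-cubic
spline of the exact studentized-range survival function (one grid evaluation
per (k, df), |error| < 1e-4, unit-tested against `scipy.stats.tukey_hsd`);
per-call quadrature would dominate the calibration studies' runtime. Nodes
whose values are constant across all subjects (degree often is, once the
mask fixes the topology) are reported as trivially non-significant.

On zero-effect cohorts the raw omnibus rejection rate sits at the nominal
5% and BH-corrected flagging stays well below it — under a global null the
FDR procedure flags almost nothing, which is its design behaviour, so
corrected rates should be read as "at most α", not "equal to α".

## Classification (`classify`)

Features are (metric, node) pairs significant at corrected p < 0.05 in
*both* contrasts, for feature sets LE (local efficiency), NS (node strength)
or their union. Class imbalance is handled by building many balanced
instances (default 100): the minority class is kept whole and the majority
class randomly undersampled without replacement to equal size; for
patients-vs-HV the patient subsample is stratified over CP/CI in cohort
proportion with largest-remainder rounding (45 HV + 25 CP + 20 CI = 90 at
the default sizes; 84 + 84 = 168 for CI-vs-CP). Each instance is scored by
stratified 10-fold cross-validation; within each training fold an RBF SVM's
(C, γ) are grid-searched over growing dyadic sequences (defaults
C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}, step 2²) by inner cross-validation, with
features z-scored using training data only — ties break toward smaller C
then smaller γ. Fold confusion counts are pooled before computing accuracy,
sensitivity (recall of the positive class: MS, respectively CI), specificity
and F1 as percentages; instances are summarised as mean ± sample SD.
Standardization and nested tuning are package choices the protocol needs to
be leakage-free; a canary test verifies that corrupting held-out rows
changes neither the fold's scaler statistics nor its chosen (C, γ).

Since RBF kernels expose no primal weights, the reported feature weights are
absolute coefficients of a companion linear-kernel SVM (C = 1) fitted on
each instance's standardized data, averaged over instances and ranked
(top 15 by default); permutation importance would be a heavier alternative.

## Pipeline and problem sizes

`pipeline.run_pipeline` chains simulate → mask → confound-correct → metrics
→ statistics → classification from one YAML-serialisable config, logs
per-stage timing, and stamps every output file with the config hash and
seeds; identical seeds reproduce byte-identical numeric outputs.

Study-scale runs in the test suite and in `scripts/acceptance.py` use a
reduced 4×4 dyadic grid with inner k = 3 and 12–100 instances; these are the
package's desk-scale reference settings — the full grid at 100 instances
behaves identically up to slower, slightly better-tuned models. The
calibration suite uses 200 replicate cohorts of 20/20/20 subjects × 30
nodes; classifier calibration averages over 8 replicate null cohorts because
the realized CV accuracy of any single cohort fluctuates by several points
purely through which healthy volunteers were drawn.

## What the synthetic results show — and what they do not

Passing tests demonstrate that the implementation is correct (oracle
equivalence), statistically calibrated (nominal error rates on nulls), able
to recover planted effects at study-scale sample sizes, and leakage-free and
deterministic. The generator reproduces the *structure* of the design —
group sizes, demographics and their confounding, consensus-edge missingness,
rule-consistent cognitive labels, attenuation concentrated at vulnerable
nodes — but real FA connectomes have topology, weight distributions,
spatial correlation and effect heterogeneity that no low-parameter simulator
matches. With the reference planted effect the synthetic groups separate
almost perfectly, so classifier outputs here are protocol demonstrations,
not predictions of achievable real-data accuracy. Known limitations: the
missingness mechanism is independent dropout; cognitive tests share a single
common factor; attenuation is uniform across vulnerable-incident edges; and
the confound model is linear in age.
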