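# Methods

This note documents the models, statistics and design choices behind
`gemreporter`, in the order the pipeline runs them.

## Data model

A metabolic model is a set of compartment-tagged metabolites
(`glutamate[c]` vs `glutamate[m]` are distinct species; the bracket suffix
is authoritative and must agree with the compartment field), stoichiometric
reactions with optional boolean gene rules (`and`/`or`, case-insensitive
keywords, parentheses), and the gene set induced by those rules. Nine
one-letter compartment codes are recognized (c, m, l, r, g, p, n, s, b);
rows for the boundary compartment `b` are never balanced. The tabular
dialect is two UTF-8 TSVs (metabolites, reactions) with reactions in arrow
notation (`=>` irreversible, `<=>` reversible; one-sided equations denote
exchanges). SBML Level 3 I/O goes through cobrapy, with the currency flag
and category stored in metabolite notes.

Flux consistency is decided per reaction by LPs that maximize (and, for
reversible reactions, minimize) its flux under steady state S·v = 0 and the
model bounds (defaults ±1000); a reaction is consistent when |v| ≥ ε with
ε = 10⁻⁴, the conventional constraint-based-modeling scale. Reactions
already carrying |v| ≥ ε in an earlier LP solution are accepted without
their own solve; the result is order-independent and monotone under bound
relaxation.

## Expression tiers

Tier quartiles are computed on the *pooled* distribution of all
gene × sample values (type-7 linear interpolation), not per gene. A gene is
ABSENT when its value lies strictly below the pooled Q1 in strictly more
than `absent_sample_frac` (default 0.80) of its samples; otherwise the tier
follows its maximum expression: > Q3 → HIGH, in (Q1, Q3] → MEDIUM, ≤ Q1 →
LOW. The same pooled Q1/Q3 serve both the ABSENT filter and the tier
boundaries. A constant matrix has coinciding quartiles and is rejected
explicitly rather than classified arbitrarily.

Two cohorts are classified independently and combined by tier maximum
(HIGH > MEDIUM > LOW > ABSENT); expression values are never averaged across
cohorts, so no cross-cohort batch harmonization is needed. External
evidence forces genes to HIGH: DEG-table genes with adjusted p below
`p_adj_force` (default 0.001; the commonly used 0.01 cut is a config knob)
and genes on a detected-protein list. Forced genes absent from the
classification are added as HIGH — they may be unexpressed in the primary
cohort but evidenced by another assay — and logged. Forcing is idempotent.

Reaction weights evaluate the gene rule over tier scores with OR → max
(isozymes are redundant) and AND → min (a complex is limited by its weakest
subunit). Default scores are HIGH +5, MEDIUM +1, LOW −2, ABSENT −8; the
magnitudes are chosen so a single HIGH gene cannot outweigh two ABSENT ones
in a summed objective. An empty rule scores 0 (spontaneous/orphan
reactions should neither attract nor repel selection).

## Context-specific extraction

One MILP selects binary reaction indicators y maximizing Σ w·y subject to,
for each metabolic task, a dedicated flux vector v with |v_r| ≤ M·y_r
(M = 1000, matching the default bounds) — so the chosen subset *jointly*
supports all tasks. A task demands a minimum net synthesis of one or more
metabolites while its declared uptake metabolites are left unbalanced; all
other (non-boundary) metabolites are held at steady state. A task whose
required metabolite is untouched by any reaction is infeasible by
definition. The MILP is solved with HiGHS via `scipy.optimize.milp`.

Ties between equal-weight optima are broken deterministically by an
id-indexed perturbation subtracted from the objective (total < 10⁻⁶,
echoed in the result); objectives that differ by less than the perturbation
budget may therefore resolve toward the lower-id set. The reported
objective is the MILP optimum over the unperturbed weights.

After the MILP, kept reactions that cannot carry |v| ≥ ε in the extracted
sub-model are removed in ascending (weight, id) order — least-supported
first — re-verifying every task after each removal; a removal that breaks a
task is reverted and the reaction locked in. Locked reactions are the one
case where the final model can retain a flux-inconsistent reaction, and the
tests assert exactly that dichotomy.

The GEM signature is the sub-model's gene set intersected with DEGs at
adjusted p < 0.01, split by fold-change sign; a significant gene with a
fold change of exactly zero belongs to neither side and is logged.

## Reporter metabolites

A metabolite's neighbor genes are the union of flattened gene rules
(AND/OR structure ignored, standard reporter-metabolite practice) over the
reactions containing it, per compartment. Gene p-values are transformed by
directional mode — `all`: unchanged; `up`: p/2 if log2FC > 0 else 1 − p/2;
`down`: mirrored — and clipped to [10⁻¹⁵, 1 − 10⁻¹⁵] so gene Z-scores stay
finite. A restrict-to-significant variant (only genes with p below a
threshold and the matching sign, p left untouched) is provided as an
alternative directional scheme; the one-sided transform is the default.

Gene scores Z_g = Φ⁻¹(1 − p_g) are aggregated per metabolite as
Z_raw = Σ Z_g/√k. The background null (μ_k, σ_k) is estimated from
`n_background` (default 10,000) random k-gene draws *from the observed
gene-score population* (without replacement within a draw), not from a
theoretical normal — this is what makes the corrected statistic robust to
non-uniform input p-value distributions. σ_k is floored at 10⁻¹² (flagged)
when all gene scores coincide. p_reporter = 1 − Φ(Z_corr); significance
uses raw p < 0.1 (no FDR correction — the statistic is used as a ranking
and seeding device, not an inferential endpoint). Genes scored but absent
from the model are excluded from both metabolite sums and the background
universe, keeping the statistic strictly topology-based.

Under uniform gene p-values the corrected statistic is calibrated: pooled
reporter p-values over 20 seeded synthetic models are uniform by KS test,
with the fraction below 0.05 inside [0.03, 0.07] (verified in the test
suite and the acceptance script). The finite-universe without-replacement
draw slightly shrinks σ_k relative to 1 (factor √((N−k)/(N−1))), which the
empirical background absorbs by construction.

## Reporter subnetwork

The bipartite graph links each reaction to its non-currency participants.
Twenty currency metabolites (H2O, CO2, O2, H+, HCO3−, Na+, CoA, Pi, PPi,
AMP, ADP, ATP, NAD+, NADH, NADP+, NADPH, PAP, PAPS, FAD, FADH2) are
removed by name in every compartment — they connect unrelated pathways and
would dominate any topology measure; per-model `is_currency` flags are
honored additionally. Reactions left without participants are dropped.

Node scores: metabolites get Φ⁻¹(1 − p_reporter) (0 when unscored, i.e.
p = 0.5); reactions get a small negative penalty (default −0.1) so they are
admitted only as bridges between positive metabolites. The aggregate score
is the Ideker-style S(A) = Σ s/√|A| over all selected nodes. Simulated
annealing toggles one uniformly chosen node per iteration (20,000
iterations, T₀ = 1, geometric cooling 0.9995), accepting improvements
always and deteriorations with probability exp(ΔS/T); the best-seen state
is returned. Connectivity is *reported, not enforced*: the selected set is
decomposed into connected components afterwards.

Because S(A) never rewards connectivity, the unconstrained optimum is
typically the set of positive-scoring metabolites with no reaction nodes
between them. For topology work the subnetwork is therefore re-assembled
in its natural bipartite form: the selected nodes plus every parent-graph
reaction adjacent to at least two of them (`augment_with_bridging_
reactions`). This restores the metabolite–reaction structure that
centrality analysis needs without altering the search result itself; the
search trace, score and raw components are reported unchanged.

## Topology

Degree, closeness and betweenness are computed on the undirected,
unweighted bipartite graph (both node types participate in shortest
paths); a metabolite-projected graph is offered as an alternative
substrate. Closeness uses the Wasserman–Faust component correction
(reachable-only, scaled by (reachable−1)/(n−1)) so disconnected graphs are
well-defined; betweenness is reported as raw path counts with endpoints
excluded — ranks are invariant to normalization. Ranks are assigned within
node type with competition ("min") ranking for ties. Hub selection takes
the union of the top-k (default 5) nodes per criterion, using rank ≤ k so
boundary ties all qualify; the hub report joins centrality ranks with the
best (lowest-p) directional reporter record, marking unscored hubs "n.s.".

## Metabolomics validation

The matrix is metabolites × samples with per-sample batch, type
(QC/primary) and group attributes. QC filtering removes metabolites
missing in > 20% of all samples or with relative standard deviation
(SD/mean, sample SD) > 50% over the pooled-QC injections — QC pools are
the repeatability reference, so the RSD is computed on them. The two rules
are independent and commute; the exclusion log records every rule
violated.

Batch correction synchronizes per-batch QC medians to the global QC
median, multiplicatively by default (peak-area ratios are scale-type
data; an additive mode is available). Metabolites with a zero or
all-missing batch QC median are flagged and left uncorrected. The
operation is idempotent and a single batch is returned unchanged.

Differential abundance gates on Shapiro–Wilk at 0.05 per group: both
normal → Student's t (equal variances); otherwise a two-sided Wilcoxon
rank-sum, exact when both n ≤ 25 without ties, normal approximation with
tie correction otherwise. Missing values are dropped pairwise (no
imputation); groups with fewer than 3 observations are not tested.
P-values are BH-adjusted across tested metabolites; calls are up/down at
adjusted p < 0.1 with direction from the sign of the case-minus-reference
median difference.

The category test permutes the call vector across all tested metabolites
(category membership fixed; under exchangeability this equals resampling
category labels) with `n_perm` = 100,000 by default, reporting
p = (1 + #{null ≥ observed})/(1 + n_perm) for over-representation and the
mirrored tail for under-representation. The add-one correction means p = 0
is never reported at finite n_perm. The exchangeable null makes the tail
hypergeometric, which the tests exploit as a closed-form oracle.

## Synthetic scenario

The generator emulates the study design the analysis assumes: two
phenotype groups, two transcriptomics cohorts, three metabolomics batches
with pooled QC. The toy GEM spans cytosol, mitochondria and the
extracellular space: parallel linear pathways (6 by default, 4–7 steps)
with exchange reactions at both ends, currency metabolites with
regeneration cycles, and a glutamate/glutamine core — glutamine synthetase
(GLUL), glutaminase (GLS), the aspartate–glutamate carrier
(SLC25A12/SLC25A13), glutamate dehydrogenase and a cytosolic
transaminase — wired so cytosolic glutamate is the unique
maximum-connectivity metabolite (8 incident reactions by default, at least
twice the median metabolite degree). Every generated model is fully
flux-consistent, which the tests assert.

Expression: per-gene baselines uniform on [4, 12] (log scale) with
Gaussian noise σ = 1; the hub's enzyme genes are shifted by δ = 2σ in the
case group of the primary cohort (20 + 20 samples); a second, unlabeled
40-sample cohort feeds only tier classification; 200 non-metabolic
background genes populate the array. The DEG table comes from per-gene
t-tests with BH adjustment — a generator-internal convenience, since
downstream stages consume only (gene, log2FC, p, p_adj). At δ = 0 the
p-value distribution is calibrated; at the default δ the planted genes are
recovered with ≥ 80% power (both verified).

Metabolomics: 109 metabolites, 35 primary (≈ balanced groups) plus 11 QC
samples randomized into 3 batches (each guaranteed ≥ 1 QC), log-normal
abundances (log₁₀ ≈ N(2–4, 0.15), QC noise 0.05), multiplicative batch
factors (1.0, 1.3, 0.8), 5% missingness completely at random, and a
2-fold case-group shift planted on 14 members of a 20-metabolite category
plus 3 scattered metabolites — giving the enrichment test a recoverable
signal while leaving most categories null.

What the generator does *not* emulate: probe-level microarray noise,
missingness that depends on abundance (detection limits), derivatization
chemistry, correlated metabolite panels, or isozyme-specific expression.
Passing tests therefore demonstrate the correctness and calibration of the
statistics, not performance on real cohort data.

## Problem sizes and numerics

Desk-scale sizes keep the full validation fast: toy GEMs of ~70–120
reactions, MILPs with ≤ 8 optional reactions checked against exhaustive
subset enumeration, 7-node annealing graphs against exhaustive optima,
≤ 30-node graphs against a Floyd–Warshall oracle, 10,000 background draws,
100,000 permutations, and 20–50 replicate runs for calibration and
recovery rates. Reproducing a full human GEM analysis (thousands of
reactions, cohort microarrays) is out of scope; the reference-scale counts
quoted in the literature depend on a specific reconstruction release and
cohort data and are not targets of this package's tests.

All stochastic components take explicit seeds (numpy Generator); identical
seeds give bit-identical outputs, including the pipeline's on-disk stage
files. LP/MILP solving uses HiGHS through scipy; cobrapy+GLPK appears only
in tests as an independent oracle.
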