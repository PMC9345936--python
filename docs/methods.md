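# Methods

## Model and scope

`endoflux` implements a plasma-to-phenotype inference chain for
endothelial-cell (EC) metabolism. The central object is a constraint-based
metabolic model: a stoichiometric matrix `S` (metabolites × reactions) with
flux bounds `lb ≤ v ≤ ub`, whose steady states form the polytope
`P = {v : Sv = 0, lb ≤ v ≤ ub}`. Transport (exchange) reactions carry
metabolites across the cell boundary; uptake is negative flux, secretion
positive. Default bound magnitude is 1000 flux units, which is also the
saturation value at which pathway capacities become uninformative.

The package assumes the user either supplies a genome-scale EC
reconstruction (SBML Level 3 FBC via cobrapy, or the package's JSON
dialect) or uses the shipped toy network. Gene–protein–reaction rules,
thermodynamic constraints and model curation are out of scope.

## Flux analysis and sampling

FBA and FVA are linear programs solved with HiGHS (scipy.optimize.linprog),
feasibility ~1e-9 at the solver and 1e-6 at the contract level. FBA returns
one optimal vertex; alternate optima exist, so only the objective value is
stable across solvers and the flux vector is documented as non-unique.

Uniform sampling uses hit-and-run in a null-space parametrisation of
`Sv = 0`: the chain starts from a strictly interior point (found by an LP
maximising a common slack, with per-reaction caps so that reactions fixed
by stoichiometry or by `lb = ub` do not block interiority), proposes an
isotropic direction inside the null space, and steps uniformly on the
feasible segment. Defaults: burn-in 1000, thinning 10; the algorithm name
and settings are recorded in the output metadata sidecar. Exact sampler
variant, chain length and convergence diagnostics are design choices of
this package; the calibration test (1-D polytope mean within 0.15 of the
interval midpoint at n = 5000) bounds the practical error.

Transport quartiles use the linear-interpolation (type-7) convention — the
dominant default across mainstream numeric stacks.

## Plasma preprocessing

- **Imputation**: the MissForest scheme — columns initialised at their
  medians, visited least-missing-first, each fitted with a 100-tree random
  forest on the remaining columns, iterating until the mean-squared change
  of the imputed entries first rises (max 10 sweeps). A deterministic
  per-column-median fallback is provided and used in the high-throughput
  recovery loops. Preconditions: <10% missing, ≥2 observed values per
  metabolite.
- **Normalisation**: log10 then Pareto scaling, `(log10 x − mean)/√sd`.
  Single application only (it is not idempotent). Applied identically
  before PCA and the volcano test.
- **Fold changes** are ratios of arithmetic group means on the raw
  concentration scale, not the log scale.
- **Volcano**: two-sided Welch t-test on log10 values (robust to the
  unequal group variances of a 35-vs-20 design; the scaling step does not
  change the statistic), Benjamini–Hochberg FDR across the panel, flag =
  |log2 fc| ≥ log2 1.5 and q ≤ 0.05. Both thresholds are configurable.

## Patient constraining

Fold-change granularity defaults to per-patient (`fc = patient value /
control-group mean`), since phenotypes are discovered per individual; a
per-phenotype mode (phenotype-mean fold changes) is available through
`patient_fold_changes(..., by_phenotype=...)` and recorded in the model
provenance. Bounds scale multiplicatively and sign-preservingly on both
quartiles (`[fc·q1, fc·q3]`), so uptake intervals scale deeper into uptake.
Transporters mapped to several measured metabolites take the arithmetic
mean of their fold changes.

Quartile constraints are applied to the measured-metabolite transports
only. Non-measured waste sinks (CO2, NH4 secretion) keep their base
bounds: their marginal quartile box encodes total baseline turnover, and
constraining them would cap every patient's catabolism at baseline levels
regardless of the measured fold changes — inverting, for example, the
expected ordering of amino-acid degradation capacity between high- and
low-catabolism phenotypes.

Infeasible bound boxes are repaired by an elastic LP minimising the L1 sum
of bound violations, with slack allowed on transport reactions first and on
all reactions only if transport slack cannot restore feasibility. Ties
between equal-slack solutions are broken by the solver's vertex choice,
recorded but not contractually stable.

## Activities

An activity is the FBA-optimal flux of a designated target reaction under
an optional knockout set that isolates a pathway (knockout = bounds
[0, 0]). A knockout that leaves the model infeasible reads as "pathway
unusable" and scores 0 rather than raising — the biological meaning of the
saturated-low state. Activities identical across all subjects (within
1e-9) are removed before phenotyping; in genome-scale practice these are
the 0-flux (blocked) and 1000-flux (saturated) pathways. The derived
energy ratio appends overall-ATP / glycolytic-ATP per subject (undefined
and flagged when glycolytic ATP is 0).

Whether such capacities should be single FBA optima or statistics of
sampled flux distributions is an open modelling question; the observed
0/1000 saturation behaviour motivates optima, and that is what this package
computes.

## Phenotyping

Clustering is agglomerative with complete linkage on Euclidean distances.
Activities are z-scored per activity by default (flux magnitudes span
decades; `scale="none"` is available for a raw-flux reading). k = 4 is
configuration, not inference — the package reports average silhouette for
k ∈ 2..8 as a diagnostic without choosing. Cluster labels are canonical:
A, B, C, … by decreasing size, ties broken by first subject index.

PLS-DA regresses the one-hot phenotype matrix on column-centred activities
(NIPALS, via scikit-learn's PLSRegression), 2 components by default. VIP
for activity j aggregates over all fitted components a:

    VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),

with `SS_a = (t_aᵀt_a)(q_aᵀq_a)` the class variance explained by component
a, so that Σ VIP² = p exactly. The top-n ranking uses aggregate VIP with
alphabetical tie-breaks. Every algorithm in this module is deterministic.

## Synthetic study materials

The generator emulates a 35-patient PH cohort (12 IPAH, 12 CTD-aPAH,
11 CTEPH) with 20 healthy controls over a 51-metabolite panel: glucose,
lactate, pyruvate, glycerol, 3-hydroxybutyrate, citrate, succinate, malate,
palmitate, the 19 amino acids whose degradation separates the phenotypes
(alanine … lysine, including ornithine), and 23 inert panel members that
pad the panel to 51.

The toy network (91 reactions, 60 metabolites) exposes the pathways the
activities read out: lumped glycolysis (2 ATP + 2 NADH per glucose, lactate
branch), pyruvate dehydrogenase + TCA (5 mitochondrial NADH per pyruvate),
oxidative phosphorylation at 2.5 ATP/NADH — hence exactly 32 ATP per
glucose overall and 2 glycolytic — β-oxidation, malonyl-CoA synthesis, one
lumped degradation per amino acid (aa → acetyl-CoA + CO2 + NH4 + 2 NADH),
an uncoupled mitochondrial NADH dissipation (so catabolism stays feasible
when oxidative phosphorylation is knocked out), and two deliberately
uninformative constructs exercising the constant filter: an internal
isomerase loop (always 1000) and a dead-end phosphorylation (always 0).
Internal reactions are carbon/nitrogen balanced under the lumped formula
annotations (H/O are not tracked across lumped steps). Nutrient uptakes are
capped at toy-physiological magnitudes so that summed patient ATP capacity
stays below the 1000 saturation bound and the energy activities remain
informative.

Cohort draws are lognormal around baseline × phenotype-effect templates
with mean-one multiplicative noise, `exp(σz − σ²/2)`, σ = 0.20 per
metabolite, z truncated at ±2.5 (emulating the outlier handling of a QC'd
targeted panel). Default effect templates: B glycolytic (glucose 2.0,
lactate 1.7, amino acids 1.1); A β-oxidation-leaning (palmitate 1.6,
3-hydroxybutyrate 1.5, amino acids 0.55); C oxidative with high catabolism
except ornithine/lysine (amino acids 1.7, palmitate 1.8, citrate 0.5,
glucose 0.65); D strongest amino-acid catabolism (2.2 across all 19).
Cluster sizes default to the unbalanced 13/15/3/4 regime. Effect sizes are
free parameters of the generator calibrated so that planted-phenotype
recovery is reliable but not exact (ARI ≥ 0.9 across seeds, with sub-1.0
outcomes at the default noise); they are synthetic settings, never
estimates of any real cohort. Missingness is MCAR at rate 0.01, with ≥2
observed values per metabolite preserved.

What the generator does not emulate: between-metabolite correlation beyond
the planted group structure, batch effects, limit-of-detection (non-MCAR)
missingness, diagnosis–phenotype association (diagnoses are assigned
independently, mirroring the observed independence), and any association
between plasma levels and clinical covariates. Passing the recovery tests
therefore shows the chain is correct and well-conditioned under the planted
design, not that real cohorts will cluster this cleanly.

## Problem sizes and numerical choices

Default analysis sizes: 1000 hit-and-run samples (burn-in 1000, thinning
10) for baseline quartiles; one LP per (patient, activity) — 35 × 26 per
cohort; recovery checks run 20 independent cohort seeds with the median
imputation path. Tolerances: LP feasibility 1e-9 (solver) / 1e-6
(contract); constant-activity equality 1e-9; relaxation slack reporting
cutoff 1e-7. Degenerate inputs: empty polytopes raise before sampling;
all-constant activity matrices raise (nothing to analyse); zero glycolytic
ATP yields an undefined, flagged energy ratio.

## Known limitations

- The shipped catalogue has 26 activities against ~190 in a genome-scale
  setting; rankings are therefore coarser (the top-20 list spans most of
  the catalogue, so the amino-acid share of the top 20 is bounded by the
  five non-degradation informative activities).
- The volcano on the default cohort flags nothing: the four phenotype
  templates average out near 1.0 when patients are pooled against
  controls. Pooled-cohort differences require asymmetric designs.
- Marginal quartile boxes are not guaranteed jointly feasible; the elastic
  relaxation handles this, but relaxation frequency depends strongly on
  how tight the baseline exchange caps are relative to the fold changes.
- FBA flux vectors (not objective values) are solver-dependent; anything
  downstream of a flux vector other than its objective coordinate should
  not be treated as reproducible across LP libraries.
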