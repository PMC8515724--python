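# Methods

This note records the modelling choices behind `teendrop`: the statistical
procedure, the parameters that matter, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Preprocessing protocol

Raw interview records (one row per respondent: age in years, sex, free-text
ethnicity self-declaration, pregnancy count including abortions, maternal
teenage-pregnancy flag, school-enrollment flag, monthly family income in
US$, labor flag) pass through four stages in a fixed order:

1. **Imputation.** Every missing cell is replaced by its column's median of
   observed values. Integer-valued columns (age, pregnancy count) use the
   low median so the fill is an observed value; 0/1 flags are encoded before
   the median and an exact 0.5 tie rounds *down* to 0 with a logged warning
   (a median-of-binary tie has no canonical resolution; down is the
   conservative "absence" reading). Sex is categorical and is the exclusion
   key of the next stage, so it is imputed with the column mode rather than
   a median; ethnicity is imputed on its white/non-white encoding. The
   impute-everything-then-exclude order is a deliberate choice: it keeps the
   imputation sample as large as possible and makes stage 2 total.
2. **Exclusion.** Only female respondents are analyzed (teenage pregnancy
   impacts girls far more directly, and males are a small minority of the
   cohort); records with missing sex are an error at this stage.
3. **Balancing.** The pregnancy classes (pregnancy count ≥ 1 vs 0) are
   equalized by randomly undersampling the majority class without
   replacement. The selection is driven by an explicit seed recorded in the
   run report, so runs are reproducible and seed sensitivity can be measured
   (`compare_reports`). Balancing is idempotent on already-balanced input.
4. **Binarization.** The Table-style encoding with a uniform "value ≥ cut →
   state 1" convention: Age cut 15 years (the midpoint of the 12–18
   adolescence window), income cut US$780/month (≈ 3× the 2019 Brazilian
   minimum wage), pregnancy cut 1. Ethnicity strings map to white/non-white
   through an explicit case-insensitive lookup; an unmapped string is an
   error, never silently non-white.

Boundary values (exactly 15 years, exactly US$780) fall in state 1; the
generator's boundary-audit test pins this convention.

## Bayesian-network core

CPTs are estimated by maximum likelihood with an optional Laplace
pseudocount `c`: each entry is `(count + c) / (rows + 2c)`. The default is
`c = 0` (the standard estimator for complete data); under MLE an unobserved
parent configuration is a loud error rather than a silent uniform row, so
sparsity at small cohort sizes cannot hide. Study-scale runs (hundreds of
rows with four-parent nodes) should pass `pseudocount = 1`.

Conditional queries use sum-product variable elimination with a greedy
min-width elimination order; probabilities stay in linear space (seven
binary nodes cannot underflow), and a zero evidence marginal is therefore a
genuine "impossible evidence" error, distinguished from underflow by
construction. MAP completions use max-product elimination for the optimum
value and a canonical decode: variables are fixed in lexicographic name
order, earlier states win ties (with a warning). The test suite checks both
engines against a brute-force enumeration oracle on hundreds of random
networks.

## Causal machinery

Interventions are graph surgery (sever incoming treatment edges, replace the
treatment CPT by a point mass). The adjustment formula is computed term by
term on the unmutilated network and fails loudly on positivity violations —
dropping a stratum would silently change the estimand. Backdoor
admissibility of an adjustment set is checked by d-separation in the
treatment-edge-pruned graph but only *warns* when violated: the default
report deliberately reproduces three single-covariate adjustments (Age, ES,
EG) even though none of them blocks every backdoor path in the shipped
graph, because that is the analysis design being reproduced; the warning
documents the gap, and the full-parent-set adjustment (which equals the
surgical answer exactly) is available through the same API.

## The study DAG is a reconstruction

The original expert-consensus structure is published only graphically. The
shipped default uses the text-supported edges — MF→TP; Age, EG, ES as shared
parents of TP and SS; TP→SS; ES→LS — and every report labels its DAG source
(`reconstruction-default`, `consensus:<file>`, `edge_list:<file>` or
`explicit`). A faithful reproduction requires transcribing the original
figure into an edge list, or re-running the consensus aggregation on the
expert surveys. The consensus rule itself (simple majority, configurable
threshold; higher-voted direction wins; ties drop both; cycles repaired by
removing the lowest-voted cycle edge) is likewise a policy choice — the
original aggregation rule is not documented. The spurious-correlation (SC)
annotation is a replaceable policy too: a pair is flagged when the DAG
contains no directed path between its members in either orientation, and the
raw phi coefficient is always kept alongside the flag so users can
re-annotate under a different rule.

## Synthetic generator: what it emulates, and what it does not

The generator draws binary profiles by ancestral sampling from a
ground-truth network, de-binarizes them into raw survey answers (state-
conditional samplers: uniform integer ages 12–14 / 15–18, incomes 0–779 /
780–2600, census-style ethnicity strings, pregnancy counts 1 + Poisson(0.2)
for the pregnant class), draws sex independently at 14.3% male, and injects
missingness completely at random (default 1% per cell — small survey
nonresponse; the real mechanism is unknown, MCAR is the neutral choice).
Every emission rule is consistent with the default cuts, verified by
`roundtrip_check`.

Ground-truth CPTs were solved offline with a logistic parameterization:
slopes were fixed a priori with signs matching the observed correlation
pattern (Age and MF raise pregnancy risk, higher income lowers it; age and
pregnancy depress enrollment, income raises it), and the four remaining free
parameters (two intercepts, the MF→TP slope, the TP→SS slope) were solved by
root finding so that, *exactly under inference*: the six non-balanced
marginals are Age .70, EG .52, MF .57, ES .24, SS .66, LS .16 (pre-balance;
whether the original descriptives were pre- or post-balancing is ambiguous,
and pre-balance is the assumption here — post-balance marginals shift by a
few points); the pre-balance pregnancy marginal is 130/294; the balanced
refit satisfies P(TP=1 | MF=1) = 0.58; and the balanced-table TP–SS phi
coefficient is −0.5. The solved values are frozen as plain numbers in
`teendrop.synthetic` and never recomputed at run time. Under this truth the
balanced-fit single-covariate ACEs of TP on SS=0 are ≈ 0.47/0.47/0.48
(adjusting Age/ES/EG) and the exact surgical ACE is ≈ 0.45 — the test suite
and acceptance script recompute these, never assume them.

What passing tests on synthetic data show: that the pipeline's estimators
recover the quantities of a known data-generating process of realistic size
and effect structure. What they do not show: anything about the real
interview population — real answers are not MCAR, real ethnicity and income
distributions are richer than the emission rules, attribute–sex independence
is an idealization, and the true causal graph may differ from the
reconstruction (notably, the reconstruction leaves Age–LS disconnected, so
its reports flag that pair SC even though a real association is plausible;
and the MAP dropout profile under the synthetic truth has EG = non-white,
where the attribute is a near coin flip).

## Numerical conventions and scale choices

- Probability normalization tolerance 1e-9 (CPT rows, query outputs,
  exhaustive joint sums); MAP tie tolerance 1e-12 relative.
- Exact-inference cross-checks run on 200 random networks of ≤ 8 binary
  nodes; large-sample recovery checks use 20,000-record samples and the
  sampling-noise floor that implies: aggregate estimands (ACEs) are
  reproducible to ±0.03, but individual CPT entries behind ~1.5%-mass parent
  configurations carry a binomial standard error of ≈ 0.027 at that n, so
  per-entry agreement tighter than that cannot be expected at this scale.
- Reports are deterministic under fixed seeds (no timestamps); `simulate`
  output is byte-identical for identical seed and config.

## Known limitations

No counterfactual (abduction–action–prediction) queries, no front-door or
instrumental-variable estimation, no structure learning from data, no
continuous or multi-category variables, no expert weighting by profession.
These are out of scope by design; the consensus DAG, thresholds and queries
are all configuration, so the package remains usable when any of them needs
to differ.
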