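# teendrop

Causal Bayesian-network analysis of teenage pregnancy and school dropout.

Adolescent pregnancy is a major public-health concern in Brazil and much of
Latin America, and one of its suspected consequences is dropping out of
school. Because randomized experiments are impossible here, the question has
to be answered from observational interview data — which means separating
genuine cause–effect relations from spurious correlations. `teendrop` is a
self-contained toolkit for doing that with discrete Bayesian networks: it is
aimed at epidemiologists and social-science analysts who have survey records
of adolescents (age, ethnic group, pregnancy history, family income, school
enrollment, labor status, maternal pregnancy history) and expert opinions
about which variable may cause which.

## The model

A Bayesian network over variables $X_1,\dots,X_n$ is a DAG plus one
conditional probability table (CPT) per node, inducing the joint

$$P(x_1,\dots,x_n)=\prod_{k=1}^{n} P\big(x_k \mid \mathrm{pa}(X_k)=\pi_k\big).$$

The seven binary study attributes are **Age** (1 if ≥ 15 years), **EG**
(ethnic group, 0 white / 1 non-white), **TP** (teenage pregnancy, 1 if at
least one pregnancy including abortions), **MF** (maternal impact factor:
the respondent's mother experienced teenage pregnancy), **ES** (economic
status, 0 if family income < US\$780/month), **SS** (school enrollment) and
**LS** (labor status). The structure comes from expert elicitation (majority
vote over asserted edges, with direction-conflict and cycle repair); the
CPTs are fitted from the preprocessed interview table (maximum likelihood,
optional Laplace smoothing).

Causal questions use the do-operator. Intervening on a treatment $X$ severs
its incoming edges ("graph surgery"); equivalently, for an adjustment set
$Z$ that blocks the backdoor paths,

$$P(Y=y \mid do(X=x)) = \sum_z P(Y=y \mid X=x, Z=z)\,P(Z=z),$$

and the average causal effect of a treatment contrast is

$$\mathrm{ACE} = P(Y=y \mid do(X=x_i)) - P(Y=y \mid do(X=x_j)),$$

e.g. $\mathrm{ACE}=P(SS{=}0\mid do(TP{=}1))-P(SS{=}0\mid do(TP{=}0))$ for
the effect of teenage pregnancy on being out of school. All inference is
exact (sum-product variable elimination, checked against brute-force
enumeration); MAP profiles ("the most likely full description of a girl who
is out of school") use max-product elimination with a canonical tie-break.

Because the original interview records cannot be shipped here, the package
includes a first-class synthetic generator: ancestral sampling from a
calibrated ground-truth network whose exact marginals match the study-style
descriptive statistics, emitted as *raw* survey answers (years, dollars,
free-text ethnicity, yes/no flags) with injectable missingness, so the whole
pipeline — median imputation, male exclusion, balancing by random
undersampling, binarization — is exercised end to end. The shipped study
DAG is a text-supported *reconstruction* and is flagged as such in every
report; supply your own edge list or expert surveys for a faithful run.

## Worked example

```bash
teendrop simulate --n 2000 --seed 7 --out raw.csv
teendrop analyze --input-csv raw.csv --seed 7 --out run
```

prints (from `run/summary.txt`):

```
teendrop 0.1.0 analysis report

records loaded           : 2000
after exclusion of males : 1726 (274 males removed)
after balancing on TP    : 1512 (seed 7)

marginals (state 1): Age=0.71  EG=0.53  TP=0.50  MF=0.59  ES=0.22  SS=0.64  LS=0.15

ACE SS=0 | do(TP=1 vs 0), adjust ['Age']: 0.458  (p_do: 0.585 vs 0.128)
ACE SS=0 | do(TP=1 vs 0), adjust ['ES']: 0.462  (p_do: 0.589 vs 0.128)
ACE SS=0 | do(TP=1 vs 0), adjust ['EG']: 0.470  (p_do: 0.596 vs 0.126)
P(TP=1|MF=1) = 0.559
MAP|SS=0: Age=1  EG=1  TP=1  MF=1  ES=0  SS=0  LS=0
```

Reading it: after preprocessing, the TP marginal is exactly 50/50 (forced by
balancing). Intervening on teenage pregnancy raises the probability of being
*out* of school from ≈ 0.13 to ≈ 0.59 whichever single covariate is adjusted
for — an average causal effect of ≈ 0.46. A girl whose mother had a teenage
pregnancy has a ≈ 0.56 probability of experiencing one herself, and the most
probable profile of a girl out of school is: 15 or older, non-white, pregnant
at least once, low family income, not working, with a maternal history of
teenage pregnancy. (`run/report.json` carries the same numbers in full
precision, plus the correlation matrix with spurious-correlation flags and
the fitted network.)

The same analysis is available as a library:

```python
from teendrop import RunConfig, run_pipeline, default_config

report = run_pipeline(RunConfig(generator=default_config(n_records=2000, seed=7),
                                balance_seed=7))
print(report["ace"][0]["ace"])
```

## Layout

- `teendrop.preprocess` — raw-record loading, imputation, exclusion,
  balancing, binarization
- `teendrop.bn` — DAG validation, CPT fitting, exact inference (queries,
  MAP), JSON/edge-list serialization
- `teendrop.causal` — graph surgery, adjustment formula, ACE, backdoor check
- `teendrop.elicitation` — expert-survey consensus DAG, correlation table
  with SC annotation
- `teendrop.synthetic` — calibrated synthetic-data generator
- `teendrop.pipeline` / `teendrop.cli` — orchestration, reports, CLI

See `docs/methods.md` for modelling assumptions, calibration details and
known limitations.
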