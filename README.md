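# motivmeta

Meta-epidemiological tooling for asking whether **baseline patient
motivation** moderates the effects reported by randomized trials of
self-care digital health interventions (DHIs, e.g. mHealth apps for cancer
patients).  Motivation is rarely measured directly in such trials, so it is
rated at the *study* level from three ordinal proxies, and the rating is
then used as a moderator in a random-effects meta-analysis.  The package is
aimed at systematic reviewers and methodologists who want the full chain —
rating rules, rater reliability, effect extraction, pooling, moderator
tests — as reusable, tested code that runs end-to-end on synthetic corpora
with known truth.

## What it computes

**Rating engine.**  Three indicators — *expectation* (does the study team
select or boost motivated participants?), *effort* (active engagement
demanded before allocation) and *bond* (trust toward the person/institution
referring to the study) — each rated low/moderate/high (scores 1–3), are
combined into an overall study-level motivation category under two schemes:

- *weighted decision rule* (`tree`): W = 2·s₁ + 2·s₂ + s₃ ∈ [5, 15], with
  W ≤ 7 → low, 8–12 → moderate, W ≥ 13 → high (expectation and effort carry
  equal weight, bond half weight; a user-supplied 27-row rule table can
  replace the default rule verbatim);
- *equal-weight sum* (`equal_sum`): s₁+s₂+s₃ ∈ [3, 9], with 3–5 → low,
  6–7 → moderate, 8–9 → high.

**Reliability.**  Inter-rater agreement on a subjects × raters grid via the
intraclass correlation from the two-way ANOVA decomposition — default
ICC(2,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n) — with the
consensus-as-extra-rater variant and Spearman correlations among
indicators.  Bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9
excellent.

**Effect sizes.**  Continuous outcomes (QoL, anxiety, depression) as
standardized mean differences, by default Hedges g = J·d with
J = 1 − 3/(4·df − 1) and Var(g) = (n_t+n_c)/(n_t n_c) + g²/(2(n_t+n_c));
attrition as the log risk ratio of dropout proportions with
Var = 1/a − 1/n_t + 1/c − 1/n_c (0.5/1 continuity correction on a single
zero cell).  Missing SDs are recovered from SEs (sd = se·√n) or CIs, else
the baseline SD is carried forward; multiple measurement tools resolve to
the lowest-attrition one and timepoints to the first post-intervention
assessment (longest follow-up when the intervention period is unclear).

**Meta-analysis engine.**  Random-effects pooling under the normal–normal
model with τ² by REML (DL and PM selectable) and **Knapp–Hartung**
inference: se²_KH = [Σw(yᵢ−μ̂)²/(k−1)]/Σw with a t(k−1) reference.
Heterogeneity via Cochran's Q and I² (≥ 50% flagged substantial).
Subgroup analyses pool each motivation level separately (own τ² each);
categorical meta-regression fits dummy-coded levels by weighted least
squares with KH-type covariance scaling and reports the omnibus F test on
(m, k−p) degrees of freedom.

**Synthetic corpora.**  A generator draws latent motivation levels,
indicator triples, normally distributed random effects
(θ = μ_level + N(0, τ²)), individual participant outcomes summarized to
arm-level n/mean/SD, binomial attrition, and noisy rater matrices — so
every extraction and inference rule is exercised against known truth.

## Worked example

```bash
motivmeta simulate --seed 11 --out-dir sim        # 27 studies: 19/5/3 by level
motivmeta report --studies sim/studies.csv --ratings sim/ratings.csv --out-dir out
```

`out/classification.json` tallies the consensus ratings — for this seed the
overall distribution is 19 high / 5 moderate / 3 low.  `out/table_qol.csv`
is the QoL outcome table (estimate = SMD, CI limits, I² in %, heterogeneity
and meta-regression p-values):

```
moderator,level,k,estimate,ci_low,ci_high,i2,het_p,metareg_p
all,all,27,0.32,0.17,0.48,86,0,
overall,high,19,0.47,0.34,0.61,66,0,0
overall,moderate,5,0.26,-0.05,0.58,70,0.009,0
overall,low,3,-0.44,-1.03,0.14,65,0.057,0
...
```

Read: across all 27 studies the intervention improved QoL by 0.32 SD
(95% KH CI 0.17–0.48) with substantial heterogeneity (I² = 86%); the
high-motivation subgroup shows a clear benefit (0.47) while the
low-motivation subgroup does not (−0.44, CI crossing 0), and the omnibus
meta-regression p < 0.001 says the subgroup effects differ — this corpus
was generated with level-dependent true effects, so that is the correct
call.  `out/reliability.csv` reports, e.g., ICC 0.57 (moderate) for the
overall rating of four simulated raters at 80% agreement, rising to 0.62
when the consensus is added as a fifth rater.  `out/reclassification.csv`
cross-tabulates the two schemes (here 7 of 27 studies shift category under
equal weighting) and the `equal_sum_table_*.csv` files repeat every
analysis under the sensitivity scheme.

The same operations are available as a library — see
`motivmeta.rating`, `motivmeta.reliability`, `motivmeta.effects`,
`motivmeta.meta`, `motivmeta.pipeline`, `motivmeta.simulate`.

## Layout

```
src/motivmeta/    rating, reliability, effects, meta, pipeline, simulate, cli
tests/            unit + property + acceptance suites (oracles in tests/_oracles.py)
scripts/          acceptance.py
docs/methods.md   models, assumptions, numerical choices, limitations
```
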