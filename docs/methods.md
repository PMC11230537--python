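# Methods

This note documents the statistical models implemented in `motivmeta`, the
choices made where the design was genuinely open, and what the synthetic
corpora do and do not establish.

## Rating model

Each study receives three ordinal indicators of baseline participant
motivation — expectation, effort, bond — on the scale low (1) < moderate
(2) < high (3).  Two combination schemes produce the overall study-level
category:

- **Weighted decision rule** (primary, `tree`).  The two primary
  indicators carry equal weight and bond carries lower weight, because bond
  is typically judged from more indirect study-level information.  The
  default rule realizes this as the weighted score W = 2s₁ + 2s₂ + s₃
  (range 5–15) cut at ≤ 7 / 8–12 / ≥ 13.  This rule satisfies unanimity
  ((x,x,x) → x), symmetry in the primary pair, monotonicity in every
  indicator, and the constraint that bond can never override agreeing
  primaries — all verified exhaustively over the 27 triples.  Any explicit
  27-row decision tree honouring the same interface can be supplied as a
  rule table and is then used verbatim; the default is *one* rule
  consistent with the stated weighting principles, not the only one, and
  in particular non-unanimous triples could be mapped differently by a
  hand-crafted tree.
- **Equal-weight sum** (sensitivity, `equal_sum`).  s₁+s₂+s₃ ∈ 3–9 cut at
  3–5 / 6–7 / 8–9.  The sensitivity pipeline cross-tabulates the two
  schemes per study and repeats every outcome analysis under the sum.

Missing indicator levels are rejected rather than imputed: the workflow
assumes every study is rated on all three indicators.  Labels are
case-insensitive on input.

## Inter-rater reliability

Ordinal levels are treated as equally spaced scores 1–3 (the same scale
the equal-weight scheme uses), and agreement is summarized by intraclass
correlations from the two-way ANOVA decomposition of the subjects × raters
grid.  The default form is ICC(2,1) — two-way random effects, absolute
agreement, single rater — appropriate when the raters are a sample from a
population of potential raters; the consistency form ICC(3,1), the average
ICC(2,k) and the one-way ICC(1,1) are exposed.  A grid with no variance at
all is returned as ICC 1.0 (logged) rather than as a 0/0 error.  Subjects
with any missing rating are dropped listwise (logged).  Confidence
intervals for the ICC are deliberately out of scope; point estimates and
the interpretation bands (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
≥ 0.9 excellent) are reported.  The consensus rating can be appended as an
extra rater column for the five-rater variant.  Indicator
intercorrelations use Spearman rank correlation by default (the data are
ordinal); Pearson is available by flag.

Note that the "mixed ≥ random" ordering of the single-rater forms is a
consequence of the random form charging rater mean differences to the
denominator; it holds whenever the rater mean square is at least the error
mean square, which random fluctuation can violate on small grids with no
systematic rater effect.  The test suite asserts the refined condition.

## Effect sizes and extraction conventions

Standardized mean differences use the pooled-SD denominator; Hedges'
small-sample correction J = 1 − 3/(4·df − 1) is applied by default (flag
to disable), with variance (n_t+n_c)/(n_t n_c) + g²/(2(n_t+n_c)).
Attrition — dropout from the intervention itself — uses the log risk
ratio with variance 1/a − 1/n_t + 1/c − 1/n_c; a single zero event cell
triggers the 0.5/1 continuity correction (flagged per study), and
double-zero studies are excluded from pooling.  Missing post SDs are
recovered in a fixed order: from the standard error (sd = se·√n), from an
arm-mean confidence interval (sd = √n·(hi−lo)/(2z)), then by carrying the
baseline SD forward; each step leaves a provenance entry.  When several
measurement tools report the same outcome the one with the lowest
attrition is used (ties keep input order, logged); timepoints resolve to
the first post-intervention assessment, or the longest follow-up when the
intervention period is unclear.  Sign conventions are per-outcome
metadata: effects are pooled as reported, so QoL benefits are positive and
anxiety/depression benefits negative, and RR > 1 means more
intervention-arm dropout.

## Random-effects engine

The normal–normal model yᵢ ~ N(θᵢ, vᵢ), θᵢ ~ N(μ, τ²).  τ² is estimated
by REML by default (Fisher scoring on the restricted likelihood,
tolerance 1e-8 on τ², at most 100 iterations, non-negativity enforced,
DerSimonian–Laird fallback on non-convergence — which occurs in well under
1% of simulated datasets); DL and Paule–Mandel are selectable, both
generalized to moderator designs through the fixed-effect projection
matrix so they reduce exactly to the familiar intercept-only formulas.
The pooled mean uses weights 1/(vᵢ+τ̂²); inference is Knapp–Hartung:
se² = [Σw(yᵢ−μ̂)²/(k−1)]/Σw with a t(k−1) reference.  The KH scale is
*not* truncated at the Wald variance by default (a `truncate_kh` flag
exists); the untruncated form is the commonly cited original method, and
the calibration simulations in the test suite show it holds near-nominal
coverage under the correctly specified model.  A single-study "pool"
degenerates to the study's own estimate with a normal Wald interval and
heterogeneity reported as NA.  Heterogeneity uses Cochran's Q with
fixed-effect weights, its χ²(k−1) p-value, and I² = max(0, (Q−(k−1))/Q),
flagged substantial at 50%.

Subgroup analyses pool each moderator level independently with its own τ²
(matching tables whose rows each carry their own I²), so no common-τ²
assumption links the rows.  The categorical meta-regression dummy-codes
the moderator against a reference level (default "high"; the omnibus test
is invariant to this choice), estimates the residual τ² under the
moderator model, fits weighted least squares, scales the coefficient
covariance by s² = Σw e²/(k−p), and reports the omnibus F on (m, k−p)
degrees of freedom — one p-value per moderator, as in the standard
moderator-table layout.  Empty levels are dropped from the design
(logged); two-sided α = 0.05 throughout, with strict inequality.

The moderator used in the main pipeline is the consensus rating.  When no
consensus row is present a stand-in is synthesized as the per-indicator
low median across raters (ties resolve toward the lower level, a
conservative choice); a deliberative consensus is not an algorithm, and
the synthesizer is logged as a stand-in.

## Synthetic data

The generator is the package's ground truth.  Defaults describe a corpus
like the rated mHealth sample: 27 studies split 19/5/3 across overall
motivation levels; true subgroup SMDs 0.4/0.2/0.0 with between-study
variance τ² = 0.04 (moderate heterogeneity on the SMD scale); arm sizes
uniform on 30–150 (the rated corpus averages ≈ 92 per arm); control-arm
dropout risk uniform on 0.10–0.30 (DHI reviews report pooled attrition
near 24%); true attrition risk ratios 1.6/1.5/1.2 by level; four raters at
80% agreement with errors confined to adjacent levels (trained raters do
not confuse low with high — and cross-level errors would also destroy the
monotone ICC-vs-agreement property the tests rely on); 15% of studies
have the post SD blanked and replaced by an SE, a CI, or only a baseline
SD, exercising every recovery path.  Individual participant outcomes are
drawn and then summarized, so arm means and SDs carry genuine sampling
error rather than being plugged in; the attrition random effect shares τ²
with the continuous outcomes for parsimony.  Every latent draw is recorded
in a manifest, and identical seeds reproduce identical CSV bytes.

What the generator does **not** emulate: publication bias and small-study
effects, non-normal random effects, correlated outcomes within a study,
cluster randomization, rating uncertainty ("certainty" judgments), and
systematically missing outcome arms.  Passing tests therefore certify the
arithmetic and the frequentist calibration of the engine under its assumed
model — not robustness to the messiness of real extracted trial data.

## Problem sizes and numerical choices

Calibration simulations use 2000 replications each: the null omnibus
F-test at k = 30 (three balanced levels, τ² = 0.05) and KH interval
coverage at k = 15 — sizes at which Monte-Carlo error on a 5% rate is
about ±0.5 percentage points.  Parameter recovery uses 200 studies per
level (600 total), where the Monte-Carlo standard error of a subgroup mean
is ≈ 0.02 SD units, so the ±0.03 recovery band is an informative but not
generous margin.  Oracle-equivalence tests compare against loop-based
brute-force implementations (ANOVA sums of squares, KH pooling formulas, a
grid-search REML maximizer) at 1e-8–1e-12, and against external
implementations (pingouin for ICC, metafor for KH/REML) at convergence
tolerance.  Ties in medians and measurement selection break downward /
first-listed deterministically, so reruns are byte-identical.

## Known limitations

- The default decision rule is one member of the family consistent with
  the stated weighting constraints; analyses of real corpora should supply
  the authors' actual rule table when available.
- ICC confidence intervals and weighted kappa are not implemented.
- Change-from-baseline effect sizes, cluster corrections and
  publication-bias diagnostics are out of scope.
- The equal-τ² link between continuous and attrition random effects in the
  generator is a modelling convenience, not an empirical claim.
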