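# Methods

This note documents the models, parameters and design decisions behind
`forumlab`, in the order the pipeline runs them.

## The analysis unit

All laboratory observations attributed to one forum account on one UTC
calendar day form one **test set**, the unit of analysis. People frequently
change treatment or lifestyle between testing days, so repeat panels by the
same account are treated as distinct data points rather than longitudinal
repeats. The post's creation day proxies the test date, since posts rarely
state when blood was drawn. Verbatim reposts of the same (test, value) pair
by the same account on a later day are dropped; partial panels posted the
same day merge into one set; a same-day conflict (same test, different
values) keeps both values and flags the set for reprocessing.

## Test catalog

`data/catalog.yaml` defines the 28-entry panel (26 analytes/derived indices
plus age and BMI): canonical unit, synonyms, alternate units with
multiplicative conversion factors, and two ranges per test in canonical
units. The *healthy* range is the standard clinical reference interval
(e.g. total testosterone 20–75 ng/dL, DHEA-S 59–328 µg/dL). The
*condition-plausible* range widens it to cover the dysregulation actually
reported in PCOS cohorts (e.g. LH up to ~90 U/L, AMH to 27 ng/mL): unit
inference and mistranscription checks use the plausible range so that
genuinely abnormal results are never discarded as transcription errors.
The bounds are data, not code, and are deliberately generous on the side of
keeping real pathology; a bound placed too tight truncates the tails of
skewed analytes and biases cohort means. Conversion factors are the
standard clinical ones (testosterone nmol/L→ng/dL ×28.84, glucose
mmol/L→mg/dL ×18.016, insulin pmol/L→mU/L ÷6, DHEA-S µmol/L→µg/dL ×36.85,
estradiol pmol/L→pg/mL ÷3.671, cholesterol mmol/L→mg/dL ×38.67,
triglycerides ×88.57, …). HbA1c ships no alternate unit because the IFCC
mmol/mol conversion is affine, not multiplicative, and the catalog contract
is multiplicative factors only.

## Synthetic corpus generator

The generator emulates the *statistical and textual structure* of a patient
forum, not its natural-language fluency. Its defaults are the study
conditions for every downstream test:

* **Latent values.** Per-test distributions parameterized by the cohort
  mean/SD recorded in the catalog (the forum-cohort summary levels).
  Right-skewed analytes (LH, PRL, FI, AMH, P, SHBG, HOMA-IR) are lognormal
  — their cohort medians sit far below their means — parameterized so the
  arithmetic mean/SD match; the rest are normal truncated at zero.
  LH/FSH and HOMA-IR are computed from their operands when those are in the
  panel, else drawn directly. A test enters a person's day-panel with the
  prevalence observed for that test in forum data (age 41.7%, total T
  34.8%, …, HDL 1.5%).
* **Styles.** Eight posting styles: full-name-with-unit,
  abbreviation-with-unit, no-unit, alternate-unit, mistyped-unit,
  split-pair (one panel across two same-day posts), duplicate-repost
  (verbatim repost on a later day), and distractor. The default mix keeps
  55% distractors and 1% mistypes — mistranscribed units are exceedingly
  rare in practice. Mistyped posts render the number on an alternate-unit
  scale under the canonical unit label, and are only emitted when that swap
  is recoverable (implausible as stated, plausible under exactly one unit);
  otherwise the style falls back to a plain abbreviation post.
* **Rendering.** ≥3 phrasing templates per style with synonym sampling;
  numbers are rounded to lab-typical precision (1 decimal for hormones,
  integers for mg/dL analytes), shifting with the order of magnitude of the
  unit factor when rendering in an alternate unit. The ground truth stores
  each mention's true canonical value together with a tolerance equal to
  half the last rendered decimal (converted to canonical units), so
  recovery is scored exactly.
* **Timestamps** are uniform over a five-year window; split pairs share a
  UTC day.

What the generator does *not* emulate — free-form prose, misspelled test
names, medication context, cross-post age references, comments — bounds
what passing tests show: they validate the recording logic and statistics,
not robustness to arbitrary human phrasing.

## Screening

Embeddings are fit to the whole corpus's word-word co-occurrence matrix by
GloVe-style weighted least squares (d=50, window 5, weighting cap
x_max=100, exponent 0.75), full-batch AdaGrad so training is deterministic
given the seed. The screen is a small text CNN in numpy: frozen embedding
lookup → parallel 1-D convolutions of widths {2,3,4,5}, 32 ReLU filters
each → global max pooling → one dense unit → sigmoid, trained with Adam on
binary cross-entropy with early stopping on a stratified 25% held-out
split. Sequences are truncated to 64 tokens; numerals map to a number-class
token. The default labeled sample is 400 posts, mirroring the
hundreds-of-labels budget such screens are realistically trained on. The
decision threshold is 0.5. A keyword rule (number token + test-name/unit
trigger token) ships alongside as a transparent baseline; every downstream
stage accepts either classifier, so pipeline correctness never hinges on
neural training.

## Unit inference and uncertainty

With a stated unit, the mistranscription check runs first: accept if the
converted value is condition-plausible; if not (or the unit is unknown for
the test), reinterpret when exactly one other common unit is plausible;
otherwise reject. Reinterpretations are decisive, not flagged uncertain —
they are rare, deliberate corrections. With no unit, the value is read
under every unit of the test: one plausible reading is taken at face
value; multiple readings agreeing within 20% are collapsed to the
canonical reading; readings disagreeing by more than 20% prefer the
canonical-unit reading when plausible (else the reading closest to the
cohort's typical level in SD units) and are flagged *uncertain*. The 20%
threshold is configurable; rejections are returned as records, never
silently dropped. This reproduces the expected uncertainty structure:
progesterone, estradiol and vitamin D — whose common units have large,
overlapping plausible ranges — show the highest uncertainty rates on the
default corpus (~14–21%).

## Quality control

z-scores use each test's own mean and sample SD (ddof=1; the values are a
sample, and at the n≥20 reporting threshold the distinction is minor but
should be fixed). Uncertain results and |z| > 2 results are flagged for
reprocessing; the uncertain members of the flagged set are re-run through
unit inference once with plausible ranges widened ×1.5, and a confident
re-reading replaces an uncertain one. (For confident stated-unit values a
widened re-run is a no-op — the accept rule is monotone in the range — and
re-running confident no-unit values with wider ranges could only introduce
ambiguity, so they are left as recorded.) Outlier removal is a single pass:
|z| > 4 against the *pre-removal* mean/SD, with no iteration — iterated
trimming changes removal rates, and one pass is the minimal reading of a
single removal event. The threshold is deliberately loose because
dysregulated cohorts legitimately contain extremes. The cohort summary
reports tests with ≥ 20 post-removal observations: n, percent of test sets
containing the result, mean, SD, median, quartiles, observed min/max,
percent uncertain (pre-removal) and percent removed. The printable table
shows "median (min–max)" in the parenthesized column; median, quartiles and
extremes are all kept as separate machine-readable fields.

## Equivalence testing

The boundary is b = 0.499 × s_pooled (medium Cohen's d) with s_pooled the
df-weighted pooled SD of the two groups being compared; standard errors are
pooled-variance with df = n_A+n_B−2, for internal consistency with the
boundary definition (Welch errors are available behind
`BoundarySpec(welch=True)`). The TOST p is the larger one-sided p-value;
p < α = .05 concludes equivalence. On non-equivalence, one-sided t tests
assign "literature lower"/"literature higher"; when neither rejects the
comparison is reported *inconclusive*. No multiple-testing correction is
applied: the comparisons are exploratory and interpreted jointly, so a
family-wise correction would be unnecessarily conservative.

Aggregate literature summaries use the sample-size-weighted mean of the
reporting studies' means and the sum of their n. The pooled SD of the
contributing studies is computed and reported, but comparisons against the
*published* aggregate take the published aggregate SD as an input: the
published aggregate SDs match neither the pooled SD nor the
root-sum-of-variances (for FSH, pooling the study SDs gives 2.4 against a
published 6.4), so reproducing the published verdicts must not depend on
reverse-engineering an unstated formula.

With the published summary statistics as inputs, the pooled-Student
procedure reproduces all 14 aggregate verdicts and 77 of the 79 populated
per-study cells. Of the two discrepant cells, one (age vs the Cai cohort,
TOST p = .078) flips to the published label within ±0.05 perturbation of
the rounded means/SDs; the other (LH vs the Wright cohort, TOST p = .067)
is not perturbation-borderline under pooled errors but reproduces exactly
under Welch errors — weak evidence that the published analysis may have
mixed error models. Welch throughout is worse overall (five per-study
mismatches), so pooled remains the default.

## Numerical choices

* Lognormal parameterization from (mean m, SD s): σ² = ln(1+s²/m²),
  μ = ln m − σ²/2; truncated-normal draws by inverse-CDF on the truncated
  uniform, so all sampling is reproducible from `numpy` Generator seeds.
* TOST p-values are computed from the t survival function; the test suite
  verifies them to 10⁻⁶ against direct numerical integration of the t
  density across 1,000 randomized inputs.
* Zero SD in a z-scoring step flags/removes nothing; both-SDs-zero or
  n < 2 in a comparison raise rather than guess.
* Overlapping synonym matches in a post resolve to the longest synonym
  (`LH/FSH 2.2` is a ratio, not an FSH value); a token after a number is a
  unit only if it normalizes into the catalog's unit vocabulary.
* Problem sizes: the default corpus is 2,000 posts with a 400-post labeled
  sample — the corpus scale is emulated, not matched, and parameter
  recovery at this size is already within ~1 SE for well-populated tests.

## Known limitations

* The synthetic corpus is templated; screen accuracies on it (≈1.00
  held-out) exceed what heterogeneous human text would allow and should be
  read as validating the pipeline, not forecasting real-corpus accuracy.
* Ages are only captured when stated in the post; approximating age from
  other posts by the same account is out of scope, as are medication
  inference and cycle-phase normalization (cycle-phase text is captured as
  a free-text field but not analyzed).
* The per-study fixture transcribes published summary rows; any rounding
  in those sources propagates into borderline verdicts, which is why the
  reproduction criterion tolerates a small number of borderline cells.
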