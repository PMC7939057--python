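# Methods

## The emulated cross-sectional design

The pipeline treats a tweet stream as a self-administered survey: each
original English tweet is one questionnaire row whose "respondent
attributes" are the author's inferred demographics and whose "responses"
are derived from the tweet text. Stages:

1. **Filtering.** The *original set* keeps records with `lang == "en"`
   that are not retweets, replies or quotes (all three originality flags
   are schema-level inputs and are trusted; no `@`-heuristics). The
   *COVID set* is the subset matching a COVID-19 keyword pattern. By
   construction the COVID set is a subset of the original set, filtering
   is order-preserving and idempotent, and every input record is accounted
   for as kept, dropped, or invalid.
2. **Annotation.** Four annotators fill the questionnaire: demographics
   (pluggable backend contract; the bundled `truth` backend reads the
   synthetic ground-truth block), concern topics (dictionary regex over
   five life-domain vocabularies), sentiment (polarity in [−1, 1], binned
   at ±0.05), and emotions (intensity vectors in [0, 1] under the
   `ekman6`, `plutchik8` and `poms6` label spaces).
3. **Assembly and analysis.** One `QuestionnaireRecord` per original
   tweet; marginal summary table; then the disparity battery of
   contingency-table statistics.

## Matching semantics

All text matching is NFKC-normalized and case-folded. A term matches only
at word boundaries (never inside a longer alphanumeric token, so
`covid` does not hit `covidiom`); hyphens inside terms are literal;
multi-word terms match as phrases; a `#`-prefixed term matches with or
without the hash. Term lists are run inputs (plain text, one term per
line, `;` comments); bundled starter lists (~40–50 terms per topic, 40
COVID keywords) back the tests and the generator. The bundled
vocabularies are deliberately pairwise disjoint — topics, COVID keywords,
valence words, emotion words and the generator's filler words share no
tokens — which is what makes exact label recovery provable on synthetic
corpora.

## Sentiment

The default scorer is the bundled valence-lexicon mean: the mean valence
of known words in the token stream, 0.0 when none occur. The bin
boundaries are: positive ⇔ polarity ≥ 0.05, negative ⇔ polarity ≤ −0.05,
else neutral — the two boundary points belong to the outer bins, the
convention of the established rule-based social-media scorers this
emulates. `bin_sentiment` therefore partitions [−1, 1] exactly. Any
scorer returning values in [−1, 1] can be plugged in; out-of-range output
is a contract violation.

## Emotions

The default backend scores each label as its share of matched
emotion-word tokens (all-zero without emotion words). The *dominant
emotion* of a vector is the maximal-score label; an all-zero vector gets
the sentinel `none`; ties break by the fixed questionnaire listing order
(anger, disgust, fear, joy, sadness, surprise [, trust, anticipation] /
anger, depression, fatigue, vigor, tension, confusion) and are logged.
Population emotion distributions are shares of tweets per dominant label.
Emotion ORs binarize on "dominant emotion == label" and are computed over
COVID-related records by default.

## Disparity statistics

- `build_table` forms 2×2 group/reference × outcome tables; group and
  reference must be non-empty and disjoint (`rest` = complement).
- `odds_ratio` is the cross-product ratio; `wald_ci` is the Woolf
  interval exp(ln OR ± z·SE), SE = √(1/a+1/b+1/c+1/d), z₀.₉₇₅ = 1.959964.
  This method reproduces the reference study's printed CIs at 2 dp, which
  is the evidence it is the method that study used.
- `chi_square` is Pearson's statistic without continuity correction
  (delegated to `scipy.stats.chi2_contingency`), df = (R−1)(C−1); on 2×2
  tables it agrees with the closed form n(ad−bc)²/(margin products) to
  1e-9 relative (property-tested against that independent oracle).
- Zero cells: ORs error by default; an optional Haldane–Anscombe +0.5 on
  all four cells can be enabled and is flagged in `ORResult.corrected`.
- References: univariate contrasts use persons, males and the ≤18 group;
  bi-/trivariate strata default to the all-baseline cell (male, ≤18,
  same topic), and reported rows always name their reference. The
  trivariate battery is gender × age × topic = 40 strata, persons only
  (organizations carry no gender/age); the five (male, ≤18, topic) cells
  are their own references and are reported without an OR.
- Rounding for reports: ratios/ORs/CIs half-up at 2 dp, polarities at
  4 dp; p-values unrounded. No multiple-testing correction is applied
  (deliberately, matching the analysis design this emulates).

## The synthetic corpus generator

`table3_default_config()` encodes the study conditions: person share
0.8994, male share 0.5274 (persons only), age shares
0.3793/0.3842/0.1141/0.1224, per-group COVID attention rates
(organizations 0.0719, persons 0.0218, genders 0.0249/0.0182, ages
0.0102/0.0165/0.0349/0.0616, topics 0.0736…0.0219), topic marginals
0.1399/0.1390/0.0727/0.0638/0.0779 with COVID-conditional rates
0.3430/0.2260/0.1997/0.1574/0.0638, and sentiment/emotion parameters
encoding the reported contrasts (organizations more positive, mean 0.1135
vs 0.0483 on COVID tweets; fear and depression elevated for organizations
and under COVID).

Only marginals are published, so the joint distribution is a modeling
choice:

- gender and age are independent given person (overridable);
- the person-level COVID rate is **multiplicative in risk**:
  p(g, a) = r_g · r_a / r_person. Under independence this makes every
  configured marginal attention ratio exact in expectation, so the
  config-implied "true" marginal odds ratios are available in closed form
  (`expected_group_rates`, `true_odds_ratio`) — which is what makes CI
  coverage a well-posed recovery target. (The published 4-dp percentages
  are internally inconsistent at the ~0.3% level; the closed form of the
  generating process, not the printed value, is the ground truth used in
  recovery tests.)
- topics are drawn conditionally on the COVID flag, with the
  non-COVID rate back-solved from the configured marginal, reproducing
  both topic prevalences and per-topic attention ratios in expectation;
- polarity is truncated-normal on [−1, 1] with (mean, sd) looked up by
  `user_type:covid` → `covid` → `user_type` → `default`. The configured
  values parameterize the *parent* normal; truncation shrinks realized
  means toward zero by up to ~30% at sd ≈ 0.49 (e.g. configured 0.048 →
  realized ≈ 0.035). Tests therefore compare against realized truth, not
  the parent parameter;
- emotion intensities are Beta(μk, (1−μ)k) with concentration k = 8 and
  additive group mean-shifts, clipped to [0.01, 0.99].

Texts are bags of sampled terms: fillers, one term per intended topic, a
COVID keyword iff the COVID flag is set, the valence word nearest the
target polarity (grid step 0.1, so lexicon-recovered polarity is within
0.05 of truth except at the ±1 edges), and two words from each of the
plutchik/POMS dominant emotions. One PCG64 stream per corpus is consumed
in fixed field-major order, so identical (config, seed) pairs are
byte-identical across platforms.

**What the generator does not emulate:** natural language (word order,
negation, sarcasm — so lexicon-annotator accuracy on synthetic text says
nothing about accuracy on real tweets, only that the pipeline plumbing is
correct), demographic-inference error (the truth backend is an oracle;
real profile-based classifiers mislabel), user-level clustering (tweets
are i.i.d.; real authors post repeatedly, shrinking effective sample
size), temporal dynamics, and non-English content beyond a configurable
language flag. Passing recovery tests demonstrates estimator correctness
under the configured joint model, not robustness to these real-data
features.

## Problem sizes and numerical choices

Marginal-recovery tests run at n = 10⁴–10⁵ with 3–4 binomial-SE bands;
the CI-coverage study uses 50 replicate corpora of 100k tweets (expected
coverage ≈95%, required ≥90%) — sizes chosen so binomial noise is well
below the effects being checked while a full run of suite plus acceptance
script stays in the minutes range on one CPU. Percentage rounding is
decimal half-up (2 dp), matching printed-table style. Degenerate inputs
error early and explicitly: empty strata, zero cells (without the
correction), out-of-range polarities/intensities, malformed probability
vectors (the error names the offending field).

## Known limitations

Bi-/trivariate reference groups in the published analysis are not
identifiable from its printed values, so their numeric ORs are not
reproduction targets here; the all-baseline-cell default is this
package's choice. The chi-square reported per summary-table variable is a
single omnibus levels × attention test (for the non-exclusive concern
flags this treats topic counts as if exclusive — an approximation). The
emotion backends are deliberately simple lexicon scorers behind the same
contract a trained model would implement.
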