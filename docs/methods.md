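# Methods

`agreesim` simulates human agreement-attraction experiments with word-level
recurrent neural language models. This note documents the models, the
linking hypotheses, the synthetic data, the statistical machinery, the
numerical choices behind each, and what the package's tests do and do not
establish about real-corpus behavior.

## The modeling framework

A language model assigns `P(w_i | w_0..w_{i-1})` by encoding the prefix
with a recurrent network and decoding the final hidden state into a
distribution over the vocabulary. Two encoder families are implemented:

* **SRN** — `h_i = tanh(W_h h_{i-1} + W_w w_i)`.
* **LSTM** — standard input/forget/output gating with a tanh candidate
  cell; the forget-gate bias is initialized at +1 so that early-sequence
  information survives the initial training phase. The LSTM is the default
  encoder because agreement is a (potentially) long-distance dependency.

A *multitask* model adds a second linear decoder that predicts the
**supertag of the most recent word** — an enriched lexical category in
categorial slash notation (`Y/X` combines rightward, `Y\X` leftward) that
encodes how the word composes with its neighborhood. The training loss is
`w1 * mean word cross-entropy + w2 * mean supertag cross-entropy` with
equal weights `(0.5, 0.5)` by default; this is the operationalization of
"equally weighted" objectives (any common rescaling is absorbed by the
learning rate). Comparing word-prediction-only (LM-Only) with multitask
(LM+CCG) instances asks whether an explicit pressure toward local syntactic
structure changes agreement behavior.

Training uses plain SGD with gradient-norm clipping and a learning rate
that is halved whenever held-out loss fails to improve across an epoch.
Dropout, truncated backpropagation length, batch size and the schedule are
configuration knobs, not fixed constants. All forward and backward passes
are written directly in NumPy; a finite-difference test enforces gradient
correctness of the combined loss to 1e-4 relative error.

**Instances.** Every configuration is trained as `n_instances` (default 5)
runs differing only in seed (initialization and data order). Downstream
analyses treat the instance as a grouping factor, the modeling analogue of
subjects in a behavioral study.

## Linking model output to behavior

* **Reading** (self-paced reading paradigms): surprisal,
  `-log2 P(w_i | prefix)`, in bits, measured at the critical token.
  Spillover pooling is deliberately not part of the statistic; the trial
  table retains the full per-token series so a user can pool post hoc.
* **Production** (sentence-completion paradigms): the model's probabilities
  for a singular/plural candidate verb pair (default *is*/*are*) are
  renormalized to sum to 1. The **one-sample** rule takes the renormalized
  `p_singular` as the probability of producing the singular form — a
  single draw from the model's posterior over the pair. **max-prob**
  deterministically picks the larger candidate (exact ties are flagged and
  excluded from error summaries with a warning — a case that cannot arise
  from generic float probabilities but must be defined). **n-sample**
  takes the majority of `n` independent draws (`n` odd; even `n` is
  rejected because majority is undefined), i.e. the upper binomial tail at
  `ceil(n/2)`. One-sample is the `n = 1` case and max-prob the `n -> inf`
  limit; the test suite verifies the identity at `n = 1`, a 3-draw
  enumeration, and monotone convergence up to `n = 1001`.
* A trial's **error rate** is the linked probability of the verb form
  incongruent with the subject's grammatical number — continuous, because
  that is what the beta regression consumes. For disjunct subjects and
  notional-number items there is no canonical agreement pattern, so the
  reported measure is the plural-agreement rate itself.
* Candidate forms that are out of vocabulary are rejected before linking;
  when both candidates carry vanishing-but-nonzero mass the renormalized
  value is propagated and the raw mass logged for audit.

## Synthetic training corpora

The real training data for this kind of study (tens of millions of words
of edited text with treebank supertags) cannot ship with a package, so the
corpus module generates sentences from a small probabilistic grammar whose
*agreement-relevant statistics* are the point:

* Every sentence contains a number-marked subject-verb dependency, and the
  generator emits **only grammatical agreement** — behavioral noise must
  come from learning, not from corpus errors, as in edited text.
* Number is marked purely morphologically (plural nouns take `-s`,
  third-singular verbs take `-s`, the copula is *is*/*are*), so number is
  learnable from surface form alone.
* Subjects may be modified by a PP (optionally containing a nested PP), a
  subject or object relative clause, or may be a disjunction of two NPs
  (verb agreeing with the linearly closer disjunct). Default per-sentence
  rates — PP 0.15, RC 0.018, nested PP 0.02, disjunct subjects 0.0035 —
  follow parser-derived counts that are typical of encyclopedic English
  text. The generator rescales conditional probabilities internally so
  these *unconditional* rates hold exactly in expectation, which the
  4-sigma/20-seed calibration test checks.
* Content words are deterministic CVCV pseudoword stems, so vocabulary
  size is controlled and items built from the grammar are OOV-free.
* Supertags come from a closed 12-category tagset derived from the grammar
  rules (`NP/N`, `N/N`, `N`, `(NP\NP)/NP`, `(NP\NP)/(S\NP)`,
  `(NP\NP)/(S/NP)`, `(S\NP)/NP`, `S\NP`, `(S\NP)/ADJ`, `ADJ`, `conj`,
  `.`). What matters for the multitask hypothesis is that tags encode
  local combination, not the size of a treebank inventory. The lexicon is
  tag-unambiguous except for the relativizer (subject vs. object relative)
  and adjectives (attributive vs. predicative), both disambiguated by one
  token of context — which is why the most-frequent-tag-per-word baseline
  is strong (~94%) and beating it requires genuinely contextual tagging.

**What the generator does not emulate:** lexical semantics (so notional
number and argument-status effects have no signal to be learned from —
null results on those paradigms are expected at toy scale), genre
variation, frequency skew within categories, sentence lengths beyond ~16
tokens, and ungrammatical input. Passing tests therefore show that the
pipeline is correct and that the *learnable* structural effects (attraction,
grammaticality asymmetry, disjunct proximity) emerge; they do not certify
magnitudes for models trained on natural corpora.

Sentence-length distribution and lexicon sizes are not pinned down by any
reference setting; the defaults (30 nouns, 20 verbs, 15 adjectives, 6
prepositions, 1 determiner) were chosen once as the smallest lexicon that
keeps item generation comfortably collision-free, and are config-exposed.

## Experimental paradigms

Six registered designs generate full factorial, minimal-pair item sets
over the grammar's lexicon (user-supplied CSV lists are also accepted):
PP vs. RC subject modifiers (2x2x2, completion); stacked PPs with a
syntactically closer and a linearly closer attractor (2x2x2, completion);
disjunct subjects (2 levels, completion); collective/distributive
preposition bias (2 levels, completion); core vs. oblique attractor
arguments with a grammaticality manipulation at the matrix verb (2x2x2,
reading); and object relatives where the matrix head attracts RC-internal
agreement (2x2, reading). Reading items end at the critical region (the
critical token's surprisal does not depend on later tokens), which keeps
match/mismatch cells exact minimal pairs. The OOV policy for user-supplied
items replaces NP-internal or design-manipulated unknown words only from a
curated substitution table (a hard error otherwise, since the unknown
token would destroy number information) and maps all other unknown words
to the reserved unknown token.

## Statistics

Probability responses are analyzed with **beta mixed-effects regression**:
`y ~ Beta(mu*phi, (1-mu)*phi)` with logit link for `mu`, log link for the
precision `phi`, and independent Gaussian variance components (random
intercepts, optional random slopes) for items and instances. Estimation is
maximum likelihood with a Laplace approximation over the random effects:
the fixed effects and random-effect modes are found jointly by
Fisher-scoring on the penalized likelihood, and the marginal likelihood is
profiled over the variance parameters (the standard GLMM Laplace scheme).
Wald standard errors use the GLS covariance `(X' V^-1 X)^-1` with
`V = W^-1 + Z D Z'` at the optimum. On reference fixtures the fit matches
R's `glmmTMB` to well under 1% on coefficients, standard errors, `phi` and
log-likelihood (an independent cross-check in the test suite, not part of
the implementation).

Surprisal responses use **linear mixed-effects regression** with the same
variance-component structure, fitted by profiled (restricted) marginal
likelihood via the Woodbury identity; it reproduces `lme4::lmer` to
4 decimals on fixtures. p-values for t statistics use a normal
approximation (no degrees-of-freedom correction), flagged in the fit notes.

Numerical choices worth knowing:

* All factors are **sum-to-zero coded** (levels sorted; last level is the
  negative pole), so in balanced designs the intercept is the grand mean on
  the link scale and a two-level coefficient is half the difference of
  level means. Coefficient magnitudes depend on this choice.
* Trigamma values are computed by a shift-recurrence + asymptotic series
  (verified against SciPy to 1e-9 relative) because the inner loop calls it
  thousands of times.
* Responses at exactly 0 or 1 are pulled inside the interval by the
  standard squeeze `y' = (y(N-1)+0.5)/N`, applied only when a boundary
  value occurs; one-sample responses are interior, so this guards only
  user-supplied data.
* A variance component whose standard deviation collapses below `e^-5` is
  flagged singular; singular or non-converged fits trigger the **pruning
  protocol**, which removes random terms in a fixed documented order —
  slopes first (highest interaction order first, then by group and term
  name), intercepts (instance before item) only as a last resort — until a
  clean fit is reached. The intercepts-only-for-items-and-instances
  endpoint that maximal models typically prune to is directly reachable on
  degenerate fixtures (one observation per item-cell).
* Equality of two fixed effects is tested by a **likelihood-ratio test**
  against a refit in which the two design columns are merged (chi-square,
  1 df); REML fits are refitted under ML before the comparison. A
  Wald-contrast alternative can be formed from the reported covariance, and
  the suite checks the asymptotic agreement `|z| ~ sqrt(chi^2)`.

The calibration of this layer is itself tested: 95% Wald coverage of a
null coefficient is ~0.95 over 200 seeded replicates at 60 items x 5
instances, the LRT type-I rate at alpha = 0.05 is within [0.02, 0.09] over
200 null replicates, and variance components at 50 groups x 20 observations
are recovered within 20% on average.

## Probing

* **Ablation sweep**: each final-layer unit is zeroed in turn (a
  non-destructive evaluation view applied before both decoders, leaving the
  recurrence intact — i.e., ignoring one dimension of the representation),
  and both held-out losses are recorded; the Pearson correlation between
  the two loss columns measures localized sharing between tasks.
* **Amnesic probing**: from a linear supertag classifier with weights `W`,
  the orthogonal projector `T = I - W^+ W` (pseudo-inverse by SVD, relative
  singular-value cutoff 1e-10) maps representations onto the nullspace of
  `W`. After projection the classifier's input-dependent logit component is
  exactly zero; the bias remains, so its predictions are constant — the
  operational sense in which it "can no longer distinguish representations".
  Projection is applied at evaluation time only (a single nullspace-
  projection step, no retraining). If `W` has full column rank the
  projector is identically zero; this is warned, not raised.
* **Frozen-encoder probe**: for LM-Only models, a multinomial logistic
  probe is trained on frozen encoder states (the encoder checksum is
  asserted unchanged); it bounds how much tag information word prediction
  alone induces. The 4-row report — (LM+CCG, LM-Only) x (baseline,
  amnesic) — gives word-prediction loss and supertag accuracy before and
  after projection.

## Toy-scale study conditions

The self-contained "replication at toy scale" uses 2-layer, 64-unit LSTMs
(embedding 64) trained for 2 epochs with SGD on 50,000 generated sentences
(~450k tokens), 5 instances per objective; the 650-unit/12-epoch reference
configuration remains the config default for users with more compute.
These sizes are where the toy grammar's learning curve saturates: held-out
perplexity falls well below the unigram baseline, attractor-free preambles
receive the congruent *be* form essentially always, and the multitask
model's supertag accuracy exceeds the most-frequent-tag baseline. Trained
at this scale the models exhibit large attraction effects (error rates
above 40% in mismatch conditions — far above human rates, as expected for
small recurrent models) and a grammaticality asymmetry in the object-
relative reading paradigm; semantic paradigms come out null, consistent
with a generator that encodes no semantics.

## Known limitations

* The Laplace approximation (with Fisher-scoring weights) is the standard
  desk-scale choice but is still an approximation; adaptive quadrature is
  not implemented.
* Random effects are independent variance components; correlated
  random-slope/intercept blocks are not supported (the pruning protocol
  compensates in practice).
* The NumPy training loop is single-threaded CPU code; it is sized for
  vocabularies of a few hundred words and hidden widths up to a few
  hundred units, not for natural corpora.
* Object relatives are generated only inside the relative-clause
  construction; the grammar has no other center-embedding, coordination of
  clauses, or long-distance dependencies beyond agreement.
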