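# agreesim

Neural language models as simulated participants in subject-verb
agreement experiments.

English requires a verb to match its subject in number ("the key **is**
rusty", "the keys **are** rusty"), yet speakers and readers err, most often
when a nearby *attractor* noun carries the other number ("the key to the
cabinets **are** rusty") — the *agreement attraction* phenomenon.
`agreesim` is a research toolkit for asking whether broad-coverage
word-prediction models reproduce the detailed structure of those human
errors: which factors modulate them, whether an explicit syntactic
training objective changes them, and where in the network the relevant
information lives. It is aimed at computational psycholinguists who want
a self-contained, fully seeded pipeline from training corpus to
mixed-effects coefficient table.

## What's inside

| module | role |
| --- | --- |
| `agreesim.corpus` | probabilistic generator of agreement-annotated training corpora (PP/RC subject modifiers, nested PPs, disjunct subjects, per-token supertags), vocabulary, construction statistics |
| `agreesim.neural_lm` | word-level SRN and LSTM language models in pure NumPy — training (optionally multitask with a supertagging decoder), perplexity, supertag accuracy, unit ablation |
| `agreesim.linking` | surprisal series; one-sample / max-prob / n-sample completion rules |
| `agreesim.stimuli` | the six agreement-attraction paradigms as factorial minimal-pair item generators, item CSV I/O, out-of-vocabulary substitution policy |
| `agreesim.simulation` | production and self-paced-reading harnesses, attraction/asymmetry effect summaries, a seeded oracle predictor for validating the pipeline |
| `agreesim.stats` | beta mixed-effects regression (logit link, Laplace), linear mixed-effects regression, random-effect pruning protocol, equality-of-effects likelihood-ratio test |
| `agreesim.probing` | per-unit ablation sweeps, nullspace ("amnesic") projection from a linear supertag probe, frozen-encoder probes |
| `agreesim.workbench` | run configuration, the end-to-end toy driver, and the `agreesim` CLI |

### The model and the linking functions

An autoregressive recurrent network assigns `P(w_i | w_0..w_{i-1})`.
Reading-time paradigms are linked through surprisal at the critical word,

```
S(w_i) = -log2 P(w_i | w_0 .. w_{i-1})   [bits],
```

and sentence-completion paradigms through the probability, renormalized
over a singular/plural candidate pair (default *is*/*are*), of producing
each verb form:

```
p_sg = P(is | preamble) / (P(is | preamble) + P(are | preamble)).
```

Interpreting `p_sg` as a single production sample (*one-sample*) makes the
simulated speaker stochastic; taking the majority of `n` samples
interpolates toward the deterministic *max-prob* rule as `n` grows. Error
probabilities from many model instances, items and conditions are then
analyzed exactly as human data would be: beta mixed-effects regression for
probabilities, linear mixed-effects regression for surprisals, with random
intercepts for items and model instances, Wald/t statistics per
coefficient, and likelihood-ratio tests for equality of two effects.

## Worked example

Train two small LSTM instances on a generated corpus and run the classic
PP/RC preamble-completion design:

```python
from agreesim.corpus import GrammarConfig, Grammar, generate_corpus, build_vocab
from agreesim.neural_lm import (EncoderConfig, TrainConfig, LanguageModel,
                                train, perplexity, UnigramModel)
from agreesim.stimuli import generate_paradigm_items
from agreesim.simulation import run_production, asymmetry_contrasts
from agreesim.stats import RegressionSpec, fit_beta_mixed

cfg = GrammarConfig(seed=0)
corpus = generate_corpus(cfg, 52_000)
train_set, heldout = corpus[:50_000], corpus[50_000:]
vocab = build_vocab(train_set)

models = []
for k in range(2):
    m = LanguageModel(vocab, EncoderConfig("lstm", 2, 64, 64), seed=k)
    m, _ = train(m, train_set, TrainConfig(epochs=2, seed=k,
                                           weight_word=1.0, weight_tag=0.0))
    models.append(m)

print(f"held-out perplexity: {perplexity(models[0], heldout):.2f} "
      f"(unigram baseline {perplexity(UnigramModel(train_set, vocab), heldout):.2f})")

items = generate_paradigm_items("bock_cutting", Grammar(cfg), n_items=24, seed=1)
trials = run_production(models, items, rule="one_sample")
effects = asymmetry_contrasts(trials)
print(f"attraction effect (error-rate difference): {effects['attraction'].mean():+.3f}")
print(f"number asymmetry: {effects['number_asymmetry'].mean():+.3f}")

spec = RegressionSpec("error_rate", "probability",
                      fixed=("attractor_match", "subject_number",
                             "attractor_match:subject_number"),
                      random_intercepts=("item", "instance"))
print(fit_beta_mixed(trials, spec).summary().round(3).to_string(index=False))
```

Output (a couple of minutes on one CPU core):

```
held-out perplexity: 6.43 (unigram baseline 33.92)
attraction effect (error-rate difference): +0.522
number asymmetry: -0.152
                          term   beta    SE    |z|   p
                   (Intercept) -1.089 0.185  5.878 0.0
               attractor_match -1.660 0.024 68.161 0.0
                subject_number  0.935 0.024 38.477 0.0
attractor_match:subject_number  0.261 0.024 10.721 0.0
```

Reading the numbers: the language model is far better than a unigram
baseline (perplexity 6.4 vs. 33.9), so it has learned real sequential
structure. The attraction effect of +0.52 says that a number-mismatching
attractor raises the simulated error rate by 52 percentage points — small
recurrent models attract far more than humans do, and the package's
analyses (like the human literature's) are about *differences between
conditions*, not absolute rates. In the coefficient table, factors are
sum-coded with "match" and "pl" on the +1 pole, so the negative
`attractor_match` coefficient is the attraction effect on the log-odds
scale (−2 x −1.660 = 3.32 log-odds of an error, mismatch − match) and is
overwhelmingly significant by a Wald test. This particular instance pair
shows a *reverse* number asymmetry (plural subjects attract more, the
negative −0.152): with a single toy corpus the direction of the asymmetry
is corpus-dependent, which is itself one of the phenomena the toolkit is
designed to expose.

The same machinery runs the other five designs (`franck`, `haskell`,
`humphreys`, `parker_an`, `wagers` — the last two are self-paced-reading
paradigms analyzed with `run_comprehension` and linear mixed models), and
`agreesim.probing` asks where tag information lives:

```python
from agreesim.probing import amnesic_report
report = amnesic_report(multitask_model, lm_only_model, heldout)
```

which yields the 4-row (model variant x baseline/amnesic) table of
word-prediction loss and supertag accuracy before and after projecting the
supertag subspace out of the encoder's representations.

### Command line

Every stage is also a subcommand of the `agreesim` console script:

```
agreesim generate-corpus --n 50000 --seed 1 --out runs/corpus
agreesim train --corpus runs/corpus --multitask on --epochs 2 --hidden 64 \
         --embedding 64 --instances 5 --seed 1 --out runs/models
agreesim simulate --models runs/models --items items.csv --linking one_sample --out runs/sim
agreesim analyze --trials runs/sim/production_trials.csv --paradigm bock_cutting --out coefs.csv
agreesim probe amnesic --model runs/models/instance_0.npz --lm-only-model ... --out report.csv
agreesim replicate-toy --out runs/toy --seed 1
```

`replicate-toy` chains the entire pipeline (corpus -> two model families ->
six paradigms -> mixed-effects tables -> probing) and writes a manifest
recording every seed and checksum needed to reproduce the run.

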