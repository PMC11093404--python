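"""Linking functions from next-word distributions to behavioral measures.

Reading-time paradigms are linked through *surprisal*,
``-log2 P(w_i | w_0..w_{i-1})``, which is approximately linear in human
reading times.  Sentence-completion paradigms are linked through the
probability, renormalized over a singular/plural candidate verb pair, with
which the simulated speaker produces each form:

* ``one_sample`` — a single draw from the renormalized pair distribution;
  ``p_singular = P(sg) / (P(sg) + P(pl))``.
* ``max_prob`` — deterministically produce the more probable form.
* ``n_sample`` — majority vote over ``n`` independent draws (``n`` odd);
  ``n = 1`` recovers one_sample, and ``n -> inf`` recovers max_prob.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CandidatePair",
    "CompletionProbability",
    "UndefinedCompletionError",
    "surprisal_series",
    "one_sample",
    "max_prob",
    "n_sample",
]

logger = logging.getLogger(__name__)

LOG2E = math.log2(math.e)


class UndefinedCompletionError(ValueError):
    """Both candidate forms have probability zero."""


@dataclass(frozen=True)
class CandidatePair:
    """Singular/plural forms of the candidate verb (default: *is*/*are*)."""

    singular: str = "is"
    plural: str = "are"

    def __post_init__(self):
        if self.singular == self.plural:
            raise ValueError("candidate forms must be distinct")

    def validate_in_vocab(self, vocab) -> None:
        for form in (self.singular, self.plural):
            if form not in vocab:
                raise ValueError(f"candidate form {form!r} is out of vocabulary")


@dataclass(frozen=True)
class CompletionProbability:
    p_singular: float
    rule: str                    # "one_sample" | "max_prob" | "n_sample"
    n: int | None = None         # n_sample only
    tie: bool = False            # max_prob only; exact ties are flagged

    @property
    def p_plural(self) -> float:
        return 1.0 - self.p_singular


def surprisal_series(model, tokens) -> np.ndarray:
    """Per-token surprisal in bits.

    Summing the series gives ``-log2`` of the chain-rule joint probability
    of the sentence (excluding the end-of-sentence event).  Zero-probability
    tokens yield ``+inf`` rather than raising.
    """
    tokens = list(tokens)
    if hasattr(model, "token_log2probs"):
        lp = np.asarray(model.token_log2probs(tokens), dtype=np.float64)
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(lp), -lp, np.inf)
    # generic path: any object exposing next_word_distribution
    vals = np.empty(len(tokens))
    for i, tok in enumerate(tokens):
        dist = np.asarray(model.next_word_distribution(tokens[:i]), dtype=np.float64)
        idx = model.vocab.word2id.get(tok, model.vocab.unk_id)
        p = dist[idx]
        vals[i] = -math.log2(p) if p > 0 else math.inf
    return vals


def _candidate_probs(dist: np.ndarray, pair: CandidatePair, vocab,
                     item_id=None) -> tuple[float, float]:
    pair.validate_in_vocab(vocab)
    p_sg = float(dist[vocab.word2id[pair.singular]])
    p_pl = float(dist[vocab.word2id[pair.plural]])
    if not (np.isfinite(p_sg) and np.isfinite(p_pl)):
        raise ValueError("candidate probabilities must be finite")
    if p_sg + p_pl <= 0.0:
        raise UndefinedCompletionError(
            f"both candidates have probability 0 (item={item_id!r})"
        )
    if p_sg + p_pl < 1e-12:
        logger.warning(
            "candidate pair carries tiny probability mass %.3e (item=%r); "
            "renormalized value propagated", p_sg + p_pl, item_id,
        )
    return p_sg, p_pl


def one_sample(dist: np.ndarray, pair: CandidatePair, vocab,
               item_id=None) -> CompletionProbability:
    """Renormalize over the candidate pair: ``p_sg / (p_sg + p_pl)``."""
    p_sg, p_pl = _candidate_probs(dist, pair, vocab, item_id)
    return CompletionProbability(p_singular=p_sg / (p_sg + p_pl), rule="one_sample")


def max_prob(dist: np.ndarray, pair: CandidatePair, vocab,
             item_id=None) -> CompletionProbability:
    """Deterministically select the more probable form; exact ties are
    flagged (and should be excluded from error-rate summaries)."""
    p_sg, p_pl = _candidate_probs(dist, pair, vocab, item_id)
    if p_sg == p_pl:
        logger.warning("exact candidate tie (item=%r)", item_id)
        return CompletionProbability(p_singular=0.5, rule="max_prob", tie=True)
    return CompletionProbability(p_singular=1.0 if p_sg > p_pl else 0.0, rule="max_prob")


def n_sample(dist: np.ndarray, pair: CandidatePair, vocab, n: int,
             item_id=None) -> CompletionProbability:
    """P(majority of ``n`` draws from the renormalized pair distribution are
    singular) — the upper binomial tail at ``ceil(n/2)`` successes."""
    if n < 1 or n % 2 == 0:
        raise ValueError("n must be odd and >= 1 (majority undefined otherwise)")
    p_sg, p_pl = _candidate_probs(dist, pair, vocab, item_id)
    p = p_sg / (p_sg + p_pl)
    k = (n + 1) // 2  # smallest majority
    p_major = float(sps.binom.sf(k - 1, n, p))
    return CompletionProbability(p_singular=p_major, rule="n_sample", n=n)
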