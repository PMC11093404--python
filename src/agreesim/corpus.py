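"""Synthetic training corpora with number-marked subject-verb agreement.

This module generates the kind of data an agreement-attraction study's
language models must be trained on: English-like sentences in which every
subject agrees with its verb in number, subjects may be modified by
prepositional phrases (optionally nested), subject or object relative
clauses, or may be disjunctions of two noun phrases.  Construction
frequencies are configurable; the defaults follow per-sentence rates that
are typical of edited English text (PP subject modifiers ~0.15/sentence,
RC modifiers ~0.018, nested PPs ~0.02, disjunct subjects ~0.0035).

Content words are pseudoword stems (e.g. ``bade``, ``mulo``).  Number is
marked purely morphologically: plural nouns and singular verbs carry an
``-s`` suffix, so a learner can recover number from surface form alone.
Every token also carries a supertag from a small closed tagset written in
categorial slash notation: ``Y/X`` combines with an ``X`` on its right to
form a ``Y``, ``Y\\X`` with an ``X`` on its left.
"""

from __future__ import annotations

import collections
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GrammarConfig",
    "SentenceRecord",
    "Vocabulary",
    "Grammar",
    "generate_corpus",
    "assign_supertags",
    "build_vocab",
    "construction_counts",
    "write_corpus",
    "read_corpus",
]

UNK = "<unk>"
BOS = "<s>"
EOS = "</s>"

# Closed supertag inventory (slash notation; "conj" and "." follow the
# conventional treatment of conjunctions and punctuation).
TAG_DET = "NP/N"
TAG_ADJ_ATTR = "N/N"
TAG_NOUN = "N"
TAG_PREP = "(NP\\NP)/NP"
TAG_REL_SUBJ = "(NP\\NP)/(S\\NP)"
TAG_REL_OBJ = "(NP\\NP)/(S/NP)"
TAG_TVERB = "(S\\NP)/NP"
TAG_IVERB = "S\\NP"
TAG_COP = "(S\\NP)/ADJ"
TAG_ADJ_PRED = "ADJ"
TAG_CONJ = "conj"
TAG_PUNCT = "."

TAGSET = (
    TAG_DET, TAG_ADJ_ATTR, TAG_NOUN, TAG_PREP, TAG_REL_SUBJ, TAG_REL_OBJ,
    TAG_TVERB, TAG_IVERB, TAG_COP, TAG_ADJ_PRED, TAG_CONJ, TAG_PUNCT,
)

_DETERMINER_POOL = ("the", "some")
_PREPOSITION_POOL = ("to", "of", "on", "near", "with", "by", "at", "from")


class ConfigurationError(ValueError):
    """Raised when a GrammarConfig violates its invariants."""


class TaggingError(KeyError):
    """Raised when a token cannot be tagged by the grammar."""


@dataclass(frozen=True)
class GrammarConfig:
    """Lexicon sizes, construction probabilities and sampling seed.

    Probabilities are unconditional per-sentence rates; the generator
    rescales internally so that, e.g., the observed fraction of sentences
    with a PP subject modifier converges to ``p_pp_modifier`` even though
    disjunct subjects never take modifiers.
    """

    n_nouns: int = 30
    n_verbs: int = 20            # split evenly into transitive / intransitive
    n_prepositions: int = 6
    n_adjectives: int = 15
    n_determiners: int = 1
    p_pp_modifier: float = 0.15
    p_rc_modifier: float = 0.018
    p_nested_pp: float = 0.02
    p_disjunct_subject: float = 0.0035
    p_plural_subject: float = 0.3
    seed: int = 0
    # Secondary knobs (sentence-shape choices the construction rates above
    # do not pin down).
    p_object_rc: float = 0.25    # fraction of RC modifiers that are object relatives
    p_copula: float = 0.4        # predicate is copula + adjective
    p_adjective: float = 0.25    # attributive adjective inside an NP
    p_plural_np: float = 0.5     # plural rate for non-subject NPs

    def validate(self) -> None:
        probs = {
            "p_pp_modifier": self.p_pp_modifier,
            "p_rc_modifier": self.p_rc_modifier,
            "p_nested_pp": self.p_nested_pp,
            "p_disjunct_subject": self.p_disjunct_subject,
            "p_plural_subject": self.p_plural_subject,
            "p_object_rc": self.p_object_rc,
            "p_copula": self.p_copula,
            "p_adjective": self.p_adjective,
            "p_plural_np": self.p_plural_np,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} is not a probability")
        if self.p_nested_pp > self.p_pp_modifier:
            raise ConfigurationError(
                "p_nested_pp must not exceed p_pp_modifier (nesting occurs inside a PP)"
            )
        if self.p_pp_modifier + self.p_rc_modifier > 1.0 - self.p_disjunct_subject:
            raise ConfigurationError(
                "p_pp_modifier + p_rc_modifier must leave room for disjunct subjects"
            )
        for name in ("n_nouns", "n_verbs", "n_prepositions", "n_adjectives", "n_determiners"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_verbs < 2:
            raise ConfigurationError("n_verbs must be >= 2 (transitive and intransitive)")
        if self.n_determiners > len(_DETERMINER_POOL):
            raise ConfigurationError(f"at most {len(_DETERMINER_POOL)} determiners available")
        if self.n_prepositions > len(_PREPOSITION_POOL):
            raise ConfigurationError(f"at most {len(_PREPOSITION_POOL)} prepositions available")


@dataclass
class SentenceRecord:
    """One generated sentence plus its gold annotations."""

    tokens: list[str]
    supertags: list[str]
    subject_head_index: int
    verb_index: int
    subject_number: str                 # "sg" | "pl"
    verb_number: str
    attractor_indices: list[int] = field(default_factory=list)
    attractor_numbers: list[str] = field(default_factory=list)
    construction_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.supertags):
            raise ValueError("tokens and supertags must have equal length")
        n = len(self.tokens)
        for idx in [self.subject_head_index, self.verb_index, *self.attractor_indices]:
            if not (0 <= idx < n):
                raise ValueError(f"annotation index {idx} out of range for {n} tokens")


def _pseudoword_stems(n: int, offset: int = 0) -> list[str]:
    """Deterministic CVCV pseudoword stems, unique across the whole grammar."""
    onsets = "bdgklmnprtvz"
    vowels = "aeiou"
    stems = []
    k = offset
    while len(stems) < n:
        c1 = onsets[k % len(onsets)]
        v1 = vowels[(k // len(onsets)) % len(vowels)]
        c2 = onsets[(k // (len(onsets) * len(vowels))) % len(onsets)]
        v2 = vowels[(k // (len(onsets) * len(vowels) * len(onsets))) % len(vowels)]
        stems.append(c1 + v1 + c2 + v2)
        k += 1
    return stems


class Grammar:
    """Lexicalized toy grammar derived from a :class:`GrammarConfig`."""

    def __init__(self, config: GrammarConfig):
        config.validate()
        self.config = config
        n_total = config.n_nouns + config.n_verbs + config.n_adjectives
        stems = _pseudoword_stems(n_total)
        self.noun_stems = stems[: config.n_nouns]
        verb_stems = stems[config.n_nouns : config.n_nouns + config.n_verbs]
        half = (config.n_verbs + 1) // 2
        self.tverb_stems = verb_stems[:half]
        self.iverb_stems = verb_stems[half:]
        self.adjectives = stems[config.n_nouns + config.n_verbs :]
        self.determiners = list(_DETERMINER_POOL[: config.n_determiners])
        self.prepositions = list(_PREPOSITION_POOL[: config.n_prepositions])
        self.relativizer = "that"
        self.conjunction = "or"
        self.copula = {"sg": "is", "pl": "are"}
        self.tagset = list(TAGSET)
        self._tag_table = self._build_tag_table()

    # -- lexicon ---------------------------------------------------------
    def noun(self, stem: str, number: str) -> str:
        return stem + "s" if number == "pl" else stem

    def verb(self, stem: str, number: str) -> str:
        # English-style marking: 3sg verbs take -s, plurals are bare.
        return stem + "s" if number == "sg" else stem

    def _build_tag_table(self) -> dict[str, str]:
        table: dict[str, str] = {}
        for det in self.determiners:
            table[det] = TAG_DET
        for adj in self.adjectives:
            table[adj] = TAG_ADJ_ATTR  # context decides ADJ vs N/N; see tag_token
        for stem in self.noun_stems:
            table[stem] = TAG_NOUN
            table[stem + "s"] = TAG_NOUN
        for stem in self.tverb_stems:
            table[stem] = TAG_TVERB
            table[stem + "s"] = TAG_TVERB
        for stem in self.iverb_stems:
            table[stem] = TAG_IVERB
            table[stem + "s"] = TAG_IVERB
        for prep in self.prepositions:
            table[prep] = TAG_PREP
        table[self.conjunction] = TAG_CONJ
        table["is"] = TAG_COP
        table["are"] = TAG_COP
        table["."] = TAG_PUNCT
        # relativizer handled contextually
        return table

    def tag_token(self, tokens: Sequence[str], i: int) -> str:
        """Supertag for ``tokens[i]``; the lexicon is unambiguous except for
        the relativizer (subject vs. object relative, disambiguated by the
        following token) and adjectives (attributive vs. predicative,
        disambiguated by the preceding token)."""
        tok = tokens[i]
        if tok == self.relativizer:
            nxt = tokens[i + 1] if i + 1 < len(tokens) else ""
            return TAG_REL_OBJ if nxt in self.determiners else TAG_REL_SUBJ
        if tok in self._tag_table:
            tag = self._tag_table[tok]
            if tag == TAG_ADJ_ATTR and i > 0 and tokens[i - 1] in ("is", "are"):
                return TAG_ADJ_PRED
            return tag
        raise TaggingError(f"token {tok!r} is not generated by this grammar")

    def all_words(self) -> list[str]:
        words = set(self._tag_table)
        words.add(self.relativizer)
        return sorted(words)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_np(g: Grammar, rng: np.random.Generator, number: str) -> tuple[list[str], int]:
    """Sample determiner (+ adjective) + noun; return tokens and head offset."""
    toks = [g.determiners[rng.integers(len(g.determiners))]]
    if rng.random() < g.config.p_adjective:
        toks.append(g.adjectives[rng.integers(len(g.adjectives))])
    stem = g.noun_stems[rng.integers(len(g.noun_stems))]
    toks.append(g.noun(stem, number))
    return toks, len(toks) - 1


def _sample_number(rng: np.random.Generator, p_plural: float) -> str:
    return "pl" if rng.random() < p_plural else "sg"


def _generate_sentence(g: Grammar, rng: np.random.Generator) -> SentenceRecord:
    cfg = g.config
    flags: list[str] = []
    attractors: list[tuple[int, str]] = []

    subj_number = _sample_number(rng, cfg.p_plural_subject)
    disjunct = rng.random() < cfg.p_disjunct_subject

    tokens: list[str] = []
    if disjunct:
        flags.append("disjunct_subject")
        n1 = _sample_number(rng, cfg.p_plural_np)
        n2 = subj_number  # the linearly closer disjunct controls agreement
        np1, h1 = _sample_np(g, rng, n1)
        np2, h2 = _sample_np(g, rng, n2)
        tokens.extend(np1)
        attractors.append((h1, n1))
        tokens.append(g.conjunction)
        subj_head = len(tokens) + h2
        tokens.extend(np2)
    else:
        np_s, h = _sample_np(g, rng, subj_number)
        subj_head = h
        tokens.extend(np_s)
        # modifier choice rescaled so unconditional rates match the config
        scale = 1.0 - cfg.p_disjunct_subject
        u = rng.random()
        if u < cfg.p_pp_modifier / scale:
            flags.append("pp_modifier")
            tokens.append(g.prepositions[rng.integers(len(g.prepositions))])
            n_a = _sample_number(rng, cfg.p_plural_np)
            np_a, h_a = _sample_np(g, rng, n_a)
            attractors.append((len(tokens) + h_a, n_a))
            tokens.extend(np_a)
            if cfg.p_pp_modifier > 0 and rng.random() < cfg.p_nested_pp / cfg.p_pp_modifier:
                flags.append("nested_pp_modifier")
                tokens.append(g.prepositions[rng.integers(len(g.prepositions))])
                n_b = _sample_number(rng, cfg.p_plural_np)
                np_b, h_b = _sample_np(g, rng, n_b)
                attractors.append((len(tokens) + h_b, n_b))
                tokens.extend(np_b)
        elif u < (cfg.p_pp_modifier + cfg.p_rc_modifier) / scale:
            flags.append("rc_modifier")
            tokens.append(g.relativizer)
            if rng.random() < cfg.p_object_rc:
                flags.append("object_rc")
                n_e = _sample_number(rng, cfg.p_plural_np)
                np_e, h_e = _sample_np(g, rng, n_e)
                attractors.append((len(tokens) + h_e, n_e))
                tokens.extend(np_e)
                stem = g.tverb_stems[rng.integers(len(g.tverb_stems))]
                tokens.append(g.verb(stem, n_e))  # RC-internal agreement
            else:
                stem = g.tverb_stems[rng.integers(len(g.tverb_stems))]
                tokens.append(g.verb(stem, subj_number))
                n_o = _sample_number(rng, cfg.p_plural_np)
                np_o, h_o = _sample_np(g, rng, n_o)
                attractors.append((len(tokens) + h_o, n_o))
                tokens.extend(np_o)

    # predicate
    verb_index = len(tokens)
    u = rng.random()
    if u < cfg.p_copula:
        tokens.append(g.copula[subj_number])
        tokens.append(g.adjectives[rng.integers(len(g.adjectives))])
    elif u < cfg.p_copula + (1 - cfg.p_copula) / 2:
        stem = g.iverb_stems[rng.integers(len(g.iverb_stems))]
        tokens.append(g.verb(stem, subj_number))
    else:
        stem = g.tverb_stems[rng.integers(len(g.tverb_stems))]
        tokens.append(g.verb(stem, subj_number))
        n_o = _sample_number(rng, cfg.p_plural_np)
        np_o, _ = _sample_np(g, rng, n_o)
        tokens.extend(np_o)
    tokens.append(".")

    record = SentenceRecord(
        tokens=tokens,
        supertags=[g.tag_token(tokens, i) for i in range(len(tokens))],
        subject_head_index=subj_head,
        verb_index=verb_index,
        subject_number=subj_number,
        verb_number=subj_number,
        attractor_indices=[i for i, _ in attractors],
        attractor_numbers=[n for _, n in attractors],
        construction_flags=flags,
    )
    return record


def generate_corpus(config: GrammarConfig, n_sentences: int) -> list[SentenceRecord]:
    """Generate ``n_sentences`` agreement-respecting sentences.

    Deterministic given ``config.seed``; every sentence satisfies
    ``subject_number == verb_number``.
    """
    if n_sentences < 0:
        raise ValueError("n_sentences must be >= 0")
    g = Grammar(config)
    rng = np.random.default_rng(config.seed)
    return [_generate_sentence(g, rng) for _ in range(n_sentences)]


def assign_supertags(record: SentenceRecord, grammar: Grammar) -> list[str]:
    """Re-derive the supertag sequence for a generated sentence."""
    return [grammar.tag_token(record.tokens, i) for i in range(len(record.tokens))]


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

class Vocabulary:
    """Word-to-id map with reserved unknown / boundary symbols.

    ids are contiguous from 0 with ``<unk>``, ``<s>``, ``</s>`` first.
    """

    def __init__(self, words: Iterable[str], min_count: int = 1):
        self.min_count = min_count
        self.id2word: list[str] = [UNK, BOS, EOS]
        seen = set(self.id2word)
        for w in words:
            if w not in seen:
                seen.add(w)
                self.id2word.append(w)
        self.word2id = {w: i for i, w in enumerate(self.id2word)}
        self.unk_id = self.word2id[UNK]
        self.bos_id = self.word2id[BOS]
        self.eos_id = self.word2id[EOS]

    def __len__(self) -> int:
        return len(self.id2word)

    def __contains__(self, word: str) -> bool:
        return word in self.word2id

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.word2id.get(t, self.unk_id) for t in tokens], dtype=np.int64)

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.id2word[i] for i in ids]


def build_vocab(corpus: Sequence[SentenceRecord], min_count: int = 1) -> Vocabulary:
    """Vocabulary over all corpus tokens with count >= ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = collections.Counter(t for rec in corpus for t in rec.tokens)
    kept = sorted(w for w, c in counts.items() if c >= min_count)
    return Vocabulary(kept, min_count=min_count)


# ---------------------------------------------------------------------------
# construction statistics
# ---------------------------------------------------------------------------

def construction_counts(corpus: Sequence[SentenceRecord]):
    """Counts and per-sentence rates of the annotated constructions.

    Computed from generator annotations (no parsing).  Every sentence has a
    matrix subject-verb relation; relative clauses contribute one more.
    All verbs in the grammar are number-marked, so the number-marked count
    equals the relation count.
    """
    import pandas as pd

    n = len(corpus)
    rc = sum("rc_modifier" in r.construction_flags for r in corpus)
    rows = {
        "Sentences": n,
        "Subject-Verb relations": n + rc,
        "Number-marked agreement relations": n + rc,
        "RC subject modifiers": rc,
        "PP subject modifiers": sum("pp_modifier" in r.construction_flags for r in corpus),
        "Nested PP subject modifiers": sum(
            "nested_pp_modifier" in r.construction_flags for r in corpus
        ),
        "Disjunct subjects": sum("disjunct_subject" in r.construction_flags for r in corpus),
    }
    df = pd.DataFrame(
        {"count": list(rows.values())},
        index=pd.Index(rows.keys(), name="phenomenon"),
    )
    df["per_sentence"] = df["count"] / n if n else 0.0
    return df


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_corpus(corpus: Sequence[SentenceRecord], prefix: str | Path) -> None:
    """Write ``<prefix>.txt`` (sentences), ``<prefix>.tags.tsv`` (supertags)
    and ``<prefix>.jsonl`` (structural annotations)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.txt", "w") as ftxt, open(f"{prefix}.tags.tsv", "w") as ftag, open(
        f"{prefix}.jsonl", "w"
    ) as fjson:
        ftag.write("sentence_index\ttoken_index\ttoken\tsupertag\n")
        for si, rec in enumerate(corpus):
            ftxt.write(" ".join(rec.tokens) + "\n")
            for ti, (tok, tag) in enumerate(zip(rec.tokens, rec.supertags)):
                ftag.write(f"{si}\t{ti}\t{tok}\t{tag}\n")
            meta = asdict(rec)
            del meta["tokens"], meta["supertags"]
            fjson.write(json.dumps(meta) + "\n")


def read_corpus(prefix: str | Path) -> list[SentenceRecord]:
    prefix = Path(prefix)
    with open(f"{prefix}.txt") as f:
        sentences = [line.split() for line in f if line.strip()]
    tags: dict[int, dict[int, str]] = collections.defaultdict(dict)
    with open(f"{prefix}.tags.tsv") as f:
        next(f)
        for line in f:
            si, ti, _tok, tag = line.rstrip("\n").split("\t")
            tags[int(si)][int(ti)] = tag
    records = []
    with open(f"{prefix}.jsonl") as f:
        for si, line in enumerate(f):
            meta = json.loads(line)
            toks = sentences[si]
            records.append(
                SentenceRecord(
                    tokens=toks,
                    supertags=[tags[si][ti] for ti in range(len(toks))],
                    **meta,
                )
            )
    return records
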