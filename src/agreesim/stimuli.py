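"""Experimental items for the six agreement-attraction paradigms.

Production (sentence-completion) items are preambles — sentence prefixes up
to but excluding the verb — paired with a singular/plural candidate verb
pair (default *is*/*are*).  Reading items are full token sequences with a
critical-token index at which surprisal is measured.

Six paradigms are registered:

* ``bock_cutting`` — PP vs. RC subject modifiers, 2 (subject number) x
  2 (attractor match) x 2 (modifier type), completion.
* ``franck`` — stacked PPs ("the threat to the president of the company"),
  with a syntactically closer and a linearly closer attractor, completion.
* ``haskell`` — disjunct subjects ("the boy or the girls"), linear
  proximity of the plural disjunct, completion.
* ``humphreys`` — collective head noun with a plural local noun and a
  collective- vs. distributive-biased preposition, completion.
* ``parker_an`` — attractors in core vs. oblique arguments inside a
  subject relative clause, grammaticality manipulated at the matrix verb,
  self-paced reading.
* ``wagers`` — object relative clauses where the matrix head acts as an
  attractor for RC-internal agreement, grammaticality manipulated at the
  RC verb, self-paced reading.

Items generated from the toy grammar's lexicon are minimal pairs: cells of
an item differ only in the manipulated tokens.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import Grammar, Vocabulary
from .linking import CandidatePair

__all__ = [
    "ExperimentItem",
    "SubstitutionTable",
    "PARADIGMS",
    "load_items",
    "save_items",
    "apply_oov_policy",
    "generate_paradigm_items",
    "OOVSubstitutionError",
]

logger = logging.getLogger(__name__)


class OOVSubstitutionError(ValueError):
    """An NP-internal or manipulated out-of-vocabulary word has no curated
    substitute."""


@dataclass(frozen=True)
class ExperimentItem:
    paradigm: str
    item: int
    condition: Mapping[str, str]
    tokens: tuple[str, ...]
    np_flags: tuple[int, ...]            # 1: NP-internal or design-manipulated
    measure: str                          # "completion" | "reading"
    candidate: CandidatePair | None = None
    critical_index: int | None = None

    def __post_init__(self):
        if len(self.np_flags) != len(self.tokens):
            raise ValueError("np_flags must align with tokens")
        if self.measure == "completion" and self.candidate is None:
            raise ValueError("completion items need a candidate pair")
        if self.measure == "reading":
            if self.critical_index is None or not (0 <= self.critical_index < len(self.tokens)):
                raise ValueError("reading items need an in-range critical_index")
        spec = PARADIGMS.get(self.paradigm)
        if spec is not None:
            for factor, levels in spec["factors"].items():
                lev = self.condition.get(factor)
                if lev not in levels:
                    raise ValueError(
                        f"{self.paradigm}: factor {factor!r} has level {lev!r}, "
                        f"expected one of {levels}"
                    )


SubstitutionTable = dict  # OOV word -> curated in-vocabulary replacement


PARADIGMS: dict[str, dict] = {
    "bock_cutting": {
        "measure": "completion",
        "factors": {
            "subject_number": ("sg", "pl"),
            "attractor_match": ("match", "mismatch"),
            "modifier": ("pp", "rc"),
        },
    },
    "franck": {
        "measure": "completion",
        "factors": {
            "subject_number": ("sg", "pl"),
            "syntactic_match": ("match", "mismatch"),
            "linear_match": ("match", "mismatch"),
        },
    },
    "haskell": {
        "measure": "completion",
        "factors": {"closer_number": ("sg", "pl")},
    },
    "humphreys": {
        "measure": "completion",
        "factors": {"preposition_bias": ("collective", "distributive")},
    },
    "parker_an": {
        "measure": "reading",
        "factors": {
            "attractor_match": ("match", "mismatch"),
            "grammaticality": ("gram", "ungram"),
            "argument": ("core", "oblique"),
        },
    },
    "wagers": {
        "measure": "reading",
        "factors": {
            "attractor_match": ("match", "mismatch"),
            "grammaticality": ("gram", "ungram"),
        },
    },
}

_RESERVED_COLS = ("paradigm", "item", "tokens", "np_flags",
                  "candidate_sg", "candidate_pl", "critical_index")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def save_items(items: Sequence[ExperimentItem], path) -> None:
    path = Path(path)
    factors = sorted({f for it in items for f in it.condition})
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(list(_RESERVED_COLS) + factors)
        for it in items:
            w.writerow([
                it.paradigm, it.item, " ".join(it.tokens),
                ",".join(map(str, it.np_flags)),
                it.candidate.singular if it.candidate else "",
                it.candidate.plural if it.candidate else "",
                "" if it.critical_index is None else it.critical_index,
            ] + [it.condition.get(f, "") for f in factors])


def load_items(path) -> list[ExperimentItem]:
    """Load and validate items from the documented CSV schema."""
    path = Path(path)
    items = []
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: missing header")
        factor_cols = [c for c in reader.fieldnames if c not in _RESERVED_COLS]
        for row in reader:
            paradigm = row["paradigm"]
            if paradigm not in PARADIGMS:
                raise ValueError(f"unknown paradigm {paradigm!r}")
            spec = PARADIGMS[paradigm]
            tokens = tuple(row["tokens"].split())
            flags = tuple(int(x) for x in row["np_flags"].split(",")) if row["np_flags"] else (0,) * len(tokens)
            condition = {c: row[c] for c in factor_cols if row[c] != ""}
            missing = set(spec["factors"]) - set(condition)
            if missing:
                raise ValueError(f"{paradigm} item {row['item']}: missing factors {sorted(missing)}")
            candidate = None
            if spec["measure"] == "completion":
                candidate = CandidatePair(row["candidate_sg"] or "is", row["candidate_pl"] or "are")
            crit = None
            if row.get("critical_index"):
                try:
                    crit = int(row["critical_index"])
                except ValueError as e:
                    raise ValueError(f"malformed critical_index {row['critical_index']!r}") from e
            items.append(ExperimentItem(
                paradigm=paradigm, item=int(row["item"]), condition=condition,
                tokens=tokens, np_flags=flags, measure=spec["measure"],
                candidate=candidate, critical_index=crit,
            ))
    return items


# ---------------------------------------------------------------------------
# OOV policy
# ---------------------------------------------------------------------------

def apply_oov_policy(item: ExperimentItem, vocab: Vocabulary,
                     table: SubstitutionTable | None = None,
                     np_token_flags: Sequence[int] | None = None,
                     ) -> tuple[ExperimentItem, list[tuple[int, str, str]]]:
    """Sanitize an item against a model vocabulary.

    Out-of-vocabulary tokens that are NP-internal or design-manipulated
    (``np_flags == 1``) must have a curated, semantically similar substitute
    in ``table`` — substituting the unknown token would destroy number
    information — otherwise a hard error names the word.  Other OOV tokens
    are replaced with the unknown token.  Idempotent; returns the sanitized
    item and a change log of ``(position, old, new)``.
    """
    flags = tuple(np_token_flags) if np_token_flags is not None else item.np_flags
    if len(flags) != len(item.tokens):
        raise ValueError("np_token_flags must align with tokens")
    table = table or {}
    new_tokens = list(item.tokens)
    log: list[tuple[int, str, str]] = []
    for i, tok in enumerate(item.tokens):
        if tok in vocab:
            continue
        if flags[i]:
            if tok not in table:
                raise OOVSubstitutionError(
                    f"no curated substitute for NP-internal/manipulated OOV word {tok!r}"
                )
            repl = table[tok]
            if repl not in vocab:
                raise OOVSubstitutionError(
                    f"substitute {repl!r} for {tok!r} is itself out of vocabulary"
                )
        else:
            repl = vocab.id2word[vocab.unk_id]
        new_tokens[i] = repl
        log.append((i, tok, repl))
        logger.info("OOV substitution in %s item %d: %r -> %r at %d",
                    item.paradigm, item.item, tok, repl, i)
    if not log:
        return item, []
    return replace(item, tokens=tuple(new_tokens)), log


# ---------------------------------------------------------------------------
# template generators over the toy lexicon
# ---------------------------------------------------------------------------

def _pick_distinct(rng, pool, k):
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[int(i)] for i in idx]


def _opp(num: str) -> str:
    return "pl" if num == "sg" else "sg"


def generate_paradigm_items(paradigm: str, grammar: Grammar, n_items: int,
                            seed: int = 0) -> list[ExperimentItem]:
    """Full factorial item sets over the toy grammar's lexicon.

    Every item appears in every condition cell; cells of an item are
    minimal pairs differing only in the manipulated tokens.  All tokens are
    drawn from the grammar, so toy pipelines are OOV-free by construction.
    """
    import numpy as np

    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    spec = PARADIGMS[paradigm]
    rng = np.random.default_rng(seed)
    g = grammar
    det = g.determiners[0]
    pair = CandidatePair("is", "are")
    n_nouns_needed = {"franck": 3}.get(paradigm, 2)
    if len(g.noun_stems) < n_nouns_needed + 1 or n_items < 1:
        raise ValueError("lexicon too small for distinct item frames")
    max_frames = len(g.noun_stems) * (len(g.noun_stems) - 1)
    if n_items > max_frames:
        raise ValueError(f"lexicon supports at most {max_frames} distinct frames")

    items: list[ExperimentItem] = []
    seen_frames: set[tuple] = set()
    item_id = 0
    attempts = 0
    while item_id < n_items:
        attempts += 1
        if attempts > 100 * n_items:
            raise ValueError("could not sample enough distinct item frames")
        nouns = _pick_distinct(rng, g.noun_stems, n_nouns_needed)
        tverb = g.tverb_stems[int(rng.integers(len(g.tverb_stems)))]
        iverb = g.iverb_stems[int(rng.integers(len(g.iverb_stems)))]
        prep = g.prepositions[int(rng.integers(len(g.prepositions)))]
        prep2 = g.prepositions[int(rng.integers(len(g.prepositions)))]
        adj = g.adjectives[int(rng.integers(len(g.adjectives)))]
        frame = (paradigm, *nouns, tverb, iverb, prep, prep2)
        if frame in seen_frames:
            continue
        seen_frames.add(frame)

        cells = list(itertools.product(*spec["factors"].values()))
        names = list(spec["factors"].keys())
        for levels in cells:
            cond = dict(zip(names, levels))
            it = _build_item(paradigm, item_id, cond, g, det, nouns, tverb,
                             iverb, prep, prep2, adj, pair)
            items.append(it)
        item_id += 1
    return items


def _build_item(paradigm, item_id, cond, g: Grammar, det, nouns, tverb, iverb,
                prep, prep2, adj, pair) -> ExperimentItem:
    n = g.noun
    v = g.verb
    if paradigm == "bock_cutting":
        ns = cond["subject_number"]
        na = ns if cond["attractor_match"] == "match" else _opp(ns)
        if cond["modifier"] == "pp":
            tokens = [det, n(nouns[0], ns), prep, det, n(nouns[1], na)]
            flags = [1, 1, 0, 1, 1]
        else:
            tokens = [det, n(nouns[0], ns), g.relativizer, v(tverb, ns), det, n(nouns[1], na)]
            flags = [1, 1, 0, 0, 1, 1]
        return ExperimentItem(paradigm, item_id, cond, tuple(tokens), tuple(flags),
                              "completion", candidate=pair)
    if paradigm == "franck":
        ns = cond["subject_number"]
        n2 = ns if cond["syntactic_match"] == "match" else _opp(ns)
        n3 = ns if cond["linear_match"] == "match" else _opp(ns)
        tokens = [det, n(nouns[0], ns), prep, det, n(nouns[1], n2), prep2, det, n(nouns[2], n3)]
        flags = [1, 1, 0, 1, 1, 0, 1, 1]
        return ExperimentItem(paradigm, item_id, cond, tuple(tokens), tuple(flags),
                              "completion", candidate=pair)
    if paradigm == "haskell":
        far, close = ("pl", "sg") if cond["closer_number"] == "sg" else ("sg", "pl")
        tokens = [det, n(nouns[0], far), g.conjunction, det, n(nouns[1], close)]
        flags = [1, 1, 0, 1, 1]
        return ExperimentItem(paradigm, item_id, cond, tuple(tokens), tuple(flags),
                              "completion", candidate=pair)
    if paradigm == "humphreys":
        # collective-biased "near" vs. distributive-biased "on"; head noun
        # singular, local noun plural, as in the original design
        p = "near" if cond["preposition_bias"] == "collective" else "on"
        tokens = [det, n(nouns[0], "sg"), p, det, n(nouns[1], "pl")]
        flags = [1, 1, 1, 1, 1]  # the preposition is design-manipulated
        return ExperimentItem(paradigm, item_id, cond, tuple(tokens), tuple(flags),
                              "completion", candidate=pair)
    if paradigm == "parker_an":
        ns = "sg"  # subject always singular in this design
        na = ns if cond["attractor_match"] == "match" else _opp(ns)
        cop = "is" if cond["grammaticality"] == "gram" else "are"
        if cond["argument"] == "core":
            rc = [g.relativizer, v(tverb, ns), det, n(nouns[1], na)]
            rc_flags = [0, 0, 1, 1]
        else:
            rc = [g.relativizer, v(iverb, ns), prep, det, n(nouns[1], na)]
            rc_flags = [0, 0, 0, 1, 1]
        tokens = [det, n(nouns[0], ns)] + rc + [cop, adj, "."]
        flags = [1, 1] + rc_flags + [1, 0, 0]
        crit = len(tokens) - 3
        return ExperimentItem(paradigm, item_id, cond, tuple(tokens), tuple(flags),
                              "reading", critical_index=crit)
    if paradigm == "wagers":
        # object relative: RC-internal subject (singular) agrees with the RC
        # verb; the matrix head is the attractor
        ns = "sg"
        na = ns if cond["attractor_match"] == "match" else _opp(ns)
        vn = ns if cond["grammaticality"] == "gram" else _opp(ns)
        tokens = [det, n(nouns[0], na), g.relativizer, det, n(nouns[1], ns), v(tverb, vn)]
        flags = [1, 1, 0, 1, 1, 1]
        crit = len(tokens) - 1
        return ExperimentItem(paradigm, item_id, cond, tuple(tokens), tuple(flags),
                              "reading", critical_index=crit)
    raise ValueError(paradigm)
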