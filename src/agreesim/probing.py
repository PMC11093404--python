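"""Representation analyses: unit ablation and amnesic (nullspace) probing.

The ablation sweep zeroes each final-layer unit in turn and records the
held-out word-prediction and supertagging losses, quantifying how much the
two tasks share localized features (their correlation across units).

Amnesic probing removes *distributed* information instead: given a linear
supertag classifier with weights ``W``, the orthogonal projector
``T = I - W^+ W`` maps hidden vectors onto the nullspace of ``W``, so the
classifier's input-dependent logit component vanishes (``W T x = 0`` for
every x) and its predictions collapse to the constant implied by the bias.
Applying ``T`` to all encoder outputs at evaluation time — a single
nullspace-projection step, with no retraining — measures how much
word prediction relied on the information the probe used.

A frozen-encoder probe (a linear classifier trained on the representations
of a word-prediction-only model) provides the baseline: the tag-relevant
information present without any supertagging supervision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import SentenceRecord
from .neural_lm import LanguageModel, score_corpus, ablate_unit, _prepare_sentences, _make_batches

__all__ = [
    "LinearProbe",
    "NullspaceProjector",
    "AblationRecord",
    "ablation_sweep",
    "nullspace_projector",
    "amnesic_eval",
    "train_frozen_probe",
    "decoder_probe",
    "amnesic_report",
]

logger = logging.getLogger(__name__)

SVD_CUTOFF = 1e-10  # relative singular-value cutoff for the pseudo-inverse


@dataclass(frozen=True)
class LinearProbe:
    """Linear supertag classifier: logits = h @ W.T + b."""

    W: np.ndarray      # (tagset, hidden)
    b: np.ndarray      # (tagset,)
    tagset: tuple[str, ...]

    def __post_init__(self):
        if self.W.shape[0] != len(self.tagset) or self.W.shape[0] != len(self.b):
            raise ValueError("probe shapes inconsistent with tagset")

    def predict(self, h: np.ndarray) -> np.ndarray:
        return (h @ self.W.T + self.b).argmax(axis=-1)


@dataclass(frozen=True)
class NullspaceProjector:
    """Orthogonal projector onto the nullspace of a probe's weight matrix."""

    T: np.ndarray
    rank_deficit: int  # rank(W)

    def __call__(self, h: np.ndarray) -> np.ndarray:
        return h @ self.T


@dataclass(frozen=True)
class AblationRecord:
    unit: int
    word_loss: float   # mean word cross-entropy (nats), unit zeroed
    tag_loss: float    # mean supertag cross-entropy (nats), unit zeroed


def decoder_probe(model: LanguageModel) -> LinearProbe:
    """The model's own trained supertag decoder viewed as a probe."""
    if not model.has_tag_decoder:
        raise ValueError("model has no supertag decoder")
    return LinearProbe(W=model.params["Wt"].T.astype(np.float64),
                       b=model.params["bt"].astype(np.float64),
                       tagset=tuple(model.tagset))


# ---------------------------------------------------------------------------
# ablation sweep
# ---------------------------------------------------------------------------

def ablation_sweep(model: LanguageModel, eval_corpus: list[SentenceRecord],
                   ) -> tuple[list[AblationRecord], float, dict]:
    """Zero each final-layer unit in turn; record both held-out losses.

    Returns ``(records, pearson_r, baseline)`` where ``baseline`` holds the
    un-ablated losses (the dashed-line reference).
    """
    if not model.has_tag_decoder:
        raise ValueError("ablation sweep requires a multitask model")
    if not all(rec.supertags for rec in eval_corpus):
        raise ValueError("eval corpus must be tagged")
    layer = model.config.num_layers - 1

    def losses(m):
        agg = score_corpus(m, eval_corpus)
        return (agg["word_nll"] / max(agg["n_word"], 1.0),
                agg["tag_nll"] / max(agg["n_tag"], 1.0))

    base_w, base_t = losses(model)
    records = []
    for j in range(model.config.hidden_size):
        w, t = losses(ablate_unit(model, layer, j))
        records.append(AblationRecord(unit=j, word_loss=w, tag_loss=t))
    ws = np.array([r.word_loss for r in records])
    ts = np.array([r.tag_loss for r in records])
    if np.std(ws) == 0.0 or np.std(ts) == 0.0:
        r = float("nan")
    else:
        r = float(np.corrcoef(ws, ts)[0, 1])
    return records, r, {"word_loss": base_w, "tag_loss": base_t}


# ---------------------------------------------------------------------------
# nullspace projection
# ---------------------------------------------------------------------------

def nullspace_projector(probe: LinearProbe) -> NullspaceProjector:
    """``T = I - W^+ W``: symmetric, idempotent, and ``W T = 0``.

    If ``W`` has full column rank (hidden dim <= number of tags) the
    projector is identically zero — warned, not an error.
    """
    W = np.asarray(probe.W, dtype=np.float64)
    if not np.any(W):
        raise ValueError("probe weight matrix is zero")
    d = W.shape[1]
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    rank = int(np.sum(s > SVD_CUTOFF * s[0]))
    if rank >= d:
        logger.warning("probe has full column rank: projector is 0")
    V1 = Vt[:rank]                      # row space basis of W
    T = np.eye(d) - V1.T @ V1
    return NullspaceProjector(T=T, rank_deficit=rank)


def _frozen_states(model: LanguageModel, corpus, tagset: list[str] | None = None,
                   batch_size=128):
    """Final-layer hidden states and tag ids at real-token positions.

    ``tagset`` fixes the tag-id order (defaults to the model's own tagset,
    else the sorted corpus tagset)."""
    if tagset is None:
        tagset = model.tagset if model.has_tag_decoder else _corpus_tagset(corpus)
    tag2id = {t: i for i, t in enumerate(tagset)}
    prepared = _prepare_sentences(corpus, model.vocab, tag2id)
    batches = _make_batches(prepared, batch_size, model.vocab.eos_id)
    hs_all, tags_all = [], []
    for ids_in, targets, wmask, tags, tagmask in batches:
        hs, _, _ = model._encode(ids_in)
        hs = model._decode_hidden(hs)
        sel = tagmask.reshape(-1) > 0
        hs_all.append(hs.reshape(-1, hs.shape[-1])[sel])
        tags_all.append(tags.reshape(-1)[sel])
    return np.concatenate(hs_all), np.concatenate(tags_all), list(tagset)


def _corpus_tagset(corpus) -> list[str]:
    return sorted({t for rec in corpus for t in rec.supertags})


def train_frozen_probe(model: LanguageModel, tagged_corpus: list[SentenceRecord],
                       seed: int = 0, max_iter: int = 500) -> LinearProbe:
    """Train a linear supertag classifier on a frozen encoder.

    Only the probe's weights are optimized (multinomial logistic
    regression); the encoder parameters are untouched, which the encoder
    checksum test asserts.  Intended for word-prediction-only models, to
    bound how much tag information word prediction alone induces.
    """
    if model.has_tag_decoder:
        raise ValueError("frozen probe expects a model without a supertag decoder")
    from sklearn.linear_model import LogisticRegression

    H, yt, tagset = _frozen_states(model, tagged_corpus)
    present = np.unique(yt)
    clf = LogisticRegression(max_iter=max_iter, C=10.0, random_state=seed)
    clf.fit(H.astype(np.float64), yt)
    W = np.zeros((len(tagset), H.shape[1]))
    b = np.full(len(tagset), -1e3)  # absent tags get a large negative bias
    W[present] = clf.coef_ if len(present) > 2 else np.vstack([-clf.coef_, clf.coef_])
    b[present] = clf.intercept_ if len(present) > 2 else np.array(
        [-clf.intercept_[0], clf.intercept_[0]])
    return LinearProbe(W=W, b=b, tagset=tuple(tagset))


def _probe_accuracy(probe: LinearProbe, H: np.ndarray, yt: np.ndarray) -> float:
    return float((probe.predict(H) == yt).mean())


def amnesic_eval(model: LanguageModel, projector: NullspaceProjector,
                 eval_corpus: list[SentenceRecord],
                 probe: LinearProbe | None = None) -> dict:
    """Word-prediction loss and supertag accuracy before/after projection.

    The supertag accuracy after projection is computed with the same
    classifier (the model's decoder or the supplied probe); because
    ``W T = 0`` its post-projection predictions are constant, so accuracy
    equals the empirical rate of the tag the bias prefers.
    """
    d = model.config.hidden_size
    if projector.T.shape != (d, d):
        raise ValueError("projector width does not match encoder output")
    probe = probe if probe is not None else decoder_probe(model)

    H, yt, tagset = _frozen_states(model, eval_corpus, tagset=list(probe.tagset))
    out = {}
    for condition, view in (("baseline", model),
                            ("amnesic", model.view(transform=projector.T))):
        agg = score_corpus(view, eval_corpus)
        Hc = H @ projector.T if condition == "amnesic" else H
        out[condition] = {
            "lm_loss": agg["word_nll"] / max(agg["n_word"], 1.0),
            "ccg_accuracy": _probe_accuracy(probe, Hc, yt),
        }
    return out


def amnesic_report(multitask_model: LanguageModel, lm_only_model: LanguageModel,
                   eval_corpus: list[SentenceRecord], train_corpus_for_probe=None,
                   seed: int = 0) -> pd.DataFrame:
    """The 4-row before/after report: (LM+CCG, LM-Only) x (baseline, amnesic).

    The LM+CCG rows use the model's own supertag decoder; the LM-Only rows
    use a probe trained on its frozen representations (on
    ``train_corpus_for_probe``, defaulting to the eval corpus).
    """
    rows = []
    dec_probe = decoder_probe(multitask_model)
    proj_mt = nullspace_projector(dec_probe)
    res = amnesic_eval(multitask_model, proj_mt, eval_corpus, probe=dec_probe)
    for cond in ("baseline", "amnesic"):
        rows.append({"model_variant": "LM+CCG", "condition": cond, **res[cond]})

    frozen = train_frozen_probe(lm_only_model,
                                train_corpus_for_probe or eval_corpus, seed=seed)
    proj_lm = nullspace_projector(frozen)
    res = amnesic_eval(lm_only_model, proj_lm, eval_corpus, probe=frozen)
    for cond in ("baseline", "amnesic"):
        rows.append({"model_variant": "LM-Only", "condition": cond, **res[cond]})
    return pd.DataFrame(rows, columns=["model_variant", "condition", "lm_loss", "ccg_accuracy"])
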