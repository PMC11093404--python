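"""Word-level recurrent language models in NumPy.

Two encoder families are provided: the simple recurrent network, whose
state update is ``h_i = tanh(W_h h_{i-1} + W_w w_i)``, and the LSTM with
standard input/forget/output gating.  A linear decoder maps the final
hidden layer to next-word logits; an optional second linear decoder maps
the same representation to a supertag distribution for the current word,
enabling multi-task (word prediction + supertagging) training with
configurable task weights (equal by default).

Everything — forward passes, backpropagation through time, SGD with
learning-rate annealing — is implemented directly on NumPy arrays, which
is adequate at the scales this package targets (2-layer encoders with
tens to hundreds of units, vocabularies of a few hundred words).
Gradient correctness is enforced by a finite-difference test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import SentenceRecord, Vocabulary

__all__ = [
    "EncoderConfig",
    "TrainConfig",
    "LanguageModel",
    "UnigramModel",
    "srn_step",
    "lstm_step",
    "next_word_distribution",
    "next_word_distribution_batch",
    "train",
    "train_instances",
    "perplexity",
    "supertag_accuracy",
    "ablate_unit",
    "score_corpus",
    "TrainingDivergedError",
]

LOG2E = math.log2(math.e)


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class EncoderConfig:
    architecture: str = "lstm"      # "srn" | "lstm"
    num_layers: int = 2
    hidden_size: int = 650
    embedding_size: int = 650

    def __post_init__(self):
        if self.architecture not in ("srn", "lstm"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        for name in ("num_layers", "hidden_size", "embedding_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 12
    learning_rate: float = 1.0
    lr_decay: float = 0.5           # multiply lr by this when validation stalls
    batch_size: int = 64
    bptt_length: int | None = None  # None: backpropagate through full sentences
    weight_word: float = 0.5
    weight_tag: float = 0.5         # ignored for models without a tag decoder
    grad_clip: float = 5.0
    dropout: float = 0.0
    val_fraction: float = 0.05
    seed: int = 0
    n_instances: int = 5

    def __post_init__(self):
        if self.weight_word < 0 or self.weight_tag < 0:
            raise ValueError("task weights must be >= 0")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# elementary steps (exposed for direct inspection and unit tests)
# ---------------------------------------------------------------------------

def srn_step(h_prev: np.ndarray, w: np.ndarray, W_h: np.ndarray, W_w: np.ndarray,
             b: np.ndarray | None = None) -> np.ndarray:
    """``tanh(W_h h_prev + W_w w [+ b])``; accepts (H,) vectors or (B, H) batches."""
    z = h_prev @ W_h + w @ W_w
    if b is not None:
        z = z + b
    return np.tanh(z)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_step(state: tuple[np.ndarray, np.ndarray], w: np.ndarray,
              W_x: np.ndarray, W_h: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update; ``state = (h, c)``; gate order i, f, o, g:

    ``c' = sigma(z_f) * c + sigma(z_i) * tanh(z_g)``,
    ``h' = sigma(z_o) * tanh(c')`` with ``z = w W_x + h W_h + b``.
    """
    h_prev, c_prev = state
    H = h_prev.shape[-1]
    z = w @ W_x + h_prev @ W_h + b
    i = _sigmoid(z[..., :H])
    f = _sigmoid(z[..., H:2 * H])
    o = _sigmoid(z[..., 2 * H:3 * H])
    g = np.tanh(z[..., 3 * H:])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class LanguageModel:
    """Embeddings + recurrent encoder + word decoder (+ optional tag decoder).

    ``mask`` and ``transform``, when set on a view, are applied to the
    final-layer hidden vector before both decoders (transform first, then
    mask); they implement amnesic projection and unit ablation as
    evaluation-time views that share parameters with the base model.
    """

    def __init__(self, vocab: Vocabulary, config: EncoderConfig,
                 tagset: Sequence[str] | None = None, seed: int = 0,
                 dtype=np.float32):
        self.vocab = vocab
        self.config = config
        self.tagset = list(tagset) if tagset is not None else None
        self.tag2id = {t: i for i, t in enumerate(self.tagset)} if self.tagset else None
        self.dtype = dtype
        self.mask: np.ndarray | None = None
        self.transform: np.ndarray | None = None
        rng = np.random.default_rng(seed)
        V, E, H, L = len(vocab), config.embedding_size, config.hidden_size, config.num_layers
        gate = 4 * H if config.architecture == "lstm" else H

        def u(*shape):
            return rng.uniform(-0.1, 0.1, size=shape).astype(dtype)

        p: dict[str, np.ndarray] = {"emb": u(V, E)}
        for l in range(L):
            in_dim = E if l == 0 else H
            p[f"Wx{l}"] = u(in_dim, gate)
            p[f"Wh{l}"] = u(H, gate)
            p[f"b{l}"] = np.zeros(gate, dtype=dtype)
            if config.architecture == "lstm":
                p[f"b{l}"][H:2 * H] = 1.0  # forget-gate bias keeps early memory alive
        p["Wd"] = u(H, V)
        p["bd"] = np.zeros(V, dtype=dtype)
        if self.tagset is not None:
            p["Wt"] = u(H, len(self.tagset))
            p["bt"] = np.zeros(len(self.tagset), dtype=dtype)
        self.params = p

    # -- views -------------------------------------------------------------
    def view(self, mask: np.ndarray | None = None,
             transform: np.ndarray | None = None) -> "LanguageModel":
        """Non-destructive evaluation view sharing this model's parameters."""
        m = object.__new__(LanguageModel)
        m.__dict__.update(self.__dict__)
        if mask is not None:
            mask = np.asarray(mask, dtype=self.dtype)
            if mask.shape != (self.config.hidden_size,):
                raise ValueError("mask must have shape (hidden_size,)")
            if not np.all(np.isin(mask, (0.0, 1.0))):
                raise ValueError("mask entries must be 0 or 1")
        m.mask = mask
        m.transform = None if transform is None else np.asarray(transform, dtype=self.dtype)
        return m

    @property
    def has_tag_decoder(self) -> bool:
        return self.tagset is not None

    def parameter_checksum(self, keys: Sequence[str] | None = None) -> float:
        keys = sorted(self.params) if keys is None else list(keys)
        return float(sum(np.abs(self.params[k].astype(np.float64)).sum() for k in keys))

    def encoder_keys(self) -> list[str]:
        return [k for k in sorted(self.params) if k not in ("Wd", "bd", "Wt", "bt")]

    # -- encoder forward ----------------------------------------------------
    def _encode(self, ids: np.ndarray, h0=None, need_cache: bool = False,
                drop_rngs=None, dropout: float = 0.0):
        """Run the encoder over an id batch (B, T).

        Returns (hs_final, cache, final_state); ``final_state`` is a list of
        per-layer (h, c) pairs for BPTT-truncated continuation.
        """
        p, cfg = self.params, self.config
        B, T = ids.shape
        H, L = cfg.hidden_size, cfg.num_layers
        lstm = cfg.architecture == "lstm"
        inp = p["emb"][ids]  # (B, T, E)
        cache = {"ids": ids, "layers": [], "drop_masks": [], "inp0": inp}
        final_state = []
        for l in range(L):
            Wx, Wh, b = p[f"Wx{l}"], p[f"Wh{l}"], p[f"b{l}"]
            if h0 is not None:
                h, c = h0[l]
            else:
                h = np.zeros((B, H), dtype=self.dtype)
                c = np.zeros((B, H), dtype=self.dtype)
            z_in = inp @ Wx + b
            hs = np.empty((B, T, H), dtype=self.dtype)
            lc = None
            if need_cache:
                lc = {
                    "inp": inp,
                    "h_prev": np.empty((B, T, H), dtype=self.dtype),
                }
                if lstm:
                    for key in ("i", "f", "o", "g", "c_prev", "c"):
                        lc[key] = np.empty((B, T, H), dtype=self.dtype)
            for t in range(T):
                if need_cache:
                    lc["h_prev"][:, t] = h
                z = z_in[:, t] + h @ Wh
                if lstm:
                    i = _sigmoid(z[:, :H])
                    f = _sigmoid(z[:, H:2 * H])
                    o = _sigmoid(z[:, 2 * H:3 * H])
                    g = np.tanh(z[:, 3 * H:])
                    c_new = f * c + i * g
                    h_new = o * np.tanh(c_new)
                    if need_cache:
                        lc["i"][:, t] = i
                        lc["f"][:, t] = f
                        lc["o"][:, t] = o
                        lc["g"][:, t] = g
                        lc["c_prev"][:, t] = c
                        lc["c"][:, t] = c_new
                    h, c = h_new, c_new
                else:
                    h = np.tanh(z)
                hs[:, t] = h
            if not lstm and need_cache:
                lc["h"] = hs
            cache["layers"].append(lc)
            final_state.append((h, c))
            if dropout > 0.0 and drop_rngs is not None:
                dm = (drop_rngs.random(hs.shape) >= dropout).astype(self.dtype) / (1.0 - dropout)
                hs = hs * dm
                cache["drop_masks"].append(dm)
            else:
                cache["drop_masks"].append(None)
            inp = hs
        return inp, cache, final_state

    def _decode_hidden(self, hs: np.ndarray) -> np.ndarray:
        """Apply the view's transform/mask to final hidden states."""
        if self.transform is not None:
            hs = hs @ self.transform
        if self.mask is not None:
            hs = hs * self.mask
        return hs

    # -- public inference ----------------------------------------------------
    def next_word_distribution(self, prefix: Sequence[str]) -> np.ndarray:
        """P(next word | prefix); prefix may be empty (start of sentence)."""
        return next_word_distribution_batch(self, [list(prefix)])[0]

    def token_log2probs(self, tokens: Sequence[str], include_eos: bool = False) -> np.ndarray:
        """log2 P(token_i | token_0..i-1) for each token (optionally + </s>)."""
        ids = self.vocab.encode(list(tokens))
        ids_in = np.concatenate([[self.vocab.bos_id], ids])[None, :]
        hs, _, _ = self._encode(ids_in)
        hs = self._decode_hidden(hs)
        # decode in float64 so surprisals satisfy the chain rule tightly
        logits = hs[0].astype(np.float64) @ self.params["Wd"] + self.params["bd"]
        logp = logits - _logsumexp(logits)
        targets = np.concatenate([ids, [self.vocab.eos_id]])
        vals = logp[np.arange(len(targets)), targets] * LOG2E
        return vals if include_eos else vals[:-1]


def _logsumexp(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    return m + np.log(np.exp(logits - m).sum(axis=-1, keepdims=True))


def next_word_distribution(model, prefix: Sequence[str]) -> np.ndarray:
    """Probability vector over the vocabulary for the next word.

    Works for any object exposing ``next_word_distribution``; provided as a
    module-level function for symmetry with the other operations.
    """
    return model.next_word_distribution(list(prefix))


def next_word_distribution_batch(model: LanguageModel, prefixes: list[list[str]]) -> np.ndarray:
    """Batched next-word distributions after each prefix (empty allowed)."""
    lengths = np.array([len(p) + 1 for p in prefixes])
    T = int(lengths.max())
    B = len(prefixes)
    ids = np.full((B, T), model.vocab.eos_id, dtype=np.int64)
    for b, pre in enumerate(prefixes):
        ids[b, 0] = model.vocab.bos_id
        ids[b, 1:1 + len(pre)] = model.vocab.encode(pre)
    hs, _, _ = model._encode(ids)
    hs = model._decode_hidden(hs)
    h_last = hs[np.arange(B), lengths - 1].astype(np.float64)  # (B, H)
    logits = h_last @ model.params["Wd"] + model.params["bd"]
    return _softmax(logits)


# ---------------------------------------------------------------------------
# loss + gradients
# ---------------------------------------------------------------------------

def batch_token_log2probs(model: LanguageModel, token_lists: list[list[str]]) -> list[np.ndarray]:
    """Per-token ``log2 P(token_i | prefix)`` for many sentences at once."""
    B = len(token_lists)
    lengths = np.array([len(t) for t in token_lists])
    T = int(lengths.max()) + 1
    ids_in = np.full((B, T), model.vocab.eos_id, dtype=np.int64)
    targets = np.full((B, T), model.vocab.eos_id, dtype=np.int64)
    for b, toks in enumerate(token_lists):
        ids = model.vocab.encode(toks)
        ids_in[b, 0] = model.vocab.bos_id
        ids_in[b, 1:1 + len(ids)] = ids
        targets[b, :len(ids)] = ids
    hs, _, _ = model._encode(ids_in)
    hs = model._decode_hidden(hs)
    flat = hs.reshape(B * T, -1).astype(np.float64)
    logits = flat @ model.params["Wd"] + model.params["bd"]
    logp = (logits - _logsumexp(logits)).reshape(B, T, -1)
    out = []
    for b in range(B):
        n = lengths[b]
        out.append(logp[b, np.arange(n), targets[b, :n]] * LOG2E)
    return out


def _batch_loss_and_grads(model: LanguageModel, ids_in, targets, wmask,
                          tag_targets=None, tag_mask=None,
                          weight_word=1.0, weight_tag=0.0,
                          drop_rngs=None, dropout=0.0):
    """Combined loss (nats) and parameter gradients for one padded batch.

    Loss = weight_word * mean word CE + weight_tag * mean tag CE, means
    taken over the non-pad tokens in the batch.
    """
    p, cfg = model.params, model.config
    B, T = ids_in.shape
    H, L = cfg.hidden_size, cfg.num_layers
    lstm = cfg.architecture == "lstm"
    hs, cache, _ = model._encode(ids_in, need_cache=True, drop_rngs=drop_rngs, dropout=dropout)

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    n_word = max(float(wmask.sum()), 1.0)
    flat_h = hs.reshape(B * T, H)

    # word decoder
    logits = flat_h @ p["Wd"] + p["bd"]
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    tflat = targets.reshape(-1)
    mflat = wmask.reshape(-1).astype(model.dtype)
    nll = -np.log(np.maximum(probs[np.arange(B * T), tflat], 1e-30)) * mflat
    loss_word = float(nll.sum()) / n_word
    dlogits = probs.astype(model.dtype)
    dlogits[np.arange(B * T), tflat] -= 1.0
    dlogits *= (mflat * (weight_word / n_word))[:, None]
    grads["Wd"] = flat_h.T @ dlogits
    grads["bd"] = dlogits.sum(axis=0)
    dhs = (dlogits @ p["Wd"].T).reshape(B, T, H)

    loss_tag = 0.0
    if tag_targets is not None and model.has_tag_decoder and weight_tag > 0.0:
        n_tag = max(float(tag_mask.sum()), 1.0)
        tlogits = flat_h @ p["Wt"] + p["bt"]
        tlogits -= tlogits.max(axis=1, keepdims=True)
        texp = np.exp(tlogits)
        tprobs = texp / texp.sum(axis=1, keepdims=True)
        ttflat = tag_targets.reshape(-1)
        tmflat = tag_mask.reshape(-1).astype(model.dtype)
        tnll = -np.log(np.maximum(tprobs[np.arange(B * T), ttflat], 1e-30)) * tmflat
        loss_tag = float(tnll.sum()) / n_tag
        dtl = tprobs.astype(model.dtype)
        dtl[np.arange(B * T), ttflat] -= 1.0
        dtl *= (tmflat * (weight_tag / n_tag))[:, None]
        grads["Wt"] = flat_h.T @ dtl
        grads["bt"] = dtl.sum(axis=0)
        dhs += (dtl @ p["Wt"].T).reshape(B, T, H)

    # encoder backward, top layer down
    for l in reversed(range(L)):
        dm = cache["drop_masks"][l]
        if dm is not None:
            dhs = dhs * dm
        lc = cache["layers"][l]
        Wx, Wh = p[f"Wx{l}"], p[f"Wh{l}"]
        gate = Wx.shape[1]
        dz_all = np.empty((B, T, gate), dtype=model.dtype)
        dWh = np.zeros_like(Wh)
        dh_next = np.zeros((B, H), dtype=model.dtype)
        if lstm:
            dc_next = np.zeros((B, H), dtype=model.dtype)
            for t in reversed(range(T)):
                dh = dhs[:, t] + dh_next
                i, f, o, g = lc["i"][:, t], lc["f"][:, t], lc["o"][:, t], lc["g"][:, t]
                c, c_prev = lc["c"][:, t], lc["c_prev"][:, t]
                tc = np.tanh(c)
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc * tc)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dz = dz_all[:, t]
                dz[:, :H] = di * i * (1.0 - i)
                dz[:, H:2 * H] = df * f * (1.0 - f)
                dz[:, 2 * H:3 * H] = do * o * (1.0 - o)
                dz[:, 3 * H:] = dg * (1.0 - g * g)
                dh_next = dz @ Wh.T
                dWh += lc["h_prev"][:, t].T @ dz
        else:
            for t in reversed(range(T)):
                dh = dhs[:, t] + dh_next
                h = lc["h"][:, t]
                dz = dh * (1.0 - h * h)
                dz_all[:, t] = dz
                dh_next = dz @ Wh.T
                dWh += lc["h_prev"][:, t].T @ dz
        inp = lc["inp"]
        in_dim = inp.shape[2]
        grads[f"Wx{l}"] = inp.reshape(B * T, in_dim).T @ dz_all.reshape(B * T, gate)
        grads[f"Wh{l}"] = dWh
        grads[f"b{l}"] = dz_all.sum(axis=(0, 1))
        dhs = (dz_all @ Wx.T).reshape(B, T, in_dim)

    # embedding gradient
    np.add.at(grads["emb"], ids_in.reshape(-1), dhs.reshape(B * T, -1))

    loss = weight_word * loss_word + weight_tag * loss_tag
    return loss, loss_word, loss_tag, grads


# ---------------------------------------------------------------------------
# data preparation and batching
# ---------------------------------------------------------------------------

def _prepare_sentences(corpus: Sequence[SentenceRecord], vocab: Vocabulary,
                       tag2id: dict | None):
    out = []
    for rec in corpus:
        ids = vocab.encode(rec.tokens)
        ids_in = np.concatenate([[vocab.bos_id], ids])
        targets = np.concatenate([ids, [vocab.eos_id]])
        tags = None
        if tag2id is not None:
            tags = np.array([tag2id[t] for t in rec.supertags], dtype=np.int64)
        out.append((ids_in, targets, tags))
    return out


def _make_batches(prepared, batch_size: int, pad_id: int):
    """Length-sorted padded batches: (ids_in, targets, wmask, tags, tagmask)."""
    order = sorted(range(len(prepared)), key=lambda k: len(prepared[k][0]))
    batches = []
    for s in range(0, len(order), batch_size):
        chunk = [prepared[k] for k in order[s:s + batch_size]]
        B = len(chunk)
        T = max(len(c[0]) for c in chunk)
        ids_in = np.full((B, T), pad_id, dtype=np.int64)
        targets = np.full((B, T), pad_id, dtype=np.int64)
        wmask = np.zeros((B, T), dtype=np.float32)
        has_tags = chunk[0][2] is not None
        tags = np.zeros((B, T), dtype=np.int64) if has_tags else None
        tagmask = np.zeros((B, T), dtype=np.float32) if has_tags else None
        for b, (ii, tt, tg) in enumerate(chunk):
            n = len(ii)
            ids_in[b, :n] = ii
            targets[b, :n] = tt
            wmask[b, :n] = 1.0
            if has_tags:
                # position t consumes token t-1 (position 0 is <s>): the tag
                # decoder predicts the most recent word's supertag.
                tags[b, 1:n] = tg
                tagmask[b, 1:n] = 1.0
        batches.append((ids_in, targets, wmask, tags, tagmask))
    return batches


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model: LanguageModel, corpus: Sequence[SentenceRecord], config: TrainConfig,
          val_corpus: Sequence[SentenceRecord] | None = None):
    """SGD training with per-epoch learning-rate annealing on stalled
    validation loss.  Returns ``(model, trace)`` where ``trace`` is one dict
    per epoch (word loss, tag loss, validation loss, learning rate)."""
    rng = np.random.default_rng(config.seed)
    tag2id = model.tag2id if model.has_tag_decoder else None
    w_tag = config.weight_tag if model.has_tag_decoder else 0.0
    prepared = _prepare_sentences(corpus, model.vocab, tag2id)

    if val_corpus is None and config.val_fraction > 0 and len(prepared) > 20:
        n_val = max(1, int(len(prepared) * config.val_fraction))
        idx = rng.permutation(len(prepared))
        val_prep = [prepared[k] for k in idx[:n_val]]
        prepared = [prepared[k] for k in idx[n_val:]]
    elif val_corpus is not None:
        val_prep = _prepare_sentences(val_corpus, model.vocab, tag2id)
    else:
        val_prep = None

    batches = _make_batches(prepared, config.batch_size, model.vocab.eos_id)
    val_batches = (_make_batches(val_prep, config.batch_size, model.vocab.eos_id)
                   if val_prep else None)

    lr = config.learning_rate
    best_val = np.inf
    trace = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(batches))
        tot_w = tot_t = 0.0
        n_w = n_t = 0.0
        for bi in order:
            ids_in, targets, wmask, tags, tagmask = batches[bi]
            seqs = (ids_in, targets, wmask, tags, tagmask)
            for chunk in _bptt_chunks(seqs, config.bptt_length):
                c_in, c_tg, c_wm, c_tags, c_tm = chunk
                loss, lw, lt, grads = _batch_loss_and_grads(
                    model, c_in, c_tg, c_wm, c_tags, c_tm,
                    weight_word=config.weight_word, weight_tag=w_tag,
                    drop_rngs=rng if config.dropout > 0 else None,
                    dropout=config.dropout,
                )
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, lr={lr}"
                    )
                _sgd_update(model.params, grads, lr, config.grad_clip)
                tot_w += lw * c_wm.sum()
                n_w += c_wm.sum()
                if c_tm is not None:
                    tot_t += lt * c_tm.sum()
                    n_t += c_tm.sum()
        epoch_word = tot_w / max(n_w, 1.0)
        epoch_tag = tot_t / max(n_t, 1.0)
        if val_batches is not None:
            val_loss = _eval_loss(model, val_batches, config.weight_word, w_tag)
        else:
            val_loss = config.weight_word * epoch_word + w_tag * epoch_tag
        trace.append({
            "epoch": epoch,
            "word_loss": epoch_word,
            "tag_loss": epoch_tag,
            "val_loss": val_loss,
            "lr": lr,
        })
        if val_loss >= best_val:
            lr *= config.lr_decay
        else:
            best_val = val_loss
    return model, trace


def _bptt_chunks(seqs, bptt_length):
    ids_in, targets, wmask, tags, tagmask = seqs
    if bptt_length is None or ids_in.shape[1] <= bptt_length:
        yield seqs
        return
    # Truncated BPTT: split the time axis; state is re-zeroed across chunks
    # (sentences here are short, so truncation is a configuration nicety).
    T = ids_in.shape[1]
    for s in range(0, T, bptt_length):
        e = min(s + bptt_length, T)
        yield (ids_in[:, s:e], targets[:, s:e], wmask[:, s:e],
               None if tags is None else tags[:, s:e],
               None if tagmask is None else tagmask[:, s:e])


def _sgd_update(params, grads, lr, clip):
    if clip is not None and clip > 0:
        norm = math.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values()))
        if norm > clip:
            scale = clip / norm
            for g in grads.values():
                g *= scale
    for k, g in grads.items():
        params[k] -= lr * g


def _eval_loss(model, batches, w_word, w_tag):
    agg = {"word_nll": 0.0, "n_word": 0.0, "tag_nll": 0.0, "n_tag": 0.0}
    for ids_in, targets, wmask, tags, tagmask in batches:
        stats = _score_batch(model, ids_in, targets, wmask, tags, tagmask)
        for k in agg:
            agg[k] += stats[k]
    loss = w_word * agg["word_nll"] / max(agg["n_word"], 1.0)
    if agg["n_tag"] > 0 and w_tag > 0:
        loss += w_tag * agg["tag_nll"] / agg["n_tag"]
    return loss


def train_instances(corpus, vocab, enc_config: EncoderConfig, train_config: TrainConfig,
                    tagset=None, val_corpus=None, dtype=np.float32):
    """Train ``n_instances`` models differing only in their seed.

    Instance k uses seed ``train_config.seed + k`` for both initialization
    and data ordering; downstream analyses treat the instance as a grouping
    factor, mirroring a multi-subject design.
    """
    models, traces = [], []
    for k in range(train_config.n_instances):
        seed = train_config.seed + k
        m = LanguageModel(vocab, enc_config, tagset=tagset, seed=seed, dtype=dtype)
        cfg_k = TrainConfig(**{**train_config.__dict__, "seed": seed})
        m, tr = train(m, corpus, cfg_k, val_corpus=val_corpus)
        models.append(m)
        traces.append(tr)
    return models, traces


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _score_batch(model, ids_in, targets, wmask, tags=None, tagmask=None):
    hs, _, _ = model._encode(ids_in)
    hs = model._decode_hidden(hs)
    B, T, H = hs.shape
    flat_h = hs.reshape(B * T, H)
    logits = (flat_h @ model.params["Wd"] + model.params["bd"]).astype(np.float64)
    logp = logits - _logsumexp(logits)
    tflat = targets.reshape(-1)
    mflat = wmask.reshape(-1)
    picked = logp[np.arange(B * T), tflat]
    word_nll = float(-(picked * mflat).sum())
    out = {"word_nll": word_nll, "n_word": float(mflat.sum()),
           "tag_nll": 0.0, "n_tag": 0.0, "tag_correct": 0.0}
    if tags is not None and model.has_tag_decoder:
        tlogits = (flat_h @ model.params["Wt"] + model.params["bt"]).astype(np.float64)
        tlogp = tlogits - _logsumexp(tlogits)
        ttflat = tags.reshape(-1)
        tmflat = tagmask.reshape(-1)
        out["tag_nll"] = float(-(tlogp[np.arange(B * T), ttflat] * tmflat).sum())
        out["n_tag"] = float(tmflat.sum())
        out["tag_correct"] = float(((tlogp.argmax(axis=1) == ttflat) * tmflat).sum())
    return out


def score_corpus(model: LanguageModel, corpus: Sequence[SentenceRecord],
                 batch_size: int = 128) -> dict:
    """Total word/tag negative log-likelihoods (nats), token counts, and
    supertag top-1 correct counts over a corpus."""
    tag2id = model.tag2id if model.has_tag_decoder else None
    prepared = _prepare_sentences(corpus, model.vocab, tag2id)
    batches = _make_batches(prepared, batch_size, model.vocab.eos_id)
    agg = {"word_nll": 0.0, "n_word": 0.0, "tag_nll": 0.0, "n_tag": 0.0, "tag_correct": 0.0}
    for ids_in, targets, wmask, tags, tagmask in batches:
        stats = _score_batch(model, ids_in, targets, wmask, tags, tagmask)
        for k in agg:
            agg[k] += stats[k]
    return agg


def perplexity(model, corpus: Sequence[SentenceRecord]) -> float:
    """``2 ** (mean per-token surprisal in bits)``, counting end-of-sentence
    predictions.  A zero-probability token yields +inf explicitly."""
    if len(corpus) == 0:
        raise ValueError("corpus must be nonempty")
    if isinstance(model, LanguageModel):
        agg = score_corpus(model, corpus)
        mean_nats = agg["word_nll"] / agg["n_word"]
        return float(np.exp(mean_nats))
    # generic path for baseline models exposing token_log2probs
    total_bits, n = 0.0, 0
    for rec in corpus:
        lp = model.token_log2probs(rec.tokens, include_eos=True)
        total_bits += float(-lp.sum())
        n += len(lp)
    if not np.isfinite(total_bits):
        return float("inf")
    return float(2.0 ** (total_bits / n))


def supertag_accuracy(model: LanguageModel, tagged_corpus: Sequence[SentenceRecord],
                      batch_size: int = 128) -> tuple[float, float]:
    """Top-1 supertag accuracy and the per-word most-frequent-tag baseline
    accuracy, both computed over ``tagged_corpus``."""
    if not model.has_tag_decoder:
        raise ValueError("model has no supertag decoder")
    agg = score_corpus(model, tagged_corpus, batch_size=batch_size)
    acc = agg["tag_correct"] / max(agg["n_tag"], 1.0)

    # most-frequent-tag-per-word baseline on the same data
    from collections import Counter, defaultdict
    table: dict[str, Counter] = defaultdict(Counter)
    for rec in tagged_corpus:
        for tok, tag in zip(rec.tokens, rec.supertags):
            table[tok][tag] += 1
    correct = total = 0
    for rec in tagged_corpus:
        for tok, tag in zip(rec.tokens, rec.supertags):
            if table[tok].most_common(1)[0][0] == tag:
                correct += 1
            total += 1
    return float(acc), correct / max(total, 1)


class UnigramModel:
    """Add-one-smoothed unigram baseline exposing the scoring interface."""

    def __init__(self, corpus: Sequence[SentenceRecord], vocab: Vocabulary):
        counts = np.ones(len(vocab), dtype=np.float64)  # add-one smoothing
        for rec in corpus:
            for i in vocab.encode(rec.tokens):
                counts[i] += 1
            counts[vocab.eos_id] += 1
        counts[vocab.bos_id] = 1e-12  # <s> is never predicted
        self.vocab = vocab
        self.probs = counts / counts.sum()

    def next_word_distribution(self, prefix) -> np.ndarray:
        return self.probs.copy()

    def token_log2probs(self, tokens, include_eos: bool = False) -> np.ndarray:
        ids = list(self.vocab.encode(list(tokens)))
        if include_eos:
            ids.append(self.vocab.eos_id)
        return np.log2(self.probs[np.array(ids, dtype=np.int64)])


def save_model(model: LanguageModel, path) -> None:
    """Single-file checkpoint: parameter arrays + JSON metadata in one .npz."""
    import json

    meta = {
        "id2word": model.vocab.id2word,
        "min_count": model.vocab.min_count,
        "tagset": model.tagset,
        "config": model.config.__dict__,
        "dtype": np.dtype(model.dtype).name,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_model(path) -> LanguageModel:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    vocab = Vocabulary(meta["id2word"][3:], min_count=meta["min_count"])
    model = LanguageModel(vocab, EncoderConfig(**meta["config"]),
                          tagset=meta["tagset"], dtype=np.dtype(meta["dtype"]))
    model.params = params
    return model


def ablate_unit(model: LanguageModel, layer: int, unit_index: int) -> LanguageModel:
    """View of ``model`` with one final-layer unit's output clamped to 0
    before both decoders.  The underlying model is unchanged."""
    final = model.config.num_layers - 1
    if layer != final:
        raise ValueError(f"ablation operates on the output layer (layer {final})")
    if not (0 <= unit_index < model.config.hidden_size):
        raise IndexError(f"unit {unit_index} out of range")
    mask = np.ones(model.config.hidden_size, dtype=model.dtype)
    mask[unit_index] = 0.0
    if model.mask is not None:
        mask = mask * model.mask
    return model.view(mask=mask, transform=model.transform)
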