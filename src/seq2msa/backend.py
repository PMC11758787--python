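"""Trainable sequence-to-sequence aligner backend.

The contract is fit / translate / fallback over space-separated token
sentences with a shared input+output dictionary, so a decoded alignment
can in principle contain any input token (a pipe in the output is one of
the invalidity modes the verdict machinery catches).

The reference model is a compact recurrent encoder–decoder with additive
attention (bidirectional GRU encoder, GRU decoder), sized to train on a
CPU in minutes.  The large published transformer configurations
("original": max-tokens 4096, "alternative": max-tokens 2048, both with
16 heads / 1024-dim embeddings / 6 layers, learning rate 5e-5, 3000
warmup updates) are carried as named presets for provenance metadata;
they share this implementation's training loop at their stated
hyperparameters but are not CPU-practical at full size.

Sentences are limited to ``max_positions`` (at most 1024) tokens; longer
inputs are rejected — segmenting long sequences is a separate problem
outside this package.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .io import read_dataset
from .represent import Reason, Sentence, ValidityVerdict, decode_output, encode_input, vocabulary
from .types import GAP, PIPE, Msa, SequenceSet

log = logging.getLogger(__name__)

PAD, BOS, EOS = "<pad>", "<s>", "</s>"
HARD_MAX_POSITIONS = 1024


@dataclass
class ModelConfig:
    """Architecture + training hyperparameters of one aligner configuration."""

    name: str = "toy"
    max_tokens: int = 2048          # per-update token budget (training only)
    learning_rate: float = 3e-3
    warmup_updates: int = 200
    n_heads: int = 1
    embed_dim: int = 64
    n_layers: int = 2
    max_positions: int = 1024       # hard input/output sentence limit
    epochs: int = 25
    beam_width: int = 1             # 1 = greedy decoding
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_positions > HARD_MAX_POSITIONS:
            raise ValueError(f"max_positions {self.max_positions} exceeds the {HARD_MAX_POSITIONS}-token limit")
        for f_ in ("max_tokens", "n_heads", "embed_dim", "n_layers", "max_positions", "beam_width"):
            if getattr(self, f_) < 1:
                raise ValueError(f"{f_} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


#: published large-transformer configurations, kept as provenance presets
ORIGINAL = ModelConfig(name="original", max_tokens=4096, learning_rate=5e-5,
                       warmup_updates=3000, n_heads=16, embed_dim=1024, n_layers=6)
ALTERNATIVE = ModelConfig(name="alternative", max_tokens=2048, learning_rate=5e-5,
                          warmup_updates=3000, n_heads=16, embed_dim=1024, n_layers=6)
PRESETS = {"original": ORIGINAL, "alternative": ALTERNATIVE, "toy": ModelConfig()}


class Dictionary:
    """Symbol <-> id table shared by source and target sides."""

    def __init__(self, tokens: Sequence[str]):
        self.symbols = [PAD, BOS, EOS] + list(tokens)
        self.index = {s: i for i, s in enumerate(self.symbols)}
        if len(self.index) != len(self.symbols):
            raise ValueError("duplicate tokens in dictionary")

    @classmethod
    def for_alphabet(cls, alphabet: str = "DNA") -> "Dictionary":
        base = vocabulary("concat", alphabet).tokens  # letters + pipe
        return cls(base + [GAP])

    def __len__(self) -> int:
        return len(self.symbols)

    def __eq__(self, other) -> bool:
        return isinstance(other, Dictionary) and self.symbols == other.symbols

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.index[t] for t in tokens], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"token {exc.args[0]!r} not in dictionary") from None

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.symbols[i] for i in ids]


# ------------------------------------------------------------ parameters


def _init_params(cfg: ModelConfig, vocab: int, rng: np.random.Generator) -> dict[str, ad.Tensor]:
    e = cfg.embed_dim
    d = cfg.embed_dim          # recurrent hidden width
    a = cfg.embed_dim          # attention projection width
    h = 2 * d                  # encoder state width (both directions)
    p: dict[str, ad.Tensor] = {"emb": ad.param((vocab, e), rng, scale=0.1)}

    def gru(prefix: str, in_dim: int) -> None:
        for gate in "zrn":
            p[f"{prefix}_W{gate}"] = ad.param((in_dim, d), rng)
            p[f"{prefix}_U{gate}"] = ad.param((d, d), rng)
            p[f"{prefix}_b{gate}"] = ad.param(np.zeros(d))

    gru("ef", e)               # encoder, forward direction
    gru("eb", e)               # encoder, backward direction
    gru("dec", e + h)          # decoder; input = [token embedding, context]
    p["Winit"] = ad.param((h, d), rng)
    p["binit"] = ad.param(np.zeros(d))
    p["Wk"] = ad.param((h, a), rng)
    p["Wq"] = ad.param((d + e, a), rng)
    p["bq"] = ad.param(np.zeros(a))
    p["Wo"] = ad.param((d + h + e, vocab), rng)
    p["bo"] = ad.param(np.zeros(vocab))
    return p


def _gru_step(p: dict, prefix: str, x: ad.Tensor, hprev: ad.Tensor) -> ad.Tensor:
    z = ad.sigmoid(x @ p[f"{prefix}_Wz"] + hprev @ p[f"{prefix}_Uz"] + p[f"{prefix}_bz"])
    r = ad.sigmoid(x @ p[f"{prefix}_Wr"] + hprev @ p[f"{prefix}_Ur"] + p[f"{prefix}_br"])
    n = ad.tanh(x @ p[f"{prefix}_Wn"] + r * (hprev @ p[f"{prefix}_Un"]) + p[f"{prefix}_bn"])
    return z * hprev + (1.0 + (-1.0) * z) * n


def _swap_last2(t: ad.Tensor) -> ad.Tensor:
    return ad.Tensor(np.swapaxes(t.data, -1, -2), (t,), (lambda g: np.swapaxes(g, -1, -2),))


def _encode_batch(p: dict, src: np.ndarray, mask: np.ndarray) -> tuple[ad.Tensor, ad.Tensor]:
    """Bidirectional GRU over (B, S) token ids; returns H (B,S,2D) and s0 (B,D)."""
    b, s = src.shape
    d = p["Winit"].shape[0] // 2
    zero = ad.constant(np.zeros((b, d)))
    hf, hb = zero, zero
    fwd: list[ad.Tensor] = [None] * s
    bwd: list[ad.Tensor] = [None] * s
    for t in range(s):
        m = mask[:, t:t + 1]
        x = ad.embedding(p["emb"], src[:, t])
        hf = ad.add(ad.mul(_gru_step(p, "ef", x, hf), m), ad.mul(hf, 1.0 - m))
        fwd[t] = hf
    for t in range(s - 1, -1, -1):
        m = mask[:, t:t + 1]
        x = ad.embedding(p["emb"], src[:, t])
        hb = ad.add(ad.mul(_gru_step(p, "eb", x, hb), m), ad.mul(hb, 1.0 - m))
        bwd[t] = hb
    steps = [ad.reshape(ad.concat([fwd[t], bwd[t]]), (b, 1, 2 * d)) for t in range(s)]
    H = ad.concat(steps, axis=1)
    s0 = ad.tanh(ad.concat([fwd[s - 1], bwd[0]]) @ p["Winit"] + p["binit"])
    return H, s0


def _decode_batch(p: dict, H: ad.Tensor, s0: ad.Tensor, src_mask: np.ndarray,
                  tgt_in: np.ndarray) -> ad.Tensor:
    """Teacher-forced decoder; returns logits (B*T, V)."""
    b, t_len = tgt_in.shape
    a = p["Wq"].shape[1]
    neg = ((1.0 - src_mask) * -1e9)[:, :, None]
    K = H @ p["Wk"]
    state = s0
    logits_steps: list[ad.Tensor] = []
    scale = 1.0 / math.sqrt(a)
    for t in range(t_len):
        y = ad.embedding(p["emb"], tgt_in[:, t])
        q = ad.tanh(ad.concat([state, y]) @ p["Wq"] + p["bq"])
        scores = scale * ad.matmul(K, ad.reshape(q, (b, a, 1)))
        alpha = ad.softmax(scores, axis=1, additive_mask=neg)
        c = ad.reshape(ad.matmul(_swap_last2(H), alpha), (b, H.shape[2]))
        state = _gru_step(p, "dec", ad.concat([y, c]), state)
        out = ad.concat([state, c, y]) @ p["Wo"] + p["bo"]
        logits_steps.append(ad.reshape(out, (b, 1, len(out.data[0]))))
    v = logits_steps[0].shape[2]
    return ad.reshape(ad.concat(logits_steps, axis=1), (b * t_len, v))


# --------------------------------------------------------------- the model


@dataclass
class AlignerModel:
    """A trained aligner: config, dictionary, parameters and lineage."""

    config: ModelConfig
    dictionary: Dictionary
    params: dict[str, ad.Tensor]
    provenance: list[str] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)
    input_scheme: str = "concat"
    output_scheme: str = "spaces"

    def parameter_list(self) -> list[ad.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    # forward-only (plain numpy) paths used for inference and embedding

    def _np_gru(self, prefix: str, x: np.ndarray, h: np.ndarray) -> np.ndarray:
        p = {k: v.data for k, v in self.params.items()}
        z = _np_sigmoid(x @ p[f"{prefix}_Wz"] + h @ p[f"{prefix}_Uz"] + p[f"{prefix}_bz"])
        r = _np_sigmoid(x @ p[f"{prefix}_Wr"] + h @ p[f"{prefix}_Ur"] + p[f"{prefix}_br"])
        n = np.tanh(x @ p[f"{prefix}_Wn"] + r * (h @ p[f"{prefix}_Un"]) + p[f"{prefix}_bn"])
        return z * h + (1 - z) * n

    def encode_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        """Encoder states, one row per input token (width 2 * embed_dim)."""
        ids = self.dictionary.encode(tokens)
        p = {k: v.data for k, v in self.params.items()}
        d = p["Winit"].shape[0] // 2
        x = p["emb"][ids]
        s = len(ids)
        fwd = np.zeros((s, d))
        bwd = np.zeros((s, d))
        h = np.zeros((1, d))
        for t in range(s):
            h = self._np_gru("ef", x[t:t + 1], h)
            fwd[t] = h[0]
        h = np.zeros((1, d))
        for t in range(s - 1, -1, -1):
            h = self._np_gru("eb", x[t:t + 1], h)
            bwd[t] = h[0]
        return np.concatenate([fwd, bwd], axis=1)

    def _decode_state(self, H: np.ndarray):
        p = {k: v.data for k, v in self.params.items()}
        s0 = np.tanh(np.concatenate([H[-1, :H.shape[1] // 2], H[0, H.shape[1] // 2:]])[None, :]
                     @ p["Winit"] + p["binit"])
        K = H @ p["Wk"]
        return p, s0, K

    def _step(self, p, state, K, H, y_id: int):
        a = p["Wq"].shape[1]
        y = p["emb"][y_id][None, :]
        q = np.tanh(np.concatenate([state, y], axis=1) @ p["Wq"] + p["bq"])
        scores = (K @ q[0]) / math.sqrt(a)
        scores -= scores.max()
        alpha = np.exp(scores)
        alpha /= alpha.sum()
        c = (alpha[:, None] * H).sum(axis=0, keepdims=True)
        state = self._np_gru("dec", np.concatenate([y, c], axis=1), state)
        logits = np.concatenate([state, c, y], axis=1) @ p["Wo"] + p["bo"]
        x = logits[0] - logits[0].max()
        logp = x - np.log(np.exp(x).sum())
        return state, logp

    def greedy_decode(self, tokens: Sequence[str], max_out_tokens: int) -> list[str]:
        H = self.encode_tokens(tokens)
        p, state, K = self._decode_state(H)
        out: list[int] = []
        prev = self.dictionary.index[BOS]
        eos = self.dictionary.index[EOS]
        for _ in range(max_out_tokens):
            state, logp = self._step(p, state, K, H, prev)
            prev = int(np.argmax(logp))
            if prev == eos:
                break
            out.append(prev)
        return self.dictionary.decode(out)

    def beam_decode(self, tokens: Sequence[str], max_out_tokens: int, width: int) -> list[str]:
        H = self.encode_tokens(tokens)
        p, state, K = self._decode_state(H)
        eos = self.dictionary.index[EOS]
        beams = [([self.dictionary.index[BOS]], state, 0.0, False)]
        for _ in range(max_out_tokens):
            if all(done for *_, done in beams):
                break
            nxt = []
            for seq, st, lp, done in beams:
                if done:
                    nxt.append((seq, st, lp, True))
                    continue
                st2, logp = self._step(p, st, K, H, seq[-1])
                for tok in np.argsort(logp)[::-1][:width]:
                    nxt.append((seq + [int(tok)], st2, lp + float(logp[tok]), int(tok) == eos))
            nxt.sort(key=lambda b: b[2] / max(1, len(b[0]) - 1), reverse=True)
            beams = nxt[:width]
        seq = beams[0][0][1:]
        if seq and seq[-1] == eos:
            seq = seq[:-1]
        return self.dictionary.decode(seq)

    def save(self, path: str | Path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        meta = {"config": asdict(self.config), "symbols": self.dictionary.symbols,
                "provenance": self.provenance, "loss_history": self.loss_history,
                "input_scheme": self.input_scheme, "output_scheme": self.output_scheme}
        np.savez(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AlignerModel":
        with np.load(str(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: ad.Tensor(z[k], requires_grad=True) for k in z.files if k != "__meta__"}
        model = cls(ModelConfig(**meta["config"]), Dictionary([]), params,
                    meta["provenance"], meta["loss_history"], meta["input_scheme"], meta["output_scheme"])
        model.dictionary.symbols = meta["symbols"]
        model.dictionary.index = {s: i for i, s in enumerate(meta["symbols"])}
        return model


def _np_sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ----------------------------------------------------------------- training


def _make_batches(pairs: list[tuple[np.ndarray, np.ndarray]], max_tokens: int,
                  order: np.ndarray) -> list[list[int]]:
    batches, current, tokens = [], [], 0
    for i in order:
        n = len(pairs[i][0]) + len(pairs[i][1])
        if current and tokens + n > max_tokens:
            batches.append(current)
            current, tokens = [], 0
        current.append(int(i))
        tokens += n
    if current:
        batches.append(current)
    return batches


def _batch_arrays(pairs, idxs, pad, bos, eos):
    src_len = max(len(pairs[i][0]) for i in idxs)
    tgt_len = max(len(pairs[i][1]) for i in idxs) + 1  # room for EOS
    b = len(idxs)
    src = np.full((b, src_len), pad, dtype=np.intp)
    tgt_in = np.full((b, tgt_len), pad, dtype=np.intp)
    tgt_out = np.full((b, tgt_len), pad, dtype=np.intp)
    for r, i in enumerate(idxs):
        s, t = pairs[i]
        src[r, :len(s)] = s
        tgt_in[r, 0] = bos
        tgt_in[r, 1:len(t) + 1] = t
        tgt_out[r, :len(t)] = t
        tgt_out[r, len(t)] = eos
    src_mask = (src != pad).astype(float)
    tgt_mask = (tgt_out != pad).astype(float)
    return src, src_mask, tgt_in, tgt_out, tgt_mask


def _dataset_loss(p: dict, pairs, batches, pad, bos, eos) -> float:
    total, weight = 0.0, 0.0
    for idxs in batches:
        src, sm, ti, to, tm = _batch_arrays(pairs, idxs, pad, bos, eos)
        H, s0 = _encode_batch(p, src, sm)
        logits = _decode_batch(p, H, s0, sm, ti)
        loss = ad.cross_entropy_logits(logits, to.reshape(-1), tm.reshape(-1))
        w = tm.sum()
        total += float(loss.data) * w
        weight += w
    return total / weight


def initialize_model(config: ModelConfig | None = None, alphabet: str = "DNA") -> AlignerModel:
    """A freshly initialized (untrained) aligner with the shared dictionary."""
    config = config or ModelConfig()
    dictionary = Dictionary.for_alphabet(alphabet)
    params = _init_params(config, len(dictionary), np.random.default_rng(config.seed))
    return AlignerModel(config, dictionary, params, ["random-init"])


def fit(data, config: ModelConfig | None = None, warm_start: AlignerModel | None = None,
        alphabet: str = "DNA", epochs: int | None = None, k: int = 2,
        verbose: bool = False) -> AlignerModel:
    """Train an aligner on a sentence-pair corpus.

    ``data`` is either a list of (source Sentence, target Sentence) pairs or
    a ``(source_path, target_path)`` tuple of corpus files.  With
    ``warm_start``, optimization begins from the given model's parameters
    (transfer learning); the two models must share a token dictionary.
    Training is fully reproducible from ``config.seed``.
    """
    config = config or ModelConfig()
    if isinstance(data, tuple) and len(data) == 2 and isinstance(data[0], (str, Path)):
        data = read_dataset(data[0], data[1], k=k)
    if not data:
        raise ValueError("empty training set")

    dictionary = Dictionary.for_alphabet(alphabet)
    if warm_start is not None:
        if warm_start.dictionary != dictionary:
            raise ValueError("warm-start model uses a different token dictionary")
        params = {name: ad.Tensor(t.data.copy(), requires_grad=True)
                  for name, t in warm_start.params.items()}
        provenance = warm_start.provenance + [f"warm-start:{warm_start.config.name}"]
    else:
        fresh = initialize_model(config, alphabet)
        params = fresh.params
        provenance = fresh.provenance

    enc = dictionary.encode
    pairs = [(enc(s.tokens), enc(t.tokens)) for s, t in data]
    for s, t in pairs:
        if len(s) > config.max_positions or len(t) + 1 > config.max_positions:
            raise ValueError(f"training sentence exceeds max_positions={config.max_positions}")
    pad, bos, eos = (dictionary.index[x] for x in (PAD, BOS, EOS))
    rng = np.random.default_rng(config.seed + 1)
    names = sorted(params)
    opt = ad.Adam([params[n] for n in names], lr=config.learning_rate, warmup=config.warmup_updates)

    eval_batches = _make_batches(pairs, config.max_tokens, np.arange(len(pairs)))
    history = [_dataset_loss(params, pairs, eval_batches, pad, bos, eos)]
    n_epochs = config.epochs if epochs is None else epochs
    for epoch in range(n_epochs):
        order = rng.permutation(len(pairs))
        total, weight = 0.0, 0.0
        for idxs in _make_batches(pairs, config.max_tokens, order):
            src, sm, ti, to, tm = _batch_arrays(pairs, idxs, pad, bos, eos)
            H, s0 = _encode_batch(params, src, sm)
            logits = _decode_batch(params, H, s0, sm, ti)
            loss = ad.cross_entropy_logits(logits, to.reshape(-1), tm.reshape(-1))
            opt.zero_grad()
            loss.backward()
            opt.step()
            w = tm.sum()
            total += float(loss.data) * w
            weight += w
        history.append(total / weight)
        if verbose:
            log.info("epoch %d/%d: training loss %.4f", epoch + 1, n_epochs, history[-1])

    model = AlignerModel(config, dictionary, params, provenance, history)
    return model


# -------------------------------------------------------------- inference


def cross_entropy_loss(distributions: np.ndarray, targets: Sequence[int],
                       floor: float = 1e-12) -> float:
    """Mean over positions of -log P(correct token).

    ``distributions`` is (L, V) with rows summing to 1; ``targets`` are the
    correct token indices.  Zero probability on a correct token is floored
    (and logged) rather than returning infinity.
    """
    d = np.asarray(distributions, float)
    if d.ndim != 2 or len(d) != len(targets):
        raise ValueError("need one distribution per target position")
    sums = d.sum(axis=1)
    if np.abs(sums - 1).max() > 1e-9:
        raise ValueError("distributions must sum to 1")
    p = d[np.arange(len(targets)), np.asarray(targets, dtype=np.intp)]
    if (p < floor).any():
        log.warning("flooring %d zero-probability positions", int((p < floor).sum()))
        p = np.maximum(p, floor)
    return float(-np.log(p).mean())


def translate(model: AlignerModel, sentence: Sentence, max_out_tokens: int | None = None) -> Sentence:
    """Autoregressive decoding of one input sentence into one output sentence."""
    if len(sentence) == 0:
        raise ValueError("empty input sentence")
    if len(sentence) > model.config.max_positions:
        raise ValueError(f"input of {len(sentence)} tokens exceeds max_positions="
                         f"{model.config.max_positions}")
    if max_out_tokens is None:
        max_out_tokens = model.config.max_positions
    max_out_tokens = min(max_out_tokens, model.config.max_positions)
    if model.config.beam_width > 1:
        toks = model.beam_decode(sentence.tokens, max_out_tokens, model.config.beam_width)
    else:
        toks = model.greedy_decode(sentence.tokens, max_out_tokens)
    return Sentence(toks, model.output_scheme, sentence.k)


@dataclass
class AlignResult:
    """Outcome of the fallback chain for one input."""

    msa: Msa | None
    model_index: int | None
    verdicts: list[ValidityVerdict]

    @property
    def valid(self) -> bool:
        return self.msa is not None


def align_with_fallback(seqset: SequenceSet, models: Sequence[AlignerModel],
                        max_out_tokens: int | None = None) -> AlignResult:
    """Try each model in order; the first whose output decodes validly wins.

    With no valid output from any model the result is a failure (counted
    against coverage downstream).
    """
    if not models:
        raise ValueError("need at least one model")
    schemes = {(m.input_scheme, m.output_scheme) for m in models}
    if len(schemes) > 1:
        raise ValueError("fallback models must share the representation schemes")
    verdicts: list[ValidityVerdict] = []
    for i, model in enumerate(models):
        sent = encode_input(seqset, model.input_scheme)
        out = translate(model, sent, max_out_tokens)
        decoded = decode_output(out, seqset)
        if isinstance(decoded, Msa):
            verdicts.append(ValidityVerdict(True, Reason.OK))
            return AlignResult(decoded, i, verdicts)
        verdicts.append(decoded)
    return AlignResult(None, None, verdicts)
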