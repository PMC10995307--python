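"""Keyword-level LSTM language model over formula/herb sequences.

The training unit is the extracted keyword, not the character: the
tagging stage already solved segmentation, so each formula entry becomes
the token sequence ``BOS [formula-name] SEP herb_1 … herb_k EOS`` with
herbs in first-appearance order.  A single- or multi-layer LSTM is
trained with the next-token cross-entropy objective and sampled
autoregressively with temperature scaling (temperature 0 = greedy) to
propose novel herb compositions.

The whole model is implemented in numpy: forward pass, backpropagation
through time, Adam, and sampling.  Training is CPU-oriented and sized
for keyword vocabularies (hundreds of tokens), not open text.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit as _sigmoid

from .extraction import Transaction

__all__ = [
    "PAD", "UNK", "BOS", "EOS", "SEP",
    "Vocabulary",
    "GeneratorConfig",
    "GeneratedFormula",
    "encode_transactions",
    "FormulaLSTM",
    "train",
    "generate",
]

PAD, UNK, BOS, EOS, SEP = "<pad>", "<unk>", "<bos>", "<eos>", "<sep>"
SPECIALS = (PAD, UNK, BOS, EOS, SEP)


class Vocabulary:
    """Token<->id map with count thresholding.

    Ids are contiguous from 0: the five specials first, then corpus
    tokens with count >= *min_count* by descending count, ties broken
    lexicographically.  Tokens below the threshold encode to UNK.
    """

    def __init__(self, tokens: Sequence[str], min_count: int = 1) -> None:
        if min_count < 1:
            raise ValueError("min_count must be >= 1")
        self.min_count = min_count
        self.id_to_token: list[str] = list(SPECIALS) + [
            t for t in tokens if t not in SPECIALS
        ]
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}

    @classmethod
    def from_sequences(
        cls, sequences: Iterable[Sequence[str]], min_count: int = 1
    ) -> "Vocabulary":
        counts: dict[str, int] = {}
        empty = True
        for seq in sequences:
            empty = False
            for tok in seq:
                counts[tok] = counts.get(tok, 0) + 1
        if empty:
            raise ValueError("need at least one sequence")
        kept = sorted(
            (t for t, c in counts.items() if c >= min_count),
            key=lambda t: (-counts[t], t),
        )
        return cls(kept, min_count)

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def encode(self, tokens: Sequence[str]) -> list[int]:
        unk = self.token_to_id[UNK]
        return [self.token_to_id.get(t, unk) for t in tokens]

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.id_to_token[i] for i in ids]


@dataclass
class GeneratorConfig:
    embedding_dim: int = 64
    hidden_dim: int = 128
    n_layers: int = 1
    dropout: float = 0.1
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    temperature: float = 1.0
    max_len: int = 32
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        for name in ("embedding_dim", "hidden_dim", "n_layers", "epochs",
                     "batch_size", "max_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.temperature < 0:
            raise ValueError("learning_rate must be > 0 and temperature >= 0")


@dataclass
class GeneratedFormula:
    prompt: list[str]
    tokens: list[str]
    log_prob: float  # log-probability of the continuation at temperature 1


def encode_transactions(
    transactions: Iterable[Transaction], vocab: Vocabulary
) -> list[list[int]]:
    """``BOS [formula] SEP herbs… EOS`` per transaction, as id sequences."""
    out: list[list[int]] = []
    for t in transactions:
        if not t.ordered_items:
            warnings.warn(f"transaction {t.entry_id} is empty; skipped")
            continue
        tokens = [BOS] + ([t.formula] if t.formula else []) + [SEP]
        tokens += list(t.ordered_items) + [EOS]
        out.append(vocab.encode(tokens))
    return out


def transaction_tokens(t: Transaction) -> list[str]:
    """Token view of a transaction (for vocabulary building)."""
    return ([t.formula] if t.formula else []) + list(t.ordered_items)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class FormulaLSTM:
    """Numpy LSTM language model with Adam training and seeded sampling."""

    def __init__(self, vocab: Vocabulary, config: GeneratorConfig | None = None):
        self.vocab = vocab
        self.config = config or GeneratorConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        V, D, H = len(vocab), c.embedding_dim, c.hidden_dim
        p: dict[str, np.ndarray] = {"E": rng.normal(0.0, 0.1, (V, D))}
        for l in range(c.n_layers):
            in_dim = D if l == 0 else H
            s = 1.0 / np.sqrt(H)
            p[f"Wx{l}"] = rng.uniform(-s, s, (in_dim, 4 * H))
            p[f"Wh{l}"] = rng.uniform(-s, s, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias
            p[f"b{l}"] = b
        p["Wout"] = rng.uniform(-s, s, (H, V))
        p["bout"] = np.zeros(V)
        self.p = p
        self._rng = rng
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------
    def _layer_forward(self, l: int, X: np.ndarray):
        """Run layer *l* over X (B,T,in); returns H_seq and caches."""
        Wx, Wh, b = self.p[f"Wx{l}"], self.p[f"Wh{l}"], self.p[f"b{l}"]
        B, T, _ = X.shape
        Hdim = Wh.shape[0]
        h = np.zeros((B, Hdim))
        cstate = np.zeros((B, Hdim))
        H_seq = np.zeros((B, T, Hdim))
        caches = []
        for t in range(T):
            z = X[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :Hdim])
            f = _sigmoid(z[:, Hdim:2 * Hdim])
            g = np.tanh(z[:, 2 * Hdim:3 * Hdim])
            o = _sigmoid(z[:, 3 * Hdim:])
            c_new = f * cstate + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            caches.append((X[:, t], h, cstate, i, f, g, o, c_new, tc))
            h, cstate = h_new, c_new
            H_seq[:, t] = h
        return H_seq, caches

    def _layer_backward(self, l: int, dH_seq: np.ndarray, caches):
        Wx, Wh = self.p[f"Wx{l}"], self.p[f"Wh{l}"]
        B, T, Hdim = dH_seq.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * Hdim)
        dX = np.zeros((B, T, Wx.shape[0]))
        dh_next = np.zeros((B, Hdim))
        dc_next = np.zeros((B, Hdim))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, c_new, tc = caches[t]
            dh = dH_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2),
                 do * o * (1 - o)], axis=1,
            )
            dWx += x.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
        return dX, {f"Wx{l}": dWx, f"Wh{l}": dWh, f"b{l}": db}

    def _loss_and_grads(self, batch: np.ndarray, train_rng: np.random.Generator | None):
        """Next-token cross-entropy on a padded (B,T) id batch."""
        c = self.config
        pad_id = self.vocab.token_to_id[PAD]
        inputs, targets = batch[:, :-1], batch[:, 1:]
        mask = targets != pad_id
        n_tok = int(mask.sum())

        X = self.p["E"][inputs]
        drop_masks = []
        layer_caches = []
        H_seq = X
        for l in range(c.n_layers):
            if train_rng is not None and c.dropout > 0:
                m = (train_rng.random(H_seq.shape) >= c.dropout) / (1 - c.dropout)
                H_seq = H_seq * m
                drop_masks.append(m)
            else:
                drop_masks.append(None)
            H_seq, caches = self._layer_forward(l, H_seq)
            layer_caches.append(caches)

        logits = H_seq @ self.p["Wout"] + self.p["bout"]
        probs = _softmax(logits)
        B, T = targets.shape
        tp = probs[np.arange(B)[:, None], np.arange(T)[None, :], targets]
        nll = -np.log(np.clip(tp, 1e-12, None))
        loss = float((nll * mask).sum() / max(n_tok, 1))

        dlogits = probs.copy()
        dlogits[np.arange(B)[:, None], np.arange(T)[None, :], targets] -= 1.0
        dlogits *= mask[..., None] / max(n_tok, 1)

        grads = {
            "Wout": np.einsum("bth,btv->hv", H_seq, dlogits),
            "bout": dlogits.sum(axis=(0, 1)),
        }
        dH = dlogits @ self.p["Wout"].T
        for l in range(c.n_layers - 1, -1, -1):
            dH, layer_grads = self._layer_backward(l, dH, layer_caches[l])
            grads.update(layer_grads)
            if drop_masks[l] is not None:
                dH = dH * drop_masks[l]
        dE = np.zeros_like(self.p["E"])
        np.add.at(dE, inputs.reshape(-1), dH.reshape(-1, dH.shape[-1]))
        grads["E"] = dE
        return loss, grads, n_tok

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        c = self.config
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = c.grad_clip / norm if norm > c.grad_clip else 1.0
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            g = g * scale
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g ** 2
            mhat = self._adam_m[k] / (1 - b1 ** self._adam_t)
            vhat = self._adam_v[k] / (1 - b2 ** self._adam_t)
            self.p[k] -= c.learning_rate * mhat / (np.sqrt(vhat) + eps)

    # -- training -----------------------------------------------------------
    def fit(self, sequences: Sequence[Sequence[int]], epochs: int | None = None
            ) -> list[float]:
        """Train on id sequences; returns per-epoch mean loss (nats/token)."""
        if not sequences:
            raise ValueError("dataset is empty")
        c = self.config
        epochs = c.epochs if epochs is None else epochs
        pad_id = self.vocab.token_to_id[PAD]
        rng = np.random.default_rng(c.seed + 1)
        history: list[float] = []
        seqs = [list(s) for s in sequences]
        for _epoch in range(epochs):
            order = rng.permutation(len(seqs))
            total_nll = 0.0
            total_tok = 0
            for start in range(0, len(seqs), c.batch_size):
                chunk = [seqs[i] for i in order[start:start + c.batch_size]]
                T = max(len(s) for s in chunk)
                batch = np.full((len(chunk), T), pad_id, dtype=np.int64)
                for r, s in enumerate(chunk):
                    batch[r, :len(s)] = s
                loss, grads, n_tok = self._loss_and_grads(batch, rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        "training diverged (non-finite loss); lower the "
                        "learning rate or raise the batch size"
                    )
                self._adam_step(grads)
                total_nll += loss * n_tok
                total_tok += n_tok
            history.append(total_nll / max(total_tok, 1))
        return history

    # -- sampling -----------------------------------------------------------
    def _step(self, token_id: int, state):
        """One decode step; returns (logits, new state)."""
        c = self.config
        x = self.p["E"][token_id][None, :]
        new_state = []
        for l in range(c.n_layers):
            h_prev, c_prev = state[l]
            Hdim = h_prev.shape[1]
            z = x @ self.p[f"Wx{l}"] + h_prev @ self.p[f"Wh{l}"] + self.p[f"b{l}"]
            i = _sigmoid(z[:, :Hdim])
            f = _sigmoid(z[:, Hdim:2 * Hdim])
            g = np.tanh(z[:, 2 * Hdim:3 * Hdim])
            o = _sigmoid(z[:, 3 * Hdim:])
            c_new = f * c_prev + i * g
            x = o * np.tanh(c_new)
            new_state.append((x, c_new))
        logits = (x @ self.p["Wout"] + self.p["bout"])[0]
        return logits, new_state

    def generate(
        self,
        prompt: Sequence[str] = (),
        temperature: float | None = None,
        max_len: int | None = None,
        seed: int | None = None,
    ) -> GeneratedFormula:
        """Autoregressive sampling; stops at EOS or *max_len* tokens.

        ``temperature == 0`` is greedy decoding.  The reported log_prob is
        the model (temperature-1) log-probability of the continuation.
        """
        c = self.config
        temperature = c.temperature if temperature is None else temperature
        max_len = c.max_len if max_len is None else max_len
        for tok in prompt:
            if tok not in self.vocab:
                raise ValueError(f"prompt token {tok!r} not in vocabulary")
        rng = np.random.default_rng(self._rng.integers(2 ** 31) if seed is None else seed)
        pad_id = self.vocab.token_to_id[PAD]
        eos_id = self.vocab.token_to_id[EOS]

        state = [
            (np.zeros((1, c.hidden_dim)), np.zeros((1, c.hidden_dim)))
            for _ in range(c.n_layers)
        ]
        ids = self.vocab.encode([BOS] + list(prompt))
        logits = None
        for tid in ids:
            logits, state = self._step(tid, state)

        out_ids: list[int] = []
        log_prob = 0.0
        while len(out_ids) < max_len:
            masked = logits.copy()
            masked[pad_id] = -np.inf
            base = _softmax(masked[None, :])[0]
            if temperature == 0:
                nxt = int(np.argmax(masked))
            else:
                probs = _softmax(masked[None, :] / temperature)[0]
                nxt = int(rng.choice(len(probs), p=probs))
            log_prob += float(np.log(base[nxt]))
            out_ids.append(nxt)
            if nxt == eos_id:
                break
            logits, state = self._step(nxt, state)
        return GeneratedFormula(list(prompt), self.vocab.decode(out_ids), log_prob)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters + vocabulary + config."""
        meta = json.dumps(
            {
                "config": asdict(self.config),
                "vocab": self.vocab.id_to_token,
                "min_count": self.vocab.min_count,
            },
            ensure_ascii=False,
        )
        np.savez(path, meta=np.array(meta), **self.p)

    @classmethod
    def load(cls, path: str | Path) -> "FormulaLSTM":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            vocab = Vocabulary.__new__(Vocabulary)
            vocab.min_count = meta["min_count"]
            vocab.id_to_token = [t for t in meta["vocab"] if t not in SPECIALS]
            vocab.id_to_token = list(SPECIALS) + vocab.id_to_token
            vocab.token_to_id = {t: i for i, t in enumerate(vocab.id_to_token)}
            model = cls(vocab, GeneratorConfig(**meta["config"]))
            for k in model.p:
                model.p[k] = data[k]
        return model


def train(
    sequences: Sequence[Sequence[int]],
    vocab: Vocabulary,
    config: GeneratorConfig | None = None,
) -> tuple[FormulaLSTM, list[float]]:
    """Train a model on encoded sequences; returns (model, loss history)."""
    model = FormulaLSTM(vocab, config)
    history = model.fit(sequences)
    return model, history


def generate(
    model: FormulaLSTM,
    prompt: Sequence[str] = (),
    temperature: float | None = None,
    max_len: int | None = None,
    seed: int | None = None,
) -> GeneratedFormula:
    return model.generate(prompt, temperature, max_len, seed)
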