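"""Bidirectional LSTM per-position codon classifier.

The network reads the encoded protein in both directions (stacked
bidirectional LSTM layers), projects each position's concatenated hidden
state to the 64-codon label space and normalizes with a softmax. Training
minimizes masked per-position cross-entropy with an L2 penalty, inverted
dropout between layers and Adam updates; the parameters with the best
validation loss are retained.

Decoding is constrained by default: each position's argmax is taken over
the synonymous family of its amino acid only, which guarantees the output
back-translates to the input protein (0.00% mutational rate by
construction). Unconstrained decoding (global argmax over all 64 classes)
is retained to measure how often the classifier would pick a
non-synonymous codon on its own.

Implemented directly on numpy (forward pass + backpropagation through
time); model archives are ``.npz`` files bundling weights, configuration,
alphabet and training history.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from codonoptim.encoding import (
    DEFAULT_ALPHABET_SPEC,
    NLF_DIM,
    AlphabetSpec,
    EncodedGene,
    encode,
    encode_gene,
)
from codonoptim.errors import (
    AlphabetError,
    ConfigError,
    DataError,
    FormatError,
)
from codonoptim.genetic_code import (
    CODON_INDEX,
    STANDARD_CODE,
    GeneticCode,
)

ARCHIVE_FORMAT_VERSION = 1
N_CLASSES = 64


@dataclass
class OptimizerConfig:
    """Hyperparameters of the recurrent classifier.

    Defaults target full-scale training; :func:`quick_profile` returns a
    reduced configuration for fast desk-scale runs.
    """

    hidden_units: int = 256
    recurrent_layers: int = 2
    dropout: float = 0.2
    l2_penalty: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    encoding: str = "onehot"
    seed: int = 0
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be >= 1")
        if self.recurrent_layers < 1:
            raise ConfigError("recurrent_layers must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.l2_penalty < 0:
            raise ConfigError("l2_penalty must be non-negative")
        if self.encoding not in ("onehot", "nlft"):
            raise ConfigError(f"unknown encoding {self.encoding!r}")

    @property
    def input_dim(self) -> int:
        return NLF_DIM if self.encoding == "nlft" else len(DEFAULT_ALPHABET_SPEC)


def quick_profile(seed: int = 0, encoding: str = "onehot",
                 epochs: int = 10) -> OptimizerConfig:
    """Small configuration (64 units, 1 layer, raised learning rate) that
    trains in well under a minute on one CPU."""
    return OptimizerConfig(
        hidden_units=64,
        recurrent_layers=1,
        epochs=epochs,
        learning_rate=5e-3,
        encoding=encoding,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# low-level numerics


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its true length, keeping right padding."""
    out = np.zeros_like(x)
    for i, L in enumerate(lengths):
        out[i, :L] = x[i, :L][::-1]
    return out


class _LSTMDirection:
    """One direction of one LSTM layer: parameters and BPTT."""

    def __init__(self, rng: np.random.Generator, input_dim: int, hidden: int):
        scale_w = np.sqrt(6.0 / (input_dim + 4 * hidden))
        scale_u = np.sqrt(6.0 / (hidden + 4 * hidden))
        self.W = rng.uniform(-scale_w, scale_w, size=(input_dim, 4 * hidden))
        self.U = rng.uniform(-scale_u, scale_u, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.hidden = hidden

    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def forward(self, x: np.ndarray, train: bool):
        """x: (B, T, F) -> h: (B, T, H); caches kept when train=True."""
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = [] if train else None
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if train:
                cache.append((xt, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        return hs, cache

    def backward(self, dh_seq: np.ndarray, cache) -> tuple[np.ndarray, list[np.ndarray]]:
        """dh_seq: (B, T, H) gradient w.r.t. outputs; returns dX and grads."""
        B, T, H = dh_seq.shape
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros((B, T, self.W.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += xt.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t, :] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dX, [dW, dU, db]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# model


class BiLSTMOptimizer:
    """Stacked bidirectional LSTM codon classifier.

    Build with a config, call :meth:`fit` with encoded genes, then
    :meth:`optimize` proteins; or use the module-level helpers.
    """

    def __init__(
        self,
        config: OptimizerConfig,
        alphabet: AlphabetSpec = DEFAULT_ALPHABET_SPEC,
        code: GeneticCode = STANDARD_CODE,
    ):
        self.config = config
        self.alphabet = alphabet
        self.code = code
        self.history: dict[str, list[float]] = {
            "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        }
        rng = np.random.default_rng(config.seed)
        H = config.hidden_units
        self.layers: list[tuple[_LSTMDirection, _LSTMDirection]] = []
        in_dim = config.input_dim
        for _ in range(config.recurrent_layers):
            fwd = _LSTMDirection(rng, in_dim, H)
            bwd = _LSTMDirection(rng, in_dim, H)
            self.layers.append((fwd, bwd))
            in_dim = 2 * H
        scale = np.sqrt(6.0 / (in_dim + N_CLASSES))
        self.W_out = rng.uniform(-scale, scale, size=(in_dim, N_CLASSES))
        self.b_out = np.zeros(N_CLASSES)

    # -- parameter plumbing -------------------------------------------------

    def _params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for fwd, bwd in self.layers:
            out.extend(fwd.params())
            out.extend(bwd.params())
        out.extend([self.W_out, self.b_out])
        return out

    def _set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self._params(), values):
            p[...] = v

    # -- forward / backward -------------------------------------------------

    def _forward(
        self,
        x: np.ndarray,
        lengths: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Returns logits (B, T, 64) and, when training, the caches."""
        caches = []
        inp = x
        for li, (fwd, bwd) in enumerate(self.layers):
            rev_in = _reverse_padded(inp, lengths)
            h_f, cache_f = fwd.forward(inp, train)
            h_b_rev, cache_b = bwd.forward(rev_in, train)
            h_b = _reverse_padded(h_b_rev, lengths)
            out = np.concatenate([h_f, h_b], axis=2)
            mask = None
            if train and self.config.dropout > 0:
                keep = 1.0 - self.config.dropout
                mask = (dropout_rng.random(out.shape) < keep) / keep
                out = out * mask
            caches.append((inp, rev_in, cache_f, cache_b, mask))
            inp = out
        logits = inp @ self.W_out + self.b_out
        return logits, inp, caches

    def _backward(
        self,
        dlogits: np.ndarray,
        last_hidden: np.ndarray,
        caches,
        lengths: np.ndarray,
    ) -> list[np.ndarray]:
        H = self.config.hidden_units
        dW_out = np.einsum("btf,btc->fc", last_hidden, dlogits)
        db_out = dlogits.sum(axis=(0, 1))
        d_out = dlogits @ self.W_out.T
        grads_layers: list[list[np.ndarray]] = []
        for li in range(len(self.layers) - 1, -1, -1):
            fwd, bwd = self.layers[li]
            inp, rev_in, cache_f, cache_b, mask = caches[li]
            if mask is not None:
                d_out = d_out * mask
            dh_f = d_out[:, :, :H]
            dh_b = _reverse_padded(d_out[:, :, H:], lengths)
            dX_f, g_f = fwd.backward(dh_f, cache_f)
            dX_b_rev, g_b = bwd.backward(dh_b, cache_b)
            dX_b = _reverse_padded(dX_b_rev, lengths)
            d_out = dX_f + dX_b
            grads_layers.append(g_f + g_b)
        grads: list[np.ndarray] = []
        for g in reversed(grads_layers):
            grads.extend(g)
        grads.extend([dW_out, db_out])
        return grads

    # -- training -----------------------------------------------------------

    @staticmethod
    def _make_batches(
        genes: Sequence[EncodedGene], batch_size: int
    ) -> list[list[int]]:
        order = sorted(range(len(genes)), key=lambda i: len(genes[i]))
        return [
            order[i : i + batch_size] for i in range(0, len(order), batch_size)
        ]

    def _pad_batch(self, genes: Sequence[EncodedGene], idx: list[int]):
        lengths = np.array([len(genes[i]) for i in idx])
        T = int(lengths.max())
        F = genes[idx[0]].features.shape[1]
        x = np.zeros((len(idx), T, F))
        y = np.zeros((len(idx), T), dtype=np.int64)
        mask = np.zeros((len(idx), T), dtype=bool)
        for r, i in enumerate(idx):
            L = len(genes[i])
            x[r, :L] = genes[i].features
            if genes[i].labels is not None:
                y[r, :L] = genes[i].labels
            mask[r, :L] = True
        return x, y, mask, lengths

    def _loss_and_grads(self, x, y, mask, lengths, dropout_rng):
        logits, last_hidden, caches = self._forward(
            x, lengths, train=True, dropout_rng=dropout_rng
        )
        logits = logits - logits.max(axis=2, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=2, keepdims=True)
        n_valid = int(mask.sum())
        B, T = y.shape
        picked = probs[np.arange(B)[:, None], np.arange(T)[None, :], y]
        loss = -np.sum(np.log(np.clip(picked, 1e-12, None)) * mask) / n_valid
        acc = float(
            ((probs.argmax(axis=2) == y) & mask).sum() / n_valid
        )
        dlogits = probs.copy()
        dlogits[np.arange(B)[:, None], np.arange(T)[None, :], y] -= 1.0
        dlogits *= mask[:, :, None] / n_valid
        grads = self._backward(dlogits, last_hidden, caches, lengths)
        # L2 on weight matrices (biases excluded)
        l2 = self.config.l2_penalty
        if l2 > 0:
            for p, g in zip(self._params(), grads):
                if p.ndim > 1:
                    g += l2 * p
                    loss += 0.5 * l2 * float(np.sum(p * p))
        return float(loss), acc, grads

    def _eval(self, genes: Sequence[EncodedGene]) -> tuple[float, float]:
        total_loss, total_correct, total = 0.0, 0, 0
        for idx in self._make_batches(genes, self.config.batch_size):
            x, y, mask, lengths = self._pad_batch(genes, idx)
            logits, _, _ = self._forward(x, lengths, train=False)
            logits = logits - logits.max(axis=2, keepdims=True)
            expz = np.exp(logits)
            probs = expz / expz.sum(axis=2, keepdims=True)
            B, T = y.shape
            picked = probs[np.arange(B)[:, None], np.arange(T)[None, :], y]
            total_loss += -np.sum(np.log(np.clip(picked, 1e-12, None)) * mask)
            total_correct += int(((probs.argmax(axis=2) == y) & mask).sum())
            total += int(mask.sum())
        return total_loss / total, total_correct / total

    def fit(
        self,
        train_set: Sequence[EncodedGene],
        val_set: Sequence[EncodedGene] = (),
    ) -> "BiLSTMOptimizer":
        """Train with Adam on masked cross-entropy; keeps best-validation
        parameters (best training loss when no validation set is given)."""
        if not train_set:
            raise DataError("empty training set")
        for g in train_set:
            if g.labels is None:
                raise DataError("training genes must carry codon labels")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        dropout_rng = np.random.default_rng(cfg.seed + 2)
        params = self._params()
        adam = _Adam(params, cfg.learning_rate)
        batches = self._make_batches(train_set, cfg.batch_size)
        best_metric = np.inf
        best_params = [p.copy() for p in params]
        for epoch in range(cfg.epochs):
            rng.shuffle(batches)
            ep_loss, ep_acc, n_batches = 0.0, 0.0, 0
            for idx in batches:
                x, y, mask, lengths = self._pad_batch(train_set, idx)
                loss, acc, grads = self._loss_and_grads(
                    x, y, mask, lengths, dropout_rng
                )
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if norm > cfg.clip_norm:
                    scale = cfg.clip_norm / norm
                    grads = [g * scale for g in grads]
                adam.step(params, grads)
                ep_loss += loss
                ep_acc += acc
                n_batches += 1
            self.history["train_loss"].append(ep_loss / n_batches)
            self.history["train_acc"].append(ep_acc / n_batches)
            if val_set:
                val_loss, val_acc = self._eval(val_set)
                self.history["val_loss"].append(val_loss)
                self.history["val_acc"].append(val_acc)
                metric = val_loss
            else:
                metric = ep_loss / n_batches
            if metric < best_metric:
                best_metric = metric
                best_params = [p.copy() for p in params]
        self._set_params(best_params)
        return self

    # -- inference ----------------------------------------------------------

    def predict_scores(self, aa_seq: str) -> np.ndarray:
        """Per-position class probabilities, shape (T, 64); rows sum to 1."""
        aa_seq = aa_seq.upper()
        if not aa_seq:
            return np.zeros((0, N_CLASSES))
        x = encode(aa_seq, self.config.encoding, self.alphabet)[None, :, :]
        lengths = np.array([len(aa_seq)])
        logits, _, _ = self._forward(x, lengths, train=False)
        logits = logits[0] - logits[0].max(axis=1, keepdims=True)
        expz = np.exp(logits)
        return expz / expz.sum(axis=1, keepdims=True)

    def decode(
        self, scores: np.ndarray, aa_seq: str, mode: str = "constrained"
    ) -> str:
        """Turn a (T, 64) score matrix into a CDS.

        ``constrained`` restricts each position to the synonymous family of
        its amino acid (translation identity guaranteed); ``unconstrained``
        takes the global argmax. Ties break lexicographically.
        """
        aa_seq = aa_seq.upper()
        if scores.shape != (len(aa_seq), N_CLASSES):
            raise DataError(
                f"score matrix shape {scores.shape} does not match "
                f"protein length {len(aa_seq)}"
            )
        if mode not in ("constrained", "unconstrained"):
            raise ConfigError(f"unknown decode mode {mode!r}")
        from codonoptim.genetic_code import CODONS

        out = []
        for t, aa in enumerate(aa_seq):
            if mode == "unconstrained":
                out.append(CODONS[int(np.argmax(scores[t]))])
            else:
                family = self.code.synonymous_codons(aa)
                fam_idx = [CODON_INDEX[c] for c in family]
                best = int(np.argmax(scores[t, fam_idx]))
                out.append(family[best])
        return "".join(out)

    def optimize(self, aa_seq: str, mode: str = "constrained") -> str:
        """Encode -> predict -> decode; output length is 3T."""
        scores = self.predict_scores(aa_seq)
        return self.decode(scores, aa_seq, mode)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for li, (fwd, bwd) in enumerate(self.layers):
            for name, d in (("f", fwd), ("b", bwd)):
                arrays[f"layer{li}_{name}_W"] = d.W
                arrays[f"layer{li}_{name}_U"] = d.U
                arrays[f"layer{li}_{name}_b"] = d.b
        arrays["W_out"] = self.W_out
        arrays["b_out"] = self.b_out
        meta = {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "config": asdict(self.config),
            "alphabet": self.alphabet.symbols,
            "history": self.history,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:  # keep the exact path (no .npz suffixing)
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "BiLSTMOptimizer":
        try:
            with np.load(path) as npz:
                arrays = {k: npz[k] for k in npz.files}
        except Exception as exc:
            raise FormatError(f"cannot read model archive {path}: {exc}") from exc
        if "meta_json" not in arrays:
            raise FormatError(f"{path} is not a model archive (no metadata)")
        meta = json.loads(bytes(arrays["meta_json"].tobytes()).decode())
        version = meta.get("format_version")
        if version != ARCHIVE_FORMAT_VERSION:
            raise FormatError(
                f"archive format version {version} not supported "
                f"(expected {ARCHIVE_FORMAT_VERSION})"
            )
        config = OptimizerConfig(**meta["config"])
        model = cls(config, alphabet=AlphabetSpec(meta["alphabet"]))
        model.history = meta["history"]
        try:
            for li, (fwd, bwd) in enumerate(model.layers):
                for name, d in (("f", fwd), ("b", bwd)):
                    d.W = arrays[f"layer{li}_{name}_W"]
                    d.U = arrays[f"layer{li}_{name}_U"]
                    d.b = arrays[f"layer{li}_{name}_b"]
            model.W_out = arrays["W_out"]
            model.b_out = arrays["b_out"]
        except KeyError as exc:
            raise FormatError(f"model archive {path} is missing {exc}") from exc
        return model


# ---------------------------------------------------------------------------
# convenience wrappers


def build_model(config: OptimizerConfig) -> BiLSTMOptimizer:
    return BiLSTMOptimizer(config)


def train_optimizer(
    train_records,
    val_records=(),
    config: OptimizerConfig | None = None,
) -> BiLSTMOptimizer:
    """Encode GeneRecords and train a classifier in one call."""
    if config is None:
        config = OptimizerConfig()
    train_set = [encode_gene(r, config.encoding) for r in train_records]
    val_set = [encode_gene(r, config.encoding) for r in val_records]
    return BiLSTMOptimizer(config).fit(train_set, val_set)


def save_model(model: BiLSTMOptimizer, path: str | Path) -> None:
    model.save(path)


def load_model(path: str | Path) -> BiLSTMOptimizer:
    return BiLSTMOptimizer.load(path)


def codon_match_accuracy(model: BiLSTMOptimizer, records) -> float:
    """Fraction of positions where constrained decoding reproduces the
    host's own codon choice on held-out genes."""
    from codonoptim.genetic_code import split_codons, strip_terminal_stop

    correct, total = 0, 0
    for rec in records:
        aa = rec.protein(model.code)
        pred = split_codons(model.optimize(aa))
        true = split_codons(strip_terminal_stop(rec.nt_seq, model.code))
        correct += sum(1 for p, t in zip(pred, true) if p == t)
        total += len(true)
    if total == 0:
        raise DataError("no positions to score")
    return correct / total
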