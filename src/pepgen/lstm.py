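"""Character-level LSTM next-residue language model.

The generator is a single-layer LSTM over peptide sequences processed
at the amino-acid (character) level: each residue is embedded in a
dense vector space, fed through the gated recurrence

    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    g_t = tanh   (W_c x_t + U_c h_{t-1} + b_c)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

with h_0 = c_0 = 0, and the final hidden state is projected through a
dense softmax layer over the 22-token vocabulary (20 residues plus
START and END).  Training minimises sparse categorical cross-entropy
of next-residue prediction with Adam; each peptide of length L
contributes L+1 supervised (prefix -> next token) examples, including
the END target that teaches the model when to stop.  Sequences are
generated by iteratively sampling successive residues from the
temperature-scaled softmax, starting from an optional seed prefix.

Everything is plain numpy and single-threaded-deterministic: given the
same records, configuration and seed, training and generation are
bitwise reproducible.  ``PeptideLSTM`` wraps the whole thing as a
scikit-learn style estimator; the module-level ``train`` / ``generate``
/ ``evaluate_accuracy`` functions are thin wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import AMINO_ACIDS, PeptideRecord

START = "<start>"
END = "<end>"


class TokenVocabulary:
    """Bijection between the 22 model tokens and indices.

    Indices 0-19 are the residues in alphabetical one-letter order,
    20 is START, 21 is END.  Index 22 is a padding slot used only
    inside batched training (masked out of loss and accuracy); it is
    not part of the vocabulary proper.
    """

    def __init__(self) -> None:
        tokens = list(AMINO_ACIDS) + [START, END]
        self.residue_to_index = {t: i for i, t in enumerate(tokens)}
        self.index_to_residue = {i: t for i, t in enumerate(tokens)}

    @property
    def size(self) -> int:
        return 22

    @property
    def start_index(self) -> int:
        return self.residue_to_index[START]

    @property
    def end_index(self) -> int:
        return self.residue_to_index[END]

    @property
    def pad_index(self) -> int:
        return 22

    def encode(self, sequence: str) -> list[int]:
        """Residue string -> indices (no START/END added)."""
        try:
            return [self.residue_to_index[aa] for aa in sequence]
        except KeyError as exc:
            raise ValueError(f"unknown residue {exc.args[0]!r}") from exc

    def decode(self, indices: Iterable[int]) -> str:
        out = []
        for i in indices:
            tok = self.index_to_residue.get(int(i))
            if tok is None or tok in (START, END):
                raise ValueError(f"index {i} does not decode to a residue")
            out.append(tok)
        return "".join(out)


@dataclass
class GeneratorConfig:
    """Hyperparameters of the next-residue model.

    Defaults mirror the published setup: 50-dimensional embedding,
    a single LSTM layer with 64 memory units, Adam at 1e-3, sparse
    categorical cross-entropy, 200 epochs with batch size 32, and an
    80/20 train/hold-out split.
    """

    embedding_dim: int = 50
    hidden_units: int = 64
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.2
    seed: int = 0
    max_generate_len: int = 20
    temperature: float = 1.0

    def validate(self) -> None:
        for name in ("embedding_dim", "hidden_units", "epochs", "batch_size",
                     "max_generate_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in [0, 1)")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class SequenceModel:
    """Learned parameters of the LSTM next-residue model.

    Array layout: ``embedding`` has 23 rows (22 tokens + padding slot);
    ``Wx`` (embedding_dim, 4*hidden) and ``Wh`` (hidden, 4*hidden) are
    the fused input/recurrent kernels with gate order (input, forget,
    output, candidate); ``b`` (4*hidden,) the fused bias; ``Wy``
    (hidden, 22) and ``by`` (22,) the softmax output projection.
    """

    vocabulary: TokenVocabulary
    embedding: np.ndarray
    Wx: np.ndarray
    Wh: np.ndarray
    b: np.ndarray
    Wy: np.ndarray
    by: np.ndarray
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    @property
    def hidden_units(self) -> int:
        return self.Wh.shape[0]

    def _params(self) -> dict[str, np.ndarray]:
        return {"embedding": self.embedding, "Wx": self.Wx, "Wh": self.Wh,
                "b": self.b, "Wy": self.Wy, "by": self.by}

    def save(self, path: str | Path) -> None:
        """Serialise config + weights to a single JSON container."""
        payload = {
            "format": "pepgen-sequence-model-v1",
            "config": self.config.__dict__,
            "weights": {k: v.tolist() for k, v in self._params().items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SequenceModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "pepgen-sequence-model-v1":
            raise ValueError(f"{path} is not a saved sequence model")
        w = {k: np.asarray(v, dtype=np.float64)
             for k, v in payload["weights"].items()}
        return cls(vocabulary=TokenVocabulary(),
                   config=GeneratorConfig(**payload["config"]), **w)


@dataclass
class TrainingTrace:
    """Per-epoch loss (nats) and argmax next-residue accuracy."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    holdout_loss: list[float] = field(default_factory=list)
    holdout_accuracy: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__))

    def to_tsv(self, path: str | Path) -> None:
        has_holdout = bool(self.holdout_loss)
        with open(path, "w") as fh:
            cols = ["epoch", "train_loss", "train_accuracy"]
            if has_holdout:
                cols += ["holdout_loss", "holdout_accuracy"]
            fh.write("\t".join(cols) + "\n")
            for e in range(len(self.train_loss)):
                row = [str(e + 1), f"{self.train_loss[e]:.6f}",
                       f"{self.train_accuracy[e]:.6f}"]
                if has_holdout:
                    row += [f"{self.holdout_loss[e]:.6f}",
                            f"{self.holdout_accuracy[e]:.6f}"]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# encoding

def _coerce_records(
    records: Sequence[PeptideRecord] | Sequence[str],
) -> list[PeptideRecord]:
    out = []
    for k, r in enumerate(records):
        if isinstance(r, PeptideRecord):
            out.append(r)
        else:
            out.append(PeptideRecord(id=f"seq{k + 1}", sequence=str(r)))
    return out


def encode_training_pairs(
    records: Sequence[PeptideRecord], vocab: TokenVocabulary
) -> list[tuple[tuple[int, ...], int]]:
    """Supervised (prefix, next-token) pairs for next-residue training.

    A peptide of length L yields L+1 pairs: (START, s1),
    (START s1, s2), ..., (START s1..sL, END).  Prefixes include the
    START index; padding for batching happens downstream and never
    alters the supervision targets.
    """
    pairs: list[tuple[tuple[int, ...], int]] = []
    for rec in records:
        tokens = [vocab.start_index] + vocab.encode(rec.sequence)
        targets = vocab.encode(rec.sequence) + [vocab.end_index]
        for k in range(len(targets)):
            pairs.append((tuple(tokens[: k + 1]), targets[k]))
    return pairs


# ---------------------------------------------------------------------------
# core numpy LSTM (forward, BPTT, Adam)

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_states(params: dict, tokens: np.ndarray, pad_index: int):
    """Run the LSTM over a (B, T) token matrix.

    Padding positions (token == pad_index) leave the state untouched.
    Returns the per-step hidden states (T, B, H) and the caches needed
    for backpropagation through time.
    """
    B, T = tokens.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    caches = []
    hs = np.empty((T, B, H))
    for t in range(T):
        idx = tokens[:, t]
        m = (idx != pad_index).astype(np.float64)[:, None]
        x = params["embedding"][idx]
        z = x @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        o = _sigmoid(z[:, 2 * H : 3 * H])
        g = np.tanh(z[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        caches.append((idx, m, x, i, f, o, g, c, tanh_c, h))
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
        hs[t] = h
    return hs, caches


def _zero_grads(params: dict) -> dict:
    return {k: np.zeros_like(v) for k, v in params.items()}


def _backward_states(params: dict, caches, dh_last: np.ndarray,
                     grads: dict) -> None:
    """Backpropagate a gradient on the final hidden state through time."""
    H = params["Wh"].shape[0]
    dh = dh_last
    dc = np.zeros_like(dh)
    for t in range(len(caches) - 1, -1, -1):
        idx, m, x, i, f, o, g, c_prev, tanh_c, h_prev = caches[t]
        dh_new = dh * m
        dh_carry = dh * (1.0 - m)
        dc_new = dc * m
        dc_carry = dc * (1.0 - m)
        do = dh_new * tanh_c
        dc_new = dc_new + dh_new * o * (1.0 - tanh_c ** 2)
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        dc = dc_new * f + dc_carry
        dz = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f),
             do * o * (1.0 - o), dg * (1.0 - g ** 2)], axis=1)
        grads["Wx"] += x.T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        np.add.at(grads["embedding"], idx, dz @ params["Wx"].T)
        dh = dz @ params["Wh"].T + dh_carry


def _batch_loss_and_grads(params: dict, tokens: np.ndarray,
                          targets: np.ndarray, pad_index: int):
    """Mean cross-entropy at the final position of each row + gradients."""
    B = tokens.shape[0]
    hs, caches = _forward_states(params, tokens, pad_index)
    h_last = hs[-1]
    logits = h_last @ params["Wy"] + params["by"]
    probs = _softmax(logits)
    loss = float(-np.mean(np.log(probs[np.arange(B), targets] + 1e-300)))
    dlogits = probs.copy()
    dlogits[np.arange(B), targets] -= 1.0
    dlogits /= B
    grads = _zero_grads(params)
    grads["Wy"] += h_last.T @ dlogits
    grads["by"] += dlogits.sum(axis=0)
    _backward_states(params, caches, dlogits @ params["Wy"].T, grads)
    return loss, grads


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _init_params(rng: np.random.Generator, config: GeneratorConfig) -> dict:
    E, H = config.embedding_dim, config.hidden_units
    embedding = rng.uniform(-0.05, 0.05, size=(23, E))
    embedding[22] = 0.0  # padding slot stays zero
    Wx = _glorot(rng, (E, 4 * H))
    Wh = np.concatenate([_orthogonal(rng, H) for _ in range(4)], axis=1)
    b = np.zeros(4 * H)
    b[H : 2 * H] = 1.0  # unit forget-gate bias
    Wy = _glorot(rng, (H, 22))
    by = np.zeros(22)
    return {"embedding": embedding, "Wx": Wx, "Wh": Wh, "b": b,
            "Wy": Wy, "by": by}


class _Adam:
    def __init__(self, params: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = _zero_grads(params)
        self.v = _zero_grads(params)
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# dataset helpers

def _sequence_arrays(records: Sequence[PeptideRecord],
                     vocab: TokenVocabulary):
    """Right-padded (inputs, targets) arrays for whole-sequence evaluation.

    Row r holds inputs [START, s1..sL] and targets [s1..sL, END]; the
    prediction at position t of row r is exactly the supervised pair
    (prefix of length t+1 -> target), so evaluating all positions is
    equivalent to evaluating every pair from ``encode_training_pairs``.
    """
    L = max(len(r.sequence) for r in records) + 1
    inputs = np.full((len(records), L), vocab.pad_index, dtype=np.int64)
    targets = np.full((len(records), L), -1, dtype=np.int64)
    for r, rec in enumerate(records):
        seq = vocab.encode(rec.sequence)
        inputs[r, : len(seq) + 1] = [vocab.start_index] + seq
        targets[r, : len(seq) + 1] = seq + [vocab.end_index]
    return inputs, targets


def _evaluate(params: dict, records: Sequence[PeptideRecord],
              vocab: TokenVocabulary) -> tuple[float, float]:
    """(mean cross-entropy, argmax accuracy) over all supervised pairs."""
    inputs, targets = _sequence_arrays(records, vocab)
    hs, _ = _forward_states(params, inputs, vocab.pad_index)
    logits = np.einsum("tbh,hv->btv", hs, params["Wy"]) + params["by"]
    valid = targets >= 0
    probs = _softmax(logits[valid])
    tgt = targets[valid]
    loss = float(-np.mean(np.log(probs[np.arange(len(tgt)), tgt] + 1e-300)))
    acc = float(np.mean(np.argmax(probs, axis=1) == tgt))
    return loss, acc


# ---------------------------------------------------------------------------
# estimator

class PeptideLSTM(BaseEstimator):
    """Scikit-learn style wrapper around the LSTM peptide generator.

    Parameters mirror :class:`GeneratorConfig`.  ``fit`` accepts a list
    of :class:`~pepgen.corpus.PeptideRecord` or plain sequence strings;
    after fitting, ``model_`` holds the learned :class:`SequenceModel`,
    ``trace_`` the per-epoch :class:`TrainingTrace`, and
    ``train_records_`` / ``holdout_records_`` the seeded split.

    Examples
    --------
    >>> est = PeptideLSTM(epochs=5, seed=0)
    >>> est.fit(["ARNDKLL", "WQELYKE"])        # doctest: +SKIP
    >>> est.sample(3, rng_seed=1)              # doctest: +SKIP
    """

    def __init__(self, embedding_dim: int = 50, hidden_units: int = 64,
                 epochs: int = 200, batch_size: int = 32,
                 learning_rate: float = 1e-3, holdout_fraction: float = 0.2,
                 seed: int = 0, max_generate_len: int = 20,
                 temperature: float = 1.0) -> None:
        self.embedding_dim = embedding_dim
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.holdout_fraction = holdout_fraction
        self.seed = seed
        self.max_generate_len = max_generate_len
        self.temperature = temperature

    def _config(self) -> GeneratorConfig:
        return GeneratorConfig(**{k: getattr(self, k)
                                  for k in GeneratorConfig().__dict__})

    def fit(self, X: Sequence[PeptideRecord] | Sequence[str],
            y: None = None) -> "PeptideLSTM":
        """Train the next-residue model on a peptide corpus."""
        config = self._config()
        config.validate()
        records = _coerce_records(X)
        if len(records) < 2:
            raise ValueError("corpus too small to split: need >= 2 records")
        vocab = TokenVocabulary()
        rng = np.random.default_rng(config.seed)
        params = _init_params(rng, config)

        perm = rng.permutation(len(records))
        n_holdout = int(round(config.holdout_fraction * len(records)))
        train_records = [records[i] for i in perm[: len(records) - n_holdout]]
        holdout_records = [records[i] for i in perm[len(records) - n_holdout:]]
        if not train_records:
            raise ValueError("corpus too small to split: empty training set")

        pairs = encode_training_pairs(train_records, vocab)
        prefix_lens = np.array([len(p) for p, _ in pairs])
        targets_all = np.array([t for _, t in pairs])
        # pre-pack prefixes into one left-padded matrix, batches index rows
        T = int(prefix_lens.max())
        packed = np.full((len(pairs), T), vocab.pad_index, dtype=np.int64)
        for r, (prefix, _) in enumerate(pairs):
            packed[r, T - len(prefix):] = prefix

        adam = _Adam(params, config.learning_rate)
        trace = TrainingTrace()
        for _ in range(config.epochs):
            order = rng.permutation(len(pairs))
            for start in range(0, len(pairs), config.batch_size):
                rows = order[start : start + config.batch_size]
                batch = packed[rows]
                # trim columns that are padding for the whole batch
                used = int(prefix_lens[rows].max())
                _, grads = _batch_loss_and_grads(
                    params, batch[:, T - used:], targets_all[rows],
                    vocab.pad_index)
                adam.step(params, grads)
            loss, acc = _evaluate(params, train_records, vocab)
            trace.train_loss.append(loss)
            trace.train_accuracy.append(acc)
            if holdout_records:
                hl, ha = _evaluate(params, holdout_records, vocab)
                trace.holdout_loss.append(hl)
                trace.holdout_accuracy.append(ha)

        self.vocabulary_ = vocab
        self.model_ = SequenceModel(vocabulary=vocab, config=config, **params)
        self.trace_ = trace
        self.train_records_ = train_records
        self.holdout_records_ = holdout_records
        return self

    def predict_proba(self, prefix: str = "") -> np.ndarray:
        """Next-token distribution after consuming START + ``prefix``."""
        return forward(self.model_, prefix)

    def sample(self, n_sequences: int, seed_prefix: str = "",
               rng_seed: int = 0,
               temperature: float | None = None) -> list[str]:
        """Generate peptides; see :func:`generate`."""
        config = self._config()
        if temperature is not None:
            config.temperature = temperature
        return generate(self.model_, seed_prefix, n_sequences, config,
                        rng_seed)

    def score(self, X: Sequence[PeptideRecord] | Sequence[str],
              y: None = None) -> float:
        """Argmax next-residue accuracy on a peptide set."""
        return evaluate_accuracy(self.model_, _coerce_records(X))


# ---------------------------------------------------------------------------
# functional surface

def forward(model: SequenceModel, prefix: str | Sequence[int]) -> np.ndarray:
    """Probability distribution over the 22 tokens after a prefix.

    ``prefix`` is either a residue string (START is prepended
    automatically) or an explicit token-index sequence beginning with
    the START index.
    """
    vocab = model.vocabulary
    if isinstance(prefix, str):
        tokens = [vocab.start_index] + vocab.encode(prefix)
    else:
        tokens = [int(t) for t in prefix]
        if not tokens or tokens[0] != vocab.start_index:
            raise ValueError("token prefix must begin with START")
        if any(not 0 <= t < vocab.size for t in tokens):
            raise ValueError("unknown token index in prefix")
    hs, _ = _forward_states(model._params(),
                            np.asarray([tokens]), vocab.pad_index)
    logits = hs[-1, 0] @ model.Wy + model.by
    return _softmax(logits)


def train(records: Sequence[PeptideRecord] | Sequence[str],
          config: GeneratorConfig | None = None,
          ) -> tuple[SequenceModel, TrainingTrace]:
    """Train a next-residue model; returns the model and its trace."""
    config = config or GeneratorConfig()
    est = PeptideLSTM(**config.__dict__)
    est.fit(records)
    return est.model_, est.trace_


def generate(model: SequenceModel, seed_prefix: str, n_sequences: int,
             config: GeneratorConfig | None = None,
             rng_seed: int = 0) -> list[str]:
    """Sample peptides by iterative next-residue prediction.

    Each sequence starts from START + ``seed_prefix``; tokens are drawn
    from the softmax with temperature scaling (logits / temperature;
    temperature 0 means argmax) until END is emitted or
    ``max_generate_len`` residues have been produced.  The START token
    is never emitted: its probability is masked out of the sampling
    distribution.  Output strings exclude START/END.
    """
    config = config or model.config
    if config.temperature < 0:
        raise ValueError("temperature must be >= 0")
    vocab = model.vocabulary
    params = model._params()
    H = model.hidden_units
    rng = np.random.default_rng(rng_seed)
    n = int(n_sequences)

    # consume START + seed prefix once, batched over all chains
    tokens = [vocab.start_index] + vocab.encode(seed_prefix)
    h = np.zeros((n, H))
    c = np.zeros((n, H))

    def step(idx: np.ndarray, h, c):
        x = params["embedding"][idx]
        z = x @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        o = _sigmoid(z[:, 2 * H : 3 * H])
        g = np.tanh(z[:, 3 * H :])
        c = f * c + i * g
        return o * np.tanh(c), c

    for t in tokens:
        h, c = step(np.full(n, t, dtype=np.int64), h, c)

    emitted = [list(seed_prefix) for _ in range(n)]
    active = np.full(n, len(seed_prefix) < config.max_generate_len)
    while active.any():
        logits = h @ params["Wy"] + params["by"]
        logits[:, vocab.start_index] = -np.inf  # never emit START
        if config.temperature == 0.0:
            choice = np.argmax(logits, axis=1)
        else:
            probs = _softmax(logits / config.temperature)
            u = rng.random(n)
            choice = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
        next_tok = np.where(active, choice, vocab.end_index)
        for r in range(n):
            if active[r]:
                if next_tok[r] == vocab.end_index:
                    active[r] = False
                else:
                    emitted[r].append(vocab.index_to_residue[int(next_tok[r])])
                    if len(emitted[r]) >= config.max_generate_len:
                        active[r] = False
        h, c = step(next_tok, h, c)
    return ["".join(e) for e in emitted]


def evaluate_accuracy(model: SequenceModel,
                      records: Sequence[PeptideRecord] | Sequence[str],
                      ) -> float:
    """Fraction of supervised (prefix -> next token) pairs predicted
    correctly under argmax."""
    records = _coerce_records(records)
    if not records:
        raise ValueError("cannot evaluate accuracy on an empty record list")
    _, acc = _evaluate(model._params(), records, model.vocabulary)
    return acc
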