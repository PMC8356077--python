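"""Character-level LSTM language model over SMILES with transfer learning.

The model is trained in two stages: *pretraining* on a broad drug-like
corpus teaches SMILES syntax and general chemistry, and *fine-tuning*
continues training from those weights on a small, structurally coherent
target family (here, kinase-inhibitor-like molecules), shifting the
sampling distribution toward that family without forgetting syntax.

Defaults follow the classic recipe for this architecture: two stacked LSTM
layers of 512 hidden units, dropout with keep probability 0.8 on each LSTM
layer's output, Adam at learning rate 0.003, and a sequence cross-entropy
loss averaged over non-padding positions.  Desk-scale runs (tests,
examples) use smaller instances via the config.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .corpus import TokenizedCorpus
from .nn import Adam, CharLSTM, clip_global_norm


@dataclass(frozen=True)
class GeneratorConfig:
    num_lstm_layers: int = 2
    hidden_units: int = 512
    embedding_dim: int = 64
    keep_probability: float = 0.8
    learning_rate: float = 0.003
    optimizer: str = "adam"
    batch_size: int = 64
    epochs: int = 50
    temperature: float = 0.75
    seed: int = 0
    max_grad_norm: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.keep_probability <= 1:
            raise ValueError("keep_probability must be in (0, 1]")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class GenerativeModel:
    """Trained weights + vocabulary + sampling configuration."""

    config: GeneratorConfig
    vocabulary: list[str]
    max_length: int
    net: CharLSTM
    training_log: list[float] = field(default_factory=list)

    def copy(self) -> "GenerativeModel":
        return GenerativeModel(
            config=self.config,
            vocabulary=list(self.vocabulary),
            max_length=self.max_length,
            net=copy.deepcopy(self.net),
            training_log=list(self.training_log),
        )


def _check_vocab(model_vocab: list[str], corpus: TokenizedCorpus) -> TokenizedCorpus:
    """Re-encode a corpus into the model's vocabulary; error on unseen tokens."""
    if corpus.vocabulary == model_vocab:
        return corpus
    missing = set(corpus.vocabulary) - set(model_vocab)
    # only tokens actually used matter
    used = {corpus.vocabulary[i] for seq in corpus.sequences for i in seq}
    missing &= used
    if missing:
        raise ValueError(f"corpus tokens absent from model vocabulary: {sorted(missing)}")
    out = TokenizedCorpus(vocabulary=list(model_vocab), sequences=[],
                          max_length=corpus.max_length)
    for seq in corpus.sequences:
        out.sequences.append(out.encode(corpus.decode(seq)))
    return out


def _train(net: CharLSTM, corpus: TokenizedCorpus, config: GeneratorConfig,
           log: list[float]) -> None:
    X = corpus.to_array()
    if X.size == 0:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params, lr=config.learning_rate)
    n = len(X)
    bs = min(config.batch_size, n)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            batch = X[order[start:start + bs]]
            loss, grads = net.loss_and_grads(batch, corpus.pad_id, train=True, rng=rng)
            clip_global_norm(grads, config.max_grad_norm)
            opt.step(grads)
            losses.append(loss)
        log.append(float(np.mean(losses)))


def pretrain(corpus: TokenizedCorpus, config: GeneratorConfig | None = None) -> GenerativeModel:
    """Train a fresh model on the base corpus; per-epoch mean token
    cross-entropy is recorded in ``training_log``."""
    config = config or GeneratorConfig()
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(config.seed)
    net = CharLSTM(
        vocab_size=len(corpus.vocabulary),
        emb_dim=config.embedding_dim,
        hidden=config.hidden_units,
        layers=config.num_lstm_layers,
        keep_prob=config.keep_probability,
        rng=rng,
    )
    model = GenerativeModel(config=config, vocabulary=list(corpus.vocabulary),
                            max_length=corpus.max_length, net=net)
    _train(net, corpus, config, model.training_log)
    return model


def fine_tune(model: GenerativeModel, corpus: TokenizedCorpus,
              config: GeneratorConfig | None = None) -> GenerativeModel:
    """Continue training from the model's weights on a second corpus.

    The input model is left unmodified; the corpus vocabulary must be a
    subset of the model's.
    """
    config = config or replace(model.config, epochs=100)
    corpus = _check_vocab(model.vocabulary, corpus)
    tuned = model.copy()
    tuned.config = config
    tuned.max_length = max(tuned.max_length, corpus.max_length)
    if config.epochs > 0:
        _train(tuned.net, corpus, config, tuned.training_log)
    return tuned


def sample(model: GenerativeModel, n: int, temperature: float | None = None,
           seed: int = 0) -> list[str]:
    """Draw n SMILES strings (specials stripped, END-terminated decodes).

    No validity guarantee — downstream filtering removes malformed strings.
    Temperatures below 1e-4 decode greedily.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    temperature = model.config.temperature if temperature is None else temperature
    helper = TokenizedCorpus(vocabulary=model.vocabulary, sequences=[],
                             max_length=model.max_length)
    rng = np.random.default_rng(seed)
    tokens = model.net.sample_tokens(
        n=n, max_len=model.max_length, start_id=helper.start_id,
        end_id=helper.end_id, temperature=temperature, rng=rng,
    )
    return [helper.decode(row) for row in tokens]


def save_model(model: GenerativeModel, path: str | Path) -> None:
    """Checkpoint as .npz weights + JSON sidecar (config, vocabulary, log)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.net.params)
    sidecar = {
        "config": model.config.__dict__,
        "vocabulary": model.vocabulary,
        "max_length": model.max_length,
        "training_log": model.training_log,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_model(path: str | Path) -> GenerativeModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = GeneratorConfig(**sidecar["config"])
    rng = np.random.default_rng(0)
    net = CharLSTM(
        vocab_size=len(sidecar["vocabulary"]),
        emb_dim=config.embedding_dim,
        hidden=config.hidden_units,
        layers=config.num_lstm_layers,
        keep_prob=config.keep_probability,
        rng=rng,
    )
    with np.load(path.with_suffix(".npz")) as data:
        net.params = {k: data[k] for k in data.files}
    return GenerativeModel(
        config=config,
        vocabulary=sidecar["vocabulary"],
        max_length=sidecar["max_length"],
        net=net,
        training_log=sidecar["training_log"],
    )
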