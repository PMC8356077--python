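"""Convolutional drug–target affinity (DTA) regression and ranking.

Affinity is expressed as pKd = −log10(Kd / 1e9) with Kd in nanomolar, so
1 nM ⇒ pKd 9.  The regressor follows the familiar two-branch sequence-CNN
design: ligand SMILES and protein amino-acid sequence are label-encoded at
character level, embedded, passed through three stacked 1-D convolutions
per branch with a global max pool, concatenated, and mapped through dense
layers with dropout to a scalar pKd.  Training minimizes mean squared
error with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .nn import (
    Adam,
    F32,
    clip_global_norm,
    conv1d_backward,
    conv1d_forward,
    global_max_pool,
    global_max_pool_backward,
)


def pkd_from_kd(kd_nm: float) -> float:
    """pKd = −log10(Kd / 1e9), Kd in nM; strictly decreasing in Kd."""
    if kd_nm <= 0:
        raise ValueError("kd must be positive")
    return float(-np.log10(kd_nm / 1e9))


def kd_from_pkd(pkd: float) -> float:
    """Inverse of :func:`pkd_from_kd` (returns Kd in nM)."""
    return float(1e9 * 10.0 ** (-pkd))


@dataclass(frozen=True)
class AffinityRecord:
    ligand_smiles: str
    protein_sequence: str
    kd: float | None = None
    pkd: float | None = None

    def __post_init__(self) -> None:
        if self.kd is not None and self.pkd is None:
            object.__setattr__(self, "pkd", pkd_from_kd(self.kd))


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def build_vocab(sequences: Sequence[str]) -> dict[str, int]:
    """Character → label map; label 0 is reserved for padding."""
    symbols = sorted({ch for s in sequences for ch in s})
    return {ch: i + 1 for i, ch in enumerate(symbols)}


def protein_vocab() -> dict[str, int]:
    return {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}


def label_encode(sequence: str, vocab: Mapping[str, int], max_len: int) -> np.ndarray:
    """Fixed-length integer encoding, right-padded with 0, truncated if long."""
    out = np.zeros(max_len, dtype=np.int64)
    for i, ch in enumerate(sequence[:max_len]):
        if ch not in vocab:
            raise ValueError(f"symbol {ch!r} not in vocabulary")
        out[i] = vocab[ch]
    return out


@dataclass
class DTAModelConfig:
    smiles_max_len: int = 100
    protein_max_len: int = 1000
    smiles_vocab: dict[str, int] = field(default_factory=dict)
    protein_vocab: dict[str, int] = field(default_factory=protein_vocab)
    embedding_dim: int = 32
    conv_filters: tuple[int, int, int] = (16, 32, 48)
    smiles_kernel: int = 4
    protein_kernel: int = 8
    dense_widths: tuple[int, int] = (256, 128)
    dropout: float = 0.1
    epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


class DTAModel:
    """Two-branch sequence CNN regressor for pKd."""

    def __init__(self, config: DTAModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        p: dict[str, np.ndarray] = {}

        def dense(name, din, dout):
            p[f"{name}_W"] = (rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)).astype(F32)
            p[f"{name}_b"] = np.zeros(dout, dtype=F32)

        for branch, vocab, kernel in (
            ("s", config.smiles_vocab, config.smiles_kernel),
            ("p", config.protein_vocab, config.protein_kernel),
        ):
            p[f"{branch}_emb"] = (
                rng.standard_normal((len(vocab) + 1, config.embedding_dim)) * 0.1
            ).astype(F32)
            cin = config.embedding_dim
            for i, cout in enumerate(config.conv_filters):
                p[f"{branch}_conv{i}_W"] = (
                    rng.standard_normal((kernel, cin, cout)) * np.sqrt(2.0 / (kernel * cin))
                ).astype(F32)
                p[f"{branch}_conv{i}_b"] = np.zeros(cout, dtype=F32)
                cin = cout
        concat = 2 * config.conv_filters[-1]
        dims = [concat, *config.dense_widths, 1]
        for i in range(len(dims) - 1):
            dense(f"fc{i}", dims[i], dims[i + 1])
        self.params = p
        self.n_fc = len(dims) - 1

    # -- forward -----------------------------------------------------------

    def _branch_forward(self, branch: str, ids: np.ndarray):
        p = self.params
        x = p[f"{branch}_emb"][ids]  # (B, T, E)
        caches = []
        for i in range(len(self.config.conv_filters)):
            W, b = p[f"{branch}_conv{i}_W"], p[f"{branch}_conv{i}_b"]
            out, win = conv1d_forward(x, W, b)
            mask = out > 0
            out = out * mask  # ReLU
            caches.append((x.shape, win, mask, out.shape))
            x = out
        pooled, idx = global_max_pool(x)
        return pooled, (caches, idx, x.shape, ids)

    def _branch_backward(self, branch: str, bcache, dpooled, grads):
        caches, idx, last_shape, ids = bcache
        p = self.params
        dx = global_max_pool_backward(last_shape, idx, dpooled)
        for i in range(len(self.config.conv_filters) - 1, -1, -1):
            x_shape, win, mask, _ = caches[i]
            dx = dx * mask
            W = p[f"{branch}_conv{i}_W"]
            dW, db, dx = conv1d_backward(x_shape, win, W, dx)
            grads[f"{branch}_conv{i}_W"] = dW
            grads[f"{branch}_conv{i}_b"] = db
        demb = np.zeros_like(p[f"{branch}_emb"])
        np.add.at(demb, ids, dx)
        grads[f"{branch}_emb"] = demb

    def forward(self, Xs: np.ndarray, Xp: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        p = self.params
        s_out, s_cache = self._branch_forward("s", Xs)
        p_out, p_cache = self._branch_forward("p", Xp)
        h = np.concatenate([s_out, p_out], axis=1)
        fc_caches = []
        drop = self.config.dropout
        for i in range(self.n_fc):
            W, b = p[f"fc{i}_W"], p[f"fc{i}_b"]
            z = h @ W + b
            if i < self.n_fc - 1:
                mask = z > 0
                z = z * mask
                dm = None
                if train and drop > 0:
                    dm = (rng.random(z.shape) >= drop).astype(F32) / F32(1 - drop)
                    z = z * dm
                fc_caches.append((h, mask, dm))
            else:
                fc_caches.append((h, None, None))
            h = z
        pred = h[:, 0]
        return pred, (s_cache, p_cache, fc_caches)

    def backward(self, caches, dpred: np.ndarray) -> dict[str, np.ndarray]:
        s_cache, p_cache, fc_caches = caches
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dh = dpred[:, None].astype(F32)
        for i in range(self.n_fc - 1, -1, -1):
            h_in, mask, dm = fc_caches[i]
            if dm is not None:
                dh = dh * dm
            if mask is not None:
                dh = dh * mask
            grads[f"fc{i}_W"] = h_in.T @ dh
            grads[f"fc{i}_b"] = dh.sum(axis=0)
            dh = dh @ p[f"fc{i}_W"].T
        nf = self.config.conv_filters[-1]
        self._branch_backward("s", s_cache, dh[:, :nf], grads)
        self._branch_backward("p", p_cache, dh[:, nf:], grads)
        return grads


def encode_pairs(records: Sequence[AffinityRecord], config: DTAModelConfig):
    Xs = np.stack([
        label_encode(r.ligand_smiles, config.smiles_vocab, config.smiles_max_len)
        for r in records
    ])
    Xp = np.stack([
        label_encode(r.protein_sequence, config.protein_vocab, config.protein_max_len)
        for r in records
    ])
    return Xs, Xp


def train_dta(records: Sequence[AffinityRecord],
              config: DTAModelConfig | None = None) -> DTAModel:
    """Fit the CNN regressor by MSE; per-epoch loss in ``model.training_log``."""
    if not records:
        raise ValueError("empty training set")
    if any(r.pkd is None for r in records):
        raise ValueError("all records must carry pkd (or kd)")
    config = config or DTAModelConfig()
    if not config.smiles_vocab:
        config.smiles_vocab = build_vocab([r.ligand_smiles for r in records])
    model = DTAModel(config)
    Xs, Xp = encode_pairs(records, config)
    y = np.asarray([r.pkd for r in records], dtype=F32)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    n = len(records)
    bs = min(config.batch_size, n)
    model.training_log = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            sel = order[start:start + bs]
            pred, caches = model.forward(Xs[sel], Xp[sel], train=True, rng=rng)
            err = pred - y[sel]
            losses.append(float(np.mean(err**2)))
            grads = model.backward(caches, 2.0 * err / len(sel))
            clip_global_norm(grads, 5.0)
            opt.step(grads)
        model.training_log.append(float(np.mean(losses)))
    return model


def predict_affinity(model: DTAModel, ligands: Sequence[str],
                     protein_sequence: str, batch_size: int = 256) -> list[float]:
    """One pKd per ligand against a single protein; order preserved."""
    if not ligands:
        return []
    config = model.config
    Xp1 = label_encode(protein_sequence, config.protein_vocab, config.protein_max_len)
    out: list[float] = []
    for start in range(0, len(ligands), batch_size):
        chunk = ligands[start:start + batch_size]
        Xs = np.stack([
            label_encode(s, config.smiles_vocab, config.smiles_max_len) for s in chunk
        ])
        Xp = np.tile(Xp1, (len(chunk), 1))
        pred, _ = model.forward(Xs, Xp, train=False)
        out.extend(float(v) for v in pred)
    return out


def rank_and_screen(scored: Sequence[tuple[str, float]],
                    top_k: int | None = None,
                    pkd_threshold: float | None = None) -> list[tuple[str, float]]:
    """Sort by pKd descending (ties broken by SMILES lexicographically) and
    keep the top_k entries or everything above the threshold."""
    if not scored:
        raise ValueError("nothing to rank")
    ranked = sorted(scored, key=lambda t: (-t[1], t[0]))
    if pkd_threshold is not None:
        ranked = [t for t in ranked if t[1] > pkd_threshold]
    if top_k is not None:
        ranked = ranked[:top_k]
    return ranked
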