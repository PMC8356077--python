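"""Minimal NumPy neural-network core: Adam, stacked LSTM, 1-D convolutions.

Implements exactly the two architectures the package needs — a character
LSTM language model and a two-branch convolutional regressor — with manual
backpropagation in float32.  Everything is deterministic given a
``numpy.random.Generator``; dropout is inverted (scaled at train time) and
never applied at inference.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adaptive-moment optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            self.params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = F32(max_norm / (total + 1e-12))
        for g in grads.values():
            g *= scale


# --------------------------------------------------------------------------
# Stacked LSTM character language model
# --------------------------------------------------------------------------

class CharLSTM:
    """Stacked-LSTM next-token model with output dropout per LSTM layer.

    Dropout is applied to the non-recurrent (upward) connections only, with
    the configured keep probability; the recurrent state stays undropped.
    """

    def __init__(self, vocab_size: int, emb_dim: int, hidden: int,
                 layers: int, keep_prob: float, rng: np.random.Generator):
        self.V, self.E, self.H, self.L = vocab_size, emb_dim, hidden, layers
        self.keep_prob = keep_prob
        p: dict[str, np.ndarray] = {}
        p["emb"] = (rng.standard_normal((vocab_size, emb_dim)) * 0.1).astype(F32)
        for l in range(layers):
            din = emb_dim if l == 0 else hidden
            scale = 1.0 / np.sqrt(din + hidden)
            p[f"Wx{l}"] = (rng.standard_normal((din, 4 * hidden)) * scale).astype(F32)
            p[f"Wh{l}"] = (rng.standard_normal((hidden, 4 * hidden)) * scale).astype(F32)
            b = np.zeros(4 * hidden, dtype=F32)
            b[hidden:2 * hidden] = 1.0  # forget-gate bias
            p[f"b{l}"] = b
        p["Wo"] = (rng.standard_normal((hidden, vocab_size)) * (1.0 / np.sqrt(hidden))).astype(F32)
        p["bo"] = np.zeros(vocab_size, dtype=F32)
        self.params = p

    # -- single LSTM layer over a full sequence ---------------------------

    def _layer_forward(self, l: int, inp: np.ndarray):
        B, T, _ = inp.shape
        H = self.H
        Wx, Wh, b = self.params[f"Wx{l}"], self.params[f"Wh{l}"], self.params[f"b{l}"]
        dt = inp.dtype
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        out = np.empty((B, T, H), dtype=dt)
        cache = []
        x_proj = inp @ Wx  # precompute input contribution for all t
        for t in range(T):
            z = x_proj[:, t] + h @ Wh + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t] = h
            cache.append((i, f, g, o, c_prev, h_prev, tc))
        return out, cache

    def _layer_backward(self, l: int, inp: np.ndarray, cache, dout: np.ndarray,
                        grads: dict[str, np.ndarray]) -> np.ndarray:
        B, T, _ = inp.shape
        H = self.H
        Wx, Wh = self.params[f"Wx{l}"], self.params[f"Wh{l}"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H, dtype=inp.dtype)
        dinp = np.empty_like(inp)
        dh_next = np.zeros((B, H), dtype=inp.dtype)
        dc_next = np.zeros((B, H), dtype=inp.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = cache[t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += inp[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ Wh.T
            dinp[:, t] = dz @ Wx.T
        grads[f"Wx{l}"] = dWx
        grads[f"Wh{l}"] = dWh
        grads[f"b{l}"] = db
        return dinp

    # -- full forward/backward on a padded batch ---------------------------

    def loss_and_grads(self, X: np.ndarray, pad_id: int, train: bool,
                       rng: np.random.Generator | None):
        """Masked next-token cross-entropy on a (B, T) int batch; PAD targets
        are excluded from the loss. Returns (loss, grads)."""
        inputs, targets = X[:, :-1], X[:, 1:]
        B, T = inputs.shape
        mask = (targets != pad_id).astype(self.params["emb"].dtype)
        n_tok = max(mask.sum(), 1.0)

        emb = self.params["emb"]
        seq = emb[inputs]  # (B, T, E)
        layer_inputs = [seq]
        caches = []
        drop_masks = []
        for l in range(self.L):
            out, cache = self._layer_forward(l, layer_inputs[-1])
            caches.append(cache)
            if train and self.keep_prob < 1.0:
                dm = (rng.random(out.shape) < self.keep_prob).astype(out.dtype) / out.dtype.type(self.keep_prob)
                out = out * dm
                drop_masks.append(dm)
            else:
                drop_masks.append(None)
            layer_inputs.append(out)

        top = layer_inputs[-1]
        logits = top @ self.params["Wo"] + self.params["bo"]
        probs = softmax(logits)
        tgt_prob = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
        loss = float(-(np.log(np.maximum(tgt_prob, 1e-12)) * mask).sum() / n_tok)

        grads: dict[str, np.ndarray] = {}
        dlogits = probs
        np.add.at(dlogits, (np.arange(B)[:, None], np.arange(T)[None, :], targets), -1.0)
        dlogits *= (mask / n_tok)[..., None]
        flat_top = top.reshape(-1, self.H)
        grads["Wo"] = flat_top.T @ dlogits.reshape(-1, self.V)
        grads["bo"] = dlogits.sum(axis=(0, 1))
        dcur = dlogits @ self.params["Wo"].T
        for l in range(self.L - 1, -1, -1):
            if drop_masks[l] is not None:
                dcur = dcur * drop_masks[l]
            dcur = self._layer_backward(l, layer_inputs[l], caches[l], dcur, grads)
        demb = np.zeros_like(emb)
        np.add.at(demb, inputs, dcur)
        grads["emb"] = demb
        return loss, grads

    # -- autoregressive sampling -------------------------------------------

    def sample_tokens(self, n: int, max_len: int, start_id: int, end_id: int,
                      temperature: float, rng: np.random.Generator) -> np.ndarray:
        """Sample n token sequences; temperatures below 1e-4 decode greedily.
        Returns an (n, max_len) int array beginning with START."""
        H = self.H
        dt = self.params["emb"].dtype
        h = [np.zeros((n, H), dtype=dt) for _ in range(self.L)]
        c = [np.zeros((n, H), dtype=dt) for _ in range(self.L)]
        tokens = np.full((n, max_len), end_id, dtype=np.int64)
        tokens[:, 0] = start_id
        x = np.full(n, start_id, dtype=np.int64)
        done = np.zeros(n, dtype=bool)
        for t in range(1, max_len):
            inp = self.params["emb"][x]
            for l in range(self.L):
                Wx, Wh, b = (self.params[f"Wx{l}"], self.params[f"Wh{l}"],
                             self.params[f"b{l}"])
                z = inp @ Wx + h[l] @ Wh + b
                i = sigmoid(z[:, :H])
                f = sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = sigmoid(z[:, 3 * H:])
                c[l] = f * c[l] + i * g
                h[l] = o * np.tanh(c[l])
                inp = h[l]
            logits = inp @ self.params["Wo"] + self.params["bo"]
            if temperature < 1e-4:
                nxt = logits.argmax(axis=1)
            else:
                p = softmax(logits / temperature)
                u = rng.random((n, 1))
                nxt = (p.cumsum(axis=1) < u).sum(axis=1)
            nxt = np.where(done, end_id, nxt)
            tokens[:, t] = nxt
            done |= nxt == end_id
            x = nxt
            if done.all():
                break
        return tokens


# --------------------------------------------------------------------------
# 1-D convolution pieces for the affinity regressor
# --------------------------------------------------------------------------

def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 1-D convolution: x (B, T, Cin), W (k, Cin, Cout) -> (B, T-k+1, Cout)."""
    k = W.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, To, Cin, k)
    out = np.tensordot(win, W, axes=([3, 2], [0, 1])) + b
    return out.astype(x.dtype), win


def conv1d_backward(x_shape, win: np.ndarray, W: np.ndarray, dout: np.ndarray):
    k = W.shape[0]
    dW = np.tensordot(win, dout, axes=([0, 1], [0, 1])).transpose(1, 0, 2).astype(W.dtype)
    db = dout.sum(axis=(0, 1)).astype(W.dtype)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    To = dout.shape[1]
    for i in range(k):
        dx[:, i:i + To, :] += dout @ W[i].T
    return dW, db, dx


def global_max_pool(x: np.ndarray):
    idx = x.argmax(axis=1)
    out = np.take_along_axis(x, idx[:, None, :], axis=1)[:, 0, :]
    return out, idx


def global_max_pool_backward(x_shape, idx: np.ndarray, dout: np.ndarray) -> np.ndarray:
    dx = np.zeros(x_shape, dtype=dout.dtype)
    B, C = dout.shape
    np.put_along_axis(dx, idx[:, None, :], dout[:, None, :], axis=1)
    return dx
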