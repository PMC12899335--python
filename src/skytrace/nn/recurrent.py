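"""Single-direction LSTM and GRU layers with backpropagation through time.

Weight layout follows the common convention of stacking the gate blocks
along the first axis of ``W_ih`` (input-to-hidden) and ``W_hh``
(hidden-to-hidden): gates ``i, f, g, o`` for the LSTM and ``r, z, n``
for the GRU, each block of size ``hidden``.  The GRU uses the variant
where the reset gate multiplies the *hidden projection* of the
candidate, ``n = tanh(W_in x + b_in + r * (W_hn h + b_hn))``.

All parameters are initialised uniformly on ``[-k, k]`` with
``k = 1/sqrt(hidden)``.  ``forward`` caches the per-step activations
needed by ``backward``; gradients accumulate into ``grads`` (zeroed by
``zero_grad``), which lets a bidirectional wrapper call backward once
per direction before an optimiser step.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RecurrentLayer"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class RecurrentLayer:
    """One direction of an LSTM or GRU over a batch-first sequence."""

    def __init__(self, input_size: int, hidden_size: int, cell: str,
                 rng: np.random.Generator) -> None:
        if cell not in ("lstm", "gru"):
            raise ValueError(f"unknown cell type {cell!r}")
        self.cell = cell
        self.input_size = input_size
        self.hidden_size = hidden_size
        n_gates = 4 if cell == "lstm" else 3
        k = 1.0 / np.sqrt(hidden_size)
        def init(*shape):
            return rng.uniform(-k, k, size=shape)
        self.params = {
            "W_ih": init(n_gates * hidden_size, input_size),
            "W_hh": init(n_gates * hidden_size, hidden_size),
            "b_ih": init(n_gates * hidden_size),
            "b_hh": init(n_gates * hidden_size),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cache = None

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    # ------------------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """Run the layer over ``X`` of shape (B, T, D); returns (B, T, H)."""
        B, T, D = X.shape
        H = self.hidden_size
        W_ih, W_hh = self.params["W_ih"], self.params["W_hh"]
        b = self.params["b_ih"] + self.params["b_hh"]
        # hidden-bias must stay separate for the GRU candidate gate
        b_hn = self.params["b_hh"][2 * H:3 * H] if self.cell == "gru" else None

        h = np.zeros((B, H))
        out = np.empty((B, T, H))
        steps = []
        if self.cell == "lstm":
            c = np.zeros((B, H))
            for t in range(T):
                x_t = X[:, t]
                a = x_t @ W_ih.T + h @ W_hh.T + b
                i = _sigmoid(a[:, :H])
                f = _sigmoid(a[:, H:2 * H])
                g = np.tanh(a[:, 2 * H:3 * H])
                o = _sigmoid(a[:, 3 * H:])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                steps.append((x_t, h, c, i, f, g, o, tc))
                h, c = h_new, c_new
                out[:, t] = h
        else:
            for t in range(T):
                x_t = X[:, t]
                a_i = x_t @ W_ih.T + self.params["b_ih"]
                a_h = h @ W_hh.T + self.params["b_hh"]
                r = _sigmoid(a_i[:, :H] + a_h[:, :H])
                z = _sigmoid(a_i[:, H:2 * H] + a_h[:, H:2 * H])
                hn = a_h[:, 2 * H:]          # W_hn h + b_hn
                n = np.tanh(a_i[:, 2 * H:] + r * hn)
                h_new = (1.0 - z) * n + z * h
                steps.append((x_t, h, r, z, n, hn))
                h = h_new
                out[:, t] = h
        self._cache = (X.shape, steps)
        return out

    # ------------------------------------------------------------------
    def backward(self, dOut: np.ndarray) -> np.ndarray:
        """Backpropagate ``dOut`` (B, T, H); returns dX and accumulates grads."""
        (B, T, D), steps = self._cache
        H = self.hidden_size
        W_ih, W_hh = self.params["W_ih"], self.params["W_hh"]
        gW_ih, gW_hh = self.grads["W_ih"], self.grads["W_hh"]
        gb_ih, gb_hh = self.grads["b_ih"], self.grads["b_hh"]
        dX = np.empty((B, T, D))
        dh_next = np.zeros((B, H))

        if self.cell == "lstm":
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                x_t, h_prev, c_prev, i, f, g, o, tc = steps[t]
                dh = dOut[:, t] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc * tc)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                da = np.concatenate([
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ], axis=1)
                gW_ih += da.T @ x_t
                gW_hh += da.T @ h_prev
                s = da.sum(axis=0)
                gb_ih += s
                gb_hh += s
                dX[:, t] = da @ W_ih
                dh_next = da @ W_hh
                dc_next = dc * f
        else:
            for t in range(T - 1, -1, -1):
                x_t, h_prev, r, z, n, hn = steps[t]
                dh = dOut[:, t] + dh_next
                dz = dh * (h_prev - n)
                dn = dh * (1.0 - z)
                dh_prev = dh * z
                da_n = dn * (1.0 - n * n)
                dr = da_n * hn
                d_hn = da_n * r                      # grad of W_hn h + b_hn
                da_r = dr * r * (1.0 - r)
                da_z = dz * z * (1.0 - z)
                da_i = np.concatenate([da_r, da_z, da_n], axis=1)
                da_h = np.concatenate([da_r, da_z, d_hn], axis=1)
                gW_ih += da_i.T @ x_t
                gW_hh += da_h.T @ h_prev
                gb_ih += da_i.sum(axis=0)
                gb_hh += da_h.sum(axis=0)
                dX[:, t] = da_i @ W_ih
                dh_next = dh_prev + da_h @ W_hh
        return dX
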