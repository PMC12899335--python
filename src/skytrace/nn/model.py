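"""Stacked bidirectional recurrent classifier with a per-frame sigmoid head.

Architecture: ``n_layers`` stacked bidirectional LSTM (or GRU) layers,
hidden size ``hidden`` per direction, inverted dropout between stacked
layers (training mode only), and an affine head mapping the
``2 * hidden`` concatenated states of the top layer to one logit per
frame, squashed through the logistic function.
"""

from __future__ import annotations

import numpy as np

from .recurrent import RecurrentLayer, _sigmoid

__all__ = ["BiRNNClassifier"]


class BiRNNClassifier:
    """Bidirectional recurrent per-frame binary classifier."""

    def __init__(self, input_size: int = 3, hidden: int = 64, n_layers: int = 2,
                 dropout: float = 0.2, cell: str = "lstm",
                 rng: np.random.Generator | None = None) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.input_size = input_size
        self.hidden = hidden
        self.n_layers = n_layers
        self.dropout = dropout
        self.cell = cell
        self.layers: list[tuple[RecurrentLayer, RecurrentLayer]] = []
        d = input_size
        for _ in range(n_layers):
            fwd = RecurrentLayer(d, hidden, cell, rng)
            bwd = RecurrentLayer(d, hidden, cell, rng)
            self.layers.append((fwd, bwd))
            d = 2 * hidden
        k = 1.0 / np.sqrt(2 * hidden)
        self.head_w = rng.uniform(-k, k, size=2 * hidden)
        self.head_b = rng.uniform(-k, k, size=1)
        self.g_head_w = np.zeros_like(self.head_w)
        self.g_head_b = np.zeros(1)
        self._cache = None

    # ------------------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        """Flat list of parameter arrays (head bias as a length-1 array)."""
        params = []
        for fwd, bwd in self.layers:
            for layer in (fwd, bwd):
                params.extend(layer.params[k] for k in ("W_ih", "W_hh", "b_ih", "b_hh"))
        params.append(self.head_w)
        params.append(self.head_b)
        return params

    def gradients(self) -> list[np.ndarray]:
        grads = []
        for fwd, bwd in self.layers:
            for layer in (fwd, bwd):
                grads.extend(layer.grads[k] for k in ("W_ih", "W_hh", "b_ih", "b_hh"))
        grads.append(self.g_head_w)
        grads.append(self.g_head_b)
        return grads

    def zero_grad(self) -> None:
        for fwd, bwd in self.layers:
            fwd.zero_grad()
            bwd.zero_grad()
        self.g_head_w[...] = 0.0
        self.g_head_b[...] = 0.0

    def get_weights(self) -> dict[str, np.ndarray]:
        """Snapshot of all weights (copies), keyed for persistence."""
        out = {}
        for li, (fwd, bwd) in enumerate(self.layers):
            for tag, layer in (("f", fwd), ("b", bwd)):
                for k, v in layer.params.items():
                    out[f"layer{li}_{tag}_{k}"] = v.copy()
        out["head_w"] = self.head_w.copy()
        out["head_b"] = self.head_b.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for li, (fwd, bwd) in enumerate(self.layers):
            for tag, layer in (("f", fwd), ("b", bwd)):
                for k in layer.params:
                    layer.params[k][...] = weights[f"layer{li}_{tag}_{k}"]
        self.head_w[...] = weights["head_w"]
        self.head_b[...] = np.asarray(weights["head_b"]).reshape(1)

    # ------------------------------------------------------------------
    def forward(self, X: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-frame probabilities of shape (B, T) for input (B, T, 3).

        Dropout between stacked layers is active only when
        ``train=True`` (which then requires ``rng``).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.input_size:
            raise ValueError(f"expected input of shape (B, T, {self.input_size})")
        h = X
        drop_masks = []
        for li, (fwd, bwd) in enumerate(self.layers):
            hf = fwd.forward(h)
            hb = bwd.forward(h[:, ::-1])[:, ::-1]
            h = np.concatenate([hf, hb], axis=2)
            if train and self.dropout > 0 and li < self.n_layers - 1:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
                drop_masks.append(mask)
            else:
                drop_masks.append(None)
        logits = h @ self.head_w + self.head_b[0]
        probs = _sigmoid(logits)
        self._cache = (h, drop_masks)
        return probs

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate loss gradients w.r.t. the per-frame logits."""
        h_top, drop_masks = self._cache
        self.g_head_w += np.einsum("bt,bth->h", dlogits, h_top)
        self.g_head_b[0] += float(dlogits.sum())
        dh = dlogits[:, :, None] * self.head_w[None, None, :]
        for li in range(self.n_layers - 1, -1, -1):
            fwd, bwd = self.layers[li]
            if drop_masks[li] is not None:
                dh = dh * drop_masks[li]
            H = self.hidden
            dXf = fwd.backward(dh[:, :, :H])
            dXb = bwd.backward(dh[:, ::-1, H:])[:, ::-1]
            dh = dXf + dXb
        # dh is now the gradient w.r.t. the network input; not needed further
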