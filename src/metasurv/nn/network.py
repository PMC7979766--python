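"""Network container and the Adam optimizer.

A :class:`Network` holds an optional convolutional image branch and a dense
head.  When both an image branch and a clinical input are present, the
flattened convolutional features are concatenated with the clinical vector
before the head — the fusion architecture.  A purely clinical network has no
image branch and feeds the clinical vector straight into the head.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .layers import Layer

__all__ = ["Network", "Adam"]


class Network:
    def __init__(self, image_layers: list[Layer] | None,
                 head_layers: list[Layer], clinical_width: int = 0) -> None:
        self.image_layers = image_layers or []
        self.head_layers = head_layers
        self.clinical_width = clinical_width

    # -- forward / backward -------------------------------------------------
    def forward(self, x_image: np.ndarray | None = None,
                x_clinical: np.ndarray | None = None, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        feats = None
        if self.image_layers:
            if x_image is None:
                raise ValueError("network has an image branch but no image input given")
            h = x_image
            for layer in self.image_layers:
                h = layer.forward(h, training=training, rng=rng)
            feats = h
        if self.clinical_width:
            if x_clinical is None:
                raise ValueError("network expects a clinical input")
            if x_clinical.shape[1] != self.clinical_width:
                raise ValueError(
                    f"clinical width {x_clinical.shape[1]} != expected {self.clinical_width}")
            feats = x_clinical.astype(np.float32) if feats is None else \
                np.concatenate([feats, x_clinical.astype(np.float32)], axis=1)
        self._n_image_features = feats.shape[1] - self.clinical_width \
            if self.image_layers else 0
        h = feats
        for layer in self.head_layers:
            h = layer.forward(h, training=training, rng=rng)
        return h

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.head_layers):
            dy = layer.backward(dy)
        if self.image_layers:
            dy = dy[:, : self._n_image_features]  # clinical branch has no parameters
            for layer in reversed(self.image_layers):
                dy = layer.backward(dy)

    # -- parameter access ---------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        return [*self.image_layers, *self.head_layers]

    def parameters(self):
        """Yields (param, grad, decay_flag) triples across all layers."""
        for layer in self.layers:
            yield from zip(layer.params, layer.grads, layer.param_decay)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    def save(self, path: str | Path) -> None:
        np.savez(path, *self.get_weights())

    def load(self, path: str | Path) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))])


class Adam:
    """Adam with decoupled-equivalent L2 weight decay added to the gradient."""

    def __init__(self, network: Network, learning_rate: float,
                 weight_decay: float = 0.0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = network
        self.lr = learning_rate
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in network.parameters()]
        self.v = [np.zeros_like(p) for p, _, _ in network.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g, decay) in enumerate(self.net.parameters()):
            grad = g + self.wd * p if (decay and self.wd) else g
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
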