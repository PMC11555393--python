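"""Graph executor: instantiate a LayerGraph as a runnable NumPy network."""

from __future__ import annotations

import pickle
from pathlib import Path
from typing import List, Optional

import numpy as np

from ..graph import LayerGraph, LayerSpec
from . import layers as L


class ShapeError(ValueError):
    """Raised when an input batch does not match the network geometry."""


def _instantiate(spec: LayerSpec, rng: np.random.Generator,
                 dropout_rng: np.random.Generator) -> Optional[L.Layer]:
    if spec.kind == "conv":
        return L.Conv2d(spec.in_channels, spec.out_channels, spec.kernel,
                        spec.stride, spec.pad_amount, spec.groups, spec.bias,
                        rng)
    if spec.kind == "batchnorm":
        return L.BatchNorm2d(spec.out_channels)
    if spec.kind == "relu":
        return L.ReLU()
    if spec.kind == "maxpool":
        return L.MaxPool2d(spec.kernel, spec.stride, spec.ceil_mode)
    if spec.kind == "avgpool":
        return L.AvgPool2d(spec.kernel, spec.stride, spec.ceil_mode)
    if spec.kind == "dropout":
        return L.Dropout(spec.rate, dropout_rng)
    if spec.kind == "concat":
        return L.Concat()
    if spec.kind == "add":
        return L.Add()
    if spec.kind == "flatten":
        return L.Flatten()
    if spec.kind == "dense":
        return L.Dense(spec.in_channels, spec.out_channels, spec.bias, rng)
    if spec.kind == "softmax":
        return L.Softmax()
    if spec.kind == "input":
        return None
    raise ValueError(f"cannot instantiate layer kind {spec.kind!r}")


class Network:
    """Runnable network derived from a symbolic layer graph.

    Weight initialization (Xavier uniform) and dropout draws are fully
    determined by ``seed``; inference mode is deterministic.
    """

    def __init__(self, graph: LayerGraph, seed: int = 0,
                 input_size: Optional[int] = None):
        graph.validate()
        self.graph = graph
        self.input_size = input_size
        init_rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(
            init_rng.integers(0, 2 ** 31))
        self.modules: List[Optional[L.Layer]] = [
            _instantiate(spec, init_rng, self.dropout_rng)
            for spec in graph.nodes]
        self._order = graph.topological_order()
        self._children = graph.children()

    # -- parameter access -------------------------------------------------

    def parameters(self) -> List[L.Param]:
        out: List[L.Param] = []
        for m in self.modules:
            if m is not None:
                out.extend(m.params)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- execution ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Run a batch through the graph; returns per-class probabilities."""
        if x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4:
            raise ShapeError(f"expected a (batch, channels, h, w) array, "
                             f"got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("input batch contains non-finite values")
        spec_in = self.graph.nodes[self.graph.input_id]
        if x.shape[1] != spec_in.in_channels:
            raise ShapeError(f"expected {spec_in.in_channels} input channels, "
                             f"got {x.shape[1]}")
        if self.input_size is not None and x.shape[-2:] != (self.input_size,
                                                            self.input_size):
            raise ShapeError(
                f"expected {self.input_size}x{self.input_size} inputs, "
                f"got {x.shape[-2]}x{x.shape[-1]}")
        self._train_mode = train
        outputs: List[Optional[np.ndarray]] = [None] * len(self.graph)
        for i in self._order:
            parents = self.graph.parents[i]
            if not parents:
                outputs[i] = x.astype(np.float64, copy=False)
                continue
            inputs = [outputs[p] for p in parents]
            outputs[i] = self.modules[i].forward(inputs, train)
        self._outputs = outputs
        return outputs[self.graph.output_id]

    def backward(self, grad_at: int, grad: np.ndarray) -> None:
        """Backpropagate from node ``grad_at`` seeded with ``grad``."""
        grads: List[Optional[np.ndarray]] = [None] * len(self.graph)
        grads[grad_at] = grad
        for i in reversed(self._order):
            if i > grad_at or grads[i] is None:
                continue
            if not self.graph.parents[i]:
                continue
            pgrads = self.modules[i].backward(grads[i])
            for p, g in zip(self.graph.parents[i], pgrads):
                if grads[p] is None:
                    grads[p] = g.copy()
                else:
                    grads[p] += g
        self._input_grad = grads[self.graph.input_id]

    def loss_and_backward(self, x: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
        """Softmax cross-entropy loss + full backward pass.

        The gradient is seeded at the softmax *input* (logits) as
        ``(p - y) / N``, the fused softmax/cross-entropy form.
        """
        probs = self.forward(x, train=True)
        n = len(labels)
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(n), labels] + eps)))
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        grad /= n
        softmax_id = self.graph.output_id
        (logits_id,) = self.graph.parents[softmax_id]
        self.backward(logits_id, grad)
        return loss, probs

    def finalize_batchnorm(self, images: np.ndarray,
                           batch_size: int = 64) -> None:
        """Re-estimate batch-norm statistics over a dataset.

        After the last optimizer step the exponential running statistics lag
        the final weights; this pass freezes each batch-norm layer's
        statistics to the average over the given data (dropout disabled), so
        inference reflects the trained network.
        """
        bns = [m for m in self.modules
               if isinstance(m, L.BatchNorm2d)]
        for m in bns:
            m.start_collect()
        for i in range(0, len(images), batch_size):
            self.forward(images[i:i + batch_size], train=False)
        for m in bns:
            m.finish_collect()

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict:
        state = {"params": [p.value.copy() for p in self.parameters()],
                 "bn": []}
        for m in self.modules:
            if isinstance(m, L.BatchNorm2d):
                state["bn"].append((m.running_mean.copy(),
                                    m.running_var.copy()))
        return state

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(params) != len(state["params"]):
            raise ValueError("state does not match network structure")
        for p, v in zip(params, state["params"]):
            p.value[...] = v
        bn_modules = [m for m in self.modules if isinstance(m, L.BatchNorm2d)]
        for m, (mean, var) in zip(bn_modules, state["bn"]):
            m.running_mean[...] = mean
            m.running_var[...] = var

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self.state_dict()))

    def load(self, path: str | Path) -> None:
        self.load_state_dict(pickle.loads(Path(path).read_bytes()))
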