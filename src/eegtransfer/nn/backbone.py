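"""Convolutional backbones partitioned into three transfer-learning stages.

Deep-adaptation networks split a backbone into:

* a **frozen** early stage extracting generic features (parameters never
  updated),
* a **fine-tuned** middle stage whose parameters keep training on the new
  task,
* an **adapted** head of fully connected layers whose representations are
  aligned across domains by the adaptation loss.

``smallcnn`` is a 5-conv / 3-fc network (conv1–3 frozen, conv4–5
fine-tuned, fc6–8 adapted).  ``resnet`` is a compact residual variant with
four stages of basic blocks: stages 1–2 frozen, stages 3–4 fine-tuned, and
the fully connected head adapted.  How a residual network maps onto the
three-part scheme is a design choice of this package.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidArgumentError
from .layers import (Conv2d, Flatten, GlobalAvgPool, Layer, Linear, MaxPool2d,
                     ReLU, Sequential)


class BasicBlock(Layer):
    """Residual block: x + conv(relu(conv(x))), relu applied after the add."""

    def __init__(self, rng: np.random.Generator, channels: int) -> None:
        super().__init__()
        self.conv1 = Conv2d(rng, channels, channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(rng, channels, channels)
        self.relu_out = ReLU()

    @property
    def children(self) -> list[Layer]:
        return [self.conv1, self.conv2]

    def forward(self, x: np.ndarray) -> np.ndarray:
        branch = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(branch + x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        g_branch = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return g_branch + g

    def zero_grads(self) -> None:
        for child in self.children:
            child.zero_grads()

    # expose child parameters through the Sequential protocol
    @property
    def params(self):  # type: ignore[override]
        return {}

    @params.setter
    def params(self, value) -> None:
        pass

    @property
    def trainable(self) -> bool:  # type: ignore[override]
        return all(c.trainable for c in self.children)

    @trainable.setter
    def trainable(self, value: bool) -> None:
        for c in self.children:
            c.trainable = value


class _ResidualSequential(Sequential):
    """Sequential that also yields parameters nested inside BasicBlocks."""

    def parameters(self):
        for layer in self.layers:
            if isinstance(layer, BasicBlock):
                for child in layer.children:
                    for name in child.params:
                        yield child, name
            else:
                for name in layer.params:
                    yield layer, name


class Backbone:
    """A three-stage feature extractor plus fully connected head.

    ``frozen`` and ``finetune`` are convolutional; the adapted head is
    fc6 → ReLU → fc7 → ReLU → fc8 (class logits).  ``forward_head``
    returns the per-layer head activations (post-ReLU for fc6/fc7, logits
    for fc8) so one adaptation term can be attached to each.
    """

    def __init__(self, frozen: Sequential, finetune: Sequential,
                 rng: np.random.Generator, feat_dim: int,
                 fc_dims: tuple[int, int] = (64, 32), n_classes: int = 2):
        self.frozen = frozen
        self.finetune = finetune
        for layer, _ in frozen.parameters():
            layer.trainable = False
        self.fc6 = Linear(rng, feat_dim, fc_dims[0])
        self.relu6 = ReLU()
        self.fc7 = Linear(rng, fc_dims[0], fc_dims[1])
        self.relu7 = ReLU()
        self.fc8 = Linear(rng, fc_dims[1], n_classes)
        self.head = Sequential([self.fc6, self.relu6, self.fc7, self.relu7, self.fc8])
        self.n_classes = n_classes

    # -- forward ----------------------------------------------------------
    def forward_frozen(self, x: np.ndarray) -> np.ndarray:
        """Frozen-stage features; safe to cache since the stage never trains."""
        return self.frozen.forward(x.astype(np.float32))

    def forward_rest(self, frozen_feats: np.ndarray
                     ) -> tuple[list[np.ndarray], np.ndarray]:
        """Fine-tuned stage + head.  Returns ([a6, a7, logits], logits)."""
        f = self.finetune.forward(frozen_feats)
        a6 = self.relu6.forward(self.fc6.forward(f))
        a7 = self.relu7.forward(self.fc7.forward(a6))
        logits = self.fc8.forward(a7)
        return [a6, a7, logits], logits

    def forward(self, x: np.ndarray) -> np.ndarray:
        _, logits = self.forward_rest(self.forward_frozen(x))
        return logits

    # -- backward ---------------------------------------------------------
    def backward_rest(self, grad_logits: np.ndarray,
                      head_grads: list[np.ndarray] | None = None) -> None:
        """Backprop through head and fine-tuned stage.

        ``head_grads`` optionally adds one extra gradient per head
        activation (adaptation-loss terms on a6, a7 and the logits).
        Backpropagation stops at the frozen stage boundary.
        """
        g6 = g7 = g8 = None
        if head_grads is not None:
            g6, g7, g8 = head_grads
        g = grad_logits if g8 is None else grad_logits + g8
        g = self.fc8.backward(g)
        if g7 is not None:
            g = g + g7
        g = self.fc7.backward(self.relu7.backward(g))
        if g6 is not None:
            g = g + g6
        g = self.fc6.backward(self.relu6.backward(g))
        self.finetune.backward(g)

    # -- bookkeeping ------------------------------------------------------
    def zero_grads(self) -> None:
        self.finetune.zero_grads()
        self.head.zero_grads()

    def trainable_modules(self) -> list[Sequential]:
        return [self.finetune, self.head]

    def frozen_parameter_vector(self) -> np.ndarray:
        """Concatenated copy of all frozen-stage parameters (audit support)."""
        parts = [layer.params[name].ravel().copy()
                 for layer, name in self.frozen.parameters()]
        return np.concatenate(parts) if parts else np.zeros(0, dtype=np.float32)

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters keyed by stage/index/name, for checkpointing."""
        out: dict[str, np.ndarray] = {}
        for stage_name, stage in (("frozen", self.frozen),
                                  ("finetune", self.finetune),
                                  ("head", self.head)):
            for i, (layer, name) in enumerate(stage.parameters()):
                out[f"{stage_name}.{i}.{name}"] = layer.params[name]
        return out


def _probe_dim(stages: list[Sequential], input_shape: tuple[int, int, int]) -> int:
    x = np.zeros((1, *input_shape), dtype=np.float32)
    for stage in stages:
        x = stage.forward(x)
    return int(np.prod(x.shape[1:]))


def build_backbone(name: str, input_shape: tuple[int, int, int],
                   n_classes: int = 2, seed: int = 0) -> Backbone:
    """Construct a named backbone for images of ``input_shape`` = (C, H, W)."""
    rng = np.random.default_rng(seed)
    c, h, w = input_shape
    if h < 32 or w < 32:
        raise InvalidArgumentError("backbones expect images of at least 32×32")
    if name == "smallcnn":
        frozen = Sequential([
            Conv2d(rng, c, 8), ReLU(), MaxPool2d(),      # conv1
            Conv2d(rng, 8, 16), ReLU(), MaxPool2d(),     # conv2
            Conv2d(rng, 16, 16), ReLU(), MaxPool2d(),    # conv3
        ])
        finetune = Sequential([
            Conv2d(rng, 16, 32), ReLU(), MaxPool2d(),    # conv4
            Conv2d(rng, 32, 32), ReLU(),                 # conv5
            Flatten(),
        ])
    elif name == "resnet":
        frozen = _ResidualSequential([
            Conv2d(rng, c, 8), ReLU(),                   # stem
            BasicBlock(rng, 8), MaxPool2d(),             # stage 1
            Conv2d(rng, 8, 16), ReLU(),
            BasicBlock(rng, 16), MaxPool2d(),            # stage 2
        ])
        finetune = _ResidualSequential([
            Conv2d(rng, 16, 32), ReLU(),
            BasicBlock(rng, 32), MaxPool2d(),            # stage 3
            Conv2d(rng, 32, 32), ReLU(),
            BasicBlock(rng, 32), MaxPool2d(),            # stage 4
            GlobalAvgPool(),
        ])
    else:
        raise InvalidArgumentError(f"unknown backbone {name!r}")
    feat_dim = _probe_dim([frozen, finetune], input_shape)
    return Backbone(frozen, finetune, rng, feat_dim, n_classes=n_classes)
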