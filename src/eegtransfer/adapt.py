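"""Deep domain adaptation: losses, model assembly and training.

The core quantity is the multi-kernel maximum mean discrepancy (MK-MMD)
between the source and target feature distributions p and q,

    d_k²(p, q) = ‖ E_p[φ(x_s)] − E_q[φ(x_t)] ‖²_{H_k},

the RKHS distance between the mean embeddings of p and q under a
characteristic kernel k = Σ_u β_u k_u, a convex combination (Σβ_u = 1,
β_u ≥ 0) of m positive semi-definite kernels.  d_k²(p, q) = 0 iff p = q,
so driving the empirical estimate down aligns the two domains' deep
features.  The deep adaptation network (DAN) attaches one MK-MMD term to
each fully connected head layer while early convolutional layers stay
frozen and middle layers fine-tune.

Two alternative alignment strategies are provided for comparison:
adversarial alignment through a gradient-reversal layer and domain
discriminator (DANN), and second-order correlation alignment of feature
covariances (DeepCoral).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .encode import EncodedImage
from .errors import InvalidArgumentError
from .nn.backbone import Backbone, build_backbone
from .nn.layers import (GradientReversal, Linear, ReLU, SGD, Sequential,
                        grad_reverse, softmax_cross_entropy)

__all__ = [
    "KernelFamily", "TrainConfig", "AdaptationModel", "AccuracyCurve",
    "mk_mmd2", "mk_mmd2_with_grad", "make_kernel_family", "coral_loss",
    "coral_loss_with_grad", "grad_reverse", "build_model", "train", "predict",
    "images_to_array", "labels_to_indices", "save_checkpoint",
    "load_checkpoint",
]

Method = Literal["dan", "dann", "deepcoral", "source_only"]

LABEL_TO_INDEX = {"healthy": 0, "depressed": 1}
INDEX_TO_LABEL = {v: k for k, v in LABEL_TO_INDEX.items()}


# ---------------------------------------------------------------------------
# Kernels and MK-MMD
# ---------------------------------------------------------------------------

@dataclass
class KernelFamily:
    """m Gaussian kernels k_u(x, y) = exp(−‖x−y‖² / (2σ_u²)) with convex β.

    ``bandwidths`` are the σ_u; β lives on the simplex (Σβ_u = 1,
    β_u ≥ 0), the constraint that keeps the combined kernel characteristic.
    """

    bandwidths: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.bandwidths = np.atleast_1d(np.asarray(self.bandwidths, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.bandwidths.size < 1 or self.bandwidths.size != self.beta.size:
            raise InvalidArgumentError("need m ≥ 1 kernels with matching β")
        if np.any(self.bandwidths <= 0):
            raise InvalidArgumentError("kernel bandwidths must be positive")
        if np.any(self.beta < -1e-12) or abs(self.beta.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("β must be convex weights (Σβ=1, β≥0)")

    @property
    def m(self) -> int:
        return self.bandwidths.size

    @property
    def gammas(self) -> np.ndarray:
        """Squared-distance denominators 2σ_u²."""
        return 2.0 * self.bandwidths**2

    @property
    def kernels(self) -> list[Callable[[np.ndarray, np.ndarray], np.ndarray]]:
        """The m kernel functions, each mapping (a, b) to a Gram matrix."""
        def make(gamma: float):
            return lambda a, b: np.exp(
                -cdist(np.atleast_2d(a), np.atleast_2d(b), "sqeuclidean") / gamma)
        return [make(g) for g in self.gammas]

    def gram(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Combined-kernel Gram matrix Σ_u β_u k_u(a_i, b_j)."""
        d2 = cdist(a, b, metric="sqeuclidean")
        g = np.zeros_like(d2)
        for gamma, beta in zip(self.gammas, self.beta):
            g += beta * np.exp(-d2 / gamma)
        return g


def make_kernel_family(pooled_feats: np.ndarray, m: int = 5,
                       spacing: float = 2.0) -> KernelFamily:
    """Median-heuristic Gaussian family with geometric bandwidth spacing.

    The central bandwidth is the median pairwise Euclidean distance of the
    pooled source+target features; the ladder is
    σ_u = median · spacing^(u − (m−1)/2), so m = 5, spacing = 2 gives the
    ×{1/4, 1/2, 1, 2, 4} ladder.  β is initialized uniform and kept fixed
    during training (learned-β is an extension point, not the default).
    """
    pooled = np.atleast_2d(np.asarray(pooled_feats, dtype=float))
    if pooled.size == 0:
        raise InvalidArgumentError("pooled features must be nonempty")
    if m < 1:
        raise InvalidArgumentError("m must be ≥ 1")
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be positive")
    med = 0.0
    if pooled.shape[0] > 1:
        d = cdist(pooled, pooled, metric="euclidean")
        iu = np.triu_indices_from(d, k=1)
        med = float(np.median(d[iu]))
    if med == 0.0:
        warnings.warn("degenerate pooled features; falling back to bandwidth 1.0")
        med = 1.0
    exponents = np.arange(m) - (m - 1) / 2.0
    bandwidths = med * np.power(float(spacing), exponents)
    beta = np.full(m, 1.0 / m)
    return KernelFamily(bandwidths=bandwidths, beta=beta)


def _check_two_sample(source: np.ndarray, target: np.ndarray,
                      min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    s = np.atleast_2d(np.asarray(source, dtype=float))
    t = np.atleast_2d(np.asarray(target, dtype=float))
    if s.shape[0] < min_n or t.shape[0] < min_n:
        raise InvalidArgumentError(f"each domain needs at least {min_n} samples")
    if s.shape[1] != t.shape[1]:
        raise InvalidArgumentError("feature dimensions differ between domains")
    return s, t


def mk_mmd2(source_feats: np.ndarray, target_feats: np.ndarray,
            family: KernelFamily,
            estimator: Literal["biased", "unbiased"] = "biased") -> float:
    """Empirical squared MK-MMD between two feature samples.

    The biased (V-statistic) estimator uses full Gram double sums,

        mean(K_ss) + mean(K_tt) − 2·mean(K_st),

    and is always ≥ 0; the unbiased (U-statistic) estimator drops diagonal
    terms and can go negative, but has expectation 0 when p = q.
    """
    min_n = 2 if estimator == "unbiased" else 1
    s, t = _check_two_sample(source_feats, target_feats, min_n=min_n)
    n, n2 = s.shape[0], t.shape[0]
    k_ss = family.gram(s, s)
    k_tt = family.gram(t, t)
    k_st = family.gram(s, t)
    if estimator == "biased":
        # mathematically ≥ 0; the clamp only absorbs float round-off
        return float(max(k_ss.mean() + k_tt.mean() - 2.0 * k_st.mean(), 0.0))
    if estimator == "unbiased":
        ss = (k_ss.sum() - np.trace(k_ss)) / (n * (n - 1))
        tt = (k_tt.sum() - np.trace(k_tt)) / (n2 * (n2 - 1))
        return float(ss + tt - 2.0 * k_st.mean())
    raise InvalidArgumentError(f"unknown estimator {estimator!r}")


def mk_mmd2_with_grad(source_feats: np.ndarray, target_feats: np.ndarray,
                      family: KernelFamily
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """Biased MK-MMD² plus its gradients w.r.t. both feature matrices.

    For k_u(x, y) = exp(−‖x−y‖²/γ_u), ∂k_u/∂x = −(2/γ_u)·k_u·(x − y); the
    estimator's gradient follows by summing over the three Gram blocks
    (the within-domain blocks pull samples together, the cross block
    pushes them toward the other domain).
    """
    s, t = _check_two_sample(source_feats, target_feats)
    n, n2 = s.shape[0], t.shape[0]
    d2_ss = cdist(s, s, metric="sqeuclidean")
    d2_tt = cdist(t, t, metric="sqeuclidean")
    d2_st = cdist(s, t, metric="sqeuclidean")
    val = 0.0
    grad_s = np.zeros_like(s)
    grad_t = np.zeros_like(t)
    for gamma, beta in zip(family.gammas, family.beta):
        k_ss = np.exp(-d2_ss / gamma)
        k_tt = np.exp(-d2_tt / gamma)
        k_st = np.exp(-d2_st / gamma)
        val += beta * (k_ss.mean() + k_tt.mean() - 2.0 * k_st.mean())
        c = beta * 4.0 / gamma
        w_ss = k_ss / (n * n)
        grad_s -= c * (w_ss.sum(axis=1, keepdims=True) * s - w_ss @ s)
        w_tt = k_tt / (n2 * n2)
        grad_t -= c * (w_tt.sum(axis=1, keepdims=True) * t - w_tt @ t)
        w_st = k_st / (n * n2)
        grad_s += c * (w_st.sum(axis=1, keepdims=True) * s - w_st @ t)
        grad_t += c * (w_st.sum(axis=0)[:, None] * t - w_st.T @ s)
    return float(val), grad_s, grad_t


# ---------------------------------------------------------------------------
# CORAL
# ---------------------------------------------------------------------------

def _covariance(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0, keepdims=True)
    return (xc.T @ xc) / (x.shape[0] - 1)


def coral_loss(source_feats: np.ndarray, target_feats: np.ndarray) -> float:
    """Correlation alignment: (1/4d²)·‖C_s − C_t‖²_F over feature covariances.

    Covariances use the sample (n−1) convention.  Zero iff the empirical
    covariances coincide; symmetric in the two domains.
    """
    s, t = _check_two_sample(source_feats, target_feats, min_n=2)
    d = s.shape[1]
    diff = _covariance(s) - _covariance(t)
    return float((diff**2).sum() / (4.0 * d * d))


def coral_loss_with_grad(source_feats: np.ndarray, target_feats: np.ndarray
                         ) -> tuple[float, np.ndarray, np.ndarray]:
    """CORAL loss plus gradients w.r.t. both feature matrices."""
    s, t = _check_two_sample(source_feats, target_feats, min_n=2)
    n, n2, d = s.shape[0], t.shape[0], s.shape[1]
    sc = s - s.mean(axis=0, keepdims=True)
    tc = t - t.mean(axis=0, keepdims=True)
    diff = (sc.T @ sc) / (n - 1) - (tc.T @ tc) / (n2 - 1)
    val = float((diff**2).sum() / (4.0 * d * d))
    grad_s = (sc @ diff) / ((n - 1) * d * d)
    grad_t = -(tc @ diff) / ((n2 - 1) * d * d)
    return val, grad_s, grad_t


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``epochs`` defaults to 500 so the network is fully trained;
    ``batch_size`` is deliberately small so every minibatch reflects varied
    training features.  λ weights the adaptation loss against the source
    cross-entropy; the learning rate decays ×0.1 at 60% and again at 80%
    of the scheduled epochs.
    """

    epochs: int = 500
    batch_size: int = 16
    lambda_: float = 1.0
    lr: float = 0.01
    momentum: float = 0.9
    seed: int = 0
    backbone: str = "smallcnn"
    grad_clip: float = 50.0
    kernel_m: int = 5
    kernel_spacing: float = 2.0
    kernel_per_batch: bool = True
    lambda_ramp: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be ≥ 1")
        if self.lambda_ < 0:
            raise InvalidArgumentError("adaptation weight λ must be ≥ 0")
        if self.batch_size < 1:
            raise InvalidArgumentError("batch_size must be ≥ 1")


@dataclass
class AccuracyCurve:
    """Per-epoch training log: target accuracy (reporting only) and losses."""

    accuracies: list[float] = field(default_factory=list)
    cls_losses: list[float] = field(default_factory=list)
    adapt_losses: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.accuracies)

    @property
    def final(self) -> float:
        return self.accuracies[-1] if self.accuracies else float("nan")


class AdaptationModel:
    """Backbone + method-specific adaptation machinery.

    ``method`` selects the alignment loss attached to the adapted head:
    one MK-MMD term per head layer for ``dan``; a domain discriminator
    behind a gradient-reversal layer for ``dann``; one CORAL term per head
    layer for ``deepcoral``; nothing for ``source_only``.
    """

    def __init__(self, method: Method, backbone: Backbone,
                 backbone_name: str, seed: int = 0) -> None:
        if method not in ("dan", "dann", "deepcoral", "source_only"):
            raise InvalidArgumentError(f"unknown method {method!r}")
        self.method = method
        self.backbone = backbone
        self.backbone_name = backbone_name
        self.input_shape: tuple[int, int, int] | None = None
        self.kernel_family: KernelFamily | None = None
        self.discriminator: Sequential | None = None
        self.grl: GradientReversal | None = None
        if method == "dann":
            rng = np.random.default_rng(int(np.random.SeedSequence(
                entropy=seed, spawn_key=(1,)).generate_state(1)[0]))
            in_dim = backbone.fc7.params["W"].shape[1]
            self.grl = GradientReversal(1.0)
            self.discriminator = Sequential([
                self.grl,
                Linear(rng, in_dim, 16), ReLU(),
                Linear(rng, 16, 2),
            ])

    def adaptation_terms(self) -> int:
        """Number of per-layer alignment terms in the loss graph."""
        if self.method in ("dan", "deepcoral"):
            return 3  # fc6, fc7 and fc8 activations
        if self.method == "dann":
            return 1  # single adversarial term
        return 0


def build_model(method: Method, backbone: str = "smallcnn", n_classes: int = 2,
                input_shape: tuple[int, int, int] = (3, 48, 48),
                seed: int = 0) -> AdaptationModel:
    """Assemble an adaptation model over a named backbone.

    The backbone is partitioned frozen / fine-tuned / adapted and the
    method's loss hooks attach to the adapted head.  Initialization is
    fully determined by ``seed``.
    """
    net = build_backbone(backbone, input_shape, n_classes=n_classes, seed=seed)
    model = AdaptationModel(method, net, backbone, seed=seed)
    model.input_shape = tuple(input_shape)
    return model


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def images_to_array(images: Sequence[EncodedImage]) -> np.ndarray:
    """Stack encoded images as a float32 (N, C, H, W) tensor in [0, 1]."""
    if not images:
        raise InvalidArgumentError("empty image list")
    arrs = []
    for img in images:
        px = img.pixels.astype(np.float32) / 255.0
        px = px[None, :, :] if px.ndim == 2 else px.transpose(2, 0, 1)
        arrs.append(px)
    if len({a.shape for a in arrs}) != 1:
        raise InvalidArgumentError("images have inconsistent shapes")
    return np.stack(arrs)


def labels_to_indices(images: Sequence[EncodedImage]) -> np.ndarray:
    try:
        return np.array([LABEL_TO_INDEX[img.label] for img in images])
    except KeyError as exc:
        raise InvalidArgumentError(f"unknown label {exc}") from exc


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def _clip_gradients(modules: Sequence[Sequential], max_norm: float) -> None:
    """Rescale all trainable gradients so their global L2 norm ≤ max_norm.

    Guards against the occasional exploding adversarial step; inactive for
    well-behaved batches.
    """
    total = 0.0
    for module in modules:
        for layer, name in module.parameters():
            if layer.trainable:
                total += float((layer.grads[name].astype(np.float64)**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / norm)
        for module in modules:
            for layer, name in module.parameters():
                if layer.trainable:
                    layer.grads[name] *= scale


def _accuracy(model: AdaptationModel, frozen_feats: np.ndarray,
              labels: np.ndarray) -> float:
    _, logits = model.backbone.forward_rest(frozen_feats)
    return float((logits.argmax(axis=1) == labels).mean())


def train(model: AdaptationModel, source_images: Sequence[EncodedImage],
          target_images: Sequence[EncodedImage], cfg: TrainConfig,
          target_labels: Sequence[int] | None = None
          ) -> tuple[AdaptationModel, AccuracyCurve]:
    """Minimize CE(source) + λ·adaptation(source, target) by minibatch SGD.

    Target labels never contribute gradients; when supplied they are used
    only to record the per-epoch target-accuracy curve.  Source and target
    minibatches are drawn in equal-size pairs each step, cycling the
    smaller domain.  The trajectory is a deterministic function of
    ``cfg.seed`` (plus the model's initialization seed); with λ = 0 it
    coincides exactly with ``source_only`` training.
    """
    if not source_images or not target_images:
        raise InvalidArgumentError("both domains must be nonempty")
    xs = images_to_array(source_images)
    ys = labels_to_indices(source_images)
    xt = images_to_array(target_images)
    yt = np.asarray(target_labels) if target_labels is not None else None

    # The frozen stage never changes, so its features are computed once.
    fs_all = model.backbone.forward_frozen(xs)
    ft_all = model.backbone.forward_frozen(xt)
    frozen_before = model.backbone.frozen_parameter_vector()

    if model.method == "dan" and model.kernel_family is None and not cfg.kernel_per_batch:
        # Fixed bandwidths from the initial head features of both domains.
        a_s, _ = model.backbone.forward_rest(fs_all)
        a_t, _ = model.backbone.forward_rest(ft_all)
        pooled = np.vstack([a_s[0], a_t[0]])
        model.kernel_family = make_kernel_family(pooled, m=cfg.kernel_m,
                                                 spacing=cfg.kernel_spacing)

    modules = model.backbone.trainable_modules()
    if model.discriminator is not None:
        modules = modules + [model.discriminator]
    opt = SGD(modules, lr=cfg.lr, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed)
    n_s, n_t = xs.shape[0], xt.shape[0]
    bs = min(cfg.batch_size, n_s, n_t)
    steps = max(1, n_s // bs)
    curve = AccuracyCurve()

    for epoch in range(cfg.epochs):
        frac = epoch / cfg.epochs
        opt.lr = cfg.lr * (0.01 if frac >= 0.8 else 0.1 if frac >= 0.6 else 1.0)
        lam = cfg.lambda_
        if cfg.lambda_ramp:
            lam = cfg.lambda_ * (2.0 / (1.0 + np.exp(-10.0 * frac)) - 1.0)
        perm_s = rng.permutation(n_s)
        perm_t = rng.permutation(n_t)
        ep_cls = 0.0
        ep_adapt = 0.0
        for step in range(steps):
            idx_s = perm_s[step * bs:(step + 1) * bs]
            start_t = (step * bs) % n_t
            idx_t = np.take(perm_t, np.arange(start_t, start_t + bs), mode="wrap")
            fb_s, fb_t = fs_all[idx_s], ft_all[idx_t]
            opt.zero_grads()

            if model.method in ("dan", "deepcoral") and lam > 0:
                acts_b, logits_b = model.backbone.forward_rest(
                    np.concatenate([fb_s, fb_t], axis=0))
                cls_loss, grad_logits = softmax_cross_entropy(logits_b[:bs],
                                                              ys[idx_s])
                grad_full = np.concatenate(
                    [grad_logits,
                     np.zeros((bs, grad_logits.shape[1]), dtype=np.float32)])
                head_grads = []
                adapt_val = 0.0
                for act in acts_b:
                    if model.method == "dan":
                        if cfg.kernel_per_batch:
                            with warnings.catch_warnings():
                                warnings.simplefilter("ignore")
                                fam = make_kernel_family(
                                    act, m=cfg.kernel_m,
                                    spacing=cfg.kernel_spacing)
                            model.kernel_family = fam
                        else:
                            fam = model.kernel_family
                        val, g_s, g_t = mk_mmd2_with_grad(act[:bs], act[bs:],
                                                          fam)
                    else:
                        val, g_s, g_t = coral_loss_with_grad(act[:bs], act[bs:])
                    adapt_val += val
                    head_grads.append(
                        lam * np.concatenate([g_s, g_t]).astype(np.float32))
                model.backbone.backward_rest(grad_full, head_grads)
                ep_cls += cls_loss
                ep_adapt += adapt_val
            elif model.method == "dann" and lam > 0:
                acts_b, logits_b = model.backbone.forward_rest(
                    np.concatenate([fb_s, fb_t], axis=0))
                cls_loss, grad_logits = softmax_cross_entropy(logits_b[:bs],
                                                              ys[idx_s])
                grad_full = np.concatenate(
                    [grad_logits,
                     np.zeros((bs, grad_logits.shape[1]), dtype=np.float32)])
                model.grl.lambda_ = lam
                dom_labels = np.concatenate([np.zeros(bs, dtype=int),
                                             np.ones(bs, dtype=int)])
                dom_logits = model.discriminator.forward(acts_b[1])
                dom_loss, dom_grad = softmax_cross_entropy(dom_logits,
                                                           dom_labels)
                g_feats = model.discriminator.backward(dom_grad)
                model.backbone.backward_rest(
                    grad_full, [None, g_feats.astype(np.float32), None])
                ep_cls += cls_loss
                ep_adapt += dom_loss
            else:
                # source_only, or λ = 0: pure classification path (the
                # target batch above is still drawn, so λ = 0 trajectories
                # match source_only under one seed)
                _, logits_s = model.backbone.forward_rest(fb_s)
                cls_loss, grad_logits = softmax_cross_entropy(logits_s,
                                                              ys[idx_s])
                model.backbone.backward_rest(grad_logits, None)
                ep_cls += cls_loss
            if cfg.grad_clip:
                _clip_gradients(modules, cfg.grad_clip)
            opt.step()

        curve.cls_losses.append(ep_cls / steps)
        curve.adapt_losses.append(ep_adapt / steps)
        curve.accuracies.append(
            _accuracy(model, ft_all, yt) if yt is not None else float("nan"))

    frozen_after = model.backbone.frozen_parameter_vector()
    if not np.array_equal(frozen_before, frozen_after):  # pragma: no cover
        raise AssertionError("frozen-stage parameters changed during training")
    return model, curve


def predict(model: AdaptationModel, images: Sequence[EncodedImage]
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class indices and softmax scores for a batch of encoded images.

    Ties break toward the lower class index (first-argmax convention).
    """
    x = images_to_array(images)
    if model.input_shape is not None and tuple(x.shape[1:]) != tuple(model.input_shape):
        raise InvalidArgumentError(
            f"image shape {tuple(x.shape[1:])} does not match model input "
            f"{model.input_shape}")
    logits = model.backbone.forward(x)
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    scores = ez / ez.sum(axis=1, keepdims=True)
    return logits.argmax(axis=1), scores


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: AdaptationModel, path, cfg: TrainConfig | None = None
                    ) -> None:
    """Serialize model weights plus a config snapshot into one .npz file."""
    import json

    meta = {
        "method": model.method,
        "backbone": model.backbone_name,
        "n_classes": model.backbone.n_classes,
        "input_shape": list(model.input_shape or ()),
        "train_config": None if cfg is None else {
            k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
    }
    arrays = {f"backbone/{k}": v
              for k, v in model.backbone.state_arrays().items()}
    if model.discriminator is not None:
        for i, (layer, name) in enumerate(model.discriminator.parameters()):
            arrays[f"discriminator/{i}.{name}"] = layer.params[name]
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> AdaptationModel:
    """Rebuild an AdaptationModel from a checkpoint written by save_checkpoint."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = build_model(meta["method"], backbone=meta["backbone"],
                            n_classes=meta["n_classes"],
                            input_shape=tuple(meta["input_shape"]))
        state = model.backbone.state_arrays()
        for key in data.files:
            if key.startswith("backbone/"):
                state[key.removeprefix("backbone/")][...] = data[key]
            elif key.startswith("discriminator/"):
                idx_name = key.removeprefix("discriminator/")
                i, name = idx_name.split(".", 1)
                params = list(model.discriminator.parameters())
                layer, _ = params[int(i)]
                layer.params[name][...] = data[key]
    return model
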