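"""Auxiliary-classifier GAN for semi-supervised patch classification.

The generator G maps a noise vector ``z`` concatenated with a one-hot class
condition ``c`` to a fake image patch ``X_fake = G(c, z)``.  The
discriminator D shares one convolutional trunk between two heads: a source
head giving ``P(S = real | X)`` and an auxiliary class head giving
``P(C | X)``.  Training maximizes, for D, the sum of the source and class
log-likelihoods ``L_C + L_S`` and minimizes, for G, ``L_S − L_C``:

    L_S = E[log P(S=real | X_real)] + E[log P(S=fake | X_fake)]
    L_C = E[log P(C=c | X_real)]    + E[log P(C=c | X_fake)]

The class term on real data is computed over *labeled* patches only, which
is what makes the scheme semi-supervised: unlabeled patches still shape the
trunk through the source loss.  Discriminator convolutions use spectral
normalization (one warm-started power iteration per step).

Also defined here: the plain CNN classifier and the convolutional
autoencoder used as fully-supervised and non-generative semi-supervised
baselines, plus checkpoint I/O.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dense, Flatten,
                 LeakyReLU, ReLU, Reshape, Sequential, Tanh, sigmoid, softmax)

LOG_EPS = 1e-7  # probability clipping before logarithms


@dataclass(frozen=True)
class ACGANSpec:
    """Architecture hyperparameters (layer dimensions are derived).

    ``patch_size`` must be a power of two >= 8; the trunk downsamples to a
    4x4 feature map, so depth scales with the patch size.  Defaults target
    desk-scale 32 px patches; 128 px is reachable by configuration.
    """

    patch_size: int = 32
    n_classes: int = 8
    d_z: int = 100
    base_width: int = 32

    def n_blocks(self) -> int:
        n = int(math.log2(self.patch_size / 4))
        if 2**n * 4 != self.patch_size or n < 1:
            raise ValueError(f"patch_size must be 4*2^k, got {self.patch_size}")
        return n


@dataclass
class DiscriminatorOutput:
    """Per-sample source probability P(S=real|X) and class posterior P(C|X)."""

    p_source: np.ndarray  # (n,)
    p_class: np.ndarray  # (n, K)


class Generator:
    """DCGAN-style conditional generator: dense projection to a 4x4 map,
    then transposed-convolution upsampling blocks, tanh output in [-1, 1]."""

    kind = "generator"

    def __init__(self, spec: ACGANSpec, rng: np.random.Generator):
        self.spec = spec
        n_blocks = spec.n_blocks()
        ch = [spec.base_width * 2 ** (n_blocks - 1 - i) for i in range(n_blocks)]
        layers: list[nn.Layer] = [
            Dense(spec.d_z + spec.n_classes, ch[0] * 16, rng),
            Reshape((ch[0], 4, 4)),
            BatchNorm2d(ch[0]),
            ReLU(),
        ]
        for i in range(1, n_blocks):
            layers += [
                ConvTranspose2d(ch[i - 1], ch[i], 2, 2, 0, rng),
                BatchNorm2d(ch[i]),
                ReLU(),
            ]
        layers += [ConvTranspose2d(ch[-1], 3, 2, 2, 0, rng), Tanh()]
        self.net = Sequential(*layers)

    def parameters(self):
        return self.net.parameters()

    def set_training(self, flag: bool):
        self.net.set_training(flag)

    def forward(self, z: np.ndarray, c_onehot: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=nn.DTYPE)
        c_onehot = np.asarray(c_onehot, dtype=nn.DTYPE)
        if z.ndim != 2 or z.shape[1] != self.spec.d_z:
            raise ValueError(f"noise must be (n, {self.spec.d_z}), got {z.shape}")
        if c_onehot.shape != (z.shape[0], self.spec.n_classes):
            raise ValueError(
                f"condition must be (n, {self.spec.n_classes}), got {c_onehot.shape}"
            )
        return self.net.forward(np.concatenate([z, c_onehot], axis=1))

    def backward(self, grad):
        return self.net.backward(grad)

    def modules(self):
        return [self.net]


class Discriminator:
    """Spectral-normalized strided-conv trunk shared by the source head
    (real/fake logit) and the auxiliary class head (K logits)."""

    kind = "discriminator"

    def __init__(self, spec: ACGANSpec, rng: np.random.Generator):
        self.spec = spec
        n_blocks = spec.n_blocks()
        ch = [spec.base_width * 2**i for i in range(n_blocks)]
        layers: list[nn.Layer] = []
        c_in = 3
        for c_out in ch:
            layers += [Conv2d(c_in, c_out, 3, 2, 1, rng, spectral_norm=True), LeakyReLU(0.2)]
            c_in = c_out
        layers.append(Flatten())
        self.trunk = Sequential(*layers)
        n_feat = ch[-1] * 16
        self.head_source = Dense(n_feat, 1, rng)
        self.head_class = Dense(n_feat, spec.n_classes, rng)

    def parameters(self):
        return (
            self.trunk.parameters()
            + self.head_source.parameters()
            + self.head_class.parameters()
        )

    def set_training(self, flag: bool):
        for m in self.modules():
            m.set_training(flag)

    def modules(self):
        return [self.trunk, self.head_source, self.head_class]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (source logits (n,), class logits (n, K))."""
        x = np.asarray(x, dtype=nn.DTYPE)
        feat = self.trunk.forward(x)
        return self.head_source.forward(feat)[:, 0], self.head_class.forward(feat)

    def backward(self, d_source: np.ndarray, d_class: np.ndarray,
                 need_input_grad: bool = True) -> np.ndarray | None:
        g = self.head_source.backward(d_source[:, None]) + self.head_class.backward(d_class)
        return self.trunk.backward(g, need_input_grad=need_input_grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class posteriors P(C|X) from the auxiliary head (eval mode)."""
        self.set_training(False)
        try:
            _, c_logits = self.forward(x)
        finally:
            self.set_training(True)
        return softmax(c_logits)


class Classifier:
    """Plain small CNN with batch normalization: the fully-supervised
    baseline (and the encoder/classifier of the autoencoder baseline)."""

    kind = "classifier"

    def __init__(self, spec: ACGANSpec, rng: np.random.Generator):
        self.spec = spec
        n_blocks = spec.n_blocks()
        ch = [spec.base_width * 2**i for i in range(n_blocks)]
        layers: list[nn.Layer] = []
        c_in = 3
        for c_out in ch:
            layers += [Conv2d(c_in, c_out, 3, 2, 1, rng), BatchNorm2d(c_out), LeakyReLU(0.2)]
            c_in = c_out
        self.trunk = Sequential(*layers)
        self._feat_ch = ch[-1]
        self.flatten = Flatten()
        self.head = Dense(ch[-1] * 16, spec.n_classes, rng)

    def parameters(self):
        return self.trunk.parameters() + self.head.parameters()

    def set_training(self, flag: bool):
        for m in self.modules():
            m.set_training(flag)

    def modules(self):
        return [self.trunk, self.flatten, self.head]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class logits (n, K)."""
        self._feat = self.trunk.forward(np.asarray(x, dtype=nn.DTYPE))
        return self.head.forward(self.flatten.forward(self._feat))

    def backward(self, d_class: np.ndarray, d_feat: np.ndarray | None = None):
        g = self.flatten.backward(self.head.backward(d_class))
        if d_feat is not None:
            g = g + d_feat
        return self.trunk.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.set_training(False)
        try:
            logits = self.forward(x)
        finally:
            self.set_training(True)
        return softmax(logits)


class Autoencoder:
    """Non-generative semi-supervised baseline: the classifier trunk with a
    mirrored transposed-convolution decoder for patch reconstruction."""

    kind = "autoencoder"

    def __init__(self, spec: ACGANSpec, rng: np.random.Generator):
        self.spec = spec
        self.classifier = Classifier(spec, rng)
        n_blocks = spec.n_blocks()
        ch = [spec.base_width * 2**i for i in range(n_blocks)]
        layers: list[nn.Layer] = []
        dec_ch = list(reversed(ch))
        for i in range(len(dec_ch) - 1):
            layers += [
                ConvTranspose2d(dec_ch[i], dec_ch[i + 1], 2, 2, 0, rng),
                BatchNorm2d(dec_ch[i + 1]),
                ReLU(),
            ]
        layers += [ConvTranspose2d(dec_ch[-1], 3, 2, 2, 0, rng), Tanh()]
        self.decoder = Sequential(*layers)

    def parameters(self):
        return self.classifier.parameters() + self.decoder.parameters()

    def set_training(self, flag: bool):
        self.classifier.set_training(flag)
        self.decoder.set_training(flag)

    def modules(self):
        return self.classifier.modules() + [self.decoder]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (class logits, reconstruction)."""
        logits = self.classifier.forward(x)
        recon = self.decoder.forward(self.classifier._feat)
        return logits, recon

    def backward(self, d_class: np.ndarray, d_recon: np.ndarray):
        d_feat = self.decoder.backward(d_recon)
        return self.classifier.backward(d_class, d_feat=d_feat)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(x)


# ---------------------------------------------------------------------------
# Spec-level forward wrappers

def generator_forward(generator: Generator, z: np.ndarray, c_onehot: np.ndarray) -> np.ndarray:
    """Generate fake patches; deterministic given (z, c, parameters)."""
    c_onehot = np.asarray(c_onehot)
    if not np.all(c_onehot.sum(axis=-1) == 1) or not np.all((c_onehot == 0) | (c_onehot == 1)):
        raise ValueError("class condition must be one-hot")
    return generator.forward(z, c_onehot)


def discriminator_forward(discriminator: Discriminator, x: np.ndarray) -> DiscriminatorOutput:
    s_logits, c_logits = discriminator.forward(x)
    return DiscriminatorOutput(p_source=sigmoid(s_logits), p_class=softmax(c_logits))


# ---------------------------------------------------------------------------
# Objectives

def _clipped_log(p: np.ndarray, eps: float = LOG_EPS) -> np.ndarray:
    return np.log(np.clip(p, eps, 1.0 - eps))


def source_loss(p_real: np.ndarray, p_fake: np.ndarray, eps: float = LOG_EPS) -> float:
    """L_S: mean log-likelihood of the correct source (natural log, <= ~0).

    ``p_real``/``p_fake`` are P(S=real|X) on the real and fake batches.
    Probabilities are clipped to [eps, 1-eps] before the logarithm.
    """
    return float(np.mean(_clipped_log(p_real, eps)) + np.mean(_clipped_log(1.0 - np.asarray(p_fake), eps)))


def class_loss(
    class_probs_real: np.ndarray,
    labels_real: np.ndarray,
    class_probs_fake: np.ndarray,
    labels_fake: np.ndarray,
    eps: float = LOG_EPS,
) -> float:
    """L_C: mean log-likelihood of the correct class on real + fake batches.

    The real-batch term runs over labeled patches only; an empty labeled
    subset contributes zero, leaving the fake term alone.  ``labels_fake``
    are the conditioning classes of the generated batch.  Labels are class
    *indices* (softmax columns).
    """
    total = 0.0
    labels_real = np.asarray(labels_real, dtype=int)
    if labels_real.size > 0:
        probs = np.asarray(class_probs_real)[np.arange(labels_real.size), labels_real]
        total += float(np.mean(_clipped_log(probs, eps)))
    labels_fake = np.asarray(labels_fake, dtype=int)
    if labels_fake.size > 0:
        probs = np.asarray(class_probs_fake)[np.arange(labels_fake.size), labels_fake]
        total += float(np.mean(_clipped_log(probs, eps)))
    return total


def objectives(l_s: float, l_c: float) -> tuple[float, float]:
    """(discriminator objective to maximize, generator objective to minimize)
    = (L_C + L_S, L_S − L_C)."""
    return l_c + l_s, l_s - l_c


# ---------------------------------------------------------------------------
# Full model state (parameters + batch-norm statistics + spectral-norm state)

def _iter_atomic_layers(layer: nn.Layer):
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _iter_atomic_layers(sub)
    else:
        yield layer


def model_state(model) -> list[np.ndarray]:
    """Snapshot everything needed to reproduce the model's eval behavior."""
    arrays: list[np.ndarray] = []
    for module in model.modules():
        for layer in _iter_atomic_layers(module):
            for p in layer.parameters():
                arrays.append(p.value.copy())
            if isinstance(layer, BatchNorm2d):
                arrays.append(layer.running_mean.copy())
                arrays.append(layer.running_var.copy())
            if getattr(layer, "spectral_norm", False):
                arrays.append(layer._sn_u.copy())
                arrays.append(np.array([layer._sn_sigma]))
    return arrays


def set_model_state(model, arrays: list[np.ndarray]) -> None:
    it = iter(arrays)
    for module in model.modules():
        for layer in _iter_atomic_layers(module):
            for p in layer.parameters():
                p.value[...] = next(it)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)
            if getattr(layer, "spectral_norm", False):
                layer._sn_u[...] = next(it)
                layer._sn_sigma = float(next(it)[0])
    try:
        next(it)
    except StopIteration:
        return
    raise ValueError("state array count does not match model")


_MODEL_KINDS = {}


def _register_kinds():
    _MODEL_KINDS.update(
        {
            "generator": Generator,
            "discriminator": Discriminator,
            "classifier": Classifier,
            "autoencoder": Autoencoder,
        }
    )


_register_kinds()


def save_checkpoint(path, model, extra: dict | None = None) -> None:
    """Save model state as ``.npz`` with a JSON sidecar describing the
    architecture (kind + spec) and any extra metadata."""
    path = Path(path)
    arrays = model_state(model)
    np.savez(path, **{f"a{i}": a for i, a in enumerate(arrays)})
    sidecar = {"kind": model.kind, "spec": asdict(model.spec), "n_arrays": len(arrays)}
    if extra:
        sidecar["extra"] = extra
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path):
    """Rebuild a model from :func:`save_checkpoint` output."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = ACGANSpec(**sidecar["spec"])
    model = _MODEL_KINDS[sidecar["kind"]](spec, np.random.default_rng(0))
    with np.load(path) as data:
        arrays = [data[f"a{i}"] for i in range(sidecar["n_arrays"])]
    set_model_state(model, arrays)
    return model
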