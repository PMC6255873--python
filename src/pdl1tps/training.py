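"""Training loops for the AC-GAN and the baseline networks.

Batch composition follows the study protocol: fully-supervised networks see
batches of 64 labeled patches; semi-supervised networks see 32 labeled plus
32 unlabeled patches (both overridable for desk-scale runs).  All networks
use Adam with lr = 1e-4, beta1 = 0.5, beta2 = 0.999.  The AC-GAN alternates
one discriminator update (ascending L_C + L_S) with one generator update
(descending L_S − L_C) per iteration.  Model selection keeps the
checkpoint that maximizes top-1 accuracy on the held-out labeled set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .acgan import (ACGANSpec, Adam, Autoencoder, Classifier, Discriminator,
                    Generator, class_loss, model_state, set_model_state,
                    sigmoid, softmax, source_loss)

MODES = ("fully_supervised", "ssl_autoencoder", "ssl_acgan")


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the full-scale study values."""

    mode: str = "ssl_acgan"
    batch_labeled: int | None = None  # defaults: 64 supervised / 32 ssl
    batch_unlabeled: int | None = None  # defaults: 0 supervised / 32 ssl
    iterations: int = 2000
    lr: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.999
    eval_every: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.batch_labeled is None:
            self.batch_labeled = 64 if self.mode == "fully_supervised" else 32
        if self.batch_unlabeled is None:
            self.batch_unlabeled = 0 if self.mode == "fully_supervised" else 32
        if self.mode == "fully_supervised" and self.batch_unlabeled != 0:
            raise ValueError("fully_supervised mode takes no unlabeled patches")


@dataclass
class TrainData:
    """Patch pools as float arrays in [-1, 1], NCHW; labels are class indices."""

    x_labeled: np.ndarray
    y_labeled: np.ndarray
    x_eval: np.ndarray
    y_eval: np.ndarray
    x_unlabeled: np.ndarray | None = None


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)
    best_iteration: int = -1
    best_accuracy: float = -np.inf

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


def patches_to_float(images: np.ndarray) -> np.ndarray:
    """uint8 HWC patches -> float NCHW in [-1, 1] (engine dtype)."""
    x = np.asarray(images, dtype=nn.DTYPE) / nn.DTYPE(127.5) - nn.DTYPE(1.0)
    if x.ndim == 3:
        x = x[None]
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


class Pool:
    """Sampling without replacement within an epoch, reshuffled between
    epochs; pools smaller than the requested batch cycle with a warning."""

    def __init__(self, x: np.ndarray, y: np.ndarray | None = None):
        self.x = x
        self.y = y
        self._order = np.arange(len(x))
        self._pos = len(x)  # force shuffle on first take
        self._warned = False

    def __len__(self):
        return len(self.x)

    def take(self, n: int, rng: np.random.Generator):
        if n > len(self.x) and not self._warned:
            warnings.warn(
                f"pool of {len(self.x)} patches is smaller than batch size {n}; cycling"
            )
            self._warned = True
        idx = np.empty(n, dtype=int)
        filled = 0
        while filled < n:
            if self._pos >= len(self._order):
                rng.shuffle(self._order)
                self._pos = 0
            grab = min(n - filled, len(self._order) - self._pos)
            idx[filled : filled + grab] = self._order[self._pos : self._pos + grab]
            self._pos += grab
            filled += grab
        if self.y is None:
            return self.x[idx]
        return self.x[idx], self.y[idx]


@dataclass
class Batch:
    x_labeled: np.ndarray
    y_labeled: np.ndarray
    x_unlabeled: np.ndarray | None


def make_batch(labeled_pool: Pool, unlabeled_pool: Pool | None,
               config: TrainConfig, rng: np.random.Generator) -> Batch:
    """Draw one training batch with the configured labeled/unlabeled split."""
    xl, yl = labeled_pool.take(config.batch_labeled, rng)
    xu = None
    if config.batch_unlabeled > 0:
        if unlabeled_pool is None:
            raise ValueError("config requests unlabeled patches but no pool given")
        xu = unlabeled_pool.take(config.batch_unlabeled, rng)
    return Batch(x_labeled=xl, y_labeled=yl, x_unlabeled=xu)


def _onehot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(labels), k), dtype=nn.DTYPE)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def evaluate_accuracy(model, x_eval: np.ndarray, y_eval: np.ndarray,
                      batch: int = 256) -> float:
    """Top-1 accuracy of the model's class posterior on a held-out set."""
    correct = 0
    for i in range(0, len(x_eval), batch):
        probs = model.predict_proba(x_eval[i : i + batch])
        correct += int(np.sum(probs.argmax(axis=1) == y_eval[i : i + batch]))
    return correct / len(x_eval)


def _check_finite(it: int, **losses: float) -> None:
    for name, value in losses.items():
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite {name}={value} at iteration {it}; aborting")


def _record_eval(model, history: TrainHistory, it: int, data: TrainData,
                 losses: dict, best: dict) -> None:
    acc = evaluate_accuracy(model, data.x_eval, data.y_eval)
    history.records.append({"iteration": it, "accuracy": acc, **losses})
    if acc > history.best_accuracy:
        history.best_accuracy = acc
        history.best_iteration = it
        best["state"] = model_state(model)
        if "aux" in best:
            best["aux_state"] = model_state(best["aux"])


def train(model_spec: ACGANSpec, data: TrainData, config: TrainConfig):
    """Train per ``config.mode``; returns ``(model, history)`` with the model
    restored to its best-accuracy checkpoint.

    For ``ssl_acgan`` the returned model is the discriminator (its auxiliary
    head is the patch classifier used downstream); the generator rides along
    as ``model.generator``.
    """
    if len(data.x_labeled) == 0:
        raise ValueError("no labeled training data")
    if config.mode == "ssl_acgan":
        return _train_acgan(model_spec, data, config)
    if config.mode == "ssl_autoencoder":
        return _train_autoencoder(model_spec, data, config)
    return train_baseline_supervised(model_spec, data, config)


def _train_acgan(spec: ACGANSpec, data: TrainData, config: TrainConfig):
    rng = np.random.default_rng(config.seed)
    gen = Generator(spec, rng)
    disc = Discriminator(spec, rng)
    opt_d = Adam(disc.parameters(), config.lr, config.beta1, config.beta2)
    opt_g = Adam(gen.parameters(), config.lr, config.beta1, config.beta2)
    labeled = Pool(data.x_labeled, data.y_labeled)
    unlabeled = Pool(data.x_unlabeled) if data.x_unlabeled is not None else None
    history = TrainHistory()
    best: dict = {"state": None, "aux": gen}
    k = spec.n_classes

    for it in range(1, config.iterations + 1):
        batch = make_batch(labeled, unlabeled, config, rng)
        n_l = len(batch.x_labeled)
        x_real = (
            np.concatenate([batch.x_labeled, batch.x_unlabeled])
            if batch.x_unlabeled is not None
            else batch.x_labeled
        )
        n_r = len(x_real)
        n_f = n_r

        # ----- discriminator update: ascend L_C + L_S
        z = rng.standard_normal((n_f, spec.d_z)).astype(nn.DTYPE)
        y_fake = rng.integers(0, k, size=n_f)
        x_fake = gen.forward(z, _onehot(y_fake, k))  # detached: G gets no grads here

        x_all = np.concatenate([x_real, x_fake])
        s_logits, c_logits = disc.forward(x_all)
        p_s = sigmoid(s_logits)
        p_c = softmax(c_logits)

        ds = np.empty(n_r + n_f, dtype=nn.DTYPE)
        ds[:n_r] = -(1.0 - p_s[:n_r]) / n_r  # d(-L_S)/d logit, real part
        ds[n_r:] = p_s[n_r:] / n_f  # fake part
        dc = np.zeros_like(c_logits)
        dc[:n_l] = (p_c[:n_l] - _onehot(batch.y_labeled, k)) / n_l
        dc[n_r:] = (p_c[n_r:] - _onehot(y_fake, k)) / n_f

        opt_d.zero_grad()
        disc.backward(ds, dc, need_input_grad=False)  # inputs are leaves here
        opt_d.step()

        l_s = source_loss(p_s[:n_r], p_s[n_r:])
        l_c = class_loss(p_c[:n_l], batch.y_labeled, p_c[n_r:], y_fake)

        # ----- generator update: descend L_S - L_C
        z2 = rng.standard_normal((n_f, spec.d_z)).astype(nn.DTYPE)
        y_fake2 = rng.integers(0, k, size=n_f)
        x_fake2 = gen.forward(z2, _onehot(y_fake2, k))
        s_f, c_f = disc.forward(x_fake2)
        p_sf = sigmoid(s_f)
        p_cf = softmax(c_f)

        dsg = -p_sf / n_f  # d(mean log(1-p))/d logit
        dcg = (p_cf - _onehot(y_fake2, k)) / n_f  # d(-mean log p[c])/d logits
        opt_d.zero_grad()  # discriminator grads are scratch here
        opt_g.zero_grad()
        dx = disc.backward(dsg, dcg)
        gen.backward(dx)
        opt_g.step()

        g_obj = source_loss(np.ones(1), p_sf) - class_loss(
            np.empty((0, k)), np.empty(0), p_cf, y_fake2
        )
        _check_finite(it, l_s=l_s, l_c=l_c, g_obj=g_obj)

        if it % config.eval_every == 0 or it == config.iterations:
            _record_eval(
                disc, history, it, data,
                {"l_s": l_s, "l_c": l_c, "d_obj": l_c + l_s, "g_obj": g_obj},
                best,
            )

    set_model_state(disc, best["state"])
    if "aux_state" in best:
        set_model_state(gen, best["aux_state"])
    disc.generator = gen
    return disc, history


def train_baseline_supervised(spec: ACGANSpec, data: TrainData, config: TrainConfig):
    """Cross-entropy training of the plain CNN classifier on labeled batches."""
    if len(data.x_labeled) == 0:
        raise ValueError("no labeled training data")
    rng = np.random.default_rng(config.seed)
    model = Classifier(spec, rng)
    opt = Adam(model.parameters(), config.lr, config.beta1, config.beta2)
    labeled = Pool(data.x_labeled, data.y_labeled)
    history = TrainHistory()
    best: dict = {"state": None}
    k = spec.n_classes

    for it in range(1, config.iterations + 1):
        xl, yl = labeled.take(config.batch_labeled, rng)
        logits = model.forward(xl)
        p = softmax(logits)
        ce = -float(np.mean(np.log(np.clip(p[np.arange(len(yl)), yl], 1e-12, None))))
        _check_finite(it, cross_entropy=ce)
        opt.zero_grad()
        model.backward((p - _onehot(yl, k)) / len(yl))
        opt.step()
        if it % config.eval_every == 0 or it == config.iterations:
            _record_eval(model, history, it, data, {"cross_entropy": ce}, best)

    set_model_state(model, best["state"])
    return model, history


def _train_autoencoder(spec: ACGANSpec, data: TrainData, config: TrainConfig):
    """Reconstruction loss on the complete batch, classification loss on the
    labeled patches only; the two losses are weighted 1:1."""
    rng = np.random.default_rng(config.seed)
    model = Autoencoder(spec, rng)
    opt = Adam(model.parameters(), config.lr, config.beta1, config.beta2)
    labeled = Pool(data.x_labeled, data.y_labeled)
    unlabeled = Pool(data.x_unlabeled) if data.x_unlabeled is not None else None
    history = TrainHistory()
    best: dict = {"state": None}
    k = spec.n_classes

    for it in range(1, config.iterations + 1):
        batch = make_batch(labeled, unlabeled, config, rng)
        n_l = len(batch.x_labeled)
        x = (
            np.concatenate([batch.x_labeled, batch.x_unlabeled])
            if batch.x_unlabeled is not None
            else batch.x_labeled
        )
        logits, recon = model.forward(x)
        p = softmax(logits)
        ce = -float(
            np.mean(np.log(np.clip(p[np.arange(n_l), batch.y_labeled], 1e-12, None)))
        )
        mse = float(np.mean((recon - x) ** 2))
        _check_finite(it, cross_entropy=ce, reconstruction=mse)
        dc = np.zeros_like(logits)
        dc[:n_l] = (p[:n_l] - _onehot(batch.y_labeled, k)) / n_l
        dr = 2.0 * (recon - x) / recon.size
        opt.zero_grad()
        model.backward(dc, dr)
        opt.step()
        if it % config.eval_every == 0 or it == config.iterations:
            _record_eval(
                model, history, it, data,
                {"cross_entropy": ce, "reconstruction": mse}, best,
            )

    set_model_state(model, best["state"])
    return model, history
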