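"""Interpretable autoencoder for cfDNA methylation deconvolution.

The encoder is a five-layer fully connected network (widths N, 512, 256,
128, 64, 2) with CELU activations and dropout on the hidden layers; its
2-dimensional latent represents the (healthy, tumor) mixing fractions. The
decoder is a stack of five bias-free linear layers whose product collapses
to a single effective N x 2 matrix; squashed through a sigmoid, that matrix
is the learned methylation atlas — one reference beta profile per
population — making the model directly interpretable. Reconstruction mixes
the atlas columns by the latent fractions, so the reconstruction loss trains
exactly the object reported as the atlas.

Training minimizes a weighted four-term loss:

* ``comp``   — mean absolute error between the (raw) latent and the known
  fraction labels of the simulated training mixtures;
* ``recon``  — mean absolute error between input and reconstruction;
* ``methy_h`` / ``methy_t`` — Bernoulli negative log-likelihood of the
  healthy / tumor reference population mean betas under the corresponding
  atlas column, anchoring the atlas to the reference.

Optimization uses Adam with seeded shuffled mini-batches; the whole model is
plain NumPy, with gradients derived analytically layer by layer.
"""

from __future__ import annotations

import json
import logging
import warnings
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cfdeconv.errors import ModelFormatError, ValidationError
from cfdeconv.simulate import reference_population_means

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1
ENCODER_HIDDEN = (512, 256, 128, 64)
LATENT_DIM = 2


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the deconvolution autoencoder.

    ``encoder_hidden`` lists hidden-layer widths; widths larger than the
    feature count are capped at it so tiny test fixtures stay well-formed.
    The four ``loss_weights`` scale (comp, recon, methy_h, methy_t).
    """

    n_features: int
    encoder_hidden: tuple[int, ...] = ENCODER_HIDDEN
    latent_dim: int = LATENT_DIM
    dropout_rate: float = 0.5
    lr: float = 1e-4
    batch_size: int = 128
    epochs: int = 256
    seed: int = 1
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.latent_dim != 2:
            raise ValidationError("latent_dim must be 2 (healthy, tumor)")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.n_features < self.latent_dim:
            raise ValidationError("n_features must be >= latent_dim")
        if self.n_features < min(self.encoder_hidden):
            warnings.warn(
                f"n_features={self.n_features} is smaller than the narrowest "
                "hidden layer; widths will be capped",
                stacklevel=2,
            )

    @property
    def capped_hidden(self) -> tuple[int, ...]:
        # hidden widths are fixed regardless of N (the input layer may expand
        # into a wider hidden layer); only for very small feature counts are
        # they capped at N so tiny test networks stay proportionate
        if self.n_features < min(self.encoder_hidden):
            return tuple(min(w, self.n_features) for w in self.encoder_hidden)
        return self.encoder_hidden

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        """Full sequence of encoder layer widths including input and latent."""
        return (self.n_features, *self.capped_hidden, self.latent_dim)

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        """Mirror of the encoder: latent -> ... -> n_features."""
        return tuple(reversed(self.encoder_widths))


def _celu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _celu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class DeconvModel:
    """Parameter bundle: encoder affine layers + bias-free decoder stack."""

    def __init__(
        self,
        config: ModelConfig,
        probe_ids: tuple[str, ...] | None = None,
    ) -> None:
        self.config = config
        if probe_ids is not None and len(probe_ids) != config.n_features:
            raise ValidationError("probe_ids length must equal n_features")
        self.probe_ids = probe_ids
        rng = np.random.default_rng(config.seed)
        widths = config.encoder_widths
        self.enc_w: list[np.ndarray] = []
        self.enc_b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.enc_w.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
            self.enc_b.append(rng.uniform(-bound, bound, size=fan_out))
        dwidths = config.decoder_widths
        self.dec_w: list[np.ndarray] = []
        for fan_in, fan_out in zip(dwidths[:-1], dwidths[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.dec_w.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))

    # ----------------------------------------------------------------- forward

    def encode(
        self,
        x: np.ndarray,
        inference: bool = True,
        rng: np.random.Generator | None = None,
        _cache: list | None = None,
    ) -> np.ndarray:
        """Map a batch of beta profiles to the 2-d fraction latent.

        In inference mode dropout is off and a ReLU clamps the latent to be
        nonnegative; during training the raw latent is returned so the
        composition loss sees unclipped values.
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.config.n_features:
            raise ValidationError(
                f"input has {x.shape[1]} features, model expects "
                f"{self.config.n_features}"
            )
        keep = 1.0 - self.config.dropout_rate
        h = x
        n_layers = len(self.enc_w)
        for i, (w, b) in enumerate(zip(self.enc_w, self.enc_b)):
            z = h @ w.T + b
            if i < n_layers - 1:
                a = _celu(z)
                # dropout is active only in training mode with an explicit rng;
                # a raw-latent pass without one is deterministic
                if not inference and keep < 1.0 and rng is not None:
                    mask = (rng.random(a.shape) < keep) / keep
                else:
                    mask = None
                h_next = a if mask is None else a * mask
                if _cache is not None:
                    _cache.append((h, z, mask))
                h = h_next
            else:
                if _cache is not None:
                    _cache.append((h, z, None))
                h = z
        return np.maximum(h, 0.0) if inference else h

    def effective_weight(self) -> np.ndarray:
        """Product of the decoder layer matrices: shape (n_features, 2)."""
        w_eff = self.dec_w[0]
        for w in self.dec_w[1:]:
            w_eff = w @ w_eff
        return w_eff

    def effective_atlas(self) -> pd.DataFrame:
        """Sigmoid-squashed effective decoder matrix: the learned atlas.

        Columns are ``healthy`` and ``tumor`` mean beta profiles; every
        entry is strictly inside (0, 1) by construction.
        """
        atlas = _sigmoid(self.effective_weight())
        index = (
            pd.Index(self.probe_ids, name="probe_id")
            if self.probe_ids is not None
            else pd.RangeIndex(self.config.n_features, name="probe_id")
        )
        return pd.DataFrame(atlas, index=index, columns=["healthy", "tumor"])

    def reconstruct(self, fractions: np.ndarray) -> np.ndarray:
        """Mix the atlas columns by a batch of (healthy, tumor) fractions."""
        fractions = np.asarray(fractions, dtype=float)
        atlas = _sigmoid(self.effective_weight())
        return fractions @ atlas.T

    # ------------------------------------------------------------------- loss

    def loss_components(
        self,
        x: np.ndarray,
        y: np.ndarray,
        ref_means: np.ndarray,
        latent: np.ndarray | None = None,
    ) -> dict[str, float]:
        """Evaluate the four loss terms (and their weighted total) on a batch.

        ``ref_means`` is (n_features, 2): per-probe mean beta of the healthy
        and tumor reference populations. ``latent`` may be supplied (e.g. a
        training-mode forward pass); otherwise a deterministic dropout-free
        raw-latent pass is used.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if latent is None:
            latent = self.encode(x, inference=False)
        ref = self._clip_ref(np.asarray(ref_means, dtype=float))
        atlas = _sigmoid(self.effective_weight())
        x_hat = latent @ atlas.T
        comp = float(np.mean(np.abs(latent - y)))
        recon = float(np.mean(np.abs(x - x_hat)))
        methy_h = float(
            -np.mean(ref[:, 0] * np.log(atlas[:, 0]) + (1 - ref[:, 0]) * np.log(1 - atlas[:, 0]))
        )
        methy_t = float(
            -np.mean(ref[:, 1] * np.log(atlas[:, 1]) + (1 - ref[:, 1]) * np.log(1 - atlas[:, 1]))
        )
        w = self.config.loss_weights
        total = w[0] * comp + w[1] * recon + w[2] * methy_h + w[3] * methy_t
        return {
            "comp": comp,
            "recon": recon,
            "methy_h": methy_h,
            "methy_t": methy_t,
            "total": total,
        }

    @staticmethod
    def _clip_ref(ref: np.ndarray, eps: float = 1e-6) -> np.ndarray:
        if ((ref <= 0) | (ref >= 1)).any():
            logger.warning(
                "reference means at the 0/1 boundary clipped to [%g, %g]", eps, 1 - eps
            )
            return np.clip(ref, eps, 1 - eps)
        return ref

    # -------------------------------------------------------------- training

    def _backward(
        self,
        x: np.ndarray,
        y: np.ndarray,
        ref: np.ndarray,
        rng: np.random.Generator,
    ) -> tuple[dict[str, float], list[np.ndarray]]:
        """One forward+backward pass; returns losses and flat gradient list."""
        w_c, w_r, w_h, w_t = self.config.loss_weights
        batch, n = x.shape

        cache: list = []
        latent = self.encode(x, inference=False, rng=rng, _cache=cache)

        # decoder forward: effective matrix and atlas
        prods_right = [self.dec_w[0]]  # cumulative products D_i ... D_1
        for w in self.dec_w[1:]:
            prods_right.append(w @ prods_right[-1])
        w_eff = prods_right[-1]
        atlas = _sigmoid(w_eff)  # (n, 2)
        x_hat = latent @ atlas.T

        comp = float(np.mean(np.abs(latent - y)))
        recon = float(np.mean(np.abs(x - x_hat)))
        methy_h = float(
            -np.mean(ref[:, 0] * np.log(atlas[:, 0]) + (1 - ref[:, 0]) * np.log(1 - atlas[:, 0]))
        )
        methy_t = float(
            -np.mean(ref[:, 1] * np.log(atlas[:, 1]) + (1 - ref[:, 1]) * np.log(1 - atlas[:, 1]))
        )
        total = w_c * comp + w_r * recon + w_h * methy_h + w_t * methy_t
        losses = {
            "comp": comp,
            "recon": recon,
            "methy_h": methy_h,
            "methy_t": methy_t,
            "total": total,
        }
        if not np.isfinite(total):
            bad = [k for k, v in losses.items() if not np.isfinite(v)]
            raise FloatingPointError(
                f"non-finite loss during training: {bad}"
            )

        # --- gradients wrt latent and atlas
        g_rec = np.sign(x_hat - x) / (batch * n)  # dL_recon/dx_hat
        d_latent = w_c * np.sign(latent - y) / latent.size + w_r * (g_rec @ atlas)
        d_atlas = w_r * (g_rec.T @ latent)  # (n, 2)
        # methy terms: d/dW_eff of the Bernoulli NLL collapses to (atlas - ref)/n
        g_eff = d_atlas * atlas * (1.0 - atlas)
        g_eff[:, 0] += w_h * (atlas[:, 0] - ref[:, 0]) / n
        g_eff[:, 1] += w_t * (atlas[:, 1] - ref[:, 1]) / n

        # --- decoder gradients: W_eff = D_k ... D_1
        k = len(self.dec_w)
        prods_left = [None] * k  # D_k ... D_{i+2} acting on the left of D_{i+1}
        left = None
        for i in range(k - 1, -1, -1):
            prods_left[i] = left
            left = self.dec_w[i] if left is None else left @ self.dec_w[i]
        dec_grads: list[np.ndarray] = []
        for i in range(k):
            right = prods_right[i - 1] if i > 0 else None  # D_i-1 ... D_1
            g = g_eff
            if prods_left[i] is not None:
                g = prods_left[i].T @ g
            if right is not None:
                g = g @ right.T
            dec_grads.append(g)

        # --- encoder backprop
        enc_w_grads = [None] * len(self.enc_w)
        enc_b_grads = [None] * len(self.enc_b)
        delta = d_latent
        for i in range(len(self.enc_w) - 1, -1, -1):
            h_in, z, mask = cache[i]
            if i < len(self.enc_w) - 1:
                if mask is not None:
                    delta = delta * mask
                delta = delta * _celu_grad(z)
            enc_w_grads[i] = delta.T @ h_in
            enc_b_grads[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.enc_w[i]

        grads = enc_w_grads + enc_b_grads + dec_grads
        return losses, grads

    def _parameters(self) -> list[np.ndarray]:
        return self.enc_w + self.enc_b + self.dec_w


def build_model(
    config: ModelConfig,
    probe_ids: tuple[str, ...] | None = None,
) -> DeconvModel:
    """Instantiate a model with seeded deterministic initialization."""
    return DeconvModel(config, probe_ids=probe_ids)


def train(
    train_x: np.ndarray,
    train_y: np.ndarray,
    ref: pd.DataFrame,
    config: ModelConfig | None = None,
    **config_overrides,
) -> tuple[DeconvModel, pd.DataFrame]:
    """Train the autoencoder on simulated mixtures.

    Parameters
    ----------
    train_x, train_y
        Simulated mixtures (samples x probes) and their fraction labels
        (samples x 2, healthy then tumor), e.g. from
        :func:`cfdeconv.simulate.generate_simulated_data`.
    ref
        Reference matrix with ``tumor_`` / ``plasma_`` columns (its per-probe
        population means anchor the methylation losses), or a ready-made
        means frame with columns ``healthy`` and ``tumor``.
    config
        Model configuration; ``n_features`` is inferred from ``train_x`` when
        omitted, and keyword overrides (``epochs=...``) are applied on top.

    Returns
    -------
    (model, history)
        The trained model and a per-epoch DataFrame of the loss components.
    """
    train_x = np.asarray(train_x, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    if train_x.ndim != 2 or train_y.ndim != 2 or train_y.shape[1] != 2:
        raise ValidationError("train_x must be 2-d and train_y samples x 2")
    if train_x.shape[0] != train_y.shape[0]:
        raise ValidationError("train_x and train_y disagree on sample count")

    if set(["healthy", "tumor"]).issubset(ref.columns):
        ref_means = ref[["healthy", "tumor"]]
    else:
        ref_means = reference_population_means(ref)
    if len(ref_means) != train_x.shape[1]:
        raise ValidationError(
            "reference probe count does not match training feature count"
        )

    if config is None:
        config = ModelConfig(n_features=train_x.shape[1], **config_overrides)
    elif config_overrides:
        config = ModelConfig(**{**asdict(config), **config_overrides})
    if config.n_features != train_x.shape[1]:
        raise ValidationError("config.n_features does not match train_x")

    model = DeconvModel(config, probe_ids=tuple(str(p) for p in ref_means.index))
    ref_clipped = DeconvModel._clip_ref(ref_means.to_numpy(dtype=float))

    rng = np.random.default_rng(config.seed + 1)
    params = model._parameters()
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    n_samples = train_x.shape[0]
    history: list[dict[str, float]] = []

    for _epoch in range(config.epochs):
        order = rng.permutation(n_samples)
        epoch_losses = np.zeros(5)
        n_batches = 0
        for start in range(0, n_samples, config.batch_size):
            idx = order[start : start + config.batch_size]
            losses, grads = model._backward(
                train_x[idx], train_y[idx], ref_clipped, rng
            )
            step += 1
            for p, g, m, v in zip(params, grads, m_state, v_state):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                m_hat = m / (1 - beta1**step)
                v_hat = v / (1 - beta2**step)
                p -= config.lr * m_hat / (np.sqrt(v_hat) + adam_eps)
            epoch_losses += [
                losses["comp"],
                losses["recon"],
                losses["methy_h"],
                losses["methy_t"],
                losses["total"],
            ]
            n_batches += 1
        history.append(
            dict(
                zip(
                    ["comp", "recon", "methy_h", "methy_t", "total"],
                    epoch_losses / n_batches,
                )
            )
        )
    return model, pd.DataFrame(history)


def predict_fractions(
    model: DeconvModel,
    x: pd.DataFrame,
    normalize: bool = True,
) -> pd.DataFrame:
    """Predict (healthy, tumor) fractions for a probe-by-sample beta matrix.

    Probes are aligned to the model's training probe set; a missing probe is
    an error. Fractions are clamped nonnegative (inference ReLU) and, by
    default, renormalized to sum to 1; a degenerate all-zero latent is
    reported as purely healthy with a warning.
    """
    if model.probe_ids is not None:
        missing = [p for p in model.probe_ids if p not in x.index]
        if missing:
            raise ValidationError(
                f"input matrix lacks {len(missing)} model probes, e.g. {missing[:5]}"
            )
        x = x.loc[list(model.probe_ids)]
    elif x.shape[0] != model.config.n_features:
        raise ValidationError("input probe count does not match the model")
    values = x.to_numpy(dtype=float).T  # samples x probes
    latent = model.encode(values, inference=True)
    out = pd.DataFrame(
        latent, columns=["healthy_fraction", "tumor_fraction"],
    )
    out.insert(0, "sample_id", list(x.columns))
    if normalize:
        totals = out[["healthy_fraction", "tumor_fraction"]].sum(axis=1)
        degenerate = totals == 0
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} sample(s) had an all-zero latent; "
                "reported as purely healthy",
                stacklevel=2,
            )
            out.loc[degenerate, "healthy_fraction"] = 1.0
            totals[degenerate] = 1.0
        out["healthy_fraction"] /= totals
        out["tumor_fraction"] /= totals
    return out


def save_model(model: DeconvModel, path: str | Path) -> None:
    """Serialize parameters, config and probe list to an .npz archive."""
    payload: dict[str, np.ndarray] = {
        "format_version": np.array(_FORMAT_VERSION),
        "config_json": np.array(json.dumps(asdict(model.config))),
        "probe_ids": np.array(
            list(model.probe_ids) if model.probe_ids is not None else [], dtype=str
        ),
    }
    for i, w in enumerate(model.enc_w):
        payload[f"enc_w_{i}"] = w
    for i, b in enumerate(model.enc_b):
        payload[f"enc_b_{i}"] = b
    for i, w in enumerate(model.dec_w):
        payload[f"dec_w_{i}"] = w
    np.savez(path, **payload)


def load_model(path: str | Path) -> DeconvModel:
    """Load a model saved by :func:`save_model` (bit-exact round trip)."""
    try:
        with np.load(path, allow_pickle=False) as archive:
            if "format_version" not in archive:
                raise ModelFormatError(f"{path}: not a cfdeconv model file")
            version = int(archive["format_version"])
            if version != _FORMAT_VERSION:
                raise ModelFormatError(
                    f"{path}: format version {version} not supported "
                    f"(expected {_FORMAT_VERSION})"
                )
            cfg_dict = json.loads(str(archive["config_json"]))
            cfg_dict["encoder_hidden"] = tuple(cfg_dict["encoder_hidden"])
            cfg_dict["loss_weights"] = tuple(cfg_dict["loss_weights"])
            config = ModelConfig(**cfg_dict)
            probe_ids = tuple(archive["probe_ids"].tolist()) or None
            model = DeconvModel(config, probe_ids=probe_ids)
            model.enc_w = [archive[f"enc_w_{i}"] for i in range(len(model.enc_w))]
            model.enc_b = [archive[f"enc_b_{i}"] for i in range(len(model.enc_b))]
            model.dec_w = [archive[f"dec_w_{i}"] for i in range(len(model.dec_w))]
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"{path}: cannot read model file ({exc})") from exc
    return model
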