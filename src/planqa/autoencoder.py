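"""Symmetric fully-connected autoencoder with a composite BCE + λ·MSE loss.

The network is a stack of basic blocks, each a fully connected layer
followed by a leaky-ReLU activation (``f(x) = act(W·x + B)``) and dropout,
except the output layer which applies a sigmoid on the binary (one-hot)
columns and the identity on continuous columns.  Implemented directly on
numpy so training is deterministic given a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .schema import DimMask, DimColumn, EncodedMatrix

__all__ = [
    "ConfigError",
    "AEConfig",
    "AEModel",
    "TrainResult",
    "build_autoencoder",
    "reconstruct",
    "recon_loss",
    "train",
    "sample_errors",
    "fit_autoencoder",
    "save_model",
    "load_model",
]

BCE_EPS = 1e-7


class ConfigError(ValueError):
    """Invalid architecture or training hyperparameters."""


@dataclass
class AEConfig:
    """Architecture and training hyperparameters.

    ``hidden_widths`` overrides the default geometric taper from the input
    dimension down to ``latent_dim`` across ``depth`` encoder blocks.
    """

    depth: int = 3
    hidden_widths: list[int] | None = None
    latent_dim: int = 8
    dropout_rate: float = 0.0
    leaky_slope: float = 0.01
    lambda_weight: float = 0.99
    learning_rate: float = 3e-3
    weight_decay: float = 1e-3
    epochs: int = 800
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= 9:
            raise ConfigError("depth must be in 1..9")
        if self.hidden_widths is not None and len(self.hidden_widths) != self.depth:
            raise ConfigError("len(hidden_widths) must equal depth")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.leaky_slope <= 0:
            raise ConfigError("leaky_slope must be > 0")
        if self.lambda_weight < 0:
            raise ConfigError("lambda_weight must be >= 0")
        if self.latent_dim < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("latent_dim, epochs and batch_size must be positive")


def encoder_widths(config: AEConfig, input_dim: int) -> list[int]:
    """Layer output widths of the encoder, tapering to the latent dimension."""
    if config.hidden_widths is not None:
        widths = list(config.hidden_widths)
        if widths[-1] != config.latent_dim:
            raise ConfigError("explicit hidden_widths must end at latent_dim")
        return widths
    d, lat = config.depth, config.latent_dim
    ratio = (lat / input_dim) ** (1.0 / d)
    widths = [max(lat, round(input_dim * ratio**k)) for k in range(1, d + 1)]
    widths[-1] = lat
    # enforce a monotone non-increasing taper
    for k in range(d - 2, -1, -1):
        widths[k] = max(widths[k], widths[k + 1])
    return widths


@dataclass
class AEModel:
    """Trained or freshly initialized encoder/decoder parameters."""

    weights: list[np.ndarray]  # per layer, shape (d_in, d_out)
    biases: list[np.ndarray]
    widths: list[int]  # [input, ...encoder..., ...decoder..., input]
    depth: int
    leaky_slope: float
    dropout_rate: float
    mask: DimMask | None = None

    @property
    def input_dim(self) -> int:
        return self.widths[0]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def encoder_parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return list(zip(self.weights[: self.depth], self.biases[: self.depth]))

    def decoder_parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return list(zip(self.weights[self.depth :], self.biases[self.depth :]))


@dataclass
class TrainResult:
    model: AEModel
    history: dict[str, np.ndarray]  # keys: total, bce, mse; length = epochs
    seed: int


def build_autoencoder(
    config: AEConfig, input_dim: int, mask: DimMask | None = None
) -> AEModel:
    """Initialize a symmetric autoencoder for ``input_dim`` encoded columns.

    Decoder widths mirror the encoder's in reverse so the full width
    sequence is palindromic.  Weights come from the seeded generator
    (He-style normal init), so the same seed yields identical parameters.
    """
    if input_dim < 2:
        raise ConfigError("input_dim must be >= 2")
    if config.latent_dim >= input_dim:
        raise ConfigError(
            f"latent_dim {config.latent_dim} must be < input_dim {input_dim}"
        )
    if mask is not None and mask.n_dims != input_dim:
        raise ConfigError("mask dimensionality does not match input_dim")

    enc = encoder_widths(config, input_dim)
    dec = enc[-2::-1] + [input_dim]
    widths = [input_dim] + enc + dec
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for d_in, d_out in zip(widths[:-1], widths[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return AEModel(
        weights=weights,
        biases=biases,
        widths=widths,
        depth=config.depth,
        leaky_slope=config.leaky_slope,
        dropout_rate=config.dropout_rate,
        mask=mask,
    )


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _output_activation(z: np.ndarray, mask: DimMask | None) -> np.ndarray:
    if mask is None:
        return z.copy()
    out = z.copy()
    bidx = mask.binary_idx
    if bidx.size:
        out[:, bidx] = _sigmoid(z[:, bidx])
    return out


def _forward(
    model: AEModel,
    X: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
):
    """Forward pass; in train mode returns caches for backprop."""
    a = X
    zs, acts, drop_masks = [], [X], []
    last = model.n_layers - 1
    for li in range(model.n_layers):
        z = a @ model.weights[li] + model.biases[li]
        zs.append(z)
        if li == last:
            a = _output_activation(z, model.mask)
        else:
            a = _leaky(z, model.leaky_slope)
            if train_mode and model.dropout_rate > 0:
                keep = 1.0 - model.dropout_rate
                dm = (rng.random(a.shape) < keep) / keep
                a = a * dm
                drop_masks.append(dm)
            else:
                drop_masks.append(None)
        acts.append(a)
    return a, zs, acts, drop_masks


def reconstruct(model: AEModel, X: np.ndarray | EncodedMatrix) -> np.ndarray:
    """Deterministic inference pass: X̂ = D(E(X)); dropout inactive."""
    if isinstance(X, EncodedMatrix):
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"input width {X.shape[1]} does not match model width {model.input_dim}"
        )
    out, _, _, _ = _forward(model, X, train_mode=False)
    return out


def _loss_cells(
    X_hat: np.ndarray, X: np.ndarray, mask: DimMask, lambda_weight: float, axis=None
):
    """BCE mean over binary cells, MSE mean over continuous cells."""
    bidx, cidx = mask.binary_idx, mask.continuous_idx
    if bidx.size:
        p = np.clip(X_hat[:, bidx], BCE_EPS, 1.0 - BCE_EPS)
        y = X[:, bidx]
        bce = np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)), axis=axis)
    else:
        bce = 0.0 if axis is None else np.zeros(X.shape[0])
    if cidx.size:
        mse = np.mean((X[:, cidx] - X_hat[:, cidx]) ** 2, axis=axis)
    else:
        mse = 0.0 if axis is None else np.zeros(X.shape[0])
    total = bce + lambda_weight * mse
    return total, bce, mse


def recon_loss(
    X_hat: np.ndarray, X: np.ndarray, mask: DimMask, lambda_weight: float
) -> tuple[float, float, float]:
    """Composite reconstruction loss ``total = bce + λ·mse``.

    BCE is the mean over binary cells of −[y·ln p + (1−y)·ln(1−p)] with
    predictions clipped to [ε, 1−ε]; MSE is the mean over continuous cells.
    """
    X_hat = np.atleast_2d(np.asarray(X_hat, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X_hat.shape != X.shape:
        raise ValueError("shape mismatch between reconstruction and target")
    total, bce, mse = _loss_cells(X_hat, X, mask, lambda_weight, axis=None)
    return float(total), float(bce), float(mse)


def sample_errors(
    model: AEModel, data: EncodedMatrix | np.ndarray, lambda_weight: float
) -> np.ndarray:
    """Per-plan composite reconstruction error, row order preserved."""
    mask = data.mask if isinstance(data, EncodedMatrix) else model.mask
    X = data.values if isinstance(data, EncodedMatrix) else np.asarray(data, float)
    X_hat = reconstruct(model, X)
    total, _, _ = _loss_cells(X_hat, X, mask, lambda_weight, axis=1)
    return np.asarray(total)


def train(model: AEModel, data: EncodedMatrix, config: AEConfig) -> TrainResult:
    """Adam training on shuffled mini-batches; per-epoch loss history.

    The recorded history evaluates the full dataset in inference mode after
    each epoch, so the decomposition ``total = bce + λ·mse`` holds exactly
    in the log.  Raises on NaN loss, warns if training failed to reduce the
    initial loss.
    """
    X = np.asarray(data.values, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("training needs at least 2 rows")
    if X.shape[1] != model.input_dim:
        raise ValueError("data width does not match model input width")
    if model.mask is None:
        model.mask = data.mask

    mask = model.mask
    lam = config.lambda_weight
    lr = config.learning_rate
    rng = np.random.default_rng(config.seed + 1)  # decoupled from init stream
    n = X.shape[0]
    bidx, cidx = mask.binary_idx, mask.continuous_idx

    # Adam state
    mW = [np.zeros_like(w) for w in model.weights]
    vW = [np.zeros_like(w) for w in model.weights]
    mB = [np.zeros_like(b) for b in model.biases]
    vB = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    init_total, _, _ = recon_loss(reconstruct(model, X), X, mask, lam)
    hist_total = np.empty(config.epochs)
    hist_bce = np.empty(config.epochs)
    hist_mse = np.empty(config.epochs)
    last = model.n_layers - 1

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx]
            out, zs, acts, drops = _forward(model, xb, train_mode=True, rng=rng)

            # gradient of the composite loss wrt the output pre-activation
            delta = np.zeros_like(out)
            if bidx.size:
                # d/dz mean-BCE(sigmoid(z)) = (p - y) / #binary cells
                delta[:, bidx] = (out[:, bidx] - xb[:, bidx]) / (
                    xb.shape[0] * bidx.size
                )
            if cidx.size:
                delta[:, cidx] = (
                    2.0 * lam * (out[:, cidx] - xb[:, cidx]) / (xb.shape[0] * cidx.size)
                )

            step += 1
            for li in range(last, -1, -1):
                gW = acts[li].T @ delta
                gB = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ model.weights[li].T
                    dm = drops[li - 1]
                    if dm is not None:
                        delta = delta * dm
                    slope = model.leaky_slope
                    delta = delta * np.where(zs[li - 1] > 0, 1.0, slope)
                # Adam update
                mW[li] = beta1 * mW[li] + (1 - beta1) * gW
                vW[li] = beta2 * vW[li] + (1 - beta2) * gW**2
                mB[li] = beta1 * mB[li] + (1 - beta1) * gB
                vB[li] = beta2 * vB[li] + (1 - beta2) * gB**2
                mW_hat = mW[li] / (1 - beta1**step)
                vW_hat = vW[li] / (1 - beta2**step)
                mB_hat = mB[li] / (1 - beta1**step)
                vB_hat = vB[li] / (1 - beta2**step)
                model.weights[li] -= lr * (
                    mW_hat / (np.sqrt(vW_hat) + eps)
                    + config.weight_decay * model.weights[li]
                )
                model.biases[li] -= lr * mB_hat / (np.sqrt(vB_hat) + eps)

        total, bce, mse = recon_loss(reconstruct(model, X), X, mask, lam)
        if not np.isfinite(total):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        hist_total[epoch] = total
        hist_bce[epoch] = bce
        hist_mse[epoch] = mse

    if hist_total[-1] > init_total:
        warnings.warn(
            f"training did not reduce the loss ({init_total:.4g} -> "
            f"{hist_total[-1]:.4g})",
            UserWarning,
        )
    return TrainResult(
        model=model,
        history={"total": hist_total, "bce": hist_bce, "mse": hist_mse},
        seed=config.seed,
    )


def fit_autoencoder(data: EncodedMatrix, config: AEConfig) -> TrainResult:
    """Convenience: build from the data's mask and train."""
    model = build_autoencoder(config, data.n_dims, mask=data.mask)
    return train(model, data, config)


def save_model(model: AEModel, config: AEConfig, path: str | Path) -> None:
    """Single-file JSON checkpoint: weights, config, mask fingerprint."""
    doc = {
        "config": asdict(config),
        "widths": model.widths,
        "depth": model.depth,
        "leaky_slope": model.leaky_slope,
        "dropout_rate": model.dropout_rate,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "mask_fingerprint": model.mask.fingerprint() if model.mask else None,
        "mask_columns": (
            [[c.name, c.source, c.feature, c.kind, c.level] for c in model.mask.columns]
            if model.mask
            else None
        ),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> tuple[AEModel, AEConfig]:
    doc = json.loads(Path(path).read_text())
    mask = None
    if doc["mask_columns"] is not None:
        mask = DimMask(
            tuple(DimColumn(n, s, f, k, l) for n, s, f, k, l in doc["mask_columns"])
        )
    model = AEModel(
        weights=[np.array(w) for w in doc["weights"]],
        biases=[np.array(b) for b in doc["biases"]],
        widths=doc["widths"],
        depth=doc["depth"],
        leaky_slope=doc["leaky_slope"],
        dropout_rate=doc["dropout_rate"],
        mask=mask,
    )
    cfg = AEConfig(**doc["config"])
    return model, cfg


def check_fingerprint(model: AEModel, data: EncodedMatrix) -> None:
    """Refuse to score tables whose encoded layout differs from training."""
    if model.mask is not None and model.mask.fingerprint() != data.mask.fingerprint():
        raise ValueError(
            "encoded table fingerprint does not match the model checkpoint"
        )
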