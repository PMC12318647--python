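"""Fully convolutional denoising autoencoder with a silent-region-aware loss.

The network maps an L2-normalized absorbance spectrum of length 1037 through
four strided 1-D convolutions (128, 64, 32, 16 filters; kernel 53, stride 2,
no padding, ELU) down to a 17x16 bottleneck — 272 latent variables — and back
up through four transposed convolutions, the last one linear.

The training objective is piece-wise: outside the silent region the model
must reproduce its input (plain squared error), while inside the
1800-2300 cm^-1 silent region it is pushed toward a *fixed* reference
spectrum, scaled by a weight ``lambda``::

    L = lambda * (1/n) sum_i sum_{j in silent} (f_j(x_i) - y~_j)^2
      +          (1/n) sum_i sum_{j not in silent} (f_j(x_i) - y_ij)^2

Mapping the silent region — where serum barely absorbs and residual structure
is instrument drift — onto one fixed target forces the network to learn a
drift-removing transformation without labels.  ``lambda`` defaults to 1000 to
balance the silent region's much smaller spectral coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import _nn
from .spectra_io import RegionMask, SpectraSet

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "LossConfig",
    "TrainConfig",
    "AutoencoderModel",
    "default_architecture",
    "build_autoencoder",
    "custom_loss",
    "make_fixed_spectrum",
    "train_autoencoder",
    "reconstruct",
    "encode",
    "silent_pc1_scores",
    "pair_preservation",
    "spectral_comparison",
    "save_model",
    "load_model",
]


class ArchitectureError(ValueError):
    pass


class NotTrainedError(RuntimeError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # "conv" | "transposed_conv"
    filters: int
    kernel_length: int = 53
    stride: int = 2
    activation: str = "elu"  # "elu" | "linear"


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative layer list; encoder convs must precede decoder deconvs."""

    layers: tuple
    input_length: int = 1037

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        kinds = [l.kind for l in self.layers]
        if any(k not in ("conv", "transposed_conv") for k in kinds):
            raise ArchitectureError(f"unknown layer kind in {kinds}")
        n_conv = kinds.count("conv")
        if kinds != ["conv"] * n_conv + ["transposed_conv"] * (len(kinds) - n_conv) or n_conv == 0:
            raise ArchitectureError("encoder convs must precede decoder transposed convs")
        shapes = self.layer_shapes()  # validates positivity
        if shapes[-1][0] != self.input_length:
            raise ArchitectureError(
                f"decoder output length {shapes[-1][0]} != input length {self.input_length}"
            )

    @property
    def n_encoder_layers(self) -> int:
        return sum(1 for l in self.layers if l.kind == "conv")

    def layer_shapes(self) -> list[tuple[int, int]]:
        """(length, channels) after each layer, starting from (input_length, 1)."""
        length, channels = self.input_length, 1
        out = []
        for spec in self.layers:
            if spec.kind == "conv":
                if length < spec.kernel_length:
                    raise ArchitectureError(
                        f"length underflow: {length} < kernel {spec.kernel_length}"
                    )
                length = (length - spec.kernel_length) // spec.stride + 1
            else:
                length = (length - 1) * spec.stride + spec.kernel_length
            if length <= 0:
                raise ArchitectureError("nonpositive intermediate length")
            channels = spec.filters
            out.append((length, channels))
        return out

    def layer_param_counts(self) -> list[int]:
        """Trainable parameters per layer: filters * (in_channels*kernel + 1)."""
        counts = []
        channels = 1
        for spec in self.layers:
            counts.append(spec.filters * (channels * spec.kernel_length + 1))
            channels = spec.filters
        return counts

    @property
    def latent_dim(self) -> int:
        length, channels = self.layer_shapes()[self.n_encoder_layers - 1]
        return length * channels


def default_architecture() -> ArchitectureSpec:
    """The bundled 8-layer architecture (input 1037, bottleneck 17x16 = 272)."""
    enc = [LayerSpec("conv", f) for f in (128, 64, 32, 16)]
    dec = [LayerSpec("transposed_conv", f) for f in (32, 64, 128)]
    dec.append(LayerSpec("transposed_conv", 1, activation="linear"))
    return ArchitectureSpec(layers=tuple(enc + dec), input_length=1037)


@dataclass
class LossConfig:
    """Silent-region mask, fixed reference spectrum y~ and weight lambda.

    ``lambda_weight = 0`` is the ablation switch: the loss degenerates to a
    plain MSE against the input everywhere (the silent region is then *not*
    mapped to the fixed spectrum).
    """

    silent: RegionMask
    fixed_spectrum: np.ndarray
    lambda_weight: float = 1000.0

    def __post_init__(self) -> None:
        self.fixed_spectrum = np.asarray(self.fixed_spectrum, dtype=float).ravel()
        if self.fixed_spectrum.size != self.silent.n_flagged:
            raise ValueError(
                f"fixed_spectrum has {self.fixed_spectrum.size} values, "
                f"mask flags {self.silent.n_flagged} points"
            )
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be nonnegative")


@dataclass
class TrainConfig:
    """ADAM training protocol (defaults follow the full-scale regime).

    ``adam_epsilon`` is the denominator fuzz of the ADAM update; raising it
    (e.g. to 1e-4) damps the large early steps the strongly weighted silent
    term provokes and is recommended for short, scaled-down runs.

    ``mse_pretrain_epochs`` enables a two-phase schedule: the first k epochs
    minimise the plain reconstruction MSE (lambda off), after which the
    optimizer moments are reset and the remaining epochs minimise the full
    silent-region objective at ``constrained_lr_factor * learning_rate``.
    The strongly weighted silent term otherwise dominates the adaptive
    moments and starves fingerprint reconstruction on short step budgets;
    the final objective optimised is unchanged.

    ``scaled_down()`` returns the settings used for quick CPU runs: small
    batches buy more optimizer steps out of the same number of epochs.
    """

    learning_rate: float = 0.001
    batch_size: int = 128
    max_epochs: int = 50
    validation_fraction: float = 0.1
    patience: int = 5
    restore_best: bool = True
    seed: int = 0
    optimizer: str = "adam"
    adam_epsilon: float = 1e-7
    mse_pretrain_epochs: int = 0
    constrained_lr_factor: float = 0.3

    @classmethod
    def scaled_down(cls, max_epochs: int = 15, seed: int = 0, **kw) -> "TrainConfig":
        defaults = dict(batch_size=8, adam_epsilon=1e-4, patience=max_epochs)
        defaults.update(kw)
        return cls(max_epochs=max_epochs, seed=seed, **defaults)

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the ADAM optimizer is supported")


@dataclass
class AutoencoderModel:
    spec: ArchitectureSpec
    network: _nn.Network
    fit_seed: int
    loss_config: LossConfig | None = None
    training_history: list = field(default_factory=list)
    trained: bool = False

    @property
    def latent_dim(self) -> int:
        return self.spec.latent_dim

    def total_params(self) -> int:
        return sum(layer.n_params for layer in self.network.layers)


def build_autoencoder(spec: ArchitectureSpec, seed: int = 0) -> AutoencoderModel:
    """Realize the spec as an untrained network with seeded initialization."""
    rng = np.random.default_rng(seed)
    layers = []
    channels = 1
    for ls in spec.layers:
        cls = _nn.Conv1D if ls.kind == "conv" else _nn.ConvTranspose1D
        layer = cls(channels, ls.filters, ls.kernel_length, ls.stride, ls.activation)
        layer.init_weights(rng)
        layers.append(layer)
        channels = ls.filters
    return AutoencoderModel(spec=spec, network=_nn.Network(layers), fit_seed=seed)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _loss_targets_weights(target: np.ndarray, cfg: LossConfig):
    flags = cfg.silent.member_flags
    if target.shape[1] != flags.size:
        raise ValueError(
            f"mask length {flags.size} does not match spectra length {target.shape[1]}"
        )
    if cfg.lambda_weight == 0:  # ablation: plain MSE against the input
        return target.copy(), np.ones(flags.size)
    full_target = target.copy()
    full_target[:, flags] = cfg.fixed_spectrum
    weights = np.where(flags, cfg.lambda_weight, 1.0)
    return full_target, weights


def custom_loss(predicted: np.ndarray, target: np.ndarray, cfg: LossConfig) -> float:
    """Silent-region-weighted squared-error loss, averaged over spectra."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if predicted.shape != target.shape:
        raise ValueError("predicted and target shapes differ")
    full_target, weights = _loss_targets_weights(target, cfg)
    sq = (predicted - full_target) ** 2
    return float((sq * weights).sum() / predicted.shape[0])


def make_fixed_spectrum(
    train: SpectraSet,
    mask: RegionMask,
    mode: str = "mean_of_training",
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """The silent-region target y~.

    ``mean_of_training`` (default) averages the training spectra over the
    flagged points; ``external_reference`` restricts a user-supplied QC
    spectrum (e.g. pooled serum measured repeatedly) to the flagged points.
    """
    if mode == "mean_of_training":
        if train.n_samples == 0:
            raise ValueError("empty training set")
        return train.absorbance[:, mask.member_flags].mean(axis=0)
    if mode == "external_reference":
        if reference is None:
            raise ValueError("external_reference mode needs a reference spectrum")
        reference = np.asarray(reference, dtype=float).ravel()
        if reference.size == mask.member_flags.size:
            return reference[mask.member_flags]
        if reference.size == mask.n_flagged:
            return reference
        raise ValueError("reference length matches neither grid nor mask")
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _check_normalized(x: np.ndarray) -> None:
    norms = np.linalg.norm(x, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        worst = float(np.abs(norms - 1.0).max())
        raise ValueError(
            f"training spectra must be L2-normalized (max |norm-1| = {worst:.2e})"
        )


def train_autoencoder(
    model: AutoencoderModel,
    train_spectra: SpectraSet,
    loss_cfg: LossConfig,
    train_cfg: TrainConfig | None = None,
) -> AutoencoderModel:
    """Train in place with ADAM, early stopping on held-out validation loss."""
    train_cfg = train_cfg or TrainConfig()
    x = np.asarray(train_spectra.absorbance, dtype=float)
    if x.shape[1] != model.spec.input_length:
        raise ValueError(
            f"spectra length {x.shape[1]} != network input {model.spec.input_length}"
        )
    _check_normalized(x)
    rng = np.random.default_rng(train_cfg.seed)
    n = x.shape[0]
    n_val = max(1, int(round(train_cfg.validation_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:  # tiny inputs: train on everything
        tr_idx, val_idx = perm, perm[:0]
    x32 = x.astype(_nn.DTYPE)
    target_full, weights = _loss_targets_weights(x32.astype(float), loss_cfg)
    target_full = target_full.astype(_nn.DTYPE)
    weights32 = weights.astype(_nn.DTYPE)[None, :, None]
    # two-phase schedule: plain-MSE pretraining targets (identical when the
    # loss is already the lambda=0 ablation)
    pretrain = min(train_cfg.mse_pretrain_epochs, train_cfg.max_epochs)
    if loss_cfg.lambda_weight == 0:
        pretrain = 0

    def batch_loss_and_grad(batch_x, batch_t, w, train: bool):
        out = model.network.forward(batch_x[:, :, None], train=train)
        resid = out - batch_t[:, :, None]
        loss = float((resid.astype(np.float64) ** 2 * w).sum() / batch_x.shape[0])
        grad = (2.0 / batch_x.shape[0]) * w * resid
        return loss, grad.astype(_nn.DTYPE)

    def dataset_loss(idx, target, w) -> float:
        if idx.size == 0:
            return np.nan
        total = 0.0
        for start in range(0, idx.size, train_cfg.batch_size):
            sel = idx[start : start + train_cfg.batch_size]
            loss, _ = batch_loss_and_grad(x32[sel], target[sel], w, train=False)
            total += loss * sel.size
        return total / idx.size

    ones = np.ones_like(weights32)
    history: list[dict] = []
    best_val = np.inf
    best_weights = None
    stall = 0
    for epoch in range(train_cfg.max_epochs):
        in_pretrain = epoch < pretrain
        if epoch == pretrain and pretrain > 0:
            for layer in model.network.layers:
                layer._adam_state = None  # fresh moments for the new objective
        target = x32 if in_pretrain else target_full
        w = ones if in_pretrain else weights32
        lr = train_cfg.learning_rate * (
            1.0 if in_pretrain else train_cfg.constrained_lr_factor
        )
        order = rng.permutation(tr_idx)
        epoch_loss = 0.0
        for start in range(0, order.size, train_cfg.batch_size):
            sel = order[start : start + train_cfg.batch_size]
            loss, grad = batch_loss_and_grad(x32[sel], target[sel], w, train=True)
            model.network.backward_and_step(grad, lr, eps=train_cfg.adam_epsilon)
            epoch_loss += loss * sel.size
        train_loss = epoch_loss / order.size
        val_loss = dataset_loss(val_idx, target, w)
        history.append(
            {
                "epoch": epoch + 1,
                "phase": "pretrain" if in_pretrain else "constrained",
                "train_loss": train_loss,
                "val_loss": val_loss,
            }
        )
        if in_pretrain:
            continue  # early stopping applies to the final objective only
        monitored = val_loss if np.isfinite(val_loss) else train_loss
        if monitored < best_val - 1e-12:
            best_val = monitored
            stall = 0
            if train_cfg.restore_best:
                best_weights = model.network.get_weights()
        else:
            stall += 1
            if stall >= train_cfg.patience:
                break
    if train_cfg.restore_best and best_weights is not None:
        model.network.set_weights(best_weights)
    model.training_history = history
    model.loss_config = loss_cfg
    model.trained = True
    return model


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def _forward_batched(model: AutoencoderModel, x: np.ndarray, upto=None, batch=256) -> np.ndarray:
    outs = []
    x32 = x.astype(_nn.DTYPE)[:, :, None]
    for start in range(0, x.shape[0], batch):
        outs.append(model.network.forward(x32[start : start + batch], train=False, upto=upto))
    return np.concatenate(outs, axis=0)


def reconstruct(model: AutoencoderModel, spectra: SpectraSet) -> SpectraSet:
    """Denoise: run spectra through the full autoencoder."""
    if spectra.absorbance.shape[1] != model.spec.input_length:
        raise ValueError("spectra length does not match network input")
    out = _forward_batched(model, spectra.absorbance)
    return spectra.copy_with(out[:, :, 0].astype(float))


def encode(model: AutoencoderModel, spectra: SpectraSet):
    """Stand-alone encoder: n_samples x latent_dim matrix.

    Flattening is position-major then channel, i.e. the (length, channels)
    bottleneck output is unravelled row by row.
    """
    from .latent_analysis import LatentMatrix

    if not model.trained:
        raise NotTrainedError("encode requires a trained model")
    if spectra.absorbance.shape[1] != model.spec.input_length:
        raise ValueError("spectra length does not match network input")
    bottleneck = _forward_batched(model, spectra.absorbance, upto=model.spec.n_encoder_layers)
    values = bottleneck.reshape(bottleneck.shape[0], -1).astype(float)
    return LatentMatrix(values=values, sample_ids=list(spectra.sample_ids))


# ---------------------------------------------------------------------------
# Denoising diagnostics
# ---------------------------------------------------------------------------

def silent_pc1_scores(spectra: SpectraSet, mask: RegionMask) -> np.ndarray:
    """First-principal-component scores of the silent-region columns.

    Columns are centered but not scaled; the component sign is fixed so the
    loading sum is positive.
    """
    if spectra.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = spectra.absorbance[:, mask.member_flags]
    centered = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    loading = vt[0]
    if loading.sum() < 0:
        loading = -loading
    return centered @ loading


def pair_preservation(original: SpectraSet, reconstructed: SpectraSet) -> float:
    """Fraction of samples whose reconstruction stays nearest its own original.

    Distances are Euclidean in the plane of the first two principal
    components of the pooled (original + reconstructed) set.
    """
    if list(original.sample_ids) != list(reconstructed.sample_ids):
        raise ValueError("sample_ids of original and reconstructed differ")
    pooled = np.vstack([original.absorbance, reconstructed.absorbance])
    centered = pooled - pooled.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[:2].T
    n = original.n_samples
    orig2, recon2 = proj[:n], proj[n:]
    dists = np.linalg.norm(recon2[:, None, :] - orig2[None, :, :], axis=2)
    return float((dists.argmin(axis=1) == np.arange(n)).mean())


def spectral_comparison(original: SpectraSet, reconstructed: SpectraSet):
    """Per-wavenumber original-vs-reconstructed comparison table.

    Columns: paired Cohen's d (mean difference over sd of differences),
    paired t statistic and p value, and the mean absolute residual.
    """
    import pandas as pd

    if list(original.sample_ids) != list(reconstructed.sample_ids):
        raise ValueError("sample_ids of original and reconstructed differ")
    if original.n_samples < 2:
        raise ValueError("comparison needs at least 2 samples")
    diff = original.absorbance - reconstructed.absorbance
    mean_d = diff.mean(axis=0)
    sd_d = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sd_d > 0, mean_d / sd_d, np.where(mean_d == 0, 0.0, np.inf * np.sign(mean_d)))
    import warnings

    with warnings.catch_warnings():
        # identical columns trigger a harmless precision warning in the t-test
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_rel(original.absorbance, reconstructed.absorbance, axis=0)
    t_stat = np.where(sd_d > 0, t_res.statistic, 0.0)
    p_val = np.where(sd_d > 0, t_res.pvalue, 1.0)
    return pd.DataFrame(
        {
            "wavenumber": original.grid.values,
            "effect_size": d,
            "t_statistic": t_stat,
            "p_value": p_val,
            "mean_abs_residual": np.abs(diff).mean(axis=0),
        }
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

SCHEMA_TAG = "ftirdae-model-v1"


def save_model(model: AutoencoderModel, path) -> None:
    """Serialize weights + architecture + loss config into one .npz file."""
    spec_json = json.dumps(
        {
            "schema": SCHEMA_TAG,
            "input_length": model.spec.input_length,
            "layers": [asdict(l) for l in model.spec.layers],
            "fit_seed": model.fit_seed,
            "trained": model.trained,
            "history": model.training_history,
            "loss": None
            if model.loss_config is None
            else {
                "lambda_weight": model.loss_config.lambda_weight,
                "lo": model.loss_config.silent.lo,
                "hi": model.loss_config.silent.hi,
            },
        }
    )
    arrays = {"__meta__": np.array(spec_json)}
    for i, w in enumerate(model.network.get_weights()):
        arrays[f"w{i:03d}"] = w
    if model.loss_config is not None:
        arrays["__mask__"] = model.loss_config.silent.member_flags
        arrays["__fixed__"] = model.loss_config.fixed_spectrum
    np.savez(path, **arrays)


def load_model(path) -> AutoencoderModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("schema") != SCHEMA_TAG:
            raise ValueError(f"unrecognized model schema {meta.get('schema')!r}")
        spec = ArchitectureSpec(
            layers=tuple(LayerSpec(**l) for l in meta["layers"]),
            input_length=meta["input_length"],
        )
        model = build_autoencoder(spec, seed=meta["fit_seed"])
        weights = [data[k] for k in sorted(k for k in data.files if k.startswith("w"))]
        model.network.set_weights(weights)
        model.trained = meta["trained"]
        model.training_history = meta["history"]
        if meta["loss"] is not None:
            mask = RegionMask(data["__mask__"], meta["loss"]["lo"], meta["loss"]["hi"])
            model.loss_config = LossConfig(
                silent=mask,
                fixed_spectrum=data["__fixed__"],
                lambda_weight=meta["loss"]["lambda_weight"],
            )
    return model
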