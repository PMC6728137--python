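"""Training protocol for the TCR β-VAE.

The schedule follows KL warm-up practice: β starts at 0 and increases
linearly each epoch until it reaches its final value (default 0.75).
Training proper is preceded by several short pre-training phases from fresh
random weights; the phase ending with the best validation loss seeds the
full run, which early-stops when validation loss has not improved for
``patience`` epochs and restores the best-validation checkpoint.

Checkpoint selection always evaluates validation loss at the *final* β so
that epochs before and after warm-up are compared on the same objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .encoding import encode_batch
from .repertoire_io import GeneRegistry, TcrTriple
from .vae import GermlineCdr3Table, TcrVae, VaeConfig, germline_match_counts

__all__ = ["TrainConfig", "TrainReport", "beta_schedule", "train",
           "fit_loss_weights", "beta_sweep"]


@dataclass
class TrainConfig:
    beta_final: float = 0.75
    warmup_epochs: int = 20
    n_pretrain_phases: int = 3
    pretrain_epochs: int = 10
    max_epochs: int = 500
    patience: int = 20
    validation_fraction: float = 0.1
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainReport:
    train_losses: list[float] = field(default_factory=list)
    validation_losses: list[float] = field(default_factory=list)
    pretrain_validation_losses: list[float] = field(default_factory=list)
    chosen_pretrain_phase: int = -1
    stopping_epoch: int = -1
    best_validation_loss: float = float("nan")
    final_beta: float = float("nan")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def beta_schedule(epoch: int, config: TrainConfig) -> float:
    """Linear KL warm-up: 0 at epoch 0, β_final from warmup_epochs onward."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if config.warmup_epochs <= 0 or epoch >= config.warmup_epochs:
        return config.beta_final
    return config.beta_final * epoch / config.warmup_epochs


def _aux_targets(
    triples: Sequence[TcrTriple], germline: GermlineCdr3Table
) -> np.ndarray:
    out = np.zeros((len(triples), 3))
    for i, t in enumerate(triples):
        v, j = germline_match_counts(t, germline)
        out[i] = (v, j, len(t.cdr3))
    return out


def _run_epochs(
    model: TcrVae,
    train_batch: dict,
    train_aux: np.ndarray | None,
    config: TrainConfig,
    n_epochs: int,
    rng: np.random.Generator,
    start_epoch: int = 0,
    step_offset: int = 0,
) -> int:
    """In-place optimisation for n_epochs; returns the new Adam step count."""
    n = train_batch["v"].shape[0]
    step = step_offset
    for epoch in range(start_epoch, start_epoch + n_epochs):
        beta = beta_schedule(epoch, config)
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            mini = {k: v[idx] for k, v in train_batch.items()}
            aux = train_aux[idx] if train_aux is not None else None
            model.loss_and_grads(mini, beta, rng, aux)
            step += 1
            model.adam_step(config.learning_rate, step,
                            *config.adam_betas)
    return step


def train(
    data: Sequence[TcrTriple],
    model_kind: str,
    config: TrainConfig,
    registry: GeneRegistry | None = None,
    vae_config: VaeConfig | None = None,
    germline: GermlineCdr3Table | None = None,
) -> tuple[TcrVae, TrainReport]:
    """Fit a β-VAE to a collection of TCR triples.

    The data are split into true-training and validation sets; several
    pre-training phases run from fresh random weights under the β schedule
    and the best (by validation loss) seeds the full run with early
    stopping.  Fully deterministic given ``config.seed``.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 sequences to train")
    registry = registry or GeneRegistry.default()
    vae_config = vae_config or VaeConfig(model_kind=model_kind,
                                         beta=config.beta_final)
    if vae_config.model_kind != model_kind:
        raise ValueError("model_kind disagrees with vae_config.model_kind")

    ss = np.random.SeedSequence(config.seed)
    split_seed, *phase_seeds = ss.generate_state(config.n_pretrain_phases + 2)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])

    # fixed validation split, disjoint from true-training data
    n_val = max(1, int(round(config.validation_fraction * len(data))))
    perm = np.random.default_rng(split_seed).permutation(len(data))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training data")
    train_triples = [data[i] for i in train_idx]
    val_triples = [data[i] for i in val_idx]

    train_batch = encode_batch(train_triples, registry)
    val_batch = encode_batch(val_triples, registry)
    if model_kind == "count_match":
        germline = germline or GermlineCdr3Table.for_registry(registry)
        train_aux = _aux_targets(train_triples, germline)
        val_aux = _aux_targets(val_triples, germline)
    else:
        train_aux = val_aux = None

    report = TrainReport(final_beta=config.beta_final)
    model = TcrVae(vae_config, registry, germline, seed=int(phase_seeds[0]))

    # pre-training phases from fresh random weights
    best_phase_weights, best_phase_loss = None, np.inf
    for phase in range(config.n_pretrain_phases):
        model.reinitialize(int(phase_seeds[phase]))
        model.reset_optimizer()
        _run_epochs(model, train_batch, train_aux, config,
                    config.pretrain_epochs, shuffle_rng)
        vloss = model.evaluate_loss(val_batch, config.beta_final, val_aux)
        report.pretrain_validation_losses.append(float(vloss))
        if vloss < best_phase_loss:
            best_phase_loss = vloss
            best_phase_weights = model.get_weights()
            report.chosen_pretrain_phase = phase

    if config.n_pretrain_phases > 0:
        model.set_weights(best_phase_weights)
    model.reset_optimizer()

    # full run with early stopping on validation loss at final beta
    best_weights = model.get_weights()
    best_val = model.evaluate_loss(val_batch, config.beta_final, val_aux)
    epochs_since_best = 0
    step = 0
    epoch = config.pretrain_epochs if config.n_pretrain_phases > 0 else 0
    for _ in range(config.max_epochs):
        step = _run_epochs(model, train_batch, train_aux, config, 1,
                           shuffle_rng, start_epoch=epoch, step_offset=step)
        tloss = model.evaluate_loss(train_batch, beta_schedule(epoch, config),
                                    train_aux)
        vloss = model.evaluate_loss(val_batch, config.beta_final, val_aux)
        report.train_losses.append(float(tloss))
        report.validation_losses.append(float(vloss))
        epoch += 1
        if vloss < best_val - 1e-9:
            best_val = vloss
            best_weights = model.get_weights()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break

    model.set_weights(best_weights)  # restore best checkpoint, never the last
    report.stopping_epoch = epoch
    report.best_validation_loss = float(best_val)
    return model, report


def fit_loss_weights(
    components: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Least-squares weights combining per-sequence loss components so the
    weighted sum best approximates per-sequence log-likelihood targets.

    Negative weights are clipped to zero with a warning; a rank-deficient
    design raises with a hint to drop collinear components.
    """
    import warnings

    components = np.asarray(components, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if components.ndim != 2:
        raise ValueError("components must be 2-D (sequences x components)")
    if components.shape[0] < components.shape[1]:
        raise ValueError("need at least as many sequences as components")
    if not (np.all(np.isfinite(components)) and np.all(np.isfinite(targets))):
        raise ValueError("non-finite values in regression inputs")
    rank = np.linalg.matrix_rank(components)
    if rank < components.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design matrix; remove collinear loss components"
        )
    weights, *_ = np.linalg.lstsq(components, targets, rcond=None)
    if np.any(weights < 0):
        warnings.warn("negative loss weights clipped to 0", stacklevel=2)
        weights = np.clip(weights, 0.0, None)
    return weights


def beta_sweep(
    data: Sequence[TcrTriple],
    model_kind: str = "basic",
    config: TrainConfig | None = None,
    betas: Sequence[float] | None = None,
    registry: GeneRegistry | None = None,
) -> dict[float, tuple[TcrVae, TrainReport]]:
    """Train one model per β over the sweep grid (seven evenly spaced values
    from 0.625 to 1 by default), each run independent and deterministic."""
    config = config or TrainConfig()
    if betas is None:
        betas = np.linspace(0.625, 1.0, 7)
    out: dict[float, tuple[TcrVae, TrainReport]] = {}
    for b in betas:
        cfg = TrainConfig(**{**asdict(config), "beta_final": float(b)})
        out[float(b)] = train(data, model_kind, cfg, registry=registry)
    return out
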