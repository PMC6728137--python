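"""β-VAE models over (V gene, J gene, CDR3) triples.

Two architectures are provided.  ``basic`` encodes the one-hot triple through
per-component learned linear embeddings (amino acids 21->21 shared across
sites, V genes projected to 30 dimensions, J genes 13->13), two dense ELU
layers, and a diagonal-normal latent head; the decoder mirrors this with two
dense layers and categorical heads for V, J and each of the 30 CDR3 sites.
``count_match`` additionally conditions the decoder on the germline CDR3
prefix/suffix of the input's V and J genes and carries three auxiliary
regression heads (V-germline match count, J-germline match count, CDR3
length) scored by squared loss during training only.

The training objective is a weighted reconstruction loss plus β times the
KL divergence of the encoder distribution from the standard-normal prior;
because the reconstruction components are separately weighted the objective
is not an evidence lower bound.

The networks are small enough that forward and backward passes are written
directly in NumPy; gradients are exact (softmax/cross-entropy, squared loss,
closed-form KL, and the reparameterization z = μ + σ·ε).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    GAP_INDEX,
    MAX_CDR3_LENGTH,
    N_SYMBOLS,
    SYMBOL_INDEX,
    SYMBOLS,
    EncodedTcr,
    decode_argmax,
    encode_batch,
    pad_middle,
    unpad,
)
from .repertoire_io import GeneRegistry, TcrTriple

__all__ = [
    "VaeConfig",
    "GermlineCdr3Table",
    "DecoderOutput",
    "TcrVae",
    "kl_divergence",
    "germline_match_counts",
    "reconstruction_loss",
    "total_loss",
    "conditional_log_prob",
    "sample_tcr",
]

#: Germline context widths for the count_match decoder conditioning: the V
#: prefix block is right-gap-padded to 6 symbols, the J suffix block
#: left-gap-padded to 8.
GERM_V_WIDTH = 6
GERM_J_WIDTH = 8

DEFAULT_LOSS_WEIGHTS = {"v": 1.0, "j": 1.0, "cdr3": 1.0, "match": 1.0, "length": 1.0}


@dataclass
class VaeConfig:
    latent_dim: int = 20
    encoder_hidden: tuple[int, int] = (100, 100)
    decoder_hidden: tuple[int, int] = (100, 100)
    v_embedding_dim: int = 30
    beta: float = 0.75
    loss_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOSS_WEIGHTS)
    )
    model_kind: str = "basic"  # basic | count_match

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.model_kind not in ("basic", "count_match"):
            raise ValueError(f"unknown model_kind: {self.model_kind}")
        if any(w < 0 for w in self.loss_weights.values()) or self.beta < 0:
            raise ValueError("beta and loss weights must be non-negative")


class GermlineCdr3Table:
    """Germline-encoded CDR3 context: per-V prefix and per-J suffix strings.

    The packaged default table is a synthetic stand-in for reference
    germline annotation: TRBJ CDR3 suffixes follow the standard
    annotations, TRBV prefixes are plausible approximations.  Replace the
    CSV with curated boundaries for production use.
    """

    def __init__(self, v_prefix: Mapping[str, str], j_suffix: Mapping[str, str]):
        self.v_prefix = dict(v_prefix)
        self.j_suffix = dict(j_suffix)

    @classmethod
    def default(cls) -> "GermlineCdr3Table":
        path = resources.files("tcrvae.data") / "trb_germline_synthetic.csv"
        with resources.as_file(path) as p:
            table = pd.read_csv(p).fillna("")
        v = dict(table.loc[table.segment == "V", ["gene", "cdr3_germline"]].values)
        j = dict(table.loc[table.segment == "J", ["gene", "cdr3_germline"]].values)
        return cls(v, j)

    @classmethod
    def for_registry(cls, registry: GeneRegistry) -> "GermlineCdr3Table":
        base = cls.default()
        return cls(
            {g: base.v_prefix.get(g, "") for g in registry.v_genes},
            {g: base.j_suffix.get(g, "") for g in registry.j_genes},
        )


def germline_match_counts(
    triple: TcrTriple, table: GermlineCdr3Table
) -> tuple[int, int]:
    """Contiguous germline matches at the CDR3 ends.

    v_count: longest prefix of the CDR3 identical to the V germline CDR3
    prefix; j_count: longest suffix identical to the J germline suffix.
    """
    vg = table.v_prefix.get(triple.v_gene, "")
    jg = table.j_suffix.get(triple.j_gene, "")
    cdr3 = triple.cdr3
    v_count = 0
    for a, b in zip(cdr3, vg):
        if a != b:
            break
        v_count += 1
    j_count = 0
    for a, b in zip(reversed(cdr3), reversed(jg)):
        if a != b:
            break
        j_count += 1
    return v_count, j_count


@dataclass
class DecoderOutput:
    """Categorical heads (each block sums to one) plus, for count_match,
    auxiliary scalar predictions used only by the training loss."""

    v_probs: np.ndarray
    j_probs: np.ndarray
    cdr3_probs: np.ndarray  # (30, 21) or (B, 30, 21)
    predicted_v_match: np.ndarray | float | None = None
    predicted_j_match: np.ndarray | float | None = None
    predicted_length: np.ndarray | float | None = None


# ----------------------------------------------------------------------------
# closed-form loss components (functional API, used by model and tests)
# ----------------------------------------------------------------------------

def kl_divergence(mean: np.ndarray, log_variance: np.ndarray) -> float:
    """KL(q || N(0, I)) for a diagonal normal q, summed over dimensions.

    0.5 * Σ_d (μ_d² + σ_d² − 1 − log σ_d²); batched inputs are averaged
    over the batch axis.
    """
    mean = np.asarray(mean, dtype=float)
    log_variance = np.asarray(log_variance, dtype=float)
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(log_variance))):
        raise ValueError("non-finite encoder output")
    per = 0.5 * np.sum(
        mean**2 + np.exp(log_variance) - 1.0 - log_variance, axis=-1
    )
    return float(np.mean(per))


def _check_normalized(out: DecoderOutput, tol: float = 1e-6) -> None:
    for name, block, axis in (
        ("v_probs", out.v_probs, -1),
        ("j_probs", out.j_probs, -1),
        ("cdr3_probs", out.cdr3_probs, -1),
    ):
        sums = np.sum(block, axis=axis)
        if not np.allclose(sums, 1.0, atol=tol):
            raise ValueError(f"decoder block {name} is not normalized")


def reconstruction_loss(
    x: EncodedTcr,
    out: DecoderOutput,
    config: VaeConfig,
    match_counts: tuple[int, int] | None = None,
    length: int | None = None,
) -> float:
    """Weighted reconstruction loss for one sequence.

    basic: w_v·CE(V) + w_j·CE(J) + w_cdr3·(mean per-site CE over the 30
    padded sites).  count_match adds w_match·((v̂−v)²+(ĵ−j)²) and
    w_len·(L̂−L)² against the true germline-match counts and CDR3 length.
    """
    from scipy.special import xlogy  # xlogy(0, 0) = 0 for one-hot targets

    _check_normalized(out)
    w = {**DEFAULT_LOSS_WEIGHTS, **config.loss_weights}
    ce_v = -xlogy(x.v, out.v_probs).sum()
    ce_j = -xlogy(x.j, out.j_probs).sum()
    ce_cdr3 = -xlogy(x.cdr3, out.cdr3_probs).sum() / MAX_CDR3_LENGTH
    loss = w["v"] * ce_v + w["j"] * ce_j + w["cdr3"] * ce_cdr3
    if config.model_kind == "count_match":
        if match_counts is None or length is None:
            raise ValueError("count_match loss needs true match counts and length")
        sq = (float(out.predicted_v_match) - match_counts[0]) ** 2
        sq += (float(out.predicted_j_match) - match_counts[1]) ** 2
        loss += w["match"] * sq
        loss += w["length"] * (float(out.predicted_length) - length) ** 2
    return float(loss)


def total_loss(
    x: EncodedTcr,
    enc: tuple[np.ndarray, np.ndarray],
    out: DecoderOutput,
    config: VaeConfig,
    match_counts: tuple[int, int] | None = None,
    length: int | None = None,
) -> float:
    """reconstruction_loss + β·KL for one sequence."""
    mean, log_variance = enc
    return reconstruction_loss(x, out, config, match_counts, length) + (
        config.beta * kl_divergence(mean, log_variance)
    )


def conditional_log_prob(x: EncodedTcr, out: DecoderOutput) -> float:
    """log p(x|z) as a product of categorical probabilities: V, J and all 30
    padded CDR3 sites (gaps included).  Returns −inf, not an exception, when
    an observed symbol has probability zero."""
    _check_normalized(out)
    with np.errstate(divide="ignore"):
        lp = np.log(np.sum(out.v_probs * x.v))
        lp += np.log(np.sum(out.j_probs * x.j))
        site_p = np.sum(out.cdr3_probs * x.cdr3, axis=-1)
        lp += np.sum(np.log(site_p))
    return float(lp)


# ----------------------------------------------------------------------------
# parameters and numerics
# ----------------------------------------------------------------------------

class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, y + 1.0)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def _softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(_log_softmax(logits))


# ----------------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------------

class TcrVae:
    """NumPy implementation of the basic / count_match β-VAE."""

    def __init__(
        self,
        config: VaeConfig,
        registry: GeneRegistry,
        germline: GermlineCdr3Table | None = None,
        seed: int = 0,
    ) -> None:
        self.config = config
        self.registry = registry
        self.n_v = len(registry.v_genes)
        self.n_j = len(registry.j_genes)
        if config.model_kind == "count_match":
            self.germline = germline or GermlineCdr3Table.for_registry(registry)
            self._germ_v_mat = self._germ_matrix(
                [self.germline.v_prefix[g] for g in registry.v_genes],
                GERM_V_WIDTH, align="left",
            )
            self._germ_j_mat = self._germ_matrix(
                [self.germline.j_suffix[g] for g in registry.j_genes],
                GERM_J_WIDTH, align="right",
            )
            self.germ_dim = (GERM_V_WIDTH + GERM_J_WIDTH) * N_SYMBOLS
        else:
            self.germline = germline
            self.germ_dim = 0
        self._init_params(np.random.default_rng(seed))

    @staticmethod
    def _germ_matrix(strings: list[str], width: int, align: str) -> np.ndarray:
        mat = np.zeros((len(strings), width, N_SYMBOLS))
        for i, s in enumerate(strings):
            s = s[:width]
            padded = s + "-" * (width - len(s)) if align == "left" else (
                "-" * (width - len(s)) + s
            )
            for site, sym in enumerate(padded):
                mat[i, site, SYMBOL_INDEX.get(sym, GAP_INDEX)] = 1.0
        return mat.reshape(len(strings), width * N_SYMBOLS)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        D = cfg.latent_dim
        eh1, eh2 = cfg.encoder_hidden
        dh1, dh2 = cfg.decoder_hidden
        enc_in = MAX_CDR3_LENGTH * N_SYMBOLS + cfg.v_embedding_dim + self.n_j
        dec_in = D + self.germ_dim
        p: dict[str, _Param] = {}

        def add(name, n_in, n_out):
            p[name + "_W"] = _Param(_glorot(rng, n_in, n_out))
            p[name + "_b"] = _Param(np.zeros(n_out))

        add("emb_aa", N_SYMBOLS, N_SYMBOLS)
        add("emb_v", self.n_v, cfg.v_embedding_dim)
        add("emb_j", self.n_j, self.n_j)
        add("enc1", enc_in, eh1)
        add("enc2", eh1, eh2)
        add("mu", eh2, D)
        add("logvar", eh2, D)
        add("dec1", dec_in, dh1)
        add("dec2", dh1, dh2)
        add("head_v", dh2, self.n_v)
        add("head_j", dh2, self.n_j)
        add("head_cdr3", dh2, MAX_CDR3_LENGTH * N_SYMBOLS)
        if cfg.model_kind == "count_match":
            add("head_aux", dh2, 3)  # v_match, j_match, length
        self.params = p

    # -- weights management ---------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.params.items()}

    def set_weights(self, weights: Mapping[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.value[...] = weights[k]

    def reinitialize(self, seed: int) -> None:
        self._init_params(np.random.default_rng(seed))

    # -- forward passes -------------------------------------------------------

    def encode(self, batch: Mapping[str, np.ndarray]):
        """Encoder means and log-variances for a batch dict from
        :func:`tcrvae.encoding.encode_batch`."""
        p = self.params
        B = batch["v"].shape[0]
        aa = batch["cdr3"] @ p["emb_aa_W"].value + p["emb_aa_b"].value
        ev = batch["v"] @ p["emb_v_W"].value + p["emb_v_b"].value
        ej = batch["j"] @ p["emb_j_W"].value + p["emb_j_b"].value
        h0 = np.concatenate([aa.reshape(B, -1), ev, ej], axis=1)
        a1 = h0 @ p["enc1_W"].value + p["enc1_b"].value
        h1 = _elu(a1)
        a2 = h1 @ p["enc2_W"].value + p["enc2_b"].value
        h2 = _elu(a2)
        mu = h2 @ p["mu_W"].value + p["mu_b"].value
        lv = h2 @ p["logvar_W"].value + p["logvar_b"].value
        cache = (batch, h0, a1, h1, a2, h2)
        return mu, lv, cache

    def germ_input(self, x_v: np.ndarray, x_j: np.ndarray) -> np.ndarray | None:
        if self.config.model_kind != "count_match":
            return None
        return np.concatenate([x_v @ self._germ_v_mat, x_j @ self._germ_j_mat], axis=1)

    def decode(self, z: np.ndarray, germ: np.ndarray | None = None):
        """Decoder probabilities (and aux heads) for latent points z (B, D)."""
        p = self.params
        z = np.atleast_2d(z)
        if self.germ_dim:
            if germ is None:
                germ = np.zeros((z.shape[0], self.germ_dim))
            din = np.concatenate([z, germ], axis=1)
        else:
            din = z
        b1 = din @ p["dec1_W"].value + p["dec1_b"].value
        d1 = _elu(b1)
        b2 = d1 @ p["dec2_W"].value + p["dec2_b"].value
        d2 = _elu(b2)
        logit_v = d2 @ p["head_v_W"].value + p["head_v_b"].value
        logit_j = d2 @ p["head_j_W"].value + p["head_j_b"].value
        logit_c = (d2 @ p["head_cdr3_W"].value + p["head_cdr3_b"].value).reshape(
            z.shape[0], MAX_CDR3_LENGTH, N_SYMBOLS
        )
        aux = None
        if self.config.model_kind == "count_match":
            aux = d2 @ p["head_aux_W"].value + p["head_aux_b"].value
        cache = (din, b1, d1, b2, d2)
        return {"logit_v": logit_v, "logit_j": logit_j, "logit_cdr3": logit_c,
                "aux": aux, "cache": cache}

    def decoder_output(self, z: np.ndarray, germ: np.ndarray | None = None,
                       index: int | None = 0) -> DecoderOutput:
        """:class:`DecoderOutput` view for a single latent point."""
        fwd = self.decode(z, germ)
        i = index if index is not None else slice(None)
        aux = fwd["aux"]
        return DecoderOutput(
            v_probs=_softmax(fwd["logit_v"])[i],
            j_probs=_softmax(fwd["logit_j"])[i],
            cdr3_probs=_softmax(fwd["logit_cdr3"])[i],
            predicted_v_match=None if aux is None else aux[i, 0],
            predicted_j_match=None if aux is None else aux[i, 1],
            predicted_length=None if aux is None else aux[i, 2],
        )

    def log_px_given_z(self, batch: Mapping[str, np.ndarray], Z: np.ndarray,
                       germ_row: np.ndarray | None = None) -> np.ndarray:
        """log p(x|z) for a single encoded x against many latent points.

        ``batch`` must contain exactly one sequence; Z is (n, D)."""
        germ = None
        if self.germ_dim:
            if germ_row is None:
                germ_row = self.germ_input(batch["v"], batch["j"])[0]
            germ = np.broadcast_to(germ_row, (Z.shape[0], self.germ_dim))
        fwd = self.decode(Z, germ)
        lv = _log_softmax(fwd["logit_v"]) @ batch["v"][0]
        lj = _log_softmax(fwd["logit_j"]) @ batch["j"][0]
        lc = np.einsum("nsk,sk->n", _log_softmax(fwd["logit_cdr3"]), batch["cdr3"][0])
        return lv + lj + lc

    # -- training step (exact gradients) --------------------------------------

    def loss_and_grads(
        self,
        batch: Mapping[str, np.ndarray],
        beta: float,
        rng: np.random.Generator,
        aux_targets: np.ndarray | None = None,
    ) -> dict[str, float]:
        """Mean batch loss and exact parameter gradients (stored on params).

        ``aux_targets`` (B, 3) carries true (v_match, j_match, length) for
        count_match models.
        """
        p = self.params
        cfg = self.config
        w = {**DEFAULT_LOSS_WEIGHTS, **cfg.loss_weights}
        B = batch["v"].shape[0]

        mu, lvar, enc_cache = self.encode(batch)
        eps = rng.standard_normal(mu.shape)
        sigma = np.exp(0.5 * lvar)
        z = mu + sigma * eps
        germ = self.germ_input(batch["v"], batch["j"])
        fwd = self.decode(z, germ)

        logp_v = _log_softmax(fwd["logit_v"])
        logp_j = _log_softmax(fwd["logit_j"])
        logp_c = _log_softmax(fwd["logit_cdr3"])
        ce_v = -np.sum(batch["v"] * logp_v) / B
        ce_j = -np.sum(batch["j"] * logp_j) / B
        ce_c = -np.sum(batch["cdr3"] * logp_c) / (B * MAX_CDR3_LENGTH)
        recon = w["v"] * ce_v + w["j"] * ce_j + w["cdr3"] * ce_c

        losses = {"ce_v": ce_v, "ce_j": ce_j, "ce_cdr3": ce_c}
        daux = None
        if cfg.model_kind == "count_match":
            if aux_targets is None:
                raise ValueError("count_match training requires aux_targets")
            diff = fwd["aux"] - aux_targets
            sq_match = np.sum(diff[:, :2] ** 2) / B
            sq_len = np.sum(diff[:, 2] ** 2) / B
            recon += w["match"] * sq_match + w["length"] * sq_len
            losses.update(sq_match=sq_match, sq_length=sq_len)
            daux = 2.0 * diff / B
            daux[:, :2] *= w["match"]
            daux[:, 2] *= w["length"]

        kl = 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - lvar) / B
        total = recon + beta * kl
        if not np.isfinite(total):
            raise FloatingPointError("non-finite training loss")
        losses.update(recon=recon, kl=kl, total=total)

        # ---- backward ----
        for prm in p.values():
            prm.grad[...] = 0.0

        d_logit_v = w["v"] * (np.exp(logp_v) - batch["v"]) / B
        d_logit_j = w["j"] * (np.exp(logp_j) - batch["j"]) / B
        d_logit_c = w["cdr3"] * (np.exp(logp_c) - batch["cdr3"]) / (
            B * MAX_CDR3_LENGTH
        )

        din, b1, d1, b2, d2 = fwd["cache"]
        dd2 = d_logit_v @ p["head_v_W"].value.T
        dd2 += d_logit_j @ p["head_j_W"].value.T
        dd2 += d_logit_c.reshape(B, -1) @ p["head_cdr3_W"].value.T
        p["head_v_W"].grad += d2.T @ d_logit_v
        p["head_v_b"].grad += d_logit_v.sum(0)
        p["head_j_W"].grad += d2.T @ d_logit_j
        p["head_j_b"].grad += d_logit_j.sum(0)
        p["head_cdr3_W"].grad += d2.T @ d_logit_c.reshape(B, -1)
        p["head_cdr3_b"].grad += d_logit_c.reshape(B, -1).sum(0)
        if daux is not None:
            dd2 += daux @ p["head_aux_W"].value.T
            p["head_aux_W"].grad += d2.T @ daux
            p["head_aux_b"].grad += daux.sum(0)

        db2 = dd2 * _elu_grad(b2, d2)
        p["dec2_W"].grad += d1.T @ db2
        p["dec2_b"].grad += db2.sum(0)
        dd1 = db2 @ p["dec2_W"].value.T
        db1 = dd1 * _elu_grad(b1, d1)
        p["dec1_W"].grad += din.T @ db1
        p["dec1_b"].grad += db1.sum(0)
        ddin = db1 @ p["dec1_W"].value.T
        dz = ddin[:, : cfg.latent_dim]  # germline block is a fixed input

        dmu = dz + beta * mu / B
        dlvar = dz * eps * 0.5 * sigma + beta * 0.5 * (sigma**2 - 1.0) / B

        xbatch, h0, a1, h1, a2, h2 = enc_cache
        dh2 = dmu @ p["mu_W"].value.T + dlvar @ p["logvar_W"].value.T
        p["mu_W"].grad += h2.T @ dmu
        p["mu_b"].grad += dmu.sum(0)
        p["logvar_W"].grad += h2.T @ dlvar
        p["logvar_b"].grad += dlvar.sum(0)
        da2 = dh2 * _elu_grad(a2, h2)
        p["enc2_W"].grad += h1.T @ da2
        p["enc2_b"].grad += da2.sum(0)
        dh1 = da2 @ p["enc2_W"].value.T
        da1 = dh1 * _elu_grad(a1, h1)
        p["enc1_W"].grad += h0.T @ da1
        p["enc1_b"].grad += da1.sum(0)
        dh0 = da1 @ p["enc1_W"].value.T

        n_aa = MAX_CDR3_LENGTH * N_SYMBOLS
        d_aa = dh0[:, :n_aa].reshape(B, MAX_CDR3_LENGTH, N_SYMBOLS)
        d_ev = dh0[:, n_aa : n_aa + cfg.v_embedding_dim]
        d_ej = dh0[:, n_aa + cfg.v_embedding_dim :]
        p["emb_aa_W"].grad += np.einsum("bsk,bsm->km", xbatch["cdr3"], d_aa)
        p["emb_aa_b"].grad += d_aa.sum(axis=(0, 1))
        p["emb_v_W"].grad += xbatch["v"].T @ d_ev
        p["emb_v_b"].grad += d_ev.sum(0)
        p["emb_j_W"].grad += xbatch["j"].T @ d_ej
        p["emb_j_b"].grad += d_ej.sum(0)

        return losses

    def adam_step(self, lr: float, t: int, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8) -> None:
        for prm in self.params.values():
            prm.m = beta1 * prm.m + (1 - beta1) * prm.grad
            prm.v = beta2 * prm.v + (1 - beta2) * prm.grad**2
            mhat = prm.m / (1 - beta1**t)
            vhat = prm.v / (1 - beta2**t)
            prm.value -= lr * mhat / (np.sqrt(vhat) + eps)

    def reset_optimizer(self) -> None:
        for prm in self.params.values():
            prm.m[...] = 0.0
            prm.v[...] = 0.0

    def evaluate_loss(self, batch: Mapping[str, np.ndarray], beta: float,
                      aux_targets: np.ndarray | None = None,
                      seed: int = 0) -> float:
        """Mean total loss without touching gradients or optimizer state."""
        grads = {k: prm.grad.copy() for k, prm in self.params.items()}
        losses = self.loss_and_grads(
            batch, beta, np.random.default_rng(seed), aux_targets
        )
        for k, prm in self.params.items():
            prm.grad[...] = grads[k]
        return losses["total"]

    # -- serialization --------------------------------------------------------

    def save(self, weights_path: str | Path, metadata_path: str | Path | None = None) -> None:
        """One .npz weights file plus a JSON metadata sidecar."""
        weights_path = Path(weights_path)
        metadata_path = Path(metadata_path) if metadata_path else (
            weights_path.with_suffix(".json")
        )
        np.savez(weights_path, **{k: prm.value for k, prm in self.params.items()})
        meta = {
            "config": asdict(self.config),
            "symbols": SYMBOLS,
            "v_genes": self.registry.v_genes,
            "j_genes": self.registry.j_genes,
            "registry_hash": self.registry.content_hash(),
        }
        metadata_path.write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, weights_path: str | Path,
             metadata_path: str | Path | None = None) -> "TcrVae":
        weights_path = Path(weights_path)
        metadata_path = Path(metadata_path) if metadata_path else (
            weights_path.with_suffix(".json")
        )
        meta = json.loads(Path(metadata_path).read_text())
        if meta["symbols"] != SYMBOLS:
            raise ValueError("model metadata mismatch: alphabet order differs")
        cfgd = dict(meta["config"])
        cfgd["encoder_hidden"] = tuple(cfgd["encoder_hidden"])
        cfgd["decoder_hidden"] = tuple(cfgd["decoder_hidden"])
        registry = GeneRegistry(meta["v_genes"], meta["j_genes"])
        if registry.content_hash() != meta["registry_hash"]:
            raise ValueError("model metadata mismatch: registry hash differs")
        model = cls(VaeConfig(**cfgd), registry)
        data = np.load(weights_path)
        if set(data.files) != set(model.params):
            raise ValueError("model metadata mismatch: parameter names differ")
        model.set_weights({k: data[k] for k in data.files})
        return model


def sample_tcr(
    model: TcrVae,
    z: np.ndarray,
    mode: str = "sample",
    seed: int = 0,
    strict: bool = False,
    max_retries: int = 100,
) -> TcrTriple:
    """Realise a TCR triple from the decoder at latent point z.

    ``mode="argmax"`` takes the most probable symbol everywhere (deterministic
    given z); ``mode="sample"`` draws each component.  Gap symbols are
    stripped from the CDR3; with ``strict=True`` draws whose gaps are not a
    contiguous central block are rejected and redrawn (bounded retries).

    count_match models draw V and J first (germline context zeroed), then
    redecode with the drawn genes' germline blocks to realise the CDR3.
    """
    if mode not in ("sample", "argmax"):
        raise ValueError(f"unknown mode: {mode}")
    rng = np.random.default_rng(seed)
    z = np.atleast_2d(np.asarray(z, dtype=float))
    reg = model.registry

    first = model.decoder_output(z, germ=None, index=0)
    if mode == "argmax":
        vi = int(np.argmax(first.v_probs))
        ji = int(np.argmax(first.j_probs))
    else:
        vi = int(rng.choice(model.n_v, p=first.v_probs))
        ji = int(rng.choice(model.n_j, p=first.j_probs))

    if model.germ_dim:
        xv = np.zeros((1, model.n_v)); xv[0, vi] = 1.0
        xj = np.zeros((1, model.n_j)); xj[0, ji] = 1.0
        out = model.decoder_output(z, germ=model.germ_input(xv, xj), index=0)
    else:
        out = first

    if mode == "argmax":
        padded = "".join(SYMBOLS[i] for i in out.cdr3_probs.argmax(axis=-1))
        cdr3 = unpad(padded, strict=False)
        if strict and (len(cdr3) == 0 or pad_middle(cdr3) != padded):
            raise RuntimeError("argmax decode has non-central gaps in strict mode")
        if len(cdr3) == 0:
            raise RuntimeError("decoder argmax produced an all-gap CDR3")
        return TcrTriple(reg.v_genes[vi], reg.j_genes[ji], cdr3)

    for _ in range(max_retries):
        draws = [
            int(rng.choice(N_SYMBOLS, p=out.cdr3_probs[s]))
            for s in range(MAX_CDR3_LENGTH)
        ]
        padded = "".join(SYMBOLS[i] for i in draws)
        cdr3 = padded.replace("-", "")
        if not cdr3:
            continue
        if strict and pad_middle(cdr3) != padded:
            continue
        return TcrTriple(reg.v_genes[vi], reg.j_genes[ji], cdr3)
    raise RuntimeError(f"sampling retry budget ({max_retries}) exhausted")


def generate(
    model: TcrVae, n: int, seed: int, mode: str = "sample", strict: bool = False
) -> list[TcrTriple]:
    """Sample n new TCRs by decoding draws from the standard-normal prior."""
    ss = np.random.SeedSequence(seed)
    prior_rng = np.random.default_rng(ss.spawn(1)[0])
    z = prior_rng.standard_normal((n, model.config.latent_dim))
    child_seeds = ss.generate_state(n + 1)[1:]
    return [
        sample_tcr(model, z[i], mode=mode, seed=int(child_seeds[i] % (2**31)),
                   strict=strict)
        for i in range(n)
    ]
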