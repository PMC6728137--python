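"""Fixed-width one-hot encoding of TCR triples.

CDR3 sequences are padded to 30 symbols with a central gap block (the extra
residue of odd-length sequences goes on the left), then one-hot encoded over
a 21-letter alphabet (20 amino acids, alphabetical, plus a trailing gap
channel).  V and J genes are one-hot over the registry's ordered gene lists
(67 and 13 by default), giving a 630 + 67 + 13 = 710-dimensional encoding.

All maps here are deterministic; learned embeddings are part of the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .repertoire_io import AMINO_ACIDS, MAX_CDR3_LENGTH, GeneRegistry, TcrTriple

GAP = "-"
#: Site alphabet: amino acids in alphabetical order, gap last (channel 20).
SYMBOLS = AMINO_ACIDS + GAP
SYMBOL_INDEX = {s: i for i, s in enumerate(SYMBOLS)}
GAP_INDEX = SYMBOL_INDEX[GAP]
N_SYMBOLS = len(SYMBOLS)  # 21


class MalformedSequenceError(ValueError):
    pass


def pad_middle(cdr3: str) -> str:
    """Pad a CDR3 to 30 symbols with a contiguous central gap block.

    The non-gap prefix keeps ceil(L/2) residues and the suffix floor(L/2),
    i.e. odd-length sequences keep one extra residue on the left.
    """
    L = len(cdr3)
    if not 1 <= L <= MAX_CDR3_LENGTH:
        raise ValueError(f"CDR3 length must be in [1, {MAX_CDR3_LENGTH}], got {L}")
    left = (L + 1) // 2
    return cdr3[:left] + GAP * (MAX_CDR3_LENGTH - L) + cdr3[left:]


def unpad(padded: str, strict: bool = False) -> str:
    """Remove gap symbols; in strict mode require the pad_middle layout."""
    if len(padded) != MAX_CDR3_LENGTH:
        raise MalformedSequenceError(
            f"padded CDR3 must have {MAX_CDR3_LENGTH} symbols, got {len(padded)}"
        )
    stripped = padded.replace(GAP, "")
    if strict and pad_middle(stripped) != padded:
        raise MalformedSequenceError(
            "gaps do not form the contiguous central block produced by pad_middle"
        )
    return stripped


@dataclass
class EncodedTcr:
    """One-hot encoding: (30, 21) CDR3 block, (n_v,) V block, (n_j,) J block."""

    cdr3: np.ndarray
    v: np.ndarray
    j: np.ndarray

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.cdr3.ravel(), self.v, self.j])


def one_hot_encode(triple: TcrTriple, registry: GeneRegistry) -> EncodedTcr:
    """Encode one triple; raises KeyError for genes outside the registry."""
    padded = pad_middle(triple.cdr3)
    cdr3 = np.zeros((MAX_CDR3_LENGTH, N_SYMBOLS))
    for site, sym in enumerate(padded):
        try:
            cdr3[site, SYMBOL_INDEX[sym]] = 1.0
        except KeyError:
            raise ValueError(f"invalid CDR3 symbol {sym!r}") from None
    v = np.zeros(len(registry.v_genes))
    v[registry.v_index(triple.v_gene)] = 1.0
    j = np.zeros(len(registry.j_genes))
    j[registry.j_index(triple.j_gene)] = 1.0
    return EncodedTcr(cdr3, v, j)


def encode_batch(
    triples: Sequence[TcrTriple], registry: GeneRegistry
) -> dict[str, np.ndarray]:
    """Vectorised encoding: arrays cdr3 (B,30,21), v (B,n_v), j (B,n_j)."""
    B = len(triples)
    cdr3 = np.zeros((B, MAX_CDR3_LENGTH, N_SYMBOLS))
    v = np.zeros((B, len(registry.v_genes)))
    j = np.zeros((B, len(registry.j_genes)))
    rows = np.arange(MAX_CDR3_LENGTH)
    for b, t in enumerate(triples):
        padded = pad_middle(t.cdr3)
        cdr3[b, rows, [SYMBOL_INDEX[s] for s in padded]] = 1.0
        v[b, registry.v_index(t.v_gene)] = 1.0
        j[b, registry.j_index(t.j_gene)] = 1.0
    return {"cdr3": cdr3, "v": v, "j": j}


def decode_argmax(
    cdr3_probs: np.ndarray,
    v_probs: np.ndarray,
    j_probs: np.ndarray,
    registry: GeneRegistry,
    strict: bool = False,
) -> TcrTriple:
    """Most-probable triple from per-block probabilities (or one-hots)."""
    padded = "".join(SYMBOLS[i] for i in np.asarray(cdr3_probs).argmax(axis=-1))
    return TcrTriple(
        registry.v_genes[int(np.argmax(v_probs))],
        registry.j_genes[int(np.argmax(j_probs))],
        unpad(padded, strict=strict),
    )


def decode_encoded(enc: EncodedTcr, registry: GeneRegistry) -> TcrTriple:
    return decode_argmax(enc.cdr3, enc.v, enc.j, registry)
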