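"""Recombination-plus-selection baseline: Q factors over (V, J, CDR3 length).

The post-selection repertoire distribution is modelled as Pgen(x)·Q(key(x)),
where Pgen comes from any generation-probability provider (the built-in
recombination simulator, or an external recombination engine plugged in
through the same interface) and Q is a per-(V gene, J gene, CDR3 length)
selection factor.  The maximum-likelihood estimate of Q for a key is the
ratio of its empirical frequency in training data to its probability under
the recombination model, truncated (default 100) for numerical stability.
Sampling from the selected distribution uses rejection sampling with
acceptance probability Q/q_max.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .repertoire_io import TcrTriple

__all__ = ["TripleKey", "QTable", "PgenProvider", "key_of",
           "estimate_key_marginals", "fit_q", "score", "normalize_scores",
           "rejection_sample"]


@dataclass(frozen=True, slots=True)
class TripleKey:
    v_gene: str
    j_gene: str
    cdr3_length: int


def key_of(triple: TcrTriple) -> TripleKey:
    return TripleKey(triple.v_gene, triple.j_gene, len(triple.cdr3))


@runtime_checkable
class PgenProvider(Protocol):
    """Contract for generation-probability providers."""

    def pgen(self, triple: TcrTriple) -> float: ...

    def sample(self, n: int, seed: int) -> list[TcrTriple]: ...

    # optional: exact key marginals, used preferentially when present
    # def key_marginal(self, key: TripleKey) -> float: ...
    # def enumerate_keys(self) -> list[TripleKey]: ...


@dataclass
class QTable:
    """Selection factors keyed by (V, J, CDR3 length), truncated at q_max.

    ``unseen_q`` is the value returned for keys absent at fit time; the MLE
    is 0, but a positive floor can be configured where finite log scores
    are required.
    """

    q: dict[TripleKey, float] = field(default_factory=dict)
    q_max: float = 100.0
    unseen_q: float = 0.0

    def __post_init__(self) -> None:
        if self.q_max <= 0:
            raise ValueError("q_max must be positive")
        bad = [k for k, v in self.q.items() if not 0 <= v <= self.q_max]
        if bad:
            raise ValueError(f"Q values outside [0, q_max] for keys: {bad[:3]}")

    def lookup(self, key: TripleKey) -> float:
        return self.q.get(key, self.unseen_q)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"v_gene": k.v_gene, "j_gene": k.j_gene,
             "cdr3_length": k.cdr3_length, "q": v}
            for k, v in sorted(self.q.items(),
                               key=lambda kv: (kv[0].v_gene, kv[0].j_gene,
                                               kv[0].cdr3_length))
        ]
        return pd.DataFrame(rows, columns=["v_gene", "j_gene", "cdr3_length", "q"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps({
            "q_max": self.q_max,
            "unseen_q": self.unseen_q,
            "q": [
                [k.v_gene, k.j_gene, k.cdr3_length, v]
                for k, v in sorted(self.q.items(),
                                   key=lambda kv: (kv[0].v_gene, kv[0].j_gene,
                                                   kv[0].cdr3_length))
            ],
        }, indent=2)

    @classmethod
    def from_csv(cls, path, q_max: float = 100.0, unseen_q: float = 0.0) -> "QTable":
        df = pd.read_csv(path)
        q = {
            TripleKey(r.v_gene, r.j_gene, int(r.cdr3_length)): float(r.q)
            for r in df.itertuples()
        }
        return cls(q=q, q_max=q_max, unseen_q=unseen_q)


def estimate_key_marginals(
    provider: PgenProvider, n_samples: int = 100_000, seed: int = 0
) -> dict[TripleKey, float]:
    """Per-key generation probabilities under the provider.

    Exact marginals are used when the provider exposes them; otherwise a
    Monte-Carlo estimate from ``n_samples`` provider draws.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if hasattr(provider, "key_marginal") and hasattr(provider, "enumerate_keys"):
        return {k: provider.key_marginal(k) for k in provider.enumerate_keys()}
    draws = provider.sample(n_samples, seed)
    out: dict[TripleKey, float] = {}
    inc = 1.0 / n_samples
    for t in draws:
        k = key_of(t)
        out[k] = out.get(k, 0.0) + inc
    return out


def fit_q(
    train: Sequence[TcrTriple],
    provider: PgenProvider,
    q_max: float = 100.0,
    unseen_q: float = 0.0,
    marginal_samples: int = 100_000,
    seed: int = 0,
) -> QTable:
    """Maximum-likelihood Q factors from training triples.

    Q(key) = empirical_freq(key) / model_prob(key), truncated at q_max.
    Keys whose model probability is zero but which occur in the data get
    q_max with a warning.
    """
    if len(train) == 0:
        raise ValueError("empty training data")
    marginals = estimate_key_marginals(provider, marginal_samples, seed)
    counts: dict[TripleKey, int] = {}
    for t in train:
        k = key_of(t)
        counts[k] = counts.get(k, 0) + 1
    n = len(train)
    q: dict[TripleKey, float] = {}
    zero_model = 0
    for k, c in counts.items():
        freq = c / n
        p = marginals.get(k, 0.0)
        if p <= 0.0:
            zero_model += 1
            q[k] = q_max
        else:
            q[k] = min(freq / p, q_max)
    if zero_model:
        warnings.warn(
            f"{zero_model} keys observed in data but impossible under the "
            "recombination model; their Q was set to q_max", stacklevel=2
        )
    return QTable(q=q, q_max=q_max, unseen_q=unseen_q)


def score(x: TcrTriple, provider: PgenProvider, qtable: QTable) -> float:
    """Unnormalized recombination-selection density Pgen(x)·Q(key(x))."""
    return provider.pgen(x) * qtable.lookup(key_of(x))


def normalize_scores(scores: Iterable[float]) -> np.ndarray:
    """Rescale a finite collection of scores to sum to one."""
    arr = np.asarray(list(scores), dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("scores sum to zero; cannot normalize")
    return arr / total


def rejection_sample(
    provider: PgenProvider,
    qtable: QTable,
    n: int,
    seed: int,
    min_acceptance: float = 1e-4,
    probe_budget: int = 100_000,
) -> list[TcrTriple]:
    """Draw n triples from the Pgen·Q distribution.

    Proposals come from the provider and are accepted with probability
    Q(key)/q_max.  Deterministic given seed.  If fewer than
    ``min_acceptance`` of the first ``probe_budget`` proposals are accepted,
    raises with a suggestion to refit with a smaller q_max.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    accept_rng = np.random.default_rng(ss.spawn(1)[0])
    proposal_seeds = ss.generate_state(10_000)
    accepted: list[TcrTriple] = []
    proposed = 0
    chunk = max(n, 1000)
    round_ = 0
    while len(accepted) < n:
        proposals = provider.sample(chunk, int(proposal_seeds[round_]))
        u = accept_rng.random(len(proposals))
        for t, ui in zip(proposals, u):
            if ui * qtable.q_max < qtable.lookup(key_of(t)):
                accepted.append(t)
        proposed += len(proposals)
        if proposed >= probe_budget and len(accepted) < max(
            1, int(min_acceptance * proposed)
        ):
            raise RuntimeError(
                "rejection sampling acceptance rate below floor "
                f"({len(accepted)}/{proposed}); consider a smaller q_max"
            )
        round_ += 1
    return accepted[:n]
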