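"""Repertoire summary statistics and divergence comparisons.

Fifteen summaries quantify how similar two repertoires are.  Numeric
per-sequence summaries (physicochemical indices of the CDR3, its length, and
Levenshtein distance statistics) are binned on shared edges computed from
the pooled pair and compared by Jensen-Shannon divergence; categorical
frequency summaries (V gene, J gene, amino acid and 2-mer usage) are
compared by ℓ1 divergence.  The module also provides the log-log
cohort-frequency regression and the latent-space PCA protocols.

Physicochemical scales: GRAVY is the mean Kyte-Doolittle hydropathy,
bulkiness the mean Zimmerman index, polarity the mean Grantham value,
aromaticity the F/W/Y fraction, aliphatic index the Ikai formula, acidity
and basicity the {D,E} and {K,R,H} fractions, and charge the net side-chain
charge at pH 7 from Henderson-Hasselbalch with standard pKa values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .repertoire_io import AMINO_ACIDS, TcrTriple

__all__ = [
    "SummaryDistribution", "DivergenceReport", "l1_divergence", "js_divergence",
    "sequence_summaries", "divergence_report", "cohort_frequency_fit",
    "latent_pca", "SUMMARY_STATISTICS",
]

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Zimmerman bulkiness
ZIMMERMAN_BULKINESS = {
    "A": 11.50, "C": 13.46, "D": 11.68, "E": 13.57, "F": 19.80, "G": 3.40,
    "H": 13.69, "I": 21.40, "K": 15.71, "L": 21.40, "M": 16.25, "N": 12.82,
    "P": 17.43, "Q": 14.45, "R": 14.28, "S": 9.47, "T": 15.77, "V": 21.57,
    "W": 21.67, "Y": 18.03,
}

# Grantham polarity
GRANTHAM_POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0, "H": 10.4,
    "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5,
    "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}

# side-chain pKa values for net charge at pH 7
SIDE_CHAIN_PKA = {
    "D": 3.65, "E": 4.25, "C": 8.30, "Y": 10.07,  # acidic
    "H": 6.00, "K": 10.53, "R": 12.48,            # basic
}

ACIDIC = set("DE")
BASIC = set("KRH")
AROMATIC = set("FWY")

#: The 15 statistics of the divergence report: (name, divergence kind).
SUMMARY_STATISTICS: tuple[tuple[str, str], ...] = (
    ("acidity", "js"),
    ("aliphatic_index", "js"),
    ("aromaticity", "js"),
    ("basicity", "js"),
    ("bulkiness", "js"),
    ("cdr3_length", "js"),
    ("charge", "js"),
    ("gravy", "js"),
    ("nearest_neighbor_levenshtein", "js"),
    ("pairwise_levenshtein", "js"),
    ("polarity", "js"),
    ("cdr3_2mer_frequency", "l1"),
    ("cdr3_amino_acid_frequency", "l1"),
    ("j_gene_frequency", "l1"),
    ("v_gene_frequency", "l1"),
)

N_BINS = 30  # equal-width bins over the pooled range for numeric summaries


@dataclass
class SummaryDistribution:
    """A named probability distribution over categorical labels or bins."""

    name: str
    support: tuple
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.sum() > 0:
            self.masses = self.masses / self.masses.sum()


@dataclass
class DivergenceReport:
    divergences: dict[str, float]
    kinds: dict[str, str]
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {"n_a": self.n_a, "n_b": self.n_b,
                "divergences": self.divergences, "kinds": self.kinds}


def _require_shared_support(p: SummaryDistribution, q: SummaryDistribution) -> None:
    if tuple(p.support) != tuple(q.support):
        raise ValueError(
            f"mismatched support for {p.name!r}: distributions must share bins"
        )


def l1_divergence(p: SummaryDistribution, q: SummaryDistribution) -> float:
    """Σ|p_i − q_i|, in [0, 2] (twice the total-variation distance)."""
    _require_shared_support(p, q)
    return float(np.abs(p.masses - q.masses).sum())


def js_divergence(p: SummaryDistribution, q: SummaryDistribution) -> float:
    """Jensen-Shannon divergence with natural log, in [0, log 2]."""
    _require_shared_support(p, q)
    a, b = p.masses, q.masses
    m = 0.5 * (a + b)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_am = np.where(a > 0, a * (np.log(a) - np.log(m)), 0.0)
        kl_bm = np.where(b > 0, b * (np.log(b) - np.log(m)), 0.0)
    return float(0.5 * kl_am.sum() + 0.5 * kl_bm.sum())


def _net_charge(cdr3: str, ph: float = 7.0) -> float:
    charge = 0.0
    for r in cdr3:
        if r in ("D", "E", "C", "Y"):
            charge -= 1.0 / (1.0 + 10 ** (SIDE_CHAIN_PKA[r] - ph))
        elif r in ("H", "K", "R"):
            charge += 1.0 / (1.0 + 10 ** (ph - SIDE_CHAIN_PKA[r]))
    return charge


def sequence_summaries(triple: TcrTriple) -> dict[str, float]:
    """Per-sequence numeric summaries of the CDR3."""
    s = triple.cdr3
    if not s:
        raise ValueError("empty CDR3")
    L = len(s)
    frac = lambda members: sum(r in members for r in s) / L
    fA, fV = s.count("A") / L, s.count("V") / L
    fIL = (s.count("I") + s.count("L")) / L
    return {
        "acidity": frac(ACIDIC),
        "aliphatic_index": 100.0 * (fA + 2.9 * fV + 3.9 * fIL),
        "aromaticity": frac(AROMATIC),
        "basicity": frac(BASIC),
        "bulkiness": float(np.mean([ZIMMERMAN_BULKINESS[r] for r in s])),
        "cdr3_length": float(L),
        "charge": _net_charge(s),
        "gravy": float(np.mean([KYTE_DOOLITTLE[r] for r in s])),
        "polarity": float(np.mean([GRANTHAM_POLARITY[r] for r in s])),
    }


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _nearest_neighbor_distances(seqs: list[str]) -> np.ndarray:
    """Distance from each sequence to its nearest neighbour (self-index
    excluded; duplicate strings give distance 0)."""
    n = len(seqs)
    out = np.zeros(n)
    for i in range(n):
        best = None
        for k in range(n):
            if k == i:
                continue
            d = _levenshtein(seqs[i], seqs[k])
            if best is None or d < best:
                best = d
                if best == 0:
                    break
        out[i] = best if best is not None else 0
    return out


def _pairwise_distances(seqs: list[str], rng: np.random.Generator,
                        max_pairs: int = 50_000) -> np.ndarray:
    n = len(seqs)
    total = n * (n - 1) // 2
    if total <= max_pairs:
        return np.array([
            _levenshtein(seqs[i], seqs[k])
            for i in range(n) for k in range(i + 1, n)
        ], dtype=float)
    i = rng.integers(0, n, size=max_pairs)
    k = rng.integers(0, n - 1, size=max_pairs)
    k = np.where(k >= i, k + 1, k)
    return np.array([_levenshtein(seqs[a], seqs[b]) for a, b in zip(i, k)],
                    dtype=float)


def _binned_pair(
    name: str, a: np.ndarray, b: np.ndarray, n_bins: int = N_BINS
) -> tuple[SummaryDistribution, SummaryDistribution]:
    """Histogram both samples on shared equal-width edges over the pooled
    range (order of the pair never changes the edges)."""
    pooled = np.concatenate([a, b])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    support = tuple(np.round(edges, 12))
    return (SummaryDistribution(name, support, ha),
            SummaryDistribution(name, support, hb))


def _categorical_pair(
    name: str, ca: dict[str, float], cb: dict[str, float]
) -> tuple[SummaryDistribution, SummaryDistribution]:
    support = tuple(sorted(set(ca) | set(cb)))
    return (
        SummaryDistribution(name, support, np.array([ca.get(s, 0.0) for s in support])),
        SummaryDistribution(name, support, np.array([cb.get(s, 0.0) for s in support])),
    )


def _gene_counts(triples: Sequence[TcrTriple], attr: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for t in triples:
        g = getattr(t, attr)
        out[g] = out.get(g, 0.0) + 1.0
    return out


def _aa_counts(triples: Sequence[TcrTriple]) -> dict[str, float]:
    out = {aa: 0.0 for aa in AMINO_ACIDS}
    for t in triples:
        for r in t.cdr3:
            out[r] = out.get(r, 0.0) + 1.0
    return out


def _2mer_counts(triples: Sequence[TcrTriple]) -> dict[str, float]:
    out: dict[str, float] = {}
    for t in triples:
        s = t.cdr3
        for i in range(len(s) - 1):
            out[s[i:i + 2]] = out.get(s[i:i + 2], 0.0) + 1.0
    return out


def divergence_report(
    a: Sequence[TcrTriple],
    b: Sequence[TcrTriple],
    levenshtein_subsample: int = 2000,
    seed: int = 0,
) -> DivergenceReport:
    """All 15 summary divergences between two repertoires.

    Levenshtein statistics subsample each side to at most
    ``levenshtein_subsample`` sequences for tractability; nearest-neighbour
    distances are computed exactly on the (sub)sample.
    """
    if not a or not b:
        raise ValueError("both repertoires must be non-empty")
    rng = np.random.default_rng(seed)

    per_seq_a = [sequence_summaries(t) for t in a]
    per_seq_b = [sequence_summaries(t) for t in b]

    def sub(seqs: Sequence[TcrTriple]) -> list[str]:
        strs = [t.cdr3 for t in seqs]
        if len(strs) > levenshtein_subsample:
            idx = rng.choice(len(strs), size=levenshtein_subsample, replace=False)
            strs = [strs[i] for i in idx]
        return strs

    # identical inputs share one subsample so self-comparison is exactly zero
    same = len(a) == len(b) and all(x == y for x, y in zip(a, b))
    sa = sub(a)
    sb = sa if same else sub(b)
    nn_a = _nearest_neighbor_distances(sa)
    pw_a = _pairwise_distances(sa, rng)
    lev = {
        "nearest_neighbor_levenshtein": (
            nn_a, nn_a if same else _nearest_neighbor_distances(sb)),
        "pairwise_levenshtein": (
            pw_a, pw_a if same else _pairwise_distances(sb, rng)),
    }

    divergences: dict[str, float] = {}
    kinds: dict[str, str] = {}
    for name, kind in SUMMARY_STATISTICS:
        if kind == "js":
            if name in lev:
                va, vb = lev[name]
            else:
                va = np.array([d[name] for d in per_seq_a])
                vb = np.array([d[name] for d in per_seq_b])
            p, q = _binned_pair(name, va, vb)
            divergences[name] = js_divergence(p, q)
        else:
            if name == "v_gene_frequency":
                ca, cb = _gene_counts(a, "v_gene"), _gene_counts(b, "v_gene")
            elif name == "j_gene_frequency":
                ca, cb = _gene_counts(a, "j_gene"), _gene_counts(b, "j_gene")
            elif name == "cdr3_amino_acid_frequency":
                ca, cb = _aa_counts(a), _aa_counts(b)
            else:
                ca, cb = _2mer_counts(a), _2mer_counts(b)
            p, q = _categorical_pair(name, ca, cb)
            divergences[name] = l1_divergence(p, q)
        kinds[name] = kind
    return DivergenceReport(divergences, kinds, n_a=len(a), n_b=len(b))


def cohort_frequency_fit(
    log_freq: Sequence[float], log_prob: Sequence[float]
) -> tuple[float, float, float, int]:
    """OLS of log frequency on log probability (the log-log protocol).

    Non-finite pairs (e.g. zero-probability sequences) are dropped and their
    count reported.  Returns (slope, intercept, r_squared, n_dropped).
    A constant predictor yields R² = 0 by convention.
    """
    x = np.asarray(log_prob, dtype=float)
    y = np.asarray(log_freq, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0:
        return 0.0, float(y.mean()), 0.0, n_dropped
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue**2), n_dropped)


def latent_pca(
    embeddings: np.ndarray, labels: Sequence | None = None
) -> dict:
    """Top-2 PCA of latent mean vectors.

    Returns the mean-centred 2-D projection, the orthonormal components,
    explained-variance ratios, and per-label groupings when labels are
    given (supports re-projection after filtering to one (V, J) pair).
    """
    X = np.asarray(embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 embedding vectors of equal dimension")
    pca = PCA(n_components=2)
    proj = pca.fit_transform(X)
    out = {
        "projection": proj,
        "components": pca.components_,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
    if labels is not None:
        labels = list(labels)
        if len(labels) != X.shape[0]:
            raise ValueError("labels length must match embeddings")
        groups: dict = {}
        for lab, row in zip(labels, proj):
            groups.setdefault(lab, []).append(row)
        out["groups"] = {k: np.array(v) for k, v in groups.items()}
    return out
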