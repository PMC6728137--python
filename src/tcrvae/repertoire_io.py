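"""Reading, filtering and counting TCR beta-chain repertoires.

A repertoire is modelled at the protein level as a collection of triples
(V gene, J gene, CDR3 amino-acid sequence).  This module parses Adaptive
ImmunoSEQ-dialect TSV exports, applies the standard preprocessing filters
(frame, conserved CDR3 boundary residues, length, ambiguous or blacklisted
gene calls), and aggregates cohort count vectors from which multinomial
training samples are drawn.

Template abundances are carried as metadata but never used for counting:
cohort counts are at the level of nucleotide-distinct records, each
contributing one occurrence of its protein triple.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TcrTriple",
    "GeneRegistry",
    "RepertoireTable",
    "FilterReport",
    "parse_immunoseq",
    "filter_records",
    "build_cohort_counts",
    "split_cohort",
    "sample_multinomial",
    "read_canonical_csv",
    "write_canonical_csv",
]

#: Standard 20-letter amino-acid alphabet, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

MAX_CDR3_LENGTH = 30

#: J genes excluded from modelling: TCRBJ02-05 is annotated incorrectly by the
#: upstream pipeline and TCRBJ02-07 receives artifactually low recombination
#: probabilities under default recombination parameters.
DEFAULT_J_BLACKLIST = frozenset({"TCRBJ02-05", "TCRBJ02-07"})

#: Default mapping from canonical column names to the header names accepted in
#: ImmunoSEQ-dialect exports (first match wins).
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "amino_acid": ("amino_acid", "aminoAcid", "cdr3_amino_acid"),
    "v_gene": ("v_gene", "vGeneName", "v_resolved"),
    "j_gene": ("j_gene", "jGeneName", "j_resolved"),
    "frame_type": ("frame_type", "sequenceStatus", "frame"),
    "templates": ("templates", "count (templates/reads)", "count"),
}

_IN_FRAME_VALUES = {"in", "in-frame", "inframe"}

_ALLELE_RE = re.compile(r"\*\d+$")


@dataclass(frozen=True, slots=True)
class TcrTriple:
    """A TCR beta chain at the protein level: V gene, J gene, CDR3."""

    v_gene: str
    j_gene: str
    cdr3: str


class GeneRegistry:
    """Ordered V/J gene lists with dialect aliases and a filter blacklist.

    Canonical names follow the Adaptive style (``TCRBV05-01``); IMGT-style
    names (``TRBV5-1``) are resolvable through auto-generated aliases.
    Allele suffixes (``*01``) are stripped before lookup.
    """

    def __init__(
        self,
        v_genes: Iterable[str],
        j_genes: Iterable[str],
        aliases: Mapping[str, str] | None = None,
        blacklist: Iterable[str] = DEFAULT_J_BLACKLIST,
    ) -> None:
        self.v_genes: list[str] = list(v_genes)
        self.j_genes: list[str] = list(j_genes)
        if len(set(self.v_genes)) != len(self.v_genes):
            raise ValueError("duplicate V gene names")
        if len(set(self.j_genes)) != len(self.j_genes):
            raise ValueError("duplicate J gene names")
        self.blacklist = frozenset(blacklist)
        self.aliases: dict[str, str] = dict(aliases or {})
        for name in (*self.v_genes, *self.j_genes):
            for alias in _imgt_aliases(name, self.v_genes + self.j_genes):
                self.aliases.setdefault(alias, name)
        self._v_index = {g: i for i, g in enumerate(self.v_genes)}
        self._j_index = {g: i for i, g in enumerate(self.j_genes)}

    @classmethod
    def default(cls) -> "GeneRegistry":
        """Registry backed by the packaged TRB gene table (67 V, 13 J).

        The table's germline CDR3 columns are synthetic approximations
        (see the filename); the gene name lists follow the Adaptive-style
        TRB locus naming.
        """
        path = resources.files("tcrvae.data") / "trb_germline_synthetic.csv"
        with resources.as_file(path) as p:
            table = pd.read_csv(p)
        v = table.loc[table.segment == "V", "gene"].tolist()
        j = table.loc[table.segment == "J", "gene"].tolist()
        return cls(v, j)

    def resolve(self, name: object) -> str | None:
        """Canonical gene name, or None when the call is ambiguous/unknown."""
        if not isinstance(name, str):
            return None
        name = _ALLELE_RE.sub("", name.strip())
        if name in self._v_index or name in self._j_index:
            return name
        return self.aliases.get(name)

    def v_index(self, gene: str) -> int:
        return self._v_index[gene]

    def j_index(self, gene: str) -> int:
        return self._j_index[gene]

    def content_hash(self) -> str:
        import hashlib

        payload = "|".join(self.v_genes) + "#" + "|".join(self.j_genes)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _imgt_aliases(canonical: str, all_names: list[str]) -> list[str]:
    """IMGT-style aliases for an Adaptive-style name, e.g. TCRBV05-01 -> TRBV5-1."""
    m = re.fullmatch(r"TCRB([VJ])(\d+)-(\d+)", canonical)
    if not m:
        return []
    seg, famnum, member = m.group(1), int(m.group(2)), int(m.group(3))
    out = [f"TRB{seg}{famnum}-{member}"]
    family = f"TCRB{m.group(1)}{m.group(2)}-"
    if member == 1 and sum(n.startswith(family) for n in all_names) == 1:
        out.append(f"TRB{seg}{famnum}")  # single-member family short form
    return out


@dataclass
class RepertoireTable:
    """Parsed repertoire records plus per-record metadata.

    ``records`` columns: amino_acid, v_gene, j_gene (canonical or None for
    unresolved calls), frame_type, templates, count.
    """

    records: pd.DataFrame
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def triples(self) -> list[TcrTriple]:
        return [
            TcrTriple(r.v_gene, r.j_gene, r.amino_acid)
            for r in self.records.itertuples()
        ]


@dataclass
class FilterReport:
    """Per-rule exclusion tallies; first matching rule is attributed."""

    excluded: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    @property
    def total_input(self) -> int:
        return self.retained + sum(self.excluded.values())

    def to_json(self) -> str:
        return json.dumps({"retained": self.retained, "excluded": self.excluded}, indent=2)


def parse_immunoseq(
    stream: IO[str] | str,
    registry: GeneRegistry,
    column_map: Mapping[str, tuple[str, ...]] | None = None,
    source_id: str = "",
) -> RepertoireTable:
    """Parse an ImmunoSEQ-dialect TSV into a :class:`RepertoireTable`.

    Gene names are canonicalised through the registry; calls that do not
    resolve are kept with ``None`` in the gene column and removed later by
    :func:`filter_records` as ambiguous.  Raises ``ValueError`` naming the
    first required column that cannot be found.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(stream, sep="\t", dtype=str)

    def pick(canonical: str, required: bool) -> pd.Series | None:
        for candidate in cmap[canonical]:
            if candidate in raw.columns:
                return raw[candidate]
        if required:
            raise ValueError(f"missing required column: {canonical} "
                             f"(accepted headers: {', '.join(cmap[canonical])})")
        return None

    amino = pick("amino_acid", required=True)
    vcol = pick("v_gene", required=True)
    jcol = pick("j_gene", required=True)
    frame = pick("frame_type", required=False)
    templates = pick("templates", required=False)

    records = pd.DataFrame(
        {
            "amino_acid": amino.astype("string"),
            "v_gene": [registry.resolve(g) for g in vcol],
            "j_gene": [registry.resolve(g) for g in jcol],
            "frame_type": frame.astype("string") if frame is not None
            else pd.Series(["In"] * len(raw), dtype="string"),
            "templates": pd.to_numeric(templates, errors="coerce")
            if templates is not None else np.nan,
            "count": 1,
        }
    )
    return RepertoireTable(records, source_id=source_id)


def _ending_ok(cdr3: str, mode: str) -> bool:
    if mode == "f_or_yv":
        return cdr3.endswith("F") or cdr3.endswith("YV")
    if mode == "f_y_v":
        return cdr3[-1:] in {"F", "Y", "V"}
    raise ValueError(f"unknown CDR3 ending mode: {mode}")


#: Fixed attribution order of the preprocessing rules.
FILTER_RULES = (
    "missing_fields",
    "out_of_frame",
    "cdr3_not_starting_C",
    "cdr3_bad_ending",
    "cdr3_too_long",
    "ambiguous_v",
    "ambiguous_j",
    "blacklisted_j",
)


def filter_records(
    table: RepertoireTable,
    registry: GeneRegistry,
    ending_mode: str = "f_or_yv",
) -> tuple[RepertoireTable, FilterReport]:
    """Apply the preprocessing exclusions, attributing each dropped record
    to the first rule it violates.

    Rules, in order: missing fields; out-of-frame rearrangement; CDR3 not
    beginning with the conserved C; CDR3 not ending with F or YV (toggleable
    to single-residue {F, Y, V} via ``ending_mode="f_y_v"``); CDR3 longer
    than 30 residues; ambiguous V call; ambiguous J call; blacklisted J gene.
    """
    report = FilterReport(excluded={rule: 0 for rule in FILTER_RULES})
    keep_idx: list[int] = []
    invalid = set("*_ ")
    for i, r in enumerate(table.records.itertuples()):
        cdr3 = r.amino_acid if isinstance(r.amino_acid, str) else None
        rule = None
        if not cdr3 or invalid & set(cdr3):
            rule = "missing_fields"
        elif not (isinstance(r.frame_type, str)
                  and r.frame_type.strip().lower() in _IN_FRAME_VALUES):
            rule = "out_of_frame"
        elif not cdr3.startswith("C"):
            rule = "cdr3_not_starting_C"
        elif not _ending_ok(cdr3, ending_mode):
            rule = "cdr3_bad_ending"
        elif len(cdr3) > MAX_CDR3_LENGTH:
            rule = "cdr3_too_long"
        elif r.v_gene is None:
            rule = "ambiguous_v"
        elif r.j_gene is None:
            rule = "ambiguous_j"
        elif r.j_gene in registry.blacklist or r.v_gene in registry.blacklist:
            rule = "blacklisted_j"
        if rule is None:
            keep_idx.append(i)
        else:
            report.excluded[rule] += 1
    report.retained = len(keep_idx)
    filtered = RepertoireTable(
        table.records.iloc[keep_idx].reset_index(drop=True), table.source_id
    )
    return filtered, report


def build_cohort_counts(repertoires: Iterable[RepertoireTable]) -> Counter[TcrTriple]:
    """Cohort count vector over protein triples.

    Each (nucleotide-distinct) record contributes its ``count`` column
    (1 for parsed TSV rows); template abundance is deliberately ignored.
    Invariant to repertoire order and to incremental accumulation.
    """
    counts: Counter[TcrTriple] = Counter()
    for rep in repertoires:
        for r in rep.records.itertuples():
            counts[TcrTriple(r.v_gene, r.j_gene, r.amino_acid)] += int(r.count)
    return counts


def split_cohort(
    c: Mapping[TcrTriple, int], fraction: float, seed: int
) -> tuple[Counter[TcrTriple], Counter[TcrTriple]]:
    """Partition the unique triples of a cohort vector, irrespective of
    abundance, into two disjoint and exhaustive cohort vectors."""
    if not c:
        raise ValueError("cannot split an empty cohort vector")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    keys = sorted(c, key=lambda t: (t.v_gene, t.j_gene, t.cdr3))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(keys))
    n_first = int(round(fraction * len(keys)))
    first_keys = {keys[i] for i in perm[:n_first]}
    first = Counter({k: int(c[k]) for k in c if k in first_keys})
    second = Counter({k: int(c[k]) for k in c if k not in first_keys})
    return first, second


def sample_multinomial(
    c: Mapping[TcrTriple, int], n: int, seed: int
) -> list[TcrTriple]:
    """Draw ``n`` triples with replacement from the multinomial distribution
    induced by the cohort counts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    keys = sorted(c, key=lambda t: (t.v_gene, t.j_gene, t.cdr3))
    weights = np.array([c[k] for k in keys], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("cohort vector has zero total count")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(keys), size=n, p=weights / total)
    return [keys[i] for i in idx]


def write_canonical_csv(path, counts_or_triples) -> None:
    """Write the canonical CSV (amino_acid, v_gene, j_gene, count)."""
    if isinstance(counts_or_triples, Mapping):
        items = counts_or_triples.items()
    else:
        items = Counter(counts_or_triples).items()
    rows = [
        {"amino_acid": t.cdr3, "v_gene": t.v_gene, "j_gene": t.j_gene, "count": n}
        for t, n in sorted(items, key=lambda kv: (kv[0].v_gene, kv[0].j_gene, kv[0].cdr3))
    ]
    pd.DataFrame(rows, columns=["amino_acid", "v_gene", "j_gene", "count"]).to_csv(
        path, index=False
    )


def read_canonical_csv(path) -> Counter[TcrTriple]:
    """Read the canonical CSV into a cohort count vector."""
    df = pd.read_csv(path, dtype={"amino_acid": str, "v_gene": str, "j_gene": str})
    for col in ("amino_acid", "v_gene", "j_gene", "count"):
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    out: Counter[TcrTriple] = Counter()
    for r in df.itertuples():
        out[TcrTriple(r.v_gene, r.j_gene, r.amino_acid)] += int(r.count)
    return out
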