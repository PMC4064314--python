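"""Core in-memory containers.

The package moves four kinds of objects around:

* :class:`ScoredVariant` — one variant (germline or somatic) with its gene
  assignment and the raw functional impact scores (FIS) produced upstream by
  tools such as SIFT, PolyPhen2 (PPH2) and MutationAssessor (MA);
* :class:`GeneSetCollection` — a flat collection of gene sets (GO terms,
  pathways, domain families) used to pool functionally related genes;
* :class:`BaselineTable` — the per-gene baseline-tolerance distributions
  (mean ``dm`` and standard deviation ``dstd`` of oriented germline scores,
  per tool) plus the catalog-wide global distribution used as fallback;
* :class:`TransficRecord` — the transformed scores and impact categories of
  one somatic mutation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

from .errors import ConfigurationError

__all__ = [
    "ScoredVariant",
    "GeneSetCollection",
    "ToolStats",
    "GeneBaseline",
    "BaselineTable",
    "Category",
    "ToolResult",
    "TransficRecord",
    "BoundaryConfig",
    "Label",
    "LabeledRecord",
    "LabeledDataset",
    "Confusion",
    "EvalResult",
    "ColumnSpec",
    "DEFAULT_BOUNDARIES",
]


@dataclass
class ScoredVariant:
    """A single variant with per-tool raw functional impact scores.

    Parameters
    ----------
    variant_id : str
        Opaque identifier, e.g. ``"chr3:178936082:A:C"`` or ``"PIK3CA:p.E545A"``.
    gene_id : str
        Identifier of the harboring gene.
    scores : dict of str to float
        Raw score per tool name; a tool with no score for this variant is
        simply absent from the mapping.
    sample_count : int
        Number of tumor samples in which the mutation was observed (used for
        recurrence-based labeling). Defaults to 1: one row, one observation.
    """

    variant_id: str
    gene_id: str
    scores: Dict[str, float]
    sample_count: int = 1

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.scores:
            raise ValueError(f"variant {self.variant_id!r} carries no score")
        if self.sample_count < 0:
            raise ValueError("sample_count must be non-negative")

    def has_all(self, tools: Iterable[str]) -> bool:
        """True if this variant carries a score for every named tool."""
        return all(t in self.scores for t in tools)


class GeneSetCollection:
    """A named, flat collection of gene sets with a gene->terms reverse index.

    Terms are treated as flat truth: no ontology closure is performed here.
    Ancestor propagation (e.g. for GO) must happen upstream if desired.
    """

    def __init__(self, name: str, terms: Mapping[str, Tuple[str, Iterable[str]]]):
        self.name = name
        self._terms: Dict[str, Tuple[str, frozenset]] = {}
        self._gene_index: Dict[str, set] = {}
        for term_id, (description, genes) in terms.items():
            members = frozenset(genes)
            if not members:
                raise ValueError(f"term {term_id!r} has no member genes")
            self._terms[term_id] = (description, members)
            for g in members:
                self._gene_index.setdefault(g, set()).add(term_id)

    @property
    def term_ids(self) -> Tuple[str, ...]:
        return tuple(self._terms)

    @property
    def genes(self) -> frozenset:
        return frozenset(self._gene_index)

    def members(self, term_id: str) -> frozenset:
        return self._terms[term_id][1]

    def description(self, term_id: str) -> str:
        return self._terms[term_id][0]

    def terms_of(self, gene_id: str) -> frozenset:
        """All term ids annotating ``gene_id`` (empty set if unannotated)."""
        return frozenset(self._gene_index.get(gene_id, ()))

    def items(self):
        return self._terms.items()

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.name == other.name and self._terms == other._terms

    def __repr__(self) -> str:
        return f"GeneSetCollection({self.name!r}, {len(self)} terms, {len(self.genes)} genes)"


@dataclass(frozen=True)
class ToolStats:
    """Mean and standard deviation of oriented scores in one pool, one tool."""

    dm: float
    dstd: float

    def __post_init__(self) -> None:
        if not (self.dstd > 0):
            raise ValueError(f"dstd must be positive, got {self.dstd}")


@dataclass
class GeneBaseline:
    """Baseline-tolerance entry for one gene.

    ``terms_used`` is the (ordered) prefix of the gene's specificity-ranked
    terms whose pooled variants reached the minimum pool size; it is empty
    exactly when ``fallback`` is true, in which case the entry duplicates the
    table-wide global statistics.
    """

    stats: Dict[str, ToolStats]
    n_pooled: int
    terms_used: Tuple[str, ...] = ()
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.fallback != (len(self.terms_used) == 0):
            raise ValueError("fallback must hold exactly when terms_used is empty")


@dataclass
class BaselineTable:
    """Per-gene baseline distributions plus the catalog-wide global entry."""

    collection_name: str
    per_gene: Dict[str, GeneBaseline]
    global_stats: Dict[str, ToolStats]
    global_n: int

    def entry_for(self, gene_id: str) -> Tuple[GeneBaseline, bool]:
        """Baseline for ``gene_id``; genes absent from the table fall back.

        Returns
        -------
        (entry, fallback_used)
            ``fallback_used`` is true when the returned entry is the global
            one, either because the gene is missing from the table or because
            its stored entry is itself a fallback entry.
        """
        entry = self.per_gene.get(gene_id)
        if entry is None:
            return self.global_entry(), True
        return entry, entry.fallback

    def global_entry(self) -> GeneBaseline:
        return GeneBaseline(
            stats=dict(self.global_stats), n_pooled=self.global_n, fallback=True
        )

    @property
    def tools(self) -> Tuple[str, ...]:
        return tuple(self.global_stats)


class Category(str, enum.Enum):
    """Impact category of a transformed score."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    def __str__(self) -> str:  # keep TSV cells clean
        return self.value


@dataclass
class ToolResult:
    """Per-tool outcome of transforming one mutation."""

    raw: float
    oriented: float
    transfic: float
    category: Category | None
    fallback_used: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.transfic):
            raise ValueError("transfic must be finite")


@dataclass
class TransficRecord:
    variant_id: str
    gene_id: str
    results: Dict[str, ToolResult]


@dataclass
class BoundaryConfig:
    """Per-tool (low_upper, high_lower) category boundaries.

    A transformed score ``t`` is *low* when ``t < low_upper``, *high* when
    ``t >= high_lower`` and *medium* otherwise.
    """

    per_tool: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for tool, (lo, hi) in self.per_tool.items():
            if not lo < hi:
                raise ConfigurationError(
                    f"tool {tool!r}: low_upper ({lo}) must be < high_lower ({hi})"
                )

    def get(self, tool: str) -> Tuple[float, float]:
        try:
            return self.per_tool[tool]
        except KeyError:
            raise ConfigurationError(f"no category boundaries configured for tool {tool!r}")

    @classmethod
    def default(cls) -> "BoundaryConfig":
        """The published boundaries: SIFT (-1, 2), PPH2 (-1, 1.5), MA (-1, 2)."""
        return cls({"sift": (-1.0, 2.0), "pph2": (-1.0, 1.5), "ma": (-1.0, 2.0)})


DEFAULT_BOUNDARIES = BoundaryConfig.default()


class Label(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class LabeledRecord:
    variant_id: str
    gene_id: str
    score: float
    label: Label


@dataclass
class LabeledDataset:
    """Binary-labeled scored mutations, the input of a cutoff sweep."""

    name: str
    records: Tuple[LabeledRecord, ...]

    def __post_init__(self) -> None:
        seen: Dict[Tuple[str, str], Label] = {}
        for r in self.records:
            key = (r.gene_id, r.variant_id)
            if key in seen and seen[key] != r.label:
                raise ValueError(f"record {key} labeled both positive and negative")
            seen[key] = r.label

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label is Label.POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label is Label.NEGATIVE)


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class EvalResult:
    """Best cutoff of an MCC sweep and the metrics attained there."""

    best_cutoff: float
    max_mcc: float
    acc_at_best: float
    confusion_at_best: Confusion


@dataclass
class ColumnSpec:
    """Maps logical fields onto the columns of a variant score table."""

    variant_id: str = "id"
    gene: str = "gene"
    scores: Dict[str, str] = field(
        default_factory=lambda: {"sift": "sift", "pph2": "pph2", "ma": "ma"}
    )
    sample_count: str | None = None
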