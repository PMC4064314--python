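"""Baseline-tolerance estimation from pooled germline variant scores.

The idea: germline nonsynonymous SNVs that survive in healthy populations
reflect how much functional perturbation a gene tolerates. Because current
germline catalogs are too sparse for per-gene estimates, variants are pooled
across functionally related genes. For each gene we

1. collect its annotation terms (GO terms, pathways, domains) from a flat
   gene-set collection;
2. rank them by specificity — ascending member-gene count, ties broken by
   term id;
3. walk that ranking, accumulating the union of germline variants occurring
   in any member gene and scored by every required tool, until at least
   ``min_pool`` (default 20) variants are pooled;
4. logit-transform bounded scores (SIFT, PPH2) and orient every scale so
   that larger means more damaging;
5. record the mean ``dm`` and sample standard deviation ``dstd`` of the
   pooled oriented scores, per tool.

Genes with no annotation, or whose terms never accumulate ``min_pool``
variants, fall back to the statistics of the entire catalog.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .errors import ConfigurationError, DomainError
from .models import BaselineTable, GeneBaseline, GeneSetCollection, ScoredVariant, ToolStats

__all__ = [
    "Orientation",
    "PreTransform",
    "ToolSpec",
    "BUILTIN_TOOLS",
    "default_tools",
    "tool_spec",
    "logit",
    "orient_and_transform",
    "rank_terms",
    "index_by_gene",
    "PoolResult",
    "pool_for_gene",
    "pool_stats",
    "build_baseline_table",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_POOL = 20
DEFAULT_LOGIT_EPSILON = 1e-3


class Orientation(str, enum.Enum):
    HIGHER_IS_DAMAGING = "higher_is_damaging"
    LOWER_IS_DAMAGING = "lower_is_damaging"


class PreTransform(str, enum.Enum):
    NONE = "none"
    LOGIT = "logit"


@dataclass(frozen=True)
class ToolSpec:
    """How to map one tool's raw scores onto a common damage-increasing scale.

    SIFT reports the probability that a substitution is tolerated (low =
    damaging, bounded in [0, 1]); PolyPhen2 reports the probability that it is
    damaging (high = damaging, [0, 1]); MutationAssessor scores are already
    unbounded with high = damaging. The bounded scales are logit-transformed
    to approximate normality before pooling.
    """

    name: str
    orientation: Orientation = Orientation.HIGHER_IS_DAMAGING
    pre_transform: PreTransform = PreTransform.NONE
    logit_epsilon: float = DEFAULT_LOGIT_EPSILON

    def __post_init__(self) -> None:
        if not (0 < self.logit_epsilon < 0.5):
            raise ConfigurationError(
                f"logit_epsilon must lie in (0, 0.5), got {self.logit_epsilon}"
            )


BUILTIN_TOOLS: Dict[str, ToolSpec] = {
    "sift": ToolSpec("sift", Orientation.LOWER_IS_DAMAGING, PreTransform.LOGIT),
    "pph2": ToolSpec("pph2", Orientation.HIGHER_IS_DAMAGING, PreTransform.LOGIT),
    "ma": ToolSpec("ma", Orientation.HIGHER_IS_DAMAGING, PreTransform.NONE),
}


def default_tools(logit_epsilon: float = DEFAULT_LOGIT_EPSILON) -> List[ToolSpec]:
    """The three built-in tool specs, with a configurable logit clamp."""
    return [replace(spec, logit_epsilon=logit_epsilon) for spec in BUILTIN_TOOLS.values()]


def tool_spec(name: str, logit_epsilon: float = DEFAULT_LOGIT_EPSILON) -> ToolSpec:
    """Spec for ``name``: a built-in if known, else an identity-scale extra column."""
    if name in BUILTIN_TOOLS:
        return replace(BUILTIN_TOOLS[name], logit_epsilon=logit_epsilon)
    return ToolSpec(name)


def logit(p: float, epsilon: float = DEFAULT_LOGIT_EPSILON) -> float:
    """log-odds of ``p`` after clamping into ``[epsilon, 1 - epsilon]``.

    The clamp keeps exact 0/1 scores (which SIFT emits frequently) finite
    while preserving strict monotonicity on the interior.
    """
    if not (0 < epsilon < 0.5):
        raise DomainError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"logit argument must lie in [0, 1], got {p}")
    q = min(max(p, epsilon), 1.0 - epsilon)
    return math.log(q / (1.0 - q))


def orient_and_transform(tool: ToolSpec, raw: float) -> float:
    """Map a raw score onto the oriented scale (larger = more damaging)."""
    if not math.isfinite(raw):
        raise DomainError(f"{tool.name}: score must be finite, got {raw}")
    if tool.pre_transform is PreTransform.LOGIT:
        if not (0.0 <= raw <= 1.0):
            raise DomainError(f"{tool.name}: raw score {raw} outside [0, 1]")
        p = 1.0 - raw if tool.orientation is Orientation.LOWER_IS_DAMAGING else raw
        return logit(p, tool.logit_epsilon)
    return -raw if tool.orientation is Orientation.LOWER_IS_DAMAGING else raw


def rank_terms(gene_id: str, collection: GeneSetCollection) -> List[str]:
    """Terms annotating ``gene_id``, most specific (fewest genes) first.

    Ties in member count break lexicographically by term id so the ranking is
    deterministic across runs and platforms. Unannotated genes yield ``[]``.
    """
    terms = collection.terms_of(gene_id)
    return sorted(terms, key=lambda t: (len(collection.members(t)), t))


def index_by_gene(catalog: Iterable[ScoredVariant]) -> Dict[str, List[ScoredVariant]]:
    """Group a variant catalog by gene (build once, share across pooling calls)."""
    index: Dict[str, List[ScoredVariant]] = {}
    for v in catalog:
        index.setdefault(v.gene_id, []).append(v)
    return index


@dataclass
class PoolResult:
    """Outcome of pooling for one annotated gene that reached ``min_pool``.

    ``per_tool_stats`` holds raw ``(dm, dstd)`` pairs; a degenerate spread
    (``dstd == 0``) is representable here and resolved by the table builder.
    """

    gene_id: str
    terms_used: Tuple[str, ...]
    pooled_variant_ids: frozenset
    n: int
    per_tool_stats: Dict[str, Tuple[float, float]]
    variants: Tuple[ScoredVariant, ...] = ()


def _qualifying(variants: Iterable[ScoredVariant], required: Set[str]) -> List[ScoredVariant]:
    return [v for v in variants if v.has_all(required)]


def pool_for_gene(
    gene_id: str,
    collection: GeneSetCollection,
    catalog_by_gene: Mapping[str, Sequence[ScoredVariant]],
    tools: Sequence[ToolSpec],
    required_tools: Set[str] | None = None,
    min_pool: int = DEFAULT_MIN_POOL,
) -> PoolResult | None:
    """Pool germline variants for one gene by walking its term ranking.

    Terms are included most-specific-first; the pool is the set union of
    qualifying variants (scored by every tool in ``required_tools``) of all
    member genes of the included terms, each variant counted once. The walk
    stops at the first prefix whose pool reaches ``min_pool``.

    Returns
    -------
    PoolResult or None
        ``None`` is the fallback marker: the gene is unannotated, or even the
        full term list pools fewer than ``min_pool`` qualifying variants.
    """
    if min_pool < 1:
        raise ConfigurationError(f"min_pool must be >= 1, got {min_pool}")
    if required_tools is None:
        required_tools = {t.name for t in tools}

    ranking = rank_terms(gene_id, collection)
    if not ranking:
        return None

    pooled: Dict[Tuple[str, str], ScoredVariant] = {}
    seen_genes: Set[str] = set()
    terms_used: List[str] = []
    for term in ranking:
        terms_used.append(term)
        for member in collection.members(term):
            if member in seen_genes:
                continue
            seen_genes.add(member)
            for v in _qualifying(catalog_by_gene.get(member, ()), required_tools):
                pooled.setdefault((v.gene_id, v.variant_id), v)
        if len(pooled) >= min_pool:
            variants = tuple(pooled.values())
            return PoolResult(
                gene_id=gene_id,
                terms_used=tuple(terms_used),
                pooled_variant_ids=frozenset(k[1] for k in pooled),
                n=len(variants),
                per_tool_stats=_raw_stats(variants, tools),
                variants=variants,
            )
    return None


def _raw_stats(
    pool: Sequence[ScoredVariant], tools: Sequence[ToolSpec]
) -> Dict[str, Tuple[float, float]]:
    """Unvalidated (dm, dstd) per tool; dstd may be 0 for degenerate pools."""
    out: Dict[str, Tuple[float, float]] = {}
    for tool in tools:
        values = np.array(
            [orient_and_transform(tool, v.scores[tool.name]) for v in pool if tool.name in v.scores]
        )
        if values.size == 0:
            continue
        dstd = float(np.std(values, ddof=1)) if values.size >= 2 else 0.0
        out[tool.name] = (float(np.mean(values)), dstd)
    return out


def pool_stats(
    pool: Sequence[ScoredVariant], tools: Sequence[ToolSpec]
) -> Dict[str, ToolStats]:
    """Mean and sample standard deviation of oriented scores, per tool.

    Uses the n-1 denominator. A pool whose variance vanishes for some tool
    (or with fewer than two values) cannot yield a usable ``dstd``; that case
    is resolved by the table builder, which substitutes the global spread, so
    here it raises.
    """
    if not pool:
        raise DomainError("pool_stats requires a non-empty pool")
    out: Dict[str, ToolStats] = {}
    for tool in tools:
        values = np.array(
            [orient_and_transform(tool, v.scores[tool.name]) for v in pool if tool.name in v.scores]
        )
        if values.size < 2:
            raise DomainError(
                f"tool {tool.name!r}: pool of size {values.size} is degenerate"
            )
        dm = float(np.mean(values))
        dstd = float(np.std(values, ddof=1))
        if dstd <= 0.0:
            raise DomainError(f"tool {tool.name!r}: pooled scores have zero variance")
        out[tool.name] = ToolStats(dm=dm, dstd=dstd)
    return out


def _stats_with_global_rescue(
    raw: Dict[str, Tuple[float, float]],
    tools: Sequence[ToolSpec],
    global_stats: Dict[str, ToolStats],
    gene_id: str,
) -> Dict[str, ToolStats]:
    """Validated per-tool stats, substituting the global dstd where degenerate.

    Centering on the pool mean is preserved whenever a mean exists; only an
    unusable spread is replaced, so transformed scores stay finite.
    """
    out: Dict[str, ToolStats] = {}
    for tool in tools:
        if tool.name not in raw:
            out[tool.name] = global_stats[tool.name]
            continue
        dm, dstd = raw[tool.name]
        if dstd <= 0.0:
            logger.warning(
                "gene %s tool %s: degenerate pool (zero spread); using global dstd",
                gene_id,
                tool.name,
            )
            dstd = global_stats[tool.name].dstd
        out[tool.name] = ToolStats(dm=dm, dstd=dstd)
    return out


def build_baseline_table(
    catalog: Sequence[ScoredVariant],
    collection: GeneSetCollection,
    tools: Sequence[ToolSpec] | None = None,
    required_tools: Set[str] | None = None,
    min_pool: int = DEFAULT_MIN_POOL,
) -> BaselineTable:
    """Assign every gene a per-tool baseline distribution.

    Every gene appearing in the catalog or the collection receives an entry.
    Genes whose pooling fails (unannotated, or under-filled pools) receive a
    fallback entry equal to the global entry — the statistics of all
    qualifying variants in the catalog — so downstream transformation never
    silently misses a gene.
    """
    if not catalog:
        raise ConfigurationError("cannot build a baseline table from an empty catalog")
    if len(collection) == 0:
        raise ConfigurationError("gene-set collection has no terms")
    if tools is None:
        tools = default_tools()
    if required_tools is None:
        required_tools = {t.name for t in tools}

    by_gene = index_by_gene(catalog)
    global_pool = _qualifying(catalog, required_tools)
    if len(global_pool) < 2:
        raise ConfigurationError(
            f"catalog has only {len(global_pool)} variants scored by all of "
            f"{sorted(required_tools)}; cannot estimate a global distribution"
        )
    global_stats = pool_stats(global_pool, tools)
    global_n = len(global_pool)

    per_gene: Dict[str, GeneBaseline] = {}
    n_fallback = 0
    genes = sorted(set(by_gene) | set(collection.genes))
    for gene in genes:
        result = pool_for_gene(
            gene, collection, by_gene, tools, required_tools=required_tools, min_pool=min_pool
        )
        if result is None:
            per_gene[gene] = GeneBaseline(
                stats=dict(global_stats), n_pooled=global_n, terms_used=(), fallback=True
            )
            n_fallback += 1
        else:
            stats = _stats_with_global_rescue(
                result.per_tool_stats, tools, global_stats, gene
            )
            per_gene[gene] = GeneBaseline(
                stats=stats,
                n_pooled=result.n,
                terms_used=result.terms_used,
                fallback=False,
            )
    logger.info(
        "baseline table: %d genes, %d fallback (%.1f%%), global pool n=%d",
        len(per_gene),
        n_fallback,
        100.0 * n_fallback / max(len(per_gene), 1),
        global_n,
    )
    return BaselineTable(
        collection_name=collection.name,
        per_gene=per_gene,
        global_stats=global_stats,
        global_n=global_n,
    )
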