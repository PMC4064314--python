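"""Score transformation and impact classification.

A somatic mutation's oriented functional impact score ``os`` is centered on
the baseline-tolerance distribution of its harboring gene::

    transfic = (os - dm) / dstd

where ``dm`` and ``dstd`` are the mean and standard deviation of the oriented
scores of pooled germline variants in genes functionally related to the
mutated one. A high transformed value means the mutation's impact is large
*relative to what the gene tolerates in healthy populations*, not merely
large in absolute terms.

Transformed scores are binned into low / medium / high impact categories
using per-tool boundary pairs; the shipped defaults are the published ones
(low upper boundary -1 for all three tools; high lower boundary 2 for SIFT
and MutationAssessor, 1.5 for PolyPhen2).
"""

from __future__ import annotations

from typing import Dict, List, Sequence

from .baseline import ToolSpec, default_tools, orient_and_transform
from .errors import ConfigurationError, DomainError
from .models import (
    BaselineTable,
    BoundaryConfig,
    Category,
    ScoredVariant,
    ToolResult,
    TransficRecord,
)

__all__ = ["transfic_score", "classify", "transform_dataset"]


def transfic_score(os: float, dm: float, dstd: float) -> float:
    """The transformed score ``(os - dm) / dstd``.

    ``os`` must already be oriented and (for bounded tools) logit-transformed
    — the same preprocessing applied to the germline pool that produced
    ``dm`` and ``dstd``.
    """
    if not dstd > 0:
        raise DomainError(f"dstd must be positive, got {dstd}")
    return (os - dm) / dstd


def classify(tool: str, transfic: float, boundaries: BoundaryConfig) -> Category:
    """Impact category of a transformed score.

    low when ``t < low_upper``; high when ``t >= high_lower``; medium in
    between. Both edges attach upward, so a score exactly at a boundary lands
    in the more severe category.
    """
    low_upper, high_lower = boundaries.get(tool)
    if transfic < low_upper:
        return Category.LOW
    if transfic >= high_lower:
        return Category.HIGH
    return Category.MEDIUM


def transform_dataset(
    mutations: Sequence[ScoredVariant],
    table: BaselineTable,
    tools: Sequence[ToolSpec] | None = None,
    boundaries: BoundaryConfig | None = None,
) -> List[TransficRecord]:
    """Transform every available tool score of every mutation.

    One record is produced per mutation; each record carries one
    :class:`~transfic.models.ToolResult` per tool for which the mutation has
    a raw score (a missing raw score yields no entry, never a fabricated
    number). Mutations in genes absent from the table are transformed with
    the table's global entry and flagged ``fallback_used``.

    Tools configured but absent from the table's statistics are skipped:
    classification for extra score columns requires user-supplied boundaries
    and a baseline built with the same spec.
    """
    if not table.per_gene and not table.global_stats:
        raise ConfigurationError("baseline table is empty")
    if tools is None:
        tools = default_tools()
    if boundaries is None:
        boundaries = BoundaryConfig.default()

    records: List[TransficRecord] = []
    for mut in mutations:
        entry, fallback_used = table.entry_for(mut.gene_id)
        results: Dict[str, ToolResult] = {}
        for tool in tools:
            if tool.name not in mut.scores or tool.name not in entry.stats:
                continue
            raw = mut.scores[tool.name]
            oriented = orient_and_transform(tool, raw)
            stats = entry.stats[tool.name]
            score = transfic_score(oriented, stats.dm, stats.dstd)
            category = (
                classify(tool.name, score, boundaries)
                if tool.name in boundaries.per_tool
                else None
            )
            results[tool.name] = ToolResult(
                raw=raw,
                oriented=oriented,
                transfic=score,
                category=category,
                fallback_used=fallback_used,
            )
        records.append(
            TransficRecord(variant_id=mut.variant_id, gene_id=mut.gene_id, results=results)
        )
    return records
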