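"""Prioritization of RNA-derived gene-fusion calls.

A fusion is reportable when the upstream caller scored it with the required
confidence (high, by default), at least five unique reads span the junction,
and the chimeric transcript has not lost its open reading frame — a
lost-ORF fusion cannot produce a functional protein and is excluded from
further analysis. Calls with unknown ORF status are retained by default
(configurable strict mode drops them too). Retained calls are ordered by
descending junction support, ties broken by gene-pair lexicographic order,
so the output is independent of input order.
"""

from __future__ import annotations

from dataclasses import replace

from .config import PipelineConfig
from .models import CONFIDENCE_LEVELS, FusionCall

_CONF_RANK = {name: i for i, name in enumerate(CONFIDENCE_LEVELS)}


def fusion_drop_reasons(call: FusionCall, config: PipelineConfig) -> list[str]:
    """Names of every prioritization criterion this call fails (empty = retained)."""
    reasons: list[str] = []
    if _CONF_RANK[call.confidence] < _CONF_RANK[config.fusion_required_confidence]:
        reasons.append("low_confidence")
    if call.junction_reads < config.min_fusion_junction_reads:
        reasons.append("min_junction_reads")
    if call.orf_status == "lost":
        reasons.append("orf_lost")
    elif call.orf_status == "unknown" and config.fusion_drop_unknown_orf:
        reasons.append("orf_unknown")
    return reasons


def prioritize_fusions(
    calls: list[FusionCall], config: PipelineConfig | None = None
) -> tuple[list[FusionCall], list[FusionCall]]:
    """Split calls into (retained, dropped); dropped calls carry their reasons.

    Retained calls are sorted by descending junction_reads then (gene_5p,
    gene_3p); dropped calls keep input order.
    """
    config = config or PipelineConfig()
    retained, dropped = [], []
    for call in calls:
        reasons = fusion_drop_reasons(call, config)
        if reasons:
            dropped.append(replace(call, drop_reasons=reasons))
        else:
            retained.append(replace(call, drop_reasons=[]))
    retained.sort(key=lambda c: (-c.junction_reads, c.gene_5p, c.gene_3p))
    return retained, dropped


def annotate_known_fusion(
    call: FusionCall, known_pairs: set[tuple[str, str]]
) -> FusionCall:
    """Flag a call known iff its ordered (5', 3') gene pair is in the curated list.

    Orientation matters: a curated A->B pair does not validate a B->A call.
    """
    return replace(call, known=call.pair in known_pairs)


def annotate_known_fusions(
    calls: list[FusionCall], known_pairs: set[tuple[str, str]]
) -> list[FusionCall]:
    return [annotate_known_fusion(c, known_pairs) for c in calls]
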