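"""Marker-gene screening: SSU hit filtering and consensus taxonomy.

A sample is called positive when at least one hit survives the e-value /
aligned-length / identity filter and the consensus lineage of the best
hits contains the target genus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import HitRecord

__all__ = [
    "ScreenDecision",
    "filter_ssu_hits",
    "consensus_classify",
    "screen_sample",
]

UNCLASSIFIED = "unclassified"


@dataclass
class ScreenDecision:
    sample_id: str
    positive: bool
    retained_hits: list
    consensus_lineage: tuple
    consensus_rank: int  # depth of consensus (0 = none)
    ambiguous: bool = False


def filter_ssu_hits(
    hits: Sequence[HitRecord],
    evalue_max: float = 1e-150,
    min_aligned_length: int = 1000,
    min_identity: float = 90.0,
) -> list[HitRecord]:
    """Retain hits with (evalue < 1e-150 OR aligned length > 1000 nt) AND
    identity > 90%.  Order is preserved."""
    out = []
    for h in hits:
        if h.evalue is None or h.aligned_length is None or h.pct_identity is None:
            raise ValueError(f"hit {h.query_id}->{h.target_id}: missing filter field")
        if (h.evalue < evalue_max or h.aligned_length > min_aligned_length) and (
            h.pct_identity > min_identity
        ):
            out.append(h)
    return out


def consensus_classify(
    hits: Sequence[HitRecord],
    top_n: int = 20,
    consensus_fraction: float = 0.8,
) -> tuple[tuple, int]:
    """Rank-descent consensus over the ``top_n`` best hits.

    Hits are ranked by bitscore (desc), then e-value (asc), then target id.
    At each rank (root to leaf) the walk descends while at least
    ``consensus_fraction`` of the considered hits (inclusive boundary) agree
    on one taxon.  Returns ``(lineage_prefix, depth)``; depth 0 means no
    consensus at the first rank (lineage is empty / "unclassified").

    With fewer than ``top_n`` hits the fraction applies to however many
    hits exist.
    """
    if consensus_fraction <= 0.5 or consensus_fraction > 1.0:
        raise ValueError("consensus_fraction must be in (0.5, 1.0]")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not hits:
        return (), 0

    ranked = sorted(hits, key=lambda h: (-h.bitscore, h.evalue, h.target_id))
    considered = ranked[:top_n]
    n = len(considered)

    lineage: list[str] = []
    depth = 0
    max_depth = max(len(h.lineage) for h in considered)
    for rank in range(max_depth):
        counts: dict[str, int] = {}
        for h in considered:
            if len(h.lineage) > rank:
                taxon = h.lineage[rank]
                counts[taxon] = counts.get(taxon, 0) + 1
        if not counts:
            break
        taxon, best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if best / n >= consensus_fraction:
            lineage.append(taxon)
            depth += 1
        else:
            break
    return tuple(lineage), depth


def screen_sample(
    sample_id: str,
    hits: Sequence[HitRecord],
    target_genus: str = "Wolbachia",
    top_n: int = 20,
    consensus_fraction: float = 0.8,
    secondary_lineages: dict | None = None,
) -> ScreenDecision:
    """Full screening decision for one sample.

    ``secondary_lineages`` optionally maps target_id -> lineage tuple from a
    second taxonomy; when given, the classifier is run once per taxonomy and
    the sample is flagged ambiguous (and negative) if the two disagree on
    whether the target genus is in the consensus.
    """
    retained = filter_ssu_hits(hits)
    lineage, rank = consensus_classify(retained, top_n, consensus_fraction)
    positive = bool(retained) and target_genus in lineage

    ambiguous = False
    if positive and secondary_lineages is not None:
        alt_hits = [
            HitRecord(
                query_id=h.query_id, target_id=h.target_id, evalue=h.evalue,
                aligned_length=h.aligned_length, pct_identity=h.pct_identity,
                bitscore=h.bitscore,
                lineage=secondary_lineages.get(h.target_id, ()),
            )
            for h in retained
        ]
        alt_lineage, _ = consensus_classify(alt_hits, top_n, consensus_fraction)
        if target_genus not in alt_lineage:
            ambiguous = True
            positive = False

    return ScreenDecision(
        sample_id=sample_id,
        positive=positive,
        retained_hits=retained,
        consensus_lineage=lineage if lineage else (UNCLASSIFIED,),
        consensus_rank=rank,
        ambiguous=ambiguous,
    )
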