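"""Gap-tolerant prophage region detection from tagged gene annotations.

A region is a maximal run of phage-linked genes in which consecutive
phage-linked genes are separated by at most ``max_gap_genes`` other genes;
it is reported only if it contains at least one gene from a core
structural module.  Completeness is called from the number of distinct
expected family slots observed per module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import GeneAnnotation, GenomeRecord

__all__ = [
    "ModuleInventory",
    "ProphageRegion",
    "DEFAULT_MODULE_SIZES",
    "COMPLETENESS_THRESHOLDS",
    "scan_prophage",
    "completeness_call",
    "prophage_span_fraction",
    "eam_cargo",
]

CORE_MODULES = ("head", "baseplate", "tail", "fibre")
PHAGE_TAGS = frozenset(CORE_MODULES) | {"phage_linked"}

#: Expected distinct family slots per module.
DEFAULT_MODULE_SIZES = {"head": 6, "baseplate": 8, "tail": 6, "fibre": 6}

#: Minimum observed slots per module for a putatively complete call.
COMPLETENESS_THRESHOLDS = {"head": 5, "baseplate": 7, "tail": 5, "fibre": 5}


@dataclass
class ModuleInventory:
    head: set = field(default_factory=set)
    baseplate: set = field(default_factory=set)
    tail: set = field(default_factory=set)
    fibre: set = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        return {m: len(getattr(self, m)) for m in CORE_MODULES}


@dataclass
class ProphageRegion:
    genome_id: str
    start: int
    end: int            # may exceed genome length for origin-wrapping regions
    gene_ids: list
    inventory: ModuleInventory
    complete: bool
    cargo_gene_ids: list

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def length(self, genome_length: int | None = None) -> int:
        return self.end - self.start


def _is_phage(gene: GeneAnnotation) -> bool:
    return bool(gene.tags & PHAGE_TAGS)


def _has_core_module(genes: Sequence[GeneAnnotation]) -> bool:
    return any(g.tags & frozenset(CORE_MODULES) for g in genes)


def scan_prophage(
    annotations: Sequence[GeneAnnotation],
    max_gap_genes: int = 5,
    circular: bool = True,
    genome_length: int | None = None,
    thresholds: Mapping[str, int] | None = None,
) -> list[ProphageRegion]:
    """Scan one genome's ordered annotations for prophage regions.

    ``annotations`` must all belong to one genome and be sorted by start.
    On circular genomes runs are joined across the origin before maximality
    is decided; a wrapped region is reported once, with ``end`` beyond the
    genome length.
    """
    genes = list(annotations)
    if not genes:
        return []
    genome_ids = {g.genome_id for g in genes}
    if len(genome_ids) != 1:
        raise ValueError("annotations from multiple genomes passed to scan_prophage")
    starts = [g.start for g in genes]
    if starts != sorted(starts):
        raise ValueError("annotations must be sorted by start position")
    thresholds = dict(thresholds or COMPLETENESS_THRESHOLDS)

    n = len(genes)
    phage_idx = [i for i in range(n) if _is_phage(genes[i])]
    if not phage_idx:
        return []

    # group consecutive phage genes: same run while <= max_gap_genes
    # non-phage genes separate them (circular gap between last and first
    # handled by merging the end run into the start run)
    runs: list[list[int]] = [[phage_idx[0]]]
    for prev, cur in zip(phage_idx, phage_idx[1:]):
        if cur - prev - 1 <= max_gap_genes:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    wrapped = False
    if circular and len(runs) > 1:
        gap_around = (n - 1 - phage_idx[-1]) + phage_idx[0]
        if gap_around <= max_gap_genes:
            runs[0] = runs.pop() + runs[0]
            wrapped = True

    regions: list[ProphageRegion] = []
    for ri, run in enumerate(runs):
        member_genes = [genes[i] for i in run]
        if not _has_core_module(member_genes):
            continue
        is_wrap = wrapped and ri == 0
        gl = genome_length
        if is_wrap and gl is None:
            gl = max(g.end for g in genes)
        start = genes[run[0]].start
        if is_wrap:
            end = genes[run[-1]].end + gl
            inside = [
                g for g in genes
                if g.start >= start or g.start < genes[run[-1]].end
            ]
        else:
            end = genes[run[-1]].end
            # inclusion convention: a gene belongs to the region iff its
            # start lies within the span
            inside = [g for g in genes if start <= g.start < end]
        inventory = ModuleInventory()
        for g in inside:
            for mod in CORE_MODULES:
                if mod in g.tags:
                    getattr(inventory, mod).add(g.family_id or g.gene_id)
        cargo = [g.gene_id for g in inside if not _is_phage(g)]
        region = ProphageRegion(
            genome_id=genes[0].genome_id,
            start=start,
            end=end,
            gene_ids=[g.gene_id for g in inside],
            inventory=inventory,
            complete=False,
            cargo_gene_ids=cargo,
        )
        region.complete = completeness_call(region, thresholds)
        regions.append(region)
    regions.sort(key=lambda r: r.start)
    return regions


def completeness_call(
    region: ProphageRegion, thresholds: Mapping[str, int] | None = None
) -> bool:
    """True iff every module meets its observed-slot threshold
    (defaults: head >= 5 of 6, baseplate >= 7 of 8, tail >= 5 of 6,
    fibre >= 5 of 6)."""
    thresholds = dict(thresholds or COMPLETENESS_THRESHOLDS)
    counts = region.inventory.counts()
    return all(counts[m] >= thresholds[m] for m in CORE_MODULES)


def prophage_span_fraction(
    genome: GenomeRecord | int, regions: Sequence[ProphageRegion]
) -> float:
    """Total prophage span divided by genome length (wrapped spans counted
    once); regions must not overlap."""
    length = genome if isinstance(genome, int) else len(genome)
    spans = sorted((r.start, min(r.end, r.start + length)) for r in regions)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping prophage regions: ({s1},{e1}) and ({s2},{e2})")
    # a wrapped region's tail beyond `length` covers the genome start
    if spans and spans[-1][1] > length and spans[0][0] < spans[-1][1] - length:
        raise ValueError("wrapped region overlaps the first region")
    total = sum(min(e - s, length) for s, e in spans)
    return total / length


def eam_cargo(
    region: ProphageRegion, annotations: Sequence[GeneAnnotation],
    genome_length: int | None = None,
) -> list[GeneAnnotation]:
    """Genes inside the region span lacking structural-module tags.

    A gene is inside iff its start lies within the span (wrapping regions
    compare modulo the genome length).
    """
    out = []
    for g in annotations:
        if g.genome_id != region.genome_id or _is_phage(g):
            continue
        s = g.start
        if region.start <= s < region.end:
            out.append(g)
        elif genome_length and region.end > genome_length and s < region.end - genome_length:
            out.append(g)
    return out
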