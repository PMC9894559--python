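"""Toxin-antitoxin pair calling (CifA/CifB), pair localization relative to
prophage regions, and biotin operon detection/disruption."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import GeneAnnotation, HitRecord, sort_genes
from .prophage import ProphageRegion

__all__ = [
    "CifPair",
    "BiotinOperonCall",
    "CifSummary",
    "BIOTIN_GENES",
    "DEFAULT_BIOTIN_ORDER",
    "find_cif_pairs",
    "summarize_cif",
    "find_biotin_operon",
]

BIOTIN_GENES = frozenset({"bioA", "bioB", "bioC", "bioD", "bioF", "bioH"})
DEFAULT_BIOTIN_ORDER = ("bioA", "bioD", "bioC", "bioH", "bioF", "bioB")

CIF_TYPES = ("I", "II", "III", "IV", "V")


@dataclass
class CifHit:
    """A gene-vs-reference hit for toxin calling.

    ``role`` names the reference's role ("cifA" or "cifB"); ``type_label``
    is the reference's phylogenetic type (I-V).
    """

    query_id: str
    reference_id: str
    role: str
    type_label: str
    evalue: float
    query_coverage: float
    bitscore: float


@dataclass
class CifPair:
    genome_id: str
    cifA_gene: str
    cifB_gene: str
    type_label: str
    in_eam: bool
    best_evalues: tuple
    span: tuple


@dataclass
class BiotinOperonCall:
    genome_id: str
    present: bool
    genes_found: frozenset
    order_conserved: bool
    disrupted: bool
    span: tuple | None


@dataclass
class CifSummary:
    n_pairs: int
    per_type: dict
    genomes_with_pair: int
    n_in_eam: int
    eam_fraction: float | None


def _qualifying(
    hits_by_gene: Mapping[str, list], role: str,
    evalue_max: float, cov_min: float, cov_max: float,
) -> dict[str, HitRecord]:
    """gene_id -> best qualifying hit for the given reference role."""
    best: dict[str, HitRecord] = {}
    for gene_id, hits in hits_by_gene.items():
        for h in hits:
            if getattr(h, "role", None) != role:
                continue
            if h.evalue > evalue_max:
                continue
            if h.query_coverage is None or not (cov_min <= h.query_coverage <= cov_max):
                continue
            if gene_id not in best or h.bitscore > best[gene_id].bitscore:
                best[gene_id] = h
    return best


def find_cif_pairs(
    hits: Sequence[HitRecord],
    annotations: Sequence[GeneAnnotation],
    prophage_regions: Sequence[ProphageRegion] = (),
    evalue_max: float = 1e-30,
    cov_min: float = 80.0,
    cov_max: float = 120.0,
) -> tuple[list[CifPair], list[str]]:
    """Call adjacent CifA/CifB gene pairs.

    ``hits`` are gene-vs-reference records: ``query_id`` is the gene id and
    each hit carries ``role`` ("cifA" or "cifB") and ``type_label``
    attributes describing the reference.  A gene qualifies for a role if it
    has a hit with e-value <= ``evalue_max`` and query coverage within
    [``cov_min``, ``cov_max``].  A pair is emitted for a qualifying A and B
    immediately adjacent in gene order (either order, any strands) on the
    same replicon.  Genes qualifying as both roles are excluded and
    returned as ambiguous.

    Returns ``(pairs, ambiguous_gene_ids)``.
    """
    hits_by_gene: dict[str, list] = {}
    for h in hits:
        hits_by_gene.setdefault(h.query_id, []).append(h)

    best_a = _qualifying(hits_by_gene, "cifA", evalue_max, cov_min, cov_max)
    best_b = _qualifying(hits_by_gene, "cifB", evalue_max, cov_min, cov_max)
    ambiguous = sorted(set(best_a) & set(best_b))
    for g in ambiguous:
        del best_a[g]
        del best_b[g]

    genes = sort_genes(annotations)
    pairs: list[CifPair] = []
    by_genome: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_genome.setdefault(g.genome_id, []).append(g)

    regions_by_genome: dict[str, list[ProphageRegion]] = {}
    for r in prophage_regions:
        regions_by_genome.setdefault(r.genome_id, []).append(r)

    for genome_id, ordered in by_genome.items():
        for u, v in zip(ordered, ordered[1:]):
            a_gene = b_gene = None
            if u.gene_id in best_a and v.gene_id in best_b:
                a_gene, b_gene = u, v
            elif u.gene_id in best_b and v.gene_id in best_a:
                a_gene, b_gene = v, u
            else:
                continue
            ha, hb = best_a[a_gene.gene_id], best_b[b_gene.gene_id]
            best_ref = ha if ha.bitscore >= hb.bitscore else hb
            span = (min(u.start, v.start), max(u.end, v.end))
            in_eam = any(
                _intersects(span, r, None)
                for r in regions_by_genome.get(genome_id, [])
            )
            pairs.append(
                CifPair(
                    genome_id=genome_id,
                    cifA_gene=a_gene.gene_id,
                    cifB_gene=b_gene.gene_id,
                    type_label=getattr(best_ref, "type_label", "V"),
                    in_eam=in_eam,
                    best_evalues=(ha.evalue, hb.evalue),
                    span=span,
                )
            )
    return pairs, ambiguous


def _intersects(span: tuple, region: ProphageRegion, genome_length: int | None) -> bool:
    s, e = span
    if s < region.end and region.start < e:
        return True
    if genome_length and region.end > genome_length:
        tail = region.end - genome_length
        return s < tail
    return False


def summarize_cif(
    pairs: Sequence[CifPair], prophage_regions: Sequence[ProphageRegion] = ()
) -> CifSummary:
    per_type = {t: 0 for t in CIF_TYPES}
    genomes = set()
    n_eam = 0
    for p in pairs:
        per_type[p.type_label] = per_type.get(p.type_label, 0) + 1
        genomes.add(p.genome_id)
        if p.in_eam:
            n_eam += 1
    n = len(pairs)
    return CifSummary(
        n_pairs=n,
        per_type=per_type,
        genomes_with_pair=len(genomes),
        n_in_eam=n_eam,
        eam_fraction=(n_eam / n) if n else None,
    )


def find_biotin_operon(
    annotations: Sequence[GeneAnnotation],
    max_intervening: int = 2,
    canonical_order: Sequence[str] = DEFAULT_BIOTIN_ORDER,
) -> BiotinOperonCall:
    """Detect the six-gene biotin operon in one genome's annotations.

    Consecutive bio-tagged genes separated by at most ``max_intervening``
    non-bio genes form a locus; the operon is present iff one locus carries
    all six genes.  Order is conserved iff the bio genes follow the
    canonical order or its exact reverse.  The locus is disrupted iff a
    transposase-tagged gene lies within its span.
    """
    genes = sort_genes(annotations)
    genome_ids = {g.genome_id for g in genes}
    if len(genome_ids) > 1:
        raise ValueError("find_biotin_operon expects annotations from one genome")
    genome_id = genome_ids.pop() if genome_ids else ""

    def _bio_tag(g: GeneAnnotation) -> str | None:
        tags = g.tags & BIOTIN_GENES
        return next(iter(tags)) if tags else None

    loci: list[list[GeneAnnotation]] = []
    gap = 0
    for g in genes:
        tag = _bio_tag(g)
        if tag is not None:
            if loci and gap <= max_intervening:
                loci[-1].append(g)
            else:
                loci.append([g])
            gap = 0
        elif loci:
            gap += 1

    best: list[GeneAnnotation] = max(
        loci, key=lambda l: len({_bio_tag(g) for g in l}), default=[]
    )
    found = frozenset(_bio_tag(g) for g in best) if best else frozenset()
    present = found == BIOTIN_GENES

    span = None
    order_ok = False
    disrupted = False
    if best:
        span = (best[0].start, best[-1].end)
        order = tuple(_bio_tag(g) for g in best)
        order_ok = order in (tuple(canonical_order), tuple(reversed(canonical_order)))
        disrupted = any(
            "transposase" in g.tags and span[0] <= g.start < span[1]
            for g in genes
        )
    return BiotinOperonCall(
        genome_id=genome_id,
        present=present,
        genes_found=found,
        order_conserved=order_ok,
        disrupted=disrupted,
        span=span,
    )
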