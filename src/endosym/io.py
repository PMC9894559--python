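"""Readers and writers for the external formats used across the toolkit.

All internal coordinates are 0-based half-open on the forward strand.
GFF3 (1-based closed) and BED (0-based half-open) are converted at the
boundary.  Wraparound features on circular replicons are represented as two
parts sharing a ``gene_id`` rather than intervals with ``end < start``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

__all__ = [
    "GenomeRecord",
    "GeneAnnotation",
    "HitRecord",
    "ReadAlignment",
    "ParseError",
    "KNOWN_TAGS",
    "read_fasta",
    "write_fasta",
    "read_gff_annotations",
    "write_gff_annotations",
    "read_alignments",
    "write_alignments",
    "write_regions_bed",
    "read_regions_bed",
    "read_newick",
    "write_newick",
    "read_family_matrix",
    "write_family_matrix",
]

VALID_BASES = set("ACGTN")

#: Tag vocabulary recognised in GFF attribute lists.  Anything else is
#: folded into "other" on read.
KNOWN_TAGS = frozenset(
    ["head", "baseplate", "tail", "fibre", "phage_linked", "cifA", "cifB",
     "bioA", "bioB", "bioC", "bioD", "bioF", "bioH", "transposase", "other"]
)


class ParseError(ValueError):
    """Raised for malformed input files; message carries file location."""


@dataclass
class GenomeRecord:
    """A (possibly circular) nucleotide sequence with host metadata."""

    genome_id: str
    sequence: str
    circular: bool = False
    supergroup: str | None = None
    host_taxon: str | None = None
    host_order: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"genome {self.genome_id!r}: illegal character(s) "
                f"{sorted(bad)} (alphabet is A,C,G,T,N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A located gene with strand, family label, and functional tags."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    family_id: str | None = None
    tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        self.tags = frozenset(self.tags)

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int, genome_length: int) -> "GeneAnnotation":
        """Shift by ``offset`` modulo ``genome_length`` (no wrap splitting)."""
        s = (self.start + offset) % genome_length
        return replace(self, start=s, end=s + self.length)


@dataclass
class HitRecord:
    """A similarity-search hit with taxonomy lineage."""

    query_id: str
    target_id: str
    evalue: float
    aligned_length: int
    pct_identity: float
    bitscore: float
    lineage: tuple = ()
    query_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.target_id}: evalue < 0")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(
                f"hit {self.query_id}->{self.target_id}: pct_identity "
                f"{self.pct_identity} outside [0, 100]"
            )
        self.lineage = tuple(self.lineage)


@dataclass
class ReadAlignment:
    """A read-to-contig alignment interval with a read classification."""

    read_id: str
    contig_id: str
    contig_start: int
    contig_end: int
    mapq: int = 60
    read_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.contig_start < self.contig_end:
            raise ValueError(
                f"alignment {self.read_id}: contig_start must be < contig_end"
            )
        if self.read_class not in ("endosymbiont", "host", "unknown"):
            raise ValueError(f"alignment {self.read_id}: bad class {self.read_class!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeRecord]:
    """Read FASTA into GenomeRecords.

    Sequences are uppercased.  A ``circular=true`` token in the description
    sets the circular flag; ``supergroup=X``, ``host_taxon=...`` and
    ``host_order=...`` tokens populate the metadata fields.
    """
    records: list[GenomeRecord] = []
    name = None
    meta: dict = {}
    chunks: list[str] = []
    header_line = 0

    def _flush():
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"{path}: line {header_line}: record {name!r} has no sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"{path}: record {name!r} (line {header_line}): illegal "
                f"character(s) {sorted(bad)}"
            )
        records.append(GenomeRecord(genome_id=name, sequence=seq, **meta))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                fields = line[1:].split()
                if not fields:
                    raise ParseError(f"{path}: line {lineno}: empty FASTA header")
                name, meta, chunks, header_line = fields[0], {}, [], lineno
                for tok in fields[1:]:
                    if "=" not in tok:
                        continue
                    key, _, val = tok.partition("=")
                    if key == "circular":
                        meta["circular"] = val.lower() in ("true", "1", "yes")
                    elif key in ("supergroup", "host_taxon", "host_order"):
                        meta[key] = val
            else:
                if name is None:
                    raise ParseError(f"{path}: line {lineno}: sequence before header")
                chunks.append(line)
    _flush()
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            toks = [rec.genome_id, f"circular={'true' if rec.circular else 'false'}"]
            if rec.supergroup:
                toks.append(f"supergroup={rec.supergroup}")
            if rec.host_taxon:
                toks.append(f"host_taxon={rec.host_taxon}")
            if rec.host_order:
                toks.append(f"host_order={rec.host_order}")
            fh.write(">" + " ".join(toks) + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff_annotations(path) -> list[GeneAnnotation]:
    """Read a GFF3-dialect annotation file.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Attributes ``ID``, ``family`` and ``tags`` (comma-separated) are parsed;
    unknown tags are folded into ``other``.
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, _source, _type, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates")
            if end1 < start1:
                raise ParseError(f"{path}: line {lineno}: end < start")
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: strand {strand!r} (must be + or -)"
                )
            attr = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, _, v = item.partition("=")
                    attr[k.strip()] = v.strip()
            tags = set()
            for t in attr.get("tags", "").split(","):
                t = t.strip()
                if not t:
                    continue
                tags.add(t if t in KNOWN_TAGS else "other")
            if "module" in attr:
                m = attr["module"]
                tags.add(m if m in KNOWN_TAGS else "other")
            genes.append(
                GeneAnnotation(
                    genome_id=seqid,
                    gene_id=attr.get("ID", f"gene_{lineno}"),
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    family_id=attr.get("family") or None,
                    tags=frozenset(tags),
                )
            )
    return genes


def write_gff_annotations(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.family_id:
                attrs.append(f"family={g.family_id}")
            if g.tags:
                attrs.append("tags=" + ",".join(sorted(g.tags)))
            fh.write(
                "\t".join(
                    [g.genome_id, "endosym", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", ";".join(attrs)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PAF-like alignment TSV

_ALN_COLS = ["read_id", "contig_id", "contig_start", "contig_end", "mapq", "read_class"]


def read_alignments(path) -> list[ReadAlignment]:
    out: list[ReadAlignment] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for rowno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != len(_ALN_COLS):
                raise ParseError(
                    f"{path}: row {rowno}: expected {len(_ALN_COLS)} columns, "
                    f"got {len(row)}"
                )
            out.append(
                ReadAlignment(
                    read_id=row[0],
                    contig_id=row[1],
                    contig_start=int(row[2]),
                    contig_end=int(row[3]),
                    mapq=int(row[4]),
                    read_class=row[5],
                )
            )
    return out


def write_alignments(alignments: Iterable[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                "\t".join(
                    [a.read_id, a.contig_id, str(a.contig_start),
                     str(a.contig_end), str(a.mapq), a.read_class]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED

def write_regions_bed(regions: Iterable[tuple], path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for region in regions:
            chrom, start, end = region[0], region[1], region[2]
            name = region[3] if len(region) > 3 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_regions_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for rowno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: row {rowno}: fewer than 3 BED columns")
            name = cols[3] if len(cols) > 3 else "."
            out.append((cols[0], int(cols[1]), int(cols[2]), name))
    return out


# ---------------------------------------------------------------------------
# Newick

def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Family matrix TSV (rows = families, columns = genomes)

def read_family_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_family_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="family_id")


# ---------------------------------------------------------------------------
# Small sequence helpers shared by several modules

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sort_genes(genes: Sequence[GeneAnnotation]) -> list[GeneAnnotation]:
    return sorted(genes, key=lambda g: (g.genome_id, g.start, g.end, g.gene_id))
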