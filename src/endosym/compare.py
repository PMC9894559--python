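"""Pairwise genome comparison without external aligners.

Collinear blocks are chained from unique shared k-mer anchors; breakpoints
are counted between consecutive blocks whose partner coordinates are not
contiguous in the same orientation; ANI follows a fragment-mapping scheme
(non-overlapping fragments of the query placed on the target by k-mer
diagonal vote, scored by ungapped identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GenomeRecord, revcomp

__all__ = [
    "AlignmentBlock",
    "BreakpointStats",
    "AniResult",
    "collinear_blocks",
    "breakpoint_stats",
    "fragment_ani",
]


@dataclass
class AlignmentBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str  # orientation of B relative to A
    n_anchors: int

    @property
    def a_length(self) -> int:
        return self.a_end - self.a_start


@dataclass
class BreakpointStats:
    n_blocks: int
    n_breakpoints: int
    alignable_length: int
    breakpoint_rate: float


@dataclass
class AniResult:
    ani: float
    aligned_fraction: float
    n_fragments_mapped: int
    n_fragments_total: int


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    """k-mer -> position for k-mers occurring exactly once."""
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        else:
            seen[kmer] = i
    return seen


def collinear_blocks(
    genome_a: GenomeRecord | str,
    genome_b: GenomeRecord | str,
    k: int = 21,
    min_block: int = 500,
    max_gap: int = 2000,
) -> list[AlignmentBlock]:
    """Chain unique shared k-mers into maximal collinear runs.

    Anchors are k-mers unique in both genomes (forward in A; forward or
    reverse complement in B).  Consecutive anchors along A extend a run when
    they share orientation, advance consistently on B, and the gap on both
    genomes is at most ``max_gap``.  Runs spanning < ``min_block`` on A are
    discarded.
    """
    seq_a = genome_a.sequence if isinstance(genome_a, GenomeRecord) else genome_a
    seq_b = genome_b.sequence if isinstance(genome_b, GenomeRecord) else genome_b
    if k > len(seq_a) or k > len(seq_b):
        raise ValueError("k exceeds a genome length")

    ka = _unique_kmer_positions(seq_a, k)
    kb = _unique_kmer_positions(seq_b, k)

    anchors = []  # (a_pos, b_pos, strand)
    for kmer, pa in ka.items():
        pb = kb.get(kmer)
        if pb is not None:
            rc_hit = kb.get(revcomp(kmer))
            if rc_hit is None or revcomp(kmer) == kmer:
                anchors.append((pa, pb, "+"))
        else:
            pb = kb.get(revcomp(kmer))
            if pb is not None:
                anchors.append((pa, pb, "-"))
    anchors.sort()

    blocks: list[AlignmentBlock] = []
    run: list[tuple[int, int, str]] = []

    def _flush():
        if not run:
            return
        a0, a1 = run[0][0], run[-1][0] + k
        if a1 - a0 >= min_block:
            strand = run[0][2]
            if strand == "+":
                b0, b1 = run[0][1], run[-1][1] + k
            else:
                b0, b1 = run[-1][1], run[0][1] + k
            blocks.append(
                AlignmentBlock(a_start=a0, a_end=a1, b_start=b0, b_end=b1,
                               strand=strand, n_anchors=len(run))
            )

    for anchor in anchors:
        if run:
            pa, pb, st = anchor
            qa, qb, qt = run[-1]
            gap_a = pa - qa
            if st == qt and 0 < gap_a <= max_gap:
                if st == "+" and 0 < pb - qb <= max_gap:
                    run.append(anchor)
                    continue
                if st == "-" and 0 < qb - pb <= max_gap:
                    run.append(anchor)
                    continue
            _flush()
            run = []
        run.append(anchor)
    _flush()
    return blocks


def _trim_overlaps(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Trim A-overlaps between consecutive blocks at the overlap midpoint."""
    out: list[AlignmentBlock] = []
    for b in sorted(blocks, key=lambda b: (b.a_start, b.a_end)):
        if out and b.a_start < out[-1].a_end:
            prev = out[-1]
            mid = (b.a_start + prev.a_end) // 2
            prev.a_end = mid
            b = AlignmentBlock(mid, b.a_end, b.b_start, b.b_end, b.strand,
                               b.n_anchors)
            if prev.a_end <= prev.a_start:
                out.pop()
        if b.a_end > b.a_start:
            out.append(b)
    return out


def breakpoint_stats(
    blocks: Sequence[AlignmentBlock],
    genome_lengths: tuple[int, int] | None = None,
    tolerance: int = 1000,
    circular: bool = True,
) -> BreakpointStats:
    """Count breakpoints between consecutive blocks along genome A.

    A junction is a breakpoint unless both blocks share orientation and
    their B coordinates continue within ``tolerance`` nt (modulo the B
    length for circular genomes).  The circular junction between the last
    and first blocks is included.  The rate is per alignable base
    (sum of block lengths on A).
    """
    blocks = _trim_overlaps(list(blocks))
    if not blocks:
        raise ValueError("no alignment blocks; breakpoint rate undefined")
    alignable = sum(b.a_length for b in blocks)
    len_a = genome_lengths[0] if genome_lengths else None
    len_b = genome_lengths[1] if genome_lengths else None

    def _cmod(d: int, L: int | None) -> int:
        """Centered modular representative (smallest absolute value)."""
        if not circular or L is None:
            return d
        return (d + L // 2) % L - L // 2

    def _contiguous(u: AlignmentBlock, v: AlignmentBlock, wrap: bool) -> bool:
        if u.strand != v.strand:
            return False
        da = v.a_start - u.a_end
        if wrap:
            da = _cmod(da, len_a)
        if u.strand == "+":
            db = v.b_start - u.b_end
        else:
            db = u.b_start - v.b_end
        db = _cmod(db, len_b)
        # the gap on B must match the gap on A (both genomes skip the same
        # unanchored span, e.g. a shared repeat)
        return abs(db - da) <= tolerance

    n = len(blocks)
    count = 0
    if n > 1:
        junctions = range(n) if circular else range(n - 1)
        for i in junctions:
            wrap = i == n - 1
            if not _contiguous(blocks[i], blocks[(i + 1) % n], wrap):
                count += 1
    return BreakpointStats(
        n_blocks=n,
        n_breakpoints=count,
        alignable_length=alignable,
        breakpoint_rate=count / alignable,
    )


def _identity(frag: str, window: str) -> float:
    a = np.frombuffer(frag.encode(), dtype=np.uint8)
    b = np.frombuffer(window[: len(frag)].encode(), dtype=np.uint8)
    if b.size < a.size:
        b = np.concatenate([b, np.zeros(a.size - b.size, np.uint8)])
    return float((a == b).mean()) * 100.0


def fragment_ani(
    genome_a: GenomeRecord | str,
    genome_b: GenomeRecord | str,
    fragment: int = 1000,
    k: int = 16,
    min_identity_to_count: float = 70.0,
) -> AniResult:
    """Fragment-mapping average nucleotide identity of A against B.

    A is cut into non-overlapping fragments; each fragment votes with its
    k-mers for a diagonal (offset) in B, forward and reverse complement;
    the best diagonal is scored by ungapped identity.  Fragments at or
    above ``min_identity_to_count`` are counted as mapped and averaged.
    """
    seq_a = genome_a.sequence if isinstance(genome_a, GenomeRecord) else genome_a
    seq_b = genome_b.sequence if isinstance(genome_b, GenomeRecord) else genome_b
    if len(seq_a) < fragment:
        raise ValueError("genome A shorter than one fragment")

    index: dict[str, list[int]] = {}
    for i in range(len(seq_b) - k + 1):
        index.setdefault(seq_b[i : i + k], []).append(i)

    ext_b = seq_b + seq_b[:fragment]
    ext_b_rc = revcomp(seq_b) + revcomp(seq_b)[:fragment]
    len_b = len(seq_b)

    n_total = len(seq_a) // fragment
    identities = []
    for fi in range(n_total):
        frag = seq_a[fi * fragment : (fi + 1) * fragment]
        votes: dict[tuple[str, int], int] = {}
        for off in range(0, fragment - k + 1, 7):
            kmer = frag[off : off + k]
            for pos in index.get(kmer, ()):
                d = (pos - off) % len_b
                votes[("+", d)] = votes.get(("+", d), 0) + 1
            for pos in index.get(revcomp(kmer), ()):
                # fragment position maps into revcomp(B) coordinates
                d = (len_b - (pos + k) - off) % len_b
                votes[("-", d)] = votes.get(("-", d), 0) + 1
        if not votes:
            continue
        (strand, d), _n = max(votes.items(), key=lambda kv: (kv[1], kv[0][1]))
        target = ext_b if strand == "+" else ext_b_rc
        ident = _identity(frag, target[d : d + fragment])
        if ident >= min_identity_to_count:
            identities.append(ident)

    if not identities:
        raise ValueError("no fragments mapped; ANI undefined")
    return AniResult(
        ani=float(np.mean(identities)),
        aligned_fraction=len(identities) / n_total,
        n_fragments_mapped=len(identities),
        n_fragments_total=n_total,
    )
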