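"""Cobiont separation: coverage of contigs by classified reads, the
nuclear-insertion (NUWT) filter, assembly ranking, and relative abundance."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import ReadAlignment

__all__ = [
    "ContigCoverage",
    "AssemblyCandidate",
    "RelativeAbundance",
    "contig_coverage",
    "classify_contigs",
    "estimate_relative_abundance",
    "rank_assemblies",
]

ENDOSYMBIONT_REPLICON = "endosymbiont_replicon"
HOST_WITH_POSSIBLE_NUWT = "host_with_possible_nuwt"


@dataclass
class ContigCoverage:
    contig_id: str
    length: int
    covered_fraction: float
    mean_depth: float
    window_depths: list = field(default_factory=list)
    window_length: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.covered_fraction <= 1.0:
            raise ValueError("covered_fraction outside [0, 1]")
        if self.mean_depth < 0:
            raise ValueError("mean_depth < 0")


@dataclass
class AssemblyCandidate:
    assembler_label: str
    completeness_pct: float
    duplication_pct: float
    n_contigs: int
    circular: bool
    depth_cv: float

    def __post_init__(self) -> None:
        if not 0 <= self.completeness_pct <= 100:
            raise ValueError("completeness outside [0, 100]")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")


@dataclass
class RelativeAbundance:
    endo_per_host: float
    endo_depth: float
    host_depth: float


def _union_and_sum(intervals: list[tuple[int, int]]) -> tuple[int, int]:
    """Sweep-line union length and summed interval length."""
    total = sum(e - s for s, e in intervals)
    union = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            union += e - s
            end = e
        elif e > end:
            union += e - end
            end = e
    return union, total


def contig_coverage(
    alignments: Sequence[ReadAlignment],
    contig_lengths: Mapping[str, int],
    window: int = 10_000,
    read_class: str | None = "endosymbiont",
) -> list[ContigCoverage]:
    """Per-contig covered fraction and mean depth from alignment intervals.

    ``covered_fraction`` is |union of intervals| / length; ``mean_depth`` is
    the summed interval length / length.  Windowed depths (for evenness and
    abundance estimation) use fixed windows of ``window`` nt, last window
    truncated.  Only alignments of ``read_class`` are used (None = all).
    """
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    for a in alignments:
        if read_class is not None and a.read_class != read_class:
            continue
        if a.contig_id not in contig_lengths:
            raise ValueError(f"alignment {a.read_id}: unknown contig {a.contig_id}")
        ln = contig_lengths[a.contig_id]
        if a.contig_start < 0 or a.contig_end > ln:
            raise ValueError(
                f"alignment {a.read_id}: interval [{a.contig_start}, "
                f"{a.contig_end}) outside contig {a.contig_id} (length {ln})"
            )
        by_contig[a.contig_id].append((a.contig_start, a.contig_end))

    out = []
    for contig_id in contig_lengths:
        ln = contig_lengths[contig_id]
        intervals = by_contig[contig_id]
        union, total = _union_and_sum(intervals)
        n_win = max(1, -(-ln // window))
        depth = np.zeros(n_win, dtype=float)
        for s, e in intervals:
            # distribute interval length over the windows it spans
            w0, w1 = s // window, (e - 1) // window
            for w in range(w0, w1 + 1):
                ws, we = w * window, min((w + 1) * window, ln)
                depth[w] += max(0, min(e, we) - max(s, ws))
        win_lens = np.array(
            [min((w + 1) * window, ln) - w * window for w in range(n_win)], float
        )
        out.append(
            ContigCoverage(
                contig_id=contig_id,
                length=ln,
                covered_fraction=union / ln,
                mean_depth=total / ln,
                window_depths=(depth / win_lens).tolist(),
                window_length=window,
            )
        )
    return out


def classify_contigs(
    coverages: Sequence[ContigCoverage], full_threshold: float = 1.0
) -> dict[str, str]:
    """Contigs fully covered by endosymbiont-classified reads are called
    endosymbiont replicons; anything less is a host contig possibly carrying
    a nuclear insertion."""
    return {
        c.contig_id: (
            ENDOSYMBIONT_REPLICON
            if c.covered_fraction >= full_threshold
            else HOST_WITH_POSSIBLE_NUWT
        )
        for c in coverages
    }


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    return float(values[np.searchsorted(cum, 0.5 * cum[-1])])


def estimate_relative_abundance(
    endo_coverages: Sequence[ContigCoverage],
    host_coverages: Sequence[ContigCoverage],
) -> RelativeAbundance:
    """Ratio of length-weighted median window depths (endosymbiont / host)."""
    if not endo_coverages or not host_coverages:
        raise ValueError("both coverage sets must be non-empty")

    def _depth(covs: Sequence[ContigCoverage]) -> float:
        vals, wts = [], []
        for c in covs:
            if c.window_depths:
                n_win = len(c.window_depths)
                for w, d in enumerate(c.window_depths):
                    ws = w * c.window_length
                    we = min((w + 1) * c.window_length, c.length)
                    vals.append(d)
                    wts.append(we - ws)
            else:
                vals.append(c.mean_depth)
                wts.append(c.length)
        return _weighted_median(np.asarray(vals, float), np.asarray(wts, float))

    endo_depth = _depth(endo_coverages)
    host_depth = _depth(host_coverages)
    if host_depth == 0:
        raise ValueError("host depth is zero; abundance ratio undefined")
    return RelativeAbundance(
        endo_per_host=endo_depth / host_depth,
        endo_depth=endo_depth,
        host_depth=host_depth,
    )


def rank_assemblies(candidates: Sequence[AssemblyCandidate]) -> list[AssemblyCandidate]:
    """Best-first ordering: completeness desc, duplication asc, circular
    first, fewer contigs, lower depth CV, then label."""
    if not candidates:
        raise ValueError("no assembly candidates to rank")
    return sorted(
        candidates,
        key=lambda c: (
            -c.completeness_pct,
            c.duplication_pct,
            not c.circular,
            c.n_contigs,
            c.depth_cv,
            c.assembler_label,
        ),
    )
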