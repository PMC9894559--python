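"""Gene-family matrix statistics: single-copy selection, strain-specific
genes, family-size histograms, and core/pan rarefaction by addition-order
permutation.

Family clustering here is single-linkage over a similarity graph; the
statistics operate on the family x genome count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RarefactionCurve",
    "cluster_families",
    "single_copy_families",
    "strain_specific_counts",
    "rarefaction",
    "rarefaction_closed_form",
    "family_size_histogram",
    "novel_flags",
]


@dataclass
class RarefactionCurve:
    k: list
    mean_core: list
    mean_pan: list
    n_permutations: int
    seed: int


def cluster_families(
    genes: Sequence[str],
    similarity_edges: Sequence[tuple],
    identity_threshold: float = 50.0,
) -> dict[str, str]:
    """Single-linkage clustering: connected components of the similarity
    graph restricted to edges at or above the threshold.

    ``similarity_edges`` are (gene_a, gene_b, score) tuples (symmetric).
    Family ids are the lexically smallest member gene id.
    """
    parent = {g: g for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, score in similarity_edges:
        if score < identity_threshold:
            continue
        if a not in parent or b not in parent:
            raise ValueError(f"edge references unknown gene: {a!r} or {b!r}")
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the lexically smaller root so ids are deterministic
            lo, hi = sorted((ra, rb))
            parent[hi] = lo
    return {g: find(g) for g in genes}


def novel_flags(matrix: pd.DataFrame) -> pd.Series:
    """True for families present in exactly one genome."""
    return (matrix > 0).sum(axis=1) == 1


def single_copy_families(matrix: pd.DataFrame, min_fraction: float = 0.95) -> list[str]:
    """Families single-copy in more than ``min_fraction`` of genomes (strict)."""
    n = matrix.shape[1]
    frac = (matrix == 1).sum(axis=1) / n
    return list(matrix.index[frac > min_fraction])


def strain_specific_counts(matrix: pd.DataFrame) -> dict[str, int]:
    """Per genome: number of genes in families found in that genome only."""
    novel = novel_flags(matrix)
    sub = matrix.loc[novel]
    return {g: int(sub[g].sum()) for g in matrix.columns}


def family_size_histogram(
    matrix: pd.DataFrame, by_presence: bool = False
) -> dict[int, int]:
    """Histogram of family sizes (total gene copies, or genome presence)."""
    if matrix.empty:
        return {}
    if by_presence:
        sizes = (matrix > 0).sum(axis=1)
    else:
        sizes = matrix.sum(axis=1)
    sizes = sizes[sizes > 0]
    out: dict[int, int] = {}
    for s in sizes:
        out[int(s)] = out.get(int(s), 0) + 1
    return dict(sorted(out.items()))


def _presence(matrix: pd.DataFrame, exclude_novel: bool) -> np.ndarray:
    pres = (matrix.to_numpy() >= 1)
    if exclude_novel:
        pres = pres[pres.sum(axis=1) > 1]
    return pres


def rarefaction(
    matrix: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    exclude_novel: bool = True,
) -> RarefactionCurve:
    """Mean core/pan family counts over random genome addition orders."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pres = _presence(matrix, exclude_novel)
    n_fam, n_gen = pres.shape
    rng = np.random.default_rng(seed)
    core_acc = np.zeros(n_gen)
    pan_acc = np.zeros(n_gen)
    for _ in range(n_permutations):
        order = rng.permutation(n_gen)
        cols = pres[:, order]
        core = np.logical_and.accumulate(cols, axis=1)
        pan = np.logical_or.accumulate(cols, axis=1)
        core_acc += core.sum(axis=0)
        pan_acc += pan.sum(axis=0)
    return RarefactionCurve(
        k=list(range(1, n_gen + 1)),
        mean_core=(core_acc / n_permutations).tolist(),
        mean_pan=(pan_acc / n_permutations).tolist(),
        n_permutations=n_permutations,
        seed=seed,
    )


def rarefaction_closed_form(
    matrix: pd.DataFrame, exclude_novel: bool = True
) -> tuple[list, list]:
    """Exact expectations under uniform addition order (hypergeometric):

    E[pan_k]  = sum_f 1 - C(N - n_f, k) / C(N, k)
    E[core_k] = sum_f C(n_f, k) / C(N, k)

    where n_f is the number of genomes containing family f.
    """
    from scipy.special import comb

    pres = _presence(matrix, exclude_novel)
    n_gen = pres.shape[1]
    n_f = pres.sum(axis=1)
    core, pan = [], []
    for k in range(1, n_gen + 1):
        denom = comb(n_gen, k, exact=False)
        pan.append(float(np.sum(1.0 - comb(n_gen - n_f, k) / denom)))
        core.append(float(np.sum(comb(n_f, k) / denom)))
    return core, pan
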