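"""Distance phylogeny from concatenated single-copy alignments and
phylogenetically corrected (Brownian-covariance) regression.

The tree builder is classic neighbor joining with deterministic
tie-breaking; the regression solves generalized least squares with the
covariance C_ij equal to the shared root-to-tip path length of the two
taxa under Brownian motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Supermatrix",
    "PglsFit",
    "build_supermatrix",
    "distance_matrix",
    "neighbor_joining",
    "brownian_covariance",
    "pgls_fit",
]


@dataclass
class Supermatrix:
    taxa: list
    rows: dict                       # taxon -> concatenated string
    family_boundaries: list          # (family_id, start, end)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def slice_family(self, family_id: str) -> dict:
        for fid, s, e in self.family_boundaries:
            if fid == family_id:
                return {t: r[s:e] for t, r in self.rows.items()}
        raise KeyError(family_id)


@dataclass
class PglsFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    sigma2: float
    slope_se: float


def build_supermatrix(
    per_family_alignments: Mapping[str, Mapping[str, str]],
    taxa: Sequence[str],
) -> Supermatrix:
    """Concatenate per-family alignments (family_id -> taxon -> row) in
    lexical family order; every family must cover every taxon with rows of
    equal length."""
    taxa = list(taxa)
    rows = {t: [] for t in taxa}
    boundaries = []
    pos = 0
    for fid in sorted(per_family_alignments):
        aln = per_family_alignments[fid]
        missing = [t for t in taxa if t not in aln]
        if missing:
            raise ValueError(
                f"family {fid!r} missing taxon {missing[0]!r}; cannot concatenate"
            )
        widths = {len(aln[t]) for t in taxa}
        if len(widths) != 1:
            raise ValueError(f"family {fid!r}: ragged alignment rows")
        w = widths.pop()
        for t in taxa:
            rows[t].append(aln[t])
        boundaries.append((fid, pos, pos + w))
        pos += w
    return Supermatrix(
        taxa=taxa,
        rows={t: "".join(parts) for t, parts in rows.items()},
        family_boundaries=boundaries,
    )


def distance_matrix(supermatrix: Supermatrix, model: str = "p") -> np.ndarray:
    """Pairwise p- or JC69 distances; gaps ('-') and N excluded pairwise."""
    if model not in ("p", "jc69"):
        raise ValueError("model must be 'p' or 'jc69'")
    taxa = supermatrix.taxa
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    mats = {
        t: np.frombuffer(supermatrix.rows[t].encode(), dtype=np.uint8)
        for t in taxa
    }
    bad = {ord("-"), ord("N"), ord("n")}
    usable = {t: ~np.isin(mats[t], list(bad)) for t in taxa}
    n = len(taxa)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = usable[taxa[i]] & usable[taxa[j]]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}"
                )
            p = float((mats[taxa[i]][both] != mats[taxa[j]][both]).sum()) / m
            if model == "jc69":
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} >= 0.75 between {taxa[i]} and "
                        f"{taxa[j]}; JC69 undefined"
                    )
                p = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = p
    return dist


def neighbor_joining(matrix: np.ndarray, taxa: Sequence[str]) -> dendropy.Tree:
    """Neighbor joining with deterministic tie-breaking (lexical taxon
    pair).  Negative branch lengths are clamped to zero with the deficit
    moved to the sibling edge."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(taxa) != n:
        raise ValueError("matrix/taxa shape mismatch")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(matrix, matrix.T) or np.any(matrix < 0):
        raise ValueError("matrix must be symmetric and non-negative")

    if n == 2:
        nwk = f"({taxa[0]}:{matrix[0, 1] / 2:.10f},{taxa[1]}:{matrix[0, 1] / 2:.10f});"
        return dendropy.Tree.get(data=nwk, schema="newick")

    # node labels: leaves are taxon names; internals are newick substrings
    labels = list(taxa)
    d = matrix.copy()
    active = list(range(n))
    sublabel = {i: str(taxa[i]) for i in range(n)}
    sortkey = {i: str(taxa[i]) for i in range(n)}
    next_id = n
    dd = {(i, j): d[i, j] for i in range(n) for j in range(n)}

    def D(i, j):
        return dd[(i, j)] if i != j else 0.0

    while len(active) > 2:
        r = len(active)
        sums = {i: sum(D(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * D(i, j) - sums[i] - sums[j]
                key = (q, tuple(sorted((sortkey[i], sortkey[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D(i, j) + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D(i, j) - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = next_id
        next_id += 1
        for m in active:
            if m in (i, j):
                continue
            dd[(new, m)] = dd[(m, new)] = 0.5 * (D(i, m) + D(j, m) - D(i, j))
        sublabel[new] = (
            f"({sublabel[i]}:{li:.10f},{sublabel[j]}:{lj:.10f})"
        )
        sortkey[new] = min(sortkey[i], sortkey[j])
        active = [m for m in active if m not in (i, j)] + [new]

    i, j = active
    lij = max(D(i, j), 0.0)
    nwk = f"({sublabel[i]}:{lij / 2:.10f},{sublabel[j]}:{lij / 2:.10f});"
    return dendropy.Tree.get(data=nwk, schema="newick")


def brownian_covariance(
    tree: dendropy.Tree, taxa: Sequence[str], midpoint_root: bool = False
) -> np.ndarray:
    """C_ij = shared root-to-tip path length under Brownian motion.

    The seed node is taken as the root as-given (so a star tree yields a
    diagonal C); pass ``midpoint_root=True`` to midpoint-root an unrooted
    tree first.
    """
    tree = tree.clone(depth=1)
    if midpoint_root:
        tree.reroot_at_midpoint(update_bipartitions=True)
    # root-to-node distances
    dist_from_root = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        dist_from_root[node] = (dist_from_root[parent] + edge) if parent else 0.0
    leaf_by_name = {
        lf.taxon.label.replace(" ", "_"): lf for lf in tree.leaf_node_iter()
    }
    missing = [t for t in taxa if t not in leaf_by_name]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    C = np.zeros((n, n))
    for i in range(n):
        li = leaf_by_name[taxa[i]]
        C[i, i] = dist_from_root[li]
        for j in range(i + 1, n):
            lj = leaf_by_name[taxa[j]]
            dij = pdm.distance(li.taxon, lj.taxon)
            C[i, j] = C[j, i] = 0.5 * (C[i, i] + dist_from_root[lj] - dij)
    return C


def pgls_fit(
    tree: dendropy.Tree,
    x: Mapping[str, float],
    y: Mapping[str, float],
    ridge: float = 0.0,
    midpoint_root: bool = False,
) -> PglsFit:
    """GLS regression of y on x with Brownian covariance from the tree."""
    taxa = sorted(x)
    if sorted(y) != taxa:
        raise ValueError("x and y must cover identical taxa")
    C = brownian_covariance(tree, taxa, midpoint_root=midpoint_root)
    n = len(taxa)
    if ridge:
        C = C + ridge * np.eye(n)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Brownian covariance matrix") from exc

    xv = np.array([x[t] for t in taxa], float)
    yv = np.array([y[t] for t in taxa], float)
    X = np.column_stack([np.ones(n), xv])
    XtCi = X.T @ Cinv
    beta_cov = np.linalg.inv(XtCi @ X)
    beta = beta_cov @ (XtCi @ yv)
    resid = yv - X @ beta
    rss = float(resid @ Cinv @ resid)
    sigma2 = rss / (n - 2)

    ones = np.ones(n)
    mu = float((ones @ Cinv @ yv) / (ones @ Cinv @ ones))
    yc = yv - mu
    tss = float(yc @ Cinv @ yc)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    slope_se = float(np.sqrt(sigma2 * beta_cov[1, 1]))
    return PglsFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n=n,
        sigma2=float(max(sigma2, 0.0)),
        slope_se=slope_se,
    )
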