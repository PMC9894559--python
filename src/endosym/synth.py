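"""Synthetic strain sets, rearrangement derivatives, and read mixtures.

Every generator plants features with explicit ground truth so downstream
detectors can be tested for exact recovery.  The default generators use
substitutions only (no indels) and error-free reads: exact expectations
first, realism second.

Feature placement (backbone layout, prophage insertions, toxin pairs, the
biotin operon) is drawn once for the ancestor and inherited by every
genome; per-genome variation comes from substitutions along the tree,
accessory-family gain/loss, and strain-specific novel genes.  With a zero
substitution rate and no accessory/novel variation, all genomes are
byte-identical clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneAnnotation, GenomeRecord, ReadAlignment, revcomp

__all__ = [
    "StrainSetTruth",
    "ReadSetTruth",
    "RearrangementResult",
    "PROPHAGE_MODULE_SIZES",
    "BIOTIN_CANONICAL_ORDER",
    "generate_strain_set",
    "apply_rearrangements",
    "simulate_reads",
]

#: Expected distinct gene-family slots per structural phage module.
PROPHAGE_MODULE_SIZES = {"head": 6, "baseplate": 8, "tail": 6, "fibre": 6}

#: Canonical physical order of the six-gene biotin operon.
BIOTIN_CANONICAL_ORDER = ("bioA", "bioD", "bioC", "bioH", "bioF", "bioB")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Random trees


class _Node:
    __slots__ = ("name", "length", "children")

    def __init__(self, name=None, length=0.0, children=None):
        self.name = name
        self.length = length
        self.children = children or []

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.length:.6f}"

    def leaves(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


def _random_tree(names: Sequence[str], rng, branch_scale: float = 0.2) -> _Node:
    """Random binary tree by sequential joining; exponential branch lengths."""
    active = [_Node(name=n, length=float(rng.exponential(branch_scale)))
              for n in names]
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        active.append(
            _Node(length=float(rng.exponential(branch_scale)), children=[a, b])
        )
    root = active[0]
    root.length = 0.0
    return root


# ---------------------------------------------------------------------------
# Truth containers


@dataclass
class StrainSetTruth:
    """Planted ground truth for one generated strain set."""

    newick: str
    anchor_family: str
    origin_position: dict
    supergroup: dict
    substitution_rate: float
    prophage_regions: dict         # genome_id -> list of region dicts
    cif_pairs: dict                # genome_id -> list of pair dicts
    biotin: dict                   # genome_id -> operon dict or None
    family_matrix: pd.DataFrame    # families x genomes counts
    novel_counts: dict             # genome_id -> planted novel gene count
    rearrangements: list = field(default_factory=list)


@dataclass
class ReadSetTruth:
    """Simulated reads with per-read source labels and alignments."""

    reads: list                    # (read_id, sequence)
    true_source: dict              # read_id -> host | endosymbiont | nuwt
    depths: dict                   # source -> requested fold coverage
    alignments: list               # list[ReadAlignment]
    contig_lengths: dict           # contig_id -> length
    nuwt_spans_host: list          # (start, end) spans in the host contig


@dataclass
class RearrangementResult:
    genome: GenomeRecord
    true_breakpoint_count: int
    segments: list                 # signed (orig_start, orig_end, strand)

    def __iter__(self):
        # allow (genome, count) unpacking per the documented 2-tuple contract
        return iter((self.genome, self.true_breakpoint_count))


# ---------------------------------------------------------------------------
# Sequence helpers


def _biased_seq(rng, length: int, gc: float, skew: float) -> np.ndarray:
    """Random base codes with GC fraction ``gc`` and (G-C)/(G+C) = ``skew``."""
    p_g = gc / 2.0 * (1.0 + skew)
    p_c = gc - p_g
    p_a = p_t = (1.0 - gc) / 2.0
    return rng.choice(4, size=length, p=[p_a, p_c, p_g, p_t]).astype(np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _mutate(arr: np.ndarray, p: float, rng) -> np.ndarray:
    out = arr.copy()
    if p <= 0 or out.size == 0:
        return out
    n = rng.binomial(out.size, min(p, 0.75))
    if n:
        pos = rng.choice(out.size, size=n, replace=False)
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        out[pos] = (out[pos] + shift) % 4
    return out


# ---------------------------------------------------------------------------
# Strain-set generation


def generate_strain_set(
    n_genomes: int,
    genome_length: int = 80_000,
    core_fraction: float = 0.7,
    accessory_rate: float = 0.3,
    n_prophages_range: tuple = (0, 2),
    cif_pair_rate: float = 1.0,
    biotin_prob: float = 0.5,
    skew_amplitude: float = 0.3,
    seed: int | None = None,
    *,
    substitution_rate: float = 0.05,
    gene_length: int = 600,
    spacer_length: int = 100,
    phage_gene_length: int = 400,
    intact_prophage_prob: float = 0.5,
    cif_in_prophage_fraction: float = 0.7,
    biotin_disrupted_prob: float = 0.0,
    prophage_gap_gene_range: tuple = (0, 2),
    novel_rate: float = 2.0,
    branch_scale: float = 0.2,
    gc_content: float = 0.34,
):
    """Generate a clade of circular genomes with planted features.

    Returns ``(genomes, annotations, truth)``.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    lo, hi = n_prophages_range
    if not (0 <= lo <= hi):
        raise ValueError("invalid n_prophages_range")

    rng = np.random.default_rng(seed)
    unit = gene_length + spacer_length
    block_budget = (
        sum(PROPHAGE_MODULE_SIZES.values()) * (phage_gene_length + 30)
        + 5 * (gene_length + 30)
    )
    feature_budget = (
        hi * block_budget
        + (int(np.ceil(3 * cif_pair_rate)) + 2) * 2 * unit
        + 7 * unit
    )
    n_slots = (genome_length - feature_budget) // unit
    if n_slots < 6:
        raise ValueError(
            f"planted features ({feature_budget} nt) do not fit in "
            f"genome_length={genome_length}"
        )

    names = [f"g{i + 1:02d}" for i in range(n_genomes)]
    tree = _random_tree(names, rng, branch_scale)
    # supergroup split at the root
    supergroup = {}
    kids = tree.children if tree.children else [tree]
    for label, child in zip("AB", kids):
        for leaf in child.leaves():
            supergroup[leaf.name] = label
    for n in names:
        supergroup.setdefault(n, "A")

    # --- backbone layout ---------------------------------------------------
    n_core = max(2, int(round(n_slots * core_fraction)))
    n_acc = n_slots - n_core
    is_core = np.array([True] * n_core + [False] * n_acc)
    rng.shuffle(is_core)
    is_core[0] = True  # anchor slot
    slot_fams = []
    ci = ai = 0
    for flag in is_core:
        if flag:
            slot_fams.append(f"OG{ci:05d}")
            ci += 1
        else:
            slot_fams.append(f"ACC{ai:04d}")
            ai += 1
    anchor_family = slot_fams[0]
    slot_strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n_slots)]
    slot_strands[0] = "+"  # anchor on + so rotation to anchor is the identity

    # --- feature plans (shared across genomes) -----------------------------
    n_proph = int(rng.integers(lo, hi + 1))
    n_cif = int(rng.poisson(cif_pair_rate))
    has_biotin = bool(rng.random() < biotin_prob)
    biotin_disrupted = has_biotin and bool(rng.random() < biotin_disrupted_prob)

    # prophage insertion sites: keep >= 7 core genes between any two feature
    # sites and between a site and either end, so accessory loss can never
    # merge planted regions under the gap-5 scanner.
    core_prefix = np.cumsum([1 if f.startswith("OG") else 0 for f in slot_fams])

    def _core_between(a: int, b: int) -> int:
        return int(core_prefix[b] - core_prefix[a])

    candidates = list(range(4, n_slots - 4))
    rng.shuffle(candidates)
    proph_sites: list[int] = []
    for c in candidates:
        if len(proph_sites) == n_proph:
            break
        if _core_between(0, c) < 7 or _core_between(c, n_slots - 1) < 7:
            continue
        if all(_core_between(min(c, s), max(c, s)) >= 7 for s in proph_sites):
            proph_sites.append(c)
    if len(proph_sites) < n_proph:
        raise ValueError(
            "genome too small to separate the requested prophages; increase "
            "genome_length or core_fraction"
        )
    proph_sites.sort()

    other_sites = [c for c in candidates if c not in proph_sites]
    n_cif_in = sum(
        1 for _ in range(n_cif) if n_proph > 0 and rng.random() < cif_in_prophage_fraction
    )
    n_cif_out = n_cif - n_cif_in
    cif_types = [["I", "II", "III", "IV", "V"][int(rng.integers(5))] for _ in range(n_cif)]

    total_module_genes = sum(PROPHAGE_MODULE_SIZES.values())
    module_gene_list = []  # (family, module) in block order
    for mod in ("head", "baseplate", "tail", "fibre"):
        for k in range(PROPHAGE_MODULE_SIZES[mod]):
            module_gene_list.append((f"WO_{mod}_{k + 1:02d}", mod))

    gap_fam_counter = 0
    prophage_plans = []
    cif_assigned = 0
    for p_idx in range(n_proph):
        intact = bool(rng.random() < intact_prophage_prob)
        if intact:
            keep = list(range(total_module_genes))
        else:
            size = int(rng.integers(3, total_module_genes - 4))
            keep = sorted(rng.choice(total_module_genes, size=size, replace=False))
        cif_here = 0
        if cif_assigned < n_cif_in and len(keep) >= 3:
            cif_here = 1
            cif_assigned += 1
        cif_junction = int(rng.integers(1, len(keep))) if cif_here else -1
        elements = []  # ("phage", fam, module) | ("gap_gene", fam) | ("cif", type)
        tallies = {m: set() for m in PROPHAGE_MODULE_SIZES}
        for pos, gi in enumerate(keep):
            fam, mod = module_gene_list[gi]
            if pos > 0:
                n_gap = 0
                if rng.random() < 0.25:
                    g_lo, g_hi = prophage_gap_gene_range
                    n_gap = int(rng.integers(g_lo, g_hi + 1))
                if pos == cif_junction:
                    n_gap = min(n_gap, 3)
                for _ in range(n_gap):
                    elements.append(("gap_gene", f"PGAP{gap_fam_counter:04d}"))
                    gap_fam_counter += 1
                if pos == cif_junction:
                    elements.append(("cif",))
            elements.append(("phage", fam, mod))
            tallies[mod].add(fam)
        counts = {m: len(v) for m, v in tallies.items()}
        complete = (
            counts["head"] >= 5 and counts["baseplate"] >= 7
            and counts["tail"] >= 5 and counts["fibre"] >= 5
        )
        prophage_plans.append(
            {"site": proph_sites[p_idx], "elements": elements,
             "tallies": counts, "complete": complete, "has_cif": bool(cif_here)}
        )

    # fix up cif type assignment order: prophage-borne pairs first, then free
    cif_type_iter = iter(cif_types)
    for plan in prophage_plans:
        if plan["has_cif"]:
            plan["cif_type"] = next(cif_type_iter)
    free_cif_types = [next(cif_type_iter) for _ in range(n_cif_out)]

    n_free_needed = n_cif_out + (1 if has_biotin else 0)
    if len(other_sites) < n_free_needed:
        raise ValueError("genome too small for the requested toxin/operon features")
    free_sites = sorted(other_sites[:n_free_needed])
    cif_sites = free_sites[:n_cif_out]
    biotin_site = free_sites[n_cif_out] if has_biotin else None

    # --- ancestral sequences ------------------------------------------------
    registry: dict[str, tuple[int, int]] = {}
    anc_chunks: list[np.ndarray] = []
    cursor = 0

    # approximate full genome length for skew sign (terminus at midpoint)
    approx_total = n_slots * unit + n_proph * block_budget + n_cif * 2 * unit
    half = approx_total / 2.0

    def _register(key: str, length: int, pos_hint: float):
        nonlocal cursor
        sign = 1.0 if pos_hint < half else -1.0
        arr = _biased_seq(rng, length, gc_content, sign * skew_amplitude)
        registry[key] = (cursor, length)
        anc_chunks.append(arr)
        cursor += length

    pos_hint = 0.0
    for i in range(n_slots):
        _register(f"SP{i:05d}", spacer_length, pos_hint)
        pos_hint += spacer_length
        _register(slot_fams[i], gene_length, pos_hint)
        pos_hint += gene_length
        # features budgeted at their sites for the position hint only
        if i in proph_sites:
            pos_hint += block_budget
        if i in cif_sites or i == biotin_site:
            pos_hint += 2 * unit

    for fam, _mod in module_gene_list:
        _register(fam, phage_gene_length, half * 0.9)
    for plan in prophage_plans:
        for el in plan["elements"]:
            if el[0] == "gap_gene":
                _register(el[1], gene_length, half * 0.9)
    _register("cifA_fam", gene_length, half * 0.9)
    _register("cifB_fam", gene_length, half * 0.9)
    for bio in BIOTIN_CANONICAL_ORDER:
        _register(bio, gene_length, half * 0.9)
    _register("tnp001", gene_length, half * 0.9)
    n_gaps_needed = sum(len(p["elements"]) + 4 for p in prophage_plans) + 64
    for j in range(n_gaps_needed):
        _register(f"NTGAP{j:04d}", int(rng.integers(5, 31)), half * 0.9)

    ancestor = np.concatenate(anc_chunks) if anc_chunks else np.zeros(0, np.uint8)

    # --- evolve down the tree ----------------------------------------------
    leaf_arrays: dict[str, np.ndarray] = {}
    acc_fams = [f for f in slot_fams if f.startswith("ACC")]
    root_presence = {f: bool(rng.random() < 0.6) for f in acc_fams}
    leaf_presence: dict[str, dict] = {}

    def _descend(node: _Node, arr: np.ndarray, presence: dict):
        arr = _mutate(arr, node.length * substitution_rate, rng)
        presence = dict(presence)
        flip_p = min(0.49, accessory_rate * node.length)
        for f in acc_fams:
            if flip_p > 0 and rng.random() < flip_p:
                presence[f] = not presence[f]
        if not node.children:
            leaf_arrays[node.name] = arr
            leaf_presence[node.name] = presence
        else:
            for child in node.children:
                _descend(child, arr, presence)

    _descend(tree, ancestor, root_presence)

    # --- assemble leaves ----------------------------------------------------
    genomes: list[GenomeRecord] = []
    annotations: list[GeneAnnotation] = []
    truth_proph: dict[str, list] = {}
    truth_cif: dict[str, list] = {}
    truth_bio: dict[str, dict | None] = {}
    novel_counts: dict[str, int] = {}
    matrix_counts: dict[str, dict] = {}

    for name in names:
        arr = leaf_arrays[name]
        presence = leaf_presence[name]
        n_novel = int(rng.poisson(novel_rate))
        novel_sites = set(
            rng.choice(range(1, n_slots), size=min(n_novel, n_slots - 1),
                       replace=False).tolist()
        ) if n_novel else set()
        novel_counts[name] = len(novel_sites)

        chunks: list[str] = []
        genes: list[GeneAnnotation] = []
        offset = 0
        gene_no = 0
        fam_counts: dict[str, int] = {}
        regions: list[dict] = []
        pairs: list[dict] = []
        bio_call: dict | None = None
        gap_iter = iter(range(n_gaps_needed))

        def _seq_of(key: str) -> str:
            off, ln = registry[key]
            return _decode(arr[off : off + ln])

        def _emit_gene(fam: str, tags: frozenset, strand: str, seq: str):
            nonlocal offset, gene_no
            gene_no += 1
            g = GeneAnnotation(
                genome_id=name, gene_id=f"{name}_{gene_no:04d}",
                start=offset, end=offset + len(seq), strand=strand,
                family_id=fam, tags=tags,
            )
            genes.append(g)
            fam_counts[fam] = fam_counts.get(fam, 0) + 1
            chunks.append(seq)
            offset += len(seq)
            return g

        def _emit_cif(ctype: str, in_prophage: bool):
            nonlocal offset
            ga = _emit_gene("cifA_fam", frozenset({"cifA"}), "+", _seq_of("cifA_fam"))
            gb = _emit_gene("cifB_fam", frozenset({"cifB"}), "+", _seq_of("cifB_fam"))
            pairs.append(
                {"cifA_gene": ga.gene_id, "cifB_gene": gb.gene_id,
                 "span": (ga.start, gb.end), "type": ctype,
                 "in_prophage": in_prophage}
            )

        for i in range(n_slots):
            chunks.append(_seq_of(f"SP{i:05d}"))
            offset += spacer_length
            fam = slot_fams[i]
            if fam.startswith("OG") or presence[fam]:
                _emit_gene(fam, frozenset(), slot_strands[i], _seq_of(fam))
            if i in novel_sites:
                ln = int(rng.integers(200, gene_length + 1))
                seq = _decode(_biased_seq(rng, ln, gc_content, 0.0))
                _emit_gene(f"NOV_{name}_{i:04d}", frozenset(), "+", seq)
            for plan in prophage_plans:
                if plan["site"] != i:
                    continue
                first_phage = last_phage = None
                span_gene_ids = []
                for el in plan["elements"]:
                    gseq = _seq_of(f"NTGAP{next(gap_iter):04d}")
                    chunks.append(gseq)
                    offset += len(gseq)
                    if el[0] == "phage":
                        g = _emit_gene(el[1], frozenset({el[2], "phage_linked"}),
                                       "+", _seq_of(el[1]))
                        if first_phage is None:
                            first_phage = g
                        last_phage = g
                        span_gene_ids.append(g.gene_id)
                    elif el[0] == "gap_gene":
                        g = _emit_gene(el[1], frozenset(), "+", _seq_of(el[1]))
                        span_gene_ids.append(g.gene_id)
                    else:  # cif cargo
                        _emit_cif(plan["cif_type"], True)
                        span_gene_ids.extend([genes[-2].gene_id, genes[-1].gene_id])
                regions.append(
                    {"span": (first_phage.start, last_phage.end),
                     "tallies": dict(plan["tallies"]),
                     "complete": plan["complete"],
                     "gene_ids": [
                         gid for gid in span_gene_ids
                     ]}
                )
            if i in cif_sites:
                _emit_cif(free_cif_types[cif_sites.index(i)], False)
            if i == biotin_site:
                bio_start = None
                for pos_b, bio in enumerate(BIOTIN_CANONICAL_ORDER):
                    g = _emit_gene(bio, frozenset({bio}), "+", _seq_of(bio))
                    if bio_start is None:
                        bio_start = g.start
                    if biotin_disrupted and pos_b == 2:
                        _emit_gene("tnp001", frozenset({"transposase"}), "+",
                                   _seq_of("tnp001"))
                bio_call = {
                    "present": True, "disrupted": biotin_disrupted,
                    "span": (bio_start, genes[-1].end),
                }

        seq = "".join(chunks)
        genomes.append(
            GenomeRecord(
                genome_id=name, sequence=seq, circular=True,
                supergroup=supergroup[name],
                host_taxon=f"Host_{name}", host_order="Synthetica",
            )
        )
        annotations.extend(genes)
        truth_proph[name] = regions
        truth_cif[name] = pairs
        truth_bio[name] = bio_call
        matrix_counts[name] = fam_counts

    all_fams = sorted({f for c in matrix_counts.values() for f in c})
    matrix = pd.DataFrame(
        {g: [matrix_counts[g].get(f, 0) for f in all_fams] for g in names},
        index=pd.Index(all_fams, name="family_id"),
    )

    truth = StrainSetTruth(
        newick=tree.newick(),
        anchor_family=anchor_family,
        origin_position={g: 0 for g in names},
        supergroup=supergroup,
        substitution_rate=substitution_rate,
        prophage_regions=truth_proph,
        cif_pairs=truth_cif,
        biotin=truth_bio,
        family_matrix=matrix,
        novel_counts=novel_counts,
    )
    return genomes, annotations, truth


# ---------------------------------------------------------------------------
# Rearrangements


def _cut(segments: list, pos: int) -> list:
    """Split the segment list at derived-coordinate ``pos``."""
    out = []
    acc = 0
    for (s, e, st) in segments:
        ln = e - s
        if acc < pos < acc + ln:
            k = pos - acc
            if st == "+":
                out.extend([(s, s + k, "+"), (s + k, e, "+")])
            else:
                out.extend([(e - k, e, "-"), (s, e - k, "-")])
        else:
            out.append((s, e, st))
        acc += ln
    return out


def _seg_index_at(segments: list, pos: int) -> int:
    acc = 0
    for i, (s, e, _st) in enumerate(segments):
        if acc == pos:
            return i
        acc += e - s
    return len(segments)


def apply_rearrangements(
    genome: GenomeRecord,
    n_inversions: int,
    n_transpositions: int,
    seed: int | None = None,
    *,
    min_segment: int = 2500,
    forbidden: Sequence[tuple] = (),
    margin: int = 500,
) -> RearrangementResult:
    """Apply random inversions/transpositions; count true broken adjacencies.

    The derived genome is tracked as a signed permutation of original
    segments; the breakpoint count is the number of segment adjacencies in
    the derived genome (circular) that were not adjacent, in the same
    relative orientation, in the original.
    """
    if n_inversions < 0 or n_transpositions < 0:
        raise ValueError("operation counts must be >= 0")
    rng = np.random.default_rng(seed)
    L = len(genome)

    segments = [(0, L, "+")]

    def _boundaries() -> list[int]:
        acc = 0
        out = [0]
        for (s, e, _st) in segments:
            acc += e - s
            out.append(acc % L)
        return out

    def _ok(pos: int) -> bool:
        if any(s - margin <= pos <= e + margin for (s, e) in forbidden):
            return False
        # keep every segment at least min_segment long so detectors cannot
        # blur adjacent junctions within their gap/contiguity tolerances
        return all(
            min(abs(pos - b), L - abs(pos - b)) >= min_segment
            for b in _boundaries()
        )

    def _draw_pos(k: int) -> list[int]:
        for _ in range(500):
            pts = sorted(int(p) for p in rng.integers(0, L, size=k))
            if len(set(pts)) < k:
                continue
            gaps = [pts[i + 1] - pts[i] for i in range(k - 1)]
            if any(g < min_segment for g in gaps):
                continue
            if all(_ok(p) for p in pts):
                return pts
        raise ValueError("could not draw rearrangement positions; relax margins")
    ops = ["inv"] * n_inversions + ["trs"] * n_transpositions
    rng.shuffle(ops)
    for op in ops:
        if op == "inv":
            i, j = _draw_pos(2)
            segments = _cut(_cut(segments, i), j)
            a, b = _seg_index_at(segments, i), _seg_index_at(segments, j)
            mid = [(s, e, "-" if st == "+" else "+") for (s, e, st) in segments[a:b]]
            segments = segments[:a] + mid[::-1] + segments[b:]
        else:
            i, j, k = 0, 0, 0
            for _ in range(200):
                i, j = _draw_pos(2)
                k = int(rng.integers(0, L))
                if (k < i - min_segment or k > j + min_segment) and _ok(k):
                    break
            else:
                raise ValueError("could not place transposition target")
            segments = _cut(_cut(_cut(segments, i), j), k)
            a, b = _seg_index_at(segments, i), _seg_index_at(segments, j)
            moved = segments[a:b]
            rest = segments[:a] + segments[b:]
            # recompute insertion index on the remaining segments
            acc = 0
            ins = len(rest)
            tgt = k if k < i else k - (j - i)
            for idx, (s, e, _st) in enumerate(rest):
                if acc == tgt:
                    ins = idx
                    break
                acc += e - s
            segments = rest[:ins] + moved + rest[ins:]

    # true breakpoints: circular adjacency not ancestral
    count = 0
    n_seg = len(segments)
    for idx in range(n_seg):
        s1, e1, st1 = segments[idx]
        s2, e2, st2 = segments[(idx + 1) % n_seg]
        if n_seg == 1:
            break
        if st1 == "+" and st2 == "+" and (e1 % L) == s2:
            continue
        if st1 == "-" and st2 == "-" and (e2 % L) == s1:
            continue
        count += 1

    parts = []
    for (s, e, st) in segments:
        piece = genome.sequence[s:e]
        parts.append(piece if st == "+" else revcomp(piece))
    derived = GenomeRecord(
        genome_id=genome.genome_id + "_rearr",
        sequence="".join(parts),
        circular=genome.circular,
        supergroup=genome.supergroup,
        host_taxon=genome.host_taxon,
        host_order=genome.host_order,
    )
    return RearrangementResult(derived, count, segments)


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    host_genome: GenomeRecord,
    endosymbiont_genome: GenomeRecord,
    nuwt_spans: Sequence[tuple],
    host_depth: float,
    endo_depth: float,
    read_length_mean: int = 10_000,
    seed: int | None = None,
    *,
    error_rate: float = 0.0,
) -> ReadSetTruth:
    """Sample error-free fixed-length reads from a host+endosymbiont mixture.

    ``nuwt_spans`` are (start, end) blocks of the endosymbiont genome copied
    into the host contig before sampling; reads overlapping a copied block
    are labelled ``nuwt`` and, when mostly endosymbiont-derived, classified
    as endosymbiont reads (mimicking a k-mer classifier).
    """
    if host_depth < 0 or endo_depth < 0:
        raise ValueError("depths must be >= 0")
    rng = np.random.default_rng(seed)

    host_seq = host_genome.sequence
    nuwt_host_spans = []
    for (s, e) in nuwt_spans:
        if not (0 <= s < e <= len(endosymbiont_genome)):
            raise ValueError(f"NUWT span ({s}, {e}) outside endosymbiont genome")
        block = endosymbiont_genome.sequence[s:e]
        ins = int(rng.integers(0, len(host_seq)))
        host_seq = host_seq[:ins] + block + host_seq[ins:]
        shifted = []
        for (hs, he) in nuwt_host_spans:
            if hs >= ins:
                shifted.append((hs + len(block), he + len(block)))
            else:
                shifted.append((hs, he))
        nuwt_host_spans = shifted + [(ins, ins + len(block))]

    host_id = host_genome.genome_id
    endo_id = endosymbiont_genome.genome_id
    contig_lengths = {host_id: len(host_seq), endo_id: len(endosymbiont_genome)}

    for cid, ln in contig_lengths.items():
        if read_length_mean > ln:
            raise ValueError(f"read length {read_length_mean} exceeds {cid} length {ln}")

    reads, alignments = [], []
    true_source: dict[str, str] = {}

    def _sample(contig_id: str, seq: str, circular: bool, depth: float, prefix: str,
                spans: Sequence[tuple], source_default: str):
        ln = len(seq)
        n_reads = int(round(depth * ln / read_length_mean))
        ext = seq + seq[:read_length_mean] if circular else seq
        hi = ln if circular else ln - read_length_mean + 1
        starts = rng.integers(0, hi, size=n_reads)
        for ridx, start in enumerate(sorted(int(s) for s in starts)):
            rid = f"{prefix}_{ridx:06d}"
            rseq = ext[start : start + read_length_mean]
            if error_rate > 0:
                arr = np.frombuffer(rseq.encode(), dtype=np.uint8).copy()
                code = np.zeros(arr.size, np.uint8)
                for b, c in zip(b"ACGT", range(4)):
                    code[arr == b] = c
                code = _mutate(code, error_rate, rng)
                rseq = _decode(code)
            end = start + read_length_mean
            pieces = [(start, min(end, ln))] + ([(0, end - ln)] if end > ln else [])
            overlap = 0
            for (ps, pe) in pieces:
                for (fs, fe) in spans:
                    overlap += max(0, min(pe, fe) - max(ps, fs))
            if overlap > 0:
                source = "nuwt"
                rclass = "endosymbiont" if overlap >= read_length_mean / 2 else "host"
            else:
                source = source_default
                rclass = "endosymbiont" if source_default == "endosymbiont" else "host"
            reads.append((rid, rseq))
            true_source[rid] = source
            for (ps, pe) in pieces:
                alignments.append(
                    ReadAlignment(read_id=rid, contig_id=contig_id,
                                  contig_start=ps, contig_end=pe,
                                  mapq=60, read_class=rclass)
                )

    _sample(endo_id, endosymbiont_genome.sequence, endosymbiont_genome.circular,
            endo_depth, "er", (), "endosymbiont")
    _sample(host_id, host_seq, host_genome.circular, host_depth, "hr",
            nuwt_host_spans, "host")

    return ReadSetTruth(
        reads=reads,
        true_source=true_source,
        depths={"host": host_depth, "endosymbiont": endo_depth},
        alignments=alignments,
        contig_lengths=contig_lengths,
        nuwt_spans_host=nuwt_host_spans,
    )
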