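"""Count/percentage reporting conventions and pipeline orchestration.

Percentages are rounded half-up to the nearest integer, matching the
"n (p%)" convention used throughout the reported results.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from . import metrics, pangenome, prophage, screen, separate, synth, toxins
from . import io as eio

__all__ = ["CountSummary", "percent_summary", "run_pipeline"]


@dataclass
class CountSummary:
    label: str
    numerator: int
    denominator: int
    percent: int

    def as_fraction(self) -> str:
        return f"{self.numerator}/{self.denominator}, {self.percent}%"

    def as_parenthetical(self) -> str:
        return f"{self.numerator} ({self.percent}%)"


def _round_half_up(value: float) -> int:
    import math

    return int(math.floor(value + 0.5))


def percent_summary(label: str, numerator: int, denominator: int) -> CountSummary:
    """Integer percentage with half-up rounding; denominator must be > 0."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if numerator < 0:
        raise ValueError("numerator must be >= 0")
    return CountSummary(
        label=label,
        numerator=numerator,
        denominator=denominator,
        percent=_round_half_up(100.0 * numerator / denominator),
    )


DEFAULT_STAGES = ("simulate", "metrics", "pangenome", "prophage", "toxins")


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages on a synthetic strain set and write
    per-stage artifacts plus a JSON summary.

    ``config`` keys: ``seed`` (required), ``simulate`` (kwargs for
    generate_strain_set), ``stages`` (subset of DEFAULT_STAGES).
    Deterministic for a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    if seed is None:
        raise ValueError("config must provide a seed")
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    summary: dict = {"seed": seed, "stages": list(stages), "counts": []}

    truth = None
    if "simulate" in stages or "inputs" not in config:
        if "simulate" not in stages and "inputs" not in config:
            needed = [s for s in stages if s in DEFAULT_STAGES]
            raise ValueError(
                f"stage(s) {needed} need genomes/annotations: add the "
                "'simulate' stage or provide config['inputs'] with 'fasta' "
                "and 'gff' paths"
            )
        sim_kwargs = dict(config.get("simulate", {}))
        sim_kwargs.setdefault("n_genomes", 4)
        genomes, annotations, truth = synth.generate_strain_set(seed=seed, **sim_kwargs)
    else:
        inputs = config["inputs"]
        for key in ("fasta", "gff"):
            if key not in inputs:
                raise ValueError(f"missing required input artifact: {key!r}")
        genomes = eio.read_fasta(inputs["fasta"])
        annotations = eio.read_gff_annotations(inputs["gff"])
    genome_by_id = {g.genome_id: g for g in genomes}
    ann_by_genome: dict[str, list] = {g.genome_id: [] for g in genomes}
    for a in annotations:
        ann_by_genome[a.genome_id].append(a)

    if "simulate" in stages:
        eio.write_fasta(genomes, out / "genomes.fasta")
        eio.write_gff_annotations(annotations, out / "annotations.gff3")
        eio.write_family_matrix(truth.family_matrix, out / "truth_families.tsv")
        (out / "truth_tree.nwk").write_text(truth.newick + "\n")

    if "metrics" in stages:
        rows = []
        anchor = truth.anchor_family if truth else config.get("anchor")
        for g in genomes:
            rotated = g
            if anchor and g.circular:
                rotated, _ = metrics.rotate_to_anchor(
                    g, ann_by_genome[g.genome_id], anchor
                )
            window = max(1000, len(g) // 30)
            prof = metrics.skew_profile(rotated.sequence, window=window)
            sk = metrics.skew_index(prof)
            rows.append(
                {
                    "genome_id": g.genome_id,
                    "length": len(g),
                    "gc_pct": round(metrics.gc_content(g.sequence), 3),
                    "skew_index": round(sk.skew_index, 4),
                }
            )
        (out / "metrics.json").write_text(json.dumps(rows, indent=2) + "\n")
        summary["metrics"] = rows

    regions_by_genome: dict[str, list] = {}
    if "prophage" in stages or "toxins" in stages:
        for g in genomes:
            genes = sorted(ann_by_genome[g.genome_id], key=lambda a: a.start)
            regions_by_genome[g.genome_id] = prophage.scan_prophage(
                genes, genome_length=len(g)
            )

    if "prophage" in stages:
        bed_rows = []
        n_regions = n_complete = 0
        for gid, regions in regions_by_genome.items():
            for i, r in enumerate(regions):
                bed_rows.append((gid, r.start, min(r.end, len(genome_by_id[gid])),
                                 f"prophage_{i + 1}"))
                n_regions += 1
                n_complete += int(r.complete)
        eio.write_regions_bed(bed_rows, out / "prophage_regions.bed")
        if n_regions:
            summary["counts"].append(
                asdict(percent_summary("complete_prophages", n_complete, n_regions))
            )
        summary["n_prophage_regions"] = n_regions

    if "toxins" in stages:
        all_pairs = []
        for gid, genes in ann_by_genome.items():
            hits = []
            for a in genes:
                for role in ("cifA", "cifB"):
                    if role in a.tags:
                        hits.append(
                            toxins.CifHit(
                                query_id=a.gene_id, reference_id=f"{role}_ref",
                                role=role, type_label="I", evalue=1e-50,
                                query_coverage=100.0, bitscore=500.0,
                            )
                        )
            pairs, _amb = toxins.find_cif_pairs(
                hits, genes, regions_by_genome.get(gid, [])
            )
            all_pairs.extend(pairs)
        cs = toxins.summarize_cif(all_pairs)
        summary["n_cif_pairs"] = cs.n_pairs
        if cs.n_pairs:
            summary["counts"].append(
                asdict(percent_summary("cif_pairs_in_eam", cs.n_in_eam, cs.n_pairs))
            )

    if "pangenome" in stages:
        if truth is not None:
            matrix = truth.family_matrix
        else:
            import pandas as pd

            counts: dict[str, dict] = {}
            for a in annotations:
                fam = a.family_id or a.gene_id
                counts.setdefault(fam, {})
                counts[fam][a.genome_id] = counts[fam].get(a.genome_id, 0) + 1
            cols = sorted(ann_by_genome)
            matrix = pd.DataFrame(
                {g: [counts[f].get(g, 0) for f in sorted(counts)] for g in cols},
                index=pd.Index(sorted(counts), name="family_id"),
            )
        curve = pangenome.rarefaction(
            matrix, n_permutations=int(config.get("perms", 200)), seed=seed,
        )
        summary["rarefaction"] = {
            "k": curve.k, "mean_core": curve.mean_core, "mean_pan": curve.mean_pan,
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
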