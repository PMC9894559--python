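import numpy as np
import pytest

from endosym.io import GeneAnnotation
from endosym.prophage import (
    ModuleInventory,
    ProphageRegion,
    completeness_call,
    eam_cargo,
    prophage_span_fraction,
    scan_prophage,
)


def _genes(layout, genome_id="g1", width=100):
    """Build ordered annotations from a compact layout string.

    Each character: H/B/T/F = module gene, p = phage_linked only,
    '.' = untagged gene, 'c' = cifA-tagged gene.
    """
    tag_map = {"H": "head", "B": "baseplate", "T": "tail", "F": "fibre"}
    out = []
    for i, ch in enumerate(layout):
        if ch in tag_map:
            tags = frozenset({tag_map[ch], "phage_linked"})
            fam = f"{tag_map[ch]}{i}"
        elif ch == "p":
            tags = frozenset({"phage_linked"})
            fam = f"pl{i}"
        elif ch == "c":
            tags = frozenset({"cifA"})
            fam = f"cif{i}"
        else:
            tags = frozenset()
            fam = f"og{i}"
        out.append(
            GeneAnnotation(genome_id, f"g_{i:03d}", i * width, i * width + 60,
                           "+", family_id=fam, tags=tags)
        )
    return out


class TestScan:
    def test_gap_of_five_joins(self):
        genes = _genes("H" + "." * 5 + "T")
        regions = scan_prophage(genes, circular=False)
        assert len(regions) == 1
        assert regions[0].start == genes[0].start
        assert regions[0].end == genes[-1].end

    def test_gap_of_six_splits_and_coreless_half_dropped(self):
        genes = _genes("H" + "." * 6 + "p")
        regions = scan_prophage(genes, circular=False)
        assert len(regions) == 1  # the lone phage_linked half has no core gene
        assert regions[0].end == genes[0].end

    def test_phage_linked_only_run_not_reported(self):
        regions = scan_prophage(_genes("ppp..ppp"), circular=False)
        assert regions == []

    def test_no_phage_tags_empty(self):
        assert scan_prophage(_genes("....."), circular=False) == []

    def test_unsorted_rejected(self):
        genes = _genes("H.T")
        with pytest.raises(ValueError, match="sorted"):
            scan_prophage(list(reversed(genes)))

    def test_cargo_in_span(self):
        genes = _genes("HcT")
        region = scan_prophage(genes, circular=False)[0]
        assert region.cargo_gene_ids == ["g_001"]

    def test_wraparound_region_joined(self):
        # phage genes at both ends of a circular gene order form one region
        genes = _genes("HT" + "." * 20 + "BF")
        joined = scan_prophage(genes, circular=True, genome_length=2400)
        assert len(joined) == 1
        assert joined[0].end > 2400  # wraps the origin
        split = scan_prophage(genes, circular=False)
        assert len(split) == 2

    def test_planted_truth_recovery(self, strain_set, annotations_by_genome):
        genomes, _ann, truth = strain_set
        for g in genomes:
            regions = scan_prophage(
                annotations_by_genome[g.genome_id], genome_length=len(g)
            )
            expected = truth.prophage_regions[g.genome_id]
            assert len(regions) == len(expected)
            for r, t in zip(regions, sorted(expected, key=lambda t: t["span"][0])):
                assert (r.start, r.end) == tuple(t["span"])
                assert r.complete == t["complete"]
                assert r.inventory.counts() == t["tallies"]

    def test_rotation_invariance(self, strain_set, annotations_by_genome):
        from endosym.metrics import rotate_to_anchor

        genomes, _ann, truth = strain_set
        g = genomes[0]
        base = scan_prophage(annotations_by_genome[g.genome_id], genome_length=len(g))
        # rotate to a gene start so no annotation is split by the new origin
        L = len(g)
        anns = annotations_by_genome[g.genome_id]
        shift = anns[len(anns) // 3].start
        rotated = [a.shifted(-shift, L) for a in anns]
        rotated.sort(key=lambda a: a.start)
        regs = scan_prophage(rotated, genome_length=L)
        assert len(regs) == len(base)
        assert sorted(r.complete for r in regs) == sorted(r.complete for r in base)
        assert sorted(
            tuple(sorted(r.inventory.counts().items())) for r in regs
        ) == sorted(tuple(sorted(r.inventory.counts().items())) for r in base)


def test_genome_size_increases_with_prophage_span():
    """Across strain sets with more prophage content, genome size grows
    with detected prophage span (positive fitted slope)."""
    from endosym import synth

    sizes, spans = [], []
    # hold the backbone constant: compensate the generator's per-prophage
    # feature budget (26 module genes + up to 5 gap genes) in genome_length
    block_budget = 26 * (400 + 30) + 5 * (600 + 30)
    for n_proph, seed in [(0, 1), (1, 2), (2, 3), (3, 4)]:
        genomes, annotations, _truth = synth.generate_strain_set(
            2, genome_length=110_000 + n_proph * block_budget,
            n_prophages_range=(n_proph, n_proph),
            intact_prophage_prob=1.0, seed=seed,
        )
        by = {}
        for a in annotations:
            by.setdefault(a.genome_id, []).append(a)
        for g in genomes:
            genes = sorted(by[g.genome_id], key=lambda a: a.start)
            regions = scan_prophage(genes, genome_length=len(g))
            sizes.append(len(g))
            spans.append(sum(r.end - r.start for r in regions))
    slope = np.polyfit(spans, sizes, 1)[0]
    assert slope > 0


class TestCompleteness:
    def _region(self, h, b, t, f):
        inv = ModuleInventory(
            head={f"h{i}" for i in range(h)},
            baseplate={f"b{i}" for i in range(b)},
            tail={f"t{i}" for i in range(t)},
            fibre={f"f{i}" for i in range(f)},
        )
        return ProphageRegion("g", 0, 100, [], inv, False, [])

    def test_threshold_met(self):
        assert completeness_call(self._region(5, 7, 5, 5))

    def test_head_below_threshold(self):
        assert not completeness_call(self._region(4, 8, 6, 6))

    def test_full_inventory(self):
        assert completeness_call(self._region(6, 8, 6, 6))

    def test_monotone_in_inventory(self):
        region = self._region(5, 7, 5, 5)
        assert completeness_call(region)
        region.inventory.head.pop()
        assert not completeness_call(region)


class TestSpanFraction:
    def _region(self, s, e):
        return ProphageRegion("g", s, e, [], ModuleInventory(), False, [])

    def test_no_regions(self):
        assert prophage_span_fraction(1_000_000, []) == 0.0

    def test_ten_percent(self):
        assert prophage_span_fraction(1_000_000, [self._region(0, 100_000)]) == (
            pytest.approx(0.10)
        )

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            prophage_span_fraction(1000, [self._region(0, 500),
                                          self._region(400, 700)])

    def test_planted_exact(self, strain_set, annotations_by_genome):
        genomes, _ann, truth = strain_set
        for g in genomes:
            regions = scan_prophage(
                annotations_by_genome[g.genome_id], genome_length=len(g)
            )
            expected = sum(
                t["span"][1] - t["span"][0]
                for t in truth.prophage_regions[g.genome_id]
            ) / len(g)
            assert prophage_span_fraction(len(g), regions) == pytest.approx(expected)


class TestCargo:
    def test_structural_only_no_cargo(self):
        genes = _genes("HBTF")
        region = scan_prophage(genes, circular=False)[0]
        assert eam_cargo(region, genes) == []

    def test_planted_cif_in_cargo(self, strain_set, annotations_by_genome):
        genomes, _ann, truth = strain_set
        found_one = False
        for g in genomes:
            genes = annotations_by_genome[g.genome_id]
            regions = scan_prophage(genes, genome_length=len(g))
            for pair in truth.cif_pairs[g.genome_id]:
                if not pair["in_prophage"]:
                    continue
                found_one = True
                cargo_ids = set()
                for r in regions:
                    cargo_ids |= {a.gene_id for a in eam_cargo(r, genes, len(g))}
                assert pair["cifA_gene"] in cargo_ids
                assert pair["cifB_gene"] in cargo_ids
        assert found_one

    def test_boundary_gene_start_convention(self):
        genes = _genes("H.T")
        region = scan_prophage(genes, circular=False)[0]
        straddler = GeneAnnotation("g1", "strad", region.end,
                                   region.end + 50, "+", family_id="s")
        inside = eam_cargo(region, genes + [straddler])
        assert "strad" not in [a.gene_id for a in inside]
        starter = GeneAnnotation("g1", "starter", region.start + 5,
                                 region.end + 50, "+", family_id="s2")
        inside = eam_cargo(region, genes + [starter])
        assert "starter" in [a.gene_id for a in inside]
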