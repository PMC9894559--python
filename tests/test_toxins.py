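import pytest

from endosym.io import GeneAnnotation
from endosym.prophage import scan_prophage
from endosym.toxins import (
    CifHit,
    find_biotin_operon,
    find_cif_pairs,
    summarize_cif,
)


def _gene(gene_id, i, tags=(), genome_id="g1", width=100):
    return GeneAnnotation(
        genome_id, gene_id, i * width, i * width + 60, "+",
        family_id=f"f_{gene_id}", tags=frozenset(tags),
    )


def _hit(gene_id, role, evalue=1e-50, coverage=100.0, bitscore=200.0,
         type_label="I"):
    return CifHit(
        query_id=gene_id, reference_id=f"{role}_ref_{type_label}", role=role,
        type_label=type_label, evalue=evalue, query_coverage=coverage,
        bitscore=bitscore,
    )


class TestCifPairs:
    def test_low_coverage_disqualifies(self):
        genes = [_gene("a", 0), _gene("b", 1)]
        hits = [_hit("a", "cifA", coverage=75.0), _hit("b", "cifB")]
        pairs, _ = find_cif_pairs(hits, genes)
        assert pairs == []

    def test_coverage_bounds_inclusive(self):
        genes = [_gene("a", 0), _gene("b", 1)]
        for cov in (80.0, 120.0):
            hits = [_hit("a", "cifA", coverage=cov), _hit("b", "cifB")]
            pairs, _ = find_cif_pairs(hits, genes)
            assert len(pairs) == 1

    def test_evalue_gate(self):
        genes = [_gene("a", 0), _gene("b", 1)]
        hits = [_hit("a", "cifA", evalue=1e-20), _hit("b", "cifB")]
        assert find_cif_pairs(hits, genes)[0] == []

    def test_adjacent_pair_typed_by_best_reference(self):
        genes = [_gene("a", 0), _gene("b", 1)]
        hits = [
            _hit("a", "cifA", bitscore=300.0, type_label="I"),
            _hit("b", "cifB", bitscore=200.0, type_label="II"),
        ]
        pairs, _ = find_cif_pairs(hits, genes)
        assert len(pairs) == 1
        assert pairs[0].type_label == "I"
        assert (pairs[0].cifA_gene, pairs[0].cifB_gene) == ("a", "b")

    def test_reversed_gene_order_still_pairs(self):
        genes = [_gene("b", 0), _gene("a", 1)]
        hits = [_hit("a", "cifA"), _hit("b", "cifB")]
        pairs, _ = find_cif_pairs(hits, genes)
        assert len(pairs) == 1
        assert pairs[0].cifA_gene == "a"

    def test_intervening_gene_blocks_pair(self):
        genes = [_gene("a", 0), _gene("x", 1), _gene("b", 2)]
        hits = [_hit("a", "cifA"), _hit("b", "cifB")]
        assert find_cif_pairs(hits, genes)[0] == []

    def test_no_hits_empty(self):
        assert find_cif_pairs([], [_gene("a", 0)])[0] == []

    def test_dual_role_gene_ambiguous(self):
        genes = [_gene("a", 0), _gene("b", 1)]
        hits = [_hit("a", "cifA"), _hit("a", "cifB"), _hit("b", "cifB")]
        pairs, ambiguous = find_cif_pairs(hits, genes)
        assert ambiguous == ["a"]
        assert pairs == []

    def test_cross_replicon_pairs_forbidden(self):
        genes = [_gene("a", 0, genome_id="g1"), _gene("b", 0, genome_id="g2")]
        hits = [_hit("a", "cifA"), _hit("b", "cifB")]
        assert find_cif_pairs(hits, genes)[0] == []

    def test_in_eam_flag(self):
        phage = [
            _gene("h1", 0, tags={"head", "phage_linked"}),
            _gene("a", 1), _gene("b", 2),
            _gene("t1", 3, tags={"tail", "phage_linked"}),
        ]
        regions = scan_prophage(sorted(phage, key=lambda g: g.start),
                                circular=False)
        hits = [_hit("a", "cifA"), _hit("b", "cifB")]
        pairs, _ = find_cif_pairs(hits, phage, regions)
        assert pairs[0].in_eam

    def test_planted_recovery(self, strain_set, annotations_by_genome):
        genomes, _ann, truth = strain_set
        for g in genomes:
            genes = annotations_by_genome[g.genome_id]
            regions = scan_prophage(genes, genome_length=len(g))
            hits = []
            for a in genes:
                for role in ("cifA", "cifB"):
                    if role in a.tags:
                        hits.append(_hit(a.gene_id, role))
            pairs, amb = find_cif_pairs(hits, genes, regions)
            assert amb == []
            expected = truth.cif_pairs[g.genome_id]
            assert len(pairs) == len(expected)
            got = {(p.cifA_gene, p.cifB_gene): p.in_eam for p in pairs}
            for t in expected:
                key = (t["cifA_gene"], t["cifB_gene"])
                assert key in got
                assert got[key] == t["in_prophage"]


class TestSummary:
    def test_empty(self):
        s = summarize_cif([])
        assert s.n_pairs == 0 and s.eam_fraction is None

    def test_two_of_three_in_eam(self):
        from endosym.report import percent_summary
        from endosym.toxins import CifPair

        pairs = [
            CifPair("g1", "a", "b", "I", True, (0, 0), (0, 100)),
            CifPair("g1", "c", "d", "V", True, (0, 0), (200, 300)),
            CifPair("g2", "e", "f", "II", False, (0, 0), (0, 100)),
        ]
        s = summarize_cif(pairs)
        assert s.n_in_eam == 2 and s.genomes_with_pair == 2
        assert percent_summary("eam", s.n_in_eam, s.n_pairs).percent == 67


class TestBiotin:
    ORDER = ("bioA", "bioD", "bioC", "bioH", "bioF", "bioB")

    def _operon(self, order=None, insert=None, genome_id="g1"):
        order = order or self.ORDER
        genes = [_gene("x0", 0), _gene("x1", 1)]
        i = 2
        for tag in order:
            genes.append(_gene(tag, i, tags={tag}, genome_id=genome_id))
            i += 1
            if insert and insert[0] == tag:
                genes.append(_gene("ins", i, tags=insert[1], genome_id=genome_id))
                i += 1
        genes.append(_gene("x2", i))
        return genes

    def test_intact_operon(self):
        call = find_biotin_operon(self._operon())
        assert call.present and call.order_conserved and not call.disrupted

    def test_five_of_six_not_present(self):
        genes = [g for g in self._operon() if "bioH" not in g.tags]
        call = find_biotin_operon(genes)
        assert not call.present
        assert len(call.genes_found) == 5

    def test_transposase_disruption(self):
        genes = self._operon(insert=("bioC", {"transposase"}))
        call = find_biotin_operon(genes)
        assert call.present and call.disrupted

    def test_reverse_order_conserved(self):
        call = find_biotin_operon(self._operon(order=tuple(reversed(self.ORDER))))
        assert call.present and call.order_conserved

    def test_scrambled_order_not_conserved(self):
        scrambled = ("bioA", "bioC", "bioD", "bioH", "bioF", "bioB")
        call = find_biotin_operon(self._operon(order=scrambled))
        assert call.present and not call.order_conserved

    def test_split_locus_not_present(self):
        # three intervening genes (> max_intervening=2) split the locus
        genes = []
        layout = ["bioA", "bioD", "bioC", "x", "x", "x", "bioH", "bioF", "bioB"]
        for i, name in enumerate(layout):
            tags = {name} if name.startswith("bio") else set()
            genes.append(_gene(f"{name}_{i}", i, tags=tags))
        call = find_biotin_operon(genes)
        assert not call.present

    def test_planted_recovery(self, strain_set, annotations_by_genome):
        genomes, _ann, truth = strain_set
        for g in genomes:
            call = find_biotin_operon(annotations_by_genome[g.genome_id])
            expected = truth.biotin[g.genome_id]
            if expected is None:
                assert not call.present
            else:
                assert call.present == expected["present"]
                assert call.disrupted == expected["disrupted"]
                assert call.order_conserved
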