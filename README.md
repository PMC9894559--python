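# endosym

Toolkit for mining endosymbiont genomes out of host genome sequencing
projects: marker-gene screening with consensus taxonomy, host/cobiont
separation with a nuclear-insertion (NUWT) filter, genome normalization and
GC-skew statistics, fragment-based ANI and rearrangement breakpoints,
pangenome rarefaction, gap-tolerant prophage detection with completeness
calls, toxin-pair (CifA/CifB) and biotin-operon calling, and
Brownian-covariance (PGLS) regression. A first-class synthetic-data module
generates strain sets, rearranged derivatives, and read mixtures with
planted ground truth so every stage is testable offline.

## Package layout

| module | contents |
| --- | --- |
| `endosym.io` | FASTA / GFF3 / BED / PAF-like TSV / newick / matrix TSV readers and writers; shared domain types; 0-based half-open coordinates everywhere internally |
| `endosym.synth` | `generate_strain_set`, `apply_rearrangements` (with true breakpoint counts), `simulate_reads` (host + endosymbiont + NUWT mixtures) |
| `endosym.screen` | SSU hit filter (e-value < 1e-150 or aligned length > 1000 nt, identity > 90%) and 80%-of-top-20 consensus classification |
| `endosym.separate` | contig coverage from classified reads, full-coverage NUWT filter, relative abundance (length-weighted median window depth), assembly ranking |
| `endosym.metrics` | rotation to a single-copy anchor family, GC content, circular windowed GC skew, two-arc skew index in [0, 1] |
| `endosym.compare` | unique-k-mer collinear blocks, breakpoint statistics per alignable base, fragment-mapping ANI |
| `endosym.pangenome` | single-linkage family clustering, near-single-copy selection (> 95%), strain-specific counts, core/pan rarefaction by addition-order permutation |
| `endosym.prophage` | gap-tolerant scan (<= 5 intervening genes), module completeness (5/6 head, 7/8 baseplate, 5/6 tail, 5/6 fibre), span fraction, EAM cargo extraction |
| `endosym.toxins` | CifA/CifB pair calling (e-value <= 1e-30, coverage 80-120%, strict adjacency), pair summaries, biotin operon detection and transposase disruption |
| `endosym.phylo` | supermatrix construction, p/JC69 distances, neighbor joining, Brownian PGLS |
| `endosym.report` | `percent_summary` ("n (p%)" convention, round half-up) and pipeline orchestration |

## CLI

```bash
endosym simulate --out out/ --seed 1 --n-genomes 4
endosym metrics  --fasta out/genomes.fasta --gff out/annotations.gff3
endosym prophage --gff out/annotations.gff3 --fasta out/genomes.fasta --out-bed regions.bed
endosym compare  --fasta-a a.fa --fasta-b b.fa
endosym pangenome --matrix out/truth_families.tsv --perms 10000 --seed 1
endosym pgls --tree tree.nwk --traits traits.tsv
endosym run --config cfg.yaml --out run/
```

All subcommands accept a global `--log-level` and log to stderr.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: prophage/rarefaction/
breakpoint oracles against planted truth and closed forms, SSU decision-rule
boundary tables, NUWT-filter and abundance recovery on simulated mixtures,
PGLS parameter-recovery simulations, ANI tolerances, skew-index invariances,
and the worked count-to-percentage conversions.

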