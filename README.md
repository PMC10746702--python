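# polyploidkit

Identifying the diploid donor genomes of an allotetraploid plant, end to
end, on a synthetic system with known truth.

## The problem

An allotetraploid carries two complete diploid genomes — an A subgenome
from its maternal donor and a B subgenome from its paternal donor.
Given genome assemblies of the polyploid and two candidate progenitor
species, the donor question is answered by combining several classical
lines of evidence:

* **Maternal lineage** — chloroplasts are maternally inherited, so a
  phylogeny of chloroplast consensus sequences (built from variant
  calls with phred quality ≥ 30) identifies the seed parent. Per-gene
  nucleotide diversity `π = 2/(n(n−1)) · Σ_{i<j} d_ij / L` locates the
  most informative genes, and Robinson–Foulds metrics
  (`maxRF = 2(n−3)`, `nRF = RF/maxRF`) compare competing trees.
* **Synteny and Ks** — collinear gene blocks chained in rank space
  (MCScanX-style: match size 5, max gap 25) mark homoeologous regions;
  the Nei–Gojobori (1986) synonymous rate
  `dS = −¾ ln(1 − 4/3·pS)` dates them. Self-synteny block pairs in the
  tetraploid are partitioned by their median dS to the candidate A
  donor: the closer copy is the A subgenome.
* **Depth of coverage (DOC)** — short reads from each progenitor are
  assigned to tetraploid contigs (best shared canonical 31-mer count);
  a contig with DOC under 16× from one progenitor but covered by the
  other derives from the other donor.
* **Gene families** — families whose tetraploid copy number is at least
  twice that of *each* diploid relative are the residue of whole-genome
  duplication; amplified families roll up to pathways.
* **Genome size** — the k-mer spectrum's main peak (`genome size =
  k-mers above the error cutoff / peak depth`).

The package implements every step as a library (`src/polyploidkit/`),
plus a simulator that generates a truth-labelled synthetic
allotetraploid system — two progenitors diverged at a configurable
NG86 dS (default 0.05), their union with small extra divergence per
subgenome copy and optional gene fractionation, reads, family count
tables, and a plastome with 23 variant-called accessions on a known
tree — so the whole pipeline is exercised against machine-checkable
truth.

## Worked example

The numbered drivers under `analysis/` run the study on the desk-scale
preset (20 contigs × 50 kb per progenitor, 10 genes of 900 bp per
contig, dS 0.05, 40× reads at 0.5% error; seed 1). Working data goes to
`scratch/run/`, result tables to `results/run/`:

```sh
python analysis/01_simulate_system.py
python analysis/02_plastome_phylogeny.py
python analysis/03_synteny_and_ks.py
python analysis/04_subgenome_assignment.py
python analysis/05_gene_families.py
python analysis/06_genome_size.py
```

Output of steps 03 and 04 (verbatim):

```
synteny and Ks:
  progenitor A vs B: 20 blocks, modal Ks = 0.0443
  tetraploid self-synteny: 20 block pairs, modal Ks = 0.0700
  true orthologs to progenitor A: 200
  initial Ks peak of A-subgenome copies: 0.0086

subgenome assignment:
  DOC classification accuracy: 1.000
  Ks partition accuracy: 1.000 (40 block copies assigned)
  route agreement: 1.000 over 40 units
  DOC under 16x for progenitorA reads: 20 contigs, 1000000 bp
  DOC under 16x for progenitorB reads: 20 contigs, 1000000 bp
```

Reading: the progenitor-vs-progenitor Ks mode (0.044) recovers the
simulated speciation divergence of 0.05; the tetraploid's self-synteny
mode (0.070) is older because each subgenome copy accrued extra
divergence after the union — the expected ordering for a recent
allopolyploid. The A-copy initial peak (0.009) matches the simulated
post-union divergence of 0.01. Both assignment routes recover the true
origin of every contig and agree with each other everywhere. Step 06
estimates the 1 Mb progenitor genome at 1,028,972 bp (+2.9%) from the
21-mer spectrum of 0.5%-error reads.

The same stages are callable from a single CLI
(`polyploidkit simulate|consensus|pi|njtree|rfdist|synteny|ks|subgenome|
doc-classify|families|kmer-size|stats|run`), with `--seed`, `--config`
(YAML defaults) and `--log-level` as global options.

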