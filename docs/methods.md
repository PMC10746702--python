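# Methods

This note documents the models, estimators and design choices behind
polyploidkit, and what the synthetic benchmark does and does not show.

## The synthetic allotetraploid system

The simulator is the study design: every downstream claim is a
recovery statement about data generated here.

**Ancestor.** Uniform-random DNA contigs with regularly spaced,
non-overlapping genes. Each CDS starts with ATG, contains random sense
codons (rejection against stops) and ends with a stop; strands are
drawn uniformly, and minus-strand genes are stored 5'→3' on the coding
strand.

**Divergence.** `diverge()` applies the *full pairwise* target to one
lineage while the other keeps the ancestor, so the single knob equals
the measured progenitor–progenitor dS. Codon substitution events are
Poisson per codon; each event moves the codon to a uniformly chosen
single-base synonymous (or nonsynonymous, for the dN channel)
neighbour, stop codons excluded. This unbiased-neighbour model is
exactly the model under which Nei–Gojobori counting is exact, which is
what lets the simulator be calibrated against the package's own
estimator: a propose/measure/adjust loop multiplies the event rates by
`target/measured` until the realized NG86 dS (and dN) is within the
acceptance band, and errors out after 10 rounds. The band is
`max(5%, 3/√Sd)` relative — the second term widens it to three
relative standard errors of the synonymous-difference count, which
dominates on short test genomes; at the desk scale (≈180 kb CDS,
Sd ≈ 2000) the band is ≈5–7%, comfortably inside the ±10% contract.
Intergenic DNA mutates at `target_dS` per site. Note one subtlety:
with a pure-synonymous process, NG86 can still report a tiny nonzero
Nd (~10⁻⁵ per site), because path-averaging over codons hit twice may
route through nonsynonymous intermediates. Proteins remain unchanged.

**Tetraploid.** The union of both (relabelled) progenitor genomes;
each subgenome copy is independently re-diverged by `extra_dS`
(default 0.01, synonymous only) and contigs get neutral shuffled ids.
Fractionation removes the gene *annotation* with the configured
probability but leaves the DNA in place (pseudogenization-style loss).
This is deliberate: copy-number tables and synteny see exactly the
loss signal the analysis needs, while read-depth classification — which
operates on sequence, not annotation — is unaffected, as it would
largely be for recent pseudogenes in real data. Consequently heavy
fractionation degrades the Ks route (blocks shrink below the minimum
chain size) but not the DOC route.

**Reads.** Single-end, uniform start positions (length-weighted across
contigs), uniform strand, per-base substitution errors, constant
quality. Read count = `coverage × genome / read_length`. Paired-end
adds nothing to mean-depth classification, so it is not modelled.

**Family counts.** Background families draw diploid counts from
{1,2,3}; the tetraploid count is the diploid sum, fractionated (−1)
with probability ½ — and *always* fractionated when the two diploid
draws are equal, because an unfractionated sum of equal counts would
satisfy the twofold rule and make the truth set unrecoverable.
Amplified families get `2·max(d₁,d₂) + {0,1,2}` tetraploid copies.
The generator therefore constructs counts strictly inside/outside the
rule; the exact precision=recall=1 result shows filter correctness,
not that real eggNOG count tables are this clean.

**Plastome accessions.** A single 30 kb reference with 40 genes of
600 bp; 23 accessions evolve by per-site substitution along a random
binary tree (branch lengths uniform in [0.002, 0.01]). Variants
against the reference carry qualities in [35, 60], spiked with
spurious calls below 30 that the consensus rule must reject; one
accession loses coverage over two genes to exercise the
comprehensive-coverage filter.

**Determinism.** All randomness flows from `numpy.random.SeedSequence`
spawning; every operation is bit-reproducible for a fixed seed.

## Estimators

**NG86.** Synonymous sites per codon are `(synonymous single-base
neighbours)/3` summed over positions (mutations to stops count in the
denominator and are nonsynonymous); sites are averaged between the two
sequences. Differences per codon pair are averaged with equal weight
over all shortest substitution paths, excluding paths through stop
codons (if every path is blocked, all paths are averaged). Jukes–Cantor
correction with saturation flagged at p ≥ ¾ (with a 10⁻⁹ epsilon so
proportions that are exactly ¾ up to float-summation order are flagged
consistently). All 64×64 pair counts are precomputed at import. Codon
alignment is protein-guided: translate, globally align (BLOSUM62,
gap cost 11 + 1·length), back-thread codons, drop gapped columns.

**Modal Ks.** Gaussian KDE (Silverman bandwidth, scipy) on a
1000-point grid over [0, max]; the mode is the grid argmax. KDE avoids
histogram bin-width choices; the bandwidth is exposed for
reproducibility. Per-block Ks is the median of non-saturated anchor dS
values. With only ~20 blocks the block-median mode carries a few
thousandths of sampling wobble, which is why the recovery band is
[0.04, 0.06] around the simulated 0.05.

**Synteny chaining.** Anchors are top-5-per-query homology hits with
identity ≥ 0.5 (within-family pairwise alignment stands in for a
BLAST search on synthetic data). Chains are found per contig pair and
orientation by dynamic programming over rank-sorted anchors: strictly
monotone ranks on both sides, rank gaps ≤ 25, score
`Σ anchor scores − 1.0 · Σ (gap−1)`. Disjoint chains are extracted
greedily by descending score; chains under 5 anchors are discarded.
Gap units are gene ranks, not bp, for robustness to intergenic length
variation. Self-synteny removes tandem anchors (same contig,
|Δrank| < 5) and reports each duplicated pair once in canonical order.

**Phylogenetics.** Distances are Jukes–Cantor with pairwise deletion
of gap/N sites; saturated pairs are an error, and bootstrap replicates
containing one are skipped and logged (supports are reported over
completed replicates). NJ is the Saitou–Nei Q-criterion agglomeration;
negative branch estimates are clamped to zero with the deficit moved
to the sibling so path lengths are preserved; Q ties break by the
lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf), making output deterministic. Trees are
compared unrooted over non-trivial bipartitions; `maxRF = 2(n−3)`
presumes fully resolved trees, and unresolved inputs are rejected
rather than silently normalised.

**Nucleotide diversity.** Complete deletion of columns with any gap/N
(the convention of the standard desktop tool for this statistic), then
the average per-site pairwise distance. The reported SD is the sample
standard deviation of the n(n−1)/2 per-pair per-site distances — the
estimator behind typical π bar plots is rarely stated, so this simple,
documented choice is used. The coverage filter defaults to requiring
100% of a gene covered in every accession ("comprehensive" read
literally), exposed as `min_fraction`.

**Consensus.** Substitutions with phred ≥ 30 (strict ≥) are applied;
indel records are skipped with a warning so all consensuses keep
reference coordinates — that shared coordinate system is what makes
the MSA-free π and distance computations valid. Conflicting accepted
calls at one position keep the highest quality.

**DOC classification.** Reads are assigned to the contig sharing the
most canonical 31-mers; ties and zero-match reads are counted
unassigned. This assigner is defined and exact on simulator data; it
is *not* a general-purpose mapper (no indels, no quality weighting).
Depth is assigned bases / contig length, unweighted across contigs in
the summary (a length-weighted mean is a flag away). The 16× threshold
with strict `<` follows the low-depth peak boundary convention; the
optional N90 filter restricts classification to contigs at least as
long as the assembly N90. Raising the threshold can only grow the
both-under-threshold class (monotonicity, tested). Block copies are
mapped to contigs for reconciliation; block pairs internal to a single
contig are flagged self-contained and excluded from the agreement
score.

**Gene families.** Amplified iff `t ≥ 2·d₁ and t ≥ 2·d₂` with both
diploid counts ≥ 1 — "twofold versus the other species" read as
against *each* relative, with the zero-diploid exclusion preventing
infinite-ratio artifacts; both the fold and the zero-diploid rule are
flags. True orthologs are pairs that are each other's best homology
hit *and* share a family assignment.

**k-mer genome size.** Canonical (strand-minimum) k-mers, k odd ≤ 31,
packed 2 bits/base into int64; exact counting via sort-unique. The
error cutoff is the first local minimum of the spectrum; a spectrum
rising from multiplicity 1 has no error peak and gets cutoff 0; a
monotonically falling spectrum is an error. Expected peak depth is
`coverage · (L−k+1)/L`, e.g. 32 at 40× with 100 bp reads and k = 21.
Only the single-peak homozygous model is implemented — no
heterozygosity mixture, matching the haploid-like simulator genomes.

## Problem sizes

The desk preset — 20 × 50 kb contigs per progenitor (1 Mb each,
≈180 kb CDS), 40× reads, 1000 families (100 amplified), 23 plastome
accessions with 50–100 bootstrap replicates — was chosen as the
smallest system in which every signal the pipeline relies on is
comfortably above its noise floor (≥100 kb CDS for dS calibration,
≥5 blocks for a stable KDE mode, depth ≫ 16× for DOC). The full
benchmark runs in a few minutes on one core.

## What passing does and does not show

Recovery at 100% on the desk preset demonstrates internal consistency:
the estimators invert the generative model they assume. Real data adds
repeats, indels, assembly chimeras, transposon-driven intergenic
turnover, heterozygosity, and biased codon usage — none of which the
simulator models. In particular, the k-mer assigner would need
replacing with a real mapper for repeat-rich genomes, the NG86
estimator ignores transition/transversion bias (a classical
underestimate of dS on real data), and fractionation-as-
pseudogenization means DOC robustness to gene loss is a modelling
choice, not a finding.
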