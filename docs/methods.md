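# Methods

## Data model and fixtures

The packaged tables transcribe the published soybean Cupin family
summaries verbatim into plain TSV: 69 gene records (locus, chromosome,
coordinates, peptide length, exon count), 18 duplicate-pair rows (mode,
fragment-size class, Ka, Ks, Ka/Ks, date in Mya), and 38 selected SNP
sites with allele counts in 17 wild and 14 cultivated accessions.
Coordinates are kept 1-based inclusive as printed; the source table has no
strand column, so strand is inferred as "−" when the printed start exceeds
the printed end, and a normalized `start ≤ end` interval is carried
alongside the raw one. Eighteen rows have printed spans too short to hold
the stated peptide (e.g. a 109-bp span for a 221-aa protein — evidently
truncated coordinates in the source); these are retained verbatim and
flagged with a warning rather than "corrected", since any correction would
be invention. The pair table lists one pair twice; both rows are kept so
the table's printed aggregates (18 rows, mean Ks, mean date) reproduce
exactly.

Reported values use decimal round-half-up at the tables' print precision
(rates 4 dp, dates 2 dp, percentages 1 dp). This matters: the mean Ks of
the 18 pairs is exactly 0.16815, which prints as 0.1682 under half-up but
0.1681 under float banker's rounding.

## Genome organization

Tandem clusters are maximal runs of genes on one chromosome whose
successive intervals are separated by at most `max_gap_bp` (default
20 kb, chosen to cover the largest within-cluster gap in the family,
~19 kb, while staying well below inter-block distances). Cluster span is
max(end) − min(start); the published per-cluster "within X kb" figures
are internally inconsistent between span conventions, so this one
convention is declared and used everywhere. A duplicate pair is *tandem*
iff both genes share a chromosome and the inter-gene gap is within the
same 20-kb window, else *segmental*; segmental pairs are classed *large*
when their covering duplicated block exceeds 1 Mb. Blocks are an input
annotation — the package never infers synteny.

## Phylogeny

Distances are p-distances (mismatches / compared sites) with pairwise gap
deletion; a pair with zero comparable sites is an error, not a zero.
Neighbor joining is the standard Saitou–Nei agglomeration: Q-matrix
minimization with ties broken at the lowest (row, column) index pair so
results are platform-independent, the usual branch-length formulas, and a
trifurcating root-equivalent node. Negative branch lengths are clamped to
zero with the deficit moved onto the sibling branch, preserving the
joined pair's summed length; this is the common printable-tree compromise
and slightly distorts individual branches but never pair sums. On any
additive matrix the algorithm is exact (property-tested on random 4–12
leaf trees).

Bootstrap resamples alignment columns with replacement; supports are the
percentage of replicate NJ trees containing each internal bipartition of
the point tree, and are bit-for-bit reproducible for a fixed seed.
Paralog pairs are cherries (mutual sister leaves) whose joining node has
support ≥ 50% by default, mirroring the convention of showing only >50%
supports. Subgroup assignment cuts the tree into k groups by greedily
splitting the cluster with the longest root-to-leaf path; since the real
family's subgroup count cannot be re-derived without the unpublished
member sequences, k is a parameter (the study's value is 10).

## Ka/Ks and dating

The estimator is Nei–Gojobori (1986) with Jukes–Cantor correction — the
classical counting method, fully specifiable from the literature, which
is why it is used here rather than a likelihood method. Per codon, each
position contributes the fraction of its three possible point mutations
that are synonymous; mutations creating stop codons count as
nonsynonymous, which keeps S + N exactly 3× the compared codons.
Differences between codons are averaged over all minimal mutational
pathways, excluding pathways that pass through a stop codon (falling back
to all pathways if every one is blocked). Proportions are corrected with
d = −(3/4)·ln(1 − (4/3)p), flagged invalid at p ≥ 3/4; the Ka/Ks ratio is
an explicit undefined flag (never infinity) when Ks is zero or invalid.
The implementation agrees with an independent brute-force enumeration on
a 12-codon toy pair and with Biopython's NG86 routine to 1e-9 on random
evolved pairs.

Dating uses the molecular clock T = Ks/2λ with λ = 6.1×10⁻⁹ synonymous
substitutions per site per year (the soybean rate), reported in Mya at
2 dp.

## Selection scan

A biallelic site is a putative selected site when the allele-count
distribution reverses between the panels: sign(w₁−w₂)·sign(c₁−c₂) < 0, or
exactly one panel is tied while the other has a strict majority. The
tie rule is forced by the data: the published site list includes tied
rows (8A/8G against 5A/9G), so ties against a majority must count;
both-tied does not. The rule is invariant under allele relabeling and
under swapping the panels. Counts are over observed calls only; a site
with zero observations in either panel is skipped with a warning. An
optional minimum frequency-difference threshold is exposed for users who
want a stricter rule than the strict-sign default, but is off by default
because the default reproduces every published row. Note this is a
descriptive classifier, not a formal selection statistic — no Fst,
XP-CLR, or significance machinery.

## Expression

RPKM is count / (length/10³) / (library/10⁶). Clustering uses
1 − Pearson distance with average linkage by default — the common
Cluster-3.0-style configuration for expression heatmaps — with Euclidean
and complete/single linkage available; whether to cluster RPKM or
log₂(RPKM+1) is left to the caller (the transform is provided but off by
default). Constant rows are an error under correlation distance, named
per gene. Cuts yield exactly k groups with labels numbered in order of
first member appearance; published group letters (A–E, I–IV) are
presentation labels, so only group structure is reproduced.

## Synthetic data

`simulate_family` draws a random sense-codon ancestor per scheduled
duplication time T and evolves two copies independently for T·10⁶ years
under a uniform-rate Markov jump process: proposals at rate λ per
nucleotide site per year, stop-creating proposals rejected, synonymous
proposals always accepted, nonsynonymous accepted with probability equal
to the target Ka/Ks. Under this scheme E[Ks] = 2λT (verified to <5%
relative error over replicates) and the realized Ka/Ks tracks the target.
Pairs alternate tandem/segmental layout so both classifier branches are
exercised, and segmental pairs ship covering blocks. The process has no
indels, no rate heterogeneity and no codon-usage bias, so passing
recovery tests demonstrates correctness of the estimators, not robustness
to real-sequence complications.

`simulate_snp_panel` draws binomial allele counts (17 wild / 14
cultivated, matching the study panels): planted reversal sites put the
wild major-allele frequency at 0.5 + contrast/2 and the cultivar
frequency of that allele at 0.5 − contrast/2; null sites share one major
frequency (default 0.7) in both panels, making the null positive rate of
the classifier analytically computable from binomial sign distributions.
Sites are unlinked, so haplotype structure is not represented here — the
haplotype counter takes explicit haplotype strings instead.

`simulate_expression` plants contiguous tissue-specific blocks (default
5 clusters across 14 conditions, signal 20× baseline, lognormal
multiplicative noise σ = 0.2) and 34 all-zero rows among 69 genes,
mirroring the 35-of-69 expressed structure of the study; at zero noise
the planted partition is exactly recoverable.

## Problem sizes and determinism

All generators are seed-deterministic (NumPy `default_rng`). The recovery
suites use 50 replicates of 500 codons for Ka/Ks, 10,000 sites for the
selection null rate, and 4–12-leaf trees for NJ — sizes at which the
Monte-Carlo error is comfortably inside the asserted tolerances and the
whole suite runs in seconds. Pipeline reports are byte-identical for a
fixed configuration and seed.

## Known limitations

Family identification itself (homolog search, domain confirmation),
multiple-alignment construction, synteny-block discovery and motif
analysis are out of scope: aligned sequences, blocks, and the family
table are inputs. The printed Ka/Ks values of the real pairs cannot be
recomputed exactly because the underlying paralog sequences were not
published; the pair-table checks therefore verify the printed arithmetic
(ratio and dating columns, aggregates), while estimator correctness is
established on synthetic sequences with known divergence.
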