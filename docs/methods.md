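# Methods

## The data model

Sleeping Beauty transposons integrate into TA dinucleotides, so an
insertion is identified by `(contig, TA position, orientation)`; the two
integration orientations at one TA are distinct mutational events (they
differ mechanistically — activating vs disrupting — depending on the
transposon's internal elements) but collapse to a single coordinate for
gene annotation and co-occurrence analysis, where only the locus
matters. A cell's genotype is a map from insertion sites to supporting
read counts; a sample is the QC-passed cell collection plus the union of
their qualifying sites (the *nonredundant site set*).

## Read processing

Read 1 carries the 16-base cell barcode at its start; read 2 carries the
transposon tag (inverted-repeat end) followed by genomic flank beginning
at the junction TA. Processing rejects read pairs with a short read 1,
without a tag hit (≤ 1 mismatch within the first 5 bases of read 2,
both configurable), without a unique full-length exact genomic
placement, or without a TA within ±2 bases of the junction coordinate.
Every rejection is counted by reason; kept + rejected always equals the
input pair count.

Mapping is exact k-mer seeding (k = 20) with full-length verification
rather than a wrapped external aligner. The contract the downstream
compilation needs is *unique exact placement*; at desk scale this is
dependency-free and exactly invertible against the simulator. The
`GenomeIndex` class is the seam where an external aligner can be plugged
in for real libraries, where sequencing error and indels matter.
Orientation convention: `+` means the tag-to-genome junction reads into
increasing reference coordinates; the simulator and the read processor
share this convention, making round trips exact.

Barcode whitelist correction (unique ≤ 1-mismatch match) exists but is
off by default; the assay as modelled does not describe correction.

## QC filter

A site *qualifies* within a cell iff its read count exceeds 9 (i.e.
≥ 10 with the default threshold); a cell is kept iff it has ≥ 2
qualifying sites. The strict inequality is deliberate and
boundary-tested: a cell with two 9-read sites is removed, one with two
10-read sites is kept. Whether sub-threshold sites inside kept cells
are carried downstream is configurable; the default excludes them from
clustering and statistics (they remain visible in the audit layer),
since a site too weakly supported to qualify a cell is too weakly
supported to define a subclone.

## Subclone reconstruction

The adjacency matrix `M[i][j]` counts cells harbouring both site *i*
and site *j* (diagonal: cells harbouring *i*). It is computed as
`BᵀB` over the sparse cell–site incidence matrix, so symmetry and the
bound `M[i][j] ≤ min(M[i][i], M[j][j])` hold by construction.

Clustering uses average-linkage agglomeration on

    d(i, j) = 1 − M[i][j] / min(M[i][i], M[j][j])

with two guards: pairs supported by fewer than `min_support = 2` cells
are forced to d = 1 (a single cell carrying two private sites is not
evidence of a subclone), and clusters with fewer than
`min_cluster_sites = 2` sites are dissolved into a singleton pool (the
smallest observed subclone carries 2 sites). The tree is cut at
distance 0.5. The choice of distance, linkage and cut is this package's
own: the normalisation makes two sites that always co-occur sit at
d ≈ 0 regardless of subclone size, while sites from different (disjoint)
subclones sit at d = 1, so on clean data any cut in (0, 1) recovers the
planted partition exactly and the result is insensitive to the linkage
choice. All knobs are exposed.

Cell assignment labels each cell with the unique subclone whose site
set overlaps the cell's qualifying sites (≥ 1 site by default); cells
overlapping two or more subclones are flagged `MULTI` — the signature
of a droplet that captured two nuclei — rather than discarded; cells
overlapping none are `UNASSIGNED` (dominated by singleton cells with
private insertions). Driver annotation intersects each subclone's
annotated genes with a bulk-screen driver list (FDR ≤ 0.05, supplied as
TSV); annotation covers the gene body plus a 40 kb promoter window.

The promoter window is strand-aware and upstream-only by default (a
promoter lies upstream of the transcription start); a symmetric mode is
available (`upstream_only=False`) since the window convention is a
modelling choice, as is the window length. Gene models are single
intervals (one per gene, BED6 or GFF3 `gene` features); no
transcript-isoform resolution is attempted.

## Co-occurrence statistics

A co-occurrence event for genes (A, B) is a pair of *distinct* sites,
one annotated to each gene, present together in at least one cell. Each
unique site may contribute to at most one event, so a subclone of 500
related cells sharing the same two insertions yields one event, not
500. This rule is implemented as a maximum bipartite matching
(Hopcroft–Karp via scipy) on the graph whose edges join co-resident
site pairs: maximum matching is deterministic and order-independent,
unlike greedy pairing, which is nevertheless available as a
sensitivity toggle (`method="greedy"`). A site annotated to both genes
of a pair (overlapping loci) is never paired with itself.

The permutation null replaces each of the sample's S nonredundant
sites with a TA site drawn uniformly *without replacement* from the
reference TA index — a bijection, so distinct sites stay distinct and
the relabelled sample's cell–site incidence graph is isomorphic to the
original. The per-trial draws derive from `(seed, trial index)` so any
trial is reproducible in isolation. Implementation note: gene
membership of every TA site is precomputed once as a sparse
(TA sites × genes) matrix; a trial is then a row slice plus one sparse
matrix product, which makes 10 000 trials on thousands of cells a
matter of seconds. A rare degenerate case — the only "pair" in a cell
being a single site annotated to both genes — is detected and excluded
exactly.

Per pair: `c` = number of trials with ≥ 1 event, `p_raw = c / N`
(reported as the bound `1/N` and flagged when c = 0), `p_adj` =
Benjamini–Hochberg step-up over all evaluated pairs within the sample
(statsmodels implementation behind the `bh_adjust` surface;
cross-checked in tests against an independent hand-written step-up),
and `p_est = p_adj ** k` for k observed events — the estimated
probability of k independent events each having adjusted probability
`p_adj`, an identity for k = 1. `p_est` is computed from the unrounded
`p_adj`; 3-significant-figure rounding is applied only for reporting.

Pairs are *recurrent* if they show k ≥ 2 in one sample or k ≥ 1 in two
or more samples. The gene universe for annotation and testing is an
input (pair list or gene models); the package does not re-derive it.

## The simulator

The generator emulates the structure the pipeline is designed to
recover, with defaults set to the observed tumour architecture:

| parameter | default | meaning |
|---|---|---|
| `genome_length` / `n_contigs` | 600 kb / 3 | synthetic reference |
| `ta_enrichment` | 0.05 /base | TA-site density (AT-rich mammalian-like) |
| `n_subclones` | 6–16 | planted subclones per sample |
| `sites_per_subclone` | 2–84 | disjoint TA sites per subclone |
| `cells_per_subclone` | 19–1250 | cells carrying the full site set |
| `singleton_cell_rate` | 0.08 | cells with unique never-reused sites |
| `doublet_rate` | 0.02 | barcodes merging two subclones' sites |
| `reads_per_site_mean`/`_shape` | 30 / 10 | negative-binomial read counts |
| `junk_read_rate` | 0 | tagless reads mixed into the FASTQ |

The genome is built from dinucleotide blocks (TA with probability
2 × density, otherwise a non-TA block that never starts with A), so no
TA can form across a block boundary and the density is exact in
expectation. Read counts are negative-binomial (mean/shape
parametrisation) to mimic overdispersed PCR amplification and to let
tests place counts on either side of the >9-read QC threshold; no
published depth distribution exists for this assay, so the defaults are
stated here as modelling choices, not measurements. Sequencing error is
an optional uniform substitution rate; PCR chimeras, ambient
contamination and barcode collisions across samples are *not*
modelled. Consequently, passing recovery tests demonstrates the
correctness of the algorithms under the generative model, not
robustness to every artefact of real libraries.

Everything derives from one mandatory seed (split into independent
streams for genome, planting and read emission); outputs are
byte-identical across runs.

## Test problem sizes and numerical choices

- Subclone-recovery tests run 20 seeded simulations in the full
  architecture regime (6–16 subclones, 2–84 sites, 19–1250 cells;
  ~10 000 cells and ~2 500 sites per sample) at the profile level, and
  one reduced-regime run (6–8 subclones, ≤ 30 cells each, fixed
  12-read depth, 5% junk reads) through the complete FASTQ path. Junk
  reads as modelled lack the transposon tag, so the read processor
  removes them; the reduced run verifies that removal end to end.
- Null calibration uses 200 disjoint gene pairs on a 1 Mb genome
  (~50 000 TA sites), 625 cells × 4 sites, 2 000 trials. Because the
  single-co-occurrence rate is a property of the null alone, calibration
  is assessed on the Monte-Carlo tail probability of the *observed*
  event count, P(k_null ≥ k_obs), which coincides with `p_raw` in the
  dominant k_obs = 1 case.
- Matching event counts are verified against exhaustive enumeration on
  100 random bipartite instances with ≤ 6 sites per gene; BH against an
  independent step-up; the TA index against a character scan; the
  annotation index against brute-force interval membership.
- Ties and degenerate inputs: site ordering is lexicographic
  `(contig, position, orientation)` everywhere a deterministic order is
  needed; a sample with a single site yields one trivial cluster or the
  pool depending on `min_cluster_sites`; an empty BH family returns an
  empty result; `c = 0` permutation counts are reported as bounds, never
  as zero p-values.

## Known limitations

- The mapper requires unique exact full-length placement; real reads
  with errors or repeats need an external aligner behind `GenomeIndex`.
- One interval per gene; no isoform-aware promoter placement.
- Subclones are recovered as flat disjoint clusters; no phylogenetic
  ordering or timing of subclone emergence is attempted (the assay
  cannot support it — mutagenesis is ongoing throughout the experiment).
- The permutation null draws TA sites uniformly; real integration has
  mild local biases (chromatin, expression) that uniform replacement
  does not model.
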