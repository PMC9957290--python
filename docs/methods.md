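# Methods

This note records the statistical model, the conventions that could have
been chosen otherwise, and what the synthetic benchmark does and does not
demonstrate.

## Data model and filters

All coordinates are 1-based inclusive end to end — base pairs on the
genome (GFF3 convention) and amino acids on proteins (HMMER envelope
convention). Inter-gene distances are computed in exactly one place
(`genomic_context.gap_bp`) to prevent convention drift.

Record-level filters mirror common metagenome practice:

* contigs shorter than `min_contig_len` (default **500 bp**, boundary
  inclusive) are removed — short contigs carry unreliable gene calls;
* genes classified as eukaryotic are removed; classification may sit on
  the gene or its contig, and a gene-level record overrides a contig-level
  one because finer evidence wins. Genes with no record at either level
  are retained and counted as unclassified. The original analyses this
  package generalises do not say whether eukaryote removal acted on genes
  or contigs, so both are supported under this precedence rule;
* domain hits with independent E-value above `max_i_evalue` (default
  **1e-5**) are dropped. Profile-specific gathering cutoffs are the ideal,
  but they are model metadata not shipped with hit tables; a single
  configurable threshold is used instead and the value is always logged.

Pooled samples carry a flag; they are included by default and excluded
with `--exclude-pooled`.

## Architectures

Overlapping hits on one protein are resolved greedily: hits are taken in
descending bit-score order (ties: lower envelope start, then lexicographic
accession) and a hit is discarded when its envelope overlaps an
already-kept hit by more than 50% of the shorter envelope. Greedy can, in
principle, differ from the score-optimal keep-set (a strong middle hit can
block two flanks worth more together); the test suite documents such a
case and verifies that on random instances greedy is valid, score-bounded
by the exhaustive optimum, and equal to it in the large majority of cases.
Determinism matters more here than squeezing out the last bit score.

The architecture string is the env-start-ordered list of lowercase Pfam
accessions joined with underscores. Three deliberate conventions:

* the N/C-terminal companion split is anchored at the **first**
  target-domain copy; companions interleaved between target copies count
  as C-terminal. One consistent rule, applied everywhere;
* signal peptides and TMDs are overlay classifiers (the localization
  class: none / sp_only / tmd_only / both), never part of the string;
* unknown companion accessions stay in the string labelled `unmapped` —
  dropping them would silently merge distinct architectures.

Two published definitions of a "diverse" architecture coexist: more than
one domain of any family (**results**, the default), or more than one
domain or any SP/TMD (**methods**). Both are implemented; neither is
presumed the authors' final intent.

A protein with more than four TMDs is flagged with a warning but kept:
such counts are rare among ice-binding proteins and usually indicate a
mis-joined gene call.

## Abundance and prevalence

RPKM is `reads / (length_bp/1000) / (total_mapped_reads/1e6)`, with the
per-sample denominator taken from the sample metadata
(`total_mapped_reads` by default; the column is configurable because the
choice between raw, filtered and assembled read totals is not pinned down
by convention). RPKM is summed across samples per architecture with no
between-sample renormalization. Abundance (share of grand-total RPKM) and
prevalence (share of gene count) are computed over **all** architectures,
so emitted subsets never distort the denominators; ranking uses full
precision and rounding to two decimals happens only at rendering.

## Genomic context

Upstream/downstream is strand-aware relative to the target gene — a
minus-strand gene's upstream neighbour lies at higher coordinates.
`--no-strand` restores pure coordinate order for sensitivity checks, since
published neighbourhood percentages do not state their convention.
Distance is the inter-gene gap exclusive of both genes (abutting = 0;
overlapping gene calls floored at 0). Flanking-frequency percentages are
reported over non-edge slots, and — because the right denominator is a
judgement call — also over all slots including contig edges. Neighbours
with no Pfam hits form an explicit "(no domain)" class. Tandem clusters
are maximal runs of target genes with at most `max_intervening`
(default 0) non-target genes between consecutive members.

## Community statistics

Composition tables are samples × taxa at a chosen rank (counts or RPKM).
Bray–Curtis runs on proportion-closed rows by default (vegan convention;
closure makes the result invariant to uniform row scaling); Euclidean and
Jaccard are available. PERMANOVA is the one-way distance-based
formulation:

    SS_total  = (1/n) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²_ij
    pseudo-F  = (SS_between/(a−1)) / (SS_within/(n−a))

with `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)` over
whole-sample label permutations. The default is 999 permutations with
seed 20200213; any seed is accepted and always recorded in the result.
Because Bray–Curtis is semimetric, SS_between can dip slightly below zero
under the null; R² (and pseudo-F) are then reported as computed rather
than clamped. Only the single-factor design is provided — no strata or
nesting — matching how such survey comparisons are usually reported.

## Trees

Alignment, trimming and inference are external (MUSCLE/TrimAl/FastTree or
equivalents): the package writes their input — one FASTA record per
retained target-domain envelope, id `gene/env_start-env_end`, so
multi-copy proteins contribute one sequence per copy — and consumes their
newick output. Nothing in those steps is project-specific, including the
trimmer's column-quality criterion, which is left to the external tool's
configuration.

Rooting: trees with fewer than 60 leaves, or with no outgroup available
(as is the case for multi-copy-architecture trees), are midpoint-rooted;
larger trees are rooted on the edge subtending the smallest clade
containing all outgroup leaves, with the root placed mid-edge. The
outgroup need not be monophyletic — the smallest spanning clade is used
and a warning emitted. Midpoint rooting delegates to dendropy after
verifying it preserves total branch length and the leaf-to-leaf path
matrix and balances root-adjacent depths to 1e-9; a guard makes it
idempotent when the root already sits at the midpoint (where dendropy's
rerooter misbehaves). The intended outgroup in practice is a set of
dinoflagellate IBP sequences; a placeholder id list stands in for it and
sequences are not bundled.

iTOL export writes one dataset file per ring: colour strips for
environment (greyscale, interior ice darkest), localization, phylum,
order and architecture class, and a simple bar chart for RPKM. Closed
vocabularies use shipped colour maps; open ones take a fixed qualitative
palette in sorted category order, so colour assignment is deterministic.
Missing annotations get an explicit white "unknown" entry.

## Synthetic data: what it emulates, and what passing means

The generator plants, per gene: target status (with a tandem-continuation
probability so adjacent target runs occur), an architecture drawn from a
configurable spectrum, SP/TMD flags, order-level taxonomy, and a
negative-binomial read count with mean
`base_read_rate · length_kb · enrichment[environment]` for target genes.
Defaults are study-like, chosen once:

| parameter | default | rationale |
|---|---|---|
| samples per environment | 4 / 3 / 6 / 2 (interior ice / interface / epipelagic / meso-bathy) | the survey's sampling design |
| architecture spectrum | 70% single, 12% double, 5% +DUF4842, 5% +PEP C-term, 3% triple, 5% +REJ | gross published prevalences |
| p(SP) per architecture | 0.40–0.58 | published per-architecture SP rates |
| enrichment | 40 / 8 / 1 / 0.2 | reproduces interior-ice dominance of target RPKM; only the qualitative ordering is published, the factors are this package's choice |
| read total per sample | 1e6 (fixed) | makes E[RPKM per target gene] = base_rate · enrichment, a closed form for environment shares |
| NB size | 5 | moderate overdispersion typical of per-gene counts |
| tandem continuation rate | 0.30 | produces multi-gene clusters at a testable rate |

Decoy rows exercise the machinery without touching the truth: fully
overlapped duplicate hits at half score (removed by overlap resolution)
and spurious hits at i-E-value 1.0 (removed by the threshold). Eukaryotic
contigs and sub-500-bp contigs are planted to exercise the filters and
never carry target genes.

Protein sequences are random strings with planted envelopes, and read
counts are emitted as if mapping had already happened. Passing the
recovery suite therefore shows the bookkeeping is exact — architecture
spectra, topology flags and tandem clusters are recovered perfectly, and
RPKM shares match their closed form within sampling error — but says
nothing about upstream annotation quality (HMM sensitivity, gene-call
accuracy, taxonomy assignment), which real data inherit from external
tools.

Default problem sizes (15 samples, ~100 contigs, ~1000 genes; the fixed
recovery benchmark uses 50 contigs / 500 genes / 5 samples) keep every
suite fast while leaving dozens of target genes per run.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng(seed)`; iteration
orders are sorted; result tables are written with 6-significant-figure
reals and a provenance header carrying a hash of the analysis
configuration (output paths excluded, so rerunning into a different
directory is byte-identical). Percent tables are computed at full
precision; ties in abundance ranking break lexicographically by
architecture string.

## Known limitations

* No TPM or other normalizations — RPKM only, matching the accounting it
  reproduces.
* One-way PERMANOVA only; no NMDS ordination.
* The genomic-context stage only sees genes inside MAGs, by design; the
  tandem-cluster function itself works on any contig.
* The function map ships the accessions appearing in the abundant
  architectures; anything else is reported as `unmapped` rather than
  resolved against a live Pfam/InterPro service.
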