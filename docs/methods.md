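# Methods

This note records the models, conventions and numerical choices behind
`clonoverge`, and what the simulator-based validation does and does not show
about real data.

## Sequence conventions

Junctions are handled **anchor-inclusive** (the IMGT "junction" sense):
CDR3 plus the conserved Cys codon on the V side and the conserved Phe/Trp
codon on the J side. A germline V segment contributes
`seq_nt[anchor_offset:]` to a junction and a J segment
`seq_nt[:anchor_offset+3]`, with `anchor_offset` 0-based at the first
nucleotide of the anchor codon. `decompose_junction(..., convention="cdr3")`
accepts anchor-stripped inputs by trimming one codon from each germline
region before matching. Sequences are upper-cased on input; IUPAC ambiguity
codes are rejected rather than expanded, since the data model is strict
A/C/G/T.

## Cell identity, merging and chain assembly

A cell is the pair `(sample_id, barcode)`, rendered `"sample:barcode"`, so
identical raw barcodes in different pooled samples remain distinct cells.
Merging is a provenance-preserving concatenation (duplicate sample ids are an
error) with a left-join of optional per-cell labels.

Non-productive contigs are read losslessly and excluded only at assembly.
Per cell and chain, the productive contig with most UMIs is retained; ties
break by read count, then lexicographically smallest junction. Cells with
several productive contigs on one chain are kept but flagged
(`multi_tra`/`multi_trb`) so reports can exclude them. Clonotype calling is
strict-paired: cells need both chains; single-chain cells are counted and
dropped (a single-chain mode is deliberately not implemented, because both
grouping definitions below reference both chains).

## Clonotypes, TCR types, ranking

The clonotype key is, by default, V/J (and TRB D) gene calls plus both
junction nucleotide sequences (`key_policy="genes+nt"`), matching upstream
caller conventions; `"nt"` restricts the key to the junction pair, since the
mRNA-level definition is ambiguous about gene calls. The TCR-type key is
amino-acid-only — gene usage across member clonotypes is *reported*
(`gene_concordant`) but never part of the grouping, so convergence of gene
combinations is an observable outcome, not an assumption.

Types are ranked by cell count, ties by clonotype count, then amino-acid key;
rank 1 is the dominant type. All orderings in the package (ids, ranks,
tie-breaks) are total, so outputs are permutation-invariant and reproducible.

## Junction decomposition

The decomposition is a deterministic maximal-attribution labeling, not a
probabilistic reconstruction of the rearrangement:

1. **V part** — longest common prefix of the junction with the germline V
   junction region (trimming only removes 3' nucleotides, so a trimmed V is
   always a prefix of the untrimmed region).
2. **J part** — longest common suffix of the remainder with the germline J
   junction region. V takes precedence over J when the two could overlap.
3. **D part** (TRB) — longest contiguous exact match of the middle segment to
   any candidate D segment, at least `min_d_match` nucleotides (default 3:
   mouse TRB D segments are 12–14 nt and shorter matches are statistically
   indistinguishable from N nucleotides). Ties break 5'-most in the
   junction, then candidate id, then 5'-most within the D segment.
4. **P parts** — assigned greedily (longest first, up to `max_p`, default 2,
   the biological convention) wherever the adjacent germline end is untrimmed
   and the nucleotides equal the reverse complement of that end. D is
   attributed before P so a chance palindromic read of a D edge can never
   shorten the maximal D match. When a single nucleotide could read either
   as N or as a 1-nt palindrome of an untrimmed end, the greedy rule labels
   it P; the distinction does not move any germline boundary.
5. Everything left is N1/N2.

The concatenation of parts always reconstructs the input exactly (asserted on
construction). The same objective — lexicographically maximal
`(v_len, j_len, d_len)` — is enforced independently in the test suite by a
brute-force enumeration oracle over all attributions; the greedy algorithm
attains that optimum by construction, and the tests verify it does.

Degenerate inputs: junctions shorter than two codons are rejected; a junction
with no germline overlap at all is returned with zero-length V/J parts and
warning flags rather than an error, since such contigs do occur in real
caller output.

## Hashtag model and demultiplexing

Normalization follows the count transform
`value = log2((count+1)/g + 1)` with `g` the per-cell geometric mean of
`count+1` across hashtag features. The ratio is computed as the exponential
of mean-centered logs, so equal counts yield exactly 1.0 in floating point.
The assignment rule (margin `δ`, default 1.0 log2 units; floor, default 2.0)
is a transparent, fully configurable stand-in: the classifier used in the
original processing environment is proprietary and unpublished, so any
re-implementation must choose an explicit rule; this one makes the
multiplet/ambiguous boundary auditable.

QC keeps cells with `total_counts <= 30000` and `mito_pct <= 30` by default.
The count threshold reads naturally in either direction in prose, so
`counts_direction="ge"` supports the opposite retention reading without code
change; neither is asserted as the original intent.

## The simulator

The generator emulates the pooled study design end-to-end: 4 control + 4
tumor-bearing mice, each contributing cells to a GFP+ and a GFP− compartment
pool, four pooled samples in total, hashtags carrying mouse identity within
each pool.

**Recombination model.** Segments drawn uniformly from the germline set;
trim lengths from a truncated geometric on `0..max_trim` (default max 4,
continuation 0.05); P additions with probability 0.5 per untrimmed end,
length uniform on `1..max_p`; N-insertion lengths Poisson(`lambda_n`,
default 4) with uniform nucleotides. Productive events are obtained by
rejection (in-frame, stop-free; bounded attempts). The sparse default trim
law is a deliberate identifiability choice: each trimmed boundary has a
1-in-4 chance per nucleotide that an adjacent non-templated nucleotide
mimics germline, which makes ground-truth boundaries unrecoverable in
principle; keeping most ends untrimmed keeps the decomposition benchmark
interpretable (recovery stays above 90% overall, and is exact wherever the
enumeration oracle admits a unique truth-attaining optimum). Real
repertoires trim more aggressively; heavier trim laws are one config field
away but degrade boundary identifiability, not reconstruction.

**Convergent spikes.** A planted TCR type holds the TRA event and all TRB
segment/trim/P choices fixed and resamples the TRB N-region nucleotides
uniformly over the set consistent with the reference amino-acid sequence
(per-codon enumeration of the free positions). This is exact conditional
sampling of the synonymous-variant space — whole-event rejection until amino
acids coincide has acceptance probability well below 1e-4 and was rejected as
a mechanism. The support size is computed exactly; configurations whose
support cannot host the requested variant count fail with an error (longer N
insertions enlarge the support). Variants therefore differ only at
non-templated positions, which is also where real convergent clonotypes
differ most.

**Clonal structure.** Cell-to-clone assignment follows a rank-size power law
(`weight ∝ rank^-alpha`, default α = 1.2, a typical expanded-repertoire
slope); ~30% of background clones are shared between conditions, the rest
split evenly; spiked clones are tumor-condition-only with high GFP
enrichment (0.85 vs 0.15 background) and a dedicated cluster label, so
compartment-composition reports have signal to find. Background clones are
rejection-sampled to have pairwise-distinct nucleotide *and* amino-acid
keys, so the planted spike is the only convergent type by construction.

**Doublets.** Planted doublets merge two cells of *different* mice within a
pooled sample: their hashtag profiles add, and the barcode carries both
cells' contigs with the primary cell's UMI counts strictly higher.
Same-mouse doublets are invisible to hashtag demultiplexing by construction
and are not planted; the simulator's "multiplet" ground truth is therefore
the detectable class. Hashtag counts are negative binomial (signal mean 200,
background mean 2, dispersion 10 — a transparent stand-in, as no count model
is published for the assay).

**What passing does not show.** The simulator draws uniform segment usage,
has no sequencing error, no UMI collisions, no allele-level gene calls, no
chimeric contigs beyond planted doublets, and its germline is synthetic.
Exact clonotype recovery on simulated bundles validates the bookkeeping
(namespacing, pairing, key policies, grouping) and the decomposition
algorithm against its stated objective — not concordance with any particular
annotation service's junction labels on real data, which additionally depend
on germline reference versions and undocumented heuristics.

## Problem sizes

Default verification scale: ~2,000 simulated cells (50 background clones +
one 5-variant spike, 8 mice × 250 cells), 1,000 junctions for the
decomposition benchmark, 500 singlets + 50 doublets for demultiplexing, and
all 2×2 tables with margins ≤ 8 for the exact test. These sizes give
sub-minute stages (the enumeration oracle dominates at ~20 s) while keeping
every stochastic check many standard errors away from its threshold.

## Exact 2×2 test

`fisher_exact_2x2` delegates to `scipy.stats.fisher_exact` (two-sided); the
test suite cross-checks every small-margin table against an independent full
hypergeometric enumeration, so the scipy route and the enumeration
definition are verified to coincide on the regime the reports use.
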