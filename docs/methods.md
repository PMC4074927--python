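# Methods

## Model and procedure

A genome is treated as a string over {A, C, G, T}. The pipeline is:

1. **Cleaning.** Lowercase bases are uppercased; every other character
   (N runs, IUPAC ambiguity codes, gaps, whitespace) is deleted and counted.
   Deleting — rather than masking whole blocks — keeps the number of blocks
   maximal, preserves base order, and guarantees each block holds exactly
   `B` informative bases. Multi-record FASTA files are concatenated in file
   order into one genome by default (one distribution per organism); a flag
   keeps records separate. Sequences are used as given, with no
   reverse-complement canonicalization: under Chargaff's second parity rule
   the block-entropy distribution is approximately strand-symmetric anyway.
2. **Blocking.** Consecutive, non-overlapping windows of `B` nucleotides
   (default 100); the trailing remainder shorter than `B` is discarded and
   recorded, never padded, because the plug-in entropy of a shorter block is
   not on the same scale. Block `i` covers positions `[iB, (i+1)B)` in
   0-based half-open coordinates.
3. **Block entropy.** The plug-in Shannon estimator over the four base
   frequencies of the block, in bits (0·log 0 := 0). No small-sample bias
   correction is applied in the method path; the estimator's first-order
   bias at uniform composition, `3/(2B ln 2)` ≈ 0.0216 bits at `B = 100`,
   is used in tests as an independent check of the generator + estimator
   combination.
4. **Histogram.** Block entropies are collected into `M` equally spaced bins
   (default 64) over the fixed support [0, 2] bits — the full possible range
   of four-letter block entropy — and normalized to a probability vector.
   Bins are left-closed right-open, the last bin closed so 2.0 is counted.
   A fixed global support, rather than each genome's observed range, makes
   bins identical across genomes by construction, which the Jensen-Shannon
   comparison requires; distance computation refuses mismatched binnings
   rather than silently rebinning. Values outside a user-narrowed range are
   an error, not silently dropped.
5. **Superinformation.** `H_s = −Σ p_j log₂ p_j`, bounded by `log₂ M`.
   `H_s` depends on both `B` and `M`, so it is only meaningful — and only
   reported — together with that context.
6. **Distances.** `D_KL(p‖m) = Σ p_j log₂(p_j/m_j)` with zero-probability
   bins contributing nothing and support violations raised as errors;
   `D_JS` via the equal-weight mixture `m = (p+q)/2`, always finite and ≤ 1
   bit; the clustering distance is `d = √D_JS`, which satisfies the triangle
   inequality (the raw divergence is available behind a flag for
   comparison).
7. **Clustering.** UPGMA by default: an ultrametric dendrogram whose merge
   heights are average inter-cluster distances; leaf-to-root depth is half
   the final merge height. Complete and single linkage, and neighbor joining
   (emitted unrooted) are selectable. Labels are sorted lexicographically
   before linkage, so input order never affects the tree and ties break
   deterministically across platforms. Trees serialize to Newick with
   branch lengths (labels quoted when they contain metacharacters); an
   hclust-style merge table is exported for the linkage methods.

## Parameters

| parameter | default | units | notes |
| --- | --- | --- | --- |
| `B` (block size) | 100 | nt | resolution of local entropy; small enough to sit far below isochore scale, large enough that per-block frequency estimates are stable. The `sweep` command recomputes results over {50, 100, 150, 200}: at 50 the histograms fluctuate strongly, from 100 upward they stabilize. |
| `M` (bins) | 64 | — | balances resolution against per-bin sampling noise for the few-thousand-block genomes (hundreds of kb at `B`=100) this method targets. `H_s` values are only comparable at equal `M`; no automatic bin-width selection is attempted. |
| bin range | [0, 2] | bits | full possible range; shared across genomes. |
| metric | `sqrt_js` | — | `raw_js` available for comparison; only the square root is a metric. |
| linkage | `average` | — | the distance matrix is ultrametric-like when groups are well separated, which UPGMA renders as a dendrogram with distance-proportional branch lengths. |

## Synthetic data

The generator emulates the one feature the method can see: block-wise
nucleotide composition varying along the sequence. A genome is a chain of
segments (default 1,000 nt, deliberately decoupled from `B` so blocks
straddle segment boundaries); each segment draws a GC fraction from a
regime — fixed, Beta(α, β), or a two-point mixture — and emits bases
i.i.d. with p(C) = p(G) = gc/2 and p(A) = p(T) = (1−gc)/2, optionally
skewed within each pair. Narrow regimes produce tight unimodal
entropy histograms (virus-like); wide or well-separated two-point regimes
produce broad or bimodal ones (organism-like). Per-genome seeds derive from
(master seed, group index, genome index) via numpy's `SeedSequence`
(`simulate.derive_seed`), so any cohort member regenerates in isolation.

What the generator does **not** emulate: genes, codon structure, introns,
repeats, dinucleotide correlations, megabase-scale isochores. Since the
method reduces every block to its base counts, first-order structure
suffices to exercise every code path — but passing tests on synthetic
cohorts demonstrate the pipeline's correctness and discriminative behavior
under its own model, not biological conclusions about real genomes.

For the three-group cohort used in the end-to-end clade-recovery check, the
two "virus-like" groups use fixed GC 0.40 and 0.43 with a wide Beta(2,2)
"organism-like" group. The narrow regimes are placed close together
deliberately: real phycodnavirus genomes cluster near 40% GC, and narrow
regimes with widely separated GC produce nearly disjoint histograms whose
JS distances saturate, leaving no contrast between "different narrow group"
and "wide group". Cohort sizes (2 genomes per group, 500 kb each, `B`=100,
`M`=64) keep the full pipeline run in seconds while leaving between- versus
within-group distance gaps of an order of magnitude.

## Numerical choices

- Entropies are computed vectorized over a (blocks × 4) count matrix; a
  per-block scalar path (`block_entropy`) exists for inspection and is
  tested equal to the vectorized path to 1e-12.
- `-0.0` entropies are normalized to `+0.0`.
- Histogramming uses `numpy.histogram`, whose equal-width bin convention is
  exactly the left-closed/last-closed rule above.
- KL support violations and unnormalized inputs raise; nothing returns
  infinity. `√D_JS` clamps tiny negative round-off at zero.
- Neighbor joining can produce slightly negative branch lengths; these are
  clamped to zero on output.
- CLI outputs print numbers with fixed 6-decimal formatting and start with
  comment headers recording version, parameters and input digests, making
  repeated runs byte-identical and diffable. The PHYLIP export carries the
  same 6-decimal precision, so trees rebuilt from an exported matrix agree
  with the direct pipeline to ~1e-6, not bit-for-bit.

## Known limitations

- `H_s` is not comparable across different `M` or `B`; the tool refuses to
  mix binnings but cannot detect values imported from elsewhere.
- Entropy collapses complement pairs (a 30% GC block and a 70% GC block have
  equal entropy), so regimes symmetric about GC 0.5 are indistinguishable in
  the histogram; this is a property of the method, not the implementation.
- Blocks are non-overlapping; no sliding-window variant is provided.
- Only single-nucleotide (order-1) composition is used; k-mer entropies are
  out of scope.
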