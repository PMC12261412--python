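# Methods

## The procedure

`promsa` builds a multiple sequence alignment progressively: groups of
already-aligned sequences are pairwise-aligned in guide-tree order, leaves
to root, with each group represented by its profile rather than its rows.
A run consists of:

1. **Tree preparation.** The Newick guide tree is parsed (polytomies
   allowed); multifurcations are resolved into random cherries with a
   seeded generator, so runs are reproducible. If any edge lacks a branch
   length the tree is treated as having uniform lengths. When no tree is
   supplied, a rough one is estimated from pairwise `1 − cosine` distances
   of k-mer count vectors (k = 12) via neighbor joining — adequate for
   ordering progressive merges, not for phylogenetic inference.
2. **Weights.** Each leaf accumulates, over the edges on its root path,
   edge length divided by the number of leaves below the edge, then weights
   are rescaled to mean 1. Mean-1 normalization keeps profile scores on the
   substitution-matrix scale regardless of group size, which matters
   because the X-drop threshold and gap penalties are absolute score
   quantities. Raw weights are floored at `1e-6 ×` the mean positive weight
   so zero-length pendant paths cannot yield non-positive weights.
3. **Scheduling.** Leaves get order 0; each internal node one more than its
   deepest child. All nodes of one order are mutually independent (they
   share no profiles), so they may be aligned concurrently; this
   implementation runs them sequentially, and the identical-result contract
   is what the determinism tests pin down.
4. **Gappy-column excision.** Before each pairwise profile alignment,
   columns whose gap fraction strictly exceeds the threshold (default 0.95;
   1.0 disables) are removed and recorded as runs anchored to the next
   retained column. After alignment they are restored: runs from both sides
   whose anchors are consumed in the same match column merge left-aligned
   (the excess pairs with new gaps); a run whose anchor is consumed by a
   gap operation is emitted against new gaps. Anchoring and left-alignment
   are implementation choices made for determinism; restoration is exact
   (an identity alignment round-trips the original profiles).
5. **Pairwise profile alignment** (below), applied between child profiles;
   the resulting per-side binary paths (`0` existing column, `1` new gap)
   are applied to the children's rows, and the parent profile is formed by
   expanding both child profiles with their paths and adding frequencies —
   never recomputed from rows (equality with recomputation is tested).
6. **Divide-and-conquer (optional).** With `--max-subtree m`, the tree is
   recursively split at the edge minimizing the larger component's leaf
   count (ties to the smaller preorder node id) until every subtree has at
   most `m` leaves. Subtree alignments are written to disk; the merge phase
   walks the skeleton using profiles and accumulated paths only, and the
   final file is assembled by streaming one subalignment at a time, so at
   no point are two subtrees' rows in memory together. Output order is
   subtree-major, input order within a subtree. `m` unset (the default) and
   `m ≥ n` take the same code path and produce byte-identical output; small
   `m` trades a little accuracy for memory, and only the integrity and
   width invariants are promised to be preserved.

## Scoring

Default matrix (nucleotide): +18 match, +5 transition (A↔G, C↔T), −8
transversion, −5 residue-vs-gap (including N-vs-gap), gap open −50, gap
extend −5. Two entries are not dictated by the above and were chosen to
keep the weighted column score well-behaved on gappy profiles: `s(N, x) = 0`
for non-gap `x`, and `s(-,-) = 0` (so shared gap columns neither attract
nor repel). A user matrix may override any subset of the 6×6 table; it must
be symmetric and cover at least A/C/G/T.

The column score is `ps(i,j) = (1/w_A w_B) Σ_p Σ_q f_{A,i,p} f_{B,j,q}
s(p,q)`. The DP recurrence is three-table affine:

    H(i,j) = max(H, I, D)(i-1,j-1) + ps(i,j)
    I(i,j) = max(H(i-1,j) + gop_{A,i},  I(i-1,j) + gep_{A,i})
    D(i,j) = max(H(i,j-1) + gop_{B,j},  D(i,j-1) + gep_{B,j})

Note the asymmetries that distinguish this from the textbook Gotoh
formulation: `H` is entered only diagonally, and a vertical gap cannot
immediately follow a horizontal one (`I` opens from `H` only, and vice
versa). With the default penalties the two formulations agree on
single-sequence profiles (adjacent opposite gaps are never optimal when a
mismatch plus savings beats two opens), which the suite cross-checks
against Biopython's pairwise aligner. Boundaries: `H(0,0)=0`,
`H(i,0)=I(i,0)`, `H(0,j)=D(0,j)`; the first row/column accrue
`gop + (k−1)·gep`. Every `max` breaks ties preferring H, then I, then D, so
tracebacks are deterministic.

Position-specific gap penalties (off by default): columns with any gap
frequency get `gop · 0.3 · (1 − gap fraction)` and `0.5 · gep`. Penalties
are computed on the *reduced* (post-excision) profiles seen by the DP.

## Banded and tiled DP

All three engines (`full`, `banded`, `tiled`) share one anti-diagonal
wavefront kernel and one precomputed `ps` matrix, so whenever the banded or
tiled variant completes, its score *and path* are bit-identical to the full
DP — equality, not approximation, is what the oracle-equivalence tests
assert. X-drop pruning drops cells scoring more than `xdrop` (default
600 × |gep| = 3000) below the running best; a single fully-dead wavefront
is tolerated because diagonal moves skip alternate anti-diagonals, two in a
row abort with `BAND_FAIL`.

The tiled engine bounds traceback memory: full pointers are stored only for
a window of `tile_size` wavefronts (default 512). Past the window's last
two wavefronts (the marker pair — a pair, because diagonal steps can jump
over any single wavefront), each live DP entry carries one convergence
pointer to the boundary entry its best path last crossed. When every live
pointer on the two current wavefronts agrees, the tile is traced back,
emitted, and the engine rewinds scoring to a snapshot of the marker pair
and replays forward with the next tile's pointers — recomputation, not
approximation, so results stay identical. Failure modes returning
`TILE_FAIL`: live band wider than `tile_size` (the analog of a bounded
wavefront on accelerator hardware), or no convergence within a tile's worth
of wavefronts. `align_with_fallback` then reruns the full DP, so the
pipeline always produces a result. Peak pointer storage is bounded by
roughly `2 · tile_size` wavefronts of at most `tile_size` cells —
independent of sequence length, which a test measures directly.

`BAND_FAIL`/`TILE_FAIL` are typed return values, not exceptions: the
orchestration falls back without unwinding.

## Synthetic data and metrics

The simulator evolves a random root sequence down the tree. Per branch of
length `b` (expected substitutions/site): each site substitutes with
probability `(3/4)(1 − e^{−4b/3})` (single-rate, uniform base frequencies);
the number of indel events is Poisson with mean `indel_rate · b · L`
(default 0.12 indels per substitution), split evenly between insertions and
deletions, with geometric lengths of mean 3. Every column ever created
carries a stable homology id threaded through a global column ordering, so
the true alignment is exact by construction, not inferred.

What this deliberately does **not** model: rate variation across sites,
GTR-style exchangeabilities, base-composition bias, structural or coding
constraints, and length-dependent indel placement. Passing recovery tests
therefore demonstrates that the aligner recovers homology under idealized
homogeneous evolution; performance on real data with heterogeneous rates
and long indels is not certified by this suite.

Sum-of-pairs error: a residue pair is "aligned" iff the two residues occupy
the same column; SPFP is the fraction of estimated pairs absent from the
truth, SPFN the fraction of true pairs missed, and the reported error is
their mean. Columns where one row has a gap contribute no pair — stated
explicitly because published tools differ on edge cases. The nRF distance
is the symmetric difference of nontrivial bipartitions over the total
nontrivial bipartitions of both trees (cross-checked against dendropy).

The scrambled control used by the recovery tests re-scatters each row's
residues independently over the alignment frame (residue order preserved).
Merely permuting whole columns would be a no-op for sum-of-pairs scoring,
since residue pairings are internal to columns.

## Defaults at a glance

| parameter | default | units / meaning |
|---|---|---|
| gappy threshold | 0.95 | excise columns with gap fraction strictly above |
| gap open / extend | −50 / −5 | score units |
| xdrop | 600 × \|gep\| = 3000 | score units below running best |
| tile size | 512 | wavefront cap and traceback window |
| max-subtree | unbounded | leaves per subtree in divide-and-conquer |
| psgp | off | position-specific gap penalties |
| fallback-tree k | 12 | k-mer size for guide-tree estimation |
| indel length mean | 3 | geometric, simulator |
| FASTA wrap | 60 | columns per line |

## Numerical and degenerate-input choices

- All engines consume one precomputed cell-score matrix (a single matrix
  product), so no engine sees differently-rounded `ps` values; DP additions
  are per-cell and identical across engines.
- Unreachable/pruned cells hold a −1e30 sentinel rather than −inf to keep
  arithmetic NaN-free.
- Profile conservation (columns sum to the total weight) is checked at
  1e−9 relative tolerance.
- Empty-vs-nonempty profile alignment is supported (single chain of gap
  ops); two empty profiles align with an empty path.
- A profile whose columns are *all* gappy is left intact rather than
  excised to nothing.
- Ambiguity codes other than N collapse to N on input; gapped input FASTA
  is rejected rather than silently degapped.
- Guide-tree/FASTA leaf-set mismatches are hard errors listing the
  difference; silent pruning would corrupt benchmark comparisons.

## Problem sizes used by the test suite

The acceptance layer runs, on one CPU: 200 random profile pairs (lengths
≤ 12) against independent oracles plus exhaustive path enumeration where
the path count permits (combined lengths ≤ 9); 50 end-to-end runs of
10–100 sequences × 100 sites across configuration combinations; exact
recovery of 10 substitution-only simulations (20 taxa × 500 sites); and a
3-seed recovery-vs-control battery at 50 taxa × 1000 sites with 0.12
indels per substitution. These sizes exercise every code path (banding,
tiling with fallback, excision, decomposition, merging) while keeping the
default suite a few minutes long.

## Known limitations

- Nucleotide alphabet only; no protein matrices.
- The gappy-column heuristic is a length/speed optimization, not an
  accuracy guarantee: at small depths excision can lengthen the output
  slightly (restored runs pairing with new gaps), and it only pays off
  when profiles deepen enough for >95%-gap columns to be common.
- The fallback guide tree is intentionally crude; for serious use supply a
  tree from a dedicated tool.
- The merge phase aligns profiles only; like all progressive methods,
  early errors are frozen — there is no iterative refinement loop.
- Execution is single-threaded; the schedule's level structure is where
  parallelism would attach.
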