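# Methods

## Model and procedure

The object of inference is the conditional distribution f(φ, ψ | c, 𝒳) of
backbone torsion angles of residues translated from codon c within
secondary-structure class 𝒳 ∈ {E, H}. The angles live on the torus
S¹ × S¹: each component wraps at ±180°, so all arithmetic (means,
distances, kernels) is wrap-aware. We make no parametric assumption about
f; it is estimated by kernel density estimation with a radial Gaussian
kernel applied to the torus distance and evaluated on a discrete
wrap-around grid. Distances between two codons' estimates are measured
with the L1 norm over grid cells, which for unit-mass densities lies in
[0, 2] (twice the total variation).

The two-sample question "do c and c′ share an underlying distribution?"
is answered by a permutation test on the KDE-L1 statistic. Observations
are pooled, re-split at the original sizes K times, and the statistic is
recomputed per split; with η the number of permuted statistics at least as
large as the base one, p = (1 + η)/(1 + K), bounded below by 1/(1 + K).
The test is one-sided: only a base distance larger than the permutation
null counts as evidence.

Sample-size bias is removed by equalization: within each synonymous group
and structure, every codon is estimated from N = min(N_max, min_c N_c)
observations. Abundant codons are still exploited via B bootstrap rounds
that re-draw N observations with replacement before each permutation
test; the aggregate p-value over all B·K permutations is
(1 + Σ_b η_b)/(1 + B·K). Self-pairs (c, c) are included as negative
controls and use two independent resamples of the same pool. All
hypotheses of one structure (148 for the full standard code: 61 self + 87
synonymous pairs) are corrected together with Benjamini–Hochberg at FDR
level q.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `bandwidth` | 2 | degrees | kernel SD used for every comparison; a single fixed value keeps KDEs of equal-size samples comparable without per-codon cross-validation |
| `grid_size` | 128 | bins/axis | bin width 360/128 = 2.8125° ≈ 2.8°, comparable to the kernel scale |
| `n_max` | 200 | observations | cap on the equalized sample size; keeps the permutation cost bounded |
| `b_test` | 25 | rounds | with `k_perm` = 200 gives 5000 permutations per p-value, floor 1/5001 |
| `k_perm` | 200 | permutations | per bootstrap round |
| `q` | 0.05 | — | FDR level |
| `tau` | 0.7 | — | redundancy cap on normalized pairwise sequence similarity |
| `b_plot` | 1000 | bootstraps | confidence bands of the contour plots, with band level α = 0.1 and mass levels λ ∈ {0.1, 0.5, 0.9} |
| `seed` | 0 | — | master seed; child streams are derived per (structure, pair) so individual pairs are independently re-runnable |

## Data pipeline

Backbone dihedrals are computed from N/CA/C coordinates
(φᵢ from C₍ᵢ₋₁₎–Nᵢ–CAᵢ–Cᵢ, ψᵢ from Nᵢ–CAᵢ–Cᵢ–N₍ᵢ₊₁₎); termini and chain
breaks (C–N distance > 2.5 Å, a standard practice threshold) leave the
affected angle undefined rather than raising. When several crystal chains
map to the same reference-sequence position, their angle pairs are
combined with the per-component circular mean (atan2 of summed sines and
cosines); an exactly antipodal configuration has no defined mean and the
position is dropped and counted. Codon and secondary-structure
annotations must be unanimous across contributing chains or they are
dropped and counted; every exclusion reason appears in the run report so
the pipeline is lossless in count.

Codon assignment translates every candidate coding sequence and aligns it
globally (Gotoh affine gaps, BLOSUM80, open −10, extend −0.5, terminal
gaps penalized) to the chain sequence. A residue keeps a codon only when
exactly one distinct codon is aligned to it with a matching amino acid;
distinct variants ⇒ AMBIGUOUS, none ⇒ UNASSIGNED. A codon aligned
against a substituted amino acid is not trusted (mismatch guard) — the
procedure's source is silent on this case, and discarding is the
conservative choice. Because chain-to-database index mapping via live
cross-references is out of scope, the command-line pipeline uses the
translation of the first usable coding sequence as the per-accession
reference frame and aligns each chain to it; this is the package's own
indexing choice and only affects bookkeeping, not the statistics.

Redundancy filtering aligns reference sequences with match score 1 and
all penalties 0 (the score then equals the longest-common-subsequence
length), normalizes s̃ᵢⱼ = sᵢⱼ/√(sᵢᵢsⱼⱼ), and runs a farthest-first
traversal from index 0 (configurable; the choice is arbitrary by design)
that stops when the next-selected sequence exceeds τ, guaranteeing the
retained set has max pairwise s̃ ≤ τ. Ties in the argmin take the lowest
index for determinism.

## Synthetic generator

The validation distribution is a product of independent per-axis von
Mises distributions with circular standard deviations 35° (φ) and 18°
(ψ), emulating the anisotropic spread of one secondary-structure mode.
The concentration κ is obtained by numerically inverting
sd = √(−2 ln(I₁(κ)/I₀(κ))) rather than the small-angle rule κ ≈ 1/sd²,
which is visibly biased at 35°. Rotations are applied along φ by default
(the choice of axis is configurable; the validation design does not
prescribe one). What the generator does **not** emulate: multi-modality
within a structure class, φ–ψ correlation, aggregation noise from
multi-chain averaging, or codon assignment errors — so passing synthetic
tests demonstrates the statistical machinery, not robustness to those
real-data features.

Ground-truth distances between generator specs evaluate the analytic
densities on the grid; L1 is the cell-wise sum, W2 is exact (entropic-free)
discrete optimal transport with squared torus distance as ground cost,
solved as a linear program on a grid coarsened to 16 bins/axis for
tractability.

The rotation-power experiment draws, per trial, two abundant pools
(20 × N observations) and applies the equalized-size bootstrap test at N.
The pool factor matters: see limitations below.

## Numerical choices

- Canonical angle interval is (−180, 180] (upper-closed), so the
  two-point circular mean crossing the seam yields +180, not −180.
- Grid points are bin left edges −180 + k·(360/grid_size); contour
  positions can shift by up to half a bin relative to a cell-center
  convention.
- The wrap-aware arc distance reduces differences mod 360 before the
  cosine, which makes whole-bin translations of a sample shift the KDE
  bit-identically.
- The radial kernel factorizes over the two axes per sample, so a KDE is
  a single matrix product of per-axis kernel factors; all N × grid²
  evaluations are exact (no truncation radius). Permutation tests reuse
  the pooled factors across all K splits.
- Super-level thresholds use the smallest-superset convention: τ is the
  largest value whose super-level set carries at least λ of the mass;
  tied cells at τ are all included.
- Confidence bands are the strict region α < mean-binary < 1 − α; a
  degenerate bootstrap (single observation) therefore has empty bands.
- In the MDS variant, negative squared target distances (possible with
  noisy inputs) are clamped to zero; classical Torgerson MDS with double
  centering recovers the locations. The target-distance expression is
  implemented in the form consistent with the generative derivation
  (subtracting the average of the two squared *self*-distances); the
  variant with d²(c,c′) inside the subtraction is available behind
  `literal_formula=True`.
- BH modes: `literal` applies the strict rule (reject p < α_M where α_M
  is the i₀-th sorted p-value), which excludes ties at the threshold
  including α_M itself; `textbook` rejects all ranks ≤ i₀. The strict
  rule is the default for fidelity to the published procedure.

## Test and validation problem sizes

The suite exercises the full machinery at desk scale: the 148-hypothesis
harness runs with B = 1, K = 5 on 20-observation codon samples; the null
calibration uses 200 trials of two independent N = 100 von Mises samples
with K = 200 (mean p ≈ 0.5); the power trend uses rotations {4°, 12°, 28°}
× N ∈ {50, 100, 200} × 10 trials with B = 2, K = 60. These sizes are the
package's chosen validation scale; the statistical defaults above are not
changed by them.

## Known limitations

- **Bootstrap duplicates bias cross-pair nulls when N approaches the pool
  size.** Resampling N observations with replacement from a pool of ~N
  creates duplicated points; under permutation the duplicates split
  across the two sides and systematically deflate the permuted statistic,
  so two *independent* samples from one distribution can reach the
  p-value floor. Self-pairs are immune (both sides resample the same
  pool symmetrically, p ≈ 0.5), which is why self-controls alone do not
  reveal the effect. The effect shrinks as pools grow relative to N
  (negligible by ~20 × N, the rotation experiment's pool factor). Users
  should read small cross-pair p-values cautiously for codons whose
  observation count is close to the equalized N.
- With the default 2° kernel and widely spread samples, a KDE is a
  collection of near-disjoint kernel islands; confidence-band *cell
  counts* then grow with N even though relative uncertainty shrinks. The
  "larger samples → narrower bands" behaviour manifests with kernels
  comparable to the feature scale.
- The literal BH rule can reject nothing when all significant p-values
  tie at the permutation floor (see README example).
- W2 ground truth is exact transport but on a coarsened (16²) grid;
  rotations that are not multiples of the coarse bin incur discretization
  error of a few degrees.
- The DSSP algorithm itself is not implemented; labels are consumed from
  DSSP output files or a plain table. Live database queries (structure
  search, cross-references) are out of scope; the documented quality
  gates (resolution ≤ 1.8 Å, R_free ≤ 0.24) are applied as metadata
  filters on user-supplied chain tables.
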