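# Methods

## Model

`rbpbind` frames protein-binding-region prediction as binary classification
of fixed-width RNA windows. The discriminative signal is positional: the
per-position mono-nucleotide log-odds profile (mPWM) and its di-nucleotide
counterpart (dPWM) contrast the k-mer frequencies of binding and
non-binding training sequences position by position, in natural-log units.
A sequence's profile blocks are simply its own log-odds terms read off the
matrices, so the classifier sees "how much does each position of this
sequence look like a binding site". Global composition blocks (mono-, di-
and tri-nucleotide frequencies) add translation-invariant sequence
character, and an optional 63-element CTD descriptor of the binding protein
(composition, transition and distribution over 7 physicochemical
amino-acid groups) conditions the model on the RBP. An RBF-kernel
soft-margin SVM separates the classes.

Key assumptions: binding regions can be represented by equal-length
windows (25 nt by default); positional preferences are shared across the
RBPs pooled into the training set; negatives drawn from genomic background
are genuinely non-binding; and features need no explicit interaction terms
beyond what the kernel supplies.

## Parameters

| parameter | default | meaning |
|---|---|---|
| window `w` | 25 nt | training-sequence length; profile width |
| pseudocount `alpha` | 1.0 | additive smoothing of positional counts |
| `C` | 32 | SVM soft-margin cost |
| `gamma` | 2⁻⁷ = 0.0078125 | RBF kernel width |
| feature scaling | on | per-feature linear map to [−1, 1], learned on training data |
| identity threshold | 0.8 | redundancy-removal cutoff |
| class ratios | 1:1 … 1:10 | negative multiplicity of constructed datasets |
| split | 70/30 | train / independent-test fraction |

`C` and `gamma` are the reference operating point; `grid_search` sweeps the
usual LIBSVM power-of-two grids (C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, exponent step
2) with stratified CV, breaking ties toward smaller C then smaller γ.

## Numerical and design choices

- **Smoothing.** Raw positional frequencies can be zero, which makes
  log-odds infinite. Counts are smoothed additively: freq(s, j) =
  (count + α) / (N + 4ᵏ·α), with the same α for both classes. This keeps
  the profile finite and exactly antisymmetric under class exchange
  (swapping positives and negatives negates the matrix). α → 0 recovers
  raw frequency ratios wherever they are defined; with α = 0 a zero
  denominator raises rather than propagating infinities.
- **Symbol and block order.** k-mers are ordered lexicographically with
  A < C < G < U everywhere; feature blocks are concatenated mPWM, dPWM,
  compositions, protein. The layout travels with each trained model and
  prediction rejects differently laid-out vectors.
- **Off-window sequences.** Longer sequences are scanned ungapped against
  the mPWM and contribute their maximum-scoring window to both profile
  blocks; compositions always cover the full sequence. Shorter sequences
  are placed at the maximum-scoring offset against the matrix columns,
  restricted to full containment (no overhang past the matrix ends); a
  mono column with no covering nucleotide is zero-filled, and a di column
  is zero-filled if either of its two positions is uncovered. Offset ties
  break to the smallest offset, making encoding deterministic.
- **Composition denominator.** k-mer frequencies are normalized by the
  window count |seq| − k + 1, so each sub-block sums to exactly 1.
- **CTD conventions.** Transitions count unordered pairs of *distinct*
  groups among adjacent residues, normalized by length − 1 (21 = C(7,2)
  features; same-group adjacencies are not counted). Distribution uses
  occurrence ranks: for a group with c occurrences, the residue positions
  of occurrence 1 and ⌈q·c⌉ for q ∈ {0.25, 0.5, 0.75, 1.0}, normalized by
  sequence length; absent groups contribute five zeros. These are the
  standard CTD definitions; the 100% point is the group's last occurrence.
- **Scaling.** Per-feature min/max scaling to [−1, 1] is learned from
  training data only and stored with the model; it can be disabled
  (`--no-scale`) for sensitivity checks. Constant features map to 0.
- **Leakage control.** Both cross-validation protocols rebuild the
  profiles inside every fold/run from that run's training portion only.
  Reusing matrices built on the full data would leak held-out positional
  information and inflate every metric.
- **LOPO pooling.** Because RBP groups differ in size by orders of
  magnitude, the LOPO summary is computed from the summed TP/TN/FP/FN of
  all runs (a weighted average), never by averaging per-group metrics.
  Groups holding a single class are evaluated but flagged. Negatives carry
  the RBP tag of the group they were generated for; untagged negatives
  must be assigned before LOPO (the synthetic generator tags round-robin).
- **Zero denominators.** A metric whose denominator is zero is reported
  as 0 by convention, keeping batch evaluations alive on degenerate
  groups; all-zero confusion counts raise.
- **Redundancy removal.** Greedy clustering in input order: a sequence is
  dropped when its global-alignment identity (matches / alignment length;
  match +1, mismatch 0, gaps free including end gaps) to any retained
  representative — or to a reference set in two-set mode — reaches the
  threshold. An infinitesimal internal-gap penalty breaks ties between
  equally matching alignments toward the least-gapped one, so the identity
  denominator is well defined. This is a deliberate stand-in for external
  clustering tools (CD-HIT-EST-style) with the same filtering semantics
  but none of their word-filter heuristics; it is O(n²) in the set size
  and intended for datasets of at most a few thousand sequences.
- **Ratio datasets.** Negatives for the 1:r datasets are nested (the 1:1
  negatives are a prefix of the 1:2 negatives, and so on), so comparisons
  across ratios differ only by added negatives. Independent per-ratio
  draws would also be defensible; nesting is cleaner for ablations.
- **10-fold metrics.** Pooled over folds (counts summed, then ratios).
  Per-fold counts are returned so a fold-averaged summary can be computed
  when preferred.

## Synthetic data generator

`MotifModel.planted()` emulates a pool of CLIP-derived binding regions: a
9-nt consensus core (ACGUACGUA) planted at positions 9–17 of a 25-nt
window, consensus base probability 0.85 per core column, all other columns
and all negative sequences i.i.d. uniform. The consensus uses all four
bases nearly equally, so the planted signal is *positional*: profile
features see it at full strength while composition features see it only
through di-/tri-nucleotide enrichment, reproducing the qualitative
ordering in which composition-only models trail profile-based ones.
Records are tagged round-robin with synthetic RBP names so LOPO is
exercisable. The generator draws each position independently — it has no
dependence between neighbouring positions beyond the planted consensus, no
sequence-composition bias, no near-duplicate reads, no mislabeled
negatives and no RBP-specific motif differences. Passing tests on this
fixture therefore demonstrates correctness of the machinery and
recoverability of positional signal at realistic sample sizes, not the
absolute accuracy attainable on real CLIP data, where label noise,
shared-motif families and compositional confounders all reduce
performance.

Problem sizes used in the shipped checks: profile recovery uses 5,000
sequences per class; pipeline-level cross-validation uses 2,000 per class
with 10 folds; unit tests use a few hundred. These sizes put sampling noise
well below the margins being asserted while keeping the whole suite quick
to run.

## Known limitations

- No RNA secondary-structure or physicochemical nucleotide features; the
  model is sequence-only.
- Profiles are ungapped; insertions/deletions relative to the window are
  handled only through the best-offset alignment.
- No probability calibration: decision values are margins, not
  probabilities.
- The greedy identity filter is quadratic and approximate relative to
  heuristic clustering tools on large sets.
- Class imbalance is handled by dataset construction (the 1:r datasets),
  not by reweighting in the SVM objective.
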