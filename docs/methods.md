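# Methods

## Problem and model

Protein kinases recognise short linear motifs around the serine,
threonine or tyrosine they phosphorylate.  Given proteins with
experimentally verified phosphosites, `phosmdd` learns those motifs and
predicts new sites in three steps:

1. **Window extraction.** Every S/T/Y residue of one class yields a
   21-mer window (half-width `w = 10`, flank coordinates −10…+10 with
   the site at 0).  Annotated residues are positives, the rest
   negatives.  Windows overhanging a terminus are padded with `X`;
   pads never enter any count.  Duplicate window strings are removed,
   with positives winning over negatives, so the two sets are disjoint.

2. **Maximal dependence decomposition (MDD).** The 20 amino acids are
   collapsed to five property groups — neutral
   {G,A,V,L,I,M,C,S,T,N,Q}, acid {D,E}, basic {K,R,H}, aromatic
   {F,W,Y}, imino {P} (configurable).  For each pair of flank positions
   a 5×5 contingency table of group co-occurrence is tested with
   Pearson's chi-square; with five groups per margin the statistic has
   (5−1)² = 16 degrees of freedom, and the default cutoff 34.3 is the
   upper 0.005 quantile of χ²₁₆.  Each node of the decomposition tree
   splits on the position whose above-cutoff chi-square values sum
   highest, partitioning fragments by presence/absence of the group
   whose table rows carry the most chi-square mass at that position
   (the group that actually drives the dependence — the modal group
   would almost always be "neutral", which covers 11 of 20 residues).
   Recursion stops when a subgroup falls below the minimum cluster
   size (defaults 200/100/30 for S/T/Y) or no dependence remains.
   Leaves are the substrate-motif subgroups.

3. **Profile scoring.** One ungapped positional model per subgroup:
   emission(p, a) = (count + κ)/(n + 20κ) with Laplace pseudocount
   κ = 1 by default.  Because the training windows are gap-free and
   fixed-length, a full match/insert/delete profile architecture
   degenerates to this positional form, and the score of a query
   window is the base-2 log-odds sum Σₚ log₂(eₚ(aₚ)/b(aₚ)) in bits.
   The background b defaults to residue frequencies pooled over the
   flank columns of all training fragments (the centre column is
   excluded — it is fixed to the class and would bias the null);
   a uniform 1/20 background can be passed instead.

A query residue is called a phosphosite when **at least one** model
scores its window above that model's threshold; the best-scoring firing
model names the matched motif (score ties break by cluster id).  Adding
a model can therefore only add predictions, never remove them.

## Threshold calibration and evaluation

Each model's integer bit-score threshold is chosen on the grid
−20…0 during five-fold cross-validation: folds are built per subgroup;
within a fold the profile trains on the other folds' positives, every
candidate t is scored on the training positives against an equal-size
seeded sample of the balanced negatives, and the t maximising accuracy
wins (ties: most balanced Sn/Sp, then the larger t, favouring
specificity).  Sensitivity is non-increasing and specificity
non-decreasing in t by construction; the implementation asserts this on
every grid search.  Held-out metrics use the standard definitions
Pre = TP/(TP+FP), Sn = TP/(TP+FN), Sp = TN/(TN+FP),
Acc = (TP+TN)/total, with zero-denominator metrics reported as missing
rather than zero and excluded from means.  The reported per-cluster
threshold is the modal fold choice (ties to the larger value); the
"Average" row is the macro-average over clusters.

Negative sets are balanced to the positive count by k-medoids on
Hamming distance (pads match pads, mismatch letters): k-means++-style
seeding, assignment to the nearest medoid, medoid update to the member
minimising total within-cluster distance, empty clusters reseeded with
the farthest point, at most 100 iterations.  Medoids keep the
representatives as real sequences.  The independent test repeats this
balancing 10 times with incremented seeds, classifies every test
fragment with the ensemble rule, and reports mean ± sd across repeats.

## Synthetic data

The generator emulates subgroup structure: positives are drawn from a
mixture of motif specifications over a uniform (or user-supplied)
residue background; each motif plants a residue or a uniform draw from
a property group at chosen flank positions with a stated probability,
and two positions may be coupled so one Bernoulli draw plants both or
neither.  Negatives are pure background.  The recorded truth label is
the *realised* plant — a fragment whose draws all missed is labelled
background, since nothing in its sequence distinguishes it.  Truth
labels live outside the fragment objects and are used only by tests.

What the generator does **not** emulate: realistic amino-acid
composition (unless supplied), correlations beyond the planted ones,
protein-level context (disorder, accessibility), and the long-tailed
subgroup size distribution of real kinase families.  Passing tests
therefore demonstrate correctness of the machinery and recoverability
of planted structure, not field performance on real proteomes.

## Numerical and design choices

- Chi-square on sparse tables: cells whose expected count is zero
  (empty row or column margin) contribute nothing; an empty table
  scores 0 with a warning.
- Split-position ties break towards the centre, negative flank first;
  split-group ties follow the fixed order neutral < acid < basic <
  aromatic < imino.
- A node splits only if both children are non-empty, so recursion
  terminates unconditionally.
- At the 0.005 level with 190 position pairs per node, roughly one
  spurious significant pair per node is expected under the null; the
  minimum-cluster-size floor is what keeps chance-level splits from
  fragmenting subgroups indefinitely.  Consequently leaf counts are
  upper bounds on motif counts, and near-duplicate leaves can be
  re-joined with `merge_similar` (single-linkage on the mean flank-wise
  Jensen–Shannon divergence between group-frequency profiles, centre
  position excluded; off by default so the raw tree is canonical).
- Motif information content at a position is log₂20 − H of the residue
  distribution, pads excluded; an all-pad position reports 0 bits with
  a flag.

## Problem sizes used by the built-in checks

The bundled verification runs use simulated datasets of 500–1000
positive fragments (1000 for planted-coupling recovery over 100 seeds,
500 per replicate for null calibration over 20 seeds, 600 + 600 for the
end-to-end cross-validation with three planted motifs of three
positions at 0.9 consensus probability, 150 + 450 for the repeated
balanced test), chosen to match the scale of the per-class training
sets the method is designed for while keeping the whole suite runnable
in minutes on one CPU.

## Known limitations

- The background model is 0th-order; compositional bias shared by
  positives and negatives cancels only through the balanced negative
  sampling.
- Thresholds are integers by design (grid −20…0); data whose optimal
  operating point lies outside that range will saturate at a grid edge.
- `merge_similar` is a heuristic stand-in for expert curation of
  near-identical subgroup logos; the default leaves it off.
- k-medoids balancing is O(n·K) per iteration in distance evaluations;
  pools of ~10⁵ negatives with K ~ 10³ are feasible but slow in pure
  numpy.
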