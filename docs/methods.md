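# Methods

## Problem and model

Pupylation is the covalent attachment of Pup (prokaryotic ubiquitin-like
protein) to a substrate lysine by the ligase PafA, the signal for
proteasome-mediated degradation in actinobacteria. Predicting which lysines
of a proteome are pupylated is a binary classification problem over peptide
windows: a fixed-length fragment centred on each candidate K, labelled
positive when the centre is an annotated site.

The pipeline is a filter-wrapper hybrid. A filter (mRMR) orders the 646
window features by class relevance penalized by redundancy; a wrapper (IFS
under jackknife-evaluated 1-NN) picks the prefix length; a margin classifier
(RBF-SVM) is trained on the chosen subset. The design follows the standard
architecture of window-based PTM predictors and keeps every stage
deterministic given a seed.

## Dataset construction

Proteins shorter than 50 residues or containing non-standard letters
(B, J, O, U, X, Z) are removed; the remainder is redundancy-reduced at 40 %
pairwise identity. The reducer is a transparent greedy clusterer: candidates
are visited longest-first (ties by id), and a sequence is kept iff its
identity to every kept sequence is < 0.40, with identity defined as exact
matches over alignment columns under a global, end-gap-free alignment
(match 1, mismatch 0, gap open −5, extend −1; Biopython `PairwiseAligner`).
This replaces an external clustering binary with a documented, testable
definition; a precomputed representative list can be supplied instead
(`keep_ids` / `--keep-ids`) for users who prefer an external tool's
clustering. Windows use flank 10 (21 residues); out-of-range positions are
`-`. Negative windows (non-annotated K) are subsampled uniformly without
replacement to 3× the positives, once over the whole dataset, after
redundancy reduction. Negatives are drawn from the same proteins as the
positives by default — the natural choice when only modified proteins carry
trustworthy "unmodified" lysines.

## Encoding

Feature addresses are site-major, sites 1–21 with the centre at 11; within a
site the order is AAF (5), PSSM (20, alphabet `ARNDCQEGHILKMFPSTWYV`),
disorder (1), SS one-hot (C, H, E), SA one-hot (buried, exposed). The centre
omits AAF (always lysine), giving 26 there and 31 elsewhere: 646 total.
Choices worth stating:

* **Atchley factors** are the published five-factor solution scores,
  transcribed as a package constant in factor order I–V. The table is
  centred (each factor mean ≈ 0 over the 20 residues), which the test suite
  uses as a transcription check alongside frozen spot values.
* **PSSM values are raw log-odds** (the profile tool's native first 20
  columns). No sigmoid rescaling is applied by default because none is part
  of the method definition; the percentage columns are ignored.
* **Padding encodes as zeros in every family**, including the one-hots, so
  the per-site SS/SA sums are 1 for real residues and 0 for pads. Zero is
  the neutral value for distance- and margin-based downstream learners.
* **No feature standardization** before mRMR/NNA; the SVM stage can
  standardize (`standardize=True`), storing the scaler inside the model.
  Off by default: the dominant PSSM block is already on a common scale.

## Feature ranking

Features are discretized per column at μ ± σ into three states (below /
within / above; constant columns collapse to the middle state). This is the
conventional preprocessing for mRMR on continuous features; the number of
states and scheme sit behind `discretize` if a user wants to change them.
One caveat of the rule: a binary column with exactly balanced classes
(p = 0.5) has μ−σ = 0 and μ+σ = 1 and degenerates to a single state;
one-hot features in real window data are never exactly balanced.

Mutual information is the plug-in estimate in bits; the base only rescales
scores and never reorders. mRMR uses the difference (MID) form
`I(f; y) − mean_{s∈S} I(f; s)` by default, with the quotient (MIQ) form as
an option; ties break toward the lower feature index everywhere, making the
ranking a pure function of the data. The implementation vectorizes the
per-feature contingency tables as three indicator-matrix products, so a full
646-feature ranking on 800 samples takes ~1 s.

## IFS, jackknife and metrics

The 1-NN classifier uses squared Euclidean distance on the raw selected
features, ties toward the lowest training-row index. (A cosine-similarity
metric is available — `metric="cosine"` — since nearest-neighbour variants
in this literature sometimes use normalized dot products.) The jackknife
unit is the peptide window; a protein-grouped jackknife
(`jackknife_evaluate(..., groups=protein_ids)`) is provided for the stricter
reading where a held-out protein's windows must all leave the training set,
because window overlap within a protein otherwise leaks neighbours.

The IFS sweep maintains the pairwise squared-distance matrix incrementally
(one rank-ordered feature added per step), reading each prefix's
leave-one-out neighbours off the matrix: O(n²) per step, ~2 s for the full
646-step curve at n = 800. Confusion counts agree exactly with an explicit
per-prefix jackknife (asserted in tests); accumulated floating-point noise
is far below inter-sample distance gaps, and exact duplicates tie
identically under both summation orders.

Metrics: Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/N, MCC with the
zero-denominator → 0 convention; an undefined rate (absent class) is
reported as missing rather than 0. AUC uses the midrank (Mann–Whitney)
construction; ROC point export goes through scikit-learn's `roc_curve`.
The optimum k\* is the smallest prefix attaining maximal MCC.

## SVM stage

RBF-kernel SVM (scikit-learn's libsvm wrapper). C and γ are chosen from
2⁻⁷…2⁸ (16 × 16 = 256 pairs) by mean accuracy under seeded stratified
5-fold CV; ties prefer smaller C, then smaller γ (the least-complex model
among equals). Accuracy is the selection criterion by default; class weights
are unweighted despite the 3:1 imbalance (a `class_weight`-style balanced
option was deliberately left out of scope of the fit surface — users can
standardize or re-balance upstream). Honest SVM performance is reported by
leave-one-out refits at the chosen (C, γ) (`jackknife_svm`), whose decision
scores also feed the ROC/AUC. Models persist with a SHA-256 integrity digest
and the descriptor-table checksum, so a model cannot silently be applied
under a different feature layout.

## Synthetic benchmark

The generator emulates a proteome where pupylation has a local sequence and
annotation signature. Defaults, fixed once as the package's study
conditions: 100 proteins of 100–180 residues with i.i.d. uniform background
composition; 2 planted interior K sites per protein (200 positives; ~700
background lysines, so 3:1 sampling yields 600 negatives); enriched residue
'E' at window sites 7 and 10 with forced-replacement probability 0.6 (final
'E' frequency ≈ 0.62 vs ≈ 0.05 background); pseudo-PSSM rows N(0, 2)
rounded to integers with a +4 log-odds shift on the enriched columns and on
the centre's K column (a conserved target lysine); disorder Beta(2, 2) with
+0.3 at site 10 (clipped); centre secondary structure redrawn with coil
probability 0.8 (background 0.45) and accessibility with exposed
probability 0.85 (background 0.5). A single `annotation_coupling` knob in
[0, 1] scales every annotation shift, with probability couplings
interpolated exactly so that coupling 0 reproduces the background marginal —
the null construction (`null_motif()`) additionally drops the sequence
enrichment, making planted and background lysines exchangeable.

What the generator does *not* emulate: realistic profile-search PSSMs
(columns here are independent noise plus shifts), amino-acid background
frequencies of real proteomes (a frequency table can be supplied),
inter-site dependence beyond the planted motif, and homology between
proteins. Passing recovery tests therefore demonstrates that the pipeline
finds localized, multi-family signal of the planted strength — not that it
attains any particular accuracy on real proteomes, which depends on the
external annotation tools and data unavailable to an offline test.

A property worth knowing when interpreting null runs: windows overlap within
a protein, so in the absence of signal a window's nearest neighbour is
typically an overlapping window, which is almost always a negative. Full
null jackknives therefore tend to predict everything negative, and MCC is 0
by the zero-factor convention rather than by cancellation.

## Problem sizes used in checks

The shipped verification runs use the default benchmark (800 windows, full
646-feature mRMR ranking and IFS sweep, 256-pair grid search, leave-one-out
SVM), 10 null datasets of the same size, 100-trial brute-force equivalence
suites at ≤ 50 samples × ≤ 30 features, and a 30-protein end-to-end
determinism replay — sizes chosen so the whole suite completes in a few
minutes on one CPU while exercising every stage at its real dimensionality.

## Known limitations

* The greedy identity clusterer is O(n²) alignments; for thousands of
  proteins an external clustering plus `keep_ids` is the practical route.
* Plug-in MI is biased upward at small n (≈ (df)/(2N ln 2) bits); rankings
  are unaffected for comparable-df features, but the MaxRel score magnitudes
  at small sample sizes should not be read as effect sizes.
* `jackknife_svm` refits n models; at n ≫ 10³ use the CV metrics instead.
* Window-level jackknife shares overlapping windows between train and test;
  the grouped option is the conservative alternative and gives lower, more
  honest numbers on real data.
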