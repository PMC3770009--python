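# pupsite

Sequence-based prediction of protein **pupylation sites** — the lysines to
which prokaryotic ubiquitin-like protein (Pup) is attached by the PafA ligase,
marking bacterial proteins (notably in *Mycobacterium tuberculosis*) for
proteasomal degradation. The package is for computational biologists who want
a transparent, fully testable re-implementation of the classic
window-encoding / mRMR / IFS / SVM pipeline for lysine-modification
prediction, including the feature-attribution analyses that ask *which*
feature families at *which* window positions carry the signal.

## The method

Every lysine of a protein is represented by a 21-residue peptide window
(10 residues up- and downstream, `-`-padded at sequence ends). Each window
site contributes five feature families:

| family | features/site | content |
|--------|---------------|---------|
| AAF    | 5 | Atchley amino-acid factors (polarity, secondary-structure propensity, molecular volume, codon diversity, electrostatic charge) |
| PSSM   | 20 | per-residue conservation log-odds from an iterated profile search |
| DIS    | 1 | structural-disorder score |
| SS     | 3 | one-hot coil/helix/strand |
| SA     | 2 | one-hot buried/exposed |

The centre is always K and omits the AAF block, so a window encodes to
20 × 31 + 26 = **646 features**. The pipeline then:

1. ranks features by **mRMR** (maximum relevance I(f; y), minimum mean
   redundancy I(f; f′), on μ±σ three-state discretized features, MI in bits);
2. runs **incremental feature selection (IFS)**: for every prefix of the
   ranked list, a 1-nearest-neighbour classifier is scored by jackknife
   (leave-one-out) cross-validation — Sn, Sp, Ac and MCC — and the smallest
   prefix maximizing MCC becomes the optimal feature set;
3. trains an **RBF-kernel SVM** on that subset, with C and γ selected from
   the 2⁻⁷…2⁸ power grid (16 × 16 = 256 pairs) by stratified 5-fold CV;
4. tabulates the optimal set by family, site and subtype (**attribution**).

Because the annotation tracks normally come from external predictors
(PSI-BLAST, VSL2, PSIPRED, SSPro), the package parses their standard output
formats and ships a synthetic-proteome generator that plants a pupylation
motif (enriched residues and coupled annotation shifts around the target K)
with known ground truth, so the whole pipeline is testable offline.

## Worked example

```python
from pupsite import synthetic_data as sd
from pupsite.model import PupylationSiteModel

dataset = sd.generate(n_proteins=40, seed=7)          # plants motifs at sites 7, 10, 11
model = PupylationSiteModel.from_synthetic(dataset, seed=7)
results = model.fit(seed=7, max_features=150)
print(results.summary())
```

```
Pupylation-site prediction results
==================================================================
windows: 320 (80 positive, 240 negative)   features: 646   ranking: mRMR-MID
optimal feature set: k* = 13   (families: AAF=5, PSSM=5, DIS=1, SS=1, SA=1)
------------------------------------------------------------------
NNA jackknife @ k*:  Sn=0.925  Sp=0.975  Ac=0.963  MCC=0.900  AUC=0.990
SVM (RBF): C=2^-1, gamma=2^-7, 256 grid pairs, seed=7
SVM jackknife @ k*:  Sn=0.950  Sp=0.983  Ac=0.975  MCC=0.933  AUC=0.995
==================================================================
```

The IFS curve peaks at 13 features; the jackknife-NNA classifier on those
features reaches MCC 0.900 and the grid-searched SVM improves it to 0.933.
The top-ranked features point straight at the planted signal:

```python
print(results.top_features(5).to_string(index=False))
```

```
 rank  feature_index  site family             subtype    score
    1            322    11   PSSM                   K 0.331116
    2            198     7   PSSM                   E 0.148289
    3            291    10   PSSM                   E 0.114831
    4            188     7    AAF secondary-structure 0.109854
    5            281    10    AAF secondary-structure 0.078828
```

Rank 1 is the conservation of the central lysine itself (site 11, PSSM
target K); ranks 2–5 are conservation toward and physicochemistry of the
enriched glutamates at sites 7 and 10 — exactly where the generator planted
the motif. `sd.recovery_report(dataset, results.ranked, k=20)` quantifies
this: 60 % of the top-20 features sit at the planted sites here (the
informative-site share of all 646 features is only ~14 %).

A `pupsite` console script exposes each stage
(`simulate`, `dataset`, `encode`, `rank`, `ifs`, `train`, `predict`,
`attribute`, `run`); `pupsite run --help` shows the one-shot pipeline.

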