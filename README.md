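# rbpbind

Sequence-based prediction of protein-binding regions in mRNA.

RNA-binding proteins (RBPs) regulate splicing, export, stability and
translation of mRNAs by binding short regions of the transcript. CLIP-seq
assays localize these binding regions experimentally, but they are
protein-by-protein and condition-specific. `rbpbind` trains a classifier on
CLIP-derived binding regions (positives) versus non-binding genomic
background (negatives) and predicts, for an arbitrary RNA sequence, whether
it contains a protein-binding region. It is aimed at computational
biologists who have labeled binding-site sequences (their own CLIP data or
curated databases) and want a reproducible train/evaluate/predict pipeline.

## Model

Each RNA sequence of length *n* (25 nt by default) is encoded as a
2*n* + 83-element feature vector:

- **mPWM** (*n* elements): per-position mono-nucleotide log-odds terms.
  From the positive and negative training sets, per-position nucleotide
  frequencies f⁺(i, j) and f⁻(i, j) are estimated (with additive pseudocount
  α) and combined into a position weight matrix

  mPWM(i, j) = ln( f⁺(i, j) / f⁻(i, j) ),  i ∈ {A, C, G, U}, j = 1…n.

  Element *j* of the block is the score of the sequence's nucleotide at
  position *j*.
- **dPWM** (*n* − 1 elements): the same construction over overlapping
  di-nucleotides, dPWM(di, j) = ln( f⁺(di, j) / f⁻(di, j) ), capturing
  first-order neighbour structure.
- **Compositions** (84 elements): normalized mono- (4), di- (16) and
  tri-nucleotide (64) frequencies over the whole sequence.
- **Protein CTD** (optional, 63 elements): the
  composition/transition/distribution descriptor of the binding protein
  over 7 physicochemical amino-acid groups (7 + 21 + 35 elements), for
  models that condition on the RBP.

For the default 25-nt window this gives 133 features (196 with the protein
block). Sequences longer than the window contribute the profile terms of
their maximum-scoring 25-mer (ungapped scan against the mPWM) and
compositions of the full sequence; shorter sequences are aligned to the
matrix at the maximum-scoring offset with uncovered columns zero-filled.

The feature vectors, scaled per feature to [−1, 1], train a soft-margin SVM
with Gaussian RBF kernel exp(−γ‖x − y‖²), with C = 32 and γ = 2⁻⁷ =
0.0078125 by default (a LIBSVM-style power-of-two grid search is included).
Performance is summarized by sensitivity, specificity, accuracy, PPV, NPV
and the Matthews correlation coefficient, under stratified 10-fold
cross-validation and leave-one-protein-out (LOPO) cross-validation, where
all sequences tied to one RBP are held out per run and the summary is
computed from pooled TP/TN/FP/FN.

## Worked example

Generate a motif-planted synthetic dataset with known ground truth, fit the
model, and cross-validate:

```python
from rbpbind import MotifModel, RnaBindingModel, synth_generate

data = synth_generate(MotifModel.planted(), n_pos=500, n_neg=500,
                      n_groups=4, seed=7)
result = RnaBindingModel(data).fit()
print(result.summary())
```

```
RNA-binding region prediction model
===================================================
Window (nt)                                      25
Training positives                              500
Training negatives                              500
Feature blocks                mPWM+dPWM+composition
Features                                        133
Pseudocount alpha                                 1
Kernel                                          rbf
C                                                32
gamma                                     0.0078125
Feature scaling                                True
---------------------------------------------------
Training accuracy                           100.00%
Training MCC                                  1.000
===================================================
```

```python
cv = result.cross_validate(k=10, seed=7)
lopo = result.leave_one_protein_out()
```

prints (via the fields of `cv.pooled` and `lopo.weighted_average`):

```
10-fold CV: sensitivity=97.00% specificity=96.80% accuracy=96.90% MCC=0.938 AUC=0.9966
LOPO CV (4 groups): accuracy=97.30% MCC=0.946
```

The 500 positives carry a 9-nt motif (consensus base probability 0.85)
planted in a uniform 25-nt background; the cross-validated accuracy near
97% reflects how well the position-specific log-odds features recover that
planted signal, and the LOPO figures show the signal generalizes across the
synthetic RBP groups. `result.predict(records)` returns per-sequence calls
with SVM decision values for sequences of any length.

The same pipeline is scriptable from the shell:

```sh
rbpbind simulate --n-pos 500 --n-neg 500 --seed 7 --out-prefix sim
rbpbind build-pwm --positive sim.pos.fasta --negative sim.neg.fasta --out-prefix pwm
rbpbind train --positive sim.pos.fasta --negative sim.neg.fasta --out-prefix fit
rbpbind cv --positive sim.pos.fasta --negative sim.neg.fasta --out cv.tsv
rbpbind lopo --positive sim.pos.fasta --negative sim.neg.fasta \
        --groups sim.groups.tsv --out lopo.tsv
```

Every command writes a `.manifest` JSON capturing parameters and seeds, so
identical manifests reproduce identical reports.

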