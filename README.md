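# p300speller

Decoding toolkit for the row/column (RC) P300 speller, the classic EEG
brain–computer interface in which a user spells by attending to one symbol
of a 6×6 grid while its rows and columns flash in random order.  The flash
covering the attended symbol is a rare, attended event and evokes a P300 —
a positive EEG deflection peaking ≈300 ms after the stimulus.  Spelling one
symbol therefore reduces to finding the one row and one column whose
flashes elicited P300s.

The package is aimed at BCI researchers and students who want a compact,
fully tested reference implementation of classical (non-deep-learning)
speller decoding, including ensemble fusion, that runs end to end on
synthetic data with no external downloads.

## The model

Let the grid have *n* rows and *m* columns; column *j* carries stimulus
code *j* and row *i* carries code *m+i*.  One *sequence* S flashes each of
the *n+m* codes once in random order; a *selection* σ is the α sequences
(α = 15 here) used to spell one symbol.  Each flash yields a post-stimulus
epoch ξ(I) of 64 channels × 667 ms at 240 Hz.

Epochs are bandpass filtered (order-8 Butterworth IIR, 0.1–10 Hz),
decimated by r = ⌊fs / 2f_high⌋ = 12 to 14 samples per channel, and
flattened to 896 = 14 × 64 features.  A binary classifier trained on
target/non-target epochs supplies ρ(ξ(I)) ∈ [0, 1], the probability that an
epoch contains a P300.  Scoring a sequence gives the code-indexed vector
τ(ξ(S)) = ⟨ρ(code 1), …, ρ(code n+m)⟩, and averaging over sequences gives
the selection score Ψ(ξ(σ)) with entries v_j = (1/α) Σ_i ρ(ξ(I_j in S_i)).
The decoded symbol sits at (argmax of the row scores, argmax of the column
scores).

Five strategies are implemented on this skeleton:

| variant | learners | training data per learner | fusion |
|---|---|---|---|
| `single` | 1 | whole set | — |
| `hetero_unweighted` | N distinct algorithms | whole set | mean of Ψ_i |
| `hetero_weighted` | N distinct algorithms | whole set | (1/N) Σ w_i Ψ_i, w_i = CV accuracy |
| `homo_horizontal` | α copies of one algorithm | all i-th sequences (β(n+m) epochs) | learner i scores sequence i; mean of τ_i |
| `homo_vertical` | N copies of one algorithm | block of β/N selections (β/N·α(n+m) epochs) | mean of Ψ_i |

Base learners: LDA, linear SVM (Platt-calibrated), PLS regression (clipped),
and logistic regression, all via scikit-learn.

A synthetic generator emulates the paradigm exactly (random flash
permutations, two target flashes per sequence, Gaussian P300 template on a
parietal channel block, additive white or AR(1) noise), so the entire stack
is testable offline.  An optional reader ingests the standard
competition-format MATLAB recordings (`Signal`, `StimulusCode`,
`StimulusType`, `TargetChar`) if you have them locally.

## Worked example

```python
from p300speller import (ClassifierSpec, SimulationConfig, SymbolMatrix,
                         evaluate, generate_dataset, train_strategy)

train = generate_dataset(SimulationConfig(beta=10, seed=1))
test  = generate_dataset(SimulationConfig(beta=6,  seed=2))
strategy = train_strategy(train, "single", ClassifierSpec("lda", seed=0))
report = evaluate(strategy, test, SymbolMatrix(), curve=False)
print(report.symbol_accuracy, report.binary_accuracy)
```

prints `1.0 1.0`: all 6 spelled symbols decoded correctly, and every one of
the 1080 test epochs classified to its correct target/non-target label at
the generator's default SNR (5 µV evoked peak vs 1 µV noise).  Comparing
all five strategies (`python examples/04_ensemble_strategies.py`):

```
single             learners= 1 accuracy=1.00
hetero_unweighted  learners= 2 accuracy=1.00
hetero_weighted    learners= 2 accuracy=1.00  weights=[1.0, 1.0]
homo_horizontal    learners=15 accuracy=1.00
homo_vertical      learners= 5 accuracy=1.00
```

The `learners` column shows each strategy's ensemble size (15 for
horizontal partitioning = one per sequence rank); `weights` are the
cross-validated voting weights of the weighted heterogeneous ensemble.
The other scripts in `examples/` walk through dataset simulation,
preprocessing, and the accuracy-vs-sequences curve at low SNR.

A thin CLI wraps the same pipeline:

```sh
p300speller simulate --beta 5 --seed 1 --out data/
p300speller train --data data/ --strategy homo-horizontal --classifier lda --out model.joblib
p300speller evaluate --model model.joblib --data data/
```

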