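"""Accuracy as a function of how many sequences are decoded.

Averaging over more flash repetitions suppresses noise, so symbol accuracy
climbs with the number of sequences used.  A deliberately poor SNR (0.6 uV
evoked peak against 4 uV noise) makes the curve visible.
"""

from p300speller import (
    ClassifierSpec,
    SimulationConfig,
    SymbolMatrix,
    evaluate,
    generate_dataset,
    train_strategy,
)

hard = dict(p300_amplitude=0.6, noise_sd=4.0)
train = generate_dataset(SimulationConfig(beta=15, seed=5, **hard))
test = generate_dataset(SimulationConfig(beta=10, seed=6, **hard))

strategy = train_strategy(train, "single", ClassifierSpec("lda", seed=0))
report = evaluate(strategy, test, SymbolMatrix(), curve=True)

for k, acc in enumerate(report.accuracy_by_sequences, start=1):
    bar = "#" * int(20 * acc)
    print(f"k={k:2d} sequences: {acc:.2f} {bar}")
# The k-th row is the symbol accuracy when only the first k of the 15
# sequences are averaged; expect low accuracy at k=1 rising toward 1.0.
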