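"""Generate a small synthetic RC-speller dataset and inspect its structure.

Each selection spells one symbol: 15 sequences, each flashing the 6 rows and
6 columns once in random order, so 180 post-stimulus epochs per selection.
"""

from p300speller import SimulationConfig, SymbolMatrix, generate_dataset, validate

cfg = SimulationConfig(beta=3, seed=42)
ds = generate_dataset(cfg)
mat = SymbolMatrix()

print(f"selections (beta): {ds.beta}")
print(f"sequences per selection (alpha): {ds.paradigm.alpha}")
print(f"epochs per sequence (n+m): {ds.paradigm.codes_per_sequence}")
print(f"total epochs: {ds.n_epochs()}")
print(f"epoch shape (channels x samples): {ds.epochs()[0].data.shape}")
print(f"spelled symbols: {[mat.symbol_at(*s.true_symbol) for s in ds.selections]}")
print(f"structural violations: {validate(ds)}")
# Expect 3 selections x 15 sequences x 12 epochs = 540 epochs of 64x160
# samples, spelling 3 random symbols, with no violations.
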