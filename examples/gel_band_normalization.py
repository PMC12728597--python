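"""Normalize gel band-intensity tables so species are comparable.

Band intensities from gel densitometry are in arbitrary units that differ
between species and stains; normalizing each species row to unit total
turns them into fractional elution distributions.
"""

import numpy as np

from gsecquant import GelBandTable, normalize_gel_bands

table = GelBandTable(
    species=("nanostructure", "staples"),
    fractions=np.arange(1, 10),
    intensities=np.array([
        [0.0, 1.2, 8.5, 4.1, 0.9, 0.1, 0.0, 0.0, 0.0],   # early-eluting target
        [0.0, 0.0, 0.3, 1.1, 3.0, 4.2, 3.1, 1.5, 0.6],   # late-eluting staples
    ]),
)

normalized = normalize_gel_bands(table)  # each row sums to 1
print(normalized.to_frame().round(3))
print("\nEach row now sums to 1, so the numbers read as the fraction of that")
print("species eluting in each collected fraction; the target's mass sits in")
print("fractions 3–4 while staples trail in 5–7.")
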