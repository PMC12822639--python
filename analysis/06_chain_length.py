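"""Aliphatic CH3/CH2 ratio and chain-length estimate for Prototaxites.

Emulates the synchrotron workflow: fresh Prototaxites spectra are
truncated to 1440-3000 cm^-1, baseline-corrected, smoothed and
vector-normalized, then the asymmetric CH3 (~2960 cm^-1) / CH2
(~2925 cm^-1) intensity ratio is converted to an equivalent unbranched
alkane chain length via n = 2k/R + 2 (k = 2.625, anchoring R = 0.75 at
nine carbons).  Lower ratios mean longer, less branched chains.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import fossilftir as ff
from fossilftir.synthgen import StudyDesign, default_profiles, generate_spectrum

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
N_SPOTS = 50
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

profile = default_profiles()["Prototaxites"]
grid = StudyDesign().grid()
spectra = [
    generate_spectrum(profile, grid, seed=[SEED + 60, i],
                      sample_id=f"spot_{i:03d}", taxon="Prototaxites")
    for i in range(N_SPOTS)
]
pre = ff.apply_recipe(ff.SpectralDataset(spectra), "synchrotron-baseline")

rows = []
for sp in pre.spectra:
    res = ff.ch3_ch2_ratio(sp, mode="height")
    rows.append({"sample_id": sp.sample_id, "ch2": res.ch2_value,
                 "ch3": res.ch3_value, "ratio": res.ratio,
                 "chain_length": res.chain_length_estimate})
table = pd.DataFrame(rows)
table.to_csv(OUT / "aliphatic_ratio.csv", index=False, float_format="%.10g")

mean_ratio = table["ratio"].mean()
print(f"{N_SPOTS} synthetic Prototaxites spots: "
      f"mean CH3/CH2 ratio {mean_ratio:.3f} (sd {table['ratio'].std():.3f})")
print(f"equivalent chain length {ff.estimate_chain_length(mean_ratio):.1f} "
      "carbons (about nine for ratios near 0.75)")
print(f"wrote {OUT / 'aliphatic_ratio.csv'}")
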