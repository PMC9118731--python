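#!/usr/bin/env python
"""Temperature response of the charged oscillator chain: per-repeat RMSF
at 37 vs 39 C and the effect of the repeat-4 charge-removal mutation.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ankylotherm.anksim import ensemble_rmsf, mutate_charge, notch_preset

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

STEPS = 100_000
SEEDS = list(range(10))

chain = notch_preset()
mutant = mutate_charge(chain, 4, -0.3)

rows = []
for label, ch, temp in [
    ("wild_type", chain, 310.15),
    ("wild_type", chain, 312.15),
    ("repeat4_discharged", mutant, 312.15),
]:
    rmsf = ensemble_rmsf(ch, temp, STEPS, seeds=SEEDS)
    rows.append({"variant": label, "temperature_K": temp,
                 **{f"repeat_{i+1}": round(v, 5) for i, v in enumerate(rmsf)}})
df = pd.DataFrame(rows)
df.to_csv(OUT / "06_rmsf.tsv", sep="\t", index=False)

wt310, wt312, mut312 = (df.iloc[i][[f"repeat_{j+1}" for j in range(7)]]
                        .to_numpy(float) for i in range(3))
print(df.to_string(index=False))
print(f"repeat-4 RMSF rises {100 * (wt312[3] / wt310[3] - 1):.2f}% from "
      f"310.15 to 312.15 K; discharging repeat 4 drops it "
      f"{100 * (1 - mut312[3] / wt312[3]):.1f}% at 312.15 K")
print(f"most mobile repeats at 312.15 K: "
      f"{list(np.argsort(wt312)[::-1][:4] + 1)} (charged: 3-6)")
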